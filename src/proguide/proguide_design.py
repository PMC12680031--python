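"""Assembly of proGuide constructs and sequential-activation cascades.

A proGuide is a Pol III guide-RNA expression unit whose scaffold carries an
*inactivation cassette*: a polyT Pol III terminator flanked by two copies of a
23-bp Cas9 target site (CTS). Transcription terminates inside the cassette, so
no functional guide RNA is made until Cas9 — directed by an upstream trigger
guide — cuts both CTS copies and NHEJ repair deletes the cassette, converting
the proGuide into an active "matureGuide".

Element orientations
--------------------
The two CTS copies can flank the cassette as direct repeats (DR1–DR4, both
copies in the same orientation, optionally decorated with extra repeat arms)
or as an inverted repeat with the PAMs facing outward (IR1). After a perfect
nested-deletion repair, a DR arrangement reconstitutes an intact, re-cuttable
CTS, whereas the PAM-out IR1 arrangement leaves only a 12-bp palindromic
inverted repeat (3-bp PAM + 3 PAM-proximal bases from each copy) that folds
into a 6-bp stem supporting the guide's tetraloop.

Cascades chain proGuides: the spacer transcribed from each step's matureGuide
is the protospacer of the next step's CTS; 14-nt payload spacers give
cleavage-free CRISPRa targeting at any step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .cts_library import DEFAULT_ENZYMES, CtsCandidate
from .seq_core import NucSeq, clean_seq, revcomp, t_runs

# Cas9 makes a blunt cut 3 bp on the 5' side of the PAM, i.e. between
# protospacer positions 17 and 18.
CUT_OFFSET_FROM_PAM = 3
SITE_LEN = 23

ORIENTATIONS = ("DR1", "DR2", "DR3", "DR4", "IR1")

NUCLEASE_SPACER_LEN = 20   # standard cutting guides
CRISPRA_SPACER_LEN = 14    # short spacers: DNA binding without cleavage

DEFAULT_DUAL_LINKER = "GCACGAGCGA"


@dataclass(frozen=True)
class ScaffoldConfig:
    """Sequence constants for the expression unit.

    The scaffold halves define where the inactivation cassette is inserted;
    defaults split the standard S. pyogenes sgRNA scaffold inside the
    tetraloop. ``insertion_site='hairpin1'`` splits inside hairpin 1 instead.
    The promoter is a U6-class Pol III placeholder: the designer depends only
    on its boundary coordinate, never on its sequence.
    """

    promoter: str = "GAGGGCCTATTTCCCATGATTCCTTCATAT"
    scaffold5: str = "GTTTTAGAGCTAGA"
    scaffold3: str = "AATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
    terminator: str = "TTTTTTT"
    insertion_site: str = "tetraloop"
    # decoration repeat arms for the DR2-DR4 geometries (configurable; the
    # defaults mirror the 12-bp / 6-bp IR1 arm lengths)
    dr3_repeat: str = "GCAGTGGCACGC"
    dr4_repeat: str = "GCAGTG"
    dr2_repeat: str = "GCAGTGGCACGC"

    @classmethod
    def hairpin1(cls) -> "ScaffoldConfig":
        full = cls()
        scaffold = full.scaffold5 + "AA" + full.scaffold3[2:]
        # split inside the hairpin-1 loop instead of the tetraloop
        cut = scaffold.index("AAGGCTA") + 4
        return replace(full, scaffold5=scaffold[:cut], scaffold3=scaffold[cut:],
                       insertion_site="hairpin1")


@dataclass(frozen=True)
class InactivationCassette:
    """PolyT Pol III terminator cassette placed between the two CTS copies.

    ``single_polyT`` is one tract of 4–10 T's; ``dual_polyT`` is two tracts
    separated by a linker (default two 8T tracts), the configuration with the
    least transcriptional readthrough.
    """

    kind: str
    tract1_len: int
    tract2_len: int = 0
    linker: str = ""

    @property
    def rendered(self) -> str:
        if self.kind == "single_polyT":
            return "T" * self.tract1_len
        return "T" * self.tract1_len + self.linker + "T" * self.tract2_len

    def __len__(self) -> int:
        return len(self.rendered)


def build_cassette(
    kind: str = "dual_polyT",
    tract1_len: int = 8,
    tract2_len: int = 8,
    linker: str = DEFAULT_DUAL_LINKER,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> InactivationCassette:
    """Build and validate an inactivation cassette.

    Tract lengths must lie in the modeled range [4, 10]. A dual-cassette
    linker may not contain a run of >= 4 consecutive T on either strand
    (it would terminate prematurely or blur the tract boundaries) and may
    not create a configured enzyme recognition site.
    """
    if kind not in ("single_polyT", "dual_polyT"):
        raise ValueError(f"unknown cassette kind {kind!r}")
    if not 4 <= tract1_len <= 10:
        raise ValueError("tract1_len must be in [4, 10]")
    if kind == "single_polyT":
        return InactivationCassette(kind, tract1_len)
    if not 4 <= tract2_len <= 10:
        raise ValueError("tract2_len must be in [4, 10]")
    linker = clean_seq(linker)
    if not linker:
        raise ValueError("dual cassette requires a non-empty linker")
    for strand in (linker, revcomp(linker)):
        if t_runs(strand, 4):
            raise ValueError("linker may not contain a run of >= 4 T on either strand")
    cassette = InactivationCassette(kind, tract1_len, tract2_len, linker)
    both = cassette.rendered + "/" + revcomp(cassette.rendered)
    for e in enzymes:
        if clean_seq(e) in both:
            raise ValueError(f"linker creates enzyme site {e}")
    return cassette


# ---------------------------------------------------------------------------
# Element geometry per orientation


def _element_pair(cts: CtsCandidate, orientation: str,
                  cfg: ScaffoldConfig) -> tuple[str, int, str, int]:
    """Return (left_element, cut_offset_left, right_element, cut_offset_right).

    Cut offsets are positions of the blunt cut within each element, always
    3 bp on the protospacer side of that element's PAM.
    """
    site = cts.site
    fwd_cut = SITE_LEN - 3 - CUT_OFFSET_FROM_PAM          # 17: PAM at the right end
    rev_cut = 3 + CUT_OFFSET_FROM_PAM                     # 6: PAM at the left end
    if orientation == "IR1":
        # PAM-out: both cut sites internal to the cassette
        return revcomp(site), rev_cut, site, fwd_cut
    if orientation == "DR1":
        return site, fwd_cut, site, fwd_cut
    if orientation == "DR2":
        # repeats nested inside the excised interval
        r = cfg.dr2_repeat
        return site + r, fwd_cut, revcomp(r) + site, len(r) + fwd_cut
    if orientation in ("DR3", "DR4"):
        # repeats outside the CTS copies: perfect repair leaves an intact CTS
        # flanked by a stem (longer arm for DR3, shorter for DR4)
        r = cfg.dr3_repeat if orientation == "DR3" else cfg.dr4_repeat
        return r + site, len(r) + fwd_cut, site + revcomp(r), fwd_cut
    raise ValueError(f"unknown orientation {orientation!r}")


@dataclass(frozen=True)
class ProGuideConstruct:
    """A fully assembled proGuide DNA with annotated Cas9 cut sites.

    The construct concatenates, in order: promoter, spacer, scaffold5,
    left_element, cassette, right_element, scaffold3, downstream terminator.
    ``cut_left``/``cut_right`` are blunt-cut coordinates on the full
    construct (0-based, between-base positions).
    """

    name: str
    spacer: str
    cts: CtsCandidate
    orientation: str
    cassette: InactivationCassette
    promoter: str
    scaffold5: str
    scaffold3: str
    left_element: str
    right_element: str
    downstream_terminator: str
    cut_left: int
    cut_right: int

    @property
    def sequence(self) -> str:
        return (self.promoter + self.spacer + self.scaffold5 + self.left_element
                + self.cassette.rendered + self.right_element + self.scaffold3
                + self.downstream_terminator)

    @property
    def is_crispra(self) -> bool:
        return len(self.spacer) == CRISPRA_SPACER_LEN

    # --- coordinate helpers -------------------------------------------------

    @property
    def left_element_start(self) -> int:
        return len(self.promoter) + len(self.spacer) + len(self.scaffold5)

    @property
    def right_element_end(self) -> int:
        return (self.left_element_start + len(self.left_element)
                + len(self.cassette) + len(self.right_element))

    @property
    def tss(self) -> int:
        """Pol III transcription start (the promoter boundary)."""
        return len(self.promoter)

    @property
    def guide_end(self) -> int:
        """End of the scaffold 3' half — a transcript must reach here to be
        a functional guide RNA."""
        return len(self.sequence) - len(self.downstream_terminator)

    @property
    def amplicon(self) -> str:
        """The sequenced region: spacer through the end of the scaffold."""
        return self.sequence[self.tss : self.guide_end]

    @property
    def amplicon_cut_left(self) -> int:
        return self.cut_left - self.tss

    @property
    def amplicon_cut_right(self) -> int:
        return self.cut_right - self.tss

    # --- serialisation ------------------------------------------------------

    def annotations(self) -> dict:
        return {
            "name": self.name,
            "spacer": self.spacer,
            "protospacer": self.cts.protospacer,
            "pam": self.cts.pam,
            "cts_id": self.cts.id,
            "orientation": self.orientation,
            "cassette_kind": self.cassette.kind,
            "tract1_len": self.cassette.tract1_len,
            "tract2_len": self.cassette.tract2_len,
            "linker": self.cassette.linker,
            "promoter": self.promoter,
            "scaffold5": self.scaffold5,
            "scaffold3": self.scaffold3,
            "left_element": self.left_element,
            "right_element": self.right_element,
            "downstream_terminator": self.downstream_terminator,
            "cut_left": self.cut_left,
            "cut_right": self.cut_right,
        }

    def to_fasta_record(self) -> NucSeq:
        kv = " ".join(f"{k}={v}" for k, v in self.annotations().items() if k != "name")
        return NucSeq(self.sequence, f"{self.name} {kv}")

    @classmethod
    def from_annotations(cls, ann: dict) -> "ProGuideConstruct":
        cassette = InactivationCassette(
            ann["cassette_kind"], int(ann["tract1_len"]), int(ann["tract2_len"]),
            ann.get("linker", "") or "")
        cts = CtsCandidate(ann["protospacer"], ann["pam"], ann.get("cts_id", ""))
        return cls(
            name=ann["name"], spacer=ann["spacer"], cts=cts,
            orientation=ann["orientation"], cassette=cassette,
            promoter=ann["promoter"], scaffold5=ann["scaffold5"],
            scaffold3=ann["scaffold3"], left_element=ann["left_element"],
            right_element=ann["right_element"],
            downstream_terminator=ann["downstream_terminator"],
            cut_left=int(ann["cut_left"]), cut_right=int(ann["cut_right"]))

    @classmethod
    def from_fasta_record(cls, rec: NucSeq) -> "ProGuideConstruct":
        parts = rec.name.split()
        ann: dict = {"name": parts[0]}
        for kv in parts[1:]:
            k, _, v = kv.partition("=")
            ann[k] = v
        pg = cls.from_annotations(ann)
        if pg.sequence != rec.bases:
            raise ValueError("FASTA sequence does not match annotated fields")
        return pg


def build_proguide(
    spacer: str,
    cts: CtsCandidate,
    orientation: str = "IR1",
    cassette: Optional[InactivationCassette] = None,
    scaffold_config: Optional[ScaffoldConfig] = None,
    name: str = "proguide",
) -> ProGuideConstruct:
    """Assemble a proGuide construct.

    ``spacer`` must be 20 nt (nuclease step) or 14 nt (CRISPRa payload); a
    spacer equal to its own CTS protospacer would self-trigger and is
    rejected.
    """
    spacer = clean_seq(spacer)
    if len(spacer) not in (NUCLEASE_SPACER_LEN, CRISPRA_SPACER_LEN):
        raise ValueError(
            f"spacer must be {NUCLEASE_SPACER_LEN} nt (nuclease) or "
            f"{CRISPRA_SPACER_LEN} nt (CRISPRa), got {len(spacer)}")
    if spacer == cts.protospacer:
        raise ValueError("spacer equals the protospacer of its own CTS (self-trigger)")
    cfg = scaffold_config or ScaffoldConfig()
    cassette = cassette or build_cassette()
    left, off_l, right, off_r = _element_pair(cts, orientation, cfg)
    left_start = len(cfg.promoter) + len(spacer) + len(cfg.scaffold5)
    right_start = left_start + len(left) + len(cassette)
    return ProGuideConstruct(
        name=name, spacer=spacer, cts=cts, orientation=orientation,
        cassette=cassette, promoter=cfg.promoter, scaffold5=cfg.scaffold5,
        scaffold3=cfg.scaffold3, left_element=left, right_element=right,
        downstream_terminator=cfg.terminator,
        cut_left=left_start + off_l, cut_right=right_start + off_r)


# ---------------------------------------------------------------------------
# Cascades


@dataclass
class TriggerGuide:
    """A conventional sgRNA (20-nt spacer) that starts the cascade."""

    spacer: str
    name: str = "trigger"

    def __post_init__(self) -> None:
        self.spacer = clean_seq(self.spacer)
        if len(self.spacer) != NUCLEASE_SPACER_LEN:
            raise ValueError("trigger spacer must be 20 nt")


@dataclass
class CascadeStep:
    cts: CtsCandidate
    core_proguide: Optional[ProGuideConstruct]
    payload_guides: list[ProGuideConstruct] = field(default_factory=list)


@dataclass
class CascadeBundle:
    """An ordered chain of proGuide steps plus the trigger sgRNA.

    Chaining rule: the trigger spacer equals the protospacer of step 1's CTS,
    and the spacer of each step's core proGuide equals the protospacer of the
    next step's CTS. All payload guides of one step share that step's CTS.
    """

    trigger: TriggerGuide
    steps: list[CascadeStep]
    direction: str = "forward"

    def all_constructs(self) -> list[ProGuideConstruct]:
        out = []
        for s in self.steps:
            if s.core_proguide is not None:
                out.append(s.core_proguide)
            out.extend(s.payload_guides)
        return out


def assemble_cascade(
    cts_chain: Sequence[CtsCandidate],
    payloads: Optional[dict[int, Sequence[str]]] = None,
    cassette: Optional[InactivationCassette] = None,
    orientation: str = "IR1",
    scaffold_config: Optional[ScaffoldConfig] = None,
    terminal_spacer: Optional[str] = None,
    direction: str = "forward",
) -> CascadeBundle:
    """Chain CTS into a cascade: trigger -> step 1 -> ... -> step n.

    ``payloads`` maps 1-based step indices to lists of 14-nt CRISPRa spacers;
    every payload guide of a step carries that step's CTS, so a single cut
    event converts the whole pool. ``terminal_spacer`` (20 nt) gives the last
    step's core proGuide an output activity; without it the last step carries
    payloads only.
    """
    if len(cts_chain) < 2:
        raise ValueError("a cascade needs at least 2 steps")
    sites = [c.site for c in cts_chain]
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate CTS across cascade steps")
    payloads = payloads or {}
    for idx in payloads:
        if not 1 <= idx <= len(cts_chain):
            raise ValueError(f"payload assigned to nonexistent step {idx}")

    cfg = scaffold_config or ScaffoldConfig()
    cassette = cassette or build_cassette()
    trigger = TriggerGuide(cts_chain[0].protospacer)
    steps: list[CascadeStep] = []
    for i, cts in enumerate(cts_chain):
        if i + 1 < len(cts_chain):
            core = build_proguide(
                cts_chain[i + 1].protospacer, cts, orientation, cassette, cfg,
                name=f"step{i + 1}_core")
        elif terminal_spacer is not None:
            core = build_proguide(terminal_spacer, cts, orientation, cassette,
                                  cfg, name=f"step{i + 1}_core")
        else:
            core = None
        pg_list = [
            build_proguide(sp, cts, orientation, cassette, cfg,
                           name=f"step{i + 1}_payload{j + 1}")
            for j, sp in enumerate(payloads.get(i + 1, []))
        ]
        steps.append(CascadeStep(cts, core, pg_list))
    return CascadeBundle(trigger, steps, direction)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_cascade(bundle: CascadeBundle, min_mismatches: int = 7) -> list[str]:
    """Audit a cascade; returns a list of violation strings (empty == valid).

    Checks pairwise protospacer orthogonality, spacer->CTS cross-talk (a 20-nt
    spacer within ``min_mismatches`` of a CTS it should not trigger), self-
    trigger, CTS reuse, and cassette/linker T-run hygiene.
    """
    issues: list[str] = []
    protos = [s.cts.protospacer for s in bundle.steps]
    if len(set(protos)) != len(protos):
        issues.append("duplicate CTS used by more than one step")
    for i in range(len(protos)):
        for j in range(i + 1, len(protos)):
            d = _hamming(protos[i], protos[j])
            if d < min_mismatches:
                issues.append(
                    f"CTS of steps {i + 1} and {j + 1} only {d} mismatches apart")
    # spacer cross-talk: each 20-nt spacer should match exactly one CTS
    spacers = [("trigger", bundle.trigger.spacer)]
    for i, s in enumerate(bundle.steps):
        if s.core_proguide is not None and not s.core_proguide.is_crispra:
            spacers.append((f"step{i + 1}_core", s.core_proguide.spacer))
    for label, sp in spacers:
        target = protos.index(sp) if sp in protos else None
        for j, proto in enumerate(protos):
            if target == j:
                continue
            d = _hamming(sp, proto)
            if d < min_mismatches:
                issues.append(
                    f"cross-talk: spacer of {label} within {d} mismatches of "
                    f"step {j + 1} CTS")
    for pg in bundle.all_constructs():
        if pg.spacer == pg.cts.protospacer:
            issues.append(f"{pg.name}: spacer equals own CTS protospacer (self-trigger)")
        cas = pg.cassette
        if cas.kind == "dual_polyT":
            for strand in (cas.linker, revcomp(cas.linker)):
                if t_runs(strand, 4):
                    issues.append(f"{pg.name}: cassette linker contains a >=4 T run")
    return issues
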