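"""Genome-orthogonal Cas9 target-site (CTS) library generation.

A CTS is a 23-bp site: a 20-nt protospacer followed by an NGG PAM. The library
pipeline generates random candidates and discards any that (a) look like
strong guides against a real genome (composition heuristics), (b) would create
new cloning-enzyme sites in the destination backbone, or (c) resemble any
window of the screened genomes too closely (orthogonality). Survivors can be
used as synthetic, non-genome-targeting trigger sites for proGuide cascades.

Composition heuristics (defaults):

* >= 5 G's in the 10 protospacer bases most distal to the PAM -> discard
  (G-rich non-seed regions promote off-target activity);
* >= 3 T's in the protospacer bases directly adjacent to the PAM -> discard
  (PAM-proximal T's disfavour Cas9 loading and cleavage);
* protospacer GC content outside [35%, 75%] -> discard.

Orthogonality (per screened genome): minimum ungapped Hamming distance of the
protospacer against every 20-nt genome window on both strands must be >= 7
mismatches, and the longest exact substring shared between the 23-mer and the
genome must stay below 16 bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seq_core import (
    GenomeIndex,
    NucSeq,
    clean_seq,
    gc_fraction,
    revcomp,
    write_fasta,
)

PAM_CHOICES = ("AGG", "TGG", "CGG", "GGG")
PROTOSPACER_LEN = 20

# EcoRI, BsmBI, SapI — the backbone cloning enzymes
DEFAULT_ENZYMES = ("GAATTC", "CGTCTC", "GCTCTTC")


@dataclass(frozen=True)
class CtsCandidate:
    """A candidate 23-bp Cas9 target site (20-nt protospacer + NGG PAM)."""

    protospacer: str
    pam: str
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", clean_seq(self.protospacer))
        object.__setattr__(self, "pam", clean_seq(self.pam))
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError("PAM must be a 3-nt NGG motif")

    @property
    def site(self) -> str:
        """The full 23-bp target site (protospacer + PAM)."""
        return self.protospacer + self.pam


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for every filtering stage; defaults mirror the published pipeline."""

    gc_min: float = 0.35
    gc_max: float = 0.75
    distal_window: int = 10
    distal_g_max: int = 4        # >= distal_g_max + 1 G's is discarded
    proximal_window: int = 4
    proximal_t_max: int = 2      # >= proximal_t_max + 1 T's is discarded
    min_mismatches: int = 7
    max_stretch: int = 16        # stretches >= max_stretch are discarded
    enzymes: tuple[str, ...] = DEFAULT_ENZYMES
    gc_over_full_site: bool = False   # compute GC over the 23-mer instead of the protospacer

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.distal_window > PROTOSPACER_LEN or self.proximal_window > PROTOSPACER_LEN:
            raise ValueError("filter windows cannot exceed the protospacer length")


@dataclass
class Verdict:
    """Outcome of a filter: pass, or fail with the first violated rule named."""

    passed: bool
    rule: Optional[str] = None
    stats: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.passed


@dataclass
class LibraryReport:
    """Per-stage survivor counts and per-candidate verdicts for a library build."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    verdicts: dict[str, str] = field(default_factory=dict)  # id -> "pass" | failing rule

    def record_stage(self, stage: str, count: int) -> None:
        self.stage_counts[stage] = count


# ---------------------------------------------------------------------------
# Candidate generation


def generate_candidates(n: int, seed: int, prefix: str = "cts") -> list[CtsCandidate]:
    """Draw *n* random CTS candidates.

    Protospacer bases are i.i.d. uniform over {A,C,G,T}; the PAM is drawn
    uniformly from {AGG,TGG,CGG,GGG}. Deterministic for a fixed seed; the
    candidate order is generation order and no deduplication is applied by
    default (collisions are negligible at 4^20).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    protos = rng.integers(0, 4, size=(n, PROTOSPACER_LEN))
    pams = rng.integers(0, 4, size=n)
    out = []
    for i in range(n):
        proto = "".join(bases[protos[i]])
        out.append(CtsCandidate(proto, PAM_CHOICES[pams[i]], id=f"{prefix}{i:06d}"))
    return out


def dedup_candidates(cands: Sequence[CtsCandidate]) -> list[CtsCandidate]:
    seen: set[str] = set()
    out = []
    for c in cands:
        if c.site not in seen:
            seen.add(c.site)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Composition filter


def composition_filter(c: CtsCandidate, p: FilterParams = FilterParams()) -> Verdict:
    """Apply the composition heuristics in fixed order: distal-G, proximal-T, GC.

    The fail verdict names the first violated rule. GC is computed over the
    20-nt protospacer by default (the PAM's constrained GG would bias GC);
    bounds are inclusive.
    """
    proto = c.protospacer
    distal = proto[: p.distal_window]
    if distal.count("G") > p.distal_g_max:
        return Verdict(False, "distal-G")
    proximal = proto[PROTOSPACER_LEN - p.proximal_window :]
    if proximal.count("T") > p.proximal_t_max:
        return Verdict(False, "proximal-T")
    gc = gc_fraction(c.site if p.gc_over_full_site else proto)
    if not (p.gc_min <= gc <= p.gc_max):
        return Verdict(False, "GC")
    return Verdict(True)


# ---------------------------------------------------------------------------
# Restriction-site filter


def _count_sites(seq: str, enzymes: Iterable[str]) -> int:
    """Occurrences of any recognition sequence on either strand of *seq*."""
    n = 0
    rc = revcomp(seq) if seq else ""
    for e in enzymes:
        e = clean_seq(e)
        n += _count_overlapping(seq, e)
        n += _count_overlapping(rc, e)
    return n


def _count_overlapping(hay: str, needle: str) -> int:
    n = start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def restriction_filter(
    c: CtsCandidate,
    flank5: str = "",
    flank3: str = "",
    p: FilterParams = FilterParams(),
) -> Verdict:
    """Fail a candidate that creates a new enzyme site in its backbone context.

    ``flank5``/``flank3`` are the backbone bases surrounding the cloning site;
    junction-spanning sites are caught because the scan runs over the full
    ``flank5 + site + flank3`` concatenation. Empty flanks are accepted as an
    explicit no-context scan; non-empty flanks shorter than the longest
    recognition sequence minus one raise a configuration error.
    """
    flank5, flank3 = clean_seq(flank5), clean_seq(flank3)
    need = max(len(e) for e in p.enzymes) - 1
    for fl in (flank5, flank3):
        if fl and len(fl) < need:
            raise ValueError(
                f"flank of length {len(fl)} too short: need >= {need} bases of context"
            )
    with_site = _count_sites(flank5 + c.site + flank3, p.enzymes)
    without = _count_sites(flank5 + flank3, p.enzymes)
    if with_site > without:
        return Verdict(False, "restriction-site",
                       stats={"sites_with": with_site, "sites_without": without})
    return Verdict(True)


# ---------------------------------------------------------------------------
# Orthogonality filter (exhaustive Hamming scan, both strands)

_BASE_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def min_hamming_to_windows(query: str, genome_seq: str) -> int:
    """Minimum Hamming distance between *query* and every |query|-length window
    of *genome_seq* (one strand). Vectorised sliding comparison."""
    k = len(query)
    g = _encode(genome_seq)
    if len(g) < k:
        return k
    q = _encode(query)
    # matches[i] = number of positions where window starting at i equals query
    matches = np.zeros(len(g) - k + 1, dtype=np.int32)
    for j in range(k):
        matches += g[j : len(g) - k + 1 + j] == q[j]
    return int(k - matches.max())


def longest_stretch_vs_genome(site: str, genome_seq: str) -> int:
    """Longest exact substring of the 23-mer found anywhere in *genome_seq*."""
    n = len(site)
    best = 0
    for k in range(n, 0, -1):
        if k <= best:
            break
        for i in range(n - k + 1):
            if site[i : i + k] in genome_seq:
                best = k
                break
        if best:
            break
    return best


def orthogonality_filter(
    c: CtsCandidate, g: GenomeIndex, p: FilterParams = FilterParams()
) -> Verdict:
    """Exhaustive both-strand genome scan for near-matches to a candidate.

    Passes iff the minimum protospacer Hamming distance over all 20-nt genome
    windows is >= ``min_mismatches`` AND the longest exact substring shared
    between the 23-mer and the genome is < ``max_stretch``. No genome-side PAM
    is required for a window to count (a deliberately strict choice).
    """
    if g.total_length == 0:
        raise ValueError("genome is empty")
    min_mm = PROTOSPACER_LEN
    max_stretch = 0
    for chrom in g:
        seq = chrom.bases
        for strand_seq in (seq, revcomp(seq)):
            min_mm = min(min_mm, min_hamming_to_windows(c.protospacer, strand_seq))
            max_stretch = max(max_stretch, longest_stretch_vs_genome(c.site, strand_seq))
    stats = {"min_mismatches_found": min_mm, "max_stretch_found": max_stretch}
    if min_mm < p.min_mismatches:
        return Verdict(False, "mismatch", stats=stats)
    if max_stretch >= p.max_stretch:
        return Verdict(False, "stretch", stats=stats)
    return Verdict(True, stats=stats)


def apply_tabular_hits(
    candidates: Sequence[CtsCandidate],
    hits_path: "str | Path",
    p: FilterParams = FilterParams(),
) -> dict[str, Verdict]:
    """Apply the orthogonality thresholds to external alignment results.

    ``hits_path`` is a standard 12-column tabular alignment file (query id,
    subject id, percent identity, alignment length, mismatches, gap opens,
    qstart, qend, sstart, send, evalue, bitscore). For each candidate the
    implied mismatch count (protospacer length minus matched bases) and the
    matched stretch are thresholded exactly as in :func:`orthogonality_filter`.
    Candidates with no reported hit pass. This import path serves users who
    screen full genomes with an external aligner; the native scan remains the
    reference implementation.
    """
    worst_mm: dict[str, int] = {}
    worst_stretch: dict[str, int] = {}
    with open(hits_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, pident, length, mism = f[0], float(f[2]), int(f[3]), int(f[4])
            matched = round(length * pident / 100.0)
            # mismatches relative to the full protospacer: unaligned bases count
            mm = PROTOSPACER_LEN - matched
            worst_mm[qid] = min(worst_mm.get(qid, PROTOSPACER_LEN), mm)
            if mism == 0 and int(f[5]) == 0:
                worst_stretch[qid] = max(worst_stretch.get(qid, 0), length)
    out = {}
    for c in candidates:
        mm = worst_mm.get(c.id, PROTOSPACER_LEN)
        stretch = worst_stretch.get(c.id, 0)
        stats = {"min_mismatches_found": mm, "max_stretch_found": stretch}
        if mm < p.min_mismatches:
            out[c.id] = Verdict(False, "mismatch", stats=stats)
        elif stretch >= p.max_stretch:
            out[c.id] = Verdict(False, "stretch", stats=stats)
        else:
            out[c.id] = Verdict(True, stats=stats)
    return out


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class LibraryConfig:
    n: int = 1000
    seed: int = 0
    params: FilterParams = field(default_factory=FilterParams)
    flank5: str = ""
    flank3: str = ""
    genomes: tuple = ()          # (name, GenomeIndex or FASTA path), screened in order
    dedup: bool = False


def build_library(
    config: LibraryConfig, out_fasta: "str | Path | None" = None
) -> tuple[list[CtsCandidate], LibraryReport]:
    """Run generate -> composition -> restriction -> per-genome orthogonality.

    Returns the surviving candidates and a report of per-stage counts plus the
    first failing rule for every candidate. Deterministic given the seed and
    genome inputs.
    """
    report = LibraryReport()
    cands = generate_candidates(config.n, config.seed)
    if config.dedup:
        cands = dedup_candidates(cands)
    report.record_stage("generated", len(cands))

    survivors = []
    for c in cands:
        v = composition_filter(c, config.params)
        if v:
            survivors.append(c)
        else:
            report.verdicts[c.id] = v.rule
    report.record_stage("after_composition", len(survivors))

    nxt = []
    for c in survivors:
        v = restriction_filter(c, config.flank5, config.flank3, config.params)
        if v:
            nxt.append(c)
        else:
            report.verdicts[c.id] = v.rule
    survivors = nxt
    report.record_stage("after_restriction", len(survivors))

    for gname, genome in config.genomes:
        if not isinstance(genome, GenomeIndex):
            try:
                genome = GenomeIndex.from_fasta(genome)
            except OSError as e:
                raise OSError(f"cannot read genome {gname!r} from {genome}: {e}") from e
        nxt = []
        for c in survivors:
            v = orthogonality_filter(c, genome, config.params)
            if v:
                nxt.append(c)
            else:
                report.verdicts[c.id] = f"{v.rule}:{gname}"
        survivors = nxt
        report.record_stage(f"after_genome_{gname}", len(survivors))

    report.record_stage("final", len(survivors))
    for c in survivors:
        report.verdicts[c.id] = "pass"

    if out_fasta is not None:
        recs = [
            NucSeq(c.site, f"{c.id} protospacer={c.protospacer} pam={c.pam}")
            for c in survivors
        ]
        write_fasta(recs, out_fasta)
    return survivors, report


def first_passing_candidate(seed: int = 0, p: FilterParams = FilterParams()) -> CtsCandidate:
    """Convenience: the first randomly generated candidate passing composition."""
    batch = 64
    offset = 0
    while True:
        for c in generate_candidates(batch, seed + offset, prefix=f"s{offset}_"):
            if composition_filter(c, p):
                return c
        offset += 1
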