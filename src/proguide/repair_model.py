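"""Cas9 cut-and-repair simulation and Pol III transcript prediction.

Cas9 is modeled as making a blunt double-strand cut between protospacer
positions 17 and 18 (3 bp on the 5' side of the PAM). Cutting both CTS copies
of a proGuide excises the interval between the two cuts; three repair products
are simulated:

* *perfect deletion* — blunt religation of the outer fragments (the intended
  conversion to a matureGuide);
* *reconstitution* — for direct-repeat arrangements the perfect-deletion
  product itself contains an intact CTS, so the plasmid can be cut again;
  this is tracked by the ``recut_possible`` flag rather than as a separate
  product;
* *inversion* — the excised fragment religates in reverse orientation.

Pol III termination is modeled as a deterministic threshold on top-strand
polyT runs: the polymerase stops at the first run of ``termination_t_run``
(default 5) or more T's, emitting a short run-in of U's. The default of 5
keeps the scaffold's native TTTT from registering as a terminator while any
intact cassette tract (>= 4+ T's by construction, 8 by default) terminates.
Runs of exactly 4 T's are flagged as partial-termination warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .proguide_design import ProGuideConstruct
from .seq_core import clean_seq, revcomp, t_runs


@dataclass(frozen=True)
class Pol3Params:
    termination_t_run: int = 5
    warn_t_run: int = 4

    def __post_init__(self) -> None:
        if not self.termination_t_run >= self.warn_t_run >= 4:
            raise ValueError("need termination_t_run >= warn_t_run >= 4")


@dataclass
class RepairOutcome:
    """One simulated post-cut product of a proGuide."""

    kind: str                      # perfect_deletion | reconstitution | inversion
    repaired: str
    deleted_interval: tuple[int, int]
    residual_insertion: str        # what remains of the cassette region
    residual_ir_arm: int
    recut_possible: bool


def _check_cuts(c: ProGuideConstruct) -> None:
    if not (0 <= c.cut_left < c.cut_right <= len(c.sequence)):
        raise ValueError("construct has no valid annotated cut sites")


def _recut_possible(repaired: str, sites: Sequence[str]) -> bool:
    rc = revcomp(repaired)
    return any(s in repaired or s in rc for s in sites)


def simulate_perfect_repair(
    c: ProGuideConstruct, cascade_sites: Optional[Sequence[str]] = None
) -> RepairOutcome:
    """Blunt religation of the outer fragments after both CTS copies are cut.

    For the PAM-out IR1 arrangement the residual insertion left in the
    scaffold is the 12-bp palindromic inverted repeat (PAM + 3 PAM-proximal
    bases from each copy). ``recut_possible`` reports whether the repaired
    sequence still contains an intact cascade CTS on either strand (always
    the case for DR arrangements, never for IR1).
    """
    _check_cuts(c)
    seq = c.sequence
    repaired = seq[: c.cut_left] + seq[c.cut_right :]
    residual = (seq[c.left_element_start : c.cut_left]
                + seq[c.cut_right : c.right_element_end])
    sites = list(cascade_sites) if cascade_sites is not None else [c.cts.site]
    kind = "perfect_deletion"
    recut = _recut_possible(repaired, sites)
    if recut:
        kind = "reconstitution"
    return RepairOutcome(
        kind=kind, repaired=repaired,
        deleted_interval=(c.cut_left, c.cut_right),
        residual_insertion=residual,
        residual_ir_arm=max_inverted_repeat_arm(residual) if residual else 0,
        recut_possible=recut)


def simulate_inversion(
    c: ProGuideConstruct, cascade_sites: Optional[Sequence[str]] = None
) -> RepairOutcome:
    """Religation with the excised fragment placed in reverse orientation.

    Length-preserving; applying the operation twice restores the original
    sequence.
    """
    _check_cuts(c)
    seq = c.sequence
    repaired = (seq[: c.cut_left]
                + revcomp(seq[c.cut_left : c.cut_right])
                + seq[c.cut_right :])
    sites = list(cascade_sites) if cascade_sites is not None else [c.cts.site]
    return RepairOutcome(
        kind="inversion", repaired=repaired,
        deleted_interval=(c.cut_left, c.cut_right),
        residual_insertion=repaired[c.left_element_start : c.right_element_end],
        residual_ir_arm=0,
        recut_possible=_recut_possible(repaired, sites))


# ---------------------------------------------------------------------------
# Pol III transcription


@dataclass
class TranscriptResult:
    transcript: str                 # DNA-coded (T for U)
    terminated_at: Optional[int]    # template coordinate of the terminating run
    is_functional_guide: bool
    warnings: list[str] = field(default_factory=list)


def predict_transcript(
    template: "str", tss: int, p: Pol3Params = Pol3Params(),
    guide_end: Optional[int] = None,
) -> TranscriptResult:
    """Predict the Pol III transcript from *template* starting at *tss*.

    The transcript runs until the first top-strand T-run of length
    ``termination_t_run`` or more (including a modeled run-in of the first
    ``min(4, run)`` U's) or to the template end. ``guide_end`` is the template
    coordinate a transcript must reach to contain the complete spacer and
    scaffold 3' end; ``is_functional_guide`` is true iff the transcript covers
    it (defaults to the template end).
    """
    template = clean_seq(template)
    if not 0 <= tss <= len(template):
        raise ValueError(f"tss {tss} outside template of length {len(template)}")
    if guide_end is None:
        guide_end = len(template)
    downstream = template[tss:]
    warnings: list[str] = []
    terminated_at: Optional[int] = None
    end = len(template)
    for start, stop in t_runs(downstream, p.warn_t_run):
        run_len = stop - start
        if run_len >= p.termination_t_run:
            terminated_at = tss + start
            end = tss + start + min(4, run_len)
            break
        warnings.append(
            f"partial-termination risk: {run_len}T run at {tss + start}")
    transcript = template[tss:end]
    # functional iff transcription reaches the guide boundary before any
    # terminator (a stop at or beyond guide_end — e.g. the construct's own
    # downstream terminator — still yields a complete guide)
    reach = len(template) if terminated_at is None else terminated_at
    functional = tss <= guide_end <= len(template) and reach >= guide_end
    return TranscriptResult(transcript, terminated_at, functional, warnings)


def predict_construct_transcript(
    c: ProGuideConstruct, p: Pol3Params = Pol3Params()
) -> TranscriptResult:
    """Transcript prediction for a construct: TSS at the promoter boundary,
    functional iff the transcript reaches the end of the scaffold 3' half."""
    return predict_transcript(c.sequence, c.tss, p, guide_end=c.guide_end)


# ---------------------------------------------------------------------------
# Inverted-repeat geometry


def max_inverted_repeat_arm(s: str) -> int:
    """Largest arm length k such that *s* contains two non-overlapping k-mers,
    the second the reverse complement of the first, separated by a loop of
    >= 0 bases. Exhaustive dynamic program, intended for |s| <= 200.
    """
    s = clean_seq(s)
    n = len(s)
    if n < 2:
        return 0
    rc = revcomp(s)
    best = 0
    # run[p] = length of the common suffix of s[:i+1] and rc[:p+1]
    prev = [0] * n
    for i in range(n):
        cur = [0] * n
        for p in range(n):
            if s[i] != rc[p]:
                continue
            cur[p] = (prev[p - 1] if p else 0) + 1
            # arm1 ends at i (inclusive); arm2 = revcomp image starts at
            # n-1-p on s; arms must not overlap: i < n-1-p
            if i + p <= n - 2 and cur[p] > best:
                best = cur[p]
        prev = cur
    return best
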