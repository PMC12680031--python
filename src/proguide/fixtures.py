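"""Synthetic inputs for every pipeline stage: toy genomes with planted
near-matches for orthogonality screening, and simulated amplicon read sets
drawn from a specified repair-outcome mixture.

The read simulator emulates the guide-RNA amplicon sequencing experiment:
each read descends from one repair product of a proGuide construct (built
mechanistically for perfect repair and inversion, rule-conformant randomised
for the near-perfect and "other" classes), gets CS1/CS2 linkers, is
fragmented into an overlapping R1/R2 pair and receives i.i.d. substitution
errors. Truth labels are recorded per read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .amplicon_classify import (
    CS1,
    CS2,
    AlignParams,
    ClassifierRules,
    align_read,
    classify,
)
from .proguide_design import ProGuideConstruct
from .repair_model import simulate_inversion, simulate_perfect_repair
from .seq_core import FastqRead, GenomeIndex, NucSeq, clean_seq, revcomp

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Toy genomes


@dataclass
class ToyGenomeSpec:
    length: int
    seed: int = 0
    plants: list[tuple[str, int, str]] = field(default_factory=list)
    # each plant: (sequence, intended_mismatches, strand '+'|'-')
    name: str = "toy"


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly k positions of *seq* (realized Hamming distance k)."""
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def make_toy_genome(spec: ToyGenomeSpec) -> tuple[GenomeIndex, dict]:
    """Uniform random background with mutated plants embedded at recorded,
    non-overlapping coordinates. Returns the genome and a truth manifest;
    the realized Hamming distance of every plant equals its intended value
    (verified post hoc)."""
    total_plant = sum(len(p[0]) for p in spec.plants)
    if total_plant > spec.length:
        raise ValueError("plants do not fit in the requested genome length")
    rng = np.random.default_rng(spec.seed)
    background = "".join(_BASES[rng.integers(0, 4, size=spec.length)])
    occupied: list[tuple[int, int]] = []
    manifest = {"length": spec.length, "seed": spec.seed, "plants": []}
    genome = list(background)
    for seq, k, strand in spec.plants:
        seq = clean_seq(seq)
        mutated = _mutate(seq, k, rng)
        realized = sum(a != b for a, b in zip(seq, mutated))
        assert realized == k
        placed = None
        for _ in range(1000):
            start = int(rng.integers(0, spec.length - len(seq) + 1))
            iv = (start, start + len(seq))
            if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
                placed = iv
                break
        if placed is None:
            raise ValueError("could not place plants without overlap")
        occupied.append(placed)
        inserted = mutated if strand == "+" else revcomp(mutated)
        genome[placed[0] : placed[1]] = list(inserted)
        manifest["plants"].append({
            "source": seq, "mutated": mutated, "start": placed[0],
            "end": placed[1], "mismatches": k, "strand": strand,
        })
    gi = GenomeIndex([NucSeq("".join(genome), spec.name)])
    return gi, manifest


# ---------------------------------------------------------------------------
# Read simulation

SUPPORTED_CLASSES = ("readthrough", "perfect", "perfect_adjacent",
                     "inversion", "other")


@dataclass
class ReadSimSpec:
    construct: ProGuideConstruct
    outcome_mix: dict[str, float]
    n_reads: int
    per_base_error: float = 0.003
    length_jitter: int = 3
    seed: int = 0
    indel_errors: bool = False
    # randomized classes draw from a finite pool of distinct products, as a
    # real repair-product population would amplify finitely many variants
    variants_per_class: int = 6
    rules: ClassifierRules = field(default_factory=ClassifierRules)

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        bad = set(self.outcome_mix) - set(SUPPORTED_CLASSES)
        if bad:
            raise ValueError(f"unsupported outcome classes in mix: {sorted(bad)}")
        if abs(sum(self.outcome_mix.values()) - 1.0) > 1e-9:
            raise ValueError("outcome mix must sum to 1")


def _apply_deletions(ref: str, dels: Sequence[tuple[int, int]]) -> str:
    out = []
    prev = 0
    for s, e in sorted(dels):
        out.append(ref[prev:s])
        prev = e
    out.append(ref[prev:])
    return "".join(out)


def _random_subs(seq: str, k: int, rng: np.random.Generator) -> str:
    return _mutate(seq, min(k, len(seq)), rng)


def _true_sequence(
    label: str,
    construct: ProGuideConstruct,
    rules: ClassifierRules,
    rng: np.random.Generator,
) -> str:
    """The error-free amplicon-region sequence of one repair product."""
    ref = construct.amplicon
    cl, cr = construct.amplicon_cut_left, construct.amplicon_cut_right
    if label == "readthrough":
        return ref
    if label == "perfect":
        repaired = simulate_perfect_repair(construct).repaired
        return repaired[construct.tss : len(repaired)
                        - len(construct.downstream_terminator)]
    if label == "inversion":
        repaired = simulate_inversion(construct).repaired
        return repaired[construct.tss : len(repaired)
                        - len(construct.downstream_terminator)]
    if label == "perfect_adjacent":
        return _rule_conformant(ref, cl, cr, rules, rng, conform=True)
    if label == "other":
        return _rule_conformant(ref, cl, cr, rules, rng, conform=False)
    raise ValueError(f"unsupported class {label!r}")


def _rule_conformant(
    ref: str, cl: int, cr: int, rules: ClassifierRules,
    rng: np.random.Generator, conform: bool,
) -> str:
    """Randomised product that the near-perfect rule accepts (conform=True)
    or violates in one randomly chosen way (conform=False); verified against
    the classifier before being returned."""
    for _ in range(200):
        if conform:
            w = rules.junction_window
            dl = cl + int(rng.integers(-w, w + 1))
            dr = cr + int(rng.integers(-w, w + 1))
            n_extra = int(rng.integers(0, rules.max_extra_dels + 1))
            n_subs = int(rng.integers(0, 3))
            if (dl, dr) == (cl, cr) and n_subs == 0 and n_extra == 0:
                n_subs = 1  # keep it non-perfect
            extra_lens = _extra_lengths(n_extra, rules, rng)
        else:
            mode = rng.choice(["far_junction", "too_many_extras", "long_extra",
                               "many_subs"])
            dl, dr = cl, cr
            n_subs, extra_lens = 0, []
            if mode == "far_junction":
                off = int(rng.integers(rules.junction_window + 2,
                                       rules.junction_window + 7))
                if rng.integers(0, 2):
                    dl = cl - off
                else:
                    dr = cr + off
            elif mode == "too_many_extras":
                extra_lens = [2] * (rules.max_extra_dels + 2)
            elif mode == "long_extra":
                extra_lens = [rules.extra_del_max_len + 2 + int(rng.integers(0, 4))]
            else:  # many_subs
                n_subs = rules.max_subs + 2
        dels = [(max(0, dl), min(len(ref), dr))]
        ok = _place_extras(ref, dels, extra_lens, cl, cr, rng)
        if not ok:
            continue
        seq = _apply_deletions(ref, dels)
        seq = _random_subs(seq, n_subs, rng)
        calls = align_read(seq, ref, AlignParams())
        label = classify(calls, cl, cr, rules, read=seq)
        if conform and label == "perfect_adjacent":
            return seq
        if not conform and label == "other_deletion":
            return seq
    raise RuntimeError("could not generate a rule-conformant product")


def _extra_lengths(n: int, rules: ClassifierRules,
                   rng: np.random.Generator) -> list[int]:
    lens, over2 = [], 0
    for _ in range(n):
        hi = rules.extra_del_max_len if over2 < rules.max_extra_dels_over2 else 2
        ln = int(rng.integers(1, hi + 1))
        if ln > 2:
            over2 += 1
        lens.append(ln)
    return lens


def _place_extras(
    ref: str, dels: list[tuple[int, int]], extra_lens: Sequence[int],
    cl: int, cr: int, rng: np.random.Generator,
) -> bool:
    """Place extra deletions well away from the junction and each other so
    that alignment recovers them as separate events."""
    margin = 12
    for ln in extra_lens:
        for _ in range(50):
            s = int(rng.integers(1, len(ref) - ln))
            iv = (s, s + ln)
            near_junction = (cl - margin) <= iv[1] and iv[0] <= (cr + margin)
            clash = any(iv[0] < e + margin and s0 < iv[1] + margin
                        for s0, e in dels)
            if not near_junction and not clash:
                dels.append(iv)
                break
        else:
            return False
    return True


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def simulate_reads(
    spec: ReadSimSpec,
) -> tuple[list[FastqRead], list[FastqRead], list[dict]]:
    """Simulate an amplicon read set from a repair-outcome mixture.

    Returns (R1 reads, R2 reads, truth rows). Each amplicon is
    CS1 + product + CS2, split into a pair overlapping by >= 10 bases; R2 is
    emitted in sequencing orientation (reverse complement). Substitution
    errors are injected i.i.d. per base; indel errors only when enabled.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.outcome_mix)
    probs = np.array([spec.outcome_mix[k] for k in labels], dtype=float)
    probs /= probs.sum()
    r1s, r2s, truth = [], [], []
    pools: dict[str, list[str]] = {}
    for i in range(spec.n_reads):
        label = labels[int(rng.choice(len(labels), p=probs))]
        if label in ("perfect_adjacent", "other"):
            pool = pools.get(label)
            if pool is None:
                pool = [_true_sequence(label, spec.construct, spec.rules, rng)
                        for _ in range(spec.variants_per_class)]
                pools[label] = pool
            product = pool[int(rng.integers(0, len(pool)))]
        else:
            product = _true_sequence(label, spec.construct, spec.rules, rng)
        amplicon = CS1 + product + CS2
        L = len(amplicon)
        jitter = int(rng.integers(-spec.length_jitter, spec.length_jitter + 1))
        read_len = min(160, max(60, (L + 24) // 2 + jitter))
        r1_seq = amplicon[:read_len]
        r2_seq = revcomp(amplicon[-read_len:])
        if spec.indel_errors and rng.random() < spec.per_base_error * read_len:
            p = int(rng.integers(1, len(r1_seq)))
            r1_seq = r1_seq[:p] + r1_seq[p + 1:]
        r1_seq = _inject_errors(r1_seq, spec.per_base_error, rng)
        r2_seq = _inject_errors(r2_seq, spec.per_base_error, rng)
        name = f"sim{i:06d}"
        r1s.append(FastqRead(name, r1_seq, [37] * len(r1_seq)))
        r2s.append(FastqRead(name, r2_seq, [37] * len(r2_seq)))
        truth.append({"read_id": name, "true_label": label,
                      "product_length": len(product)})
    return r1s, r2s, truth
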