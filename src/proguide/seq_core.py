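"""Sequence primitives shared by every stage of the proGuide toolkit.

Conventions used throughout the package:

* DNA sequences are uppercase strings over the strict alphabet ``{A,C,G,T}``.
  Lowercase input is uppercased on ingest; ambiguity codes (``N`` etc.) are
  rejected because no step of the pipeline needs them.
* All interval coordinates are 0-based, half-open, on the top (coding) strand.
  Features found on the reverse strand are reported in top-strand coordinates
  together with a strand flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T}."""


def clean_seq(bases: str) -> str:
    """Uppercase *bases* and validate the strict DNA alphabet.

    Raises
    ------
    AlphabetError
        If any character is not one of A/C/G/T after uppercasing.
    """
    s = bases.upper()
    if not set(s) <= DNA_ALPHABET:
        bad = sorted(set(s) - DNA_ALPHABET)
        raise AlphabetError(f"non-ACGT characters in sequence: {bad}")
    return s


@dataclass(frozen=True)
class NucSeq:
    """A named, validated DNA sequence (top strand, uppercase ACGT)."""

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", clean_seq(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


def _as_str(s: "NucSeq | str") -> str:
    return clean_seq(s.bases if isinstance(s, NucSeq) else s)


def revcomp(s: "NucSeq | str") -> str:
    """Reverse complement of a DNA string. Involution: revcomp(revcomp(s)) == s."""
    return _as_str(s).translate(_COMPLEMENT)[::-1]


def gc_fraction(s: "NucSeq | str") -> float:
    """Fraction of G+C bases, in [0, 1].

    Raises
    ------
    ValueError
        On an empty sequence (GC content is undefined).
    """
    t = _as_str(s)
    if not t:
        raise ValueError("GC fraction is undefined for an empty sequence")
    return (t.count("G") + t.count("C")) / len(t)


def longest_match_stretch(a: "NucSeq | str", b: "NucSeq | str",
                          both_strands: bool = False) -> int:
    """Length of the longest exact common substring of *a* and *b*.

    With ``both_strands=True`` the reverse complement of *b* is also searched
    and the maximum over both orientations is returned.
    """
    sa, sb = _as_str(a), _as_str(b)
    if not sa or not sb:
        raise ValueError("longest_match_stretch requires non-empty sequences")
    best = _lcs_len(sa, sb)
    if both_strands:
        best = max(best, _lcs_len(sa, revcomp(sb)))
    return best


def _lcs_len(a: str, b: str) -> int:
    # classic O(len(a)*len(b)) DP over match-run lengths; sequences here are
    # short (23-mers against flanks or other short sequences)
    if len(a) > len(b):
        a, b = b, a
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def t_runs(s: "NucSeq | str", min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive T on the top strand, length >= min_len.

    Returns 0-based half-open intervals, left to right.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    t = _as_str(s)
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(t)
    while i < n:
        if t[i] == "T":
            j = i
            while j < n and t[j] == "T":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# Genome container


@dataclass
class GenomeIndex:
    """A set of named chromosomes searchable over both strands.

    Reverse-strand hits elsewhere in the package are reported in top-strand
    coordinates with a strand flag; this container just holds the sequences.
    """

    chromosomes: list[NucSeq] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not all(isinstance(c, NucSeq) for c in self.chromosomes):
            self.chromosomes = [
                c if isinstance(c, NucSeq) else NucSeq(str(c)) for c in self.chromosomes
            ]

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def __iter__(self) -> Iterator[NucSeq]:
        return iter(self.chromosomes)

    @classmethod
    def from_fasta(cls, path: "str | Path") -> "GenomeIndex":
        return cls([NucSeq(str(rec.seq), rec.id) for rec in SeqIO.parse(str(path), "fasta")])


# ---------------------------------------------------------------------------
# File I/O (FASTA / FASTQ / TSV / JSON); parsing delegated to Biopython


@dataclass
class FastqRead:
    """A FASTQ read; quality is carried but only consulted by pair merging."""

    name: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        self.bases = clean_seq(self.bases)
        if len(self.quals) != len(self.bases):
            raise ValueError("quality string length differs from sequence length")

    def __len__(self) -> int:
        return len(self.bases)


def read_fasta(path: "str | Path") -> list[NucSeq]:
    """Read a (possibly line-wrapped) FASTA file into NucSeq records."""
    return [NucSeq(str(rec.seq), rec.id) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[NucSeq], path: "str | Path", width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def read_fastq(path: "str | Path") -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(FastqRead(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(reads: Iterable[FastqRead], path: "str | Path") -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(min(q, 93) + 33) for q in r.quals)
            fh.write(f"@{r.name}\n{r.bases}\n+\n{q}\n")


def write_tsv(rows: Sequence[dict], path: "str | Path") -> None:
    """Write a list of homogeneous dicts as a TSV with a header line."""
    rows = list(rows)
    with open(path, "w") as fh:
        if not rows:
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_json(obj, path: "str | Path") -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
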