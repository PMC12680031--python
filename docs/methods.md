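# Methods

This note documents the models, conventions and design choices behind
`proguide`. Coordinates are 0-based and half-open on the top strand
throughout; reverse-strand features carry a strand flag.

## Cas9 target sites and the orthogonality screen

A Cas9 target site (CTS) is a 23-bp sequence: a 20-nt protospacer followed by
an NGG PAM. The library generator draws protospacer bases i.i.d. uniformly
over {A,C,G,T} and the PAM uniformly from {AGG, TGG, CGG, GGG}, from a single
seeded generator; candidate order is generation order and no deduplication is
applied by default (collision probability is negligible at 4^20).

Candidates pass through filters in a fixed order, and a failing candidate is
labelled with the first violated rule:

1. **Distal G rule** — discard if the 10 protospacer bases most distal to the
   PAM contain ≥ 5 G (G-rich non-seed regions promote off-target activity).
2. **Proximal T rule** — discard if the bases directly adjacent to the PAM
   contain ≥ 3 T (PAM-proximal T's disfavour Cas9 loading and cleavage). The
   width of "directly adjacent" is not fixed by convention; the default
   window is the 4 PAM-proximal protospacer bases, matching common
   seed-region usage, and is exposed in `FilterParams`.
3. **GC rule** — retain only protospacer GC content in [35%, 75%], bounds
   inclusive. GC is computed over the 20-nt protospacer, not the 23-mer: the
   PAM is constrained to NGG and would bias the statistic. A flag switches to
   the full site for users who prefer that convention.
4. **Restriction sites** — the destination backbone uses EcoRI (GAATTC),
   BsmBI (CGTCTC) and SapI (GCTCTTC) for cloning. A candidate is discarded if
   `flank5 + site + flank3` contains any recognition sequence, on either
   strand (BsmBI and SapI are non-palindromic), that is absent from
   `flank5 + flank3` alone — this catches junction-spanning sites. Empty
   flanks are accepted as an explicit no-context scan; non-empty flanks
   shorter than the longest recognition sequence minus one are a
   configuration error.
5. **Genome orthogonality** — for each screened genome, the scan computes
   (a) the minimum ungapped Hamming distance between the protospacer and
   every 20-nt genome window on both strands and (b) the longest exact
   substring shared between the 23-mer and the genome. A candidate passes iff
   the minimum distance is ≥ 7 mismatches **and** the longest shared stretch
   is < 16 bases. No genome-side PAM is required for a window to count; this
   is deliberately stricter than a PAM-aware screen. The native scanner is
   exhaustive (a vectorised sliding comparison) and therefore a superset
   detector relative to heuristic short-read aligners; an import path for
   12-column tabular alignment results applies the same thresholds for users
   screening full genomes externally.

The expected composition pass rate for uniform candidates has a closed form
(the GC rule alone passes with probability P(7 ≤ K ≤ 15), K ~ Binomial(20, ½)
≈ 0.9364; the joint probability accounts for the GC count shared with the two
window rules) and the test suite checks the generator against it.

## proGuide constructs

A proGuide concatenates: promoter · spacer · scaffold5 · left element ·
inactivation cassette · right element · scaffold3 · downstream terminator.

* The **promoter** is a U6-class Pol III placeholder constant; only its
  boundary coordinate (the TSS) matters to the designer.
* The **scaffold** is the standard S. pyogenes sgRNA scaffold split at the
  tetraloop by default (`scaffold5` ends inside the tetraloop); a hairpin-1
  split is available as an alternative insertion site. The exact junction
  bases are configuration constants, not hard-coded assumptions.
* **Spacers** are 20 nt for nuclease steps and 14 nt for CRISPRa payloads
  (DNA binding without cleavage); a spacer equal to its own CTS protospacer
  would self-trigger and is rejected.
* The **inactivation cassette** is a single polyT tract (4–10 T) or, by
  default, two 8T tracts separated by a linker. The linker may not contain a
  run of ≥ 4 T on either strand and may not create a configured enzyme site.
  The default linker is a package constant chosen to satisfy those
  constraints and is fully configurable.

### Element orientations and cut geometry

Cas9 cuts blunt, 3 bp on the 5′ side of the PAM (between protospacer
positions 17/18). Orientations of the two CTS copies:

* **IR1** (PAM-out inverted repeat): left element = revcomp(site), right
  element = site. Both cuts are internal to the cassette, 6 bp in from the
  outer element edges. Perfect repair therefore retains
  `revcomp(site[17:23]) + site[17:23]` — a 12-bp palindrome (3-bp PAM plus
  3 PAM-proximal bases from each copy) with a 6-bp stem arm that supports
  the matureGuide tetraloop.
* **DR1** — both elements are the site in the same orientation; perfect
  repair reconstitutes one intact CTS, which remains cuttable.
* **DR2/DR3/DR4** — DR geometries decorated with repeat arms: DR3/DR4 place
  a repeat outside each copy (12-bp and 6-bp arms by default, mirroring the
  IR1 arm lengths) so repair leaves an intact CTS flanked by a stem; DR2
  nests the repeats inside the excised interval. The published geometries
  are schematic, so all decoration sequences and lengths are configurable
  parameters rather than fixed truths.

### Cascades

`assemble_cascade` chains CTS: the trigger sgRNA's 20-nt spacer equals the
protospacer of step 1's CTS, and each step's core proGuide spacer equals the
next step's protospacer. All payload guides of one step share that step's
CTS, so one cut event converts the whole pool. `validate_cascade` audits
pairwise protospacer Hamming distance (≥ 7 mismatches between any two CTS,
the same bound used for genome orthogonality, reused as an intra-cascade
cross-talk bound), self-trigger, CTS reuse and cassette T-run hygiene.

## Repair simulation and Pol III transcription

Three repair modes are simulated mechanistically: perfect nested deletion
(blunt religation of the outer fragments), reconstitution (the DR perfect-
repair product containing an intact CTS, tracked by `recut_possible`), and
inversion (the excised interval reverse-complemented in place; an
involution). Arbitrary indel spectra are not modeled mechanistically — the
fixtures module generates them rule-conformantly instead.

Pol III termination is a deterministic threshold: transcription stops at the
first top-strand run of ≥ 5 T (configurable), emitting a run-in of
min(4, run) U's. The threshold of 5 keeps the scaffold's native TTTT from
registering as a terminator; 4-T runs are flagged as partial-termination
warnings instead. The wet-lab dose response of leak versus tract length is
not fitted here — the model is a design-time predicate (functional guide /
terminated fragment), not a quantitative leak model. A transcript is a
functional guide iff it covers the spacer and the complete scaffold 3′ end;
termination at or beyond that boundary (e.g. at the construct's own
downstream terminator) still yields a functional guide.

`max_inverted_repeat_arm` finds the largest k such that the sequence contains
two non-overlapping k-mers, the second the reverse complement of the first
(loop ≥ 0), by an O(n²) dynamic program over the sequence and its reverse
complement; it is intended for sequences ≤ 200 bp and is checked against a
cubic brute-force oracle.

## Amplicon classification

Pipeline order: length QC (drop < 50 bp or > 160 bp), trigger-read removal
(first 20 nt matching the trigger spacer with ≤ 1 mismatch; re-checked after
linker trimming, since trigger reads share the amplicon linkers), CS1/CS2
linker trimming (≤ 1 mismatch, both mate orientations), pair merging (best
overlap ≥ 10 by lowest mismatch fraction, ties to the longer overlap;
disagreements resolve to the higher-quality base, ties to R1), global
alignment to the unedited amplicon, call extraction, classification.

Alignment uses an affine-gap global aligner (match +2, mismatch −1, gap open
−6, gap extend −0.5 by default) with end gaps penalized; a `free_end_gaps`
flag exists for partially covering reads. The extend penalty is far below
the open penalty so one long deletion is preferred over scattered gaps.
Extracted indels are left-aligned through identical bases (VCF-style),
never past a preceding deletion.

The outcome taxonomy and its thresholds are in the `amplicon_classify`
module docstring. Two interpretation choices deserve note:

* The "one and only one deletion within 3 bp of a perfect repair site" rule
  is applied jointly to both junctions: the single qualifying deletion must
  have its left endpoint within 3 bp of the left cut **and** its right
  endpoint within 3 bp of the right cut.
* Inversion detection requires an exact match to the inversion template by
  default (`inversion_max_mismatches = 0`, configurable). The template
  comparison runs before any reference-based logic: an inverted read aligns
  to the unedited reference with zero deletions and would otherwise be
  indistinguishable from readthrough.
* The rule text is silent on insertions; `perfect_adjacent` tolerates a
  total of ≤ 1 inserted base (configurable), motivated by the observed
  1-bp insertion/deletion products of IR1 conversion.
* The substitution cap counts substitutions anywhere on the aligned read,
  not only inside CTS remnants.

Profiling excludes distinct read sequences supported by fewer than 2 reads
(profiling only — individual reads are always classified), then reports
per-base deletion frequency, the deletion-size distribution stratified into
perfect / near-perfect / other, and class fractions that sum to 1. The
support filter is what makes mixtures recoverable in the presence of
sequencing error: an error-bearing perfect read legitimately classifies as
near-perfect under the taxonomy, but its error pattern is almost always a
singleton sequence and drops out of the profile.

## Synthetic data

`make_toy_genome` embeds mutated plants (exact realized Hamming distance,
verified post hoc) at non-overlapping random coordinates in a uniform
background, with a truth manifest. `simulate_reads` draws each read's
outcome from a mixture, builds the true product (mechanistically for
perfect/inversion, rule-conformant randomised for near-perfect and "other" —
each verified against the classifier at generation time), adds CS1/CS2
linkers, splits the amplicon into an R1/R2 pair overlapping by well over the
10-base merge minimum, and injects i.i.d. substitution errors (0.3% per base
by default; indel errors are an optional flag, off by default to keep
classifier boundary tests sharp). Randomised classes draw from a finite pool
of distinct product variants (6 by default), as a real repair-product
population would amplify finitely many molecules; this is also what lets the
two-read support filter behave as it does on real data.

What the simulator does not emulate: instrument-specific error and quality
profiles, PCR amplification bias and chimeras, UMI structure, and RNA-level
effects (the reads are DNA-coded products). Passing round-trip tests
therefore demonstrate the internal consistency of generator, aligner and
classifier under idealised noise — not performance on a specific instrument.

## Problem sizes and determinism

Default verification sizes, chosen to keep the full suite in seconds to a
few minutes: 10,000 candidates for composition-rate checks; a 12-kb toy
genome with plants at Hamming distances 0–10 for the orthogonality oracle
(the exhaustive pure-Python oracle is quadratic, the production scanner is
vectorised and handles 100-kb genomes in seconds); 1,000 random CTS for
orientation properties; 2,000 simulated read pairs at 0.3% error for mixture
round trips; an exhaustive ~23,000-case grid for the classifier-versus-
oracle equivalence sweep. All randomness flows through explicitly seeded
NumPy generators; property tests are derandomised.

## Known limitations

* No on-target activity scoring (Doench/CFD-style), no PAM variants beyond
  NGG, and no gapped off-target model — mismatch counting is ungapped.
* CRISPRa efficacy of 14-nt payload spacers is taken as given input.
* No thermodynamic RNA folding; IR arm length is a proxy for stem support.
* Pol III termination is a threshold, not a per-length efficiency curve.
* No plasmid assembly (Golden Gate) simulation; restriction screening only
  checks for site creation, not cloning feasibility.
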