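# proguide

Design and analysis toolkit for **sequentially activatable CRISPR guide
RNAs** ("proGuides"). A proGuide is a Pol III guide-RNA gene whose scaffold
carries an inactivation cassette — a polyT terminator flanked by two copies
of a synthetic 23-bp Cas9 target site (CTS) — so that no functional guide is
transcribed until Cas9, directed by an upstream trigger guide, cuts both CTS
copies and NHEJ repair deletes the cassette. Chaining such units (each
matureGuide's spacer targeting the next unit's CTS) yields programmable
multi-step cascades of gene editing or CRISPRa activation.

The package covers the computational layer of that system, for synthetic
biologists building and debugging such circuits:

* **`cts_library`** — generation of random CTS candidates and filtering into
  a genome-orthogonal library: composition heuristics (≥5 G in the 10
  PAM-distal bases, ≥3 T adjacent to the PAM, GC outside 35–75% are
  discarded), backbone restriction-site screening (EcoRI/BsmBI/SapI, both
  strands, junction-spanning included) and an exhaustive per-genome
  orthogonality scan (pass iff ≥7 mismatches to every 20-nt window on both
  strands and no shared exact stretch ≥16 bases).
* **`proguide_design`** — assembly of proGuide DNA in direct-repeat (DR1–4)
  or PAM-out inverted-repeat (IR1) CTS orientations, with single- or dual-
  polyT cassettes (default two 8T tracts), annotated blunt-cut coordinates
  3 bp from each PAM, and cascade chaining with orthogonality validation.
* **`repair_model`** — simulation of Cas9 cutting plus perfect nested
  deletion, re-cuttable reconstitution, or inversion; Pol III transcript
  prediction with a deterministic ≥5T termination threshold; inverted-repeat
  arm detection. The key structural result: perfect repair of a PAM-out IR1
  proGuide leaves a 12-bp palindromic inverted repeat (3-bp PAM + 3
  PAM-proximal bases from each copy, 6-bp arms) and no re-cuttable site,
  while every DR orientation reconstitutes an intact CTS.
* **`amplicon_classify`** — reimplementation of the guide-RNA amplicon
  sequencing analysis: length QC (50–160 bp), trigger-read removal, CS1/CS2
  linker trimming (≤1 mismatch), pair merging (min overlap 10), affine-gap
  global alignment, and classification into readthrough / perfect /
  perfect-adjacent (≤5 substitutions, one junction deletion with endpoints
  within 3 bp of the cut sites, ≤4 extra deletions all <5 bp of which ≤2
  may exceed 2 bp) / inversion / other-deletion, plus deletion profiling
  over reads with ≥2-read support.
* **`fixtures`** — synthetic toy genomes with planted near-matches and a
  read simulator that draws from a specified repair-outcome mixture.

## Worked example

```python
from proguide.cts_library import generate_candidates, composition_filter
from proguide.proguide_design import build_proguide
from proguide.repair_model import (simulate_perfect_repair,
                                   predict_construct_transcript,
                                   predict_transcript)

lib = [c for c in generate_candidates(1000, seed=1) if composition_filter(c)]
print(f"{len(lib)}/1000 candidates pass the composition filters")

cts = lib[0]
print("CTS:", cts.site)
pg = build_proguide("GACGTCTAAGAAACCATTAT", cts, "IR1", name="demo")
print(f"construct: {len(pg.sequence)} bp, cuts at {pg.cut_left} and {pg.cut_right}")
print("intact proGuide functional:", predict_construct_transcript(pg).is_functional_guide)

o = simulate_perfect_repair(pg)
print("residual insertion:", o.residual_insertion, f"({o.residual_ir_arm}-bp arms)")
res = predict_transcript(o.repaired, pg.tss,
                         guide_end=len(o.repaired) - len(pg.downstream_terminator))
print("matureGuide functional:", res.is_functional_guide)
```

prints

```
818/1000 candidates pass the composition filters
CTS: CGTTAATTACTCCTCCGGAAAGG
construct: 205 bp, cuts at 70 and 130
intact proGuide functional: False
residual insertion: CCTTTCGAAAGG (6-bp arms)
matureGuide functional: True
```

Reading: 818 of 1,000 uniform random candidates survive the composition
heuristics (close to the closed-form expectation); the intact construct
terminates inside its dual-8T cassette, so it makes no guide; after
simulated cutting and perfect repair, only the 12-bp self-complementary
remnant `CCTTTCGAAAGG` stays in the scaffold tetraloop and a full-length,
functional matureGuide is transcribed.

The same steps are available from a shell via the `proguide` CLI
(`proguide cts generate/filter`, `proguide design proguide/cascade`,
`proguide simulate repair/transcript`, `proguide classify`,
`proguide fixtures genome/reads`); run any subcommand with `--help`.

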