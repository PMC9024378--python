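# fkhconsensus

Consensus analysis of transcription-factor target genes across multiple
genome-wide binding studies, built around the budding-yeast Forkhead
factors Fkh1 and Fkh2.

Genome-wide binding assays (ChIP-chip, ChIP-exo, ChEC) disagree
substantially about which genes a transcription factor targets: each method
and lab has its own sensitivity, thresholds and false-positive profile.
`fkhconsensus` treats each study's target list as a Boolean vector over a
declared gene universe and integrates six such studies per factor into a
reliable consensus, which is then validated against independent
perturbation experiments and profiled by cell-cycle timing and function.
It is aimed at regulatory-genomics analysts who have per-study gene-level
target tables and want a reproducible, fully tabular integration pipeline.

## The method

For studies *s = 1..n* over a universe of genes *g*, let
*x<sub>gs</sub> ∈ {0,1}* indicate that study *s* calls *g* a target
(either pre-called, or by a per-study score threshold).

* **Hamming similarity** between studies *s, t*:
  *H(s,t) = |{g : x<sub>gs</sub> = x<sub>gt</sub>}| / N* — the fraction of
  genes on which two studies agree, both-true or both-false. The
  denominator *N* (whole universe vs. union of targets) is recorded in
  every report, because the value depends on it.
* **Exclusive intersections** (UpSet semantics): for each non-empty study
  subset *S*, the genes with *x<sub>gs</sub> = 1* exactly for *s ∈ S*.
  Exclusive counts partition the union of all targets — this identity is
  asserted on every run.
* **k-of-n consensus**: genes with row sum Σ<sub>s</sub> x<sub>gs</sub> ≥ k
  (default k = 4 of n = 6).
* **Validation**: a consensus gene *responds* to TF deletion when its
  deletion score crosses a symmetric cutoff (±c), and to TF overexpression
  when the final time-course point does. Responding to both makes it
  **fully validated**; to at least one, **(partially) validated**. Time
  courses that cross +c early and −c at the end are flagged UP_THEN_DOWN
  (and mirror).
* **Phase enrichment**: cell-cycle-regulated (CCR) targets are binned by
  phase of peak expression (G1(P), G1, G1/S, S, G2, G2/M, M, M/G1; grouped
  EARLY/MID/LATE) and compared with the genome-wide CCR distribution as
  differences and ratios of proportions.

A seeded synthetic generator emulates every input — latent true-target
sets, per-study sensitivity/false-positive rates, conditional perturbation
responses, multinomial phase assignments — so the whole pipeline is
testable end to end without any external download.

## Worked example

```python
from fkhconsensus import (GeneUniverse, StudyDataset, build_target_matrix,
                          hamming_similarity, exclusive_intersections,
                          k_of_n_consensus)

universe = GeneUniverse(("G1", "G2", "G3", "G4", "G5"))
studies = [StudyDataset("A", "FKH1", frozenset({"G1", "G2"})),
           StudyDataset("B", "FKH1", frozenset({"G2", "G3"}))]
matrix = build_target_matrix(studies, universe)
print(hamming_similarity(matrix).loc["A", "B"])   # 0.6
print(sorted(k_of_n_consensus(matrix, 2)))        # ['G2']
```

The studies agree on G2 (both call it) and on G4, G5 (neither does): 3 of
5 genes, hence similarity 0.6. The exclusive intersections are
{A}: G1, {B}: G3, {A,B}: G2 — counts 1+1+1 equal |A ∪ B| = 3.

`examples/` contains one narrative script per capability; for the full
pipeline:

```
$ python examples/04_full_pipeline_on_synthetic_bundle.py
FKH1: 64 consensus targets (k=4 of 6); 55 (partially) validated, 22 fully validated; Jaccard with latent truth 0.80
      CCR fraction among (partially) validated: 30/55 = 0.55
...
genome-wide CCR fraction:             0.135
```

i.e. on a 1000-gene bundle the 4-of-6 consensus recovers the latent truth
with Jaccard 0.80, and validated targets are CCR-enriched (55% vs. 13.5%
genome-wide).

## Command line

```bash
fkh-consensus simulate --out bundle/ --seed 1      # write a synthetic bundle
fkh-consensus run --config bundle/config.yaml --out report/
fkh-consensus check report/                        # re-assert consistency
```

All outputs are TSV tables plus a `report.json` metadata file; re-running
on identical inputs is byte-identical.

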