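# Methods

## Problem setting

Six genome-wide binding studies — three ChIP-chip, two ChIP-exo, one ChEC —
each report a target-gene list for the budding-yeast Forkhead transcription
factors Fkh1 and Fkh2. The lists disagree widely: the assays differ in
resolution and chemistry, and each list reflects lab-specific scoring
thresholds. This package integrates such study-level gene calls into a
consensus, validates the consensus against independent TF-deletion and
TF-overexpression experiments, and profiles the validated targets by
cell-cycle phase of peak expression, functional category and interaction
network. The pipeline starts from gene-level calls: peak calling and any
upstream signal processing are out of scope, as are live queries to
SGD/YeastMine-style services (annotation is consumed as exported tables).

## Data model and normalization

Gene identifiers are canonicalized to uppercase systematic names via an
alias table (standard → systematic, case-insensitive). Unmapped names are
uppercased, kept verbatim and logged — never dropped — because the input
studies mix naming conventions and silent deletion would bias every count.
Normalization is idempotent. Duplicate rows in a study table (multiple
peaks per promoter) collapse to a single membership by OR over rows.
Per-study thresholds are explicit configuration (`score_column`,
comparator `>=`/`<=`, cutoff), or `precalled` when a table already lists
final calls; no numeric threshold is hard-coded.

All tables are plain TSV (header row, UTF-8, `#` comments); all outputs are
TSV plus JSON metadata, written with stable orderings so identical inputs
reproduce byte-identical reports.

## Consensus statistics

The studies form a Boolean gene × study matrix over a declared universe.

* **Universe mode.** `genome` (default) keeps every universe gene as a row,
  appending (and logging) any study gene outside the universe; `union`
  keeps only genes called by at least one study. The Hamming denominator is
  the row count, so the mode is echoed in the report metadata — similarity
  values are not comparable across modes. Genome mode is the default
  because both-false agreement is informative when the universe is the
  genome.
* **Hamming similarity** is computed as 1 − normalized Hamming distance
  over study columns (scipy `pdist`); symmetric, unit diagonal.
* **Exclusive intersections** follow UpSet semantics (genes in exactly a
  subset). Rows are ordered by count descending, then subset size, then
  subset lexicographically. The conservation identity Σ exclusive counts =
  |union of all targets| is asserted on every computation, not only in
  tests.
* **k-of-n consensus** is a plain row-sum threshold (default k = 4 of 6).
  No study weighting or probabilistic reliability model is used: the
  integration rule of interest is the transparent vote count.

## Validation classification

Deletion response: UP if score ≥ +c, DOWN if ≤ −c, NONE otherwise, with
c ≥ 0 configurable (default 1.0, a log2-fold-change-like scale).
Overexpression response is judged at the final time point by the same rule;
an any-time-point rule is available (`oe_rule: any`) for sensitivity
analyses, with the final point taking precedence when it crosses.
End-of-course is the default because a sustained response is the natural
summary of an overexpression time course, and because direction-at-the-end
is the quantity the downstream tallies report.

Trajectory labels (UP_THEN_DOWN / DOWN_THEN_UP) require threshold
exceedance on *both* sides — an early point past +c and a final point past
−c, or the mirror. A mere sign change inside the noise band stays
MONOTONE_OR_FLAT; this keeps the label meaningful for the
transient-activation pattern it is meant to catch.

A gene absent from a table has no evidence, not a zero response: it can
still be DELETION_ONLY via the other table, and genes absent from both are
NEITHER. The four categories partition the consensus set by construction;
raising either cutoff can only move genes toward NEITHER (monotone
shrinkage), which is property-tested.

## Phase enrichment

Phases of peak expression: G1(P), G1, G1/S, S, G2, G2/M, M, M/G1, grouped
EARLY = {G1(P), G1, G1/S} (growth), MID = {S} (genome duplication),
LATE = {G2, G2/M, M, M/G1} (division). Genes without an assignment are
NO_DATA: they enter the CCR-fraction denominator (how many targets are
cell-cycle-regulated at all) but not the per-phase denominators (when the
CCR targets peak). Sets with zero CCR genes get explicitly undefined
fractions rather than zeros.

Enrichment is reported per phase and per group as target − baseline
difference (exact) and target/baseline ratio (NaN-flagged at zero
baseline). The default baseline is the genome-wide CCR population, not all
genes, so the comparison asks "among CCR genes, when do targets peak?".
No hypothesis test is attached: the scientific quantities are the
proportions, and n per phase is small enough that a test would suggest
false precision. Differences over phases sum to zero by construction.

Functional tallies count each of a gene's labels once (a gene may be both
"Cell cycle" and "Metabolism"); unlabeled genes fall under UNANNOTATED and
fractions use the gene-set size as denominator, so fractions may sum above
one. The network export is a plain node table (gene, phase; grouped by
phase then name, TF hubs included) and edge table (source, target,
regulatory|physical, evidence) restricted to edges with both endpoints in
the node set; rendering (edge bundling etc.) is left to external tools.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without downloads. One latent true-target set per
TF is drawn inside a universe of `n_genes` synthetic genes (G000001…, plus
the two TF-encoding genes themselves, which are genome members but never
latent targets). Each of `n_studies` studies then includes a true target
with probability `sens` and any other gene with probability `fpr`,
independently across genes and studies. Independence is the simplest null
consistent with the Boolean treatment of the studies; correlated false
positives (shared artifacts between assays) are deliberately out of scope,
and results on synthetic data therefore say nothing about how the pipeline
behaves under systematically correlated study errors.

Perturbation tables are genome-wide: true targets respond to deletion with
probability `p_del` (direction up with `q_del_up`) and to overexpression
with `p_oe` (final point down with `q_oe_down`); non-targets respond at
background rates `bg_del`/`bg_oe`. Responder magnitudes are
cutoff + |N(1, 0.5²)| with the drawn sign; non-responders N(0, (cutoff/4)²),
sub-threshold at four sigma. With probability `p_oe_spike` a down-responder
also overshoots +cutoff at an interior point, giving the classifier genuine
UP_THEN_DOWN cases. These score shapes are recorded in the bundle manifest;
all downstream logic depends only on threshold crossings. Phases are
multinomial per gene, with targets drawn from a CCR-enriched distribution
and other genes from a genome-like one.

All draws flow from a single `numpy.random.default_rng(seed)` in the order
documented in the manifest, making bundles byte-identical across
regenerations.

### Default conditions

The defaults describe one fixed, yeast-scale study design and are not
tuned per run: 6000-gene universe; true-target sets of 350 (Fkh1-like) and
100 (Fkh2-like) sharing ⌈0.55·100⌉ = 55 genes (the two factors' targets
overlap in slightly more than half of the smaller set); six studies at
`sens = 0.75`, `fpr = 0.01`; `p_del = 0.55`, `p_oe = 0.45`,
`q_del_up = 0.8`, `q_oe_down = 0.9`, backgrounds 0.02; eight time points;
all cutoffs 1.0. Target genes are CCR with probability 0.60 versus 0.10
for non-targets, which keeps the genome-wide CCR fraction below the ~15%
ceiling typical of whole genomes while validated target sets come out
50–60% CCR. The spec'd single `n_true` is extended with an optional
`n_true_tf2` because the two factors' target repertoires differ several-
fold in size and the shared fraction is only meaningful relative to the
smaller set.

Under these conditions a 4-of-6 consensus recovers the latent truth with
Jaccard around 0.8 (the binomial tail of 4+ detections at sensitivity
0.75 is ≈ 0.83 per true target, while false positives essentially never
co-occur four times at fpr 0.01); at `sens = 0.9` recovery exceeds 0.9,
which is the parameter-recovery property the acceptance tests pin.

## Pipeline and reproducibility

`run_pipeline` executes data_io → consensus → validation → enrichment per
TF, then the cross-TF shared-target sets, entirely in memory before any
file is written — a failing stage leaves no partial output. The report's
internal consistency (category counts vs. gene lists, exclusive counts vs.
union, phase counts vs. CCR totals, shared sets vs. the per-TF sets) is
asserted on every run, and `fkh-consensus check` re-derives the same
assertions from an on-disk report directory. Logging emits one line per
stage with input/output cardinalities, which is the primary debugging
surface when per-study thresholds disagree with expectations.

Problem sizes in the test suite and acceptance script (universes of
120–6000 genes, 20-seed recovery sweeps at 1000 genes) were chosen so the
full suite runs in seconds while keeping binomial fluctuations small
relative to the asserted margins.

## Known limitations

* Study errors are modeled as independent; the consensus's real-world
  precision under shared experimental artifacts is not characterized here.
* Validation responsiveness is a threshold rule on reported scores; no
  significance modeling of the underlying expression measurements is
  attempted.
* The Hamming similarity values depend on the chosen denominator; only the
  within-report ranking of study pairs is meaningful without fixing the
  universe mode.
* Phase enrichment reports descriptive differences of proportions, not
  calibrated significance statements.
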