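# Methods

## The problem

A CRISPR-Cas9 ribonucleoprotein is directed to a genomic site by a
17–20-nt single guide RNA (sgRNA). Cleavage requires a protospacer
complementary to the guide and a 3-nt protospacer-adjacent motif (PAM,
canonically NGG, with NAG tolerated) immediately 3′ of it. Sites with
partial complementarity can still be cut (off-targets), which is the
central safety concern of plant genome editing. `cleavesite` frames
off-target identification as binary classification: given an
(sgRNA, candidate site) pair, predict whether the site behaves as the
intended cleavage site (label 1) or as an off-target (label 0), using
only sequence-derived features plus optional genomic-context
annotations.

The package reproduces a published benchmark design for plant systems:
a curated corpus of 51 sgRNAs with 174 on-target and 205 off-target
sites across 15 crops (379 labeled pairs), thirty features in three
blocks, eleven classifier configurations evaluated by eight metrics on
a 70/30 holdout and under 5-fold cross-validation, and a TOPSIS
multi-criteria ranking of the models. The curated corpus itself is not
redistributable, so a synthetic generator with the same per-crop counts
is the test substrate; consequences of that substitution are discussed
below.

## Alignment model

The guide (U→T transliterated) is aligned to the candidate protospacer
by global Needleman–Wunsch with a linear gap penalty. Defaults: match
+1, mismatch −1, gap −2, all configurable and recorded in run
metadata; the published study never states its scheme, so these are
declared defaults of this implementation, not claims about the original
program. Traceback ties resolve deterministically (diagonal over
gap-in-site over gap-in-guide), so every pair has a unique alignment.

Columns are classified as MATCH, RR (purine–purine), YY
(pyrimidine–pyrimidine), TV (transversion), RNA_BULGE (gap in the site
row: an unpaired guide base) or DNA_BULGE (gap in the guide row).
Wobble pairing — guide G over site A (rG:dT against the target strand)
or guide T over site C (rU:dG) — is a flag on top of the column's
RR/YY class: wobble columns are counted both in `wobble_total` and in
their `rr_total`/`yy_total`, because the feature registry lists the
three counts as separate features; the overlap is accepted and
documented rather than reapportioned.

Guide positions are numbered 1 at the PAM-distal 5′ end. "Positions
17–20" always means the four PAM-proximal bases (the seed region,
where mismatches most strongly abolish cleavage); for a 17-nt guide
that is positions 14–17. At featurization an alignment with more than
2 total bulges is rejected — larger indel structures are outside the
CRISPR off-target regime; the cap is configurable.

## Feature registry

Thirty named features in three blocks (9 alignment, 12 nucleotide
content, 9 PAM), expanded to a fixed 72-column matrix by one-hot
encoding of the categorical features (single nucleotides: 4 levels;
the position-4–5 dinucleotide: 16; PAM type: NGG/NAG/OTHER). Downstream
bases past a short context expand to an all-zero group plus a
missingness flag, never an imputed base; one extra column flags a
truncated extended window. The registry order is stable and equals the
feature-matrix header; a machine-readable manifest (name, block, type,
encoding) is emitted next to every matrix.

Numeric choices:

* **GC content (extended)** — (G+C)/(A+C+G+T) over the extended
  window; N excluded from numerator and denominator.
* **DNA enthalpy (extended 223 nt)** — nearest-neighbor duplex ΔH°:
  the sum over adjacent dinucleotide stacks of the SantaLucia (1998)
  unified parameters (kcal/mol), shipped as a versioned data file and
  swappable via configuration. Windows containing N are summed over
  their maximal N-free runs (equivalent to truncating at the N, which
  only arises as edge padding here), with a warning. Additivity
  (ΔH(xyz) = ΔH(xy) + ΔH(yz)) holds exactly and is property-tested
  over all 64 trinucleotides.
* **Extended window** — 223 nt centered symmetrically-as-possible on
  the protospacer+PAM; shorter contexts are used whole and flagged.
  The published study names the window length but not its anchor.
* **Annotation features** (DHS signal, nucleosome distance, guanine
  occupancy, minor groove width at the PAM pentamer, exon /
  transcription / coding flags, strand expression) come from a
  pluggable provider. The default provider returns documented neutral
  values (0 for every signal and flag) so the pipeline runs on
  sequence alone; a file-backed provider serves per-site values from a
  tab-delimited track table. No MGW pentamer table ships with the
  package, so the default MGW is the neutral 0.0.

## Synthetic data generator

The generator is first-class, tested code, not a fixture. Defaults are
the emulated study conditions:

* per-crop guide/site counts of the curated corpus (51/174/205 over 15
  crops; the published per-crop table's on-target column is internally
  inconsistent with its own printed total, and the totals are what
  every downstream count depends on — the maize on-target entry is
  taken as 21 so the column sums to 174);
* guides: uniform-random ACGT, lengths 17–20;
* on-targets: exact protospacer match, NGG PAM, 223-nt context;
* off-targets: k substitutions with k drawn from a declared
  distribution over 1..6 (mass 0.15/0.25/0.25/0.20/0.10/0.05), placed
  with seed-region positions down-weighted 4× (observed off-targets
  are depleted in seed mismatches); a 1-nt bulge with probability 0.1;
  NAG PAM with probability 0.2. A bulged protospacer whose optimal
  alignment re-registers as more than 2 gaps is redrawn.

The mismatch-count distribution and the realism knobs are declared
assumptions — the published study does not describe its sites'
mismatch statistics. One RNG stream, seeded once, drives the whole
dataset; generation is byte-reproducible.

**What passing tests do and do not show.** Because every label-1 site
aligns perfectly and every label-0 site carries at least one lesion,
the synthetic classes are separable almost by construction; the
random-forest holdout AUC ≳ 0.99 here says the pipeline is wired
correctly (features carry the construction signal, no leakage), not
that any model would reach such numbers on curated experimental data,
where on/off status is an experimental outcome rather than a sequence
identity. The generator also does not emulate real annotation tracks
(all annotation features are neutral constants in synthetic runs, so
those twelve columns are inert), nor sequence composition biases of
real genomes.

## Models

Eleven fixed configurations — no hyperparameter search:

| id | family | details |
|----|--------|---------|
| ANN1-{Logistic,Tanh,ReLU} | MLP | hidden layers (25, 25, 25) |
| ANN2-{Logistic,Tanh,ReLU} | MLP | hidden layers (30, 20, 10, 5) |
| SVM-{Linear,Polynomial,Gaussian,Sigmoid} | SVC | C = 1.0, γ = "scale", degree 3 for polynomial |
| RF | random forest | 100 trees, Gini, bootstrap |

MLPs use Adam, initial learning rate 0.001, at most 1000 epochs, early
stopping on a 10% validation split with tolerance 1e-4 and patience
400 epochs. The long patience is deliberate: on a 27-row validation
split the accuracy signal moves in ~4-point steps and can plateau for
hundreds of epochs while the loss still improves; short patience
intermittently collapses the logistic-activation nets to the majority
class. SVM scores are probability-like values from Platt-style sigmoid
calibration fitted on training folds; AUC is invariant to that
monotone mapping. Continuous features are standardized for the ANN and
SVM families (fitted on the training portion only — verified by a
leakage probe in the test suite); the forest sees raw features.
Classification threshold is 0.5 on the predicted score; AUC uses raw
scores. Every fit is deterministic under its seed.

The published tables do not state whether they report holdout metrics,
CV means, or pooled CV predictions; this pipeline computes both the
70/30 holdout surface and the per-fold + mean CV surface and labels
them distinctly.

## Evaluation metrics

Accuracy, precision, recall, FPR, specificity (= 100 − FPR, exact),
F1, F2 (F-beta with β = 1, 2: (1+β²)PR/(β²P+R)), and AUC, reported as
percentages to 2 decimals with full-precision internals. A ratio with
a zero denominator is reported as missing with a warning, never
silently 0. ROC thresholds sweep the distinct score values with ties
grouped, so the trapezoidal AUC equals the Mann–Whitney rank statistic
with tie correction (property-tested against explicit pair counting).

## TOPSIS ranking

Models × metrics form the decision matrix (percentage scale, FPR as
the sole cost criterion, equal weights 1/8 by default). The default
variant is classical Hwang–Yoon TOPSIS: vector normalization
x/‖x‖₂, weighting, ideal/anti-ideal per column, Euclidean distances,
closeness C = S⁻/(S⁺+S⁻), descending rank with deterministic id
tie-break.

Two further normalizations are exposed. `minmax` rescales each column
to [0, 1]. `rank` replaces each column by within-column dense ranks
(direction-aware, best = 1) and applies the classical steps to the
rank matrix; this makes the result invariant to any monotone
per-criterion rescaling. The reference benchmark shipped with the
package is the reason `rank` exists: the published closeness column
for the eleven models is not reproduced by the classical continuous
variants under any weighting we probed (best achievable maximum
deviation ≈ 0.23 even optimizing weights freely), while the
rank-transform variant reproduces the complete published ordering
exactly and the closeness scores to a maximum deviation of 0.022.
The acceptance script sweeps normalization × FPR direction and reports
the variant closest to the published column, which is `rank`. The
published prose score for the top ANN (0.85134) also conflicts with
the published table (0.789202); the table is taken as canonical.

## Pipeline and reproducibility

`run_all` (or the `cleavesite` CLI: `simulate | featurize | train |
evaluate | rank | run`) writes a run directory containing the dataset
(FASTA + CSV + profile manifest), the feature matrix and registry
manifest, the train/test split, eleven fitted models, CV and holdout
metric tables, the TOPSIS table, and a manifest with all derived
seeds. One global seed fans out to per-stage seeds through
`SeedSequence([seed, crc32(stage)])`, so chained subcommands reproduce
`run_all` byte-for-byte and any stage can be re-run alone.
Coordinates are 0-based half-open internally; human-readable reports
use 1-based inclusive positions. The train size is
floor(fraction × N), which maps 379 records at 0.7 to the 265/114
split the benchmark design prescribes. Splitting is by site record;
a `group_by_guide` option keeps all sites of a guide together but is
off by default, matching the benchmark's random division.

For ranking only, a metric left undefined by a collapsed classifier
(e.g. precision when nothing is predicted positive) is scored as the
worst observed value of that criterion; the metric tables themselves
keep the cell empty.

## Known limitations

* Synthetic labels are construction artifacts; absolute performance
  numbers on synthetic runs do not transfer to curated data.
* Annotation features default to neutral constants; with the default
  provider they contribute nothing to the models.
* The alignment scoring scheme, wobble convention and position
  numbering are declared defaults — the published study left them
  unspecified.
* No affine gaps, no local alignment, no genome-wide site scanning:
  candidate sites are inputs, as in the benchmark design.
* Property tests size their simulations for a single CPU (e.g. 10,000
  off-target draws for the seed-bias check, 5 label permutations for
  the null band); these sizes are stated in the tests themselves.
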