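# cleavesite

Machine-learning benchmark pipeline for CRISPR-Cas9 cleavage-site
classification in plant genomes: does a candidate genomic site behave
as the intended (on-target) cleavage site of a given sgRNA, or as an
off-target?

`cleavesite` is aimed at plant genome-editing researchers who want a
reproducible, end-to-end harness for comparing classical classifiers
on sgRNA/target-site data. It implements:

* **Feature extraction** — global guide/protospacer alignment with
  1-nt RNA/DNA bulge support and per-column mismatch typing (wobble,
  transversion, purine–purine, pyrimidine–pyrimidine); seed-region
  (positions 17–20) mismatch counts; nucleotide-content features
  including GC content and nearest-neighbor DNA enthalpy
  (ΔH° = Σ stacks, SantaLucia 1998 unified parameters) over a 223-nt
  context window; PAM features (NGG/NAG/other, PAM N, downstream
  bases); and a pluggable genomic-annotation interface — thirty
  registry features in all.
* **A model suite** — eleven fixed configurations (six MLPs, four
  SVMs, one random forest) trained on a 70/30 split with 5-fold
  cross-validation.
* **Evaluation** — accuracy, precision, recall, FPR, specificity, F1,
  F2 and AUC per model, on both the holdout and CV surfaces.
* **TOPSIS ranking** — multi-criteria ordering of the models by
  closeness C = S⁻/(S⁺+S⁻) to the ideal point in weighted normalized
  metric space (FPR as cost, equal weights), with vector, min–max and
  rank-transform normalizations.
* **A synthetic-data generator** emulating the curated plant corpus
  the benchmark design is based on (51 sgRNAs, 174 on-targets, 205
  off-targets across 15 crops), so the whole pipeline runs without any
  download.

See `docs/methods.md` for the model, its assumptions, and what results
on synthetic data do and do not mean.

## Worked example

Run the whole study on synthetic data:

```
$ cleavesite run -o demo --seed 1
run complete: demo
```

`demo/metrics_holdout.csv` then holds the eight metrics per model on
the 114-site holdout (here the random-forest row):

```
model,surface,accuracy,precision,recall,fpr,specificity,f1,f2,auc
RF,holdout,100.0,100.0,100.0,0.0,100.0,100.0,100.0,100.0
```

and `demo/topsis.csv` the multi-criteria ranking (top rows):

```
model,score,rank
RF,1.0,1
SVM-Linear,0.9094118122041744,2
SVM-Sigmoid,0.9094118122041744,3
```

The forest separates the synthetic classes perfectly because synthetic
labels are sequence-construction artifacts (every on-target aligns
with zero lesions); this demonstrates pipeline correctness, not
expected performance on curated experimental data. The same run can be
reproduced stage by stage:

```
cleavesite simulate -o demo --seed 1     # guides.fasta, sites.csv, profile.json
cleavesite featurize -o demo             # features.csv (72 columns), registry.json
cleavesite train -o demo --seed 1        # split.csv, models/, metrics_cv.csv
cleavesite evaluate -o demo --seed 1     # metrics_holdout.csv
cleavesite rank -o demo                  # topsis.csv
```

Library use mirrors the CLI:

```python
import cleavesite as cs

aln = cs.align_guide_to_site("GGCAGTGACGTTACAGGAAC", "GGCAGTAACGTTACAGGAAC")
aln.counts["mismatches"]        # 1 (a G:A wobble-flagged purine-purine pair)

cs.f_beta(0.9475, 0.9856, 2)    # 0.9777... -> F2 = 97.77%
```

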