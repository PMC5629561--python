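# splicemod

Infer which alternatively spliced exons act as **modulators** of
transcription-factor (TF) activity from bulk RNA-seq cohorts.

Alternative splicing can rewire a regulator without changing its
expression level: an exon skipped in one isoform of a co-factor (say, an
MDM2 exon affecting its interaction with the glucocorticoid receptor) can
strengthen, weaken, or invert the TF's effect on its targets. splicemod
detects this from three plain-text inputs — a gene-expression matrix
(genes × samples), a percent-spliced-in (PSI) matrix of exon-inclusion
fractions (events × samples), and a TF→target pair list — by fitting, for
every (target, TF, event) triplet, the interaction model

    Y'_target = β0 + β1·X'_tf + β2·X'_m + β3·X'_tf·X'_m + ε

on log2(x+1)-transformed expression and logistic-ratio-transformed PSI
(X'_m = log2(X_m/(1−X_m) + 1), PSI clamped to [0.01, 0.99]). A two-sided
t test on the interaction coefficient β3, with Benjamini–Hochberg FDR
correction across the whole scan (significant at q < 0.05), flags the
triplets where exon inclusion modulates TF→target regulation. Significant
triplets are then classified by comparing the TF–target Pearson
correlation between the bottom-30% and top-30% PSI samples
(Active / Repress / Inverts modes of action), and aggregated into a
bipartite TF–modulator network weighted by the percentage of each TF's
tested targets the event influences, optionally restricted to pairs with
documented protein–protein interaction.

It is aimed at computational biologists with a processed expression
table, MISO/rMATS-style PSI estimates, and ENCODE/ChIP-derived TF–target
pairs in hand. See `docs/methods.md` for the full model, preprocessing
rules, and limitations.

## Worked example

The package ships a simulator that writes cohorts with known ground
truth, so the whole pipeline can be exercised without external data:

```sh
splicemod simulate --seed 7 --n-samples 480 --n-tfs 3 --n-targets-per-tf 10 \
    --n-events 2 --frac-modulated 0.3 --beta3-effect 1.5 --out-dir demo
splicemod scan --expr demo/expression.tsv --psi demo/psi.tsv \
    --pairs demo/pairs.tsv --out demo/triplets.tsv
splicemod classify --triplets demo/triplets.tsv --expr demo/expression.tsv \
    --psi demo/psi.tsv --out demo/modes.tsv
splicemod network --triplets demo/triplets.tsv --psi demo/psi.tsv \
    --min-pct 10 --out demo/edges.tsv
```

which prints

```
attempted=60 fit=60 skipped=0 significant=5
          Active  Repress  Inverts  Uncalled
positive       0        5        0         0
negative       0        0        0         0
edges=2 tfs=2 modulators=2
```

Reading: all 60 triplets (30 pairs × 2 events) were fit; 5 passed
q < 0.05, all with β3 > 0 and a same-sign ("Repress"-type) correlation
transition — expected here, since the simulator plants a positive
interaction on top of a positive β1, so the TF–target correlation stays
positive but changes strength between inclusion strata. Two TF–modulator
edges clear the 10% influence threshold:

```
tf      event   gene    n_targets_tested  n_influenced  pct_influenced  ...
TF002   E001    MOD001  10                2             20.0
TF003   E002    MOD002  10                2             20.0
```

i.e. event E001 (hosted in gene MOD001) modulates TF002's regulation of
20% of its tested targets. `demo/truth.tsv` holds the planted β values
for comparison, and `demo/modes.tsv` the per-triplet correlation states.

All subcommands accept `--config config.yaml` with the same keys as the
flags; `splicemod <cmd> --help` lists them.

## Library surface

- `splicemod.io` — TSV readers/writers with validation (expression, PSI
  with optional host-gene column, pair lists, PPI edges, result tables);
  round-trips are bit-exact.
- `splicemod.preprocess` — PSI clamping, the two transforms, per-gene
  mean ± 3·std outlier masks, triplet assembly.
- `splicemod.scan` — `fit_triplet`, `scan_all`, `correct_fdr`.
- `splicemod.classify` — PSI stratification, correlation states,
  mode-of-action calls and the sign × category summary table.
- `splicemod.network` — `summarize_edges`, strict `threshold_network`,
  `filter_ppi`, networkx bipartite export.
- `splicemod.simulate` — cohort and single-triplet generators with
  ground-truth β and planted correlation transitions.

## Acceptance script

`scripts/acceptance.py` re-runs the package end to end: it simulates a
480-sample cohort (4 TFs × 25 targets × 4 events, 25% of triplets
modulated), scans all triplets, applies FDR correction, classifies modes
of action, builds the thresholded network, prints the run's summary
counts, and writes its JSON result object:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
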