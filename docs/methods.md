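# Methods

## Model

splicemod asks, for each ordered triplet (target gene T, transcription
factor TF, alternatively spliced exon M), whether the exon's inclusion
level changes the TF's regulatory effect on the target. With X_tf and
X_target the expression levels, X_m the exon's percent-spliced-in (PSI)
fraction, the working model on transformed variables is

    Y'_target = β0 + β1·X'_tf + β2·X'_m + β3·X'_tf·X'_m + ε,   ε ~ N(0, σ²)

where

    X'_tf     = log2(X_tf + 1)
    Y'_target = log2(X_target + 1)
    X'_m      = log2( X_m / (1 − X_m) + 1 ),  X_m first clamped to [0.01, 0.99]

A non-zero interaction coefficient β3 means the slope of the TF–target
relationship depends on exon inclusion — the event *modulates* the TF.
β3 > 0 is called positive modulation, β3 < 0 negative.

The clamp maps PSI values of exactly 0 to 0.01 and exactly 1 to 0.99 and
leaves interior values untouched, keeping the ratio transform finite; it
is idempotent, and both transforms are strictly increasing on their
domains.

## Preprocessing

- **Outlier filter.** For each gene (TF and target alike) samples whose
  raw expression lies outside mean ± 3·std of that gene's finite values
  are dropped. The std is the sample estimate (ddof = 1); the paper does
  not specify the estimator and the difference is negligible at cohort
  scale, but one choice had to be fixed for reproducibility. Borders are
  computed once per gene over its full finite vector — not re-computed per
  triplet after intersection — which makes the filter deterministic and
  order-independent. A sample is removed if *either* the TF or the target
  value is an outlier.
- **Sample intersection.** A triplet uses the samples with all three
  measurements present that survive both outlier masks.
- **Eligibility floors.** Genes need ≥ `min_samples_gene` (default 400)
  non-missing expression samples, mirroring the source cohort's "over
  400 samples" filter; triplets need ≥ `min_samples_triplet` (default 30)
  retained samples to fit a 4-parameter model stably. Triplets below the
  floor are reported as skipped rows, never silently dropped.

## Fitting and multiple testing

Each eligible triplet is fit by ordinary least squares on the design
[1, x_tf, x_m, x_tf·x_m]. β3 is tested with a two-sided t statistic on
n − 4 degrees of freedom. Rank-deficient designs (e.g. an event whose PSI
is constant across retained samples) are flagged "unfit" with a reason.
Benjamini–Hochberg correction is applied once across all fit triplets of
the scan (pooled over TFs; per-TF correction is available as an option),
and a triplet is significant when q3 < α (default α = 0.05, strict). The
alternative raw-p rule (p3 < 0.01) is exposed as `sig_mode: pvalue`.

## Mode-of-action classification

For each significant triplet, samples are ranked by *raw* PSI (monotone
transforms cannot change the ranking, so raw values are used) and the
bottom and top ⌊f·n⌋ samples form the low- and high-inclusion strata
(default f = 0.30; PSI ties are broken by sample id so the split is
deterministic). Within each stratum the Pearson correlation between the
transformed TF and target expression is called

    '+'  if p < α_corr and r > 0
    '-'  if p < α_corr and r < 0
    'ns' otherwise

and the low→high transition of that state determines the category:

| transition                        | category |
|-----------------------------------|----------|
| exactly one side 'ns'             | Active   |
| same signed state both sides      | Repress (annotated "reduced" when \|r_high\| < \|r_low\|) |
| '+'→'-' or '-'→'+'                | Inverts  |
| 'ns'→'ns'                         | Uncalled (outside the three categories) |

α_corr defaults to 0.05 but is the least-constrained parameter of the
whole procedure — the source analysis never states how "no correlation"
was decided — and is prominently configurable. Note an inherent ceiling:
a stratum whose true correlation is exactly zero is called 'ns' with
probability 1 − α_corr, so no classifier of this form can recover
'ns'-sided transitions more often than that. The recovery benchmarks in
the test suite therefore call states at α_corr = 0.01.

## Network aggregation

For every (TF, event) pair the percent influenced is
100 × (significant triplets) / (fit triplets) over that TF's targets —
skipped/unfit triplets are excluded from the denominator, a deliberate
reading of the ambiguous "percentage of targets of individual TFs".
Edges are kept when the percentage *strictly* exceeds the threshold
(default 30, matching "more than 30%"; 10/20/25 are useful presets).
Protein-interaction filtering marks an edge supported when the unordered
pair (TF, event host gene) appears in the supplied edge list; it never
alters percentages, only membership/flags.

## Synthetic cohorts

`simulate_dataset` emulates a tumor RNA-seq cohort at the scale the
method expects: 480 samples, log2-scale expression with gene-specific
means (~N(8, 1)) and gene-specific sd drawn around 2, Beta(2, 2)
exon-inclusion fractions, unit Gaussian noise on the transformed scale,
and 5% missingness. Each target's transformed expression is generated
from the model equation using exactly one "driver" event, so every
triplet pairing it with another event is a true null; ground-truth β
coefficients are defined on the transformed scale used in fitting.
Expression is back-transformed to the raw scale as 2^x − 1 (floored at 0,
hit with probability ~3e-5 at the defaults) so the pipeline's log2(x + 1)
inverts the generator exactly. All draws flow from one numpy Generator
seeded by a single integer, in documented order, so equal configs give
bit-identical outputs.

`simulate_transition_triplet` plants a correlation-state transition: the
low-PSI half of the cohort gets inclusion ~U(0.02, 0.45) and TF–target
correlation r_low, the high half ~U(0.55, 0.98) and r_high, with 'ns'
encoded as r = 0 and same-sign (Repress) transitions using a halved
magnitude on the high side.

What the generator does **not** emulate: read-level count noise or PSI
estimation uncertainty, correlated co-expression structure among targets,
batch effects, tumor purity, or survival-linked event selection. A green
recovery test therefore establishes correctness of the estimator and the
bookkeeping under the model's own assumptions, not robustness to
real-data violations of them.

## Numerical choices

- OLS via `numpy.linalg.lstsq` with a relative singular-value cutoff of
  1e-10; rank < 4 ⇒ "unfit". Standard errors from σ̂²·(XᵀX)⁻¹ with
  σ̂² = RSS/(n − 4). A perfect fit (se3 = 0) reports p3 = 0 when β3 ≠ 0
  and p3 = 1 otherwise rather than dividing by zero.
- Zero-variance vectors in a correlation stratum yield state 'ns' with r
  recorded as NaN.
- Floats are serialized with Python's shortest round-tripping repr, so
  every written table re-reads bit-exactly; missing values are "NA".
- Outputs are emitted in sorted (tf, target, event) order, making the
  whole pipeline byte-deterministic for a fixed seed and config.

## Known limitations

- The mode-of-action categories condition on the β3 test's significance;
  the correlation-state procedure is descriptive and its α_corr has no
  multiplicity correction (matching the source procedure).
- Outlier borders are computed before per-triplet intersection; a gene
  whose expression is missing in most samples can keep borders driven by
  few observations (the `min_samples_gene` floor guards the realistic
  regime).
- Percent-influenced denominators depend on which triplets were testable,
  so cohorts with heavy missingness can make percentages incomparable
  across TFs.
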