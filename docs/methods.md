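# Methods

## The bridging model

For each protein, serum and plasma log2(RFU) measurements across matched
(patient, timepoint) pairs are modelled as linearly related:

    plasma = slope · serum + intercept + ε,    ε ~ N(0, σ²)

Slope and intercept are estimated per protein by ordinary least squares of
plasma (response) on serum (predictor), using the closed-form
covariance/variance solution; no regularization is applied. A serum
measurement is mapped to its plasma equivalent by
`scaled = value·slope + intercept`. The model is deliberately minimal: a
two-parameter line per protein needs few pairs, cannot overfit much, and the
dominant serum–plasma differences (multiplicative offsets and systematic
shifts on the log scale) are affine. Proteins whose serum variance is zero
cannot be fitted and are skipped explicitly — a factor table never contains
silent zero-filled rows.

Assumptions worth stating: pairs are independent observations (a patient
contributing T0 and T1 contributes two pairs; see cross-validation below for
where this matters), residuals are homoskedastic enough for OLS to be
sensible, and the relation is stable across the patients used for fitting.
Monotone but non-linear relations are handled adequately in rank terms but
not in scale terms; the concordance screen (below) is what keeps pathological
proteins out of the factor set.

## Protein selection

Bridgeability is screened with Spearman correlation per protein across
pairs, two-sided p-values, and Benjamini–Hochberg adjustment across
proteins; the default screen keeps q < 0.05. Spearman rather than Pearson:
proteins compressed near the assay's limit of detection (LOD) produce a
cloud of noise plus a few far-from-floor values that agree well between
specimens — those few points inflate Pearson while ranks stay uninformative,
so Pearson systematically overstates bridgeability for floor-limited
analytes. With many pairs the q < 0.05 cut corresponds to a weak correlation,
so `select_proteins` exposes an `r_floor` to demand a minimum Spearman r on
top of significance. Spearman p-values use the exact permutation null for
n ≤ 9 untied pairs and the t approximation otherwise.

`lod_inflation_diagnostic` makes the LOD mechanism visible: per protein it
reports the gap Pearson r − Spearman r alongside a distance-from-floor
statistic, defined as the median log2 value minus the 1st-percentile value
of that protein across all samples of both specimens. Floor-compressed
proteins sit at small distances with large gaps, so the two columns rank-
anticorrelate. The 1st-percentile floor proxy is a package convention —
assay-reported detection limits, where available, are the better anchor.

Plasma-to-serum ratios are computed on the raw RFU scale (median over pairs
of plasma/serum per protein) and classified by the 1.5·IQR rule applied to
log2 of the median ratio, so the plasma-retained (~100×) and
serum-accumulated (~0.01×) coagulation tails are treated symmetrically.
Panel enrichment of a selection uses the two-sided Fisher exact test with BH
adjustment across panels (default FDR 0.1).

## Outlier machinery and normalization

All outlier decisions share one primitive: lower = Q1 − m·(Q3 − Q1),
upper = Q3 + m·(Q3 − Q1), default m = 1.5, with quartiles computed by linear
interpolation between order statistics. The interpolation convention is a
config knob because the thresholds depend on it; values strictly beyond a
threshold are outliers, so a zero-IQR (constant) distribution flags nothing.

Two per-protein normalizations are provided. **Iterative scaling** is
z-score standardization with outlier handling: standardize, exclude values
with |z| > 4 (the bound is configurable), re-standardize, repeat until no
new outliers (the excluded set grows monotonically, so at most n iterations;
a hard cap of 50 guards adversarial input), then impute excluded values to
exactly ±4 in units of the final outlier-excluded distribution. **Robust
scaling** is (x − median)/IQR and preserves extreme values; it exists to
check that conclusions do not hinge on outlier imputation. Zero-variance or
fully-degenerate proteins are zeroed and flagged rather than erroring,
because multiplexed panels routinely contain dead analytes and a pipeline
must proceed past them. Sample standard deviation (ddof = 1) is the default
throughout, switchable in config.

## QC checkpoints

**Assay QC.** Samples with a per-sample normalization scale factor outside
[0.4, 2.5] (inclusive at both ends) are excluded; a pair is excluded when
either member fails. A missing factor is flagged, not excluded.

**Pairing QC.** Within each specimen, proteins are z-scored (pooled across
cohorts — a per-cohort switch exists); each pair's Pearson correlation is
computed over a biomarker panel (all proteins when no panel is given —
supplying a curated panel is recommended, since LOD-floored analytes add
pure noise to pair correlations). Pairs below the lower IQR bound of the
correlation distribution are excluded. If the median correlation falls below
0.2 the run halts: bridging unmatched samples is meaningless.

**Contamination QC.** Iterative-scaling moments (outlier-robust mean/sd per
protein) are fitted on an external reference of the same specimen type;
screened samples' marker-panel proteins are standardized with those moments,
clipped at ±4 (mirroring the imputation rule), and averaged into one score
per sample and panel — a sample spiked by δ reference-sds scores ≈ δ.
A cohort is flagged when its median score exceeds the IQR upper bound of the
per-sample scores pooled over the *other* cohorts. The leave-one-out form is
deliberate: an upper bound computed across the cohort medians themselves can
never flag anything with three cohorts, because the extreme median inflates
Q3 and the IQR enough to cover itself — with two clean cohorts near zero and
one at +s, the bound lands at ~1.25·s. Testing each cohort against the
pooled score distribution of the remaining cohorts keeps the rule
reproducible and well defined for ≥2 cohorts.

**Generalizability QC.** Per-protein medians of a cohort and an external
reference are compared: IQR outliers of the difference distribution identify
proteins that will not transfer, and Pearson/Spearman of the median vectors
summarize overall agreement. The verdict flags when the outlier tail exceeds
5% of proteins or Spearman falls below 0.8 (both configurable — published
analyses of this kind judge the scatter visually, so a reproducible rule has
to pick thresholds). A uniform global offset shifts every difference equally,
flags no protein, and is reported as a note.

**Bridging QC.** After scaling: (i) the mutual-nearest-neighbour fraction —
on per-protein z-scores of the combined sample set, the fraction of pairs
where each member is the other's closest cross-specimen sample; (ii) the
adjusted Rand index between a 2-cluster Ward cut and the specimen labels
(high before scaling, near zero after successful scaling); (iii) when a
predictor is plugged in, agreement between its outputs on plasma vs scaled
serum: unity-line R² = 1 − Σ(y−x)²/Σ(y−ȳ)² with plasma as reference y
(negative when bias exceeds the spread), fitted-line r² = squared Pearson
correlation, and class agreement at a threshold with a two-sided Fisher
exact p. R² < r² with high r² is the signature of an affine bias —
correctable by re-calibration — whereas low r² means lost signal.

## Cross-validation and the negative control

When factors are applied to the same cohort they were fitted on, a k-fold
(default k = 5) cross-validation is used with **patient-grouped** folds: all
pairs of one patient stay in one fold, so a patient's T0 pair can never
inform the scaling of its own T1 sample. The deliverable is the concatenated
out-of-fold scaled matrix — every pair scaled exactly once by factors fitted
without it — rather than averaged factors.

The negative control rebuilds the paired dataset with a seeded
**derangement** of the plasma side (no pair keeps its mate; a uniform random
permutation could preserve pairs by chance, which would dilute the null).
On exchangeable data the control's slopes center on 0 and its intercepts on
the per-protein plasma mean — the fingerprint that distinguishes genuine
protein-wise signal from structure-free noise.

## The synthetic-data generator

`generate_cohorts` emulates the features of matched-pair RFU data that the
pipeline must detect, with every parameter seeded and configurable:

- **Baselines** log2-normal with mean 8, sd 2 across proteins — a typical
  multiplexed-assay dynamic range.
- **Patient effects** from 25 equal-strength latent factors with per-protein
  Gaussian loadings totalling sd 1.0 per protein (inter-patient biological
  variation dominating technical noise, as it must for any biomarker assay
  to be useful). Factor vectors have fixed norm with an optional bounded
  Uniform amplitude. Two deliberate choices here: a multi-factor structure
  makes the leading principal components carry structured, pair-shared
  variance (as real proteomes do) instead of white noise, and the bounded
  amplitude keeps derived per-pair statistics short-tailed, which is what
  makes self-referential IQR cuts behave the way they do on real cohorts.
- **The linear law**: plasma = slope·serum + intercept + independent noise,
  slopes ~ N(1, 0.1), intercepts ~ N(0, 0.3), noise sd 0.3 by default with a
  bounded per-sample quality multiplier (Uniform ±40%) emulating variable
  sample handling. The law acts on the serum *measurement*, so OLS of plasma
  on serum recovers the planted slope exactly in expectation; generating
  plasma from a latent noise-free signal instead would attenuate every
  fitted slope by σ²_signal/(σ²_signal+σ²_noise) and the generator's own
  recovery guarantees could not hold.
- **LOD proteins** (5%): both specimens collapse onto a noisy floor
  (baseline − 1, half-normal noise sd 0.15), destroying rank correlation —
  the mechanism behind floor-limited analytes failing the screen.
- **Coagulation extremes** (2%, split between tails): intercepts adjusted to
  place the plasma–serum offset at ±log2(100), producing ~100× and ~0.01×
  ratio tails.
- **Contamination**: in one flagged cohort (the last of ≥3 by default), the
  marker-panel proteins of every plasma sample are spiked by 1.5 clean-sd
  units.
- **Cohort shifts**: per-protein offsets with sd 0.2 — weaker than the
  specimen difference, so cohorts sub-cluster inside specimen clusters.
- **Longitudinal T1 re-samples** (20% of patients): the patient factor
  vector is perturbed at half strength, so within-patient correlation across
  timepoints exceeds between-patient correlation.
- **Mismatch injection**: optional pairs whose plasma is regenerated from a
  fresh patient effect, with truth flags, as planted faults for pairing QC.

What the generator does *not* emulate: analyte-specific dilution groups or
calibrator chemistry, heteroskedastic protein-specific technical CVs,
non-linear saturation, missing values (real matrices from this assay class
are complete), or real biological covariance structure beyond the latent
factors. Passing tests therefore demonstrate that the machinery recovers
planted structure under realistic magnitudes — not that any particular real
cohort will pass QC.

## Verification scenarios and problem sizes

The acceptance script runs desk-scale problems chosen to keep the whole
recomputation within a couple of minutes while leaving Monte-Carlo margins
far from the asserted tolerances: 1000 proteins for the OLS oracle; 500
proteins × 50 pairs for parameter recovery (homoskedastic noise, matching
the OLS sampling-variance formula being checked); 500 proteins × 100 pairs
with per-protein-independent patient effects for the mismatched null
(exchangeability makes the 500 slope estimates effectively independent, so
their mean concentrates); 2000 proteins × 50 pairs × 3 seeds for the null
calibration of the Spearman screen; 100 seeded replicates for the
contamination flag rate; 10,000 fuzzed vector pairs for the agreement
inequality; and a 2-cohort, 300-protein, 40-pairs-per-cohort bridging run at
noise 0.2 with patient-effect sd 1.5 — the regime where a downstream
predictor is meaningful — and a 40-protein surrogate panel.

The surrogate predictor is a frozen linear score on standardized panel
proteins through a logistic link. Its weights are a fixed positive mean
(0.25 by default; 0.38 in the bridging scenario) plus mean-centered Gaussian
heterogeneity, so the per-panel weight *sum* — and with it the score's
response to a uniform input shift — is a design constant rather than a draw.
The positive mean mimics a risk panel dominated by up-regulated markers and
gives intercept biases a consistent direction, as observed for
contamination-biased factor sets. Standardization centers/scales are fitted
once on a reference matrix and frozen; a predictor that re-standardized its
input per dataset would silently absorb exactly the biases bridging QC
exists to detect.

## Numerical conventions and degenerate inputs

Quartiles: linear interpolation (numpy's default), configurable. z-scores:
ddof 1. Matrices must be complete; missing cells are hard errors naming the
offending (sample, protein). Raw RFU must be strictly positive; log2 is
applied without pseudocount. Factor tables are written with 9 significant
digits; matrix TSVs at full float precision so write→read is the identity.
Constant columns: zeroed and flagged in transforms, skipped in fitting,
NaN-with-flag in concordance. Fisher tables with empty margins fall back to
p = 1. The logistic link clips at 1e-12 from either end so probabilities
remain in the open interval in floating point. All randomness flows through
explicit integer seeds; identical seeds give bit-identical outputs,
including pipeline artifacts.

## Known limitations

- Factors are estimated protein-by-protein; no information sharing across
  proteins (deliberate — mirrors the minimal model — but noisy for small
  pair counts).
- The serum→plasma direction is fixed; the reverse mapping is obtained by
  swapping inputs, not by inverting fitted factors.
- Survival-based validation of downstream predictors is out of scope; the
  bridging verdict is agreement- and clustering-based.
- Panel enrichment is restricted to user-supplied panels; no external
  annotation databases are consulted.
- The pairing-QC halt rule (median pair correlation < 0.2) and the
  generalizability thresholds encode judgment calls that published work
  makes by eye; both are exposed in `BridgeConfig`.
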