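# Methods

This note documents the models, parameter choices and numerical conventions
behind `pulseprot`, and what the synthetic-data generator does and does not
emulate.

## Quantification model and missing data

A pSILAC sample yields, per protein, three channel intensities (L
pre-existing, M control synthesis, H stimulated synthesis), the H/M and M/L
ratios and their peptide ratio counts. Zero intensities in input tables are
treated as non-detection and mapped to missing — MS intensity zero almost
always means "not sampled", not "absent" — and a ratio is considered missing
whenever either parent channel is missing. No imputation is performed
anywhere in the pipeline. Contaminant and reverse-decoy rows are removed at
parse time in the MaxQuant dialect (via its `+` flag columns); the
long-format dialect is assumed clean. All tables are UTF-8 TSV with `.`
decimals; floats are written with 12 significant digits so write/read round
trips are lossless.

## Basal incorporation

The per-protein incorporation fraction is M/(M+L), computed over cells where
both channels were measured, and the per-minute rate divides by the sample's
pulse duration. Because the observed ~1.4% could denote either the raw
5-minute fraction or a per-minute figure, the module reports **both**
medians, explicitly labelled, rather than guessing. A protein counts as a
detected NSP in a sample when its M intensity is present. Abundance
correlations use natural logs (the base does not affect a correlation
coefficient); a perfectly constant margin (e.g. exactly constant M/L) is
reported as correlation 0 rather than the undefined coefficient.

## Differential pipeline

Per (cue, modulator, pulse) condition:

1. ratios with peptide ratio count < 2 are dropped (quantification
   reliability floor), log2-transformed and median-centered per sample; the
   per-sample offsets are kept for audit;
2. consistency filter: quantified in > 50% of replicates (strict), replicate
   SD ≤ 1 (n−1 denominator over quantified replicates), |mean| > 0.3
   (strict). Proteins with fewer than two quantified replicates have no SD
   and are never consistent (flagged, not silently dropped);
3. the consistent set is tested against zero with the empirical-Bayes
   moderated one-sample t-test and BH-adjusted within the tested set.
   Testing only the filtered set mirrors the standard workflow in which
   filtered NSP changes are "subjected to further statistical analysis";
   note that conditioning on |mean| > 0.3 makes the q-values conditional
   quantities — calibration claims (type-I error, FDR) therefore refer to
   the unfiltered moderated test, which `moderated_test` exposes directly.

**Variance prior estimation.** Under the hierarchical scaled-χ² model,
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean log s₀² − ψ(d₀/2) + log(d₀/2)
and variance ψ′(d_g/2) + ψ′(d₀/2). The prior df solves
ψ′(d₀/2) = var(e) − mean(ψ′(d_g/2)) by bracketed root finding on the
strictly decreasing trigamma (Brent, xtol 1e-12); s₀² then follows from the
mean equation. Non-positive variance excess (observed variances no more
dispersed than sampling alone explains) yields the infinite-prior branch:
every posterior variance equals exp(mean(e)) and test statistics use normal
tails. d₀ above 1e6 is reported as infinite to avoid overflow in the
inversion. d₀ = 0 reduces exactly to the ordinary one-sample t. The
implementation agrees with `limma::eBayes` (intercept-only design) to
machine precision on a frozen fixture with missing values; limma serves as
an independent cross-check there, never as the implementation.

**BH adjustment.** q_(i) = min_{j≥i} p_(j)·m/j capped at 1, stable sort, so
tied p receive equal q; verified against a brute-force O(m²) oracle and
against `statsmodels.multipletests`.

## Signatures and set logic

Time-averaged cue profiles are unweighted means over available time points
(missing time points are left out, not zero-filled). Signed regulated sets
require the consistency flag and |mean| > 0.3 strictly. In overlaps,
shared membership additionally requires direction agreement; a sign flip
places the protein in the same intersection region but labels it
"opposite". "Unique per cue" is the exclusive region of one cue's set —
both absent-from-set and unquantified count as "not in" by default (a strict
mode can exclude unquantified proteins via the consistency flags supplied).

The cross-cue partition takes the sample SD of the three per-cue averages:
SD < 0.5 is "common", SD ≥ 0.5 "different"; assignment of the boundary value
to "different" is a documented convention. Proteins missing any cue are
"unassigned".

Condition similarity uses pairwise-complete Pearson correlation (pairs
sharing fewer than 3 proteins are undefined) and SVD-based PCA with
conditions as observations on the complete-protein submatrix — component
scores require a full matrix and we prefer dropping proteins over imputing
them. UPGMA clustering (Euclidean distances, average linkage) runs on
complete rows only, mirroring the desktop tools used for such heatmaps;
dropped rows are returned for logging. The merge sequence is computed by
SciPy's average-linkage implementation; its nearest-neighbor-chain ordering
is deterministic, which replaces the lexicographic tie-break originally
considered (ties are measure-zero for real-valued profiles).

Over-representation uses the one-sided hypergeometric tail P(X ≥ k) with a
minimum category overlap of 3, BH-adjusted across tested categories. An
optional EASE mode (scoring k−1) is provided as a conservative, non-default
variant.

## Switch analysis

"Count > 50%" is read as the replicate-quantification fraction — the same
meaning as the first consistency criterion. Membership in a cue's common
set requires fraction > 0.5 and |average| > 0.30 in both the repulsive and
attractive condition; concordance is pure sign agreement (a zero average is
impossible inside the common set). Aggregate fractions are unweighted means
across cues (each cue counts once, matching "on average among the three cue
stimulations" semantics), alongside the maximum.

## Growth-cone polarity

Pixel coordinates are 0-based pixel centers, (x, y) = (column, row).
Polygons in geometry sidecars are rasterized by point-in-polygon on pixel
centers. The bisection uses the signed half-plane test against the shaft
line; pixels exactly on the line belong to neither half (unbiased under
reflection). Background subtraction applies to the mean-intensity and
near/far measures only; center-of-mass weighting uses raw intensities, and
both centroids are computed over the ROI by default (a whole-image mode
exists behind a flag). With a uniform brightfield the brightfield centroid
reduces to the geometric ROI centroid. The projected shift is signed along
the unit vector from the ROI centroid toward the gradient source: positive
toward the source, so a repulsive redistribution (dimmer near side) is
negative.

## Synthetic-data generator

The pulse simulator emulates the structure of a guidance-cue pSILAC
experiment with explicit ground truth:

* abundance A_g ~ LogNormal(μ = 16, σ = 1.5) in natural-log MS-intensity
  units (a realistic 4–5 decade dynamic range);
* basal incorporation κ_g with median 1.4% per 5-min pulse, log-normal
  protein jitter (σ = 0.5) and slope −0.3 on centered log abundance. The
  construction M₀ = L·κ/(1−κ) makes M/(M+L) = κ exactly, reproducing the
  qualitative structure of real data: NSP intensity correlates positively,
  and M/L negatively, with pre-existing abundance;
* fixed signed effects ±δ for designed fractions π_up/π_down of proteins,
  Gaussian replicate noise (σ_rep = 0.5 log2 units) and small multiplicative
  measurement noise on channel intensities, so H/M = 2^(effect + noise)
  exactly — the fixed-effect, log-normal model the moderated t assumes;
* logistic detection per channel, P(detect) = expit(slope·(ln I − mid)) with
  slope 1 and midpoint 8.5, evaluated at the protein's **expected** channel
  intensity. Missingness is therefore abundance-dependent but ignorable
  given the protein: detection does not condition on the realized replicate
  noise, keeping ratio statistics exactly calibrated under the null. Real
  MS missingness is partially intensity-coupled at the replicate level
  (missing-not-at-random); the generator deliberately does not emulate
  that, so passing calibration tests demonstrate correctness of the
  statistics under ignorable missingness, not robustness to MNAR;
* peptide ratio counts 1 + Poisson with an intensity-dependent rate tied to
  the expected intensity of the dimmer parent channel (ratio counts reflect
  a protein's peptide coverage; ~1% singletons at typical intensities).

One master seed drives everything; per-stream and per-condition substreams
are derived with `numpy.random.SeedSequence.spawn`, so multi-condition
studies share per-protein biology (abundance, κ) while regulation classes
and noise are independent per condition. Fixed seeds give byte-identical
output tables.

The image simulator renders an elliptical ROI centered on half-integer
pixel coordinates so the default 90°-gradient geometry is exactly
mirror-symmetric about the shaft line: symmetric configurations give
near/far ratio 1 and zero centroid shift to machine precision, and
noiseless asymmetry g gives ratio exactly g. It does not emulate real
growth-cone morphology (filopodia, uneven illumination, point-spread blur).

## Problem sizes and defaults

Simulation-based tests and the acceptance script use 1000–3000 proteins,
3–5 replicates and 10–20 seeds per estimate — large enough that binomial
and 3·SE bounds are tight, small enough to run in seconds on one core. The
study-scale runs use 3 replicates (the basal triplicate design) and 5/15/30
min pulses. The significance cutoff defaults to q < 0.05 and is
configurable; the consistency thresholds (0.5, 1.0, 0.3, ratio count 2) are
the standard criteria and are likewise configurable.

## Known limitations

* One-sample designs only: no covariates, no two-sample contrasts, no
  variance-trend modeling.
* The q-values reported for the filtered set are conditional on passing the
  consistency filter (see above); compare conditions via the signature and
  switch modules rather than by thresholding q across conditions.
* Enrichment operates on user-supplied annotation sets; no ontology
  retrieval or semantics.
* ROI tracing is manual (polygon input); there is no segmentation.
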