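# Methods

This note records the statistical and image-analysis procedures implemented in
`senoscreen`, the models behind its synthetic data generators, and the
rationale for default parameter values. Units are given where applicable.

## 1. Viable-cell counting from two-channel fields

Each microscope field carries a nuclear-stain channel and a cell-body
(cytoplasm) channel.

**Nuclear segmentation.** Nuclei are foreground components of an adaptive Otsu
threshold surface. The Otsu threshold is computed as the exact exhaustive
maximizer of between-class variance over a 256-bin histogram of the observed
intensity range; the returned threshold is the center of the optimal cut bin.
The adaptive surface divides the image into 128 px tiles, thresholds each tile,
and bilinearly interpolates tile-center values to a full-resolution surface.
Two guards make this robust on sparse plates:

- *Per-tile clamp* (`threshold_bounds = (0.7, 1.5)` x the global Otsu value):
  a tile containing only background would otherwise drop its threshold to the
  noise floor and emit spurious objects.
- *Minimum class separation* (`min_separation_sigma = 5.0`): a field is called
  empty unless the Otsu foreground mean exceeds the background mean by at least
  5 background standard deviations. On a signal-free channel Otsu merely
  bisects the noise (separation of roughly 1.6 sd for Gaussian noise), whereas
  genuine nuclei at realistic signal-to-noise ratios separate by more than
  20 sd, so the guard rejects empty fields without masking weak signal.

Connected components (8-connectivity) smaller than `min_object_px = 30` pixels
are discarded as debris; the default corresponds to roughly a quarter of the
area of the smallest nucleus the synthetic generator draws.

**Cytoplasm mask and live/dead calling.** The cytoplasm channel is first
illumination-corrected: a 3x3 median filter suppresses shot outliers, the
result is divided by a Gaussian-blur background estimate (sigma = width/8),
and the output is rescaled to preserve the input mean. The mask is then the
minimum-cross-entropy (Li) threshold, again an exact exhaustive optimizer over
a 256-bin histogram, with the same minimum-separation guard (a cytoplasm
channel with no detectable signal yields an empty mask). A nucleus is counted
*live* iff at least 50% of its pixels fall inside the cytoplasm mask; nuclei
failing this are dead cells that survived the wash steps and are excluded. A
well's count is the sum over its fields.

Both threshold primitives are validated bin-for-bin against brute-force
enumeration in the test suite; scikit-image is used for connected-component
labeling and filtering but not for the thresholds themselves.

## 2. Screen statistics

Per-well viable counts are converted to fold changes against the median of the
same-plate DMSO (vehicle) wells, so plate-to-plate scale effects cancel
exactly. Fold changes are averaged over the replicate plates of each
condition. Within each condition x concentration stratum, sample wells are
scored with a robust Z:

    Z = (x - median) / MAD,    MAD = median(|x - median(x)|)  (raw, unscaled)

The raw MAD (no 1.4826 consistency factor) follows the screening convention in
which Z <= -3 anchors a large viability decrease; with the scaled MAD the same
cutoff would be substantially less stringent. A compound is a *hit* iff
Z <= -3 (boundary inclusive) in **both** drug conditions (cisplatin- and
CX-5461-induced senescence) at **either** concentration (1 or 5 uM). The
two-condition intersection is what gives the rule its false-positive control:
well noise is independent across conditions, so background compounds must draw
a deep negative tail twice.

## 3. Dose-response

Viability curves are fit with the four-parameter logistic

    r(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

by Levenberg-Marquardt least squares on log10 dose, parameterizing log10(ic50)
so the search space is unconstrained. Fits with fewer than 4 points are
rejected; rising curves are normalized to `hill > 0, top >= bottom` and
flagged `increasing`. The normalized area under the curve is the trapezoidal
integral of responses (clipped to [0, 1.2]) over log10 dose, divided by the
log-dose span, so 1.0 means no effect and 0.0 complete kill regardless of dose
units. With 4 free parameters and plate noise of sd 0.02, a 10-point 3-fold
serial dilution recovers IC50 with a median relative error just under 5%;
5-point designs cannot reach that bound (the error floor of a 2-free-parameter
fit under the same noise is about 3.3%).

## 4. Expression normalization and differential expression

Counts are converted to log2 counts per million with a 0.5 prior:
`log2((c + 0.5) / (L + 1) * 1e6)`. Optional TMM normalization (trimmed mean of
M-values) follows the edgeR procedure: reference sample = the one whose
upper-quartile is closest to the mean upper-quartile; two-sided trims of 0.30
on M and 0.05 on A; inverse-asymptotic-variance weights; factors scaled to
geometric mean 1. A sample dominated by a few very abundant genes therefore
receives a factor below 1, shrinking its effective library so the deflated
majority genes compare correctly.

Differential expression between treated and control samples uses a vectorized
Welch t-test per gene on log2 CPM (at least 2 samples per group; a gene with
zero variance in both groups gets p = 1), with Benjamini-Hochberg adjustment
(statsmodels). This is deliberately a simple test: the package's contribution
is the signature logic downstream, and the acceptance tests show it recovers
planted programs exactly at realistic depth.

## 5. Signature derivation, scoring and enrichment

The therapy-induced senescence (TIS) signature is the set of genes
significant (adjusted p < alpha, default 0.01; 0.1 available) with a
*consistent sign* of log2 fold change in **all** contrasts
(cell line x drug). Genes missing from any table, or flipping sign, are
excluded; a union-based variant (`require_all=False`) is available.

Samples are scored by standardizing each signature gene across samples
(z-score, ddof = 1; zero-variance genes contribute 0) and taking
mean(z of up genes) - mean(z of down genes). A sample is *signature-high* iff
its score exceeds median + k * MAD (raw MAD, k = 2). This cutoff presumes the
scored cohort is mostly non-senescent (the median must sit in the control
population); in a 50/50 cohort no median-anchored rule can flag half the
samples, so classification is intended for screening a majority-control
cohort for senescent samples.

Recurrent features count, per gene, the contrasts with |fold change| > 1.5
(i.e. |log2 FC| > log2 1.5) in each direction.

Pre-ranked enrichment uses the weighted Kolmogorov-Smirnov running sum
(weight 1 on |statistic|): ES is the signed extremum of the running sum; the
null distribution comes from random gene sets of the same size; NES is ES
divided by the mean |null ES| of the same sign, and the permutation p-value is
`(1 + #{|null| >= |ES|, same sign}) / (1 + n_same)`.

## 6. Synthetic data models

- **Fields.** Nuclei and cytoplasm are Gaussian blobs (sigma = radius/2,
  truncated at 3 sigma; defaults: nucleus radius 6 px, cytoplasm 11 px,
  amplitudes 3000/1500 over background 100), optionally under a linear
  illumination gradient, with Poisson shot noise plus Gaussian read noise
  (sd 10) on a uint16 range. Cell centers are rejection-sampled with a
  minimum separation so ground-truth counts are unambiguous. Dead cells have
  a nucleus but no cytoplasm blob.
- **Screens.** Expected well count = baseline (5000) x plate effect
  (U(0.5, 2.0) per plate) x (1 - kill fraction), with multiplicative
  lognormal well noise of CV 0.15 — a realistic cell-count CV for 384-well
  screens; the kill fraction is 0 for background compounds, 0.95 for planted
  senolytics and 0.85 for positive-control wells.
- **Expression.** Gene baselines are lognormal (ln-mean 4, ln-sd 1) with
  per-cell-line shifts (sd 0.5); planted program genes' baselines are floored
  at the mean + 1 ln-unit (signature genes are robustly expressed; a planted
  gene at the low-expression tail is statistically undetectable at n = 5 by
  any method). Treated samples apply the shared program (log2 FC +4/-4 by
  default), plus private per-line responses on 5% of genes (lfc sd 2) that
  the cross-line intersection must reject. Counts are negative binomial
  (dispersion 0.05) over compositional gene shares with library sizes
  U(4e6, 6e6) — realistic bulk depth at which 2000 genes leave every planted
  gene above shot noise.

## 7. Reproducibility

Every generator takes an explicit seed; derived seeds are drawn below 2^31
from a master `numpy.random.Generator`. Pipeline runs write a JSON manifest
(package version, full configuration, per-stage timing, output list) alongside
their tables, and rerunning a configuration reproduces outputs byte-for-byte.

## 8. Limitations

- Synthetic fields contain well-separated cells; no declumping/watershed is
  implemented, so touching nuclei would merge.
- The DE test is a per-gene Welch t on log-CPM, not a count-model test; it is
  adequate at the planted effect sizes but underpowered for subtle signals.
- The hit rule's false-discovery behavior is quantized when the true hit list
  is small: with 10 true hits, a single false positive yields FDR 1/11, so
  single-realization FDR estimates are coarse.
- TMM is implemented to the edgeR defaults but without the library-size
  special cases for zero-heavy single-cell data.
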