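# Methods

## Composition measurement

**Model.** An axial T2-weighted-like slice is treated as a two-tissue image
inside each segmented muscle region: lean muscle with mean intensity
`mu_muscle` and fat with mean intensity `mu_fat > mu_muscle`, multiplied by
a smooth, strictly positive bias field (coil shading) and perturbed by
additive Gaussian noise. The bias field is modeled as a full 2-D quadratic,
six coefficients over coordinates normalized to `[-1, 1]²` across the image
extent. The multiplicative form is the standard MRI shading model; the
normalized coordinates keep the least-squares design well conditioned
regardless of image size.

**Threshold.** The fat/muscle cut is Otsu's criterion — the threshold that
maximizes between-class variance — computed exactly on the region's sample
values via cumulative sums over the sorted sample, not on a binned
histogram. The returned threshold is the midpoint of the optimal cut, so it
always lies strictly between the sample extremes. A pixel exactly at the
threshold counts as muscle: the classification rule is "above = fat", and
assigning ties to muscle is the conservative choice for a fat-infiltration
measure. Classification is invariant under positive rescaling of the
intensities.

**Coupled bias fit.** The threshold depends on the corrected intensities
and the correction depends on which pixels are lean muscle, so both are
solved by fixed-point iteration per region: (1) split the current corrected
intensities with Otsu's threshold; (2) least-squares fit the quadratic
surface to the *raw* intensities of the muscle-class pixels (lean muscle is
assumed homogeneous, so its raw signal traces the shading); (3) divide the
raw intensities by the fitted surface and repeat. Iteration stops when the
muscle/fat membership is a fixed point or the threshold moves by less than
`1e-6` of the corrected intensity range (default cap 25 iterations; on
bias-free two-class input the loop converges after a single fit). The
fitted surface absorbs the mean muscle intensity — a global scale that
cancels on division. Fits are rejected if the surface is not strictly
positive over the region or the region has fewer than 12 pixels (twice the
coefficient count). Each muscle region is corrected and thresholded
independently, since psoas and paraspinal compartments have different
signal characteristics. A region with a degenerate (single-valued)
intensity histogram is reported as single-tissue with FI = 0 and a warning
rather than an error.

**Areas.** Every pixel belongs wholly to its label. CSA is the pixel count
times the pixel area (mm² → cm² by /100); FAT likewise over fat pixels;
fCSA = CSA − FAT, so CSA = fCSA + FAT holds exactly by construction, also
after bilateral summation and height normalization. Bilateral FI is
area-weighted (ΣFAT/ΣCSA), consistent with applying the FI definition to
the summed areas, and deliberately *not* the mean of the per-side FIs.
Height normalization divides areas by height in metres squared (units
cm²/m²) and leaves FI unchanged; heights outside (1.0, 2.5) m are rejected.

**Cobb angle.** Lordosis is the unsigned angle in [0°, 90°] between the
line through the two L1 superior-endplate landmarks and the line through
the two S1 superior-endplate landmarks, computed from direction vectors and
therefore independent of point order.

## Phantoms

Phantoms exist to give the measurement an exact ground truth. Default
layout: a 128×128 grid at 1×1 mm with four elliptical regions (paraspinal
pair posteriorly, psoas pair anteriorly) — a fixture convention, not
anatomy. Default intensities are `mu_muscle = 100`, `mu_fat = 140`,
arbitrary instrument units; no claim is made that they match any particular
scanner protocol. Fat pixels are placed in deterministic-count mode by
default — exactly `round(f·N)` fat pixels at seeded positions, so the truth
fraction is exact — with a per-pixel Bernoulli mode behind a flag. The
truth mask is recorded before the bias surface and noise are applied. Noise
is additive Gaussian; Rician noise is out of scope. Identical spec and seed
reproduce the phantom bit for bit.

The validation experiments use a single large elliptical region (96×96
grid) with `mu_fat = 130` and a linear shading term of 0.25, giving a 1.5×
max/min intensity ratio *across the region* — enough for the brightest
lean-muscle pixels to overlap the darkest fat pixels, which is the regime
where the correction matters. With the default four-region layout the
shading varies too little within each small region to confuse the
threshold, which is itself an informative property: bias correction earns
its keep on large regions or steep fields.

## Synthetic cohorts

The generator emulates a degenerative lumbar-fusion population of n = 190
(57.9% female) undergoing posterior fusion, with per-sex blocks:

* **Age, BMI** — truncated normal, location = target median (65.6/63.1 y,
  27.8/29.0 kg/m² for women/men), scale = IQR/1.349 (the normal-law
  factor), truncation [18, 95] y and [15, 60] kg/m².
* **Height** — truncated normal (1.62 ± 0.065 m women, 1.76 ± 0.070 m men),
  a population-typical choice; only used as a table column, since areas are
  generated directly on the normalized cm²/m² scale.
* **FI_PPM** — logit-normal, `FI = 100·expit(mu + sigma·z)`, which respects
  the (0, 100) bounds and the empirical fact that such patients essentially
  never have FI_PPM below 10%. Location/scale per sex (−0.114/0.495 women,
  −0.3985/0.4264 men) were solved from the target quartiles and the target
  exceedance fractions P(FI_PPM ≥ 50%) = 45/110 for women and 14/80 for
  men.
* **Age coupling** — the latent normals of age and logit-FI_PPM share a
  correlation of 0.55 (fat infiltration rises with age). Besides being
  physiologic, this coupling is what reconciles a large standardized FI_PPM
  effect with a modest overall R² in the regression below; it also puts the
  age predictor's variance inflation factor near 1.45, a realistic value.
* **FI_Psoas** — the linear model
  `FI_Psoas = 26.0 − 0.297·FI_PPM + 0.070·age + 0.024·BMI + 1.870·[female]
  − 0.315·[non-Caucasian] + ε`, with per-sex residual SD 6.80 (women) /
  4.72 (men), clipped to [0, 100]. Sex is coded female = 1 so the positive
  sex coefficient reflects the higher psoas fat infiltration of women; race
  enters as binary Caucasian/other (90% Caucasian). The intercept is set
  so that clipping is rare (~0.3% of draws; a clip rate above 5% triggers a
  warning), because censoring at zero would bias every downstream estimate;
  a location shift changes no correlation, group contrast or variance
  ratio. The per-sex residual SDs were calibrated by simulation so the
  mean within-sex Spearman ρ(FI_PPM, FI_Psoas) lands near −0.40 (women)
  and −0.45 (men), and jointly with the age coupling so a pooled OLS refit
  recovers mean b_FI_PPM ≈ −0.29, standardized Beta ≈ −0.50 and adjusted
  R² ≈ 0.19.
* **Areas** — bilateral height-normalized CSA per muscle is log-normal
  around per-sex medians (PPM ≈ 19, psoas 6.65/9.5 cm²/m²); FAT =
  CSA·FI/100 and fCSA = CSA − FAT, so the accounting identities hold to
  machine precision. CSA is generated independently of FI; cross-measure
  correlations other than FI–FI are therefore not calibrated.
* **Lordosis** — normal within sex × collapsed FI group (women 51.9 ± 13.4
  / 52.3 ± 11.1; men 49.6 ± 14.8 / 46.0 ± 9.9 degrees), so the generator
  builds in no real lordosis–FI effect, matching the null finding this
  design emulates.

What the cohort generator does **not** emulate: the absolute level of
FI_Psoas (its median is higher than in real fusion patients — a deliberate
consequence of keeping the bounded variable away from zero while preserving
every relational statistic), skewness of the FI_Psoas residuals, and any
correlation structure beyond FI_PPM→FI_Psoas and age↔FI_PPM. Passing tests
therefore certify the *relational* structure (correlations, group
contrasts, regression recovery), not marginal psoas levels.

## Statistics stage

Group comparisons use a per-group Shapiro–Wilk gate at 0.05: Student's t
only when both groups pass, otherwise Mann–Whitney U; summaries follow the
test (mean ± SD vs median [IQR]). Spearman correlations use mid-ranks for
ties with t-approximation p-values (standard for n > 10; exact permutation
p-values are out of scope). The regression report computes standardized
Beta as b·sd(x)/sd(y) with n−1 sample SDs, VIF_j = 1/(1−R²_j) from
auxiliary regressions, adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), and the
Durbin–Watson statistic over residuals in table row order (meaningful only
as a reporting convention here, since synthetic records are exchangeable).
No multiple-testing correction is applied anywhere — every p-value is raw
by design, and the report states each test choice with its normality
p-values in a log.

## Validation experiment sizes

The replicated validation runs use 200 replicates for cohort-level
summaries (110 women / 80 men per replicate for correlations, 190 patients
for regression refits), a fat-fraction grid of 0.05–0.60 in steps of 0.05
on clean 96×96 phantoms for recovery, and 20 seeded phantoms for the
bias-correction benefit comparison. These sizes put the Monte-Carlo error
of each summary well below the tolerance it is checked against.

## Known limitations

2-D single-slice only; no automatic segmentation (masks are inputs); no
Rician noise or k-space artifacts; the quadratic bias model cannot express
higher-order shading; cohort realism is limited to the moments and
relationships listed above; Durbin–Watson on exchangeable rows is a report
field, not a diagnostic of real autocorrelation.
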