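# Methods

## CEC retention factor

For ionized analytes, migration in a liposome-coated capillary mixes three
effects: electroosmotic flow (EOF), the analyte's own electrophoretic
mobility, and partitioning into the coating. The retention factor

    k′ = t_R (1/t_EOF + 1/t_R′ − 1/t_EOF′) − 1

uses coated-capillary times (analyte t_R, neutral marker t_EOF) and
uncoated times (t_R′, t_EOF′). The formula is read as t_R times the sum of
reciprocal times, minus one — not as a reciprocal of the sum — because only
that reading is dimensionless, reduces to the classical (t_R − t0)/t0 with
t0 = (1/t_EOF + 1/t_R′ − 1/t_EOF′)⁻¹, and matches the near-zero and
slightly negative magnitudes observed for weakly retained drugs. When the
reconstructed t0 is non-positive (pathological uncoated mobilities) the
computation is refused rather than returning a value derived from a
negative time. Times are stored in seconds; readers accept a `unit` column
with `s` or `min`. Replicate spread uses the sample (n−1) standard
deviation, defined as 0 for a single replicate.

EOF mobility is μ = L_eff·L_tot/(V·t_EOF) with defaults L_tot = 0.591 m,
L_eff = 0.49 m, V = 20 kV (a standard 59.1 cm × 50 µm capillary with the
detector at 49 cm).

## Titration-derived descriptors

**Yasuda–Shedlovsky extrapolation.** Apparent pKa values measured in
methanol–water mixtures are corrected by log10 of the molar water
concentration and regressed (unweighted OLS) on the reciprocal dielectric
constant; the line evaluated at pure water's 1/ε, minus log10(55.3), is the
aqueous pKa. The built-in solvent table maps methanol wt% ∈ {0, 30, 40, 50}
to (ε, [H₂O]) at 25 °C using handbook values (pure water ε = 78.3,
[H₂O] = 55.3 M); intermediate compositions are linearly interpolated and
compositions outside the table are rejected. The reported standard error is
the regression SE of the extrapolated mean; with two points the line is
exactly determined and the SE is reported as 0. Note that with three points
the error/SE ratio follows a 1-df t (Cauchy) law, so "±3 SE" covers only
~80% of repeats — the tests account for this.

**log P from the poKa shift.** With octanol present at volume ratio r, the
apparent pKa shifts up for acids and down for bases;
log P = log10((10^|shift| − 1)/r). A zero or wrong-direction shift raises a
no-partitioning error.

**log D.** Only the neutral microspecies is assumed to partition:
log D(pH) = log P − log10(1 + Σ ionized/neutral ratios), with ratios
10^(pH−pKa) for an acid group, 10^(pKa−pH) for a base, cumulative terms for
diprotic species, and the two-site (anion + cation) approximation for
ampholytes. This reproduces the packaged reference log D7.4 values from
their printed pKa/log P within ±0.15 for monoprotic compounds — and within
±0.01 for amitriptyline, acetylsalicylic acid, atenolol, metoprolol,
zidovudine and chlorpromazine — except for seven documented outliers
(salicylic acid, ketorolac, indomethacin, desipramine, nortriptyline,
paroxetine, loperamide; `cecbbb.io.ION_PAIR_OUTLIERS`) whose printed values
are consistent with additional ion-pair partitioning inside the titration
instrument's refinement software. These are documented, not force-fitted.

**Bjerrum curves.** Mean bound protons n̄(pH) from macroscopic pKa values
via species fractions computed in log space (logsumexp), monotone
non-increasing and bounded by [0, n_protons].

## log BB regression

log BB ~ 1 + k′ + logD7.4 + pKa by OLS (statsmodels backend) on natural
predictor scales; levofloxacin enters with pKa 8.13 (its basic constant,
per the reference table's annotation). Reported diagnostics: R², adjusted
R², the overall F statistic on (3, n−4) df and its p-value (the headline
test; per-coefficient t values are available but secondary), and residual
σ. Prediction intervals are exact t intervals,
ŷ ± t_{(1−level)/2, n−4}·σ·sqrt(1 + xᵀ(XᵀX)⁻¹x). Fitted models serialize
to JSON (coefficients, covariance factor, df), making predictions and
intervals bit-for-bit reproducible.

On the packaged 57-compound table the refit gives
β = (−2.449, 0.136, 0.301, 0.269), R² = 0.630, F = 30.12, p = 1.7 × 10⁻¹¹
(the acceptance script recomputes these at run time). The F statistic is
algebraically locked to the refit R² via F = (R²/3)/((1−R²)/53), so any
difference from an externally quoted F of the same design traces back to
rounding of the tabulated inputs, not to the fit.

## Trace classifier

**Preprocessing.** Non-numeric entries are coerced to NaN and dropped, the
first 100 samples are trimmed (the simulated injection artifact lives
entirely inside this window), and each trace is z-normalized (population
SD; constant traces become zeros with a warning). Unequal cleaned lengths
are right-truncated to the dataset minimum by default (linear resampling is
available as a config option). Class labels come from log BB cut-offs
−1/0.3 with inclusive outer bounds.

**DTW k-NN.** Point cost is the squared amplitude difference; the distance
is the square root of the minimal cumulative cost over monotone warping
paths within a Sakoe–Chiba band of absolute radius r (numba kernel;
radius ≥ length reproduces unconstrained DTW). Probabilities are vote
fractions over the k nearest training traces, optionally inverse-distance
weighted (exact matches absorb all weight). Neighbor-distance ties break by
stable input order; argmax ties break toward the lower class index.
Training-set evaluation uses leave-one-out neighbor sets.

**BOSSVS.** Stride-1 windows are z-normalized and Fourier-transformed; the
first `word_length` real components (real/imag interleaved, mean
coefficient dropped) are quantized per component into `n_bins` symbols via
quantile breakpoints learned from the training windows. Because the
breakpoints are themselves feature quantiles, features are rounded to 1e−8
before binning so quantization is stable under floating-point noise.
Consecutive duplicate words collapse (numerosity reduction). Class vectors
are log(1+tf) × log(1 + n_classes/df); queries score by cosine similarity
of their log(1+tf) vector, clipped at zero and normalized into
pseudo-probabilities (uniform fallback when all similarities vanish) — the
vector-space model natively yields similarities, not probabilities, and
this normalization is our documented choice.

**Ensemble and nested CV.** P_ens = ω P_kNN + (1−ω) P_BOSSVS, ω ∈ [0, 1].
The outer loop is stratified K-fold (default 5, capped by the smallest
class; an optional group-aware mode keeps all replicates of a compound in
one fold but is off by default, matching a protocol that treats repeated
measurements as independent samples). Per outer split, a stratified inner
K-fold (up to 3) selects k-NN and BOSSVS hyperparameters by weighted F1
from the default grids k ∈ {1,3,5} × {uniform, distance} × band ∈ {5,10,25}
and window ∈ {32,64,128} × word length ∈ {4,6,8} × bins ∈ {3,4} (all
configurable; infeasible window sizes are filtered against the series
length, and k is capped at the inner-training size when producing OOF
probabilities). OOF probability matrices from inner refits feed the ω scan
(0.00–1.00, step 0.05), which maximizes weighted F1 with ties broken toward
the smaller ω — the BOSSVS-heavy side. Note a consequence of this
tie-break: when one component is perfect, every blend past ω = 0.5 is also
perfect, so the selected weight is the smallest perfect one rather than the
endpoint. The chosen configuration is refit on the full outer-training
split and evaluated on the outer fold; per-fold and pooled metrics
(accuracy, balanced accuracy, weighted precision/recall/F1), the pooled
confusion matrix and one-vs-rest ROC/AUC are reported. The whole procedure
is a pure function of (data, grids, seed); DTW distances are precomputed
once per band radius, which is safe because pairwise distances involve no
fitting.

## Synthetic data

The trace simulator emulates what the classifier consumes: 512-sample
traces with a large injection spike confined to the first 100 samples, a
linear baseline drift, Gaussian noise (SD 0.05 against unit-height peaks),
and one Gaussian analyte peak inside a window mapping to the 3–11 min
elution band. Classes differ by mean peak position (−120/0/+120 samples
around the window center, between-compound SD 12); replicate traces of a
synthetic compound jitter around the compound's latent peak position
(SD 2), mirroring repeated measurements, with 3 replicates per compound by
default. It does not attempt detector physics, realistic peak asymmetry
(an exponentially modified peak is a config option away), co-eluting
species, or compound-specific spectra — so a passing classifier check shows
the pipeline recovers constructed class structure and refuses to invent
structure where none exists, not that real electropherograms are this
separable. The null-hypothesis fixture uses zero class separation *and*
one trace per compound: with replicate groups, a test trace's siblings in
the training set would legitimately reveal its label, which is a property
of the replicate protocol rather than of the classifier.

Titration and regression generators invert the corresponding models
exactly (a Yasuda–Shedlovsky line through the true pKa with slope 150
against 1/ε, giving the ~1-unit apparent shift at 50% methanol typical of
acids; uniform predictors over the experimental ranges with Gaussian
response noise), so noise-free round trips recover ground truth to machine
precision.

## Problem sizes and determinism

The validation suite uses 90-trace fixtures (30 per class) for the nested
CV checks, 200 random short pairs for the DTW path-enumeration oracle, and
1000 seeded repeats for the regression-recovery, interval-coverage and
titration-bias studies. All randomness flows through explicit seeds
(classifier default 42); repeated runs are byte-identical.

## Known limitations

* The log D model ignores ion-pair partitioning; the seven outliers above
  are reported, not modeled.
* BOSSVS probabilities are normalized cosine similarities, not calibrated
  probabilities; no probability calibration or class-specific thresholds
  are applied.
* The regression fixes the three-predictor linear form; no variable
  selection or regularization.
* Classifier performance claims are relative to the simulator's class
  structure; instrument traces may differ in ways the simulator does not
  capture.
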