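# Methods

This note documents the models implemented in `sptkin`, the assumptions
behind them, the numerical choices that matter, and what the synthetic
data generator does and does not emulate.

## Track model and simulator

Tracks are 2D (a TIRF-style microscopy projection), so the Brownian MSD
constant is 4Dτ throughout. Coordinates are physical micrometres; frame
indices are 0-based integers and time is `frame × frame_interval`. The
default frame interval is 0.024 s (a 20 ms exposure plus camera transfer
time).

The simulator draws each track's diffusive state once, at birth, with the
configured occupancy probabilities: states are **static per track**. This
matches the static-mixture assumption of the SQD decomposition — the
analysis cannot represent within-track state switching, and neither does
the generator. Per-frame displacements per axis are Gaussian with
variance 2·D·Δt; an i.i.d. Gaussian localization error (default σ = 0.02
µm per axis, a typical dye-label TIRF precision) is added to every stored
position, which inflates the apparent one-frame mean squared displacement
to 4·D·Δt + 4·σ². Track lengths are geometric with mean 12 frames,
truncated below at 5 (tracking pipelines filter at a 5-localization
minimum; the true length distribution of any given experiment is unknown,
so both the model and the mean are exposed as parameters). Optional
circular confinement reflects steps at the boundary radius; it is off by
default because pole-proximal confinement is a biological observation,
not part of the fitted model.

Not emulated: photophysics (blinking/bleaching kinetics), PSF/image
formation, spot detection and linking errors (misconnections, gap
closures of the wrong molecule), drift, and state switching. Passing
tests on this generator therefore demonstrate correctness of the
estimators under the model's own assumptions — they do not certify
robustness to detection artifacts in real movies.

## Filtering

`filter_tracks` first drops localizations before the bleach-cutoff frame
(default 500, the early high-density phase of a dye-labelled movie;
simulated data uses 0), then removes tracks with fewer than 5
localizations. The cutoff is applied at the localization level — the
closest track-level equivalent of removing early frames before detection.
When gaps exist, the 5-localization minimum counts localizations, not
spanned frames. The filter is idempotent and recorded in provenance.

## MSD and TAMSD

The ensemble MSD is the mean of squared displacements over all pairs of
localizations separated by exactly m frames (m = 1..4 by default, i.e.
τ = 24/48/72/96 ms), pooled across tracks. Displacement pairs ending at a
track's final localization are excluded (track-ending artifacts), and
only exact frame-index separations count, so gap-closed tracks never
contribute a spurious short-lag jump. The linear fit MSD = 4·D·τ + b is
ordinary least squares; the intercept estimates 4σ² of the localization
error. TAMSD is the same quantity time-averaged within one track; tracks
too short to populate every requested lag are excluded with a warning.

## SQD mixture decomposition

The empirical CDF of pooled squared displacements at one lag (rank/n at
each sorted value) is fitted by least squares to

    CDF(x) = 1 − Σᵢ fᵢ · exp(−x / (4·Dᵢ·τ + 4·σ²_eff)),   i = 1..k ≤ 3.

Least squares on the CDF (rather than per-point maximum likelihood) is
the convention of this analysis family and is numerically robust; the
exponential-mixture MLE is retained as an independent test oracle
(brute-force grid search), and the two agree within grid resolution on
simulated data. σ²_eff is a single shared localization-error offset,
fixed at 0 by default and optionally set by the caller; fitting it from
one lag alone is poorly identified, which is why it is not free by
default.

Numerics: fractions are kept on the simplex by a stick-breaking
parameterization, diffusion coefficients positive by log-parameterization
with wide bounds; optimization is `scipy.optimize.least_squares` (TRF)
with 8 starts — a quantile-based first guess (component means placed at
spread quantiles of the sample) plus seeded log-normal perturbations, and,
inside model selection, one warm start built from the (k−1)-component
optimum with its dominant component split. The warm start keeps nested
fits monotone in rss; if an optimizer still returns a higher rss than the
simpler model, the simpler optimum is re-expressed at k (duplicated
component, zero mass) with a logged warning. Components are reported in
descending-D order and labelled fast mobile / slow mobile / immobile.

## Model selection

Models with k = 1, 2, 3 components are compared stepwise. The step k−1 → k
is accepted only when all three criteria hold:

1. **F-test** on the CDF residual sums of squares,
   F = ((rss₍k−1₎ − rss₍k₎)/Δp) / (rss₍k₎/(n − p₍k₎)) with Δp = 2 (one D,
   one fraction per added state) and p₍k₎ = 2k − 1, significant at
   α = 0.05.
2. **Relative BIC decrease** of the Gaussian-residual BIC on the CDF fit,
   BIC = n·ln(rss/n) + p·ln(n), by more than 5%:
   (BIC₍k−1₎ − BIC₍k₎)/|BIC₍k−1₎| > 0.05.
3. **Likelihood-BIC guard**: the standard BIC under the
   exponential-mixture density of the squared displacements,
   −2·loglik + p·ln(n), must improve at all.

The third criterion is this package's own addition, and it is what makes
the procedure calibrated. Empirical-CDF residuals are strongly
correlated, so criteria 1–2 alone are anti-conservative: on single-state
data (n = 5000) a spurious second component absorbs enough of the
empirical-process fluctuation to pass the 5% gate in roughly a fifth of
datasets. Under the proper sampling density a spurious component
essentially never improves the BIC (the χ²-scale likelihood gain never
beats the 2·ln n penalty in practice), while a genuinely supported
component improves it by hundreds to thousands, so the guard removes the
false acceptances without costing power. With it, simulations select
k = 1 on one-state data and k = 2 on well-separated two-state data in
50/50 of seeded runs, and resolve the wild-type-like three-state mixture
at k = 3. The search stops at the first rejected step; a perfect simpler
fit (rss = 0) retains the simpler model. Degrees of freedom, the BIC
formula, and the gate structure are all stated here rather than asserted
to be identical to any external tracking-analysis tool, whose internals
are not public.

## Global fitting and TAMSD clustering

The global fit minimizes the summed CDF residuals of several conditions
with one shared D vector and per-condition fraction vectors, enabling
direct fraction comparison across strains or treatments; with a single
condition it reproduces the plain fit. TAMSD clustering standardizes
log₁₀-TAMSD feature vectors (lags 1–4) and runs k-means (10 restarts,
fixed seed) with k supplied by the caller — by convention the k accepted
by SQD model selection, never refit. Clusters are reported in descending
mean-TAMSD order. Perfectly stationary tracks are floored to the smallest
positive TAMSD before the log transform.

## Jump-distance check

The fitted CDF mixture implies a Rayleigh-mixture density of step lengths,
p(r) = Σᵢ fᵢ · r/(2(Dᵢτ + σ²_eff)) · exp(−r²/(4Dᵢτ + 4σ²_eff)). The
check histograms jump distances (Freedman–Diaconis bins by default,
sparse tails merged to an expected count ≥ 5) and scores the fixed-
parameter prediction by χ² and R² — a goodness report, not a refit.

## Binding kinetics (BLI)

The 1:1 model: association Y = Y₀ + a·(1 − e^(−kobs·t)) with
kobs = ka·[A] + kd; dissociation Y = Y₀ + a·e^(−kd·t); KD = kd/ka. A
single-concentration sensorgram is fitted dissociation-first (kd), then
association (kobs), then ka = (kobs − kd)/[A]; a titration series instead
regresses kobs on [A] (slope ka, intercept a consistency check on kd).
Initial guesses: rate from a log-linearized early response, amplitude
from plateau minus baseline; kobs > 0 enforced; flat or collapsed
segments raise an unidentifiability error instead of returning a
meaningless rate. χ² uses unit weights unless a noise estimate is
supplied. Heterogeneous-ligand and 2:1 models are out of scope: real
sensorgrams that deviate from 1:1 at high analyte (more than one bait
bound per analyte) will show it in the residuals, not in a model switch.

## ATPase kinetics

Time courses are reduced to rates by OLS over a window: the full course
by default, or a sliding window of stated length scored by maximal R²
(ties — e.g. an exhausted plateau, which also scores R² = 1 — go to the
steeper window, so the initial rate wins). Auto-hydrolysis and
no-substrate control rates are subtracted; negative corrected rates are
retained and flagged, because near the assay detection limit they are
real data. The Hill fit v = vmax·S^n_h/(k_half^n_h + S^n_h) uses
`lmfit` with vmax, k_half > 0 and n_h ∈ [0.001, 10], optionally fixed to
1 for pure Michaelis–Menten (k_half ≡ Km). Units: rates nmol/min,
substrate mM — conversions are the caller's, never hidden.

## qPCR relative quantification

Primer efficiency comes from a dilution series: slope of Ct vs
log₁₀(input), E = 10^(−1/slope) (slope −3.3219 ⇔ E = 2); a non-negative
slope is rejected as unphysical. Relative copy number uses the
efficiency-corrected (Pfaffl-style) form

    ratio = E_t^(−Ct_t) / E_r^(−Ct_r) · (d_r·v_r)/(d_t·v_t)

with per-primer efficiencies and dilution/volume correction factors
(d = fraction of material carried into the reaction, v = sample volume
used for purification; both default to 1). This reduces to 2^(−ΔCt) for
equal efficiencies of 2 and equal factors, and inverts the generator
exactly on noiseless input for any efficiencies in (1, 2]. Replicates
are paired by index; the ratio is reported as mean ± sd over pairs.

## Problem sizes and tolerances used in validation

The validation suite and the acceptance script use simulation sizes
chosen to make the stochastic checks decisive at desk scale: 3000–8000
tracks (≈ 30k–80k single-frame displacements) for mixture recovery, 5000
displacements × 50 seeds for selection calibration, 10⁴ draws for
estimator-consistency checks, and n = 2000 for the MLE-oracle comparison.
At these sizes the fast component of the three-state reference mixture is
recovered within a few percent in D and ≈ 1–2 percentage points in
fraction; single-dataset results at 3000 tracks scatter roughly twice as
wide. All random draws flow from explicit integer seeds; fixed seeds give
bit-identical outputs.

## Known limitations

- No state-switching (HMM-style) inference and no anomalous-diffusion
  exponents; a molecule that changes state mid-track biases all
  estimators built on the static-mixture assumption.
- The SQD decomposition resolves components whose D ratios are a few-fold
  or more at these sample sizes; closer states merge, with the mass
  absorbed by neighbours.
- σ²_eff is shared across states and fixed by default; strong
  localization error with it left at 0 inflates the smallest D instead.
- The jump-distance χ² assumes independent bin counts, which pooled
  displacements from finite tracks only approximate.
- The qPCR correction assumes target and reference are measured on the
  same purified material per replicate; cross-sample normalization is out
  of scope.
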