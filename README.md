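# sptkin

Quantitative analysis of single-molecule mobility and binding/enzyme
kinetics for bacterial cell-biology experiments, built around the study of
condensin-like plasmid-defense complexes: proteins that switch between
freely diffusing, DNA-associated and pole-anchored pools inside the cell.
The package answers four recurring questions from such projects:

1. **How mobile is a tagged protein, and in how many diffusive states does
   it live?** — from single-particle-tracking (SPT) trajectories: ensemble
   mean-squared-displacement (MSD) fits, square-displacement (SQD)
   cumulative-distribution mixture decomposition with statistical model
   selection, cross-condition global fitting, jump-distance goodness
   checks and per-track TAMSD clustering.
2. **How tightly do two subunits bind?** — 1:1 bio-layer interferometry
   (BLI) kinetics: kobs, ka, kd and KD = kd/ka.
3. **How fast does the ATPase turn over?** — plate-assay preprocessing and
   Hill / Michaelis–Menten fits.
4. **How many plasmid copies per chromosome?** — efficiency-corrected
   2^−ΔCt relative quantification from qPCR Ct tables.

A synthetic-data module generates every input with known ground truth
(multi-state Brownian tracks with localization error, noiseless or noisy
sensorgrams, Hill rate curves, Ct tables), so the full pipeline is
testable end-to-end without any raw microscopy or plate data.

## The core model

For a molecule diffusing in 2D in one of *k* static states, the squared
single-lag displacement x = r² at lag τ is exponentially distributed
within each state, so the pooled cumulative distribution is

```
CDF(x) = 1 − Σᵢ fᵢ · exp( −x / (4·Dᵢ·τ + 4·σ²) )        Σᵢ fᵢ = 1
```

with per-state diffusion coefficients Dᵢ (µm²/s), occupancy fractions fᵢ
and an optional localization-error offset σ². The model CDF is fitted to
the empirical CDF by multi-start least squares; k is chosen by nested
comparison of k−1 vs k components with an F-test (p < 0.05) coupled to a
BIC-decrease gate (see `docs/methods.md`). Components are labelled
fast mobile / slow mobile / immobile by descending D. The ensemble MSD at
lags τ = 24, 48, 72, 96 ms is fitted to MSD = 4·D·τ + b for the
single-population mobility summary, and the fitted mixture is
cross-checked against the jump-distance (step-length) histogram, a
Rayleigh mixture under this model.

## Worked example

Simulate a wild-type-like three-state track set (fast state D = 0.479
µm²/s at 47.7%, slow 0.105, immobile 0.0151 µm²/s; Δt = 24 ms), then run
the standard SPT analysis:

```python
from sptkin import (TrackSimParams, simulate_tracks, filter_tracks,
                    compute_msd, fit_msd_linear, compute_sqd, select_model)

params = TrackSimParams(
    diffusion_constants=(0.479, 0.105, 0.0151),
    fractions=(0.477, 0.2615, 0.2615),
    n_tracks=3000, localization_sigma=0.0, seed=1,
)
ts = filter_tracks(simulate_tracks(params), min_length=5, bleach_cutoff_frame=0)
print(fit_msd_linear(compute_msd(ts)).summary())
print(select_model(compute_sqd(ts, lag=1), seed=1).summary())
```

```
Linear MSD fit (MSD = 4·D·τ + b)
  lags used : 24 ms, 48 ms, 72 ms, 96 ms
  D         : 0.2664 ± 0.00084 µm²/s
  intercept : -0.0002617 µm² (≙ 4σ², σ = 0 µm)
  R²        : 1.0000
Model selection (F-test α = 0.05, BIC drop > 5%): selected k = 3
  k 1→2: F = 1.81e+06, p = 0, ΔBIC/|BIC| = 103.94% → accepted
  k 2→3: F = 1.6e+06, p = 0, ΔBIC/|BIC| = 49.66% → accepted
SQD mixture fit: k = 3 states, lag τ = 24 ms, n = 30067 displacements
  rss = 0.0228   BIC = -423662.9
  fast mobile  D = 0.4563 µm²/s   fraction = 52.7%
  slow mobile  D = 0.08729 µm²/s   fraction = 22.9%
  immobile     D = 0.01406 µm²/s   fraction = 24.5%
```

The single-population MSD estimate (0.27 µm²/s) is the
occupancy-weighted average mobility; the mixture decomposition resolves
it into the three generating states — the fast component is recovered at
0.456 µm²/s / 52.7% versus the true 0.479 µm²/s / 47.7% at this track
count (3000; the estimates tighten as more tracks are pooled).

A binding-kinetics round trip looks like:

```python
from sptkin import SensorgramSimParams, simulate_sensorgram, BindingKineticsModel

sg = simulate_sensorgram(SensorgramSimParams(ka=7.42e4, kd=0.16, analyte_conc=2e-6))
print(BindingKineticsModel(sg).fit().summary())
```

```
1:1 binding kinetics
  kobs : 0.3084 s⁻¹
  kd   : 0.16 s⁻¹ (dissociation phase)
  ka   : 7.42e+04 M⁻¹s⁻¹
  KD   : 2.156e-06 M = 2.16 µM
  χ²   : 1.622e-22   R² : 1.0000
```

Everything is also available from the command line (`sptkin simulate`,
`sptkin spt fit`, `sptkin spt global-fit`, `sptkin bli fit`,
`sptkin atpase fit`, `sptkin qpcr quant`, and a config-driven
`sptkin run`); see `sptkin --help`.

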