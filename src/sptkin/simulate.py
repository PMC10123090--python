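"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here: 2D Brownian
track sets drawn from a 1–3 state diffusion mixture, 1:1 binding
sensorgrams, Hill-kinetic ATPase rate curves and qPCR Ct tables. Each
generator takes a frozen parameter dataclass (validated on construction)
and an explicit seed, and is bit-reproducible for a fixed seed.

The track generator emulates a TIRF-style SPT experiment: molecules diffuse
in 2D, each track keeps a single diffusive state for its whole lifetime
(static mixture, no state switching), per-frame displacements per axis are
Gaussian with variance 2·D·Δt, and an independent Gaussian localization
error is added to every stored position. Photophysics (blinking, bleaching)
and image formation are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

__all__ = [
    "TrackSimParams",
    "SensorgramSimParams",
    "HillSimParams",
    "QpcrSimParams",
    "simulate_tracks",
    "simulate_sensorgram",
    "simulate_rate_curve",
    "simulate_qpcr",
    "Sensorgram",
]

#: Camera cycle time of the emulated acquisition (20 ms exposure plus
#: transfer time), in seconds.
DEFAULT_FRAME_INTERVAL = 0.024

#: Default static localization error per axis, µm. Typical for HaloTag-TMR
#: TIRF imaging; exposed because real precision varies with photon counts.
DEFAULT_LOCALIZATION_SIGMA = 0.02


@dataclass(frozen=True)
class TrackSimParams:
    """Parameters of the multi-state Brownian track generator.

    diffusion_constants are per-state D in µm²/s; fractions are the
    per-state occupancy probabilities (must sum to 1). Track lengths are
    either fixed or geometric with the stated mean, truncated below at
    ``min_track_length``. ``confinement_radius`` optionally reflects
    trajectories into a circle of that radius (µm).
    """

    diffusion_constants: tuple[float, ...]
    fractions: tuple[float, ...]
    n_tracks: int = 1000
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA
    track_length_model: str = "geometric"  # "geometric" | "fixed"
    track_length_mean: float = 12.0
    min_track_length: int = 5
    confinement_radius: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        d = tuple(float(v) for v in self.diffusion_constants)
        f = tuple(float(v) for v in self.fractions)
        object.__setattr__(self, "diffusion_constants", d)
        object.__setattr__(self, "fractions", f)
        if len(d) != len(f):
            raise ValueError("diffusion_constants and fractions differ in length")
        if not 1 <= len(d) <= 3:
            raise ValueError("between 1 and 3 diffusive states are supported")
        if any(v < 0 for v in d):
            raise ValueError("diffusion constants must be >= 0")
        if any(v < 0 for v in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.track_length_model not in ("geometric", "fixed"):
            raise ValueError("track_length_model must be 'geometric' or 'fixed'")
        if self.track_length_mean < self.min_track_length:
            raise ValueError("track_length_mean below the minimum track length")


def _draw_lengths(params: TrackSimParams, rng: np.random.Generator) -> np.ndarray:
    if params.track_length_model == "fixed":
        return np.full(params.n_tracks, int(round(params.track_length_mean)))
    # geometric on top of the minimum so the truncated mean is exact:
    # length = min + (G - 1), G ~ Geometric(p), E[G] = 1/p
    excess_mean = params.track_length_mean - params.min_track_length
    p = 1.0 / (excess_mean + 1.0)
    return params.min_track_length + rng.geometric(p, size=params.n_tracks) - 1


def simulate_tracks(params: TrackSimParams) -> TrackSet:
    """Draw a TrackSet from a static 1–3 state Brownian mixture.

    Each track is assigned one state for its lifetime with probability
    ``fractions[i]``; the true per-frame mean squared displacement of state
    *i* (before localization error) is ``4·D_i·Δt``. The stored positions
    carry additive i.i.d. Gaussian localization error per axis, which
    raises the apparent one-frame MSD to ``4·D·Δt + 4·σ²``. Ground-truth
    state indices are retained on each ``Track.state_label``.
    """
    rng = np.random.default_rng(params.seed)
    states = rng.choice(len(params.fractions), size=params.n_tracks, p=params.fractions)
    lengths = _draw_lengths(params, rng)
    step_sd = np.sqrt(2.0 * np.asarray(params.diffusion_constants) * params.frame_interval)

    tracks = []
    for tid in range(params.n_tracks):
        n = int(lengths[tid])
        sd = step_sd[states[tid]]
        steps = rng.normal(0.0, sd, size=(n - 1, 2)) if sd > 0 else np.zeros((n - 1, 2))
        pos = np.zeros((n, 2))
        if params.confinement_radius is None:
            pos[1:] = np.cumsum(steps, axis=0)
        else:
            r = params.confinement_radius
            for i in range(1, n):
                cand = pos[i - 1] + steps[i - 1]
                rho = np.hypot(*cand)
                if rho > r:  # radial reflection at the circular boundary
                    cand *= (2 * r - rho) / rho
                pos[i] = cand
        if params.localization_sigma > 0:
            pos = pos + rng.normal(0.0, params.localization_sigma, size=pos.shape)
        tracks.append(
            Track(
                track_id=tid,
                frames=np.arange(n, dtype=np.int64),
                x=pos[:, 0],
                y=pos[:, 1],
                state_label=int(states[tid]),
            )
        )
    return TrackSet(
        tracks=tracks,
        frame_interval=params.frame_interval,
        condition_label="simulated",
        provenance=[f"simulate_tracks:seed={params.seed}"],
    )


# ---------------------------------------------------------------------------
# Bio-layer interferometry sensorgrams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorgramSimParams:
    """1:1 Langmuir binding sensorgram parameters.

    ka in M⁻¹s⁻¹, kd in s⁻¹, analyte concentration in M, rmax in response
    units at analyte saturation. The association phase lasts t_assoc
    seconds, the dissociation phase t_dissoc seconds.
    """

    ka: float
    kd: float
    analyte_conc: float
    rmax: float = 1.0
    t_assoc: float = 300.0
    t_dissoc: float = 180.0
    sample_rate: float = 5.0  # Hz
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("ka must be > 0")
        if self.kd < 0:
            raise ValueError("kd must be >= 0")
        if self.analyte_conc < 0:
            raise ValueError("analyte_conc must be >= 0")
        if self.t_assoc <= 0 or self.t_dissoc < 0:
            raise ValueError("phase durations must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass
class Sensorgram:
    """A BLI response curve with annotated phase boundaries.

    ``phases`` maps phase name → (start, stop) index slice into ``t`` /
    ``response``. Times are in seconds from the start of the record.
    """

    t: np.ndarray
    response: np.ndarray
    phases: dict[str, tuple[int, int]]
    analyte_conc: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("negative times rejected")
        prev_stop = 0
        for name, (a, b) in self.phases.items():
            if not (prev_stop <= a < b <= len(t)):
                raise ValueError(f"phase {name!r} indices overlap or are out of order")
            prev_stop = b

    def segment(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (t, response) of one phase, with t re-zeroed to its start."""
        a, b = self.phases[name]
        return self.t[a:b] - self.t[a], self.response[a:b]

    def to_dataframe(self) -> pd.DataFrame:
        phase_col = np.empty(len(self.t), dtype=object)
        for name, (a, b) in self.phases.items():
            phase_col[a:b] = name
        return pd.DataFrame({"t_s": self.t, "response": self.response, "phase": phase_col})


def simulate_sensorgram(params: SensorgramSimParams) -> Sensorgram:
    """Simulate a noiseless or noisy 1:1 binding sensorgram.

    Association: R(t) = R_eq·(1 − e^(−kobs·t)) with kobs = ka·[A] + kd and
    R_eq = rmax·[A]/([A] + KD), KD = kd/ka. Dissociation: R(t) = R0·e^(−kd·t)
    from the response R0 reached at the end of association. Optional
    additive Gaussian noise; the ground truth is kept in ``meta``.
    """
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.sample_rate
    t_a = np.arange(0.0, params.t_assoc + dt / 2, dt)
    kobs = params.ka * params.analyte_conc + params.kd
    kd_over_ka = params.kd / params.ka
    if params.analyte_conc + kd_over_ka > 0:
        r_eq = params.rmax * params.analyte_conc / (params.analyte_conc + kd_over_ka)
    else:
        r_eq = 0.0
    resp_a = r_eq * (1.0 - np.exp(-kobs * t_a))

    r0 = resp_a[-1]
    t_d = np.arange(dt, params.t_dissoc + dt / 2, dt)
    resp_d = r0 * np.exp(-params.kd * t_d)

    t = np.concatenate([t_a, t_a[-1] + t_d])
    resp = np.concatenate([resp_a, resp_d])
    if params.noise_sd > 0:
        resp = resp + rng.normal(0.0, params.noise_sd, size=resp.shape)
    phases = {
        "association": (0, len(t_a)),
        "dissociation": (len(t_a), len(t)),
    }
    return Sensorgram(
        t=t,
        response=resp,
        phases=phases,
        analyte_conc=params.analyte_conc,
        meta={
            "true_ka": params.ka,
            "true_kd": params.kd,
            "true_kobs": kobs,
            "true_req": r_eq,
            "seed": params.seed,
        },
    )


# ---------------------------------------------------------------------------
# ATPase rate curves (Hill kinetics)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillSimParams:
    """Hill-kinetic rate-curve parameters.

    vmax and background_rate in nmol/min, k_half (substrate concentration
    at half-maximal rate) in mM, n_h dimensionless. ``substrate_grid`` is
    the list of substrate concentrations (mM) at which rates are emitted.
    """

    vmax: float
    k_half: float
    n_h: float = 1.0
    substrate_grid: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0)
    background_rate: float = 0.0
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "substrate_grid", tuple(float(s) for s in self.substrate_grid)
        )
        if self.vmax < 0:
            raise ValueError("vmax must be >= 0")
        if self.k_half <= 0:
            raise ValueError("k_half must be > 0")
        if self.n_h <= 0:
            raise ValueError("n_h must be > 0")
        if any(s < 0 for s in self.substrate_grid):
            raise ValueError("substrate concentrations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def hill_rate(s, vmax: float, k_half: float, n_h: float):
    """Hill rate law v(S) = vmax·S^n_h / (k_half^n_h + S^n_h)."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    nz = s > 0
    sn = np.power(s[nz], n_h)
    out[nz] = vmax * sn / (np.power(k_half, n_h) + sn)
    return out


def simulate_rate_curve(params: HillSimParams) -> pd.DataFrame:
    """Emit a rate table v(S) = Hill + background + noise.

    Returns a tidy DataFrame with columns ``substrate_mM``, ``replicate``,
    ``rate_nmol_min`` and the generating parameters in ``attrs``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for rep in range(params.replicates):
        v = hill_rate(params.substrate_grid, params.vmax, params.k_half, params.n_h)
        v = v + params.background_rate
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
        rows.append(
            pd.DataFrame(
                {
                    "substrate_mM": params.substrate_grid,
                    "replicate": rep,
                    "rate_nmol_min": v,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.attrs["ground_truth"] = {
        "vmax": params.vmax,
        "k_half": params.k_half,
        "n_h": params.n_h,
        "background_rate": params.background_rate,
        "seed": params.seed,
    }
    return df


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrSimParams:
    """Relative-quantification qPCR simulation parameters.

    ``true_copy_ratio`` is target copies per reference copy (e.g. plasmid
    per chromosomal origin). Efficiencies are per-cycle amplification
    factors in (1, 2]. Dilution factors are the fraction of the original
    material carried into the reaction; sample volumes normalize for
    different amounts of purified DNA.
    """

    true_copy_ratio: float
    efficiency_target: float = 2.0
    efficiency_ref: float = 2.0
    ct_ref: float = 20.0
    dilution_target: float = 1.0
    dilution_ref: float = 1.0
    volume_target: float = 1.0
    volume_ref: float = 1.0
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_copy_ratio <= 0:
            raise ValueError("true_copy_ratio must be > 0")
        for e in (self.efficiency_target, self.efficiency_ref):
            if not 1.0 < e <= 2.0:
                raise ValueError("efficiencies must be in (1, 2]")
        if self.dilution_target <= 0 or self.dilution_ref <= 0:
            raise ValueError("dilution factors must be > 0")
        if self.volume_target <= 0 or self.volume_ref <= 0:
            raise ValueError("sample volumes must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_qpcr(params: QpcrSimParams) -> pd.DataFrame:
    """Emit a Ct table for a target/reference amplicon pair.

    The cycle threshold is where input·E^Ct crosses a fixed fluorescence
    threshold, so with the reference anchored at ``ct_ref``:

        Ct_target = (ct_ref·ln E_ref − ln(ratio·(d_t·v_t)/(d_r·v_r))) / ln E_target

    which reduces to ``ct_ref − log_E(ratio)`` when both primers share one
    efficiency and the dilution/volume factors are equal. Gaussian Ct noise
    is added per replicate. Columns: sample, target, replicate, ct,
    dilution, volume; ground truth in ``attrs``.
    """
    rng = np.random.default_rng(params.seed)
    scale = (params.dilution_target * params.volume_target) / (
        params.dilution_ref * params.volume_ref
    )
    ct_target = (
        params.ct_ref * np.log(params.efficiency_ref)
        - np.log(params.true_copy_ratio * scale)
    ) / np.log(params.efficiency_target)

    rows = []
    for rep in range(params.replicates):
        noise_t = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        noise_r = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        rows.append(
            ("sample1", "target", rep, ct_target + noise_t,
             params.dilution_target, params.volume_target)
        )
        rows.append(
            ("sample1", "reference", rep, params.ct_ref + noise_r,
             params.dilution_ref, params.volume_ref)
        )
    df = pd.DataFrame(
        rows, columns=["sample", "target", "replicate", "ct", "dilution", "volume"]
    )
    df.attrs["ground_truth"] = {
        "true_copy_ratio": params.true_copy_ratio,
        "efficiency_target": params.efficiency_target,
        "efficiency_ref": params.efficiency_ref,
        "seed": params.seed,
    }
    return df
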