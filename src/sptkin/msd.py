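"""Ensemble and time-averaged mean squared displacement (MSD) analysis.

For 2D Brownian motion the ensemble MSD grows linearly with lag time,
MSD(τ) = 4·D·τ + 4σ², where σ is the static localization error per axis.
The slope of an ordinary least-squares line through the first few lags is
therefore a robust single-population estimate of the diffusion
coefficient, and the intercept estimates 4σ².

By convention here the MSD is evaluated at the first four lag multiples of
the frame interval (24/48/72/96 ms at the default 24 ms cycle time), and
displacement pairs that end at a track's final localization are excluded
to avoid track-ending artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tracks import Track, TrackSet

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "MSDLinearModel",
    "compute_msd",
    "compute_tamsd",
    "fit_msd_linear",
    "squared_displacements",
]


@dataclass(frozen=True)
class MSDCurve:
    """MSD values per lag with the pair counts that produced them.

    ``scope`` is "ensemble" (pooled over all tracks) or "track" (a single
    track's time average, TAMSD).
    """

    lags: np.ndarray  # seconds, strictly increasing
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # displacement pairs per lag
    scope: str = "ensemble"

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(msd < 0):
            raise ValueError("msd must be >= 0")
        if np.any(n_pairs < 1):
            raise ValueError("each reported lag needs >= 1 pair")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)
        object.__setattr__(self, "n_pairs", n_pairs)


def _pair_indices(frames: np.ndarray, lag: int, exclude_last_point: bool) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) with frames[j] - frames[i] == lag.

    Only exact frame-index separations count, so gap-closed tracks never
    contribute a spurious short-lag jump across a gap.
    """
    pos = {int(f): i for i, f in enumerate(frames)}
    last = len(frames) - 1
    ii, jj = [], []
    for i, f in enumerate(frames):
        j = pos.get(int(f) + lag)
        if j is None:
            continue
        if exclude_last_point and j == last:
            continue
        ii.append(i)
        jj.append(j)
    return np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64)


def squared_displacements(
    track: Track, lag: int = 1, exclude_last_point: bool = True
) -> np.ndarray:
    """Squared displacements of one track at an exact frame-index lag (µm²)."""
    ii, jj = _pair_indices(track.frames, lag, exclude_last_point)
    if len(ii) == 0:
        return np.empty(0)
    return (track.x[jj] - track.x[ii]) ** 2 + (track.y[jj] - track.y[ii]) ** 2


def compute_msd(
    ts: TrackSet, max_lag: int = 4, exclude_last_point: bool = True
) -> MSDCurve:
    """Ensemble MSD at lags 1..max_lag frames, pooled over all tracks.

    Lags with no usable pairs are omitted with a warning rather than
    reported as zero.
    """
    lags_s, msds, counts = [], [], []
    for m in range(1, max_lag + 1):
        sq = [squared_displacements(t, m, exclude_last_point) for t in ts.tracks]
        sq = np.concatenate(sq) if sq else np.empty(0)
        if len(sq) == 0:
            warnings.warn(f"no displacement pairs at lag {m}; lag omitted")
            continue
        lags_s.append(m * ts.frame_interval)
        msds.append(float(np.mean(sq)))
        counts.append(len(sq))
    return MSDCurve(
        lags=np.asarray(lags_s), msd=np.asarray(msds), n_pairs=np.asarray(counts)
    )


def compute_tamsd(
    track: Track, frame_interval: float, max_lag: int = 4, exclude_last_point: bool = True
) -> MSDCurve:
    """Time-averaged MSD of a single track at lags 1..max_lag frames.

    Raises ValueError for tracks too short to populate every requested lag
    (callers typically exclude those tracks with a warning).
    """
    lags_s, msds, counts = [], [], []
    for m in range(1, max_lag + 1):
        sq = squared_displacements(track, m, exclude_last_point)
        if len(sq) == 0:
            raise ValueError(
                f"track {track.track_id} too short for TAMSD at lag {m}"
            )
        lags_s.append(m * frame_interval)
        msds.append(float(np.mean(sq)))
        counts.append(len(sq))
    return MSDCurve(
        lags=np.asarray(lags_s),
        msd=np.asarray(msds),
        n_pairs=np.asarray(counts),
        scope="track",
    )


@dataclass(frozen=True)
class DiffusionEstimate:
    """Results of the linear MSD fit MSD(τ) = 4·D·τ + b.

    d is the diffusion coefficient in µm²/s, intercept b in µm²
    (interpretable as 4σ² of the localization error), with the OLS
    standard error of d and the fit R².
    """

    d: float
    intercept: float
    r_squared: float
    stderr_d: float
    curve: MSDCurve

    def summary(self) -> str:
        return (
            "Linear MSD fit (MSD = 4·D·τ + b)\n"
            f"  lags used : {', '.join(f'{1e3 * l:.0f} ms' for l in self.curve.lags)}\n"
            f"  D         : {self.d:.4g} ± {self.stderr_d:.2g} µm²/s\n"
            f"  intercept : {self.intercept:.4g} µm² (≙ 4σ², σ = "
            f"{np.sqrt(max(self.intercept, 0.0) / 4):.3g} µm)\n"
            f"  R²        : {self.r_squared:.4f}"
        )

    def plot(self, ax=None):
        """Plot the MSD points and the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.lags, self.curve.msd, "o", label="MSD")
        tau = np.linspace(0, self.curve.lags[-1] * 1.05, 50)
        ax.plot(tau, 4 * self.d * tau + self.intercept, "-",
                label=f"fit: D = {self.d:.3g} µm²/s")
        ax.set_xlabel("lag τ (s)")
        ax.set_ylabel("MSD (µm²)")
        ax.legend()
        return ax


class MSDLinearModel:
    """OLS fit of an MSDCurve to MSD(τ) = 4·D·τ + b."""

    def __init__(self, curve: MSDCurve):
        if len(curve.lags) < 2:
            raise ValueError("need at least 2 lags for a linear MSD fit")
        self.curve = curve

    def fit(self) -> DiffusionEstimate:
        tau = self.curve.lags
        y = self.curve.msd
        design = np.column_stack([tau, np.ones_like(tau)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        resid = y - design @ coef
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = len(tau) - 2
        if dof > 0 and ss_res > 0:
            s2 = ss_res / dof
            sxx = float(np.sum((tau - tau.mean()) ** 2))
            stderr_slope = np.sqrt(s2 / sxx)
        else:
            stderr_slope = 0.0
        return DiffusionEstimate(
            d=slope / 4.0,
            intercept=intercept,
            r_squared=r2,
            stderr_d=stderr_slope / 4.0,
            curve=self.curve,
        )


def fit_msd_linear(curve: MSDCurve) -> DiffusionEstimate:
    """Convenience wrapper: ``MSDLinearModel(curve).fit()``."""
    return MSDLinearModel(curve).fit()
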