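"""ATPase plate-assay preprocessing and Hill / Michaelis–Menten fitting.

Continuous phosphate-release time courses are reduced to initial rates by
linear regression over a window (fixed, or auto-detected as the window of
maximal R²); control rates (ATP auto-hydrolysis, no-substrate enzyme
background) are subtracted. The corrected rate–substrate curve is fitted
to the Hill equation

    v(S) = vmax · S^n_h / (k_half^n_h + S^n_h)

with the Hill coefficient n_h optionally fixed to 1 (pure
Michaelis–Menten, k_half = Km). Negative corrected rates are retained and
flagged rather than clipped — near the detection limit they are real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .simulate import hill_rate

__all__ = [
    "RateTable",
    "HillFit",
    "HillModel",
    "preprocess_rates",
    "fit_hill",
    "linear_rate",
]


@dataclass(frozen=True)
class RateTable:
    """Corrected reaction rates per substrate concentration.

    ``data`` has columns substrate_mM, replicate, rate_nmol_min; negative
    rates are listed in ``flagged_negative`` (row indices) but kept.
    """

    data: pd.DataFrame
    condition_label: str = ""
    flagged_negative: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        required = {"substrate_mM", "rate_nmol_min"}
        if not required <= set(self.data.columns):
            raise ValueError(f"rate table needs columns {sorted(required)}")
        if (self.data["substrate_mM"] < 0).any():
            raise ValueError("substrate concentrations must be >= 0")

    @property
    def substrate(self) -> np.ndarray:
        return self.data["substrate_mM"].to_numpy(float)

    @property
    def rates(self) -> np.ndarray:
        return self.data["rate_nmol_min"].to_numpy(float)


def linear_rate(t_min, signal, window: int | None = None) -> tuple[float, dict]:
    """Slope (signal units per minute) of a time course by OLS.

    With ``window=None`` the full course is used; otherwise a sliding
    window of that many points is scanned and the window with maximal R²
    is taken (the linear early phase of a saturating course).
    """
    t = np.asarray(t_min, float)
    y = np.asarray(signal, float)
    if len(t) != len(y):
        raise ValueError("time and signal lengths differ")
    n = len(t)
    w = n if window is None else int(window)
    if w < 3:
        raise ValueError("regression window must span at least 3 points")
    if w > n:
        raise ValueError(f"window of {w} points exceeds the {n}-point course")

    best = None
    for start in range(0, n - w + 1):
        tt, yy = t[start : start + w], y[start : start + w]
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        # ties (e.g. a flat plateau also scores R² = 1) go to the steeper
        # window: the initial rate, not the exhausted phase
        key = (round(r2, 9), abs(float(slope)))
        if best is None or key > best[0]:
            best = (key, float(slope), r2, start)
    _, slope, r2, start = best
    return slope, {"r_squared": r2, "window_start": start, "window_points": w}


def preprocess_rates(
    timecourses: pd.DataFrame,
    auto_hydrolysis: pd.DataFrame | None = None,
    no_substrate: pd.DataFrame | None = None,
    window: int | None = None,
    condition_label: str = "",
) -> RateTable:
    """Reduce plate time courses to control-corrected rates.

    ``timecourses`` is tidy: columns ``t_min``, ``substrate_mM``,
    ``replicate``, ``signal`` (nmol phosphate released). Controls share
    the layout; ``auto_hydrolysis`` may omit ``substrate_mM`` (one series
    per substrate is matched by concentration when present, otherwise one
    global series is used), ``no_substrate`` is a single series. Each
    control contributes its regression slope, subtracted from every sample
    rate.
    """
    required = {"t_min", "substrate_mM", "replicate", "signal"}
    if not required <= set(timecourses.columns):
        raise ValueError(f"timecourses needs columns {sorted(required)}")

    def _control_rate(df: pd.DataFrame | None, substrate: float) -> float:
        if df is None or df.empty:
            return 0.0
        sel = df
        if "substrate_mM" in df.columns and df["substrate_mM"].nunique() > 1:
            sel = df[np.isclose(df["substrate_mM"], substrate)]
            if sel.empty:
                sel = df
        slopes = [
            linear_rate(g["t_min"], g["signal"], window=window)[0]
            for _, g in sel.groupby("replicate")
        ] if "replicate" in sel.columns else [linear_rate(sel["t_min"], sel["signal"], window=window)[0]]
        return float(np.mean(slopes))

    rows = []
    for (s, rep), grp in timecourses.groupby(["substrate_mM", "replicate"]):
        slope, diag = linear_rate(grp["t_min"], grp["signal"], window=window)
        corrected = slope - _control_rate(auto_hydrolysis, s) - _control_rate(no_substrate, s)
        rows.append((float(s), int(rep), corrected, diag["r_squared"]))
    data = pd.DataFrame(rows, columns=["substrate_mM", "replicate",
                                       "rate_nmol_min", "fit_r_squared"])
    flagged = tuple(int(i) for i in np.flatnonzero(data["rate_nmol_min"] < 0))
    return RateTable(data=data, condition_label=condition_label,
                     flagged_negative=flagged)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with standard errors and R².

    vmax in nmol/min, k_half in mM, n_h dimensionless. ``n_h_fixed``
    records whether the Hill coefficient was held at 1 (Michaelis–Menten,
    k_half ≡ Km).
    """

    vmax: float
    k_half: float
    n_h: float
    vmax_stderr: float
    k_half_stderr: float
    n_h_stderr: float
    r_squared: float
    n_h_fixed: bool

    def predict(self, s) -> np.ndarray:
        return hill_rate(s, self.vmax, self.k_half, self.n_h)

    def summary(self) -> str:
        form = "Michaelis–Menten (n_h fixed at 1)" if self.n_h_fixed else "Hill"
        return (
            f"{form} fit\n"
            f"  vmax   : {self.vmax:.4g} ± {self.vmax_stderr:.2g} nmol/min\n"
            f"  k_half : {self.k_half:.4g} ± {self.k_half_stderr:.2g} mM\n"
            f"  n_h    : {self.n_h:.4g} ± {self.n_h_stderr:.2g}\n"
            f"  R²     : {self.r_squared:.4f}"
        )

    def plot(self, table: RateTable | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if table is not None:
            ax.plot(table.substrate, table.rates, "o", label="rates")
            smax = table.substrate.max()
        else:
            smax = 4 * self.k_half
        grid = np.linspace(0, smax, 100)
        ax.plot(grid, self.predict(grid), "-",
                label=f"fit: vmax={self.vmax:.3g}, n_h={self.n_h:.2f}")
        ax.set_xlabel("substrate (mM)")
        ax.set_ylabel("rate (nmol/min)")
        ax.legend()
        return ax


class HillModel:
    """Least-squares Hill fit of a RateTable."""

    def __init__(self, table: RateTable):
        if table.data["substrate_mM"].nunique() < 4:
            raise ValueError("need at least 4 substrate levels for a Hill fit")
        if np.allclose(table.rates, 0.0, atol=1e-15):
            raise ValueError("all rates ~ 0: kinetic parameters unidentifiable")
        self.table = table

    def fit(self, fix_n_h: float | None = None) -> HillFit:
        s = self.table.substrate
        v = self.table.rates
        vmax0 = float(np.max(v))
        if vmax0 <= 0:
            raise ValueError("maximal observed rate <= 0: cannot initialize fit")
        half = np.interp(vmax0 / 2, np.sort(v), np.sort(s)) if len(s) > 1 else 1.0
        model = lmfit.Model(hill_rate, independent_vars=["s"])
        params = model.make_params(
            vmax=vmax0, k_half=max(half, 1e-6), n_h=1.0 if fix_n_h is None else fix_n_h
        )
        params["vmax"].set(min=0.0)
        params["k_half"].set(min=1e-9)
        params["n_h"].set(min=1e-3, max=10.0, vary=fix_n_h is None)
        res = model.fit(v, params, s=s)
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - float(np.sum(res.residual**2)) / ss_tot if ss_tot > 0 else 1.0
        p = res.params
        return HillFit(
            vmax=float(p["vmax"].value),
            k_half=float(p["k_half"].value),
            n_h=float(p["n_h"].value),
            vmax_stderr=float(p["vmax"].stderr or np.nan),
            k_half_stderr=float(p["k_half"].stderr or np.nan),
            n_h_stderr=float(p["n_h"].stderr or np.nan) if fix_n_h is None else 0.0,
            r_squared=r2,
            n_h_fixed=fix_n_h is not None,
        )


def fit_hill(table: RateTable, fix_n_h: float | None = None) -> HillFit:
    """Convenience wrapper: ``HillModel(table).fit()``."""
    return HillModel(table).fit(fix_n_h=fix_n_h)
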