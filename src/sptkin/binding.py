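"""1:1 bio-layer interferometry binding kinetics.

For a 1:1 Langmuir interaction A + B ⇌ AB the association-phase response
follows a single exponential

    Y(t) = Y0 + a·(1 − e^(−kobs·t)),        kobs = ka·[A] + kd,

the dissociation phase decays as Y(t) = Y0 + a·e^(−kd·t), and the
equilibrium dissociation constant is KD = kd/ka. A single-concentration
sensorgram yields kd from the dissociation phase, kobs from the
association phase and hence ka = (kobs − kd)/[A]; a titration series
yields ka as the slope of kobs against [A] (with the intercept as a
consistency check on kd).
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .simulate import Sensorgram

__all__ = [
    "PhaseFit",
    "BindingFit",
    "BindingKineticsModel",
    "fit_association",
    "fit_dissociation",
    "estimate_ka",
    "compute_kd",
]


class UnidentifiableFitError(RuntimeError):
    """The data cannot constrain the requested rate (e.g. flat segment)."""


@dataclass(frozen=True)
class PhaseFit:
    """One exponential phase fit: Y0, amplitude a, rate, χ² and R²."""

    y0: float
    a: float
    rate: float  # kobs (association) or kd (dissociation), s⁻¹
    rate_stderr: float
    chi2: float
    r_squared: float


def _r_squared(y, resid) -> float:
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0


def _fit_exponential(t, y, rising: bool) -> PhaseFit:
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 10:
        raise ValueError("need at least 10 samples in the phase segment")
    amp0 = float(y[-1] - y[0]) if rising else float(y[0] - y[-1])
    if abs(amp0) < 1e-12 * max(1.0, np.abs(y).max()) and np.ptp(y) == 0:
        raise UnidentifiableFitError("flat segment: rate unidentifiable")
    # log-linearized initial rate guess from the early response
    span = t[-1] - t[0]
    rate0 = 3.0 / span
    frac = (y - y[0]) / amp0 if rising else None
    if rising and amp0 != 0:
        early = (frac > 0.05) & (frac < 0.95)
        if early.sum() >= 3:
            with np.errstate(invalid="ignore", divide="ignore"):
                z = -np.log1p(-np.clip(frac[early], 1e-9, 1 - 1e-9))
            slope = np.polyfit(t[early], z, 1)[0]
            if slope > 0:
                rate0 = slope

    if rising:
        def model(tt, y0, a, rate):
            return y0 + a * (1.0 - np.exp(-rate * tt))
        a0, y00 = amp0, float(y[0])
    else:
        def model(tt, y0, a, rate):
            return y0 + a * np.exp(-rate * tt)
        y00, a0 = float(y[-1]), float(y[0] - y[-1])

    m = lmfit.Model(model)
    params = m.make_params(y0=y00, a=a0, rate=max(rate0, 1e-8))
    params["rate"].set(min=0.0)
    try:
        res = m.fit(y, params, tt=t)
    except Exception as exc:  # pragma: no cover - lmfit rarely hard-fails
        raise RuntimeError(
            f"phase fit failed to converge (initial guess y0={y00:.3g}, "
            f"a={a0:.3g}, rate={rate0:.3g})"
        ) from exc
    rate = float(res.params["rate"].value)
    a_fit = float(res.params["a"].value)
    if abs(a_fit) < 1e-10 * max(1.0, np.abs(y).max()) or rate < 1e-10:
        raise UnidentifiableFitError(
            "amplitude or rate collapsed to zero: rate unidentifiable"
        )
    return PhaseFit(
        y0=float(res.params["y0"].value),
        a=a_fit,
        rate=rate,
        rate_stderr=float(res.params["rate"].stderr or np.nan),
        chi2=float(res.chisqr),
        r_squared=_r_squared(y, res.residual),
    )


def fit_association(t, response) -> PhaseFit:
    """Fit Y = Y0 + a·(1 − e^(−kobs·t)) to an association segment.

    ``t`` should be re-zeroed to the segment start. Returns the fitted
    kobs (s⁻¹) in ``rate`` with χ² (unit weights) and R².
    """
    return _fit_exponential(t, response, rising=True)


def fit_dissociation(t, response) -> PhaseFit:
    """Fit Y = Y0 + a·e^(−kd·t) to a dissociation segment."""
    return _fit_exponential(t, response, rising=False)


def estimate_ka(kobs_values, analyte_concs, kd: float) -> tuple[float, dict]:
    """Association rate from kobs = ka·[A] + kd.

    One (kobs, [A]) pair inverts the relation directly,
    ka = (kobs − kd)/[A]; several pairs give ka as the regression slope of
    kobs on [A], with the intercept reported as a consistency diagnostic
    against the supplied kd.
    """
    kobs = np.atleast_1d(np.asarray(kobs_values, float))
    conc = np.atleast_1d(np.asarray(analyte_concs, float))
    if len(kobs) != len(conc) or len(kobs) == 0:
        raise ValueError("need matching, non-empty kobs and concentration lists")
    if len(kobs) == 1:
        if conc[0] <= 0:
            raise ValueError("analyte concentration must be > 0")
        if kobs[0] <= kd:
            raise ValueError(
                f"kobs = {kobs[0]:.4g} <= kd = {kd:.4g} at positive [A]: unphysical"
            )
        return float((kobs[0] - kd) / conc[0]), {"mode": "single"}
    slope, intercept = np.polyfit(conc, kobs, 1)
    if slope <= 0:
        raise ValueError("kobs does not increase with [A]: unphysical")
    return float(slope), {
        "mode": "regression",
        "intercept": float(intercept),
        "intercept_minus_kd": float(intercept - kd),
    }


def compute_kd(ka: float, kd: float) -> dict:
    """Equilibrium dissociation constant KD = kd/ka, in M and µM."""
    if ka <= 0:
        raise ValueError("ka must be > 0")
    kd_m = kd / ka
    return {"KD_M": kd_m, "KD_uM": kd_m * 1e6}


@dataclass(frozen=True)
class BindingFit:
    """Full 1:1 kinetic characterization of one sensorgram.

    KD is stored exactly as kd/ka. ``kd_from_dissoc`` is the directly
    fitted dissociation rate (the one used for ka extraction);
    ``chi2``/``r_squared`` summarize both phases together.
    """

    ka: float
    kd: float
    kobs: float
    kd_from_dissoc: float
    y0: float
    a: float
    KD: float
    chi2: float
    r_squared: float
    association: PhaseFit
    dissociation: PhaseFit

    def summary(self) -> str:
        return (
            "1:1 binding kinetics\n"
            f"  kobs : {self.kobs:.4g} s⁻¹\n"
            f"  kd   : {self.kd:.4g} s⁻¹ (dissociation phase)\n"
            f"  ka   : {self.ka:.4g} M⁻¹s⁻¹\n"
            f"  KD   : {self.KD:.4g} M = {1e6 * self.KD:.3g} µM\n"
            f"  χ²   : {self.chi2:.4g}   R² : {self.r_squared:.4f}"
        )


class BindingKineticsModel:
    """Fit the 1:1 model to a phase-annotated sensorgram.

    The dissociation phase is fitted first for kd, the association phase
    for kobs, and ka follows from kobs = ka·[A] + kd at the sensorgram's
    analyte concentration.
    """

    def __init__(self, sensorgram: Sensorgram):
        if sensorgram.analyte_conc <= 0:
            raise ValueError("sensorgram must carry a positive analyte concentration")
        for phase in ("association", "dissociation"):
            if phase not in sensorgram.phases:
                raise ValueError(f"sensorgram lacks a {phase!r} phase annotation")
        self.sensorgram = sensorgram

    def fit(self) -> BindingFit:
        t_a, y_a = self.sensorgram.segment("association")
        t_d, y_d = self.sensorgram.segment("dissociation")
        assoc = fit_association(t_a, y_a)
        dissoc = fit_dissociation(t_d, y_d)
        kd = dissoc.rate
        ka, _ = estimate_ka([assoc.rate], [self.sensorgram.analyte_conc], kd)
        n_a, n_d = len(t_a), len(t_d)
        r2 = (assoc.r_squared * n_a + dissoc.r_squared * n_d) / (n_a + n_d)
        return BindingFit(
            ka=ka,
            kd=kd,
            kobs=assoc.rate,
            kd_from_dissoc=kd,
            y0=assoc.y0,
            a=assoc.a,
            KD=kd / ka,
            chi2=assoc.chi2 + dissoc.chi2,
            r_squared=r2,
            association=assoc,
            dissociation=dissoc,
        )
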