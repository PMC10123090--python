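"""Diffusive-state decomposition from square-displacement distributions.

The workhorse of multi-state mobility analysis: for tracks undergoing
Brownian motion in 2D in one of *k* static diffusive states, the squared
single-lag displacement x = r² is exponentially distributed within each
state, so the cumulative distribution of pooled squared displacements is a
k-component exponential mixture

    CDF(x) = 1 − Σᵢ fᵢ · exp( −x / (4·Dᵢ·τ + 4·σ²_eff) )

with occupancy fractions fᵢ (Σfᵢ = 1), diffusion coefficients Dᵢ and an
optional shared localization-error offset σ²_eff. The model CDF is fitted
to the empirical CDF by least squares with multi-start optimization;
nested models (k vs k−1) are compared with an F-test coupled to a relative
BIC-decrease gate, and the jump-distance (step length) histogram provides
an independent goodness-of-fit check of the accepted decomposition, with
parameters held fixed.

Components are always reported in descending-D order and labelled
"fast mobile" / "slow mobile" / "immobile".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .msd import squared_displacements
from .tracks import TrackSet

__all__ = [
    "SQDSample",
    "MixtureFit",
    "ModelSelectionResult",
    "GlobalFit",
    "JumpDistanceReport",
    "SQDMixtureModel",
    "GlobalSQDModel",
    "compute_sqd",
    "fit_sqd_mixture",
    "select_model",
    "global_fit_sqd",
    "fit_jump_distance",
    "STATE_LABELS",
]

STATE_LABELS = {1: ("mobile",), 2: ("slow mobile", "immobile"),
                3: ("fast mobile", "slow mobile", "immobile")}


class FitConvergenceError(RuntimeError):
    """All optimizer starts failed; carries the best attempt for diagnosis."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SQDSample:
    """Pooled squared displacements at one lag, with their empirical CDF."""

    lag: float  # seconds
    sq_displacements: np.ndarray  # µm², sorted ascending
    n: int
    condition_label: str = ""

    def __post_init__(self) -> None:
        x = np.sort(np.asarray(self.sq_displacements, dtype=float))
        if np.any(x < 0) or not np.all(np.isfinite(x)):
            raise ValueError("squared displacements must be finite and >= 0")
        object.__setattr__(self, "sq_displacements", x)
        object.__setattr__(self, "n", len(x))

    @property
    def empirical_cdf(self) -> np.ndarray:
        """Empirical CDF values rank/n at each sorted displacement."""
        return np.arange(1, self.n + 1) / self.n


def compute_sqd(ts: TrackSet, lag: int = 1, exclude_last_point: bool = True) -> SQDSample:
    """Pool squared displacements at an exact frame lag across all tracks.

    Pairs of localizations separated by a different number of frames (gap
    closures) contribute nothing. Warns below 100 displacements; raises on
    an empty sample.
    """
    sq = [squared_displacements(t, lag, exclude_last_point) for t in ts.tracks]
    sq = np.concatenate(sq) if sq else np.empty(0)
    if len(sq) == 0:
        raise ValueError(f"no displacement pairs at lag {lag}")
    if len(sq) < 100:
        warnings.warn(
            f"only {len(sq)} squared displacements at lag {lag}; mixture fits unreliable"
        )
    return SQDSample(
        lag=lag * ts.frame_interval,
        sq_displacements=sq,
        n=len(sq),
        condition_label=ts.condition_label,
    )


@dataclass(frozen=True)
class MixtureFit:
    """A fitted k-state diffusive mixture.

    d_components (µm²/s) sorted descending; fractions sum to 1; rss is the
    residual sum of squares of the model CDF against the empirical CDF;
    bic = n·ln(rss/n) + n_params·ln(n) with n_params = 2k − 1 (the
    Gaussian-residual form on the fitted CDF). ``loglik`` is the
    log-likelihood of the squared displacements under the fitted
    exponential-mixture density — the basis of the ``likelihood_bic``
    guard used in model selection.
    """

    k: int
    d_components: np.ndarray
    fractions: np.ndarray
    sigma2_eff: float
    lag: float
    rss: float
    n: int
    n_params: int
    bic: float
    loglik: float = np.nan
    condition_label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.d_components, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if len(d) != self.k or len(f) != self.k:
            raise ValueError("component count mismatch")
        if np.any(np.diff(d) > 0):
            raise ValueError("d_components must be sorted descending")
        if np.any((f < -1e-9) | (f > 1 + 1e-9)) or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must lie in [0,1] and sum to 1")
        object.__setattr__(self, "d_components", d)
        object.__setattr__(self, "fractions", np.clip(f, 0.0, 1.0))

    @property
    def labels(self) -> tuple[str, ...]:
        """Mobility class per component, by descending D."""
        return STATE_LABELS[self.k]

    @property
    def likelihood_bic(self) -> float:
        """BIC under the exponential-mixture density, −2·loglik + p·ln n."""
        return -2.0 * self.loglik + self.n_params * np.log(self.n)

    def cdf(self, x) -> np.ndarray:
        """Model CDF of squared displacements at this fit's lag."""
        return _mixture_cdf(np.asarray(x, float), self.d_components, self.fractions,
                            self.lag, self.sigma2_eff)

    def summary(self) -> str:
        lines = [
            f"SQD mixture fit: k = {self.k} states, lag τ = {1e3 * self.lag:.0f} ms, "
            f"n = {self.n} displacements",
            f"  rss = {self.rss:.4g}   BIC = {self.bic:.1f}",
        ]
        for lab, d, f in zip(self.labels, self.d_components, self.fractions):
            lines.append(f"  {lab:<12s} D = {d:.4g} µm²/s   fraction = {100 * f:.1f}%")
        return "\n".join(lines)

    def plot(self, sample: SQDSample | None = None, ax=None):
        """Overlay the fitted CDF on an empirical CDF."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if sample is not None:
            ax.semilogx(sample.sq_displacements, sample.empirical_cdf,
                        ".", ms=2, label="empirical")
            grid = np.geomspace(max(sample.sq_displacements[0], 1e-8),
                                sample.sq_displacements[-1], 200)
        else:
            grid = np.geomspace(1e-6, 1.0, 200)
        ax.semilogx(grid, self.cdf(grid), "-", label=f"k = {self.k} fit")
        ax.set_xlabel("squared displacement (µm²)")
        ax.set_ylabel("cumulative probability")
        ax.legend()
        return ax


def _mixture_cdf(x, d, f, lag, sigma2_eff):
    means = 4.0 * np.asarray(d) * lag + 4.0 * sigma2_eff  # E[r²] per state
    means = np.maximum(means, 1e-300)
    return 1.0 - np.exp(-x[:, None] / means[None, :]) @ np.asarray(f)


def _mixture_loglik(x, d, f, lag, sigma2_eff) -> float:
    """Log-likelihood of squared displacements under the exponential mixture."""
    means = np.maximum(4.0 * np.asarray(d) * lag + 4.0 * sigma2_eff, 1e-300)
    f = np.asarray(f)
    log_comp = np.log(np.maximum(f / means, 1e-300))[None, :] - x[:, None] / means[None, :]
    m = log_comp.max(axis=1)
    return float(np.sum(m + np.log(np.sum(np.exp(log_comp - m[:, None]), axis=1))))


def _stick_to_fractions(u: np.ndarray) -> np.ndarray:
    """Stick-breaking map from k−1 values in [0,1] to k fractions summing to 1."""
    f = []
    rest = 1.0
    for ui in u:
        f.append(rest * ui)
        rest *= 1.0 - ui
    f.append(rest)
    return np.asarray(f)


def _fractions_to_stick(f: np.ndarray) -> np.ndarray:
    u = []
    rest = 1.0
    for fi in f[:-1]:
        u.append(np.clip(fi / rest if rest > 1e-12 else 0.5, 1e-6, 1 - 1e-6))
        rest -= fi
    return np.asarray(u)


def _quantile_starts(sqd: SQDSample, k: int, n_starts: int, seed: int,
                     sigma2_eff: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Initial (D, fractions) guesses from spread quantiles of the sample.

    The first start places each component's mean squared displacement at a
    quantile of the data (fast components at high quantiles); the remaining
    starts perturb it log-normally with a seeded generator.
    """
    rng = np.random.default_rng(seed)
    qs = {1: [0.63], 2: [0.85, 0.30], 3: [0.90, 0.55, 0.15]}[k]
    x_q = np.quantile(sqd.sq_displacements, qs)
    # mean of Exp = x at CDF 0.63; treat each quantile as a component mean
    d0 = np.maximum((x_q - 4 * sigma2_eff) / (4.0 * sqd.lag), 1e-8)
    f0 = np.full(k, 1.0 / k)
    starts = [(d0, f0)]
    for _ in range(n_starts - 1):
        d = d0 * rng.lognormal(0.0, 0.7, size=k)
        f = rng.dirichlet(np.ones(k))
        starts.append((np.sort(d)[::-1], f))
    return starts


class SQDMixtureModel:
    """Least-squares fit of the k-exponential CDF mixture to an SQDSample.

    Fractions are constrained to the simplex by a stick-breaking
    parameterization; diffusion coefficients are kept non-negative by
    bounds. ``fit`` runs ``n_starts`` optimizer starts (quantile-based
    first guess plus seeded log-normal perturbations) and returns the best.

    Parameters
    ----------
    sqd : SQDSample
    k : int
        Number of diffusive states, 1–3.
    sigma2_eff : float
        Shared localization-error variance offset (µm²) inside each
        exponential mean, ``4·D·τ + 4·σ²_eff``. Fixed, default 0.
    """

    def __init__(self, sqd: SQDSample, k: int, sigma2_eff: float = 0.0):
        if not 1 <= k <= 3:
            raise ValueError("k must be between 1 and 3")
        if sqd.n < 2 * k:
            raise ValueError("sample too small for the requested k")
        self.sqd = sqd
        self.k = k
        self.sigma2_eff = sigma2_eff

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        d = np.exp(theta[: self.k])
        u = theta[self.k :]
        f = _stick_to_fractions(u)
        model = _mixture_cdf(self.sqd.sq_displacements, d, f, self.sqd.lag,
                             self.sigma2_eff)
        return model - self.sqd.empirical_cdf

    def fit(self, n_starts: int = 8, seed: int = 0,
            warm_start: MixtureFit | None = None) -> MixtureFit:
        """Fit the k-component mixture; returns the best of all starts.

        ``warm_start`` seeds one extra start from a simpler fit's optimum
        with its dominant component split in two — this keeps nested fits
        monotone in rss and is used by ``select_model``.
        """
        best = None
        starts = _quantile_starts(self.sqd, self.k, n_starts, seed, self.sigma2_eff)
        if warm_start is not None and warm_start.k == self.k - 1:
            j = int(np.argmax(warm_start.fractions))
            d = np.insert(warm_start.d_components, j, warm_start.d_components[j] * 3.0)
            f = warm_start.fractions.copy()
            f[j] /= 2.0
            f = np.insert(f, j, f[j])
            order = np.argsort(d)[::-1]
            starts.insert(0, (np.maximum(d[order], 1e-8), f[order]))
        lo = np.concatenate([np.full(self.k, np.log(1e-8)),
                             np.full(self.k - 1, 1e-9)])
        hi = np.concatenate([np.full(self.k, np.log(1e4)),
                             np.full(self.k - 1, 1 - 1e-9)])
        for d0, f0 in starts:
            theta0 = np.concatenate([np.log(np.clip(d0, 1e-8, 1e4)),
                                     _fractions_to_stick(f0)])
            theta0 = np.clip(theta0, lo, hi)
            try:
                sol = optimize.least_squares(
                    self._residuals, theta0, bounds=(lo, hi),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:  # singular starts happen; other starts cover
                continue
            rss = 2.0 * sol.cost
            if best is None or rss < best[0]:
                best = (rss, sol)
        if best is None:
            raise FitConvergenceError(
                f"no optimizer start converged for k={self.k}", best=None
            )
        rss, sol = best
        d = np.exp(sol.x[: self.k])
        f = _stick_to_fractions(sol.x[self.k :])
        order = np.argsort(d)[::-1]
        d, f = d[order], f[order]
        n, p = self.sqd.n, 2 * self.k - 1
        bic = n * np.log(max(rss, 1e-300) / n) + p * np.log(n)
        loglik = _mixture_loglik(self.sqd.sq_displacements, d, f,
                                 self.sqd.lag, self.sigma2_eff)
        return MixtureFit(
            k=self.k, d_components=d, fractions=f, sigma2_eff=self.sigma2_eff,
            lag=self.sqd.lag, rss=float(rss), n=n, n_params=p, bic=float(bic),
            loglik=loglik,
            condition_label=self.sqd.condition_label,
        )


def fit_sqd_mixture(sqd: SQDSample, k: int, sigma2_eff: float = 0.0,
                    n_starts: int = 8, seed: int = 0,
                    warm_start: MixtureFit | None = None) -> MixtureFit:
    """Convenience wrapper: ``SQDMixtureModel(sqd, k).fit()``."""
    return SQDMixtureModel(sqd, k, sigma2_eff=sigma2_eff).fit(
        n_starts=n_starts, seed=seed, warm_start=warm_start
    )


@dataclass(frozen=True)
class ComparisonStep:
    """One nested-model comparison (k−1 → k).

    ``bic_decrease`` is the relative decrease of the CDF-residual BIC,
    (BIC_prev − BIC_new)/|BIC_prev|, gated against the 5% threshold;
    ``likelihood_bic_decrease`` is the absolute improvement of the
    likelihood-based BIC, required to be positive (see ``select_model``).
    """

    k_from: int
    k_to: int
    f_statistic: float
    p_value: float
    bic_decrease: float
    likelihood_bic_decrease: float
    accepted: bool
    note: str = ""


@dataclass(frozen=True)
class ModelSelectionResult:
    """Fits for k = 1..k_max and the accepted component count.

    A step from k−1 to k components is accepted only when the F-test is
    significant (p < alpha) AND the BIC decreases by more than ``bic_drop``
    relative to the simpler model; the search stops at the first rejection.
    """

    fits: tuple[MixtureFit, ...]
    comparisons: tuple[ComparisonStep, ...]
    selected_k: int
    alpha: float
    bic_drop: float

    @property
    def selected_fit(self) -> MixtureFit:
        return self.fits[self.selected_k - 1]

    def summary(self) -> str:
        lines = [f"Model selection (F-test α = {self.alpha}, "
                 f"BIC drop > {100 * self.bic_drop:.0f}%): selected k = {self.selected_k}"]
        for c in self.comparisons:
            verdict = "accepted" if c.accepted else "rejected"
            extra = f" [{c.note}]" if c.note else ""
            lines.append(
                f"  k {c.k_from}→{c.k_to}: F = {c.f_statistic:.3g}, "
                f"p = {c.p_value:.3g}, ΔBIC/|BIC| = {100 * c.bic_decrease:.2f}% "
                f"→ {verdict}{extra}"
            )
        lines.append(self.selected_fit.summary())
        return "\n".join(lines)


def select_model(sqd: SQDSample, k_max: int = 3, alpha: float = 0.05,
                 bic_drop: float = 0.05, sigma2_eff: float = 0.0,
                 n_starts: int = 8, seed: int = 0) -> ModelSelectionResult:
    """Choose the number of diffusive states by nested F-test + BIC gates.

    A step from k−1 to k components is accepted only when all three hold:

    1. F-test on the CDF residual sums of squares is significant:
       F = ((rss_{k−1} − rss_k)/Δp) / (rss_k/(n − p_k)) with Δp = 2 extra
       parameters per added state (one D, one fraction), p < ``alpha``.
    2. The CDF-residual BIC falls by more than ``bic_drop`` relative to
       the simpler model: (BIC_{k−1} − BIC_k)/|BIC_{k−1}| > bic_drop.
    3. The likelihood-based BIC (−2·loglik + p·ln n under the
       exponential-mixture density of the squared displacements) improves
       at all. CDF residuals are strongly correlated, so criteria 1–2
       alone are anti-conservative; this guard restores calibration
       without ever rejecting a decisively supported component.

    A perfect simpler fit (rss = 0) retains the simpler model.
    """
    fits: list[MixtureFit] = []
    comparisons: list[ComparisonStep] = []
    selected = 1
    prev: MixtureFit | None = None
    for k in range(1, k_max + 1):
        fit = fit_sqd_mixture(sqd, k, sigma2_eff=sigma2_eff,
                              n_starts=n_starts, seed=seed, warm_start=prev)
        if prev is not None and fit.rss > prev.rss:
            # nested models cannot genuinely fit worse; keep the simpler
            # optimum re-expressed at k (duplicate component, zero mass)
            warnings.warn(
                f"k={k} optimizer returned higher rss than k={k - 1}; reusing k={k - 1}"
            )
            d_aug = np.concatenate([prev.d_components, [prev.d_components[-1]]])
            f_aug = np.concatenate([prev.fractions, [0.0]])
            order = np.argsort(d_aug)[::-1]
            d, f = d_aug[order], f_aug[order]
            n, p = prev.n, 2 * k - 1
            fit = MixtureFit(
                k=k, d_components=d, fractions=f, sigma2_eff=prev.sigma2_eff,
                lag=prev.lag, rss=prev.rss, n=n, n_params=p,
                bic=float(n * np.log(max(prev.rss, 1e-300) / n) + p * np.log(n)),
                loglik=prev.loglik,
                condition_label=prev.condition_label,
            )
        fits.append(fit)
        if prev is not None:
            n = sqd.n
            p_k = fit.n_params
            if prev.rss <= 0:
                comparisons.append(ComparisonStep(
                    k_from=k - 1, k_to=k, f_statistic=np.nan, p_value=1.0,
                    bic_decrease=0.0, likelihood_bic_decrease=0.0, accepted=False,
                    note="perfect fit, simpler model retained",
                ))
                break
            dp = 2
            fstat = ((prev.rss - fit.rss) / dp) / (fit.rss / (n - p_k))
            pval = float(stats.f.sf(fstat, dp, n - p_k))
            bic_dec = (prev.bic - fit.bic) / abs(prev.bic) if prev.bic != 0 else np.inf
            lik_dec = prev.likelihood_bic - fit.likelihood_bic
            accepted = bool((pval < alpha) and (bic_dec > bic_drop) and (lik_dec > 0))
            comparisons.append(ComparisonStep(
                k_from=k - 1, k_to=k, f_statistic=float(fstat), p_value=pval,
                bic_decrease=float(bic_dec),
                likelihood_bic_decrease=float(lik_dec), accepted=accepted,
            ))
            if not accepted:
                break
            selected = k
        prev = fit
    return ModelSelectionResult(
        fits=tuple(fits), comparisons=tuple(comparisons), selected_k=selected,
        alpha=alpha, bic_drop=bic_drop,
    )


# ---------------------------------------------------------------------------
# Global (cross-condition) fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlobalFit:
    """Shared diffusion coefficients across conditions.

    One D vector (sorted descending) for all conditions; each condition
    keeps its own fraction vector, enabling direct population-fraction
    comparison across strains/treatments.
    """

    k: int
    d_components: np.ndarray
    fractions: dict[str, np.ndarray]
    rss_per_condition: dict[str, float]
    total_rss: float
    lag: float
    sigma2_eff: float

    def summary(self) -> str:
        labels = STATE_LABELS[self.k]
        lines = [f"Global SQD fit: k = {self.k}, shared D across "
                 f"{len(self.fractions)} conditions (lag {1e3 * self.lag:.0f} ms)"]
        for lab, d in zip(labels, self.d_components):
            lines.append(f"  {lab:<12s} D = {d:.4g} µm²/s")
        for cond, f in self.fractions.items():
            fr = ", ".join(f"{lab}: {100 * fi:.1f}%" for lab, fi in zip(labels, f))
            lines.append(f"  [{cond}] {fr}  (rss = {self.rss_per_condition[cond]:.4g})")
        return "\n".join(lines)


class GlobalSQDModel:
    """Simultaneous CDF fit of several conditions with one shared D vector."""

    def __init__(self, samples: dict[str, SQDSample], k: int, sigma2_eff: float = 0.0):
        if len(samples) < 1:
            raise ValueError("need at least one condition")
        lags = {round(s.lag, 12) for s in samples.values()}
        if len(lags) > 1:
            raise ValueError(f"conditions have incompatible lags: {sorted(lags)}")
        if not 1 <= k <= 3:
            raise ValueError("k must be between 1 and 3")
        self.samples = dict(samples)
        self.k = k
        self.sigma2_eff = sigma2_eff
        self.lag = next(iter(samples.values())).lag

    def _unpack(self, theta):
        d = np.exp(theta[: self.k])
        fracs = {}
        off = self.k
        for name in self.samples:
            fracs[name] = _stick_to_fractions(theta[off : off + self.k - 1])
            off += self.k - 1
        return d, fracs

    def _residuals(self, theta):
        d, fracs = self._unpack(theta)
        out = []
        for name, s in self.samples.items():
            model = _mixture_cdf(s.sq_displacements, d, fracs[name], s.lag,
                                 self.sigma2_eff)
            out.append(model - s.empirical_cdf)
        return np.concatenate(out)

    def fit(self, n_starts: int = 8, seed: int = 0) -> GlobalFit:
        pooled = SQDSample(
            lag=self.lag,
            sq_displacements=np.concatenate(
                [s.sq_displacements for s in self.samples.values()]
            ),
            n=0,
        )
        best = None
        nc = len(self.samples)
        lo = np.concatenate([np.full(self.k, np.log(1e-8)),
                             np.full(nc * (self.k - 1), 1e-9)])
        hi = np.concatenate([np.full(self.k, np.log(1e4)),
                             np.full(nc * (self.k - 1), 1 - 1e-9)])
        for d0, f0 in _quantile_starts(pooled, self.k, n_starts, seed, self.sigma2_eff):
            theta0 = np.concatenate(
                [np.log(np.clip(d0, 1e-8, 1e4))]
                + [_fractions_to_stick(f0)] * nc
            )
            theta0 = np.clip(theta0, lo, hi)
            try:
                sol = optimize.least_squares(
                    self._residuals, theta0, bounds=(lo, hi),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitConvergenceError("global fit failed to converge", best=None)
        d, fracs = self._unpack(best.x)
        order = np.argsort(d)[::-1]
        d = d[order]
        fracs = {name: f[order] for name, f in fracs.items()}
        rss_per = {}
        for name, s in self.samples.items():
            model = _mixture_cdf(s.sq_displacements, d, fracs[name], s.lag,
                                 self.sigma2_eff)
            rss_per[name] = float(np.sum((model - s.empirical_cdf) ** 2))
        return GlobalFit(
            k=self.k, d_components=d, fractions=fracs,
            rss_per_condition=rss_per, total_rss=float(sum(rss_per.values())),
            lag=self.lag, sigma2_eff=self.sigma2_eff,
        )


def global_fit_sqd(samples: dict[str, SQDSample], k: int, sigma2_eff: float = 0.0,
                   n_starts: int = 8, seed: int = 0) -> GlobalFit:
    """Convenience wrapper: ``GlobalSQDModel(samples, k).fit()``."""
    return GlobalSQDModel(samples, k, sigma2_eff=sigma2_eff).fit(
        n_starts=n_starts, seed=seed
    )


# ---------------------------------------------------------------------------
# Jump-distance goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JumpDistanceReport:
    """Goodness of an SQD mixture against the step-length histogram.

    The fitted CDF mixture implies a Rayleigh-mixture density of jump
    distances r:  p(r) = Σᵢ fᵢ · r/(2(Dᵢτ + σ²_eff)) · e^(−r²/(4Dᵢτ + 4σ²_eff)).
    Parameters are held fixed (nothing is refitted); the report carries χ²
    against the histogram and R² between observed and predicted bin masses.
    """

    bin_edges: np.ndarray
    observed: np.ndarray  # counts per bin
    expected: np.ndarray  # model counts per bin
    chi2: float
    dof: int
    r_squared: float

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        widths = np.diff(self.bin_edges)
        ax.bar(centers, self.observed, width=widths, alpha=0.5, label="observed")
        ax.plot(centers, self.expected, "k-", label="Rayleigh mixture")
        ax.set_xlabel("jump distance r (µm)")
        ax.set_ylabel("counts")
        ax.legend()
        return ax


def _rayleigh_mixture_cdf(r, fit: MixtureFit):
    means = 4.0 * fit.d_components * fit.lag + 4.0 * fit.sigma2_eff
    means = np.maximum(means, 1e-300)
    return 1.0 - np.exp(-(r[:, None] ** 2) / means[None, :]) @ fit.fractions


def fit_jump_distance(ts: TrackSet, fit: MixtureFit, lag: int = 1,
                      bins: str | int = "fd", min_count: int = 5) -> JumpDistanceReport:
    """Score a fitted mixture against the jump-distance histogram.

    Jump distances at the given frame lag are histogrammed
    (Freedman–Diaconis by default); the expected counts come from the
    Rayleigh mixture implied by ``fit`` with its parameters held fixed.
    Sparse trailing bins (expected < ``min_count``) are merged before the
    χ² is computed.
    """
    sq = compute_sqd(ts, lag=lag)
    if abs(sq.lag - fit.lag) > 1e-12:
        raise ValueError("MixtureFit lag does not match the requested track lag")
    r = np.sqrt(sq.sq_displacements)
    edges = np.histogram_bin_edges(r, bins=bins)
    if len(edges) - 1 < 5:
        raise ValueError("fewer than 5 histogram bins; supply finer binning")
    observed, _ = np.histogram(r, bins=edges)
    cdf_at_edges = _rayleigh_mixture_cdf(edges, fit)
    expected = sq.n * np.diff(cdf_at_edges)

    # merge bins from the tail until every expected count is adequate
    obs_m, exp_m, edge_list = [], [], [edges[0]]
    acc_o, acc_e = 0.0, 0.0
    for o, e, edge in zip(observed, expected, edges[1:]):
        acc_o += o
        acc_e += e
        if acc_e >= min_count:
            obs_m.append(acc_o)
            exp_m.append(acc_e)
            edge_list.append(edge)
            acc_o, acc_e = 0.0, 0.0
    if acc_e > 0:
        if obs_m:
            obs_m[-1] += acc_o
            exp_m[-1] += acc_e
            edge_list[-1] = edges[-1]
        else:
            obs_m, exp_m = [acc_o], [acc_e]
            edge_list.append(edges[-1])
    observed_m = np.asarray(obs_m)
    expected_m = np.asarray(exp_m)
    if len(observed_m) < 5:
        raise ValueError("fewer than 5 usable bins after merging")
    chi2 = float(np.sum((observed_m - expected_m) ** 2 / expected_m))
    dof = len(observed_m) - 1  # parameters were fixed, not fitted here
    ss_res = float(np.sum((observed_m - expected_m) ** 2))
    ss_tot = float(np.sum((observed_m - observed_m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return JumpDistanceReport(
        bin_edges=np.asarray(edge_list), observed=observed_m, expected=expected_m,
        chi2=chi2, dof=dof, r_squared=r2,
    )
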