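"""Relative quantification from qPCR cycle-threshold tables.

Primer efficiencies E (per-cycle amplification factor, ideally 2) are
calibrated from dilution series: the regression of Ct on log10(input) has
slope −1/log10(E), so E = 10^(−1/slope). Relative copy number of a target
amplicon versus a reference is computed by the efficiency-corrected
(Pfaffl-style) generalization of the 2^−ΔCt method,

    ratio = E_t^(−Ct_t) / E_r^(−Ct_r) · (d_r·v_r)/(d_t·v_t),

which reduces to 2^(−ΔCt) for equal efficiencies of 2 and equal
dilution/volume factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CopyRatio",
    "primer_efficiency",
    "relative_copy_number",
]


def primer_efficiency(log10_dilution, ct) -> dict:
    """Amplification efficiency from a calibration dilution series.

    Parameters
    ----------
    log10_dilution : array-like
        log10 of the relative template input per point.
    ct : array-like
        Measured cycle thresholds.

    Returns a dict with ``efficiency``, the regression ``slope`` and
    ``r_squared``. A non-negative slope (Ct not decreasing with more
    template) is rejected as unphysical.
    """
    x = np.asarray(log10_dilution, float)
    y = np.asarray(ct, float)
    if len(x) < 3:
        raise ValueError("need at least 3 dilution points")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError(
            f"dilution-curve slope {slope:.3g} >= 0: Ct must fall with more template"
        )
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return {
        "efficiency": float(10.0 ** (-1.0 / slope)),
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": r2,
    }


@dataclass(frozen=True)
class CopyRatio:
    """Relative copy number (target per reference) with replicate spread."""

    ratio: float
    sd: float
    n_replicates: int
    efficiency_target: float
    efficiency_ref: float

    def summary(self) -> str:
        return (
            f"Relative copy number: {self.ratio:.4g} ± {self.sd:.2g} "
            f"(n = {self.n_replicates}; E_target = {self.efficiency_target:.3f}, "
            f"E_ref = {self.efficiency_ref:.3f})"
        )


def relative_copy_number(
    ct_table: pd.DataFrame,
    efficiency_target: float = 2.0,
    efficiency_ref: float = 2.0,
    target: str = "target",
    reference: str = "reference",
) -> CopyRatio:
    """Efficiency-corrected relative quantification of target vs reference.

    ``ct_table`` is tidy with columns ``target`` (amplicon name),
    ``replicate``, ``ct`` and optional ``dilution``/``volume`` correction
    factors (fraction of material carried into the reaction, and sample
    volume used for purification; both default to 1). Replicates are
    paired by replicate index; the ratio is reported as mean ± sd over
    replicate pairs.
    """
    for col in ("target", "replicate", "ct"):
        if col not in ct_table.columns:
            raise ValueError(f"Ct table needs column {col!r}")
    for e in (efficiency_target, efficiency_ref):
        if not 1.0 < e <= 2.0:
            raise ValueError("efficiencies must be in (1, 2]")
    df = ct_table.copy()
    if "dilution" not in df.columns:
        df["dilution"] = 1.0
    if "volume" not in df.columns:
        df["volume"] = 1.0
    tgt = df[df["target"] == target].set_index("replicate")
    ref = df[df["target"] == reference].set_index("replicate")
    if ref.empty:
        raise ValueError(f"no reference rows (target == {reference!r})")
    if tgt.empty:
        raise ValueError(f"no target rows (target == {target!r})")
    common = tgt.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError("no replicate indices shared between target and reference")
    ratios = []
    for rep in common:
        t_row, r_row = tgt.loc[rep], ref.loc[rep]
        scale = (r_row["dilution"] * r_row["volume"]) / (
            t_row["dilution"] * t_row["volume"]
        )
        ratios.append(
            efficiency_target ** (-t_row["ct"])
            / efficiency_ref ** (-r_row["ct"])
            * scale
        )
    ratios = np.asarray(ratios, float)
    return CopyRatio(
        ratio=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        n_replicates=len(ratios),
        efficiency_target=efficiency_target,
        efficiency_ref=efficiency_ref,
    )
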