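"""Config-driven simulate → analyze → report pipeline.

A YAML/JSON config describes any subset of four stages — SPT (tracks →
filter → MSD → SQD model selection → optional global fit and TAMSD
clustering), BLI binding kinetics, ATPase Hill kinetics and qPCR relative
quantification. Inputs are either file paths or simulation parameter
blocks; every stage records the seed and parameters that produced it, and
a fixed config + seed reproduces byte-identical JSON output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import BindingKineticsModel
from .cluster import cluster_tamsd
from .enzyme import RateTable, fit_hill
from .msd import compute_msd, fit_msd_linear
from .qpcr import relative_copy_number
from .simulate import (
    HillSimParams,
    QpcrSimParams,
    Sensorgram,
    SensorgramSimParams,
    TrackSimParams,
    simulate_qpcr,
    simulate_rate_curve,
    simulate_sensorgram,
    simulate_tracks,
)
from .sqd import compute_sqd, fit_jump_distance, global_fit_sqd, select_model
from .tracks import filter_tracks, read_tracks_csv, write_tracks_csv

__all__ = ["run_pipeline", "load_config", "make_fixtures"]

log = logging.getLogger("sptkin.pipeline")


def _jsonable(obj):
    """Recursively convert results objects / arrays to JSON-ready values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_config(path) -> dict:
    """Load a YAML (or JSON, which YAML subsumes) pipeline config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _get_tracks(block: dict, seed: int):
    if "tracks_csv" in block:
        p = Path(block["tracks_csv"])
        if not p.exists():
            raise FileNotFoundError(p)
        return read_tracks_csv(p, frame_interval=block.get("frame_interval", 0.024))
    sim = dict(block["simulate"])
    sim.setdefault("seed", seed)
    sim["diffusion_constants"] = tuple(sim["diffusion_constants"])
    sim["fractions"] = tuple(sim["fractions"])
    return simulate_tracks(TrackSimParams(**sim))


def _spt_stage(block: dict, seed: int) -> dict:
    ts = _get_tracks(block, seed)
    ts = filter_tracks(
        ts,
        min_length=block.get("min_length", 5),
        bleach_cutoff_frame=block.get(
            "bleach_cutoff_frame", 0 if "simulate" in block else 500
        ),
    )
    lag = block.get("lag", 1)
    msd = compute_msd(ts, max_lag=block.get("max_lag", 4))
    msd_fit = fit_msd_linear(msd)
    sqd = compute_sqd(ts, lag=lag)
    selection = select_model(
        sqd,
        k_max=block.get("k_max", 3),
        alpha=block.get("alpha", 0.05),
        bic_drop=block.get("bic_drop", 0.05),
        seed=seed,
    )
    out = {
        "n_tracks": len(ts),
        "msd_fit": _jsonable(msd_fit)
        | {"curve": {"lags_s": msd.lags.tolist(), "msd_um2": msd.msd.tolist(),
                     "n_pairs": msd.n_pairs.tolist()}},
        "model_selection": _jsonable(selection),
        "selected_k": selection.selected_k,
    }
    if block.get("jump_distance", True):
        try:
            out["jump_distance"] = _jsonable(
                fit_jump_distance(ts, selection.selected_fit, lag=lag)
            )
        except ValueError as exc:
            out["jump_distance_warning"] = str(exc)
    if block.get("cluster", True):
        clu = cluster_tamsd(ts, k=selection.selected_k, seed=seed)
        out["tamsd_clusters"] = _jsonable(clu)
    return out


def _spt_global_stage(block: dict, seed: int) -> dict:
    samples = {}
    for cond in block["conditions"]:
        ts = _get_tracks(cond, seed)
        ts = filter_tracks(
            ts,
            min_length=cond.get("min_length", 5),
            bleach_cutoff_frame=cond.get(
                "bleach_cutoff_frame", 0 if "simulate" in cond else 500
            ),
        )
        samples[cond.get("label", f"condition{len(samples)}")] = compute_sqd(
            ts, lag=block.get("lag", 1)
        )
    gf = global_fit_sqd(samples, k=block["k"], seed=seed)
    return _jsonable(gf)


def _bli_stage(block: dict, seed: int) -> dict:
    if "sensorgram_csv" in block:
        df = pd.read_csv(block["sensorgram_csv"])
        phases = {}
        for name in ("association", "dissociation"):
            idx = np.flatnonzero((df["phase"] == name).to_numpy())
            if len(idx):
                phases[name] = (int(idx[0]), int(idx[-1]) + 1)
        sg = Sensorgram(
            t=df["t_s"].to_numpy(float),
            response=df["response"].to_numpy(float),
            phases=phases,
            analyte_conc=float(block["analyte_conc"]),
        )
    else:
        sim = dict(block["simulate"])
        sim.setdefault("seed", seed)
        sg = simulate_sensorgram(SensorgramSimParams(**sim))
    fit = BindingKineticsModel(sg).fit()
    return _jsonable(fit)


def _atpase_stage(block: dict, seed: int) -> dict:
    if "rates_csv" in block:
        df = pd.read_csv(block["rates_csv"])
        table = RateTable(data=df)
    else:
        sim = dict(block["simulate"])
        sim.setdefault("seed", seed)
        sim["substrate_grid"] = tuple(sim.get("substrate_grid",
                                              HillSimParams.substrate_grid))
        df = simulate_rate_curve(HillSimParams(**sim))
        table = RateTable(data=df)
    fit = fit_hill(table, fix_n_h=block.get("fix_n_h"))
    return _jsonable(fit)


def _qpcr_stage(block: dict, seed: int) -> dict:
    if "ct_csv" in block:
        df = pd.read_csv(block["ct_csv"])
    else:
        sim = dict(block["simulate"])
        sim.setdefault("seed", seed)
        df = simulate_qpcr(QpcrSimParams(**sim))
    ratio = relative_copy_number(
        df,
        efficiency_target=block.get("efficiency_target", 2.0),
        efficiency_ref=block.get("efficiency_ref", 2.0),
    )
    return _jsonable(ratio)


_STAGES = {
    "spt": _spt_stage,
    "spt_global": _spt_global_stage,
    "bli": _bli_stage,
    "atpase": _atpase_stage,
    "qpcr": _qpcr_stage,
}


def run_pipeline(config: dict, out_dir=None, seed: int | None = None) -> dict:
    """Execute the stages present in ``config`` and return the run report.

    The report maps stage name → results dict, plus a ``provenance`` block
    (package version, config hash, seed). A stage failure is recorded with
    its error and aborts only that stage's downstream dependents; completed
    stages are retained. If ``out_dir`` is given, ``report.json`` and a
    per-stage TSV summary are written there.
    """
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config_sha256_16": cfg_hash,
            "seed": seed,
        },
        "stages": {},
        "warnings": [],
    }
    for name, fn in _STAGES.items():
        if name not in config:
            continue
        log.info("running stage %s", name)
        try:
            report["stages"][name] = fn(config[name], seed)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            report["warnings"].append(f"stage {name} failed: {exc}")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        _write_tsv_summary(report, out / "summary.tsv")
    return report


def _write_tsv_summary(report: dict, path: Path) -> None:
    rows = []
    for stage, res in report["stages"].items():
        if "error" in res:
            rows.append((stage, "error", res["error"]))
            continue
        flat = pd.json_normalize(res, sep=".").iloc[0].to_dict()
        for k, v in flat.items():
            if isinstance(v, (int, float, str, bool)):
                rows.append((stage, k, v))
    pd.DataFrame(rows, columns=["stage", "quantity", "value"]).to_csv(
        path, sep="\t", index=False
    )


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the small file-fixture set used by the test suite.

    Produces a track CSV, a sensorgram CSV, a rate table CSV and a Ct
    table CSV, plus ``manifest.json`` listing every ground-truth parameter.
    Regenerates identically for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    tp = TrackSimParams(
        diffusion_constants=(0.5, 0.01),
        fractions=(0.5, 0.5),
        n_tracks=200,
        localization_sigma=0.0,
        seed=seed,
    )
    ts = simulate_tracks(tp)
    write_tracks_csv(ts, out / "tracks.csv")
    manifest["files"]["tracks.csv"] = {
        "ground_truth": _jsonable(dataclasses.asdict(tp)),
        "n_tracks": len(ts),
        "n_tracks_after_default_sim_filter": len(
            filter_tracks(ts, min_length=5, bleach_cutoff_frame=0)
        ),
    }

    sp = SensorgramSimParams(ka=7.42e4, kd=0.16, analyte_conc=2e-6, rmax=1.0,
                             noise_sd=0.0, seed=seed)
    sg = simulate_sensorgram(sp)
    sg.to_dataframe().to_csv(out / "sensorgram.csv", index=False)
    manifest["files"]["sensorgram.csv"] = {
        "ground_truth": _jsonable(dataclasses.asdict(sp))
    }

    hp = HillSimParams(vmax=0.023, k_half=0.5, n_h=0.97, noise_sd=0.0, seed=seed)
    simulate_rate_curve(hp).to_csv(out / "rates.csv", index=False)
    manifest["files"]["rates.csv"] = {"ground_truth": _jsonable(dataclasses.asdict(hp))}

    qp = QpcrSimParams(true_copy_ratio=5.0, efficiency_target=1.9,
                       efficiency_ref=2.0, noise_sd=0.0, seed=seed)
    simulate_qpcr(qp).to_csv(out / "ct.csv", index=False)
    manifest["files"]["ct.csv"] = {"ground_truth": _jsonable(dataclasses.asdict(qp))}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
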