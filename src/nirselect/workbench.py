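"""Experiment driver: full-spectrum PLS vs the four selectors, with a
comparison table in the usual reporting shape (method / variable number /
RMSEP / R^2) and convergence diagnostics for the optimizer runs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, NIRCalibration
from .dataset import read_dataset
from .partition import MCCVPlan
from .preprocess import PreprocessSpec
from .synthetic import planted_band_benchmark

log = logging.getLogger("nirselect")

__all__ = ["ExperimentConfig", "run_comparison", "convergence_report"]

_PREPROCESS_ALIASES = {
    "none": PreprocessSpec("none"),
    "snv": PreprocessSpec("snv"),
    "msc": PreprocessSpec("msc"),
    "sg1": PreprocessSpec("sg_derivative", deriv_order=1),
    "sg2": PreprocessSpec("sg_derivative", deriv_order=2),
}


@dataclass
class ExperimentConfig:
    """One comparison run, fully reproducible from (config, seed).

    Flat key=value config-file dialect (version 1)::

        dataset = spectra.csv        # or: preset = planted-band
        response = protein
        preprocess = snv             # none|snv|msc|sg1|sg2
        fraction = 0.6667
        n_lv = auto                  # or an integer
        methods = full,uve,mcuve,rt,dbwo
        seed = 1
        pop_size = 20
        max_iter = 100
        tf = V2
        mccv_repeats = 20
        mccv_fraction = 0.8
        out_dir = results
    """

    dataset_path: Optional[str] = None
    response_column: str = "y"
    preset: Optional[str] = None
    preprocess: str = "none"
    fraction: float = 2.0 / 3.0
    n_lv: Optional[int] = None
    methods: tuple = ("full", "uve", "mcuve", "rt", "dbwo")
    seed: int = 0
    pop_size: int = 20
    max_iter: int = 100
    tf: str = "V2"
    mccv_repeats: int = 20
    mccv_fraction: float = 0.8
    out_dir: Optional[str] = None
    selector_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dataset_path is None and self.preset is None:
            raise ValueError("config needs a dataset path or a preset")
        if not self.methods:
            raise ValueError("need at least one method (or 'full')")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        kv = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
        c: dict = {}
        if "dataset" in kv:
            c["dataset_path"] = kv["dataset"]
        if "preset" in kv:
            c["preset"] = kv["preset"]
        if "response" in kv:
            c["response_column"] = kv["response"]
        if "preprocess" in kv:
            c["preprocess"] = kv["preprocess"]
        if "fraction" in kv:
            c["fraction"] = float(kv["fraction"])
        if "n_lv" in kv:
            c["n_lv"] = None if kv["n_lv"] == "auto" else int(kv["n_lv"])
        if "methods" in kv:
            c["methods"] = tuple(m.strip() for m in kv["methods"].split(","))
        for key, cast in (("seed", int), ("pop_size", int), ("max_iter", int),
                          ("mccv_repeats", int), ("mccv_fraction", float)):
            if key in kv:
                c[key] = cast(kv[key])
        if "tf" in kv:
            c["tf"] = kv["tf"]
        if "out_dir" in kv:
            c["out_dir"] = kv["out_dir"]
        return cls(**c)


def _load(cfg: ExperimentConfig):
    if cfg.preset is not None:
        if cfg.preset != "planted-band":
            raise ValueError(f"unknown preset {cfg.preset!r}")
        ds, _ = planted_band_benchmark(cfg.seed)
        return ds
    return read_dataset(cfg.dataset_path, cfg.response_column)


def run_comparison(cfg: ExperimentConfig) -> pd.DataFrame:
    """Fit every requested method on the shared Kennard-Stone training
    partition, evaluate on the prediction partition, and tabulate
    (method, n_variables, RMSEP, R^2, RMSECV) rows plus the percentage
    improvement of each selector's RMSECV over the full spectrum's.

    A selector failure is recorded in its row and the run continues.
    """
    ds = _load(cfg)
    plan = MCCVPlan(n_repeats=cfg.mccv_repeats,
                    calib_fraction=cfg.mccv_fraction, seed=cfg.seed)
    cal = NIRCalibration(ds, preprocess=_PREPROCESS_ALIASES[cfg.preprocess],
                         train_fraction=cfg.fraction, n_lv=cfg.n_lv,
                         mccv_plan=plan)
    log.info("comparison run: n_lv=%d seed=%d methods=%s",
             cal.n_lv, cfg.seed, ",".join(cfg.methods))
    rows, results = [], {}
    for method in cfg.methods:
        kw = dict(cfg.selector_kwargs.get(method, {}))
        if method == "dbwo":
            kw.setdefault("pop_size", cfg.pop_size)
            kw.setdefault("max_iter", cfg.max_iter)
            kw.setdefault("tf", cfg.tf)
        try:
            log.info("method=%s seed=%d", method, cfg.seed)
            res = cal.fit(method=method, seed=cfg.seed, selector_kwargs=kw)
            results[method] = res
            rows.append(res.to_row())
        except Exception as exc:  # failure is a row, not an abort
            log.warning("method=%s failed: %s", method, exc)
            rows.append({"method": method.upper(), "n_variables": np.nan,
                         "rmsecv": np.nan, "rmsep": np.nan, "r2": np.nan,
                         "error": str(exc)})
    table = pd.DataFrame(rows)
    full = table.loc[table["method"] == "FULL"]
    if len(full):
        base = float(full["rmsecv"].iloc[0])
        table["rmsecv_improvement_pct"] = 100.0 * (base - table["rmsecv"]) / base
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparison.csv", index=False)
        for method, res in results.items():
            if res.selection is not None and res.selection.fitness_curve is not None:
                pd.DataFrame({
                    "iteration": np.arange(1, len(res.selection.fitness_curve) + 1),
                    "best_rmsecv": res.selection.fitness_curve,
                }).to_csv(out / f"convergence_{method}.csv", index=False)
    table.attrs["results"] = results
    return table


def convergence_report(curves: dict[str, np.ndarray]) -> pd.DataFrame:
    """Summarise per-transfer-function fitness curves.

    One row per curve: initial and final best RMSECV and the iteration of
    the last improvement (0 for a constant curve).  A non-monotone curve
    means broken greedy acceptance and is a hard failure.
    """
    if not curves:
        raise ValueError("need at least one curve")
    rows = []
    for name, curve in curves.items():
        c = np.asarray(curve, dtype=float)
        if np.any(np.diff(c) > 1e-12):
            raise ValueError(
                f"curve {name!r} is not monotone non-increasing: greedy "
                "acceptance is broken")
        drops = np.flatnonzero(np.diff(c) < 0)
        rows.append({"curve": name,
                     "initial_rmsecv": float(c[0]),
                     "final_rmsecv": float(c[-1]),
                     "last_improvement_iter": int(drops[-1] + 1) if drops.size else 0})
    return pd.DataFrame(rows)
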