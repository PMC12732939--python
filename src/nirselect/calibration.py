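"""Model/Results facade tying the pipeline together.

:class:`NIRCalibration` is the model object: it owns the data, the
pretreatment, the Kennard-Stone partition and the latent-variable policy.
``fit(method=...)`` runs the chosen variable selector (or none) on the
calibration partition, fits the final PLS model on the surviving
channels, evaluates it on the held-out prediction partition, and returns
a :class:`CalibrationResult` carrying the fitted model, the selection
diagnostics, the figures of merit and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .dbwo import BWOConfig, dbwo_select
from .partition import MCCVPlan, SplitResult, kennard_stone_split
from .pls import (MetricReport, PLSModel, fit_pls, predict, r_squared,
                  rmse, rmsecv, select_lv_mccv)
from .preprocess import PreprocessSpec, apply_preprocess
from .selectors import (SelectionResult, mcuve_select, rt_select, uve_select)

__all__ = ["NIRCalibration", "CalibrationResult"]

_METHODS = ("full", "uve", "mcuve", "rt", "dbwo")


class NIRCalibration:
    """A PLS calibration problem on one spectral dataset.

    Parameters
    ----------
    dataset : SpectralDataset
        Spectra plus reference values.
    preprocess : PreprocessSpec, optional
        Pretreatment; per-sample transforms (SNV, derivatives) are applied
        before the split, MSC uses the training-mean reference after it.
    train_fraction : float
        Kennard-Stone calibration share (default two-thirds).
    n_lv : int or None
        Latent-variable count; None selects it by MCCV on the calibration
        partition (full spectrum) and then holds it fixed for every
        selector, including inside the DBWO fitness.
    mccv_plan : MCCVPlan
        Shared Monte Carlo cross-validation plan for RMSECV and LV choice.
    """

    def __init__(self, dataset: SpectralDataset,
                 preprocess: PreprocessSpec = PreprocessSpec("none"),
                 train_fraction: float = 2.0 / 3.0,
                 n_lv: Optional[int] = None,
                 max_lv: int = 15,
                 mccv_plan: MCCVPlan = MCCVPlan()):
        self.dataset = dataset
        self.preprocess = preprocess
        self.train_fraction = train_fraction
        self.mccv_plan = mccv_plan

        if preprocess.method in ("snv", "sg_derivative"):
            # per-sample transforms: order w.r.t. the split is immaterial
            Xt, _ = apply_preprocess(dataset.X, None, preprocess)
            self.split = kennard_stone_split(Xt, train_fraction)
            self.X_train = Xt[self.split.train_idx]
            self.X_test = Xt[self.split.test_idx]
        else:
            self.split = kennard_stone_split(dataset.X, train_fraction)
            Xtr = dataset.X[self.split.train_idx]
            Xte = dataset.X[self.split.test_idx]
            self.X_train, self.X_test = apply_preprocess(Xtr, Xte, preprocess)
        self.y_train = dataset.y[self.split.train_idx]
        self.y_test = dataset.y[self.split.test_idx]

        self.lv_curve = None
        if n_lv is None:
            bound = min(max_lv, len(self.y_train) - 1,
                        dataset.n_channels,
                        int(round(mccv_plan.calib_fraction
                                  * len(self.y_train))) - 1)
            n_lv, self.lv_curve = select_lv_mccv(
                self.X_train, self.y_train, bound, mccv_plan)
        self.n_lv = int(n_lv)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response_column: str,
                       **kwargs) -> "NIRCalibration":
        """Build from a wide DataFrame (first column sample id, numeric
        wavelength columns, one response column)."""
        id_col = df.columns[0]
        chan = [c for c in df.columns if c not in (id_col, response_column)]
        ds = SpectralDataset(X=df[chan].to_numpy(float),
                             wavelengths=np.array([float(c) for c in chan]),
                             y=df[response_column].to_numpy(float),
                             sample_ids=df[id_col].astype(str).tolist())
        return cls(ds, **kwargs)

    def fit(self, method: str = "full", seed: int = 0,
            selector_kwargs: Optional[dict] = None) -> "CalibrationResult":
        """Select variables (per ``method``) and fit/evaluate the PLS model.

        method: "full" (no selection), "uve", "mcuve", "rt" or "dbwo".
        """
        method = method.lower()
        if method not in _METHODS:
            raise ValueError(f"unknown method {method!r}; use one of {_METHODS}")
        kw = dict(selector_kwargs or {})
        sel: Optional[SelectionResult] = None
        if method == "uve":
            sel = uve_select(self.X_train, self.y_train, self.n_lv,
                             seed=seed, **kw)
        elif method == "mcuve":
            sel = mcuve_select(self.X_train, self.y_train, self.n_lv,
                               seed=seed, **kw)
        elif method == "rt":
            sel = rt_select(self.X_train, self.y_train, self.n_lv,
                            seed=seed, **kw)
        elif method == "dbwo":
            tf = kw.pop("tf", "V2")
            cfg = kw.pop("config", None) or BWOConfig(seed=seed, **kw)
            ds_train = self.dataset.subset(self.split.train_idx)
            sel = dbwo_select(ds_train, self.n_lv, cfg, tf=tf,
                              plan=self.mccv_plan, X=self.X_train)
        mask = None if sel is None else sel.mask
        n_lv = min(self.n_lv,
                   self.dataset.n_channels if mask is None else int(mask.sum()))
        model = fit_pls(self.X_train, self.y_train, n_lv, mask=mask)
        y_hat = predict(model, self.X_test)
        cv = rmsecv(self.X_train, self.y_train, n_lv, self.mccv_plan,
                    mask=mask)
        metrics = MetricReport(
            rmsecv=cv, rmsep=rmse(self.y_test, y_hat),
            r2=r_squared(self.y_test, y_hat),
            n_variables=self.dataset.n_channels if mask is None
            else int(mask.sum()))
        return CalibrationResult(calibration=self, method=method, model=model,
                                 selection=sel, metrics=metrics,
                                 y_pred=y_hat, seed=seed)


@dataclass
class CalibrationResult:
    """A fitted, externally validated calibration."""

    calibration: NIRCalibration
    method: str
    model: PLSModel
    selection: Optional[SelectionResult]
    metrics: MetricReport
    y_pred: np.ndarray
    seed: int
    extras: dict = field(default_factory=dict)

    @property
    def selected_wavelengths(self) -> np.ndarray:
        wl = self.calibration.dataset.wavelengths
        if self.selection is None:
            return wl
        return wl[self.selection.mask]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict new spectra given on the full (preprocessed) channel grid."""
        return predict(self.model, np.atleast_2d(X))

    def summary(self) -> str:
        """Plain-text summary table in the usual reporting shape
        (method / variable number / RMSEP / R^2, plus RMSECV)."""
        m = self.metrics
        lines = [
            "PLS calibration summary",
            "=" * 47,
            f"{'method':<22}{self.method.upper()}",
            f"{'n latent variables':<22}{self.model.n_lv}",
            f"{'variable number':<22}{m.n_variables}",
            f"{'RMSECV':<22}{m.rmsecv:.4f}",
            f"{'RMSEP':<22}{m.rmsep:.4f}",
            f"{'R^2':<22}{m.r2:.4f}",
            f"{'train/test samples':<22}"
            f"{len(self.calibration.y_train)}/{len(self.calibration.y_test)}",
            f"{'seed':<22}{self.seed}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        """One comparison-table row."""
        return {"method": self.method.upper(),
                "n_variables": self.metrics.n_variables,
                "rmsecv": self.metrics.rmsecv,
                "rmsep": self.metrics.rmsep,
                "r2": self.metrics.r2}
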