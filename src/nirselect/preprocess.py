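"""Spectral pretreatments: SNV, MSC and Savitzky-Golay derivatives.

Scatter in diffuse-reflectance NIR shows up as a per-sample affine
distortion of the true absorbance spectrum.  SNV removes it by
standardising each spectrum; MSC by regressing each spectrum on a
reference (conventionally the mean training spectrum) and inverting the
fitted affine map.  Derivatives suppress baseline and enhance band
resolution; they are computed with Savitzky-Golay polynomial filters so
the output stays aligned with the wavelength axis (no shape shrinkage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["PreprocessSpec", "snv", "msc", "sg_derivative", "apply_preprocess"]


@dataclass(frozen=True)
class PreprocessSpec:
    """Which pretreatment to apply, with its parameters.

    method: one of {"none", "snv", "msc", "sg_derivative"}.
    window_length / poly_order / deriv_order apply to Savitzky-Golay only;
    msc_reference "mean-of-training" uses the training-partition mean
    spectrum (leakage-free), or an explicit vector may be given.
    """

    method: str = "none"
    window_length: int = 11
    poly_order: int = 2
    deriv_order: int = 1
    msc_reference: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.method not in ("none", "snv", "msc", "sg_derivative"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "sg_derivative":
            if self.window_length % 2 == 0:
                raise ValueError("window_length must be odd")
            if self.window_length <= self.poly_order:
                raise ValueError("window_length must exceed poly_order")
            if self.deriv_order not in (1, 2):
                raise ValueError("deriv_order must be 1 or 2")
            if self.deriv_order > self.poly_order:
                raise ValueError("deriv_order cannot exceed poly_order")


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centred and scaled to unit sample
    standard deviation (n-1 denominator).  Idempotent.  A constant row has
    zero spread and is rejected.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant spectrum (zero spread) at sample index {bad[0]}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is modelled as x ~ a + b*reference by least squares and
    corrected to (x - a) / b, undoing the per-sample affine scatter.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] != X.shape[1]:
        raise ValueError(
            f"reference length {ref.shape[0]} != n_channels {X.shape[1]}")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    bad = np.flatnonzero(b == 0)
    if bad.size:
        raise ValueError(
            f"zero scatter slope for sample index {bad[0]}; row has no "
            "component along the reference trend")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def sg_derivative(X: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Row-wise Savitzky-Golay derivative (order 1 or 2), same shape as the
    input; boundary windows use polynomial extrapolation (mode='interp')."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if spec.method != "sg_derivative":
        raise ValueError("spec.method must be 'sg_derivative'")
    if X.shape[1] < spec.window_length:
        raise ValueError(
            f"need >= {spec.window_length} channels, got {X.shape[1]}")
    return savgol_filter(X, spec.window_length, spec.poly_order,
                         deriv=spec.deriv_order, delta=1.0, axis=1,
                         mode="interp")


def apply_preprocess(X_train: np.ndarray, X_test: Optional[np.ndarray],
                     spec: PreprocessSpec):
    """Apply a pretreatment to a train/test pair without leakage.

    SNV and derivatives are per-sample transforms, applied independently.
    MSC defaults its reference to the mean spectrum of the *training*
    partition, then corrects both partitions against it.
    Returns (X_train_t, X_test_t) with X_test_t None when X_test is None.
    """
    if spec.method == "none":
        return X_train, X_test
    if spec.method == "snv":
        return snv(X_train), None if X_test is None else snv(X_test)
    if spec.method == "sg_derivative":
        return (sg_derivative(X_train, spec),
                None if X_test is None else sg_derivative(X_test, spec))
    # msc
    ref = spec.msc_reference
    if ref is None:
        ref = np.asarray(X_train, dtype=float).mean(axis=0)
    return msc(X_train, ref), None if X_test is None else msc(X_test, ref)
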