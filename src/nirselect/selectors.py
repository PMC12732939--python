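"""Comparator variable-selection methods: UVE, MC-UVE and the
randomization test.

UVE appends artificial near-zero noise channels to the spectrum, refits
PLS under resampling (leave-one-out here; Monte Carlo subsampling for
MC-UVE), and keeps the real channels whose coefficient stability
mean(b)/sd(b) exceeds the largest stability any noise channel achieves —
a data-driven null threshold.  The randomization test instead builds a
per-channel permutation null by refitting on shuffled responses and keeps
channels with small permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pls import fit_pls

__all__ = ["SelectionResult", "EmptySelectionError", "uve_select",
           "mcuve_select", "rt_select"]


class EmptySelectionError(ValueError):
    """No channel survived the threshold — a configuration error, not a
    result: an empty model cannot be fit."""


@dataclass
class SelectionResult:
    """Outcome of a variable-selection run.

    ``score_per_channel`` holds stabilities (UVE/MC-UVE), p-values (RT) or
    selection frequencies (DBWO); ``fitness_curve`` is the per-iteration
    best RMSECV for the optimizer only.
    """

    mask: np.ndarray
    method: str
    score_per_channel: np.ndarray
    threshold: float
    seed: int
    fitness_curve: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 1:
            raise EmptySelectionError(
                f"{self.method}: empty selection is a configuration error; "
                "relax the threshold or resampling settings")
        if len(self.score_per_channel) != len(self.mask):
            raise ValueError("score vector length != mask length")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def selected_idx(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def _coef_matrix(X, y, n_lv, index_sets):
    """Stack PLS coefficient vectors refit on each row-index subset."""
    B = np.empty((len(index_sets), X.shape[1]))
    for i, idx in enumerate(index_sets):
        B[i] = fit_pls(X[idx], y[idx], n_lv).b
    return B


def _stability(B: np.ndarray) -> np.ndarray:
    sd = B.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.finfo(float).tiny, sd)
    return B.mean(axis=0) / sd


def _with_noise(X, noise_amplitude, rng):
    p = X.shape[1]
    noise = rng.uniform(0.0, 1.0, size=(X.shape[0], p)) * noise_amplitude
    return np.hstack([X, noise]), p


def uve_select(X: np.ndarray, y: np.ndarray, n_lv: int,
               noise_amplitude: float = 1e-10, seed: int = 0) -> SelectionResult:
    """Uninformative variable elimination with leave-one-out stability.

    Appends p uniform-noise channels scaled to ``noise_amplitude`` (small
    enough not to perturb the fit, nonzero so coefficients exist), fits
    PLS leaving each sample out in turn, and keeps real channels whose
    |mean/sd| coefficient stability exceeds the noise channels' maximum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < n_lv + 2:
        raise ValueError(f"need >= n_lv+2 = {n_lv + 2} samples for leave-one-out")
    rng = np.random.default_rng(seed)
    Xa, p = _with_noise(X, noise_amplitude, rng)
    loo = [np.delete(np.arange(n), i) for i in range(n)]
    s = _stability(_coef_matrix(Xa, y, n_lv, loo))
    cut = float(np.max(np.abs(s[p:])))
    mask = np.abs(s[:p]) > cut
    return SelectionResult(mask=mask, method="UVE", score_per_channel=s[:p],
                           threshold=cut, seed=seed)


def mcuve_select(X: np.ndarray, y: np.ndarray, n_lv: int, n_mc: int = 500,
                 calib_fraction: float = 0.8, keep_rule: str = "noise-max",
                 top_k: Optional[int] = None, noise_amplitude: float = 1e-10,
                 seed: int = 0) -> SelectionResult:
    """Monte Carlo UVE: stability over ``n_mc`` random subsample refits.

    ``keep_rule`` is "noise-max" (threshold at the noise channels' maximum
    |stability|, as in UVE) or "top-k" (keep the ``top_k`` most stable real
    channels — for when a tuned model size is wanted).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2; a single split cannot "
                         "estimate coefficient spread")
    n = X.shape[0]
    n_cal = int(round(calib_fraction * n))
    if n_cal < n_lv + 1 or n_cal >= n:
        raise ValueError("calib_fraction infeasible for n and n_lv")
    rng = np.random.default_rng(seed)
    Xa, p = _with_noise(X, noise_amplitude, rng)
    subs = [np.sort(rng.permutation(n)[:n_cal]) for _ in range(n_mc)]
    s = _stability(_coef_matrix(Xa, y, n_lv, subs))
    if keep_rule == "noise-max":
        cut = float(np.max(np.abs(s[p:])))
        mask = np.abs(s[:p]) > cut
    elif keep_rule == "top-k":
        if top_k is None or not 1 <= top_k <= p:
            raise ValueError("top-k rule requires 1 <= top_k <= n_channels")
        order = np.argsort(-np.abs(s[:p]), kind="stable")
        mask = np.zeros(p, dtype=bool)
        mask[order[:top_k]] = True
        cut = float(np.abs(s[:p])[order[top_k - 1]])
    else:
        raise ValueError(f"unknown keep_rule {keep_rule!r}")
    return SelectionResult(mask=mask, method="MC-UVE", score_per_channel=s[:p],
                           threshold=cut, seed=seed)


def rt_select(X: np.ndarray, y: np.ndarray, n_lv: int, n_perm: int = 499,
              alpha: float = 0.05, seed: int = 0) -> SelectionResult:
    """Randomization test on PLS coefficients.

    The null distribution of each coefficient comes from ``n_perm`` refits
    on response vectors permuted without replacement;
    p_j = (1 + #{|b_perm| >= |b_obs|}) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm+1) and selection at alpha=0.05 needs
    n_perm >= 19.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for alpha=0.05 granularity")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    rng = np.random.default_rng(seed)
    b_obs = np.abs(fit_pls(X, y, n_lv).b)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_perm):
        b_perm = fit_pls(X, rng.permutation(y), n_lv).b
        exceed += np.abs(b_perm) >= b_obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    mask = pvals < alpha
    return SelectionResult(mask=mask, method="RT", score_per_channel=pvals,
                           threshold=alpha, seed=seed,
                           diagnostics={"n_perm": n_perm})
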