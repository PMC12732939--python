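"""Sample-set partitioning: Kennard-Stone calibration/prediction split and
Monte Carlo cross-validation split plans."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SplitResult", "MCCVPlan", "kennard_stone_split", "mccv_splits"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive index partition into calibration and prediction."""
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass(frozen=True)
class MCCVPlan:
    """Monte Carlo cross-validation: ``n_repeats`` independent random splits
    at ``calib_fraction``, reproducible from ``seed``."""
    n_repeats: int = 50
    calib_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.calib_fraction < 1:
            raise ValueError("calib_fraction must be in (0, 1)")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def kennard_stone_split(X: np.ndarray, train_fraction: float) -> SplitResult:
    """Deterministic maximin Kennard-Stone selection of a calibration set.

    Seeds with the pair of samples at maximal Euclidean distance, then
    repeatedly adds the sample whose minimum distance to the selected set
    is largest, until round(train_fraction * n) samples are selected
    (half away from zero, so two-thirds of 100/310/72 gives 67/207/48).
    Ties are broken by lowest sample index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = _round_half_away(train_fraction * n)
    n_train = max(2, min(n_train, n - 1))

    D = cdist(X, X)
    # seed pair: global max distance, lowest (i, j) on ties
    flat = np.argmax(D)  # argmax scans row-major -> lexicographic tie-break
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    mind = np.minimum(D[selected[0]], D[selected[1]])
    mind[selected] = -np.inf
    for _ in range(n_train - 2):
        k = int(np.argmax(mind))  # argmax takes the lowest index on ties
        selected.append(k)
        mind = np.minimum(mind, D[k])
        mind[k] = -np.inf
    train = np.sort(np.array(selected))
    mask = np.ones(n, dtype=bool)
    mask[train] = False
    return SplitResult(train_idx=train, test_idx=np.flatnonzero(mask))


def mccv_splits(n: int, plan: MCCVPlan) -> list[SplitResult]:
    """Generate the plan's random calibration/validation splits.

    Each repeat samples round(calib_fraction * n) calibration indices
    without replacement; repeats are independent but the whole sequence is
    a pure function of ``plan.seed``.
    """
    if n < 5:
        raise ValueError("need at least 5 samples for MCCV")
    n_cal = _round_half_away(plan.calib_fraction * n)
    if n_cal >= n or n_cal < 1:
        raise ValueError(
            f"calib_fraction {plan.calib_fraction} leaves an empty partition "
            f"for n={n}")
    rng = np.random.default_rng(plan.seed)
    out = []
    for _ in range(plan.n_repeats):
        perm = rng.permutation(n)
        out.append(SplitResult(train_idx=np.sort(perm[:n_cal]),
                               test_idx=np.sort(perm[n_cal:])))
    return out
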