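"""Discretized beluga whale optimization for spectral variable selection.

Beluga whale optimization (BWO) is a population metaheuristic built on
three behaviours: swimming (global exploration), preying (local
exploitation with a Levy-flight kick) and whale fall (random replacement
that preserves diversity).  A per-whale balance factor
B_f = B0 * (1 - T / (2 T_max)), B0 ~ U(0,1), drives the phase switch:
B_f > 0.5 explores, otherwise exploits; whales with B_f <= W_f (the
whale-fall probability, decaying linearly over iterations) are
additionally perturbed by the whale-fall move.

The optimizer works on continuous positions; a transfer function maps
each coordinate to [0,1] to produce the binary include/exclude channel
mask that the PLS fitness (RMSECV) actually evaluates.  S-shaped
(sigmoid) transfer sets a bit with probability T(x); V-shaped transfer
(V1: error function, V2: hyperbolic tangent) flips the previous bit with
probability T(step), so flips fade as a whale's moves shrink; that
preserves good incumbent masks and usually converges faster.  Per-whale acceptance is greedy (a move is kept only if
its fitness does not worsen), so the best-so-far RMSECV curve is monotone
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma, pi, sin

import numpy as np
from scipy.special import erf

from .dataset import SpectralDataset
from .partition import MCCVPlan, mccv_splits
from .pls import rmsecv
from .selectors import SelectionResult

__all__ = ["BWOConfig", "WhaleState", "transfer", "levy_step", "binarize",
           "bwo_iterate", "dbwo_select"]

_TRANSFER_KINDS = ("sigmoid", "V1", "V2")


@dataclass(frozen=True)
class BWOConfig:
    """Optimizer settings.

    Bounds [-6, 6] cover the effective range of all three transfer
    functions (sigmoid saturates beyond |x| ~ 6).  The whale-fall
    probability decays linearly from ``wf_start`` to ``wf_end``.
    ``tf_step_scale`` normalises the move size fed to the V-shaped
    transfer functions; the default (twice the bound width) makes a
    typical proposal flip a few percent of the channels instead of
    saturating the flip probability at 1.
    """

    pop_size: int = 30
    max_iter: int = 500
    lower: float = -6.0
    upper: float = 6.0
    levy_beta: float = 1.5
    levy_scale: float = 0.05
    wf_start: float = 0.1
    wf_end: float = 0.05
    tf_step_scale: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if not 1 < self.levy_beta <= 2:
            raise ValueError("levy_beta must be in (1, 2]")


@dataclass
class WhaleState:
    """Population snapshot: continuous positions, their binarizations,
    fitnesses and the incumbent best."""

    positions: np.ndarray
    bits: np.ndarray
    fitness: np.ndarray
    best_bits: np.ndarray
    best_fitness: float
    best_position: np.ndarray = field(default_factory=lambda: np.empty(0))
    iteration: int = 0
    balance_factors: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_lv: int = 1
    whale_falls: int = 0  # instrumentation: replacements applied so far


def transfer(x, kind: str):
    """Map a continuous position to [0,1].

    sigmoid: 1/(1+exp(-x)) (S-shaped); V1: |erf(sqrt(pi)/2 * x)|;
    V2: |tanh(x)| (V-shaped, even, zero at the origin).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite transfer input")
    if kind == "sigmoid":
        out = 1.0 / (1.0 + np.exp(-x))
    elif kind == "V1":
        out = np.abs(erf(np.sqrt(pi) / 2.0 * x))
    elif kind == "V2":
        out = np.abs(np.tanh(x))
    else:
        raise ValueError(f"unknown transfer kind {kind!r}; use one of "
                         f"{_TRANSFER_KINDS}")
    return out if out.ndim else float(out)


def levy_sigma(beta: float) -> float:
    """Mantegna scale sigma_u for the numerator normal draw."""
    num = gamma(1.0 + beta) * sin(pi * beta / 2.0)
    den = gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(dim: int, beta: float, scale: float,
              rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Levy-flight step via the Mantegna construction:
    step = scale * u / |v|^(1/beta), u ~ N(0, sigma_u^2), v ~ N(0, 1)."""
    if not 1 < beta <= 2:
        raise ValueError("beta must be in (1, 2]")
    u = rng.normal(0.0, levy_sigma(beta), size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return scale * u / np.abs(v) ** (1.0 / beta)


def binarize(position_row: np.ndarray, previous_bits: np.ndarray, tf: str,
             n_lv: int, rng: np.random.Generator,
             previous_position: np.ndarray | None = None,
             step_scale: float = 1.0) -> np.ndarray:
    """Turn one whale's continuous position into a channel mask.

    S-shaped: bit_j = 1 iff rand_j < T(x_j), read off the position itself.
    V-shaped: flip the previous bit where rand_j < T(d_j), keep it
    otherwise, where d_j is the position *change* this move (divided by
    ``step_scale``) when ``previous_position`` is given, and the position
    itself otherwise.  Driving V-shaped flips by the normalised step means
    a converging whale stops flipping and keeps its incumbent mask — the
    property that makes V-shaped discretization settle faster than the
    S-shaped rule.  If fewer than ``n_lv`` channels end up active, random
    extra channels are switched on so the PLS fitness stays well-defined
    (minimum-selection guard).
    """
    position_row = np.asarray(position_row, dtype=float)
    previous_bits = np.asarray(previous_bits, dtype=bool)
    if position_row.shape != previous_bits.shape:
        raise ValueError("position/bits length mismatch")
    if tf == "sigmoid":
        bits = rng.uniform(size=position_row.shape) < transfer(position_row, tf)
    else:
        arg = position_row if previous_position is None \
            else (position_row - previous_position) / step_scale
        prob = transfer(arg, tf)
        r = rng.uniform(size=position_row.shape)
        bits = np.where(r < prob, ~previous_bits, previous_bits)
    deficit = n_lv - int(bits.sum())
    if deficit > 0:
        off = np.flatnonzero(~bits)
        bits[rng.choice(off, size=deficit, replace=False)] = True
    return bits


def _wf_probability(cfg: BWOConfig, t: int) -> float:
    frac = t / cfg.max_iter if cfg.max_iter > 0 else 0.0
    return cfg.wf_start + (cfg.wf_end - cfg.wf_start) * frac


def bwo_iterate(state: WhaleState, cfg: BWOConfig, fitness_fn, tf: str,
                rng: np.random.Generator) -> WhaleState:
    """Advance the population one generation (in place), returning the state.

    Per whale: draw B_f and apply the exploration (paired-dimension
    sine/cosine move toward a random whale) or exploitation (move toward
    the incumbent best with a Levy-flight term) update; whales with
    B_f <= W_f additionally undergo the whale-fall replacement; positions
    are clamped to bounds, binarized, and accepted greedily.
    """
    pos, bits = state.positions, state.bits
    npop, dim = pos.shape
    T, Tmax = state.iteration + 1, cfg.max_iter
    wf = _wf_probability(cfg, T)
    b0 = rng.uniform(size=npop)
    bf = b0 * (1.0 - T / (2.0 * Tmax))
    state.balance_factors = bf

    for i in range(npop):
        x = pos[i]
        if bf[i] > 0.5:  # exploration: synchronised swimming toward a peer
            r = _other(rng, npop, i)
            pj = rng.permutation(dim)
            r1, r2 = rng.uniform(size=2)
            new = x.copy()
            even = pj[::2]
            odd = pj[1::2]
            new[even] = x[even] + (pos[r][pj[0]] - x[even]) * (1 + r1) * sin(2 * pi * r2)
            new[odd] = x[odd] + (pos[r][pj[0]] - x[odd]) * (1 + r1) * np.cos(2 * pi * r2)
        else:  # exploitation: prey near the incumbent best with a Levy kick
            r = _other(rng, npop, i)
            r3, r4 = rng.uniform(size=2)
            c1 = 2.0 * r4 * (1.0 - T / Tmax)
            lf = levy_step(dim, cfg.levy_beta, cfg.levy_scale, rng)
            best_pos = state.best_position
            new = r3 * best_pos - r4 * x + c1 * lf * (pos[r] - x)
        if bf[i] <= wf:  # whale fall: partial random re-seeding
            r5, r6, r7 = rng.uniform(size=3)
            xr = pos[_other(rng, npop, i)]
            c2 = 2.0 * wf * npop
            xstep = (cfg.upper - cfg.lower) * np.exp(-c2 * T / Tmax)
            new = r5 * x - r6 * xr + r7 * xstep
            state.whale_falls += 1
        np.clip(new, cfg.lower, cfg.upper, out=new)
        new_bits = binarize(new, bits[i], tf, state.n_lv, rng,
                            previous_position=x,
                            step_scale=cfg.tf_step_scale)
        f_new = float(fitness_fn(new_bits))
        if not np.isfinite(f_new):
            raise ValueError(f"non-finite fitness for whale {i}")
        if f_new <= state.fitness[i]:  # greedy acceptance
            pos[i] = new
            bits[i] = new_bits
            state.fitness[i] = f_new
            if f_new < state.best_fitness:
                state.best_fitness = f_new
                state.best_bits = new_bits.copy()
                state.best_position = new.copy()
    state.iteration = T
    return state


def _other(rng: np.random.Generator, npop: int, i: int) -> int:
    r = int(rng.integers(npop - 1))
    return r + 1 if r >= i else r


def dbwo_select(ds: SpectralDataset, n_lv: int, cfg: BWOConfig,
                tf: str = "V2", plan: MCCVPlan | None = None,
                X: np.ndarray | None = None) -> SelectionResult:
    """Run the full DBWO-PLS variable-selection procedure on a training set.

    The fitness of a candidate channel mask is the pooled MCCV RMSECV of a
    PLS model (fixed ``n_lv``) restricted to that mask; one shared split
    plan is reused for every evaluation so mask comparisons are paired.
    Returns the incumbent best mask together with the per-iteration best
    RMSECV curve (monotone non-increasing by greedy acceptance).

    ``X`` overrides the dataset's absorbance matrix (e.g. a preprocessed
    copy); the response always comes from ``ds.y``.
    """
    if tf not in _TRANSFER_KINDS:
        raise ValueError(f"unknown transfer kind {tf!r}")
    Xtr = ds.X if X is None else np.asarray(X, dtype=float)
    y = ds.y
    n, p = Xtr.shape
    if n_lv > min(n - 1, p):
        raise ValueError("n_lv infeasible for this dataset")
    plan = plan or MCCVPlan()
    splits = mccv_splits(n, plan)

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        val = cache.get(key)
        if val is None:
            val = rmsecv(Xtr, y, n_lv, plan, mask=mask, splits=splits)
            cache[key] = val
        return val

    rng = np.random.default_rng(cfg.seed)
    positions = rng.uniform(cfg.lower, cfg.upper, size=(cfg.pop_size, p))
    if tf == "sigmoid":
        bits = np.array([binarize(positions[i], np.zeros(p, bool), tf, n_lv, rng)
                         for i in range(cfg.pop_size)])
    else:
        # V-shaped needs a previous mask: start from unbiased random bits
        prev = rng.uniform(size=(cfg.pop_size, p)) < 0.5
        bits = np.array([binarize(positions[i], prev[i], tf, n_lv, rng)
                         for i in range(cfg.pop_size)])
    fit = np.array([fitness(b) for b in bits])
    ib = int(np.argmin(fit))
    state = WhaleState(positions=positions, bits=bits, fitness=fit,
                       best_bits=bits[ib].copy(), best_fitness=float(fit[ib]),
                       n_lv=n_lv)
    state.best_position = positions[ib].copy()

    curve = np.empty(cfg.max_iter)
    for t in range(cfg.max_iter):
        bwo_iterate(state, cfg, fitness, tf, rng)
        curve[t] = state.best_fitness
    freq = state.bits.mean(axis=0)  # final population inclusion frequency
    return SelectionResult(mask=state.best_bits, method="DBWO",
                           score_per_channel=freq,
                           threshold=float("nan"), seed=cfg.seed,
                           fitness_curve=curve,
                           diagnostics={"tf": tf, "n_lv": n_lv,
                                        "whale_falls": state.whale_falls,
                                        "initial_rmsecv": float(fit[ib])})
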