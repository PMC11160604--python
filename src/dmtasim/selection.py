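"""Selection policy (Pareto fronts + scalarization + epsilon-greedy) and the
Analyze-step bias correction.

Candidates are compared on per-objective *utilities* (predictions after bias
correction, overridden by measurements where available), which puts
non-commensurable objectives on one scale.  Selection partitions candidates
into successive non-dominated fronts, scalarizes within fronts by a weighted
mean, and fills the batch epsilon-greedily.

Because predictions are noisy, the highest predicted scores are overestimates
on average (regression to the mean), which would crowd already-measured
molecules out of future batches.  The bias model regresses measured values on
predicted ones per objective and uses the fit to deflate raw predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionPolicy",
    "BiasModel",
    "pareto_fronts",
    "rank_candidates",
    "epsilon_greedy_select",
    "fit_bias",
    "correct_scores",
]


@dataclass(frozen=True)
class SelectionPolicy:
    """Epsilon-greedy selection on top of front-then-scalar ranking."""

    epsilon: float = 0.1
    weights: tuple[float, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.weights:
            total = sum(self.weights)
            if total <= 0 or any(w < 0 for w in self.weights):
                raise ValueError("weights must be non-negative, not all zero")
            object.__setattr__(
                self, "weights", tuple(w / total for w in self.weights)
            )


def pareto_fronts(utilities: np.ndarray) -> np.ndarray:
    """Fast non-dominated sort: front index (0 = best) per candidate.

    ``utilities`` is (n candidates x m objectives), maximized.  Candidate a
    dominates b iff a >= b in every objective and a > b in at least one.
    -inf sentinel entries are permitted.  Deterministic by construction.
    """
    u = np.asarray(utilities, dtype=float)
    if u.ndim != 2:
        raise ValueError("utilities must be 2-D (candidates x objectives)")
    n = u.shape[0]
    fronts = np.full(n, -1, dtype=int)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominators = np.zeros(n, dtype=int)
    for i in range(n):
        ge = np.all(u[i] >= u, axis=1)
        gt = np.any(u[i] > u, axis=1)
        dominates_i = ge & gt  # i dominates these
        for j in np.nonzero(dominates_i)[0]:
            dominated_by[i].append(int(j))
            n_dominators[j] += 1
    current = [i for i in range(n) if n_dominators[i] == 0]
    k = 0
    while current:
        nxt = []
        for i in current:
            fronts[i] = k
            for j in dominated_by[i]:
                n_dominators[j] -= 1
                if n_dominators[j] == 0:
                    nxt.append(j)
        current = nxt
        k += 1
    return fronts


def _scalar_scores(utilities: np.ndarray, weights) -> np.ndarray:
    u = np.asarray(utilities, dtype=float)
    m = u.shape[1]
    w = np.asarray(weights if weights else np.full(m, 1.0 / m), dtype=float)
    w = w / w.sum()
    with np.errstate(invalid="ignore"):
        return u @ w


def rank_candidates(
    utilities: np.ndarray,
    fronts: np.ndarray,
    policy: SelectionPolicy,
    keys: list[str] | None = None,
) -> list[int]:
    """Total ordering: front ascending, weighted-mean utility descending,
    then dedup key lexicographic (stable, reproducible)."""
    scores = _scalar_scores(utilities, policy.weights)
    n = len(scores)
    tiebreak = keys if keys is not None else [str(i) for i in range(n)]
    return sorted(range(n), key=lambda i: (fronts[i], -scores[i], tiebreak[i]))


def epsilon_greedy_select(
    ordering: list[int],
    k: int,
    epsilon: float,
    rng: np.random.Generator,
    slot_log: list | None = None,
) -> list[int]:
    """Fill k slots sequentially: each slot is a uniform draw over remaining
    candidates with probability epsilon, else the best-ranked remaining.

    If k exceeds the pool, all candidates are selected (shortfall logged).
    """
    pool = list(ordering)
    if k > len(pool):
        logger.info(
            "epsilon_greedy_select: requested %d from pool of %d", k, len(pool)
        )
        k = len(pool)
    chosen: list[int] = []
    for _ in range(k):
        if epsilon > 0 and rng.random() < epsilon:
            j = int(rng.integers(len(pool)))
            slot = "random"
        else:
            j = 0
            slot = "greedy"
        chosen.append(pool.pop(j))
        if slot_log is not None:
            slot_log.append(slot)
    return chosen


@dataclass
class BiasModel:
    """Per-objective OLS fit measured = alpha + beta * predicted.

    Inactive (identity correction) until ``min_pairs`` complete
    prediction-measurement pairs have accumulated, or if the predictor has
    degenerate variance.
    """

    slope: dict[str, float] = field(default_factory=dict)
    intercept: dict[str, float] = field(default_factory=dict)
    n_pairs: dict[str, int] = field(default_factory=dict)
    active: dict[str, bool] = field(default_factory=dict)

    def is_active(self, objective: str) -> bool:
        return self.active.get(objective, False)


def fit_bias(
    pairs: dict[str, list[tuple[float, float]]], min_pairs: int = 10
) -> BiasModel:
    """Refit the bias model from the full (predicted, measured) pair ledger.

    Deterministic given the ledger; each objective activates independently
    once it has ``min_pairs`` finite pairs and non-degenerate predictions.
    """
    model = BiasModel()
    for objective, pair_list in pairs.items():
        arr = np.array(
            [(p, m) for p, m in pair_list if np.isfinite(p) and np.isfinite(m)]
        )
        n = len(arr)
        model.n_pairs[objective] = n
        if n < min_pairs:
            model.active[objective] = False
            continue
        pred, meas = arr[:, 0], arr[:, 1]
        var = pred.var()
        if var <= 1e-12:
            logger.info("fit_bias(%s): degenerate predictor variance", objective)
            model.active[objective] = False
            continue
        beta = float(np.cov(pred, meas, bias=True)[0, 1] / var)
        alpha = float(meas.mean() - beta * pred.mean())
        model.slope[objective] = beta
        model.intercept[objective] = alpha
        model.active[objective] = True
    return model


def correct_scores(
    predictions: dict[str, np.ndarray] | dict[str, float], bias: BiasModel
) -> dict:
    """Apply the fitted correction alpha + beta * prediction per objective.

    Identity where the model is inactive.  Measured values are never passed
    through here: they always supersede predictions upstream.
    """
    out = {}
    for objective, value in predictions.items():
        if bias.is_active(objective):
            out[objective] = (
                bias.intercept[objective] + bias.slope[objective] * np.asarray(value)
                if isinstance(value, np.ndarray)
                else bias.intercept[objective] + bias.slope[objective] * value
            )
        else:
            out[objective] = value
    return out
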