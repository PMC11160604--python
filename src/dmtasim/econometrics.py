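"""Cross-trial statistics: success CDFs, expected costs, cost-model fits,
breakeven model value, and progress-normalized property trajectories.

A campaign ensemble is a set of independent realizations of the same
stochastic process.  The central object is the empirical CDF of program
success over a resource axis (molecules made or DMTA cycles); failed trials
are right-censored at the budget and never counted at any abscissa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .campaign import CampaignConfig, CampaignResult, run_campaign

__all__ = [
    "UNATTAINABLE",
    "run_ensemble",
    "SuccessCDF",
    "success_cdf",
    "success_rate_at_budget",
    "expected_cost_at_rate",
    "CostModelFit",
    "fit_cost_model",
    "breakeven_value",
    "progress_normalize",
    "property_trajectories",
]

#: Sentinel returned when a target success rate is beyond the CDF plateau.
UNATTAINABLE = math.inf


def derive_trial_seed(base_seed: int, trial: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    return int(
        np.random.SeedSequence((base_seed, trial)).generate_state(1)[0] % (2**31)
    )


def run_ensemble(
    config: CampaignConfig,
    oracles,
    templates,
    library,
    hits,
    n_trials: int,
    base_seed: int = 0,
) -> list[CampaignResult]:
    """n independent campaign realizations; trial i reseeds the config from
    (base_seed, i), so results are independent of execution order."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    results = []
    for i in range(n_trials):
        cfg = dc_replace(config, seed=derive_trial_seed(base_seed, i))
        try:
            results.append(run_campaign(cfg, oracles, templates, library, hits))
        except Exception as exc:  # record and continue; never kill the sweep
            import logging

            logging.getLogger(__name__).warning("trial %d errored: %s", i, exc)
    return results


@dataclass(frozen=True)
class SuccessCDF:
    """Empirical step CDF of success over a resource axis.

    CDF(b) = (# successes with cost <= b) / n_trials.  Failures are censored:
    they contribute to the denominator at every b but never to the numerator,
    so the CDF plateaus at the overall success fraction.
    """

    costs: np.ndarray  # sorted success costs
    n_trials: int

    def __call__(self, b: float) -> float:
        return float(np.searchsorted(self.costs, b, side="right")) / self.n_trials

    @property
    def plateau(self) -> float:
        return len(self.costs) / self.n_trials


def _trial_cost(result: CampaignResult, axis: str) -> float:
    if axis == "molecules_made":
        return result.molecules_made
    if axis == "cycles":
        return result.cycles
    raise ValueError(f"unknown axis {axis!r}")


def success_cdf(
    results: list[CampaignResult], axis: str = "molecules_made"
) -> SuccessCDF:
    if not results:
        raise ValueError("need >= 1 trial")
    costs = sorted(_trial_cost(r, axis) for r in results if r.success)
    return SuccessCDF(costs=np.array(costs, dtype=float), n_trials=len(results))


def _bootstrap_ci(
    values: list[tuple[bool, float]],
    statistic,
    n_resamples: int,
    seed: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(values)
    stats = []
    for _ in range(n_resamples):
        idx = rng.integers(n, size=n)
        stats.append(statistic([values[i] for i in idx]))
    stats = np.array(stats, dtype=float)
    finite = stats[np.isfinite(stats)]
    if len(finite) == 0:
        return (UNATTAINABLE, UNATTAINABLE)
    return (
        float(np.quantile(finite, alpha / 2)),
        float(np.quantile(finite, 1 - alpha / 2)),
    )


def success_rate_at_budget(
    results: list[CampaignResult],
    budget: float,
    axis: str = "molecules_made",
    ci: bool = False,
    n_resamples: int = 1000,
    seed: int = 0,
):
    """CDF evaluated at the budget; optionally with a 95% bootstrap interval
    over trials."""
    cdf = success_cdf(results, axis)
    rate = cdf(budget)
    if not ci:
        return rate
    samples = [(r.success, _trial_cost(r, axis)) for r in results]

    def stat(sample):
        good = sorted(c for s, c in sample if s)
        return float(np.searchsorted(good, budget, side="right")) / len(sample)

    return rate, _bootstrap_ci(samples, stat, n_resamples, seed)


def expected_cost_at_rate(
    results: list[CampaignResult],
    target_rate: float,
    axis: str = "molecules_made",
    ci: bool = False,
    n_resamples: int = 1000,
    seed: int = 0,
):
    """Smallest budget at which the success CDF reaches the target rate.

    Returns the UNATTAINABLE sentinel (never an extrapolation) when the CDF
    plateaus below the target.
    """
    cdf = success_cdf(results, axis)

    def min_cost(costs: np.ndarray, n: int) -> float:
        need = int(math.ceil(target_rate * n))
        if need <= 0:
            return 0.0
        if need > len(costs):
            return UNATTAINABLE
        return float(costs[need - 1])

    point = min_cost(cdf.costs, cdf.n_trials)
    if not ci:
        return point
    samples = [(r.success, _trial_cost(r, axis)) for r in results]

    def stat(sample):
        good = np.array(sorted(c for s, c in sample if s), dtype=float)
        return min_cost(good, len(sample))

    return point, _bootstrap_ci(samples, stat, n_resamples, seed)


@dataclass(frozen=True)
class CostModelFit:
    """Exponential cost model budget(sigma) = a * exp(k * sigma), fit by OLS
    in log space; goodness reported on the natural (molecules) scale."""

    a: float
    k: float
    r_squared: float
    mae: float
    points: tuple = ()

    def predict(self, sigma) -> np.ndarray:
        return self.a * np.exp(self.k * np.asarray(sigma, dtype=float))


def fit_cost_model(points: list[tuple[float, float]]) -> CostModelFit:
    """Fit log(cost) = log(a) + k * sigma to (sigma, cost) points.

    Non-positive costs are excluded (logged); fewer than 3 usable points is
    an error (under-determined)."""
    usable = [(s, c) for s, c in points if c > 0 and np.isfinite(c)]
    if len(usable) < len(points):
        import logging

        logging.getLogger(__name__).info(
            "fit_cost_model: excluded %d non-positive/censored points",
            len(points) - len(usable),
        )
    if len(usable) < 3:
        raise ValueError("need >= 3 points with positive cost")
    sigma = np.array([s for s, _ in usable], dtype=float)
    cost = np.array([c for _, c in usable], dtype=float)
    k, log_a = np.polyfit(sigma, np.log(cost), 1)
    fit = CostModelFit(a=float(np.exp(log_a)), k=float(k), r_squared=0.0, mae=0.0)
    pred = fit.predict(sigma)
    resid = cost - pred
    ss_res = float((resid**2).sum())
    ss_tot = float(((cost - cost.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CostModelFit(
        a=fit.a,
        k=fit.k,
        r_squared=r2,
        mae=float(np.abs(resid).mean()),
        points=tuple(usable),
    )


def breakeven_value(
    cost_no_model: float,
    cost_with_model: float,
    cost_per_compound: float,
    n_scored: float,
) -> float:
    """Per-calculation monetary value of a scoring model.

    Inputs are 50th-percentile molecules-made counts with and without the
    model in the loop.  value = (savings in molecules) x cost-per-compound
    / number of scoring calculations; negative if the model is harmful.
    Above this price per calculation, using the model is not cost-effective.
    """
    if n_scored <= 0:
        raise ValueError("n_scored must be > 0")
    return (cost_no_model - cost_with_model) * cost_per_compound / n_scored


# ---------------------------------------------------------------------------
# Progress-normalized trajectories


def _made_records_in_order(result: CampaignResult):
    made = [
        r
        for r in result.ledger.values()
        if r.status in ("made", "tested") and r.cycle_made is not None
    ]
    # Ledger insertion order is ideation order; stable sort by make-cycle
    # preserves within-cycle ordering.
    made.sort(key=lambda r: r.cycle_made)
    return made


def progress_normalize(result: CampaignResult) -> list[tuple[str, float]]:
    """Progress of each made molecule: the m-th of M made molecules gets
    100 * m / M percent."""
    made = _made_records_in_order(result)
    M = len(made)
    return [(r.key, 100.0 * (m + 1) / M) for m, r in enumerate(made)]


_TRAJECTORY_COLUMNS = [
    "affinity",
    "lipophilicity",
    "solubility",
    "heavy_atoms",
    "rings",
    "rings_per_1000_atoms",
    "fraction_csp3",
    "qed",
    "ligand_efficiency",
    "lipophilic_efficiency",
]


def property_trajectories(
    results: list[CampaignResult], bins: int = 10
) -> pd.DataFrame:
    """Per-progress-bin means of TCP properties and drug-likeness metrics.

    Ligand efficiency is pIC50 over heavy atoms; lipophilic efficiency is
    pIC50 minus Log P; ring density is rings per 1000 heavy atoms.  Empty
    bins yield missing values.
    """
    from rdkit.Chem import QED, rdMolDescriptors

    from .chem_space import mol_from_smiles

    rows = []
    for result in results:
        for key, progress in progress_normalize(result):
            rec = result.ledger[key]
            if not rec.measured:
                continue
            mol = mol_from_smiles(rec.structure)
            if mol is None:
                continue
            heavy = mol.GetNumHeavyAtoms()
            rings = rdMolDescriptors.CalcNumRings(mol)
            pic50 = rec.measured.get("affinity", math.nan)
            logp = rec.measured.get("lipophilicity", math.nan)
            rows.append(
                {
                    "progress": progress,
                    "affinity": pic50,
                    "lipophilicity": logp,
                    "solubility": rec.measured.get("solubility", math.nan),
                    "heavy_atoms": heavy,
                    "rings": rings,
                    "rings_per_1000_atoms": 1000.0 * rings / heavy,
                    "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
                    "qed": QED.qed(mol),
                    "ligand_efficiency": pic50 / heavy,
                    "lipophilic_efficiency": pic50 - logp,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no measured molecules in results")
    edges = np.linspace(0.0, 100.0, bins + 1)
    df["progress_bin"] = pd.cut(
        df["progress"], edges, labels=False, include_lowest=True
    )
    grouped = df.groupby("progress_bin")[_TRAJECTORY_COLUMNS].mean()
    grouped.insert(0, "progress_mid", [
        (edges[int(i)] + edges[int(i) + 1]) / 2 for i in grouped.index
    ])
    return grouped.reset_index(drop=True)
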