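"""The design-make-test-analyze (DMTA) loop.

A campaign starts from a handful of weak hits and iterates cycles of
Design (ideate analogs of the best molecules so far, score them with noisy
predictive models, bias-correct, rank, epsilon-greedy select), Make (annotate
selected molecules as synthesized, depleting the budget), Test (measure made
molecules with the noiseless ground-truth oracles) and Analyze (supplant
predictions with measurements, refit the prediction-bias model, check the
TCP).  Success is a race: the program wins if a tested molecule satisfies
every TCP objective before the budget of molecules made runs out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .chem_space import CompoundRecord, ReactionTemplate, SyntheticRoute
from .ideation import IdeationConfig, ideate_batch
from .oracles import NoisyOracle, Oracle
from .selection import (
    BiasModel,
    SelectionPolicy,
    correct_scores,
    epsilon_greedy_select,
    fit_bias,
    pareto_fronts,
    rank_candidates,
)
from .tcp import TCP, composite_utility, tcp_satisfied, utilities_vector

__all__ = [
    "CampaignConfig",
    "CampaignState",
    "CampaignResult",
    "CampaignEnv",
    "reset",
    "run_cycle",
    "run_campaign",
    "lineage_graph",
    "ledger_dataframe",
]


@dataclass(frozen=True)
class CampaignConfig:
    """All knobs of one campaign realization."""

    tcp: TCP
    ideation: IdeationConfig = IdeationConfig()
    policy: SelectionPolicy = SelectionPolicy()
    sigmas: dict = field(default_factory=dict)  # objective -> sigma
    scoring_ratio: int = 10
    batch_size: int = 8
    budget: int = 250
    cost_per_compound: float = 3000.0
    max_cycles: int = 200
    parent_pool: int = 5
    min_bias_pairs: int = 10
    use_scoring: bool = True
    frozen_noise: bool = False
    stall_limit: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.budget >= self.batch_size >= 1:
            raise ValueError("need budget >= batch_size >= 1")
        if self.scoring_ratio < 1:
            raise ValueError("scoring_ratio must be >= 1")


@dataclass
class CampaignState:
    """The evolving ledger of one campaign."""

    config: CampaignConfig
    cycle: int = 0
    ledger: dict[str, CompoundRecord] = field(default_factory=dict)
    made_count: int = 0
    scored_count: int = 0
    cache: set[str] = field(default_factory=set)
    pairs: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    bias: BiasModel = field(default_factory=BiasModel)
    success: bool = False
    success_key: str | None = None
    terminated: bool = False
    stalls: int = 0
    events: list[dict] = field(default_factory=list)
    rng_ideation: np.random.Generator | None = None
    rng_selection: np.random.Generator | None = None
    noisy_oracles: dict[str, NoisyOracle] = field(default_factory=dict)


@dataclass
class CampaignResult:
    """Summary of a finished campaign."""

    success: bool
    molecules_made: int
    molecules_scored: int
    cycles: int
    monetary_cost: float
    ledger: dict[str, CompoundRecord]
    success_key: str | None
    events: list[dict]
    seed: int


def _build_noisy(
    oracles: dict[str, Oracle], config: CampaignConfig, rng: np.random.Generator
) -> dict[str, NoisyOracle]:
    out = {}
    for name, oracle in oracles.items():
        sigma = float(config.sigmas.get(name, 0.0))
        out[name] = NoisyOracle(oracle, sigma, rng=rng, frozen=config.frozen_noise)
    return out


def _measure(
    records: list[CompoundRecord],
    oracles: dict[str, Oracle],
    cycle: int,
) -> None:
    structures = [r.structure for r in records]
    values = {name: o.evaluate(structures) for name, o in oracles.items()}
    for i, rec in enumerate(records):
        rec.advance("tested", cycle)
        for name in oracles:
            rec.measured[name] = float(values[name][i])


def reset(
    config: CampaignConfig,
    oracles: dict[str, Oracle],
    hits: list[CompoundRecord] | list[str],
) -> CampaignState:
    """Initialize a campaign: hits are made and tested immediately (counting
    against the budget) and seed the dedup cache.

    Hits may be records with routes or bare SMILES (given trivial routes,
    in which case only growth moves can elaborate them).
    """
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for h in hits:
        if isinstance(h, str):
            route = SyntheticRoute.trivial(h)
            rec = CompoundRecord(structure=route.product, route=route)
        else:
            rec = CompoundRecord(structure=h.structure, route=h.route)
        if rec.structure in seen:
            continue
        seen.add(rec.structure)
        records.append(rec)
    if not records:
        raise ValueError("no valid hits")

    ss = np.random.SeedSequence(config.seed)
    rng_ideation, rng_noise, rng_selection = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    state = CampaignState(
        config=config,
        rng_ideation=rng_ideation,
        rng_selection=rng_selection,
        noisy_oracles=_build_noisy(oracles, config, rng_noise),
        pairs={name: [] for name in oracles},
    )
    for rec in records:
        rec.cycle_ideated = 0
        rec.advance("made", 0)
        rec.advance("tested", 0)
        state.ledger[rec.key] = rec
        state.cache.add(rec.key)
    state.made_count = len(records)
    _measure(records, oracles, cycle=0)
    for rec in records:
        rec.status = "tested"
        if tcp_satisfied(rec.measured, config.tcp) and not state.success:
            state.success = True
            state.success_key = rec.key
    if state.success or state.made_count >= config.budget:
        state.terminated = True
    state.events.append(
        {"event": "reset", "cycle": 0, "n_hits": len(records), "made": state.made_count}
    )
    return state


def _select_parents(state: CampaignState) -> list[CompoundRecord]:
    tested = [r for r in state.ledger.values() if r.status == "tested"]
    tested.sort(
        key=lambda r: (-composite_utility(r.measured, state.config.tcp), r.key)
    )
    return tested[: state.config.parent_pool]


def run_cycle(
    state: CampaignState,
    oracles: dict[str, Oracle],
    templates: dict[str, ReactionTemplate],
    library,
) -> CampaignState:
    """Advance one DMTA cycle in place; returns the state for chaining."""
    if state.terminated:
        raise RuntimeError("campaign already terminated")
    config = state.config
    state.cycle += 1
    cycle = state.cycle

    # --- Design: ideation -------------------------------------------------
    parents = _select_parents(state)
    target = config.scoring_ratio * config.batch_size
    candidates: list[CompoundRecord] = []
    per_parent = max(1, math.ceil(target / max(len(parents), 1)))
    ideation_cfg = dc_replace(config.ideation, analogs_per_parent=per_parent)
    for _ in range(3):
        new = ideate_batch(
            parents,
            library,
            templates,
            ideation_cfg,
            state.cache,
            state.rng_ideation,
            cycle=cycle,
            event_log=state.events,
        )
        candidates.extend(new)
        if len(candidates) >= target or not new:
            break
    if not candidates:
        state.stalls += 1
        state.events.append({"event": "stall", "cycle": cycle})
        if state.stalls >= config.stall_limit:
            state.terminated = True
            state.events.append({"event": "terminate", "reason": "stalled"})
        return state
    state.stalls = 0
    candidates = candidates[:target]
    for rec in candidates:
        state.ledger[rec.key] = rec
    structures = [r.structure for r in candidates]
    keys = [r.key for r in candidates]

    n_make = min(config.batch_size, config.budget - state.made_count)

    # --- Design: scoring + selection -------------------------------------
    if config.use_scoring:
        raw = {
            name: noracle.evaluate(structures)
            for name, noracle in state.noisy_oracles.items()
        }
        state.scored_count += len(candidates)
        for i, rec in enumerate(candidates):
            rec.predicted = {name: float(raw[name][i]) for name in raw}
        corrected = correct_scores(raw, state.bias)
        util = np.vstack(
            [
                utilities_vector(
                    {name: float(corrected[name][i]) for name in corrected},
                    config.tcp,
                )
                for i in range(len(candidates))
            ]
        )
        fronts = pareto_fronts(util)
        ordering = rank_candidates(util, fronts, config.policy, keys=keys)
        slot_log: list[str] = []
        chosen_idx = epsilon_greedy_select(
            ordering, n_make, config.policy.epsilon, state.rng_selection, slot_log
        )
        for i, slot in zip(chosen_idx, slot_log):
            state.events.append(
                {
                    "event": "select",
                    "cycle": cycle,
                    "key": keys[i],
                    "front": int(fronts[i]),
                    "slot": slot,
                }
            )
    else:
        # No-model baseline: no scoring; selection is uniform at random among
        # the ideated candidates ("make every molecule we ideate" in spirit --
        # the batch is a random subset when ideation outruns the batch size).
        perm = state.rng_selection.permutation(len(candidates))
        chosen_idx = [int(j) for j in perm[:n_make]]

    chosen = [candidates[i] for i in chosen_idx]

    # --- Make -------------------------------------------------------------
    for rec in chosen:
        rec.advance("made", cycle)
    state.made_count += len(chosen)

    # --- Test -------------------------------------------------------------
    _measure(chosen, oracles, cycle)

    # --- Analyze ----------------------------------------------------------
    for rec in chosen:
        for name in oracles:
            if name in rec.predicted:
                state.pairs[name].append((rec.predicted[name], rec.measured[name]))
    state.bias = fit_bias(state.pairs, min_pairs=config.min_bias_pairs)
    for rec in chosen:
        if tcp_satisfied(rec.measured, config.tcp):
            state.success = True
            state.success_key = rec.key
            break
    if (
        state.success
        or state.made_count >= config.budget
        or state.cycle >= config.max_cycles
    ):
        state.terminated = True
    state.events.append(
        {
            "event": "cycle",
            "cycle": cycle,
            "n_candidates": len(candidates),
            "n_made": len(chosen),
            "made_total": state.made_count,
            "success": state.success,
        }
    )
    return state


def run_campaign(
    config: CampaignConfig,
    oracles: dict[str, Oracle],
    templates: dict[str, ReactionTemplate] | list[ReactionTemplate],
    library,
    hits,
) -> CampaignResult:
    """Run reset + cycles until success, budget exhaustion, a stall-out, or
    the cycle cap; deterministic given (config, hits, seed)."""
    if not isinstance(templates, dict):
        templates = {t.template_id: t for t in templates}
    state = reset(config, oracles, hits)
    while not state.terminated:
        run_cycle(state, oracles, templates, library)
    return CampaignResult(
        success=state.success,
        molecules_made=state.made_count,
        molecules_scored=state.scored_count,
        cycles=state.cycle,
        monetary_cost=state.made_count * config.cost_per_compound,
        ledger=state.ledger,
        success_key=state.success_key,
        events=state.events,
        seed=config.seed,
    )


class CampaignEnv:
    """A thin reset/step environment wrapper around the campaign loop.

    ``reset()`` returns the initial state; ``step()`` advances one DMTA cycle
    and returns (state, terminated).  With fixed seeds the whole trajectory
    is exactly reproducible.
    """

    def __init__(self, config: CampaignConfig, oracles, templates, library, hits):
        self.config = config
        self.oracles = oracles
        self.templates = (
            templates
            if isinstance(templates, dict)
            else {t.template_id: t for t in templates}
        )
        self.library = library
        self.hits = hits
        self.state: CampaignState | None = None

    def reset(self) -> CampaignState:
        self.state = reset(self.config, self.oracles, self.hits)
        return self.state

    def step(self) -> tuple[CampaignState, bool]:
        if self.state is None:
            raise RuntimeError("call reset() first")
        run_cycle(self.state, self.oracles, self.templates, self.library)
        return self.state, self.state.terminated


def lineage_graph(result: CampaignResult):
    """Directed acyclic graph over made molecules: parent -> child edges from
    the ideation bookkeeping, nodes annotated with make-cycle and utility."""
    import networkx as nx

    g = nx.DiGraph()
    made = {
        k: r for k, r in result.ledger.items() if r.status in ("made", "tested")
    }
    for key, rec in made.items():
        g.add_node(key, cycle=rec.cycle_made, status=rec.status)
    for key, rec in made.items():
        for parent in rec.parents:
            if parent in made:
                g.add_edge(parent, key)
    return g


def ledger_dataframe(result: CampaignResult, tcp: TCP | None = None) -> pd.DataFrame:
    """One row per compound: key, structure, lifecycle, predictions,
    measurements, composite utility, serialized route."""
    rows = []
    for key, rec in result.ledger.items():
        row = {
            "key": key,
            "structure": rec.structure,
            "status": rec.status,
            "cycle_ideated": rec.cycle_ideated,
            "cycle_made": rec.cycle_made,
            "cycle_tested": rec.cycle_tested,
            "parents": ";".join(rec.parents),
            "route": rec.route.to_json(),
        }
        for name, v in rec.predicted.items():
            row[f"predicted_{name}"] = v
        for name, v in rec.measured.items():
            row[f"measured_{name}"] = v
        if tcp is not None and rec.status == "tested":
            row["utility"] = composite_utility(rec.measured, tcp)
        rows.append(row)
    return pd.DataFrame(rows)
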