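"""The Design-step analog generator.

Two moves are available per parent: *replacement* (swap building blocks in the
final step of the parent's synthetic route for similar catalog members, drawn
by Boltzmann-weighted fingerprint similarity at temperature T) and *growth*
(append one synthesis step joining the parent product with a random
size-admissible block under a random compatible reaction).  A campaign-wide
cache of canonical-SMILES keys prevents re-ideating old chemical space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from rdkit import DataStructs

from .chem_space import (
    BuildingBlock,
    CompoundRecord,
    ReactionTemplate,
    RouteStep,
    SyntheticRoute,
    apply_template,
    canonical_smiles,
    fingerprint,
    mol_from_smiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ALL",
    "INFINITE",
    "IdeationConfig",
    "similarity_rank",
    "boltzmann_sample",
    "replace_reactants",
    "grow_compound",
    "ideate_batch",
]

#: Sentinel for "replace every block reactant".
ALL = "all"
#: Sentinel temperature for uniform-random (infinite-T) sampling.
INFINITE = math.inf


@dataclass(frozen=True)
class IdeationConfig:
    """Knobs of the analog generator.

    temperature
        Boltzmann temperature of the block draw.  0 is maximally conservative
        (deterministic top-k by similarity); INFINITE is uniform random.
    n_replace
        How many final-step block reactants to swap per analog (or ALL).
    analogs_per_parent
        Target number of analogs emitted per parent per cycle, split between
        replacement and growth by ``growth_fraction``.
    growth_max_heavy_atoms
        Size cap on blocks added during growth.
    """

    temperature: float = 0.08
    n_replace: int | str = 1
    analogs_per_parent: int = 8
    growth_fraction: float = 0.5
    growth_max_heavy_atoms: int = 12
    sample_with_replacement: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.analogs_per_parent < 1:
            raise ValueError("analogs_per_parent must be >= 1")
        if self.n_replace != ALL and (
            not isinstance(self.n_replace, int) or self.n_replace < 1
        ):
            raise ValueError("n_replace must be a positive integer or ALL")


def similarity_rank(
    reference: BuildingBlock | str, library: list[BuildingBlock]
) -> list[tuple[BuildingBlock, float]]:
    """Rank a library by Tanimoto similarity to a reference, descending.

    Ties are broken lexicographically by block_id so the ordering is stable.
    """
    if not library:
        raise ValueError("library must be non-empty")
    ref_fp = (
        reference.fingerprint
        if isinstance(reference, BuildingBlock)
        else fingerprint(reference)
    )
    sims = DataStructs.BulkTanimotoSimilarity(ref_fp, [b.fingerprint for b in library])
    order = sorted(
        range(len(library)), key=lambda i: (-sims[i], library[i].block_id)
    )
    return [(library[i], sims[i]) for i in order]


def boltzmann_sample(
    ranked: list[tuple[BuildingBlock, float]],
    temperature: float,
    k: int,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> list[BuildingBlock]:
    """Draw k blocks with probability proportional to exp(similarity / T).

    Weights are max-subtracted before exponentiation for numerical stability.
    T=0 degenerates to the deterministic top-k of the ranking; T=INFINITE to
    uniform sampling.  Sampling is without replacement by default.
    """
    n = len(ranked)
    if k > n and not with_replacement:
        raise ValueError(f"cannot draw {k} from {n} without replacement")
    if temperature == 0:
        return [b for b, _ in ranked[:k]]
    if math.isinf(temperature):
        probs = np.full(n, 1.0 / n)
    else:
        sims = np.array([s for _, s in ranked])
        logw = (sims - sims.max()) / temperature
        w = np.exp(logw)
        probs = w / w.sum()
    idx = rng.choice(n, size=k, replace=with_replacement, p=probs)
    return [ranked[int(i)][0] for i in idx]


def _final_step_block_positions(route: SyntheticRoute) -> list[int]:
    if not route.steps:
        return []
    return [
        i
        for i, (kind, _) in enumerate(route.steps[-1].reactants)
        if kind == "block"
    ]


def replace_reactants(
    parent: CompoundRecord,
    library: list[BuildingBlock],
    templates: dict[str, ReactionTemplate],
    config: IdeationConfig,
    rng: np.random.Generator,
    n_analogs: int | None = None,
) -> list[tuple[str, SyntheticRoute, list[str]]]:
    """Emit analogs of a parent by swapping blocks in its route's final step.

    For each analog, ``n_replace`` reactant positions (all of them under ALL)
    are chosen at random; each position draws a role-compatible replacement by
    similarity-ranked Boltzmann sampling against the original block.  The
    modified final step is re-applied and only valid, sanitized products are
    returned, each as (structure, updated route, chosen block ids).
    """
    route = parent.route
    positions = _final_step_block_positions(route)
    if not positions:
        return []
    final = route.steps[-1]
    template = templates.get(final.template_id)
    if template is None:
        logger.warning("replace_reactants: unknown template %r", final.template_id)
        return []
    n_analogs = n_analogs if n_analogs is not None else config.analogs_per_parent

    # Per-position candidate pools (role-compatible library members) and
    # similarity rankings against the original block, computed once.
    rankings: dict[int, list[tuple[BuildingBlock, float]]] = {}
    for pos in positions:
        pool = [b for b in library if template.matches_role(b.structure, pos)]
        if not pool:
            logger.info(
                "replace_reactants: no role-compatible blocks for position %d "
                "of %s; skipped",
                pos,
                final.template_id,
            )
            continue
        rankings[pos] = similarity_rank(final.reactants[pos][1], pool)
    if not rankings:
        return []

    usable = sorted(rankings)
    if config.n_replace == ALL:
        n_rep = len(usable)
    else:
        n_rep = min(config.n_replace, len(usable))

    # Draw one candidate stream per position, then assemble analogs by taking
    # the i-th draw at each chosen position.
    draws: dict[int, list[BuildingBlock]] = {}
    for pos in usable:
        ranked = rankings[pos]
        k = min(n_analogs, len(ranked))
        draws[pos] = boltzmann_sample(
            ranked, config.temperature, k, rng, config.sample_with_replacement
        )

    out: list[tuple[str, SyntheticRoute, list[str]]] = []
    seen: set[str] = set()
    for i in range(n_analogs):
        if n_rep < len(usable):
            chosen = sorted(rng.choice(len(usable), size=n_rep, replace=False))
            chosen_pos = [usable[j] for j in chosen]
        else:
            chosen_pos = usable
        new_reactants = list(final.reactants)
        chosen_ids = []
        for pos in chosen_pos:
            stream = draws[pos]
            block = stream[i % len(stream)]
            new_reactants[pos] = ("block", block.structure)
            chosen_ids.append(block.block_id)
        resolved = [
            ref if kind == "block" else route.steps[ref].product
            for kind, ref in new_reactants
        ]
        products = apply_template(template, resolved)
        if not products:
            continue
        product = products[0]
        if product in seen:
            continue
        seen.add(product)
        new_step = RouteStep(
            template_id=final.template_id,
            reactants=tuple(new_reactants),
            product=product,
        )
        new_route = SyntheticRoute(
            steps=route.steps[:-1] + (new_step,), product=product
        )
        out.append((product, new_route, chosen_ids))
    return out


def grow_compound(
    parent: CompoundRecord,
    library: list[BuildingBlock],
    templates: dict[str, ReactionTemplate] | list[ReactionTemplate],
    config: IdeationConfig,
    rng: np.random.Generator,
    n_analogs: int | None = None,
) -> list[tuple[str, SyntheticRoute, list[str]]]:
    """Grow a parent by one synthesis step with a random compatible block.

    A uniformly random (template, role) pair matching the parent product is
    combined with a uniformly random size-admissible block matching the other
    role.  Returns (structure, extended route, [block_id]) tuples.
    """
    template_list = (
        list(templates.values()) if isinstance(templates, dict) else list(templates)
    )
    parent_mol = mol_from_smiles(parent.structure)
    if parent_mol is None:
        return []
    n_analogs = n_analogs if n_analogs is not None else config.analogs_per_parent

    # All (template, parent role) slots the parent can occupy.
    slots = []
    for t in template_list:
        if t.arity != 2:
            continue
        for role in range(2):
            if parent_mol.HasSubstructMatch(t.role_pattern(role)):
                slots.append((t, role))
    if not slots:
        logger.info("grow_compound: no compatible template for %s", parent.structure)
        return []

    small = [b for b in library if b.heavy_atoms <= config.growth_max_heavy_atoms]
    out: list[tuple[str, SyntheticRoute, list[str]]] = []
    seen: set[str] = set()
    parent_step_idx = len(parent.route.steps) - 1
    for _ in range(n_analogs):
        t, role = slots[int(rng.integers(len(slots)))]
        other = 1 - role
        pool = [b for b in small if t.matches_role(b.structure, other)]
        if not pool:
            continue
        block = pool[int(rng.integers(len(pool)))]
        reactants = [None, None]
        reactants[role] = parent.structure
        reactants[other] = block.structure
        products = apply_template(t, reactants)
        if not products:
            continue
        product = products[0]
        if product in seen:
            continue
        seen.add(product)
        if parent.route.steps:
            parent_ref = ("step", parent_step_idx)
        else:
            parent_ref = ("block", parent.structure)
        refs = [None, None]
        refs[role] = parent_ref
        refs[other] = ("block", block.structure)
        new_step = RouteStep(
            template_id=t.template_id, reactants=tuple(refs), product=product
        )
        new_route = SyntheticRoute(
            steps=parent.route.steps + (new_step,), product=product
        )
        out.append((product, new_route, [block.block_id]))
    return out


def ideate_batch(
    parents: list[CompoundRecord],
    library: list[BuildingBlock],
    templates: dict[str, ReactionTemplate],
    config: IdeationConfig,
    cache: set[str],
    rng: np.random.Generator,
    cycle: int = 0,
    event_log: list | None = None,
) -> list[CompoundRecord]:
    """One Design-step ideation round over a set of parents.

    Pools replacement and growth analogs per parent (split by
    ``growth_fraction``), discards anything whose dedup key is already in the
    campaign cache, adds survivors to the cache, and returns them as fresh
    ideated records carrying their parent's key for lineage.
    """
    if not parents:
        raise ValueError("parents must be non-empty")
    n_grow = int(round(config.analogs_per_parent * config.growth_fraction))
    n_rep = config.analogs_per_parent - n_grow
    out: list[CompoundRecord] = []
    for parent in parents:
        produced = []
        if n_rep > 0:
            produced += [
                ("replace", s, r, ids)
                for s, r, ids in replace_reactants(
                    parent, library, templates, config, rng, n_analogs=n_rep
                )
            ]
        if n_grow > 0:
            produced += [
                ("grow", s, r, ids)
                for s, r, ids in grow_compound(
                    parent, library, templates, config, rng, n_analogs=n_grow
                )
            ]
        for op, structure, route, block_ids in produced:
            key = canonical_smiles(structure)
            if key is None or key in cache:
                continue
            cache.add(key)
            rec = CompoundRecord(
                structure=key,
                route=route,
                parents=[parent.key],
                status="ideated",
                cycle_ideated=cycle,
            )
            out.append(rec)
            if event_log is not None:
                event_log.append(
                    {
                        "event": "ideate",
                        "cycle": cycle,
                        "parent": parent.key,
                        "operation": op,
                        "template_id": route.steps[-1].template_id
                        if route.steps
                        else None,
                        "block_ids": block_ids,
                        "temperature": config.temperature,
                        "n_replace": config.n_replace,
                    }
                )
    return out
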