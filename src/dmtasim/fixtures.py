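"""Desk-scale synthetic stand-ins for external dependencies.

Everything a self-contained experiment needs is generated here from a seed:
a building-block catalog with the functional handles the default reaction
repertoire consumes, fragment-sized starting hits with valid one-step routes,
and ground-truth oracles.  The synthetic affinity oracle is a hidden-optimum
Gaussian landscape over a normalized physicochemical descriptor space,
decorated with substructure "cliff" motifs so that it exhibits the two
characteristics of real potency data: smooth structure-activity
relationships between related compounds, and activity cliffs where a small
structural change swings potency sharply.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from scipy.stats import norm

from .chem_space import (
    BuildingBlock,
    CompoundRecord,
    FingerprintParams,
    ReactionTemplate,
    RouteStep,
    SyntheticRoute,
    apply_template,
    mol_from_smiles,
)
from .oracles import Oracle
from .tcp import TCP, ObjectiveSpec

__all__ = [
    "default_reactions",
    "generate_building_blocks",
    "generate_hits",
    "LandscapeSpec",
    "make_landscape",
    "synthetic_affinity",
    "synthetic_solubility",
    "fixture_tcp",
    "default_fixture",
]

# ---------------------------------------------------------------------------
# Reaction repertoire

_DEFAULT_REACTIONS = [
    (
        "amide_coupling",
        "[CX3:1](=[OX1:2])[OX2H1].[NX3;H2,H1;!$(N-C=O);!$(N-S(=O)=O):3]"
        ">>[C:1](=[O:2])[N:3]",
    ),
    (
        "sulfonamide",
        "[SX4:1](=[OX1:2])(=[OX1:3])[Cl].[NX3;H2,H1;!$(N-C=O);!$(N-S(=O)=O):4]"
        ">>[S:1](=[O:2])(=[O:3])[N:4]",
    ),
    (
        "reductive_amination",
        "[CX3H1:1]=[OX1].[NX3;H2,H1;!$(N-C=O);!$(N-S(=O)=O):2]>>[CH2:1][N:2]",
    ),
    (
        "suzuki_coupling",
        "[c:1][Cl,Br,I].[c:2][BX3](-[OX2H])-[OX2H]>>[c:1][c:2]",
    ),
]


def default_reactions() -> list[ReactionTemplate]:
    """Four robust two-component medicinal-chemistry workhorses: amide
    coupling, sulfonamide formation, reductive amination, Suzuki coupling."""
    return [ReactionTemplate(tid, smarts) for tid, smarts in _DEFAULT_REACTIONS]


# ---------------------------------------------------------------------------
# Building blocks

_AROMATIC_SCAFFOLDS = [
    "c1ccc({h})cc1",
    "c1ccc({h})c({d})c1",
    "c1cc({d})ccc1{h}",
    "c1cc({d})cc({d2})c1{h}",
    "c1ccnc({h})c1",
    "c1cc({d})cnc1{h}",
    "c1ccc({h})o1",
    "c1cc({d})c({h})o1",
    "c1ccc({h})s1",
    "c1cc({d})c({h})s1",
    "c1cnc({h})cn1",
    "c1cc({h})c({d})cn1",
]
_ALIPHATIC_SCAFFOLDS = [
    "C1CCC({h})CC1",
    "C1CCC({d})CC1{h}",
    "CC(C){h}",
    "CCC{h}",
    "C1CC({h})C1",
    "CC({d}){h}",
    "CC({d})C({d2}){h}",
    "C1CCC({h})OC1",
    "CCCC{h}",
    "C1CC({d})CC({h})C1",
    "CC(C)(C){h}",
]
# Functional handles; the aryl-only ones exist for the Suzuki roles.
_HANDLES_ANY = {
    "acid": "C(=O)O",
    "amine": "CN",
    "sec_amine": "CNC",
    "aldehyde": "C=O",
    "sulfonyl_chloride": "S(=O)(=O)Cl",
}
_HANDLES_ARYL = {"aryl_halide": "Br", "boronic": "B(O)O"}
_DECORATIONS = ["C", "CC", "CCC", "F", "OC", "OCC", "Cl", "O", "C(C)C", "C(F)(F)F"]


def generate_building_blocks(
    n: int,
    seed: int,
    fp_params: FingerprintParams = FingerprintParams(),
    templates: list[ReactionTemplate] | None = None,
    min_per_role: int = 5,
) -> list[BuildingBlock]:
    """Generate n distinct valid blocks (<= 12 heavy atoms) by seeded
    combinatorial decoration of ring/chain scaffolds with functional handles.

    Handles are cycled round-robin so every reaction role of the default
    repertoire stays populated; an audit enforces ``min_per_role`` compatible
    blocks per role and raises if n is too small to satisfy it.
    """
    if n < 20:
        raise ValueError("need n >= 20 building blocks")
    rng = np.random.default_rng(seed)
    handle_cycle = list(_HANDLES_ANY.items()) + list(_HANDLES_ARYL.items())
    seen: set[str] = set()
    blocks: list[BuildingBlock] = []
    attempts = 0
    while len(blocks) < n and attempts < 200 * n:
        attempts += 1
        hname, h = handle_cycle[len(blocks) % len(handle_cycle)]
        if hname in _HANDLES_ARYL:
            sc = _AROMATIC_SCAFFOLDS[int(rng.integers(len(_AROMATIC_SCAFFOLDS)))]
        else:
            all_sc = _AROMATIC_SCAFFOLDS + _ALIPHATIC_SCAFFOLDS
            sc = all_sc[int(rng.integers(len(all_sc)))]
        d = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
        d2 = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
        smi = sc.replace("{h}", h).replace("{d2}", d2).replace("{d}", d)
        mol = mol_from_smiles(smi)
        if mol is None or mol.GetNumHeavyAtoms() > 12:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        block = BuildingBlock.from_smiles(f"BB{len(blocks):04d}", can, fp_params)
        blocks.append(block)
    if len(blocks) < n:
        raise ValueError(
            f"could only generate {len(blocks)} distinct blocks for n={n}"
        )
    for t in templates if templates is not None else default_reactions():
        for role in range(t.arity):
            count = sum(1 for b in blocks if t.matches_role(b.structure, role))
            if count < min_per_role:
                raise ValueError(
                    f"role coverage audit failed: {t.template_id} role {role} "
                    f"has {count} < {min_per_role} compatible blocks"
                )
    return blocks


def generate_hits(
    k: int,
    catalog: list[BuildingBlock],
    templates: list[ReactionTemplate],
    seed: int,
    max_heavy_atoms: int = 20,
) -> list[CompoundRecord]:
    """k fragment-sized one-step products of random compatible block pairs,
    each with a valid replayable route."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    two_component = [t for t in templates if t.arity == 2]
    hits: list[CompoundRecord] = []
    seen: set[str] = set()
    attempts = 0
    while len(hits) < k and attempts < 500 * k:
        attempts += 1
        t = two_component[int(rng.integers(len(two_component)))]
        pools = [
            [b for b in catalog if t.matches_role(b.structure, role)]
            for role in range(2)
        ]
        if not all(pools):
            continue
        pair = [p[int(rng.integers(len(p)))] for p in pools]
        products = apply_template(t, [b.structure for b in pair])
        if not products:
            continue
        product = products[0]
        mol = mol_from_smiles(product)
        if mol is None or mol.GetNumHeavyAtoms() > max_heavy_atoms:
            continue
        if product in seen:
            continue
        seen.add(product)
        route = SyntheticRoute(
            steps=(
                RouteStep(
                    template_id=t.template_id,
                    reactants=(
                        ("block", pair[0].structure),
                        ("block", pair[1].structure),
                    ),
                    product=product,
                ),
            ),
            product=product,
        )
        hits.append(CompoundRecord(structure=product, route=route))
    if len(hits) < k:
        raise ValueError(f"could only generate {len(hits)} hits")
    return hits


# ---------------------------------------------------------------------------
# Synthetic affinity landscape

_DESCRIPTOR_FNS = [
    ("logp", Crippen.MolLogP),
    ("mw", Descriptors.MolWt),
    ("tpsa", rdMolDescriptors.CalcTPSA),
    ("hbd", rdMolDescriptors.CalcNumHBD),
    ("hba", rdMolDescriptors.CalcNumHBA),
    ("rings", rdMolDescriptors.CalcNumRings),
    ("fcsp3", rdMolDescriptors.CalcFractionCSP3),
    ("heavy", lambda m: m.GetNumHeavyAtoms()),
]

# Minor cliffs: potency swings on small, common motifs.  Single-atom and
# single-group motifs ("magic halogen" style) let two near-identical
# molecules differ sharply -- the signature of real activity cliffs.
_CLIFF_CANDIDATES = [
    ("c1ccncc1", 1.6),  # pyridyl gain
    ("c1ccco1", -1.6),  # furyl loss
    ("C(F)(F)F", 1.6),  # trifluoromethyl gain
    ("Cl", -1.6),  # chloro liability
    ("S(=O)(=O)N", -1.5),  # sulfonamide loss
]

# Pharmacophore candidates: one is chosen (by prevalence in the reference
# sample) to carry a large potency bonus, so top-of-range potency requires a
# specific structural feature and not merely the right physicochemical
# profile -- the "make or break" character of real activity cliffs.
_PHARMACOPHORE_CANDIDATES = [
    "c1cnccn1",  # pyrazinyl
    "c1cncnc1",  # pyrimidinyl
    "c1ccc(-c2ccccc2)cc1",  # biphenyl
    "c1ccc(-c2ccco2)cc1",  # phenyl-furyl
    "C(=O)Nc1ccccc1",  # anilide
]
_PHARMACOPHORE_BONUS = 2.5


def descriptor_vector(mol) -> np.ndarray:
    return np.array([fn(mol) for _, fn in _DESCRIPTOR_FNS], dtype=float)


@dataclass
class LandscapeSpec:
    """A hidden-optimum affinity landscape over normalized descriptor space.

    pIC50(m) = base + amplitude * exp(-d(m)^2 / smooth_scale^2) + cliffs,
    clipped to the dynamic range, where d is the Euclidean distance of m's
    z-scored descriptor vector from the hidden optimum.  Cliff motifs add a
    fixed potency offset when their substructure is present.
    """

    seed: int
    optimum: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    smooth_scale: float
    cliff_motifs: list[tuple[str, float]]
    base_level: float = 3.0
    amplitude: float = 3.0
    dynamic_range: tuple[float, float] = (3.0, 11.0)

    @property
    def achievable_top(self) -> float:
        """Best reachable potency: the basin maximum plus the largest
        positive cliff bonus, clipped to the dynamic range."""
        best_cliff = max((d for _, d in self.cliff_motifs if d > 0), default=0.0)
        return min(self.base_level + self.amplitude + best_cliff, self.dynamic_range[1])

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "optimum": self.optimum.tolist(),
                "mean": self.mean.tolist(),
                "std": self.std.tolist(),
                "smooth_scale": self.smooth_scale,
                "cliff_motifs": [list(c) for c in self.cliff_motifs],
                "base_level": self.base_level,
                "amplitude": self.amplitude,
                "dynamic_range": list(self.dynamic_range),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "LandscapeSpec":
        d = json.loads(payload)
        return cls(
            seed=d["seed"],
            optimum=np.array(d["optimum"]),
            mean=np.array(d["mean"]),
            std=np.array(d["std"]),
            smooth_scale=d["smooth_scale"],
            cliff_motifs=[(s, float(x)) for s, x in d["cliff_motifs"]],
            base_level=d["base_level"],
            amplitude=d["amplitude"],
            dynamic_range=tuple(d["dynamic_range"]),
        )


def _extend_once(
    product: str,
    two_component: list[ReactionTemplate],
    pools: dict,
    rng: np.random.Generator,
) -> str | None:
    """Apply one more random compatible step to a product, or None."""
    for ti in rng.permutation(len(two_component)):
        t = two_component[int(ti)]
        for role in range(2):
            if not t.matches_role(product, role):
                continue
            other = pools[(t.template_id, 1 - role)]
            if not other:
                continue
            pair = [None, None]
            pair[role] = product
            pair[1 - role] = other[int(rng.integers(len(other)))]
            products = apply_template(t, pair)
            if products:
                return products[0]
    return None


def _reference_products(
    catalog: list[BuildingBlock],
    templates: list[ReactionTemplate],
    rng: np.random.Generator,
    n: int = 300,
    max_steps: int = 3,
) -> list[tuple[str, int]]:
    """A seeded sample of enumerable 1-3 step products (with step counts),
    used to normalize the descriptor space and place the optimum at a
    reachable point."""
    two_component = [t for t in templates if t.arity == 2]
    pools = {
        (t.template_id, role): [
            b.structure for b in catalog if t.matches_role(b.structure, role)
        ]
        for t in two_component
        for role in range(2)
    }
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        t = two_component[int(rng.integers(len(two_component)))]
        p0 = pools[(t.template_id, 0)]
        p1 = pools[(t.template_id, 1)]
        if not p0 or not p1:
            continue
        products = apply_template(
            t, [p0[int(rng.integers(len(p0)))], p1[int(rng.integers(len(p1)))]]
        )
        if not products:
            continue
        product = products[0]
        steps = 1
        # Extend so the sample covers the multi-step size spectrum evenly.
        target_steps = 1 + int(rng.integers(max_steps))
        while steps < target_steps:
            extended = _extend_once(product, two_component, pools, rng)
            if extended is None:
                break
            product = extended
            steps += 1
        if product not in seen:
            seen.add(product)
            out.append((product, steps))
    return out


def make_landscape(
    catalog: list[BuildingBlock],
    templates: list[ReactionTemplate],
    seed: int,
    n_reference: int = 300,
    n_cliffs: int = 2,
    smooth_factor: float = 0.8,
    amplitude: float = 3.0,
) -> LandscapeSpec:
    """Build a landscape whose optimum is the descriptor vector of an actual
    enumerable product, so the top of the dynamic range is reachable."""
    rng = np.random.default_rng(seed)
    refs = _reference_products(catalog, templates, rng, n=n_reference)
    mats = []
    mols = []
    steps = []
    for smi, n_steps in refs:
        mol = mol_from_smiles(smi)
        if mol is None:
            continue
        mols.append(mol)
        steps.append(n_steps)
        mats.append(descriptor_vector(mol))
    X = np.array(mats)
    steps = np.array(steps)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-9] = 1.0
    Z = (X - mean) / std
    # Optimum: a *multi-step* product in the upper size range, so fragment
    # hits must be elaborated over several make-test-reparent rungs to reach
    # it, and whose Log P sits inside the lipophilicity/solubility acceptance
    # window -- otherwise maximum potency and progressable ADME could be
    # mutually exclusive.
    sizes = np.array([m.GetNumHeavyAtoms() for m in mols])
    logps = X[:, 0]
    upper = np.nonzero(
        (steps >= steps.max())
        & (sizes >= np.quantile(sizes, 0.6))
        & (logps >= 1.0)
        & (logps <= 3.5)
    )[0]
    if len(upper) == 0:
        upper = np.nonzero(sizes >= np.median(sizes))[0]
    opt_idx = int(upper[int(rng.integers(len(upper)))])
    optimum = Z[opt_idx]
    # The basin width is a fraction of the median reference distance to the
    # optimum: wide enough that nearby analogs feel a potency gradient, narrow
    # enough that only a small minority of random products clear the potency
    # bar (so campaigns require genuine optimization).
    dists = np.linalg.norm(Z - optimum, axis=1)
    smooth_scale = float(smooth_factor * np.median(dists))
    # Pharmacophore cliff: pick (seeded) among candidate motifs that are
    # present in 2-25% of the reference sample -- rare enough that the bonus
    # is discriminating, common enough that campaigns can encounter it.
    pharmacophore = None
    qualifying = []
    for smarts in _PHARMACOPHORE_CANDIDATES:
        patt = Chem.MolFromSmarts(smarts)
        prevalence = float(np.mean([m.HasSubstructMatch(patt) for m in mols]))
        if 0.02 <= prevalence <= 0.25:
            qualifying.append(smarts)
    if qualifying:
        pharmacophore = qualifying[int(rng.integers(len(qualifying)))]
    # Minor cliffs must not overlap the pharmacophore (a sub-motif would
    # silently cancel part of its bonus and distort the achievable top).
    minor_pool = _CLIFF_CANDIDATES
    if pharmacophore is not None:
        pharma_mol = Chem.MolFromSmiles(pharmacophore) or Chem.MolFromSmarts(
            pharmacophore
        )
        minor_pool = [
            (smarts, delta)
            for smarts, delta in _CLIFF_CANDIDATES
            if not pharma_mol.HasSubstructMatch(Chem.MolFromSmarts(smarts))
        ]
    order = rng.permutation(len(minor_pool))
    cliffs = [minor_pool[int(i)] for i in order[:n_cliffs]]
    if pharmacophore is not None:
        cliffs = [(pharmacophore, _PHARMACOPHORE_BONUS)] + cliffs
    return LandscapeSpec(
        seed=seed,
        optimum=optimum,
        mean=mean,
        std=std,
        smooth_scale=smooth_scale,
        cliff_motifs=cliffs,
        amplitude=amplitude,
    )


def synthetic_affinity(spec: LandscapeSpec) -> Oracle:
    """The pIC50 oracle over the landscape; deterministic given the spec."""
    cliff_patterns = [
        (Chem.MolFromSmarts(smarts), delta) for smarts, delta in spec.cliff_motifs
    ]
    lo, hi = spec.dynamic_range

    def pic50(mol) -> float:
        z = (descriptor_vector(mol) - spec.mean) / spec.std
        d = float(np.linalg.norm(z - spec.optimum))
        value = spec.base_level + spec.amplitude * np.exp(
            -(d**2) / spec.smooth_scale**2
        )
        for patt, delta in cliff_patterns:
            if mol.HasSubstructMatch(patt):
                value += delta
        return float(np.clip(value, lo, hi))

    return Oracle("affinity", pic50, units="pIC50")


def synthetic_solubility(
    seed: int,
    c0: float = 0.8,
    c1: float = 1.0,
    c2: float = 0.02,
    jitter_sd: float = 0.3,
    dynamic_range: tuple[float, float] = (-8.0, 1.0),
) -> Oracle:
    """Log S surrogate: anti-correlated with Log P (c1 > 0), with a smooth
    molecular-size term and a seeded structure-hashed jitter.  Deterministic
    per molecule across processes."""

    def logs(mol) -> float:
        logp = Crippen.MolLogP(mol)
        size = mol.GetNumHeavyAtoms()
        smi = Chem.MolToSmiles(mol)
        h = zlib.crc32(f"{seed}:{smi}".encode()) / 2**32
        jitter = jitter_sd * float(norm.ppf(min(max(h, 1e-9), 1 - 1e-9)))
        value = c0 - c1 * logp - c2 * size + jitter
        return float(np.clip(value, *dynamic_range))

    return Oracle("solubility", logs, units="Log S")


def fixture_tcp(
    spec: LandscapeSpec,
    acceptable_fraction: float = 0.75,
    ideal_fraction: float = 0.85,
) -> TCP:
    """The hit-to-lead TCP with affinity thresholds rescaled to the
    landscape's achievable top (basin maximum plus best cliff bonus);
    lipophilicity and solubility bounds kept at the standard oral-drug
    values.

    The default fractions put the acceptance bar at 75% of the achievable
    potency span, which on this landscape requires both proximity to the
    hidden optimum and the bonus motif -- so campaigns must genuinely
    optimize rather than stumble on an adequate molecule.
    """
    inf = float("inf")
    lo, hi = spec.dynamic_range
    top = spec.achievable_top
    acc = spec.base_level + acceptable_fraction * (top - spec.base_level)
    ideal = spec.base_level + ideal_fraction * (top - spec.base_level)
    return TCP(
        objectives=(
            ObjectiveSpec("affinity", "pIC50", (lo, hi), (acc, inf), (ideal, inf)),
            ObjectiveSpec(
                "lipophilicity", "Log P", (-1.0, 8.0), (0.0, 4.0), (0.0, 3.0)
            ),
            ObjectiveSpec(
                "solubility", "Log S", (-8.0, 1.0), (-4.0, 0.0), (-3.0, 0.0)
            ),
        ),
    )


def analog_families(
    catalog: list[BuildingBlock],
    templates: list[ReactionTemplate],
    seed: int,
    n_families: int = 30,
    family_size: int = 12,
) -> list[list[str]]:
    """Families of close analogs: one reaction and one fixed partner block,
    varied over compatible co-blocks.

    Within-family pairs share a scaffold and differ by one building block --
    the regime where structure-activity relationships and activity cliffs
    are defined and audited.
    """
    rng = np.random.default_rng(seed)
    two_component = [t for t in templates if t.arity == 2]
    families: list[list[str]] = []
    attempts = 0
    while len(families) < n_families and attempts < 50 * n_families:
        attempts += 1
        t = two_component[int(rng.integers(len(two_component)))]
        fixed_role = int(rng.integers(2))
        vary_role = 1 - fixed_role
        fixed_pool = [b for b in catalog if t.matches_role(b.structure, fixed_role)]
        vary_pool = [b for b in catalog if t.matches_role(b.structure, vary_role)]
        if not fixed_pool or len(vary_pool) < 3:
            continue
        fixed = fixed_pool[int(rng.integers(len(fixed_pool)))]
        chosen = rng.choice(
            len(vary_pool), size=min(family_size, len(vary_pool)), replace=False
        )
        family = []
        for i in chosen:
            pair = [None, None]
            pair[fixed_role] = fixed.structure
            pair[vary_role] = vary_pool[int(i)].structure
            products = apply_template(t, pair)
            if products:
                family.append(products[0])
        family = list(dict.fromkeys(family))
        if len(family) >= 3:
            families.append(family)
    return families


@dataclass
class Fixture:
    """A complete self-contained testbed instance."""

    catalog: list[BuildingBlock]
    templates: list[ReactionTemplate]
    hits: list[CompoundRecord]
    landscape: LandscapeSpec
    oracles: dict[str, Oracle]
    tcp: TCP


def default_fixture(
    seed: int = 0,
    n_blocks: int = 250,
    n_hits: int = 5,
    min_hit_pic50: float = 3.1,
    max_hit_pic50: float = 4.5,
) -> Fixture:
    """The standard desk-scale condition: 250 blocks, 4 reactions, 5 hits.

    Hits are *weak but measurable*, as in a fragment screen: candidates are
    over-generated and the weakest whose true potency falls inside
    [min_hit_pic50, max_hit_pic50] are kept -- above the landscape floor (so
    a potency gradient is felt from the start) yet far below the acceptance
    bar.
    """
    templates = default_reactions()
    catalog = generate_building_blocks(n_blocks, seed, templates=templates)
    landscape = make_landscape(catalog, templates, seed + 2)
    affinity = synthetic_affinity(landscape)
    pool = generate_hits(12 * n_hits, catalog, templates, seed + 1)
    potencies = affinity.evaluate([h.structure for h in pool])
    order = np.argsort(potencies)
    hits = [
        pool[i]
        for i in order
        if min_hit_pic50 <= potencies[i] <= max_hit_pic50
    ][:n_hits]
    if len(hits) < n_hits:
        hits = [pool[i] for i in order[:n_hits]]
    oracles = {
        "affinity": synthetic_affinity(landscape),
        "lipophilicity": Oracle("lipophilicity", Crippen.MolLogP, units="Log P"),
        "solubility": synthetic_solubility(seed + 3),
    }
    return Fixture(
        catalog=catalog,
        templates=templates,
        hits=hits,
        landscape=landscape,
        oracles=oracles,
        tcp=fixture_tcp(landscape),
    )
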