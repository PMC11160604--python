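"""Chemical space primitives: building blocks, reaction templates, routes, records.

Molecules are carried as canonical SMILES throughout; RDKit ``Mol`` objects are
constructed on demand and never stored in the serialized data model.  The
deduplication key for every compound in a campaign is the canonical SMILES of
the sanitized molecule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintParams",
    "BuildingBlock",
    "ReactionTemplate",
    "RouteStep",
    "SyntheticRoute",
    "CompoundRecord",
    "canonical_smiles",
    "mol_from_smiles",
    "fingerprint",
    "load_catalog",
    "load_templates",
    "apply_template",
    "replay_route",
    "space_size_estimate",
    "RouteError",
    "CatalogError",
]


class RouteError(ValueError):
    """A synthetic route could not be replayed as recorded."""


class CatalogError(ValueError):
    """A building-block catalog file is malformed or empty."""


@dataclass(frozen=True)
class FingerprintParams:
    """Hashed circular-substructure (Morgan) fingerprint settings.

    Defaults are radius 2 / 2048 bits, the de-facto similarity standard.
    Recorded in the campaign config so similarity values are reproducible.
    """

    radius: int = 2
    n_bits: int = 2048


_FP_GENERATORS: dict[FingerprintParams, object] = {}


def _fp_generator(params: FingerprintParams):
    gen = _FP_GENERATORS.get(params)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=params.radius, fpSize=params.n_bits
        )
        _FP_GENERATORS[params] = gen
    return gen


from functools import lru_cache


@lru_cache(maxsize=200_000)
def _parse_smiles(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse and sanitize; returns None on failure instead of raising.

    Parsed molecules are cached and must be treated as read-only; callers
    that annotate atoms take a copy first.
    """
    return _parse_smiles(smiles)


def canonical_smiles(smiles: str) -> str | None:
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def fingerprint(
    structure: str | Chem.Mol, params: FingerprintParams = FingerprintParams()
) -> ExplicitBitVect:
    mol = mol_from_smiles(structure) if isinstance(structure, str) else structure
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return _fp_generator(params).GetFingerprint(mol)


@dataclass(frozen=True)
class BuildingBlock:
    """One catalog entry: identifier, canonical SMILES, fingerprint, size."""

    block_id: str
    structure: str
    fingerprint: ExplicitBitVect = field(compare=False, repr=False)
    heavy_atoms: int = 0

    @classmethod
    def from_smiles(
        cls,
        block_id: str,
        smiles: str,
        fp_params: FingerprintParams = FingerprintParams(),
    ) -> "BuildingBlock | None":
        mol = mol_from_smiles(smiles)
        if mol is None:
            return None
        return cls(
            block_id=block_id,
            structure=Chem.MolToSmiles(mol),
            fingerprint=fingerprint(mol, fp_params),
            heavy_atoms=mol.GetNumHeavyAtoms(),
        )


class ReactionTemplate:
    """A reaction-SMARTS transform with R >= 1 reactant roles."""

    def __init__(self, template_id: str, transform: str):
        rxn = AllChem.ReactionFromSmarts(transform)
        if rxn is None:
            raise ValueError(f"invalid reaction SMARTS for {template_id!r}")
        rxn.Initialize()
        self.template_id = template_id
        self.transform = transform
        self._rxn = rxn
        self.arity = rxn.GetNumReactantTemplates()
        if self.arity < 1:
            raise ValueError(f"template {template_id!r} has no reactant roles")
        self._role_patterns = [
            rxn.GetReactantTemplate(i) for i in range(self.arity)
        ]
        self._match_cache: dict[tuple[int, str], bool] = {}

    def role_pattern(self, role: int) -> Chem.Mol:
        return self._role_patterns[role]

    def matches_role(self, structure: str | Chem.Mol, role: int) -> bool:
        if isinstance(structure, str):
            hit = self._match_cache.get((role, structure))
            if hit is not None:
                return hit
            mol = mol_from_smiles(structure)
            result = (
                mol is not None
                and mol.HasSubstructMatch(self._role_patterns[role])
            )
            self._match_cache[(role, structure)] = result
            return result
        if structure is None:
            return False
        return structure.HasSubstructMatch(self._role_patterns[role])

    def rxn(self) -> AllChem.ChemicalReaction:
        return self._rxn

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReactionTemplate({self.template_id!r}, arity={self.arity})"


@dataclass(frozen=True)
class RouteStep:
    """One forward-synthesis step.

    ``reactants`` holds references in role order: ``("block", smiles)`` for a
    building block, or ``("step", i)`` for the product of an earlier step.
    ``product`` pins which of the enumerated products this route took.
    """

    template_id: str
    reactants: tuple[tuple[str, object], ...]
    product: str


@dataclass(frozen=True)
class SyntheticRoute:
    """An acyclic sequence of steps; ``product`` is the final step's product.

    A zero-step route represents a molecule used as-is (e.g. a screening hit
    with no recorded synthesis); its product is the molecule itself.
    """

    steps: tuple[RouteStep, ...]
    product: str

    @classmethod
    def trivial(cls, structure: str) -> "SyntheticRoute":
        smi = canonical_smiles(structure)
        if smi is None:
            raise ValueError(f"unparseable structure: {structure!r}")
        return cls(steps=(), product=smi)

    def to_json(self) -> str:
        return json.dumps(
            {
                "product": self.product,
                "steps": [
                    {
                        "template_id": s.template_id,
                        "reactants": [list(r) for r in s.reactants],
                        "product": s.product,
                    }
                    for s in self.steps
                ],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "SyntheticRoute":
        d = json.loads(payload)
        steps = tuple(
            RouteStep(
                template_id=s["template_id"],
                reactants=tuple((r[0], r[1]) for r in s["reactants"]),
                product=s["product"],
            )
            for s in d["steps"]
        )
        return cls(steps=steps, product=d["product"])


STATUS_ORDER = {"ideated": 0, "made": 1, "tested": 2}


@dataclass
class CompoundRecord:
    """One candidate molecule and its campaign lifecycle annotations."""

    structure: str
    route: SyntheticRoute
    parents: list[str] = field(default_factory=list)
    status: str = "ideated"
    cycle_ideated: int | None = None
    cycle_made: int | None = None
    cycle_tested: int | None = None
    predicted: dict[str, float] = field(default_factory=dict)
    measured: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return self.structure

    def advance(self, status: str, cycle: int) -> None:
        if STATUS_ORDER[status] < STATUS_ORDER[self.status]:
            raise ValueError(
                f"status may not regress: {self.status} -> {status}"
            )
        self.status = status
        if status == "made" and self.cycle_made is None:
            self.cycle_made = cycle
        elif status == "tested" and self.cycle_tested is None:
            self.cycle_tested = cycle


# ---------------------------------------------------------------------------
# Catalog / template I/O


def load_catalog(
    path: str, fp_params: FingerprintParams = FingerprintParams()
) -> list[BuildingBlock]:
    """Load a building-block catalog from CSV (``id,smiles``) or SDF.

    Unparseable rows are dropped with a logged count; file order is preserved.
    """
    path = str(path)
    rows: list[tuple[str, str]]
    if path.lower().endswith(".sdf"):
        rows = []
        supplier = Chem.SDMolSupplier(path, sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                rows.append((f"row{i}", "<unparseable>"))
                continue
            block_id = (
                mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"row{i}"
            )
            rows.append((block_id, Chem.MolToSmiles(mol)))
    else:
        import csv

        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(
                reader.fieldnames
            ):
                raise CatalogError(
                    f"catalog {path!r} must have 'id' and 'smiles' columns, "
                    f"found {reader.fieldnames}"
                )
            rows = [(r["id"], r["smiles"]) for r in reader]

    blocks: list[BuildingBlock] = []
    dropped = 0
    seen: set[str] = set()
    for block_id, smiles in rows:
        block = BuildingBlock.from_smiles(block_id, smiles, fp_params)
        if block is None:
            dropped += 1
            continue
        if block.block_id in seen:
            raise CatalogError(f"duplicate block_id {block.block_id!r} in {path!r}")
        seen.add(block.block_id)
        blocks.append(block)
    if dropped:
        logger.info("load_catalog(%s): dropped %d unparseable rows", path, dropped)
    if not blocks:
        raise CatalogError(f"catalog {path!r} contains no valid rows")
    return blocks


def load_templates(path: str) -> list[ReactionTemplate]:
    """Load reaction templates: one reaction SMARTS per line, ``#`` comments.

    An optional ``id<TAB>smarts`` form names the template; otherwise templates
    are named ``rxn0``, ``rxn1``, ... in file order.
    """
    templates = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "\t" in line:
                template_id, smarts = line.split("\t", 1)
            else:
                template_id, smarts = f"rxn{len(templates)}", line
            templates.append(ReactionTemplate(template_id.strip(), smarts.strip()))
    return templates


# ---------------------------------------------------------------------------
# Reaction application


def _protect_atoms(mol: Chem.Mol, pattern: Chem.Mol, site: tuple[int, ...] | None):
    """Mark every pattern-matching atom outside the allowed site as protected.

    RDKit reaction matching skips atoms carrying the ``_protected`` property,
    so a reactant with several reactive sites yields products only at the
    allowed one.
    """
    matches = mol.GetSubstructMatches(pattern)
    if not matches:
        return
    allowed = set(site) if site is not None else set(matches[0])
    for match in matches:
        for idx in match:
            if idx not in allowed:
                mol.GetAtomWithIdx(idx).SetProp("_protected", "1")


def apply_template(
    template: ReactionTemplate,
    reactants: list[str],
    protect: bool = False,
    reactive_sites: list[tuple[int, ...] | None] | None = None,
) -> list[str]:
    """Apply a reaction template to reactant SMILES; return distinct products.

    When ``protect`` is true, atoms outside one matched reactive substructure
    per reactant (the first match, or the atom tuple given in
    ``reactive_sites``) are barred from participating, so multi-site reactants
    contribute a single regiochemistry.  Role mismatches yield an empty list
    (logged), never an exception.  Products failing sanitization are dropped
    and counted.
    """
    if len(reactants) != template.arity:
        logger.info(
            "apply_template(%s): got %d reactants, arity %d",
            template.template_id,
            len(reactants),
            template.arity,
        )
        return []
    mols = []
    for role, smi in enumerate(reactants):
        mol = mol_from_smiles(smi)
        if mol is None or not mol.HasSubstructMatch(template.role_pattern(role)):
            logger.info(
                "apply_template(%s): reactant %d (%r) does not match its role",
                template.template_id,
                role,
                smi,
            )
            return []
        if protect:
            site = None
            if reactive_sites is not None:
                site = reactive_sites[role]
            mol = Chem.Mol(mol)  # cached parse is shared; copy before annotating
            _protect_atoms(mol, template.role_pattern(role), site)
        mols.append(mol)

    products: list[str] = []
    seen: set[str] = set()
    n_failed = 0
    for product_set in template.rxn().RunReactants(tuple(mols)):
        for prod in product_set:
            try:
                Chem.SanitizeMol(prod)
            except Exception:
                n_failed += 1
                continue
            smi = Chem.MolToSmiles(prod)
            if smi not in seen:
                seen.add(smi)
                products.append(smi)
    if n_failed:
        logger.debug(
            "apply_template(%s): %d side-products failed sanitization",
            template.template_id,
            n_failed,
        )
    return products


def replay_route(
    route: SyntheticRoute, templates: dict[str, ReactionTemplate]
) -> str:
    """Replay every step forward and return the canonical final product.

    Raises :class:`RouteError` naming the first step whose recorded product
    cannot be reproduced.
    """
    if not route.steps:
        return route.product
    step_products: list[str] = []
    for i, step in enumerate(route.steps):
        template = templates.get(step.template_id)
        if template is None:
            raise RouteError(f"step {i}: unknown template {step.template_id!r}")
        resolved = []
        for kind, ref in step.reactants:
            if kind == "block":
                resolved.append(ref)
            elif kind == "step":
                if not isinstance(ref, int) or not 0 <= ref < i:
                    raise RouteError(
                        f"step {i}: reactant references step {ref!r}, "
                        "which is not an earlier step"
                    )
                resolved.append(step_products[ref])
            else:
                raise RouteError(f"step {i}: bad reactant reference kind {kind!r}")
        products = apply_template(template, resolved)
        if step.product not in products:
            raise RouteError(
                f"step {i} ({step.template_id}): recorded product "
                f"{step.product!r} not among {len(products)} enumerated products"
            )
        step_products.append(step.product)
    final = step_products[-1]
    if final != route.product:
        raise RouteError(
            f"final step product {final!r} != route product {route.product!r}"
        )
    return final


def space_size_estimate(
    role_counts: dict[str, list[int]], templates: list[ReactionTemplate] | None = None
) -> int:
    """Upper bound on enumerable products: sum over templates of the product
    of per-role compatible-block counts (duplicates not discounted).

    ``role_counts`` maps template_id -> per-role counts.  ``templates`` is
    accepted for interface symmetry and only used to validate arity.
    """
    by_id = {t.template_id: t for t in templates} if templates else {}
    total = 0
    for template_id, counts in role_counts.items():
        t = by_id.get(template_id)
        if t is not None and len(counts) != t.arity:
            raise ValueError(
                f"{template_id}: {len(counts)} role counts for arity {t.arity}"
            )
        prod = 1
        for c in counts:
            prod *= c
        total += prod
    return total
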