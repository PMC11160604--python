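"""Property oracles: noiseless ground truth plus Gaussian-noise wrappers.

An :class:`Oracle` is a deterministic, vectorized map from structures to real
property values (the simulated "assay truth").  A :class:`NoisyOracle` models
an imperfect predictive model of stated inaccuracy sigma: it returns the true
value plus i.i.d. Normal(0, sigma^2) error drawn from a dedicated RNG stream.
Unevaluable structures yield NaN (flagged and logged), never an exception.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Sequence

import numpy as np
from rdkit.Chem import Crippen

from .chem_space import mol_from_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "Oracle",
    "NoisyOracle",
    "lipophilicity_oracle",
    "solubility_oracle",
    "affinity_oracle",
    "HUGE_SIGMA",
]

# Stand-in for "infinite" model error: finite so arithmetic stays well-defined,
# but vastly larger than any objective's dynamic range.
HUGE_SIGMA = 1.0e6


class Oracle:
    """A named, deterministic property function over molecules.

    ``fn`` maps one RDKit Mol to a float; vectorization and structure caching
    are handled here.  ``cost_per_call`` feeds the campaign's econometric
    accounting (ground-truth assays carry the make-and-test cost elsewhere;
    scoring calls default to free).
    """

    def __init__(
        self,
        name: str,
        fn: Callable[[object], float],
        units: str = "",
        cost_per_call: float = 0.0,
    ):
        self.name = name
        self.units = units
        self.cost_per_call = cost_per_call
        self._fn = fn
        self._cache: dict[str, float] = {}

    def evaluate(self, structures: Sequence[str]) -> np.ndarray:
        """One value per structure, order-preserving; NaN for unevaluable."""
        out = np.empty(len(structures))
        for i, smi in enumerate(structures):
            val = self._cache.get(smi)
            if val is None:
                mol = mol_from_smiles(smi)
                if mol is None:
                    logger.info("oracle %s: unevaluable structure %r", self.name, smi)
                    val = math.nan
                else:
                    try:
                        val = float(self._fn(mol))
                    except Exception:
                        logger.info("oracle %s: evaluation failed for %r", self.name, smi)
                        val = math.nan
                self._cache[smi] = val
            out[i] = val
        return out

    def __call__(self, structures: Sequence[str]) -> np.ndarray:
        return self.evaluate(structures)


class NoisyOracle:
    """A ground-truth oracle wrapped with Gaussian error of spread sigma.

    By default noise is resampled on every scoring call (a molecule rescored
    in a later cycle gets fresh error); ``frozen=True`` instead fixes one
    error per molecule for the oracle's lifetime, derived from the molecule's
    own hash so it is reproducible.
    """

    def __init__(
        self,
        base: Oracle,
        sigma: float,
        rng: np.random.Generator | int | None = None,
        frozen: bool = False,
    ):
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.base = base
        self.name = base.name
        self.sigma = float(sigma)
        self.frozen = frozen
        self._rng = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )
        self._frozen_eps: dict[str, float] = {}

    def evaluate(self, structures: Sequence[str]) -> np.ndarray:
        true = self.base.evaluate(structures)
        if self.sigma == 0:
            return true
        if self.frozen:
            eps = np.empty(len(structures))
            for i, smi in enumerate(structures):
                e = self._frozen_eps.get(smi)
                if e is None:
                    e = self._rng.normal(0.0, self.sigma)
                    self._frozen_eps[smi] = e
                eps[i] = e
        else:
            eps = self._rng.normal(0.0, self.sigma, size=len(structures))
        return true + eps

    def __call__(self, structures: Sequence[str]) -> np.ndarray:
        return self.evaluate(structures)


def lipophilicity_oracle() -> Oracle:
    """Atomic-contribution (Crippen) Log P."""
    return Oracle("lipophilicity", Crippen.MolLogP, units="Log P")


def solubility_oracle(model: Oracle | Callable[[object], float]) -> Oracle:
    """Wrap a pluggable solubility regressor as a Log S oracle.

    The regressor either already honors the Oracle contract or is a
    per-molecule callable.  A trained model can be dropped in; the bundled
    synthetic surrogate (:func:`dmtasim.fixtures.synthetic_solubility`)
    serves for self-contained experiments.
    """
    if model is None:
        raise ValueError("solubility_oracle requires a model")
    if isinstance(model, Oracle):
        logger.info("solubility oracle backed by %r", model.name)
        return model
    logger.info("solubility oracle backed by callable %r", getattr(model, "__name__", model))
    return Oracle("solubility", model, units="Log S")


def affinity_oracle(backend: Oracle | Callable[[object], float]) -> Oracle:
    """Wrap a pluggable affinity backend (docking adapter or synthetic
    landscape) as a pIC50 oracle."""
    if backend is None:
        raise ValueError("affinity_oracle requires a backend")
    if isinstance(backend, Oracle):
        return backend
    return Oracle("affinity", backend, units="pIC50")
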