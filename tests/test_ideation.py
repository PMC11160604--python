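"""The analog generator: similarity ranking, Boltzmann draws, replacement,
growth, and the repetition-avoiding cache."""

import math

import numpy as np
import pytest
from rdkit import Chem, DataStructs

from dmtasim.chem_space import BuildingBlock, fingerprint, replay_route
from dmtasim.ideation import (
    ALL,
    INFINITE,
    IdeationConfig,
    boltzmann_sample,
    grow_compound,
    ideate_batch,
    replace_reactants,
    similarity_rank,
)


@pytest.fixture(scope="module")
def library(fixture0):
    return fixture0.catalog


class TestSimilarityRank:
    def test_self_similarity_first(self, library):
        ranked = similarity_rank(library[7], library)
        assert ranked[0][0].block_id == library[7].block_id
        assert ranked[0][1] == 1.0

    def test_matches_brute_force_sort(self, library):
        subset = library[:20]
        ref = subset[3]
        ranked = similarity_rank(ref, subset)
        sims = DataStructs.BulkTanimotoSimilarity(
            ref.fingerprint, [b.fingerprint for b in subset]
        )
        expected = sorted(
            zip(subset, sims), key=lambda p: (-p[1], p[0].block_id)
        )
        assert [b.block_id for b, _ in ranked] == [b.block_id for b, _ in expected]

    def test_disjoint_fingerprints_zero_similarity(self):
        a = BuildingBlock.from_smiles("a", "CCCC")
        b = BuildingBlock.from_smiles("b", "O=S(=O)(O)O")
        ranked = similarity_rank(a, [b])
        assert ranked[0][1] == 0.0

    def test_empty_library_rejected(self, library):
        with pytest.raises(ValueError):
            similarity_rank(library[0], [])


def _equal_sim_ranked(n=20):
    blocks = [BuildingBlock.from_smiles(f"b{i:02d}", "C" * (i + 1)) for i in range(n)]
    return [(b, 0.5) for b in blocks]


class TestBoltzmannSample:
    def test_zero_temperature_is_deterministic_top_k(self, library, rng):
        ranked = similarity_rank(library[5], library)
        out = boltzmann_sample(ranked, temperature=0.0, k=3, rng=rng)
        assert [b.block_id for b in out] == [b.block_id for b, _ in ranked[:3]]

    def test_infinite_temperature_uniform_chi_square(self):
        ranked = _equal_sim_ranked(4)
        rng = np.random.default_rng(11)
        counts = np.zeros(4)
        for _ in range(10_000):
            chosen = boltzmann_sample(ranked, INFINITE, k=1, rng=rng)[0]
            counts[int(chosen.block_id[1:])] += 1
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.001

    def test_seeded_reproducibility(self, library):
        ranked = similarity_rank(library[2], library)
        a = boltzmann_sample(ranked, 0.1, 5, np.random.default_rng(42))
        b = boltzmann_sample(ranked, 0.1, 5, np.random.default_rng(42))
        assert [x.block_id for x in a] == [x.block_id for x in b]

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            boltzmann_sample(_equal_sim_ranked(3), 0.1, 5, rng)

    def test_monotone_temperature_effect(self, library):
        # Mean similarity of drawn blocks to the reference is non-increasing
        # in temperature.
        ranked = similarity_rank(library[5], library)
        means = []
        for i, temp in enumerate([0.0, 0.04, 0.16, 0.64, INFINITE]):
            rng = np.random.default_rng(100 + i)
            sims = []
            for _ in range(200):
                chosen = boltzmann_sample(ranked, temp, 4, rng)
                lookup = {b.block_id: s for b, s in ranked}
                sims.extend(lookup[b.block_id] for b in chosen)
            means.append(np.mean(sims))
        assert all(a >= b - 0.03 for a, b in zip(means, means[1:]))
        assert means[0] > means[-1]


class TestReplaceReactants:
    def test_identity_replacement_at_zero_temperature(self, fixture0, template_map):
        # With T=0 and the original block in the library, the top analog is
        # the parent itself (removed later by the campaign cache).
        parent = fixture0.hits[0]
        config = IdeationConfig(temperature=0.0, n_replace=1, analogs_per_parent=1)
        out = replace_reactants(
            parent, fixture0.catalog, template_map, config, np.random.default_rng(0),
            n_analogs=1,
        )
        assert out and out[0][0] == parent.structure

    def test_all_replacement_replaces_both_positions(self, fixture0, template_map):
        parent = fixture0.hits[0]
        original = [ref for kind, ref in parent.route.steps[-1].reactants]
        config = IdeationConfig(temperature=INFINITE, n_replace=ALL)
        out = replace_reactants(
            parent, fixture0.catalog, template_map, config,
            np.random.default_rng(1), n_analogs=12,
        )
        assert out
        for _, route, chosen_ids in out:
            assert len(chosen_ids) == 2
            new = [ref for kind, ref in route.steps[-1].reactants]
            assert new != original

    def test_emitted_routes_replay_to_emitted_structures(
        self, fixture0, template_map
    ):
        parent = fixture0.hits[1]
        config = IdeationConfig(temperature=0.08, n_replace=1)
        out = replace_reactants(
            parent, fixture0.catalog, template_map, config,
            np.random.default_rng(2), n_analogs=8,
        )
        assert out
        for structure, route, _ in out:
            assert replay_route(route, template_map) == structure

    def test_all_replacement_more_dissimilar_than_one(self, fixture0, template_map):
        # Fixed temperature: replacing every reactant strays further from the
        # parent than replacing one.
        parent = fixture0.hits[0]
        parent_fp = fingerprint(parent.structure)

        def mean_sim(n_replace, seed):
            config = IdeationConfig(temperature=0.64, n_replace=n_replace)
            sims = []
            for s in range(seed, seed + 8):
                out = replace_reactants(
                    parent, fixture0.catalog, template_map, config,
                    np.random.default_rng(s), n_analogs=25,
                )
                sims += [
                    DataStructs.TanimotoSimilarity(parent_fp, fingerprint(p))
                    for p, _, _ in out
                ]
            return np.mean(sims)

        assert mean_sim(1, 10) > mean_sim(ALL, 10) - 0.02


class TestGrowCompound:
    def test_growth_adds_heavy_atoms(self, fixture0, template_map):
        parent = fixture0.hits[0]
        parent_heavy = Chem.MolFromSmiles(parent.structure).GetNumHeavyAtoms()
        config = IdeationConfig()
        out = grow_compound(
            parent, fixture0.catalog, template_map, config,
            np.random.default_rng(3), n_analogs=6,
        )
        assert out
        for structure, route, _ in out:
            assert Chem.MolFromSmiles(structure).GetNumHeavyAtoms() > parent_heavy
            assert len(route.steps) == len(parent.route.steps) + 1

    def test_amide_growth_creates_amide_bond(self, template_map, fixture0):
        from dmtasim.chem_space import CompoundRecord, SyntheticRoute

        parent = CompoundRecord(
            structure="O=C(O)c1ccccc1", route=SyntheticRoute.trivial("O=C(O)c1ccccc1")
        )
        amines = [
            b for b in fixture0.catalog
            if template_map["amide_coupling"].matches_role(b.structure, 1)
        ]
        config = IdeationConfig()
        out = grow_compound(
            parent, amines, [template_map["amide_coupling"]], config,
            np.random.default_rng(4), n_analogs=5,
        )
        assert out
        amide = Chem.MolFromSmarts("C(=O)N")
        for structure, _, _ in out:
            assert Chem.MolFromSmiles(structure).HasSubstructMatch(amide)

    def test_size_filter_empties_output(self, fixture0, template_map):
        parent = fixture0.hits[0]
        config = IdeationConfig(growth_max_heavy_atoms=1)
        out = grow_compound(
            parent, fixture0.catalog, template_map, config,
            np.random.default_rng(5), n_analogs=5,
        )
        assert out == []

    def test_route_replay_closure(self, fixture0, template_map):
        parent = fixture0.hits[2]
        config = IdeationConfig()
        out = grow_compound(
            parent, fixture0.catalog, template_map, config,
            np.random.default_rng(6), n_analogs=5,
        )
        for structure, route, _ in out:
            assert replay_route(route, template_map) == structure


class TestIdeateBatch:
    def test_cache_prevents_repeats_across_runs(self, fixture0, template_map):
        config = IdeationConfig(temperature=0.08, analogs_per_parent=8)
        cache: set[str] = set()
        first = ideate_batch(
            fixture0.hits, fixture0.catalog, template_map, config, cache,
            np.random.default_rng(7),
        )
        second = ideate_batch(
            fixture0.hits, fixture0.catalog, template_map, config, cache,
            np.random.default_rng(7),
        )
        keys1 = {r.key for r in first}
        keys2 = {r.key for r in second}
        assert keys1 and not (keys1 & keys2)

    def test_no_duplicate_keys_within_batch(self, fixture0, template_map):
        config = IdeationConfig(analogs_per_parent=8)
        out = ideate_batch(
            fixture0.hits, fixture0.catalog, template_map, config, set(),
            np.random.default_rng(8),
        )
        keys = [r.key for r in out]
        assert len(keys) == len(set(keys))

    def test_lineage_recorded(self, fixture0, template_map):
        config = IdeationConfig(analogs_per_parent=4)
        parent = fixture0.hits[0]
        out = ideate_batch(
            [parent], fixture0.catalog, template_map, config, set(),
            np.random.default_rng(9),
        )
        assert out
        for rec in out:
            assert rec.parents == [parent.key]
            assert rec.status == "ideated"

    def test_empty_parents_rejected(self, fixture0, template_map):
        with pytest.raises(ValueError):
            ideate_batch(
                [], fixture0.catalog, template_map, IdeationConfig(), set(),
                np.random.default_rng(0),
            )
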