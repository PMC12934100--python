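"""Weighted co-expression network: adjacency, TOM, modules, eigengene, hub."""

import numpy as np
import pandas as pd
import pytest

import dormsig as ds
from dormsig import NetworkParams
from dormsig.network import (
    adjacency,
    detect_modules,
    hub_gene,
    intramodular_connectivity,
    module_eigengene,
    module_trait_correlation,
    network_analysis,
    topological_overlap,
)


def exact_corr_pair(r, n=12, seed=0):
    """Two gene rows whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    a = (a - a.mean()) / np.linalg.norm(a - a.mean())
    b = rng.standard_normal(n)
    b = b - b.mean()
    b = b - (b @ a) * a
    b /= np.linalg.norm(b)
    g2 = r * a + np.sqrt(1 - r * r) * b
    return pd.DataFrame([a, g2], index=["g1", "g2"])


class TestAdjacency:
    def test_diagonal_is_one(self):
        z = exact_corr_pair(0.3)
        a = adjacency(z)
        assert np.allclose(np.diag(a), 1.0)

    def test_perfect_anticorrelation_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        z = pd.DataFrame([x, -x], index=["g1", "g2"])
        assert adjacency(z).loc["g1", "g2"] == pytest.approx(1.0)

    def test_soft_threshold_power_value(self):
        a = adjacency(exact_corr_pair(0.5), NetworkParams(beta=6))
        assert a.loc["g1", "g2"] == pytest.approx(0.5**6)
        assert a.loc["g1", "g2"] == pytest.approx(0.015625)

    def test_degenerate_gene_gets_zero_adjacency(self):
        z = exact_corr_pair(0.5)
        z.loc["flat"] = 1.0
        a = adjacency(z)
        assert a.loc["flat", "g1"] == 0.0
        assert a.loc["flat", "flat"] == 1.0

    def test_too_few_samples_rejected(self):
        z = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["g1", "g2"])
        with pytest.raises(ValueError):
            adjacency(z)

    def test_entries_symmetric_in_unit_interval(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(15, 10)))
        a = adjacency(z).to_numpy()
        assert np.allclose(a, a.T)
        assert (a >= 0).all() and (a <= 1).all()


class TestTopologicalOverlap:
    def test_two_gene_network_equals_adjacency(self):
        for c in (0.0, 0.2, 0.7, 1.0):
            a = pd.DataFrame([[1.0, c], [c, 1.0]], index=list("ab"), columns=list("ab"))
            tom = topological_overlap(a)
            assert tom.loc["a", "b"] == pytest.approx(c)

    def test_fully_connected_triple_saturates(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        tom = topological_overlap(a)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(rng.normal(size=(8, 10)))
        tom = topological_overlap(adjacency(z))
        assert np.allclose(np.diag(tom), 1.0)

    def test_symmetric_unit_interval_on_random_networks(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            z = pd.DataFrame(rng.normal(size=(12, 9)))
            tom = topological_overlap(adjacency(z)).to_numpy()
            assert np.allclose(tom, tom.T)
            assert (tom >= 0).all() and (tom <= 1).all()

    def test_asymmetric_input_rejected(self):
        a = pd.DataFrame([[1.0, 0.3], [0.6, 1.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            topological_overlap(a)


def two_block_z(n=30, block=10, within=0.9, seed=3):
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for b in (1, 2):
        f = rng.standard_normal(n)
        for i in range(block):
            rows.append(np.sqrt(within) * f + np.sqrt(1 - within) * rng.standard_normal(n))
            names.append(f"B{b}G{i:02d}")
    return pd.DataFrame(rows, index=names)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        z = two_block_z()
        mods = detect_modules(topological_overlap(adjacency(z)), NetworkParams())
        assert len(mods) == 2
        prefixes = sorted({g[:2] for m in mods for g in m})
        assert prefixes == ["B1", "B2"]
        assert all(len({g[:2] for g in m}) == 1 for m in mods)

    def test_uncorrelated_genes_yield_no_modules(self):
        rng = np.random.default_rng(4)
        z = pd.DataFrame(rng.normal(size=(60, 30)))
        assert detect_modules(topological_overlap(adjacency(z)), NetworkParams()) == []

    def test_fewer_genes_than_min_module_size(self):
        z = two_block_z(block=2)
        tom = topological_overlap(adjacency(z))
        assert detect_modules(tom, NetworkParams(min_module_size=5)) == []

    def test_modules_partition_genes(self):
        z = two_block_z()
        mods = detect_modules(topological_overlap(adjacency(z)), NetworkParams())
        flat = [g for m in mods for g in m]
        assert len(flat) == len(set(flat))

    def test_gene_relabelling_invariance(self):
        z = two_block_z()
        perm = np.random.default_rng(5).permutation(len(z))
        mods_a = detect_modules(topological_overlap(adjacency(z)), NetworkParams())
        mods_b = detect_modules(
            topological_overlap(adjacency(z.iloc[perm])), NetworkParams()
        )
        assert {frozenset(m) for m in mods_a} == {frozenset(m) for m in mods_b}


class TestEigengene:
    def test_rank_one_module_reproduces_shared_profile(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        z = pd.DataFrame([profile] * 4, index=list("abcd"))
        eig, explained = module_eigengene(z, list("abcd"))
        assert explained == pytest.approx(1.0)
        for g in "abcd":
            r = np.corrcoef(eig, z.loc[g])[0, 1]
            assert r == pytest.approx(1.0)

    def test_orientation_against_module_mean(self):
        rng = np.random.default_rng(6)
        z = pd.DataFrame(rng.normal(size=(6, 10)), index=list("abcdef"))
        eig, _ = module_eigengene(z, list("abcdef"))
        mean_profile = z.mean(axis=0)
        assert np.corrcoef(eig, mean_profile)[0, 1] >= 0

    def test_unit_norm(self):
        rng = np.random.default_rng(7)
        z = pd.DataFrame(rng.normal(size=(5, 9)), index=list("abcde"))
        eig, _ = module_eigengene(z, list("abcde"))
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_empty_module_rejected(self):
        z = pd.DataFrame(np.ones((2, 4)), index=list("ab"))
        with pytest.raises(ValueError):
            module_eigengene(z, [])


class TestModuleTraitCorrelation:
    def test_self_correlation_is_one(self):
        eig = pd.Series([0.1, -0.4, 0.3, 0.2, -0.2])
        r, p = module_trait_correlation(eig, eig)
        assert r == pytest.approx(1.0)

    def test_orthogonal_trait_gives_zero(self):
        eig = pd.Series([1.0, -1.0, 1.0, -1.0])
        trait = pd.Series([1.0, 1.0, -1.0, -1.0])
        r, _ = module_trait_correlation(eig, trait)
        assert abs(r) < 1e-9

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(8)
        eig = pd.Series(rng.normal(size=12))
        trait = pd.Series(rng.normal(size=12))
        from scipy import stats

        r, p = module_trait_correlation(eig, trait)
        t = r * np.sqrt((12 - 2) / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 12 - 2))

    def test_degenerate_inputs_rejected(self):
        eig = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            module_trait_correlation(eig, pd.Series([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError):
            module_trait_correlation(eig.iloc[:2], pd.Series([1.0, 2.0]))


class TestHubGene:
    def test_star_topology_center_wins(self):
        """Hub = max intramodular connectivity; verified against brute force."""
        rng = np.random.default_rng(9)
        n = 40
        center = rng.standard_normal(n)
        rows = {"HUB": center}
        for i in range(6):
            rows[f"S{i}"] = 0.9 * center + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        z = pd.DataFrame.from_dict(rows, orient="index")
        a = adjacency(z)
        module = list(z.index)
        best_brute = max(
            module,
            key=lambda g: sum(a.loc[g, h] for h in module if h != g),
        )
        assert hub_gene(a, module) == best_brute == "HUB"

    def test_single_gene_module(self):
        z = exact_corr_pair(0.4)
        a = adjacency(z)
        assert hub_gene(a, ["g1"]) == "g1"

    def test_missing_module_gene_rejected(self):
        a = adjacency(exact_corr_pair(0.4))
        with pytest.raises(ValueError):
            hub_gene(a, ["g1", "nope"])

    def test_connectivity_values(self):
        a = pd.DataFrame(
            [[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        k = intramodular_connectivity(a, list("abc"))
        assert k["a"] == pytest.approx(0.7)
        assert k["b"] == pytest.approx(0.6)
        assert k["c"] == pytest.approx(0.3)


class TestPipeline:
    def test_default_cohort_recovers_planted_hub_and_trait_link(self, default_cohort):
        cfg, m, labels = default_cohort
        z, _ = ds.zscore_genes(ds.log_transform(m))
        trait = ds.dormancy_score(z, ds.default_signature())["score"]
        mods = network_analysis(z, NetworkParams(), trait=trait)
        significant = [mo for mo in mods if mo.trait_p is not None and mo.trait_p < 0.05]
        assert len(significant) == 1
        best = significant[0]
        assert best.hub == cfg.module_hub
        assert best.trait_r > 0
        assert set(cfg.module_member_ids()) <= set(best.genes)
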