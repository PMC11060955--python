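"""Adjacency, TOM, module detection, eigengenes, and tissue-specific calls."""

import numpy as np
import pandas as pd
import pytest

from tempro.coexpression import (
    CoexpressionModules,
    adjacency_matrix,
    detect_modules,
    module_eigengene,
    module_trait_association,
    pick_soft_threshold,
    tissue_associated_modules,
    tissue_specific_intersection,
    topological_overlap,
)


def correlated_block(n_genes, n_samples, rho, rng, scale=1.0):
    base = rng.normal(size=n_samples)
    rows = [np.sqrt(rho) * base + np.sqrt(1 - rho) * rng.normal(size=n_samples)
            for _ in range(n_genes)]
    return np.vstack(rows) * scale


class TestAdjacency:
    def test_power_six_of_half(self):
        x = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        A = adjacency_matrix(x, 6)
        assert A[0, 1] == pytest.approx(1.0)  # cor 1 -> adjacency 1 at any power
        # direct check of the arithmetic |0.5|^6
        assert 0.5**6 == pytest.approx(0.015625)

    def test_beta_one_on_perfect_block(self, rng):
        base = rng.normal(size=20)
        x = pd.DataFrame([base, 2 * base + 1, -base])
        A = adjacency_matrix(x, 1)
        off = A[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)
        np.testing.assert_allclose(np.diag(A), 0.0)

    def test_soft_threshold_deterministic(self, rng):
        X = np.vstack([correlated_block(30, 25, 0.8, rng),
                       correlated_block(30, 25, 0.8, rng)])
        vals = pd.DataFrame(10 ** (X * 0.3 + 1.0))
        b1, fits1 = pick_soft_threshold(vals.apply(np.log10))
        b2, fits2 = pick_soft_threshold(vals.apply(np.log10))
        assert b1 == b2
        pd.testing.assert_series_equal(fits1, fits2)


class TestTOM:
    def test_four_node_hand_computation(self):
        A = np.array(
            [
                [0.0, 0.8, 0.4, 0.0],
                [0.8, 0.0, 0.5, 0.1],
                [0.4, 0.5, 0.0, 0.6],
                [0.0, 0.1, 0.6, 0.0],
            ]
        )
        tom = topological_overlap(A)
        k = A.sum(axis=1)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(4))
                expected = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_fully_connected_nodes_have_tom_one(self):
        # nodes 0 and 1: a_01 = 1 and identical unit connections to node 2
        A = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        tom = topological_overlap(A)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_empty_graph_has_zero_overlap(self):
        tom = topological_overlap(np.zeros((4, 4)))
        assert (tom[~np.eye(4, dtype=bool)] == 0).all()

    def test_asymmetric_input_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 0.5
        with pytest.raises(ValueError):
            topological_overlap(A)

    def test_tom_bounded_by_unit_interval(self, rng):
        C = np.abs(np.corrcoef(rng.normal(size=(12, 30)))) ** 4
        np.fill_diagonal(C, 0.0)
        tom = topological_overlap(C)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()


class TestModules:
    def planted_two_blocks(self, rho_between=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        if rho_between > 0:
            shared = rng.normal(size=40)
            b1 = np.sqrt(rho_between) * shared + np.sqrt(1 - rho_between) * rng.normal(size=40)
            b2 = np.sqrt(rho_between) * shared + np.sqrt(1 - rho_between) * rng.normal(size=40)
        else:
            b1, b2 = rng.normal(size=40), rng.normal(size=40)
        rows = []
        for b in (b1, b2):
            rows.append(np.vstack([
                np.sqrt(0.9) * b + np.sqrt(0.1) * rng.normal(size=40) for _ in range(n)
            ]))
        X = np.vstack(rows)
        return pd.DataFrame(10 ** (X * 0.3 + 1.0),
                            index=[f"g{i}" for i in range(2 * n)])

    def test_two_planted_blocks_recovered(self):
        vals = self.planted_two_blocks()
        mods = detect_modules(vals, min_module_size=50)
        assigned = set(mods.labels.unique()) - {0}
        assert len(assigned) == 2
        first = mods.labels.iloc[:60]
        second = mods.labels.iloc[60:]
        acc = max(
            ((first == a).mean() + (second == b).mean()) / 2
            for a in assigned for b in assigned if a != b
        )
        assert acc >= 0.95

    def test_single_small_block_left_unassigned(self):
        rng = np.random.default_rng(1)
        X = correlated_block(40, 30, 0.9, rng)
        vals = pd.DataFrame(10 ** (X * 0.3 + 1.0))
        mods = detect_modules(vals, min_module_size=50)
        assert (mods.labels == 0).all()

    def test_correlated_blocks_merged_by_eigengene_rule(self):
        # planted underlying profiles correlate ~0.9 -> eigengene dissim < 0.3
        vals = self.planted_two_blocks(rho_between=0.9, seed=2)
        mods = detect_modules(vals, min_module_size=50, merge_cut_height=0.3)
        assert len(set(mods.labels.unique()) - {0}) == 1

    def test_no_module_below_min_size(self):
        vals = self.planted_two_blocks()
        mods = detect_modules(vals, min_module_size=50)
        sizes = mods.labels[mods.labels != 0].value_counts()
        assert (sizes >= 50).all()


class TestEigengene:
    def test_identical_rows_give_their_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 4.0])
        vals = pd.DataFrame(np.tile(profile, (5, 1)), columns=list("abcd"))
        e = module_eigengene(vals)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(e, z / np.linalg.norm(z), atol=1e-12)

    def test_sign_orientation_invariant_to_global_flip(self, rng):
        vals = pd.DataFrame(rng.normal(size=(6, 10)))
        e1 = module_eigengene(vals)
        cor = float(np.corrcoef(e1, vals.mean(axis=0))[0, 1])
        assert cor >= 0

    def test_matches_direct_svd(self, rng):
        vals = pd.DataFrame(rng.lognormal(size=(3, 8)))
        Z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=1), axis=0)
        _, _, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        direct = vt[0] if vt[0] @ Z.mean(axis=0).to_numpy() >= 0 else -vt[0]
        np.testing.assert_allclose(module_eigengene(vals), direct, atol=1e-8)

    def test_explains_most_variance(self, rng):
        vals = pd.DataFrame(rng.normal(size=(8, 12)))
        Z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=1), axis=0)
        e = module_eigengene(vals).to_numpy()
        var_e = ((Z.to_numpy() @ e) ** 2).sum()
        for _ in range(50):
            v = rng.normal(size=12)
            v /= np.linalg.norm(v)
            assert ((Z.to_numpy() @ v) ** 2).sum() <= var_e + 1e-9


class TestTraitsAndSpecificity:
    def tumor_module_setup(self):
        rng = np.random.default_rng(3)
        design = pd.DataFrame(
            [
                {"sample_id": f"{t}_{i}", "tissue": t, "day": 3, "replicate": i}
                for t in ("tumor", "LN", "MLN", "spleen") for i in (1, 2, 3)
            ]
        )
        high = {s: (10.0 if s.startswith("tumor") else 0.1) for s in design["sample_id"]}
        rows = {}
        for g in range(60):
            rows[f"g{g}"] = [high[s] * rng.lognormal(0, 0.05) for s in design["sample_id"]]
        values = pd.DataFrame.from_dict(rows, orient="index",
                                        columns=design["sample_id"])
        mods = detect_modules(values, min_module_size=30)
        return values, design, mods

    def test_tumor_only_module_correlates_with_tumor_trait(self):
        values, design, mods = self.tumor_module_setup()
        trait = module_trait_association(mods, design)
        assert trait.shape[1] == 4
        assert trait["tumor"].max() > 0.9
        assoc = tissue_associated_modules(trait, threshold=0.6)
        assert len(assoc["tumor"]) >= 1

    def test_single_tissue_design_rejected(self):
        values, design, mods = self.tumor_module_setup()
        with pytest.raises(ValueError):
            module_trait_association(mods, design[design["tissue"] == "tumor"])

    def test_intersection_rule(self):
        labels = pd.Series({"a": 1, "b": 1, "c": 0})
        eig = pd.DataFrame([[0.5, -0.5]], index=[1], columns=["s1", "s2"])
        mods = CoexpressionModules(soft_power=2, labels=labels, eigengenes=eig,
                                   scale_free_fit=pd.Series(dtype=float))
        trait = pd.DataFrame({"spleen": [0.9], "tumor": [-0.3]}, index=[1])
        tier3 = {"spleen": ["a", "c", "x"], "tumor": ["x", "b"]}
        calls = tissue_specific_intersection(tier3, mods, trait, threshold=0.6)
        calls = calls.set_index(["gene", "tissue"])
        # a: unique to spleen AND in spleen-associated module 1 -> specific
        assert calls.loc[("a", "spleen"), "tissue_specific"]
        # c: unique to spleen but module 0 (unassigned) -> not specific
        assert not calls.loc[("c", "spleen"), "tissue_specific"]
        # x: detected in two tissues -> never venn-unique
        assert not calls.loc[("x", "spleen"), "venn_unique"]

    def test_planted_tissue_unique_recovery(self):
        values, design, mods = self.tumor_module_setup()
        trait = module_trait_association(mods, design)
        tier3 = {"tumor": [f"g{i}" for i in range(60)], "LN": [], "MLN": [], "spleen": []}
        calls = tissue_specific_intersection(tier3, mods, trait, threshold=0.6)
        specific = calls[calls["tissue_specific"]]
        assert len(specific) / 60 >= 0.9
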