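"""Pseudo-count fold changes, t/KW tests, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tempro.config import SimulationConfig
from tempro import synthetic
from tempro.differential import (
    bh_adjust,
    call_differential,
    fold_change,
    kruskal_wallis,
    parse_contrast,
    student_t,
)


class TestFoldChange:
    def test_pseudo_count_examples(self):
        assert fold_change([0, 0, 0], [1, 1, 1]) == pytest.approx(0.1 / 1.1)
        assert fold_change([1, 1, 1], [0, 0, 0]) == pytest.approx(11.0)

    def test_equal_means_give_one(self):
        assert fold_change([2.0, 4.0], [3.0, 3.0]) == 1.0

    def test_zero_vs_zero_gives_one(self):
        assert fold_change([0.0], [0.0]) == 1.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            fold_change([-1.0], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=1, max_size=5),
        b=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=1, max_size=5),
    )
    def test_antisymmetry(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, rel=1e-9)


class TestStudentT:
    def test_identical_groups_give_p_one(self):
        assert student_t([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 1.0

    def test_separated_groups_give_tiny_p(self):
        a = [0.0, 0.001, -0.001]
        b = [10.0, 10.001, 9.999]
        assert student_t(a, b) < 1e-4

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 3.5, 5.0])
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        expected = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert student_t(a, b) == pytest.approx(expected, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            student_t([1.0], [1.0, 2.0])


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_ps_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(1e-10, 1.0, allow_nan=False), min_size=1, max_size=20))
    def test_never_below_raw_and_order_preserving(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_manual_step_up(self, rng):
        p = rng.uniform(1e-6, 1, size=25)
        n = len(p)
        order = np.argsort(p)
        manual = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            manual[i] = running
        np.testing.assert_allclose(bh_adjust(p), manual, atol=1e-12)


class TestKruskalWallis:
    def test_all_equal_gives_zero(self):
        h, p = kruskal_wallis([1.0, 1.0], [1.0, 1.0], [1.0])
        assert h == 0.0 and p == 1.0

    def test_matches_manual_rank_computation(self):
        groups = [(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)]
        # no ties: H = 12/(N(N+1)) Σ n_i R̄_i² − 3(N+1), ranks 1..6
        rbar = [1.5, 3.5, 5.5]
        H = 12 / (6 * 7) * sum(2 * r**2 for r in rbar) - 3 * 7
        h, p = kruskal_wallis(*groups)
        assert h == pytest.approx(H, abs=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(H, 2)), abs=1e-12)

    def test_label_permutation_p_is_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            pooled = rng.lognormal(size=9)
            h, p = kruskal_wallis(pooled[:3], pooled[3:6], pooled[6:])
            ps.append(p)
        assert 0.35 < np.median(ps) < 0.75

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [])


class TestCallDifferential:
    def test_contrast_parsing(self):
        assert parse_contrast("tumor:D3 vs tumor:D0") == (("tumor", 3), ("tumor", 0))
        assert parse_contrast("LN:D7 vs D0") == (("LN", 7), ("LN", 0))
        with pytest.raises(ValueError):
            parse_contrast("D3 versus D0")

    def test_planted_up_gene_called_up(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(6)], "tissue": ["tumor"] * 6,
             "day": [0, 0, 0, 3, 3, 3], "replicate": [1, 2, 3, 1, 2, 3]}
        )
        base = rng.lognormal(2, 0.05, size=(20, 6))
        base[0, 3:] *= 4  # planted 4-fold up on D3
        values = pd.DataFrame(base, index=[f"g{i}" for i in range(20)],
                              columns=design["sample_id"])
        out = call_differential(values, design, "tumor:D3 vs tumor:D0")
        assert out.loc["g0", "call"] == "up"

    def test_tenfold_variant_rule(self):
        design = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(6)], "tissue": ["tumor"] * 6,
             "day": [0, 0, 0, 3, 3, 3], "replicate": [1, 2, 3, 1, 2, 3]}
        )
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.lognormal(1, 0.02, size=(10, 6)),
                            index=[f"g{i}" for i in range(10)],
                            columns=design["sample_id"])
        vals.iloc[0, 3:] *= 11
        out = call_differential(vals, design, "tumor:D3 vs tumor:D0", fc_threshold=10)
        assert out.loc["g0", "fold_change"] > 10
        assert out.loc["g0", "call"] == "up"
        # genes between 2x and 10x are not called at threshold 10
        vals.iloc[1, 3:] *= 3
        out = call_differential(vals, design, "tumor:D3 vs tumor:D0", fc_threshold=10)
        assert out.loc["g1", "call"] == "ns"

    def test_swapping_direction_inverts_fc_and_calls(self):
        design = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(6)], "tissue": ["LN"] * 6,
             "day": [0, 0, 0, 7, 7, 7], "replicate": [1, 2, 3, 1, 2, 3]}
        )
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.lognormal(1, 0.3, size=(30, 6)),
                            columns=design["sample_id"])
        fwd = call_differential(vals, design, "LN:D7 vs D0")
        rev = call_differential(vals, design, "LN:D0 vs D7")
        np.testing.assert_allclose(fwd["fold_change"] * rev["fold_change"], 1.0,
                                   rtol=1e-9)
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert (fwd["call"].map(swap) == rev["call"]).all()

    def test_null_simulation_controls_type_one_error(self):
        """Raw-p rejection at 0.05 sits in the 99% binomial band under the null."""
        arch = np.zeros((1, 2))
        cfg = SimulationConfig(
            n_genes=2000, tissues=("tumor",), days=(0, 3), n_replicates=3,
            n_temporal_clusters=1, cluster_archetypes=arch,
            archetypes_exclude_day0=False, tissue_unique_fraction=0.0,
            intensity_log_sd=0.2, seed=11,
        )
        expr, _ = synthetic.simulate_expression(cfg)
        de = call_differential(expr.values, expr.design, "tumor:D3 vs D0")
        rejections = int((de["p_value"] < 0.05).sum())
        lo, hi = stats.binom.interval(0.99, 2000, 0.05)
        assert lo <= rejections <= hi
        assert (de["adj_p"] >= de["p_value"] - 1e-15).all()
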