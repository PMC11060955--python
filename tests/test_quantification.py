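"""iBAQ/iFOT arithmetic, the in-silico digest, and normalization identities."""

import numpy as np
import pandas as pd
import pytest

from tempro.quantification import (
    collapse_to_gene,
    compute_ibaq,
    count_theoretical_peptides,
    normalize_ifot,
    replicate_correlation,
)


class TestDigest:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAAAAAKCCCCCCRDDDDDD", 2),   # DDDDDD is length 6, excluded
            ("KKKK", 0),                   # all fragments too short
            ("AAAAAAKPAAAAAA", 1),         # no cleavage before proline
        ],
    )
    def test_manual_digest_examples(self, seq, expected):
        assert count_theoretical_peptides(seq, 7, 30, 0) == expected

    def test_missed_cleavage_adds_longer_peptides(self):
        seq = "AAAAAAKCCCCCCRDDDDDD"
        assert count_theoretical_peptides(seq, 7, 30, 1) == 4  # + AAAAAAKCCCCCCR, CCCCCCRDDDDDD

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            count_theoretical_peptides("")

    def test_invalid_characters_are_error(self):
        with pytest.raises(ValueError, match="invalid"):
            count_theoretical_peptides("AAAAAAKBZ")


class TestIbaq:
    def evidence(self):
        return pd.DataFrame(
            {
                "accession": ["P1", "P1"],
                "gene": ["G1", "G1"],
                "sequence": ["AAAAAACK", "CCCCCCR"],
                "ion_score": [50.0, 30.0],
                "is_unique": [True, False],
                "s1": [6.0, 4.0],
                "s2": [2.0, 0.0],
            }
        )

    def test_division_by_theoretical_count(self):
        # digest of the sequence below gives 5 peptides in [7, 30]
        seqs = {"P1": "AAAAAACK" "CCCCCCR" "DDDDDDK" "EEEEEER" "FFFFFFK"}
        assert count_theoretical_peptides(seqs["P1"]) == 5
        ibaq = compute_ibaq(self.evidence(), seqs, ["s1", "s2"])
        assert ibaq.loc["P1", "s1"] == pytest.approx(10.0 / 5)
        assert ibaq.loc["P1", "s2"] == pytest.approx(2.0 / 5)

    def test_linearity_in_intensity(self):
        seqs = {"P1": "AAAAAACKCCCCCCR"}
        ev = self.evidence()
        ref = compute_ibaq(ev, seqs, ["s1", "s2"])
        ev2 = ev.copy()
        ev2[["s1", "s2"]] *= 2
        np.testing.assert_allclose(
            compute_ibaq(ev2, seqs, ["s1", "s2"])[["s1", "s2"]],
            ref[["s1", "s2"]] * 2,
        )

    def test_missing_sequence_names_accession(self):
        with pytest.raises(ValueError, match="P1"):
            compute_ibaq(self.evidence(), {}, ["s1", "s2"])


class TestIfot:
    def test_hand_example_three_to_one(self):
        m = pd.DataFrame({"s": [3.0, 1.0]}, index=["A", "B"])
        out = normalize_ifot(m)
        assert out.loc["A", "s"] == pytest.approx(75000.0)
        assert out.loc["B", "s"] == pytest.approx(25000.0)

    def test_equal_abundance_splits_evenly(self):
        m = pd.DataFrame({"s": [2.0] * 8})
        np.testing.assert_allclose(normalize_ifot(m)["s"], 1e5 / 8)

    def test_column_sums_and_scale_invariance(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(50, 4)), columns=list("abcd"))
        out = normalize_ifot(m)
        np.testing.assert_allclose(out.sum(axis=0), 1e5, rtol=1e-6)
        scaled = m.copy()
        scaled["b"] *= 17.3
        pd.testing.assert_frame_equal(normalize_ifot(scaled), out)

    def test_all_zero_column_names_sample(self):
        m = pd.DataFrame({"ok": [1.0, 2.0], "bad": [0.0, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            normalize_ifot(m)


class TestCollapse:
    def test_isoforms_sum(self):
        pq = pd.DataFrame(
            {"gene": ["G", "G", "H"], "s1": [10.0, 5.0, 1.0], "s2": [1.0, 1.0, 1.0]},
            index=["P1", "P2", "P3"],
        )
        out = collapse_to_gene(pq, ["s1", "s2"])
        assert out.loc["G", "s1"] == 15.0
        assert out.loc["H", "s1"] == 1.0

    def test_collapse_normalize_commutes(self, rng):
        genes = rng.choice(["G1", "G2", "G3"], size=10)
        pq = pd.DataFrame(rng.lognormal(size=(10, 3)), columns=["a", "b", "c"])
        pq.insert(0, "gene", genes)
        a = normalize_ifot(collapse_to_gene(pq, ["a", "b", "c"]))
        b = collapse_to_gene(
            pd.concat([pq[["gene"]], normalize_ifot(pq[["a", "b", "c"]])], axis=1),
            ["a", "b", "c"],
        )
        pd.testing.assert_frame_equal(a, b)

    def test_missing_gene_symbol_is_error(self):
        pq = pd.DataFrame({"gene": ["G", ""], "s1": [1.0, 2.0]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="P2"):
            collapse_to_gene(pq, ["s1"])


class TestReplicateCorrelation:
    def design(self):
        return pd.DataFrame(
            {
                "sample_id": ["r1", "r2"],
                "tissue": ["tumor", "tumor"],
                "day": [3, 3],
                "replicate": [1, 2],
            }
        )

    def test_identical_columns_give_rho_one(self):
        m = pd.DataFrame({"r1": [1.0, 5, 3, 2, 4], "r2": [1.0, 5, 3, 2, 4]})
        out = replicate_correlation(m, self.design())
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_decreasing_transform_gives_minus_one(self):
        a = np.array([1.0, 5, 3, 2, 4])
        m = pd.DataFrame({"r1": a, "r2": 1.0 / a})
        out = replicate_correlation(m, self.design())
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_hand_computed_rank_correlation(self):
        # ranks of r1: 1,4,3,2,5; ranks of r2: 2,3,1,4,5 -> rho = 1 - 6*Σd²/(n(n²-1))
        m = pd.DataFrame({"r1": [10.0, 40, 30, 20, 50], "r2": [15.0, 22, 11, 30, 41]})
        d2 = np.array([1, 1, 2, 2, 0]) ** 2
        expected = 1 - 6 * d2.sum() / (5 * 24)
        out = replicate_correlation(m, self.design())
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)
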