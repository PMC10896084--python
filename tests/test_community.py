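import itertools

import numpy as np
import pandas as pd
import pytest

from detritrace import community as cm
from detritrace.taxonomy import RANKS


def make_matrix(data, groups, rank="order", lineage=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    return cm.CommunityMatrix(
        data=df, groups=pd.Series(groups), rank=rank, lineage=lineage
    )


def taxonomy_table(detections):
    """Rows of (sample, order[, phylum]) -> consolidated-style table."""
    rows = []
    for sample, orders in detections.items():
        for o in orders:
            row = {"sample_id": sample, "phylum": f"P_{o[0]}", "class": None,
                   "order": o, "family": None, "genus": None, "species": None}
            rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *RANKS])


class TestFrequencyOfOccurrence:
    def _fixture(self):
        # 11 EAM samples, taxon present in 9
        table = taxonomy_table({f"s{i}": ["Harpacticoida"] for i in range(9)})
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(11)],
            "sample_type": "EAM",
        })
        return table, meta

    def test_nine_of_eleven_rounds_to_82(self):
        table, meta = self._fixture()
        f = cm.frequency_of_occurrence(table, meta, "EAM", "Harpacticoida", "order")
        assert (f.numerator, f.denominator) == (9, 11)
        assert f.percent == pytest.approx(81.818, abs=1e-2)
        assert f.percent_rounded == 82

    def test_absent_and_ubiquitous(self):
        table, meta = self._fixture()
        assert cm.frequency_of_occurrence(table, meta, "EAM", "Nothing").percent == 0.0
        table_all = taxonomy_table({f"s{i}": ["X"] for i in range(11)})
        assert cm.frequency_of_occurrence(table_all, meta, "EAM", "X").percent == 100.0

    def test_unknown_sample_type_rejected(self):
        table, meta = self._fixture()
        with pytest.raises(ValueError):
            cm.frequency_of_occurrence(table, meta, "lava", "X")

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(8)]
        taxa = ["A", "B", "C"]
        det = {s: [t for t in taxa if rng.random() < 0.5] for s in samples}
        table = taxonomy_table(det)
        meta = pd.DataFrame({"sample_id": samples, "sample_type": "EAM"})
        for t in taxa:
            expected = sum(t in det[s] for s in samples)
            f = cm.frequency_of_occurrence(table, meta, "EAM", t, "order")
            assert f.numerator == expected


class TestCollapseToRank:
    def test_two_species_one_order_single_column(self):
        table = pd.DataFrame([
            {"sample_id": "s1", "phylum": "P", "class": "C", "order": "O",
             "family": "F1", "genus": "G1", "species": "sp1"},
            {"sample_id": "s1", "phylum": "P", "class": "C", "order": "O",
             "family": "F2", "genus": "G2", "species": "sp2"},
        ])
        m = cm.collapse_to_rank(table, "order", {"s1": "g"})
        assert list(m.data.columns) == ["O"]
        assert m.data.loc["s1", "O"] == 1

    def test_phylum_only_detection_excluded_at_order(self):
        table = pd.DataFrame([
            {"sample_id": "s1", "phylum": "P", "class": None, "order": None,
             "family": None, "genus": None, "species": None},
        ])
        m = cm.collapse_to_rank(table, "order", {"s1": "g"})
        assert m.data.shape[1] == 0

    def test_matches_hand_collapsed_matrix(self):
        det = {"s1": ["O1", "O2"], "s2": ["O2"], "s3": ["O1", "O3"]}
        m = cm.collapse_to_rank(taxonomy_table(det), "order",
                                {"s1": "a", "s2": "a", "s3": "b"})
        expected = pd.DataFrame(
            [[1, 1, 0], [0, 1, 0], [1, 0, 1]],
            index=["s1", "s2", "s3"], columns=["O1", "O2", "O3"],
        )
        assert m.data.equals(expected)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            cm.collapse_to_rank(taxonomy_table({}), "kingdom", {})


class TestJaccard:
    def test_identical_disjoint_partial(self):
        data = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 1]],
            index=["a", "a2", "b"], columns=list("wxyz"),
        )
        d = cm.jaccard_distance_matrix(data)
        assert d.loc["a", "a2"] == 0.0
        assert d.loc["a", "b"] == 1.0
        # A = {x,y,z}, B = {y,z,w}: 1 - 2/4
        data2 = pd.DataFrame([[0, 1, 1, 1], [1, 0, 1, 1]], index=["A", "B"],
                             columns=list("wxyz"))
        assert cm.jaccard_distance_matrix(data2).loc["A", "B"] == pytest.approx(0.5)

    def test_all_zero_row_names_sample(self):
        data = pd.DataFrame([[1, 0], [0, 0]], index=["ok", "empty"], columns=["t1", "t2"])
        with pytest.raises(ValueError, match="empty"):
            cm.jaccard_distance_matrix(data)


def _random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 2))
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(pts))


class TestPermanova:
    def test_exact_enumeration_agrees_with_monte_carlo(self):
        rng = np.random.default_rng(1)
        d = _random_distance_matrix(rng, 6)
        groups = ["a"] * 3 + ["b"] * 3
        exact = cm.permanova(d, groups, method="exact")
        assert exact.permutations == 720
        mc = cm.permanova(d, groups, permutations=9999, seed=0)
        se = np.sqrt(exact.p * (1 - exact.p) / 9999)
        assert abs(mc.p - exact.p) < max(4 * se, 0.01)
        assert mc.f == pytest.approx(exact.f)

    def test_identical_groups_give_high_p(self):
        base = np.array([[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]])
        d = np.block([[base, base], [base, base]])
        np.fill_diagonal(d, 0)
        groups = ["a"] * 3 + ["b"] * 3
        res = cm.permanova(d, groups, permutations=199, seed=0)
        assert np.isfinite(res.f)
        assert res.p > 0.5

    def test_invariant_under_consistent_relabelling(self):
        rng = np.random.default_rng(2)
        d = _random_distance_matrix(rng, 8)
        groups = np.array(["a", "a", "a", "b", "b", "b", "b", "a"])
        perm = rng.permutation(8)
        r1 = cm.permanova(d, groups, permutations=99, seed=3)
        r2 = cm.permanova(d[np.ix_(perm, perm)], groups[perm], permutations=99, seed=3)
        assert r1.f == pytest.approx(r2.f, rel=1e-12)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(4)
        d = _random_distance_matrix(rng, 10)
        groups = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        ours = cm.permanova(d, groups, permutations=99, seed=0)
        theirs = sk_permanova(DistanceMatrix(d), groups, permutations=99)
        assert ours.f == pytest.approx(float(theirs["test statistic"]), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cm.permanova(np.zeros((3, 3)), ["a", "a", "a"])


class TestPairwisePermanova:
    def _three_groups(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([
            rng.normal(0, 1, (4, 2)),
            rng.normal(3, 1, (4, 2)),
            rng.normal(6, 1, (4, 2)),
        ])
        from scipy.spatial.distance import pdist, squareform
        d = pd.DataFrame(squareform(pdist(pts)))
        groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        return d, groups

    def test_three_groups_give_three_tests(self):
        d, groups = self._three_groups()
        out = cm.pairwise_permanova(d, groups, permutations=99, seed=0)
        assert len(out) == 3
        assert set(zip(out["group_a"], out["group_b"])) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_bonferroni_triples_raw_p(self):
        assert cm.adjust_pvalues([0.008, 0.5, 0.9]) == [0.024, 1.0, 1.0]

    def test_no_adjustment_returns_raw(self):
        d, groups = self._three_groups()
        out = cm.pairwise_permanova(d, groups, permutations=99, adjustment="none", seed=0)
        assert (out["p_adjusted"] == out["p_raw"]).all()


class TestSimper:
    def test_single_differing_taxon_contributes_everything(self):
        data = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [1, 1, 1], [1, 1, 1]],
            index=["a1", "a2", "b1", "b2"], columns=["t1", "t2", "t3"],
        )
        m = make_matrix(data, {"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
        out = cm.simper(m, "a", "b")
        top = out.set_index("taxon")["percent"]
        assert top["t3"] == pytest.approx(100.0)
        assert out["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_pairwise_decomposition_oracle(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.integers(0, 2, (4, 5)),
                            index=["a1", "a2", "b1", "b2"],
                            columns=[f"t{i}" for i in range(5)])
        data.iloc[:, 0] = 1  # no empty samples
        m = make_matrix(data, {"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
        out = cm.simper(m, "a", "b").set_index("taxon")
        # oracle: average the per-taxon Bray-Curtis terms over cross pairs
        expected = np.zeros(5)
        for i in ["a1", "a2"]:
            for j in ["b1", "b2"]:
                x, y = data.loc[i].to_numpy(), data.loc[j].to_numpy()
                expected += np.abs(x - y) / (x + y).sum()
        expected /= 4
        for t, e in zip(data.columns, expected):
            assert out.loc[t, "contribution"] == pytest.approx(e, abs=1e-12)

    def test_invariant_to_taxon_order(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.integers(0, 2, (4, 6)),
                            index=["a1", "a2", "b1", "b2"],
                            columns=[f"t{i}" for i in range(6)])
        data.iloc[:, 0] = 1
        groups = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        out1 = cm.simper(make_matrix(data, groups), "a", "b").set_index("taxon")
        shuffled = data[list(reversed(data.columns))]
        out2 = cm.simper(make_matrix(shuffled, groups), "a", "b").set_index("taxon")
        for t in data.columns:
            assert out1.loc[t, "percent"] == pytest.approx(out2.loc[t, "percent"])

    def test_rollup_to_phylum_sums_members(self):
        data = pd.DataFrame([[1, 0, 1], [0, 1, 1]], index=["a1", "b1"],
                            columns=["O1", "O2", "O3"])
        lineage = pd.DataFrame({"phylum": ["P1", "P1", "P2"]}, index=["O1", "O2", "O3"])
        m = make_matrix(data, {"a1": "a", "b1": "b"}, lineage=lineage)
        out = cm.simper(m, "a", "b", rollup_rank="phylum").set_index("taxon")
        assert out.loc["P1", "percent"] == pytest.approx(100.0)
        assert out["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_empty_group_rejected(self):
        data = pd.DataFrame([[1, 0]], index=["a1"], columns=["t1", "t2"])
        m = make_matrix(data, {"a1": "a"})
        with pytest.raises(ValueError):
            cm.simper(m, "a", "b")


class TestNmds:
    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        res = cm.nmds(d, k=2, restarts=4, seed=0)
        assert res.stress < 0.01

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(9)
        d = _random_distance_matrix(rng, 8)
        r1 = cm.nmds(d, seed=3)
        r2 = cm.nmds(d, seed=3)
        assert np.array_equal(r1.coordinates.to_numpy(), r2.coordinates.to_numpy())

    def test_equidistant_triple_has_zero_stress(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(RuntimeWarning):
            res = cm.nmds(d, k=2)
        assert res.stress == 0.0
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_centered_at_origin(self):
        rng = np.random.default_rng(10)
        d = _random_distance_matrix(rng, 9)
        res = cm.nmds(d, seed=1)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)
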