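"""Occupancy classification, clustering, DE filter and overlap statistics."""

import itertools
import math

import numpy as np
import pytest

from mitobook import bookmark as bk
from mitobook.core import Peak
from mitobook.simulate import DERecord


def mkpeak(contig, start, end, name, fe=5.0):
    return Peak(contig, start, end, (start + end) // 2, 10, 1e-8, fe, name)


class TestReproduciblePeaks:
    def test_supported_in_all_replicates_kept(self):
        pooled = [mkpeak("c", 100, 300, "p1")]
        reps = [[mkpeak("c", 150, 250, "r1")], [mkpeak("c", 290, 400, "r2")]]
        assert bk.reproducible_peaks(pooled, reps) == pooled

    def test_supported_in_one_of_two_dropped(self):
        pooled = [mkpeak("c", 100, 300, "p1")]
        reps = [[mkpeak("c", 150, 250, "r1")], [mkpeak("c", 500, 600, "r2")]]
        assert bk.reproducible_peaks(pooled, reps) == []

    def test_identical_replicates_keep_all_supported(self):
        pooled = [mkpeak("c", 100, 300, "p1"), mkpeak("c", 900, 1100, "p2")]
        reps = [list(pooled), list(pooled)]
        assert bk.reproducible_peaks(pooled, reps) == pooled

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            bk.reproducible_peaks([], [])


class TestOccupancyMatrix:
    def tracks(self, values_by_cond, L=1000):
        return {
            cond: {"c": np.full(L, v, dtype=float)} for cond, v in values_by_cond.items()
        }

    def test_row_unit_max_normalization(self):
        union = [mkpeak("c", 100, 200, "u1")]
        fe = self.tracks({"A": 2.0, "M": 4.0, "G1": 8.0})
        m = bk.occupancy_matrix(union, fe)
        np.testing.assert_allclose(m.values[0], [0.25, 0.5, 1.0])

    def test_all_zero_row_dropped(self):
        union = [mkpeak("c", 100, 200, "u1"), mkpeak("c", 400, 500, "u2")]
        fe = self.tracks({"A": 0.0, "M": 0.0, "G1": 0.0})
        fe["M"]["c"][400:500] = 3.0
        m = bk.occupancy_matrix(union, fe)
        assert m.dropped == ["u1"]
        assert m.peak_ids == ["u2"]

    def test_shape(self):
        union = [mkpeak("c", i * 100, i * 100 + 50, f"u{i}") for i in range(1, 6)]
        m = bk.occupancy_matrix(union, self.tracks({"A": 1.0, "M": 2.0, "G1": 3.0}))
        assert m.values.shape == (5, 3)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="missing FE track"):
            bk.occupancy_matrix([], self.tracks({"A": 1.0, "M": 1.0}))


class TestClusterProfiles:
    def test_recovers_separated_archetypes(self):
        rng = np.random.default_rng(0)
        archetypes = np.array(
            [[1.0, 0.1, 0.1], [0.1, 1.0, 0.1], [0.1, 0.1, 1.0], [1.0, 1.0, 1.0]]
        )
        rows, truth = [], []
        for i, arch in enumerate(archetypes):
            for _ in range(50):
                rows.append(arch + rng.normal(0, 0.01, size=3))
                truth.append(i)
        m = bk.OccupancyMatrix(
            [f"r{i}" for i in range(len(rows))], ("A", "M", "G1"), np.array(rows)
        )
        labels = bk.cluster_profiles(m, k=4, seed=1)
        # every archetype maps to exactly one label and vice versa
        mapping = {}
        for lbl, t in zip(labels, truth):
            mapping.setdefault(t, set()).add(lbl)
        assert all(len(v) == 1 for v in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == 4

    def test_deterministic_and_size_ordered(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(40, 3))
        m = bk.OccupancyMatrix([f"r{i}" for i in range(40)], ("A", "M", "G1"), vals)
        l1 = bk.cluster_profiles(m, k=4, seed=5)
        l2 = bk.cluster_profiles(m, k=4, seed=5)
        assert np.array_equal(l1, l2)
        sizes = [np.sum(l1 == lbl) for lbl in range(1, 5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_rows_rejected(self):
        m = bk.OccupancyMatrix(["a"], ("A", "M", "G1"), np.ones((1, 3)))
        with pytest.raises(ValueError, match="< k"):
            bk.cluster_profiles(m, k=4)


class TestClassifyGenes:
    def test_study_scale_arithmetic(self):
        """|M|=551, |G1|=1095, |M∩G1|=378 imply union 1268 and M-only 173."""
        shared = {f"s{i}" for i in range(378)}
        m = shared | {f"m{i}" for i in range(551 - 378)}
        g1 = shared | {f"g{i}" for i in range(1095 - 378)}
        classes = bk.classify_genes({"A": set(), "M": m, "G1": g1})
        counts = classes.counts()
        assert counts["M"] == 551
        assert counts["G1"] == 1095
        assert counts["shared_M_G1"] == 378
        assert counts["M_union_G1"] == 1268
        assert counts["M_only"] == 173

    def test_small_example(self):
        classes = bk.classify_genes(
            {"A": {"g1", "g2"}, "M": {"g2", "g3"}, "G1": {"g2"}}
        )
        assert classes.a_not_mg1 == {"g1"}
        assert classes.shared == {"g2"}
        assert classes.m_only == {"g3"}
        assert classes.g1_only == set()

    def test_disjoint_sets(self):
        classes = bk.classify_genes({"A": set(), "M": {"a"}, "G1": {"b"}})
        assert classes.shared == set()
        assert classes.counts()["M_union_G1"] == 2

    def test_inclusion_exclusion_random_sets(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(20):
            a = {g for g in universe if rng.random() < 0.4}
            m = {g for g in universe if rng.random() < 0.4}
            g1 = {g for g in universe if rng.random() < 0.4}
            counts = bk.classify_genes({"A": a, "M": m, "G1": g1}).counts()
            assert counts["M_union_G1"] == counts["M"] + counts["G1"] - counts["shared_M_G1"]
            assert counts["M"] == counts["shared_M_G1"] + counts["M_only"]


class TestFilterDe:
    @pytest.mark.parametrize(
        "base_mean,lfc,p,kept",
        [
            (6.0, 1.2, 0.01, True),
            (5.0, 2.0, 0.001, False),  # base_mean strictly > 5
            (100.0, -1.5, 0.05, False),  # p strictly < 0.05
            (100.0, 1.0, 0.01, False),  # |lfc| strictly > 1
            (100.0, -1.01, 0.049, True),
        ],
    )
    def test_strict_boundaries(self, base_mean, lfc, p, kept):
        rec = DERecord("g", base_mean, lfc, p, False)
        assert (bk.filter_de([rec]) == {"g"}) is kept

    def test_null_table_pass_rate_matches_product(self):
        """All-null Monte-Carlo pass-rate equals the product of marginal
        threshold probabilities within 3 binomial sd."""
        from scipy import stats

        rng = np.random.default_rng(13)
        n = 100_000
        recs = [
            DERecord(
                f"g{i}",
                float(bm),
                float(lfc),
                float(p),
                False,
            )
            for i, (bm, lfc, p) in enumerate(
                zip(
                    rng.lognormal(3.0, 1.0, size=n),
                    rng.normal(0.0, 0.2, size=n),
                    rng.uniform(0.0, 1.0, size=n),
                )
            )
        ]
        observed = len(bk.filter_de(recs))
        p_bm = stats.norm.sf((math.log(5.0) - 3.0) / 1.0)
        p_lfc = 2 * stats.norm.sf(1.0 / 0.2)
        expected_rate = p_bm * p_lfc * 0.05
        sd = math.sqrt(n * expected_rate * (1 - expected_rate))
        assert abs(observed - n * expected_rate) <= 3 * sd + 1


class TestOverlapEnrichment:
    def test_exact_small_case(self):
        """universe 10, DE 5, category 4, overlap 4 -> p = C(5,4)/C(10,4)."""
        universe = {f"g{i}" for i in range(10)}
        de = {f"g{i}" for i in range(5)}
        cat = {f"g{i}" for i in range(4)}
        rows = bk.overlap_enrichment({"c": cat}, de, universe)
        assert rows["c"]["overlap"] == 4
        assert rows["c"]["pvalue"] == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_empty_de(self):
        universe = {f"g{i}" for i in range(10)}
        rows = bk.overlap_enrichment({"c": {"g1", "g2"}}, set(), universe)
        assert rows["c"]["pvalue"] == 1.0

    def test_matches_exhaustive_enumeration(self):
        """Brute-force oracle over subsets for all universe sizes <= 12."""
        rng = np.random.default_rng(4)
        for N in range(2, 13):
            universe = list(range(N))
            K = int(rng.integers(0, N + 1))
            n_cat = int(rng.integers(0, N + 1))
            de = set(rng.choice(universe, size=K, replace=False).tolist())
            cat = set(rng.choice(universe, size=n_cat, replace=False).tolist())
            obs = len(de & cat)
            # oracle: enumerate all n_cat-subsets, count those with >= obs hits
            hits = total = 0
            for subset in itertools.combinations(universe, n_cat):
                total += 1
                hits += len(de & set(subset)) >= obs
            expected = hits / total if obs > 0 else 1.0
            got = bk.hypergeom_overlap_pvalue(obs, N, K, n_cat)
            assert got == pytest.approx(expected, abs=1e-12), (N, K, n_cat, obs)

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            bk.overlap_enrichment({"c": {"x"}}, set(), {"g1"})

    def test_bh_adjustment_monotone(self):
        universe = {f"g{i}" for i in range(40)}
        de = {f"g{i}" for i in range(10)}
        cats = {
            "strong": {f"g{i}" for i in range(8)},
            "weak": {f"g{i}" for i in range(30, 38)},
        }
        rows = bk.overlap_enrichment(cats, de, universe)
        assert rows["strong"]["padj"] <= rows["weak"]["padj"]
        for r in rows.values():
            assert r["padj"] >= r["pvalue"]
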