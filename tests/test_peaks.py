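"""Poisson local-lambda peak caller: pileup, background model, significance."""

import math

import numpy as np
import pytest
from scipy import stats

from mitobook import peaks as pk
from mitobook import simulate as sim
from mitobook.core import Tag


class TestPileup:
    def test_plus_tag_extension(self):
        cov = pk.pileup([Tag("c", 100, "+")], 180, {"c": 1000})["c"]
        assert cov[100] == 1 and cov[279] == 1
        assert cov[99] == 0 and cov[280] == 0
        assert cov.sum() == 180

    def test_minus_tag_mirror(self):
        cov = pk.pileup([Tag("c", 279, "-")], 180, {"c": 1000})["c"]
        assert cov[100] == 1 and cov[279] == 1
        assert cov[99] == 0 and cov[280] == 0

    def test_mass_conservation_without_clipping(self):
        rng = np.random.default_rng(1)
        tags = [
            Tag("c", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(300, 700, size=200)
        ]
        cov = pk.pileup(tags, 180, {"c": 2000})["c"]
        assert cov.sum() == 200 * 180

    def test_edge_clipping(self):
        cov = pk.pileup([Tag("c", 5, "-")], 180, {"c": 1000})["c"]
        assert cov.sum() == 6  # [0, 6)

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            pk.pileup([Tag("x", 0, "+")], 180, {"c": 100})


class TestLambdaTrack:
    def test_no_control_lambda_constant(self):
        tags = [Tag("c", int(p), "+") for p in range(0, 5000, 10)]
        lam = pk.lambda_track(
            tags, pk.PeakCallParams(), {"c": 10_000}, is_control=False
        )["c"]
        assert np.all(lam == lam[0])
        assert lam[0] == pytest.approx(np.sum(pk.pileup(tags, 180, {"c": 10_000})["c"]) / 10_000)

    def test_uniform_control_near_genome_rate(self):
        rng = np.random.default_rng(2)
        tags = [
            Tag("c", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(0, 100_000, size=2000)
        ]
        lam = pk.lambda_track(tags, pk.PeakCallParams(), {"c": 100_000})["c"]
        genome_rate = 2000 * 180 / 100_000
        interior = lam[20_000:80_000]
        assert np.all(np.abs(interior - genome_rate) / genome_rate < 0.6)
        assert np.median(np.abs(interior - genome_rate)) / genome_rate < 0.1

    def test_control_cluster_elevates_locally_only(self):
        cluster = [Tag("c", 50_000 + i % 50, "+") for i in range(500)]
        sparse = [Tag("c", int(p), "+") for p in range(0, 100_000, 500)]
        lam = pk.lambda_track(cluster + sparse, pk.PeakCallParams(), {"c": 100_000})["c"]
        baseline = lam[10_000]
        assert lam[50_025] > 10 * baseline
        # > 10 kb away the largest window no longer sees the cluster
        assert lam[75_000] == pytest.approx(baseline, rel=0.5)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="lambda is 0"):
            pk.lambda_track([], pk.PeakCallParams(), {"c": 1000})


class TestPoissonSf:
    def test_count_zero_is_exactly_one(self):
        assert pk.poisson_sf(0, 0.123) == 1.0
        assert pk.poisson_sf(0, 17.0) == 1.0

    def test_closed_form_count5_lam1(self):
        # 1 - sum_{k=0..4} e^{-1}/k!  (independent closed-form oracle)
        expected = 1.0 - math.exp(-1) * sum(1 / math.factorial(k) for k in range(5))
        assert pk.poisson_sf(5, 1.0) == pytest.approx(expected, abs=1e-10)

    def test_monotone_nonincreasing_in_count(self):
        vals = [pk.poisson_sf(c, 3.7) for c in range(15)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            pk.poisson_sf(-1, 1.0)
        with pytest.raises(ValueError):
            pk.poisson_sf(1, -0.5)


class TestCallPeaks:
    def toy_site_tags(self, seed=3, reads=200, bg_rate=0.0005, L=200_000):
        p = sim.SimParams(
            n_contigs=1,
            contig_length=L,
            n_genes=4,
            n_true_sites=1,
            bookmark_fraction=1.0,
            n_artifacts=0,
            reads_per_site=reads,
            background_rate=bg_rate,
            seed=seed,
        )
        genome = sim.make_genome(p)
        genes = sim.make_genes(genome, p)
        truth = sim.plant_sites(genes, p, genome.lengths())
        tags = sim.simulate_tags(truth, p, "M", genome.lengths())
        return tags, truth[0].center, genome.lengths()

    def test_single_planted_site_single_peak(self):
        tags, center, lengths = self.toy_site_tags()
        peaks, _ = pk.call_peaks(tags, pk.PeakCallParams(), lengths)
        assert len(peaks) == 1
        assert peaks[0].start <= center < peaks[0].end
        assert peaks[0].min_pvalue <= 1e-5

    def test_pure_background_rarely_yields_peaks(self):
        """Background-only genomes produce no peak in >= 95% of seeds."""
        n_with_peaks = 0
        params = pk.PeakCallParams()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            L = 1_000_000
            n = rng.poisson(0.0005 * L * 2)
            tags = sorted(
                (
                    Tag("c", int(p), "+" if rng.random() < 0.5 else "-")
                    for p in rng.integers(0, L, size=n)
                ),
                key=lambda t: t.pos,
            )
            peaks, _ = pk.call_peaks(tags, params, {"c": L})
            n_with_peaks += bool(peaks)
        assert n_with_peaks <= 1

    def test_candidate_bases_match_brute_force_oracle(self):
        """On a 2 kb toy contig the caller's significant bases equal direct
        per-base Poisson tail evaluation."""
        rng = np.random.default_rng(7)
        tags = [
            Tag("c", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(0, 2000, size=120)
        ]
        tags += [Tag("c", 900, "+")] * 25  # a dense spot
        params = pk.PeakCallParams(min_peak_length=1, merge_gap=0)
        lengths = {"c": 2000}
        pile = pk.pileup(tags, params.fragment_size, lengths)["c"]
        lam_genome = pile.sum() / 2000
        # brute force: independent per-base evaluation via the closed form
        brute = set()
        for x in range(2000):
            c = int(pile[x])
            tail = 1.0 - sum(
                math.exp(-lam_genome) * lam_genome**k / math.factorial(k)
                for k in range(c)
            )
            if tail <= params.p_threshold:
                brute.add(x)
        peaks, _ = pk.call_peaks(tags, params, lengths)
        called = set()
        for peak in peaks:
            called.update(range(peak.start, peak.end))
        assert called == brute

    def test_fe_is_one_where_pileup_equals_lambda(self):
        tags, _, lengths = self.toy_site_tags()
        params = pk.PeakCallParams()
        _, fe = pk.call_peaks(tags, params, lengths)
        pile = pk.pileup(tags, params.fragment_size, lengths)
        lam = pk.lambda_track(tags, params, lengths, is_control=False)
        for c in lengths:
            match = np.isclose(pile[c], lam[c])
            assert np.allclose(fe[c][match], 1.0)

    def test_threshold_monotonicity(self):
        tags, _, lengths = self.toy_site_tags(seed=4)

        def candidate_count(p_threshold):
            params = pk.PeakCallParams(p_threshold=p_threshold)
            pile = pk.pileup(tags, params.fragment_size, lengths)
            lam = pk.lambda_track(tags, params, lengths, is_control=False)
            return sum(
                int(np.sum(stats.poisson.sf(pile[c] - 1, lam[c]) <= p_threshold))
                for c in lengths
            )

        counts = [candidate_count(p) for p in (1e-7, 1e-5, 1e-3)]
        assert counts == sorted(counts)

    def test_peaks_disjoint_sorted_in_bounds(self, default_experiment):
        lengths = default_experiment.genome.lengths()
        tags = default_experiment.pooled_tags("A")
        peaks, _ = pk.call_peaks(tags, pk.PeakCallParams(), lengths)
        assert len(peaks) > 5
        by_contig: dict[str, list] = {}
        for peak in peaks:
            assert 0 <= peak.start < peak.end <= lengths[peak.contig]
            by_contig.setdefault(peak.contig, []).append(peak)
        for plist in by_contig.values():
            for a, b in zip(plist, plist[1:]):
                assert a.end <= b.start

    def test_empty_tags_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pk.call_peaks([], pk.PeakCallParams(), {"c": 100})
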