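"""Planted-truth recovery experiments on synthetic data.

These drive the package's self-validation: simulate experiments with known
truth, run the pipeline stages, and measure how well the planted structure
is recovered — retention of true-site peaks and rejection of phantom stacks
by the cross-correlation filter, and precision/recall of the bookmarked
(M ∩ G1) gene set end to end.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from mitobook import peaks as pk
from mitobook import pipeline as pl
from mitobook import simulate as sim
from mitobook import xcor as xc


def _peak_kind(peak, truth) -> str:
    for s in truth:
        if s.interval.contig == peak.contig and peak.start <= s.center < peak.end:
            return s.kind
    return "background"


def filter_discrimination(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_true_sites: int = 20,
    n_artifacts: int = 10,
    reads_per_site: float = 300.0,
    background_rate: float = 5e-4,
) -> dict:
    """Retention of true-site peaks and rejection of phantom stacks.

    Simulates ``n_seeds`` independent experiments in which every planted
    site is occupied, calls peaks on the mitotic sample, applies the
    cross-correlation filter at the default thresholds, and pools the
    outcomes over all seeds.
    """
    true_total = true_kept = ph_total = ph_rejected = 0
    for i in range(n_seeds):
        params = sim.SimParams(
            n_true_sites=n_true_sites,
            n_artifacts=n_artifacts,
            bookmark_fraction=1.0,
            reads_per_site=reads_per_site,
            background_rate=background_rate,
            n_replicates=1,
            seed=(base_seed * 1000 + i) % (2**31),
        )
        genome = sim.make_genome(params)
        genes = sim.make_genes(genome, params)
        truth = sim.plant_sites(genes, params, genome.lengths())
        tags = sim.simulate_tags(truth, params, "M", genome.lengths())
        peaks, _ = pk.call_peaks(tags, pk.PeakCallParams(), genome.lengths())
        _, results = xc.filter_peaks(peaks, tags, xc.XcorParams(), genome.lengths())
        for peak, res in zip(peaks, results):
            kind = _peak_kind(peak, truth)
            if kind == "true_site":
                true_total += 1
                true_kept += res.passed
            elif kind == "phantom_artifact":
                ph_total += 1
                ph_rejected += not res.passed
    return {
        "true_total": true_total,
        "true_retention": true_kept / true_total if true_total else float("nan"),
        "phantom_total": ph_total,
        "phantom_rejection": ph_rejected / ph_total if ph_total else float("nan"),
    }


def bookmark_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    params: sim.SimParams | None = None,
) -> dict:
    """End-to-end recovery of the planted bookmarked (M ∩ G1) gene set.

    Runs the full analysis per seed and compares the reported shared
    category against the genes whose planted sites are occupied in both M
    and G1. Precision and recall are pooled over seeds; per-seed shared
    counts are returned for interval checks.
    """
    params = params or sim.SimParams()
    shared_counts: list[int] = []
    tp = fp = fn = 0
    for i in range(n_seeds):
        p = replace(params, seed=(base_seed * 1000 + i) % (2**31))
        exp = sim.simulate_experiment(p)
        analysis = pl.analyze_experiment(
            exp.tags, exp.genes, exp.genome.lengths(), cluster_seed=p.seed
        )
        predicted = analysis.classes.shared
        planted = exp.bookmarked_genes
        shared_counts.append(len(predicted))
        tp += len(predicted & planted)
        fp += len(predicted - planted)
        fn += len(planted - predicted)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return {
        "shared_counts": shared_counts,
        "mean_shared": float(np.mean(shared_counts)),
        "precision": precision,
        "recall": recall,
        "planted_per_seed": round(params.bookmark_fraction * params.n_true_sites),
    }


def binomial_bounds(n: int, p: float, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation 95% bounds for a Binomial(n, p) count."""
    mu = n * p
    sd = np.sqrt(n * p * (1 - p))
    return mu - z * sd, mu + z * sd
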