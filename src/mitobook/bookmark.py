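"""Occupancy classification across A/M/G1, profile clustering and DE overlap.

A gene is "bookmarked" when it retains a called, artifact-filtered peak in
the mitotic (M) sample. Set algebra over the per-condition bound-gene sets
yields the occupancy categories:

    shared (M and G1)   M ∩ G1      — bookmarked through mitosis into G1
    M-only              M \\ G1
    G1-only             G1 \\ M
    A-not-MG1           A \\ (M ∪ G1)

The union enrichment matrix (fold enrichment at each union-peak summit in
each condition's FE track, rows scaled to unit maximum) is clustered with
k-means (k = 4, k-means++ init, best of 10 restarts).

Differential-expression significance uses strict thresholds: base mean > 5,
|log2 fold change| > 1, p < 0.05. Category-vs-DE overlaps are scored with a
hypergeometric upper tail and Benjamini-Hochberg adjustment across
categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from mitobook.core import Interval, Peak
from mitobook.refbuild import merge_intervals

CONDITIONS = ("A", "M", "G1")


# ---------------------------------------------------------------------------
# Replicate reproducibility (simplified stand-in for ranked-list consistency)


def reproducible_peaks(
    pooled_peaks: list[Peak], replicate_peaksets: list[list[Peak]]
) -> list[Peak]:
    """Keep pooled peaks that overlap (>= 1 bp) a peak in EVERY replicate."""
    if not replicate_peaksets:
        raise ValueError("at least one replicate peak set required")
    rep_intervals = [
        sorted((p.interval for p in reps), key=lambda iv: (iv.contig, iv.start))
        for reps in replicate_peaksets
    ]
    kept = []
    for pk in pooled_peaks:
        iv = pk.interval
        if all(any(iv.overlaps(r) for r in reps) for reps in rep_intervals):
            kept.append(pk)
    return kept


# ---------------------------------------------------------------------------
# Union enrichment matrix and clustering


@dataclass
class OccupancyMatrix:
    peak_ids: list[str]
    conditions: tuple[str, ...]
    values: np.ndarray  # (n_peaks, n_conditions)
    row_normalized: bool = False
    dropped: list[str] = field(default_factory=list)


def union_peaks(peaksets: list[list[Peak]]) -> list[Peak]:
    """Merge kept peaks from all conditions into disjoint union peaks.

    The summit of a union peak is the summit of the constituent peak with
    the highest fold enrichment (ties: leftmost summit).
    """
    all_peaks = [p for ps in peaksets for p in ps]
    merged = merge_intervals([p.interval for p in all_peaks])
    out = []
    for i, iv in enumerate(merged):
        members = [p for p in all_peaks if p.interval.overlaps(iv)]
        best = max(members, key=lambda p: (p.fold_enrichment, -p.summit))
        out.append(
            Peak(
                contig=iv.contig,
                start=iv.start,
                end=iv.end,
                summit=best.summit,
                max_pileup=max(p.max_pileup for p in members),
                min_pvalue=min(p.min_pvalue for p in members),
                fold_enrichment=best.fold_enrichment,
                name=f"union_{i + 1}",
            )
        )
    return out


def occupancy_matrix(
    union: list[Peak],
    fe_tracks: dict[str, dict[str, np.ndarray]],
    conditions: tuple[str, ...] = CONDITIONS,
    normalize: bool = True,
) -> OccupancyMatrix:
    """FE at each union-peak summit per condition; rows scaled to unit max.

    All-zero rows cannot be normalized and are dropped (recorded in
    ``dropped``).
    """
    for cond in conditions:
        if cond not in fe_tracks:
            raise ValueError(f"missing FE track for condition {cond!r}")
    rows, ids, dropped = [], [], []
    for pk in union:
        row = np.array(
            [fe_tracks[c][pk.contig][pk.summit] for c in conditions], dtype=float
        )
        if normalize:
            m = row.max()
            if m == 0.0:
                dropped.append(pk.name)
                continue
            row = row / m
        ids.append(pk.name)
        rows.append(row)
    values = np.array(rows) if rows else np.empty((0, len(conditions)))
    return OccupancyMatrix(ids, tuple(conditions), values, normalize, dropped)


def cluster_profiles(
    matrix: OccupancyMatrix,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """k-means labels for the enrichment profiles, 1..k.

    Uses k-means++ initialization with the best of ``n_init`` restarts by
    within-cluster sum of squares; labels are renumbered by descending
    cluster size (ties by original label) so label 1 is the largest cluster.
    """
    n = matrix.values.shape[0]
    if n < k:
        raise ValueError(f"{n} profiles < k={k} clusters")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    raw = km.fit_predict(matrix.values)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]


# ---------------------------------------------------------------------------
# Occupancy set algebra


@dataclass
class OccupancyClasses:
    shared: set[str]  # M ∩ G1 — bookmarked into G1
    m_only: set[str]
    g1_only: set[str]
    a_not_mg1: set[str]

    def counts(self) -> dict[str, int]:
        return {
            "M": len(self.shared | self.m_only),
            "G1": len(self.shared | self.g1_only),
            "shared_M_G1": len(self.shared),
            "M_only": len(self.m_only),
            "G1_only": len(self.g1_only),
            "A_not_MG1": len(self.a_not_mg1),
            "M_union_G1": len(self.shared | self.m_only | self.g1_only),
        }


def classify_genes(bound_sets: dict[str, set[str]]) -> OccupancyClasses:
    """Set algebra over the A/M/G1 bound-gene sets.

    The reported union satisfies |M ∪ G1| = |M| + |G1| − |M ∩ G1|.
    """
    a = set(bound_sets.get("A", set()))
    m = set(bound_sets.get("M", set()))
    g1 = set(bound_sets.get("G1", set()))
    return OccupancyClasses(
        shared=m & g1,
        m_only=m - g1,
        g1_only=g1 - m,
        a_not_mg1=a - (m | g1),
    )


# ---------------------------------------------------------------------------
# Differential-expression filter and overlap enrichment


@dataclass(frozen=True)
class DEFilterParams:
    min_base_mean: float = 5.0  # strict >
    min_abs_lfc: float = 1.0  # strict >
    max_pvalue: float = 0.05  # strict <


def filter_de(records, params: DEFilterParams = DEFilterParams()) -> set[str]:
    """Significant genes under the strict base-mean/|lfc|/p thresholds.

    ``records`` is an iterable of objects with ``gene_id``, ``base_mean``,
    ``log2fc`` and ``pvalue`` attributes (e.g. :class:`simulate.DERecord`).
    """
    out = set()
    for r in records:
        if (
            r.base_mean > params.min_base_mean
            and abs(r.log2fc) > params.min_abs_lfc
            and r.pvalue < params.max_pvalue
        ):
            out.add(r.gene_id)
    return out


def hypergeom_overlap_pvalue(
    overlap: int, universe_size: int, de_size: int, category_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(N, K, n)."""
    if overlap == 0:
        return 1.0
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, de_size, category_size)
    )


def overlap_enrichment(
    category_sets: dict[str, set[str]],
    de_set: set[str],
    universe: set[str],
) -> dict[str, dict]:
    """Overlap counts and hypergeometric p per category, BH-adjusted.

    Every category set and the DE set must be subsets of the universe.
    """
    if not de_set <= universe:
        raise ValueError("DE set is not a subset of the universe")
    names, pvals, rows = [], [], {}
    for name, cat in category_sets.items():
        if not cat <= universe:
            raise ValueError(f"category {name!r} is not a subset of the universe")
        ov = len(cat & de_set)
        p = hypergeom_overlap_pvalue(ov, len(universe), len(de_set), len(cat))
        names.append(name)
        pvals.append(p)
        rows[name] = {"overlap": ov, "category_size": len(cat), "pvalue": p}
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for name, q in zip(names, adj):
            rows[name]["padj"] = float(q)
    return rows
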