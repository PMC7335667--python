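"""Minimal single-sample peak caller with a Poisson local-lambda background.

Model: each stranded 5' tag is extended to the mean fragment size (a '+' tag
at p covers [p, p+f); a '-' tag at p covers [p-f+1, p+1)), giving a per-base
pileup. The expected background coverage at base x is

    lambda(x) = max(lambda_genome, lambda_1k(x), lambda_5k(x), lambda_10k(x))

where lambda_w is the pileup of the background source averaged over a window
of w bases centred on x and lambda_genome is total mass over genome length.
With a control sample the windowed terms are computed on the control pileup;
without one, the background is the treatment's genome-wide rate alone (the
local windows would simply reproduce the peak itself).

A base is a candidate when the Poisson upper tail P(X >= pileup) at
lambda(x) falls at or below the p-value threshold (default 1e-5). Candidate
bases merge across gaps up to ``merge_gap``; regions shorter than
``min_peak_length`` are dropped. Duplicate reads are deliberately kept:
single-position read stacks must survive calling so that the downstream
strand cross-correlation filter can catch them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mitobook.core import Peak, Tag


@dataclass(frozen=True)
class PeakCallParams:
    p_threshold: float = 1e-5
    fragment_size: int = 180
    read_length: int = 85
    local_windows: tuple[int, ...] = (1000, 5000, 10000)
    min_peak_length: int | None = None  # defaults to fragment_size
    merge_gap: int | None = None  # defaults to read_length
    fe_pseudocount: float = 1.0

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if any(w <= 0 for w in self.local_windows):
            raise ValueError("local windows must be positive")

    @property
    def effective_min_length(self) -> int:
        return self.min_peak_length if self.min_peak_length is not None else self.fragment_size

    @property
    def effective_merge_gap(self) -> int:
        return self.merge_gap if self.merge_gap is not None else self.read_length


def pileup(
    tags: list[Tag], fragment_size: int, contig_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Fragment-extension coverage per contig, clipped at contig edges."""
    delta = {c: np.zeros(n + 1, dtype=np.int64) for c, n in contig_lengths.items()}
    for t in tags:
        if t.contig not in delta:
            raise ValueError(f"tag on unknown contig {t.contig!r}")
        n = contig_lengths[t.contig]
        if t.strand == "+":
            s, e = t.pos, t.pos + fragment_size
        else:
            s, e = t.pos - fragment_size + 1, t.pos + 1
        s, e = max(0, s), min(n, e)
        if s < e:
            delta[t.contig][s] += 1
            delta[t.contig][e] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in delta.items()}


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean of ``values`` over a window centred on each base, edge-clipped."""
    n = len(values)
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    centers = np.arange(n)
    lo = np.clip(centers - window // 2, 0, n)
    hi = np.clip(lo + window, 0, n)
    lo = np.minimum(lo, hi)
    width = np.maximum(hi - lo, 1)
    return (csum[hi] - csum[lo]) / width


def lambda_track(
    tags: list[Tag],
    params: PeakCallParams,
    contig_lengths: dict[str, int],
    is_control: bool = True,
) -> dict[str, np.ndarray]:
    """Expected background coverage per base.

    ``tags`` is the background source. When it is the treatment itself
    (``is_control=False``) only the genome-wide rate is used.
    """
    pile = pileup(tags, params.fragment_size, contig_lengths)
    genome_len = sum(contig_lengths.values())
    total_mass = float(sum(p.sum() for p in pile.values()))
    lam_genome = total_mass / genome_len
    if lam_genome == 0.0:
        raise ValueError("empty background tag set: genome-wide lambda is 0")
    out: dict[str, np.ndarray] = {}
    for contig, n in contig_lengths.items():
        lam = np.full(n, lam_genome)
        if is_control:
            for w in params.local_windows:
                np.maximum(lam, _windowed_mean(pile[contig], w), out=lam)
        out[contig] = lam
    return out


def poisson_sf(count, lam):
    """Upper tail P(X >= count) for X ~ Poisson(lam); exact 1.0 at count 0.

    Accepts scalars or arrays.
    """
    count_arr = np.asarray(count)
    lam_arr = np.asarray(lam)
    if np.any(count_arr < 0) or np.any(lam_arr < 0):
        raise ValueError("count and lam must be non-negative")
    result = stats.poisson.sf(count_arr - 1, lam_arr)
    if np.ndim(count) == 0 and np.ndim(lam) == 0:
        return float(result)
    return result


def _candidate_runs(candidates: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Merge True-runs of a boolean mask across gaps <= merge_gap."""
    idx = np.nonzero(candidates)[0]
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > merge_gap + 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def call_peaks(
    tags: list[Tag],
    params: PeakCallParams,
    contig_lengths: dict[str, int],
    control: list[Tag] | None = None,
) -> tuple[list[Peak], dict[str, np.ndarray]]:
    """Call peaks and build the fold-enrichment track.

    Returns ``(peaks, fe_track)`` where ``fe_track`` maps each contig to the
    per-base ratio (pileup + pc) / (lambda + pc).
    """
    if not tags:
        raise ValueError("empty tag set")
    pile = pileup(tags, params.fragment_size, contig_lengths)
    if control is not None:
        lam = lambda_track(control, params, contig_lengths, is_control=True)
    else:
        lam = lambda_track(tags, params, contig_lengths, is_control=False)
    peaks: list[Peak] = []
    fe_track: dict[str, np.ndarray] = {}
    pc = params.fe_pseudocount
    for contig in contig_lengths:
        p_arr = pile[contig]
        l_arr = lam[contig]
        fe_track[contig] = (p_arr + pc) / (l_arr + pc)
        pvals = stats.poisson.sf(p_arr - 1, l_arr)
        runs = _candidate_runs(pvals <= params.p_threshold, params.effective_merge_gap)
        for s, e in runs:
            if e - s < params.effective_min_length:
                continue
            local = p_arr[s:e]
            summit = s + int(np.argmax(local))  # argmax ties break leftmost
            peaks.append(
                Peak(
                    contig=contig,
                    start=s,
                    end=e,
                    summit=summit,
                    max_pileup=int(p_arr[summit]),
                    min_pvalue=float(pvals[s:e].min()),
                    fold_enrichment=float(fe_track[contig][summit]),
                )
            )
    for i, pk in enumerate(peaks):
        pk.name = f"peak_{i + 1}"
    return peaks, fe_track
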