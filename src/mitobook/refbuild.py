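"""rDNA-aware reference construction.

The human ribosomal repeat unit (the U13369 45S region) is only partially and
redundantly represented in standard assemblies, which scatters rDNA-derived
reads across fragmentary loci. The remedy implemented here: tile short
in-silico reads across the full repeat unit, find every exact match of each
read (or its reverse complement) in the assembly, hard-mask those positions
with 'N', and append the complete unit as a distinct contig so that all rDNA
reads align there and only there.

Exact substring search on both strands stands in for aligning the error-free
in-silico reads: with no sequencing errors, mismatch-tolerant alignment
reduces to exact matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mitobook.core import GenomeSequence, Interval, revcomp

DEFAULT_RDNA_CONTIG = "chrU13369.1"


@dataclass(frozen=True)
class TileParams:
    """Tiling of in-silico reads across the repeat unit."""

    read_length: int = 50
    step: int = 1

    def __post_init__(self):
        if self.read_length < 1 or self.step < 1:
            raise ValueError("read_length and step must be >= 1")


@dataclass
class MaskResult:
    masked_genome: GenomeSequence
    mask_intervals: list[Interval] = field(default_factory=list)
    appended_contig_name: str = DEFAULT_RDNA_CONTIG


def tile_reads(unit_seq: str, params: TileParams = TileParams()) -> list[str]:
    """All windows of ``read_length`` at ``step`` spacing across the unit.

    Returns floor((L - read_length)/step) + 1 reads, in order.
    """
    unit_seq = unit_seq.upper()
    L, k = len(unit_seq), params.read_length
    if L < k:
        raise ValueError(f"unit length {L} shorter than read length {k}")
    return [unit_seq[i : i + k] for i in range(0, L - k + 1, params.step)]


def locate_matches(reads: list[str], genome: GenomeSequence) -> list[Interval]:
    """Every exact occurrence of each read or its reverse complement.

    Intervals are reported on the forward coordinate system; duplicates and
    overlaps are allowed (merge afterwards). Matches containing 'N' never
    occur because reads are drawn from the unmasked unit, and 'N' in the
    genome cannot equal any ACGT read base.
    """
    if not reads:
        return []
    k = len(reads[0])
    if any(len(r) != k for r in reads):
        raise ValueError("all reads must have equal length")
    # Dedupe queries: a read and its reverse complement hit the same loci set.
    queries = set()
    for r in reads:
        r = r.upper()
        queries.add(r)
        queries.add(revcomp(r))
    hits: list[Interval] = []
    for name, seq in genome.contigs.items():
        for q in queries:
            start = seq.find(q)
            while start != -1:
                hits.append(Interval(name, start, start + k))
                start = seq.find(q, start + 1)
    return hits


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching intervals per contig."""
    if not intervals:
        return []
    merged: list[Interval] = []
    for iv in sorted(intervals, key=lambda i: (i.contig, i.start, i.end)):
        if (
            merged
            and merged[-1].contig == iv.contig
            and iv.start <= merged[-1].end  # touching merges too
        ):
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.contig, merged[-1].start, iv.end)
        else:
            merged.append(Interval(iv.contig, iv.start, iv.end))
    return merged


def hard_mask(genome: GenomeSequence, intervals: list[Interval]) -> GenomeSequence:
    """Replace the bases under ``intervals`` with 'N'; lengths unchanged."""
    seqs = dict(genome.contigs)
    for iv in intervals:
        if iv.contig not in seqs:
            raise ValueError(f"mask interval on unknown contig {iv.contig!r}")
        seq = seqs[iv.contig]
        if iv.end > len(seq):
            raise ValueError(
                f"mask interval [{iv.start}, {iv.end}) exceeds {iv.contig!r} "
                f"length {len(seq)}"
            )
        seqs[iv.contig] = seq[: iv.start] + "N" * iv.width + seq[iv.end :]
    return GenomeSequence(seqs)


def build_rdna_reference(
    genome: GenomeSequence,
    unit_seq: str,
    params: TileParams = TileParams(),
    contig_name: str = DEFAULT_RDNA_CONTIG,
) -> MaskResult:
    """Tile -> locate -> merge -> hard-mask -> append the unit as a contig.

    The appended contig sequence is byte-identical to ``unit_seq``
    (upper-cased); every original contig keeps its length.
    """
    if contig_name in genome:
        raise ValueError(f"contig name {contig_name!r} already present in genome")
    reads = tile_reads(unit_seq, params)
    mask = merge_intervals(locate_matches(reads, genome))
    masked = hard_mask(genome, mask)
    seqs = dict(masked.contigs)
    seqs[contig_name] = unit_seq.upper()
    return MaskResult(
        masked_genome=GenomeSequence(seqs),
        mask_intervals=mask,
        appended_contig_name=contig_name,
    )
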