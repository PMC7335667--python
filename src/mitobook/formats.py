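"""Readers and writers for the file formats the pipeline touches.

Supported formats: FASTA, Gencode-dialect GTF, BED6, narrowPeak (BED6+4),
bedGraph, and a BED-like stranded tag TSV (contig, pos, strand).

Coordinate conventions are strict: all in-memory coordinates are 0-based
half-open; GTF is 1-based inclusive, so conversion adds/subtracts exactly 1
on the start coordinate at the file boundary and nowhere else.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
from Bio import SeqIO

from mitobook.core import GenomeSequence, GeneModel, Interval, Peak, Tag

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are upper-cased; duplicate headers, empty files and non-ACGTN
    characters are rejected.
    """
    genome = GenomeSequence({})
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        genome._add(record.id, str(record.seq))
        n += 1
    if n == 0:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: GenomeSequence, path, line_width: int = 60) -> None:
    """Write a genome as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Tag TSV: contig <TAB> pos <TAB> strand, '#' comments skipped


def read_tags(path) -> list[Tag]:
    """Read a stranded tag TSV; output is sorted by (contig, pos)."""
    tags: list[Tag] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            contig, pos_s, strand = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer position {pos_s!r}") from e
            try:
                tags.append(Tag(contig, pos, strand))
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: {e}") from e
    tags.sort(key=lambda t: (t.contig, t.pos, t.strand))
    return tags


def write_tags(tags: list[Tag], path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tags, key=lambda t: (t.contig, t.pos, t.strand)):
            fh.write(f"{t.contig}\t{t.pos}\t{t.strand}\n")


# ---------------------------------------------------------------------------
# GTF (Gencode dialect)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, path, ln: int) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    stripped = attr_field.strip()
    if not stripped:
        raise ValueError(f"{path}:{ln}: empty attribute field")
    matched = _ATTR_RE.findall(stripped)
    if not matched:
        raise ValueError(f"{path}:{ln}: malformed attributes {attr_field!r}")
    for key, value in matched:
        attrs.setdefault(key, []).append(value)
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Parse a Gencode-style GTF into gene models.

    Only ``gene`` and ``exon`` features are consumed; exons are restricted to
    those carrying the ``basic`` tag. Coordinates convert from 1-based
    inclusive to 0-based half-open. The TSS is derived from the basic exons
    (first exon start on '+', last exon end-1 on '-').
    """
    order: list[str] = []
    meta: dict[str, dict] = {}
    exons: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GTF fields")
            contig, _, feature, start_s, end_s, _, strand, _, attr_field = fields
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"{path}:{ln}: end {end1} < start {start1}")
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            attrs = _parse_attributes(attr_field, path, ln)
            if "gene_id" not in attrs:
                raise ValueError(f"{path}:{ln}: missing gene_id attribute")
            gid = attrs["gene_id"][0]
            if feature == "gene":
                if gid in meta:
                    raise ValueError(f"{path}:{ln}: duplicate gene {gid!r}")
                order.append(gid)
                meta[gid] = {
                    "gene_name": attrs.get("gene_name", [gid])[0],
                    "biotype": attrs.get("gene_type", ["other"])[0],
                    "contig": contig,
                    "strand": strand,
                }
            elif feature == "exon":
                if "basic" not in attrs.get("tag", []):
                    continue
                exons.setdefault(gid, []).append(Interval(contig, start, end, strand))
    genes: list[GeneModel] = []
    for gid in order:
        m = meta[gid]
        ex = sorted(exons.get(gid, []), key=lambda e: e.start)
        if not ex:
            raise ValueError(f"gene {gid!r} has no basic-tag exons")
        tss = ex[0].start if m["strand"] == "+" else ex[-1].end - 1
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=m["gene_name"],
                biotype=m["biotype"],
                contig=m["contig"],
                strand=m["strand"],
                tss=tss,
                exons=ex,
            )
        )
    return genes


def write_gtf(genes: list[GeneModel], path, source: str = "mitobook") -> None:
    """Write gene models as Gencode-dialect GTF (gene + basic-tag exon rows)."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span()
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_type "{g.biotype}";'
            )
            fh.write(
                f"{g.contig}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.contig}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f'{g.strand}\t.\t{attrs} tag "basic";\n'
                )


# ---------------------------------------------------------------------------
# BED6 / narrowPeak / bedGraph


def write_bed(intervals: list[Interval], path, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            intervals.append(Interval(f[0], int(f[1]), int(f[2]), strand))
    return intervals


def _neglog10(p: float) -> float:
    # Poisson tails underflow to 0.0 well before float granularity matters;
    # cap at 330 (just past the smallest positive double's exponent).
    if p <= 0.0:
        return 330.0
    return min(330.0, -math.log10(p))


def write_narrowpeak(peaks: list[Peak], path) -> None:
    """Write peaks in ENCODE narrowPeak (BED6+4).

    Column 7 is fold enrichment at the summit, column 8 is -log10 p-value,
    column 9 (q-value) is -1 (not computed), column 10 the summit offset from
    the peak start.
    """
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            nlp = _neglog10(p.min_pvalue)
            score = int(min(1000, round(10 * nlp)))
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{name}\t{score}\t.\t"
                f"{p.fold_enrichment:.5f}\t{nlp:.5f}\t-1\t{p.summit - p.start}\n"
            )


def read_narrowpeak(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"narrowPeak needs 10 columns, got {len(f)}")
            start, end = int(f[1]), int(f[2])
            offset = int(f[9])
            summit = start + offset if offset >= 0 else (start + end) // 2
            peaks.append(
                Peak(
                    contig=f[0],
                    start=start,
                    end=end,
                    summit=summit,
                    max_pileup=0.0,
                    min_pvalue=10 ** (-float(f[7])),
                    fold_enrichment=float(f[6]),
                    name=f[3],
                )
            )
    return peaks


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Write per-base tracks as run-length-compressed bedGraph (4 decimals)."""
    with open(path, "w") as fh:
        for contig, values in track.items():
            vals = np.round(np.asarray(values, dtype=float), 4)
            if len(vals) == 0:
                continue
            # boundaries of constant runs
            change = np.nonzero(np.diff(vals))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{vals[s]:.4f}\n")


def read_bedgraph(path, contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph back into per-base arrays (uncovered bases are 0)."""
    track = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            contig, s, e, v = line.split("\t")
            if contig not in track:
                raise ValueError(f"bedGraph contig {contig!r} not in genome")
            track[contig][int(s) : int(e)] = float(v)
    return track


def read_genome_sizes(path) -> dict[str, int]:
    """Read a two-column contig-sizes TSV (samtools faidx style)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split("\t")
            sizes[f[0]] = int(f[1])
    return sizes


def write_genome_sizes(lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, n in lengths.items():
            fh.write(f"{c}\t{n}\n")
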