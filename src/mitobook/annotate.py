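"""TSS annotation of peaks and regional distribution.

Peaks are assigned, separately for protein-coding and lncRNA genes, to the
nearest transcription start site within a distance cutoff (default 5000 bp,
inclusive), measured from the peak summit. A gene is "bound" when at least
one peak is assigned to it.

Regional distribution classifies each peak once by its summit with
precedence promoter > exonic > intronic > intergenic, where the promoter is
a strand-oriented window around the TSS (default +/-2 kb) and exons are the
annotation's basic-tag exons.
"""

from __future__ import annotations

from dataclasses import dataclass

from mitobook.core import GeneModel, Peak


@dataclass(frozen=True)
class AnnotateParams:
    max_tss_distance: int = 5000
    promoter_up: int = 2000
    promoter_down: int = 2000
    nearest_only: bool = True

    def __post_init__(self):
        if min(self.max_tss_distance, self.promoter_up, self.promoter_down) < 0:
            raise ValueError("annotation distances must be >= 0")


@dataclass(frozen=True)
class TssAssignment:
    peak_name: str
    gene_id: str
    biotype: str
    distance: int


# biotype classes annotated separately, per the mRNA/lncRNA split
_BIOTYPE_CLASSES = ("protein_coding", "lncRNA")


def _peak_refpoint(peak: Peak) -> int:
    return peak.summit if peak.summit is not None else (peak.start + peak.end) // 2


def annotate_tss(
    peaks: list[Peak],
    genes: list[GeneModel],
    params: AnnotateParams = AnnotateParams(),
) -> list[TssAssignment]:
    """Assign each peak to TSSs within the cutoff, per biotype class.

    With ``nearest_only`` (default) a peak gets at most one gene per biotype
    class — the nearest TSS, ties broken by lexicographically smaller
    gene_id. Distances are |summit - TSS|, cutoff inclusive.
    """
    by_class: dict[str, dict[str, list[GeneModel]]] = {b: {} for b in _BIOTYPE_CLASSES}
    for g in genes:
        if g.biotype in by_class:
            by_class[g.biotype].setdefault(g.contig, []).append(g)
    out: list[TssAssignment] = []
    for pk in peaks:
        ref = _peak_refpoint(pk)
        for biotype in _BIOTYPE_CLASSES:
            candidates = [
                (abs(ref - g.tss), g.gene_id)
                for g in by_class[biotype].get(pk.contig, [])
                if abs(ref - g.tss) <= params.max_tss_distance
            ]
            if not candidates:
                continue
            candidates.sort()  # (distance, gene_id): nearest, then lexicographic
            if params.nearest_only:
                candidates = candidates[:1]
            for dist, gid in candidates:
                out.append(TssAssignment(pk.name, gid, biotype, dist))
    return out


def regional_distribution(
    peaks: list[Peak],
    genes: list[GeneModel],
    params: AnnotateParams = AnnotateParams(),
) -> dict[str, int]:
    """Count peaks by summit location: promoter/exonic/intronic/intergenic."""
    counts = {"promoter": 0, "exonic": 0, "intronic": 0, "intergenic": 0}
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for pk in peaks:
        ref = _peak_refpoint(pk)
        in_promoter = in_exon = in_body = False
        for g in by_contig.get(pk.contig, []):
            if g.strand == "+":
                lo, hi = g.tss - params.promoter_up, g.tss + params.promoter_down
            else:
                lo, hi = g.tss - params.promoter_down, g.tss + params.promoter_up
            if lo <= ref <= hi:
                in_promoter = True
                break
            span = g.span()
            if span.start <= ref < span.end:
                in_body = True
                if any(e.start <= ref < e.end for e in g.exons):
                    in_exon = True
        if in_promoter:
            counts["promoter"] += 1
        elif in_exon:
            counts["exonic"] += 1
        elif in_body:
            counts["intronic"] += 1
        else:
            counts["intergenic"] += 1
    return counts


def bound_gene_sets(
    annotations_by_condition: dict[str, list[TssAssignment]],
    conditions: tuple[str, ...] = ("A", "M", "G1"),
) -> dict[str, dict[str, set[str]]]:
    """Per-condition bound-gene sets split by biotype class."""
    out: dict[str, dict[str, set[str]]] = {}
    for cond, annots in annotations_by_condition.items():
        if cond not in conditions:
            raise ValueError(f"unknown condition label {cond!r}")
        sets: dict[str, set[str]] = {b: set() for b in _BIOTYPE_CLASSES}
        for a in annots:
            sets[a.biotype].add(a.gene_id)
        out[cond] = sets
    return out


def write_annotations(annotations: list[TssAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("peak\tgene_id\tbiotype\tdistance\n")
        for a in annotations:
            fh.write(f"{a.peak_name}\t{a.gene_id}\t{a.biotype}\t{a.distance}\n")
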