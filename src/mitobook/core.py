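"""Core domain types shared across the pipeline.

Coordinate convention: 0-based half-open everywhere. A ``Tag`` stores the
5'-most genomic base of a read; for a minus-strand read that is the
highest-coordinate base of the aligned read's 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-")


class GenomeSequence:
    """Named contigs over the alphabet {A,C,G,T,N}, order-preserving.

    Sequences are stored upper-case. Contig names must be unique and
    non-empty, sequences non-empty.
    """

    def __init__(self, contigs: dict[str, str]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            self._add(name, seq)

    def _add(self, name: str, seq: str) -> None:
        if not name:
            raise ValueError("empty contig name")
        if name in self.contigs:
            raise ValueError(f"duplicate contig name: {name!r}")
        seq = seq.upper()
        if not seq:
            raise ValueError(f"contig {name!r} has empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, b in enumerate(seq) if b in bad)
            raise ValueError(
                f"contig {name!r}: invalid base {seq[pos]!r} at position {pos}"
            )
        self.contigs[name] = seq

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeSequence):
            return NotImplemented
        return list(self.contigs.items()) == list(other.contigs.items())

    def __repr__(self) -> str:
        return f"GenomeSequence({len(self)} contigs, {self.total_length} bp)"

    def copy(self) -> "GenomeSequence":
        return GenomeSequence(dict(self.contigs))


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open, optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class Tag:
    """A stranded 5' read-start position."""

    contig: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative tag position {self.pos} on {self.contig}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid tag strand {self.strand!r}")


@dataclass
class GeneModel:
    """A gene with a strand-aware TSS and its basic-tag exons.

    The TSS is the 5'-most exon boundary respecting strand: the start of the
    first exon on '+', and ``end - 1`` (the 0-based last base) of the last
    exon on '-'.
    """

    gene_id: str
    gene_name: str
    biotype: str  # protein_coding | lncRNA | other
    contig: str
    strand: str
    tss: int
    exons: list[Interval] = field(default_factory=list)

    def span(self) -> Interval:
        return Interval(
            self.contig,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


@dataclass
class Peak:
    """A called enrichment peak."""

    contig: str
    start: int
    end: int
    summit: int
    max_pileup: float
    min_pvalue: float
    fold_enrichment: float
    name: str = ""

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> Interval:
        return Interval(self.contig, self.start, self.end)

    @property
    def width(self) -> int:
        return self.end - self.start


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]
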