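"""Synthetic ChIP-seq experiment generator with known planted truth.

The generator emulates the data a mitotic-bookmarking ChIP-seq study
produces, at desk scale:

* a random genome (i.i.d. uniform ACGT contigs),
* a Gencode-style gene annotation (protein-coding and lncRNA genes with
  1-3 basic-tag exons, strand-aware TSSs, enforced spacing),
* true binding sites planted near distinct gene TSSs with per-condition
  (A/M/G1) occupancy, a configurable fraction "bookmarked" (occupied in
  both M and G1),
* phantom read-stack artifacts far from any TSS (all tags at one position
  on one strand — the failure mode the cross-correlation filter targets),
* stranded 5'-start tags: each fragment has a Normal-jittered centre and
  yields one single-end read on a random strand, with the '+' tag at
  centre − fragment/2 and the '−' tag at centre + fragment/2 (the
  fragment's right end, the read's 5' base),
* Poisson background tags uniform along each contig and strand,
* a differential-expression table with planted effects.

Every generator is deterministic given the seed; conditions and replicates
draw from independent child streams of the master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from mitobook.core import GenomeSequence, GeneModel, Interval, Tag

CONDITIONS = ("A", "M", "G1")


@dataclass(frozen=True)
class SimParams:
    n_contigs: int = 2
    contig_length: int = 500_000
    n_genes: int = 60
    lncRNA_fraction: float = 0.25
    n_true_sites: int = 40
    bookmark_fraction: float = 0.5
    n_artifacts: int = 10
    reads_per_site: float = 200.0
    fragment_size: int = 180
    read_length: int = 85
    background_rate: float = 5e-4  # tags per base per strand
    n_replicates: int = 2
    site_halfwidth: int = 50
    center_jitter_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not (self.fragment_size > self.read_length > 0):
            raise ValueError("require fragment_size > read_length > 0")
        for frac in (self.lncRNA_fraction, self.bookmark_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_contigs, self.contig_length) < 1:
            raise ValueError("genome dimensions must be positive")


@dataclass
class SiteTruth:
    site_id: str
    interval: Interval
    kind: str  # true_site | phantom_artifact
    occupancy: frozenset
    bound_gene_id: str | None = None
    artifact_strand: str | None = None  # phantom stacks live on one strand

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class DERecord:
    gene_id: str
    base_mean: float
    log2fc: float
    pvalue: float
    truly_de: bool


def _rng(params: SimParams, *stream) -> np.random.Generator:
    """Independent child stream of the master seed, keyed by stage labels.

    Labels hash through crc32 so streams are stable across processes.
    """
    key = [params.seed] + [zlib.crc32(str(s).encode()) % (2**31) for s in stream]
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# Genome and annotation


def make_genome(params: SimParams) -> GenomeSequence:
    """i.i.d. uniform-ACGT contigs named chr1..chrN."""
    rng = _rng(params, "genome")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    contigs = {}
    for i in range(params.n_contigs):
        seq = rng.choice(bases, size=params.contig_length)
        contigs[f"chr{i + 1}"] = seq.tobytes().decode()
    return GenomeSequence(contigs)


# fraction of each contig reserved gene-free so artifacts can sit >= 10 kb
# from every TSS
_GENE_ZONE = 0.70


def make_genes(genome: GenomeSequence, params: SimParams) -> list[GeneModel]:
    """Place non-colliding genes in the proximal portion of each contig.

    Each contig's first 70% holds equal-width gene slots (one gene per slot,
    which enforces TSS spacing); the distal 30% stays gene-free for artifact
    placement. Start jitter within a slot is capped at 1 kb so that adjacent
    TSSs stay further apart than the downstream annotation cutoff whenever
    the slot width allows. Genes get 1-3 basic-tag exons and a strand-aware
    TSS. The number of lncRNA genes is round(lncRNA_fraction * n_genes),
    ties-to-even.
    """
    rng = _rng(params, "genes")
    contig_names = list(genome.contigs)
    n_genes = params.n_genes
    # distribute genes over contigs as evenly as possible
    per_contig = [n_genes // len(contig_names)] * len(contig_names)
    for i in range(n_genes % len(contig_names)):
        per_contig[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    for cname, n_here in zip(contig_names, per_contig):
        L = len(genome[cname])
        zone_end = int(L * _GENE_ZONE)
        if n_here == 0:
            continue
        slot = (zone_end - 1000) // n_here
        span_max = min(4000, max(1500, slot - 1200))
        if slot < 2000:
            raise ValueError(
                f"genome too small: slot width {slot} bp for {n_here} genes "
                f"on {cname}"
            )
        for s in range(n_here):
            gi += 1
            gid = f"G{gi:04d}"
            slot_start = 1000 + s * slot
            span = int(rng.integers(1500, span_max + 1))
            jitter_max = max(1, min(slot - span - 200, 1000))
            start = slot_start + int(rng.integers(0, jitter_max))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            exons = _split_exons(cname, start, start + span, n_exons, strand, rng)
            tss = exons[0].start if strand == "+" else exons[-1].end - 1
            genes.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=f"gene{gi}",
                    biotype="protein_coding",
                    contig=cname,
                    strand=strand,
                    tss=tss,
                    exons=exons,
                )
            )
    # assign lncRNA biotype to a deterministic random subset
    n_lnc = round(params.lncRNA_fraction * n_genes)  # Python round: ties-to-even
    lnc_idx = rng.choice(n_genes, size=n_lnc, replace=False)
    for i in lnc_idx:
        genes[i].biotype = "lncRNA"
    return genes


def _split_exons(contig, start, end, n_exons, strand, rng) -> list[Interval]:
    """Partition [start, end) into n_exons exons separated by introns."""
    if n_exons == 1:
        return [Interval(contig, start, end, strand)]
    width = end - start
    # pick internal breakpoints leaving room for >= 100 bp exons and introns
    cuts = np.sort(rng.choice(np.arange(200, width - 200, 100), size=2 * (n_exons - 1), replace=False))
    bounds = [start] + [start + int(c) for c in cuts] + [end]
    exons = []
    for i in range(n_exons):
        exons.append(Interval(contig, bounds[2 * i], bounds[2 * i + 1], strand))
    return exons


# ---------------------------------------------------------------------------
# Planted sites and artifacts


def plant_sites(
    genes: list[GeneModel],
    params: SimParams,
    genome_lengths: dict[str, int] | None = None,
) -> list[SiteTruth]:
    """Plant true sites near distinct TSSs and phantom stacks far from TSSs.

    round(bookmark_fraction * n_true_sites) sites are bookmarked (occupancy
    {A, M, G1}); the rest split as evenly as possible among A-only, M-only
    and G1-only. Artifacts sit >= 10 kb from every TSS, carry no bound gene,
    and are emitted in all three conditions.
    """
    if params.n_true_sites > len(genes):
        raise ValueError("more true sites requested than genes available")
    rng = _rng(params, "sites")
    chosen = rng.choice(len(genes), size=params.n_true_sites, replace=False)
    n_bm = round(params.bookmark_fraction * params.n_true_sites)
    single = ["A", "M", "G1"]
    sites: list[SiteTruth] = []
    for rank, gidx in enumerate(chosen):
        g = genes[int(gidx)]
        offset = int(rng.integers(-1000, 1001))
        center = max(params.site_halfwidth, g.tss + offset)
        if rank < n_bm:
            occ = frozenset({"A", "M", "G1"})
        else:
            occ = frozenset({single[(rank - n_bm) % 3]})
        sites.append(
            SiteTruth(
                site_id=f"site_{rank + 1:03d}",
                interval=Interval(
                    g.contig,
                    center - params.site_halfwidth,
                    center + params.site_halfwidth,
                ),
                kind="true_site",
                occupancy=occ,
                bound_gene_id=g.gene_id,
            )
        )
    # phantom artifacts: uniform positions rejected within 10 kb of any TSS
    if genome_lengths is None:
        genome_lengths = {}
        for g in genes:
            genome_lengths[g.contig] = max(
                genome_lengths.get(g.contig, 0), g.span().end + 80_000
            )
    tss_by_contig: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_contig.setdefault(g.contig, [])
    for g in genes:
        tss_by_contig[g.contig].append(g.tss)
    tss_by_contig = {c: np.array(v) for c, v in tss_by_contig.items()}
    contig_names = list(genome_lengths)
    placed = 0
    attempts = 0
    while placed < params.n_artifacts:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place artifacts >= 10 kb from all TSSs")
        cname = contig_names[int(rng.integers(len(contig_names)))]
        L = genome_lengths[cname]
        pos = int(rng.integers(1000, L - 1000))
        tsss = tss_by_contig.get(cname)
        if tsss is not None and len(tsss) and np.min(np.abs(tsss - pos)) < 10_000:
            continue
        if any(
            s.interval.contig == cname and abs(s.center - pos) < 2000 for s in sites
        ):
            continue
        placed += 1
        sites.append(
            SiteTruth(
                site_id=f"phantom_{placed:03d}",
                interval=Interval(cname, pos - 1, pos + 1),
                kind="phantom_artifact",
                occupancy=frozenset({"A", "M", "G1"}),
                bound_gene_id=None,
                artifact_strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Tag simulation


def simulate_tags(
    truth: list[SiteTruth],
    params: SimParams,
    condition: str,
    genome_lengths: dict[str, int],
    replicate: int = 0,
) -> list[Tag]:
    """Stranded 5'-start tags for one condition and replicate.

    True sites occupied in this condition emit Poisson(reads_per_site)
    fragments with Normal(centre, jitter_sd) centres; each fragment yields
    one read on a Bernoulli(0.5) strand. Phantom artifacts emit
    Poisson(reads_per_site) tags all at one position on one strand.
    Background tags are Poisson(rate * length) per strand at uniform
    positions.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = _rng(params, "tags", condition, replicate)
    half = params.fragment_size // 2
    tags: list[Tag] = []
    for site in truth:
        if condition not in site.occupancy:
            continue
        L = genome_lengths[site.interval.contig]
        n = rng.poisson(params.reads_per_site)
        if site.kind == "phantom_artifact":
            pos = int(np.clip(site.center, 0, L - 1))
            tags.extend(
                Tag(site.interval.contig, pos, site.artifact_strand)
                for _ in range(n)
            )
            continue
        centers = rng.normal(site.center, params.center_jitter_sd, size=n)
        strands = rng.random(n) < 0.5
        for c, plus in zip(centers, strands):
            if plus:
                pos = int(round(c)) - half
                strand = "+"
            else:
                pos = int(round(c)) + half
                strand = "-"
            tags.append(Tag(site.interval.contig, int(np.clip(pos, 0, L - 1)), strand))
    for cname, L in genome_lengths.items():
        for strand in ("+", "-"):
            n_bg = rng.poisson(params.background_rate * L)
            positions = rng.integers(0, L, size=n_bg)
            tags.extend(Tag(cname, int(p), strand) for p in positions)
    tags.sort(key=lambda t: (t.contig, t.pos, t.strand))
    return tags


# ---------------------------------------------------------------------------
# Differential expression

# planted DE structure: fraction of site-bound genes truly deregulated, and a
# smaller off-target fraction of unbound genes
DE_FRACTION_BOUND = 0.6
DE_FRACTION_UNBOUND = 0.05


def simulate_de(
    genes: list[GeneModel], truth: list[SiteTruth], params: SimParams
) -> list[DERecord]:
    """DE table with planted effects among site-bound genes.

    Truly-DE rows: base_mean ~ LogNormal(mu=3, sd=1), |log2fc| ~ 1 + Exp(1)
    with a random sign, p ~ Uniform(0, 0.01). Null rows share the base_mean
    law but get log2fc ~ Normal(0, 0.2) and p ~ Uniform(0, 1).
    """
    rng = _rng(params, "de")
    bound = {s.bound_gene_id for s in truth if s.bound_gene_id is not None}
    records = []
    for g in genes:
        frac = DE_FRACTION_BOUND if g.gene_id in bound else DE_FRACTION_UNBOUND
        truly = bool(rng.random() < frac)
        base_mean = float(rng.lognormal(3.0, 1.0))
        if truly:
            lfc = (1.0 + rng.exponential(1.0)) * (1 if rng.random() < 0.5 else -1)
            pval = float(rng.uniform(0.0, 0.01))
        else:
            lfc = float(rng.normal(0.0, 0.2))
            pval = float(rng.uniform(0.0, 1.0))
        records.append(DERecord(g.gene_id, base_mean, float(lfc), pval, truly))
    return records


# ---------------------------------------------------------------------------
# Whole-experiment bundle


@dataclass
class SimulatedExperiment:
    params: SimParams
    genome: GenomeSequence
    genes: list[GeneModel]
    truth: list[SiteTruth]
    tags: dict[str, list[list[Tag]]]  # condition -> [replicate tag lists]
    de_records: list[DERecord] = field(default_factory=list)

    @property
    def bookmarked_genes(self) -> set[str]:
        return {
            s.bound_gene_id
            for s in self.truth
            if s.kind == "true_site" and {"M", "G1"} <= s.occupancy
        }

    def pooled_tags(self, condition: str) -> list[Tag]:
        pooled = [t for rep in self.tags[condition] for t in rep]
        pooled.sort(key=lambda t: (t.contig, t.pos, t.strand))
        return pooled


def simulate_experiment(params: SimParams) -> SimulatedExperiment:
    """Generate genome, annotation, truth, tags and DE table in one call."""
    genome = make_genome(params)
    genes = make_genes(genome, params)
    truth = plant_sites(genes, params, genome.lengths())
    tags = {
        cond: [
            simulate_tags(truth, params, cond, genome.lengths(), replicate=r)
            for r in range(params.n_replicates)
        ]
        for cond in CONDITIONS
    }
    de = simulate_de(genes, truth, params)
    return SimulatedExperiment(params, genome, genes, truth, tags, de)


def write_truth(truth: list[SiteTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tcontig\tstart\tend\tkind\toccupancy\tbound_gene_id\n")
        for s in truth:
            occ = ",".join(sorted(s.occupancy))
            fh.write(
                f"{s.site_id}\t{s.interval.contig}\t{s.interval.start}\t"
                f"{s.interval.end}\t{s.kind}\t{occ}\t{s.bound_gene_id or '.'}\n"
            )


def write_de_table(records: list[DERecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbase_mean\tlog2fc\tpvalue\ttruly_de\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.base_mean:.4f}\t{r.log2fc:.4f}\t"
                f"{r.pvalue:.6g}\t{int(r.truly_de)}\n"
            )


def read_de_table(path) -> list[DERecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                DERecord(
                    gene_id=f[idx["gene_id"]],
                    base_mean=float(f[idx["base_mean"]]),
                    log2fc=float(f[idx["log2fc"]]),
                    pvalue=float(f[idx["pvalue"]]),
                    truly_de=bool(int(f[idx.get("truly_de", -1)]))
                    if "truly_de" in idx
                    else False,
                )
            )
    return records
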