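"""End-to-end pipeline: peaks -> reproducibility -> cross-correlation filter
-> TSS annotation -> occupancy classification, clustering and DE overlap.

The stage order mirrors the analysis this package re-implements: peaks are
called per condition on pooled replicates, pruned to those supported by
every replicate, artifact-filtered by strand cross-correlation, annotated to
protein-coding and lncRNA TSSs, and finally classified by A/M/G1 occupancy
with k-means profile clustering and an optional differential-expression
overlap.

Configuration is a flat YAML mapping (see :class:`PipelineConfig`). A single
global seed deterministically derives every stage seed, so identical config
plus seed reproduces summary.json byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from mitobook import annotate as ann
from mitobook import bookmark as bk
from mitobook import formats, peaks as pk
from mitobook import simulate as sim
from mitobook import xcor as xc
from mitobook.core import Peak, Tag

log = logging.getLogger("mitobook")

CONDITIONS = ("A", "M", "G1")


@dataclass
class PipelineConfig:
    outdir: str = "mitobook_out"
    seed: int = 0
    # input mode 1: generate a synthetic experiment
    simulate: dict | None = None
    # input mode 2: paths to real inputs
    genome_sizes: str | None = None
    gtf: str | None = None
    tags: dict[str, list[str]] | None = None  # condition -> replicate TSVs
    de_table: str | None = None
    # stage parameters (flat overrides of the dataclass defaults)
    peakcall: dict = field(default_factory=dict)
    xcor: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    de_filter: dict = field(default_factory=dict)
    cluster_k: int = 4
    repro_mode: str = "overlap"  # overlap | none
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            if self.genome_sizes is None or self.gtf is None or not self.tags:
                raise ValueError(
                    "config needs either a 'simulate' block or genome_sizes, "
                    "gtf and tags paths"
                )
            for p in [self.genome_sizes, self.gtf] + [
                t for reps in self.tags.values() for t in reps
            ]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file missing: {p}")
            if self.de_table and not Path(self.de_table).exists():
                raise FileNotFoundError(f"input file missing: {self.de_table}")
        if self.repro_mode not in ("overlap", "none"):
            raise ValueError(f"unknown repro_mode {self.repro_mode!r}")


def _stage_seed(global_seed: int, stage: str) -> int:
    import zlib

    return (global_seed * 100_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ConditionResult:
    pooled_peaks: list[Peak]
    reproducible: list[Peak]
    kept: list[Peak]
    xcor_results: list
    fe_track: dict


def process_condition(
    condition: str,
    replicate_tags: list[list[Tag]],
    contig_lengths: dict[str, int],
    peak_params: pk.PeakCallParams,
    xcor_params: xc.XcorParams,
    repro_mode: str = "overlap",
) -> ConditionResult:
    """Peak calling, reproducibility pruning and artifact filtering for one
    condition."""
    pooled = sorted(
        (t for rep in replicate_tags for t in rep),
        key=lambda t: (t.contig, t.pos, t.strand),
    )
    pooled_peaks, fe_track = pk.call_peaks(pooled, peak_params, contig_lengths)
    if repro_mode == "overlap" and len(replicate_tags) >= 2:
        rep_sets = [
            pk.call_peaks(rep, peak_params, contig_lengths)[0]
            for rep in replicate_tags
        ]
        reproducible = bk.reproducible_peaks(pooled_peaks, rep_sets)
    else:
        reproducible = list(pooled_peaks)
    kept, xres = xc.filter_peaks(reproducible, pooled, xcor_params, contig_lengths)
    log.info(
        "condition %s: %d pooled peaks, %d reproducible, %d after xcor filter",
        condition,
        len(pooled_peaks),
        len(reproducible),
        len(kept),
    )
    return ConditionResult(pooled_peaks, reproducible, kept, xres, fe_track)


@dataclass
class AnalysisResult:
    per_condition: dict[str, ConditionResult]
    annotations: dict[str, list]
    bound_all: dict[str, set[str]]
    classes: bk.OccupancyClasses
    union: list[Peak]
    matrix: bk.OccupancyMatrix
    cluster_labels: object  # ndarray or None


def analyze_experiment(
    tags_by_cond: dict[str, list[list[Tag]]],
    genes,
    contig_lengths: dict[str, int],
    peak_params: pk.PeakCallParams | None = None,
    xcor_params: xc.XcorParams | None = None,
    ann_params: ann.AnnotateParams | None = None,
    cluster_k: int = 4,
    cluster_seed: int = 0,
    repro_mode: str = "overlap",
) -> AnalysisResult:
    """Run the analysis stages in memory: peaks -> reproducibility -> xcor
    filter -> TSS annotation -> occupancy classification and clustering."""
    peak_params = peak_params or pk.PeakCallParams()
    xcor_params = xcor_params or xc.XcorParams()
    ann_params = ann_params or ann.AnnotateParams()
    results = {
        cond: process_condition(
            cond, tags_by_cond[cond], contig_lengths, peak_params, xcor_params,
            repro_mode,
        )
        for cond in CONDITIONS
    }
    annotations = {
        cond: ann.annotate_tss(results[cond].kept, genes, ann_params)
        for cond in CONDITIONS
    }
    bound = ann.bound_gene_sets(annotations)
    bound_all = {
        cond: bound[cond]["protein_coding"] | bound[cond]["lncRNA"]
        for cond in CONDITIONS
    }
    classes = bk.classify_genes(bound_all)
    union = bk.union_peaks([results[c].kept for c in CONDITIONS])
    fe_tracks = {c: results[c].fe_track for c in CONDITIONS}
    matrix = bk.occupancy_matrix(union, fe_tracks, CONDITIONS)
    labels = None
    if matrix.values.shape[0] >= cluster_k:
        labels = bk.cluster_profiles(matrix, k=cluster_k, seed=cluster_seed)
    return AnalysisResult(
        results, annotations, bound_all, classes, union, matrix, labels
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write per-stage artifacts and return the summary."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", config)

    peak_params = pk.PeakCallParams(**config.peakcall)
    xcor_params = xc.XcorParams(**config.xcor)
    ann_params = ann.AnnotateParams(**config.annotate)
    de_params = bk.DEFilterParams(**config.de_filter)

    # ------------------------------------------------------------------ inputs
    if config.simulate is not None:
        sim_params = sim.SimParams(
            **{**config.simulate, "seed": config.simulate.get("seed", config.seed)}
        )
        exp = sim.simulate_experiment(sim_params)
        genes = exp.genes
        contig_lengths = exp.genome.lengths()
        tags_by_cond = {c: exp.tags[c] for c in CONDITIONS}
        de_records = exp.de_records
        simdir = outdir / "sim"
        simdir.mkdir(exist_ok=True)
        formats.write_fasta(exp.genome, simdir / "genome.fa")
        formats.write_genome_sizes(contig_lengths, simdir / "genome.sizes")
        formats.write_gtf(genes, simdir / "genes.gtf")
        sim.write_truth(exp.truth, simdir / "truth.tsv")
        sim.write_de_table(de_records, simdir / "de.tsv")
        for cond in CONDITIONS:
            for r, tg in enumerate(tags_by_cond[cond]):
                formats.write_tags(tg, simdir / f"tags_{cond}_rep{r + 1}.tsv")
    else:
        contig_lengths = formats.read_genome_sizes(config.genome_sizes)
        genes = formats.read_gtf(config.gtf)
        tags_by_cond = {
            cond: [formats.read_tags(p) for p in reps]
            for cond, reps in config.tags.items()
        }
        de_records = (
            sim.read_de_table(config.de_table) if config.de_table else []
        )

    # ------------------------------------------------------------- all stages
    analysis = analyze_experiment(
        tags_by_cond,
        genes,
        contig_lengths,
        peak_params,
        xcor_params,
        ann_params,
        cluster_k=config.cluster_k,
        cluster_seed=_stage_seed(config.seed, "kmeans"),
        repro_mode=config.repro_mode,
    )
    results = analysis.per_condition
    for cond in CONDITIONS:
        res = results[cond]
        formats.write_narrowpeak(res.kept, outdir / f"peaks_{cond}.narrowPeak")
        formats.write_bedgraph(res.fe_track, outdir / f"fe_{cond}.bedGraph")
        xc.write_xcor_report(res.xcor_results, outdir / f"xcor_{cond}.tsv")
        ann.write_annotations(
            analysis.annotations[cond], outdir / f"annotations_{cond}.tsv"
        )
    bound = ann.bound_gene_sets(analysis.annotations)
    bound_all = analysis.bound_all
    classes = analysis.classes
    union = analysis.union
    if analysis.cluster_labels is not None:
        cluster_sizes = {
            str(lbl): int((analysis.cluster_labels == lbl).sum())
            for lbl in range(1, config.cluster_k + 1)
        }
    else:
        cluster_sizes = {}
        log.warning(
            "too few union peaks (%d) for k-means", analysis.matrix.values.shape[0]
        )

    # ------------------------------------------------------------- DE overlap
    enrichment = {}
    de_sig: set[str] = set()
    if de_records:
        de_sig = bk.filter_de(de_records, de_params)
        universe = {g.gene_id for g in genes}
        category_sets = {
            "shared_M_G1": classes.shared,
            "M_only": classes.m_only,
            "G1_only": classes.g1_only,
            "A_not_MG1": classes.a_not_mg1,
        }
        enrichment = bk.overlap_enrichment(
            {k: v & universe for k, v in category_sets.items()},
            de_sig & universe,
            universe,
        )

    summary = {
        "seed": config.seed,
        "n_genes": len(genes),
        "peaks": {
            cond: {
                "pooled": len(results[cond].pooled_peaks),
                "reproducible": len(results[cond].reproducible),
                "kept": len(results[cond].kept),
            }
            for cond in CONDITIONS
        },
        "bound_genes": {
            cond: {
                "protein_coding": len(bound[cond]["protein_coding"]),
                "lncRNA": len(bound[cond]["lncRNA"]),
                "total": len(bound_all[cond]),
            }
            for cond in CONDITIONS
        },
        "occupancy": classes.counts(),
        "union_peaks": len(union),
        "cluster_sizes": cluster_sizes,
        "de_significant": len(de_sig),
        "de_overlap": enrichment,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "genes_by_category.tsv", "w") as fh:
        fh.write("gene_id\tcategory\tde_significant\n")
        for cat_name, cat in (
            ("shared_M_G1", classes.shared),
            ("M_only", classes.m_only),
            ("G1_only", classes.g1_only),
            ("A_not_MG1", classes.a_not_mg1),
        ):
            for gid in sorted(cat):
                fh.write(f"{gid}\t{cat_name}\t{int(gid in de_sig)}\n")
    log.info("summary written to %s", outdir / "summary.json")
    return summary
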