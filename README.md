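# mitobook

Analysis pipeline for **mitotic gene bookmarking ChIP-seq**: which genes
retain a transcription factor on their regulatory regions through mitosis
(M) and into early G1, relative to an asynchronous population (A)?

The pipeline implements the computational stages such a study needs:

1. **rDNA-aware reference construction** — tile 50 bp in-silico reads
   across the ribosomal repeat unit, hard-mask every exact genomic match
   with `N`, and append the complete unit as contig `chrU13369.1`, so rDNA
   reads map there and only there.
2. **Poisson peak calling** — fragment-extension pileup against a local-λ
   background, λ(x) = max(λ_genome, λ_1k, λ_5k, λ_10k), candidate bases at
   P(X ≥ pileup) ≤ 1e−5, with a per-base fold-enrichment (FE) bedGraph.
3. **Replicate reproducibility** — pooled peaks kept when they overlap a
   peak in every replicate.
4. **Strand cross-correlation artifact filter** — per peak, Pearson
   correlation between plus- and minus-strand read coverage at a shift of
   fragment − read = 180 − 85 = 95 bp and at zero shift; keep iff
   shifted ≥ 0.7 and shifted − unshifted ≥ 0.1. Single-position read
   stacks ("phantom peaks") fail this test; genuine bidirectional read
   clouds pass.
5. **TSS annotation** — nearest protein-coding and lncRNA TSS within 5 kb
   of the summit (annotated separately per biotype), plus a
   promoter/exonic/intronic/intergenic regional distribution.
6. **Occupancy classification** — set algebra over the A/M/G1 bound-gene
   sets (shared M∩G1 = bookmarked, M-only, G1-only, A-not-MG1), k-means
   clustering (k = 4) of row-normalized FE profiles over the union peaks,
   a strict differential-expression filter (baseMean > 5, |log2FC| > 1,
   p < 0.05) and hypergeometric category-vs-DE overlap statistics.
7. **Synthetic data** — a generator that plants true binding sites with
   per-condition occupancy, a bookmarked subset, phantom stacks and a DE
   table with known truth, so every stage is validated against planted
   ground truth.

See `docs/methods.md` for the models, parameters and design choices.

## Worked example

Run the numbered analyses (each writes under `results/`):

```sh
python analysis/01_simulate.py          # synthetic A/M/G1 experiment
python analysis/02_mask_reference.py    # rDNA-aware reference build
python analysis/03_run_pipeline.py      # full pipeline + recovery check
python analysis/04_filter_benchmark.py  # phantom-filter discrimination
python analysis/05_bookmark_recovery.py # end-to-end recovery across seeds
```

`01` plants 40 true sites (20 bookmarked, i.e. occupied in A, M and G1) and
10 phantom stacks on a 2 × 500 kb genome with 60 genes. `03` then prints:

```
{
  "A_not_MG1": 7,
  "G1": 26,
  "G1_only": 6,
  "M": 27,
  "M_only": 7,
  "M_union_G1": 33,
  "shared_M_G1": 20
}
bookmarked-gene recovery: planted=20 predicted=20 precision=1.000 recall=1.000
```

Reading this: 27 genes carry a filtered mitotic peak, 20 of them shared
with G1 — exactly the planted bookmarked set (precision = recall = 1.0) —
and the identity |M ∪ G1| = 27 + 26 − 20 = 33 holds. `04` reports the
artifact filter keeping 100% of true-site peaks while rejecting 98.5% of
phantom stacks (400 and 200 peaks pooled over 20 seeds):

```
true-site retention 1.000 (400 peaks); phantom rejection 0.985 (200 peaks)
```

The same stages are available as a CLI (`mitobook simulate`, `mask-genome`,
`callpeaks`, `xcor-filter`, `annotate`, `run --config pipeline.yaml`) for
use on real tag files; `mitobook run` consumes a flat YAML config and
writes narrowPeak, FE bedGraph, cross-correlation reports, annotations and
a `summary.json` whose bytes are reproducible given config + seed.

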