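# Methods

`mitobook` re-implements, as a tested pipeline, the computational analysis
behind a mitotic gene-bookmarking ChIP-seq study: which genes retain a
transcription factor through mitosis (M) and into early G1, compared with an
asynchronous population (A). This note documents the models, the parameters
that matter, the synthetic-data generator, and the design choices made where
the problem was genuinely open.

## Coordinate and data conventions

All in-memory coordinates are 0-based half-open. GTF (1-based inclusive) is
converted at the file boundary only: subtract 1 from the start, leave the
end. Tags store the 5′-most genomic base of a read: for a minus-strand read
this is the highest-coordinate base of the read. A gene's TSS is the
5′-most basic-tag exon boundary respecting strand (first exon start on `+`,
last exon end − 1 on `−`).

## rDNA-aware reference

The human ribosomal repeat unit (the U13369 45S region) is fragmentarily and
redundantly represented in standard assemblies, which scatters rDNA reads
over partial loci. The builder tiles `read_length` (default 50 bp) windows
at `step` (default 1) across the full unit, finds every exact occurrence of
each window or its reverse complement in the assembly, merges the hit
intervals (touching intervals merge), hard-masks them with `N`, and appends
the complete unit as contig `chrU13369.1`.

Exact two-strand substring search replaces read alignment: the in-silico
reads are error-free, so mismatch-tolerant alignment reduces to exact
matching, and every exact occurrence is masked (the multi-mapping question
does not arise). Masking is idempotent: rebuilding on an already-masked
assembly yields an empty mask.

## Peak calling

A minimal single-sample caller with a Poisson local-λ background. Each tag
is extended to the mean fragment size f (default 180 bp): a `+` tag at p
covers [p, p+f), a `−` tag covers [p−f+1, p+1), clipped at contig edges.
The expected coverage at base x is

    λ(x) = max(λ_genome, λ_1k(x), λ_5k(x), λ_10k(x))

with λ_w the control pileup averaged over a w-base window centred on x
(edge-truncated) and λ_genome the genome-wide rate. Without a control the
local windows would reproduce the peak itself, so only λ_genome is used.
The control is assumed depth-matched; no scaling is applied.

A base is a candidate when P(X ≥ pileup) ≤ 1e−5 for X ~ Poisson(λ(x)).
Candidates merge across gaps ≤ `merge_gap` (default: the read length);
regions shorter than `min_peak_length` (default: the fragment size) are
dropped. The summit is the leftmost position of maximal pileup (ties break
left for determinism); fold enrichment is (pileup + 1)/(λ + 1), the
pseudocount guarding empty-background division. Duplicate reads are kept
deliberately: single-position read stacks must survive calling so that the
cross-correlation filter downstream — not an upstream deduplication — is
what removes them.

## Replicate reproducibility

A pooled peak is kept when it overlaps (≥ 1 bp) a peak called in every
replicate. This overlap rule is a deliberately permissive stand-in for
ranked-list consistency procedures (IDR-style analyses at lenient cutoffs
retain nearly all pooled peaks); re-deriving the full copula mixture model
is out of scope. `repro_mode: none` disables the stage.

## Strand cross-correlation artifact filter

Genuine binding yields fragments sequenced from either end: plus-strand
reads upstream of the site, minus-strand reads downstream. The filter
evaluates every peak independently on its interval extended by one shift on
each side and computes Pearson correlations between the strand-specific
coverage profiles — each read occupying `read_size` bases from its 5′ end —
at the fragment-derived shift s = fragment − read (180 − 85 = 95 bp by
default) and at zero shift. A peak is kept iff

    shifted ≥ 0.7   and   shifted − unshifted ≥ 0.1.

Correlating *coverage* rather than raw per-base start counts is a
deliberate choice: on these profiles the plus and minus signals of a true
site sit exactly s bases apart, and the read-length footprint averages the
per-base Poisson sampling noise that raw start counts carry. At realistic
peak depths (a few hundred reads) raw start-count correlations plateau
around 0.6 and cannot clear a 0.7 retention threshold even for perfect
sites, whereas coverage correlations of true sites concentrate near 0.99 —
so a 0.7 threshold separates signal from artifact rather than rejecting
both. A zero-variance slice (e.g. the empty strand of a single-strand
stack) returns correlation 0, so one-strand phantoms always fail; a
both-strand stack at a single position correlates unshifted but not at the
shift and fails the delta rule.

## TSS annotation

Peaks are assigned, separately for protein-coding and lncRNA genes, to the
nearest TSS within 5000 bp (inclusive) of the peak summit, ties broken by
lexicographically smaller gene id; `--all-within` assigns every TSS in
range instead. Nearest-only is the default because it keeps gene-set sizes
interpretable (one gene per biotype class per peak). A gene is *bound* when
at least one filtered peak is assigned to it. Regional distribution
classifies each summit once with precedence promoter > exonic > intronic >
intergenic, the promoter being a strand-oriented TSS ± 2 kb window (a
common convention; the span is a parameter, not a claim).

## Occupancy classification, clustering, DE overlap

Set algebra over the per-condition bound-gene sets defines the categories:
shared = M ∩ G1 (bookmarked into G1), M-only = M \ G1, G1-only = G1 \ M,
A-not-MG1 = A \ (M ∪ G1); |M ∪ G1| = |M| + |G1| − |M ∩ G1| holds by
construction and is asserted in tests.

The union of kept peaks across conditions is profiled by fold enrichment at
the union-peak summit in each condition's FE track. The summit of a merged
union peak is taken from the constituent peak with the highest fold
enrichment (ties: leftmost) — the merged interval itself has no natural
summit. Rows are scaled to unit maximum (scale-invariant for profile-shape
clustering; all-zero rows are dropped and logged) and clustered with
k-means (k = 4, k-means++ initialization, best of 10 restarts by
within-cluster sum of squares, fixed seed), labels renumbered by descending
cluster size. Clustering delegates to scikit-learn.

Differential-expression significance uses strict thresholds — base mean
> 5, |log2FC| > 1, p < 0.05 — so rows at exactly a threshold are excluded.
Category-vs-DE overlaps are scored by the hypergeometric upper tail
P(X ≥ k) with Benjamini–Hochberg adjustment across the categories tested —
a defensible, labelled default for studies that otherwise report raw
overlap counts.

## Synthetic-data generator

The generator defines the study conditions every test runs under:

| parameter | default | meaning |
|---|---|---|
| n_contigs × contig_length | 2 × 500 kb | i.i.d. uniform-ACGT genome |
| n_genes | 60 | genes in the proximal 70% of each contig |
| lncRNA_fraction | 0.25 | round-ties-to-even share of lncRNA biotype |
| n_true_sites | 40 | sites planted ≤ 1 kb from distinct TSSs |
| bookmark_fraction | 0.5 | share of true sites occupied in A, M and G1 |
| n_artifacts | 10 | single-position, single-strand phantom stacks |
| reads_per_site | 200 | Poisson mean fragments per occupied site |
| fragment_size / read_length | 180 / 85 | fragment extension and read footprint |
| center_jitter_sd | 20 bp | Normal jitter of fragment centres |
| background_rate | 5e-4 | tags per base per strand, uniform |
| n_replicates | 2 | per condition |

Each fragment centre is Normal(site centre, 20 bp); the fragment yields one
single-end read on a Bernoulli(0.5) strand, the `+` tag at centre − f/2 and
the `−` tag at centre + f/2 (the fragment's right end, the read's 5′ base).
Non-bookmarked true sites split as evenly as possible among A-only, M-only
and G1-only; bookmarked sites are occupied in all three conditions
(constitutive binding retained through mitosis). Phantom stacks are placed
≥ 10 kb from every TSS and emit in all conditions on one fixed strand. Gene
slots cap start jitter at 1 kb so adjacent TSSs stay farther apart than the
5 kb annotation cutoff — on denser layouts nearest-TSS gene assignment is
ill-posed by construction, which is an annotation dialect issue, not a
pipeline property. The DE table marks 60% of site-bound and 5% of unbound
genes truly deregulated; truly-DE rows draw base_mean ~ LogNormal(3, 1),
|log2FC| ~ 1 + Exp(1) with random sign and p ~ U(0, 0.01), null rows share
the base_mean law with log2FC ~ N(0, 0.2) and p ~ U(0, 1).

Every generator draws from an independent, crc32-keyed child stream of the
master seed, so outputs are reproducible across processes and conditions /
replicates are mutually independent.

What the generator does *not* emulate — sequence-dependent mappability,
GC bias, nucleosome structure, fragment-length dispersion beyond a fixed
mean, overdispersed background — bounds what passing tests show: they
validate the algorithms against their own generative assumptions, not
performance on real libraries.

## Problem sizes

Recovery experiments run 20 seeds of the default 1 Mb / 40-site experiment
(end-to-end) and 20 seeds of the 20-true-site / 10-phantom configuration at
300 reads per site (filter benchmark); both finish in about a minute on one
core. These sizes give several hundred true-site and phantom peaks per
experiment, enough to resolve the 0.95 retention/rejection levels the
package asserts.

## Known limitations

* The caller mirrors only the documented behaviour of the tool it stands in
  for (p ≤ 1e−5 candidate bases, FE track); no broad-peak mode, q-values,
  or paired-end support, and no claim of numeric parity with MACS2.
* The reproducibility rule is overlap-based, not rank-consistency-based.
* Gene-level occupancy inherits the nearest-TSS dialect; transcript-level
  annotation is out of scope.
* Exact-match masking cannot find diverged rDNA copies; that is a repeat
  discovery problem, not a reference-construction one.
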