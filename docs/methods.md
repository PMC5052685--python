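# Methods

## The analysis model

`parclipkit` treats a PAR-CLIP experiment as a marked point process on
transcript coordinates. Reads are intervals on a transcript's sense strand;
a read may carry substitutions, of which T→C is the diagnostic crosslink
signature (4-thiouridine at a protein-contact position reverse-transcribes
as C). Everything downstream is built from three measurable quantities per
position: read depth, the number of distinct reads recording a T→C there,
and the number recording any other substitution. Coordinates are 0-based
half-open throughout; U and T are identified and sequences upper-cased on
ingestion.

### Binding-site calling

Reads on a transcript are grouped into *clusters* — maximal unions of reads
sharing ≥ 1 nt (half-open intervals that merely touch do not overlap and
stay separate). Within a cluster two read-weighted kernel density estimates
are formed on the integer positions of the cluster span, with a Gaussian
kernel of bandwidth 3 nt: one over T→C event positions, one over covered
reference-T positions where the covering read did *not* convert. Both
densities are **normalized to unit mass** and a site is each maximal run
where the conversion density exceeds the non-conversion density, padded
symmetrically to a minimum length of 8 nt, clipped to the cluster, and
required to retain ≥ 2 distinct conversion-carrying reads.

The normalization is the load-bearing choice. At a per-read conversion
probability of 0.2, four of five covering reads leave a crosslinked uridine
unconverted, so raw (unnormalized) event densities would place the
non-conversion curve above the conversion curve at every position and no
site could ever be called. What distinguishes a crosslink site is not that
conversions outnumber non-conversions locally, but that the conversion
*distribution* concentrates where the protein sat while the non-conversion
distribution spreads over every uridine the read population covered; the
unit-mass comparison asks exactly that. Degenerate situations behave
correctly under this rule: a cluster with no conversions yields no sites,
and a fully converted cluster (non-conversion mass zero) yields one site
spanning essentially the whole cluster.

Sites are annotated to the region (5′UTR / CDS / 3′UTR) of maximal overlap,
ties broken CDS > 3′UTR > 5′UTR; non-mRNA biotypes are "noncoding".
Replicate reproducibility requires ≥ 1 nt of shared sequence between a
replicate-1 and replicate-2 site on the same transcript.

### Target ranking and filtering

A transcript's evidence in a replicate is the number of *distinct* reads
carrying ≥ 1 T→C that overlap any reproducible site of that transcript
(read-level, not event-level, counting; an `all-reads` mode that drops the
site restriction is available). A transcript passes the target filter when
every replicate contributes ≥ 4 such reads; ranking is by the summed count
over replicates, descending, ties broken lexicographically so the ranking
is total and reproducible under input shuffling.

### Metagene profiles

Site midpoints are mapped to fractional positions within their annotated
region and histogrammed (default 20 bins, normalized to sum 1 per region);
a parallel profile restricted to high-support sites (≥ 20 conversion reads)
mirrors the usual low/high read-support split. Empty regions yield all-zero
profiles and are flagged rather than erroring.

### Motif discovery

K-mer spectra are computed in sliding windows (default k = 4, window =
20 nt, step 1): per-window k-mer frequencies are averaged uniformly over
all windows pooled across sequences, so interior k-mers of long sequences
are up-weighted exactly as often as they appear in windows, and the
spectrum sums to 1. Backgrounds are ensembles of composition-preserving
shuffles of coding sequence — mononucleotide permutations by default, or
exact dinucleotide-preserving shuffles via the Eulerian-path
(Altschul–Erickson) construction. Enrichment per k-mer is the z-score of
the observed frequency against the empirical mean and sd over shuffles,
plus the observed/mean ratio; a zero background sd is flagged and reported
as z = +∞ (observed above mean) or 0. The top k-mers (default 2) collapse
position-wise to the minimal IUPAC code covering the union of observed
bases.

Tandem arrangement is quantified by counting pairs of motif matches whose
second match starts exactly (motif length + s) after the first, for each
spacer s in [0, 8]; overlapping matches are allowed and pairs are counted
left to right. Background pair counts from each shuffle are rescaled to
the foreground's total sequence length before the z-score, so a
shuffled-ORF background of different size is comparable with the
binding-site foreground.

### Differential secretion

Intensities are median-normalized (each sample scaled so its median equals
the grand median of pre-normalization sample medians), log2-transformed
(nonpositive values become missing), and tested with the moderated
statistic d = (mean_A − mean_B)/(s + s0), where s is the pooled two-sample
standard error computed pairwise over observed values and s0 = 0.5 damps
small-variance proteins. The null distribution comes from group-label
permutations (all 70 distinct assignments for a 4-vs-4 design, otherwise
250 sampled without replacement); the FDR at a cutoff c is the median
permuted count of |d| ≥ c divided by the observed count, and the threshold
is the smallest qualifying cutoff at the 1% target. Missing values are
ignored pairwise (no imputation); constant proteins get d = 0 by
convention. The procedure is a re-implementation in the spirit of the
classic microarray significance analysis and is not bit-compatible with
spreadsheet implementations of the same idea.

### Stratification, ECDFs, correlation

Genes with abundance ≥ 2 (FPKM-like floor) are partitioned into the
top-100 targets by crosslink rank, the remaining filter-passing targets
("poor"), and expressed never-captured genes ("non"). Strata are compared
by ECDF, per-stratum median, and two-sample Kolmogorov–Smirnov tests of
top-vs-non and poor-vs-non (identical samples report KS = 0, p = 1 by
convention; strata under 3 members report an undefined p and are flagged).
The binding–regulation relation is the Pearson correlation of secretion
log2 fold change with log10(1 + crosslink reads); zero variance in either
vector is an error rather than a silent NaN.

## The synthetic study

The generator is a pure function of (config, seed, replicate): identical
seeds give bit-identical outputs, with independent substreams for the
transcriptome, each read replicate, the expression table and the secretome.

Defaults (the study conditions): 1,000 transcripts of 120/900/240 nt
(5′UTR/CDS/3′UTR) at uniform base composition; 30% targets, each with 2
non-overlapping tandem `CUUC + N5 + CACC` windows written at random CDS
positions (degenerate motif configs are instantiated uniformly over their
expansions). Non-target CDS windows matching the planted tandem by chance
are rejection-resampled; chance single motif matches elsewhere are left in,
as in real transcriptomes. Reads: Normal(32, 6) nt truncated to [20, 50]
(the ≥ 20 nt mappability regime); per planted site Poisson(30) reads
covering the interval midpoint with per-uridine conversion probability 0.2
inside the interval; background Poisson(1 read/kb) per transcript with
conversion probability 0.2/20 — a background error rate chosen so that
replicate filtering is non-trivial, since no empirical background model is
available at desk scale. Expression: per-gene FPKM-like abundance
log-normal(ln 8, 1.2), expected counts = abundance × 50, negative-binomial
sampling at dispersion 0.05 in both conditions, observed log2fc =
log2((b+0.5)/(a+0.5)); targets have true fold change exactly 0. Secretome:
base log2 intensities Normal(25, 2); knockdown shift =
−0.5·log10(1 + reads) for targets plus per-protein effect noise
Normal(0, 0.2) applied to *every* protein (knockdown response noise is not
target-specific; this also makes target and non-target shifts
indistinguishable in the slope-0 limit, as they must be); within-group
replicate noise 0.2 log2 units (CV ≈ 15%, typical of secreted-protein
LFQ), 4 samples per group. Crosslink-read counts used for the secretome
stage follow a log-normal with σ = 2 in natural log (≈ 2 decades of
spread), matching the orders-of-magnitude range of real per-target
crosslink counts. PAR-CLIP library depth has no published desk-scale
anchor; the read defaults are chosen for test power, not realism.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels and non-substitution sequencing errors,
PCR duplication structure, intron/genome space and antisense mapping,
transcript-length and composition heterogeneity, LFQ missingness (the
missing-value code paths are tested, but the default generator produces
complete matrices), protein inference ambiguity, and any RNA secondary
structure contribution to binding (recognition here is purely sequence
density; real binding additionally needs backbone context, e.g. the known
≥ 18 nt length requirement for in-vitro shifts).

## Numerical and design choices

- KDE bandwidth 3 nt, evaluated at integer positions with the kernel
  truncated at 4σ; exposed as a parameter since no canonical value exists.
- Minimum site length 8 nt and minimum cluster membership 5 reads are
  engineering defaults, both parameterized.
- "Crosslinked reads" are counted as distinct reads, not conversion
  events, and restricted to reproducible sites by default; both choices
  are exposed (`site_restricted=False` gives the all-reads mode). The
  top-100 stratum is per transcript.
- Shuffle count for backgrounds defaults to 200 in the pipeline
  configuration: the empirical sd across shuffles stabilizes well below
  that at the background sizes used here, and the parameter scales up
  freely.
- The IUPAC collapse is the *minimal* code per position: a column whose
  observed bases are {C, U} is Y, never the broader H.
- Permutation seeds, shuffle seeds and generator seeds all derive from one
  configured seed; no stage reads clocks or other environment entropy.
- Test and acceptance problem sizes (300–1,000 transcripts, 10–50 seeds
  per stochastic property, 100 background shuffles) are the package's
  chosen working scale: large enough that every recovery property is
  measured with tight Monte-Carlo error, small enough that the whole suite
  runs in well under a minute per property.

## Known limitations

- The site caller assumes substitution-only alignments (M-only CIGARs);
  spliced or clipped alignments are out of scope.
- Median normalization assumes most proteins unchanged; when half the
  proteome shifts (as in the aggressive synthetic defaults) strata are
  ordered correctly but not anchored at zero.
- The permutation FDR is conservative (no π₀ correction); with 4-vs-4
  designs only 70 distinct permutations exist, which quantizes attainable
  FDR estimates.
- Gene-level collapsing of transcripts is a thin option; the synthetic
  data is one-transcript-per-gene, so isoform aggregation is untested
  against truth.
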