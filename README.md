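# parclipkit

Identification of an RNA-binding protein's mRNA targets from PAR-CLIP
crosslinking data, and integration of those targets with transcriptome and
secretome quantification.

PAR-CLIP (photoactivatable-ribonucleoside-enhanced crosslinking and
immunoprecipitation) marks protein-bound RNA positions as T→C conversions
introduced during reverse transcription of 4-thiouridine-labelled,
UV-crosslinked RNA. `parclipkit` provides the full desk-side analysis chain
for such an experiment, exercised end-to-end on synthetic data with known
ground truth:

1. **Site calling** — overlapping reads are grouped into clusters; within a
   cluster the read-weighted Gaussian kernel density of T→C events,
   normalized to unit mass, is compared with the normalized density of
   covered-but-unconverted reference Ts. A *binding site* is each maximal
   run where the conversion likelihood exceeds the non-conversion
   likelihood, with ≥ 2 distinct conversion-carrying reads. Sites must
   overlap (≥ 1 nt) between two biological replicates; transcripts are
   *targets* if they carry ≥ 4 T→C crosslinked reads in both replicates,
   and are ranked by the summed conversion-read count.
2. **Motif discovery** — 4-mer frequencies inside binding-site sequences,
   averaged over sliding 20-nt windows, are z-scored against
   composition-preserving shuffles of coding sequence; top k-mers collapse
   to a degenerate IUPAC element (e.g. CHHC, with H = A/C/U), and tandem
   pairs of the element are counted at each spacer length 0–8 nt.
3. **Quantitative integration** — label-free (LFQ) secretome intensities
   are median-normalized and tested with a SAM-style moderated statistic
   `d_i = (mean_A − mean_B) / (s_i + s0)` (fudge factor `s0 = 0.5`, 250
   label permutations, FDR 0.01 estimated as median permuted exceedances
   over observed exceedances); genes are stratified into top-100 / poor /
   non-targets by crosslink rank, their fold-change ECDFs compared by
   Kolmogorov–Smirnov, and secretion change is correlated with
   `log10(1 + crosslink reads)` (Pearson).
4. **Synthetic data** — a generator plants tandem `CUUC–N5–CACC` elements
   into the CDS of a configurable fraction of transcripts, simulates
   two-replicate reads whose conversions concentrate there, and produces
   mRNA count tables (targets unchanged) and secretome matrices (targets
   down-regulated proportionally to crosslink reads), so every stage has a
   parameter-recovery test.

## Worked example

```sh
python examples/02_call_binding_sites.py
```

```
replicate 1: 120 sites, replicate 2: 120
reproducible sites (>=1 nt overlap in both): 120
precision 1.000  recall 1.000 vs planted intervals
targets with >=4 conversion reads in both replicates: 60
top-ranked target: TX00126 with 81 conversion reads
```

All 120 planted tandem-element intervals in the 60 target transcripts are
recovered as reproducible binding sites with no false calls, and the ≥4-in-
both-replicates filter captures exactly the planted target set; the top
target is simply the transcript that drew the most conversion-carrying
reads. `examples/03_discover_motif.py` continues the chain (CTTC and CACC
are the two most-enriched 4-mers, z ≈ 330 and 313; their collapse scans as
a CU-rich degenerate element whose tandem arrangement peaks at the planted
5-nt spacer), and `examples/04_differential_secretion.py` shows the
integration stage (Pearson r ≈ −0.83 between secretion log2 fold change and
log10 crosslink reads; strata medians ordered top < poor < non).

The same chain is available as a CLI producing a reproducible report
directory (identical config + seed ⇒ byte-identical tables):

```sh
parclipkit all --seed 3 --outdir run/        # simulate → sites → motif → integrate
parclipkit --show-defaults                   # full default configuration (YAML)
```

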