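# clonoscope

Clonal genomic-instability analysis for single-cell-derived tumour
organoids, bundled with a synthetic clonal-evolution simulator so the whole
pipeline runs end-to-end without any external data.

The package covers the downstream analyses of an exome study of mouse
colorectal tumours driven by up to three driver genes (Apc / Kras / Tp53):

* **`genome`** — toy reference builder: chromosome sequences with
  controllable CpG depletion, gene models (BED12), replication-timing
  domains (BED), and the 32-class pyrimidine-collapsed triplet census.
* **`sim`** — clonal-evolution simulator: time-constant Poisson
  substitution accrual (independent of driver genotype), Tp53-gated copy
  number events, signature-1-like / signature-17-like / uniform context
  mixtures, organoid sampling (binomial reads, VAF ≈ 0.5 for heterozygous
  copy-neutral variants) and purity-diluted bulk-biopsy sampling.
* **`variants`** — variant containers, consequence annotation
  (missense / nonsense / synonymous / splice-site / noncoding), tiered
  presence calling, minimal VCF 4.2 and TSV I/O.
* **`clonality`** — samples × variants presence matrix,
  trunk / semi-private / private sharing classification over organoids, and
  metastasis seeding-event counting.
* **`signatures`** — 96-context spectra, triplet-prevalence normalization,
  and non-negative decomposition against fixed reference profiles.
* **`genesize`** — Monte-Carlo test for substitution enrichment in large
  genes (1e6 reps by default), exact binomial-tail oracle, Obs/Exp ratios.
* **`cna`** — depth-ratio computation, recursive binary change-point
  segmentation with boundary refinement, panel-of-normals filtering,
  large-scale (>10 Mb-equivalent) flagging, targeted-locus recombination
  status, and Tp53–CNA association (Fisher exact).
* **`phylo`** — perfect-phylogeny reconstruction (laminar-family test,
  greedy conflict exclusion, Hasse-diagram tree), Newick I/O with edge
  character annotations.
* **`rates`** — burden-vs-age regression, doubling-time formula,
  replication-timing / territory stratification, multi-group t tests with
  Benjamini–Hochberg correction.
* **`pipeline` / `cli`** — one-config orchestration of
  simulate → analyze → report.

## CLI

```sh
# simulate the default four-tumour cohort (2/10/20/25 weeks; Tp53
# inactivated only in the two late tumours)
clonoscope simulate --seed 1 --out dataset/

# run every analysis stage; writes report.json, TSV tables, Newick trees
clonoscope analyze dataset/ --out report/

# run the bundled worked examples (two-organoid tumour: 14 shared/8
# private; metastatic tumour: 4 truncal SNSs, 3 trunk branches, 3 seeding
# events, 2 unplaceable characters)
clonoscope examples --out examples/
```

`clonoscope simulate` emits the genome as FASTA, gene models as BED12,
timing domains as BED, per-sample calls as VCF + TSV, depth bins as TSV,
and the true clone trees as JSON + Newick for recovery testing. Re-running
with the same config is byte-identical.

## Conventions

* Coordinates are 0-based half-open everywhere internally; VCF output is
  1-based.
* Substitution contexts are collapsed to the pyrimidine strand at census
  and spectrum time; the fixed 96-class order is substitution-type major
  (C>A, C>G, C>T, T>A, T>C, T>G), then 5′ flank, then 3′ flank, each in
  A,C,G,T order (labels like `A[C>T]G`).
* The ">10 Mb" large-scale CNA threshold is scaled onto the toy genome via
  `genome_scale` = mean chromosome length / 100 Mb.
* Presence tiers default to <10 % low, 10–20 % mid, ≥20 % high with ≥3 alt
  reads; all thresholds are configurable.
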