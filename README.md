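# ribobuffer

Integration of mRNA abundance, ribosome occupancy and protein abundance
across pluripotency states, on fully synthetic data with planted ground
truth.

## The problem

In mouse embryonic stem cells, the transition from the naïve ground state
(2iL: GSK3 inhibitor + MEK inhibitor + LIF) through serum/LIF (SL) to the
primed epiblast-like state (EPI) rewires gene expression at three layers:
transcript abundance (RNA-seq), translation (ribosome profiling) and
protein abundance (label-free proteomics). Two questions drive the
analysis:

1. **Which mRNAs change translation efficiency between states?**
   Translation efficiency (TE) for gene *g* is the ratio of normalized
   ribosome-footprint (RFP) to normalized mRNA abundance,
   `TE_g = RFP_g / RNA_g`, and the quantity tested between conditions is
   `Δlog₂TE = log₂FC(RFP) − log₂FC(RNA)`.
2. **Do TE changes propagate to protein?** Frequently they do not:
   *translational buffering* — an mRNA change compensated by an opposite TE
   change — keeps protein output constant. Where protein *does* change, the
   change can be decomposed into transcriptional (RNA-driven),
   translational (RFP-driven at stable RNA) and post-translational (stable
   RNA and RFP) modes by fold-change rules.

Because the questions span three noisy layers with different replicate
structure, missingness mechanisms and filters, this package pairs every
statistical step with a generative model: a synthetic cohort in which
every gene carries a known regulatory mode, so each pipeline stage can be
validated by parameter recovery rather than by eyeballing.

## What is in the box

| module | role |
| --- | --- |
| `ribobuffer.synthdata` | synthetic cohort generator: NB counts (var = μ + φμ²), censored log-normal proteome, structured transcripts with plantable AU-rich elements, footprints with fixed P-site geometry |
| `ribobuffer.riboqc` | P-site offset histograms, 10-nt-bin metagene coverage, union-mode CDS counting |
| `ribobuffer.diffte` | CPM / median-of-ratios normalization, 50/25 expression filters, delta-method z-test on Δlog₂TE with a trended NB dispersion |
| `ribobuffer.proteo` | reproducibility filter, down-shifted normal imputation (width 0.3 σ, downshift 1.8 σ), t-test differential calling (FDR < 0.05, FC ≥ 3), state-exclusive detection |
| `ribobuffer.integrate` | RNA–RFP–protein triplets, regulatory-mode classifier, buffering detector, inhibitor-withdrawal classes (CP/2i/P/C), layer correlations |
| `ribobuffer.seqfeat` | UTR composition, exact ARE scan (UAUUUAU), PWM scanning, rank-sum comparisons |
| `ribobuffer.setstats` | exact hypergeometric tails (log-space), Benjamini–Hochberg, GMT gene-set enrichment |
| `ribobuffer.pipeline` / `ribobuffer.cli` | one-config orchestration and a thin `ribobuffer` CLI |

The `analysis/` directory holds the numbered drivers that run the study
end to end and write their tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_riboseq_qc.py
python analysis/03_differential_te.py
python analysis/04_proteomics.py
python analysis/05_integrate_layers.py
python analysis/06_utr_motif_enrichment.py
```

Selected output (seed 1, 2000 genes):

```
modal P-site offset(s): [-12] nt (7261 reads within +/-30 nt of a TIS)
SL vs 2iL: 328 of 1903 tested genes called differential TE; planted-shift recovery 99.7%
set partition: SL_only=31, EPI_only=35, common=297
SL vs 2iL: 449 differential proteins (FDR<0.05, FC>=3)
SL vs 2iL: 1782 uniquely assigned triplets; 428 protein-differential genes decompose as
  transcriptional=73.6%, post_translational=17.8%, translational=8.6%
  planted-mode recovery: 99.5% (n=428); buffered genes detected: 262
  correlations: r(RNA,RFP)=0.78, r(dTE,protein)=0.12
withdrawal classes over 472 differential proteins: {'CP': 309, '2i': 64, 'C': 51, 'P': 48}
ARE (UAUUUAU) present in 93/166 query 3'UTRs (56%) vs 656/1903 in background (34%);
  hypergeometric p = 2.16e-09
```

Reading this: the footprint library behaves like real ribosome-protected
fragments (5′ ends peak 12 nt upstream of the P-site codon); roughly 17%
of tested genes change TE between states, and most of those are
*buffered* — their protein stays within 2-fold because TE moved against
RNA. Where protein does change, ~74% of changes are transcriptional, ~9%
translational and ~18% post-translational, and the change-vs-change
correlation structure shows the same signature as the biological setting
being emulated: RNA and RFP fold changes track each other (r ≈ 0.78)
while TE changes are uncoupled from protein changes (r ≈ 0.12). The
3′UTRs of mRNAs translated more efficiently in the ground state are
enriched for the AU-rich element UAUUUAU.

The same pipeline runs from a single config:

```sh
ribobuffer run --out results/run --seed 1
```

## Scope notes

The package consumes transcript-coordinate alignments and intensity
matrices; read alignment, contaminant depletion and database search are
upstream of it. The differential-TE test is a documented surrogate (a
delta-method z-test with trended dispersion), not a reimplementation of
any published tool's internals. See `docs/methods.md` for the model,
parameter defaults and known limitations.
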