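# Methods

## The generative model

The synthetic cohort is the backbone of every validation in this package.
Each gene receives a regulatory mode with planted log2 effect sizes
(condition vs the 2iL reference):

| mode | RNA shift | TE shift | protein shift | default fraction | default \|shift\| |
| --- | --- | --- | --- | --- | --- |
| transcriptional | s | 0 | s | 0.20 | 2.0 |
| translational | 0 | s | s | 0.02 | 2.0 |
| buffered | s | −s | 0 | 0.13 | 1.5 |
| post_translational | 0 | 0 | s | 0.05 | 2.0 |
| null | 0 | 0 | 0 | 0.60 | — |

Signs are random per gene. The fractions were fixed once, at design time,
so that (a) the protein-differential subset decomposes approximately
74% / 7% / 19% into transcriptional / translational / post-translational —
the regime reported for naïve-to-primed ESC transitions, where
transcription dominates protein change — and (b) buffered genes dominate
the differential-TE set, reproducing the qualitative correlation
signature (RNA–RFP fold changes strongly correlated; ΔTE–protein
essentially uncorrelated). Mode counts use largest-remainder rounding, so
composition is exact and deterministic.

**Counts.** RNA counts are negative binomial with var = μ + φμ²
(Gamma–Poisson mixture; φ = 0 degenerates to Poisson). The expected
relative abundance of gene *g* is 2^(base + rna_shift·I[condition ≠ ref]),
scaled so each library's expected total equals its depth (default 5×10⁶
per sample, 2 replicates per condition). RFP means multiply in
2^(te_shift·I)·rfp_scale. Default dispersion is φ = 0.02, the regime of
highly similar isogenic culture replicates; at 2 replicates this is also
the regime in which a 1.5-log2 buffering shift is detectable with the
power the recovery checks require — a design constraint verified by the
delta-method power calculation se ≈ (1/ln 2)·√(2φ) before any data were
drawn. The type-I-error calibration check deliberately uses a harsher
φ = 0.05.

**Proteome.** log2 intensity = base + protein_shift·I + N(0, σ), σ = 0.25,
3 replicates per condition. Missingness is left-censored and
missing-not-at-random: within each sample, cells below the 10% intensity
quantile drop out with probability 0.8. Five percent of protein groups
map to two genes, to exercise the unique-assignment filter. Withdrawal
cultures (CHL = MEK inhibitor withdrawn, PDL = GSK3 inhibitor withdrawn)
receive each gene's protein shift only if its planted withdrawal class
(CP / 2i / P / C, apportioned 0.6 / 0.2 / 0.1 / 0.1 to mirror the
dominance of the both-inhibitors-required class) responds in that
culture.

**Transcripts and footprints.** Transcripts have structured
5′UTR/CDS/3′UTR (defaults 60–200 / 300–1800 / 150–600 nt); CDS starts
with AUG, ends with a stop, contains no internal in-frame stop. 3′UTR AU
content defaults to 0.60; genes flagged `has_are` get one UAUUUAU
heptamer planted at a random 3′UTR position (60% of buffered genes, 25%
background). Note the generator plants *motifs*, not elevated bulk AU
content, so composition contrasts between planted and background sets are
null by construction — a deliberate separation that lets the enrichment
test be validated independently of composition. Footprints are 28–32 nt,
placed with their 5′ end 12 nt upstream of the decoded codon. The decoded
codon is the start codon with probability 0.10 (the initiation pause seen
in real libraries — without it, uniform elongation would produce a
3-nt comb with no unique mode near the TIS) and otherwise uniform over
CDS codons; 3% of reads land in UTRs as background.

## Statistical procedures

**Differential TE.** After CPM normalization, genes must exceed 50
normalized RNA reads and 25 normalized RFP reads in every replicate of at
least one compared condition (strict inequalities) and have mean raw
counts ≥ 50 in both layers. The test statistic is z = ΔlogTE/se with
Var(log₂ μ̂) ≈ (1/ln 2)²(1/μ + φ(μ))/n per layer and condition, summed
over the four terms. φ(μ) is a mean–dispersion trend: per-gene
method-of-moments estimates (s² − m)/m², averaged within ~20 log-mean
quantile bins and monotonised non-increasing by pool-adjacent-violators.
The bin aggregate is the *mean*, not the median — with 2 replicates the
per-gene estimate has one degree of freedom and its median is biased low
by more than a factor of two, which makes the test anticonservative.
Dispersion is estimated on raw counts, which assumes near-equal library
depths within a comparison (true of the default design). Calls require
BH FDR < 0.1 and fold change > 1.5. p-values come from the normal
distribution; with 2 replicates the trend, not the per-gene sample
variance, carries the uncertainty, which is what keeps the null
calibration near nominal.

**Proteomics.** The Perseus-style sequence: keep proteins with ≥ 3 valid
values in at least one condition; impute per sample from
Normal(μ̂ − 1.8σ̂, (0.3σ̂)²); Student's t (pooled variance; Welch
available), BH, called at FDR < 0.05 and FC ≥ 3. Imputation statistics
are computed per sample column, and each sample's draw stream is keyed by
(seed, sample name), so adding samples never perturbs existing draws.
Whether the original workflow's FDR was BH or permutation-based is not
documented; BH is used here.

**Integration.** Triplets keep only genes uniquely assigned to one
protein group and quantified in all layers. The mode classifier follows
the fold-change rules (protein > 3×; RNA > 2× ⇒ transcriptional;
RFP > 2× at RNA < 2× ⇒ translational; both < 2× ⇒ post-translational)
with two deliberate extensions: a sign-concordance requirement between
the driving layer and protein (so a protein increase is never attributed
to a transcript decrease) and an explicit `unclassified` bucket, making
the four labels a partition. Buffering requires a significant TE call
whose sign opposes a non-zero RNA change with protein inside 2-fold —
opposite signs alone are not enough. Withdrawal classes are a pure truth
table over "responds" (significant, > 2-fold, steady-state-directed
change) in the two single-inhibitor cultures.

**Set statistics.** The hypergeometric upper tail P(X ≥ k) is an exact
log-space summation (lgamma), inclusive of k; term sets are intersected
with the universe before testing. BH is the standard step-up. The
rank-sum comparison enumerates all label assignments exactly when
n₁ + n₂ ≤ 12 (two-sided via the symmetric-deviation criterion
P(|U − mn/2| ≥ |u − mn/2|), valid under ties), and otherwise uses the
tie-corrected normal approximation.

**PWM scanning** scores log₂ odds against the background at every
position; a hit requires ≥ 0.9 × the motif's maximum achievable log-odds.
That relative-score semantics is a documented choice — the threshold
conventions of scanning tools differ and are rarely specified precisely.

## Numerical and interface choices

* One global seed; every consumer derives a named substream via
  CRC32-keyed `SeedSequence`, so outputs are reproducible and insensitive
  to the order in which stages run.
* Offset sign convention: negative = upstream of the TIS; the TIS is
  position 0, the first nucleotide of AUG. Modal offsets report *all*
  ties, ascending.
* Metagene bins anchor at the TIS (5′ flank and CDS) and the stop codon
  (3′ flank); a final partial bin is normalized by its true width.
* Pseudocount 0.5 CPM in fold-change computation avoids ±∞ at zero
  counts; at the fixture's expression levels its effect on Δlog₂TE is
  < 10⁻³.
* BH runs only across genes that passed the expression filters.
* The union-mode counter accepts several genes' CDS intervals on one
  transcript; reads overlapping more than one CDS are discarded.

## Problem sizes

The default fixture is 2000 genes, 2 RNA/RFP replicates and 3 protein
replicates per condition, 5×10⁶ reads depth, 5×10⁴ footprints; the
calibration simulations use 5000 (null) and 3000 (power) genes. These
sizes make every distributional property measurable (hundreds of genes
per planted class) while the full suite and drivers run in well under a
minute each.

## What passing tests do and do not show

The generator draws independent genes with identical dispersion, no
isoform structure, no sequencing-error model, no correlated replicates
and no batch effects; transcripts are single-isoform with idealized
headers. Recovery rates measured here are therefore upper bounds on what
the same procedures achieve on real libraries, where dispersion varies
per gene, protein groups share peptides, and UTR annotation is imperfect.
The surrogate TE test is calibrated under the NB model it assumes; it is
not a reimplementation of published posterior-based tools, and its
p-values on real data would inherit any NB misfit. Inhibitor-withdrawal
classes assume the steady-state direction is estimable from the SL
comparison (EPI as fallback), and genome-space concerns (strandedness,
multimapping) are out of scope because inputs are transcript-coordinate
alignments.
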