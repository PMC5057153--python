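# Methods

## Model and procedure

The pipeline asks whether a stimulus regulates transcription by broadly
accelerating *initiation* (more paused Pol II at promoters) or by selectively
releasing *elongation* (more Pol II across whole gene bodies, with more
mRNA). Its observables are per-base Pol II ChIP coverage and gene-level
RNA-seq counts; its unit of analysis is the annotated gene body, a single
strand-aware interval from TSS to EAG (isoform structure is deliberately
ignored — occupancy is a gene-body quantity).

Stages:

1. **Quantification.** RNA counts → TPM (`rate = count/length`, scaled so
   each sample sums to 10⁶). ChIP coverage → summed depth over full body,
   PPR (first `ppr_len` = 400 bp from the TSS, strand-aware) and beyond-PPR,
   with `full = ppr + beyond` by construction. Metagene profiles average
   depth over a 1000 bp upstream flank (per-bp), the body rescaled to 100
   bins (equal genomic sub-intervals, floor partition; minus-strand genes
   are reversed base-wise *before* binning), and a 1000 bp downstream flank.
2. **Differential statistics.** Effects are `log2(treated/vehicle)` of
   normalized values with pseudocount 0.5. RNA: Welch two-sample t on
   log2(TPM+0.5), effect = difference of group means (9 vs 9). ChIP: paired
   one-sample t on the per-pair log2 ratios (3 pairs); an unpaired variant
   is available (`paired=False`) since either could be defended for the
   study design. The fold-change gate is empirical: per control:control
   sample pair, take the SD across genes of per-gene log2 ratios; `SE^cc` is
   the median pair SD and the gate is `2 × SE^cc`. Calls use strict
   inequalities and require both gates.
3. **Integration.** RNA call × beyond-PPR ChIP call, with the PPR call as a
   tiebreaker class: same-direction agreement ⇒ net transcriptional
   regulation; RNA-only ⇒ post-transcriptional candidate; ChIP-only ⇒
   occupancy change without mRNA change; PPR-up with flat beyond-PPR ⇒ the
   initiation-only (paused) archetype. The scatter axis for net-regulation
   calls is always the beyond-PPR effect; the full-body effect is carried in
   separate columns and never conflated (the two answer different
   questions).
4. **Sequence features.** ARE scan of 3′-UTRs, sense strand only (mRNA
   semantics), default pattern `[AT][AT]TTTATTTA[AT][AT]` (ATTTA core in an
   A/T-rich framework; a stricter overlapping-pentamer class `ATTTATTTA` is
   selectable — motif-database version ambiguity makes the class
   configurable). Enrichment of AREs among RNA-upregulated vs not-upregulated
   transcripts by exact hypergeometric test: one-sided is the enrichment
   tail, two-sided sums all tables with the fixed margins whose probability
   does not exceed the observed table's. smORFs: every in-frame ATG to the
   first in-frame stop (stop required) in the three forward frames, length
   10–100 codons (a common smORF convention) excluding the stop; nested ATGs
   each open their own candidate.
5. **Selectivity calculus.** Bits to specify M regulated genes of G:
   `log2(G/M)` (G defaults to 24 000 protein-coding genes); per-TF
   information `log2(G/M_TF)` with `M_TF` = 1000 typical target sites; the
   minimum factor count is `ceil(required/per_tf)`. Because a published
   lower bound of this kind can also be stated with the floor (2.09 bits
   ratio quoted as "at least two"), both `floor` and `ceil` are reported.
   Fold changes quoted as "approximately N-fold" use the integer part of
   the linear magnitude, matching how such ratios are conventionally
   truncated in print (2^4.52 = 22.9 → "≈22-fold"; 2^2.78 = 6.87 → "6.8").

## ChIP normalization — a deliberate default

The ChIP ratio analysis runs on **raw paired occupancy sums** by default,
treating each vehicle:treated pair as sequenced to matched depth (the
simulator's default). Library-size normalization (dividing by total depth
over all gene bodies) is implemented and selectable (`chip_normalize=True`)
but is *not* the default for a structural reason: when a majority of genes
gain promoter-proximal signal under treatment, the gene-body total itself
carries the treatment effect; dividing by it would drag every beyond-PPR
ratio negative and erase exactly the two-panel signature the analysis is
designed to expose (full-body median shifted up, beyond-PPR median ≈ 0).
RNA-seq needs no such care — TPM absorbs depth by construction, and the RNA
response is not global.

## The synthetic generator

`SimulationConfig` defaults are the study conditions: 2000 genes of
1500–4000 bp on two synthetic chromosomes with ≥2200 bp intergenic gaps
(room for metagene flanks); archetype mix 70% initiation-only, 2%
elongation-up, 1% elongation-down, 27% unresponsive; pause peak 10× the
gene-body baseline over the first 400 bp; treatment multiplies the PPR
component by 1.5 for every responsive (non-unresponsive) gene and the
whole-gene component by `2^effect` for elongation archetypes, with effects
drawn uniformly from ±[1.5, 3.0] log2 units and one designated extreme
responder fixed at +4.5 on both axes (so the "maximum responder on both
axes" property has a known answer). RNA expression is lognormal across genes
(ln-mean 5.3, ln-SD 1.0 — typical counts in the hundreds), multiplied by
`2^effect` for elongation archetypes only: the initiation-only response
produces no full-length transcripts and leaves mRNA untouched. Noise is
negative binomial (gamma-Poisson), per base for ChIP and per gene for RNA,
with a common overdispersion 0.02 — chosen so the empirical `2 × SE^cc` gate
lands around 0.6 log2 units, comfortably below the configured elongation
effects, mirroring the real analysis where the regulated genes cleared the
gate. Dispersion 0 short-circuits to the exact expectation so zero-noise
limits are exact. Protein-coding genes get 400 bp 3′-UTRs carrying an ARE
framework motif with probability 0.10 (independent of regulation status;
negatives are scrubbed of every stray ATTTA); five lncRNAs each embed one
ORF of 15–60 codons built from non-stop codons. Everything derives from
`(config, seed)` and is byte-reproducible.

What the generator does **not** emulate: read-level artifacts (fragment
length, GC bias, mappability), the 3′ coverage bias of oligo-dT priming,
upstream-promoter and downstream ChIP signal outside gene bodies,
correlated biological replicate structure, and any coupling between ARE
status and regulation. Passing recovery tests therefore show the estimators
are correct under the assumed signal model, not that the thresholds are
optimal for any particular real dataset.

## Numerical choices

* Pseudocount 0.5 before every log2 of a normalized quantity (zeros occur).
* Zero-variance t-tests: identical groups give `t = 0, P = 1`; a nonzero
  effect with zero SE gives `P = 0`.
* Genes ≤ 400 bp are counted entirely as PPR (`beyond = 0`) and excluded
  from beyond-PPR differential testing (no zero-denominator ratios).
* Expressed-gene filter: nonzero quantification in every sample of the
  assay; integration runs on the intersection of the assays' expressed sets.
* Genes shorter than the bin count are skipped (with a warning) in metagene
  profiles.
* Two-sided exact-test ties: a table is included if its probability is
  ≤ observed × (1 + 1e-9), so exactly tied tables (e.g. the transpose) are
  always included despite floating-point pmf evaluation.
* Ranking ties are broken lexicographically by gene id (determinism).
* No multiple-testing correction by default — the raw `P < 0.05` gate is
  paired with the empirical ratio gate; Benjamini–Hochberg is available
  (`diffstats.bh_adjust`).

## Problem sizes

The default synthetic experiment (2000 genes, 6 ChIP tracks of ~10 Mb
per-base coverage, 18 RNA samples) simulates and analyzes in well under a
minute on one core; unit tests use 40–600-gene configurations and 3–5 seeds
where sampling distributions are being checked.

## Known limitations

Single-interval gene models (no isoforms, no exon-aware RNA quantification);
strandless coverage only; the ARE pattern classes approximate a
motif-database definition whose exact published hierarchy is ambiguous;
ChIP paired-vs-unpaired testing defaults to paired without a way to decide
from data; the information calculus treats transcription-factor binding as
independent and equally informative, an idealization.
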