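# polpause

Integrated RNA-seq / RNA-polymerase-II ChIP-seq analysis that separates
**promoter-proximal (initiation) responses** from **selective control of
transcriptional elongation**.

## The problem

A hormone stimulus can change a transcriptome in two very different ways.
It can accelerate transcriptional *initiation* broadly — loading more Pol II
onto the promoter-proximal region (PPR, the first ~400 bp downstream of the
TSS) of most expressed genes, where the polymerase pauses — without producing
more full-length transcripts. Or it can release *elongation* selectively at a
handful of genes, raising Pol II occupancy across the whole gene body
together with the mRNA. Distinguishing the two requires looking at both
assays at once, and splitting ChIP occupancy at the +400 bp position:

* per gene and sample, Pol II occupancy is summed over the **full gene
  body**, the **PPR** (first 400 bp from the TSS, strand-aware), and
  **beyond the PPR**;
* RNA-seq counts are normalized to **TPM** (each column sums to 10⁶);
* per-gene effects are `log2(treated/vehicle)` with t-tests (Welch across the
  9+9 RNA replicates; paired across the 3 ChIP pairs), and a gene is called
  only if it clears **both** `P < 0.05` and an **empirical fold-change gate**
  `2 × SE^cc`, where `SE^cc` is the median across-gene SD of log2 ratios over
  control:control sample pairs;
* RNA and beyond-PPR ChIP calls are joined: agreement in direction is *net
  transcriptional regulation*; a PPR-only rise is *initiation with pausing*;
* the selectivity of the outcome is quantified in Shannon bits: specifying
  M regulated genes out of G requires `log2(G/M)` bits, and a transcription
  factor with M target sites conveys `log2(G/M)` bits, so single-gene
  selectivity (`log2(24000/1) ≈ 14.6` bits) needs several independent
  factors at ~4.5 bits each.

The package also scans 3′-UTRs for AU-rich elements (ATTTA-core motifs, with
an exact hypergeometric enrichment test) and long non-coding RNAs for small
open reading frames (smORFs).

A first-class synthetic-data generator (`polpause.synthetic_data`) emulates
the assumed signal structure — a 10× pause peak, a 1.5× PPR increase on the
majority of genes, a small elongation-regulated set, one designated extreme
responder, negative-binomial noise — with ground-truth labels, so every
estimator in the pipeline can be scored for parameter recovery.

## Worked example

```sh
polpause all --seed 7 --n-genes 400 --out demo_out
cat demo_out/summary.txt
```

prints (abridged):

```
expressed genes in integration: 400
rna calls: up=8 down=4 ns=388
chip_full calls: up=288 down=4 ns=108
chip_beyond calls: up=8 down=4 ns=388
rna ratio threshold (2 x SE_cc): 0.6234
median log2(dDAVP/vehicle), full gene body: 0.3358
median log2(dDAVP/vehicle), beyond PPR: 0.0007
joint classes: chip_only=280 none=108 transcription_down=4 transcription_up=8
max responder (rna): g0068; (chip beyond-PPR): g0068; single max responder: True
information: log2(24000/12) = 11.0 bits; per-TF 4.6 bits; min TFs ceil=3 floor=2
```

Reading it: 288 of 400 genes gained full-gene-body Pol II (the near-global
initiation response — median full-body log2 ratio +0.34), but only 12
changed beyond the PPR, and those 12 are exactly the genes whose mRNA also
moved (`transcription_up`/`down`). One gene (`g0068`, the simulator's
designated extreme responder) is the maximum responder on both axes.
Specifying those 12 genes out of 24 000 takes ~11 bits, i.e. at least three
typical transcription factors binding independently.

The same analysis runs on real inputs (GTF/BED12 annotation, bedGraph
coverage per ChIP sample, a TSV count table, a TSV design table, FASTA
sequences) via `Dataset.from_paths(...)` or the CLI stage subcommands.

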