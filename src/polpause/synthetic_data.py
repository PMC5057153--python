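"""Synthetic experiment generator with ground truth.

Emulates the statistical structure the analysis assumes: 9 vehicle + 9 dDAVP
RNA-seq replicates, 3 vehicle:dDAVP ChIP pairs, Pol II coverage dominated by
a promoter-proximal pause peak, a dDAVP promoter-proximal (initiation)
increase on the majority of genes, a small elongation-regulated set whose
occupancy rises across the whole gene body together with mRNA, one designated
extreme responder on both axes, 3'-UTRs with or without AU-rich elements, and
lncRNAs with embedded small ORFs.  Every gene carries a ground-truth
archetype label so downstream estimators can be scored for recovery.

Per-gene expected Pol II depth is a rectangular gene-body baseline plus a
rectangular pause peak over the first ``ppr_len`` bases downstream of the
TSS; realized per-base counts are negative binomial (gamma-Poisson) with a
common overdispersion, or exactly the expectation when the dispersion is 0.
RNA counts are negative binomial at the gene level around a lognormal
baseline.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_model import (CoverageTrack, ExperimentDesign, GeneModel, SequenceSet,
                           write_annotation_gtf, write_bedgraph, write_design,
                           write_fasta)

ARCHETYPES = ("initiation_only", "elongation_up", "elongation_down", "unresponsive")

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    The defaults reproduce the structure of the real study: ~2000 genes,
    70% with a promoter-proximal-only initiation response (ppr_effect 1.5 on
    a 10x pause peak), a handful of elongation-regulated genes whose effects
    comfortably exceed the empirical fold-change gate, one designated extreme
    responder fixed at +4.5 log2 units on both axes, 9+9 RNA replicates and
    3 ChIP pairs.
    """

    n_genes: int = 2000
    gene_length_range: Tuple[int, int] = (1500, 4000)
    archetype_fractions: Dict[str, float] = field(default_factory=lambda: {
        "initiation_only": 0.70,
        "elongation_up": 0.02,
        "elongation_down": 0.01,
        "unresponsive": 0.27,
    })
    ppr_effect: float = 1.5
    elongation_effect_range_log2: Tuple[float, float] = (1.5, 3.0)
    aqp2_like_effect_log2: float = 4.5
    pause_peak_height: float = 10.0
    noise_dispersion: float = 0.02
    n_rna_reps: int = 9
    n_chip_pairs: int = 3
    ppr_len: int = 400
    # ChIP gene-body baseline depth (lognormal across genes, natural-log scale)
    chip_baseline_ln_mean: float = 1.1
    chip_baseline_ln_sd: float = 0.5
    # ChIP pairs are taken as sequenced to matched depth; jitter is optional
    chip_library_jitter: float = 0.0
    # RNA baseline expression (lognormal, natural-log scale) and depth jitter
    rna_baseline_ln_mean: float = 5.3
    rna_baseline_ln_sd: float = 1.0
    rna_library_jitter: float = 0.05
    rna_library_factors: Optional[Sequence[float]] = None
    # sequences
    are_fraction: float = 0.10
    utr_length: int = 400
    n_lncrna: int = 5
    n_pseudogene: int = 20
    lncrna_length: int = 600
    smorf_codon_range: Tuple[int, int] = (15, 60)
    # layout
    n_chroms: int = 2
    intergenic_gap: int = 2200
    chrom_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_fractions.get(a, 0.0) for a in ARCHETYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1, got {total}")
        if set(self.archetype_fractions) - set(ARCHETYPES):
            raise ValueError("unknown archetype in fractions")
        if self.ppr_effect <= 0 or self.pause_peak_height <= 0:
            raise ValueError("effects must be positive in linear scale")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad gene_length_range")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.rna_library_factors is not None and \
                len(self.rna_library_factors) != 2 * self.n_rna_reps:
            raise ValueError("rna_library_factors must have one entry per RNA sample "
                             f"({2 * self.n_rna_reps})")


@dataclass
class GroundTruth:
    """Per-gene simulator truth used as the recovery oracle."""

    archetype: Dict[str, str]
    elongation_effect_log2: Dict[str, float]
    are_status: Dict[str, bool]
    smorfs: Dict[str, Tuple[int, int, int]]  # lncRNA id -> (frame, start, end)
    aqp2_like: Optional[str]

    def genes_of_archetype(self, name: str) -> List[str]:
        return sorted(g for g, a in self.archetype.items() if a == name)

    def to_json(self) -> str:
        return json.dumps({
            "archetype": self.archetype,
            "elongation_effect_log2": self.elongation_effect_log2,
            "are_status": self.are_status,
            "smorfs": {k: list(v) for k, v in self.smorfs.items()},
            "aqp2_like": self.aqp2_like,
        }, indent=1, sort_keys=True)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _scrub_pentamer(seq: str) -> str:
    """Remove every ATTTA occurrence (replace its final A with G)."""
    while "ATTTA" in seq:
        i = seq.index("ATTTA")
        seq = seq[:i + 4] + "G" + seq[i + 5:]
    return seq


def _are_motif(rng: np.random.Generator) -> str:
    ws = np.array(list("AT"))[rng.integers(0, 2, size=4)]
    return f"{ws[0]}{ws[1]}TTTATTTA{ws[2]}{ws[3]}"


def _sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = _random_dna(rng, 3)
        if codon not in _STOPS:
            return codon


def simulate_annotation(config: SimulationConfig) -> Tuple[List[GeneModel], SequenceSet, GroundTruth]:
    """Gene models on synthetic chromosomes, their sequences, and ground truth.

    Genes are non-overlapping with intergenic gaps wide enough for metagene
    flanks.  Each protein-coding gene gets a 3'-UTR containing an ARE motif
    iff its ground-truth label says so (and no stray ATTTA pentamer
    otherwise); each lncRNA carries one embedded ORF of known frame and span.
    """
    rng = _rng(config, 0)
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # archetypes: exact counts from the fractions, then shuffled
    counts = {a: int(round(config.archetype_fractions.get(a, 0.0) * n)) for a in ARCHETYPES}
    if config.archetype_fractions.get("elongation_up", 0) > 0 and counts["elongation_up"] == 0:
        counts["elongation_up"] = 1
    counts["unresponsive"] = n - sum(v for a, v in counts.items() if a != "unresponsive")
    if counts["unresponsive"] < 0:
        raise ValueError("archetype fractions leave no room for unresponsive genes")
    labels = np.array([a for a in ARCHETYPES for _ in range(counts[a])])
    rng.shuffle(labels)

    # biotypes: lncRNAs and pseudogenes are drawn outside the elongation set so
    # the designated extreme responder is always protein-coding
    gene_ids = [f"g{i:04d}" for i in range(n)]
    biotype = np.array(["protein_coding"] * n, dtype=object)
    non_elong = [i for i in range(n) if labels[i] not in ("elongation_up", "elongation_down")]
    special = rng.choice(non_elong, size=min(len(non_elong), config.n_lncrna + config.n_pseudogene),
                         replace=False)
    for j, i in enumerate(special):
        biotype[i] = "lncRNA" if j < config.n_lncrna else "pseudogene"

    # placement
    gap = config.intergenic_gap
    per_chrom = int(math.ceil(n / config.n_chroms))
    genes: List[GeneModel] = []
    for c in range(config.n_chroms):
        idx = range(c * per_chrom, min((c + 1) * per_chrom, n))
        pos = gap
        chrom = f"chrS{c + 1}"
        for i in idx:
            start, end = pos, pos + int(lengths[i])
            genes.append(GeneModel(gene_id=gene_ids[i], chrom=chrom, strand=str(strands[i]),
                                   start=start, end=end, biotype=str(biotype[i])))
            pos = end + gap
        if config.chrom_length is not None and pos > config.chrom_length:
            raise ValueError(
                f"genome too small: {chrom} needs {pos} bp but chrom_length is "
                f"{config.chrom_length}")

    # effects
    e_lo, e_hi = config.elongation_effect_range_log2
    effects: Dict[str, float] = {}
    for i, gid in enumerate(gene_ids):
        if labels[i] == "elongation_up":
            effects[gid] = float(rng.uniform(e_lo, e_hi))
        elif labels[i] == "elongation_down":
            effects[gid] = float(-rng.uniform(e_lo, e_hi))
        else:
            effects[gid] = 0.0
    up_ids = [gid for i, gid in enumerate(gene_ids) if labels[i] == "elongation_up"]
    aqp2_like = None
    if up_ids:
        aqp2_like = up_ids[int(rng.integers(0, len(up_ids)))]
        effects[aqp2_like] = config.aqp2_like_effect_log2

    # sequences + sequence-level truth
    seqs = SequenceSet()
    are_status: Dict[str, bool] = {}
    smorfs: Dict[str, Tuple[int, int, int]] = {}
    for i, gid in enumerate(gene_ids):
        if biotype[i] == "protein_coding":
            has_are = bool(rng.random() < config.are_fraction)
            utr = _scrub_pentamer(_random_dna(rng, config.utr_length))
            if has_are:
                motif = _are_motif(rng)
                at = int(rng.integers(0, len(utr) - len(motif) + 1))
                utr = utr[:at] + motif + utr[at + len(motif):]
            are_status[gid] = has_are
            seqs.add(gid, utr)
        elif biotype[i] == "lncRNA":
            k = int(rng.integers(config.smorf_codon_range[0], config.smorf_codon_range[1] + 1))
            orf = "ATG" + "".join(_sense_codon(rng) for _ in range(k - 1)) + \
                  str(np.array(_STOPS)[rng.integers(0, 3)])
            max_start = config.lncrna_length - len(orf)
            at = int(rng.integers(0, max(1, max_start)))
            body = _random_dna(rng, config.lncrna_length - len(orf))
            seq = body[:at] + orf + body[at:]
            smorfs[gid] = (at % 3, at, at + len(orf))
            seqs.add(gid, seq)

    truth = GroundTruth(archetype={gid: str(labels[i]) for i, gid in enumerate(gene_ids)},
                        elongation_effect_log2=effects, are_status=are_status,
                        smorfs=smorfs, aqp2_like=aqp2_like)
    return genes, seqs, truth


def simulate_design(config: SimulationConfig) -> ExperimentDesign:
    rows = []
    for i in range(config.n_rna_reps):
        rows.append((f"rna_vehicle_{i + 1}", "rna", "vehicle", pd.NA))
    for i in range(config.n_rna_reps):
        rows.append((f"rna_ddavp_{i + 1}", "rna", "ddavp", pd.NA))
    for i in range(config.n_chip_pairs):
        rows.append((f"chip_vehicle_{i + 1}", "chip", "vehicle", i + 1))
        rows.append((f"chip_ddavp_{i + 1}", "chip", "ddavp", i + 1))
    return ExperimentDesign(pd.DataFrame(rows, columns=["sample_id", "assay",
                                                        "condition", "pair_id"]))


def _expected_tracks(genes: Sequence[GeneModel], truth: GroundTruth,
                     config: SimulationConfig,
                     baselines: Mapping[str, float]) -> Dict[str, Dict[str, np.ndarray]]:
    """Expected per-base depth per condition, keyed condition -> chrom -> array."""
    sizes: Dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end + config.intergenic_gap)
    expected = {cond: {c: np.zeros(nc, dtype=np.float64) for c, nc in sizes.items()}
                for cond in ("vehicle", "ddavp")}
    for g in genes:
        b = baselines[g.gene_id]
        arch = truth.archetype[g.gene_id]
        ppr_len = min(config.ppr_len, g.length)
        if g.strand == "+":
            ppr = slice(g.start, g.start + ppr_len)
        else:
            ppr = slice(g.end - ppr_len, g.end)
        body = slice(g.start, g.end)

        veh = expected["vehicle"][g.chrom]
        veh[body] += b
        veh[ppr] += b * (config.pause_peak_height - 1.0)

        dd = expected["ddavp"][g.chrom]
        whole = 2.0 ** truth.elongation_effect_log2[g.gene_id] \
            if arch in ("elongation_up", "elongation_down") else 1.0
        ppr_factor = config.ppr_effect if arch != "unresponsive" else 1.0
        dd[body] += b * whole
        dd[ppr] += b * (config.pause_peak_height - 1.0) * whole * ppr_factor
    return expected


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with mean mu and
    variance mu + dispersion * mu^2; exactly mu when dispersion is 0."""
    if dispersion == 0:
        return mu.copy()
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam).astype(np.float64)


def simulate_polii_coverage(genes: Sequence[GeneModel], truth: GroundTruth,
                            config: SimulationConfig) -> Dict[str, CoverageTrack]:
    """Per-sample Pol II coverage tracks for the ChIP pairs.

    Expected depth: gene-body baseline (lognormal across genes) plus a pause
    peak of ``pause_peak_height`` x baseline over the promoter-proximal
    region; dDAVP multiplies the PPR component by ``ppr_effect`` for every
    responsive gene and the whole-gene component by 2^effect for elongation
    archetypes.  Per-base counts are negative binomial.
    """
    rng = _rng(config, 1)
    baselines = {g.gene_id: float(rng.lognormal(config.chip_baseline_ln_mean,
                                                config.chip_baseline_ln_sd))
                 for g in genes}
    expected = _expected_tracks(genes, truth, config, baselines)

    tracks: Dict[str, CoverageTrack] = {}
    for i in range(config.n_chip_pairs):
        for cond, label in (("vehicle", f"chip_vehicle_{i + 1}"),
                            ("ddavp", f"chip_ddavp_{i + 1}")):
            factor = float(rng.lognormal(0.0, config.chip_library_jitter)) \
                if config.chip_library_jitter > 0 else 1.0
            depths: Dict[str, np.ndarray] = {}
            for chrom, exp_arr in expected[cond].items():
                arr = np.zeros(exp_arr.size, dtype=np.float32)
                mask = exp_arr > 0
                arr[mask] = _nb_sample(rng, exp_arr[mask] * factor,
                                       config.noise_dispersion)
                depths[chrom] = arr
            track = CoverageTrack(depths)
            track.compute_library_size(genes)
            tracks[label] = track
    return tracks


def simulate_rna_counts(genes: Sequence[GeneModel], truth: GroundTruth,
                        config: SimulationConfig) -> pd.DataFrame:
    """Gene x sample RNA-seq count table (9 vehicle + 9 dDAVP replicates).

    Baseline expression is lognormal across genes; dDAVP multiplies
    expression by 2^effect for elongation archetypes only — the
    promoter-proximal initiation increase produces no full-length
    transcripts and leaves mRNA unchanged.  Counts scale with gene length
    and a per-sample library factor, with gene-level negative-binomial noise.
    """
    rng = _rng(config, 2)
    n = len(genes)
    expr = rng.lognormal(config.rna_baseline_ln_mean, config.rna_baseline_ln_sd, size=n)
    lengths = np.array([g.length for g in genes], dtype=float)
    effect = np.array([truth.elongation_effect_log2[g.gene_id]
                       if truth.archetype[g.gene_id] in ("elongation_up", "elongation_down")
                       else 0.0 for g in genes])

    samples = [f"rna_vehicle_{i + 1}" for i in range(config.n_rna_reps)] + \
              [f"rna_ddavp_{i + 1}" for i in range(config.n_rna_reps)]
    if config.rna_library_factors is not None:
        lib = np.asarray(config.rna_library_factors, dtype=float)
    elif config.rna_library_jitter > 0:
        lib = rng.lognormal(0.0, config.rna_library_jitter, size=len(samples))
    else:
        lib = np.ones(len(samples))

    base_mu = expr * lengths / 1000.0
    cols = {}
    for j, sample in enumerate(samples):
        mu = base_mu * lib[j]
        if sample.startswith("rna_ddavp"):
            mu = mu * 2.0 ** effect
        cols[sample] = _nb_sample(rng, mu, config.noise_dispersion)
    return pd.DataFrame(cols, index=[g.gene_id for g in genes])


@dataclass
class SimulatedExperiment:
    """One complete synthetic dataset plus its ground truth."""

    config: SimulationConfig
    genes: List[GeneModel]
    sequences: SequenceSet
    truth: GroundTruth
    design: ExperimentDesign
    chip_tracks: Dict[str, CoverageTrack]
    rna_counts: pd.DataFrame


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    genes, seqs, truth = simulate_annotation(config)
    design = simulate_design(config)
    tracks = simulate_polii_coverage(genes, truth, config)
    counts = simulate_rna_counts(genes, truth, config)
    return SimulatedExperiment(config=config, genes=genes, sequences=seqs,
                               truth=truth, design=design, chip_tracks=tracks,
                               rna_counts=counts)


def write_dataset(exp: SimulatedExperiment, outdir: str | Path) -> Dict[str, Path]:
    """Write the dataset in its interchange formats (GTF, FASTA, TSV, bedGraph,
    JSON ground truth); returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["annotation"] = outdir / "annotation.gtf"
    write_annotation_gtf(exp.genes, paths["annotation"])
    paths["sequences"] = outdir / "sequences.fa"
    write_fasta(exp.sequences, paths["sequences"])
    paths["design"] = outdir / "design.tsv"
    write_design(exp.design, paths["design"])
    paths["counts"] = outdir / "rna_counts.tsv"
    exp.rna_counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    for sample, track in exp.chip_tracks.items():
        p = outdir / f"{sample}.bedgraph"
        write_bedgraph(track, p)
        paths[sample] = p
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(exp.truth.to_json())
    return paths
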