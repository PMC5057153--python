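"""End-to-end orchestration: dataset -> quantification -> differential calls ->
integration -> sequence features -> selectivity report.

The ChIP ratio analysis runs on raw (depth-matched) paired occupancy sums by
default.  Dividing by the summed gene-body library size is available as an
option but is not the default: when a majority of genes gain promoter-proximal
signal under treatment, the gene-body total itself carries the treatment
effect, and normalizing by it would push every beyond-PPR ratio negative —
masking the very signature (full-body median shifted up, beyond-PPR median
~0) the analysis is designed to expose.  RNA-seq is normalized by TPM, which
is insensitive to per-sample depth by construction.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import diffstats, infotheory, integrate, quantify, seqfeatures
from .genome_model import (CoverageTrack, ExperimentDesign, GeneModel, SequenceSet,
                           load_annotation, load_coverage, load_design,
                           load_sequences)
from .synthetic_data import SimulatedExperiment, SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """The pipeline's in-memory inputs, however they were obtained."""

    genes: List[GeneModel]
    design: ExperimentDesign
    rna_counts: pd.DataFrame
    chip_tracks: Dict[str, CoverageTrack]
    sequences: Optional[SequenceSet] = None

    @classmethod
    def from_simulation(cls, exp: SimulatedExperiment) -> "Dataset":
        return cls(genes=exp.genes, design=exp.design, rna_counts=exp.rna_counts,
                   chip_tracks=exp.chip_tracks, sequences=exp.sequences)

    @classmethod
    def from_paths(cls, annotation: str, design: str, counts: str,
                   bedgraphs: Mapping[str, str],
                   sequences: Optional[str] = None) -> "Dataset":
        genes = load_annotation(annotation)
        des = load_design(design)
        rna = pd.read_csv(counts, sep="\t", index_col=0)
        tracks = {sample: load_coverage(path, genes)
                  for sample, path in bedgraphs.items()}
        seqs = load_sequences(sequences) if sequences else None
        return cls(genes=genes, design=des, rna_counts=rna,
                   chip_tracks=tracks, sequences=seqs)


@dataclass
class AnalysisParams:
    """Tunables of the analysis itself (as opposed to the data)."""

    ppr_len: int = 400
    pseudocount: float = 0.5
    alpha: float = 0.05
    body_bins: int = 100
    flank: int = 1000
    n_cc_pairs: int = 3
    are_pattern: str = "ared_core"
    smorf_min_codons: int = 10
    smorf_max_codons: int = 100
    total_protein_coding: int = infotheory.DEFAULT_GENOME_GENES
    tf_targets: int = infotheory.DEFAULT_TF_TARGETS
    chip_normalize: bool = False


@dataclass
class AnalysisResult:
    tpm: pd.DataFrame
    occupancy: pd.DataFrame
    metagene: quantify.MetageneProfile
    rna_threshold: diffstats.ThresholdSpec
    chip_threshold_full: diffstats.ThresholdSpec
    chip_threshold_beyond: diffstats.ThresholdSpec
    rna_diff: pd.DataFrame
    chip_full_diff: pd.DataFrame
    chip_beyond_diff: pd.DataFrame
    chip_ppr_diff: pd.DataFrame
    median_full_log2: float
    median_beyond_log2: float
    records: pd.DataFrame
    report: integrate.SelectivityReport
    are_result: Optional[seqfeatures.FisherResult]
    smorfs: List[seqfeatures.SmORF]
    n_expressed: int


def rna_cc_pairs(matrix: pd.DataFrame, design: ExperimentDesign,
                 n_pairs: int = 3) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Disjoint vehicle:vehicle sample pairs for the RNA empirical threshold."""
    veh = design.samples("rna", "vehicle")
    pairs = []
    for i in range(0, min(2 * n_pairs, len(veh) - len(veh) % 2), 2):
        pairs.append((matrix[veh[i]].values, matrix[veh[i + 1]].values))
    return pairs


def chip_cc_pairs(matrix: pd.DataFrame, design: ExperimentDesign) -> List[Tuple[np.ndarray, np.ndarray]]:
    """All vehicle:vehicle combinations for the ChIP empirical threshold
    (3 vehicle samples give 3 pairs)."""
    veh = design.samples("chip", "vehicle")
    return [(matrix[a].values, matrix[b].values) for a, b in combinations(veh, 2)]


def analyze(data: Dataset, params: AnalysisParams = AnalysisParams()) -> AnalysisResult:
    """Run the full integrated analysis on one dataset."""
    genes_by_id = {g.gene_id: g for g in data.genes}
    lengths = pd.Series({g.gene_id: g.length for g in data.genes})

    # --- RNA side: TPM, expressed filter, empirical threshold, Welch test
    rna_samples = data.design.samples("rna")
    counts = data.rna_counts[rna_samples]
    expr = quantify.compute_tpm(counts, lengths)
    rna_expressed = diffstats.expressed_mask(counts)
    tpm = expr.tpm[rna_expressed]

    rna_thr = diffstats.empirical_threshold(
        rna_cc_pairs(tpm, data.design, params.n_cc_pairs),
        pseudocount=params.pseudocount, alpha=params.alpha)
    rna_diff = diffstats.classify_volcano(
        diffstats.differential_test(tpm, data.design, "rna",
                                    pseudocount=params.pseudocount), rna_thr)

    # --- ChIP side: occupancy, thresholds per region, paired tests
    occ = quantify.occupancy_table(data.chip_tracks, data.genes, params.ppr_len)
    full_m = quantify.occupancy_matrix(occ, "full", normalize=params.chip_normalize)
    ppr_m = quantify.occupancy_matrix(occ, "ppr", normalize=params.chip_normalize)
    beyond_m = quantify.occupancy_matrix(occ, "beyond", normalize=params.chip_normalize)
    chip_expressed = diffstats.expressed_mask(full_m)
    full_m = full_m[chip_expressed]
    ppr_m = ppr_m[chip_expressed]
    # genes no longer than the PPR have no beyond-PPR signal by construction
    long_enough = beyond_m.index.map(lambda g: genes_by_id[g].length > params.ppr_len)
    beyond_m = beyond_m[chip_expressed & np.asarray(long_enough, bool)]

    thr_full = diffstats.empirical_threshold(chip_cc_pairs(full_m, data.design),
                                             pseudocount=params.pseudocount,
                                             alpha=params.alpha)
    thr_beyond = diffstats.empirical_threshold(chip_cc_pairs(beyond_m, data.design),
                                               pseudocount=params.pseudocount,
                                               alpha=params.alpha)
    thr_ppr = diffstats.empirical_threshold(chip_cc_pairs(ppr_m, data.design),
                                            pseudocount=params.pseudocount,
                                            alpha=params.alpha)
    chip_full = diffstats.classify_volcano(
        diffstats.differential_test(full_m, data.design, "chip",
                                    pseudocount=params.pseudocount), thr_full)
    chip_beyond = diffstats.classify_volcano(
        diffstats.differential_test(beyond_m, data.design, "chip",
                                    pseudocount=params.pseudocount), thr_beyond)
    chip_ppr = diffstats.classify_volcano(
        diffstats.differential_test(ppr_m, data.design, "chip",
                                    pseudocount=params.pseudocount), thr_ppr)

    median_full = diffstats.ratio_median(chip_full["effect"])
    median_beyond = diffstats.ratio_median(chip_beyond["effect"])

    # --- metagene profile per condition
    cond_tracks = {
        cond: [data.chip_tracks[s] for s in data.design.samples("chip", cond)]
        for cond in ("vehicle", "ddavp")}
    metagene = quantify.metagene_profile(cond_tracks, data.genes,
                                         body_bins=params.body_bins,
                                         flank=params.flank,
                                         normalize=params.chip_normalize)

    # --- integration and selectivity
    records = integrate.integrate_assays(rna_diff, chip_beyond, chip_ppr,
                                         chip_full=chip_full)
    report = integrate.selectivity_report(records,
                                          total_genes=params.total_protein_coding,
                                          tf_targets=params.tf_targets)

    # --- sequence features
    are_result = None
    smorf_hits: List[seqfeatures.SmORF] = []
    if data.sequences:
        pc_ids = {g.gene_id for g in data.genes
                  if g.biotype == "protein_coding" and g.gene_id in data.sequences}
        labels = seqfeatures.are_labels(
            {i: data.sequences[i] for i in sorted(pc_ids)}, params.are_pattern)
        up = {g for g in rna_diff.index[rna_diff["call"] == "up"] if g in pc_ids}
        bg = {g for g in rna_diff.index if g in pc_ids} - up
        if up and bg:
            try:
                are_result = seqfeatures.are_enrichment(up, bg, labels)
            except ValueError as exc:
                logger.warning("ARE enrichment skipped: %s", exc)
        for g in data.genes:
            if g.biotype == "lncRNA" and g.gene_id in data.sequences:
                smorf_hits.extend(seqfeatures.find_smorfs(
                    data.sequences[g.gene_id], params.smorf_min_codons,
                    params.smorf_max_codons, transcript_id=g.gene_id))

    return AnalysisResult(
        tpm=tpm, occupancy=occ, metagene=metagene,
        rna_threshold=rna_thr, chip_threshold_full=thr_full,
        chip_threshold_beyond=thr_beyond,
        rna_diff=rna_diff, chip_full_diff=chip_full,
        chip_beyond_diff=chip_beyond, chip_ppr_diff=chip_ppr,
        median_full_log2=median_full, median_beyond_log2=median_beyond,
        records=records, report=report, are_result=are_result,
        smorfs=smorf_hits, n_expressed=len(records))


def _call_counts(table: pd.DataFrame) -> Dict[str, int]:
    return {c: int((table["call"] == c).sum()) for c in ("up", "down", "ns")}


def summarize(result: AnalysisResult) -> str:
    """Human-readable run summary: call tallies, median shifts, selectivity."""
    lines = ["# polpause run summary", ""]
    lines.append(f"expressed genes in integration: {result.n_expressed}")
    for name, tab in (("rna", result.rna_diff), ("chip_full", result.chip_full_diff),
                      ("chip_beyond", result.chip_beyond_diff),
                      ("chip_ppr", result.chip_ppr_diff)):
        cc = _call_counts(tab)
        lines.append(f"{name} calls: up={cc['up']} down={cc['down']} ns={cc['ns']}")
    lines.append(f"rna ratio threshold (2 x SE_cc): {result.rna_threshold.ratio_threshold:.4f}")
    lines.append(f"median log2(dDAVP/vehicle), full gene body: {result.median_full_log2:.4f}")
    lines.append(f"median log2(dDAVP/vehicle), beyond PPR: {result.median_beyond_log2:.4f}")
    jc = result.records["joint_class"].value_counts().to_dict()
    lines.append("joint classes: " + " ".join(f"{k}={v}" for k, v in sorted(jc.items())))
    ac = result.records["archetype"].value_counts().to_dict()
    lines.append("archetypes: " + " ".join(f"{k}={v}" for k, v in sorted(ac.items())))
    rep = result.report
    lines.append(f"max responder (rna): {rep.max_rna_gene}; (chip beyond-PPR): "
                 f"{rep.max_chip_gene}; single max responder: {rep.single_max_responder}")
    if rep.info is not None:
        lines.append(
            f"information: log2({rep.info.total_genes}/{rep.info.regulated_genes}) = "
            f"{rep.info.bits:.1f} bits; per-TF {rep.info.per_tf_bits:.1f} bits; "
            f"min TFs ceil={rep.info.min_tfs_ceil} floor={rep.info.min_tfs_floor}")
    if result.are_result is not None:
        fr = result.are_result
        lines.append(
            f"ARE enrichment: {fr.a}/{fr.a + fr.b} ({100 * fr.case_proportion:.1f}%) up vs "
            f"{fr.c}/{fr.c + fr.d} ({100 * fr.control_proportion:.1f}%) background; "
            f"OR={fr.odds_ratio:.2f} P(one-sided)={fr.p_one_sided:.3g} "
            f"P(two-sided)={fr.p_two_sided:.3g}")
    lines.append(f"smORFs found: {len(result.smorfs)}")
    return "\n".join(lines) + "\n"


def write_outputs(result: AnalysisResult, outdir: str | Path) -> Dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def tsv(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        p = outdir / name
        frame.to_csv(p, sep="\t", index=index, float_format="%.6g")
        paths[name] = p

    tsv("tpm.tsv", result.tpm.rename_axis("gene"))
    tsv("occupancy.tsv", result.occupancy, index=False)
    tsv("differential_rna.tsv", result.rna_diff)
    tsv("differential_chip_full.tsv", result.chip_full_diff)
    tsv("differential_chip_beyondppr.tsv", result.chip_beyond_diff)
    tsv("differential_chip_ppr.tsv", result.chip_ppr_diff)
    tsv("integration.tsv", result.records)
    up, down = integrate.regulated_tables(result.records)
    tsv("regulated_up.tsv", up)
    tsv("regulated_down.tsv", down)

    meta = pd.DataFrame(result.metagene.profiles)
    meta.insert(0, "position", np.arange(len(meta)))
    tsv("metagene.tsv", meta, index=False)

    report = result.report.to_dict()
    report["median_full_log2"] = result.median_full_log2
    report["median_beyond_log2"] = result.median_beyond_log2
    if result.are_result is not None:
        fr = result.are_result
        report["are_enrichment"] = {
            "table": [fr.a, fr.b, fr.c, fr.d], "odds_ratio": fr.odds_ratio,
            "p_one_sided": fr.p_one_sided, "p_two_sided": fr.p_two_sided,
            "case_proportion": fr.case_proportion,
            "control_proportion": fr.control_proportion}
    p = outdir / "selectivity_report.json"
    p.write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
    paths["selectivity_report.json"] = p

    if result.smorfs:
        smorf_df = pd.DataFrame([s.__dict__ for s in result.smorfs])
    else:
        smorf_df = pd.DataFrame(columns=["transcript_id", "frame", "start", "end",
                                         "n_codons", "peptide"])
    tsv("smorfs.tsv", smorf_df, index=False)

    p = outdir / "summary.txt"
    p.write_text(summarize(result))
    paths["summary.txt"] = p
    return paths


@dataclass
class PipelineConfig:
    """Exactly one of ``simulation`` or the real-input paths must be set."""

    outdir: str = "polpause_out"
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    annotation: Optional[str] = None
    design: Optional[str] = None
    counts: Optional[str] = None
    bedgraphs: Optional[Dict[str, str]] = None
    sequences: Optional[str] = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        has_paths = any(x is not None for x in
                        (self.annotation, self.design, self.counts, self.bedgraphs))
        if self.simulation is not None and has_paths:
            raise ValueError("config must give either a simulation block or "
                             "real-input paths, not both")
        if self.simulation is None and not has_paths:
            raise ValueError("config gives neither a simulation block nor input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        params = raw.pop("params", None)
        cfg = cls(simulation=SimulationConfig(**sim) if sim is not None else None,
                  params=AnalysisParams(**params) if params else AnalysisParams(),
                  **raw)
        return cfg


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Run the whole pipeline and write all outputs under ``config.outdir``.

    Deterministic for a fixed (config, seed); on failure any partially
    written output directory content from this run is removed.
    """
    outdir = Path(config.outdir)
    created = not outdir.exists()
    try:
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
            data = Dataset.from_simulation(simulate_experiment(sim))
        else:
            data = Dataset.from_paths(config.annotation, config.design, config.counts,
                                      config.bedgraphs or {}, config.sequences)
        result = analyze(data, config.params)
        write_outputs(result, outdir)
        return result
    except Exception:
        if created and outdir.exists():
            shutil.rmtree(outdir, ignore_errors=True)
        raise
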