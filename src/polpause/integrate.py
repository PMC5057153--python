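"""Dual-assay integration: net transcriptional regulation calls, the
initiation-vs-elongation archetype, and the selectivity ranking.

A gene is under *net* transcriptional control only when both assays agree:
its mRNA call and its Pol II occupancy call beyond the promoter-proximal
region (the elongation-sensitive signal) move in the same direction.  Genes
whose mRNA moves without a beyond-PPR Pol II change are post-transcriptional
candidates; genes whose Pol II rises only in the PPR are initiation-regulated
but paused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import infotheory

logger = logging.getLogger(__name__)

JOINT_CLASSES = ("transcription_up", "transcription_down", "rna_only_up",
                 "rna_only_down", "chip_only", "none")
ARCHETYPES = ("initiation_only", "elongation_regulated", "unclassified")


def joint_class(rna_call: str, chip_beyond_call: str, chip_ppr_call: str) -> str:
    """Map the three volcano calls to the joint regulation class.

    Rule order: agreement of RNA and beyond-PPR ChIP in the same direction is
    net transcriptional regulation; an RNA call without that agreement is
    RNA-only (post-transcriptional candidate); any remaining ChIP call (PPR
    or beyond) without an RNA call is chip_only; otherwise none.
    """
    if rna_call == "up" and chip_beyond_call == "up":
        return "transcription_up"
    if rna_call == "down" and chip_beyond_call == "down":
        return "transcription_down"
    if rna_call == "up":
        return "rna_only_up"
    if rna_call == "down":
        return "rna_only_down"
    if chip_beyond_call != "ns" or chip_ppr_call != "ns":
        return "chip_only"
    return "none"


def archetype(chip_beyond_call: str, chip_ppr_call: str) -> str:
    """Initiation-vs-elongation archetype from the two ChIP calls: any
    beyond-PPR change marks elongation regulation; a PPR-up with flat
    beyond-PPR is initiation-only (paused); everything else is unclassified."""
    if chip_beyond_call != "ns":
        return "elongation_regulated"
    if chip_ppr_call == "up":
        return "initiation_only"
    return "unclassified"


def integrate_assays(rna: pd.DataFrame, chip_beyond: pd.DataFrame,
                     chip_ppr: pd.DataFrame,
                     chip_full: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Join the per-assay differential tables into one record per gene.

    All tables must carry ``effect`` and ``call`` columns and share a gene
    index; the integration runs on the common gene set (an error if the sets
    are disjoint).  The scatter axis for net-regulation calls is the
    beyond-PPR ChIP effect; the full-gene-body effect, when provided, is
    carried as separate ``chip_full_*`` columns and never conflated with it.
    Output is sorted by RNA effect descending (ranked-listing order).
    """
    for name, tab in (("rna", rna), ("chip_beyond", chip_beyond), ("chip_ppr", chip_ppr)):
        for col in ("effect", "call"):
            if col not in tab.columns:
                raise ValueError(f"{name} table lacks column {col!r}")
    shared = rna.index.intersection(chip_beyond.index).intersection(chip_ppr.index)
    if len(shared) == 0:
        raise ValueError("gene sets of the differential tables are disjoint")
    if len(shared) < max(len(rna), len(chip_beyond), len(chip_ppr)):
        logger.warning("integrate_assays: restricting to %d shared genes", len(shared))

    out = pd.DataFrame(index=shared)
    out.index.name = "gene"
    out["rna_effect"] = rna.loc[shared, "effect"]
    out["rna_se"] = rna.loc[shared].get("se", np.nan)
    out["rna_call"] = rna.loc[shared, "call"]
    out["chip_beyond_effect"] = chip_beyond.loc[shared, "effect"]
    out["chip_beyond_se"] = chip_beyond.loc[shared].get("se", np.nan)
    out["chip_beyond_call"] = chip_beyond.loc[shared, "call"]
    out["chip_ppr_effect"] = chip_ppr.loc[shared, "effect"]
    out["chip_ppr_call"] = chip_ppr.loc[shared, "call"]
    if chip_full is not None:
        out["chip_full_effect"] = chip_full.loc[shared.intersection(chip_full.index), "effect"]
        out["chip_full_call"] = chip_full.loc[shared.intersection(chip_full.index), "call"]
    out["joint_class"] = [joint_class(r, b, p) for r, b, p in
                          zip(out["rna_call"], out["chip_beyond_call"], out["chip_ppr_call"])]
    out["archetype"] = [archetype(b, p) for b, p in
                        zip(out["chip_beyond_call"], out["chip_ppr_call"])]
    return out.sort_values("rna_effect", ascending=False)


def regulated_tables(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Net-regulated gene listings (up and down), sorted by RNA effect
    descending — the two-table report of coordinately changed genes."""
    cols = ["rna_effect", "rna_se", "chip_beyond_effect", "chip_beyond_se"]
    up = records[records["joint_class"] == "transcription_up"].sort_values(
        "rna_effect", ascending=False)[cols]
    down = records[records["joint_class"] == "transcription_down"].sort_values(
        "rna_effect")[cols]
    return up, down


@dataclass
class SelectivityReport:
    """Who responds most, and how much information that selectivity implies."""

    ranked_by_rna: List[str]
    ranked_by_chip: List[str]
    max_rna_gene: Optional[str]
    max_chip_gene: Optional[str]
    single_max_responder: bool
    n_regulated_up: int
    n_regulated_down: int
    info: Optional[infotheory.SelectivityInfo]

    def to_dict(self) -> Dict:
        d = {
            "ranked_by_rna": self.ranked_by_rna,
            "ranked_by_chip": self.ranked_by_chip,
            "max_rna_gene": self.max_rna_gene,
            "max_chip_gene": self.max_chip_gene,
            "single_max_responder": self.single_max_responder,
            "n_regulated_up": self.n_regulated_up,
            "n_regulated_down": self.n_regulated_down,
        }
        if self.info is not None:
            d["information"] = {
                "total_genes": self.info.total_genes,
                "regulated_genes": self.info.regulated_genes,
                "bits_to_specify_set": self.info.bits,
                "per_tf_bits": self.info.per_tf_bits,
                "min_tfs_ceil": self.info.min_tfs_ceil,
                "min_tfs_floor": self.info.min_tfs_floor,
            }
        return d


def _argmax_gene(records: pd.DataFrame, column: str) -> str:
    """Gene with the largest effect; ties broken lexicographically by gene_id."""
    best = records[column].max()
    tied = sorted(records.index[records[column] == best])
    return tied[0]


def selectivity_report(records: pd.DataFrame,
                       total_genes: int = infotheory.DEFAULT_GENOME_GENES,
                       tf_targets: int = infotheory.DEFAULT_TF_TARGETS) -> SelectivityReport:
    """Rank the net-upregulated genes on each assay axis and flag whether one
    gene is maximal on both; summarize the information content of the
    regulated set size (up + down) against ``total_genes``."""
    up = records[records["joint_class"] == "transcription_up"]
    down = records[records["joint_class"] == "transcription_down"]
    n_up, n_down = len(up), len(down)
    if n_up == 0:
        logger.warning("selectivity_report: no net-upregulated genes")
        info = None
        if n_up + n_down >= 1:
            info = infotheory.selectivity_info(n_up + n_down, total_genes, tf_targets)
        return SelectivityReport(ranked_by_rna=[], ranked_by_chip=[],
                                 max_rna_gene=None, max_chip_gene=None,
                                 single_max_responder=False,
                                 n_regulated_up=0, n_regulated_down=n_down, info=info)
    by_rna = up.sort_values(["rna_effect"], ascending=False)
    by_chip = up.sort_values(["chip_beyond_effect"], ascending=False)
    max_rna = _argmax_gene(up, "rna_effect")
    max_chip = _argmax_gene(up, "chip_beyond_effect")
    info = infotheory.selectivity_info(n_up + n_down, total_genes, tf_targets)
    return SelectivityReport(
        ranked_by_rna=list(by_rna.index),
        ranked_by_chip=list(by_chip.index),
        max_rna_gene=max_rna,
        max_chip_gene=max_chip,
        single_max_responder=max_rna == max_chip,
        n_regulated_up=n_up,
        n_regulated_down=n_down,
        info=info,
    )
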