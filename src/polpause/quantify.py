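"""Per-gene quantification: TPM, gene-body Pol II occupancy with the
promoter-proximal split, and metagene profiles.

The promoter-proximal region (PPR) is the first ``ppr_len`` (default 400) bp
of the gene body downstream of the TSS, where paused polymerase accumulates.
Genes no longer than the PPR are counted entirely as PPR (beyond = 0) and are
excluded from beyond-PPR differential testing upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import CoverageTrack, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_PPR_LEN = 400


@dataclass
class ExpressionMatrix:
    """TPM table (gene x sample) with its raw counts and gene lengths."""

    tpm: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum_g(rate_g), per
    sample, so every TPM column sums to 1e6.  A sample with all-zero counts
    has no defined normalization and raises ``ValueError``.
    """
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"all-zero samples, TPM undefined: {list(zero.index)}")
    tpm = rate.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm=tpm, counts=counts, lengths=lengths)


class RegionOccupancy(NamedTuple):
    full: float
    ppr: float
    beyond: float


def region_occupancy(track: CoverageTrack, gene: GeneModel,
                     ppr_len: int = DEFAULT_PPR_LEN) -> RegionOccupancy:
    """Summed depth over the full gene body, the PPR, and beyond the PPR.

    The PPR is anchored at the TSS in the direction of transcription: the
    leftmost ``ppr_len`` bases on the + strand, the rightmost on the - strand.
    full == ppr + beyond always holds.
    """
    body = track.gene_body(gene)  # raises if gene outside track
    full = float(body.sum(dtype=np.float64))
    if gene.length <= ppr_len:
        return RegionOccupancy(full=full, ppr=full, beyond=0.0)
    if gene.strand == "+":
        ppr = float(body[:ppr_len].sum(dtype=np.float64))
    else:
        ppr = float(body[-ppr_len:].sum(dtype=np.float64))
    return RegionOccupancy(full=full, ppr=ppr, beyond=full - ppr)


def occupancy_table(tracks: Mapping[str, CoverageTrack], genes: Sequence[GeneModel],
                    ppr_len: int = DEFAULT_PPR_LEN) -> pd.DataFrame:
    """Tidy per-gene, per-sample occupancy: columns gene, sample, full, ppr,
    beyond, norm_factor (the sample's library size over annotated gene bodies)."""
    records = []
    for sample_id, track in tracks.items():
        if track.library_size is None:
            track.compute_library_size(genes)
        for g in genes:
            occ = region_occupancy(track, g, ppr_len)
            records.append((g.gene_id, sample_id, occ.full, occ.ppr, occ.beyond,
                            track.library_size))
    return pd.DataFrame.from_records(
        records, columns=["gene", "sample", "full", "ppr", "beyond", "norm_factor"])


def occupancy_matrix(table: pd.DataFrame, region: str = "full",
                     normalize: bool = True, scale: float = 1e6) -> pd.DataFrame:
    """Pivot an occupancy table to gene x sample for one region.

    With ``normalize`` the values are depth per ``scale`` units of library
    size, making samples of different sequencing depth comparable.
    """
    if region not in ("full", "ppr", "beyond"):
        raise ValueError(f"unknown region {region!r}")
    wide = table.pivot(index="gene", columns="sample", values=region)
    if normalize:
        factors = table.drop_duplicates("sample").set_index("sample")["norm_factor"]
        if (factors <= 0).any():
            raise ValueError("nonpositive library size; cannot normalize")
        wide = wide.div(factors, axis=1) * scale
    wide.columns.name = None
    return wide


@dataclass
class MetageneProfile:
    """Average normalized depth around a composite gene.

    Each profile vector covers ``flank`` upstream bases (per-bp bins), the
    gene body rescaled to ``body_bins`` bins, and ``flank`` downstream bases,
    oriented 5' -> 3' regardless of strand.
    """

    profiles: Dict[str, np.ndarray]
    body_bins: int
    flank: int
    n_genes: int

    @property
    def body_slice(self) -> slice:
        return slice(self.flank, self.flank + self.body_bins)


def _bin_body(body: np.ndarray, body_bins: int) -> np.ndarray:
    """Average depth within body_bins equal genomic sub-intervals (floor partition)."""
    L = body.size
    idx = (np.arange(L) * body_bins) // L
    sums = np.bincount(idx, weights=body, minlength=body_bins)
    sizes = np.bincount(idx, minlength=body_bins)
    return sums / sizes


def _gene_profile(track: CoverageTrack, gene: GeneModel, body_bins: int,
                  flank: int) -> np.ndarray:
    arr = track.depths[gene.chrom]
    body = arr[gene.start:gene.end]

    def flank_values(lo: int, hi: int) -> np.ndarray:
        out = np.zeros(hi - lo)
        s, e = max(lo, 0), min(hi, arr.size)
        if e > s:
            out[s - lo:e - lo] = arr[s:e]
        return out

    left = flank_values(gene.start - flank, gene.start)
    right = flank_values(gene.end, gene.end + flank)
    if gene.strand == "+":
        return np.concatenate([left, _bin_body(body, body_bins), right])
    # 5'->3' on the - strand runs right to left in genomic coordinates:
    # reverse the per-base arrays first, then bin
    return np.concatenate([right[::-1], _bin_body(body[::-1], body_bins), left[::-1]])


def metagene_profile(tracks_by_condition: Mapping[str, Sequence[CoverageTrack]],
                     genes: Sequence[GeneModel], body_bins: int = 100,
                     flank: int = 1000, normalize: bool = True,
                     scale: float = 1e6) -> MetageneProfile:
    """Composite TSS->EAG occupancy profile per condition.

    Each gene body is rescaled to ``body_bins`` bins by averaging within
    equal genomic sub-intervals; minus-strand genes are reversed before
    averaging so every profile runs 5' to 3'.  Tracks are scaled by
    ``scale / library_size`` when ``normalize`` is set, then averaged over
    genes and then over the samples of a condition.  Genes shorter than
    ``body_bins`` are skipped with a logged warning.
    """
    usable = [g for g in genes if g.length >= body_bins]
    skipped = len(genes) - len(usable)
    if skipped:
        logger.warning("metagene_profile: skipped %d genes shorter than %d bp",
                       skipped, body_bins)
    if not usable:
        raise ValueError("no genes long enough for the requested body_bins")

    profiles: Dict[str, np.ndarray] = {}
    for condition, tracks in tracks_by_condition.items():
        per_sample = []
        for track in tracks:
            factor = 1.0
            if normalize:
                if track.library_size is None:
                    track.compute_library_size(genes)
                if track.library_size <= 0:
                    raise ValueError("nonpositive library size; cannot normalize")
                factor = scale / track.library_size
            gene_profiles = np.stack([_gene_profile(track, g, body_bins, flank)
                                      for g in usable])
            per_sample.append(factor * gene_profiles.mean(axis=0))
        profiles[condition] = np.stack(per_sample).mean(axis=0)
    return MetageneProfile(profiles=profiles, body_bins=body_bins, flank=flank,
                           n_genes=len(usable))
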