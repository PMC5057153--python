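"""Per-gene differential statistics and the dual-criterion volcano classification.

The fold-change gate is empirical: 2 x SE_cc, where SE_cc is the median over
same-condition (control:control) sample pairs of the across-gene standard
deviation of per-gene log2 ratios.  A gene is called only when it clears both
the fold-change gate and the t-test gate (strict inequalities) — a stringent
criterion that favors false negatives over false positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_ALPHA = 0.05

CALLS = ("up", "down", "ns")


@dataclass(frozen=True)
class ThresholdSpec:
    """Volcano gates: significance level and empirical fold-change threshold."""

    alpha: float
    se_cc: float
    ratio_threshold: float

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.ratio_threshold < 0:
            raise ValueError("ratio_threshold must be >= 0")


def log2_ratio(a: np.ndarray, b: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Per-gene log2((a+pc)/(b+pc)); the pseudocount guards against zeros."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.log2(a + pseudocount) - np.log2(b + pseudocount)


def empirical_threshold(cc_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
                        pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        alpha: float = DEFAULT_ALPHA) -> ThresholdSpec:
    """Fold-change gate from control:control pairs.

    For each pair, the standard deviation across genes of the per-gene log2
    ratio is taken; SE_cc is the median of those pair SDs and the threshold
    is 2 x SE_cc (the 95% band for random between-replicate variation).
    A pair of identical samples is allowed (SD 0).
    """
    if len(cc_pairs) == 0:
        raise ValueError("at least one control:control pair is required")
    sds = []
    for a, b in cc_pairs:
        ratios = log2_ratio(a, b, pseudocount)
        if not np.all(np.isfinite(ratios)):
            raise ValueError("non-finite log2 ratios in control:control pair")
        sds.append(float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0)
    se_cc = float(np.median(sds))
    return ThresholdSpec(alpha=alpha, se_cc=se_cc, ratio_threshold=2.0 * se_cc)


def _t_sf(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def _safe_tp(effect: np.ndarray, se: np.ndarray, df: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """t and two-sided P with the zero-variance corner handled explicitly:
    identical groups (effect 0, SE 0) get t=0, P=1; a nonzero effect with SE 0
    gets t=+-inf, P=0."""
    effect = np.asarray(effect, float)
    se = np.asarray(se, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0),
                     np.where(effect == 0, 0.0, np.sign(effect) * np.inf))
        p = np.where(se > 0, _t_sf(np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0), df),
                     np.where(effect == 0, 1.0, 0.0))
    return t, p


def differential_test(matrix: pd.DataFrame, design, assay: str,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      paired: Optional[bool] = None) -> pd.DataFrame:
    """Per-gene effect, SE, t and P for dDAVP vs vehicle.

    RNA (``assay='rna'``): Welch two-sample t-test on log2(value + pc); the
    effect is the difference of group means of log2 values (9 vs 9 replicates
    in the study design).  ChIP (``assay='chip'``): by default a paired
    one-sample t-test on the per-pair log2 ratios (3 pairs); ``paired=False``
    falls back to the Welch test.  Values are assumed normalized upstream.

    Returns a DataFrame indexed by gene with columns effect, se, t, p, n.
    """
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("non-finite values in quantification matrix")
    if assay not in ("rna", "chip"):
        raise ValueError(f"unknown assay {assay!r}")
    if paired is None:
        paired = assay == "chip"

    if paired:
        pairs = design.chip_pairs()
        if len(pairs) < 2:
            raise ValueError("paired test needs >= 2 pairs")
        ratios = np.column_stack([
            log2_ratio(matrix[dd].values, matrix[veh].values, pseudocount)
            for veh, dd in pairs])
        n = ratios.shape[1]
        effect = ratios.mean(axis=1)
        sd = ratios.std(axis=1, ddof=1)
        se = sd / math.sqrt(n)
        t, p = _safe_tp(effect, se, np.full_like(effect, n - 1))
        out = pd.DataFrame({"effect": effect, "se": se, "t": t, "p": p, "n": n},
                           index=matrix.index)
    else:
        veh = design.samples(assay, "vehicle")
        dda = design.samples(assay, "ddavp")
        if len(veh) < 2 or len(dda) < 2:
            raise ValueError("need >= 2 samples per condition")
        lv = np.log2(matrix[veh].values + pseudocount)
        ld = np.log2(matrix[dda].values + pseudocount)
        n1, n2 = ld.shape[1], lv.shape[1]
        m1, m2 = ld.mean(axis=1), lv.mean(axis=1)
        v1, v2 = ld.var(axis=1, ddof=1), lv.var(axis=1, ddof=1)
        effect = m1 - m2
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
        t, p = _safe_tp(effect, se, df)
        out = pd.DataFrame({"effect": effect, "se": se, "t": t, "p": p,
                            "n": n1 + n2}, index=matrix.index)
    out.index.name = "gene"
    return out


def classify_volcano(table: pd.DataFrame, thresholds: ThresholdSpec) -> pd.DataFrame:
    """Add the volcano call: up / down / ns under strict dual gates.

    ``up`` requires effect > ratio_threshold AND P < alpha; ``down`` mirrors
    with effect < -ratio_threshold; anything else (including effects exactly
    at the threshold) is ``ns``.
    """
    out = table.copy()
    up = (out["effect"] > thresholds.ratio_threshold) & (out["p"] < thresholds.alpha)
    down = (out["effect"] < -thresholds.ratio_threshold) & (out["p"] < thresholds.alpha)
    out["call"] = np.select([up, down], ["up", "down"], default="ns")
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values (optional; raw P is the default gate)."""
    return stats.false_discovery_control(np.asarray(p, float), method="bh")


def ratio_median(values: Iterable[float]) -> float:
    """Exact median of log2 ratios (mean of the central two for even n)."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty ratio list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite ratios")
    return float(np.median(arr))


def expressed_mask(matrix: pd.DataFrame, min_value: float = 0.0) -> pd.Series:
    """Genes quantified above ``min_value`` in every sample of the assay."""
    return (matrix > min_value).all(axis=1)


def fold_change(log2_ratio_value: float) -> float:
    """Linear fold change 2**x for a log2 ratio."""
    return float(2.0 ** log2_ratio_value)


def approx_fold(log2_ratio_value: float) -> int:
    """Fold change as conventionally reported ('approximately N-fold'):
    the integer part of the linear magnitude."""
    return int(2.0 ** abs(log2_ratio_value))
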