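"""Shannon-information selectivity calculus.

Specifying that M particular genes out of G protein-coding genes are to be
regulated requires log2(G/M) bits; a transcription factor with M high-affinity
target sites among G genes conveys log2(G/M) bits by binding.  Regulating a
single gene out of 24000 therefore needs log2(24000) ~ 14.6 bits, and if a
typical factor targets ~1000 genes (~4.5 bits each), several independently
binding factors are needed to achieve single-gene selectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

DEFAULT_GENOME_GENES = 24000
DEFAULT_TF_TARGETS = 1000

_EPS = 1e-12


def information_bits(total_genes: int, selected_genes: int) -> float:
    """log2(G/M): bits needed to specify M regulated genes out of G.

    Returned at full precision; rounding for presentation is the caller's
    concern.  Requires G >= M >= 1.
    """
    if selected_genes < 1:
        raise ValueError("selected_genes must be >= 1")
    if total_genes < selected_genes:
        raise ValueError("total_genes must be >= selected_genes")
    return math.log2(total_genes / selected_genes)


def min_tf_count(required_bits: float, per_tf_bits: float) -> int:
    """Minimum number of independently binding transcription factors:
    ceil(required_bits / per_tf_bits).  Both arguments must be positive."""
    if required_bits <= 0 or per_tf_bits <= 0:
        raise ValueError("bits arguments must be positive")
    return math.ceil(required_bits / per_tf_bits - _EPS)


def tf_count_bounds(required_bits: float, per_tf_bits: float) -> Tuple[int, int]:
    """(floor, ceil) of required_bits / per_tf_bits.

    Exposed because reported lower bounds in the literature sometimes use the
    floor (e.g. 9.4/4.5 = 2.09 described as 'at least two factors') while the
    strict information argument needs the ceiling (3).
    """
    if required_bits <= 0 or per_tf_bits <= 0:
        raise ValueError("bits arguments must be positive")
    x = required_bits / per_tf_bits
    return math.floor(x + _EPS), math.ceil(x - _EPS)


@dataclass(frozen=True)
class SelectivityInfo:
    """Information-content summary for a regulated gene set."""

    total_genes: int
    regulated_genes: int
    bits: float
    per_tf_bits: float
    min_tfs_ceil: int
    min_tfs_floor: int


def selectivity_info(regulated_genes: int,
                     total_genes: int = DEFAULT_GENOME_GENES,
                     tf_targets: int = DEFAULT_TF_TARGETS) -> SelectivityInfo:
    """Bits to specify the regulated set and the implied minimum TF count,
    assuming a typical factor targets ``tf_targets`` of ``total_genes`` genes."""
    bits = information_bits(total_genes, regulated_genes)
    per_tf = information_bits(total_genes, tf_targets)
    if bits == 0:
        floor_n = ceil_n = 0
    else:
        floor_n, ceil_n = tf_count_bounds(bits, per_tf)
    return SelectivityInfo(total_genes=total_genes, regulated_genes=regulated_genes,
                           bits=bits, per_tf_bits=per_tf,
                           min_tfs_ceil=ceil_n, min_tfs_floor=floor_n)
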