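"""AU-rich element scanning of 3'-UTRs, exact enrichment testing, and small-ORF
detection in long non-coding RNAs.

AREs are scanned on the sense strand only (mRNA semantics) in DNA alphabet:
the core pentamer is ATTTA (AUUUA in RNA).  The default pattern class is the
ATTTA core embedded in an A/T-rich framework, [AT][AT]TTTATTTA[AT][AT]; a
stricter class requiring overlapping pentamer repeats (ATTTATTTA) is
selectable.  Overlapping matches are all reported.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from scipy import stats

ARE_PATTERNS: Dict[str, re.Pattern] = {
    # ATTTA core in an A/T-rich context (ARED-style framework)
    "ared_core": re.compile(r"(?=([AT][AT]TTTATTTA[AT][AT]))"),
    # overlapping pentamer repeat, a stricter class
    "pentamer_repeat": re.compile(r"(?=(ATTTATTTA))"),
}

_DNA = set("ACGTN")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class AREHit:
    """One ARE match: where it is and what matched."""

    sequence_id: str
    offset: int
    pattern_class: str
    match: str


def _check_dna(seq: str, seq_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{seq_id}: non-ACGTN symbols {sorted(bad)}")
    return seq


def scan_ares(seq: str, pattern_class: str = "ared_core",
              sequence_id: str = "seq") -> List[AREHit]:
    """All (overlapping) ARE matches in a sense-strand DNA sequence."""
    if pattern_class not in ARE_PATTERNS:
        raise ValueError(f"unknown ARE pattern class {pattern_class!r}; "
                         f"choose from {sorted(ARE_PATTERNS)}")
    seq = _check_dna(seq, sequence_id)
    pattern = ARE_PATTERNS[pattern_class]
    return [AREHit(sequence_id=sequence_id, offset=m.start(),
                   pattern_class=pattern_class, match=m.group(1))
            for m in pattern.finditer(seq)]


def are_labels(sequences: Mapping[str, str],
               pattern_class: str = "ared_core") -> Dict[str, bool]:
    """id -> whether the sequence carries at least one ARE."""
    return {sid: bool(scan_ares(s, pattern_class, sid)) for sid, s in sequences.items()}


@dataclass(frozen=True)
class FisherResult:
    """2x2 exact test: (a,b) = with/without feature among cases,
    (c,d) = with/without among controls."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float

    @property
    def case_proportion(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def control_proportion(self) -> float:
        return self.c / (self.c + self.d)


def fisher_exact_from_counts(a: int, b: int, c: int, d: int) -> FisherResult:
    """Exact hypergeometric test on a 2x2 table.

    One-sided P is the enrichment tail P(X >= a) for X hypergeometric with
    the table's margins; the two-sided P sums the probabilities of all tables
    (same margins) whose probability does not exceed that of the observed
    table.  The odds ratio is ad/bc (inf when bc = 0 and ad > 0, nan for an
    all-degenerate diagonal).
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError("contingency counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("empty margin in 2x2 table")
    N = a + b + c + d
    K = a + c          # feature-positive total
    n = a + b          # cases total
    rv = stats.hypergeom(N, K, n)
    p_one = float(rv.sf(a - 1))
    k_lo, k_hi = max(0, n - (N - K)), min(n, K)
    ks = range(k_lo, k_hi + 1)
    p_obs = rv.pmf(a)
    p_two = float(sum(rv.pmf(k) for k in ks if rv.pmf(k) <= p_obs * (1 + 1e-9)))
    p_two = min(p_two, 1.0)
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    return FisherResult(a=a, b=b, c=c, d=d, odds_ratio=odds,
                        p_one_sided=p_one, p_two_sided=p_two)


def are_enrichment(upregulated_ids: Iterable[str], background_ids: Iterable[str],
                   labels: Mapping[str, bool]) -> FisherResult:
    """Is the ARE-bearing fraction higher among upregulated transcripts than
    among the not-upregulated background?  The two id sets must be disjoint
    and every id must have a label."""
    up = set(upregulated_ids)
    bg = set(background_ids)
    if up & bg:
        raise ValueError("upregulated and background sets overlap")
    missing = (up | bg) - set(labels)
    if missing:
        raise ValueError(f"missing ARE labels for {sorted(missing)[:5]}")
    a = sum(1 for g in up if labels[g])
    b = len(up) - a
    c = sum(1 for g in bg if labels[g])
    d = len(bg) - c
    return fisher_exact_from_counts(a, b, c, d)


@dataclass(frozen=True)
class SmORF:
    """A putative small open reading frame: ATG to the first in-frame stop."""

    transcript_id: str
    frame: int
    start: int            # offset of the A of ATG
    end: int              # offset past the stop codon
    n_codons: int         # length in codons, stop excluded
    peptide: str


def find_smorfs(seq: str, min_codons: int = 10, max_codons: int = 100,
                transcript_id: str = "seq") -> List[SmORF]:
    """All candidate smORFs in the three forward frames.

    An ORF runs from an ATG to the first in-frame stop (a stop is required);
    its length in codons excludes the stop and must satisfy
    min_codons <= length <= max_codons (inclusive).  Every in-frame ATG opens
    its own candidate — nested ORFs are all reported.  Peptides use the
    standard genetic code.
    """
    from Bio.Seq import Seq

    if not (1 <= min_codons <= max_codons):
        raise ValueError("need 1 <= min_codons <= max_codons")
    seq = _check_dna(seq, transcript_id)
    orfs: List[SmORF] = []
    for frame in range(3):
        codon_starts = range(frame, len(seq) - 2, 3)
        stops = [i for i in codon_starts if seq[i:i + 3] in _STOPS]
        for i in codon_starts:
            if seq[i:i + 3] != "ATG":
                continue
            stop = next((s for s in stops if s > i), None)
            if stop is None:
                continue
            n_codons = (stop - i) // 3
            if not (min_codons <= n_codons <= max_codons):
                continue
            peptide = str(Seq(seq[i:stop]).translate())
            orfs.append(SmORF(transcript_id=transcript_id, frame=frame, start=i,
                              end=stop + 3, n_codons=n_codons, peptide=peptide))
    return orfs
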