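"""Domain types for gene annotations, coverage tracks, sequences and experiment design.

Internal coordinates are 0-based half-open everywhere.  GTF input (1-based,
inclusive) is converted on ingest; BED is native.  The transcription start
site (TSS) of a gene is ``start`` on the + strand and ``end - 1`` on the -
strand; the end of the annotated gene (EAG) is the opposite extremity.

Coverage is strandless: Pol II ChIP fragments carry no strand information, so
strand matters only for orienting the promoter-proximal region and metagene
profiles relative to the TSS.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")
ASSAYS = ("rna", "chip")
CONDITIONS = ("vehicle", "ddavp")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class CoverageError(ValueError):
    """Malformed coverage input."""


class SequenceError(ValueError):
    """Malformed sequence input."""


class DesignError(ValueError):
    """Inconsistent experiment design."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: a strand-aware interval from TSS to EAG.

    A single interval per gene — isoform structure is out of scope; Pol II
    occupancy is quantified over whole gene bodies.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise AnnotationError(f"{self.gene_id}: coordinates must be integers")
        if self.end <= self.start:
            raise AnnotationError(f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})")
        if self.start < 0:
            raise AnnotationError(f"{self.gene_id}: negative start coordinate")
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def eag(self) -> int:
        """End of annotated gene (0-based position of the last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start


def _check_unique_ids(genes: Sequence[GeneModel]) -> None:
    seen: set = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)


# ---------------------------------------------------------------------------
# Annotation I/O


def load_annotation(path: str | Path, default_biotype: str = "protein_coding") -> List[GeneModel]:
    """Load gene models from a GTF (feature type ``gene``) or BED/BED12 file.

    Format is chosen by extension (.gtf/.gff/.gff3 vs anything else treated
    as BED).  GTF 1-based inclusive coordinates are converted to 0-based
    half-open.  Raises :class:`AnnotationError` on malformed rows (with line
    number) or duplicate gene ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        genes = _load_gtf(path)
    else:
        genes = _load_bed(path, default_biotype)
    _check_unique_ids(genes)
    return genes


def _load_gtf(path: Path) -> List[GeneModel]:
    import gffutils

    # Pre-validate so parse errors carry a line number.
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise AnnotationError(f"{path}:{i}: expected 9 tab-separated GTF fields")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene"):
        try:
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(f"{path}: gene feature without gene_id attribute") from exc
        biotype = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
        if biotype not in BIOTYPES:
            biotype = "other"
        genes.append(GeneModel(gene_id=gene_id, chrom=feat.seqid, strand=feat.strand,
                               start=feat.start - 1, end=feat.end, biotype=biotype))
    return genes


def _load_bed(path: Path, default_biotype: str) -> List[GeneModel]:
    genes: List[GeneModel] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise AnnotationError(f"{path}:{i}: BED line needs >= 6 fields (chrom start end name score strand)")
        try:
            chrom, start, end, name, _score, strand = fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4], fields[5]
        except ValueError as exc:
            raise AnnotationError(f"{path}:{i}: malformed BED coordinates") from exc
        try:
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand,
                                   start=start, end=end, biotype=default_biotype))
        except AnnotationError as exc:
            raise AnnotationError(f"{path}:{i}: {exc}") from exc
    return genes


def write_annotation_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "polpause") -> None:
    """Write gene models as GTF ``gene`` features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


def write_annotation_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (biotype is not representable in BED and is dropped)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{g.length},\t0,\n"
            )


# ---------------------------------------------------------------------------
# Coverage


class CoverageTrack:
    """Per-base, strandless, nonnegative read depth on named sequences.

    ``library_size`` is the total depth summed over the gene bodies of a
    reference annotation — the per-sample normalization denominator used by
    occupancy ratios and metagene profiles.
    """

    def __init__(self, depths: Mapping[str, np.ndarray],
                 annotation: Optional[Sequence[GeneModel]] = None):
        self.depths: Dict[str, np.ndarray] = {}
        for chrom, arr in depths.items():
            arr = np.asarray(arr)
            if arr.dtype.kind != "f":
                arr = arr.astype(np.float64)
            if arr.ndim != 1:
                raise CoverageError(f"{chrom}: depth array must be 1-D")
            if np.any(arr < 0):
                raise CoverageError(f"{chrom}: negative depth")
            self.depths[chrom] = arr
        self.library_size: Optional[float] = None
        if annotation is not None:
            self.library_size = self.compute_library_size(annotation)

    def chrom_length(self, chrom: str) -> int:
        return len(self.depths[chrom])

    def gene_body(self, gene: GeneModel) -> np.ndarray:
        """Depth over the gene body in genomic orientation (left to right)."""
        if gene.chrom not in self.depths:
            raise CoverageError(f"gene {gene.gene_id}: chrom {gene.chrom!r} not in track")
        arr = self.depths[gene.chrom]
        if gene.end > len(arr):
            raise CoverageError(
                f"gene {gene.gene_id}: interval [{gene.start},{gene.end}) exceeds "
                f"chrom length {len(arr)}")
        return arr[gene.start:gene.end]

    def compute_library_size(self, annotation: Sequence[GeneModel]) -> float:
        total = 0.0
        for g in annotation:
            total += float(self.gene_body(g).sum(dtype=np.float64))
        self.library_size = total
        return total


def load_coverage(path: str | Path, annotation: Sequence[GeneModel],
                  chrom_sizes: Optional[Mapping[str, int]] = None) -> CoverageTrack:
    """Read a bedGraph file into a :class:`CoverageTrack`.

    Intervals must be non-overlapping within a chromosome.  If ``chrom_sizes``
    is given, intervals beyond the declared length are an error; otherwise
    lengths are taken as max(annotation end, bedGraph end) per chromosome.
    An empty file yields an all-zero track with library_size 0.
    """
    path = Path(path)
    rows: List[Tuple[str, int, int, float]] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise CoverageError(f"{path}:{i}: bedGraph line needs 4 fields")
        try:
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise CoverageError(f"{path}:{i}: malformed bedGraph line") from exc
        if value < 0:
            raise CoverageError(f"{path}:{i}: negative coverage value {value}")
        if end <= start or start < 0:
            raise CoverageError(f"{path}:{i}: bad interval [{start},{end})")
        rows.append((chrom, start, end, value))

    sizes: Dict[str, int] = dict(chrom_sizes) if chrom_sizes else {}
    for g in annotation:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end)
    for chrom, start, end, _v in rows:
        if chrom_sizes is not None and chrom in chrom_sizes and end > chrom_sizes[chrom]:
            raise CoverageError(f"interval [{start},{end}) beyond declared length of {chrom}")
        sizes[chrom] = max(sizes.get(chrom, 0), end)

    depths = {chrom: np.zeros(n, dtype=np.float64) for chrom, n in sizes.items()}
    last_end: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end, value in rows:
        last_end.setdefault(chrom, []).append((start, end))
        depths[chrom][start:end] = value
    for chrom, ivals in last_end.items():
        ivals.sort()
        for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise CoverageError(f"{chrom}: overlapping bedGraph intervals at {s2}")
    return CoverageTrack(depths, annotation=annotation)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length merging equal adjacent depths; zeros omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            arr = track.depths[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Sequences


class SequenceSet(dict):
    """id -> DNA sequence over {A,C,G,T,N}; RNA input is mapped U->T on read."""

    def add(self, seq_id: str, seq: str) -> None:
        if seq_id in self:
            raise SequenceError(f"duplicate sequence id {seq_id!r}")
        seq = seq.upper().replace("U", "T")
        if not seq:
            raise SequenceError(f"{seq_id}: empty sequence")
        if set(seq) - set("ACGTN"):
            raise SequenceError(f"{seq_id}: non-ACGTN symbols {sorted(set(seq) - set('ACGTN'))}")
        self[seq_id] = seq


def load_sequences(path: str | Path) -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet` (uppercased, U->T)."""
    from Bio import SeqIO

    seqs = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.add(rec.id, str(rec.seq))
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id in seqs:
            fh.write(f">{seq_id}\n")
            s = seqs[seq_id]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Experiment design


@dataclass
class ExperimentDesign:
    """Sample sheet: sample_id, assay (rna|chip), condition (vehicle|ddavp), pair_id.

    ChIP samples come in vehicle:ddavp pairs sharing a pair_id (the paired
    study design); RNA samples need no pairing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "assay", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design table missing columns {sorted(missing)}")
        if "pair_id" not in self.table.columns:
            self.table = self.table.assign(pair_id=pd.NA)
        if self.table["sample_id"].duplicated().any():
            raise DesignError("duplicate sample_id in design")
        bad_assay = set(self.table["assay"]) - set(ASSAYS)
        if bad_assay:
            raise DesignError(f"unknown assay values {sorted(bad_assay)}")
        bad_cond = set(self.table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DesignError(f"unknown condition values {sorted(bad_cond)}")
        chip = self.table[self.table["assay"] == "chip"]
        if len(chip):
            if chip["pair_id"].isna().any():
                raise DesignError("chip samples must carry a pair_id")
            for pid, grp in chip.groupby("pair_id"):
                conds = sorted(grp["condition"])
                if conds != ["ddavp", "vehicle"]:
                    raise DesignError(f"chip pair {pid} must be one vehicle + one ddavp sample")

    def samples(self, assay: str, condition: Optional[str] = None) -> List[str]:
        t = self.table[self.table["assay"] == assay]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["sample_id"])

    def chip_pairs(self) -> List[Tuple[str, str]]:
        """(vehicle_sample, ddavp_sample) per pair_id, sorted by pair_id."""
        chip = self.table[self.table["assay"] == "chip"]
        pairs = []
        for pid, grp in sorted(chip.groupby("pair_id"), key=lambda kv: kv[0]):
            veh = grp.loc[grp["condition"] == "vehicle", "sample_id"].iloc[0]
            dda = grp.loc[grp["condition"] == "ddavp", "sample_id"].iloc[0]
            pairs.append((veh, dda))
        return pairs


def load_design(path: str | Path) -> ExperimentDesign:
    table = pd.read_csv(path, sep="\t")
    return ExperimentDesign(table)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)
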