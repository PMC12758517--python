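"""Readers, writers and core containers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) throughout the
package; interval width is always ``end - start``.  GTF-style 1-based inputs
must be converted at the boundary by the caller.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CountMatrix",
    "IntervalSet",
    "GeneModelTable",
    "MotifPFM",
    "FormatError",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_bed",
    "write_bed",
    "read_jaspar",
    "write_jaspar",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


@dataclass
class CountMatrix:
    """Sparse feature × cell matrix of nonnegative integer counts.

    ``modality`` is ``"rna"`` (features are genes) or ``"atac"`` (features are
    peaks, identified as ``chrom:start-end``).
    """

    values: sp.csr_matrix
    feature_ids: list[str]
    barcodes: list[str]
    modality: str = "rna"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = list(self.feature_ids)
        self.barcodes = list(self.barcodes)
        if self.values.shape != (len(self.feature_ids), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.barcodes)} barcodes"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative count entry")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def cell_totals(self) -> np.ndarray:
        """Per-cell library size (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_cells(self, barcodes: Iterable[str]) -> "CountMatrix":
        barcodes = list(barcodes)
        idx = {b: i for i, b in enumerate(self.barcodes)}
        cols = [idx[b] for b in barcodes]
        return CountMatrix(self.values[:, cols], self.feature_ids, barcodes, self.modality)

    def subset_features(self, feature_ids: Iterable[str]) -> "CountMatrix":
        feature_ids = list(feature_ids)
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return CountMatrix(self.values[rows, :], feature_ids, self.barcodes, self.modality)


@dataclass
class IntervalSet:
    """A set of genomic intervals, 0-based half-open."""

    df: pd.DataFrame = field(default_factory=lambda: _empty_interval_df())

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("name", "."), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "start", "end", "name", "strand"]].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise FormatError(f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        rows = []
        for rec in records:
            rec = tuple(rec)
            rows.append(rec + (".",) * (5 - len(rec)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
        if not rows:
            df = _empty_interval_df()
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def ids(self) -> list[str]:
        """Canonical ``chrom:start-end`` identifiers."""
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])]

    def sort(self) -> "IntervalSet":
        return IntervalSet(self.df.sort_values(["chrom", "start", "end"], kind="mergesort"))


def _empty_interval_df() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64), "name": pd.Series(dtype=str),
         "strand": pd.Series(dtype=str)}
    )


def interval_set_from_ids(ids: Iterable[str]) -> IntervalSet:
    """Rebuild an IntervalSet from canonical ``chrom:start-end`` ids."""
    recs = []
    for pid in ids:
        chrom, span = pid.rsplit(":", 1)
        start, end = span.split("-")
        recs.append((chrom, int(start), int(end), pid))
    return IntervalSet.from_records(recs)


@dataclass
class GeneModelTable:
    """Gene id, chromosome, strand and TSS (0-based) for every gene.

    Optional ``start``/``end`` columns carry the transcript span when known.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        required = {"gene_id", "chrom", "strand", "tss"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"gene model table missing columns: {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            raise FormatError("duplicate gene_id in gene model table")
        if len(df) and not df["strand"].isin(["+", "-"]).all():
            raise FormatError("gene strand must be '+' or '-'")
        df["tss"] = df["tss"].astype(np.int64)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def tss_of(self, gene_id: str) -> tuple[str, int]:
        row = self.df.loc[self.df["gene_id"] == gene_id].iloc[0]
        return row["chrom"], int(row["tss"])


@dataclass
class MotifPFM:
    """Position frequency matrix: 4 × width base counts, rows A, C, G, T."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(f"PFM {self.motif_id}: counts must be 4 x width")
        if self.counts.shape[1] < 1:
            raise FormatError(f"PFM {self.motif_id}: zero width")
        if (self.counts < 0).any():
            raise FormatError(f"PFM {self.motif_id}: negative count")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError(f"PFM {self.motif_id}: column with no positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# MatrixMarket triplet + features/barcodes TSV
# ---------------------------------------------------------------------------

def read_mtx_triplet(mtx_path, features_path, barcodes_path, modality: str = "rna") -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet with feature/barcode sidecars.

    Duplicate (i, j) entries are summed, per MatrixMarket coordinate semantics.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises bare ValueError on malformed files
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative entry")
    features = _read_single_column(features_path)
    barcodes = _read_single_column(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{mtx_path}: declared shape {mat.shape} does not match "
            f"{len(features)} features / {len(barcodes)} barcodes"
        )
    csr = sp.csr_matrix(mat)  # sums duplicates
    csr.sum_duplicates()
    return CountMatrix(csr, features, barcodes, modality)


def write_mtx_triplet(matrix: CountMatrix, mtx_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.values), field="integer")
    Path(features_path).write_text("".join(f"{f}\n" for f in matrix.feature_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in matrix.barcodes))


def _read_single_column(path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line.split("\t")[0])
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise FormatError(f"{path}:{ln}: start >= end ({start} >= {end})")
        name = fields[3] if len(fields) > 3 else "."
        strand = fields[5] if len(fields) > 5 else "."
        records.append((chrom, start, end, name, strand))
    return IntervalSet.from_records(records)


def write_bed(intervals: IntervalSet, path, scores: np.ndarray | None = None) -> None:
    """Write BED3/5/6.  If ``scores`` is given, emits name/score/strand columns."""
    with open(path, "w") as fh:
        for i, rec in enumerate(intervals.df.itertuples(index=False)):
            cols = [rec.chrom, str(rec.start), str(rec.end)]
            if rec.name != "." or rec.strand != "." or scores is not None:
                cols.append(rec.name)
            if scores is not None:
                cols.append(f"{scores[i]:g}")
            if rec.strand != "." or scores is not None:
                if len(cols) == 4:
                    cols.append("0")
                cols.append(rec.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# JASPAR 2022 PFM text
# ---------------------------------------------------------------------------

def read_jaspar(path) -> list[MotifPFM]:
    """Parse JASPAR text PFMs: '>ID NAME' header then four 'A [ n n .. ]' rows."""
    text = Path(path).read_text()
    motifs: list[MotifPFM] = []
    blocks = [b for b in text.split(">") if b.strip()]
    for block in blocks:
        lines = [ln for ln in block.splitlines() if ln.strip()]
        header = lines[0].split(None, 1)
        motif_id = header[0]
        name = header[1].strip() if len(header) > 1 else motif_id
        rows: dict[str, list[float]] = {}
        for line in lines[1:]:
            base = line.strip()[0].upper()
            if base not in BASE_INDEX:
                raise FormatError(f"motif {motif_id}: unexpected row '{line.strip()}'")
            body = line.strip()[1:].strip().strip("[]").replace("[", " ").replace("]", " ")
            try:
                rows[base] = [float(x) for x in body.split()]
            except ValueError as exc:
                raise FormatError(f"motif {motif_id}: non-numeric count in row {base}") from exc
        if set(rows) != set(BASES):
            raise FormatError(f"motif {motif_id}: expected rows A,C,G,T, got {sorted(rows)}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise FormatError(f"motif {motif_id}: ragged rows")
        counts = np.array([rows[b] for b in BASES])
        motifs.append(MotifPFM(motif_id, name, counts))
    return motifs


def write_jaspar(motifs: list[MotifPFM], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(f"{v:g}" for v in m.counts[i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA and gene models
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {chrom: sequence}; sequences uppercased, N permitted."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"duplicate chromosome name {record.id}")
        genome[record.id] = str(record.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta-2line" if width == 0 else "fasta")


def read_gene_models(path) -> GeneModelTable:
    df = pd.read_csv(path, sep="\t")
    return GeneModelTable(df)


def write_gene_models(table: GeneModelTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
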