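"""Per-cell QC gates, peak filtering, module scoring and the chromosomal sex filter.

The sex filter verifies the declared sex of each nucleus against two pieces of
evidence: expression of Y-linked genes (``Kdm5d``, ``Eif2s3y``, ``Uty``,
``Ddx3y``) summarized as a rank-based module score, and ATAC fragment counts in
a defined chrY peak region.  Cutoffs are anchored on the latest developmental
stage (default E13.5), where sexual differentiation makes declared labels most
trustworthy: the XY cutoff sits 1 SD below the mean XY module score and the XX
cutoff 1 SD above the mean XX score at that stage.  Earlier-stage cells are
removed from an XY dataset when they have zero chrY fragments AND a score below
the XY cutoff, and from an XX dataset when they have any chrY fragment OR a
score above the XX cutoff.  Boundary ties keep the cell (removal conditions are
strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from scipy.stats import rankdata

from .io import CountMatrix, IntervalSet

DEFAULT_Y_GENES = ("Kdm5d", "Eif2s3y", "Uty", "Ddx3y")

#: chrY peak region used for fragment counting: positions 1-90,000,000 (1-based)
#: converted to 0-based half-open.
DEFAULT_CHRY_REGION = IntervalSet.from_records([("chrY", 0, 90_000_000, "chrY_region")])


@dataclass
class CellTable:
    """Per-cell metadata with QC metrics."""

    df: pd.DataFrame

    REQUIRED = (
        "barcode", "declared_sex", "stage", "cell_type", "n_count_rna",
        "percent_mt", "n_count_atac", "nucleosome_signal", "tss_enrichment",
        "chry_fragments",
    )

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")
        if df["barcode"].duplicated().any():
            raise ValueError("duplicate barcodes in cell table")
        if len(df) and ((df["percent_mt"] < 0) | (df["percent_mt"] > 100)).any():
            raise ValueError("percent_mt outside [0, 100]")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, barcodes) -> "CellTable":
        keep = self.df[self.df["barcode"].isin(set(barcodes))]
        return CellTable(keep)


@dataclass
class SexFilterConfig:
    y_gene_set: tuple[str, ...] = DEFAULT_Y_GENES
    chry_region: IntervalSet = field(default_factory=lambda: DEFAULT_CHRY_REGION)
    reference_stage: str = "E13.5"
    sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_counts(matrix: CountMatrix) -> np.ndarray:
    """Counts-per-median-library depth scaling (linear scale).

    Returns a dense float array (features × cells).  Cells with zero counts
    are left at zero.  Fold changes and detection fractions are computed on
    this scale; apply :func:`log_normalize` for correlation/regression work.
    """
    counts = np.asarray(matrix.values.todense(), dtype=float)
    totals = counts.sum(axis=0)
    scale = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(totals > 0, counts * (scale / np.where(totals > 0, totals, 1.0)), 0.0)


def log_normalize(matrix: CountMatrix) -> np.ndarray:
    """log2(depth-normalized counts + 1)."""
    return np.log2(normalize_counts(matrix) + 1.0)


# ---------------------------------------------------------------------------
# QC gates
# ---------------------------------------------------------------------------

def apply_rna_qc(cells: CellTable, min_count: int = 1000, max_count: int = 25_000,
                 max_percent_mt: float = 25.0) -> list[str]:
    """Keep cells with min_count < nCount_RNA < max_count and percent.mt < max.

    All three inequalities are strict.
    """
    df = cells.df
    for col in ("n_count_rna", "percent_mt"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "barcode"].iloc[0]
            raise ValueError(f"missing {col} for barcode {bad}")
    keep = (df["n_count_rna"] > min_count) & (df["n_count_rna"] < max_count) & \
           (df["percent_mt"] < max_percent_mt)
    return df.loc[keep, "barcode"].tolist()


def apply_atac_qc(cells: CellTable, min_count: int = 1000, max_count: int = 100_000,
                  max_nucleosome_signal: float = 2.0, min_tss_enrichment: float = 1.0) -> list[str]:
    """Keep cells passing the four strict ATAC QC inequalities."""
    df = cells.df
    for col in ("n_count_atac", "nucleosome_signal", "tss_enrichment"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "barcode"].iloc[0]
            raise ValueError(f"missing {col} for barcode {bad}")
    keep = (df["n_count_atac"] > min_count) & (df["n_count_atac"] < max_count) & \
           (df["nucleosome_signal"] < max_nucleosome_signal) & \
           (df["tss_enrichment"] > min_tss_enrichment)
    return df.loc[keep, "barcode"].tolist()


def filter_peaks(peaks: IntervalSet, blacklist: IntervalSet | None = None,
                 min_width: int = 20, max_width: int = 10_000,
                 allowed_chroms: set[str] | None = None) -> IntervalSet:
    """Merge overlapping peaks, then apply size and blacklist filters.

    Overlapping (or bookended) input peaks are first union-reduced; merged
    peaks must then satisfy ``min_width < width < max_width`` (strict); any
    peak overlapping a blacklist interval by >= 1 bp is dropped, as is any
    peak on a chromosome outside ``allowed_chroms`` when given.
    """
    merged = _reduce(peaks)
    widths = merged.widths()
    keep = (widths > min_width) & (widths < max_width)
    df = merged.df[keep]
    if allowed_chroms is not None:
        df = df[df["chrom"].isin(allowed_chroms)]
    if blacklist is not None and len(blacklist):
        trees = build_interval_trees(blacklist)
        hit = df.apply(
            lambda r: r["chrom"] in trees and bool(trees[r["chrom"]].overlap(r["start"], r["end"])),
            axis=1,
        )
        df = df[~hit.to_numpy(dtype=bool)] if len(df) else df
    return IntervalSet(df.reset_index(drop=True))


def _reduce(peaks: IntervalSet) -> IntervalSet:
    """Union-reduce overlapping or adjacent intervals per chromosome."""
    if not len(peaks):
        return peaks
    records = []
    for chrom, grp in peaks.sort().df.groupby("chrom", sort=True):
        cur_start = cur_end = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_start is None:
                cur_start, cur_end = s, e
            elif s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                records.append((chrom, cur_start, cur_end))
                cur_start, cur_end = s, e
        records.append((chrom, cur_start, cur_end))
    recs = [(c, s, e, f"{c}:{s}-{e}") for c, s, e in records]
    return IntervalSet.from_records(recs)


def build_interval_trees(intervals: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in intervals:
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end)
    return trees


# ---------------------------------------------------------------------------
# Module score (rank-based signature score, UCell-style)
# ---------------------------------------------------------------------------

def module_score(rna: CountMatrix, gene_set, r_max: int = 1500,
                 expr: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell rank-based signature score in [0, 1].

    For each cell, genes are ranked by descending expression (average ranks on
    ties), ranks capped at ``r_max``; with S the signature genes present,

        U' = sum_{g in S} min(rank_g, r_max) - |S|(|S|+1)/2
        score = 1 - U' / (|S| * r_max)

    Invariant under monotone transforms of the cell's expression vector.
    ``expr`` may supply a precomputed dense expression array to avoid
    densifying twice.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty signature gene set")
    present = [g for g in gene_set if g in rna.feature_ids]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"signature genes absent from matrix, dropped: {missing}")
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if expr is None:
        expr = np.asarray(rna.values.todense(), dtype=float)
    n_sig = len(present)
    sig_idx = [rna.feature_ids.index(g) for g in present]
    scores = np.empty(rna.n_cells)
    for j in range(rna.n_cells):
        ranks = rankdata(-expr[:, j], method="average")
        capped = np.minimum(ranks[sig_idx], r_max)
        u = capped.sum() - n_sig * (n_sig + 1) / 2.0
        scores[j] = 1.0 - u / (n_sig * r_max)
    return pd.DataFrame({"barcode": rna.barcodes, "score": scores,
                         "signature_id": "+".join(present), "r_max": r_max})


# ---------------------------------------------------------------------------
# Sex filter
# ---------------------------------------------------------------------------

def sex_filter(scores: pd.DataFrame, cells: CellTable,
               cfg: SexFilterConfig | None = None) -> pd.DataFrame:
    """Apply the chromosomal sex verification rule; returns a per-cell verdict.

    Output columns: barcode, declared_sex, stage, score, chry_fragments, kept.
    Reference-stage cells (which define the cutoffs) are kept unfiltered.
    """
    cfg = cfg or SexFilterConfig()
    df = cells.df.merge(scores[["barcode", "score"]], on="barcode", how="left")
    if df["score"].isna().any():
        bad = df.loc[df["score"].isna(), "barcode"].iloc[0]
        raise ValueError(f"no module score for barcode {bad}")

    ref = df[df["stage"] == cfg.reference_stage]
    cutoffs = {}
    for sex, sign in (("XY", -1.0), ("XX", +1.0)):
        ref_scores = ref.loc[ref["declared_sex"] == sex, "score"]
        if len(ref_scores) < 2:
            raise ValueError(f"fewer than 2 {sex} cells at reference stage "
                             f"{cfg.reference_stage}; SD undefined")
        cutoffs[sex] = ref_scores.mean() + sign * cfg.sd_multiplier * ref_scores.std(ddof=1)

    is_ref = (df["stage"] == cfg.reference_stage).to_numpy()
    frags = df["chry_fragments"].to_numpy()
    score = df["score"].to_numpy()
    xy = (df["declared_sex"] == "XY").to_numpy()
    xx = (df["declared_sex"] == "XX").to_numpy()

    remove = np.zeros(len(df), dtype=bool)
    remove |= xy & ~is_ref & (frags == 0) & (score < cutoffs["XY"])
    remove |= xx & ~is_ref & ((frags > 0) | (score > cutoffs["XX"]))

    out = df[["barcode", "declared_sex", "stage", "chry_fragments"]].copy()
    out["score"] = score
    out["kept"] = ~remove
    out.attrs["cutoff_XY"] = cutoffs["XY"]
    out.attrs["cutoff_XX"] = cutoffs["XX"]
    return out


# ---------------------------------------------------------------------------
# Marker-based cell type annotation
# ---------------------------------------------------------------------------

def annotate_cell_types(rna: CountMatrix, marker_sets: dict[str, list[str]],
                        r_max: int = 1500) -> pd.DataFrame:
    """Assign each cell the marker set with the highest module score.

    Ties are broken by lexicographic type name and flagged.
    """
    if not marker_sets:
        raise ValueError("empty marker map")
    expr = np.asarray(rna.values.todense(), dtype=float)
    types = sorted(marker_sets)
    score_mat = np.column_stack([
        module_score(rna, marker_sets[t], r_max=r_max, expr=expr)["score"].to_numpy()
        for t in types
    ])
    best = score_mat.argmax(axis=1)
    max_score = score_mat.max(axis=1)
    tie = (np.isclose(score_mat, max_score[:, None]).sum(axis=1) > 1)
    return pd.DataFrame({
        "barcode": rna.barcodes,
        "cell_type": [types[i] for i in best],
        "score": max_score,
        "tie": tie,
    })
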