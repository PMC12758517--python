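"""Genomic-feature annotation of peaks, region accessibility, and histone-mark
overlap of differential peak sets.

Feature assignment is decided on the peak midpoint with precedence
promoter (TSS ± 3 kb) > exon > first intron > other intron > downstream
(<= 3 kb past the 3' end) > distal intergenic.  All overlap predicates are
>= 1 bp on 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CountMatrix, IntervalSet
from .qc import build_interval_trees
from .differential import wilcoxon_rank_sum

FEATURES = ("promoter", "exon", "first_intron", "other_intron", "downstream",
            "distal_intergenic")

PROMOTER_WINDOW = 3000
DOWNSTREAM_WINDOW = 3000


@dataclass
class GeneAnnotation:
    """Transcript spans, exon spans and TSS positions for annotation.

    ``transcripts``: gene_id, chrom, strand, start, end, tss.
    ``exons``: gene_id, chrom, start, end, rank (rank 1 = first exon in
    transcription order).
    """

    transcripts: pd.DataFrame
    exons: pd.DataFrame


def annotate_peaks(peaks: IntervalSet, annotation: GeneAnnotation) -> pd.DataFrame:
    """Assign one genomic feature per peak, plus nearest gene and signed TSS
    distance (positive = downstream of the TSS in transcription direction)."""
    if annotation is None or not len(annotation.transcripts):
        import warnings
        warnings.warn("empty gene annotation; all peaks distal_intergenic")
        return pd.DataFrame({
            "peak_id": peaks.ids(),
            "feature": ["distal_intergenic"] * len(peaks),
            "nearest_gene": [None] * len(peaks),
            "distance_to_tss": [np.nan] * len(peaks),
        })
    tx = annotation.transcripts

    promoter_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    first_intron_trees: dict[str, IntervalTree] = {}
    other_intron_trees: dict[str, IntervalTree] = {}
    downstream_trees: dict[str, IntervalTree] = {}

    exons_by_gene = {g: df for g, df in annotation.exons.groupby("gene_id")} if len(annotation.exons) else {}

    for row in tx.itertuples():
        chrom = row.chrom
        promoter_trees.setdefault(chrom, IntervalTree()).addi(
            max(0, row.tss - PROMOTER_WINDOW), row.tss + PROMOTER_WINDOW + 1)
        tail = row.end if row.strand == "+" else row.start
        if row.strand == "+":
            downstream_trees.setdefault(chrom, IntervalTree()).addi(tail, tail + DOWNSTREAM_WINDOW + 1)
        else:
            downstream_trees.setdefault(chrom, IntervalTree()).addi(max(0, tail - DOWNSTREAM_WINDOW), tail + 1)
        ex = exons_by_gene.get(row.gene_id)
        if ex is None or not len(ex):
            continue
        ex = ex.sort_values("rank")
        for e in ex.itertuples():
            exon_trees.setdefault(chrom, IntervalTree()).addi(e.start, e.end)
        # introns between consecutive exons in genomic order; the first intron
        # follows exon rank 1 in transcription order
        exg = ex.sort_values("start")
        spans = list(zip(exg["start"], exg["end"], exg["rank"]))
        for (s1, e1, r1), (s2, e2, r2) in zip(spans, spans[1:]):
            if s2 <= e1:
                continue
            is_first = r1 == 1 if row.strand == "+" else r2 == 1
            tree = first_intron_trees if is_first else other_intron_trees
            tree.setdefault(chrom, IntervalTree()).addi(e1, s2)

    def hit(trees, chrom, pos):
        return chrom in trees and bool(trees[chrom].overlap(pos, pos + 1))

    tss_arr = tx["tss"].to_numpy()
    tx_chrom = tx["chrom"].to_numpy()
    tx_strand = tx["strand"].to_numpy()
    tx_gene = tx["gene_id"].to_numpy()

    rows = []
    for pid, rec in zip(peaks.ids(), peaks):
        mid = (rec.start + rec.end) // 2
        if hit(promoter_trees, rec.chrom, mid):
            feature = "promoter"
        elif hit(exon_trees, rec.chrom, mid):
            feature = "exon"
        elif hit(first_intron_trees, rec.chrom, mid):
            feature = "first_intron"
        elif hit(other_intron_trees, rec.chrom, mid):
            feature = "other_intron"
        elif hit(downstream_trees, rec.chrom, mid):
            feature = "downstream"
        else:
            feature = "distal_intergenic"
        same = np.flatnonzero(tx_chrom == rec.chrom)
        if len(same):
            d = mid - tss_arr[same]
            j = same[np.abs(d).argmin()]
            signed = int(mid - tss_arr[j]) if tx_strand[j] == "+" else int(tss_arr[j] - mid)
            nearest, dist = tx_gene[j], signed
        else:
            nearest, dist = None, np.nan
        rows.append((pid, feature, nearest, dist))
    return pd.DataFrame(rows, columns=["peak_id", "feature", "nearest_gene", "distance_to_tss"])


# ---------------------------------------------------------------------------
# region accessibility
# ---------------------------------------------------------------------------

def counts_in_region(atac: CountMatrix, peaks: IntervalSet, region_set: IntervalSet,
                     barcodes: list[str] | None = None,
                     groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-cell summed ATAC counts over peaks overlapping a region set.

    A matrix peak is counted when it overlaps any region by >= 1 bp.  Returns
    (barcode, summed_counts[, group]); a ``per_group_mean`` attrs entry holds
    group means when ``groups`` (indexed by barcode) is given.
    """
    if atac.n_features != len(peaks):
        raise ValueError("atac matrix rows do not match the peak set")
    trees = build_interval_trees(region_set)
    matched = [
        i for i, rec in enumerate(peaks)
        if rec.chrom in trees and bool(trees[rec.chrom].overlap(rec.start, rec.end))
    ]
    sub = atac.values[matched, :] if matched else None
    sums = np.asarray(sub.sum(axis=0)).ravel() if sub is not None else np.zeros(atac.n_cells)
    out = pd.DataFrame({"barcode": atac.barcodes, "summed_counts": sums})
    if barcodes is not None:
        out = out[out["barcode"].isin(set(barcodes))].reset_index(drop=True)
    if groups is not None:
        out["group"] = out["barcode"].map(groups)
        out.attrs["per_group_mean"] = out.groupby("group")["summed_counts"].mean().to_dict()
    return out


def compare_region_accessibility(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of per-cell region accessibility."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs >= 2 cells")
    return {
        "p_value": wilcoxon_rank_sum(values_a, values_b),
        "median_a": float(np.median(values_a)),
        "median_b": float(np.median(values_b)),
    }


# ---------------------------------------------------------------------------
# histone marks
# ---------------------------------------------------------------------------

def histone_overlap(dap_set: IntervalSet, chip_peaks: IntervalSet,
                    dap_set_id: str = "", mark: str = "", cell_state: str = "") -> dict:
    """Percentage of a DAP set overlapping a ChIP track by >= 1 bp."""
    if not len(dap_set):
        raise ValueError("empty DAP set: percentage undefined")
    trees = build_interval_trees(chip_peaks)
    n_hit = sum(
        1 for rec in dap_set
        if rec.chrom in trees and bool(trees[rec.chrom].overlap(rec.start, rec.end))
    )
    return {
        "dap_set_id": dap_set_id,
        "mark": mark,
        "cell_state": cell_state,
        "n_overlapping": n_hit,
        "n_total": len(dap_set),
        "percent_positive": 100.0 * n_hit / len(dap_set),
    }


def bivalent_peaks(dap_set: IntervalSet, k4me3_set: IntervalSet, k27me3_set: IntervalSet,
                   links: pd.DataFrame | None = None) -> tuple[IntervalSet, list[str]]:
    """DAPs overlapping both H3K4me3 and H3K27me3 (>= 1 bp each), with the
    genes linked to them when a links table is supplied."""
    t4 = build_interval_trees(k4me3_set)
    t27 = build_interval_trees(k27me3_set)
    keep = [
        i for i, rec in enumerate(dap_set)
        if rec.chrom in t4 and bool(t4[rec.chrom].overlap(rec.start, rec.end))
        and rec.chrom in t27 and bool(t27[rec.chrom].overlap(rec.start, rec.end))
    ]
    bivalent = IntervalSet(dap_set.df.iloc[keep].reset_index(drop=True))
    genes: list[str] = []
    if links is not None and len(links) and keep:
        ids = set(bivalent.ids())
        genes = sorted(set(links.loc[links["peak_id"].isin(ids), "gene_id"]))
    return bivalent, genes
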