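"""Peak-gene linkage and DEG/DAP categorization across developmental stages.

A peak is a candidate regulator of a gene when its midpoint lies within
500 kb of the gene's TSS.  For each candidate pair, the Pearson correlation
between peak accessibility (depth-scaled counts) and normalized gene
expression is computed across the entire cell set, then compared with the
correlations of background peaks matched to the focal peak on GC fraction,
mean accessibility and width; the resulting z-score yields a two-sided
normal p-value.  Links with p below the cutoff are retained with their sign.

DEGs are then classified by their significant links: ``linked_DAP`` when at
least one linked peak is itself differentially accessible for the same
contrast, ``linked_nonDAP`` when links exist but none is a DAP, and
``no_linked_peak`` otherwise.  Stage-to-stage transitions between those
categories, and the "newly formed linked-DAP" peak sets they define, follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, GeneModelTable, IntervalSet, interval_set_from_ids

CATEGORIES = ("linked_DAP", "linked_nonDAP", "no_linked_peak")


@dataclass
class PeakGeneLink:
    peak_id: str
    gene_id: str
    r: float
    z: float
    p_value: float
    distance_bp: int
    sign: str


def gc_fraction(genome: dict[str, str], intervals: IntervalSet) -> np.ndarray:
    """Per-interval GC fraction of the genome sequence."""
    out = np.empty(len(intervals))
    for i, rec in enumerate(intervals):
        seq = genome[rec.chrom][rec.start:rec.end]
        out[i] = (seq.count("G") + seq.count("C")) / max(1, len(seq))
    return out


def _standardize(cols: np.ndarray) -> np.ndarray:
    mu = cols.mean(axis=0)
    sd = cols.std(axis=0)
    sd[sd == 0] = 1.0
    return (cols - mu) / sd


def link_peaks(atac: CountMatrix, rna_normalized: np.ndarray, rna_feature_ids: list[str],
               peaks: IntervalSet, gene_models: GeneModelTable,
               genome: dict[str, str], genes: list[str] | None = None,
               distance: int = 500_000, n_background: int = 200,
               p_cutoff: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Compute significant peak-gene links over the entire cell set.

    ``atac`` rows must correspond 1:1 to ``peaks``; ``rna_normalized`` is a
    dense genes × cells matrix aligned with ``rna_feature_ids`` and the same
    cell ordering as ``atac``.  Returns a links table (peak_id, gene_id, r, z,
    p_value, distance_bp, sign) with p < ``p_cutoff``.
    """
    if atac.n_features != len(peaks):
        raise ValueError("atac matrix rows do not match the peak set")
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else list(rna_feature_ids)

    acc = np.asarray(atac.values.todense(), dtype=float)
    depth = acc.sum(axis=0)
    scale = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    acc_scaled = np.where(depth > 0, acc * (scale / np.where(depth > 0, depth, 1.0)), 0.0)

    # standardized matrices -> full peak x gene correlation in one product
    gidx = {g: i for i, g in enumerate(rna_feature_ids)}
    gene_rows = [gidx[g] for g in genes if g in gidx]
    gene_list = [g for g in genes if g in gidx]
    expr = rna_normalized[gene_rows, :]
    n_cells = acc_scaled.shape[1]

    def zrows(mat):
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, keepdims=True)
        ok = sd.ravel() > 0
        out = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return out, ok

    zp, peak_ok = zrows(acc_scaled)
    zg, gene_ok = zrows(expr)
    corr = zp @ zg.T / n_cells

    # background-matching features
    feats = _standardize(np.column_stack([
        gc_fraction(genome, peaks),
        acc_scaled.mean(axis=1),
        peaks.widths().astype(float),
    ]))
    n_peaks = len(peaks)
    k_query = min(n_peaks, 3 * n_background + 50)
    nn = NearestNeighbors(n_neighbors=k_query).fit(feats)
    _, neighbor_idx = nn.kneighbors(feats)

    mids = peaks.midpoints()
    peak_chrom = peaks.df["chrom"].to_numpy()
    peak_ids = peaks.ids()
    gmdf = gene_models.df.set_index("gene_id")

    rows = []
    n_evaluated = 0
    for gj, gene in enumerate(gene_list):
        if gene not in gmdf.index:
            continue
        g_chrom, g_tss = gmdf.loc[gene, "chrom"], int(gmdf.loc[gene, "tss"])
        in_window = (peak_chrom == g_chrom) & (np.abs(mids - g_tss) <= distance)
        cand = np.flatnonzero(in_window)
        if not len(cand) or not gene_ok[gj]:
            continue
        window_set = set(cand.tolist())
        for pi in cand:
            if not peak_ok[pi]:
                continue
            r = corr[pi, gj]
            # matched background: nearest peaks in feature space outside the
            # gene's linkage window
            pool = [q for q in neighbor_idx[pi] if q != pi and q not in window_set
                    and peak_ok[q]]
            if len(pool) < n_background:
                warnings.warn(f"background pool for {peak_ids[pi]} has only "
                              f"{len(pool)} peaks (< {n_background})")
                chosen = np.array(pool, dtype=int)
            else:
                take = min(len(pool), int(1.5 * n_background))
                chosen = rng.choice(pool[:take], size=n_background, replace=False)
            if len(chosen) < 2:
                continue
            null_r = corr[chosen, gj]
            sd = null_r.std(ddof=1)
            if sd == 0:
                continue
            z = (r - null_r.mean()) / sd
            p = 2.0 * norm.sf(abs(z))
            n_evaluated += 1
            if p < p_cutoff:
                rows.append((peak_ids[pi], gene, float(r), float(z), float(p),
                             int(abs(mids[pi] - g_tss)),
                             "positive" if r >= 0 else "negative"))
    out = pd.DataFrame(rows, columns=["peak_id", "gene_id", "r", "z", "p_value",
                                      "distance_bp", "sign"])
    out.attrs["n_candidates_evaluated"] = n_evaluated
    return out


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def categorize_degs(degs: list[str] | pd.Series, daps: list[str] | pd.Series,
                    links: pd.DataFrame) -> pd.DataFrame:
    """Classify each DEG by its significant links.

    Returns (gene_id, category, supporting_peaks) where supporting_peaks is a
    comma-joined list of linked DAPs (linked_DAP) or linked peaks
    (linked_nonDAP).
    """
    dap_set = set(daps)
    by_gene = links.groupby("gene_id")["peak_id"].agg(list) if len(links) else pd.Series(dtype=object)
    rows = []
    for gene in degs:
        linked = by_gene.get(gene, [])
        linked_daps = [p for p in linked if p in dap_set]
        if linked_daps:
            cat, support = "linked_DAP", linked_daps
        elif linked:
            cat, support = "linked_nonDAP", linked
        else:
            cat, support = "no_linked_peak", []
        rows.append((gene, cat, ",".join(sorted(set(support)))))
    return pd.DataFrame(rows, columns=["gene_id", "category", "supporting_peaks"])


def annotate_daps(daps: list[str] | pd.Series, degs: list[str] | pd.Series,
                  links: pd.DataFrame) -> pd.DataFrame:
    """Mirror-image classification of DAPs by their linked genes."""
    deg_set = set(degs)
    by_peak = links.groupby("peak_id")["gene_id"].agg(list) if len(links) else pd.Series(dtype=object)
    rows = []
    for peak in daps:
        linked = by_peak.get(peak, [])
        linked_degs = [g for g in linked if g in deg_set]
        if linked_degs:
            cat, support = "linked_DEG", linked_degs
        elif linked:
            cat, support = "linked_nonDEG", linked
        else:
            cat, support = "no_linked_gene", []
        rows.append((peak, cat, ",".join(sorted(set(support)))))
    return pd.DataFrame(rows, columns=["peak_id", "category", "supporting_genes"])


def track_transitions(categories_t1: pd.DataFrame,
                      categories_t2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-to-stage category transitions for the union of DEGs.

    Genes absent from a stage's DEG list carry category ``absent``.  Returns
    (per-gene records with a flow label, flow count table).  The flow table's
    attrs carry ``frac_nonDAP_to_DAP``: the fraction of stage-1 linked_nonDAP
    genes that became linked_DAP at stage 2.
    """
    c1 = categories_t1.set_index("gene_id")["category"]
    c2 = categories_t2.set_index("gene_id")["category"]
    genes = sorted(set(c1.index) | set(c2.index))
    rows = [(g, c1.get(g, "absent"), c2.get(g, "absent")) for g in genes]
    records = pd.DataFrame(rows, columns=["gene_id", "category_t1", "category_t2"])
    records["flow"] = records["category_t1"] + "→" + records["category_t2"]
    flows = (records.groupby(["category_t1", "category_t2"]).size()
             .reset_index(name="count"))
    n_teal = (records["category_t1"] == "linked_nonDAP").sum()
    n_conv = ((records["category_t1"] == "linked_nonDAP") &
              (records["category_t2"] == "linked_DAP")).sum()
    flows.attrs["frac_nonDAP_to_DAP"] = float(n_conv / n_teal) if n_teal else float("nan")
    return records, flows


def newly_formed_linked_daps(categories_t1: pd.DataFrame, categories_t2: pd.DataFrame,
                             links_t2: pd.DataFrame, daps_t2) -> IntervalSet:
    """Unique DAPs linked (at stage 2) to genes newly in the linked_DAP category.

    A gene contributes when its stage-2 category is linked_DAP and its stage-1
    category is anything else (linked_nonDAP, no_linked_peak or absent);
    stage-persistent linked_DAP genes are excluded.  Peaks shared between
    contributing genes are deduplicated by coordinates.
    """
    c1 = categories_t1.set_index("gene_id")["category"]
    dap_set = set(daps_t2)
    new_genes = [
        g for g in categories_t2.loc[categories_t2["category"] == "linked_DAP", "gene_id"]
        if c1.get(g, "absent") != "linked_DAP"
    ]
    if not len(links_t2):
        return interval_set_from_ids([])
    sel = links_t2[links_t2["gene_id"].isin(set(new_genes)) &
                   links_t2["peak_id"].isin(dap_set)]
    unique_ids = sorted(set(sel["peak_id"]))
    return interval_set_from_ids(unique_ids)
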