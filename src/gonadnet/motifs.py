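"""PWM scanning, GC-matched motif enrichment, per-cell motif activity
deviations, and TF→target network assembly.

PFMs are converted to log2-odds PWMs against a 0-order background; scan
thresholds are score quantiles of the exact null score distribution, computed
by dynamic programming over discretized scores.  Motif enrichment compares
hit-bearing target peaks with GC/accessibility-matched background peaks via
the hypergeometric upper tail, BH-adjusted, with the standard pass filter
(adjusted p < 0.05 and fold enrichment > 1.25).  Per-cell motif activity
follows the chromVAR recipe: raw deviation of observed-vs-expected counts in
the motif peak set, z-scored against matched background peak sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.neighbors import NearestNeighbors

from .differential import adjust_pvalues
from .io import BASES, CountMatrix, IntervalSet, MotifPFM
from .linkage import gc_fraction


@dataclass
class PWM:
    motif_id: str
    log_odds: np.ndarray  # 4 x width, rows A,C,G,T, log2 scale
    background: np.ndarray
    pseudocount: float
    name: str = ""

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.log_odds[::-1, ::-1].copy(),
                   self.background, self.pseudocount, self.name)


def pfm_to_pwm(pfm: MotifPFM, pseudocount: float = 0.8,
               background: np.ndarray | None = None) -> PWM:
    """Convert base counts to log2-odds scores.

    Per column, ``p_b = (count_b + 4 * pc * bg_b) / (colsum + 4 * pc)`` — the
    pseudocount is split across bases in proportion to the background — and
    the score is ``log2(p_b / bg_b)``.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    if pseudocount == 0 and (counts == 0).any():
        raise ValueError("zero count with zero pseudocount: log-odds undefined")
    prob = (counts + 4.0 * pseudocount * bg[:, None]) / (colsum + 4.0 * pseudocount)
    return PWM(pfm.motif_id, np.log2(prob / bg[:, None]), bg, pseudocount, pfm.name)


def score_threshold(pwm: PWM, p: float = 1e-4, resolution: float = 1e-3) -> float:
    """Smallest score whose null upper-tail mass is <= p.

    The exact distribution of scores of random k-mers under the 0-order
    background is accumulated column by column over a discretized score grid
    (bin width = ``resolution``); scores are floored onto the grid, so the
    returned threshold is conservative to within one bin.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    scaled = np.floor(pwm.log_odds / resolution).astype(np.int64)
    dist = np.ones(1)  # dist[i] = P(partial score index == offset + i)
    offset = 0
    for j in range(pwm.width):
        col = scaled[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + (cmax - cmin))
        for b in range(4):
            new[col[b] - cmin: col[b] - cmin + len(dist)] += pwm.background[b] * dist
        dist = new
        offset += cmin
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.flatnonzero(tail <= p + 1e-12)
    i = idx[0] if len(idx) else len(dist)
    return (offset + i) * resolution


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Window scores for one strand; windows containing N score -inf."""
    w = lo.shape[1]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(w):
        c = codes[j: j + n_win]
        miss = c < 0
        bad |= miss
        scores += np.where(miss, 0.0, lo[np.where(miss, 0, c), j])
    scores[bad] = -np.inf
    return scores


def scan_peaks(pwm: PWM, peaks: IntervalSet, genome: dict[str, str],
               threshold: float, resolution: float = 1e-3) -> pd.DataFrame:
    """Report every window on either strand scoring >= threshold.

    Window scores are computed on the same per-column score grid used by
    :func:`score_threshold` (columns floored to multiples of ``resolution``),
    so a threshold from that function selects exactly the k-mers whose
    discretized null score clears it.  Minus-strand hits are windows whose
    reverse complement matches; their coordinates are given on the forward
    strand.  Returns (motif_id, chrom, start, end, strand, score, peak_id).
    """
    rc = pwm.reverse_complement()
    w = pwm.width
    rows = []
    quant = {
        "+": np.floor(pwm.log_odds / resolution) * resolution,
        "-": np.floor(rc.log_odds / resolution) * resolution,
    }
    for pid, rec in zip(peaks.ids(), peaks):
        seq = genome[rec.chrom][rec.start:rec.end]
        if len(seq) < w:
            continue
        codes = encode_sequence(seq)
        for strand, mat in (("+", quant["+"]), ("-", quant["-"])):
            scores = _scan_strand(codes, mat)
            for off in np.flatnonzero(scores >= threshold - 1e-9):
                rows.append((pwm.motif_id, rec.chrom, rec.start + int(off),
                             rec.start + int(off) + w, strand, float(scores[off]), pid))
    return pd.DataFrame(rows, columns=["motif_id", "chrom", "start", "end",
                                       "strand", "score", "peak_id"])


def scan_motif_library(motifs: list[MotifPFM], peaks: IntervalSet,
                       genome: dict[str, str], hit_p: float = 1e-4,
                       pseudocount: float = 0.8) -> pd.DataFrame:
    """Scan a PFM library over a peak set; one threshold per motif."""
    frames = []
    for pfm in motifs:
        pwm = pfm_to_pwm(pfm, pseudocount=pseudocount)
        thr = score_threshold(pwm, p=hit_p)
        frames.append(scan_peaks(pwm, peaks, genome, thr))
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["motif_id", "chrom", "start", "end",
                                       "strand", "score", "peak_id"]))


# ---------------------------------------------------------------------------
# GC-matched backgrounds and enrichment
# ---------------------------------------------------------------------------

def peak_match_features(peaks: IntervalSet, atac: CountMatrix,
                        genome: dict[str, str]) -> np.ndarray:
    """Standardized (GC fraction, mean accessibility) per peak."""
    gc = gc_fraction(genome, peaks)
    mean_acc = np.asarray(atac.values.mean(axis=1)).ravel()
    feats = np.column_stack([gc, mean_acc])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    return (feats - mu) / sd


def match_background_peaks(target_peaks: IntervalSet, pool_peaks: IntervalSet,
                           atac: CountMatrix, genome: dict[str, str], n: int,
                           seed: int = 0) -> IntervalSet:
    """Select n pool peaks matching the targets on GC and mean accessibility.

    Pool peaks are ranked by distance to their nearest target in the
    standardized feature space (seeded jitter breaks ties); the n closest are
    returned.  If the pool is smaller than n, the whole pool is used with a
    warning.
    """
    if n == 0 or not len(pool_peaks):
        return IntervalSet.from_records([])
    target_ids = set(target_peaks.ids())
    if target_ids & set(pool_peaks.ids()):
        raise ValueError("background pool must be disjoint from targets")
    combined = IntervalSet(pd.concat([target_peaks.df, pool_peaks.df], ignore_index=True))
    order = combined.ids()
    atac_cmb = atac.subset_features([pid for pid in order if pid in set(atac.feature_ids)]) \
        if set(order) <= set(atac.feature_ids) else atac
    feats = peak_match_features(combined, atac_cmb, genome)
    tf = feats[: len(target_peaks)]
    pf = feats[len(target_peaks):]
    nn = NearestNeighbors(n_neighbors=1).fit(tf)
    dist, _ = nn.kneighbors(pf)
    dist = dist.ravel()
    rng = np.random.default_rng(seed)
    dist = dist + rng.uniform(0, 1e-9, size=len(dist))
    if len(pool_peaks) < n:
        warnings.warn(f"background pool ({len(pool_peaks)}) smaller than n={n}; using all")
        chosen = np.arange(len(pool_peaks))
    else:
        chosen = np.argsort(dist)[:n]
    return IntervalSet(pool_peaks.df.iloc[np.sort(chosen)].reset_index(drop=True))


def motif_enrichment(hits: pd.DataFrame, target_peaks: IntervalSet,
                     background_peaks: IntervalSet,
                     p_cutoff: float = 0.05, fold_cutoff: float = 1.25) -> pd.DataFrame:
    """Hypergeometric enrichment of motif-bearing peaks in targets vs background.

    A peak counts once per motif regardless of hit multiplicity.  ``passes``
    is adjusted p < 0.05 AND fold enrichment > 1.25.
    """
    if not len(target_peaks):
        raise ValueError("empty target peak set")
    t_ids = set(target_peaks.ids())
    b_ids = set(background_peaks.ids())
    n_t, n_b = len(t_ids), len(b_ids)
    rows = []
    motif_ids = sorted(hits["motif_id"].unique()) if len(hits) else []
    for mid in motif_ids:
        peaks_with_hit = set(hits.loc[hits["motif_id"] == mid, "peak_id"])
        k_t = len(peaks_with_hit & t_ids)
        k_b = len(peaks_with_hit & b_ids)
        K = k_t + k_b
        p = float(hypergeom.sf(k_t - 1, n_t + n_b, K, n_t))
        rate_b = k_b / n_b if n_b else np.nan
        fold = (k_t / n_t) / rate_b if rate_b and rate_b > 0 else np.inf if k_t else np.nan
        rows.append((mid, k_t, n_t, k_b, n_b, fold, p))
    out = pd.DataFrame(rows, columns=["motif_id", "n_target_with_hit", "n_target",
                                      "n_bg_with_hit", "n_bg", "fold_enrichment",
                                      "p_value"])
    out["p_adjusted"] = adjust_pvalues(out["p_value"].to_numpy(), method="BH") if len(out) else []
    out["passes"] = (out["p_adjusted"] < p_cutoff) & (out["fold_enrichment"] > fold_cutoff)
    return out


# ---------------------------------------------------------------------------
# chromVAR-style deviations
# ---------------------------------------------------------------------------

def chromvar_deviations(atac: CountMatrix, annotation: pd.DataFrame,
                        peaks: IntervalSet, genome: dict[str, str],
                        n_background_sets: int = 50, seed: int = 0,
                        n_neighbors: int = 50) -> dict[str, pd.DataFrame]:
    """Per-cell motif activity deviations with matched background correction.

    ``annotation`` is a boolean peaks × motifs frame (index = peak ids).  For
    motif set M and cell i with depth d_i: E_i = total_M * d_i / total_all and
    raw_i = (X_iM - E_i) / E_i.  Background sets replace each member peak with
    one of its ``n_neighbors`` nearest peaks in (GC, accessibility) space;
    z_i = (raw_i - mean_bg) / sd_bg.  Cells with E_i = 0 are masked (NaN).

    Returns {"raw": cells × motifs, "z": cells × motifs}.
    """
    counts = np.asarray(atac.values.todense(), dtype=float)
    depth = counts.sum(axis=0)
    total_all = depth.sum()
    peak_totals = counts.sum(axis=1)
    feats = peak_match_features(peaks, atac, genome)
    k = min(n_neighbors + 1, len(peaks))
    nn = NearestNeighbors(n_neighbors=k).fit(feats)
    _, nbr = nn.kneighbors(feats)
    nbr = nbr[:, 1:]  # drop self
    rng = np.random.default_rng(seed)

    pid_index = {pid: i for i, pid in enumerate(peaks.ids())}
    raw_cols, z_cols = {}, {}
    for motif in annotation.columns:
        members = np.array([pid_index[p] for p in annotation.index[annotation[motif]]],
                           dtype=int)
        if not len(members):
            raw_cols[motif] = np.full(atac.n_cells, np.nan)
            z_cols[motif] = np.full(atac.n_cells, np.nan)
            continue

        def raw_dev(idx):
            x = counts[idx].sum(axis=0)
            expected = peak_totals[idx].sum() * depth / total_all
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(expected > 0, (x - expected) / expected, np.nan)

        raw = raw_dev(members)
        bg = np.empty((n_background_sets, atac.n_cells))
        for s in range(n_background_sets):
            picks = nbr[members, rng.integers(0, nbr.shape[1], size=len(members))]
            bg[s] = raw_dev(picks)
        mu = np.nanmean(bg, axis=0)
        sd = np.nanstd(bg, axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (raw - mu) / sd, np.nan)
        raw_cols[motif] = raw
        z_cols[motif] = z
    index = pd.Index(atac.barcodes, name="barcode")
    return {"raw": pd.DataFrame(raw_cols, index=index),
            "z": pd.DataFrame(z_cols, index=index)}


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def build_regulatory_network(enrichment: pd.DataFrame, degs: list[str],
                             hits: pd.DataFrame, links: pd.DataFrame,
                             daps: list[str],
                             motif_tf_map: dict[str, str],
                             expressed_genes: list[str] | None = None) -> pd.DataFrame:
    """TF→target edges from enriched motifs whose TF gene is itself a DEG.

    For each passing motif with TF gene in the DEG list: an edge to every gene
    significantly linked to a focal DAP containing a hit of that motif; the
    edge sign is the sign of the supporting peak-gene link.  A TF may both
    activate and (apparently) repress the same gene through different peaks,
    so rows are one per (tf, target, sign), listing the mediating peaks
    ordered by descending link strength (|z|).
    """
    deg_set = set(degs)
    dap_set = set(daps)
    rows = []
    passing = enrichment.loc[enrichment["passes"], "motif_id"] if len(enrichment) else []
    for mid in passing:
        tf = motif_tf_map.get(mid)
        if tf is None:
            continue
        if expressed_genes is not None and tf not in set(expressed_genes):
            warnings.warn(f"enriched motif {mid}: TF gene {tf} absent from matrix; skipped")
            continue
        if tf not in deg_set:
            continue
        mh = hits[(hits["motif_id"] == mid) & hits["peak_id"].isin(dap_set)]
        if not len(mh):
            continue
        hit_peaks = mh.groupby("peak_id")
        for peak_id, grp in hit_peaks:
            coords = ";".join(f"{r.chrom}:{r.start}-{r.end}({r.strand})"
                              for r in grp.itertuples())
            linked = links[links["peak_id"] == peak_id]
            for lr in linked.itertuples():
                strength = abs(getattr(lr, "z", lr.r if hasattr(lr, "r") else 0.0))
                rows.append((tf, lr.gene_id, lr.sign, strength, peak_id, coords))
    df = pd.DataFrame(rows, columns=["tf", "target_gene", "sign", "strength",
                                     "peak_id", "hit_coordinates"])
    if not len(df):
        return pd.DataFrame(columns=["tf", "target_gene", "sign", "mediating_peaks",
                                     "hit_coordinates"])

    def collapse(grp: pd.DataFrame) -> pd.Series:
        grp = grp.sort_values("strength", ascending=False)
        return pd.Series({
            "strength": float(grp["strength"].iloc[0]),
            "mediating_peaks": ",".join(dict.fromkeys(grp["peak_id"])),
            "hit_coordinates": ";".join(dict.fromkeys(grp["hit_coordinates"])),
        })

    agg = (df.groupby(["tf", "target_gene", "sign"], sort=True)
           .apply(collapse, include_groups=False).reset_index())
    return agg


def motif_cooccurrence(edges: pd.DataFrame, scope: str = "gene") -> pd.DataFrame:
    """Symmetric TF × TF matrix counting shared distinct target genes.

    value(A, B) = number of distinct targets with both an A→target and a
    B→target edge; the diagonal is each TF's distinct-target count.  With
    ``scope="peak"`` sharing is counted at the mediating-peak level instead.
    """
    if scope not in ("gene", "peak"):
        raise ValueError("scope must be 'gene' or 'peak'")
    if not len(edges):
        return pd.DataFrame()
    if scope == "gene":
        pairs = edges[["tf", "target_gene"]].drop_duplicates()
        unit = "target_gene"
    else:
        pairs = (edges.assign(peak=edges["mediating_peaks"].str.split(","))
                 .explode("peak")[["tf", "peak"]].drop_duplicates())
        unit = "peak"
    tfs = sorted(pairs["tf"].unique())
    sets = {tf: set(pairs.loc[pairs["tf"] == tf, unit]) for tf in tfs}
    mat = np.array([[len(sets[a] & sets[b]) for b in tfs] for a in tfs], dtype=int)
    return pd.DataFrame(mat, index=tfs, columns=tfs)
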