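"""Synthetic joint RNA+ATAC single-nucleus data with known ground truth.

The generator emulates the statistical structure of a multiome experiment on
embryonic gonads: cell populations organized by (sex in {XX, XY}) x (stage in
{E11.5, E12.5, E13.5}) x cell type, with the supporting lineage sex-restricted
(Sertoli only in XY, pregranulosa only in XX).  It plants, with full truth
tables:

* sex-differential genes (DEGs) between Sertoli and pregranulosa cells,
  including designated TF genes;
* sex-differential peaks (DAPs), a configurable fraction of which only become
  differential from E12.5 onward ("late onset", which creates the
  linked-non-DAP -> linked-DAP category transitions downstream);
* peak-gene links: a linked peak and its target gene share a per-cell latent
  factor, the peak lies within 500 kb of the target's TSS, and the link sign
  is the sign of the peak's loading;
* motif instances: each motif's consensus is substituted into the genome
  sequence of a fraction of its host DAP set, on a random strand;
* histone ChIP tracks covering a configured fraction of each DAP set;
* Y-linked genes and chrY peaks with exactly zero signal in XX cells.

RNA counts are negative binomial with lognormal per-cell size factors; ATAC
counts are Poisson with rate = size factor x peak propensity x group
multiplier x exp(loading x latent factor).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .io import (BASES, CountMatrix, GeneModelTable, IntervalSet, MotifPFM,
                 write_bed, write_fasta, write_gene_models, write_mtx_triplet)
from .qc import CellTable

STAGES = ("E11.5", "E12.5", "E13.5")
SEXES = ("XX", "XY")
MARKS = ("H3K4me3", "H3K27me3", "H3K27ac")

DEFAULT_MARKERS = {
    "epithelial": ["Upk3b", "Krt19", "Lhx9", "Epcam", "Wt1"],
    "presupporting": ["Sfrp1", "Wnt5a", "Nr0b1", "Cbx2", "Runx1"],
    "Sertoli": ["Amh", "Sox9", "Dhh", "Ptgds", "Inha"],
    "pregranulosa": ["Fst", "Foxl2", "Wnt4", "Irx3", "Rspo1"],
}

DEFAULT_Y_GENES = ("Kdm5d", "Eif2s3y", "Uty", "Ddx3y")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def make_default_motifs() -> list[MotifPFM]:
    """Three sharp synthetic motifs, each tied to a TF gene by name."""
    consensi = {
        ("M_SOX9", "Sox9"): "AACAATGG",
        ("M_DMRT1", "Dmrt1"): "TTGCACTT",
        ("M_LEF1", "Lef1"): "CTTTGTTC",
    }
    motifs = []
    for (mid, name), cons in consensi.items():
        counts = np.zeros((4, len(cons)))
        for j, base in enumerate(cons):
            counts[BASES.index(base), j] = 100.0
        motifs.append(MotifPFM(mid, name, counts))
    return motifs


@dataclass
class SimConfig:
    """Parameters of the synthetic multiome experiment.

    Fractions are in [0, 1]; counts nonnegative; at least two chromosomes are
    required (the last is designated chrY).
    """

    seed: int = 0
    n_cells_per_group: int = 110
    cell_types: tuple[str, ...] = ("epithelial", "presupporting", "Sertoli", "pregranulosa")
    stages: tuple[str, ...] = STAGES
    n_genes: int = 500
    n_peaks: int = 2000
    genome_length_bp: int = 20_000_000
    n_chromosomes: int = 3
    mean_library_rna: float = 5000.0
    mean_library_atac: float = 10000.0
    nb_dispersion: float = 0.1
    deg_log2fc: float = 1.0
    dap_log2fc: float = 2.0
    frac_deg: float = 0.10
    frac_dap: float = 0.10
    frac_dap_late: float = 0.3
    link_strength: float = 0.35
    frac_linked: float = 0.5
    frac_negative_links: float = 0.2
    motif_library: list[MotifPFM] = field(default_factory=make_default_motifs)
    plant_rate: float = 0.8
    histone_overlap_frac: float | dict[str, float] = 0.4
    y_gene_ids: tuple[str, ...] = DEFAULT_Y_GENES
    n_chry_peaks: int = 5
    marker_sets: dict[str, list[str]] = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_MARKERS.items()})
    peak_width_range: tuple[int, int] = (300, 700)
    size_factor_sigma: float = 0.3

    def __post_init__(self) -> None:
        fracs = [self.frac_deg, self.frac_dap, self.frac_dap_late, self.frac_linked,
                 self.frac_negative_links, self.plant_rate]
        if isinstance(self.histone_overlap_frac, dict):
            fracs.extend(self.histone_overlap_frac.values())
        else:
            fracs.append(self.histone_overlap_frac)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        if min(self.n_cells_per_group, self.n_genes, self.n_peaks) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_chromosomes < 2:
            raise ValueError("at least 2 chromosomes required (one must be chrY)")

    def histone_frac(self, mark: str) -> float:
        if isinstance(self.histone_overlap_frac, dict):
            return self.histone_overlap_frac[mark]
        return self.histone_overlap_frac

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes - 1)] + ["chrY"]


@dataclass
class TruthTables:
    true_degs: pd.DataFrame
    true_daps: pd.DataFrame
    true_links: pd.DataFrame
    true_motif_sites: pd.DataFrame
    true_network_edges: pd.DataFrame
    true_histone_membership: pd.DataFrame

    TABLES = ("true_degs", "true_daps", "true_links", "true_motif_sites",
              "true_network_edges", "true_histone_membership")

    SCHEMAS = {
        "true_degs": ["gene_id", "contrast", "sign"],
        "true_daps": ["peak_id", "contrast", "sign"],
        "true_links": ["peak_id", "gene_id", "sign"],
        "true_motif_sites": ["motif_id", "chrom", "start", "end", "strand"],
        "true_network_edges": ["tf", "target", "sign"],
        "true_histone_membership": ["peak_id", "mark", "cell_state", "member"],
    }

    @classmethod
    def empty(cls) -> "TruthTables":
        return cls(**{name: pd.DataFrame(columns=cols)
                      for name, cols in cls.SCHEMAS.items()})


@dataclass
class SyntheticDataset:
    rna: CountMatrix
    atac: CountMatrix
    cells: CellTable
    peaks: IntervalSet
    gene_models: GeneModelTable
    exons: pd.DataFrame
    genome: dict[str, str]
    chip_tracks: dict[tuple[str, str], IntervalSet]  # (mark, cell_state) -> track
    truth: TruthTables
    config: SimConfig


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named deterministic substream of the global seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _groups(config: SimConfig) -> list[tuple[str, str, str]]:
    """(sex, stage, cell_type) populations; supporting lineage sex-restricted."""
    out = []
    for sex in SEXES:
        for stage in config.stages:
            for ct in config.cell_types:
                if ct == "Sertoli" and sex != "XY":
                    continue
                if ct == "pregranulosa" and sex != "XX":
                    continue
                out.append((sex, stage, ct))
    return out


def simulate_multiome(config: SimConfig) -> SyntheticDataset:
    """Generate a complete synthetic multiome dataset plus truth tables."""
    groups = _groups(config)
    cells = []
    for sex, stage, ct in groups:
        for k in range(config.n_cells_per_group):
            cells.append((f"{sex}_{stage}_{ct}_{k:04d}", sex, stage, ct))
    cell_df = pd.DataFrame(cells, columns=["barcode", "sex", "stage", "cell_type"])
    n_cells = len(cell_df)

    gene_ids, gene_roles = _gene_catalogue(config)
    n_genes = len(gene_ids)

    genome = _random_genome(config)
    gene_models, exons = _place_genes(config, gene_ids, gene_roles)
    peaks, peak_info = _place_peaks(config, gene_models, gene_roles)
    truth = _build_truth(config, gene_roles, peak_info)

    genome, motif_sites = _plant_motifs(config, genome, peaks, peak_info)
    truth.true_motif_sites = motif_sites

    rna_counts = _simulate_rna(config, cell_df, gene_ids, gene_roles, peak_info)
    atac_counts = _simulate_atac(config, cell_df, peaks, peak_info, gene_roles)

    chip_tracks, histone_truth = _make_chip_tracks(config, peaks, peak_info)
    truth.true_histone_membership = histone_truth

    cell_table = _make_cell_table(config, cell_df, rna_counts, atac_counts,
                                  gene_ids, peaks, peak_info)

    rna = CountMatrix(sp.csr_matrix(rna_counts), gene_ids, cell_df["barcode"].tolist(), "rna")
    atac = CountMatrix(sp.csr_matrix(atac_counts), peaks.ids(), cell_df["barcode"].tolist(), "atac")
    return SyntheticDataset(rna=rna, atac=atac, cells=cell_table, peaks=peaks,
                            gene_models=gene_models, exons=exons, genome=genome,
                            chip_tracks=chip_tracks, truth=truth, config=config)


def null_config(seed: int = 0, n_cells_per_group: int = 200, n_genes: int = 200,
                n_peaks: int = 500) -> SimConfig:
    """Configuration with every planted effect switched off.

    Two populations (Sertoli / pregranulosa) at a single stage, no marker
    programs, no sex-linked features, no DEGs, DAPs, links or motifs — any
    feature flagged downstream is a false positive, so the raw-p<0.05 rate
    should sit at the nominal 5%.
    """
    return SimConfig(
        seed=seed,
        n_cells_per_group=n_cells_per_group,
        cell_types=("Sertoli", "pregranulosa"),
        stages=("E11.5",),
        n_genes=n_genes,
        n_peaks=n_peaks,
        frac_deg=0.0,
        frac_dap=0.0,
        link_strength=0.0,
        frac_linked=0.0,
        motif_library=[],
        marker_sets={},
        y_gene_ids=(),
        n_chry_peaks=0,
    )


# ---------------------------------------------------------------------------
# gene catalogue and placement
# ---------------------------------------------------------------------------

def _gene_catalogue(config: SimConfig) -> tuple[list[str], dict]:
    """Assign ids and roles (marker / DEG / TF / Y-linked / mito / background)."""
    named: list[str] = []
    for ms in config.marker_sets.values():
        named.extend(ms)
    tf_genes = [m.name for m in config.motif_library]
    named.extend(g for g in tf_genes if g not in named)
    y_genes = list(config.y_gene_ids)
    mt_genes = [f"mt-Nd{i + 1}" for i in range(5)]
    named.extend(y_genes)
    named.extend(mt_genes)
    n_fill = max(0, config.n_genes - len(named))
    gene_ids = named + [f"Gene{i:04d}" for i in range(n_fill)]
    gene_ids = list(dict.fromkeys(gene_ids))[: max(config.n_genes, len(named))]

    # DEG set between Sertoli (XY supporting) and pregranulosa (XX supporting):
    # TF genes are DEGs up in their own lineage; filler genes complete the set.
    rng = _rng(config.seed, "deg_choice")
    n_deg = int(round(config.frac_deg * len(gene_ids)))
    sertoli_tfs = [m.name for m in config.motif_library if m.name not in ("Lef1", "Msx1")]
    preg_tfs = [m.name for m in config.motif_library if m.name in ("Lef1", "Msx1")]
    reserved = set(named)
    pool = [g for g in gene_ids if g not in reserved]
    extra = [pool[i] for i in rng.choice(len(pool), size=min(len(pool), max(0, n_deg - len(sertoli_tfs) - len(preg_tfs))), replace=False)] if pool and n_deg else []
    half = len(extra) // 2
    deg_up_sertoli = sertoli_tfs + extra[:half]
    deg_up_preg = preg_tfs + extra[half:]

    roles = {
        "markers": config.marker_sets,
        "tf_genes": tf_genes,
        "y_genes": [g for g in y_genes if g in gene_ids],
        "mt_genes": mt_genes,
        "deg_up_sertoli": deg_up_sertoli,
        "deg_up_preg": deg_up_preg,
    }
    return gene_ids, roles


def _random_genome(config: SimConfig) -> dict[str, str]:
    rng = _rng(config.seed, "genome")
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom in config.chrom_names:
        arr = rng.integers(0, 4, size=config.genome_length_bp)
        genome[chrom] = lut[arr].tobytes().decode() if config.genome_length_bp else ""
    return genome


def _place_genes(config: SimConfig, gene_ids: list[str], roles: dict):
    rng = _rng(config.seed, "genes")
    autosomes = config.chrom_names[:-1]
    rows, exon_rows = [], []
    margin = 60_000
    L = config.genome_length_bp
    for g in gene_ids:
        if g in roles["y_genes"]:
            chrom = "chrY"
        else:
            chrom = autosomes[rng.integers(0, len(autosomes))]
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(margin, max(margin + 1, L - margin)))
        length = int(rng.integers(5_000, 50_000))
        if strand == "+":
            start, end = tss, min(tss + length, L - 1)
        else:
            start, end = max(0, tss - length), tss + 1
        rows.append((g, chrom, strand, tss, start, end))
        # three exons spread over the span
        span = end - start
        bounds = sorted(rng.integers(0, span, size=6).tolist())
        for r in range(3):
            es, ee = start + bounds[2 * r], start + bounds[2 * r + 1]
            if ee > es:
                rank = r + 1 if strand == "+" else 3 - r
                exon_rows.append((g, chrom, es, ee, rank))
    gm = GeneModelTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]))
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end", "rank"])
    return gm, exons


# ---------------------------------------------------------------------------
# peak placement
# ---------------------------------------------------------------------------

def _place_peaks(config: SimConfig, gene_models: GeneModelTable, roles: dict):
    """Place disjoint peaks; linked DAPs land within 500 kb of their target TSS.

    Returns the IntervalSet plus a per-peak info frame with columns
    (peak_index, dap_group, late, link_gene, link_sign, motif_id, chry).
    """
    rng = _rng(config.seed, "peaks")
    L = config.genome_length_bp
    autosomes = config.chrom_names[:-1]
    trees = {c: IntervalTree() for c in config.chrom_names}
    wmin, wmax = config.peak_width_range

    n_dap = int(round(config.frac_dap * config.n_peaks))
    n_dap -= n_dap % 2
    n_linked = int(round(config.frac_linked * n_dap))
    deg_s, deg_p = roles["deg_up_sertoli"], roles["deg_up_preg"]

    def sample_disjoint(chrom, lo, hi, width):
        for _ in range(200):
            if hi - width <= lo:
                return None
            s = int(rng.integers(lo, hi - width))
            if not trees[chrom].overlap(s, s + width):
                trees[chrom].addi(s, s + width)
                return s
        return None

    records, info = [], []
    gm = gene_models.df.set_index("gene_id")

    # late onset is decided per target gene: all linked DAPs of a "late" gene
    # only become differential from the second stage on, so the gene converts
    # from linked-non-DAP to linked-DAP between stages
    deg_cycle = deg_s + deg_p
    late_gene = {g: bool(rng.random() < config.frac_dap_late) for g in deg_cycle}

    # linked DAPs first (position-constrained)
    made = 0
    gi = 0
    while made < n_linked and deg_cycle:
        gene = deg_cycle[gi % len(deg_cycle)]
        gi += 1
        if gene not in gm.index:
            continue
        chrom, tss = gm.loc[gene, "chrom"], int(gm.loc[gene, "tss"])
        width = int(rng.integers(wmin, wmax))
        lo = max(0, tss - 500_000 + width)
        hi = min(L - 1, tss + 500_000 - width)
        start = sample_disjoint(chrom, lo, hi, width)
        if start is None:
            continue
        # peak midpoint must sit within the 500 kb window of the TSS
        if abs((start + start + width) // 2 - tss) > 500_000:
            trees[chrom].remove_overlap(start, start + width)
            continue
        up_sertoli = gene in deg_s
        neg = rng.random() < config.frac_negative_links
        # negative link: peak anti-correlated with target -> DAP favors the
        # opposite lineage to the gene
        dap_group = ("sertoli_up" if up_sertoli else "preg_up") if not neg else \
                    ("preg_up" if up_sertoli else "sertoli_up")
        late = late_gene[gene]
        records.append((chrom, start, start + width))
        info.append({"dap_group": dap_group, "late": late, "link_gene": gene,
                     "link_sign": -1 if neg else 1, "chry": False})
        made += 1

    # unlinked DAPs, balanced between the two directions
    n_unlinked = n_dap - made
    for k in range(n_unlinked):
        chrom = autosomes[rng.integers(0, len(autosomes))]
        width = int(rng.integers(wmin, wmax))
        start = sample_disjoint(chrom, 0, L - 1, width)
        if start is None:
            continue
        records.append((chrom, start, start + width))
        info.append({"dap_group": "sertoli_up" if k % 2 == 0 else "preg_up",
                     "late": bool(rng.random() < config.frac_dap_late),
                     "link_gene": None, "link_sign": 0, "chry": False})

    # chrY peaks
    for _ in range(config.n_chry_peaks if config.n_peaks else 0):
        width = int(rng.integers(wmin, wmax))
        start = sample_disjoint("chrY", 0, L - 1, width)
        if start is None:
            continue
        records.append(("chrY", start, start + width))
        info.append({"dap_group": None, "late": False, "link_gene": None,
                     "link_sign": 0, "chry": True})

    # background peaks
    while len(records) < config.n_peaks:
        chrom = autosomes[rng.integers(0, len(autosomes))]
        width = int(rng.integers(wmin, wmax))
        start = sample_disjoint(chrom, 0, L - 1, width)
        if start is None:
            continue
        records.append((chrom, start, start + width))
        info.append({"dap_group": None, "late": False, "link_gene": None,
                     "link_sign": 0, "chry": False})

    recs = [(c, s, e, f"{c}:{s}-{e}") for c, s, e in records]
    peaks = IntervalSet.from_records(recs)
    pdf = pd.DataFrame(info)
    if len(pdf):
        pdf["peak_id"] = peaks.ids()
    else:
        pdf = pd.DataFrame(columns=["dap_group", "late", "link_gene", "link_sign",
                                    "chry", "peak_id"])
    # assign motifs to linked DAP hosts round-robin within each lineage
    pdf["motif_id"] = None
    sert_motifs = [m for m in config.motif_library if m.name in roles["deg_up_sertoli"]]
    preg_motifs = [m for m in config.motif_library if m.name in roles["deg_up_preg"]]
    plant_rng = _rng(config.seed, "motif_assign")
    for group, motifs in (("sertoli_up", sert_motifs), ("preg_up", preg_motifs)):
        idx = pdf.index[(pdf["dap_group"] == group) & pdf["link_gene"].notna()].tolist()
        for j, pi in enumerate(idx):
            if motifs and plant_rng.random() < config.plant_rate:
                pdf.at[pi, "motif_id"] = motifs[j % len(motifs)].motif_id
    return peaks, pdf


def _build_truth(config: SimConfig, roles: dict, peak_info: pd.DataFrame) -> TruthTables:
    truth = TruthTables.empty()
    deg_rows = []
    for stage in config.stages:
        contrast = f"sertoli_vs_pregranulosa@{stage}"
        for g in roles["deg_up_sertoli"]:
            deg_rows.append((g, contrast, 1))
        for g in roles["deg_up_preg"]:
            deg_rows.append((g, contrast, -1))
    truth.true_degs = pd.DataFrame(deg_rows, columns=["gene_id", "contrast", "sign"])

    dap_rows = []
    for stage in config.stages:
        contrast = f"sertoli_vs_pregranulosa@{stage}"
        for row in peak_info.itertuples():
            if row.dap_group is None:
                continue
            if row.late and stage == config.stages[0]:
                continue
            dap_rows.append((row.peak_id, contrast, 1 if row.dap_group == "sertoli_up" else -1))
    truth.true_daps = pd.DataFrame(dap_rows, columns=["peak_id", "contrast", "sign"])

    linked = peak_info[peak_info["link_gene"].notna()]
    truth.true_links = pd.DataFrame({
        "peak_id": linked["peak_id"].to_numpy(),
        "gene_id": linked["link_gene"].to_numpy(),
        "sign": linked["link_sign"].to_numpy(),
    })

    motif_by_id = {m.motif_id: m for m in config.motif_library}
    net_rows = []
    for row in linked.itertuples():
        if row.motif_id is not None:
            tf = motif_by_id[row.motif_id].name
            net_rows.append((tf, row.link_gene, row.link_sign))
    truth.true_network_edges = pd.DataFrame(
        net_rows, columns=["tf", "target", "sign"]).drop_duplicates().reset_index(drop=True)
    return truth


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def _plant_motifs(config: SimConfig, genome: dict[str, str], peaks: IntervalSet,
                  peak_info: pd.DataFrame):
    rng = _rng(config.seed, "motif_plant")
    motif_by_id = {m.motif_id: m for m in config.motif_library}
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    rows = []
    pdf = peaks.df
    for i, row in enumerate(peak_info.itertuples()):
        if row.motif_id is None:
            continue
        motif = motif_by_id[row.motif_id]
        cons = motif.consensus
        w = len(cons)
        start, end = int(pdf.iloc[i]["start"]), int(pdf.iloc[i]["end"])
        chrom = pdf.iloc[i]["chrom"]
        if end - start < w:
            continue
        offset = int(rng.integers(start, end - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        planted = cons if strand == "+" else revcomp(cons)
        seqs[chrom][offset:offset + w] = planted.encode("ascii")
        rows.append((motif.motif_id, chrom, offset, offset + w, strand))
    genome = {c: s.decode("ascii") for c, s in seqs.items()}
    sites = pd.DataFrame(rows, columns=["motif_id", "chrom", "start", "end", "strand"])
    return genome, sites


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _group_key(sex: str, ct: str) -> str:
    if ct == "Sertoli":
        return "sertoli"
    if ct == "pregranulosa":
        return "preg"
    return f"{sex}_{ct}"


def _simulate_rna(config: SimConfig, cell_df: pd.DataFrame, gene_ids: list[str],
                  roles: dict, peak_info: pd.DataFrame) -> np.ndarray:
    n_genes, n_cells = len(gene_ids), len(cell_df)
    if n_cells == 0 or n_genes == 0:
        return np.zeros((n_genes, n_cells))
    rng = _rng(config.seed, "rna")
    gidx = {g: i for i, g in enumerate(gene_ids)}

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # differential programs live on expressed genes: floor the baseline of
    # marker, TF and DEG genes at the 60th percentile of the draw
    floor = float(np.quantile(base, 0.6)) if n_genes else 0.0
    for group in ("deg_up_sertoli", "deg_up_preg", "tf_genes"):
        for g in roles[group]:
            if g in gidx:
                base[gidx[g]] = max(base[gidx[g]], floor)
    for ms in roles["markers"].values():
        for g in ms:
            if g in gidx:
                base[gidx[g]] = max(base[gidx[g]], max(1.0, floor))
    for g in roles["mt_genes"]:
        if g in gidx:
            base[gidx[g]] = 0.01 * base.sum()  # a few percent mito content
    half = config.deg_log2fc / 2.0

    # per-(sex, stage, cell type) expression multipliers
    mult = {}
    for sex in SEXES:
        for stage in config.stages:
            for ct in config.cell_types:
                m = np.ones(n_genes)
                for g in roles["y_genes"]:
                    if g in gidx:
                        m[gidx[g]] = 1.0 if sex == "XY" else 0.0
                if ct in roles["markers"]:
                    for g in roles["markers"][ct]:
                        if g in gidx:
                            m[gidx[g]] *= 8.0
                # TF driver genes are strongly lineage-restricted (Sox9,
                # Dmrt1, Lef1 expression patterns): extra 2x on the DEG effect
                tf_set = set(roles["tf_genes"])
                if ct == "Sertoli":
                    for g in roles["deg_up_sertoli"]:
                        m[gidx[g]] *= 2.0 ** half * (2.0 if g in tf_set else 1.0)
                    for g in roles["deg_up_preg"]:
                        m[gidx[g]] *= 2.0 ** -half / (2.0 if g in tf_set else 1.0)
                if ct == "pregranulosa":
                    for g in roles["deg_up_preg"]:
                        m[gidx[g]] *= 2.0 ** half * (2.0 if g in tf_set else 1.0)
                    for g in roles["deg_up_sertoli"]:
                        m[gidx[g]] *= 2.0 ** -half / (2.0 if g in tf_set else 1.0)
                mult[(sex, stage, ct)] = m

    sigma = config.size_factor_sigma
    size_factors = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=n_cells)

    # latent link factors, one per linked gene, shared with the linked peaks
    factors = _link_factors(config, cell_df, peak_info)

    counts = np.zeros((n_genes, n_cells))
    l = config.link_strength
    for key, cols in cell_df.groupby(["sex", "stage", "cell_type"]).groups.items():
        cols = np.asarray(cols)
        m = mult[key]
        mu_gene = base * m
        tot = mu_gene.sum()
        if tot > 0:
            mu_gene = mu_gene * (config.mean_library_rna / tot)
        mu = mu_gene[:, None] * size_factors[cols][None, :]
        for gene, f in factors.items():
            gi2 = gidx.get(gene)
            if gi2 is not None:
                mu[gi2, :] *= np.exp(l * f[cols] - l ** 2 / 2.0)
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(mu > 0, r / (r + mu), 1.0)
            counts[:, cols] = rng.negative_binomial(r, p)
        else:
            counts[:, cols] = rng.poisson(mu)
        # hard zeros must stay exactly zero (Y genes in XX cells)
        counts[:, cols] = np.where(mu > 0, counts[:, cols], 0.0)
    return counts


def _link_factors(config: SimConfig, cell_df: pd.DataFrame,
                  peak_info: pd.DataFrame) -> dict[str, np.ndarray]:
    rng = _rng(config.seed, "link_factors")
    factors = {}
    for gene in peak_info.loc[peak_info["link_gene"].notna(), "link_gene"].unique():
        factors[gene] = rng.standard_normal(len(cell_df))
    return factors


def _simulate_atac(config: SimConfig, cell_df: pd.DataFrame, peaks: IntervalSet,
                   peak_info: pd.DataFrame, roles: dict) -> np.ndarray:
    n_peaks, n_cells = len(peaks), len(cell_df)
    if n_cells == 0 or n_peaks == 0:
        return np.zeros((n_peaks, n_cells))
    rng = _rng(config.seed, "atac")
    propensity = rng.lognormal(mean=0.0, sigma=0.8, size=n_peaks)

    dap_group = peak_info["dap_group"].to_numpy()
    late = peak_info["late"].to_numpy(dtype=bool)
    chry = peak_info["chry"].to_numpy(dtype=bool)
    half = config.dap_log2fc / 2.0

    factors = _link_factors(config, cell_df, peak_info)
    link_gene = peak_info["link_gene"].to_numpy()
    link_sign = peak_info["link_sign"].to_numpy()

    sigma = config.size_factor_sigma
    size_factors = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=n_cells)

    counts = np.zeros((n_peaks, n_cells))
    early_stage = config.stages[0]
    l = config.link_strength
    for key, cols in cell_df.groupby(["sex", "stage", "cell_type"]).groups.items():
        sex, stage, ct = key
        cols = np.asarray(cols)
        m = np.ones(n_peaks)
        active = ~(late & (stage == early_stage))
        if ct == "Sertoli":
            m[(dap_group == "sertoli_up") & active] *= 2.0 ** half
            m[(dap_group == "preg_up") & active] *= 2.0 ** -half
        elif ct == "pregranulosa":
            m[(dap_group == "preg_up") & active] *= 2.0 ** half
            m[(dap_group == "sertoli_up") & active] *= 2.0 ** -half
        m[chry] = 1.0 if sex == "XY" else 0.0
        rate_peak = propensity * m
        tot = rate_peak.sum()
        if tot > 0:
            rate_peak = rate_peak * (config.mean_library_atac / tot)
        lam = rate_peak[:, None] * size_factors[cols][None, :]
        for pi in np.flatnonzero(pd.notna(link_gene)):
            f = factors[link_gene[pi]][cols]
            lam[pi, :] *= np.exp(link_sign[pi] * l * f - l ** 2 / 2.0)
        counts[:, cols] = np.where(lam > 0, rng.poisson(lam), 0.0)
    return counts


# ---------------------------------------------------------------------------
# ChIP tracks and cell metadata
# ---------------------------------------------------------------------------

def _make_chip_tracks(config: SimConfig, peaks: IntervalSet, peak_info: pd.DataFrame):
    rng = _rng(config.seed, "chip")
    pdf = peaks.df
    states = ("PSC", "Sertoli", "pregranulosa")
    tracks: dict[tuple[str, str], IntervalSet] = {}
    member_rows = []
    for mark in MARKS:
        frac = config.histone_frac(mark)
        for state in states:
            recs = []
            for group in ("sertoli_up", "preg_up"):
                idx = peak_info.index[peak_info["dap_group"] == group].to_numpy()
                n_pos = int(round(frac * len(idx)))
                chosen = set(rng.choice(idx, size=n_pos, replace=False).tolist()) if n_pos else set()
                for pi in idx:
                    member_rows.append((peak_info.at[pi, "peak_id"], mark, state, pi in chosen))
                for pi in chosen:
                    row = pdf.iloc[pi]
                    pad = int(rng.integers(0, 200))
                    recs.append((row["chrom"], max(0, row["start"] - pad), row["end"] + pad,
                                 f"{mark}_{state}"))
            # background intervals not tied to any DAP
            for _ in range(50):
                chrom = config.chrom_names[rng.integers(0, max(1, config.n_chromosomes - 1))]
                s = int(rng.integers(0, max(1, config.genome_length_bp - 2000)))
                recs.append((chrom, s, s + int(rng.integers(500, 2000)), f"{mark}_{state}_bg"))
            tracks[(mark, state)] = IntervalSet.from_records(recs).sort()
    membership = pd.DataFrame(member_rows, columns=["peak_id", "mark", "cell_state", "member"])
    return tracks, membership


def _make_cell_table(config: SimConfig, cell_df: pd.DataFrame, rna_counts: np.ndarray,
                     atac_counts: np.ndarray, gene_ids: list[str], peaks: IntervalSet,
                     peak_info: pd.DataFrame) -> CellTable:
    rng = _rng(config.seed, "cell_qc")
    n_cells = len(cell_df)
    n_rna = rna_counts.sum(axis=0) if n_cells else np.array([])
    n_atac = atac_counts.sum(axis=0) if n_cells else np.array([])
    mt_idx = [i for i, g in enumerate(gene_ids) if g.startswith("mt-")]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mt = np.where(n_rna > 0, 100.0 * rna_counts[mt_idx].sum(axis=0) / np.where(n_rna > 0, n_rna, 1), 0.0) if n_cells else np.array([])
    chry_idx = peak_info.index[peak_info["chry"]].to_numpy() if len(peak_info) else np.array([], dtype=int)
    chry_frag = atac_counts[chry_idx].sum(axis=0) if n_cells else np.array([])
    df = pd.DataFrame({
        "barcode": cell_df["barcode"],
        "declared_sex": cell_df["sex"],
        "stage": cell_df["stage"],
        "cell_type": cell_df["cell_type"],
        "n_count_rna": n_rna.astype(int),
        "percent_mt": pct_mt,
        "n_count_atac": n_atac.astype(int),
        "nucleosome_signal": rng.uniform(0.3, 1.5, size=n_cells),
        "tss_enrichment": rng.uniform(2.0, 8.0, size=n_cells),
        "chry_fragments": chry_frag.astype(int),
    })
    return CellTable(df)


# ---------------------------------------------------------------------------
# on-disk output
# ---------------------------------------------------------------------------

def write_truth(truth: TruthTables, directory) -> list[Path]:
    """One TSV per truth table; round-trippable with :func:`read_truth`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in TruthTables.TABLES:
        path = directory / f"{name}.tsv"
        getattr(truth, name).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_truth(directory) -> TruthTables:
    directory = Path(directory)
    tables = {}
    for name in TruthTables.TABLES:
        df = pd.read_csv(directory / f"{name}.tsv", sep="\t")
        if df.empty:
            df = pd.DataFrame(columns=TruthTables.SCHEMAS[name])
        tables[name] = df
    return TruthTables(**tables)


def write_dataset(dataset: SyntheticDataset, directory) -> None:
    """Write the full dataset in the standard plain-text formats."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(dataset.rna, d / "rna.mtx", d / "rna_features.tsv", d / "barcodes.tsv")
    write_mtx_triplet(dataset.atac, d / "atac.mtx", d / "atac_features.tsv", d / "barcodes.tsv")
    dataset.cells.df.to_csv(d / "cells.tsv", sep="\t", index=False)
    write_bed(dataset.peaks, d / "peaks.bed")
    write_fasta(dataset.genome, d / "genome.fa")
    write_gene_models(dataset.gene_models, d / "genes.tsv")
    dataset.exons.to_csv(d / "exons.tsv", sep="\t", index=False)
    for (mark, state), track in dataset.chip_tracks.items():
        write_bed(track, d / f"chip_{mark}_{state}.bed")
    write_truth(dataset.truth, d / "truth")
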