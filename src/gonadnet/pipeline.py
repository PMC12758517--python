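"""End-to-end orchestration: QC → sex filter → differential → linkage →
categorization → chromatin profiles → motif network, with TSV/BED artifacts
and a machine-readable run manifest at every stage."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import lr_dap, results_to_frame, wilcoxon_deg
from .io import (CountMatrix, IntervalSet, interval_set_from_ids, read_bed,
                 read_fasta, read_gene_models, read_mtx_triplet, write_bed)
from .linkage import (categorize_degs, annotate_daps, link_peaks,
                      newly_formed_linked_daps, track_transitions)
from .motifs import (build_regulatory_network, chromvar_deviations,
                     match_background_peaks, motif_cooccurrence,
                     motif_enrichment, scan_motif_library)
from .profiles import GeneAnnotation, annotate_peaks, counts_in_region, histone_overlap
from .qc import (CellTable, SexFilterConfig, apply_atac_qc, apply_rna_qc,
                 filter_peaks, log_normalize, module_score, normalize_counts,
                 sex_filter)
from .simulate import (SimConfig, SyntheticDataset, read_truth, simulate_multiome,
                       write_dataset)


@dataclass
class PipelineParams:
    """Every tunable threshold of the pipeline, with its standard default."""

    seed: int = 0
    # QC
    rna_min_count: int = 1000
    rna_max_count: int = 25_000
    max_percent_mt: float = 25.0
    atac_min_count: int = 1000
    atac_max_count: int = 100_000
    max_nucleosome_signal: float = 2.0
    min_tss_enrichment: float = 1.0
    peak_min_width: int = 20
    peak_max_width: int = 10_000
    # differential
    deg_min_pct: float = 0.25
    deg_logfc: float = 0.25
    dap_min_pct: float = 0.01    # between-sex DAP thresholds
    dap_logfc: float = 0.1
    alpha_adjusted: float = 0.05
    # linkage
    link_distance: int = 500_000
    link_n_background: int = 200
    link_p_cutoff: float = 0.05
    # motifs
    motif_hit_p: float = 1e-4
    pwm_pseudocount: float = 0.8
    enrichment_p: float = 0.05
    enrichment_fold: float = 1.25
    n_chromvar_background: int = 50
    # contrast
    group1_type: str = "Sertoli"
    group2_type: str = "pregranulosa"
    stages: tuple[str, ...] = ("E11.5", "E12.5", "E13.5")
    focal_stage: str = "E12.5"
    run_chromvar: bool = True


def load_dataset(directory) -> SyntheticDataset:
    """Reload a dataset written by :func:`gonadnet.simulate.write_dataset`."""
    d = Path(directory)
    rna = read_mtx_triplet(d / "rna.mtx", d / "rna_features.tsv", d / "barcodes.tsv", "rna")
    atac = read_mtx_triplet(d / "atac.mtx", d / "atac_features.tsv", d / "barcodes.tsv", "atac")
    cells = CellTable(pd.read_csv(d / "cells.tsv", sep="\t"))
    peaks = read_bed(d / "peaks.bed")
    genome = read_fasta(d / "genome.fa")
    gene_models = read_gene_models(d / "genes.tsv")
    exons = pd.read_csv(d / "exons.tsv", sep="\t")
    chip = {}
    for path in sorted(d.glob("chip_*.bed")):
        _, mark, state = path.stem.split("_", 2)
        chip[(mark, state)] = read_bed(path)
    truth = read_truth(d / "truth")
    return SyntheticDataset(rna=rna, atac=atac, cells=cells, peaks=peaks,
                            gene_models=gene_models, exons=exons, genome=genome,
                            chip_tracks=chip, truth=truth, config=None)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}': {detail}")
        self.stage = stage


def run_pipeline(dataset: SyntheticDataset, outdir, params: PipelineParams | None = None) -> dict:
    """Run every stage on a dataset; write artifacts; return in-memory results.

    The returned dict carries per-stage tables plus a ``manifest`` with input
    parameters, the seed and record counts in/out of every filter.
    """
    params = params or PipelineParams()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": params.seed,
                      "params": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(params).items()},
                      "stages": {}}
    results: dict = {"manifest": manifest}

    for ct in (params.group1_type, params.group2_type):
        if ct not in set(dataset.cells.df["cell_type"]):
            raise PipelineError("config", f"unknown cell type in contrast: {ct}")

    # ---- QC ----------------------------------------------------------------
    cells = dataset.cells
    kept_rna = set(apply_rna_qc(cells, params.rna_min_count, params.rna_max_count,
                                params.max_percent_mt))
    kept_atac = set(apply_atac_qc(cells, params.atac_min_count, params.atac_max_count,
                                  params.max_nucleosome_signal, params.min_tss_enrichment))
    kept_qc = [b for b in cells.df["barcode"] if b in kept_rna and b in kept_atac]
    manifest["stages"]["qc"] = {"cells_in": len(cells), "cells_out": len(kept_qc)}

    peaks_f = filter_peaks(dataset.peaks, None, params.peak_min_width, params.peak_max_width)
    peak_ids_kept = [p for p in dataset.atac.feature_ids if p in set(peaks_f.ids())]
    manifest["stages"]["peak_filter"] = {"peaks_in": len(dataset.peaks),
                                         "peaks_out": len(peak_ids_kept)}

    # ---- sex filter --------------------------------------------------------
    rna_qc = dataset.rna.subset_cells(kept_qc)
    cells_qc = cells.subset(kept_qc)
    sex_cfg = SexFilterConfig()
    y_present = [g for g in sex_cfg.y_gene_set if g in rna_qc.feature_ids]
    if y_present:
        scores = module_score(rna_qc, y_present)
        verdict = sex_filter(scores, cells_qc, sex_cfg)
        kept = verdict.loc[verdict["kept"], "barcode"].tolist()
        verdict.to_csv(out / "sex_filter.tsv", sep="\t", index=False)
    else:
        kept = list(kept_qc)
    manifest["stages"]["sex_filter"] = {"cells_in": len(kept_qc), "cells_out": len(kept)}

    rna = dataset.rna.subset_cells(kept)
    atac = dataset.atac.subset_cells(kept).subset_features(peak_ids_kept)
    peaks = interval_set_from_ids(atac.feature_ids)
    cell_meta = cells.subset(kept).df.set_index("barcode").loc[rna.barcodes].reset_index()

    expr_lin = normalize_counts(rna)
    acc_lin = normalize_counts(atac)
    expr_log = log_normalize(rna)

    # ---- differential per stage -------------------------------------------
    degs_by_stage, daps_by_stage = {}, {}
    for stage in params.stages:
        sel = cell_meta["stage"] == stage
        g1 = np.flatnonzero(sel & (cell_meta["cell_type"] == params.group1_type))
        g2 = np.flatnonzero(sel & (cell_meta["cell_type"] == params.group2_type))
        if len(g1) < 2 or len(g2) < 2:
            raise PipelineError("differential", f"too few cells at {stage}")
        deg = results_to_frame(wilcoxon_deg(expr_lin, rna.feature_ids, g1, g2,
                                            params.deg_min_pct, params.deg_logfc))
        dap = results_to_frame(lr_dap(acc_lin, atac.feature_ids, g1, g2,
                                      params.dap_min_pct, params.dap_logfc))
        deg = deg[deg["p_adjusted"] < params.alpha_adjusted].reset_index(drop=True) if len(deg) else deg
        dap = dap[dap["p_adjusted"] < params.alpha_adjusted].reset_index(drop=True) if len(dap) else dap
        degs_by_stage[stage], daps_by_stage[stage] = deg, dap
        deg.to_csv(out / f"degs_{stage}.tsv", sep="\t", index=False)
        dap.to_csv(out / f"daps_{stage}.tsv", sep="\t", index=False)
        manifest["stages"][f"differential_{stage}"] = {
            "n_deg": int(len(deg)), "n_dap": int(len(dap)),
            "cells_group1": int(len(g1)), "cells_group2": int(len(g2))}

    # ---- linkage on the entire dataset ------------------------------------
    links = link_peaks(atac, expr_log, rna.feature_ids, peaks, dataset.gene_models,
                       dataset.genome, distance=params.link_distance,
                       n_background=params.link_n_background,
                       p_cutoff=params.link_p_cutoff, seed=params.seed)
    links.to_csv(out / "links.tsv", sep="\t", index=False)
    manifest["stages"]["linkage"] = {
        "n_candidates": int(links.attrs.get("n_candidates_evaluated", 0)),
        "n_links": int(len(links))}

    # ---- categorization and transitions ------------------------------------
    categories = {}
    for stage in params.stages:
        deg_ids = degs_by_stage[stage]["feature_id"].tolist() if len(degs_by_stage[stage]) else []
        dap_ids = daps_by_stage[stage]["feature_id"].tolist() if len(daps_by_stage[stage]) else []
        cats = categorize_degs(deg_ids, dap_ids, links)
        categories[stage] = cats
        cats.to_csv(out / f"deg_categories_{stage}.tsv", sep="\t", index=False)
        dap_cats = annotate_daps(dap_ids, deg_ids, links)
        dap_cats.to_csv(out / f"dap_categories_{stage}.tsv", sep="\t", index=False)
        manifest["stages"][f"categories_{stage}"] = \
            cats["category"].value_counts().to_dict() if len(cats) else {}

    t1, t2 = params.stages[0], params.stages[1] if len(params.stages) > 1 else params.stages[0]
    trans, flows = track_transitions(categories[t1], categories[t2])
    trans.to_csv(out / "transitions.tsv", sep="\t", index=False)
    flows.to_csv(out / "flows.tsv", sep="\t", index=False)
    newly = newly_formed_linked_daps(
        categories[t1], categories[t2], links,
        daps_by_stage[t2]["feature_id"].tolist() if len(daps_by_stage[t2]) else [])
    write_bed(newly, out / "newly_formed_daps.bed")
    manifest["stages"]["transitions"] = {
        "frac_nonDAP_to_DAP": flows.attrs.get("frac_nonDAP_to_DAP"),
        "n_newly_formed_peaks": int(len(newly))}
    results["transitions"], results["flows"], results["newly_formed"] = trans, flows, newly

    # ---- chromatin profiles -------------------------------------------------
    annot = GeneAnnotation(dataset.gene_models.df, dataset.exons)
    peak_annot = annotate_peaks(peaks, annot)
    peak_annot.to_csv(out / "peak_annotation.tsv", sep="\t", index=False)

    focal_daps = daps_by_stage[params.focal_stage]
    histone_rows = []
    if len(focal_daps):
        dirn = focal_daps.set_index("feature_id")["direction"]
        dap_sets = {
            f"{params.group1_type}_up": interval_set_from_ids(dirn.index[dirn == "up_in_1"]),
            f"{params.group2_type}_up": interval_set_from_ids(dirn.index[dirn == "up_in_2"]),
        }
        groups = cell_meta.set_index("barcode")["cell_type"]
        for set_id, dset in dap_sets.items():
            if not len(dset):
                continue
            acc_tab = counts_in_region(atac, peaks, dset, groups=groups)
            acc_tab.to_csv(out / f"accessibility_{set_id}.tsv", sep="\t", index=False)
            for (mark, state), track in dataset.chip_tracks.items():
                histone_rows.append(histone_overlap(dset, track, set_id, mark, state))
    histone_df = pd.DataFrame(histone_rows)
    histone_df.to_csv(out / "histone_overlap.tsv", sep="\t", index=False)
    results["histone_overlap"] = histone_df

    # ---- motif network ------------------------------------------------------
    motif_lib = dataset.config.motif_library if dataset.config is not None else []
    network = pd.DataFrame()
    enrich = pd.DataFrame()
    if motif_lib:
        focal_cats = categories[params.focal_stage]
        linked_dap_peaks = sorted({
            p for s in focal_cats.loc[focal_cats["category"] == "linked_DAP",
                                      "supporting_peaks"]
            for p in s.split(",") if p})
        if linked_dap_peaks:
            target = interval_set_from_ids(linked_dap_peaks)
            pool = interval_set_from_ids(
                [p for p in atac.feature_ids if p not in set(linked_dap_peaks)])
            background = match_background_peaks(target, pool, atac, dataset.genome,
                                                n=min(len(pool), 10 * len(target)),
                                                seed=params.seed)
            scan_set = interval_set_from_ids(sorted(set(target.ids()) | set(background.ids())))
            hits = scan_motif_library(motif_lib, scan_set, dataset.genome,
                                      hit_p=params.motif_hit_p,
                                      pseudocount=params.pwm_pseudocount)
            hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
            enrich = motif_enrichment(hits, target, background,
                                      params.enrichment_p, params.enrichment_fold)
            enrich.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
            focal_degs = degs_by_stage[params.focal_stage]["feature_id"].tolist()
            focal_dap_ids = daps_by_stage[params.focal_stage]["feature_id"].tolist()
            tf_map = {m.motif_id: m.name for m in motif_lib}
            network = build_regulatory_network(enrich, focal_degs, hits, links,
                                               focal_dap_ids, tf_map,
                                               expressed_genes=rna.feature_ids)
            network.to_csv(out / "network_edges.tsv", sep="\t", index=False)
            cooc = motif_cooccurrence(network)
            cooc.to_csv(out / "motif_cooccurrence.tsv", sep="\t")
            results["cooccurrence"] = cooc
        if params.run_chromvar:
            all_hits = scan_motif_library(motif_lib, peaks, dataset.genome,
                                          hit_p=params.motif_hit_p,
                                          pseudocount=params.pwm_pseudocount)
            annotation = pd.DataFrame(False, index=peaks.ids(),
                                      columns=[m.motif_id for m in motif_lib])
            for row in all_hits.itertuples():
                annotation.at[row.peak_id, row.motif_id] = True
            dev = chromvar_deviations(atac, annotation, peaks, dataset.genome,
                                      n_background_sets=params.n_chromvar_background,
                                      seed=params.seed)
            dev["z"].to_csv(out / "chromvar_z.tsv", sep="\t")
            results["chromvar"] = dev
    manifest["stages"]["network"] = {"n_edges": int(len(network)),
                                     "n_enriched_motifs": int(enrich["passes"].sum())
                                     if len(enrich) else 0}

    results.update({
        "kept_barcodes": kept, "peaks": peaks, "links": links,
        "degs_by_stage": degs_by_stage, "daps_by_stage": daps_by_stage,
        "categories": categories, "peak_annotation": peak_annot,
        "network": network, "enrichment": enrich, "cell_meta": cell_meta,
    })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results


def make_demo(seed: int = 0, outdir="demo_data", config: SimConfig | None = None) -> SyntheticDataset:
    """Generate and write a ready-to-run synthetic demo dataset (~2000 cells)."""
    config = config or SimConfig(seed=seed)
    dataset = simulate_multiome(config)
    write_dataset(dataset, outdir)
    return dataset
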