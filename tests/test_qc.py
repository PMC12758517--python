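"""QC gates, peak filtering, module scoring, sex filter and annotation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gonadnet.io import CountMatrix, IntervalSet
from gonadnet.qc import (CellTable, SexFilterConfig, annotate_cell_types,
                         apply_atac_qc, apply_rna_qc, filter_peaks,
                         module_score, sex_filter)


def make_cells(rows):
    defaults = dict(declared_sex="XY", stage="E11.5", cell_type="x",
                    n_count_rna=5000, percent_mt=5.0, n_count_atac=50_000,
                    nucleosome_signal=1.0, tss_enrichment=3.0, chry_fragments=1)
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, barcode=f"bc{i}", **row)
        recs.append(rec)
    return CellTable(pd.DataFrame(recs))


class TestCountGates:
    @pytest.mark.parametrize("n_count,mt,kept", [
        (1000, 0.0, False),    # boundary: strict >
        (1001, 24.9, True),    # interior
        (5000, 25.0, False),   # boundary: strict <
        (25_000, 0.0, False),  # upper boundary
    ])
    def test_rna_gate_strict_inequalities(self, n_count, mt, kept):
        cells = make_cells([{"n_count_rna": n_count, "percent_mt": mt}])
        assert (apply_rna_qc(cells) == ["bc0"]) is kept

    @pytest.mark.parametrize("n,ns,tss,kept", [
        (1000, 1.0, 3.0, False),      # boundary: strict > 1000
        (50_000, 1.5, 2.0, True),
        (50_000, 2.0, 2.0, False),    # nucleosome boundary
        (50_000, 1.0, 1.0, False),    # tss boundary
        (100_000, 1.0, 3.0, False),   # upper boundary
    ])
    def test_atac_gate_strict_inequalities(self, n, ns, tss, kept):
        cells = make_cells([{"n_count_atac": n, "nucleosome_signal": ns,
                             "tss_enrichment": tss}])
        assert (apply_atac_qc(cells) == ["bc0"]) is kept

    def test_missing_metric_names_barcode(self):
        cells = make_cells([{"percent_mt": np.nan}])
        with pytest.raises(ValueError, match="bc0"):
            apply_rna_qc(cells)

    def test_gates_idempotent(self):
        cells = make_cells([{"n_count_rna": v} for v in (500, 2000, 30_000)])
        once = apply_rna_qc(cells)
        again = apply_rna_qc(cells.subset(once))
        assert once == again


class TestFilterPeaks:
    def test_overlapping_peaks_are_union_reduced(self):
        peaks = IntervalSet.from_records([("chr1", 0, 15), ("chr1", 10, 40)])
        out = filter_peaks(peaks)
        assert len(out) == 1
        rec = next(iter(out))
        assert (rec.start, rec.end) == (0, 40)

    @pytest.mark.parametrize("width,kept", [(20, False), (21, True),
                                            (9_999, True), (10_000, False)])
    def test_size_gate_strict(self, width, kept):
        out = filter_peaks(IntervalSet.from_records([("chr1", 0, width)]))
        assert (len(out) == 1) is kept

    def test_blacklist_single_bp_overlap_drops_peak(self):
        peaks = IntervalSet.from_records([("chr1", 100, 200), ("chr1", 300, 400)])
        blacklist = IntervalSet.from_records([("chr1", 199, 250)])
        out = filter_peaks(peaks, blacklist)
        assert out.ids() == ["chr1:300-400"]

    def test_nonstandard_chromosomes_dropped(self):
        peaks = IntervalSet.from_records([("chr1", 0, 100), ("chrUn_x", 0, 100)])
        out = filter_peaks(peaks, allowed_chroms={"chr1"})
        assert out.df["chrom"].tolist() == ["chr1"]


class TestModuleScore:
    def make_matrix(self, values):
        values = np.asarray(values)
        return CountMatrix(sp.csr_matrix(values),
                           [f"g{i}" for i in range(values.shape[0])],
                           [f"c{j}" for j in range(values.shape[1])])

    def test_top_ranked_signature_scores_one(self):
        # signature genes are the 3 highest expressed of 10
        expr = np.arange(10, 0, -1).reshape(-1, 1)
        cm = self.make_matrix(expr)
        out = module_score(cm, ["g0", "g1", "g2"], r_max=8)
        assert out["score"].iloc[0] == pytest.approx(1.0)

    def test_bottom_ranked_signature_closed_form(self):
        # all signature ranks >= r_max: score = (|S|+1)/(2 r_max)
        n, r_max, s = 2000, 1500, 4
        expr = np.arange(n, 0, -1).reshape(-1, 1)
        cm = self.make_matrix(expr)
        sig = [f"g{i}" for i in range(n - s, n)]  # the s lowest
        out = module_score(cm, sig, r_max=r_max)
        assert out["score"].iloc[0] == pytest.approx((s + 1) / (2 * r_max))

    def test_constant_cell_ties_closed_form(self):
        # every gene tied: all ranks (N+1)/2, same score for any signature
        n, r_max = 100, 80
        cm = self.make_matrix(np.full((n, 1), 7))
        tie_rank = min((n + 1) / 2, r_max)
        s = 5
        expected = 1 - (s * tie_rank - s * (s + 1) / 2) / (s * r_max)
        for sig in (["g0", "g1", "g2", "g3", "g4"], ["g50", "g90", "g7", "g13", "g22"]):
            out = module_score(cm, sig, r_max=r_max)
            assert out["score"].iloc[0] == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self, rng):
        counts = rng.integers(0, 50, size=(60, 5))
        cm = self.make_matrix(counts)
        sig = ["g3", "g17", "g41"]
        base = module_score(cm, sig, r_max=40)["score"]
        # monotone transforms preserving order and ties leave scores unchanged
        for mono in (counts * 7 + 1, counts ** 2, np.expm1(counts).astype(np.float64)):
            out = module_score(self.make_matrix(mono), sig, r_max=40)["score"]
            assert np.allclose(out, base)

    def test_absent_gene_dropped_with_warning_and_empty_set_errors(self):
        cm = self.make_matrix(np.arange(5).reshape(-1, 1))
        with pytest.warns(UserWarning):
            module_score(cm, ["g0", "nope"])
        with pytest.raises(ValueError):
            module_score(cm, [])


class TestSexFilter:
    def build(self):
        """A 12-cell truth table exercising every removal rule."""
        # reference stage cells define cutoffs: XY scores ~0.8 (sd .1), XX ~0.1
        rows = [
            {"declared_sex": "XY", "stage": "E13.5"}, {"declared_sex": "XY", "stage": "E13.5"},
            {"declared_sex": "XX", "stage": "E13.5"}, {"declared_sex": "XX", "stage": "E13.5"},
            # XY early cells
            {"declared_sex": "XY", "stage": "E11.5", "chry_fragments": 3},   # kept: frags > 0
            {"declared_sex": "XY", "stage": "E11.5", "chry_fragments": 0},   # removed: 0 frags AND low score
            {"declared_sex": "XY", "stage": "E11.5", "chry_fragments": 0},   # kept: score == cutoff (strict <)
            {"declared_sex": "XY", "stage": "E11.5", "chry_fragments": 0},   # kept: high score
            # XX early cells
            {"declared_sex": "XX", "stage": "E12.5", "chry_fragments": 1},   # removed: frags > 0
            {"declared_sex": "XX", "stage": "E12.5", "chry_fragments": 0},   # removed: score > cutoff
            {"declared_sex": "XX", "stage": "E12.5", "chry_fragments": 0},   # kept: score == cutoff
            {"declared_sex": "XX", "stage": "E12.5", "chry_fragments": 0},   # kept: low score
        ]
        cells = make_cells(rows)
        # XY ref: mean .8 sd ~.1414 -> cutoff_XY ~ .6586; XX ref: mean .1 -> cutoff_XX ~ .2414
        sd = np.std([0.7, 0.9], ddof=1)
        cut_xy, cut_xx = 0.8 - sd, 0.1 + sd
        scores = pd.DataFrame({
            "barcode": [f"bc{i}" for i in range(12)],
            "score": [0.7, 0.9, 0.0, 0.2,
                      0.0, cut_xy - 0.01, cut_xy, 0.9,
                      0.0, cut_xx + 0.01, cut_xx, 0.0],
        })
        return scores, cells, cut_xy, cut_xx

    def test_quoted_removal_rules_exactly(self):
        scores, cells, cut_xy, cut_xx = self.build()
        out = sex_filter(scores, cells)
        kept = out.set_index("barcode")["kept"]
        expected = {
            "bc0": True, "bc1": True, "bc2": True, "bc3": True,  # reference kept
            "bc4": True, "bc5": False, "bc6": True, "bc7": True,
            "bc8": False, "bc9": False, "bc10": True, "bc11": True,
        }
        assert kept.to_dict() == expected
        assert out.attrs["cutoff_XY"] == pytest.approx(cut_xy)
        assert out.attrs["cutoff_XX"] == pytest.approx(cut_xx)

    def test_too_few_reference_cells_errors(self):
        scores, cells, *_ = self.build()
        thin = CellTable(cells.df[cells.df["barcode"] != "bc0"])
        with pytest.raises(ValueError, match="SD undefined"):
            sex_filter(scores, thin)

    def test_sd_multiplier_positive(self):
        with pytest.raises(ValueError):
            SexFilterConfig(sd_multiplier=0)


class TestAnnotateCellTypes:
    def test_marker_argmax_and_tie_flag(self):
        genes = ["Fst", "Foxl2", "Amh", "Sox9", "other"]
        # cell0 expresses only pregranulosa markers, cell1 only Sertoli, cell2 nothing
        mat = np.array([
            [9, 0, 0],
            [8, 0, 0],
            [0, 9, 0],
            [0, 8, 0],
            [1, 1, 0],
        ])
        cm = CountMatrix(sp.csr_matrix(mat), genes, ["c0", "c1", "c2"])
        out = annotate_cell_types(cm, {"pregranulosa": ["Fst", "Foxl2"],
                                       "Sertoli": ["Amh", "Sox9"]}, r_max=4)
        assert out["cell_type"].tolist()[:2] == ["pregranulosa", "Sertoli"]
        assert bool(out["tie"].iloc[2]) is True
        assert not out["tie"].iloc[0]

    def test_empty_marker_map_errors(self):
        cm = CountMatrix(sp.csr_matrix(np.eye(2, dtype=int)), ["a", "b"], ["c", "d"])
        with pytest.raises(ValueError):
            annotate_cell_types(cm, {})
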