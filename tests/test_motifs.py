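"""PWM conversion, threshold DP, scanning, enrichment, deviations, network."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gonadnet.io import CountMatrix, IntervalSet, MotifPFM
from gonadnet.motifs import (build_regulatory_network, chromvar_deviations,
                             match_background_peaks, motif_cooccurrence,
                             motif_enrichment, pfm_to_pwm, scan_peaks,
                             score_threshold)
from gonadnet.simulate import make_default_motifs, revcomp


class TestPfmToPwm:
    def test_uniform_pfm_scores_zero(self):
        pwm = pfm_to_pwm(MotifPFM("M", "m", np.full((4, 3), 5.0)))
        assert np.allclose(pwm.log_odds, 0.0)

    def test_single_column_hand_computed(self):
        pfm = MotifPFM("M", "m", np.array([[1.0], [0.0], [0.0], [0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=0.25)
        # p_A = (1 + 0.25) / (1 + 4*0.25) = 0.625; score = log2(0.625/0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(math.log2(2.5))

    def test_reverse_complement_symmetry(self, rng):
        pfm = MotifPFM("M", "m", rng.integers(1, 20, size=(4, 6)).astype(float))
        pwm = pfm_to_pwm(pfm)
        rc = pwm.reverse_complement()
        assert np.allclose(rc.log_odds, pwm.log_odds[::-1, ::-1])
        assert np.allclose(rc.reverse_complement().log_odds, pwm.log_odds)

    def test_zero_pseudocount_with_zero_count_errors(self):
        pfm = MotifPFM("M", "m", np.array([[1.0], [0.0], [0.0], [0.0]]))
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, pseudocount=0.0)


def brute_force_accepted_kmers(pwm, p, resolution=1e-3):
    """Oracle: enumerate all 4^w k-mers on the per-column score grid and
    accept those whose (tie-aggregated) upper-tail mass is <= p."""
    scaled = np.floor(pwm.log_odds / resolution) * resolution
    w = pwm.width
    kmers = list(itertools.product(range(4), repeat=w))
    scores = np.array([sum(scaled[b, j] for j, b in enumerate(kmer))
                       for kmer in kmers])
    prob = 0.25 ** w
    accepted = set()
    for kmer, s in zip(kmers, scores):
        tail = prob * np.sum(scores >= s - 1e-9)
        if tail <= p + 1e-12:
            accepted.add(kmer)
    return accepted, dict(zip(kmers, scores))


class TestScoreThreshold:
    @pytest.mark.parametrize("width", [2, 3, 4, 6])
    def test_selects_same_kmers_as_exhaustive_enumeration(self, width, rng):
        """The DP threshold accepts exactly the k-mers whose exact null tail
        mass is <= p, for every width <= 6 tested."""
        for _ in range(3):
            pfm = MotifPFM("M", "m", rng.integers(0, 30, size=(4, width)) + 0.0)
            if (pfm.counts.sum(axis=0) == 0).any():
                continue
            pwm = pfm_to_pwm(pfm)
            for p in (1e-4, 1e-2, 0.2, 0.5):
                thr = score_threshold(pwm, p)
                oracle, scores = brute_force_accepted_kmers(pwm, p)
                selected = {k for k, s in scores.items() if s >= thr - 1e-9}
                assert selected == oracle

    def test_p_one_gives_minimal_score(self, rng):
        pfm = MotifPFM("M", "m", rng.integers(1, 9, size=(4, 3)).astype(float))
        pwm = pfm_to_pwm(pfm)
        thr = score_threshold(pwm, p=1.0)
        assert thr <= pwm.min_score() + 3e-3

    def test_uniform_pwm_everything_passes_at_p_one(self):
        pwm = pfm_to_pwm(MotifPFM("M", "m", np.full((4, 4), 2.0)))
        assert np.allclose(pwm.log_odds, 0.0)
        assert score_threshold(pwm, p=1.0) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_p_errors(self):
        pwm = pfm_to_pwm(MotifPFM("M", "m", np.full((4, 2), 1.0)))
        with pytest.raises(ValueError):
            score_threshold(pwm, p=0.0)


class TestScanPeaks:
    def setup_scan(self):
        motif = make_default_motifs()[0]  # SOX-like, consensus AACAATGG
        pwm = pfm_to_pwm(motif)
        thr = score_threshold(pwm, p=1e-4)
        return motif, pwm, thr

    def test_planted_consensus_found_at_exact_offset(self, rng):
        motif, pwm, thr = self.setup_scan()
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 500))
        planted = seq[:200] + motif.consensus + seq[208:]
        genome = {"chr1": planted}
        peaks = IntervalSet.from_records([("chr1", 0, 500)])
        hits = scan_peaks(pwm, peaks, genome, thr)
        fw = hits[hits["strand"] == "+"]
        assert (fw["start"] == 200).any()
        assert ((fw["end"] - fw["start"]) == motif.width).all()

    def test_reverse_complement_genome_swaps_strands(self, rng):
        motif, pwm, thr = self.setup_scan()
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
        seq = seq[:100] + motif.consensus + seq[108:]
        hits_f = scan_peaks(pwm, IntervalSet.from_records([("chr1", 0, 300)]),
                            {"chr1": seq}, thr)
        hits_r = scan_peaks(pwm, IntervalSet.from_records([("chr1", 0, 300)]),
                            {"chr1": revcomp(seq)}, thr)
        assert sorted(hits_f["strand"]) != [] and len(hits_f) == len(hits_r)
        assert sorted(hits_f["strand"]) == sorted(
            {"+": "-", "-": "+"}[s] for s in hits_r["strand"])

    def test_all_n_sequence_yields_no_hits(self):
        _, pwm, thr = self.setup_scan()
        hits = scan_peaks(pwm, IntervalSet.from_records([("chr1", 0, 100)]),
                          {"chr1": "N" * 100}, thr)
        assert len(hits) == 0

    def test_peak_shorter_than_motif_no_hits(self):
        _, pwm, thr = self.setup_scan()
        hits = scan_peaks(pwm, IntervalSet.from_records([("chr1", 0, 4)]),
                          {"chr1": "ACGTACGT"}, thr)
        assert len(hits) == 0


class TestMatchBackground:
    def make_peaks(self, gc_rich, n, offset=0):
        # GC-rich stratum: GGCC repeats; AT stratum: AATT repeats
        seqs, recs = {}, []
        base = "GGCC" if gc_rich else "AATT"
        for i in range(n):
            start = offset + i * 300
            recs.append(("chr1", start, start + 200))
        return recs

    def test_two_gc_strata_selects_matching_stratum(self, rng):
        genome = {"chr1": ("GGCC" * 5000) + ("AATT" * 5000)}
        targets = IntervalSet.from_records(self.make_peaks(True, 20))
        pool_gc = self.make_peaks(True, 50, offset=7000)
        pool_at = self.make_peaks(False, 50, offset=20_000)
        pool = IntervalSet.from_records(pool_gc + pool_at)
        all_ids = targets.ids() + pool.ids()
        counts = rng.poisson(5.0, size=(len(all_ids), 10))
        atac = CountMatrix(sp.csr_matrix(counts), all_ids,
                           [f"c{i}" for i in range(10)], "atac")
        bg = match_background_peaks(targets, pool, atac, genome, n=40, seed=0)
        frac_gc = np.mean([s < 20_000 for s in bg.df["start"]])
        assert frac_gc >= 0.9

    def test_n_zero_empty(self, rng):
        targets = IntervalSet.from_records([("chr1", 0, 100)])
        pool = IntervalSet.from_records([("chr1", 500, 600)])
        atac = CountMatrix(sp.csr_matrix(np.ones((2, 3), dtype=int)),
                           targets.ids() + pool.ids(), ["a", "b", "c"], "atac")
        out = match_background_peaks(targets, pool, atac, {"chr1": "A" * 1000}, n=0)
        assert len(out) == 0

    def test_small_pool_used_entirely_with_warning(self, rng):
        targets = IntervalSet.from_records([("chr1", 0, 100)])
        pool = IntervalSet.from_records([("chr1", 500, 600), ("chr1", 700, 800)])
        ids = targets.ids() + pool.ids()
        atac = CountMatrix(sp.csr_matrix(np.ones((3, 3), dtype=int)), ids,
                           ["a", "b", "c"], "atac")
        with pytest.warns(UserWarning):
            out = match_background_peaks(targets, pool, atac, {"chr1": "A" * 1000}, n=10)
        assert len(out) == 2


def hypergeom_sum(k, N, K, n):
    """Oracle: exact upper-tail hypergeometric by direct combinatorial sum."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += (math.comb(K, i) * math.comb(N - K, n - i)) / math.comb(N, n)
    return total


class TestEnrichment:
    def make_hits(self, target_hit, bg_hit, n_t=10, n_b=100):
        t = IntervalSet.from_records([("chr1", i * 1000, i * 1000 + 100) for i in range(n_t)])
        b = IntervalSet.from_records([("chr2", i * 1000, i * 1000 + 100) for i in range(n_b)])
        hit_ids = t.ids()[:target_hit] + b.ids()[:bg_hit]
        hits = pd.DataFrame({"motif_id": "M", "peak_id": hit_ids})
        return hits, t, b

    def test_equal_rates_fold_one_not_passing(self):
        hits, t, b = self.make_hits(5, 50)
        out = motif_enrichment(hits, t, b).iloc[0]
        assert out["fold_enrichment"] == pytest.approx(1.0)
        assert not out["passes"]

    def test_8_of_10_vs_10_of_100_exact_hypergeometric(self):
        hits, t, b = self.make_hits(8, 10)
        out = motif_enrichment(hits, t, b).iloc[0]
        assert out["fold_enrichment"] == pytest.approx(8.0)
        assert out["p_value"] == pytest.approx(hypergeom_sum(8, 110, 18, 10), abs=1e-12)
        assert out["passes"]

    def test_low_fold_fails_despite_significance(self):
        # craft fold 1.2 with large counts: p small but fold <= 1.25
        t = IntervalSet.from_records([("chr1", i * 1000, i * 1000 + 100) for i in range(1000)])
        b = IntervalSet.from_records([("chr2", i * 1000, i * 1000 + 100) for i in range(1000)])
        hits = pd.DataFrame({"motif_id": "M",
                             "peak_id": t.ids()[:600] + b.ids()[:500]})
        out = motif_enrichment(hits, t, b).iloc[0]
        assert out["fold_enrichment"] == pytest.approx(1.2)
        assert out["p_adjusted"] < 0.05
        assert not out["passes"]

    def test_empty_target_set_errors(self):
        hits, t, b = self.make_hits(1, 1)
        with pytest.raises(ValueError):
            motif_enrichment(hits, IntervalSet.from_records([]), b)


class TestChromvar:
    def test_all_peaks_set_has_zero_raw_deviation(self, rng):
        n_peaks, n_cells = 30, 12
        peaks = IntervalSet.from_records(
            [("chr1", i * 1000, i * 1000 + 200) for i in range(n_peaks)])
        counts = rng.poisson(4.0, size=(n_peaks, n_cells)) + 1
        atac = CountMatrix(sp.csr_matrix(counts), peaks.ids(),
                           [f"c{i}" for i in range(n_cells)], "atac")
        genome = {"chr1": "ACGT" * 10_000}
        annotation = pd.DataFrame({"M": [True] * n_peaks}, index=peaks.ids())
        dev = chromvar_deviations(atac, annotation, peaks, genome,
                                  n_background_sets=5, seed=0)
        assert np.allclose(dev["raw"]["M"].to_numpy(), 0.0, atol=1e-12)

    def test_permuted_annotation_mean_z_near_zero(self, null_dataset):
        ds = null_dataset
        rng = np.random.default_rng(0)
        n_peaks = len(ds.peaks)
        annotation = pd.DataFrame(
            {f"perm{j}": rng.permutation(np.arange(n_peaks) < n_peaks // 10)
             for j in range(3)}, index=ds.peaks.ids())
        dev = chromvar_deviations(ds.atac, annotation, ds.peaks, ds.genome,
                                  n_background_sets=25, seed=0)
        mean_z = np.nanmean(dev["z"].to_numpy(), axis=0)
        assert np.all(np.abs(mean_z) < 0.2)


class TestNetworkAssembly:
    def make_inputs(self):
        enrichment = pd.DataFrame({
            "motif_id": ["M1", "M2"],
            "passes": [True, True],
        })
        hits = pd.DataFrame({
            "motif_id": ["M1", "M2"],
            "peak_id": ["chr1:0-100", "chr1:500-600"],
            "chrom": ["chr1", "chr1"], "start": [10, 510], "end": [18, 518],
            "strand": ["+", "-"],
        })
        links = pd.DataFrame({
            "peak_id": ["chr1:0-100", "chr1:500-600"],
            "gene_id": ["target1", "target2"],
            "z": [8.0, -6.0],
            "sign": ["positive", "negative"],
        })
        daps = ["chr1:0-100", "chr1:500-600"]
        tf_map = {"M1": "Tf1", "M2": "Tf2"}
        return enrichment, hits, links, daps, tf_map

    def test_tf_not_deg_yields_no_edges(self):
        enrichment, hits, links, daps, tf_map = self.make_inputs()
        net = build_regulatory_network(enrichment, ["Tf1"], hits, links, daps, tf_map)
        assert set(net["tf"]) == {"Tf1"}
        row = net.iloc[0]
        assert (row["target_gene"], row["sign"]) == ("target1", "positive")

    def test_negative_link_gives_negative_edge(self):
        enrichment, hits, links, daps, tf_map = self.make_inputs()
        net = build_regulatory_network(enrichment, ["Tf1", "Tf2"], hits, links,
                                       daps, tf_map)
        row = net[net["tf"] == "Tf2"].iloc[0]
        assert row["sign"] == "negative"

    def test_no_hits_in_linked_daps_empty_network(self):
        enrichment, hits, links, daps, tf_map = self.make_inputs()
        net = build_regulatory_network(enrichment, ["Tf1", "Tf2"], hits, links,
                                       ["chr9:0-5"], tf_map)
        assert len(net) == 0


class TestCooccurrence:
    def edges(self, rows):
        return pd.DataFrame(rows, columns=["tf", "target_gene", "sign",
                                           "mediating_peaks", "hit_coordinates"])

    def test_single_tf_three_targets(self):
        e = self.edges([("A", f"g{i}", "positive", "p", "h") for i in range(3)])
        m = motif_cooccurrence(e)
        assert m.loc["A", "A"] == 3

    def test_two_tfs_sharing_two_of_three(self):
        e = self.edges([("A", "g1", "positive", "p", "h"),
                        ("A", "g2", "positive", "p", "h"),
                        ("A", "g3", "positive", "p", "h"),
                        ("B", "g1", "negative", "p", "h"),
                        ("B", "g2", "positive", "p", "h")])
        m = motif_cooccurrence(e)
        assert m.loc["A", "B"] == 2
        assert m.loc["B", "A"] == 2
        assert m.loc["A", "A"] == 3 and m.loc["B", "B"] == 2

    def test_symmetric_and_bounded(self, rng):
        rows = [(f"T{rng.integers(0, 4)}", f"g{rng.integers(0, 10)}",
                 "positive", "p", "h") for _ in range(40)]
        m = motif_cooccurrence(self.edges(rows))
        assert np.array_equal(m.to_numpy(), m.to_numpy().T)
        diag = np.diag(m.to_numpy())
        for i in range(len(m)):
            for j in range(len(m)):
                if i != j:
                    assert m.iloc[i, j] <= min(diag[i], diag[j])

    def test_peak_scope_flag(self):
        e = self.edges([("A", "g1", "positive", "pk1,pk2", "h"),
                        ("B", "g2", "positive", "pk2", "h")])
        m = motif_cooccurrence(e, scope="peak")
        assert m.loc["A", "B"] == 1  # share pk2
        with pytest.raises(ValueError):
            motif_cooccurrence(e, scope="bogus")
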