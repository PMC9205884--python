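"""Synthetic-data generator: determinism, ground-truth contracts, oracles."""

import re

import numpy as np
import pytest

from ivtseq.simulate import (
    RESTRICTION_MOTIFS,
    SimulationTruth,
    simulate_fragment_ends,
    simulate_genome,
    simulate_study,
)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        a = simulate_genome(10, 20_000, seed=3)
        b = simulate_genome(10, 20_000, seed=3)
        assert a[0] == b[0]
        assert a[1].to_frame().equals(b[1].to_frame())

    def test_zero_genes(self):
        contigs, genes, pairs = simulate_genome(0, 5_000, seed=1)
        assert len(genes) == 0 and pairs == []
        assert len(contigs["chrom"]) == 5_000

    def test_minus_strand_initiation_codon_rightmost(self):
        _, genes, _ = simulate_genome(30, 60_000, seed=2)
        minus = [g for g in genes if g.strand == "-"]
        assert minus, "expect some minus-strand genes"
        for g in minus:
            assert g.start > g.end

    def test_genes_do_not_overlap(self):
        _, genes, _ = simulate_genome(40, 80_000, seed=4)
        spans = sorted((g.left, g.right) for g in genes)
        for (l1, r1), (l2, r2) in zip(spans, spans[1:]):
            assert r1 < l2

    def test_operon_pairs_same_strand_small_gap(self):
        _, genes, pairs = simulate_genome(20, 40_000, seed=5, n_operon_pairs=4)
        assert len(pairs) == 4
        for up, dn in pairs:
            gu, gd = genes[up], genes[dn]
            assert gu.strand == gd.strand
            gap = (gd.start - gu.end - 1) if gu.strand == "+" else (gu.end - gd.start - 1)
            assert 0 <= gap <= 50


class TestFragmentEnds:
    def test_absent_motif_no_ends(self):
        assert simulate_fragment_ends({"chrom": "AAAAAAA"}) == []

    def test_planted_site_found(self):
        seq = "A" * 50 + "GAATTC" + "A" * 50
        assert simulate_fragment_ends({"chrom": seq}) == [51]

    def test_count_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        naive = set()
        for motif in RESTRICTION_MOTIFS:
            for i in range(len(seq) - len(motif) + 1):
                if seq[i: i + len(motif)] == motif:
                    naive.add(i + 1)
        assert simulate_fragment_ends({"chrom": seq}) == sorted(naive)

    def test_asymmetric_motif_scanned_on_both_strands(self):
        seq = "A" * 20 + "GGGTC" + "A" * 20  # revcomp GACCC present only as given
        ends = simulate_fragment_ends({"chrom": seq}, recognition_motifs=["GACCC"])
        assert ends == [21]


class TestTracks:
    def test_same_seed_identical_tracks(self):
        a = simulate_study(seed=7)
        b = simulate_study(seed=7)
        for ta, tb in zip(a.sigma_tracks + a.control_tracks,
                          b.sigma_tracks + b.control_tracks):
            assert ta.counts == tb.counts
        assert a.count_matrix.equals(b.count_matrix)

    def test_different_seed_differs(self):
        a = simulate_study(seed=7)
        b = simulate_study(seed=8)
        assert a.sigma_tracks[0].counts != b.sigma_tracks[0].counts

    def test_planted_tss_within_upstream_window(self, default_study):
        genes = default_study.genes
        for t in default_study.truth.planted_tss:
            g = genes[t.gene_id]
            d = g.start - t.position if g.strand == "+" else t.position - g.start
            assert 0 <= d <= 300

    def test_planted_signal_only_in_sigma_condition(self, default_study):
        """Control tracks carry no pile-up at planted TSSs beyond background."""
        truth = default_study.truth
        for track in default_study.control_tracks:
            at_tss = [
                track.get(t.contig, t.strand, t.position) for t in truth.planted_tss
            ]
            assert sum(at_tss) < 0.2 * sum(t.mean_count for t in truth.planted_tss)

    def test_planted_mean_recovered(self):
        """Realized sigma-track counts at a planted TSS match the NB mean
        x library efficiency (simulation CI over generator replicates)."""
        totals, mean_expected = [], []
        for seed in range(40):
            st = simulate_study(seed=seed, n_genes=20, contig_length=40_000,
                                n_tss=6, n_direct_genes=6, n_operon_pairs=0)
            t = st.truth.planted_tss[0]
            rep = st.sigma_tracks[0]
            realized = sum(
                rep.get(t.contig, t.strand, t.position + j) for j in (-1, 0, 1)
            )
            totals.append(realized)
            mean_expected.append(t.mean_count * st.efficiencies[rep.sample_id])
        ratio = np.sum(totals) / np.sum(mean_expected)
        assert 0.9 < ratio < 1.1

    def test_ercc_first_nt_counts_scale_with_abundance(self, default_study):
        truth = default_study.truth
        track = default_study.sigma_tracks[0]
        ids = sorted(truth.ercc_abundance, key=truth.ercc_abundance.get)
        low = np.mean([track.get(e, "+", 1) for e in ids[:10]])
        high = np.mean([track.get(e, "+", 1) for e in ids[-10:]])
        assert high > 20 * low


class TestCountMatrix:
    def test_ercc_rows_condition_independent(self, default_study):
        """Spike-in means depend on efficiency only, not on condition:
        the planted fold change never touches ERCC rows."""
        truth = default_study.truth
        mat = default_study.count_matrix
        ercc = mat.loc[mat.index.isin(default_study.ercc_ids)]
        # correlate each sample against true abundance: all strong
        ab = np.array([truth.ercc_abundance[e] for e in ercc.index])
        for col in ercc.columns:
            r = np.corrcoef(np.log1p(ercc[col]), np.log(ab))[0, 1]
            assert r > 0.95

    def test_regulon_fold_change_planted(self, default_study):
        mat = default_study.count_matrix
        design = default_study.design
        sig = design.replicates("sigA")
        ctl = design.replicates("no_sigma")
        reg = sorted(default_study.truth.regulon)
        ratio = (
            mat.loc[reg, sig].mean(axis=1) / mat.loc[reg, ctl].mean(axis=1)
        )
        assert 3.0 < ratio.median() < 5.5

    def test_null_simulation_no_systematic_fold_change(self):
        st = simulate_study(seed=13, n_tss=12, n_direct_genes=12,
                            n_operon_pairs=0, fold_change=1.0)
        mat = st.count_matrix
        chrom = mat.loc[~mat.index.isin(st.ercc_ids)]
        sig = st.design.replicates("sigA")
        ctl = st.design.replicates("no_sigma")
        fc = chrom[sig].mean(axis=1) / chrom[ctl].mean(axis=1).clip(lower=1)
        assert (fc >= 2.0).mean() < 0.05


def test_truth_round_trips(tmp_path, default_study):
    p = tmp_path / "truth.json"
    default_study.truth.to_json(p)
    again = SimulationTruth.from_json(p)
    assert again == default_study.truth
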