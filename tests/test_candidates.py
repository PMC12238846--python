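"""Candidate cascade: CPM, differential expression, filters, selection."""

import numpy as np
import pandas as pd
import pytest

import lncscreen as L
from lncscreen.config import CandidateThresholds

from conftest import toy_annotation


def _matrix(counts: dict, groups: dict) -> L.ExpressionMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    df.index.name = "gene_id"
    return L.ExpressionMatrix(counts=df, sample_groups=pd.Series(groups))


class TestCPM:
    def test_basic_scaling(self):
        m = _matrix({"s1": [10, 90]}, {"s1": "a"})
        cpm = L.compute_cpm(m)
        assert cpm["s1"].tolist() == [100_000.0, 900_000.0]

    def test_equal_counts_share_evenly(self):
        m = _matrix({"s1": [7] * 8}, {"s1": "a"})
        assert np.allclose(L.compute_cpm(m)["s1"], 1e6 / 8)

    def test_pseudocount_formula(self):
        # zero-count guide among 1000 total raw counts, pc = 0.5
        counts = pd.DataFrame({"s1": [0, 400, 600]})
        cpm = L.compute_cpm(counts, pseudocount=0.5)
        total = (counts["s1"] + 0.5).sum()
        assert cpm.loc[0, "s1"] == pytest.approx(0.5 / total * 1e6)
        assert cpm["s1"].sum() == pytest.approx(1e6)

    def test_all_zero_sample_error_names_sample(self):
        m = _matrix({"ok": [1, 2], "empty": [0, 0]}, {"ok": "a", "empty": "a"})
        with pytest.raises(ValueError, match="empty"):
            L.compute_cpm(m)


class TestDGE:
    def test_identical_groups_give_zero_logfc(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=20)
        m = _matrix(
            {"a1": base, "a2": base * 2, "b1": base, "b2": base * 2},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        dge = L.differential_expression(m, "A", "B")
        assert np.allclose(dge.table["log2fc"], 0.0)

    def test_planted_fourfold_effect_detected_reliably(self):
        """4x planted effect, 6 vs 6 samples at mean 500: estimated log2 fc
        in [1.6, 2.4] and FDR < 0.05 in >= 95% of seeded runs."""
        hits = 0
        runs = 100
        for seed in range(runs):
            cfg = L.SimConfig(
                seed=seed, n_genes=100, n_lnc_true=1, expr_logfc=2.0,
                expr_base_mean=500.0, expr_mean_sigma=0.0, planted_min_mean_factor=0.0,
                groups=(("ctrl", 6), ("tumor", 6)), tumor_groups=("tumor",),
            )
            b = L.simulate_annotation(cfg)
            mat, truth = L.simulate_expression(cfg, b.annotation)
            dge = L.differential_expression(mat, "ctrl", "tumor")
            gid = next(iter(truth.true_candidates))
            row = dge.table.loc[gid]
            if 1.6 <= row["log2fc"] <= 2.4 and row["padj"] < 0.05:
                hits += 1
        assert hits >= 0.95 * runs

    def test_requires_replicates(self):
        m = _matrix({"a1": [1], "b1": [2], "b2": [3]}, {"a1": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError, match="need >= 2"):
            L.differential_expression(m, "A", "B")

    def test_adjusted_p_at_least_raw(self, default_sim):
        mat = default_sim.expression
        dge = L.differential_expression(mat, "melanocyte", "brain_met")
        assert (dge.table["padj"] >= dge.table["pvalue"] - 1e-12).all()
        assert dge.table["padj"].between(0, 1).all()


class TestTssMark:
    ann = None

    @classmethod
    def setup_class(cls):
        cls.ann = toy_annotation({"gA": ("chr1", "+", 1200, 2200, [2])})

    @staticmethod
    def _peaks(start, end, celltype="mel"):
        return pd.DataFrame(
            [["chr1", start, end, "H3K4me3", celltype]],
            columns=["chrom", "start", "end", "mark", "celltype"],
        )

    def test_overlapping_peak_detected(self):
        ann = toy_annotation({"gA": ("chr1", "+", 1200, 2200, [2])})
        assert L.tss_active_mark(ann, self._peaks(1000, 1500), "mel", 2000)["gA"]

    def test_distant_peak_ignored(self):
        ann = toy_annotation({"gA": ("chr1", "+", 10_000, 11_000, [2])})
        assert not L.tss_active_mark(ann, self._peaks(1000, 1500), "mel", 2000)["gA"]

    def test_half_open_boundary(self):
        # peak ending exactly at TSS - window does not overlap [TSS-w, TSS+w)
        ann = toy_annotation({"gA": ("chr1", "+", 3500, 4000, [2])})
        assert not L.tss_active_mark(ann, self._peaks(1000, 1500), "mel", 2000)["gA"]
        # one base further in does overlap
        assert L.tss_active_mark(ann, self._peaks(1000, 1501), "mel", 2000)["gA"]

    def test_unknown_celltype_rejected(self):
        ann = toy_annotation({"gA": ("chr1", "+", 1200, 2200, [2])})
        with pytest.raises(ValueError, match="unknown cell type"):
            L.tss_active_mark(ann, self._peaks(1000, 1500), "nosuch", 2000)

    def test_wrong_mark_ignored(self):
        ann = toy_annotation({"gA": ("chr1", "+", 1200, 2200, [2])})
        peaks = self._peaks(1000, 1500)
        peaks["mark"] = "H3K9me3"
        assert not L.tss_active_mark(ann, peaks, "mel", 2000)["gA"]


class TestMonoExonic:
    def test_mixed_transcripts_pass(self):
        ann = toy_annotation({"gA": ("chr1", "+", 100, 1100, [1, 3])})
        assert L.filter_mono_exonic(ann)["gA"]

    def test_all_single_exon_fails(self):
        ann = toy_annotation({"gA": ("chr1", "+", 100, 1100, [1, 1])})
        assert not L.filter_mono_exonic(ann)["gA"]

    def test_empty_gene_set(self):
        ann = toy_annotation({})
        assert len(L.filter_mono_exonic(ann)) == 0


def _dge_from_table(rows, group_a="A", group_b="B"):
    table = pd.DataFrame(
        rows, columns=["log2fc", "pvalue", "padj", "mean_cpm_a", "mean_cpm_b"],
        index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
    )
    return L.DGEResult(table=table, group_a=group_a, group_b=group_b)


class TestSelectCandidates:
    def _toy(self):
        # five genes; only g0 satisfies every condition
        dge = _dge_from_table([
            (1.5, 0.001, 0.01, 2.0, 8.0),   # g0: passes everything
            (1.5, 0.001, 0.10, 2.0, 8.0),   # g1: fails FDR
            (0.5, 0.001, 0.01, 2.0, 3.0),   # g2: fails logFC
            (1.5, 0.001, 0.01, 0.2, 0.6),   # g3: fails CPM
            (1.5, 0.001, 0.01, 2.0, 8.0),   # g4: fails mark
        ])
        genes = dge.table.index
        marks = pd.Series([True, True, True, True, False], index=genes)
        exons = pd.Series(True, index=genes)
        return dge, marks, exons

    def test_hand_evaluated_cascade(self):
        dge, marks, exons = self._toy()
        rec = L.select_candidates([dge], marks, exons)
        assert list(rec.index[rec["candidate"]]) == ["g0"]
        assert not rec.loc["g1", "fdr_pass"]
        assert not rec.loc["g2", "logfc_pass"]
        assert not rec.loc["g3", "cpm_pass"]
        assert not rec.loc["g4", "mark_pass"]

    def test_degenerate_thresholds_select_all_up(self):
        dge, marks, exons = self._toy()
        marks[:] = True
        thr = CandidateThresholds(fdr=1.0, logfc=0.0, cpm=0.0, cellline_logfc=-np.inf)
        rec = L.select_candidates([dge], marks, exons, thresholds=thr)
        assert set(rec.index[rec["candidate"]]) == set(rec.index[rec["direction"] == "up"])
        assert rec["candidate"].sum() == 5

    def test_cellline_rule_any_of(self):
        dge, marks, exons = self._toy()
        cl_pass = _dge_from_table([(0.6, 1, 1, 1, 1)] * 5)
        cl_fail = _dge_from_table([(0.1, 1, 1, 1, 1)] * 5)
        rec = L.select_candidates([dge], marks, exons, cellline_dge=[cl_fail, cl_pass])
        assert rec.loc["g0", "candidate"]
        rec2 = L.select_candidates([dge], marks, exons, cellline_dge=[cl_fail])
        assert not rec2.loc["g0", "candidate"]

    def test_missing_gene_reported(self):
        dge, marks, exons = self._toy()
        with pytest.raises(KeyError, match="g4"):
            L.select_candidates([dge], marks.drop("g4"), exons)

    def test_monotonicity_tightening_never_adds(self, default_sim):
        b, cfg = default_sim.bundle, default_sim.config
        mat = default_sim.expression
        dges = [L.differential_expression(mat, "melanocyte", g) for g in cfg.tumor_groups]
        marks = L.tss_active_mark(b.annotation, default_sim.peaks, "brain_met")
        exons = L.filter_mono_exonic(b.annotation)
        loose = L.select_candidates([dge for dge in dges], marks, exons)
        base = set(loose.index[loose["candidate"]])
        for tight in (
            CandidateThresholds(fdr=0.01),
            CandidateThresholds(logfc=1.5),
            CandidateThresholds(cpm=10.0),
        ):
            rec = L.select_candidates(dges, marks, exons, thresholds=tight)
            assert set(rec.index[rec["candidate"]]) <= base

    def test_planted_truth_recovery(self, default_sim):
        sim = default_sim
        mat = sim.expression
        dges = [L.differential_expression(mat, "melanocyte", g) for g in sim.config.tumor_groups]
        marks = L.tss_active_mark(sim.bundle.annotation, sim.peaks, "brain_met")
        exons = L.filter_mono_exonic(sim.bundle.annotation)
        rec = L.select_candidates(dges, marks, exons)
        assert set(rec.index[rec["candidate"]]) == sim.truth.true_candidates

    def test_union_of_comparisons(self):
        dge, marks, exons = self._toy()
        rec = L.select_candidates([dge], marks, exons)
        other = rec.copy()
        other.index = [f"x{i}" for i in range(len(other))]
        union = L.union_candidates([rec, other])
        assert list(union) == ["g0", "x0"]
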