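"""Five-filter lncRNA candidate prioritization.

A gene becomes a screen candidate when, for every expression comparison it
is tested in, it (i) is significant at FDR <= 0.05, (ii) has |log2 fc| >
0.75, (iii) has mean CPM >= 1 in the higher-expressed group, (iv) carries
an active histone mark (H3K4me3 or H3K27ac) near its TSS in the cell type
where it is highly expressed, (v) is not composed solely of mono-exonic
transcripts, and additionally is expressed (log2 fc >= 0.5) in a
screenable cell line. Only up-regulated candidates feed library design;
down-regulated sets are reported with full per-filter provenance.

The differential test is a Welch t-test on log2(CPM + 0.5) with
Benjamini-Hochberg adjustment; an externally computed table (e.g. from an
NB-based engine) can be substituted wherever a DGEResult is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CandidateThresholds
from .types import ACTIVE_MARKS, ExpressionMatrix, TranscriptAnnotation, validate_peaks

__all__ = [
    "compute_cpm",
    "differential_expression",
    "DGEResult",
    "tss_active_mark",
    "filter_mono_exonic",
    "select_candidates",
    "union_candidates",
]


def compute_cpm(matrix: ExpressionMatrix | pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Counts-per-million per sample: (c + pc) / sum(c + pc) * 1e6.

    With pseudocount 0 each column sums to exactly 1e6. An all-zero sample
    (zero total at pseudocount 0) is an error naming the sample.
    """
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = counts.astype(float) + pseudocount
    totals = shifted.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(f"samples with zero total count: {list(dead.index)}")
    return shifted / totals * 1e6


@dataclass
class DGEResult:
    """Per-gene differential-expression outcome of group B over group A."""

    table: pd.DataFrame  # index gene_id: log2fc, pvalue, padj, mean_cpm_a, mean_cpm_b
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        t = self.table
        if ((t["padj"] < t["pvalue"] - 1e-12) | (t["padj"] > 1) | (t["padj"] < 0)).any():
            raise ValueError("adjusted p-values must lie in [0, 1] and be >= raw p")


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
) -> DGEResult:
    """Welch t-test per gene on log2(CPM + pc), B vs A, BH-adjusted.

    log2 fc is computed on group-mean CPM with the same pseudocount, so a
    gene silent in both groups has fc 0 rather than NaN.
    """
    a_cols = matrix.samples_in_group(group_a)
    b_cols = matrix.samples_in_group(group_b)
    for name, cols in ((group_a, a_cols), (group_b, b_cols)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has {len(cols)} sample(s); need >= 2")

    cpm = compute_cpm(matrix, pseudocount=0.0)
    mean_a = cpm[a_cols].mean(axis=1)
    mean_b = cpm[b_cols].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    log_cpm = np.log2(cpm + pseudocount)
    tstat, pval = stats.ttest_ind(
        log_cpm[b_cols], log_cpm[a_cols], axis=1, equal_var=False
    )
    pval = np.where(np.isnan(pval), 1.0, pval)  # zero-variance identical groups
    padj = multipletests(pval, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pval,
            "padj": padj,
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
        },
        index=cpm.index,
    )
    return DGEResult(table=table, group_a=group_a, group_b=group_b)


def tss_active_mark(
    annotation: TranscriptAnnotation,
    peaks: pd.DataFrame,
    celltype: str,
    window_bp: int = 2_000,
) -> pd.Series:
    """True per gene iff an H3K4me3/H3K27ac peak of `celltype` overlaps
    [TSS - window_bp, TSS + window_bp) (half-open)."""
    validate_peaks(peaks)
    known = set(peaks["celltype"].unique())
    if celltype not in known:
        raise ValueError(f"unknown cell type {celltype!r}; peak table has {sorted(known)}")
    sel = peaks[(peaks["celltype"] == celltype) & (peaks["mark"].isin(ACTIVE_MARKS))]
    flags = {}
    by_chrom = {c: g for c, g in sel.groupby("chrom")}
    for gid, chrom, tss in annotation.genes[["gene_id", "chrom", "tss"]].itertuples(index=False):
        sub = by_chrom.get(chrom)
        lo, hi = tss - window_bp, tss + window_bp
        flags[gid] = bool(sub is not None and ((sub["start"] < hi) & (sub["end"] > lo)).any())
    return pd.Series(flags, name="mark_pass")


def filter_mono_exonic(annotation: TranscriptAnnotation) -> pd.Series:
    """True per gene iff the gene has at least one multi-exonic transcript.

    Genes whose transcripts are all single-exon fail (they may be
    enhancer-associated RNAs rather than bona fide lncRNAs).
    """
    if len(annotation.genes) == 0:
        return pd.Series(dtype=bool, name="multiexon_pass")
    n_exons = annotation.exons.groupby("transcript_id").size()
    tx = annotation.transcripts.assign(n_exons=annotation.transcripts["transcript_id"].map(n_exons))
    if tx["n_exons"].isna().any():
        bad = tx.loc[tx["n_exons"].isna(), "transcript_id"].tolist()
        raise ValueError(f"transcripts without exons: {bad}")
    multi = tx.groupby("gene_id")["n_exons"].max() >= 2
    return multi.reindex(annotation.genes["gene_id"]).fillna(False).rename("multiexon_pass")


def select_candidates(
    dge_list: list[DGEResult],
    mark_flags: pd.Series,
    exon_flags: pd.Series,
    cellline_dge: list[DGEResult] | DGEResult | None = None,
    thresholds: CandidateThresholds | None = None,
) -> pd.DataFrame:
    """Apply the full cascade; return per-gene provenance.

    A gene must satisfy the FDR / log2 fc / CPM rules in *every* DGE
    comparison supplied (e.g. up in brain metastasis AND lymph node vs
    melanocytes), with a consistent direction; the cell-line rule requires
    log2 fc >= cellline_logfc in the same direction in *any* of the
    supplied cell-line comparisons (None means the rule is not applied).

    The returned table has one boolean column per filter, a direction
    column ('up' / 'down' / 'mixed'), and `candidate` = conjunction of all
    six filters for up-regulated genes. Filters are pure per-gene
    conjunctions, so their application order cannot change the result.
    """
    if thresholds is None:
        thresholds = CandidateThresholds()
    if not dge_list:
        raise ValueError("at least one DGE comparison required")
    if isinstance(cellline_dge, DGEResult):
        cellline_dge = [cellline_dge]

    genes = dge_list[0].table.index
    for inputs, label in ((mark_flags, "mark flags"), (exon_flags, "exon flags")):
        missing = genes.difference(inputs.index)
        if len(missing):
            raise KeyError(f"genes missing from {label}: {sorted(missing)[:10]}")
    for dge in dge_list[1:] + (cellline_dge or []):
        missing = genes.difference(dge.table.index)
        if len(missing):
            raise KeyError(f"genes missing from DGE {dge.group_b} vs {dge.group_a}: {sorted(missing)[:10]}")

    lfc = pd.DataFrame({i: d.table["log2fc"].reindex(genes) for i, d in enumerate(dge_list)})
    padj = pd.DataFrame({i: d.table["padj"].reindex(genes) for i, d in enumerate(dge_list)})
    # higher-expressed group's mean CPM, per comparison
    hi_cpm = pd.DataFrame(
        {
            i: np.maximum(d.table["mean_cpm_a"].reindex(genes), d.table["mean_cpm_b"].reindex(genes))
            for i, d in enumerate(dge_list)
        }
    )

    all_up = (lfc > 0).all(axis=1)
    all_down = (lfc < 0).all(axis=1)
    direction = pd.Series("mixed", index=genes)
    direction[all_up] = "up"
    direction[all_down] = "down"

    fdr_pass = (padj <= thresholds.fdr).all(axis=1)
    logfc_pass = (lfc.abs() > thresholds.logfc).all(axis=1) & (direction != "mixed")
    cpm_pass = (hi_cpm >= thresholds.cpm).all(axis=1)
    mark_pass = mark_flags.reindex(genes).astype(bool)
    multiexon_pass = exon_flags.reindex(genes).astype(bool)

    if cellline_dge:
        cl = pd.DataFrame({i: d.table["log2fc"].reindex(genes) for i, d in enumerate(cellline_dge)})
        signed = cl.mul(np.where(direction == "down", -1.0, 1.0), axis=0)
        cellline_pass = (signed >= thresholds.cellline_logfc).any(axis=1)
    else:
        cellline_pass = pd.Series(True, index=genes)

    out = pd.DataFrame(
        {
            "fdr_pass": fdr_pass,
            "logfc_pass": logfc_pass,
            "cpm_pass": cpm_pass,
            "mark_pass": mark_pass,
            "multiexon_pass": multiexon_pass,
            "cellline_pass": cellline_pass,
            "direction": direction,
        },
        index=genes,
    )
    filters = ["fdr_pass", "logfc_pass", "cpm_pass", "mark_pass", "multiexon_pass", "cellline_pass"]
    out["all_filters_pass"] = out[filters].all(axis=1)
    out["candidate"] = out["all_filters_pass"] & (out["direction"] == "up")
    return out


def union_candidates(records: list[pd.DataFrame]) -> pd.Index:
    """Union of up-regulated candidate sets from several comparisons
    (e.g. metastasis-vs-melanocyte and resistant-vs-parental) — the gene
    list handed to library design."""
    ids: set[str] = set()
    for rec in records:
        ids.update(rec.index[rec["candidate"]])
    return pd.Index(sorted(ids), name="gene_id")
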