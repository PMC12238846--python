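"""Post-screen quantitative validation analyses.

Two pieces of arithmetic: (1) GFP competition-assay normalization — the
GFP-positive fraction of each knockdown series divided by its own
baseline-day value and by the matched non-targeting control (sgROSA)
series, so a value of 0.5 means the knockdown population was
half-depleted relative to the control trajectory; (2) the cis-neighbor
check — Z-scored expression of genes within a window (default +/-1 Mb)
around a perturbed locus, tested knockdown vs control to ask whether the
locus acts on its chromatin neighborhood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .candidates import compute_cpm
from .types import ExpressionMatrix, TranscriptAnnotation

__all__ = ["competition_normalize", "neighbor_gene_analysis"]


def competition_normalize(
    series: pd.DataFrame,
    control_id: str,
    baseline_day: int | float | None = None,
) -> pd.DataFrame:
    """Doubly normalized GFP fold change per (sgRNA, day).

    `series` has columns sgRNA, day, fraction (GFP-positive fraction in
    [0, 1]). norm(sg, d) = [f(sg,d)/f(sg,baseline)] / [f(ctrl,d)/
    f(ctrl,baseline)]; the baseline day (assay start) defaults to the
    earliest day present and must exist — with a positive fraction — for
    every series; days missing from the control are refused rather than
    interpolated.
    """
    required = {"sgRNA", "day", "fraction"}
    if not required.issubset(series.columns):
        raise ValueError(f"series must have columns {sorted(required)}")
    if ((series["fraction"] < 0) | (series["fraction"] > 1)).any():
        raise ValueError("GFP fractions must lie in [0, 1]")
    if control_id not in set(series["sgRNA"]):
        raise ValueError(f"control series {control_id!r} absent")
    if baseline_day is None:
        baseline_day = series["day"].min()

    wide = series.pivot(index="day", columns="sgRNA", values="fraction")
    if baseline_day not in wide.index:
        raise ValueError(f"baseline day {baseline_day} missing")
    base = wide.loc[baseline_day]
    if (base.isna() | (base <= 0)).any():
        bad = base.index[base.isna() | (base <= 0)].tolist()
        raise ValueError(f"zero or missing baseline fraction for: {bad}")
    ctrl = wide[control_id]
    if ctrl.isna().any():
        missing = wide.index[ctrl.isna()].tolist()
        raise ValueError(f"control series missing at day(s) {missing}; interpolation refused")

    rel = wide.div(base, axis=1)
    norm = rel.div(rel[control_id], axis=0)
    out = norm.reset_index().melt(id_vars="day", value_name="normalized_fc").dropna()
    return out.sort_values(["sgRNA", "day"], ignore_index=True)


def neighbor_gene_analysis(
    annotation: TranscriptAnnotation,
    matrix: ExpressionMatrix,
    locus: str,
    kd_group: str,
    control_group: str,
    window_bp: int = 1_000_000,
    min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Test expressed neighbors of `locus` for knockdown response.

    Neighbors are genes (excluding the locus itself) whose TSS lies
    within locus TSS +/- window_bp on the same chromosome and whose mean
    CPM across all samples is >= min_cpm ("expressed"). Expression is
    Z-scored per gene across all samples jointly, then compared knockdown
    vs control with a Welch t-test and BH adjustment across neighbors.
    Genes with zero variance have no defined Z-score and are reported
    with missing statistics, excluded from testing.

    Returns one row per neighbor: distance_bp, mean_z per condition,
    log2fc (CPM scale), pvalue, qvalue, tested flag.
    """
    genes = annotation.genes.set_index("gene_id")
    if locus not in genes.index:
        raise KeyError(f"locus {locus!r} not in annotation")
    loc = genes.loc[locus]

    same_chrom = genes[(genes["chrom"] == loc["chrom"]) & (genes.index != locus)]
    dist = (same_chrom["tss"] - loc["tss"]).abs()
    neighbors = same_chrom[dist <= window_bp].index

    kd_cols = matrix.samples_in_group(kd_group)
    ctrl_cols = matrix.samples_in_group(control_group)
    if len(kd_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per condition")

    cpm = compute_cpm(matrix, pseudocount=0.0)
    expressed = cpm.mean(axis=1) >= min_cpm
    rows = []
    for gid in neighbors:
        if gid not in cpm.index or not expressed.get(gid, False):
            continue
        vals = np.log2(cpm.loc[gid] + 0.5)
        sd = vals.std(ddof=0)
        d = int(dist[gid])
        if sd == 0:
            rows.append((gid, d, np.nan, np.nan, np.nan, np.nan, False))
            continue
        z = (vals - vals.mean()) / sd
        _, p = stats.ttest_ind(vals[kd_cols], vals[ctrl_cols], equal_var=False)
        lfc = np.log2((cpm.loc[gid, kd_cols].mean() + 0.5) / (cpm.loc[gid, ctrl_cols].mean() + 0.5))
        rows.append((gid, d, float(z[kd_cols].mean()), float(z[ctrl_cols].mean()), float(lfc), float(p), True))

    report = pd.DataFrame(
        rows,
        columns=["gene_id", "distance_bp", "mean_z_kd", "mean_z_control", "log2fc", "pvalue", "tested"],
    ).set_index("gene_id")
    report["qvalue"] = np.nan
    tested = report["tested"]
    if tested.any():
        report.loc[tested, "qvalue"] = multipletests(report.loc[tested, "pvalue"], method="fdr_bh")[1]
    return report.sort_values("distance_bp")
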