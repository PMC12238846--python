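"""Drop-off screen scoring and QC.

The analysis follows the standard pooled-screen arithmetic: CPM
normalization with a 0.5 pseudocount on raw counts, per-guide log2 fold
change against the matched replicate's screening-start reference, and a
per-gene top-k depleted statistic (k = 3): the median (default) or mean
of the k most negative guide fold changes at the end time point. A gene
is a hit when its aggregate is at or below the depletion threshold
(default -1, i.e. the top-3 guides lost at least half their abundance).

QC mirrors what a screen analyst checks before trusting hits: pairwise
replicate Pearson correlation on log2 CPM, hierarchical clustering and
PCA of Z-scored guide counts, and drift in the no-induction control arm.
A scrambled-guide resampling null gives empirical per-gene p-values for
users who want more than a fixed threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .candidates import compute_cpm
from .rng import substream
from .types import ScreenCounts

__all__ = [
    "normalize_screen",
    "guide_log2fc",
    "gene_topk_score",
    "call_hits",
    "qc_replicate_correlation",
    "qc_cluster_pca",
    "control_drift_check",
    "empirical_null",
    "rank_overlap",
]

log = logging.getLogger(__name__)


def normalize_screen(screen: ScreenCounts, pseudocount: float = 0.5) -> pd.DataFrame:
    """CPM per sample with the pseudocount applied to raw counts.

    The plasmid column is normalized identically to the time-course
    samples.
    """
    return compute_cpm(screen.counts, pseudocount=pseudocount)


def guide_log2fc(
    cpm: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-guide log2(CPM_t / CPM_ref) against the matched replicate's
    screening-start sample.

    `pseudocount` here acts at CPM level and is only needed when the
    upstream CPM was computed without one; with the default raw-count
    pseudocount of 0.5 all fold changes are already finite. The plasmid
    column has no reference and is excluded. Columns of the returned
    frame are MultiIndexed by (arm, day, replicate).
    """
    refs = samples[samples["is_reference"]]
    if refs.empty:
        raise ValueError("no reference (screening start) sample in sample sheet")
    ref_by_rep = refs.set_index("replicate")["sample"]

    out = {}
    for row in samples.itertuples(index=False):
        if row.is_reference or row.arm == "plasmid":
            continue
        if row.replicate not in ref_by_rep.index:
            raise ValueError(f"no reference sample for replicate {row.replicate!r}")
        ref_col = ref_by_rep[row.replicate]
        out[(row.arm, int(row.day), row.replicate)] = np.log2(
            (cpm[row.sample] + pseudocount) / (cpm[ref_col] + pseudocount)
        )
    fc = pd.DataFrame(out)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["arm", "day", "replicate"])
    return fc.sort_index(axis=1)


def _combine_replicates(fc: pd.DataFrame, arm: str, day: int) -> pd.Series:
    """Average each guide's fold change across replicates of (arm, day)."""
    try:
        sub = fc.loc[:, (arm, day)]
    except KeyError:
        raise ValueError(f"no samples for arm={arm!r} day={day}") from None
    if isinstance(sub, pd.Series):
        return sub
    return sub.mean(axis=1)


def gene_topk_score(
    fc: pd.DataFrame,
    gene_of_guide: pd.Series,
    guide_class: pd.Series | None = None,
    day: int | None = None,
    arm: str = "induced",
    k: int = 3,
    aggregator: str = "median",
) -> pd.DataFrame:
    """Per-gene aggregate of the k most depleted guides.

    Replicate fold changes of (arm, day) are averaged per guide first
    (day defaults to the latest assayed day); guides are then sorted by
    (fold change ascending, guide id) for a deterministic selected set
    and the first min(k, n_guides) aggregated. Both median and mean are
    reported; `aggregator` picks which one fills the `score` column and
    drives ranking. Scrambled controls are excluded; genes with fewer
    than k guides are scored over what they have and flagged.
    """
    if aggregator not in ("median", "mean"):
        raise ValueError(f"aggregator must be 'median' or 'mean', got {aggregator!r}")
    if day is None:
        day = int(max(d for a, d, r in fc.columns if a == arm))
    per_guide = _combine_replicates(fc, arm, day).rename("fc")

    frame = pd.DataFrame({"fc": per_guide, "gene_id": gene_of_guide.reindex(per_guide.index)})
    orphans = frame["gene_id"].isna()
    if orphans.any():
        raise ValueError(f"guides without a gene mapping: {sorted(frame.index[orphans])[:10]}")
    if guide_class is not None:
        frame = frame[guide_class.reindex(frame.index) != "scrambled"]

    rows = []
    for gene, grp in frame.groupby("gene_id", sort=True):
        # sort ascending by fc with guide-id tie-break for a deterministic set
        ordered = grp.iloc[np.lexsort((grp.index.to_numpy(), grp["fc"].to_numpy()))]
        n_used = min(k, len(ordered))
        top = ordered["fc"].iloc[:n_used]
        if n_used < k:
            log.warning("gene %s has %d guide(s); top-%d statistic uses all of them", gene, len(ordered), k)
        rows.append(
            (gene, float(top.median()), float(top.mean()), n_used, len(ordered), n_used < k)
        )
    scores = pd.DataFrame(
        rows,
        columns=["gene_id", "score_median", "score_mean", "k_used", "n_guides", "shortfall"],
    ).set_index("gene_id")
    scores["score"] = scores["score_median"] if aggregator == "median" else scores["score_mean"]
    scores["aggregator"] = aggregator
    scores["day"] = day
    scores["rank"] = rank_by_score(scores)
    return scores.sort_values(["score", "gene_id"], kind="mergesort")


def rank_by_score(scores: pd.DataFrame) -> pd.Series:
    """1-based rank by score ascending (most depleted first), id tie-break."""
    order = scores.iloc[np.lexsort((scores.index.to_numpy(), scores["score"].to_numpy()))]
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return ranks.reindex(scores.index)


def call_hits(scores: pd.DataFrame, threshold: float = -1.0) -> pd.DataFrame:
    """Flag genes whose top-k aggregate is at or below `threshold`.

    The boundary is inclusive: a score of exactly -1.0 is a hit. The
    returned table is sorted most-depleted first.
    """
    out = scores.copy()
    out["hit"] = out["score"] <= threshold
    return out.sort_values(["score", "gene_id"], kind="mergesort")


def qc_replicate_correlation(cpm: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Pairwise Pearson R between samples on log2(CPM + pseudocount).

    Constant samples yield missing values rather than a fabricated 0.
    """
    if cpm.shape[1] < 2:
        raise ValueError("need >= 2 samples for replicate correlation")
    logged = np.log2(cpm + pseudocount)
    r = logged.corr(method="pearson")
    constant = logged.std(axis=0) == 0
    r.loc[constant, :] = np.nan
    r.loc[:, constant] = np.nan
    np.fill_diagonal(r.values, np.where(constant, np.nan, 1.0))
    return r


@dataclass
class ClusterPCAResult:
    zscores: pd.DataFrame  # guides x samples, per-guide mean 0 / sd 1
    linkage: np.ndarray  # scipy linkage of samples
    pca_coordinates: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    n_dropped_guides: int
    metadata: dict = field(default_factory=dict)


def qc_cluster_pca(
    cpm: pd.DataFrame,
    pseudocount: float = 0.5,
    n_components: int = 2,
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> ClusterPCAResult:
    """Z-score guides across samples, cluster and project the samples.

    Zero-variance guide rows carry no signal and are dropped (count
    reported); linkage method and distance are recorded in the result
    metadata so the clustering is reproducible from its output alone.
    """
    if cpm.shape[1] < 3:
        raise ValueError("need >= 3 samples for clustering/PCA")
    logged = np.log2(cpm + pseudocount)
    sd = logged.std(axis=1, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d zero-variance guide row(s) before Z-scoring", n_dropped)
    z = logged[keep].sub(logged[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)

    lk = linkage(z.T.to_numpy(), method=linkage_method, metric=metric)
    n_comp = min(n_components, z.shape[1], z.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(z.T.to_numpy())
    coords = pd.DataFrame(
        coords, index=z.columns, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return ClusterPCAResult(
        zscores=z,
        linkage=lk,
        pca_coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_dropped_guides=n_dropped,
        metadata={"linkage_method": linkage_method, "metric": metric,
                  "scale": f"zscore(log2(CPM+{pseudocount}))"},
    )


@dataclass
class DriftReport:
    skipped: bool
    passed: bool | None
    n_exceeders: int
    frac_exceeders: float
    exceeders: pd.DataFrame
    abs_fc_summary: pd.Series


def control_drift_check(
    fc: pd.DataFrame,
    arm: str = "no_induction",
    bound: float = 1.0,
    max_frac: float = 0.01,
) -> DriftReport:
    """Stochastic-loss check on the control arm.

    Summarises per-guide |log2 fc| in the named arm (vs the screening
    start reference), lists guides whose replicate-mean |fc| exceeds
    `bound`, and passes when exceeders are at most `max_frac` of guides.
    A missing arm is a skipped check with a warning, not an error.
    """
    arms = fc.columns.get_level_values("arm")
    if arm not in set(arms):
        warnings.warn(f"control arm {arm!r} absent; drift check skipped", stacklevel=2)
        return DriftReport(True, None, 0, 0.0, pd.DataFrame(), pd.Series(dtype=float))
    sub = fc.loc[:, arms == arm]
    mean_fc = sub.mean(axis=1)
    abs_fc = mean_fc.abs()
    exceed = abs_fc[abs_fc > bound]
    frac = len(exceed) / len(abs_fc)
    return DriftReport(
        skipped=False,
        passed=bool(frac <= max_frac),
        n_exceeders=int(len(exceed)),
        frac_exceeders=float(frac),
        exceeders=pd.DataFrame({"mean_fc": mean_fc[exceed.index], "abs_fc": exceed}),
        abs_fc_summary=abs_fc.describe(),
    )


def empirical_null(
    scores: pd.DataFrame,
    scrambled_fc: pd.Series,
    k: int = 3,
    guides_per_gene: int = 10,
    aggregator: str = "median",
    n_resample: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Scrambled-resampling empirical p per gene, BH-adjusted.

    Each null draw resamples `guides_per_gene` fold changes with
    replacement from the scrambled-control pool and takes the top-k
    aggregate; p = (1 + #{null <= observed}) / (1 + n_resample).
    """
    if len(scrambled_fc) < k:
        raise ValueError(f"need >= {k} scrambled guides, have {len(scrambled_fc)}")
    if aggregator not in ("median", "mean"):
        raise ValueError("aggregator must be 'median' or 'mean'")
    rng = substream(seed, "empirical-null")
    pool = scrambled_fc.to_numpy()
    draws = rng.choice(pool, size=(n_resample, guides_per_gene), replace=True)
    draws.sort(axis=1)
    topk = draws[:, :k]
    null = np.median(topk, axis=1) if aggregator == "median" else topk.mean(axis=1)
    observed = scores["score"].to_numpy()
    p = (1 + (null[None, :] <= observed[:, None]).sum(axis=1)) / (1 + n_resample)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"score": observed, "p_empirical": p, "q_bh": q}, index=scores.index)


def rank_overlap(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, top_n: int = 50
) -> dict:
    """Overlap of the top-`top_n` most depleted genes of two screens.

    Ranks by aggregate ascending with gene-id tie-break; `top_n` larger
    than the shared universe is capped with a warning.
    """
    universe = scores_a.index.intersection(scores_b.index)
    if len(universe) == 0:
        raise ValueError("screens share no genes")
    if top_n > len(universe):
        warnings.warn(
            f"top_n={top_n} exceeds shared universe of {len(universe)}; capping", stacklevel=2
        )
        top_n = len(universe)

    def top(scores: pd.DataFrame) -> set:
        sub = scores.loc[universe]
        order = sub.iloc[np.lexsort((sub.index.to_numpy(), sub["score"].to_numpy()))]
        return set(order.index[:top_n])

    ta, tb = top(scores_a), top(scores_b)
    inter = ta & tb
    return {
        "top_n": top_n,
        "overlap": len(inter),
        "jaccard": len(inter) / len(ta | tb) if (ta | tb) else 0.0,
        "genes": sorted(inter),
    }
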