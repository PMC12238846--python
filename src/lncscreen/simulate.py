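"""Synthetic inputs with planted ground truth.

Every generator is a pure function of (config, seed): annotation with
promoter sequence, grouped negative-binomial expression with planted
over-expressed lncRNAs, TSS-proximal histone-mark peaks co-occurring with
high expression, and guide-count time courses with planted depletion.

Screen count model: plasmid representation of guide g is log-normal
(a_g); each replicate passes the library through a Poisson(coverage)
cell bottleneck; the cell population carrying guide g then decays as
n_g(t) = n_g(0) * 2**(-s_g * t) for per-day depletion rate s_g (s_g = 0
in the no-induction arm and for all controls); sequencing draws
negative-binomial reads around each guide's CPM share at the configured
depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .rng import substream
from .types import ACTIVE_MARKS, PEAK_COLUMNS, ExpressionMatrix, ScreenCounts, TranscriptAnnotation, Truth

__all__ = [
    "AnnotationBundle",
    "simulate_annotation",
    "simulate_expression",
    "simulate_peaks",
    "plant_guide_effects",
    "simulate_screen",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class AnnotationBundle:
    """Annotation plus the genome it lives on and per-gene promoter slices.

    Promoter sequences are given in transcription orientation; sequence
    index `tss_offset` is the TSS base, so index i is offset
    (i - tss_offset) relative to the TSS.
    """

    annotation: TranscriptAnnotation
    genome: dict[str, str]
    promoters: pd.Series  # gene_id -> sequence (transcription orientation)
    tss_offset: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_annotation(config: SimConfig) -> AnnotationBundle:
    """Generate gene models on a small synthetic genome.

    Genes are laid out at fixed spacing on `n_chroms` chromosomes with
    random strand; exactly round(mono_exonic_fraction * n_genes) genes get
    only single-exon transcripts, every other gene has at least one
    multi-exonic transcript. Promoters are genome slices of length
    promoter_upstream + promoter_downstream centred on the TSS.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1; cannot build an empty annotation")
    rng = substream(config.seed, "annotation")

    n = config.n_genes
    per_chrom = int(np.ceil(n / config.n_chroms))
    margin = config.promoter_length + 200
    chrom_len = per_chrom * config.gene_spacing + 2 * margin

    n_mono = int(round(config.mono_exonic_fraction * n))
    mono_idx = set(rng.choice(n, size=n_mono, replace=False).tolist())

    genome: dict[str, str] = {}
    gene_rows, tx_rows, exon_rows = [], [], []
    for c in range(config.n_chroms):
        genome[f"chr{c + 1}"] = _random_sequence(rng, chrom_len)

    for i in range(n):
        chrom = f"chr{i // per_chrom + 1}"
        local = i % per_chrom
        gstart = margin + local * config.gene_spacing
        glen = int(rng.integers(500, 1500))
        gend = gstart + glen
        strand = "+" if rng.random() < 0.5 else "-"
        tss = gstart if strand == "+" else gend - 1
        gid = f"LNC{i + 1:04d}"
        gene_rows.append((gid, chrom, strand, gstart, gend, tss))

        n_tx = 1 + int(rng.integers(0, 2))
        for t in range(n_tx):
            tid = f"{gid}.t{t + 1}"
            if t == 0:
                ts, te = gstart, gend
            else:
                # shorter isoform sharing the gene 3' end (keeps the 5'-most
                # start, hence the gene TSS, on transcript 1)
                trim = int(rng.integers(50, max(51, glen // 3)))
                ts, te = (gstart + trim, gend) if strand == "+" else (gstart, gend - trim)
            tx_rows.append((tid, gid, chrom, strand, ts, te))
            if i in mono_idx:
                exon_bounds = [(ts, te)]
            else:
                n_ex = int(rng.integers(2, 5)) if t == 0 else int(rng.integers(1, 3))
                exon_bounds = _split_exons(rng, ts, te, n_ex)
            for es, ee in exon_bounds:
                exon_rows.append((tid, gid, chrom, es, ee))

    annotation = TranscriptAnnotation(
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss"]),
        transcripts=pd.DataFrame(tx_rows, columns=["transcript_id", "gene_id", "chrom", "strand", "start", "end"]),
        exons=pd.DataFrame(exon_rows, columns=["transcript_id", "gene_id", "chrom", "start", "end"]),
    )

    promoters = {}
    up, down = config.promoter_upstream, config.promoter_downstream
    for gid, chrom, strand, tss in annotation.genes[["gene_id", "chrom", "strand", "tss"]].itertuples(index=False):
        seq = genome[chrom]
        if strand == "+":
            promoters[gid] = seq[tss - up: tss + down]
        else:
            promoters[gid] = reverse_complement(seq[tss - down + 1: tss + up + 1])
    return AnnotationBundle(
        annotation=annotation,
        genome=genome,
        promoters=pd.Series(promoters, name="promoter"),
        tss_offset=up,
    )


def _split_exons(rng: np.random.Generator, start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
    """Partition [start, end) into n_exons exons separated by introns."""
    length = end - start
    if n_exons == 1 or length < 40 * n_exons:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(20, length - 20), size=2 * (n_exons - 1), replace=False))
    bounds = [start] + (start + cuts).tolist() + [end]
    return [(bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with var = mean + dispersion * mean**2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        r = 1.0 / dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_expression(
    config: SimConfig, annotation: TranscriptAnnotation
) -> tuple[ExpressionMatrix, Truth]:
    """Grouped NB expression with `n_lnc_true` planted over-expressed genes.

    Planted genes have group-mean ratio 2**expr_logfc in every tumor group
    relative to the baseline group(s); all other genes share one mean
    across groups. Planted genes are drawn from multi-exonic genes only —
    the planted truth is meant to be recoverable, and mono-exonic-only
    genes are excluded downstream as putative enhancer RNAs.
    """
    if len(config.groups) < 2:
        raise ValueError("need at least 2 groups for differential expression")
    for name, n_samples in config.groups:
        if n_samples < 2:
            raise ValueError(f"group {name!r} has {n_samples} sample(s); replicates required")
    rng = substream(config.seed, "expression")

    gene_ids = annotation.genes["gene_id"].to_numpy()
    n = len(gene_ids)
    base_mean = config.expr_base_mean * rng.lognormal(0.0, config.expr_mean_sigma, size=n)

    # planted truth lives in recoverable genes: multi-exonic (mono-exonic
    # genes are excluded downstream as putative enhancer RNAs) and well
    # expressed (CRISPRi candidates are, by construction, not low-CPM genes)
    n_exons = annotation.exons.groupby(["gene_id", "transcript_id"]).size()
    multi = n_exons.groupby("gene_id").max() >= 2
    floor = config.planted_min_mean_factor * config.expr_base_mean
    eligible = np.array([
        g for g, m in zip(gene_ids, base_mean)
        if multi.get(g, False) and m >= floor
    ])
    if len(eligible) < config.n_lnc_true:
        fallback = np.array([g for g in gene_ids if multi.get(g, False)])
        eligible = fallback if len(fallback) else gene_ids
    n_true = min(config.n_lnc_true, len(eligible))
    planted = set(rng.choice(eligible, size=n_true, replace=False).tolist())

    fold = np.where(np.isin(gene_ids, list(planted)), 2.0 ** config.expr_logfc, 1.0)

    cols, data = [], []
    for group, n_samples in config.groups:
        mean = base_mean * (fold if group in config.tumor_groups else 1.0)
        for s in range(n_samples):
            cols.append(f"{group}_s{s + 1}")
            data.append(_nb_draw(rng, mean, config.expr_dispersion))
    counts = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    sample_groups = pd.Series(
        {f"{g}_s{s + 1}": g for g, ns in config.groups for s in range(ns)}, name="group"
    )
    matrix = ExpressionMatrix(counts=counts, sample_groups=sample_groups)
    return matrix, Truth(true_candidates=planted)


def simulate_peaks(
    annotation: TranscriptAnnotation, truth: Truth, config: SimConfig
) -> pd.DataFrame:
    """Histone-mark peaks (H3K4me3 / H3K27ac) around gene TSSs.

    Each planted gene receives, with probability peak_at_true_tss_prob, a
    TSS-spanning peak in every tumor cell type; non-planted genes receive
    background peaks at rate background_peak_prob in a random cell type.
    """
    if len(annotation.genes) == 0:
        raise ValueError("annotation is empty")
    rng = substream(config.seed, "peaks")
    celltypes = [g for g, _ in config.groups]
    rows = []
    for gid, chrom, tss in annotation.genes[["gene_id", "chrom", "tss"]].itertuples(index=False):
        if gid in truth.true_candidates:
            if rng.random() < config.peak_at_true_tss_prob:
                for ct in config.tumor_groups:
                    start = tss - int(rng.integers(100, 400))
                    end = tss + int(rng.integers(100, 400))
                    rows.append((chrom, start, end, rng.choice(ACTIVE_MARKS), ct))
        elif rng.random() < config.background_peak_prob:
            start = tss - int(rng.integers(100, 400))
            end = tss + int(rng.integers(100, 400))
            rows.append((chrom, start, end, rng.choice(ACTIVE_MARKS), rng.choice(celltypes)))
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    if len(peaks):
        peaks["start"] = peaks["start"].clip(lower=0).astype(int)
    return peaks


def plant_guide_effects(library, truth: Truth, config: SimConfig) -> Truth:
    """Assign per-day depletion rates to guides of planted genes.

    round(frac_active_guides * n) of each planted gene's guides become
    active with s_g drawn from a Gamma with mean effect_mean and CV
    effect_cv; all other guides (including every scrambled control) keep
    s_g = 0.
    """
    rng = substream(config.seed, "effects")
    effects: dict[str, float] = {}
    mask: dict[str, list[str]] = {}
    targeting = library.table[library.table["guide_class"] != "scrambled"]
    for gene in sorted(truth.true_candidates):
        guides = sorted(targeting.loc[targeting["gene_id"] == gene, "guide_id"])
        if not guides:
            continue
        n_active = int(round(config.frac_active_guides * len(guides)))
        active = sorted(rng.choice(guides, size=n_active, replace=False).tolist())
        if config.effect_cv > 0:
            shape = 1.0 / config.effect_cv ** 2
            s = rng.gamma(shape, config.effect_mean / shape, size=n_active)
        else:
            s = np.full(n_active, config.effect_mean)
        for g, sg in zip(active, s):
            effects[g] = float(sg)
        mask[gene] = active
    return Truth(true_candidates=set(truth.true_candidates), guide_effects=effects, active_guide_mask=mask)


def simulate_screen(library, truth: Truth, config: SimConfig) -> ScreenCounts:
    """Guide-count time course for the drop-off screen.

    Emits one column per (arm, day, replicate) plus the plasmid library;
    the day-0 sample of each replicate is flagged as the screening-start
    reference. The no-induction arm (all s_g = 0) is sampled at the end
    time point only.
    """
    if len(library.table) == 0:
        raise ValueError("guide library is empty")
    if config.depth <= 0:
        raise ValueError(f"depth must be > 0, got {config.depth}")
    if 0 not in config.timepoints_days:
        raise ValueError("timepoints must include day 0 (screening start)")
    rng = substream(config.seed, "screen")

    guide_ids = library.table["guide_id"].to_numpy()
    n_guides = len(guide_ids)
    s = np.array([truth.effect_for(g) for g in guide_ids])
    total_reads = config.depth * n_guides

    a = rng.lognormal(0.0, config.plasmid_sigma, size=n_guides)
    rel = a / a.mean()

    cols: dict[str, np.ndarray] = {}
    sheet_rows = []
    cols["plasmid"] = _nb_draw(rng, config.depth * rel, config.nb_dispersion)
    sheet_rows.append(("plasmid", "plasmid", pd.NA, pd.NA, False))

    end_day = max(config.timepoints_days)
    for rep in range(1, config.replicates + 1):
        n0 = rng.poisson(config.coverage * rel).astype(float)
        if n0.sum() == 0:
            raise ValueError("bottleneck lost the entire library; increase coverage")
        for day in sorted(config.timepoints_days):
            expect = n0 * np.exp2(-s * day)
            share = expect / expect.sum()
            name = f"induced_d{day}_r{rep}"
            cols[name] = _nb_draw(rng, total_reads * share, config.nb_dispersion)
            sheet_rows.append((name, "induced", day, rep, day == 0))
        if config.include_no_induction_arm:
            share = n0 / n0.sum()
            name = f"no_induction_d{end_day}_r{rep}"
            cols[name] = _nb_draw(rng, total_reads * share, config.nb_dispersion)
            sheet_rows.append((name, "no_induction", end_day, rep, False))

    counts = pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id"))
    samples = pd.DataFrame(sheet_rows, columns=["sample", "arm", "day", "replicate", "is_reference"])
    return ScreenCounts(
        counts=counts,
        samples=samples,
        guide_class=library.table.set_index("guide_id")["guide_class"],
    )
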