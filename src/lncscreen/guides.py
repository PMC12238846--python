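"""Focused CRISPRi sgRNA library design.

Guides are 20-nt protospacers adjacent to an NGG PAM whose cut site (the
blunt cut between protospacer positions 17 and 18, i.e. 3 bp 5' of the
PAM) falls in a window around the TSS, by default [-300, +50] in
transcription orientation. Specificity is scored with a transparent
multiplicative mismatch-weight aggregate over enumerated off-target
sites:

    score = 100 * prod_over_offtarget_sites (1 - s_h),
    s_h   = prod_over_mismatched_positions (1 - w_p)

with the per-position weight vector w (config.MISMATCH_WEIGHTS, the Hsu
2013 SpCas9 vector) and sites enumerated up to a mismatch cap. A second
perfect-match site therefore zeroes the score; a guide with no off-target
sites scores 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MISMATCH_WEIGHTS
from .rng import substream
from .simulate import AnnotationBundle, reverse_complement
from .types import GuideLibrary, TranscriptAnnotation

__all__ = [
    "enumerate_guides",
    "ReferenceIndex",
    "score_offtargets",
    "select_library",
    "generate_scrambled_controls",
    "design_library",
    "GUIDE_WINDOW",
]

#: Cut-site window relative to the TSS, transcription orientation.
GUIDE_WINDOW = (-300, 50)

PROTOSPACER_LEN = 20
#: 0-based index of the cut boundary within the protospacer: the cut falls
#: between positions 17 and 18 (1-based), i.e. before index 17.
CUT_INDEX = 17


def enumerate_guides(
    promoter_sequence: str,
    tss_offset: int,
    window: tuple[int, int] = GUIDE_WINDOW,
    gene_id: str = "gene",
) -> pd.DataFrame:
    """All NGG-adjacent 20-mers on either strand whose cut site lies in
    `window` relative to the TSS.

    `tss_offset` is the index of the TSS base within the promoter
    sequence (which is given in transcription orientation). Returned
    cut_offset is the cut boundary relative to the TSS; sense guides read
    the promoter strand, antisense guides its reverse complement.
    """
    lo, hi = window
    seq = promoter_sequence.upper()
    if tss_offset + lo < 0 or tss_offset + hi > len(seq):
        raise ValueError(
            f"promoter sequence (length {len(seq)}, TSS at {tss_offset}) does not cover "
            f"window [{lo}, {hi}] around the TSS"
        )
    rows = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        L = len(s)
        for p in range(0, L - PROTOSPACER_LEN - 2):
            if not (s[p + PROTOSPACER_LEN + 1] == "G" and s[p + PROTOSPACER_LEN + 2] == "G"):
                continue
            cut_in_s = p + CUT_INDEX
            cut_fwd = cut_in_s if strand == "+" else L - cut_in_s
            offset = cut_fwd - tss_offset
            if not (lo <= offset <= hi):
                continue
            proto = s[p: p + PROTOSPACER_LEN]
            pam = s[p + PROTOSPACER_LEN: p + PROTOSPACER_LEN + 3]
            rows.append(
                (f"{gene_id}.sg{offset:+04d}{strand}", gene_id, proto, pam, strand, offset, p, L)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "guide_id", "gene_id", "protospacer", "pam",
            "promoter_strand", "cut_offset", "scan_pos", "promoter_len",
        ],
    )
    return out.sort_values("guide_id", kind="mergesort", ignore_index=True)


_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_ENC[ord("N")] = 255


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


class ReferenceIndex:
    """Sliding-window view over a genome for brute-force site search.

    Holds, per chromosome and strand, the encoded sequence plus a
    boolean mask of positions whose downstream 3-mer matches NGG; guide
    queries compare the 20-mer windows at masked (or all) positions.
    """

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self._strands: list[tuple[str, str, np.ndarray, np.ndarray, np.ndarray]] = []
        win = PROTOSPACER_LEN
        for chrom, seq in genome.items():
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                enc = _encode(s)
                if len(enc) < win + 3:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(enc, win)[: len(enc) - win - 2]
                g = enc == _ENC[ord("G")]
                # window at i has PAM at i+20..i+22; require G at i+21 and i+22
                pam_ok = g[win + 1: -1] & g[win + 2:]
                self._strands.append((chrom, strand, enc, windows, pam_ok))

    def find_sites(
        self,
        protospacer: str,
        max_mismatches: int = 3,
        require_pam: bool = True,
    ) -> list[dict]:
        """Sites with <= max_mismatches to the protospacer.

        Returns dicts with chrom, strand, pos (0-based protospacer start
        on the forward strand's coordinate system for '+', on the
        reverse-complement coordinate system mapped back for '-'),
        n_mismatches, and mismatch position indices (0-based, 5'->3').
        """
        q = _encode(protospacer)
        if len(q) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        sites = []
        for chrom, strand, enc, windows, pam_ok in self._strands:
            cand = np.flatnonzero(pam_ok) if require_pam else np.arange(len(windows))
            if len(cand) == 0:
                continue
            mm = np.count_nonzero(windows[cand] != q, axis=1)
            hits = cand[mm <= max_mismatches]
            L = len(enc)
            for pos in hits:
                mism = np.flatnonzero(windows[pos] != q)
                fwd_pos = int(pos) if strand == "+" else L - int(pos) - PROTOSPACER_LEN
                sites.append(
                    {
                        "chrom": chrom,
                        "strand": strand,
                        "pos": fwd_pos,
                        "n_mismatches": int(len(mism)),
                        "mismatch_positions": mism.tolist(),
                    }
                )
        return sites

    def min_mismatches(self, seq: str, require_pam: bool = False) -> int:
        """Smallest mismatch count of `seq` against any genomic window."""
        q = _encode(seq)
        best = PROTOSPACER_LEN
        for _, _, _, windows, pam_ok in self._strands:
            sub = windows[pam_ok] if require_pam else windows
            if len(sub) == 0:
                continue
            mm = np.count_nonzero(sub != q, axis=1)
            best = min(best, int(mm.min()))
        return best


def score_offtargets(
    protospacer: str,
    index: ReferenceIndex,
    on_target: tuple[str, str, int] | None = None,
    max_mismatches: int = 3,
    weights: tuple[float, ...] = MISMATCH_WEIGHTS,
    sites: list[dict] | None = None,
) -> float:
    """Specificity score in [0, 100]; 100 means no off-target site.

    `on_target` = (chrom, strand, pos) removes the guide's own site from
    the product. If the guide has no perfect-match site at all, a warning
    is emitted and the score runs over every enumerated site.
    Pre-enumerated `sites` may be supplied to skip the genome scan.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != PROTOSPACER_LEN:
        raise ValueError("weight vector must have 20 entries")
    if sites is None:
        sites = index.find_sites(protospacer, max_mismatches=max_mismatches)
    perfect = [s for s in sites if s["n_mismatches"] == 0]
    if on_target is not None:
        chrom, strand, pos = on_target
        sites = [
            s for s in sites
            if not (s["chrom"] == chrom and s["strand"] == strand and s["pos"] == pos)
        ]
    elif perfect:
        # with no stated on-target, the first perfect site is taken as it
        sites = [s for s in sites if s is not perfect[0]]
    if not perfect:
        warnings.warn(
            f"guide {protospacer} has no perfect-match site in the reference; "
            "scoring over all enumerated sites",
            stacklevel=2,
        )
    score = 100.0
    for s in sites:
        s_h = float(np.prod(1.0 - w[s["mismatch_positions"]]))
        score *= 1.0 - s_h
    return float(score)


def _score_guides_bulk(
    guides: pd.DataFrame, index: ReferenceIndex, max_mismatches: int, weights
) -> pd.Series:
    """Score a located guide table, excluding each guide's own site."""
    scores = {}
    for row in guides.itertuples(index=False):
        on_target = (
            (row.chrom, row.strand, int(row.genomic_start))
            if pd.notna(row.genomic_start)
            else None
        )
        scores[row.guide_id] = score_offtargets(
            row.protospacer, index, on_target=on_target,
            max_mismatches=max_mismatches, weights=weights,
        )
    return pd.Series(scores, name="offtarget_score")


def locate_guides(
    guides: pd.DataFrame, annotation: TranscriptAnnotation, tss_offset: int
) -> pd.DataFrame:
    """Attach genomic coordinates to promoter-relative guides.

    A sense (promoter '+') guide reads the gene strand; an antisense
    guide the opposite strand. `genomic_start` is the leftmost (forward
    strand) coordinate of the protospacer; `cut_site` is tss +
    cut_offset for '+' genes and tss - cut_offset for '-' genes.
    """
    gene_info = annotation.genes.set_index("gene_id")
    chrom = guides["gene_id"].map(gene_info["chrom"])
    gstrand = guides["gene_id"].map(gene_info["strand"]).to_numpy()
    tss = guides["gene_id"].map(gene_info["tss"]).to_numpy()
    pstrand = guides["promoter_strand"].to_numpy()
    p = guides["scan_pos"].to_numpy()
    plen = guides["promoter_len"].to_numpy()
    up = tss_offset
    down = plen - up

    flip = np.vectorize({"+": "-", "-": "+"}.get)
    strand = np.where(pstrand == "+", gstrand, flip(gstrand))
    # promoter index -> genome mapping differs by gene strand; the four
    # (gene strand x scan strand) cases each give the leftmost coordinate
    start = np.select(
        [
            (gstrand == "+") & (pstrand == "+"),
            (gstrand == "+") & (pstrand == "-"),
            (gstrand == "-") & (pstrand == "+"),
            (gstrand == "-") & (pstrand == "-"),
        ],
        [
            tss - up + p,
            tss - up + plen - PROTOSPACER_LEN - p,
            tss + up - p - (PROTOSPACER_LEN - 1),
            tss - down + 1 + p,
        ],
    )
    cut = np.where(gstrand == "+", tss + guides["cut_offset"], tss - guides["cut_offset"])
    return guides.assign(
        chrom=chrom, strand=strand, genomic_start=start.astype(int), cut_site=cut.astype(int)
    )


def select_library(
    scored_guides: pd.DataFrame,
    guides_per_gene: int = 10,
    min_score: float = 70.0,
    positive_controls: set[str] | None = None,
) -> GuideLibrary:
    """Keep score >= min_score, take the top `guides_per_gene` per gene by
    (score desc, |cut offset| asc, id asc).

    Genes with fewer passing guides are kept with a shortfall record;
    genes with none land in the exclusions report rather than vanishing.
    """
    positive_controls = positive_controls or set()
    passing = scored_guides[scored_guides["offtarget_score"] >= min_score].copy()
    passing["_dist"] = passing["cut_offset"].abs()
    passing = passing.sort_values(
        ["gene_id", "offtarget_score", "_dist", "guide_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    selected = (
        passing.groupby("gene_id", sort=True)
        .head(guides_per_gene)
        .drop(columns=["_dist", "scan_pos", "promoter_len"], errors="ignore")
    )

    counts = selected.groupby("gene_id").size()
    all_genes = scored_guides["gene_id"].unique()
    shortfall_rows, exclusion_rows = [], []
    for gene in sorted(all_genes):
        n = int(counts.get(gene, 0))
        if n == 0:
            exclusion_rows.append((gene, "no guide passed the off-target score threshold"))
        elif n < guides_per_gene:
            shortfall_rows.append((gene, n, guides_per_gene))
            warnings.warn(
                f"gene {gene}: only {n}/{guides_per_gene} guides pass the score threshold",
                stacklevel=2,
            )
    selected = selected.assign(
        guide_class=np.where(
            selected["gene_id"].isin(list(positive_controls)), "positive_control", "targeting"
        )
    ).reset_index(drop=True)
    return GuideLibrary(
        table=selected,
        exclusions=pd.DataFrame(exclusion_rows, columns=["gene_id", "reason"]),
        shortfalls=pd.DataFrame(shortfall_rows, columns=["gene_id", "n_selected", "n_requested"]),
    )


def generate_scrambled_controls(
    index: ReferenceIndex,
    n: int = 50,
    seed: int = 0,
    gc_range: tuple[float, float] = (0.40, 0.60),
    max_homopolymer: int = 4,
    max_mismatches_excluded: int = 2,
    max_attempts_per_guide: int = 2_000,
) -> pd.DataFrame:
    """Random 20-mers with no genomic site within <= 2 mismatches.

    Constraints: GC fraction in gc_range, no homopolymer longer than
    max_homopolymer, and a brute-force scan of the reference finds no
    window within max_mismatches_excluded mismatches.
    """
    rng = substream(seed, "scrambled")
    bases = np.array(list("ACGT"))
    out, attempts = [], 0
    budget = n * max_attempts_per_guide
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not generate {n} scrambled controls after {attempts} attempts"
            )
        attempts += 1
        seq = "".join(rng.choice(bases, size=PROTOSPACER_LEN))
        gc = (seq.count("G") + seq.count("C")) / PROTOSPACER_LEN
        if not (gc_range[0] <= gc <= gc_range[1]):
            continue
        if _max_homopolymer(seq) > max_homopolymer:
            continue
        if index.min_mismatches(seq) <= max_mismatches_excluded:
            continue
        out.append(seq)
    return pd.DataFrame(
        {
            "guide_id": [f"scrambled_{i + 1:03d}" for i in range(n)],
            "gene_id": "scrambled",
            "protospacer": out,
            "pam": pd.NA,
            "promoter_strand": pd.NA,
            "cut_offset": np.nan,
            "chrom": pd.NA,
            "strand": pd.NA,
            "genomic_start": np.nan,
            "cut_site": np.nan,
            "offtarget_score": 100.0,
            "guide_class": "scrambled",
        }
    )


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def design_library(
    bundle: AnnotationBundle,
    target_genes: list[str],
    guides_per_gene: int = 10,
    min_score: float = 70.0,
    n_scrambled: int = 50,
    window: tuple[int, int] = GUIDE_WINDOW,
    max_mismatches: int = 3,
    positive_controls: set[str] | None = None,
    seed: int = 0,
    weights: tuple[float, ...] = MISMATCH_WEIGHTS,
) -> GuideLibrary:
    """End-to-end design: enumerate, locate, score, select, add controls."""
    index = ReferenceIndex(bundle.genome)
    frames = []
    for gene in target_genes:
        if gene not in bundle.promoters.index:
            raise KeyError(f"no promoter sequence for gene {gene!r}")
        frames.append(
            enumerate_guides(bundle.promoters[gene], bundle.tss_offset, window=window, gene_id=gene)
        )
    guides = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[
            "guide_id", "gene_id", "protospacer", "pam",
            "promoter_strand", "cut_offset", "scan_pos", "promoter_len",
        ]
    )
    guides = locate_guides(guides, bundle.annotation, bundle.tss_offset)
    guides["offtarget_score"] = guides["guide_id"].map(
        _score_guides_bulk(guides, index, max_mismatches, weights)
    )
    library = select_library(
        guides, guides_per_gene=guides_per_gene, min_score=min_score,
        positive_controls=positive_controls,
    )
    scrambled = generate_scrambled_controls(index, n=n_scrambled, seed=seed)
    table = pd.concat([library.table, scrambled], ignore_index=True)
    return GuideLibrary(table=table, exclusions=library.exclusions, shortfalls=library.shortfalls)
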