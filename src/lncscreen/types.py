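"""Core in-memory containers shared across pipeline stages.

Coordinates are 0-based half-open throughout; GTF (1-based closed) is
converted at the I/O boundary. The TSS of a gene is the 0-based coordinate
of its first transcribed base (5'-most transcript start on the gene's
strand: `start` for '+' genes, `end - 1` for '-' genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptAnnotation",
    "ExpressionMatrix",
    "Truth",
    "GuideLibrary",
    "ScreenCounts",
    "PEAK_COLUMNS",
    "validate_peaks",
]

#: Column layout of a peak table (BED6-like plus mark and cell type).
PEAK_COLUMNS = ["chrom", "start", "end", "mark", "celltype"]

ACTIVE_MARKS = ("H3K4me3", "H3K27ac")


def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Check a peak table for required columns and valid intervals."""
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    bad = peaks[peaks["start"] >= peaks["end"]]
    if len(bad):
        raise ValueError(f"{len(bad)} peak intervals have start >= end")
    return peaks


@dataclass
class TranscriptAnnotation:
    """Gene/transcript/exon structure, 0-based half-open.

    genes: one row per gene — gene_id, chrom, strand, start, end, tss
    transcripts: transcript_id, gene_id, chrom, strand, start, end
    exons: transcript_id, gene_id, chrom, start, end
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            dups = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))}")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def n_exons_per_transcript(self) -> pd.Series:
        return self.exons.groupby("transcript_id").size()

    def tss(self) -> pd.Series:
        """Per-gene TSS coordinate, indexed by gene_id."""
        return self.genes.set_index("gene_id")["tss"]


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with a sample -> group assignment."""

    counts: pd.DataFrame  # index gene_id, columns sample ids
    sample_groups: pd.Series  # index sample id -> group label

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        unassigned = self.counts.columns.difference(self.sample_groups.index)
        if len(unassigned):
            raise ValueError(f"samples without a group: {list(unassigned)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def samples_in_group(self, group: str) -> list[str]:
        hits = self.sample_groups[self.sample_groups == group].index
        cols = [s for s in self.counts.columns if s in set(hits)]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return cols

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_groups))


@dataclass
class Truth:
    """Planted ground truth carried alongside synthetic data.

    guide_effects maps guide id -> per-day log2 depletion rate s_g >= 0
    (abundance of the guide's cell population decays as 2**(-s_g * day)).
    Scrambled controls and guides of non-planted genes have s_g = 0.
    """

    true_candidates: set[str] = field(default_factory=set)
    guide_effects: dict[str, float] = field(default_factory=dict)
    active_guide_mask: dict[str, list[str]] = field(default_factory=dict)

    def effect_for(self, guide_id: str) -> float:
        return self.guide_effects.get(guide_id, 0.0)


@dataclass
class GuideLibrary:
    """Designed sgRNA library.

    table columns: guide_id, gene_id, guide_class (targeting | scrambled |
    positive_control), protospacer, pam, chrom, strand, cut_site (genomic,
    0-based boundary; NaN for scrambled), tss_offset, offtarget_score.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "reason"])
    )
    shortfalls: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "n_selected", "n_requested"])
    )

    def __post_init__(self) -> None:
        if self.table["guide_id"].duplicated().any():
            raise ValueError("duplicate guide ids in library")

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    def guides_of_class(self, guide_class: str) -> pd.DataFrame:
        return self.table[self.table["guide_class"] == guide_class]

    def composition(self) -> dict[str, int]:
        """Per-class guide counts plus the total; reported, never asserted."""
        out = self.table["guide_class"].value_counts().to_dict()
        out["total"] = int(len(self.table))
        return out

    def gene_of_guide(self) -> pd.Series:
        return self.table.set_index("guide_id")["gene_id"]


@dataclass
class ScreenCounts:
    """Guide x sample raw screen counts plus a sample-role sheet.

    samples: sample, arm (induced | no_induction | plasmid), day,
    replicate, is_reference. Exactly one reference (screening start)
    sample per cell replicate; the plasmid column has no reference.
    """

    counts: pd.DataFrame  # index guide_id, columns sample names
    samples: pd.DataFrame
    guide_class: pd.Series | None = None  # guide_id -> class

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative screen counts")
        missing = set(self.counts.columns) - set(self.samples["sample"])
        if missing:
            raise ValueError(f"count columns absent from sample sheet: {sorted(missing)}")
        refs = self.samples[self.samples["is_reference"]]
        cell_reps = self.samples.loc[self.samples["arm"] != "plasmid", "replicate"].unique()
        for rep in cell_reps:
            n = int((refs["replicate"] == rep).sum())
            if n != 1:
                raise ValueError(
                    f"replicate {rep!r} has {n} reference samples; exactly one required"
                )

    def reference_sample(self, replicate) -> str:
        refs = self.samples[self.samples["is_reference"] & (self.samples["replicate"] == replicate)]
        return str(refs["sample"].iloc[0])

    def samples_where(self, **conditions) -> pd.DataFrame:
        sel = pd.Series(True, index=self.samples.index)
        for key, val in conditions.items():
            sel &= self.samples[key] == val
        return self.samples[sel]
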