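"""Readers and writers for the pipeline's interchange formats.

TSV with a header row is the matrix format; sample metadata travels in a
separate sample sheet (the encoded `<arm>_d<day>_r<rep>` column-name
dialect of the simulator is accepted when no sheet is given). GTF is
read through pyranges (1-based closed on disk, converted to the internal
0-based half-open convention at this boundary), BED through pyranges,
FASTA through Biopython.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import PEAK_COLUMNS, ExpressionMatrix, GuideLibrary, ScreenCounts, TranscriptAnnotation, Truth

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_sample_sheet", "write_sample_sheet",
    "read_expression", "read_screen_counts",
    "read_gtf", "write_gtf",
    "read_bed", "write_bed",
    "read_fasta", "write_fasta",
    "read_library", "write_library",
    "read_truth", "write_truth",
]


def read_counts_tsv(path: str | Path, id_column: str | None = None) -> pd.DataFrame:
    """Integer count matrix with a header row; duplicate ids rejected."""
    df = pd.read_csv(path, sep="\t")
    id_column = id_column or df.columns[0]
    if df[id_column].duplicated().any():
        dup = df.loc[df[id_column].duplicated(), id_column].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in {path}")
    df = df.set_index(id_column)
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"non-numeric counts in column {col!r} of {path}")
        if (vals < 0).any():
            row = vals.index[vals < 0][0]
            raise ValueError(f"negative count at row {row!r}, column {col!r} of {path}")
        if not np.allclose(vals, np.round(vals)):
            row = vals.index[~np.isclose(vals, np.round(vals))][0]
            raise ValueError(f"non-integer count at row {row!r}, column {col!r} of {path}")
    return df.astype(np.int64)


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    if "sample" not in sheet.columns:
        raise ValueError(f"sample sheet {path} lacks a 'sample' column")
    if "is_reference" in sheet.columns:
        sheet["is_reference"] = sheet["is_reference"].astype(bool)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_expression(counts_path: str | Path, sheet_path: str | Path) -> ExpressionMatrix:
    counts = read_counts_tsv(counts_path)
    sheet = read_sample_sheet(sheet_path)
    if "group" not in sheet.columns:
        raise ValueError("expression sample sheet needs a 'group' column")
    return ExpressionMatrix(counts=counts, sample_groups=sheet.set_index("sample")["group"])


_ENCODED_SAMPLE = re.compile(r"^(?P<arm>[a-z_]+)_d(?P<day>\d+)_r(?P<rep>\d+)$")


def _sheet_from_encoded_names(columns) -> pd.DataFrame:
    """Recover a sample sheet from `<arm>_d<day>_r<rep>` column names."""
    rows = []
    for col in columns:
        if col == "plasmid":
            rows.append((col, "plasmid", pd.NA, pd.NA, False))
            continue
        m = _ENCODED_SAMPLE.match(col)
        if not m:
            raise ValueError(f"cannot parse sample name {col!r}; provide a sample sheet")
        day, rep = int(m["day"]), int(m["rep"])
        rows.append((col, m["arm"], day, rep, m["arm"] == "induced" and day == 0))
    return pd.DataFrame(rows, columns=["sample", "arm", "day", "replicate", "is_reference"])


def read_screen_counts(
    counts_path: str | Path,
    sheet_path: str | Path | None = None,
    library: GuideLibrary | None = None,
) -> ScreenCounts:
    counts = read_counts_tsv(counts_path)
    sheet = read_sample_sheet(sheet_path) if sheet_path else _sheet_from_encoded_names(counts.columns)
    guide_class = library.table.set_index("guide_id")["guide_class"] if library else None
    return ScreenCounts(counts=counts, samples=sheet, guide_class=guide_class)


def write_gtf(annotation: TranscriptAnnotation, path: str | Path) -> None:
    """Serialize to GTF: internal 0-based half-open -> 1-based closed."""
    frames = []
    g = annotation.genes
    frames.append(pd.DataFrame({
        "Chromosome": g["chrom"], "Feature": "gene", "Start": g["start"], "End": g["end"],
        "Strand": g["strand"], "gene_id": g["gene_id"], "transcript_id": np.nan,
    }))
    t = annotation.transcripts
    frames.append(pd.DataFrame({
        "Chromosome": t["chrom"], "Feature": "transcript", "Start": t["start"], "End": t["end"],
        "Strand": t["strand"], "gene_id": t["gene_id"], "transcript_id": t["transcript_id"],
    }))
    e = annotation.exons.merge(
        annotation.transcripts[["transcript_id", "strand"]], on="transcript_id"
    )
    frames.append(pd.DataFrame({
        "Chromosome": e["chrom"], "Feature": "exon", "Start": e["start"], "End": e["end"],
        "Strand": e["strand"], "gene_id": e["gene_id"], "transcript_id": e["transcript_id"],
    }))
    df = pd.concat(frames, ignore_index=True)
    df["Source"] = "lncscreen"
    pr.PyRanges(df).to_gtf(str(path))


def read_gtf(path: str | Path) -> TranscriptAnnotation:
    """Parse GTF into the internal annotation (0-based half-open).

    The gene TSS is recomputed as the 5'-most transcript start on the
    gene strand, so annotations lacking explicit gene rows still work.
    """
    df = pr.read_gtf(str(path)).df
    if df.empty:
        raise ValueError(f"no features parsed from {path}")
    tx = df[df["Feature"] == "transcript"]
    transcripts = pd.DataFrame({
        "transcript_id": tx["transcript_id"], "gene_id": tx["gene_id"],
        "chrom": tx["Chromosome"].astype(str), "strand": tx["Strand"].astype(str),
        "start": tx["Start"].astype(int), "end": tx["End"].astype(int),
    }).reset_index(drop=True)
    ex = df[df["Feature"] == "exon"]
    exons = pd.DataFrame({
        "transcript_id": ex["transcript_id"], "gene_id": ex["gene_id"],
        "chrom": ex["Chromosome"].astype(str),
        "start": ex["Start"].astype(int), "end": ex["End"].astype(int),
    }).reset_index(drop=True)

    agg = transcripts.groupby("gene_id").agg(
        chrom=("chrom", "first"), strand=("strand", "first"),
        start=("start", "min"), end=("end", "max"),
    )
    genes = agg.reset_index()
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return TranscriptAnnotation(genes=genes, transcripts=transcripts, exons=exons)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED6 / broadPeak-style intervals into a peak table.

    The BED name field is interpreted as `<mark>:<celltype>` when it
    contains a colon, else as the mark with unknown cell type.
    """
    df = pr.read_bed(str(path)).df
    name = df.get("Name", pd.Series(["."] * len(df)))
    marks, cells = [], []
    for n in name.astype(str):
        mark, _, cell = n.partition(":")
        marks.append(mark)
        cells.append(cell or "unknown")
    return pd.DataFrame({
        "chrom": df["Chromosome"].astype(str), "start": df["Start"].astype(int),
        "end": df["End"].astype(int), "mark": marks, "celltype": cells,
    })


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "chrom": peaks["chrom"], "start": peaks["start"], "end": peaks["end"],
        "name": peaks["mark"].astype(str) + ":" + peaks["celltype"].astype(str),
        "score": 0, "strand": ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str] | pd.Series, path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences.items()
    records = [SeqRecord(Seq(seq), id=str(name), description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


_LIBRARY_COLUMNS = [
    "guide_id", "gene_id", "guide_class", "protospacer", "pam",
    "chrom", "strand", "cut_site", "cut_offset", "offtarget_score",
]


def write_library(library: GuideLibrary, path: str | Path) -> None:
    cols = [c for c in _LIBRARY_COLUMNS if c in library.table.columns]
    library.table[cols].to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> GuideLibrary:
    table = pd.read_csv(path, sep="\t")
    missing = {"guide_id", "gene_id", "guide_class", "protospacer"} - set(table.columns)
    if missing:
        raise ValueError(f"library file {path} lacks columns: {sorted(missing)}")
    return GuideLibrary(table=table)


def write_truth(truth: Truth, path: str | Path) -> None:
    doc = {
        "true_candidates": sorted(truth.true_candidates),
        "guide_effects": truth.guide_effects,
        "active_guide_mask": truth.active_guide_mask,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> Truth:
    doc = json.loads(Path(path).read_text())
    return Truth(
        true_candidates=set(doc["true_candidates"]),
        guide_effects={k: float(v) for k, v in doc["guide_effects"].items()},
        active_guide_mask={k: list(v) for k, v in doc["active_guide_mask"].items()},
    )
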