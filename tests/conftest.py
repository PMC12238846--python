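import numpy as np
import pandas as pd
import pytest

import lncscreen as L


@pytest.fixture(scope="session")
def small_bundle():
    """40-gene annotation on a compact genome."""
    return L.simulate_annotation(L.SimConfig(seed=3, n_genes=40))


@pytest.fixture(scope="session")
def default_sim():
    """Full default-condition synthetic dataset, shared across tests."""
    cfg = L.SimConfig(seed=11, n_genes=120, n_lnc_true=10)
    return L.simulate_all(cfg, n_library_genes=30)


def make_dummy_library(n_genes: int = 50, guides_per_gene: int = 10, n_scrambled: int = 50):
    """Library skeleton (ids + classes only) for count-model tests."""
    rows = [
        (f"G{i:03d}_sg{j:02d}", f"G{i:03d}", "targeting")
        for i in range(n_genes)
        for j in range(guides_per_gene)
    ]
    rows += [(f"scr_{i:03d}", "scrambled", "scrambled") for i in range(n_scrambled)]
    return L.GuideLibrary(table=pd.DataFrame(rows, columns=["guide_id", "gene_id", "guide_class"]))


@pytest.fixture
def dummy_library():
    return make_dummy_library()


def toy_annotation(genes):
    """Annotation from a compact spec: {gene_id: (chrom, strand, start, end, [exon_counts per transcript])}."""
    gene_rows, tx_rows, exon_rows = [], [], []
    for gid, (chrom, strand, start, end, exon_counts) in genes.items():
        tss = start if strand == "+" else end - 1
        gene_rows.append((gid, chrom, strand, start, end, tss))
        for t, n_ex in enumerate(exon_counts):
            tid = f"{gid}.t{t + 1}"
            tx_rows.append((tid, gid, chrom, strand, start, end))
            bounds = np.linspace(start, end, 2 * n_ex, dtype=int)
            for k in range(n_ex):
                exon_rows.append((tid, gid, chrom, int(bounds[2 * k]), int(bounds[2 * k + 1])))
    return L.TranscriptAnnotation(
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss"]),
        transcripts=pd.DataFrame(tx_rows, columns=["transcript_id", "gene_id", "chrom", "strand", "start", "end"]),
        exons=pd.DataFrame(exon_rows, columns=["transcript_id", "gene_id", "chrom", "start", "end"]),
    )
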