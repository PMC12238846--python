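"""End-to-end synthetic runs tying the generators to the design stage.

`simulate_all` produces every input the analysis stages consume —
annotation + genome, expression with planted truth, peaks, a designed
guide library against a chosen target set, and screen counts with
planted depletion — all from one config and one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import SimConfig
from .guides import design_library
from .simulate import (
    AnnotationBundle,
    plant_guide_effects,
    simulate_annotation,
    simulate_expression,
    simulate_peaks,
    simulate_screen,
)
from .types import ExpressionMatrix, GuideLibrary, ScreenCounts, Truth

__all__ = ["SimOutput", "simulate_all"]


@dataclass
class SimOutput:
    config: SimConfig
    bundle: AnnotationBundle
    expression: ExpressionMatrix
    peaks: pd.DataFrame
    library: GuideLibrary
    truth: Truth
    screen: ScreenCounts


def simulate_all(config: SimConfig, n_library_genes: int | None = None) -> SimOutput:
    """Run every generator in dependency order.

    The guide library targets all planted genes plus, when
    `n_library_genes` asks for more, non-planted genes in id order — the
    synthetic analogue of a candidate list that inevitably contains
    non-essential genes.
    """
    bundle = simulate_annotation(config)
    expression, truth = simulate_expression(config, bundle.annotation)
    peaks = simulate_peaks(bundle.annotation, truth, config)

    planted = sorted(truth.true_candidates)
    targets = list(planted)
    if n_library_genes is not None and n_library_genes > len(targets):
        extra = [g for g in bundle.annotation.genes["gene_id"] if g not in truth.true_candidates]
        targets += extra[: n_library_genes - len(targets)]
    library = design_library(
        bundle,
        sorted(targets),
        guides_per_gene=config.guides_per_gene,
        n_scrambled=config.n_scrambled,
        seed=config.seed,
    )
    truth = plant_guide_effects(library, truth, config)
    screen = simulate_screen(library, truth, config)
    return SimOutput(
        config=config, bundle=bundle, expression=expression, peaks=peaks,
        library=library, truth=truth, screen=screen,
    )
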