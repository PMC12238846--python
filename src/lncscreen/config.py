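"""Simulation and run configuration.

SimConfig holds every tunable of the synthetic-data generator; the defaults
describe the screen conditions the package targets (1,000x coverage,
~1,000 reads per guide, MOI 0.1-0.3, sampling days 0/7/14/21, two
replicates, a no-induction control arm). CandidateThresholds carries the
five-filter cascade cutoffs. RunConfig tags every parameter with its
provenance (paper_default / assumed_default / user) and round-trips
through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "SimConfig",
    "CandidateThresholds",
    "RunConfig",
    "MISMATCH_WEIGHTS",
]

#: Per-position single-mismatch weights for SpCas9 off-target scoring
#: (Hsu et al. 2013 experimentally derived vector), indexed 5'->3' along
#: the 20-nt protospacer with the PAM adjacent to position 20. Position 1
#: (PAM-distal) mismatches are tolerated (weight 0); PAM-proximal
#: mismatches are strongly penalised.
MISMATCH_WEIGHTS: tuple[float, ...] = (
    0.000, 0.000, 0.014, 0.000, 0.000,
    0.395, 0.317, 0.000, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732,
    0.828, 0.615, 0.804, 0.685, 0.583,
)


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generator.

    Expression side: grouped negative-binomial counts with `n_lnc_true`
    planted over-expressed lncRNAs (log2 effect `expr_logfc`) in the tumor
    groups, TSS peaks co-emitted for planted genes with probability
    `peak_at_true_tss_prob`, and a `mono_exonic_fraction` of genes whose
    transcripts are all single-exon.

    Screen side: plasmid abundance is log-normal (sigma
    `plasmid_sigma`), each replicate passes through a Poisson(`coverage`)
    cell bottleneck, a planted guide's cell population decays as
    2**(-s_g * day), and reads are negative-binomial at `depth` reads per
    guide. `moi` records the infection multiplicity of the emulated
    experiment; it constrains the wet protocol, not the count model.
    """

    seed: int = 0
    # annotation
    n_genes: int = 300
    n_chroms: int = 2
    gene_spacing: int = 3_000
    mono_exonic_fraction: float = 0.2
    promoter_upstream: int = 350
    promoter_downstream: int = 100
    # expression
    groups: tuple[tuple[str, int], ...] = (
        ("melanocyte", 4),
        ("brain_met", 5),
        ("lymph_node", 4),
    )
    tumor_groups: tuple[str, ...] = ("brain_met", "lymph_node")
    n_lnc_true: int = 20
    expr_logfc: float = 2.0
    expr_base_mean: float = 200.0
    expr_mean_sigma: float = 1.0
    expr_dispersion: float = 0.01
    planted_min_mean_factor: float = 2.0
    nb_dispersion: float = 0.05
    peak_at_true_tss_prob: float = 1.0
    background_peak_prob: float = 0.3
    # screen
    guides_per_gene: int = 10
    n_scrambled: int = 50
    coverage: int = 1_000
    depth: float = 1_000.0
    moi: float = 0.2
    timepoints_days: tuple[int, ...] = (0, 7, 14, 21)
    replicates: int = 2
    frac_active_guides: float = 0.7
    effect_mean: float = 2.0 / 21.0
    effect_cv: float = 0.25
    include_no_induction_arm: bool = True
    plasmid_sigma: float = 0.4

    def __post_init__(self) -> None:
        for name in ("mono_exonic_fraction", "peak_at_true_tss_prob",
                     "background_peak_prob", "frac_active_guides"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        self.groups = tuple((str(g), int(n)) for g, n in self.groups)
        self.timepoints_days = tuple(int(t) for t in self.timepoints_days)

    @property
    def promoter_length(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple((g, int(n)) for g, n in d["groups"])
        if "tumor_groups" in d:
            d["tumor_groups"] = tuple(d["tumor_groups"])
        if "timepoints_days" in d:
            d["timepoints_days"] = tuple(d["timepoints_days"])
        return cls(**d)


@dataclass
class CandidateThresholds:
    """Cutoffs of the five-filter candidate cascade.

    Defaults are the published cascade settings: FDR <= 0.05, |log2 fc| >
    0.75, mean CPM >= 1 in the higher-expressed group, an active histone
    mark (H3K4me3 or H3K27ac) near the TSS in the high-expression cell
    type, no mono-exonic-only genes, and log2 fc >= 0.5 in a screenable
    cell line. The mark window around the TSS is not published; +/-2 kb is
    the package default.
    """

    fdr: float = 0.05
    logfc: float = 0.75
    cpm: float = 1.0
    cellline_logfc: float = 0.5
    mark_window_bp: int = 2_000


_PAPER_DEFAULTS = {
    "fdr", "logfc", "cpm", "cellline_logfc", "guides_per_gene", "n_scrambled",
    "coverage", "depth", "moi", "timepoints_days", "replicates",
    "include_no_induction_arm", "guide_window", "min_offtarget_score",
    "top_k", "hit_threshold",
}

_VALID_TAGS = ("paper_default", "assumed_default", "user")


@dataclass
class RunConfig:
    """Flat parameter store with one provenance tag per parameter."""

    params: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: Any, tag: str | None = None) -> None:
        if tag is None:
            tag = "paper_default" if name in _PAPER_DEFAULTS else "assumed_default"
        if tag not in _VALID_TAGS:
            raise ValueError(f"unknown provenance tag {tag!r}")
        self.params[name] = value
        self.provenance[name] = tag

    def __getitem__(self, name: str) -> Any:
        return self.params[name]

    def to_yaml(self) -> str:
        doc = {
            name: {"value": self.params[name], "provenance": self.provenance[name]}
            for name in self.params
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        cfg = cls()
        for name, entry in doc.items():
            cfg.set(name, entry["value"], entry["provenance"])
        return cfg
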