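"""Configuration dataclasses for the pipeline and its stages.

Every threshold used by the analysis lives here with its default; the
YAML config files mirror the field names.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["AnnotationConfig", "SyntheticConfig", "PipelineConfig", "load_config", "validate_config"]


@dataclass
class AnnotationConfig:
    """Thresholds for regulatory/inactive element calling."""

    fpkm_threshold: float = 1.0        # stable transcript: mean FPKM strictly above
    min_tx_length: int = 1000          # stable transcript: span strictly above, nt
    promoter_window: int = 1000        # nt upstream of a stable TSS
    pe_overlap_window: int = 500       # nt upstream window for P/E association
    k4me3_top_n: int = 20_000          # peaks kept per replicate by score
    k4me1_top_n: int = 80_000
    k27ac_top_n: int = 80_000
    peak_resize: int = 1000            # consensus peak width, summit-centered
    min_replicates: int = 3            # consensus support (both when only 2)
    bivalence_distance: int = 1000     # enhancer exclusion gap to any H3K4me3
    inactive_target: int = 1_500_000   # sampled inactive loci, upper bound
    inactive_length: int = 1000
    inactive_exclusion_distance: int = 1000
    gc_match_threshold: float = 0.46   # 0.46 human-like, 0.41 mouse-like
    gc_match_max_n: int = 30_000


@dataclass
class SyntheticConfig:
    """Study conditions for the three-species synthetic clade.

    Species A carries the enhancer side, sister species B the promoter
    side, and O is the outgroup used to polarize turnover.  Planted rates
    follow the biological contrasts under test: promoter-side CpG gain of
    0.02, downstream U1 at 3.0/kb on the promoter side vs 2.0/kb at the
    orthologous enhancer, PAS mildly depleted on the promoter side
    (1.45 vs 1.70 per kb).
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 600_000
    gc_background: float = 0.41
    n_promoters: int = 100
    n_enhancers: int = 120             # includes the planted P/E enhancers
    n_inactive: int = 500              # target for the inactive sampler
    n_planted_pe: int = 50
    novel_fraction: float = 0.5        # planted P/E split novel vs extended
    pe_cpg_shift: float = 0.02         # added CpG frequency, promoter side
    u1_downstream_rate_promoter: float = 3.0   # sites per kb
    u1_downstream_rate_enhancer: float = 2.0
    u1_upstream_rate: float = 2.0      # both sides, keeps upstream null true
    pas_rate_promoter: float = 1.45
    pas_rate_enhancer: float = 1.70
    pas_upstream_rate: float = 1.70
    substitution_rate: float = 0.005   # per-base divergence between species
    block_break_rate: float = 0.0      # orthology-map fragmentation (0 = noise-free)
    fpkm_lognormal_mu: float = 2.0
    fpkm_lognormal_sigma: float = 0.5
    n_replicates: int = 3
    organs: tuple[str, ...] = ("liver", "brain")
    # planted outgroup states for P/E events (fractions of n_planted_pe)
    pe_ancestral_enhancer_fraction: float = 0.40
    pe_ancestral_promoter_fraction: float = 0.04
    # additional (non-P/E) element fates
    n_enh_conserved: int = 30
    n_enh_lost: int = 30
    n_prom_conserved: int = 40
    n_prom_lost: int = 20
    n_prom_repurposed: int = 1
    n_bivalent_decoys: int = 5
    n_truncated_isoform_decoys: int = 5
    n_unstable_transcripts: int = 5

    def validate(self) -> list[str]:
        problems = []
        for name in (
            "pe_cpg_shift",
            "u1_downstream_rate_promoter",
            "u1_downstream_rate_enhancer",
            "u1_upstream_rate",
            "pas_rate_promoter",
            "pas_rate_enhancer",
            "pas_upstream_rate",
            "substitution_rate",
            "block_break_rate",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not 0 < self.n_planted_pe <= self.n_enhancers:
            problems.append("n_planted_pe must be in (0, n_enhancers]")
        if not 0 < self.gc_background < 1:
            problems.append("gc_background must be in (0, 1)")
        if not self.organs:
            problems.append("organs list is empty")
        return problems


@dataclass
class PipelineConfig:
    seed: int = 0
    organ: str = "liver"               # the organ the turnover analysis is restricted to
    min_match_sister: float = 0.6
    min_match_outgroup: float = 0.4
    ancestral_assoc_window: int = 500  # upstream window for ancestral-promoter association
    n_resamples: int = 10_000
    tss_projection_max_shift: int = 50
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def validate(self) -> list[str]:
        problems = []
        if not 0 < self.min_match_sister <= 1:
            problems.append("min_match_sister must be in (0, 1]")
        if not 0 < self.min_match_outgroup <= 1:
            problems.append("min_match_outgroup must be in (0, 1]")
        if self.annotation.fpkm_threshold < 0:
            problems.append("fpkm_threshold must be >= 0")
        for name in (
            "promoter_window",
            "pe_overlap_window",
            "peak_resize",
            "inactive_length",
        ):
            if getattr(self.annotation, name) <= 0:
                problems.append(f"{name} must be > 0")
        problems.extend(self.synthetic.validate())
        return problems


def _from_mapping(cls, data: dict):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if known[key].name == "synthetic":
            value = _from_mapping(SyntheticConfig, value or {})
        elif known[key].name == "annotation":
            value = _from_mapping(AnnotationConfig, value or {})
        elif known[key].name == "organs":
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; missing keys take their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(PipelineConfig, data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def validate_config(path: str | Path) -> list[str]:
    """Range-check a config file; returns a list of problems (empty = ok)."""
    try:
        config = load_config(path)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        return [str(exc)]
    return config.validate()
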