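import pytest

from regswitch.config import PipelineConfig, SyntheticConfig
from regswitch.pipeline import run_pipeline


def mini_synthetic_config(seed: int = 5) -> SyntheticConfig:
    """A small clade that still exercises every element fate."""
    return SyntheticConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length=120_000,
        n_promoters=6,
        n_enhancers=10,
        n_inactive=30,
        n_planted_pe=4,
        n_enh_conserved=2,
        n_enh_lost=2,
        n_prom_conserved=2,
        n_prom_lost=2,
        n_prom_repurposed=1,
        n_bivalent_decoys=1,
        n_truncated_isoform_decoys=1,
        n_unstable_transcripts=1,
    )


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default noise-free clade (50 planted events)."""
    return run_pipeline(PipelineConfig(seed=11))


@pytest.fixture(scope="session")
def default_dataset(default_result):
    return default_result.dataset


@pytest.fixture(scope="session")
def axis_result():
    """Pipeline at the motif-axis scale: 100 planted novel events."""
    config = PipelineConfig(
        seed=7,
        synthetic=SyntheticConfig(
            seed=7,
            n_planted_pe=100,
            novel_fraction=1.0,
            n_enhancers=170,
            n_chromosomes=5,
        ),
    )
    return run_pipeline(config)


def planted_site_keys(truth):
    return {(p.a_chrom, p.a_start, p.a_end) for p in truth.planted_pe}


def detected_site_keys(result):
    return {
        (
            e.a_enhancer.interval.seq_name,
            e.a_enhancer.interval.start,
            e.a_enhancer.interval.end,
        )
        for e in result.pe_elements
    }
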