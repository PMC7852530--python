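import pytest

from triodnv.synth import (
    SyntheticCohortConfig,
    simulate_sv_data,
    simulate_tracks,
    simulate_trio_cohort,
)


def mini_config(**overrides) -> SyntheticCohortConfig:
    """A reduced-genome study configuration for fast unit tests."""
    base = dict(
        seed=11,
        chrom_lengths={"chr1": 400_000, "chr2": 200_000},
        n_genes=18,
        n_enhancers=12,
        n_intergenic_dhs=8,
        n_gc_rich_windows=16,
        n_difficult_promoters=3,
        n_trios=8,
        control_size=4000,
        informative_fraction=0.5,
        sv_len_range=(800, 3000),
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


@pytest.fixture(scope="session")
def mini_cfg():
    return mini_config()


@pytest.fixture(scope="session")
def mini_tracks(mini_cfg):
    return simulate_tracks(mini_cfg)


@pytest.fixture(scope="session")
def mini_cohort(mini_cfg, mini_tracks):
    return simulate_trio_cohort(mini_cfg, mini_tracks)


@pytest.fixture(scope="session")
def mini_sv(mini_cfg, mini_tracks):
    return simulate_sv_data(mini_cfg, mini_tracks)
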