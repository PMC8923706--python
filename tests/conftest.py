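"""Shared fixtures: small synthetic studies reused across test modules."""

import pytest

from sexlink import poolscreen, simdata

#: compact config: 100 kb scaffolds keep digestion and haplotype assembly fast
#: while leaving room for amplicon-sized windows around every planted site.
SMALL = dict(
    n_scaffolds=3,
    scaffold_length=100_000,
    n_sex_linked_snps=20,
    n_sex_linked_indels=6,
    n_autosomal_sites=60,
    depth_mean=60.0,
)


def small_config(**overrides) -> simdata.SimConfig:
    params = {**SMALL, **overrides}
    return simdata.SimConfig(**params)


@pytest.fixture(scope="session")
def small_sim() -> simdata.Simulation:
    """One fully realised small XX_XY study (no noise knobs disabled)."""
    return simdata.run_simulation(small_config(seed=7))


@pytest.fixture(scope="session")
def clean_sim() -> simdata.Simulation:
    """Noise-free small XX_XY study: zero sequencing error, no deliberately
    filter-failing sites, no tag dropout — planted truth is exactly
    recoverable."""
    return simdata.run_simulation(
        small_config(seed=11, seq_error_rate=0.0, frac_filter_fail_sites=0.0,
                     tag_dropout_rate=0.0)
    )


@pytest.fixture(scope="session")
def clean_screen(clean_sim):
    return poolscreen.run_screen(
        clean_sim.vcf_records, poolscreen.ScreenConfig(model="XX_XY")
    )
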