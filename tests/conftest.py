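import pytest

from sedomain.synthetic_data import SimConfig, simulate_cohort


def scaled_config(seed: int, **overrides) -> SimConfig:
    """A reduced cohort for multi-seed harnesses: same structure, faster."""
    defaults = dict(
        seed=seed,
        n_chrom=3,
        chrom_length=30_000_000,
        n_genes=800,
        n_tfs=15,
        n_enriched_tfs=3,
        tf_regions_per_tf=900,  # keeps the default per-bp cistrome density
        n_sed_t=40,
        n_sed_n=40,
        n_sed_c=20,
        n_background_enhancers=250,
        n_promoter_peaks=150,
        n_core_genes=30,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged fixture: the generator at its default seed (17)."""
    return simulate_cohort(SimConfig(seed=17))


@pytest.fixture(scope="session")
def default_elements(default_cohort):
    from sedomain.element_domains import call_elements

    return {
        sid: call_elements(default_cohort.peaks[sid], default_cohort.genes)
        for sid in sorted(default_cohort.peaks)
    }


@pytest.fixture(scope="session")
def default_sed_domains(default_cohort, default_elements):
    from sedomain.element_domains import pool_domains

    return pool_domains(default_elements, "SE", default_cohort.sample_sheet)


@pytest.fixture(scope="session")
def default_mrna_de(default_cohort):
    from sedomain.expression_de import DEConfig, de_test

    return de_test(
        default_cohort.mrna_counts,
        default_cohort.mrna_labels,
        DEConfig(),
        condition_a="tumor",
        condition_b="normal",
    )
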