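import pytest

from linckit.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study, generated once per session."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A reduced configuration for tests that regenerate data repeatedly."""
    return SimulationConfig(
        seed=7,
        n_chroms=3,
        chrom_length=40_000,
        n_genes=9,
        n_nats=2,
        n_repeats=6,
        class_counts={
            "lincRNA": 6,
            "coding": 3,
            "repeat_overlap": 3,
            "flank_overlap": 3,
            "short": 3,
            "long_orf": 3,
            "housekeeping_like": 3,
            "redundant_copy": 2,
        },
        n_tissues=6,
        n_accessions=12,
        n_background_loci=60,
        n_specific=2,
        n_pos_pairs=1,
        n_neg_pairs=1,
        n_modules=0,
    )
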