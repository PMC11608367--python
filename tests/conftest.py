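import pytest

from gatascan import SyntheticConfig, generate_dataset


def small_config(seed=7, **overrides):
    """A compact cohort spanning three strata, defaults otherwise."""
    base = dict(
        seed=seed,
        species_per_group={"eudicots": 3, "monocots": 2, "bryophyta": 1},
        gene_count_params={
            "eudicots": (5, 15, 10.0),
            "monocots": (5, 15, 10.0),
            "bryophyta": (6, 6, 6.0),
        },
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_records_by_id(small_dataset):
    return {r.protein_id: r for r in small_dataset.records}
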