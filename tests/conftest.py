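from pathlib import Path

import numpy as np
import pytest

import socialcircles as sc

DATA_DIR = Path(__file__).parent / "data"

#: zeroed coefficient map for planting specific effects in tests
ZERO_COEFFS = {
    k: 0.0
    for k in (
        "intercept", "ego_size", "group_size", "species", "sex",
        "habitat", "age", "species_x_age", "species_x_sex",
    )
}


@pytest.fixture(scope="session")
def toy_paths():
    return DATA_DIR / "toy_interactions.csv", DATA_DIR / "toy_metadata.csv"


@pytest.fixture(scope="session")
def toy_groups(toy_paths):
    inter, meta = toy_paths
    records = sc.read_interactions(inter)
    metadata = sc.read_metadata(meta)
    return sc.build_group_networks(records, metadata), metadata


@pytest.fixture()
def rng():
    # fresh, fixed-seed stream per test so every test is order-independent
    return np.random.default_rng(20260927)


def make_cohort(seed=0, **overrides):
    """Small synthetic cohort with study-condition defaults."""
    cfg = sc.SyntheticConfig(seed=seed, **overrides)
    return sc.generate_cohort(cfg), cfg


def cohort_to_networks(cohort):
    """Route a generated cohort through the reader-side containers."""
    records = [
        sc.InteractionRecord(r.group_id, r.actor_id, r.receiver_id, float(r.weight))
        for r in cohort.interactions.itertuples(index=False)
    ]
    meta = [
        sc.IndividualMeta(m.individual_id, m.group_id, m.species, m.sex,
                          float(m.age), m.habitat)
        for m in cohort.metadata.itertuples(index=False)
    ]
    return sc.build_group_networks(records, meta), meta
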