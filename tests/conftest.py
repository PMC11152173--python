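import numpy as np
import pytest

from rriclass.config import Config
from rriclass.curation import curate
from rriclass.features import featurize_instances
from rriclass.occupied import build_occupied_library
from rriclass.pipeline import build_training_instances
from rriclass.synthetic import default_fixture, energy_matched_fixture


def run_pipeline(bundle):
    """Fixture bundle -> (trusted, occupancy index, instances, features)."""
    trusted = curate(bundle.replicates, bundle.config)
    occ = build_occupied_library(
        [r for table in bundle.replicates for r in table],
        bundle.config.score_min_occupied,
    )
    instances = build_training_instances(
        trusted, bundle.genome, occ, bundle.config
    )
    features = featurize_instances(instances, bundle.config)
    return trusted, occ, instances, features


@pytest.fixture(scope="session")
def small_bundle():
    """12-site default-variant fixture on a small genome (fast)."""
    return default_fixture(seed=11, n_sites=12, n_chrom=2, chrom_len=12_000)


@pytest.fixture(scope="session")
def small_pipeline(small_bundle):
    return run_pipeline(small_bundle)


@pytest.fixture(scope="session")
def small_matched_bundle():
    """12-site energy-matched variant (planted context decoys)."""
    return energy_matched_fixture(
        seed=13, n_sites=12, n_chrom=2, chrom_len=12_000
    )


@pytest.fixture(scope="session")
def small_matched_pipeline(small_matched_bundle):
    return run_pipeline(small_matched_bundle)


# full-size study fixtures, built once per session (used by the
# acceptance tests; lazy, so unit-test runs never pay for them)


@pytest.fixture(scope="session")
def study_bundle():
    return default_fixture(seed=202)


@pytest.fixture(scope="session")
def study_pipeline(study_bundle):
    return run_pipeline(study_bundle)


@pytest.fixture(scope="session")
def matched_bundle():
    return energy_matched_fixture(seed=202)


@pytest.fixture(scope="session")
def matched_pipeline(matched_bundle):
    return run_pipeline(matched_bundle)


@pytest.fixture(scope="session")
def study_model(study_bundle, study_pipeline):
    from rriclass.model import train_model

    *_, features = study_pipeline
    return train_model(features, study_bundle.config, training_set_id="default")


@pytest.fixture(scope="session")
def matched_model(matched_bundle, matched_pipeline):
    from rriclass.model import train_model

    *_, features = matched_pipeline
    return train_model(features, matched_bundle.config, training_set_id="matched")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def config():
    return Config()
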