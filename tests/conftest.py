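import numpy as np
import pytest

from rplphewas import cohort as cohort_mod
from rplphewas import ehr_io, phenome, synth


@pytest.fixture(scope="session")
def fixture_bundle():
    bundle, concept_sets = synth.handcrafted_fixture()
    return bundle, concept_sets


@pytest.fixture(scope="session")
def phecode_map():
    return ehr_io.bundled_phecode_map()


@pytest.fixture(scope="session")
def small_center():
    """One generated center (no utilization link), reused across modules."""
    cfg = synth.ucsf_like_config(seed=11, n_rpl=400, n_control=1200)
    bundle, truth = synth.generate_center(cfg)
    return bundle, truth, cfg


@pytest.fixture(scope="session")
def small_cohort(small_center):
    bundle, _, _ = small_center
    concept_sets = synth.default_concept_sets()
    cohort, report = cohort_mod.build_cohort(bundle, concept_sets)
    return cohort, report


@pytest.fixture(scope="session")
def small_matrix(small_center, small_cohort, phecode_map):
    bundle, _, _ = small_center
    cohort, _ = small_cohort
    concept_sets = synth.default_concept_sets()
    outcome_ids = {cid for cs in concept_sets.values() for cid in cs.concept_ids}
    return phenome.build_matrix(
        cohort, bundle, phecode_map, outcome_concept_ids=outcome_ids
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
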