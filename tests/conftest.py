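"""Shared fixtures: one default 29-subject phantom cohort, segmented and
featurized once per session, reused by the module and acceptance tests."""

import numpy as np
import pytest

import habitatsurv as hs

COHORT_SEED = 1105
SUBJECT_SEED = 424242


@pytest.fixture(scope="session")
def spec29():
    return hs.PhantomSpec(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort29(spec29):
    subjects, manifest = hs.generate_cohort(spec29)
    return subjects, manifest


@pytest.fixture(scope="session")
def catalogs29(cohort29):
    subjects, _ = cohort29
    seeds = np.random.default_rng(COHORT_SEED + 1).integers(
        0, 2 ** 31 - 1, size=len(subjects))
    return [hs.segment_subject(vols, seed=int(s))
            for (vols, _), s in zip(subjects, seeds)]


@pytest.fixture(scope="session")
def table29(cohort29, catalogs29):
    subjects, manifest = cohort29
    vectors = [hs.extract_subject_features(vols, cat)
               for (vols, _), cat in zip(subjects, catalogs29)]
    return hs.assemble_feature_table(
        vectors, list(manifest["survival_class"]),
        subject_ids=list(manifest["subject_id"]))


@pytest.fixture(scope="session")
def one_subject():
    """One default short-group subject with maps and ground truth."""
    spec = hs.PhantomSpec(seed=COHORT_SEED)
    gm = hs.default_group_model("short")
    vols, truth = hs.generate_subject(spec, gm, SUBJECT_SEED)
    return spec, gm, vols, truth


@pytest.fixture(scope="session")
def one_catalog(one_subject):
    _, _, vols, _ = one_subject
    return hs.segment_subject(vols, seed=7)
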