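import numpy as np
import pytest

from connectopath.connectome_io import (
    CohortTable,
    ConnectivityMatrix,
    ParcellationAtlas,
    SubjectRecord,
    default_atlas,
)


@pytest.fixture(scope="session")
def atlas82():
    return default_atlas()


@pytest.fixture
def toy_atlas():
    return ParcellationAtlas(
        names=("left_a", "left_b", "right_c"),
        hemispheres=("left", "left", "right"),
        networks=("visual", "subcortical", "default_mode"),
    )


def make_matrix(weights, subject_id="sub-001", regions=None):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if regions is None:
        regions = tuple(f"region_{i:02d}" for i in range(n))
    return ConnectivityMatrix(subject_id=subject_id, regions=regions, weights=weights)


def random_symmetric_matrix(rng, n, density=0.5):
    """Random non-negative symmetric matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(len(iu)) < density
    vals = np.where(present, rng.uniform(0.1, 10.0, len(iu)), 0.0)
    w[iu, ju] = vals
    return w + w.T


def make_record(sid, group="ADHD", **kw):
    defaults = dict(
        subject_id=sid,
        group=group,
        age=12.0,
        gender="male",
        adhdrs_total_w0=30 if group == "ADHD" else 5,
        adhdrs_inatt_w0=15 if group == "ADHD" else 3,
        adhdrs_hyper_w0=15 if group == "ADHD" else 2,
    )
    if group == "ADHD":
        defaults.update(
            adhd_subtype="combined",
            mph_dose_mg_per_kg=1.0,
            prior_stimulant_6mo=False,
            prior_stimulant_duration=0.0,
            adhdrs_total_w6=20,
            adhdrs_inatt_w6=10,
            adhdrs_hyper_w6=10,
        )
    defaults.update(kw)
    return SubjectRecord(**defaults)


@pytest.fixture
def tiny_cohort(toy_atlas):
    """Six-subject cohort on the 3-region toy atlas."""
    rng = np.random.default_rng(7)
    subjects, matrices = [], {}
    for i in range(3):
        sid = f"sub-adhd-{i:02d}"
        subjects.append(make_record(sid, "ADHD"))
        matrices[sid] = make_matrix(
            random_symmetric_matrix(rng, 3, density=1.0), sid, toy_atlas.names
        )
    for i in range(3):
        sid = f"sub-tdc-{i:02d}"
        subjects.append(make_record(sid, "TDC"))
        matrices[sid] = make_matrix(
            random_symmetric_matrix(rng, 3, density=1.0), sid, toy_atlas.names
        )
    return CohortTable(subjects=subjects, matrices=matrices)
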