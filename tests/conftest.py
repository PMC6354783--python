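import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allomorph import (
    core_config,
    generate_mesh,
    generate_subjects,
    generate_vertex_table,
    normative_config,
)
from allomorph.config import KARYOTYPES, REGIONS, STRUCTURES
from allomorph.synthesize import make_vertex_fields

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def small_vertex_config(seed=0, label="core"):
    """Reduced 300-vertex mesh for fast vertex-wise tests."""
    cfg = core_config(seed=seed)
    cfg.sample_label = label
    cfg.vertex_counts = {
        "right_amygdala": 80,
        "left_amygdala": 84,
        "right_hippocampus": 70,
        "left_hippocampus": 66,
    }
    return cfg


def null_config(seed, sizes, label="core"):
    """Embedded null: no karyotype offsets, no focal fields, shared TBV
    distribution across groups."""
    cfg = core_config(seed=seed)
    cfg.sample_label = label
    cfg.group_sizes = {k: 0 for k in KARYOTYPES}
    cfg.group_sizes.update(sizes)
    for r in REGIONS:
        cfg.group_offsets[r] = {k: 0.0 for k in KARYOTYPES}
    cfg.focal_scale = {k: 0.0 for k in KARYOTYPES}
    cfg.tbv_mean = {k: 1392.0 for k in KARYOTYPES}
    cfg.tbv_sd = {k: 122.7 for k in KARYOTYPES}
    return cfg


@pytest.fixture(scope="session")
def core_subjects():
    return generate_subjects(core_config(seed=1))


@pytest.fixture(scope="session")
def normative_subjects():
    return generate_subjects(normative_config(seed=1))


@pytest.fixture(scope="session")
def default_mesh():
    return generate_mesh(core_config())


@pytest.fixture(scope="session")
def default_fields(default_mesh):
    return make_vertex_fields(core_config(), default_mesh)


@pytest.fixture(scope="session")
def default_vertex_data(core_subjects, normative_subjects, default_mesh,
                        default_fields):
    """(core vertex table, normative vertex table) on the full shared mesh."""
    _, cvt = generate_vertex_table(core_config(seed=1), core_subjects,
                                   mesh=default_mesh, fields=default_fields)
    _, nvt = generate_vertex_table(normative_config(seed=1), normative_subjects,
                                   mesh=default_mesh, fields=default_fields)
    return cvt, nvt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
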