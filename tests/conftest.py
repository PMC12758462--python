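import numpy as np
import pytest

from atlas_cpet import CentileGrid, CentileSet, SyntheticSpec, generate_centile_table


@pytest.fixture
def hand_grid_set() -> CentileSet:
    """Small hand-written table with distinct, strictly spread curves.

    The P5-P95 spread is positive at every work rate, so no point is
    inertial and hand-computed REL values are not perturbed by
    reweighing.
    """
    work_rates = np.array([0.0, 100.0, 200.0])
    values = np.array(
        [
            [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0],
            [1.0, 1.5, 2.0, 4.0, 5.0, 6.0, 8.0],
            [2.0, 2.5, 3.0, 5.0, 7.0, 9.0, 10.0],
        ]
    )
    return CentileSet(
        symptom="dyspnea",
        sex="M",
        age_band=(40, 80),
        grid=CentileGrid(work_rates, values),
        source="hand-written test table",
    )


@pytest.fixture
def default_spec() -> SyntheticSpec:
    return SyntheticSpec()


@pytest.fixture
def synthetic_set(default_spec) -> CentileSet:
    return generate_centile_table(default_spec)
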