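import numpy as np
import pytest

from upsit_panel.cohort import CohortMatrix
from upsit_panel.simulate import default_spec, simulate_cohort


@pytest.fixture
def toy_cohort():
    """4 subjects (2 PD, 2 HS) × 3 items, hand-enumerable."""
    return CohortMatrix(
        subject_ids=("p1", "p2", "h1", "h2"),
        labels=("PD", "PD", "HS", "HS"),
        responses=np.array([[0, 1, 0],
                            [1, 1, 0],
                            [1, 0, 1],
                            [1, 1, 1]]),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One calibrated synthetic cohort at the study sizes (68 PD / 61 HS)."""
    return simulate_cohort(default_spec(seed=11))


def make_two_class_cohort(p_pd, p_hs, n_pd, n_hs, seed):
    """Cohort with arbitrary per-item class probabilities (test helper)."""
    from upsit_panel.simulate import SyntheticSpec, simulate_cohort

    spec = SyntheticSpec(
        n_pd=n_pd, n_hs=n_hs,
        p_correct_pd=np.asarray(p_pd, dtype=float),
        p_correct_hs=np.asarray(p_hs, dtype=float),
        seed=seed,
    )
    return simulate_cohort(spec)
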