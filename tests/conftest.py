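import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bronchmech import GeneratorConfig, analyze_cohort, generate_tabular_cohort
from bronchmech.phantom import PhantomSubject, VoxelGridSpec, generate_voxel_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_and_truth():
    """Default-condition noise-free cohort (seed 1) with its ground truth."""
    return generate_tabular_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def analysis(cohort_and_truth):
    cohort, _ = cohort_and_truth
    return analyze_cohort(cohort)


def make_phantom_subject(n_airways=5, seed=0, e_lung=None, slope=None):
    """Small phantom subject with simple per-condition area tables."""
    rng = np.random.default_rng(seed)
    a_o_t = np.exp(rng.uniform(np.log(30.0), np.log(50.0), size=n_airways))
    tables = {
        c: pd.DataFrame(dict(
            airway_id=np.arange(n_airways),
            a_o_mm2=frac * a_o_t,
            a_i_mm2=0.5 * frac * a_o_t,
        ))
        for c, frac in (("B", 0.8), ("P", 0.75), ("T", 1.0))
    }
    return PhantomSubject(
        e_lung=e_lung or {"B": 3.9, "P": 5.2, "T": 8.66},
        slope=slope or {"B": 3.0, "P": 3.0, "T": 3.0},
        airways=tables,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free phantom on a small (<=64^3) grid, 5 airways."""
    subject = make_phantom_subject(n_airways=5)
    grid = VoxelGridSpec(shape=(64, 48, 64), spacing=(1.6, 1.6, 1.6))
    return generate_voxel_phantom(subject, grid, seed=0)
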