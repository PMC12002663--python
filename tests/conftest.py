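import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chronocycle as cc
from chronocycle.lineage import ArrestedCellWarning

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

warnings.simplefilter("ignore", ArrestedCellWarning)


@pytest.fixture(scope="session")
def model2():
    """Calibrated uncoupled Model 2 at the entrainment-figure default TCC."""
    return cc.build_model(2, C1=0.0, C2=0.0, autonomous_TCC=20)


@pytest.fixture(scope="session")
def model2_coupled():
    return cc.build_model(2, C1=0.55, C2=0.0, autonomous_TCC=20)


@pytest.fixture(scope="session")
def noise_ref(model2_coupled):
    return cc.reference_noise(model2_coupled)


@pytest.fixture(scope="session")
def ens_ref(model2_coupled, noise_ref):
    """Reference coupled ensemble: C1=0.55, TCC=20 h, 40 runs, cap 256."""
    return cc.ensemble(model2_coupled, noise_ref, n_runs=40, base_seed=11,
                       stop={"max_population": 256})


@pytest.fixture(scope="session")
def ens_reverse():
    """Reverse-coupled control: C1=0, high C2, 20 runs, cap 128."""
    spec = cc.reference_model(C1=0.0, C2=cc.REVERSE_C2_HIGH, TCC=20)
    noise = cc.reference_noise(spec)
    return cc.ensemble(spec, noise, n_runs=20, base_seed=11,
                       stop={"max_population": 128})


@pytest.fixture(scope="session")
def ens_tcc15():
    """HCT116-matched condition: C1=0.55, TCC=15 h, 40 runs, cap 256."""
    spec = cc.reference_model(C1=0.55, C2=0.0, TCC=15)
    noise = cc.reference_noise(spec)
    return cc.ensemble(spec, noise, n_runs=40, base_seed=11,
                       stop={"max_population": 256})


@pytest.fixture(scope="session")
def kl001_ensembles():
    """Paired control / max-dose lineage ensembles at TCC=15 h."""
    res = cc.kl001_cmi_experiment(factors=(1.0, 100.0, 1000.0), TCC=15,
                                  n_runs=20, base_seed=23,
                                  max_population=128)
    return res


@pytest.fixture(scope="session")
def small_run(model2_coupled, noise_ref):
    """One small stochastic run for structural tests."""
    return cc.run_lineage(model2_coupled, noise_ref, n_ancestors=4,
                          stop={"max_population": 64}, seed=5)


@pytest.fixture(scope="session")
def fixtures():
    return cc.make_fixtures(seed=0)


def bootstrap_median_ci(values, n_boot=2000, seed=0, alpha=0.05):
    rng = np.random.default_rng(seed)
    values = np.asarray(values, float)
    meds = np.array([np.median(rng.choice(values, len(values)))
                     for _ in range(n_boot)])
    return (float(np.percentile(meds, 100 * alpha / 2)),
            float(np.percentile(meds, 100 * (1 - alpha / 2))))
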