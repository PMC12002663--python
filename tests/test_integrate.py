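"""Chemical-Langevin integrator behaviour."""

import numpy as np
import pytest

import chronocycle as cc
from chronocycle.integrate import (
    IntegratorConfig,
    NoiseSpec,
    burn_in_ensemble,
    integrate,
)


def test_config_validation():
    with pytest.raises(ValueError):
        IntegratorConfig(dt=0.1)
    with pytest.raises(ValueError):
        IntegratorConfig(dt=0.01, t_max=-1)
    with pytest.raises(ValueError):
        NoiseSpec(mode="pink")
    with pytest.raises(ValueError):
        NoiseSpec(mode="constant", sigma=-1.0)


def test_deterministic_exponential_decay(model2):
    """With basal Wee1 transcription switched off, wee1 mRNA obeys pure
    first-order decay; the Euler scheme must match exp(-k t) to O(dt)."""
    spec = cc.build_model(2, overrides={"v_mw0": 0.0}, autonomous_TCC=20)
    k = spec.params["d_mw"]
    x0 = np.full(spec.n_species, 0.0)
    i = spec.index("wee1_mRNA")
    x0[i] = 1.0
    dt = 0.01
    cfg = IntegratorConfig(dt=dt, t_max=10.0, record_every=1, seed=0)
    tr = integrate(spec, NoiseSpec(mode="none"), x0, cfg)
    exact = np.exp(-k * 10.0)
    assert tr["wee1_mRNA"][-1] == pytest.approx(exact, rel=2 * dt)


def test_halving_dt_halves_endpoint_error(model2):
    spec = cc.build_model(2, overrides={"v_mw0": 0.0}, autonomous_TCC=20)
    k = spec.params["d_mw"]
    i = spec.index("wee1_mRNA")
    errs = []
    for dt in (0.04, 0.02, 0.01):
        x0 = np.zeros(spec.n_species)
        x0[i] = 1.0
        cfg = IntegratorConfig(dt=dt, t_max=10.0, record_every=1, seed=0)
        tr = integrate(spec, NoiseSpec(mode="none"), x0, cfg)
        errs.append(abs(tr["wee1_mRNA"][-1] - np.exp(-k * 10.0)))
    assert errs[0] > errs[1] > errs[2]
    assert errs[0] / errs[2] == pytest.approx(4.0, rel=0.3)


def test_zero_sigma_equals_deterministic(model2):
    x0 = np.full(model2.n_species, 0.5)
    cfg = IntegratorConfig(dt=0.01, t_max=24.0, record_every=10, seed=3)
    a = integrate(model2, NoiseSpec(mode="none"), x0, cfg)
    b = integrate(model2, NoiseSpec(mode="constant", sigma=0.0), x0, cfg)
    np.testing.assert_array_equal(a.X, b.X)


def test_noise_off_matches_reference_integrator(model2):
    """Deterministic Euler trajectory tracks an adaptive LSODA reference
    within 1 % sup-norm (relative to signal range) over one clock period."""
    from scipy.integrate import solve_ivp

    x0 = np.full(model2.n_species, 0.5)
    burn = IntegratorConfig(dt=0.01, t_max=240.0, record_every=100, seed=0)
    x0 = integrate(model2, NoiseSpec(mode="none"), x0, burn).X[-1]
    cfg = IntegratorConfig(dt=0.01, t_max=24.0, record_every=10, seed=0)
    tr = integrate(model2, NoiseSpec(mode="none"), x0, cfg)
    sol = solve_ivp(lambda t, x: cc.rhs(model2, np.maximum(x, 0)),
                    (0, 24.0), x0, t_eval=tr.t, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    # normalise each species by its dynamic range; constant species
    # (uncoupled Wee1) are compared against their level instead
    scale = np.maximum(np.ptp(sol.y, axis=1), 0.1 * np.abs(sol.y).max(axis=1))
    err = np.max(np.abs(tr.X.T - sol.y) / scale[:, None])
    assert err < 0.01


def test_seed_reproducibility_and_divergence(model2, noise_ref):
    x0 = np.full(model2.n_species, 0.5)
    cfg = IntegratorConfig(dt=0.01, t_max=48.0, record_every=10, seed=7)
    a = integrate(model2, noise_ref, x0, cfg)
    b = integrate(model2, noise_ref, x0, cfg)
    np.testing.assert_array_equal(a.X, b.X)
    c = integrate(model2, noise_ref, x0,
                  IntegratorConfig(dt=0.01, t_max=48.0, record_every=10, seed=8))
    assert np.max(np.abs(a.X - c.X)) > 1e-3


def test_state_dependent_variance_scales_with_system_size(model2):
    """CLE fluctuations around the deterministic path shrink like
    1/sqrt(omega)."""
    x0 = np.full(model2.n_species, 0.5)
    burn = IntegratorConfig(dt=0.01, t_max=240.0, record_every=100, seed=0)
    x0 = integrate(model2, NoiseSpec(mode="none"), x0, burn).X[-1]
    cfg = IntegratorConfig(dt=0.01, t_max=2.0, record_every=1, seed=0)
    det = integrate(model2, NoiseSpec(mode="none"), x0, cfg)
    i = model2.index("PER_CRY_N")

    def mean_sq_dev(omega, seeds=range(40)):
        devs = []
        for s in seeds:
            c = IntegratorConfig(dt=0.01, t_max=2.0, record_every=1, seed=100 + s)
            tr = integrate(model2, NoiseSpec(mode="state_dependent",
                                             omega=omega), x0, c)
            devs.append((tr.X[-1, i] - det.X[-1, i]) ** 2)
        return np.mean(devs)

    ratio = mean_sq_dev(50.0) / mean_sq_dev(800.0)
    assert ratio == pytest.approx(16.0, rel=0.6)


def test_trajectory_tidy_export(model2, noise_ref):
    x0 = np.full(model2.n_species, 0.5)
    cfg = IntegratorConfig(dt=0.01, t_max=1.0, record_every=10, seed=0)
    tr = integrate(model2, noise_ref, x0, cfg)
    df = tr.to_frame(cell_id=3, run_id=1)
    assert set(df.columns) == {"time", "species", "value", "cell_id", "run_id"}
    assert len(df) == len(tr.t) * model2.n_species
    assert (df.value >= 0).all()


class TestBurnIn:
    def test_single_state(self, model2, noise_ref):
        cfg = IntegratorConfig(dt=0.02, t_max=360.0, record_every=10, seed=0)
        (x,) = burn_in_ensemble(model2, noise_ref, cfg, 1)
        assert x.shape == (model2.n_species,)
        assert np.all(x >= 0)

    def test_states_span_mpf_cycle(self, model2, noise_ref):
        cfg = IntegratorConfig(dt=0.02, t_max=360.0, record_every=10, seed=1)
        states = burn_in_ensemble(model2, noise_ref, cfg, 100)
        mpf = np.array([s[model2.index("MPF")] for s in states])
        tr = integrate(model2, NoiseSpec(mode="none"),
                       np.full(model2.n_species, 0.5),
                       IntegratorConfig(dt=0.02, t_max=360.0, record_every=10,
                                        seed=0))
        cyc = tr["MPF"][tr.t > 180]
        lo, hi = cyc.min(), cyc.max()
        rng = hi - lo
        assert mpf.min() < lo + 0.10 * rng
        assert mpf.max() > hi - 0.10 * rng

    def test_clock_phases_uniform(self, model2, noise_ref):
        """Rayleigh circular-uniformity test on sampled clock phases is
        non-significant at alpha = 0.01 (n = 200)."""
        cfg = IntegratorConfig(dt=0.02, t_max=480.0, record_every=10, seed=2)
        states = burn_in_ensemble(model2, noise_ref, cfg, 200)
        i, j = model2.index("per_cry_mRNA"), model2.index("PER_CRY_N")
        xs = np.array([s[i] for s in states])
        ys = np.array([s[j] for s in states])
        ang = np.arctan2(ys - ys.mean(), xs - xs.mean())
        n = len(ang)
        R = np.hypot(np.cos(ang).sum(), np.sin(ang).sum()) / n
        p = np.exp(-n * R ** 2)  # Rayleigh approximation
        assert p > 0.01

    def test_horizon_too_short(self, model2, noise_ref):
        cfg = IntegratorConfig(dt=0.02, t_max=100.0, record_every=10, seed=0)
        with pytest.raises(cc.IntegrationError, match="too short"):
            burn_in_ensemble(model2, noise_ref, cfg, 10)

    def test_clock_synced_mode_aligns_clock_only(self, model2_coupled,
                                                 noise_ref):
        cfg = IntegratorConfig(dt=0.02, t_max=360.0, record_every=10, seed=3)
        states = burn_in_ensemble(model2_coupled, noise_ref, cfg, 20,
                                  mode="clock_synced")
        clk = [model2_coupled.index(s) for s in
               ("per_cry_mRNA", "PER_CRY_N", "BMAL1_CLOCK")]
        first = states[0][clk]
        for s in states[1:]:
            np.testing.assert_array_equal(s[clk], first)
        mpf = np.array([s[model2_coupled.index("MPF")] for s in states])
        assert np.ptp(mpf) > 0.1
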