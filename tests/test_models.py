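"""Network-model construction, wiring and calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import root

import chronocycle as cc
from chronocycle import _kernels
from chronocycle.models import (
    CLOCK_SPECIES,
    PER_CRY_DEG_PARAMS,
    SPECIES,
    production_degradation,
)


class TestBuildModel:
    def test_model1_rejects_reverse_coupling(self):
        with pytest.raises(ValueError, match="reverse"):
            cc.build_model(1, C1=0.0, C2=0.5, autonomous_TCC=20)

    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="model_id"):
            cc.build_model(4)

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            cc.build_model(2, overrides={"not_a_rate": 1.0})

    def test_tcc_range_enforced(self):
        with pytest.raises(ValueError):
            cc.build_model(2, autonomous_TCC=8.0)

    @pytest.mark.parametrize("mid", [1, 2, 3])
    def test_species_lists(self, mid):
        spec = cc.build_model(mid, autonomous_TCC=20)
        assert spec.species == SPECIES[mid]
        core = {"per_cry_mRNA", "PER_CRY_C", "PER_CRY_N", "BMAL1_CLOCK",
                "wee1_mRNA", "WEE1", "MPF"}
        assert core <= set(spec.species)
        if mid >= 2:
            assert {"reverb_mRNA", "REV_ERB", "bmal1_mRNA"} <= set(spec.species)
        if mid == 3:
            assert {"CycD", "CycE", "CycA", "p21"} <= set(spec.species)

    def test_calibration_failure_is_explicit(self):
        # killing MPF self-activation removes the cell-cycle limit cycle
        with pytest.raises(cc.CalibrationError):
            cc.build_model(2, overrides={"v_m": 0.0}, autonomous_TCC=20)


class TestRhs:
    def test_zero_state_gives_basal_production(self, model2):
        prod, deg = production_degradation(model2, np.zeros(model2.n_species))
        assert np.allclose(deg, 0.0)
        p, s = model2.params, model2
        ix = s.index
        # repression-free / activation-at-zero values of every synthesis term
        assert prod[ix("per_cry_mRNA")] == pytest.approx(s.s_clock * p["v_mp"])
        assert prod[ix("bmal1_mRNA")] == pytest.approx(s.s_clock * p["v_mb"])
        assert prod[ix("reverb_mRNA")] == pytest.approx(s.s_clock * p["b_mr"])
        assert prod[ix("wee1_mRNA")] == pytest.approx(p["v_mw0"])
        assert prod[ix("MPF")] == pytest.approx(s.s_cc * p["ks_m"])

    def test_uncoupled_wee1_production_ignores_bmal1(self, model2):
        x = np.full(model2.n_species, 0.5)
        iB, iMw = model2.index("BMAL1_CLOCK"), model2.index("wee1_mRNA")
        prods = []
        for b in (0.0, 0.5, 3.0):
            x2 = x.copy()
            x2[iB] = b
            prods.append(production_degradation(model2, x2)[0][iMw])
        assert prods[0] == prods[1] == prods[2] == model2.params["v_mw0"]

    def test_rhs_vanishes_at_numerical_fixed_point(self):
        # a KL001-saturated clock has a stable fixed point: find it by
        # root-finding and check the rhs there
        from chronocycle.integrate import IntegratorConfig, NoiseSpec, integrate

        spec = cc.apply_kl001(cc.build_model(2, autonomous_TCC=20), 1000.0)
        cfg = IntegratorConfig(dt=0.02, t_max=600, record_every=100, seed=0)
        x0 = integrate(spec, NoiseSpec(mode="none"),
                       np.full(spec.n_species, 0.5), cfg).X[-1]
        # the clock has converged; seed the (unstable) cell-cycle fixed
        # point with a mid-branch guess
        x0[spec.index("MPF")] = 0.5
        x0[spec.index("APC")] = 0.3
        sol = root(lambda x: cc.rhs(spec, np.maximum(x, 0)), x0)
        assert sol.success
        assert np.max(np.abs(cc.rhs(spec, np.maximum(sol.x, 0)))) < 1e-8

    def test_dimension_mismatch(self, model2):
        with pytest.raises(ValueError, match="shape"):
            cc.rhs(model2, np.zeros(3))

    def test_nan_rejected(self, model2):
        x = np.full(model2.n_species, 0.5)
        x[0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cc.rhs(model2, x)

    @given(st.integers(0, 10 ** 9))
    def test_boundary_nonnegativity(self, seed):
        """A species at zero can only be produced, never pushed negative."""
        spec = cc.build_model(2, C1=0.4, C2=1.0, autonomous_TCC=20)
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 3, spec.n_species)
        zero = rng.integers(0, spec.n_species)
        x[zero] = 0.0
        assert cc.rhs(spec, x)[zero] >= 0.0

    def test_uncoupled_separability(self, model2):
        """With C1=C2=0 clock derivatives ignore cell-cycle species and
        vice versa (finite-difference sensitivity is exactly zero)."""
        rng = np.random.default_rng(0)
        x = rng.uniform(0.2, 2.0, model2.n_species)
        clk = [model2.index(s) for s in CLOCK_SPECIES[2]]
        cyc = [i for i in range(model2.n_species) if i not in clk]
        f0 = cc.rhs(model2, x)
        for i in cyc:
            x2 = x.copy()
            x2[i] += 0.37
            assert np.allclose(cc.rhs(model2, x2)[clk], f0[clk])
        for i in clk:
            x2 = x.copy()
            x2[i] += 0.37
            # wee1_mRNA production reads BMAL1-CLOCK only through C1 = 0
            assert np.allclose(cc.rhs(model2, x2)[cyc], f0[cyc])

    def test_monotone_coupling(self):
        """Wee1 production is nondecreasing in C1 and BMAL1-CLOCK;
        Rev-erba production nonincreasing in C2*MPF."""
        x = np.full(11, 0.8)
        prev = -np.inf
        for c1 in (0.0, 0.3, 0.8):
            spec = cc.build_model(2, C1=c1, autonomous_TCC=20)
            v = production_degradation(spec, x)[0][spec.index("wee1_mRNA")]
            assert v >= prev
            prev = v
        spec = cc.build_model(2, C1=0.5, autonomous_TCC=20)
        iB = spec.index("wee1_mRNA")
        vals = []
        for b in (0.1, 0.5, 2.0):
            x2 = x.copy()
            x2[spec.index("BMAL1_CLOCK")] = b
            vals.append(production_degradation(spec, x2)[0][iB])
        assert vals[0] <= vals[1] <= vals[2]
        iMr = spec.index("reverb_mRNA")
        prev = np.inf
        for c2 in (0.0, 1.0, 4.0):
            s2 = cc.build_model(2, C2=c2, autonomous_TCC=20)
            v = production_degradation(s2, x)[0][iMr]
            assert v <= prev
            prev = v


class TestKL001:
    def test_factor_one_is_identity(self, model2):
        out = cc.apply_kl001(model2, 1.0)
        assert out.params == model2.params
        assert out.kl001_factor == 1.0

    def test_divides_only_tagged_parameters(self, model2):
        out = cc.apply_kl001(model2, 10.0)
        for k, v in model2.params.items():
            if k in PER_CRY_DEG_PARAMS:
                assert out.params[k] == pytest.approx(v / 10.0)
            else:
                assert out.params[k] == v
        assert out.kl001_factor == 10.0

    def test_multiplicative_composition(self, model2):
        a = cc.apply_kl001(cc.apply_kl001(model2, 4.0), 25.0)
        b = cc.apply_kl001(model2, 100.0)
        assert a.params == b.params
        assert a.kl001_factor == b.kl001_factor == 100.0

    def test_factor_below_one_rejected(self, model2):
        with pytest.raises(ValueError):
            cc.apply_kl001(model2, 0.5)


class TestTimescales:
    def test_set_autonomous_period_rescales_exactly(self, model2):
        """Time rescaling by s multiplies the uncoupled MPF period by 1/s."""
        fast = cc.set_autonomous_period(model2, 12.0)
        assert fast.s_cc == pytest.approx(model2.s_cc * 20.0 / 12.0)
        assert fast.params == model2.params  # clock untouched
        per = _measured_mpf_period(fast)
        assert per == pytest.approx(12.0, abs=0.5)

    def test_serialisation_round_trip(self, model2_coupled):
        d = cc.spec_to_dict(model2_coupled)
        back = cc.spec_from_dict(d)
        assert back == model2_coupled


def _measured_mpf_period(spec):
    from chronocycle.analysis import peak_to_peak_period
    from chronocycle.integrate import IntegratorConfig, NoiseSpec, integrate

    cfg = IntegratorConfig(dt=0.01, t_max=20 * spec.autonomous_TCC,
                           record_every=5, seed=0)
    tr = integrate(spec, NoiseSpec(mode="none"),
                   np.full(spec.n_species, 0.5), cfg)
    m = tr.t > tr.t[-1] / 2
    return peak_to_peak_period(tr.t[m], tr["MPF"][m])


@pytest.mark.parametrize("mid", [1, 2, 3])
def test_kernels_match_reference_rhs(mid):
    """The numba production/degradation kernels agree with the numpy
    reference to machine precision on random states."""
    spec = cc.build_model(mid, C1=0.3, C2=0.0 if mid == 1 else 0.7,
                          autonomous_TCC=18)
    p = _kernels.flat_params(spec)
    rng = np.random.default_rng(mid)
    for _ in range(50):
        x = rng.uniform(0.0, 4.0, spec.n_species)
        prod = np.empty(spec.n_species)
        deg = np.empty(spec.n_species)
        _kernels._pd(mid, x, p, spec.C1, spec.C2, spec.s_clock, spec.s_cc,
                     prod, deg)
        prod0, deg0 = production_degradation(spec, x)
        np.testing.assert_allclose(prod, prod0, rtol=0, atol=1e-13)
        np.testing.assert_allclose(deg, deg0, rtol=0, atol=1e-13)


def test_antiphase_bmal1_vs_per_cry(model2):
    """BMAL1-CLOCK and nuclear PER-CRY peak roughly half a period apart."""
    from chronocycle.integrate import IntegratorConfig, NoiseSpec, integrate
    from scipy.signal import find_peaks

    cfg = IntegratorConfig(dt=0.01, t_max=480, record_every=10, seed=0)
    tr = integrate(model2, NoiseSpec(mode="none"),
                   np.full(model2.n_species, 0.5), cfg)
    m = tr.t > 240
    t = tr.t[m]
    b, pn = tr["BMAL1_CLOCK"][m], tr["PER_CRY_N"][m]
    pkb, _ = find_peaks(b, prominence=0.1 * np.ptp(b))
    pkp, _ = find_peaks(pn, prominence=0.1 * np.ptp(pn))
    offsets = [min(abs(tb - tp) for tp in t[pkp]) for tb in t[pkb][1:-1]]
    # peaks should sit 12 +/- 4 h from the nearest PER-CRY peak
    assert 8.0 < np.median(offsets) < 16.0
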