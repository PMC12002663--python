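"""Lineage engine: phases, division, stopping rules, tree invariants."""

import numpy as np
import pytest

import chronocycle as cc
from chronocycle.integrate import IntegratorConfig, NoiseSpec, integrate
from chronocycle.lineage import PhaseThresholds, divide, phase_of, CellRecord


class TestThresholds:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhaseThresholds(theta_S=1.0, theta_M=0.5, theta_div=0.2)
        with pytest.raises(ValueError):
            PhaseThresholds(theta_S=0.2, theta_M=0.5, theta_div=0.9)

    def test_from_spec_fractions(self, model2):
        thr = PhaseThresholds.from_spec(model2)
        assert thr.theta_M / thr.theta_S == pytest.approx(3.0)
        assert thr.theta_div == thr.theta_S


class TestPhaseOf:
    thr = PhaseThresholds(theta_S=0.3, theta_M=0.9, theta_div=0.3)

    def test_zero_mpf_is_g1(self):
        assert phase_of(0.0, self.thr, False) == "G1"

    def test_above_theta_m_is_m(self):
        assert phase_of(1.5, self.thr, False) == "M"

    def test_between_thresholds_is_sg2(self):
        assert phase_of(0.5, self.thr, False) == "S/G2"

    def test_latch_holds_m_below_threshold(self):
        assert phase_of(0.5, self.thr, True) == "M"
        assert phase_of(0.0, self.thr, True) == "M"


class TestDivide:
    def test_daughters_inherit_state_exactly(self):
        mother = CellRecord(cell_id=0, lineage_id=0, parent_id=None,
                            birth_time=0.0, generation=0,
                            birth_state=np.zeros(3))
        state = np.array([0.1, 0.2, 0.3])
        d1, d2 = divide(mother, state, 17.0, (1, 2))
        for d in (d1, d2):
            np.testing.assert_array_equal(d.birth_state, state)
            assert d.birth_time == 17.0
            assert d.generation == 1
            assert d.parent_id == 0
        assert mother.division_time == 17.0
        assert not mother.censored


def test_deterministic_uncoupled_run_divides_every_tcc(model2):
    """One noise-free uncoupled ancestor: a regular binary tree whose
    non-ancestor IMTs all equal the autonomous period within 0.5 h."""
    # start the ancestor at a defined cycle point (fresh G1, post-division)
    burn = IntegratorConfig(dt=0.01, t_max=320.0, record_every=2, seed=0)
    tr = integrate(model2, NoiseSpec(mode="none"),
                   np.full(model2.n_species, 0.5), burn)
    thr = PhaseThresholds.from_spec(model2)
    mpf = tr["MPF"]
    below = (mpf[:-1] >= thr.theta_div) & (mpf[1:] < thr.theta_div)
    x0 = tr.X[np.nonzero(below)[0][-1] + 1]
    run = cc.run_lineage(model2, NoiseSpec(mode="none"), thresholds=thr,
                         ancestors=[x0], stop={"max_time": 65.0}, seed=0)
    run.tree.validate()
    imts = [r.IMT for r in run.tree.cells()
            if r.IMT is not None and r.full_cycle]
    assert len(imts) >= 2
    assert np.allclose(imts, 20.0, atol=0.5)
    # consecutive IMTs down a lineage differ by < 1 % (limit cycle)
    assert np.ptp(imts) / np.mean(imts) < 0.01


def test_max_population_stop(model2_coupled, noise_ref):
    run = cc.run_lineage(model2_coupled, noise_ref, n_ancestors=1,
                         stop={"max_population": 16}, seed=2)
    run.tree.validate()
    assert run.n_divisions == 15
    leaves = [r for r in run.tree.cells() if r.censored]
    assert len(leaves) >= 16
    # population conservation: alive = ancestors + divisions
    t, n = cc.population_curve(run)
    assert n[-1] == 1 + run.n_divisions


def test_seed_reproducibility(model2_coupled, noise_ref):
    a = cc.run_lineage(model2_coupled, noise_ref, n_ancestors=2,
                       stop={"max_population": 32}, seed=9)
    b = cc.run_lineage(model2_coupled, noise_ref, n_ancestors=2,
                       stop={"max_population": 32}, seed=9)
    ra = {r.cell_id: (r.parent_id, r.birth_time, r.division_time)
          for r in a.tree.cells()}
    rb = {r.cell_id: (r.parent_id, r.birth_time, r.division_time)
          for r in b.tree.cells()}
    assert ra == rb
    c = cc.run_lineage(model2_coupled, noise_ref, n_ancestors=2,
                       stop={"max_population": 32}, seed=10)
    rc = {r.cell_id: (r.parent_id, r.birth_time, r.division_time)
          for r in c.tree.cells()}
    assert ra != rc


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_tree_invariants_after_stochastic_runs(model2_coupled, noise_ref, seed):
    run = cc.run_lineage(model2_coupled, noise_ref, n_ancestors=3,
                         stop={"max_population": 48}, seed=seed)
    run.tree.validate()
    # time ordering and binary out-degree are covered by validate();
    # additionally each lineage has exactly one root
    roots = run.tree.roots()
    assert len(roots) == 3
    assert {run.tree.record(r).lineage_id for r in roots} == {0, 1, 2}


class TestSnapshots:
    def test_counts_sum_to_alive_population(self, small_run):
        ts = np.linspace(0.0, small_run.t_stop, 9)
        counts = cc.snapshot_phase_counts(small_run, ts)
        t, n = cc.population_curve(small_run, ts)
        np.testing.assert_array_equal(counts.sum(axis=1), n)

    def test_initial_count_equals_ancestors(self, small_run):
        counts = cc.snapshot_phase_counts(small_run, [0.0])
        assert counts.sum() == 4

    def test_beyond_horizon_raises(self, small_run):
        with pytest.raises(ValueError, match="beyond"):
            cc.snapshot_phase_counts(small_run, [small_run.t_stop + 5.0])

    def test_synchronized_deterministic_population_single_phase(self, model2):
        thr = PhaseThresholds.from_spec(model2)
        burn = IntegratorConfig(dt=0.01, t_max=320.0, record_every=2, seed=0)
        tr = integrate(model2, NoiseSpec(mode="none"),
                       np.full(model2.n_species, 0.5), burn)
        x0 = tr.X[-1]
        run = cc.run_lineage(model2, NoiseSpec(mode="none"), thresholds=thr,
                             ancestors=[x0.copy() for _ in range(5)],
                             stop={"max_time": 30.0}, seed=0)
        counts = cc.snapshot_phase_counts(run, np.linspace(0, 29, 8))
        # identical cells: at every time exactly one phase is occupied
        assert ((counts > 0).sum(axis=1) == 1).all()


def test_censored_cells_excluded_from_imt_stats(small_run):
    stats = cc.imt_stats(small_run)
    n_uncensored_fullcycle = sum(
        1 for r in small_run.tree.cells()
        if not r.censored and r.full_cycle)
    assert stats["n"] == n_uncensored_fullcycle


@pytest.mark.parametrize("mid", [1, 3])
def test_other_model_variants_grow_lineages(mid):
    """Models 1 and 3 run through the same engine: calibrated, dividing,
    with valid trees and defined IMT statistics."""
    spec = cc.build_model(mid, C1=0.55, autonomous_TCC=18)
    noise = cc.reference_noise(spec)
    run = cc.run_lineage(spec, noise, n_ancestors=2,
                         stop={"max_population": 24}, seed=4)
    run.tree.validate()
    assert run.n_divisions >= 8
    st = cc.imt_stats(run)
    assert 10.0 < st["mean"] < 30.0
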