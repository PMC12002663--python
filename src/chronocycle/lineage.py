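"""Single-cell lineage simulation.

Each cell carries its own copy of the coupled clock/cell-cycle network,
integrated as a chemical-Langevin SDE with a per-cell random stream spawned
deterministically from the run seed and the cell id.  Cell-cycle phase is
read off the MPF concentration against fixed thresholds:

* G1 while MPF is below ``theta_S``;
* S/G2 between ``theta_S`` and ``theta_M``;
* M once MPF rises above ``theta_M`` — latched, so a cell stays in M even
  if MPF dips, until the division trigger fires;
* division on the downward crossing of ``theta_div`` while latched in M
  (the post-peak collapse of the MPF relaxation oscillation).

At division the mother is replaced by two daughters inheriting her exact
concentrations (symmetric inheritance, no partitioning noise).  Lineages
are represented as a forest of binary trees in a directed graph.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _kernels
from .integrate import IntegratorConfig, NoiseSpec, _GMODE, burn_in_ensemble
from .models import ModelSpec

__all__ = [
    "PhaseThresholds",
    "CellRecord",
    "LineageTree",
    "SimulationRun",
    "ArrestedCellWarning",
    "phase_of",
    "divide",
    "run_lineage",
    "snapshot_phase_counts",
]

PHASES = ("G1", "S/G2", "M")


class ArrestedCellWarning(UserWarning):
    """A cell failed to divide within the guard horizon and was censored."""


@dataclass(frozen=True)
class PhaseThresholds:
    """MPF thresholds separating G1, S/G2 and M.

    Defaults are derived from the deterministic uncoupled MPF peak via
    :meth:`from_spec` — M entry at 60 % of the peak, G1/S boundary and the
    division trigger at 20 % — values that give the deterministic cycle a
    short M phase and a G1 share smaller than S/G2, and fire division once
    per relaxation cycle.
    """

    theta_S: float
    theta_M: float
    theta_div: float

    def __post_init__(self):
        if not (0 < self.theta_S < self.theta_M):
            raise ValueError("require 0 < theta_S < theta_M")
        if not (self.theta_div < self.theta_M):
            raise ValueError("require theta_div < theta_M")

    @classmethod
    def from_spec(cls, spec: ModelSpec, frac_S: float = 0.2,
                  frac_M: float = 0.6) -> "PhaseThresholds":
        peak = _mpf_peak(spec)
        return cls(theta_S=frac_S * peak, theta_M=frac_M * peak,
                   theta_div=frac_S * peak)


_mpf_peak_cache: dict = {}


def _mpf_peak(spec: ModelSpec) -> float:
    """Deterministic uncoupled MPF peak concentration (cached)."""
    from .integrate import integrate
    from .models import build_model

    key = (spec.model_id, tuple(sorted(spec.params.items())), spec.s_cc)
    if key not in _mpf_peak_cache:
        from dataclasses import replace
        probe = replace(spec, C1=0.0, C2=0.0)
        cfg = IntegratorConfig(dt=0.01, t_max=16 * spec.autonomous_TCC,
                               record_every=5, seed=0)
        traj = integrate(probe, NoiseSpec(mode="none"),
                         np.full(spec.n_species, 0.5), cfg)
        tail = traj["MPF"][traj.t > traj.t[-1] / 2]
        _mpf_peak_cache[key] = float(tail.max())
    return _mpf_peak_cache[key]


def phase_of(mpf: float, thresholds: PhaseThresholds, in_M_latch: bool) -> str:
    """Cell-cycle phase for an MPF level (total function).

    ``in_M_latch`` carries the hysteresis: a cell that entered M stays in M
    until division regardless of the instantaneous MPF level.
    """
    if in_M_latch or mpf >= thresholds.theta_M:
        return "M"
    if mpf < thresholds.theta_S:
        return "G1"
    return "S/G2"


@dataclass
class CellRecord:
    cell_id: int
    lineage_id: int
    parent_id: int | None
    birth_time: float
    generation: int
    birth_state: np.ndarray
    division_time: float | None = None
    censored: bool = True
    arrested: bool = False
    #: False for simulation ancestors, whose first recorded cycle starts
    #: mid-phase at t = 0 and is truncated; such cells never contribute an
    #: IMT to statistics.
    full_cycle: bool = True

    @property
    def IMT(self) -> float | None:
        """Intermitotic time (h); None for censored cells."""
        if self.censored or self.division_time is None:
            return None
        return self.division_time - self.birth_time


class LineageTree:
    """Forest of binary cell-lineage trees (directed mother -> daughter)."""

    def __init__(self):
        self.graph = nx.DiGraph()

    def add_cell(self, rec: CellRecord):
        self.graph.add_node(rec.cell_id, record=rec)
        if rec.parent_id is not None:
            self.graph.add_edge(rec.parent_id, rec.cell_id)

    def record(self, cell_id: int) -> CellRecord:
        return self.graph.nodes[cell_id]["record"]

    def cells(self):
        return [self.graph.nodes[n]["record"] for n in self.graph.nodes]

    def roots(self):
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def children(self, cell_id: int):
        return list(self.graph.successors(cell_id))

    def parent(self, cell_id: int):
        preds = list(self.graph.predecessors(cell_id))
        return preds[0] if preds else None

    def __len__(self):
        return self.graph.number_of_nodes()

    def validate(self):
        """Raise if the forest-of-binary-trees invariants are violated."""
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("lineage graph contains a cycle")
        for n in self.graph.nodes:
            deg = self.graph.out_degree(n)
            rec = self.record(n)
            if deg not in (0, 2):
                raise ValueError(f"cell {n} has out-degree {deg} (must be 0 or 2)")
            if self.graph.in_degree(n) > 1:
                raise ValueError(f"cell {n} has more than one mother")
            if deg == 2 and rec.censored:
                raise ValueError(f"censored cell {n} has daughters")
            if deg == 0 and not rec.censored:
                raise ValueError(f"divided cell {n} has no daughters")
            for c in self.graph.successors(n):
                crec = self.record(c)
                if crec.generation != rec.generation + 1:
                    raise ValueError(f"generation bookkeeping broken at {c}")
                if rec.division_time is None or crec.birth_time != rec.division_time:
                    raise ValueError(f"birth/division time mismatch at {c}")


@dataclass
class SimulationRun:
    tree: LineageTree
    spec: ModelSpec
    noise: NoiseSpec
    thresholds: PhaseThresholds
    config: IntegratorConfig
    seed: int
    stop: dict
    t_stop: float
    phase_events: dict           # cell_id -> (times array, phase-code array)
    n_divisions: int

    def alive_at(self, t: float):
        """Cell ids alive at time t (born at or before t, not yet divided)."""
        out = []
        for rec in self.tree.cells():
            end = rec.division_time if rec.division_time is not None else self.t_stop
            if rec.birth_time <= t < end or (rec.birth_time <= t and rec.censored
                                             and t <= self.t_stop):
                out.append(rec.cell_id)
        return out


def divide(mother: CellRecord, state_at_division: np.ndarray, t: float,
           next_ids: tuple[int, int]) -> tuple[CellRecord, CellRecord]:
    """Split a mother in M into two daughters inheriting her concentrations."""
    daughters = tuple(
        CellRecord(
            cell_id=nid,
            lineage_id=mother.lineage_id,
            parent_id=mother.cell_id,
            birth_time=t,
            generation=mother.generation + 1,
            birth_state=np.array(state_at_division, dtype=float),
        )
        for nid in next_ids
    )
    mother.division_time = t
    mother.censored = False
    return daughters


_CHUNK = 1024


def _cell_rng(seed: int, cell_id: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, cell_id])))


def _simulate_cell(spec, noise, thresholds, config, seed, rec, guard_h):
    """Integrate one cell from birth until division or the guard horizon.

    Returns (divided, division_time, division_state, ev_t, ev_ph).
    """
    p = _kernels.flat_params(spec)
    gmode = _GMODE[noise.mode]
    sigma = noise.effective_sigma(spec)
    nscale = noise.noise_scale(spec)
    i_mpf = spec.index("MPF")
    rng = _cell_rng(seed, rec.cell_id)
    x = rec.birth_state.copy()

    m0 = x[i_mpf]
    latch = 1 if (rec.parent_id is None and m0 >= thresholds.theta_M) else 0
    phase = 2 if latch else (0 if m0 < thresholds.theta_S else 1)
    ev_t = [rec.birth_time]
    ev_ph = [phase]

    n_guard = int(round(guard_h / config.dt))
    done = 0
    t0 = rec.birth_time
    while done < n_guard:
        chunk = min(_CHUNK, n_guard - done)
        if gmode == 0:
            z = np.zeros((1, spec.n_species))
        else:
            z = rng.standard_normal((chunk, spec.n_species))
        et = np.empty(chunk + 4)
        ep = np.empty(chunk + 4, dtype=np.int64)
        status, steps, n_ev, latch, phase = _kernels.em_cell(
            spec.model_id, x, p, spec.C1, spec.C2, spec.s_clock, spec.s_cc,
            config.dt, chunk, z, gmode, sigma, nscale, noise.omega,
            i_mpf, thresholds.theta_S, thresholds.theta_M, thresholds.theta_div,
            latch, phase, t0 + done * config.dt, et, ep, 0,
        )
        ev_t.extend(et[:n_ev])
        ev_ph.extend(ep[:n_ev])
        done += steps
        if status == _kernels.DIVIDED:
            return True, t0 + done * config.dt, x, np.array(ev_t), np.array(ev_ph)
        if status == _kernels.OVERFLOW:
            raise RuntimeError(
                f"cell {rec.cell_id}: integration overflow at t={t0 + done * config.dt:.2f} h")
    return False, None, x, np.array(ev_t), np.array(ev_ph)


def run_lineage(
    spec: ModelSpec,
    noise: NoiseSpec,
    thresholds: PhaseThresholds | None = None,
    n_ancestors: int = 1,
    stop: dict | None = None,
    seed: int = 0,
    config: IntegratorConfig | None = None,
    ancestors: list | None = None,
    ancestor_mode: str = "random_times",
    guard_factor: float = 10.0,
) -> SimulationRun:
    """Grow cell lineages from ``n_ancestors`` ancestral cells.

    ``stop`` is ``{"max_population": int}`` (halt when the alive count
    reaches the cap, processing divisions in chronological order) or
    ``{"max_time": hours}``.  Ancestors are drawn from
    :func:`chronocycle.integrate.burn_in_ensemble` unless given explicitly.
    Cells that fail to divide within ``guard_factor * autonomous_TCC``
    hours are flagged arrested and censored.  The run is bit-reproducible
    given the seed.
    """
    if stop is None:
        stop = {"max_population": 64}
    if len(stop) != 1 or next(iter(stop)) not in ("max_population", "max_time"):
        raise ValueError("stop must be {'max_population': n} or {'max_time': h}")
    if config is None:
        config = IntegratorConfig(dt=0.01, t_max=480.0, record_every=10, seed=seed)
    if thresholds is None:
        thresholds = PhaseThresholds.from_spec(spec)
    if ancestors is None:
        burn_cfg = IntegratorConfig(dt=config.dt, t_max=24 * spec.clock_period,
                                    record_every=10, seed=seed)
        ancestors = burn_in_ensemble(spec, noise, burn_cfg, n_ancestors,
                                     mode=ancestor_mode)
    else:
        n_ancestors = len(ancestors)

    guard_h = guard_factor * spec.autonomous_TCC
    max_pop = stop.get("max_population", np.inf)
    max_time = stop.get("max_time", np.inf)

    tree = LineageTree()
    phase_events: dict = {}
    pending: list = []  # heap of (division_time, cell_id, division_state)
    next_id = 0
    n_arrested = 0

    def new_cell(lineage_id, parent, birth_time, generation, state):
        nonlocal next_id
        rec = CellRecord(cell_id=next_id, lineage_id=lineage_id,
                         parent_id=parent, birth_time=birth_time,
                         generation=generation,
                         birth_state=np.array(state, dtype=float),
                         full_cycle=parent is not None)
        next_id += 1
        return rec

    def process(rec):
        """Simulate a cell; push its division event if it divides in time."""
        nonlocal n_arrested
        divided, t_div, x_div, ev_t, ev_ph = _simulate_cell(
            spec, noise, thresholds, config, seed, rec, guard_h)
        tree.add_cell(rec)
        phase_events[rec.cell_id] = (ev_t, ev_ph)
        if divided and t_div <= max_time:
            heapq.heappush(pending, (t_div, rec.cell_id, x_div))
        elif not divided and rec.birth_time + guard_h < max_time:
            rec.arrested = True
            n_arrested += 1

    for k in range(n_ancestors):
        process(new_cell(k, None, 0.0, 0, ancestors[k]))

    alive = n_ancestors
    n_div = 0
    t_stop = 0.0 if np.isinf(max_time) else max_time
    while pending:
        t_div, cid, x_div = heapq.heappop(pending)
        mother = tree.record(cid)
        d1, d2 = divide(mother, x_div, t_div, (next_id, next_id + 1))
        next_id += 2
        n_div += 1
        alive += 1
        if alive >= max_pop:
            # halt before processing further divisions; the two newborn
            # daughters are recorded as censored leaves at t_stop
            t_stop = t_div
            for d in (d1, d2):
                tree.add_cell(d)
                m0 = d.birth_state[spec.index("MPF")]
                ph = 0 if m0 < thresholds.theta_S else (
                    2 if m0 >= thresholds.theta_M else 1)
                phase_events[d.cell_id] = (np.array([t_div]), np.array([ph]))
            break
        process(d1)
        process(d2)
    else:
        if np.isinf(max_time):
            t_stop = max(
                (r.division_time or r.birth_time) for r in tree.cells())

    # censor divisions that fall beyond the stop time
    for t_div, cid, _x in pending:
        rec = tree.record(cid)
        rec.division_time = None
        rec.censored = True

    if n_arrested:
        warnings.warn(
            f"{n_arrested} cell(s) did not divide within the guard horizon "
            f"({guard_h:.0f} h) and were censored", ArrestedCellWarning)

    return SimulationRun(tree=tree, spec=spec, noise=noise,
                         thresholds=thresholds, config=config, seed=seed,
                         stop=stop, t_stop=t_stop,
                         phase_events=phase_events, n_divisions=n_div)


def snapshot_phase_counts(run: SimulationRun, times) -> np.ndarray:
    """Counts of alive cells in (G1, S/G2, M) at each requested time.

    Returns an ``(len(times), 3)`` integer array; rows sum to the alive
    population size at that time.
    """
    times = np.asarray(times, dtype=float)
    if times.max() > run.t_stop + 1e-9:
        raise ValueError(
            f"requested time {times.max():.2f} h beyond run horizon "
            f"{run.t_stop:.2f} h")
    counts = np.zeros((len(times), 3), dtype=np.int64)
    for rec in run.tree.cells():
        end = rec.division_time if rec.division_time is not None else np.inf
        m = (times >= rec.birth_time) & (times < end)
        if not m.any():
            continue
        ev_t, ev_ph = run.phase_events[rec.cell_id]
        idx = np.searchsorted(ev_t, times[m], side="right") - 1
        idx = np.clip(idx, 0, len(ev_ph) - 1)
        ph = ev_ph[idx].astype(np.int64)
        for j, tj in zip(ph, np.nonzero(m)[0]):
            counts[tj, j] += 1
    return counts
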