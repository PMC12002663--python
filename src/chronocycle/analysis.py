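"""Dynamics analyses: spectra, entrainment, KL001 dose response, growth and
ergodic phase-fraction predictions.

Period/amplitude conventions
----------------------------
The dominant frequency is read from the discrete Fourier transform of the
linearly detrended, Hann-tapered signal.  Because the KL001-perturbed clock
rings down non-stationarily, the *period* is also measured in the time
domain as the mean of the final (up to three) peak-to-peak intervals, and
the *amplitude* as half the mean peak-to-trough excursion over those final
cycles; a signal with fewer than two discernible peaks is reported
non-oscillatory (period undefined, amplitude ~0).  Peak-based periods are
also far more precise than a Fourier bin for calibration-grade checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .integrate import IntegratorConfig, NoiseSpec, Trajectory, integrate
from .lineage import SimulationRun, snapshot_phase_counts
from .models import ModelSpec, apply_kl001

__all__ = [
    "SpectralSummary",
    "GrowthFit",
    "ErgodicPrediction",
    "DoseResponseCurve",
    "PhaseProportionSeries",
    "spectral_summary",
    "dominant_frequency",
    "peak_to_peak_period",
    "entrainment_curve",
    "kl001_dose_response",
    "population_curve",
    "fit_growth_rate",
    "growth_rate_of_run",
    "ergodic_prediction",
    "ergodic_phase_fractions",
    "deterministic_phase_durations",
    "phase_proportion_analysis",
    "peak_phase_24h",
]


@dataclass
class SpectralSummary:
    frequency: float          # dominant frequency (1/h); NaN if non-oscillatory
    period: float             # 1/frequency (h)
    peak_period: float        # mean of final peak-to-peak intervals (h)
    amplitude: float          # half mean peak-to-trough, final cycles (conc)
    non_oscillatory: bool
    species: str | None = None
    window: float = 0.0       # analysed window length (h)


def _detrended(t, y):
    coef = np.polyfit(t, y, 1)
    return y - np.polyval(coef, t)


def dominant_frequency(t, y) -> float:
    """Dominant positive frequency of a uniformly sampled signal (1/h)."""
    t = np.asarray(t, float)
    y = _detrended(t, np.asarray(y, float))
    y = y * np.hanning(len(y))
    dt = t[1] - t[0]
    f = np.fft.rfftfreq(len(y), dt)
    p = np.abs(np.fft.rfft(y)) ** 2
    return float(f[np.argmax(p[1:]) + 1])


def peak_to_peak_period(t, y, n_last: int = 3, prominence_frac: float = 0.05):
    """Mean of the final ``n_last`` peak-to-peak intervals, or NaN."""
    y = np.asarray(y, float)
    rng = np.ptp(y)
    if rng <= 0:
        return float("nan")
    pk, _ = find_peaks(y, prominence=prominence_frac * rng)
    if len(pk) < 2:
        return float("nan")
    ints = np.diff(np.asarray(t, float)[pk])
    return float(np.mean(ints[-n_last:]))


def spectral_summary(
    traj,
    species: str | None = None,
    amplitude_floor: float = 0.0,
    prominence_frac: float = 0.005,
) -> SpectralSummary:
    """Spectral and time-domain oscillation summary of one signal.

    ``traj`` is a :class:`~chronocycle.integrate.Trajectory` (then
    ``species`` selects the column) or a ``(t, y)`` pair.  Signals whose
    final-cycles amplitude falls below ``amplitude_floor`` (or which have
    fewer than two discernible peaks) are flagged non-oscillatory with an
    undefined period.
    """
    if isinstance(traj, Trajectory):
        t, y = traj.t, traj[species]
    else:
        t, y = traj
        t = np.asarray(t, float)
        y = np.asarray(y, float)
    if len(t) < 8:
        raise ValueError("signal too short for spectral analysis")
    window = float(t[-1] - t[0])
    rng = np.ptp(y)
    if rng <= 1e-12:
        return SpectralSummary(float("nan"), float("nan"), float("nan"), 0.0,
                               True, species, window)
    pk, _ = find_peaks(y, prominence=prominence_frac * rng)
    tr, _ = find_peaks(-y, prominence=prominence_frac * rng)
    if len(pk) >= 2 and len(tr) >= 2:
        n = min(3, len(pk), len(tr))
        amp = 0.5 * float(y[pk][-n:].mean() - y[tr][-n:].mean())
        per = float(np.mean(np.diff(t[pk])[-3:]))
    else:
        amp, per = 0.0, float("nan")
    non_osc = (amp <= amplitude_floor) or not np.isfinite(per)
    freq = dominant_frequency(t, y) if not non_osc else float("nan")
    return SpectralSummary(
        frequency=freq,
        period=1.0 / freq if freq and np.isfinite(freq) else float("nan"),
        peak_period=per if not non_osc else float("nan"),
        amplitude=amp,
        non_oscillatory=bool(non_osc),
        species=species,
        window=window,
    )


# --------------------------------------------------------------------------
# entrainment
# --------------------------------------------------------------------------


def entrainment_curve(
    spec: ModelSpec,
    which: str,
    grid,
    config: IntegratorConfig | None = None,
) -> "pd.DataFrame":
    """Dominant-frequency sweep over a coupling-strength grid (deterministic).

    ``which`` is ``"C1"`` (forward sweep; the MPF frequency is reported) or
    ``"C2"`` (reverse sweep; the BMAL1-CLOCK frequency is reported).
    Non-oscillatory grid points are recorded with NaN frequency rather than
    raising.
    """
    import pandas as pd

    if which not in ("C1", "C2"):
        raise ValueError("which must be 'C1' or 'C2'")
    species = "MPF" if which == "C1" else "BMAL1_CLOCK"
    if config is None:
        config = IntegratorConfig(dt=0.02, t_max=960.0, record_every=5, seed=0)
    rows = []
    for v in grid:
        s = replace(spec, **{which: float(v)})
        traj = integrate(s, NoiseSpec(mode="none"),
                         np.full(s.n_species, 0.5), config)
        m = traj.t >= traj.t[-1] / 2
        sub = (traj.t[m], traj[species][m])
        summ = spectral_summary(sub, species)
        rows.append({which: float(v), "species": species,
                     "frequency": summ.frequency, "period": summ.period,
                     "peak_period": summ.peak_period,
                     "non_oscillatory": summ.non_oscillatory})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# KL001 dose response
# --------------------------------------------------------------------------


@dataclass
class DoseResponseCurve:
    factors: np.ndarray
    period: np.ndarray        # h; NaN where non-oscillatory
    amplitude: np.ndarray     # reporter concentration units
    species: str
    control_amplitude: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "kl001_factor": self.factors,
            "period": self.period,
            "amplitude": self.amplitude,
            "relative_amplitude": self.amplitude / self.control_amplitude,
        })


def kl001_dose_response(
    spec: ModelSpec,
    factors=(1, 2, 5, 10, 100, 1000),
    species: str = "BMAL1_CLOCK",
    window: float = 240.0,
    config: IntegratorConfig | None = None,
) -> DoseResponseCurve:
    """Clock period/amplitude versus KL001 dose factor (deterministic).

    Mimics a *Bmal1*-luciferase bioluminescence recording (the reporter
    used in the CRY-stabiliser experiments): the control system is first
    relaxed onto its attractor, the drug is switched on, and the reporter
    is recorded over ``window`` hours.  Near the oscillation-death dose the
    signal is a slow ring-down; far beyond it the reporter settles to a
    constant and is reported non-oscillatory with amplitude ~0.
    """
    factors = np.asarray(sorted(factors), dtype=float)
    if factors[0] != 1:
        raise ValueError("factor grid must start at 1 (control)")
    if np.any(np.diff(factors) <= 0):
        raise ValueError("factor grid must be strictly increasing")
    if config is None:
        config = IntegratorConfig(dt=0.02, t_max=window, record_every=5, seed=0)
    burn = IntegratorConfig(dt=config.dt, t_max=480.0, record_every=50, seed=0)
    x0 = integrate(spec, NoiseSpec(mode="none"),
                   np.full(spec.n_species, 0.5), burn).X[-1]
    # control amplitude defines the 1 % floor for "non-oscillatory"
    ctrl = integrate(spec, NoiseSpec(mode="none"), x0, config)
    ctrl_summ = spectral_summary(ctrl, species)
    floor = 0.01 * ctrl_summ.amplitude
    periods, amps = [], []
    for f in factors:
        s = apply_kl001(spec, float(f)) if f > 1 else spec
        traj = integrate(s, NoiseSpec(mode="none"), x0, config)
        summ = spectral_summary(traj, species, amplitude_floor=floor)
        periods.append(summ.peak_period)
        amps.append(summ.amplitude)
    return DoseResponseCurve(factors=factors, period=np.array(periods),
                             amplitude=np.array(amps), species=species,
                             control_amplitude=ctrl_summ.amplitude)


# --------------------------------------------------------------------------
# population growth
# --------------------------------------------------------------------------


@dataclass
class GrowthFit:
    lam: float            # proliferation rate (1/h)
    intercept: float
    r_squared: float

    @property
    def doubling_time(self) -> float:
        return math.log(2) / self.lam if self.lam > 0 else float("inf")


def population_curve(run: SimulationRun, times=None):
    """Alive-cell counts over time (ancestors + net divisions)."""
    if times is None:
        times = np.linspace(0.0, run.t_stop, 49)[1:]
    times = np.asarray(times, float)
    n0 = sum(1 for r in run.tree.cells() if r.parent_id is None)
    t_div = np.sort([r.division_time for r in run.tree.cells()
                     if r.division_time is not None])
    return times, n0 + np.searchsorted(t_div, times, side="right")


def fit_growth_rate(times, counts) -> GrowthFit:
    """Ordinary least squares of ln(cell count) on time."""
    times = np.asarray(times, float)
    counts = np.asarray(counts, float)
    if len(times) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive for a log-linear fit")
    if np.ptp(times) == 0:
        raise ValueError("degenerate time grid")
    y = np.log(counts)
    slope, intercept = np.polyfit(times, y, 1)
    yhat = slope * times + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GrowthFit(lam=float(slope), intercept=float(intercept), r_squared=r2)


def growth_rate_of_run(run: SimulationRun) -> GrowthFit:
    t, n = population_curve(run)
    return fit_growth_rate(t, n)


# --------------------------------------------------------------------------
# ergodic rate analysis
# --------------------------------------------------------------------------


def ergodic_prediction(a1: float, a2: float, T: float,
                       lam: float | None = None) -> float:
    """Expected fraction of cells aged in [a1, a2) in steady exponential growth.

    For a population in which every cell divides at age ``T`` and grows at
    rate ``lam``, the stationary age density is proportional to
    ``e^{-lam a}`` on [0, T); young cells are enriched because each
    division produces two age-zero daughters.  The fraction in [a1, a2) is

    ``(e^{-lam a1} - e^{-lam a2}) / (1 - e^{-lam T})``

    which for the self-consistent rate ``lam = ln2/T`` (the default)
    reduces to ``2 (e^{-lam a1} - e^{-lam a2})``, and for ``lam -> 0`` to
    the duration-proportional fraction ``(a2 - a1)/T``.
    """
    if not (0 <= a1 < a2 <= T + 1e-9):
        raise ValueError(f"require 0 <= a1 < a2 <= T, got [{a1}, {a2}) with T={T}")
    if lam is None:
        lam = math.log(2) / T
    if lam * T < 1e-9:
        return (a2 - a1) / T
    return (math.exp(-lam * a1) - math.exp(-lam * a2)) / (1.0 - math.exp(-lam * T))


def ergodic_phase_fractions(durations: dict, lam: float | None = None) -> dict:
    """Per-phase ergodic fractions for a G1 -> S/G2 -> M partition.

    ``durations`` maps phase name to mean duration (h), in cycle order
    G1, S/G2, M.  With ``lam = ln2 / T`` (T the summed cycle length) the
    fractions sum to one exactly.
    """
    order = ["G1", "S/G2", "M"]
    T = float(sum(durations[k] for k in order))
    if lam is None:
        lam = math.log(2) / T
    out, a = {}, 0.0
    for k in order:
        out[k] = ergodic_prediction(a, a + durations[k], T, lam)
        a += durations[k]
    return out


# --------------------------------------------------------------------------
# phase proportions
# --------------------------------------------------------------------------


@dataclass
class PhaseProportionSeries:
    times: np.ndarray
    fractions: np.ndarray       # (n_times, 3) columns G1, S/G2, M
    alive: np.ndarray
    m_spectrum: SpectralSummary
    ergodic: dict               # per-phase predicted fraction
    mean_durations: dict        # measured mean phase durations (h)
    growth: GrowthFit
    low_count: np.ndarray       # mask of times with < 20 alive cells

    @property
    def m_fraction(self):
        return self.fractions[:, 2]


def deterministic_phase_durations(spec, thresholds=None) -> dict:
    """Mean G1/S-G2/M durations of the noise-free system at ``spec``'s
    coupling, measured from division-to-division threshold crossings.

    These are the natural inputs for the ergodic baseline: with noise the
    *occupancy* of each phase stays close to its deterministic share even
    though noise-driven escape skews the per-cell duration distribution
    (length-biased sampling shortens the measured mean dwell times).
    """
    from .lineage import PhaseThresholds, run_lineage

    if thresholds is None:
        thresholds = PhaseThresholds.from_spec(spec)
    burn = IntegratorConfig(dt=0.01, t_max=16 * spec.autonomous_TCC,
                            record_every=50, seed=0)
    x0 = integrate(spec, NoiseSpec(mode="none"),
                   np.full(spec.n_species, 0.5), burn).X[-1]
    run = run_lineage(spec, NoiseSpec(mode="none"), thresholds=thresholds,
                      ancestors=[x0], seed=0,
                      stop={"max_time": 6 * spec.autonomous_TCC},
                      config=IntegratorConfig(
                          dt=0.01, t_max=6 * spec.autonomous_TCC, seed=0))
    return _mean_phase_durations(run)


def _mean_phase_durations(run: SimulationRun) -> dict:
    """Mean G1, S/G2, M durations from phase-crossing events.

    Only full cycles are used: non-ancestor, uncensored cells born in G1
    whose event sequence reaches M before division.
    """
    g1, sg2, m = [], [], []
    for rec in run.tree.cells():
        if rec.censored or rec.parent_id is None:
            continue
        ev_t, ev_ph = run.phase_events[rec.cell_id]
        if len(ev_t) < 3 or ev_ph[0] != 0:
            continue
        # first entry into S/G2 and first entry into M after birth
        i_s = np.argmax(ev_ph == 1)
        i_m = np.argmax(ev_ph == 2)
        if i_s == 0 or i_m == 0 or ev_t[i_m] < ev_t[i_s]:
            continue
        g1.append(ev_t[i_s] - rec.birth_time)
        sg2.append(ev_t[i_m] - ev_t[i_s])
        m.append(rec.division_time - ev_t[i_m])
    if not g1:
        raise ValueError("no complete G1->S/G2->M cycles recorded")
    return {"G1": float(np.mean(g1)), "S/G2": float(np.mean(sg2)),
            "M": float(np.mean(m))}


def phase_proportion_analysis(run: SimulationRun, times=None) -> PhaseProportionSeries:
    """Phase-fraction time series with spectral and ergodic overlays.

    The ergodic baseline uses the deterministic-limit phase durations at
    the run's coupling (see :func:`deterministic_phase_durations`) and the
    self-consistent growth rate ``ln2 / T`` so the predicted full-cycle
    partition sums to one.
    """
    if times is None:
        times = np.arange(0.0, run.t_stop, 0.5)
    times = np.asarray(times, float)
    counts = snapshot_phase_counts(run, times)
    alive = counts.sum(axis=1)
    frac = counts / np.maximum(alive, 1)[:, None]
    m_spec = spectral_summary((times, frac[:, 2]), "M_fraction",
                              prominence_frac=0.05)
    durations = _mean_phase_durations(run)
    growth = growth_rate_of_run(run)
    try:
        ref = deterministic_phase_durations(run.spec, run.thresholds)
    except (ValueError, RuntimeError):
        ref = durations  # arrested deterministic limit: fall back
    erg = ergodic_phase_fractions(ref)
    return PhaseProportionSeries(
        times=times, fractions=frac, alive=alive, m_spectrum=m_spec,
        ergodic=erg, mean_durations=durations, growth=growth,
        low_count=alive < 20,
    )


def peak_phase_24h(times, series, period: float = 24.0) -> float:
    """Phase (h, in [0, period)) of the ``period``-h component of a series.

    Quadrature demodulation at the target period; equivalent to the lag of
    the cross-correlation peak against a cosine restricted to (-T/2, T/2].
    """
    times = np.asarray(times, float)
    y = np.asarray(series, float)
    y = y - y.mean()
    w = 2 * np.pi / period
    ph = math.atan2(float(np.sum(y * np.sin(w * times))),
                    float(np.sum(y * np.cos(w * times))))
    return (ph % (2 * np.pi)) / w
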