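"""The headline in-silico experiments, as plain functions plus a config
dispatcher.

Every function takes explicit arguments, returns pandas DataFrames (plus
richer objects where useful) and derives per-run seeds with
:func:`chronocycle.config.run_seed`, so a campaign is bit-reproducible from
``(configuration, base_seed)`` regardless of execution order.

Study conditions
----------------
The defaults reproduce the reference conditions used throughout: Model 2
with clock period 24 h; forward coupling ``C1 = 0.55`` (the value at which
the simulated IMT distribution matches HCT116 microscopy data and the
deterministic entrainment of a 20 h cell cycle completes); constant-mode
noise at level :data:`DEFAULT_NOISE_LEVEL`, calibrated so the pooled IMT
coefficient of variation at the reference condition lies in the 0.10-0.20
band measured for HCT116 cells; KL001 experiments at ``TCC = 15 h``.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .analysis import (
    entrainment_curve,
    growth_rate_of_run,
    kl001_dose_response,
    phase_proportion_analysis,
)
from .config import ExperimentConfig, run_seed
from .integrate import IntegratorConfig, NoiseSpec, burn_in_ensemble, calibrated_noise
from .lineage import run_lineage
from .models import ModelSpec, apply_kl001, build_model, set_autonomous_period
from .stats import RELATIONS, cmi, correlation_summary, extract_pairs, imt_stats, pearson

__all__ = [
    "DEFAULT_NOISE_LEVEL",
    "REVERSE_C2_HIGH",
    "reference_model",
    "reference_noise",
    "ensemble",
    "correlation_table",
    "cmi_experiment",
    "kl001_cmi_experiment",
    "growth_experiment",
    "phase_proportion_experiment",
    "run_experiment",
]

log = logging.getLogger("chronocycle")

#: constant-noise level (fraction of each species' deterministic limit-cycle
#: half-range) calibrated so the pooled IMT CV at C1=0.55, TCC=20 h falls in
#: the 0.10-0.20 band of HCT116 single-cell microscopy.
DEFAULT_NOISE_LEVEL = 0.065

#: reverse coupling strength used as the "high C2" condition: the smallest
#: grid value at which the BMAL1-CLOCK rhythm is fully entrained by the
#: cell cycle (1:1, within the clean locking window).
REVERSE_C2_HIGH = 5.0


def reference_model(C1=0.55, C2=0.0, TCC=20.0, model_id=2, overrides=None,
                    kl001_factor=1.0) -> ModelSpec:
    spec = build_model(model_id, overrides=overrides, C1=C1, C2=C2,
                       autonomous_TCC=TCC)
    if kl001_factor > 1:
        spec = apply_kl001(spec, kl001_factor)
    return spec


def reference_noise(spec: ModelSpec, level=DEFAULT_NOISE_LEVEL,
                    mode="constant", clock_noise_scale=1.0,
                    omega=100.0) -> NoiseSpec:
    """Noise calibrated on the *control* dynamics of ``spec``.

    For KL001-perturbed specs the amplitudes are still taken from the
    unperturbed system (the drug does not change the noise model), so pass
    the control spec here.
    """
    return calibrated_noise(spec, level, mode=mode,
                            clock_noise_scale=clock_noise_scale, omega=omega)


def ensemble(spec, noise, n_runs=20, base_seed=0, n_ancestors=8,
             stop=None, dt=0.01, ancestor_mode="random_times",
             thresholds=None):
    """Independent lineage-simulation runs with derived per-run seeds."""
    if stop is None:
        stop = {"max_population": 128}
    runs = []
    for k in range(n_runs):
        seed = run_seed(base_seed, k)
        cfg = IntegratorConfig(dt=dt, t_max=480.0, seed=seed)
        runs.append(run_lineage(spec, noise, thresholds=thresholds,
                                n_ancestors=n_ancestors, stop=dict(stop),
                                seed=seed, config=cfg,
                                ancestor_mode=ancestor_mode))
    return runs


def correlation_table(runs, relations=RELATIONS, **meta) -> pd.DataFrame:
    """Tidy per-run correlation table (run_id, relation, r, n_pairs, ...)."""
    rows = []
    for i, run in enumerate(runs):
        for rel in relations:
            ps = extract_pairs(run, rel)
            rows.append({"run_id": i, "seed": run.seed, "relation": rel,
                         "r": pearson(ps), "n_pairs": ps.n, **meta})
    return pd.DataFrame(rows)


def cmi_experiment(
    C1=0.55,
    C2=0.0,
    TCC=20.0,
    n_runs=20,
    base_seed=0,
    n_ancestors=8,
    max_population=128,
    noise_level=DEFAULT_NOISE_LEVEL,
    clock_noise_scale=1.0,
    model_id=2,
    kl001_factor=1.0,
):
    """One CMI condition: runs, per-run correlation table and CMI statistic."""
    control = reference_model(C1=C1, C2=C2, TCC=TCC, model_id=model_id)
    noise = reference_noise(control, noise_level,
                            clock_noise_scale=clock_noise_scale)
    spec = apply_kl001(control, kl001_factor) if kl001_factor > 1 else control
    runs = ensemble(spec, noise, n_runs=n_runs, base_seed=base_seed,
                    n_ancestors=n_ancestors,
                    stop={"max_population": max_population})
    table = correlation_table(runs, C1=C1, C2=C2, TCC=TCC,
                              kl001_factor=kl001_factor)
    return {"runs": runs, "correlations": table, "cmi": cmi(runs),
            "imt": imt_stats(runs)}


def kl001_cmi_experiment(
    factors=(1.0, 1000.0),
    TCC=15.0,
    C1=0.55,
    n_runs=20,
    base_seed=0,
    n_ancestors=8,
    max_population=128,
    noise_level=DEFAULT_NOISE_LEVEL,
):
    """CMI, IMT statistics and growth rate across a KL001 dose ladder.

    The control (factor 1) and all doses share noise calibrated on the
    control system and the same derived seed schedule, so dose effects are
    paired.
    """
    control = reference_model(C1=C1, C2=0.0, TCC=TCC)
    noise = reference_noise(control, noise_level)
    out = {}
    rows = []
    for f in factors:
        spec = apply_kl001(control, float(f)) if f > 1 else control
        runs = ensemble(spec, noise, n_runs=n_runs, base_seed=base_seed,
                        n_ancestors=n_ancestors,
                        stop={"max_population": max_population})
        stat = cmi(runs)
        st = imt_stats(runs)
        lams = [growth_rate_of_run(r).lam for r in runs]
        out[float(f)] = {"runs": runs, "cmi": stat, "imt": st,
                         "lambdas": np.array(lams)}
        rows.append({"kl001_factor": float(f), "cmi_median": stat.median,
                     "imt_mean": st["mean"], "imt_cv": st["cv"],
                     "lambda_median": float(np.median(lams))})
    return {"by_factor": out, "summary": pd.DataFrame(rows)}


def growth_experiment(
    C1_grid=(0.0, 0.2, 0.4, 0.55),
    TCC=20.0,
    n_runs=12,
    base_seed=0,
    n_ancestors=8,
    max_population=128,
    noise_level=DEFAULT_NOISE_LEVEL,
):
    """Proliferation rate versus forward coupling strength."""
    rows = []
    for c1 in C1_grid:
        spec = reference_model(C1=c1, C2=0.0, TCC=TCC)
        noise = reference_noise(spec, noise_level)
        runs = ensemble(spec, noise, n_runs=n_runs, base_seed=base_seed,
                        n_ancestors=n_ancestors,
                        stop={"max_population": max_population})
        lams = np.array([growth_rate_of_run(r).lam for r in runs])
        rows.append({"C1": c1, "lambda_median": float(np.median(lams)),
                     "lambda_sd": float(lams.std(ddof=1)), "n_runs": n_runs})
    df = pd.DataFrame(rows)
    ref = df.loc[df.C1 == df.C1.min(), "lambda_median"].iloc[0]
    df["lambda_pct_change"] = 100.0 * (df["lambda_median"] - ref) / ref
    return df


def phase_proportion_experiment(
    TCC=20.0,
    C1=0.55,
    n_ancestors=100,
    t_max=96.0,
    base_seed=0,
    zeitgeber_seed=None,
    noise_level=DEFAULT_NOISE_LEVEL,
    dt=0.02,
    ancestor_mode="clock_synced",
):
    """Cell-cycle phase proportions over time from a shared-zeitgeber population.

    Ancestors share the clock phase of one burn-in trajectory (the common
    circadian time of the culture) while their cell-cycle states are drawn
    at independent random phases.  ``zeitgeber_seed`` pins the shared clock
    phase so different conditions can be compared at a common circadian
    reference; it defaults to ``base_seed``.
    """
    if zeitgeber_seed is None:
        zeitgeber_seed = base_seed
    spec = reference_model(C1=C1, C2=0.0, TCC=TCC)
    noise = reference_noise(spec, noise_level)
    burn = IntegratorConfig(dt=dt, t_max=360.0, record_every=10,
                            seed=zeitgeber_seed)
    anc = burn_in_ensemble(spec, noise, burn, n_ancestors, mode=ancestor_mode)
    seed = run_seed(base_seed, 0)
    run = run_lineage(spec, noise, n_ancestors=n_ancestors,
                      stop={"max_time": t_max}, seed=seed, ancestors=anc,
                      config=IntegratorConfig(dt=dt, t_max=t_max, seed=seed))
    return phase_proportion_analysis(run)


# --------------------------------------------------------------------------
# config-driven dispatcher
# --------------------------------------------------------------------------


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Dispatch a named experiment and write CSV outputs.

    Outputs land in ``out_dir`` (default ``config.out_dir``) together with
    a YAML echo of the configuration; every table carries the config hash.
    Rerunning with the same config reproduces bit-identical tables.
    """
    import pathlib

    out = pathlib.Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    h = config.hash()
    tables = {}
    name = config.experiment

    if name == "entrainment":
        spec = reference_model(C1=0.0, C2=0.0, TCC=config.autonomous_TCC,
                               model_id=config.model_id,
                               overrides=config.overrides)
        fwd = entrainment_curve(spec, "C1",
                                np.round(np.arange(0, 0.81, 0.1), 2))
        rev = entrainment_curve(spec, "C2", [0, 1, 2, 3, 4, 5])
        tables["entrainment_forward"] = fwd
        tables["entrainment_reverse"] = rev
    elif name == "cmi":
        res = cmi_experiment(
            C1=config.C1, C2=config.C2, TCC=config.autonomous_TCC,
            n_runs=config.n_runs, base_seed=config.base_seed,
            n_ancestors=config.n_ancestors,
            max_population=config.stop.get("max_population", 128),
            noise_level=config.noise_level,
            clock_noise_scale=config.clock_noise_scale,
            model_id=config.model_id)
        tables["correlations"] = res["correlations"]
        tables["cmi"] = pd.DataFrame(
            {"delta": res["cmi"].deltas}).assign(median=res["cmi"].median)
    elif name == "kl001_sweep":
        spec = reference_model(C1=config.C1, C2=0.0, TCC=config.autonomous_TCC,
                               model_id=config.model_id)
        dr = kl001_dose_response(spec, config.kl001_factors)
        tables["dose_response"] = dr.to_frame()
        res = kl001_cmi_experiment(
            factors=config.kl001_factors, TCC=config.autonomous_TCC,
            C1=config.C1, n_runs=config.n_runs, base_seed=config.base_seed,
            n_ancestors=config.n_ancestors,
            max_population=config.stop.get("max_population", 128),
            noise_level=config.noise_level)
        tables["kl001_lineages"] = res["summary"]
    elif name == "growth":
        tables["growth"] = growth_experiment(
            TCC=config.autonomous_TCC, n_runs=config.n_runs,
            base_seed=config.base_seed, n_ancestors=config.n_ancestors,
            max_population=config.stop.get("max_population", 128),
            noise_level=config.noise_level)
    elif name == "phases":
        pps = phase_proportion_experiment(
            TCC=config.autonomous_TCC, C1=config.C1,
            n_ancestors=max(config.n_ancestors, 100),
            base_seed=config.base_seed, noise_level=config.noise_level,
            dt=max(config.dt, 0.02))
        tables["phase_fractions"] = pd.DataFrame({
            "time": pps.times, "G1": pps.fractions[:, 0],
            "SG2": pps.fractions[:, 1], "M": pps.fractions[:, 2],
            "alive": pps.alive})
        tables["phase_summary"] = pd.DataFrame([{
            "m_dominant_period": pps.m_spectrum.period,
            "lambda": pps.growth.lam,
            **{f"ergodic_{k}": v for k, v in pps.ergodic.items()},
            **{f"duration_{k}": v for k, v in pps.mean_durations.items()}}])
    elif name == "simulate":
        spec = reference_model(C1=config.C1, C2=config.C2,
                               TCC=config.autonomous_TCC,
                               model_id=config.model_id,
                               overrides=config.overrides)
        noise = reference_noise(spec, config.noise_level)
        seed = run_seed(config.base_seed, 0)
        run = run_lineage(spec, noise, n_ancestors=config.n_ancestors,
                          stop=dict(config.stop), seed=seed,
                          config=IntegratorConfig(dt=config.dt, t_max=480.0,
                                                  seed=seed))
        from .io import tree_to_frame, export_tree

        export_tree(run, out / "lineage.csv", "csv")
        export_tree(run, out / "lineage.nwk", "newick")
        tables["cells"] = tree_to_frame(run.tree)
    else:
        raise ValueError(f"experiment {name!r} has no dispatcher")

    for key, df in tables.items():
        df = df.copy()
        df["config_hash"] = h
        df.to_csv(out / f"{key}.csv", index=False)
        log.info("wrote %s (%d rows)", out / f"{key}.csv", len(df))
    return tables
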