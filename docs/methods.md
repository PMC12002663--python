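# Methods

This note documents the models, the calibration contract, the numerical
choices and the limitations of `chronocycle`. It is the package's own
account of its science; every number quoted here is computed by the code
(tests, examples or `scripts/acceptance.py`), not asserted.

## Models

All variants are systems of ODEs with Hill-type transcription regulation
and Michaelis–Menten (plus first-order) degradation, converted to SDEs in
the chemical Langevin framework. Concentrations are in arbitrary units;
rates in 1/h or conc/h.

### Circadian clock

The pacemaker is a three-stage Goodwin-type PER-CRY loop: *Per/Cry* mRNA
(M_P) is translated to cytoplasmic PER-CRY (P_C), which is imported into
the nucleus (P_N) and represses its own transcription with Hill
coefficient 4:

    dM_P/dt = v_mp K^4/(K^4 + P_N^4) − vd_mp M_P/(Kd + M_P)
    dP_C/dt = ks_pc M_P − vd_pc P_C/(Kd + P_C) − d_leak P_C
    dP_N/dt = k_imp P_C − vd_pn P_N/(Kd + P_N) − d_leak P_N

The saturable (zero-order) degradation terms are essential for a limit
cycle at n = 4; `d_leak` (0.05/h) is a small non-saturable turnover (see
KL001 below). In Model 2/3 a secondary loop carries BMAL1-CLOCK (B):
REV-ERBα protein represses *Bmal1* transcription (Hill n = 1), *Rev-erbα*
transcription is activated by B (n = 2) and gated by the reverse coupling
(see below), and nuclear PER-CRY inactivates B with a saturating Hill
term (n = 4, threshold K_ib = 2). Two properties were imposed when fixing
the loop's rate constants:

* with P_N frozen, the secondary loop is a *stable follower* (no
  autonomous oscillation) — steeper Hill slopes or slower kinetics turn
  it into an independent oscillator or produce period-doubled responses
  to reverse forcing;
* the loop acts as a homeostat whose fixed point under saturating PER-CRY
  inhibition is close to the mean of the oscillating control (B* ≈ ⟨B⟩ ≈
  0.3), which is what keeps the forward coupling alive when the clock
  rhythm is abolished.

BMAL1-CLOCK peaks about half a clock period away from nuclear PER-CRY
(direct inactivation), matching the canonical anti-phase relation. In
Model 1 there is no REV-ERB loop; B is synthesised constitutively and
inactivated by P_N, so it oscillates as a slave of the PER-CRY loop. (A
strictly constant B would transmit no rhythm through the forward coupling
and Model 1 could not produce any lineage-correlation phenotype, which is
why the constant-level option was rejected.)

### Cell cycle

Models 1–2 use a two-variable MPF relaxation oscillator: MPF (M) has a
basal activation, a positive self-activation (Hill n = 2) and three
inactivation routes — WEE1-dependent (saturating in W), APC-dependent
(mass action in the APC-like activity A) and first-order; A is activated
by MPF and decays:

    dM/dt = ks_m + v_m M²/(K² + M²) − [k_w W/(K_w + W) + k_a A + d_m] M
    dA/dt = v_a M²/(K² + M²) − d_a A

The cycle is a slow creep of M along its low branch (G1), a fast
self-activated spike (entry into M phase) and an APC-driven collapse.
The APC time constant is deliberately short relative to the cycle
(d_a = 0.2/h): division fires at a fixed MPF level, so the daughter's
cell-cycle state is pinned by the threshold and almost no cell-cycle
memory crosses a division. With a slower APC the oscillator transmits an
*anti-correlated* state across generations, which by itself generates a
cousin-versus-mother-daughter correlation difference with no clock at all
— exactly the artefact the uncoupled and reverse-coupled controls must
exclude.

Model 3 replaces the basal MPF activation by a CycD→CycE→CycA cascade
feeding CycB/CDK1 (which keeps the species name MPF), adds p21 as a
shared Cdk inhibitor, and lets REV-ERBα repress p21 synthesis — the
second forward-coupling route.

### Coupling

* Forward (`C1`): *Wee1* transcription = v_mw0 + C1·v_mw1·B²/(K_wb²+B²);
  WEE1 protein inactivates MPF. Dimensionless multiplier on the activated
  term, 0 = uncoupled.
* Reverse (`C2`, Models 2–3): *Rev-erbα* transcription is multiplied by
  1/(1 + C2·M/K_c2). The soft (n = 1) gate is what allows clean 1:1
  entrainment of the clock's secondary loop; sharper gates drive it into
  a 2:1 subharmonic.

## Calibration contract

Free parameters are pinned by behaviour, not by a published table:

1. **Periods.** `build_model` measures the uncoupled deterministic base
   periods once (LSODA, peak-to-peak) and stores per-module time-scale
   factors `s_clock`, `s_cc` multiplying every clock-module (resp.
   MPF-module) rate. Rescaling an autonomous subsystem's rates by `s`
   rescales its period by exactly 1/s, so the clock runs at 24.00 h and
   the cell cycle at the requested `autonomous_TCC` to within the
   peak-measurement error (≪ 0.1 h). `set_autonomous_period` reuses the
   cached base period; the Wee1 branch is part of the coupling interface
   and is not rescaled.
2. **Entrainment.** The Wee1 gain v_mw1 = 0.8 places the completion of
   the deterministic TCC = 20 h entrainment transition exactly at
   C1 = 0.55: the MPF frequency moves from 1/20 h⁻¹ through intermediate
   quasiperiodic values and reads 1/24 h⁻¹ for C1 ≥ 0.55. This boundary
   placement matters: with locking completing much below 0.55 the locked
   state is so stable that phase diversity — and with it the cousin–
   mother inequality at TCC = 20 — collapses.
3. **Noise.** Constant-mode noise uses per-species amplitudes
   σ_i = level × (half peak-to-trough range of species i on the
   deterministic attractor), with a single calibration knob
   `DEFAULT_NOISE_LEVEL = 0.065` chosen so the pooled IMT CV at the
   reference condition (C1 = 0.55, TCC = 20 h) lies mid-way in the
   0.10–0.20 HCT116 band (measured ≈ 0.17; at the TCC = 15 h condition
   the pooled IMT distribution is unimodal with mean ≈ 16.4 h, matching
   the ≈ 16.5 h HCT116 average). State-dependent mode uses
   g_i = √((production_i + degradation_i)/Ω) from the term-level
   decomposition that the model definitions expose.

## KL001

`apply_kl001(spec, f)` divides the Michaelis–Menten degradation Vmax of
cytoplasmic and nuclear PER-CRY by `f` (f = 1 is the control; the map is
multiplicative under composition). The first-order `d_leak` term is *not*
divided: the drug blocks the ubiquitin-mediated route specifically, and
the residual turnover is what keeps the saturated system bounded with
clock proteins settling at finite non-zero levels — the property that
preserves the mean WEE1 drive, and hence the mean cycle time and growth
rate, at saturating dose.

Dose–response protocol: the control system is relaxed onto its attractor,
the dose is switched on, and the BMAL1-CLOCK reporter (the *Bmal1*-
luciferase analogue) is recorded for 240 h. The period is the mean of the
final ≤ 3 peak-to-peak intervals; the amplitude is half the mean
peak-to-trough of those cycles; fewer than two discernible peaks, or an
amplitude below 1 % of control, is reported non-oscillatory. Under this
protocol the period jumps abruptly (24.3 → 29.6 h at the first dose step)
and then becomes undefined, while the amplitude collapses to ≤ 1 % of
control by factor 2 and stays there — the amplitude dies earlier in dose
than the period rises, so intermediate doses reduce clock amplitude with
little period change. The *Per/Cry* mRNA readout additionally reveals a
~1 % amplitude, ~66 h remnant cycle through the leak pathway at very high
dose; remnant oscillations at high dose are also an experimental
observation, but they are excluded from the headline amplitude by using
the Bmal1 reporter.

## Lineage engine

Phase thresholds default to 20 % (θ_S, also the division trigger θ_div)
and 60 % (θ_M) of the deterministic uncoupled MPF peak. M is latched:
once MPF crosses θ_M the cell remains in M until the downward crossing of
θ_div fires division; daughters inherit the mother's state verbatim and
start in G1 just below θ_S. Ancestors are sampled from a burned-in
trajectory (≥ 10 clock periods) at uniform random times, giving
phase-randomised (Rayleigh-uniform) initial conditions; ancestor "IMTs"
are truncated at t = 0 and are excluded from every statistic. Stops:
`max_population` (divisions processed in chronological order; the run is
cut at the division that reaches the cap, and all later divisions are
censored) or `max_time`. Cells that fail to divide within 10×TCC are
flagged arrested and censored. Each cell draws noise from its own PCG64
stream spawned from (run seed, cell id), so runs are bit-reproducible
regardless of scheduling. Negative Euler–Maruyama excursions are clipped
to zero after each step.

Default dt = 0.01 h (≤ 1/1000 of the fastest period of interest); the
large phase-fraction populations use dt = 0.02 h (1/600 of a 12 h cycle),
which changes deterministic periods by ≲ 0.1 h. The Euler kernels are
numba-compiled and verified against the pure-numpy rate laws to 1e-13.

## Statistics

Pairs are extracted from the lineage forest with both IMTs defined
(uncensored, non-ancestor): sisters share a mother; cousins share a
grandmother but not a mother; (great-)grandmother pairs are 2 (3)
generations apart with the ancestor in slot a. Symmetric relations enter
the Pearson correlation in both orders. Correlations are per run (pairs
pooled across the run's ancestors); ensembles are across runs, summarised
by medians, with percent changes of medians between conditions. A
correlation with fewer than 3 pairs or a degenerate margin is undefined
and the run is dropped from that statistic.

## Phase-fraction analysis and the ergodic baseline

Population rhythms require a shared circadian reference: with ancestors
uniformly phase-randomised the per-lineage rhythms cancel by symmetry. The
`clock_synced` burn-in mode therefore gives every ancestor the clock-module
state of a single reference time (a culture with common zeitgeber history)
while sampling each ancestor's cell-cycle-module state at an independent
random phase. The composite states are off-attractor for at most a few
hours of relaxation.

The ergodic baseline predicts the fraction of cells in an age interval
[a₁,a₂) of a T-hour cycle as (e^{−λa₁} − e^{−λa₂})/(1 − e^{−λT}); with
λ = ln2/T this is the young-cell-enriched form 2(e^{−λa₁} − e^{−λa₂}) and
a full partition sums to one. Phase boundaries are taken from the
*deterministic-limit* phase durations at the run's coupling: under noise
the G1 escape is partly noise-driven, the per-cell G1 duration
distribution is strongly right-skewed, and length-biased sampling makes
the measured mean dwell time much shorter than the occupancy share — the
deterministic durations are the inputs for which the uncoupled simulation
matches the prediction within Monte-Carlo error.

Dominant periods of fraction series are read from the detrended,
Hann-tapered FFT. For across-condition comparisons the acceptance script
averages the M-fraction series over four replicate populations sharing
the zeitgeber before the FFT: division waves (bunched division cohorts at
the mean cycle time) have replicate-specific phases and decohere, while
the clock-locked component adds coherently. Peak phases of the 24 h
component are obtained by quadrature demodulation, with offsets folded
into (−12, 12] h.

## Study conditions and problem sizes

Desk-scale conditions used throughout tests and the acceptance script:
ensembles of 20–40 runs, 8 ancestors per run, population caps 128–256
(giving ≈ 10²–10³ cousin pairs per run), 100-ancestor populations over
96 h for phase fractions, and the seed schedule derived from a single base
seed. The full-scale profile (100 runs, cap 256) is a configuration away
(`ExperimentConfig.with_profile("full")`). Boxplot-style ensemble
statistics at 20 runs carry substantial sampling error (the per-run CMI
delta has SD ≈ 0.1–0.25 depending on tree depth); medians of
percent-changes between small ensembles inherit that noise.

## Known limitations

* The kinetic skeletons and every rate constant are this package's own,
  pinned by the behavioural contract above; absolute correlation values
  are not meaningful, only their qualitative structure (this limitation
  is shared by the model class itself).
* Reverse entrainment is carried by the REV-ERBα/BMAL1 secondary loop;
  the PER-CRY core receives no afferent input in this skeleton and keeps
  its 24 h rhythm even when BMAL1-CLOCK is entrained to the cell cycle.
* At TCC = 12 h the coupled population's M-fraction is dominated by
  division waves near the mean cycle time (~13.5 h) that are partially
  locked to the daily gate; the 24 h clock component is present but
  usually subdominant, unlike at TCC = 20 and 24 h where the M-fraction
  rhythm is cleanly circadian. Fast-cycling populations are therefore the
  least faithful regime of this implementation.
* At saturating KL001 the cousin–mother inequality is abolished almost
  completely (≈ −85 % to −100 % median change) rather than halved: once
  the clock rhythm is flat, the remaining BMAL1-CLOCK fluctuations are
  too fast to carry heritable gating correlations in this skeleton.
* The cell-cycle phase thresholds make M comparatively long (~20 % of the
  cycle) and S/G2 short; they are a documented stand-in, and all
  phase-fraction conclusions are about rhythmicity, not absolute phase
  shares.
* Symmetric inheritance without partitioning noise, no cell death or
  quiescence, no cell-size mechanics, and Michaelis–Menten propensities
  inside a Langevin approximation (no exact stochastic simulation of
  elementary reactions).
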