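"""KL001 clock inhibition: dose response, lineage correlations, growth.

KL001 stabilises CRY; the model divides the PER-CRY complex degradation
rates by a dose factor (1 = control).  The deterministic dose-response
shows the clock period jumping abruptly and the amplitude collapsing
toward zero, while stochastic lineages at TCC = 15 h show the CMI
shrinking strongly at saturating dose with almost no change in the
population growth rate — the signature separating lineage-correlation
readouts from bulk proliferation readouts.
"""

import warnings

import numpy as np

import chronocycle as cc
from chronocycle.lineage import ArrestedCellWarning

warnings.simplefilter("ignore", ArrestedCellWarning)

spec = cc.reference_model(C1=0.55, C2=0.0, TCC=15)
dr = cc.kl001_dose_response(spec, (1, 2, 5, 10, 100, 1000))
print("deterministic dose response (BMAL1-CLOCK reporter):")
for f, per, amp in zip(dr.factors, dr.period, dr.amplitude):
    rel = amp / dr.control_amplitude
    ptxt = f"{per:6.1f} h" if np.isfinite(per) else "   --  "
    print(f"  factor {f:6.0f}: period {ptxt}  amplitude {rel:6.1%} of control")

res = cc.kl001_cmi_experiment(factors=(1.0, 1000.0), TCC=15, n_runs=20,
                              base_seed=23, max_population=128)
ctrl = res["by_factor"][1.0]
hi = res["by_factor"][1000.0]
print(f"\nlineage ensembles (20 runs each): control CMI median "
      f"{ctrl['cmi'].median:+.3f}, saturating dose {hi['cmi'].median:+.3f}"
      f"  ({hi['cmi'].percent_change_vs(ctrl['cmi']):+.0f} % change)")
dl = 100 * (np.median(hi["lambdas"]) - np.median(ctrl["lambdas"])) \
    / np.median(ctrl["lambdas"])
print(f"growth rate change at saturating dose: {dl:+.2f} % "
      f"(lambda = {np.median(ctrl['lambdas']):.4f} /h in control)")
print(f"IMT CV: control {ctrl['imt']['cv']:.3f} -> "
      f"dose 1000 {hi['imt']['cv']:.3f} (variability shrinks)")
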