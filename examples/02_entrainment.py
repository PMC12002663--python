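"""Mutual entrainment of the two oscillators.

Sweeps the forward coupling C1 (clock -> cell cycle via WEE1) and the
reverse coupling C2 (cell cycle -> clock via MPF repression of Rev-erba)
and prints the dominant oscillation frequency of the driven oscillator.
Forward: the MPF frequency moves from 1/20 h^-1 to 1/24 h^-1 (the cell
cycle adopts the clock period).  Reverse: the BMAL1-CLOCK frequency moves
from 1/24 to 1/20 h^-1 (the clock's secondary loop adopts the cell-cycle
period).
"""

import chronocycle as cc

spec = cc.build_model(2, C1=0.0, C2=0.0, autonomous_TCC=20)

fwd = cc.entrainment_curve(spec, "C1", [0.0, 0.2, 0.3, 0.4, 0.5, 0.55, 0.7])
print("forward sweep (MPF frequency):")
for _, row in fwd.iterrows():
    print(f"  C1={row.C1:4.2f}  1/f = {1 / row.frequency:6.2f} h")

rev = cc.entrainment_curve(spec, "C2", [0.0, 1.0, 2.0, 3.0, 4.0,
                                        cc.REVERSE_C2_HIGH])
print("reverse sweep (BMAL1-CLOCK frequency):")
for _, row in rev.iterrows():
    print(f"  C2={row.C2:4.2f}  1/f = {1 / row.frequency:6.2f} h")
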