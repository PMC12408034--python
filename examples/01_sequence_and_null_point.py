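"""Inversion-recovery timing: the white-matter null and per-spoke weights.

Builds the default tissue table, solves the long-T2 white-matter null
inversion time, and prints the steady-state longitudinal magnetization of
each tissue across the 21-spoke segment together with the dual-echo signal
weights that echo subtraction exploits.
"""
import numpy as np

import irute as ir
from irute.phantom import DEFAULT_TISSUES

seq = ir.SequenceParams()  # 15 deg, TR 1000 ms, TI 379.9 ms, 21 spokes/segment

wm = next(t for t in DEFAULT_TISSUES if t.name == "WM_L")
print(f"WM_L null point: ti_null(T1={wm.t1_ms:.0f} ms, TR={seq.tr_ms:.0f} ms) "
      f"= {ir.ti_null(wm.t1_ms, seq.tr_ms):.1f} ms")
print(f"(the protocol's TI; spokes span TI +/- {(seq.spokes_per_segment - 1) / 2 * seq.spoke_interval_ms:.0f} ms)\n")

print(f"{'tissue':8s} {'Mz[first]':>10s} {'Mz[center]':>11s} {'Mz[last]':>9s} "
      f"{'w(TE1)':>9s} {'w(TE2)':>9s}")
for t in DEFAULT_TISSUES:
    if t.pd == 0:
        continue
    mz = ir.steady_state_mz(seq, t)
    c = seq.spokes_per_segment // 2
    w1 = ir.signal_weight(seq, t, c, seq.te1_ms, mz=mz)
    w2 = ir.signal_weight(seq, t, c, seq.te2_ms, mz=mz)
    print(f"{t.name:8s} {mz[0]:+10.4f} {mz[c]:+11.4f} {mz[-1]:+9.4f} "
          f"{w1:+9.5f} {w2:+9.5f}")

print("\nLong-T2 tissues are near zero at the segment center (nulled) and"
      "\nchange little between TE1 and TE2, so the complex echo difference"
      "\ncancels them; saturated short-T2* pools (myelin, bone) recover fast,"
      "\ncarry large weight at TE1 and have vanished by TE2 - the difference"
      "\nis the myelin-specific signal.")
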