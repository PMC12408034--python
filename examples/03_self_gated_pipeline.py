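"""End-to-end self-gated acquisition with intentional head nods.

Encodes a nodding-head IR-UTE acquisition (bit-reversed ordering), derives
the per-segment motion metric from the SI self-navigator, gates, and
compares gated vs ungated myelin reconstructions against the motion-free
reference.
"""
import numpy as np

import irute as ir
from irute.nufft import GriddingNufft

N = 64
ph = ir.build_default_phantom(N, n_lesions=4, seed=1)
seq = ir.SequenceParams(matrix_size=N)
sched = ir.make_schedule(692, 21, "bit_reversed")  # 33 segments = 33 s scan
trace = ir.make_nod_trace(sched.n_segments, tr_ms=seq.tr_ms)  # nod every 20 s
print(f"scan: {sched.n_spokes} spokes, {sched.n_segments} segments "
      f"({ir.scan_duration_s(sched.n_spokes, 21, seq.tr_ms):.0f} s); "
      f"head moves in segments {np.nonzero(trace.moving)[0].tolist()}")

peak = float(ph.pd_map().sum(axis=1).max())
nav = ir.simulate_navigator(ph, trace, noise_sd=0.001 * peak, seed=2)
metric, ref_px = ir.navigator_metric(nav)
gate = ir.threshold_gate(metric, sched, "robust", 3.0)
print(f"navigator reference pixel {ref_px}; gate rejected "
      f"{gate.n_rejected_spokes}/{sched.n_spokes} spokes "
      f"({100 * gate.rejected_fraction:.1f}%) in segments "
      f"{np.nonzero(~gate.keep_segment)[0].tolist()}")

nufft = GriddingNufft(N)
masks = ir.roi_masks(ph)
reference = ir.recon_dual_echo(ir.encode(ph, seq, sched), nufft=nufft)
ks_mov = ir.encode(ph, seq, sched, motion=trace)
ungated = ir.recon_dual_echo(ks_mov, nufft=nufft)
gated = ir.recon_dual_echo(ks_mov, gate=gate, nufft=nufft)

for name, result in (("ungated (motion-corrupted)", ungated),
                     ("gated (self-navigated)", gated)):
    m = ir.image_metrics(result, reference, masks)
    print(f"{name:27s}: myelin NRMSE vs motion-free reference "
          f"{m['nrmse_vs_reference']:.4f}, myelin-mask mean "
          f"{m['myelin_mask_mean']:.4f}")

m = ir.image_metrics(reference, reference, masks)
print(f"\nmotion-free reference myelin/CSF contrast: "
      f"{reference.myelin_img[masks['myelin']].mean() / reference.myelin_img[masks['csf']].mean():.1f}x")
print("Discarding the navigator-flagged segments removes the motion error"
      "\nat the cost of ~6% of the data; with bit-reversed ordering that"
      "\nloss is benign (incoherent), so the gated image is closer to the"
      "\nmotion-free reference than the ungated one despite using fewer"
      "\nspokes. Longer scans with more nods widen the margin.")
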