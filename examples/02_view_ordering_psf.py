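"""Sequential vs bit-reversed view ordering under retrospective gating.

Rejects a contiguous 10% block of acquisition slots (what a motion episode
costs) from both orderings of the same radial trajectory and compares the
resulting k-space angular gap and point-spread-function side-lobes.
"""
import math

import numpy as np

import irute as ir

N = 64
n_spokes = ir.nyquist_spokes(N)
print(f"matrix {N} -> {n_spokes} Nyquist spokes, 21 per segment\n")

perm = ir.bit_reverse_permutation(8)
print(f"bit reversal of 0..7: {perm.tolist()} (pseudo-random, self-inverse)\n")

gate = None
for scheme in ("sequential", "bit_reversed"):
    sched = ir.make_schedule(n_spokes, 21, scheme)
    gate = ir.reject_contiguous_segments(sched, 0.10, start_segment=3)
    kept = sched.angles_acquired[gate.keep_spoke]
    gap = ir.max_angular_gap(kept)  # modulo pi
    _, pslr = ir.psf(sched, N, gate=gate)
    print(f"{scheme:13s}: rejected {gate.n_rejected_spokes}/{n_spokes} spokes, "
          f"max angular gap {gap / math.pi:.3f}*pi, "
          f"PSF peak side-lobe ratio {pslr:.3f}")

_, pslr_full = ir.psf(ir.make_schedule(n_spokes, 21, "sequential"), N)
print(f"\n(full sampling side-lobe ratio for reference: {pslr_full:.3f})")
print("Sequential rejection carves one angular wedge out of k-space and the"
      "\nPSF grows coherent side-lobes (streaks); bit-reversal scatters the"
      "\nsame loss over azimuth and the PSF stays close to the fully sampled"
      "\none.")
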