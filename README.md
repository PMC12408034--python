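# irute — self-gated IR-UTE direct myelin imaging, simulated end to end

Myelin protons have T2\* below ~0.3 ms at 3 T and are invisible to
conventional MRI. Inversion-recovery-prepared ultrashort-echo-time
(IR-UTE) imaging detects them directly: an adiabatic inversion nulls the
long-T2 white-matter water at a chosen inversion time TI, a center-out
radial readout catches the signal within tens of microseconds of
excitation, and subtracting a second echo (by which time the myelin signal
has fully decayed) cancels whatever long-T2 signal survives the null. The
price is a ~10-minute scan (TR ≈ 1 s per inversion segment), which makes
the already low-SNR myelin images very sensitive to head motion.

`irute` is a simulation and reconstruction toolbox for the two sequence
modifications that make this acquisition motion-robust **without extra
hardware or scan time**:

* a **superior–inferior (SI) self-navigator** — a projection readout at the
  tail of every segment whose profile tracks head position, enabling
  retrospective rejection of motion-corrupted segments, and
* **bit-reversed view ordering** — permuting the spoke acquisition order by
  reversing the binary spoke index, so that the temporally contiguous data
  loss caused by gating is scattered pseudo-randomly over k-space azimuth
  instead of carving out one coherent wedge.

It is aimed at sequence developers and reconstruction researchers who want
a quantitative, fully synthetic testbed for these mechanisms: a six-tissue
digital head phantom, an analytic Bloch model of the segmented
inversion-recovery experiment, exact k-space motion injection, navigator
simulation, robust threshold gating, and density-compensated gridding
reconstruction with PSF and image-quality metrics.

## The model in brief

Per TR: ideal inversion (Mz → −Mz for long-T2 tissues; Mz → 0 for
sub-millisecond-T2\* pools like myelin and cortical bone, which an
adiabatic pulse saturates rather than inverts), free T1 recovery, then S
excitations of flip angle α spaced τ apart centered on TI. Everything is
affine in Mz, so the steady state across TRs is the closed-form fixed
point of the per-TR map. The tissue null satisfies

    TI = T1 · ln( 2 / (1 + e^(−TR/T1)) )

which for white matter (T1 = 1000 ms, TR = 1000 ms) gives TI = 379.9 ms.
Spoke `j` of a segment contributes transverse signal

    w = pd · sin α · Mz[slot] · exp(−t / T2*)

per readout sample at time `t` after excitation; the encoder evaluates
each tissue map's nonuniform Fourier transform (Kaiser–Bessel convolution
gridding, 2× oversampling) and weights it per spoke/echo/sample. A
trajectory of `ceil(π·N)` center-out spokes (692 for N = 220) samples the
circular k-space at the azimuthal Nyquist limit; the myelin image is the
magnitude of the complex echo-1 − echo-2 difference.

## Worked example

`examples/03_self_gated_pipeline.py` runs the whole loop at a reduced
matrix (64×64, 692 spokes = 33 one-second segments, intentional head nods
every 20 s):

```text
scan: 692 spokes, 33 segments (33 s); head moves in segments [20, 21]
navigator reference pixel 27; gate rejected 42/692 spokes (6.1%) in segments [20, 21]
ungated (motion-corrupted) : myelin NRMSE vs motion-free reference 0.0713, myelin-mask mean 0.0173
gated (self-navigated)     : myelin NRMSE vs motion-free reference 0.0632, myelin-mask mean 0.0165

motion-free reference myelin/CSF contrast: 9.7x
```

The navigator metric (profile intensity at the fixed reference pixel)
drops by ~90 standard deviations during each nod, so robust thresholding
rejects exactly the moving segments; gating then brings the
reconstruction closer to the motion-free reference than using all data.
`examples/02_view_ordering_psf.py` isolates the ordering mechanism — the
same 10% contiguous rejection leaves a `0.109·π` angular hole (PSF
side-lobe ratio 0.079) under sequential ordering but only `0.010·π`
(side-lobe ratio 0.040, near the fully sampled 0.036) under bit-reversal —
and `examples/01_sequence_and_null_point.py` prints the per-tissue Mz and
dual-echo weights behind the contrast mechanism.

The same functionality is scriptable from the shell:

```bash
irute protocol                      # Nyquist spoke count, scan duration
irute simulate --matrix 64 --scheme bitrev --motion --seed 1 --out run/
irute gate  --run-dir run/          # navigator -> keep/reject mask
irute recon --run-dir run/          # echo1/echo2/myelin NIfTI images
irute run-arm --arm bitrev_motion_selfgated --matrix 64 --out arm3/
```

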