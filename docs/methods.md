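# Methods

## Signal model

The sequence modeled is a segmented dual-echo IR-UTE acquisition. Each TR
contains one inversion event followed, after a delay, by a train of `S`
hard-pulse excitations (flip angle α, spacing τ) centered on the
inversion time TI, each reading out two center-out radial echoes at TE1
and TE2. The Bloch dynamics used are:

* **Inversion.** Ideal: long-T2 tissues are inverted with efficiency −1;
  pools with sub-millisecond T2\* (myelin protons, cortical bone water)
  cannot follow an adiabatic sweep lasting several milliseconds and are
  modeled as exactly saturated (Mz → 0). No RF waveform is simulated.
* **Recovery and excitation.** Between events Mz relaxes exponentially
  toward M0 = 1; each excitation scales Mz by cos α (the
  `include_pulse_train_in_mz` switch disables this, yielding the pure
  inversion-recovery curve sampled at the slot times). Every event is
  affine in Mz, so the steady state over TRs is the fixed point of the
  composed affine map and is computed in closed form; the map's
  contraction factor is asserted at runtime. The slot `k` (0-based)
  fires at `TI + (k − (S−1)/2)·τ`: "TI" refers to the segment center.
* **Null point.** `ti_null` solves the zero crossing of the
  periodic-inversion steady state without the excitation-train
  correction, `TI = T1·ln(2/(1+exp(−TR/T1)))`. The default simulator
  *includes* the pulse train, so white matter is slightly off-null and a
  realistic long-T2 residual survives — echo subtraction, not perfect
  nulling, is the suppression mechanism being studied.
* **Readout.** Transverse magnetization is assumed fully spoiled between
  spokes. Sample `j` of echo `e` sees weight
  `pd·sin α·Mz[slot]·exp(−(TE_e + j·dwell)/T2*)`, so within-readout T2\*
  decay (significant for myelin, whose T2\* is shorter than the readout)
  is exact per tissue. Both echoes reuse the same center-out trajectory.

Off-resonance, chemical shift, B1 inhomogeneity, relaxation during RF,
and transverse coherence pathways are excluded.

## Phantom

A procedurally generated 2D label map with concentric anatomically
ordered shells — subcutaneous fat, skull, CSF, a gray-matter ribbon, and
a white-matter interior — plus two CSF ventricles and `n_lesions`
demyelinated lesion discs. Myelin co-exists with long-T2 white-matter
water: `Myelin`-labeled pixels carry both pools, and lesions relabel
Myelin → WM_L (myelin density zeroed, water unchanged). Default MR
parameters (pd / T1 ms / T2\* ms at 3 T):

| tissue | pd | T1 | T2\* | inversion response |
|---|---|---|---|---|
| CSF | 1.00 | 4000 | 2000 | invert |
| GM_L | 0.80 | 1400 | 60 | invert |
| WM_L | 0.65 | 1000 | 50 | invert |
| Myelin | 0.10 | 300 | 0.3 | saturate |
| Skull | 0.25 | 250 | 0.4 | saturate |
| Fat | 0.90 | 380 | 30 | invert |

These are representative literature values; WM_L T1 = 1000 ms is the
anchor that puts the white-matter null at TI = 379.9 ms for TR = 1 s.
Label maps are categorical and resampled only with nearest-neighbor
interpolation; derived continuous maps (proton density for the
navigator) use linear interpolation. Pixel convention: 0-based indices,
image center at `(N//2, N//2)`, k-space in cycles/FOV, rows = SI axis.

## Trajectory and view ordering

`ceil(π·N)` center-out spokes satisfy the azimuthal Nyquist criterion at
the k-space edge. Spoke angles follow `angles[i] = i·(π + π/n) mod 2π`:
successive angle indices alternate hemispheres while advancing by π/n
modulo π, giving full-circle coverage with spacing 2π/n per hemisphere
and — crucially for gap statistics on a real-valued object — `n`
*distinct* angles modulo π with uniform spacing π/n. (The naive
`2πi/n` layout places spokes `i` and `i+n/2` at identical angles modulo
π for even `n`, which makes angular-gap statistics degenerate:
conjugate-duplicate angles mask exactly the contiguous losses the gap
statistic exists to expose.) Sequential acquisition therefore sweeps
azimuth monotonically modulo π, and a contiguous rejected block opens a
single angular wedge of width ≈ fraction·π.

Bit-reversed ordering reverses the `B = ceil(log2 n)`-bit binary index
and compacts values ≥ n, preserving the pseudo-random spread for any
spoke count. Golden-angle and other alternative orderings are
deliberately out of scope.

## Encoding and motion

Per tissue class the occupancy map's Fourier transform is evaluated once
per distinct segment transform at all sample locations (type-2 gridding
NUFFT: 2× oversampled FFT, width-6 Kaiser–Bessel kernel with the Beatty
shape parameter, deapodization by the numerically integrated kernel
transform; agreement with a direct-summation DFT is ~1e−5 relative).
Rigid motion is constant within a segment — the navigator samples
position once per segment — and is injected *exactly* in k-space:
translations as phase ramps, rotations by rotating the sample
coordinates. This keeps Fourier-shift identities exact to numerical
interpolation accuracy and avoids resampling artifacts conflating with
motion artifacts. The nod generator emits periodic nods (default every
20 s, 2 s long, 15 mm SI translation + 8° in-plane rotation, ±20%
seeded amplitude jitter), with an option to settle at a displaced
position after the last nod instead of returning to baseline.

The navigator is modeled as the proton-density projection of the
(possibly moved) head onto the SI axis with additive Gaussian noise,
magnitude taken. Its placement at the segment tail keeps the tissue
weighting constant across segments, so a fixed pd-weighted contrast is
used rather than re-deriving the inversion-recovery weighting; it
occupies no imaging slot, so gating costs no scan time. The default
noise (0.1% of the baseline profile peak) reflects the very high SNR of
a whole-head projection; with the default nod amplitude the per-segment
metric separates moving from still segments by far more than the 10σ the
gating analysis assumes.

## Gating

The per-segment metric is the profile intensity at a fixed reference
pixel — the argmax of the first profile. Robust mode rejects segments
with `|metric − median| > k·σ̂`, where `σ̂ = max(1.4826·MAD,
0.002·|median|)`. The 1.4826 factor makes the MAD a consistent Gaussian
σ estimate, so the default k = 3 is a true 3σ gate (the raw MAD would
make it ~2σ and reject still segments on noise alone); the small
relative floor ignores metric fluctuations far below anything a
resolvable displacement produces and also handles the degenerate
constant-metric case gracefully. Rejection granularity is always the
whole segment, and a recorded mask can be re-applied to any k-space set
with the same schedule (the "reuse the motion trace on motion-free
data" experiment). A permanently shifted post-nod baseline stays
rejected by default; re-accepting a settled position would require
re-baselining, which is intentionally not applied.

## Reconstruction and metrics

Reconstruction is the density-compensated adjoint NUFFT (no iterative
or compressed-sensing step is modeled). Radial ramp
weights `[1/8, 1, 2, …]` per spoke (the 1/8 is the analytic
center-cell weight: the innermost half-radius disc shared by all
spokes, relative to the first ring annulus) are normalized over the
*full* sampling pattern so gated and ungated images share one intensity
scale and the fully sampled PSF has unit DC gain. The myelin image is
the magnitude of the complex echo difference (the simulation is
phase-consistent; magnitude-before-subtraction is available for noisy
data). The PSF of a sampling pattern is the adjoint image of all-ones
samples, peak-normalized; its side-lobe metric uses a fixed 3-pixel
main-lobe radius (about twice the fully sampled FWHM, insensitive to
apodization details; the fully sampled radial-ramp PSF itself retains a
first Gibbs ring of ~3.5% just outside that radius). `streak_energy` is
the summed squared difference-image intensity outside the head support:
coherent streaks radiate past the head, whereas dispersed (bit-reversed)
loss leaves only a low noise floor there — an energy measure separates
the two regimes cleanly, while total-variation-type measures do not
(noise has higher TV per unit energy than smooth streaks). ROI means
use masks eroded by 2 pixels (backing off where a structure is too thin
at small matrices) to exclude boundary partial-volume/ringing pixels.

## Problem sizes and numerics

The package defaults mirror the full protocol configuration (220×220,
692 spokes, 21 per segment, TI 379.9 ms, TE 0.03/3 ms, 250 kHz). The
test suite exercises mechanisms at N = 64 (202 Nyquist spokes) where the
spec'd oracle tolerances are unchanged — gridding vs direct DFT < 1%,
encoder vs closed-form disc transform < 1%, shift theorem 1e−6, Bloch
vs 1 µs Euler integration < 1e−4 — and the echo-subtraction contrast
checks run at the full 220×692 configuration. Analytic disc tests use
an anti-aliased (subpixel area-weighted) disc: a binary rasterization
differs from the continuous disc transform by ~3% in l2 over the
sampled band, which would measure rasterization rather than the
encoder.

## Known limitations

* 2D only; no partial-volume mixing in the generated phantom, no
  cortical folding, no through-plane motion, single coil, no gradient
  imperfections.
* The navigator model is pd-weighted and noise-limited; real navigator
  profiles carry inversion-recovery contrast, receive-coil shading and
  physiological fluctuations, so real metric SNR and threshold behavior
  will be less clean than the synthetic fixture.
* Skull bone, being a saturated short-T2\* pool, is intrinsically bright
  in the echo-subtraction image (brighter per pixel than myelin under
  these parameters, as in vivo). Its point-spread leakage sets the floor
  of the subtraction image inside the brain: in the fully demyelinated
  control, the brain-mask residual is dominated by skull leakage rather
  than by uncancelled long-T2 water. Quantitative myelin claims should
  therefore be referenced to interior ROIs away from the skull, and the
  package makes no attempt at quantitative myelin density estimation.
* Motion is rigid, in-plane and segment-constant; gating discards data
  and performs no motion *correction* (no phase-ramp repair, no
  multi-axis navigators).
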