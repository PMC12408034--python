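"""Synthesize dual-echo radial k-space and the SI self-navigator.

The encoder evaluates, per tissue class, the Fourier transform of the
tissue's indicator map at every radial sample location, then reweights
those values per spoke/echo/sample with the analytic Bloch signal weight
``pd * sin(alpha) * Mz[slot] * exp(-t/T2*)``.  This gives exact
within-readout T2* decay per tissue without per-spoke image transforms.

Rigid motion is applied per segment (the navigator samples position once
per segment, so the transform is constant within one) and is injected
*exactly* in k-space: a translation becomes a linear phase ramp, a
rotation rotates the sample coordinates.  The SI navigator is modeled as
the proton-density projection of the (possibly moved) head onto the
superior-inferior axis, one profile per segment.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .nufft import GriddingNufft
from .phantom import PhantomModel, RigidTransform, transform_continuous
from .sequence import SequenceParams, steady_state_mz
from .trajectory import SpokeSchedule, make_schedule


@dataclass
class MotionTrace:
    """Per-segment rigid transforms with ground-truth motion labels.

    ``moving[i]`` is True where the head is displaced from its reference
    position during segment ``i``; the transform is the identity wherever
    ``moving`` is False.  Segment ``i`` spans time ``[i, i+1) * TR``.
    """

    transforms: list[RigidTransform]
    moving: np.ndarray
    tr_ms: float = 1000.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=bool)
        if len(self.transforms) != self.moving.size:
            raise ValueError("transforms and moving labels disagree in length")
        for t, mv in zip(self.transforms, self.moving):
            if not mv and not t.is_identity:
                raise ValueError("non-identity transform on a segment labeled still")

    @property
    def n_segments(self) -> int:
        return len(self.transforms)

    @classmethod
    def still(cls, n_segments: int, tr_ms: float = 1000.0) -> "MotionTrace":
        return cls(
            transforms=[RigidTransform()] * n_segments,
            moving=np.zeros(n_segments, dtype=bool),
            tr_ms=tr_ms,
        )


def make_nod_trace(
    n_segments: int,
    tr_ms: float = 1000.0,
    nod_period_s: float = 20.0,
    nod_duration_s: float = 2.0,
    dy_mm: float = 15.0,
    dx_mm: float = 0.0,
    theta_deg: float = 8.0,
    amp_jitter: float = 0.2,
    seed: int = 0,
    return_to_baseline: bool = True,
) -> MotionTrace:
    """Periodic intentional head nods: every ``nod_period_s`` the head tips
    (SI translation ``dy_mm`` plus in-plane rotation ``theta_deg``) for
    ``nod_duration_s`` seconds, then returns to baseline (or, with
    ``return_to_baseline=False``, settles at half amplitude after the last
    nod — the "changed head position" case).  Per-nod amplitudes are
    jittered by ``amp_jitter`` (fractional, seeded)."""
    rng = np.random.default_rng(seed)
    tr_s = tr_ms / 1e3
    transforms: list[RigidTransform] = []
    moving = np.zeros(n_segments, dtype=bool)
    total_s = n_segments * tr_s
    nod_starts = np.arange(nod_period_s, total_s + nod_period_s, nod_period_s)
    nod_amps = 1.0 + amp_jitter * rng.uniform(-1.0, 1.0, size=nod_starts.size)
    last_nod_end = -np.inf
    for i in range(n_segments):
        t_mid = (i + 0.5) * tr_s
        t = RigidTransform()
        for start, amp in zip(nod_starts, nod_amps):
            if start <= t_mid < start + nod_duration_s:
                t = RigidTransform(amp * dx_mm, amp * dy_mm, amp * theta_deg)
                last_nod_end = max(last_nod_end, start + nod_duration_s)
                break
        if not return_to_baseline and t.is_identity and t_mid >= last_nod_end > 0:
            t = RigidTransform(0.5 * dx_mm, 0.5 * dy_mm, 0.5 * theta_deg)
        transforms.append(t)
        moving[i] = not t.is_identity
    return MotionTrace(
        transforms=transforms,
        moving=moving,
        tr_ms=tr_ms,
        seed=seed,
        params={
            "nod_period_s": nod_period_s,
            "nod_duration_s": nod_duration_s,
            "dy_mm": dy_mm,
            "dx_mm": dx_mm,
            "theta_deg": theta_deg,
            "amp_jitter": amp_jitter,
            "return_to_baseline": return_to_baseline,
        },
    )


@dataclass
class NavigatorSeries:
    """One SI projection profile per segment (magnitude, non-negative)."""

    profiles: np.ndarray      # (n_segments, matrix_size)
    segment_times_s: np.ndarray

    @property
    def n_segments(self) -> int:
        return int(self.profiles.shape[0])


@dataclass
class KSpaceSet:
    """Complex dual-echo radial samples plus geometry and timing.

    ``samples[slot, echo, j]`` is indexed by *acquisition slot*; the
    attached ``schedule`` maps slots to angles and segments.  Both echoes
    reuse the same center-out trajectory (the readout is rewound and
    re-ramped between echoes), so ``k_coords`` is shared and the first
    sample of echo 1 sits at |k| = 0.
    """

    samples: np.ndarray          # (n_spokes, 2, n_readout) complex
    k_coords: np.ndarray         # (n_spokes, n_readout, 2) cycles/FOV
    sample_times_ms: np.ndarray  # (2, n_readout)
    echo_times_ms: tuple[float, float]
    schedule: SpokeSchedule
    matrix_size: int

    @property
    def n_spokes(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_readout(self) -> int:
        return int(self.samples.shape[2])


def spoke_coordinates(schedule: SpokeSchedule, n_readout: int) -> np.ndarray:
    """Sample locations per acquisition slot: ``n_readout`` center-out
    samples at integer radii (cycles/FOV) along each spoke direction."""
    angles = schedule.angles_acquired
    radii = np.arange(n_readout, dtype=float)
    coords = np.empty((schedule.n_spokes, n_readout, 2))
    coords[..., 0] = radii[None, :] * np.cos(angles)[:, None]
    coords[..., 1] = radii[None, :] * np.sin(angles)[:, None]
    return coords


def _rotate_coords(coords: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate k-space coordinates by -theta (object rotated by +theta)."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    out = np.empty_like(coords)
    out[..., 0] = c * coords[..., 0] + s * coords[..., 1]
    out[..., 1] = -s * coords[..., 0] + c * coords[..., 1]
    return out


def encode(
    phantom: PhantomModel,
    seq: SequenceParams,
    schedule: SpokeSchedule,
    motion: MotionTrace | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KSpaceSet:
    """Bloch-weighted dual-echo radial k-space of the phantom.

    For every tissue class the indicator map is Fourier-evaluated once per
    distinct segment transform (rotations rotate the sample coordinates,
    translations multiply a phase ramp — both exact), then combined with
    the per-slot steady-state Mz and per-sample T2* decay.  Optional
    complex Gaussian noise (``noise_sd``, seeded) is off by default.
    Deterministic for a fixed seed.
    """
    n = seq.matrix_size
    if phantom.matrix_size != n:
        raise ValueError("phantom matrix does not match sequence matrix_size")
    if schedule.spokes_per_segment != seq.spokes_per_segment:
        raise ValueError("schedule segment size does not match sequence")
    if motion is not None and motion.n_segments != schedule.n_segments:
        raise ValueError(
            f"motion trace has {motion.n_segments} segments, "
            f"schedule has {schedule.n_segments}"
        )

    n_read = seq.n_readout
    coords = spoke_coordinates(schedule, n_read)
    tissues = phantom.imaged_tissues()
    sin_a = math.sin(math.radians(seq.flip_deg))

    nufft = GriddingNufft(n)
    spectra = [nufft.plan_image(phantom.tissue_map(t.name)) for t in tissues]

    # group acquisition slots by their segment's rigid transform
    seg_t = (
        [RigidTransform()] * schedule.n_segments
        if motion is None
        else motion.transforms
    )
    groups: dict[tuple[float, float, float], np.ndarray] = {}
    slot_seg = schedule.segment_of
    for key in {t.as_tuple() for t in seg_t}:
        segs = [i for i, t in enumerate(seg_t) if t.as_tuple() == key]
        groups[key] = np.nonzero(np.isin(slot_seg, segs))[0]

    f_tissue = np.empty((len(tissues), schedule.n_spokes, n_read), dtype=complex)
    for (dx, dy, th), slots in groups.items():
        sub = coords[slots]
        eval_coords = _rotate_coords(sub, th) if th else sub
        if dx or dy:
            d_px = np.array([dy / phantom.pixel_mm, dx / phantom.pixel_mm])
            ramp = np.exp(-2j * math.pi * (sub @ d_px) / n)
        else:
            ramp = 1.0
        for ti, spec in enumerate(spectra):
            f_tissue[ti, slots] = nufft.interpolate(spec, eval_coords) * ramp

    mz = np.stack([steady_state_mz(seq, t) for t in tissues])       # (T, S)
    times = seq.sample_times_ms()                                    # (2, n_read)
    decay = np.stack(
        [np.exp(-times / t.t2s_ms) for t in tissues]
    )                                                                # (T, 2, n_read)
    pd = np.array([t.pd for t in tissues])
    # weight[t, slot, echo, j]
    w = (
        pd[:, None, None, None]
        * sin_a
        * mz[:, schedule.slot_in_segment, None, None]
        * decay[:, None, :, :]
    )
    samples = np.einsum("tsj,tsej->sej", f_tissue, w)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + noise_sd * (
            rng.standard_normal(samples.shape)
            + 1j * rng.standard_normal(samples.shape)
        )

    return KSpaceSet(
        samples=samples,
        k_coords=coords,
        sample_times_ms=times,
        echo_times_ms=seq.echo_times_ms,
        schedule=schedule,
        matrix_size=n,
    )


def simulate_navigator(
    phantom: PhantomModel,
    motion: MotionTrace,
    axis: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> NavigatorSeries:
    """SI self-navigator profiles: per segment, project the proton-density
    map of the (possibly moved) head along the axis orthogonal to SI, add
    Gaussian noise of ``noise_sd``, take the magnitude.

    ``axis`` designates the superior-inferior direction (0 = rows, the
    default).  Navigator contrast is modeled as pd-weighted: the navigator
    spoke sits at the end of every segment, at a fixed delay from the
    inversion, so its tissue weighting is constant across segments and
    drops out of the motion metric.
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (rows = SI) or 1 (columns)")
    rng = np.random.default_rng(seed)
    pdm = phantom.pd_map()
    base = pdm.sum(axis=1 - axis)
    profiles = np.empty((motion.n_segments, pdm.shape[axis]))
    cache: dict[tuple[float, float, float], np.ndarray] = {(0.0, 0.0, 0.0): base}
    for i, t in enumerate(motion.transforms):
        key = t.as_tuple()
        if key not in cache:
            cache[key] = transform_continuous(pdm, t, phantom.pixel_mm).sum(axis=1 - axis)
        prof = cache[key]
        if noise_sd > 0:
            prof = prof + rng.normal(0.0, noise_sd, size=prof.shape)
        profiles[i] = np.abs(prof)
    times = (np.arange(motion.n_segments) + 1.0) * motion.tr_ms / 1e3
    return NavigatorSeries(profiles=profiles, segment_times_s=times)


# -- persistence ----------------------------------------------------------

def save_kspace(ks: KSpaceSet, npz_path: str, json_path: str | None = None) -> None:
    """Persist samples/geometry as a compressed array archive + JSON metadata."""
    np.savez_compressed(
        npz_path,
        samples=ks.samples,
        k_coords=ks.k_coords,
        sample_times_ms=ks.sample_times_ms,
    )
    if json_path is None:
        json_path = str(npz_path).rsplit(".npz", 1)[0] + ".json"
    meta = {
        "echo_times_ms": list(ks.echo_times_ms),
        "matrix_size": ks.matrix_size,
        "schedule": ks.schedule.to_json_dict(),
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_kspace(npz_path: str, json_path: str | None = None) -> KSpaceSet:
    arr = np.load(npz_path)
    if json_path is None:
        json_path = str(npz_path).rsplit(".npz", 1)[0] + ".json"
    with open(json_path) as fh:
        meta = json.load(fh)
    sched_meta = meta["schedule"]
    schedule = make_schedule(
        sched_meta["n_spokes"], sched_meta["spokes_per_segment"], sched_meta["scheme"]
    )
    return KSpaceSet(
        samples=arr["samples"],
        k_coords=arr["k_coords"],
        sample_times_ms=arr["sample_times_ms"],
        echo_times_ms=tuple(meta["echo_times_ms"]),
        schedule=schedule,
        matrix_size=int(meta["matrix_size"]),
    )
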