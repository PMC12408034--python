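"""Analytic Bloch modeling of the segmented IR-UTE experiment.

One repetition (TR) of the sequence is: an adiabatic inversion pulse
(ideal inversion Mz -> -Mz for long-T2 tissues; saturation Mz -> 0 for
sub-millisecond-T2* species that cannot follow the adiabatic sweep), free
T1 recovery, then a train of S low-flip-angle excitations spaced tau apart
and centered on the inversion time TI, then recovery to the end of the TR.
Everything is piecewise-affine in Mz, so the steady state across TRs is the
fixed point of an affine map and is solved in closed form — no numerical
integration.

Transverse magnetization is assumed fully spoiled between spokes; each
excitation converts ``sin(alpha) * Mz`` into signal that decays as
``exp(-t / T2*)`` during the dual-echo readout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import TissueParams


@dataclass(frozen=True)
class SequenceParams:
    """Sequence/trajectory timing parameters (defaults: the 2D simulation
    protocol — 15 deg, TR 1000 ms, TI 379.9 ms, 250 kHz, 220x220 over a
    220 mm FOV, 21 spokes per segment 6 ms apart, TE 0.03 / 3 ms)."""

    tr_ms: float = 1000.0
    ti_ms: float = 379.9
    flip_deg: float = 15.0
    spokes_per_segment: int = 21
    spoke_interval_ms: float = 6.0
    te1_ms: float = 0.03
    te2_ms: float = 3.0
    readout_bandwidth_hz: float = 250e3
    matrix_size: int = 220
    fov_mm: float = 220.0
    include_pulse_train_in_mz: bool = True

    def __post_init__(self) -> None:
        if not self.te1_ms < self.te2_ms:
            raise ValueError("te1_ms must be < te2_ms")
        if not self.ti_ms < self.tr_ms:
            raise ValueError("ti_ms must be < tr_ms")
        if self.spokes_per_segment < 1:
            raise ValueError("spokes_per_segment must be >= 1")
        if self.spokes_per_segment * self.spoke_interval_ms >= self.tr_ms:
            raise ValueError("segment (S * tau) must fit inside the TR")
        st = self.slot_times_ms
        if st[0] <= 0 or st[-1] >= self.tr_ms:
            raise ValueError("excitation train extends outside (0, TR)")

    @property
    def slot_times_ms(self) -> np.ndarray:
        """Time of each excitation after inversion; slot k (0-based) fires at
        ``TI + (k - (S-1)/2) * tau`` so the segment is centered on TI."""
        s = self.spokes_per_segment
        k = np.arange(s, dtype=float)
        return self.ti_ms + (k - (s - 1) / 2.0) * self.spoke_interval_ms

    @property
    def dwell_ms(self) -> float:
        return 1e3 / self.readout_bandwidth_hz

    @property
    def n_readout(self) -> int:
        """Center-out samples per echo (radial Nyquist along the spoke)."""
        return self.matrix_size // 2

    @property
    def echo_times_ms(self) -> tuple[float, float]:
        return (self.te1_ms, self.te2_ms)

    def sample_times_ms(self) -> np.ndarray:
        """(2, n_readout) time since excitation of every readout sample."""
        j = np.arange(self.n_readout, dtype=float)
        return np.stack([self.te1_ms + j * self.dwell_ms,
                         self.te2_ms + j * self.dwell_ms])


def ti_null(t1_ms: float, tr_ms: float) -> float:
    """Inversion time that nulls a tissue in the periodic-inversion steady
    state, with ideal inversion and no excitation-train correction:

        TI = T1 * ln( 2 / (1 + exp(-TR / T1)) )

    For T1 -> infinity relative to TR this approaches ``T1 * ln 2``.
    """
    if t1_ms <= 0 or tr_ms <= 0:
        raise ValueError("t1_ms and tr_ms must be > 0")
    return t1_ms * math.log(2.0 / (1.0 + math.exp(-tr_ms / t1_ms)))


def steady_state_mz(seq: SequenceParams, tissue: TissueParams) -> np.ndarray:
    """Pre-pulse longitudinal magnetization at each of the S excitation
    slots, in steady state across TRs (M0 = 1).

    The per-TR map is composed of: the inversion event (Mz -> -Mz for
    ``invert`` tissues, Mz -> 0 for ``saturate``), exponential T1 recovery
    toward 1 between events, and — when ``include_pulse_train_in_mz`` —
    a cos(alpha) scaling at each excitation.  The steady state is the fixed
    point of the resulting affine map ``M -> a*M + b``; the contraction
    factor |a| < 1 always (asserted).
    """
    t1 = tissue.t1_ms
    ca = math.cos(math.radians(seq.flip_deg)) if seq.include_pulse_train_in_mz else 1.0
    slots = seq.slot_times_ms

    # track the affine map M_before_inversion -> M(t) as (a, b)
    a, b = 1.0, 0.0

    def relax(a: float, b: float, dt: float) -> tuple[float, float]:
        e = math.exp(-dt / t1)
        return a * e, b * e + (1.0 - e)

    if tissue.inversion_response == "invert":
        a, b = -a, -b
    else:  # saturate
        a, b = 0.0, 0.0

    a, b = relax(a, b, slots[0])
    slot_maps = []
    for k in range(seq.spokes_per_segment):
        slot_maps.append((a, b))
        a, b = ca * a, ca * b
        if k < seq.spokes_per_segment - 1:
            a, b = relax(a, b, seq.spoke_interval_ms)
    a, b = relax(a, b, seq.tr_ms - slots[-1])

    assert abs(a) < 1.0, f"per-TR map is not a contraction (|a| = {abs(a)})"
    m0 = b / (1.0 - a)  # steady-state Mz just before the inversion pulse
    return np.array([ak * m0 + bk for ak, bk in slot_maps])


def signal_weight(
    seq: SequenceParams,
    tissue: TissueParams,
    slot: int,
    t_since_excitation_ms: float,
    mz: np.ndarray | None = None,
) -> float:
    """Transverse signal weight ``pd * sin(alpha) * Mz[slot] * exp(-t/T2*)``.

    May be negative: invert tissues carry negative Mz at slots before their
    null point.  ``mz`` may be passed to reuse a precomputed schedule.
    """
    if not 0 <= slot < seq.spokes_per_segment:
        raise ValueError(f"slot {slot} outside 0..{seq.spokes_per_segment - 1}")
    if t_since_excitation_ms < 0:
        raise ValueError("t_since_excitation_ms must be >= 0")
    if mz is None:
        mz = steady_state_mz(seq, tissue)
    sa = math.sin(math.radians(seq.flip_deg))
    return float(
        tissue.pd * sa * mz[slot] * math.exp(-t_since_excitation_ms / tissue.t2s_ms)
    )
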