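"""Radial trajectory: Nyquist spoke count, view ordering, segment layout.

Spokes are center-out half-lines.  ``n`` spoke angles cover the full circle
but are constructed so that, taken modulo pi (a spoke at theta and one at
theta + pi sample conjugate-symmetric regions of a real object's k-space),
they are ``n`` distinct angles with uniform spacing ``pi / n``:

    angles[i] = i * (pi + pi/n)  mod 2*pi

i.e. successive angle indices alternate hemispheres while advancing by
pi/n modulo pi.  Sequential acquisition therefore sweeps k-space azimuth
monotonically (modulo pi), and a contiguous block of rejected spokes
carves out a single angular wedge — the failure mode that bit-reversed
view ordering disperses.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpokeSchedule",
    "nyquist_spokes",
    "bit_reverse_permutation",
    "make_schedule",
    "max_angular_gap",
]

SCHEMES = ("sequential", "bit_reversed")


@dataclass(frozen=True)
class SpokeSchedule:
    """Spoke angles plus acquisition ordering and segment layout.

    ``acq_order`` maps acquisition slot -> angle index (a permutation);
    ``segment_of`` / ``slot_in_segment`` map acquisition slot -> segment
    index and position within the segment.  Angles are identical across
    ordering schemes; only the acquisition order changes.
    """

    n_spokes: int
    angles_rad: np.ndarray
    acq_order: np.ndarray
    segment_of: np.ndarray
    slot_in_segment: np.ndarray
    spokes_per_segment: int
    scheme: str

    @property
    def n_segments(self) -> int:
        return int(self.segment_of[-1]) + 1

    @property
    def angles_acquired(self) -> np.ndarray:
        """Spoke angle at each acquisition slot."""
        return self.angles_rad[self.acq_order]

    def segment_slots(self, segment: int) -> np.ndarray:
        return np.nonzero(self.segment_of == segment)[0]

    def to_json_dict(self) -> dict:
        return {
            "n_spokes": self.n_spokes,
            "spokes_per_segment": self.spokes_per_segment,
            "scheme": self.scheme,
            "angles_rad": self.angles_rad.tolist(),
            "acq_order": self.acq_order.tolist(),
            "segment_of": self.segment_of.tolist(),
        }


def nyquist_spokes(matrix_size: int) -> int:
    """Number of uniformly spaced center-out spokes over 360 degrees that
    satisfies the azimuthal Nyquist criterion at the k-space edge:
    ``ceil(pi * matrix_size)``."""
    if matrix_size < 2:
        raise ValueError("matrix_size must be >= 2")
    return math.ceil(math.pi * matrix_size)


def bit_reverse_permutation(n: int) -> np.ndarray:
    """Bit-reversed acquisition order for ``n`` spokes.

    With ``B = ceil(log2 n)``: enumerate i = 0 .. 2**B - 1, reverse the
    B-bit binary representation of each i, and keep values < n in
    enumeration order (discard-and-compact, so the scheme applies to any
    spoke count).  For n a power of two the permutation is an involution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b = max(0, math.ceil(math.log2(n)))
    codes = np.arange(1 << b, dtype=np.int64)
    rev = np.zeros_like(codes)
    for bit in range(b):
        rev |= ((codes >> bit) & 1) << (b - 1 - bit)
    return rev[rev < n].copy()


def make_schedule(
    n_spokes: int, spokes_per_segment: int, scheme: str = "sequential"
) -> SpokeSchedule:
    """Build a spoke schedule: uniform angles, the requested view ordering,
    and segments of ``spokes_per_segment`` filled in acquisition order (only
    the last segment may be partial)."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if not n_spokes >= spokes_per_segment >= 1:
        raise ValueError("need n_spokes >= spokes_per_segment >= 1")
    n = int(n_spokes)
    angles = (np.arange(n) * (math.pi + math.pi / n)) % (2.0 * math.pi)
    if scheme == "sequential":
        order = np.arange(n, dtype=np.int64)
    else:
        order = bit_reverse_permutation(n)
    slots = np.arange(n)
    return SpokeSchedule(
        n_spokes=n,
        angles_rad=angles,
        acq_order=order,
        segment_of=slots // spokes_per_segment,
        slot_in_segment=slots % spokes_per_segment,
        spokes_per_segment=int(spokes_per_segment),
        scheme=scheme,
    )


def max_angular_gap(angles_of_kept_spokes: np.ndarray, modulo: float = math.pi) -> float:
    """Largest angular distance between azimuthally adjacent kept spokes.

    Angles are compared modulo pi by default (real-object conjugate
    symmetry); pass ``modulo=2*pi`` to treat each center-out direction as
    distinct.  The convention used should be recorded alongside any
    reported gap statistic.
    """
    a = np.sort(np.asarray(angles_of_kept_spokes, dtype=float) % modulo)
    if a.size < 2:
        raise ValueError("need at least 2 kept spokes")
    gaps = np.diff(a)
    wrap = a[0] + modulo - a[-1]
    return float(max(gaps.max(), wrap))
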