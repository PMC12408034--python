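"""Retrospective motion gating from the self-navigator signal.

The navigator series is reduced to one scalar per segment — the profile
intensity at a fixed reference pixel, chosen as the position of maximum
signal in the first profile — and segments whose metric deviates from the
robust baseline are rejected.  Gating granularity is always the segment
(one navigator per segment); the per-segment decision is expanded to a
per-spoke mask through the spoke schedule, so a recorded mask can be
re-applied to a different (e.g. motion-free) k-space set acquired with the
same schedule.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .encoder import NavigatorSeries
from .trajectory import SpokeSchedule

logger = logging.getLogger(__name__)

#: floor on the robust scale estimate, as a fraction of the median metric:
#: metric excursions below this correspond to displacements far below the
#: image resolution and are never worth rejecting a segment for.
MIN_REL_SCALE = 0.002


@dataclass
class GateMask:
    """Per-segment keep/reject decisions expanded to per-spoke masks."""

    keep_segment: np.ndarray          # bool, (n_segments,)
    keep_spoke: np.ndarray            # bool, (n_spokes,) by acquisition slot
    threshold_used: float
    mode: str
    metric: np.ndarray | None = None  # per-segment metric the gate saw
    reference_pixel: int | None = None

    def __post_init__(self) -> None:
        self.keep_segment = np.asarray(self.keep_segment, dtype=bool)
        self.keep_spoke = np.asarray(self.keep_spoke, dtype=bool)

    @property
    def n_rejected_spokes(self) -> int:
        return int((~self.keep_spoke).sum())

    @property
    def rejected_fraction(self) -> float:
        return float((~self.keep_spoke).mean())

    def to_json_dict(self) -> dict:
        return {
            "keep_segment": self.keep_segment.astype(int).tolist(),
            "threshold_used": float(self.threshold_used),
            "mode": self.mode,
            "metric": None if self.metric is None else [float(m) for m in self.metric],
            "reference_pixel": self.reference_pixel,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str, schedule: SpokeSchedule) -> "GateMask":
        with open(path) as fh:
            d = json.load(fh)
        keep_segment = np.asarray(d["keep_segment"], dtype=bool)
        return cls(
            keep_segment=keep_segment,
            keep_spoke=keep_segment[schedule.segment_of],
            threshold_used=d["threshold_used"],
            mode=d["mode"],
            metric=None if d["metric"] is None else np.asarray(d["metric"]),
            reference_pixel=d["reference_pixel"],
        )


def from_segment_mask(
    schedule: SpokeSchedule,
    keep_segment: np.ndarray,
    threshold_used: float = float("nan"),
    mode: str = "manual",
    **kw,
) -> GateMask:
    keep_segment = np.asarray(keep_segment, dtype=bool)
    if keep_segment.size != schedule.n_segments:
        raise ValueError("segment mask length does not match schedule")
    return GateMask(
        keep_segment=keep_segment,
        keep_spoke=keep_segment[schedule.segment_of],
        threshold_used=threshold_used,
        mode=mode,
        **kw,
    )


def reject_contiguous_segments(
    schedule: SpokeSchedule, fraction: float, start_segment: int = 0
) -> GateMask:
    """Reject a contiguous run of whole segments covering at least
    ``fraction`` of all spokes (wrapping past the last segment), emulating
    the temporally contiguous data loss a motion episode produces."""
    n_seg = schedule.n_segments
    sizes = np.bincount(schedule.segment_of, minlength=n_seg)
    target = fraction * schedule.n_spokes
    keep = np.ones(n_seg, dtype=bool)
    rejected, i = 0, 0
    while rejected < target and i < n_seg:
        seg = (start_segment + i) % n_seg
        keep[seg] = False
        rejected += sizes[seg]
        i += 1
    return from_segment_mask(schedule, keep, mode="contiguous")


def navigator_metric(nav: NavigatorSeries) -> tuple[np.ndarray, int]:
    """Per-segment motion metric: the profile intensity at a fixed reference
    pixel, defined as the position of maximum signal in the first profile."""
    if nav.n_segments < 1:
        raise ValueError("need at least one navigator profile")
    first = nav.profiles[0]
    if first.max() <= 0:
        raise ValueError("first navigator profile is all zero; no reference pixel")
    ref = int(np.argmax(first))
    return nav.profiles[:, ref].copy(), ref


def threshold_gate(
    metric: np.ndarray,
    schedule: SpokeSchedule,
    mode: str = "robust",
    k_or_value: float = 3.0,
    reference_pixel: int | None = None,
) -> GateMask:
    """Threshold-based gating of the per-segment metric.

    ``robust`` mode rejects segments with ``|metric - median| > k * sigma``,
    where ``sigma`` is the normalized median absolute deviation
    (``1.4826 * MAD``, the consistent Gaussian scale estimate) floored at
    ``MIN_REL_SCALE`` of the median metric so that sub-resolution intensity
    fluctuations are never rejected.  The rule is scale-free, and a
    permanent post-nod baseline shift keeps those segments rejected.
    ``absolute`` mode rejects segments with ``metric < value``.  If both
    the MAD and the median are zero (no usable baseline) the gate falls
    back to absolute mode with a warning.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.size < 2:
        raise ValueError("need at least 2 segments to gate")
    if metric.size != schedule.n_segments:
        raise ValueError("metric length does not match schedule segments")
    if mode == "robust":
        med = float(np.median(metric))
        mad = float(np.median(np.abs(metric - med)))
        if mad == 0.0 and med == 0.0:
            logger.warning("MAD and median are zero; falling back to absolute thresholding")
            return threshold_gate(metric, schedule, "absolute", k_or_value,
                                  reference_pixel=reference_pixel)
        sigma = max(1.4826 * mad, MIN_REL_SCALE * abs(med))
        thresh = k_or_value * sigma
        keep = np.abs(metric - med) <= thresh
    elif mode == "absolute":
        thresh = k_or_value
        keep = metric >= thresh
    else:
        raise ValueError(f"mode must be 'robust' or 'absolute', got {mode!r}")
    return from_segment_mask(
        schedule, keep,
        threshold_used=float(thresh), mode=mode,
        metric=metric, reference_pixel=reference_pixel,
    )


def gate_from_navigator(
    nav: NavigatorSeries,
    schedule: SpokeSchedule,
    mode: str = "robust",
    k_or_value: float = 3.0,
) -> GateMask:
    """Convenience: navigator series -> metric -> threshold gate."""
    metric, ref = navigator_metric(nav)
    return threshold_gate(metric, schedule, mode, k_or_value, reference_pixel=ref)
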