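import logging

import numpy as np
import pytest

import irute as ir
from irute.encoder import NavigatorSeries
from irute.gating import from_segment_mask


@pytest.fixture(scope="module")
def sched600():
    return ir.make_schedule(12000, 20, "bit_reversed")


class TestNavigatorMetric:
    def test_reference_pixel_is_first_profile_argmax(self, phantom64):
        motion = ir.MotionTrace.still(4)
        nav = ir.simulate_navigator(phantom64, motion)
        metric, ref = ir.navigator_metric(nav)
        assert ref == int(np.argmax(nav.profiles[0]))
        assert metric[0] == nav.profiles[0].max()

    def test_identical_profiles_constant_metric(self, phantom64):
        nav = ir.simulate_navigator(phantom64, ir.MotionTrace.still(6))
        metric, _ = ir.navigator_metric(nav)
        assert np.all(metric == metric[0])

    def test_shifted_profile_drops_by_local_slope(self):
        """Shifting a profile off the reference pixel changes the metric by
        the profile's local variation at that fixed pixel."""
        x = np.arange(64.0)
        prof = np.exp(-0.5 * ((x - 30) / 6.0) ** 2)
        shifted = np.roll(prof, 4)
        nav = NavigatorSeries(profiles=np.stack([prof, shifted]),
                              segment_times_s=np.array([1.0, 2.0]))
        metric, ref = ir.navigator_metric(nav)
        assert metric[1] == pytest.approx(shifted[ref])
        assert metric[1] < metric[0]

    def test_all_zero_first_profile_raises(self):
        nav = NavigatorSeries(profiles=np.zeros((3, 16)),
                              segment_times_s=np.arange(3.0))
        with pytest.raises(ValueError):
            ir.navigator_metric(nav)


class TestThresholdGate:
    def test_constant_metric_rejects_nothing(self, sched600):
        gate = ir.threshold_gate(np.full(600, 5.0), sched600, "robust", 3.0)
        assert gate.keep_segment.all()

    def test_reproduces_in_vivo_rejection_count(self, sched600):
        """64 of 600 segments perturbed far beyond threshold with 20 spokes
        per segment: exactly 1280 of 12000 spokes rejected (10.7%)."""
        rng = np.random.default_rng(0)
        metric = 100.0 + 0.1 * rng.standard_normal(600)
        metric[300:364] -= 20.0
        gate = ir.threshold_gate(metric, sched600, "robust", 3.0)
        assert gate.n_rejected_spokes == 1280
        assert (~gate.keep_segment).sum() == 64
        assert round(100 * gate.rejected_fraction, 1) == 10.7

    def test_gating_is_idempotent(self):
        """Gating the kept subset again with the same rule rejects nothing."""
        rng = np.random.default_rng(1)
        sched = ir.make_schedule(600, 20, "sequential")
        metric = 50.0 + 0.05 * rng.standard_normal(30)
        metric[10:13] -= 10.0
        gate = ir.threshold_gate(metric, sched, "robust", 3.0)
        kept_metric = metric[gate.keep_segment]
        sub_sched = ir.make_schedule(20 * kept_metric.size, 20, "sequential")
        gate2 = ir.threshold_gate(kept_metric, sub_sched, "robust", 3.0)
        assert gate2.keep_segment.all()

    def test_rejection_monotone_in_k(self, sched600):
        rng = np.random.default_rng(2)
        metric = 10.0 + 0.2 * rng.standard_normal(600)
        metric[::7] -= rng.uniform(0.0, 3.0, size=metric[::7].shape)
        fracs = [
            ir.threshold_gate(metric, sched600, "robust", k).rejected_fraction
            for k in (0.5, 1.0, 2.0, 3.0, 5.0, 10.0)
        ]
        assert np.all(np.diff(fracs) <= 0)

    def test_absolute_mode(self, sched600):
        metric = np.linspace(0.0, 10.0, 600)
        gate = ir.threshold_gate(metric, sched600, "absolute", 5.0)
        assert (~gate.keep_segment).sum() == (metric < 5.0).sum()

    def test_degenerate_metric_falls_back_to_absolute(self, sched600, caplog):
        with caplog.at_level(logging.WARNING, logger="irute.gating"):
            gate = ir.threshold_gate(np.zeros(600), sched600, "robust", 3.0)
        assert any("absolute" in r.message for r in caplog.records)
        assert gate.mode == "absolute"

    def test_spoke_mask_is_segment_mask_expanded(self, sched600):
        metric = np.ones(600)
        metric[5] = 0.0
        gate = ir.threshold_gate(metric, sched600, "robust", 3.0)
        np.testing.assert_array_equal(
            gate.keep_spoke, gate.keep_segment[sched600.segment_of]
        )
        assert gate.n_rejected_spokes == (~gate.keep_segment).sum() * 20


class TestGroundTruthRecovery:
    def test_perfect_precision_and_recall_on_nod_fixture(self, phantom64):
        """Default nod trace (nods every 20 s) with metric SNR >= 10:
        threshold gating recovers exactly the moving segments."""
        sched = ir.make_schedule(692, 21, "bit_reversed")
        trace = ir.make_nod_trace(sched.n_segments, tr_ms=1000.0)
        peak = float(phantom64.pd_map().sum(axis=1).max())
        nav = ir.simulate_navigator(phantom64, trace, noise_sd=0.001 * peak, seed=3)
        metric, _ = ir.navigator_metric(nav)
        still, moving = metric[~trace.moving], metric[trace.moving]
        snr = abs(moving.mean() - still.mean()) / still.std()
        assert snr >= 10
        gate = ir.threshold_gate(metric, sched, "robust", 3.0)
        np.testing.assert_array_equal(~gate.keep_segment, trace.moving)


class TestMaskReuse:
    def test_mask_applies_to_other_kspace(self, ks64_bit, nufft64, sched64_bit):
        """A recorded gate mask applied to a different k-space set changes
        only which spokes enter the reconstruction."""
        keep_segment = np.ones(sched64_bit.n_segments, dtype=bool)
        keep_segment[2:4] = False
        gate = from_segment_mask(sched64_bit, keep_segment)
        img = ir.adjoint_recon(ks64_bit, gate=gate, echo=0, nufft=nufft64)
        # manual equivalent: zero weights outside the kept subset
        manual = ir.adjoint_recon(
            _subset_kspace(ks64_bit, gate.keep_spoke), echo=0, nufft=nufft64
        )
        np.testing.assert_allclose(img, manual, atol=1e-12 * np.abs(img).max())

    def test_save_load_roundtrip(self, tmp_path, sched64_bit):
        keep_segment = np.ones(sched64_bit.n_segments, dtype=bool)
        keep_segment[5] = False
        gate = from_segment_mask(sched64_bit, keep_segment, threshold_used=1.5,
                                 mode="robust")
        path = str(tmp_path / "mask.json")
        gate.save(path)
        back = ir.GateMask.load(path, sched64_bit)
        np.testing.assert_array_equal(back.keep_segment, gate.keep_segment)
        np.testing.assert_array_equal(back.keep_spoke, gate.keep_spoke)


def _subset_kspace(ks, keep):
    """K-space restricted to kept spokes, with matching full-pattern
    density weights (weights depend only on geometry, so simply dropping
    the spokes reproduces adjoint_recon's gated path)."""
    import dataclasses

    # adjoint_recon normalizes weights by the full pattern, which is keyed
    # off n_spokes; keep the schedule/coords but zero rejected samples.
    samples = ks.samples.copy()
    samples[~keep] = 0.0
    return dataclasses.replace(ks, samples=samples)


class TestContiguousRejection:
    def test_covers_requested_fraction_in_whole_segments(self, sched600):
        gate = ir.reject_contiguous_segments(sched600, 0.10, start_segment=100)
        assert gate.n_rejected_spokes == 1200
        rejected = np.nonzero(~gate.keep_segment)[0]
        np.testing.assert_array_equal(rejected, np.arange(100, 160))

    def test_wraps_past_last_segment(self, sched600):
        gate = ir.reject_contiguous_segments(sched600, 0.02, start_segment=595)
        rejected = set(np.nonzero(~gate.keep_segment)[0].tolist())
        assert rejected == {595, 596, 597, 598, 599, 0, 1, 2, 3, 4, 5, 6}
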