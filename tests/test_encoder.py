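import math

import numpy as np
import pytest

import irute as ir
from irute.phantom import PhantomModel, TissueParams

from _oracles import antialiased_disc, disc_transform


def uniform_weight_sequence(n=64):
    """Sequence whose every slot carries unit signal weight: flip 90 deg,
    instantly recovering saturated tissue, negligible decay."""
    return ir.SequenceParams(flip_deg=90.0, matrix_size=n)


def disc_phantom(n=64, radius=12.0, pd=1.0):
    """Single-tissue phantom: constant pd inside a centered disc, with a
    partial-volume (anti-aliased) occupancy map so its spectrum follows the
    closed-form disc transform."""
    frac = antialiased_disc(n, radius)
    lab = (frac > 0.5).astype(np.int16)
    tissues = (
        TissueParams(0, "Background", 0.0, 1.0, 1.0, "invert"),
        # T1 -> 0: recovers to Mz=1 before every pulse; T2* -> inf: no decay
        TissueParams(1, "Disc", pd, 1e-3, 1e12, "saturate"),
    )
    return PhantomModel(lab, tissues, pixel_mm=1.0, fov_mm=float(n),
                        pv_maps={"Disc": frac})


class TestEncodeOracles:
    def test_disc_kspace_matches_closed_form(self, sched64_seq):
        """Encoded k-space of a uniform disc equals the analytic jinc-form
        disc transform to < 1% relative l2 error."""
        seq = uniform_weight_sequence(64)
        ph = disc_phantom(64, radius=12.0)
        ks = ir.encode(ph, seq, sched64_seq)
        oracle = disc_transform(ks.k_coords, 12.0, 64)
        for echo in (0, 1):
            err = np.linalg.norm(ks.samples[:, echo, :] - oracle)
            assert err / np.linalg.norm(oracle) < 0.01

    def test_linearity_over_tissues(self, seq64, sched64_seq, phantom64):
        """encode(A + B) = encode(A) + encode(B): restricting the tissue
        table to disjoint subsets and summing reproduces the full encode."""
        def restricted(names):
            tissues = tuple(
                TissueParams(t.label, t.name, t.pd if t.name in names else 0.0,
                             t.t1_ms, t.t2s_ms, t.inversion_response)
                for t in phantom64.tissues
            )
            p = PhantomModel(phantom64.label_map, tissues, phantom64.pixel_mm,
                             phantom64.fov_mm, phantom64.lesion_specs)
            return ir.encode(p, seq64, sched64_seq).samples

        full = ir.encode(phantom64, seq64, sched64_seq).samples
        part_a = restricted({"CSF", "GM_L", "Myelin"})
        part_b = restricted({"WM_L", "Skull", "Fat"})
        np.testing.assert_allclose(part_a + part_b, full, rtol=0, atol=1e-12 * np.abs(full).max())

    def test_fourier_shift_theorem(self, phantom64, seq64, sched64_seq):
        """A pure translation applied to every segment multiplies each
        sample by exp(-2 pi i k . delta / N) exactly."""
        base = ir.encode(phantom64, seq64, sched64_seq)
        d = ir.RigidTransform(dx_mm=2.5 * phantom64.pixel_mm,
                              dy_mm=-1.25 * phantom64.pixel_mm)
        motion = ir.MotionTrace(
            transforms=[d] * sched64_seq.n_segments,
            moving=np.ones(sched64_seq.n_segments, dtype=bool),
        )
        moved = ir.encode(phantom64, seq64, sched64_seq, motion=motion)
        d_px = np.array([d.dy_mm, d.dx_mm]) / phantom64.pixel_mm
        ramp = np.exp(-2j * np.pi * (base.k_coords @ d_px) / 64)
        expect = base.samples * ramp[:, None, :]
        num = np.linalg.norm(moved.samples - expect)
        assert num / np.linalg.norm(base.samples) < 1e-6

    def test_dc_sample_consistent_across_spokes(self, ks64_bit, seq64, phantom64):
        """The |k|=0 sample of echo 1 is the same head integral on every
        spoke once the slot-dependent Mz weighting is divided out."""
        tissues = phantom64.imaged_tissues()
        mz = np.stack([ir.steady_state_mz(seq64, t) for t in tissues])
        sa = math.sin(math.radians(seq64.flip_deg))
        areas = np.array([phantom64.tissue_map(t.name).sum() for t in tissues])
        pd = np.array([t.pd for t in tissues])
        dec = np.array([math.exp(-seq64.te1_ms / t.t2s_ms) for t in tissues])
        slots = ks64_bit.schedule.slot_in_segment
        expect = (pd * sa * areas * dec) @ mz[:, slots]
        scale = np.abs(expect).max()
        np.testing.assert_allclose(ks64_bit.samples[:, 0, 0].real, expect,
                                   rtol=0, atol=1e-4 * scale)
        assert np.abs(ks64_bit.samples[:, 0, 0].imag).max() < 1e-8 * scale

    def test_echo2_bounded_by_myelin_decay(self, sched64_seq):
        """For a myelin-only object every echo-2 sample is at most
        exp(-(TE2-TE1)/T2*) times its echo-1 counterpart."""
        seq = ir.SequenceParams(matrix_size=64)
        myelin = next(t for t in ir.DEFAULT_TISSUES if t.name == "Myelin")
        lab = np.zeros((64, 64), dtype=np.int16)
        lab[24:40, 24:40] = 4
        # tissue table restricted to myelin only: no co-located WM_L water
        bg = next(t for t in ir.DEFAULT_TISSUES if t.name == "Background")
        ph = PhantomModel(lab, (bg, myelin), 1.0, 64.0)
        ks = ir.encode(ph, seq, sched64_seq)
        bound = math.exp(-(seq.te2_ms - seq.te1_ms) / myelin.t2s_ms)
        a1 = np.abs(ks.samples[:, 0, :])
        a2 = np.abs(ks.samples[:, 1, :])
        assert np.all(a2 <= bound * a1 * (1 + 1e-9))


class TestEncodeContracts:
    def test_motionless_trace_bit_identical(self, phantom64, seq64, sched64_bit, ks64_bit):
        still = ir.MotionTrace.still(sched64_bit.n_segments)
        ks = ir.encode(phantom64, seq64, sched64_bit, motion=still, seed=0)
        np.testing.assert_array_equal(ks.samples, ks64_bit.samples)

    def test_first_echo_starts_at_k_zero(self, ks64_bit):
        assert np.all(np.hypot(ks64_bit.k_coords[:, 0, 0], ks64_bit.k_coords[:, 0, 1]) == 0)

    def test_sample_times(self, ks64_bit, seq64):
        dwell = 1e3 / seq64.readout_bandwidth_hz
        j = np.arange(seq64.n_readout)
        np.testing.assert_allclose(ks64_bit.sample_times_ms[0], seq64.te1_ms + j * dwell)
        np.testing.assert_allclose(ks64_bit.sample_times_ms[1], seq64.te2_ms + j * dwell)

    def test_segment_count_mismatch_raises(self, phantom64, seq64, sched64_bit):
        bad = ir.MotionTrace.still(sched64_bit.n_segments - 1)
        with pytest.raises(ValueError):
            ir.encode(phantom64, seq64, sched64_bit, motion=bad)

    def test_noise_is_seeded_and_optional(self, phantom64, seq64, sched64_seq):
        a = ir.encode(phantom64, seq64, sched64_seq, noise_sd=0.5, seed=9)
        b = ir.encode(phantom64, seq64, sched64_seq, noise_sd=0.5, seed=9)
        c = ir.encode(phantom64, seq64, sched64_seq, noise_sd=0.5, seed=10)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)


class TestNavigator:
    def test_no_motion_no_noise_profiles_identical(self, phantom64):
        motion = ir.MotionTrace.still(10)
        nav = ir.simulate_navigator(phantom64, motion)
        assert np.all(nav.profiles == nav.profiles[0])
        assert nav.profiles.min() >= 0

    def test_si_translation_shifts_profile(self, phantom64):
        """+d mm along SI shifts the projection by d/pixel_mm pixels."""
        d_px = 3
        t = ir.RigidTransform(dy_mm=d_px * phantom64.pixel_mm)
        motion = ir.MotionTrace(transforms=[ir.RigidTransform(), t],
                                moving=np.array([False, True]))
        nav = ir.simulate_navigator(phantom64, motion)
        base, moved = nav.profiles
        interior = slice(d_px + 1, 63)
        np.testing.assert_allclose(moved[interior],
                                   np.roll(base, d_px)[interior], atol=1e-9)

    def test_profiles_linear_in_pd(self, phantom64):
        tissues = tuple(
            TissueParams(t.label, t.name, 2 * t.pd, t.t1_ms, t.t2s_ms,
                         t.inversion_response)
            for t in phantom64.tissues
        )
        doubled = PhantomModel(phantom64.label_map, tissues, phantom64.pixel_mm,
                               phantom64.fov_mm, phantom64.lesion_specs)
        motion = ir.MotionTrace.still(3)
        a = ir.simulate_navigator(phantom64, motion)
        b = ir.simulate_navigator(doubled, motion)
        np.testing.assert_allclose(b.profiles, 2 * a.profiles, rtol=1e-12)

    def test_one_profile_per_segment_at_segment_end(self, phantom64):
        motion = ir.MotionTrace.still(5, tr_ms=1000.0)
        nav = ir.simulate_navigator(phantom64, motion)
        assert nav.profiles.shape == (5, 64)
        np.testing.assert_allclose(nav.segment_times_s, [1, 2, 3, 4, 5])


class TestNodTrace:
    def test_nods_every_period(self):
        trace = ir.make_nod_trace(45, tr_ms=1000.0, nod_period_s=20.0,
                                  nod_duration_s=2.0)
        moving = np.nonzero(trace.moving)[0]
        np.testing.assert_array_equal(moving, [20, 21, 40, 41])

    def test_still_segments_have_identity_transform(self):
        trace = ir.make_nod_trace(45, tr_ms=1000.0)
        for t, mv in zip(trace.transforms, trace.moving):
            assert mv or t.is_identity

    def test_settled_position_when_not_returning(self):
        trace = ir.make_nod_trace(33, tr_ms=1000.0, return_to_baseline=False)
        # after the nod at 20 s the head stays displaced
        assert trace.moving[25:].all()

    def test_kspace_roundtrip(self, tmp_path, ks64_bit):
        path = str(tmp_path / "ks.npz")
        ir.save_kspace(ks64_bit, path)
        back = ir.load_kspace(path)
        np.testing.assert_array_equal(back.samples, ks64_bit.samples)
        np.testing.assert_array_equal(back.k_coords, ks64_bit.k_coords)
        assert back.schedule.scheme == ks64_bit.schedule.scheme
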