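"""Footprints, registration, anatomical masking, LOAD/FUNC variables."""

import numpy as np
import pytest

from pedarch.errors import MaskingError
from pedarch.pressure import (
    LABEL_CODES,
    LOAD_VARIABLES,
    REGIONS_FOREFOOT,
    Footprint,
    PressureFrameSequence,
    RegionMask,
    arch_index,
    contact_time,
    foot_load_and_func,
    peak_pressure_image,
    plantar_angle_masks,
    regional_metrics,
    register_and_average,
)
from pedarch.synthetic import default_gait_spec, make_pressure_trials


def _seq(frames, markers=None):
    markers = markers or {
        "CAL": (40, 20), "M1": (60, 120), "M2": (40, 120), "M5": (20, 120),
        "HLX": (60, 140),
    }
    return PressureFrameSequence(np.asarray(frames, float), markers=markers)


def _rect_footprint(rows=30, cols=12, value=100.0, row0=2, col0=2):
    img = np.zeros((40, 20))
    img[row0 : row0 + rows, col0 : col0 + cols] = value
    return img


class TestPeakImage:
    def test_single_frame_identity(self):
        img = _rect_footprint()
        fp = peak_pressure_image(_seq([img]))
        np.testing.assert_array_equal(fp.peak_image, img)
        assert fp.contact_mask.sum() == (img > 10).sum()

    def test_per_sensor_maximum(self):
        a, b = _rect_footprint(value=50.0), _rect_footprint(value=80.0)
        fp = peak_pressure_image(_seq([a, b]))
        assert fp.peak_image.max() == 80.0

    def test_triangular_pulse_amplitude_map(self, rng):
        amp = np.zeros((20, 10))
        amp[5:15, 2:8] = rng.uniform(50, 400, size=(10, 6))
        ramp = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        frames = amp[None] * ramp[:, None, None]
        fp = peak_pressure_image(_seq(frames))
        np.testing.assert_allclose(fp.peak_image, amp)

    def test_all_zero_sequence_rejected(self):
        with pytest.raises(MaskingError):
            peak_pressure_image(_seq([np.zeros((10, 10))]))


class TestContactTime:
    def test_frame_count_times_dt(self):
        frames = np.zeros((68, 10, 10))
        frames[:, 5, 5] = 100.0
        assert contact_time(_seq(frames)) == 680.0

    def test_zero_contact(self):
        assert contact_time(_seq([np.zeros((5, 5))])) == 0.0

    def test_ramped_sequence_brute_force(self):
        frames = np.zeros((80, 8, 8))
        levels = np.concatenate([np.full(30, 5.0), np.linspace(20, 120, 50)])
        frames[:, 4, 4] = levels
        expected = int((levels > 10.0).sum()) * 10.0  # brute-force frame count
        assert expected == 500.0
        assert contact_time(_seq(frames)) == expected


class TestRegistration:
    def test_identical_footprints_average_to_themselves(self):
        fp = peak_pressure_image(_seq([_rect_footprint()]))
        avg = register_and_average([fp] * 5)
        np.testing.assert_allclose(avg.peak_image, fp.peak_image, atol=1e-9)

    def test_planted_shift_recovered(self, clean_trials):
        trials, _ = clean_trials
        ref = peak_pressure_image(trials[0])
        shifted = np.roll(trials[0].frames, shift=(2, -1), axis=(1, 2))
        fp2 = peak_pressure_image(_seq(shifted, trials[0].markers))
        avg = register_and_average([ref, fp2])
        drow, dcol, dth = avg.transforms[1]
        assert abs(drow - (-2)) <= 1.0 and abs(dcol - 1) <= 1.0  # within one pitch
        assert avg.residuals[1] < 0.2

    def test_planted_rotation_recovered(self, clean_trials):
        from scipy import ndimage

        trials, _ = clean_trials
        ref = peak_pressure_image(trials[0])
        rot = ndimage.rotate(
            ref.peak_image, 15.0, reshape=False, order=1, mode="constant"
        )
        fp2 = Footprint(rot, rot > 10, pitch=5.0)
        avg = register_and_average([ref, fp2])
        assert abs(np.degrees(avg.transforms[1][2]) - (-15.0)) <= 2.0


class TestPlantarAngleMasks:
    def test_sector_boundaries_are_30_and_81_percent(self, clean_trials):
        trials, _ = clean_trials
        fp = peak_pressure_image(trials[0])
        mask = plantar_angle_masks(fp, trials[0].markers)
        b1, b2 = mask.boundaries
        assert b1 == pytest.approx(0.30 * mask.gamma, abs=1e-9)
        assert b2 == pytest.approx(0.81 * mask.gamma, abs=1e-9)
        assert mask.gamma > 0

    def test_rectangle_partition_property(self):
        img = _rect_footprint(rows=30, cols=12)
        markers = {
            "CAL": (40, 15), "M1": (55, 120), "M2": (40, 120), "M5": (25, 120),
            "HLX": (55, 140),
        }
        fp = peak_pressure_image(_seq([img], markers))
        mask = plantar_angle_masks(fp, markers, met_offset=-25.0)
        fore = np.zeros_like(fp.contact_mask)
        for name in ("I_MET", "II_IV_MET", "V_MET"):
            region = mask.region(name)
            assert not (fore & region).any()  # disjoint
            fore |= region
        # union covers the whole forefoot band of the contact area
        assert fore.sum() > 0
        labels = mask.labels[fp.contact_mask]
        assert not np.isin(labels, [0]).all()

    def test_synthetic_foot_label_agreement(self, clean_trials):
        """Marker-based masks recover the generator's per-sensor region
        assignment for >= 95 % of forefoot pixels."""
        trials, truth = clean_trials
        fp = peak_pressure_image(trials[0])
        mask = plantar_angle_masks(fp, trials[0].markers)
        gt = truth["labels"][0][fp.contact_mask]
        got = mask.labels[fp.contact_mask]
        for name in REGIONS_FOREFOOT:
            code = LABEL_CODES[name]
            sel = gt == code
            assert sel.sum() > 0
            assert (got[sel] == code).mean() >= 0.95

    def test_missing_marker_rejected(self, clean_trials):
        trials, _ = clean_trials
        fp = peak_pressure_image(trials[0])
        markers = dict(trials[0].markers)
        del markers["M5"]
        with pytest.raises(MaskingError):
            plantar_angle_masks(fp, markers)


def _manual_mask(shape, region_rows, region_cols):
    labels = np.zeros(shape, dtype=np.int8)
    labels[region_rows, region_cols] = LABEL_CODES["II_IV_MET"]
    return RegionMask(
        labels=labels, gamma=15.0, boundaries=(4.5, 12.15),
        axis=np.array([0.0, 1.0]), apex=np.array([0.0, 0.0]),
        toe_s=1e9, met_s=0.0,
    )


class TestRegionalMetrics:
    def test_constant_pressure_closed_form(self):
        # 100 kPa held for 0.5 s: PP 100, PTI 50 kPa s, PTI_N 100 kPa
        frames = np.zeros((50, 10, 10))
        frames[:, 4:6, 4:6] = 100.0
        mask = _manual_mask((10, 10), slice(4, 6), slice(4, 6))
        m, flag = regional_metrics(_seq(frames), mask, "II_IV_MET")
        assert not flag
        assert m["PP"] == pytest.approx(100.0)
        assert m["PTI"] == pytest.approx(50.0)
        assert m["PTI_N"] == pytest.approx(100.0)

    def test_single_frame(self):
        frames = np.zeros((1, 10, 10))
        frames[0, 4, 4] = 200.0
        mask = _manual_mask((10, 10), 4, 4)
        m, _ = regional_metrics(_seq(frames), mask, "II_IV_MET")
        assert m["PP"] == 200.0
        assert m["PTI"] == pytest.approx(2.0)

    def test_empty_region_flagged(self):
        frames = np.zeros((5, 10, 10))
        frames[:, 8, 8] = 100.0
        mask = _manual_mask((10, 10), 2, 2)
        m, flag = regional_metrics(_seq(frames), mask, "II_IV_MET")
        assert flag and m == {"PP": 0.0, "PTI": 0.0, "PTI_N": 0.0}

    def test_pti_bounded_by_pp_times_contact(self, jittered_trials):
        trials, _ = jittered_trials
        for seq in trials[:2]:
            fp = peak_pressure_image(seq)
            mask = plantar_angle_masks(fp, seq.markers)
            ct_s = contact_time(seq) / 1000.0
            for name in REGIONS_FOREFOOT:
                m, flag = regional_metrics(seq, mask, name)
                if not flag:
                    assert 0.0 <= m["PTI"] <= m["PP"] * ct_s + 1e-9
                    assert m["PTI_N"] <= m["PP"] + 1e-9


class TestArchIndex:
    def _mask_for(self, fp, markers):
        return plantar_angle_masks(fp, markers, met_offset=-25.0)

    def test_solid_rectangle_is_one_third(self):
        img = _rect_footprint(rows=30, cols=12)
        markers = {
            "CAL": (40, 15), "M1": (55, 120), "M2": (40, 120), "M5": (25, 120),
            "HLX": (55, 170),
        }
        fp = peak_pressure_image(_seq([img], markers))
        ai = arch_index(fp, self._mask_for(fp, markers))
        assert ai == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_lifted_midfoot_gives_zero(self):
        img = _rect_footprint(rows=30, cols=12)
        img[12:22, :] = 0.0  # middle third of rows 2..31 lifted
        markers = {
            "CAL": (40, 15), "M1": (55, 120), "M2": (40, 120), "M5": (25, 120),
            "HLX": (55, 170),
        }
        fp = peak_pressure_image(_seq([img], markers))
        ai = arch_index(fp, self._mask_for(fp, markers))
        assert ai == 0.0

    def test_planted_midfoot_share(self):
        # 30 x 12 rectangle minus 40 symmetric middle-band pixels:
        # middle 80, total 320 -> AI = 0.25 exactly
        img = _rect_footprint(rows=30, cols=12)
        img[15:19, 3:13] = 0.0
        markers = {
            "CAL": (40, 15), "M1": (55, 120), "M2": (40, 120), "M5": (25, 120),
            "HLX": (55, 170),
        }
        fp = peak_pressure_image(_seq([img], markers))
        ai = arch_index(fp, self._mask_for(fp, markers))
        assert ai == pytest.approx(0.25, abs=1e-12)


class TestTrialAveraging:
    def test_five_identical_trials_equal_single(self, clean_trials):
        trials, _ = clean_trials
        from pedarch.pressure import trial_load_variables

        single = trial_load_variables(trials[0])
        load, ct, ai = foot_load_and_func(trials)
        np.testing.assert_allclose(load.values, single.values, rtol=1e-12)
        assert ct == contact_time(trials[0])
        assert list(load.index) == list(LOAD_VARIABLES)
        assert len(load) == 12
        assert 0.0 <= ai <= 1.0

    def test_quarter_turn_grid_invariance(self, clean_trials):
        """A joint 90-degree rotation of frames and markers leaves every
        LOAD metric unchanged (grid rotations are exact)."""
        trials, _ = clean_trials
        seq = trials[0]
        H, W = seq.frames.shape[1:]
        rot_frames = np.rot90(seq.frames, k=1, axes=(1, 2))
        # pixel (r, c) -> (W-1-c, r); in mm: (x, y) -> (y, (W-1)*pitch - x)
        def move(p):
            return (p[1], (W - 1) * seq.pitch - p[0])
        rot = PressureFrameSequence(
            rot_frames, pitch=seq.pitch, dt=seq.dt,
            markers={k: move(v) for k, v in seq.markers.items()},
        )
        from pedarch.pressure import trial_load_variables

        a = trial_load_variables(seq)
        b = trial_load_variables(rot)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)
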