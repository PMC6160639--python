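import numpy as np
import pandas as pd
import pytest

from execsim import connectivity as C
from execsim.core import AcquisitionSpec, Volume4D
from execsim.rois import ROI, ROISet
from execsim.synth import build_nback_schedule, make_connectivity_structure

from conftest import make_events


def vol_from(data, affine=None, tr=2.5):
    return Volume4D(np.asarray(data, float), np.eye(4) if affine is None else affine, tr)


class TestDVARS:
    def test_constant_volume_zero(self):
        v = vol_from(np.full((4, 4, 4, 10), 500.0))
        assert np.allclose(C.compute_dvars(v), 0.0)

    def test_length_t_minus_one(self, rng):
        v = vol_from(rng.normal(1000, 5, size=(4, 4, 4, 17)))
        assert len(C.compute_dvars(v)) == 16

    def test_spike_is_argmax(self, rng):
        data = rng.normal(1000, 1, size=(5, 5, 5, 30))
        data[..., 12] += 50.0  # global spike at frame 12
        d = C.compute_dvars(vol_from(data))
        # differences 11->12 and 12->13 are the two largest
        top2 = set(np.argsort(d)[-2:])
        assert top2 == {11, 12}

    def test_scaling_invariance_via_mode_1000(self, rng):
        data = rng.normal(1000, 5, size=(5, 5, 5, 20))
        d1 = C.compute_dvars(vol_from(data))
        d2 = C.compute_dvars(vol_from(data * 7.0))
        assert np.allclose(d1, d2, rtol=1e-6)

    def test_analytic_prediction_for_white_noise(self, rng):
        sigma = 5.0
        data = 1000.0 + rng.normal(0, sigma, size=(10, 10, 10, 200))
        d = C.compute_dvars(vol_from(data))
        assert d.mean() == pytest.approx(np.sqrt(2) * sigma, rel=0.05)

    def test_empty_mask_raises(self, rng):
        v = vol_from(rng.normal(size=(3, 3, 3, 5)))
        v.mask[:] = False
        with pytest.raises(ValueError):
            C.compute_dvars(v)


class TestOutliersAndExclusion:
    def test_quiet_data_no_flags(self):
        motion = np.zeros((50, 6))
        flags = C.detect_outliers(motion, np.full(50, 1000.0))
        assert not flags.any()

    def test_translation_jump_flagged(self, rng):
        motion = np.zeros((50, 6))
        motion[20:, 0] = 2.0  # 2 mm jump at frame 20
        flags = C.detect_outliers(motion, np.full(50, 1000.0))
        assert flags[20]
        assert flags.sum() == 1
        # oracle: FD at frame 20 = 2.0 > 0.9
        fd = C.framewise_displacement(motion)
        assert fd[20] == pytest.approx(2.0)

    def test_rotation_contributes_via_sphere_radius(self):
        motion = np.zeros((10, 6))
        motion[5:, 3] = 0.02  # radians -> 50 mm * 0.02 = 1 mm
        fd = C.framewise_displacement(motion)
        assert fd[5] == pytest.approx(1.0)

    def test_infinite_thresholds_no_flags(self, rng):
        motion = rng.normal(size=(30, 6))
        flags = C.detect_outliers(
            motion, rng.normal(size=30), fd_max_mm=np.inf, global_z_max=np.inf
        )
        assert not flags.any()

    def test_exclusion_boundary_exactly_25_percent_retained(self):
        motion = np.zeros((100, 6))
        motion[:25, 0] = 3.5  # exactly 25% violating
        assert C.motion_exclusion(motion) is False

    def test_26_percent_excluded(self):
        motion = np.zeros((100, 6))
        motion[:26, 1] = 3.5
        assert C.motion_exclusion(motion) is True

    def test_exactly_3mm_not_a_violation(self):
        motion = np.zeros((100, 6))
        motion[:90, 0] = 3.0  # |t| > 3 is strict
        assert C.motion_exclusion(motion) is False

    def test_zero_motion_retained(self):
        assert C.motion_exclusion(np.zeros((100, 6))) is False


class TestROIExtraction:
    def test_single_voxel_roi(self, rng):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        data = rng.normal(size=(6, 6, 6, 8))
        v = Volume4D(data, affine, 2.5)
        rois = ROISet([ROI(name="a", center_mm=(6.0, 6.0, 6.0), radius_mm=1.0)])
        series = C.extract_roi_timecourses(v, rois)
        assert np.allclose(series["a"].to_numpy(), data[2, 2, 2, :])

    def test_uniform_volume_constant_series(self):
        v = Volume4D(np.full((6, 6, 6, 5), 3.14), np.diag([3, 3, 3, 1.0]), 2.5)
        rois = ROISet([ROI(name="a", center_mm=(7.5, 7.5, 7.5), radius_mm=7.0)])
        series = C.extract_roi_timecourses(v, rois)
        assert np.allclose(series["a"], 3.14)

    def test_membership_matches_bruteforce(self, rng):
        acq = AcquisitionSpec(n_volumes=5, n_dummy=0, grid_shape=(10, 11, 9))
        roi = ROI(name="a", center_mm=(0.0, 3.0, -3.0), radius_mm=7.0)
        member = ROISet([roi]).membership(acq.grid_shape, acq.affine)["a"]
        coords = Volume4D(
            np.zeros(acq.grid_shape + (1,)), acq.affine, 2.5
        ).voxel_centers_mm()
        oracle = np.zeros(acq.grid_shape, bool)
        for idx in np.ndindex(*acq.grid_shape):
            oracle[idx] = (
                np.linalg.norm(coords[idx] - np.array(roi.center_mm)) <= 7.0
            )
        assert np.array_equal(member, oracle)

    def test_empty_roi_raises(self, rng):
        v = Volume4D(rng.normal(size=(4, 4, 4, 5)), np.diag([3, 3, 3, 1.0]), 2.5)
        rois = ROISet([ROI(name="far", center_mm=(500.0, 0.0, 0.0), radius_mm=2.0)])
        with pytest.raises(ValueError, match="far"):
            C.extract_roi_timecourses(v, rois)


class TestConfoundRegression:
    def test_series_equal_to_confound_vanishes(self, rng):
        conf = rng.normal(size=(50,))
        series = pd.DataFrame({"a": conf})
        cs = C.ConfoundSet(wm=conf)
        resid = C.regress_confounds(series, cs)
        assert np.abs(resid["a"]).max() < 1e-10

    def test_orthogonal_series_only_demeaned(self, rng):
        t = np.arange(50, dtype=float)
        conf = np.sin(t)
        conf = conf - conf.mean()  # centered confound
        y = np.cos(2 * t) + 5.0
        # orthogonalize y to the centered confound
        y = y - (y @ conf) / (conf @ conf) * conf
        series = pd.DataFrame({"a": y})
        resid = C.regress_confounds(series, C.ConfoundSet(wm=conf))
        assert np.allclose(resid["a"], y - y.mean(), atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self, rng):
        motion = rng.normal(size=(60, 6))
        wm = rng.normal(size=60)
        series = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        cs = C.ConfoundSet(motion=motion, wm=wm)
        resid = C.regress_confounds(series, cs)
        x = cs.matrix(60)
        assert np.abs(x.T @ resid.to_numpy()).max() < 1e-8


class TestFisherZ:
    def test_zero(self):
        assert C.fisher_z(0.0) == 0.0

    def test_half(self):
        assert C.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_matches_atanh_on_grid(self):
        r = np.linspace(-0.999, 0.999, 2001)
        assert np.abs(C.fisher_z(r) - np.arctanh(r)).max() < 1e-12

    def test_clipping_keeps_finite(self):
        assert np.isfinite(C.fisher_z(1.0))
        assert np.isfinite(C.fisher_z(-1.0))


def _eight_rois():
    rois = []
    for i in range(8):
        rois.append(ROI(name=f"r{i}", center_mm=(float(3 * i), 0.0, 0.0), radius_mm=1.0))
    return ROISet(rois)


class TestTaskwiseConnectivity:
    def _runs(self, rng, n_frames=120, tr=2.5, corr=None):
        events = make_events(
            [
                dict(onset=2.5 * i, duration=2.5, condition="divided_attention",
                     block="b_div")
                for i in range(40)
            ]
        )
        if corr is None:
            data = rng.normal(size=(n_frames, 8))
        else:
            chol = np.linalg.cholesky(corr)
            data = rng.normal(size=(n_frames, 8)) @ chol.T
        series = pd.DataFrame(data, columns=[f"r{i}" for i in range(8)])
        return [(series, events, tr)]

    def test_vector_has_28_values(self, rng):
        vec = C.taskwise_connectivity(self._runs(rng), "DivA", _eight_rois())
        assert len(vec) == 28
        assert len(vec.pair_labels) == 28

    def test_recovers_planted_correlation(self, rng):
        mats, _ = make_connectivity_structure(0.5, rng_seed=0)
        corr = mats["DivA"]
        runs = self._runs(rng, n_frames=60000, corr=corr)
        # stretch block to cover all frames
        runs[0][1].loc[:, "onset"] = np.linspace(0, 60000 * 2.5 - 5, 40)
        runs[0][1].loc[:, "duration"] = 2.5
        vec = C.taskwise_connectivity(runs, "DivA", _eight_rois())
        iu = np.triu_indices(8, 1)
        assert np.abs(vec.r - corr[iu]).max() < 0.05

    def test_too_few_frames_raises(self, rng):
        events = make_events(
            [dict(onset=0.0, duration=2.5, condition="divided_attention", block="b")]
        )
        series = pd.DataFrame(
            rng.normal(size=(100, 8)), columns=[f"r{i}" for i in range(8)]
        )
        with pytest.raises(ValueError):
            C.taskwise_connectivity([(series, events, 2.5)], "DivA", _eight_rois())

    def test_zero_variance_roi_raises(self, rng):
        runs = self._runs(rng)
        runs[0][0]["r3"] = 1.0
        with pytest.raises(ValueError, match="r3"):
            C.taskwise_connectivity(runs, "DivA", _eight_rois())

    def test_affine_rescaling_invariance(self, rng):
        runs = self._runs(rng)
        v1 = C.taskwise_connectivity(runs, "DivA", _eight_rois())
        scaled = runs[0][0].copy()
        scaled["r0"] = 10.0 * scaled["r0"] + 4.0
        v2 = C.taskwise_connectivity([(scaled, runs[0][1], 2.5)], "DivA", _eight_rois())
        assert np.allclose(v1.z, v2.z)

    def test_unknown_task_raises(self, rng):
        with pytest.raises(ValueError):
            C.task_frame_indices(make_events([]), "Oddball", 100, 2.5)


class TestFrameSelection:
    def test_modswi_windows(self):
        events = make_events(
            [
                dict(onset=30.0, duration=0.5, task="nback", condition="2back",
                     modality="visual", switch="post_switch", block="nb"),
            ]
        )
        frames = C.task_frame_indices(events, "ModSwi", 100, 2.5, hrf_lag_frames=2)
        assert frames.tolist() == [14, 15, 16]  # floor(30/2.5) + 2 .. + 4

    def test_block_frames_lagged(self):
        events = make_events(
            [dict(onset=0.0 + 5 * i, duration=2.5, condition="divided_attention",
                  block="b") for i in range(12)]
        )
        frames = C.task_frame_indices(events, "DivA", 100, 2.5, hrf_lag_frames=2)
        assert frames.min() == 2  # shifted by the lag
        assert len(frames) > 8

    def test_long_table_format(self, rng):
        runs_events = make_events(
            [dict(onset=2.5 * i, duration=2.5, condition="divided_attention",
                  block="b") for i in range(40)]
        )
        series = pd.DataFrame(
            rng.normal(size=(120, 8)), columns=[f"r{i}" for i in range(8)]
        )
        vec = C.taskwise_connectivity(
            [(series, runs_events, 2.5)], "DivA", _eight_rois(), participant="p1"
        )
        table = C.connectivity_long_table([vec], cohort="young_adult")
        assert set(table.columns) == {
            "participant", "cohort", "task", "roi_i", "roi_j", "r", "z"
        }
        assert len(table) == 28
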