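import numpy as np
import pandas as pd
import pytest

from execsim import glm as G
from execsim.core import AcquisitionSpec, Volume4D, empty_events
from execsim.synth import (
    build_attention_schedule,
    build_nback_schedule,
    make_activation_atlas,
    simulate_bold,
)

from conftest import make_events


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        assert G.canonical_hrf(0.0) == 0.0

    def test_peak_between_4_and_6_seconds(self):
        grid = np.arange(0.0, 30.0, 0.1)
        vals = G.canonical_hrf(grid)
        assert 4.0 <= grid[np.argmax(vals)] <= 6.0
        assert vals.max() == pytest.approx(1.0, abs=1e-3)

    def test_decays_to_zero_by_32s(self):
        assert abs(G.canonical_hrf(31.9)) < 1e-2

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            G.canonical_hrf(-1.0)


class TestDropDummies:
    def test_frame_count(self, rng):
        vol = Volume4D(rng.normal(size=(4, 4, 4, 222)), np.eye(4), 2.5)
        out = G.drop_dummies(vol, 4)
        assert out.n_frames == 218

    def test_zero_is_identity(self, rng):
        vol = Volume4D(rng.normal(size=(4, 4, 4, 10)), np.eye(4), 2.5)
        out = G.drop_dummies(vol, 0)
        assert np.array_equal(out.data, vol.data)

    def test_onset_shift(self, rng):
        vol = Volume4D(rng.normal(size=(2, 2, 2, 10)), np.eye(4), 2.5)
        events = make_events([dict(onset=10.0, duration=2.5)])
        _, shifted = G.drop_dummies(vol, 4, events)
        assert shifted["onset"].iloc[0] == pytest.approx(0.0)

    def test_too_many_dummies(self, rng):
        vol = Volume4D(rng.normal(size=(2, 2, 2, 5)), np.eye(4), 2.5)
        with pytest.raises(ValueError):
            G.drop_dummies(vol, 5)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        vol = Volume4D(rng.normal(size=(6, 6, 6, 3)), np.diag([3, 3, 3, 1.0]), 2.5)
        out = G.smooth_gaussian(vol, 0.0)
        assert np.array_equal(out.data, vol.data)

    def test_constant_volume_unchanged(self):
        vol = Volume4D(np.full((8, 8, 8, 2), 7.0), np.diag([3, 3, 3, 1.0]), 2.5)
        out = G.smooth_gaussian(vol, 6.0)
        assert np.allclose(out.data, 7.0)

    def test_interior_impulse_mass_conserved(self):
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 1.0
        vol = Volume4D(data, np.diag([3, 3, 3, 1.0]), 2.5)
        out = G.smooth_gaussian(vol, 6.0)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-6)

    def test_negative_fwhm_rejected(self, rng):
        vol = Volume4D(rng.normal(size=(4, 4, 4, 2)), np.eye(4), 2.5)
        with pytest.raises(ValueError):
            G.smooth_gaussian(vol, -1.0)


class TestDesignMatrix:
    def test_empty_events_nuisance_only(self):
        X = G.build_design_matrix(empty_events(), (100, 2.5))
        assert "constant" in X.labels
        assert all(lab.startswith("dct_") or lab == "constant" for lab in X.labels)

    def test_dct_count_closed_form(self):
        # floor(2 * run_seconds / cutoff) columns
        X = G.build_design_matrix(empty_events(), (218, 2.5), hp_cutoff_seconds=128.0)
        n_dct = sum(lab.startswith("dct_") for lab in X.labels)
        assert n_dct == int(np.floor(2 * 218 * 2.5 / 128.0)) == 8

    def test_block_response_peak_lags_onset(self):
        events = make_events(
            [dict(onset=30.0 + 2.5 * i, duration=2.5) for i in range(12)]
        )
        X = G.build_design_matrix(events, (100, 2.5))
        col = [lab for lab in X.labels if lab.startswith("divided")][0]
        series = X.values[col].to_numpy()
        t_peak = np.argmax(series) * 2.5
        assert t_peak > 30.0 + 2.5  # peak lags block onset hemodynamically

    def test_motion_columns_and_shape_check(self, rng):
        motion = rng.normal(size=(100, 6))
        X = G.build_design_matrix(empty_events(), (100, 2.5), motion=motion)
        assert sum(lab.startswith("motion_") for lab in X.labels) == 6
        with pytest.raises(ValueError):
            G.build_design_matrix(empty_events(), (100, 2.5), motion=motion[:50])

    def test_event_past_run_end_rejected(self):
        events = make_events([dict(onset=260.0, duration=2.5)])
        with pytest.raises(ValueError):
            G.build_design_matrix(events, (100, 2.5))


class TestFitGLM:
    def test_noiseless_recovery_exact(self, rng):
        x = rng.normal(size=(40, 4))
        x[:, 0] = 1.0
        X = G.DesignMatrix(
            values=pd.DataFrame(x, columns=["constant", "a", "b", "c"]),
            convolved={},
        )
        b_true = rng.normal(size=(4, 5))
        y = x @ b_true
        res = G.fit_glm_ols(y, X)
        assert np.abs(res.betas - b_true).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=(40, 4))
        x[:, 0] = 1.0
        X = G.DesignMatrix(
            values=pd.DataFrame(x, columns=["constant", "a", "b", "c"]),
            convolved={},
        )
        y = rng.normal(size=(40, 5))
        res = G.fit_glm_ols(y, X)
        # independent oracle: pseudoinverse normal equations
        b_or = np.linalg.pinv(x) @ y
        resid = y - x @ b_or
        s2 = (resid**2).sum(0) / (40 - 4)
        xtx_inv = np.linalg.inv(x.T @ x)
        for j in range(4):
            t_or = b_or[j] / np.sqrt(s2 * xtx_inv[j, j])
            t_mine = res.betas[j] / np.sqrt(res.sigma2 * res.xtx_inv[j, j])
            assert np.abs(t_or - t_mine).max() < 1e-8

    def test_duplicated_column_raises(self, rng):
        x = rng.normal(size=(30, 2))
        x = np.column_stack([x, x[:, 1]])
        X = G.DesignMatrix(
            values=pd.DataFrame(x, columns=["a", "b", "b_copy"]), convolved={}
        )
        with pytest.raises(ValueError, match="collinear"):
            G.fit_glm_ols(rng.normal(size=(30, 2)), X)

    def test_betas_linear_in_data(self, rng):
        x = rng.normal(size=(30, 3))
        X = G.DesignMatrix(
            values=pd.DataFrame(x, columns=["a", "b", "c"]), convolved={}
        )
        y = rng.normal(size=(30, 4))
        r1 = G.fit_glm_ols(y, X)
        r2 = G.fit_glm_ols(3.5 * y, X)
        assert np.allclose(r2.betas, 3.5 * r1.betas)


class TestContrasts:
    @pytest.fixture
    def attention_design(self, att_acq):
        events = build_attention_schedule(1, att_acq, rng_seed=0)
        from execsim.core import shift_event_onsets

        events = shift_event_onsets(events, att_acq.dummy_seconds)
        return G.build_design_matrix(
            events, (att_acq.n_volumes - att_acq.n_dummy, att_acq.tr_seconds)
        )

    @pytest.fixture
    def nback_design(self, nb_acq):
        events = build_nback_schedule(1, nb_acq, rng_seed=0)
        from execsim.core import shift_event_onsets

        events = shift_event_onsets(events, nb_acq.dummy_seconds)
        return G.build_design_matrix(
            events, (nb_acq.n_volumes - nb_acq.n_dummy, nb_acq.tr_seconds)
        )

    def test_diva_weights_sum_to_zero(self, attention_design):
        specs = G.make_executive_contrasts(attention_design)
        assert specs["DivA"].weights.sum() == pytest.approx(0.0, abs=1e-12)
        assert specs["DistrA"].weights.sum() == pytest.approx(0.0, abs=1e-12)

    def test_wm_excludes_switch_columns(self, nback_design):
        specs = G.make_executive_contrasts(nback_design)
        for lab in specs["WM"].weights.index:
            assert "|non|" in lab  # nonswitch trials only

    def test_modswi_post_minus_pre(self, nback_design):
        specs = G.make_executive_contrasts(nback_design)
        w = specs["ModSwi"].weights
        assert all("|post|" in lab for lab in w.index[w > 0])
        assert all("|pre|" in lab for lab in w.index[w < 0])

    def test_missing_members_raise(self):
        X = G.build_design_matrix(empty_events(), (50, 2.5))
        with pytest.raises(ValueError):
            G.make_executive_contrasts(X)

    def test_estimability(self, attention_design):
        specs = G.make_executive_contrasts(attention_design)
        labels = attention_design.labels
        x = attention_design.matrix()
        for spec in specs.values():
            c = spec.vector(labels)
            # weight vector lies in the row space of X
            proj = x.T @ np.linalg.lstsq(x.T, c, rcond=None)[0]
            assert np.allclose(proj, c, atol=1e-8)

    def test_equal_amplitudes_give_zero_t(self, rng):
        # planted divided == distracted amplitude -> DivA t ~ 0
        acq = AcquisitionSpec(
            n_volumes=222, n_dummy=4, grid_shape=(6, 6, 6)
        )
        schedule = build_attention_schedule(1, acq, rng_seed=1)
        amp = np.zeros((6, 6, 6))
        amp[2:4, 2:4, 2:4] = 1.0
        atlas = {"DivA": np.zeros((6, 6, 6)), "DistrA": amp,
                 "WM": np.zeros((6, 6, 6)), "ModSwi": np.zeros((6, 6, 6))}
        sim = simulate_bold(schedule, atlas, {}, acq, rng_seed=0,
                            noise_sd=0.0, drift_sd=0.0)
        vol, events = G.drop_dummies(sim.volume, acq.n_dummy, sim.events)
        X = G.build_design_matrix(events, (vol.n_frames, acq.tr_seconds))
        fit = G.fit_glm_ols(vol, X)
        spec = G.make_executive_contrasts(X)["DivA"]
        effect, _ = G.contrast_effect_variance(fit, spec)
        assert np.abs(effect).max() < 1e-8


class TestParameterRecovery:
    def test_noiseless_amplitude_recovery(self):
        acq = AcquisitionSpec(n_volumes=222, n_dummy=4, grid_shape=(10, 10, 10))
        schedule = build_attention_schedule(1, acq, rng_seed=3)
        atlas, _, _ = make_activation_atlas(0.4, acq, sigma_mm=6.0)
        sim = simulate_bold(schedule, atlas, {}, acq, rng_seed=0,
                            noise_sd=0.0, drift_sd=0.0)
        vol, events = G.drop_dummies(sim.volume, acq.n_dummy, sim.events)
        X = G.build_design_matrix(events, (vol.n_frames, acq.tr_seconds))
        fit = G.fit_glm_ols(vol, X)
        specs = G.make_executive_contrasts(X)
        for name in ("DivA", "DistrA"):
            effect, _ = G.contrast_effect_variance(fit, specs[name])
            planted = atlas[name][vol.mask]
            scale = max(planted.max(), 1e-12)
            assert np.abs(effect - planted).max() / scale < 1e-6


class TestGroupLevel:
    def _map(self, data, mask=None):
        mask = np.ones(data.shape, bool) if mask is None else mask
        return G.ContrastMap(
            t=data, effect=data, df=10, level="participant",
            affine=np.eye(4), mask=mask,
        )

    def test_identical_nonzero_maps_capped(self):
        data = np.full((4, 4, 4), 2.0)
        maps = [self._map(data.copy()) for _ in range(5)]
        out = G.group_level_t(maps)
        assert np.all(out.t == G.GROUP_T_CAP)

    def test_alternating_signs_give_zero(self):
        data = np.full((4, 4, 4), 3.0)
        maps = [self._map(data * (1 if i % 2 == 0 else -1)) for i in range(6)]
        out = G.group_level_t(maps)
        assert np.allclose(out.t, 0.0)

    def test_matches_one_sample_t_oracle(self, rng):
        stack = rng.normal(size=(5, 5, 5, 10))
        maps = [self._map(stack[..., i]) for i in range(10)]
        out = G.group_level_t(maps)
        for vox in [(0, 0, 0), (2, 3, 1), (4, 4, 4)]:
            v = stack[vox]
            t_or = v.mean() / (v.std(ddof=1) / np.sqrt(10))
            assert out.t[vox] == pytest.approx(t_or, abs=1e-10)

    def test_grid_mismatch_raises(self, rng):
        a = self._map(rng.normal(size=(4, 4, 4)))
        b = self._map(rng.normal(size=(5, 5, 5)))
        with pytest.raises(ValueError):
            G.group_level_t([a, b])

    def test_needs_two_maps(self, rng):
        with pytest.raises(ValueError):
            G.group_level_t([self._map(rng.normal(size=(3, 3, 3)))])
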