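import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcbp import connectivity as conn
from rcbp.types import BoldSeries, ConfoundTable
from conftest import as_matrix


def mk_series(data, tr=0.72, voxel_mm=2.0):
    return BoldSeries(data=np.asarray(data, float),
                      affine=np.diag([voxel_mm] * 3 + [1.0]), tr_seconds=tr)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        s = mk_series(rng.standard_normal((4, 4, 4, 5)))
        out = conn.smooth_bold(s, conn.SmoothingSpec(0.0))
        assert out is s

    def test_constant_volume_unchanged(self):
        s = mk_series(np.full((6, 6, 6, 3), 3.5))
        out = conn.smooth_bold(s, conn.SmoothingSpec(5.0))
        assert np.allclose(out.data, 3.5)

    def test_impulse_peak_matches_discrete_gaussian(self):
        # closed-form oracle: separable normalized sampled Gaussian
        fwhm, voxel = 5.0, 2.0
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        radius = int(4.0 * sigma_vox + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma_vox) ** 2)
        w /= w.sum()
        expected_peak = w[radius] ** 3
        data = np.zeros((15, 15, 15, 2))
        data[7, 7, 7, 0] = 1.0
        out = conn.smooth_bold(mk_series(data, voxel_mm=voxel),
                               conn.SmoothingSpec(fwhm))
        assert out.data[7, 7, 7, 0] == pytest.approx(expected_peak, rel=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            conn.SmoothingSpec(-1.0)


class TestNuisanceRegression:
    def test_confound_equal_to_series_zeroes_it(self, rng):
        ts = rng.standard_normal(50)
        data = np.tile(ts, (2, 2, 2, 1))
        out = conn.regress_nuisance(mk_series(data),
                                    ConfoundTable(column_names=["c"],
                                                  values=ts[:, None]))
        assert np.allclose(out.data, 0, atol=1e-10)

    def test_orthogonal_confound_leaves_demeaned_series(self, rng):
        t = np.arange(64)
        series = np.sin(2 * np.pi * 4 * t / 64)       # zero mean
        confound = np.cos(2 * np.pi * 4 * t / 64)     # orthogonal over full periods
        data = series.reshape(1, 1, 1, -1)
        out = conn.regress_nuisance(mk_series(data),
                                    ConfoundTable(column_names=["c"],
                                                  values=confound[:, None]))
        assert np.allclose(out.data[0, 0, 0], series, atol=1e-10)

    def test_constant_only_design_demeans(self, rng):
        data = rng.standard_normal((2, 2, 1, 30)) + 5.0
        out = conn.regress_nuisance(mk_series(data),
                                    ConfoundTable(column_names=["one"],
                                                  values=np.ones((30, 1))))
        assert np.allclose(out.data, data - data.mean(axis=-1, keepdims=True))

    def test_residuals_orthogonal_to_confounds(self, rng):
        data = rng.standard_normal((3, 3, 3, 60))
        confounds = ConfoundTable(column_names=["a", "b"],
                                  values=rng.standard_normal((60, 2)))
        out = conn.regress_nuisance(mk_series(data), confounds)
        resid = out.data.reshape(-1, 60)
        dots = resid @ confounds.values
        scale = np.abs(resid).sum() * np.abs(confounds.values).max()
        assert np.all(np.abs(dots) <= 1e-8 * max(scale, 1.0))

    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="timepoints"):
            conn.regress_nuisance(mk_series(np.zeros((2, 2, 2, 10))),
                                  ConfoundTable(column_names=["c"],
                                                values=np.zeros((9, 1))))

    def test_motion_expansion_makes_24_from_6(self, rng):
        table = ConfoundTable(column_names=[f"m{i}" for i in range(6)],
                              values=rng.standard_normal((40, 6)))
        expanded = conn.expand_motion_confounds(table)
        assert len(expanded.column_names) == 24
        assert expanded.values.shape == (40, 24)


class TestBandpass:
    def test_midband_sinusoid_amplitude_preserved(self):
        tr = 0.72
        t = np.arange(400) * tr
        sig = np.sin(2 * np.pi * 0.04 * t)
        out = conn.bandpass(mk_series(sig.reshape(1, 1, 1, -1), tr=tr),
                            conn.BandpassSpec(0.01, 0.08))
        # FFT amplitude oracle at the driven frequency
        freqs = np.fft.rfftfreq(len(t), tr)
        bin_ = np.argmin(np.abs(freqs - 0.04))
        a_in = np.abs(np.fft.rfft(sig))[bin_]
        a_out = np.abs(np.fft.rfft(out.data[0, 0, 0]))[bin_]
        assert a_out == pytest.approx(a_in, rel=0.05)

    def test_dc_removed(self):
        out = conn.bandpass(mk_series(np.full((1, 1, 1, 300), 7.0), tr=0.72),
                            conn.BandpassSpec(0.01, 0.08))
        assert abs(out.data.mean()) < 1e-6

    def test_stopband_attenuated(self):
        tr = 0.72
        t = np.arange(400) * tr
        sig = np.sin(2 * np.pi * 0.16 * t)  # 2x high cut
        out = conn.bandpass(mk_series(sig.reshape(1, 1, 1, -1), tr=tr),
                            conn.BandpassSpec(0.01, 0.08))
        freqs = np.fft.rfftfreq(len(t), tr)
        bin_ = np.argmin(np.abs(freqs - 0.16))
        a_in = np.abs(np.fft.rfft(sig))[bin_]
        a_out = np.abs(np.fft.rfft(out.data[0, 0, 0]))[bin_]
        assert a_out <= a_in / 10

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            conn.bandpass(mk_series(np.zeros((1, 1, 1, 100)), tr=10.0),
                          conn.BandpassSpec(0.01, 0.08))


class TestComputeFc:
    def idx(self, n):
        return np.c_[np.arange(n), np.zeros((n, 2), dtype=int)]

    def test_identical_series_correlate_one(self, rng):
        ts = rng.standard_normal((1, 100))
        m = conn.compute_fc(ts, ts, self.idx(1))
        assert m.values[0, 0] == pytest.approx(1.0)

    def test_negated_series_correlate_minus_one(self, rng):
        ts = rng.standard_normal((1, 100))
        m = conn.compute_fc(ts, -ts, self.idx(1))
        assert m.values[0, 0] == pytest.approx(-1.0)

    def test_quadrature_sinusoids_uncorrelated(self):
        t = np.arange(200)
        sin = np.sin(2 * np.pi * 5 * t / 200)[None, :]
        cos = np.cos(2 * np.pi * 5 * t / 200)[None, :]
        m = conn.compute_fc(sin, cos, self.idx(1))
        assert abs(m.values[0, 0]) < 1e-10

    def test_zero_variance_series_give_zero(self, rng):
        roi = np.vstack([np.ones(50), rng.standard_normal(50)])
        tgt = rng.standard_normal((3, 50))
        m = conn.compute_fc(roi, tgt, self.idx(2))
        assert np.allclose(m.values[0], 0.0)
        assert np.all(np.abs(m.values[1]) <= 1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.1, 10), st.floats(-5, 5))
    def test_invariant_to_positive_affine_rescaling(self, seed, a, b):
        rng = np.random.default_rng(seed)
        roi = rng.standard_normal((3, 40))
        tgt = rng.standard_normal((4, 40))
        m1 = conn.compute_fc(roi, tgt, self.idx(3))
        m2 = conn.compute_fc(a * roi + b, tgt, self.idx(3))
        assert np.allclose(m1.values, m2.values, atol=1e-10)


class TestTransforms:
    def test_fisher_z_values(self):
        m = as_matrix([[0.0, 0.5]])
        out = conn.fisher_z(m)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(0.5493061443, abs=1e-9)
        assert out.transform_log[-1] == "fisher_z"

    def test_fisher_z_clips_unit_correlation(self):
        out = conn.fisher_z(as_matrix([[1.0, -1.0]]))
        assert np.all(np.isfinite(out.values))
        assert out.values[0, 0] > 10

    def test_fisher_z_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            conn.fisher_z(as_matrix([[1.5]]))

    def test_cubic_signed_root(self):
        out = conn.cubic_transform(as_matrix([[8.0, 0.0, -27.0]]))
        assert np.allclose(out.values, [[2.0, 0.0, -3.0]])
        assert out.transform_log[-1] == "cubic"

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_fisher_z_and_cubic_strictly_monotone_and_odd(self, x, y):
        fz = lambda v: conn.fisher_z(as_matrix([[v]])).values[0, 0]
        cb = lambda v: conn.cubic_transform(as_matrix([[v]])).values[0, 0]
        for f in (fz, cb):
            assert f(-x) == pytest.approx(-f(x), abs=1e-12)
            if x < y:
                assert f(x) < f(y)


class TestPca:
    def test_rank_one_matrix_exact_with_one_component(self, rng):
        u = rng.standard_normal((10, 1))
        v = rng.standard_normal((1, 6))
        m = as_matrix(u @ v)
        out = conn.pca_reduce(m, 1)
        centered = m.values - m.values.mean(axis=0)
        assert np.allclose((out.values ** 2).sum(), (centered ** 2).sum())

    def test_all_components_keep_total_variance(self, rng):
        m = as_matrix(rng.standard_normal((8, 5)))
        out = conn.pca_reduce(m, 5)
        centered = m.values - m.values.mean(axis=0)
        assert (out.values ** 2).sum() == pytest.approx((centered ** 2).sum(),
                                                        rel=1e-9)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((20, 7))
        out = conn.pca_reduce(as_matrix(X), 3)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1][:3]
        oracle = Xc @ evecs[:, order]
        assert np.allclose(np.abs(out.values), np.abs(oracle), atol=1e-8)

    def test_infeasible_count_rejected(self, rng):
        with pytest.raises(ValueError):
            conn.pca_reduce(as_matrix(rng.standard_normal((4, 3))), 5)


class TestPipelineOrder:
    def test_transform_log_records_canonical_order(self, tiny_design):
        from rcbp.synthetic import make_bold_cohort
        cohort = make_bold_cohort(tiny_design, n_timepoints=80,
                                  inject_confounds=True)
        m = conn.rsfmri_connectivity(
            cohort.roi_series[0], cohort.roi_mask, cohort.target_mask,
            smoothing=conn.SmoothingSpec(4.0),
            confounds=cohort.confounds[0],
            band=conn.BandpassSpec(0.01, 0.08),
            apply_fisher_z=True)
        assert m.transform_log == ["smooth(4.0mm)", "nuisance_regression",
                                   "bandpass(0.01-0.08Hz)",
                                   "pearson_correlation", "fisher_z"]
        assert m.n_voxels == cohort.roi_mask.n_voxels
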