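"""Nuisance regression, filtering, volume dropping, ROI extraction."""

import numpy as np
import pytest

from dynconn.conditioning import (
    ConfoundSet,
    compcor_components,
    drop_initial_volumes,
    extract_roi_series,
    lowpass_filter,
    two_stage_nuisance_regression,
)
from dynconn.regions import load_region_table
from dynconn.series import RoiSeries


def _series(values, tr=2.0, runs=None):
    values = np.asarray(values, dtype=float)
    runs = runs or [(0, values.shape[0])]
    ids = [f"R{i:02d}" for i in range(values.shape[1])]
    return RoiSeries(values=values, tr_seconds=tr, run_boundaries=runs,
                     region_ids=ids)


class TestDropInitialVolumes:
    def test_drops_three_per_run(self):
        s = _series(np.arange(600.0).reshape(300, 2))
        out = drop_initial_volumes(s, n=3)
        assert out.n_volumes == 297
        assert out.values[0, 0] == s.values[3, 0]

    def test_identity_for_zero(self):
        s = _series(np.random.default_rng(0).normal(size=(20, 2)))
        out = drop_initial_volumes(s, n=0)
        np.testing.assert_array_equal(out.values, s.values)

    def test_short_run_errors(self):
        s = _series(np.zeros((5, 2)), runs=[(0, 2), (2, 5)])
        with pytest.raises(ValueError, match="cannot drop"):
            drop_initial_volumes(s, n=3)

    def test_multi_run_reindexing(self):
        s = _series(np.arange(40.0).reshape(20, 2), runs=[(0, 10), (10, 20)])
        out = drop_initial_volumes(s, n=2)
        assert out.run_boundaries == [(0, 8), (8, 16)]
        assert out.values[8, 0] == s.values[12, 0]


class TestCompCor:
    def test_recovers_planted_sinusoid(self, rng):
        t = np.arange(200)
        sinus = np.sin(2 * np.pi * t / 50)
        load = rng.uniform(0.5, 2.0, size=50)
        noise = np.outer(sinus, load) + 1e-3 * rng.standard_normal((200, 50))
        comps = compcor_components(noise, n_components=5)
        r = np.corrcoef(comps[:, 0], sinus)[0, 1]
        assert abs(r) > 0.99

    def test_orthonormal_scores(self, rng):
        X = rng.standard_normal((100, 30))
        comps = compcor_components(X, n_components=5)
        gram = comps.T @ comps
        np.testing.assert_allclose(gram, 100 * np.eye(5), atol=1e-8)

    def test_too_few_voxels_errors(self, rng):
        with pytest.raises(ValueError, match="at least"):
            compcor_components(rng.standard_normal((50, 3)), n_components=5)

    def test_constant_columns_dropped(self, rng):
        X = rng.standard_normal((80, 10))
        X[:, 0] = 7.0
        comps = compcor_components(X, n_components=5)
        assert comps.shape == (80, 5)


class TestNuisanceRegression:
    def test_residuals_orthogonal_to_regressors(self, rng):
        T = 120
        motion = rng.standard_normal((T, 6))
        noise = rng.standard_normal((T, 40))
        s = _series(rng.standard_normal((T, 4)))
        conf = ConfoundSet(motion=motion, noise_roi_series=noise)
        out = two_stage_nuisance_regression(s, conf)
        t = np.linspace(-1, 1, T)
        regressors = np.column_stack([np.ones(T), t, t**2, motion])
        for j in range(4):
            resid = out.values[:, j]
            for k in range(regressors.shape[1]):
                reg = regressors[:, k]
                cos = resid @ reg / (np.linalg.norm(resid) * np.linalg.norm(reg))
                assert abs(cos) < 1e-8

    def test_quadratic_trend_removed_exactly(self):
        t = np.linspace(-1, 1, 100)
        s = _series(np.outer(3 * t**2 - t + 2, np.ones(3)))
        out = two_stage_nuisance_regression(s, ConfoundSet())
        assert np.max(np.abs(out.values)) < 1e-8

    def test_signal_orthogonal_to_confounds_survives(self):
        T = 200
        t = np.arange(T)
        sig = np.sin(2 * np.pi * t / 7.3)  # fast sinusoid, not a trend
        s = _series(sig[:, None])
        out = two_stage_nuisance_regression(s, ConfoundSet())
        r = np.corrcoef(out.values[:, 0], sig)[0, 1]
        assert r > 0.99

    def test_idempotent(self, rng):
        T = 150
        conf = ConfoundSet(motion=rng.standard_normal((T, 6)))
        s = _series(rng.standard_normal((T, 3)))
        once = two_stage_nuisance_regression(s, conf)
        twice = two_stage_nuisance_regression(once, conf)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)

    def test_per_run_independence(self, rng):
        """Regression is per-run: each run's residuals are unaffected by
        the other run's data."""
        A = rng.standard_normal((50, 2))
        B = rng.standard_normal((50, 2))
        sAB = _series(np.vstack([A, B]), runs=[(0, 50), (50, 100)])
        out = two_stage_nuisance_regression(sAB, ConfoundSet())
        sA = _series(A)
        outA = two_stage_nuisance_regression(sA, ConfoundSet())
        np.testing.assert_allclose(out.values[:50], outA.values, atol=1e-10)

    def test_misaligned_confounds_error(self, rng):
        s = _series(rng.standard_normal((50, 2)))
        with pytest.raises(ValueError, match="rows"):
            two_stage_nuisance_regression(
                s, ConfoundSet(motion=rng.standard_normal((49, 6)))
            )


class TestLowpass:
    def test_dc_gain_unity(self):
        s = _series(np.full((100, 2), 5.0))
        out = lowpass_filter(s, 0.1)
        np.testing.assert_allclose(out.values, 5.0, atol=1e-8)

    @pytest.mark.parametrize(
        "freq,bound,kind",
        [(0.2, 0.10, "stop"), (0.01, 0.95, "pass")],
    )
    def test_transfer_function(self, freq, bound, kind):
        tr = 2.0
        t = np.arange(600) * tr
        sig = np.sin(2 * np.pi * freq * t)
        out = lowpass_filter(_series(sig[:, None], tr=tr), 0.1)
        # steady-state amplitude away from the edges
        amp = np.max(np.abs(out.values[100:-100, 0]))
        if kind == "stop":
            assert amp < bound
        else:
            assert amp > bound

    def test_cutoff_above_nyquist_errors(self):
        s = _series(np.zeros((50, 1)), tr=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(s, 0.3)


class TestExtractRoi:
    @staticmethod
    def _images(rng, shape=(40, 40, 30), T=5):
        import nibabel as nib

        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        affine[:3, 3] = [-80, -80, -60]
        data = rng.standard_normal(shape + (T,))
        bold = nib.Nifti1Image(data, affine)
        mask = nib.Nifti1Image(np.ones(shape, dtype=np.int16), affine)
        return bold, mask, data

    def test_k30_voxels_mean(self, rng):
        bold, mask, data = self._images(rng)
        table = load_region_table()
        out = extract_roi_series(bold, table, mask, k=30, tr_seconds=2.0)
        assert out.values.shape == (5, 14)
        # cross-check one region by brute force
        affine = bold.affine
        vox = np.array(np.nonzero(np.asanyarray(mask.dataobj) > 0)).T
        mm = vox @ affine[:3, :3].T + affine[:3, 3]
        peak = table.mni_xyz[0]
        d = np.linalg.norm(mm - peak, axis=1)
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], d))
        sel = vox[order[:30]]
        expected = data[sel[:, 0], sel[:, 1], sel[:, 2], :].mean(axis=0)
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)

    def test_single_voxel_mask_k1(self, rng):
        import nibabel as nib

        bold, _, data = self._images(rng)
        m = np.zeros((40, 40, 30), dtype=np.int16)
        m[22, 17, 19] = 1  # some voxel
        mask = nib.Nifti1Image(m, bold.affine)
        table = load_region_table()
        with pytest.warns(UserWarning, match="using all"):
            out = extract_roi_series(bold, table, mask, k=30, tr_seconds=2.0)
        np.testing.assert_allclose(out.values[:, 3], data[22, 17, 19, :])

    def test_peak_outside_grid_errors(self, rng):
        bold, mask, _ = self._images(rng)
        table = load_region_table()
        table.mni_xyz[0] = [1e3, 1e3, 1e3]
        with pytest.raises(ValueError, match="outside"):
            extract_roi_series(bold, table, mask, k=30)

    def test_row_order_invariance(self, rng):
        bold, mask, _ = self._images(rng)
        table = load_region_table()
        out1 = extract_roi_series(bold, table, mask, k=10, tr_seconds=2.0)
        perm = np.random.default_rng(0).permutation(14)
        from dynconn.regions import RegionTable

        shuffled = RegionTable(
            labels=[table.labels[i] for i in perm],
            hemispheres=[table.hemispheres[i] for i in perm],
            mni_xyz=table.mni_xyz[perm],
        )
        out2 = extract_roi_series(bold, shuffled, mask, k=10, tr_seconds=2.0)
        np.testing.assert_allclose(out2.values, out1.values[:, perm],
                                   atol=1e-12)
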