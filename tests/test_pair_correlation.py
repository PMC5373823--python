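"""Correlation functions, variance model, density estimator, PMF transforms."""

import numpy as np
import pytest
from scipy import signal

from phasecorr.loc_data import LocalizationTable, RoiMask, reconstruct_image
from phasecorr.pair_correlation import (
    CorrelationResult,
    average_cells,
    crosscorr_direct,
    crosscorr_fft,
    density_from_autocorr,
    pmf_from_corr,
    subtract_offset,
    variance_dc1,
    variance_dc2,
)
from phasecorr.synthetic_data import (
    BlinkModel,
    SceneSpec,
    generate_scene,
    generate_topology_mask,
    sample_localizations,
)


def _uniform_table(rng, n, fov, channel):
    return LocalizationTable.from_arrays(
        rng.uniform(0, fov, n), rng.uniform(0, fov, n), 0, channel
    )


def brute_force_crosscorr(locs_a, locs_b, mask, dr, r_max):
    """Independent O(N^2) oracle: explicit double loop over pixel-snapped pairs
    and direct (non-FFT) mask autocorrelation via scipy.signal.correlate2d."""
    ra, ca = mask.pixel_indices(locs_a.x, locs_a.y)
    rb, cb = mask.pixel_indices(locs_b.x, locs_b.y)
    ny, nx = mask.shape

    def _keep(r, c):
        ok = (r >= 0) & (r < ny) & (c >= 0) & (c < nx)
        ok[ok] &= mask.mask[r[ok], c[ok]]
        return r[ok], c[ok]

    ra, ca = _keep(ra, ca)
    rb, cb = _keep(rb, cb)
    edges = np.arange(0.0, r_max + dr, dr)
    nb = len(edges) - 1
    counts = np.zeros(nb)
    px = mask.pixel_size
    for i in range(len(ra)):
        d = np.hypot(rb - ra[i], cb - ca[i]) * px
        di = np.digitize(d, edges) - 1  # half-open [edge_k, edge_{k+1})
        ok = (di >= 0) & (di < nb)
        counts += np.bincount(di[ok], minlength=nb)
    mc = signal.correlate2d(mask.mask.astype(float), mask.mask.astype(float), mode="full")
    lag_y = np.arange(mc.shape[0]) - (ny - 1)
    lag_x = np.arange(mc.shape[1]) - (nx - 1)
    lr = np.hypot(lag_y[:, None], lag_x[None, :]) * px
    s = mask.mask.sum()
    expected = np.zeros(nb)
    idx = np.digitize(lr.ravel(), edges) - 1
    sel = (idx >= 0) & (idx < nb)
    expected = np.bincount(
        idx[sel], weights=mc.ravel()[sel] * len(ra) * len(rb) / s**2, minlength=nb
    )
    return counts / expected


class TestRouteEquivalence:
    @pytest.mark.parametrize("scenario", ["random", "co_clustered", "hole_mask"])
    def test_direct_equals_fft(self, scenario, rng):
        fov = 5000.0
        if scenario == "hole_mask":
            _, mask = generate_topology_mask((fov, fov), (2500.0, 2500.0), 800.0)
        else:
            mask = RoiMask.rectangle(fov, fov)
        if scenario == "co_clustered":
            spec = SceneSpec(mode="co_clustered", fov_nm=(fov, fov), n_discs=20, seed=2)
            locs = sample_localizations(generate_scene(spec), BlinkModel(), seed=3)
            locs_a, locs_b = locs.select_channel("a"), locs.select_channel("b")
        else:
            locs_a = _uniform_table(rng, 2500, fov, "a")
            locs_b = _uniform_table(rng, 2500, fov, "b")
        res_d = crosscorr_direct(locs_a, locs_b, mask, r_max=800.0)
        res_f = crosscorr_fft(
            reconstruct_image(locs_a, mask), reconstruct_image(locs_b, mask), mask, r_max=800.0
        )
        ok = np.isfinite(res_f.c) & (res_f.c > 0)
        rel = np.abs(res_d.c[ok] - res_f.c[ok]) / res_f.c[ok]
        assert rel.max() < 1e-6
        assert np.allclose(res_d.counts, res_f.counts, rtol=1e-9, atol=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        fov = 1500.0
        mask = RoiMask.rectangle(fov, fov)
        spec = SceneSpec(
            mode="co_clustered", fov_nm=(fov, fov), n_discs=6, disc_radius_nm=50.0,
            molecules_per_disc=8, seed=4,
        )
        locs = sample_localizations(
            generate_scene(spec), BlinkModel(mean_observations=5.0, localization_sigma=20.0),
            seed=5,
        )
        locs_a, locs_b = locs.select_channel("a"), locs.select_channel("b")
        res = crosscorr_direct(locs_a, locs_b, mask, r_max=500.0)
        oracle = brute_force_crosscorr(locs_a, locs_b, mask, 25.0, 500.0)
        assert np.allclose(res.c, oracle, rtol=1e-9)
        # co-clustering: strong short-range enrichment decaying to ~1
        assert res.c[0] > 2.0
        assert abs(np.nanmean(res.c[res.r > 300]) - 1.0) < 0.5


class TestNormalization:
    def test_flat_images_give_unity(self, small_mask):
        img = reconstruct_image(
            LocalizationTable.from_arrays([10.0], [10.0], [0], "a"), small_mask
        )
        img.counts[:] = 3.0  # constant intensity everywhere in the mask
        res = crosscorr_fft(img, img, small_mask, r_max=1000.0)
        assert np.allclose(res.c[np.isfinite(res.c)], 1.0)

    def test_identical_channels_first_bin_closed_form(self, rng):
        fov = 5000.0
        mask = RoiMask.rectangle(fov, fov)
        n = 500
        locs = _uniform_table(rng, n, fov, "a")
        res = crosscorr_direct(locs, locs, mask, r_max=300.0)
        # all N self-pairs land in the zero-lag first bin whose discrete area
        # is one pixel: C_first ~ N * S_px / N^2 = S_px / N
        s_px = mask.mask.sum()
        assert res.c[0] == pytest.approx(s_px / n, rel=0.05)

    def test_random_channels_flat_within_variance(self, small_mask, rng):
        locs_a = _uniform_table(rng, 3000, 5000.0, "a")
        locs_b = _uniform_table(rng, 3000, 5000.0, "b")
        res = variance_dc1(crosscorr_direct(locs_a, locs_b, small_mask, r_max=500.0))
        z = (res.c - 1.0) / res.dc1
        assert np.nanmax(np.abs(z[1:])) < 3.5

    def test_hole_mask_stays_normalized(self, rng):
        _, mask = generate_topology_mask((5000.0, 5000.0), (2500.0, 2500.0), 1000.0)
        keep_a = _uniform_table(rng, 6000, 5000.0, "a")
        keep_b = _uniform_table(rng, 6000, 5000.0, "b")
        ka = mask.contains(keep_a.x, keep_a.y)
        kb = mask.contains(keep_b.x, keep_b.y)
        locs_a = LocalizationTable(keep_a.data[ka].copy())
        locs_b = LocalizationTable(keep_b.data[kb].copy())
        res = crosscorr_fft(
            reconstruct_image(locs_a, mask), reconstruct_image(locs_b, mask), mask, r_max=800.0
        )
        assert abs(np.nanmean(res.c) - 1.0) < 0.03

    def test_overcounting_invariance(self, coclustered_locs, small_mask):
        locs_a = coclustered_locs.select_channel("a")
        locs_b = coclustered_locs.select_channel("b")
        res1 = crosscorr_direct(locs_a, locs_b, small_mask, r_max=400.0)
        dup = LocalizationTable(
            locs_a.data.loc[locs_a.data.index.repeat(3)].reset_index(drop=True)
        )
        res3 = crosscorr_direct(dup, locs_b, small_mask, r_max=400.0)
        assert np.allclose(res1.c, res3.c, rtol=1e-12)

    def test_empty_channel_error_names_channel(self, small_mask, rng):
        locs_a = _uniform_table(rng, 10, 5000.0, "a")
        empty = LocalizationTable.from_arrays([], [], [], "b")
        with pytest.raises(ValueError, match="B"):
            crosscorr_direct(locs_a, empty, small_mask)

    def test_rmax_truncated_with_warning(self, small_mask, rng):
        locs = _uniform_table(rng, 200, 5000.0, "a")
        with pytest.warns(UserWarning, match="truncat"):
            crosscorr_direct(locs, locs, small_mask, r_max=50_000.0)


class TestVarianceModel:
    @staticmethod
    def _result_with_unit_errors(nbins=20, dr=25.0):
        edges = np.arange(0, (nbins + 1) * dr, dr)
        ones = np.ones(nbins)
        return CorrelationResult(
            edges, ones, ones, ones, dc_raw=np.full(nbins, 0.01),
            meta={"N1": 1000.0, "N2": 1000.0, "sigma_psf": 30.0},
        )

    def test_dc1_factor_large_r_limit(self):
        # (1 + 2*30/25) * (1 + e^{-r^2/4 sigma^2}) -> 3.4 for r >> sigma
        res = variance_dc1(self._result_with_unit_errors(), sigma_psf=30.0)
        assert res.dc1[-1] / res.dc_raw[-1] == pytest.approx(3.4, rel=1e-3)

    def test_dc1_factor_at_bin_centers(self):
        res = variance_dc1(self._result_with_unit_errors(), sigma_psf=30.0)
        r = res.r
        expect = (1 + 2 * 30.0 / 25.0) * (1 + np.exp(-(r**2) / (4 * 30.0**2))) * 0.01
        assert np.allclose(res.dc1, expect)

    def test_dc1_zero_precision_reduces_to_raw(self):
        res = variance_dc1(self._result_with_unit_errors(), sigma_psf=0.0)
        assert np.allclose(res.dc1, res.dc_raw)  # bin centers all have r > 0

    def test_dc2_oversampled_limit_equals_dc1(self):
        res = variance_dc1(self._result_with_unit_errors())
        res = variance_dc2(res, n_emitters_1=1e-6, n_emitters_2=1e-6)
        # N^2/n -> infinity: the subtracted term vanishes
        assert np.allclose(res.dc2, res.dc1, rtol=1e-6)

    def test_dc2_subtracts_under_sampling_term(self):
        res = variance_dc1(self._result_with_unit_errors())
        n_emit = 900.0  # ~1.1 observations per emitter
        res = variance_dc2(res, n_emit, n_emit)
        assert np.all(res.dc2 <= res.dc1)
        r = res.r
        term = (4 * np.pi * 30.0**2 / 25.0**2) / (2 * 1000.0**2 / n_emit) * (
            1 + 4 * np.exp(-(r**2) / (4 * 30.0**2))
        )
        assert np.allclose(res.dc1 - res.dc2, np.minimum(term, res.dc1))

    def test_dc2_requires_emitter_counts(self):
        res = variance_dc1(self._result_with_unit_errors())
        with pytest.raises(ValueError, match="density"):
            variance_dc2(res, 0.0, 10.0)

    def test_dc2_floors_at_zero_with_warning(self):
        res = variance_dc1(self._result_with_unit_errors())
        with pytest.warns(UserWarning, match="floor"):
            res = variance_dc2(res, 1e9, 1e9)
        assert np.all(res.dc2 >= 0)


class TestDensityEstimator:
    def test_recovers_ground_truth_density(self, square_mask):
        rho, mobs = 10.0, 20.0
        ests = []
        for seed in (1, 2, 3):
            scene = generate_scene(
                SceneSpec(mode="random", density_um2=rho, seed=seed)
            )
            locs = sample_localizations(
                scene, BlinkModel(mean_observations=mobs, localization_sigma=30.0), seed=seed
            ).select_channel("a")
            locs.grouped = True  # single-frame blinks: grouping is a no-op
            ests.append(density_from_autocorr(locs, square_mask).rho_um2)
        assert np.mean(ests) == pytest.approx(rho, rel=0.10)

    def test_invariant_to_doubling_observations(self, square_mask):
        scene = generate_scene(SceneSpec(mode="random", density_um2=10.0, seed=6))

        def est(mobs):
            locs = sample_localizations(
                scene, BlinkModel(mean_observations=mobs, localization_sigma=30.0), seed=8
            ).select_channel("a")
            locs.grouped = True
            return density_from_autocorr(locs, square_mask).rho_um2

        assert est(40.0) == pytest.approx(est(20.0), rel=0.10)

    def test_warns_on_ungrouped_input(self, square_mask):
        scene = generate_scene(SceneSpec(mode="random", density_um2=10.0, seed=9))
        locs = sample_localizations(scene, BlinkModel(), seed=9).select_channel("a")
        with pytest.warns(UserWarning, match="grouped"):
            density_from_autocorr(locs, square_mask)

    def test_rho_formula_consistency(self, square_mask):
        scene = generate_scene(SceneSpec(mode="random", density_um2=10.0, seed=10))
        locs = sample_localizations(scene, BlinkModel(), seed=10).select_channel("a")
        locs.grouped = True
        est = density_from_autocorr(locs, square_mask)
        # rho = 1/(2 pi sigma^2 A) exactly, with units nm^-2 -> um^-2
        assert est.rho_um2 == pytest.approx(
            1e6 / (2 * np.pi * est.sigma_nm**2 * est.amplitude), rel=1e-9
        )


class TestAggregation:
    @staticmethod
    def _flat_result(value, nbins=10):
        edges = np.arange(0, (nbins + 1) * 25.0, 25.0)
        ones = np.ones(nbins)
        return CorrelationResult(edges, ones, ones, np.full(nbins, value), ones * 0.1)

    def test_identical_curves_zero_sem(self):
        avg = average_cells([self._flat_result(1.3), self._flat_result(1.3)])
        assert np.allclose(avg.c, 1.3)
        assert np.allclose(avg.dc_raw, 0.0)

    def test_two_cell_arithmetic(self):
        avg = average_cells([self._flat_result(1.0), self._flat_result(2.0)])
        assert np.allclose(avg.c, 1.5)
        assert np.allclose(avg.dc_raw, 0.5)  # SEM of {1, 2}

    def test_single_cell_sem_flagged(self):
        with pytest.warns(UserWarning, match="SEM"):
            avg = average_cells([self._flat_result(1.0)])
        assert np.all(np.isnan(avg.dc_raw))

    def test_mismatched_binning_rejected(self):
        a = self._flat_result(1.0)
        b = self._flat_result(1.0, nbins=12)
        with pytest.raises(ValueError):
            average_cells([a, b])


class TestTransforms:
    def test_offset_subtraction(self):
        res = TestAggregation._flat_result(1.1)
        out = subtract_offset(res, (100.0, 250.0))
        assert np.allclose(out.c, 1.0)
        unity = TestAggregation._flat_result(1.0)
        assert np.allclose(subtract_offset(unity, (100.0, 250.0)).c, 1.0)

    def test_offset_empty_window_rejected(self):
        with pytest.raises(ValueError):
            subtract_offset(TestAggregation._flat_result(1.0), (5000.0, 6000.0))

    def test_pmf_closed_forms(self):
        res = TestAggregation._flat_result(1.0)
        res.c = np.array([1.0, np.e, 0.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        pmf = pmf_from_corr(res)
        assert pmf.pmf_kt[0] == pytest.approx(0.0)
        assert pmf.pmf_kt[1] == pytest.approx(-1.0)  # enrichment = attraction
        assert pmf.pmf_kt[2] == pytest.approx(np.log(2))  # depletion = repulsion

    def test_pmf_masks_nonpositive_bins(self):
        res = TestAggregation._flat_result(1.0)
        res.c = np.array([0.0, -0.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            pmf = pmf_from_corr(res)
        assert not pmf.valid[0] and not pmf.valid[1]
        assert np.isnan(pmf.pmf_kt[0])
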