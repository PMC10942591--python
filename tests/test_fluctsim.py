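"""Synthetic-data generators against their closed-form ground truths."""

import warnings

import numpy as np
import pytest

from piezomech import coloc, fluctsim, motility
from piezomech.model import (
    MechanicalParams,
    SpectralGrid,
    helfrich_psd,
    total_height_variance_nm2,
)
from piezomech.optics import IRMOptics

pytestmark = pytest.mark.filterwarnings(
    "ignore:.*undersampled.*:UserWarning")


class TestHeightSimulator:
    def test_zero_amplitude_limit(self, grid):
        p = MechanicalParams.from_kbt_kappa(sigma=5e-5, eta_eff=10.0,
                                            gamma=1e8, A=1e-9)
        hm = fluctsim.simulate_height_series(p, grid, n_pixels=4, seed=0)
        # A scales the variance linearly: 1e-9 of the thermal ~14 nm^2
        assert np.all(hm.heights.var(axis=0) < 1e-6)

    def test_stationary_variance_matches_mode_sum(self, params, grid):
        """Median single-pixel variance over 64 pixels agrees with the
        closed-form sum of per-mode variances within 20%."""
        hm = fluctsim.simulate_height_series(params, grid, n_pixels=64,
                                             seed=11)
        med = np.median(hm.heights.var(axis=0, ddof=1))
        assert med == pytest.approx(total_height_variance_nm2(params, grid),
                                    rel=0.20)

    def test_point_sampled_variance_is_exact(self, params, grid):
        """Without exposure averaging the stationary variance equals the
        mode sum tightly (exact OU updating, no dt bias)."""
        hm = fluctsim.simulate_height_series(params, grid, n_pixels=64,
                                             seed=11, exposure_substeps=1)
        med = np.median(hm.heights.var(axis=0, ddof=1))
        assert med == pytest.approx(total_height_variance_nm2(params, grid),
                                    rel=0.08)

    def test_welch_psd_matches_model_over_central_decade(self, params,
                                                         grid):
        """64-pixel-averaged Welch PSD tracks the analytic model pointwise
        within 25% over the central frequency decade."""
        from scipy.signal import welch

        hm = fluctsim.simulate_height_series(params, grid, n_pixels=64,
                                             seed=3)
        series = hm.heights[:, 0, :].T
        f, psd = welch(series - series.mean(axis=1, keepdims=True),
                       fs=grid.fs, nperseg=256, axis=1)
        mean_psd = psd.mean(axis=0)
        band = (f >= 0.3) & (f <= 3.0)
        model = helfrich_psd(f[band], params, grid)
        assert np.all(np.abs(mean_psd[band] - model) / model < 0.25)

    def test_psd_scales_linearly_with_A(self, params, grid):
        from scipy.signal import welch

        out = []
        for A in (1.0, 2.0):
            hm = fluctsim.simulate_height_series(params.with_(A=A), grid,
                                                 n_pixels=48, seed=9)
            s = hm.heights[:, 0, :].T
            f, psd = welch(s - s.mean(axis=1, keepdims=True), fs=grid.fs,
                           nperseg=256, axis=1)
            out.append(psd.mean(axis=0))
        band = (f >= 0.2) & (f <= 5.0)
        ratio = out[1][band] / out[0][band]
        assert np.all(np.abs(ratio - 2.0) < 0.5)
        assert np.mean(ratio) == pytest.approx(2.0, rel=0.1)

    def test_parseval(self, height_stack, grid):
        """Series variance equals trapezoid-integrated Welch PSD within
        10%, averaged over 32 pixels."""
        from piezomech import irm

        ratios = []
        for i in range(height_stack.heights.shape[2]):
            s = height_stack.heights[:, 0, i]
            spec = irm.estimate_psd_fft(s, grid.fs)
            ratios.append(spec.total_power() / s.var(ddof=1))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)

    def test_bit_reproducible(self, params, grid):
        small = SpectralGrid(q_min=grid.q_min, q_max=grid.q_max, n_q=16,
                             fs=grid.fs, n_frames=64)
        a = fluctsim.simulate_height_series(params, small, 4, seed=7)
        b = fluctsim.simulate_height_series(params, small, 4, seed=7)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_undersampled_modes_warn(self, grid):
        fast = MechanicalParams.from_kbt_kappa(sigma=5e-5, eta_eff=0.1,
                                               gamma=1e8)
        small = SpectralGrid(q_min=grid.q_min, q_max=grid.q_max, n_q=8,
                             fs=grid.fs, n_frames=32)
        with pytest.warns(UserWarning, match="undersampled"):
            fluctsim.simulate_height_series(fast, small, 2, seed=0)


class TestIrmConversion:
    def test_interference_extrema(self):
        optics = IRMOptics(noise_sd=0.0)
        from piezomech.stacks import HeightMapStack

        h = HeightMapStack(np.zeros((1, 1, 1)), dt=0.05, pixel_nm=180.0)
        stack = fluctsim.heights_to_irm(h, optics, seed=0)
        assert stack.intensity[0, 0, 0] == pytest.approx(optics.i_min)

    def test_mid_branch_midpoint(self):
        optics = IRMOptics(noise_sd=0.0)
        from piezomech.stacks import HeightMapStack

        mid = optics.wavelength_nm / (8 * optics.n_medium)
        h = HeightMapStack(np.full((1, 1, 1), mid), dt=0.05, pixel_nm=180.0)
        stack = fluctsim.heights_to_irm(h, optics, seed=0)
        assert stack.intensity[0, 0, 0] == pytest.approx(
            (optics.i_min + optics.i_max) / 2)

    def test_round_trip_noise_free(self, height_stack):
        """heights -> IRM -> heights at zero noise recovers to < 0.5 nm
        RMS inside the first branch."""
        from piezomech import irm

        optics = IRMOptics(noise_sd=0.0)
        stack = fluctsim.heights_to_irm(height_stack, optics, seed=0)
        back = irm.intensity_to_height(stack, optics)
        rms = np.sqrt(np.mean((back.heights - height_stack.heights) ** 2))
        assert rms < 0.5

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            IRMOptics(noise_sd=-1.0)

    def test_out_of_branch_clipped_with_warning(self):
        from piezomech.stacks import HeightMapStack

        optics = IRMOptics(noise_sd=0.0)
        h = HeightMapStack(np.full((1, 1, 2), 150.0), dt=0.05,
                           pixel_nm=180.0)
        with pytest.warns(UserWarning, match="clipped"):
            stack = fluctsim.heights_to_irm(h, optics, seed=0)
        assert np.all(stack.intensity <= optics.i_max + 1e-9)


class TestTracks:
    def test_stationary_when_motionless(self):
        t = fluctsim.simulate_tracks("brownian", D=0.0, n_tracks=5,
                                     n_steps=10, dt=30.0, seed=0)
        curve = motility.compute_msd(t)["all"]
        assert np.all(curve.msd_um2 == 0)

    def test_brownian_diffusion_recovered(self):
        t = fluctsim.simulate_tracks("brownian", D=0.5, n_tracks=200,
                                     n_steps=30, dt=30.0, seed=4)
        curve = motility.compute_msd(t)["all"]
        d_hat = motility.estimate_diffusion(curve)
        assert d_hat == pytest.approx(0.5, rel=0.10)

    def test_persistent_ballistic_limit(self):
        """At lags much shorter than the persistence time the MSD is
        (speed * t)^2."""
        speed, dt = 0.2, 5.0
        t = fluctsim.simulate_tracks("persistent", speed=speed,
                                     persistence_s=5000.0, n_tracks=40,
                                     n_steps=20, dt=dt, seed=2)
        curve = motility.compute_msd(t)["all"]
        expect = (speed * curve.lag_s[1:3]) ** 2
        np.testing.assert_allclose(curve.msd_um2[1:3], expect, rtol=0.02)

    def test_reproducible(self):
        a = fluctsim.simulate_tracks(seed=3, n_tracks=3, n_steps=5)
        b = fluctsim.simulate_tracks(seed=3, n_tracks=3, n_steps=5)
        assert a.data.equals(b.data)


class TestPolarizedMovie:
    def test_ground_truth_shapes(self):
        stack, truth = fluctsim.simulate_polarized_cell_movie(
            n_cells=3, n_frames=4, seed=0)
        assert len(truth) == 12
        assert stack.intensity.shape[0] == 4

    def test_skew_exact_by_construction(self):
        """Summing intensity over the true front half reproduces the
        configured skew fraction exactly."""
        skew = 0.75
        stack, truth = fluctsim.simulate_polarized_cell_movie(
            n_cells=1, skew_fraction=skew, n_frames=1, seed=5)
        img = stack.intensity[0]
        g = truth.iloc[0]
        th = np.deg2rad(g.heading_deg)
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        front = ((xx - g.cx_px) * np.cos(th)
                 + (yy - g.cy_px) * np.sin(th)) > 0
        assert img[front].sum() / img.sum() == pytest.approx(skew,
                                                             abs=1e-9)

    def test_invalid_skew_rejected(self):
        with pytest.raises(ValueError):
            fluctsim.simulate_polarized_cell_movie(skew_fraction=0.3)


@pytest.fixture(scope="module")
def puncta_mask():
    m = np.zeros((160, 160), dtype=bool)
    yy, xx = np.mgrid[0:160, 0:160]
    m[(yy - 80) ** 2 + (xx - 80) ** 2 <= 70 ** 2] = True
    return m


class TestPunctaField:
    @pytest.fixture
    def mask(self, puncta_mask):
        return puncta_mask

    def test_full_colocalization(self, mask):
        ref, query = fluctsim.simulate_puncta_field(
            mask, n_ref=20, n_query=20, coloc_fraction=1.0,
            area_range_px=(50, 120), seed=1)
        assert coloc.overlap_percentage(query, ref) == pytest.approx(100.0)

    def test_zero_fraction_matches_null(self, mask):
        """With no built-in colocalization the observed overlap sits at
        the random-placement chance level."""
        ref, query = fluctsim.simulate_puncta_field(
            mask, n_ref=20, n_query=20, coloc_fraction=0.0,
            area_range_px=(50, 120), seed=2)
        obs = coloc.overlap_percentage(query, ref)
        null = coloc.random_placement_null(query, ref, mask, n_sims=60,
                                           seed=3)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo - 5 <= obs <= hi + 5

    def test_overlap_monotone_in_fraction(self, mask):
        out = []
        for frac in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(4):
                ref, query = fluctsim.simulate_puncta_field(
                    mask, n_ref=20, n_query=20, coloc_fraction=frac,
                    area_range_px=(50, 120), seed=10 + seed)
                vals.append(coloc.overlap_percentage(query, ref))
            out.append(np.mean(vals))
        assert out[0] < out[1] < out[2]

    def test_mask_too_small_raises(self):
        tiny = np.ones((20, 20), dtype=bool)
        with pytest.raises(ValueError):
            fluctsim.simulate_puncta_field(tiny, n_ref=50, n_query=50,
                                           coloc_fraction=0.0,
                                           area_range_px=(50, 120), seed=0)
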