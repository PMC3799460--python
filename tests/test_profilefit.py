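"""Profile-fitting contracts: exact recovery on noiseless model profiles,
grid-search oracle equivalence on noisy ones, kymograph extraction and
alignment, and per-molecule summaries."""

import numpy as np
import pytest

from nanostain import (
    FrameFit,
    ImageStack,
    Kymograph,
    align_kymograph,
    erf_box,
    extract_kymograph,
    fit_frame,
    fit_kymograph,
    summarize_molecule,
)

from _oracles import grid_search_rss

PX = 0.1  # pixel size (µm) used for pixel-unit tests


def model_profile(n, c, w, a, b, s):
    x = np.arange(n) + 0.5
    return erf_box(x, c, w, a, b, s)


class TestExtractKymograph:
    def test_identical_frames_give_identical_rows(self):
        frame = np.arange(24, dtype=float).reshape(4, 6)
        stack = ImageStack(np.stack([frame] * 5), 0.1, 0.1)
        kymo = extract_kymograph(stack)
        assert kymo.n_frames == 5
        assert np.array_equal(kymo.rows, np.tile(frame.sum(axis=0), (5, 1)))

    def test_zero_stack_gives_zero_kymograph(self):
        stack = ImageStack(np.zeros((3, 4, 6)), 0.1, 0.1)
        assert not extract_kymograph(stack).rows.any()

    def test_rows_equal_hand_computed_column_sums(self):
        # 3 frames of a 4x6 integer grid with known transverse sums
        base = np.array(
            [
                [1, 2, 3, 4, 5, 6],
                [0, 1, 0, 1, 0, 1],
                [2, 2, 2, 2, 2, 2],
                [3, 0, 0, 0, 0, 3],
            ],
            dtype=float,
        )
        frames = np.stack([base, 2 * base, 3 * base])
        kymo = extract_kymograph(ImageStack(frames, 0.1, 0.1))
        hand = np.array([6, 5, 5, 7, 7, 12], dtype=float)
        for k in range(3):
            assert np.array_equal(kymo.rows[k], (k + 1) * hand)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_kymograph(ImageStack(np.zeros((0, 4, 6)), 0.1, 0.1))


class TestFitFrame:
    def test_noiseless_self_consistency(self):
        profile = model_profile(64, c=32.0, w=16.0, a=100.0, b=5.0, s=2.0)
        fit = fit_frame(profile, PX)
        assert fit.valid
        assert fit.center_um / PX == pytest.approx(32.0, abs=1e-3)
        assert fit.extension_um / PX == pytest.approx(16.0, abs=1e-3)
        assert fit.plateau == pytest.approx(100.0, rel=1e-4)
        assert fit.background == pytest.approx(5.0, abs=1e-3)
        assert fit.blur_sigma_px == pytest.approx(2.0, abs=1e-3)
        assert fit.integrated_intensity == pytest.approx(fit.plateau * fit.extension_um)

    @pytest.mark.parametrize("w", [8.0, 16.0, 28.0, 40.0])
    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("contrast", [5.0, 20.0, 100.0])
    def test_exact_recovery_grid(self, w, sigma, contrast):
        b = 10.0
        profile = model_profile(96, c=48.0, w=w, a=contrast * b, b=b, s=sigma)
        fit = fit_frame(profile, PX)
        assert fit.valid
        assert fit.center_um / PX == pytest.approx(48.0, abs=1e-3)
        assert fit.extension_um / PX == pytest.approx(w, abs=1e-3)

    def test_flat_profile_flagged_no_signal(self):
        fit = fit_frame(np.full(64, 7.0), PX)
        assert not fit.valid
        assert "no signal" in fit.message

    def test_pure_noise_flagged_invalid(self):
        rng = np.random.default_rng(0)
        fit = fit_frame(rng.normal(100.0, 3.0, size=64), PX)
        assert not fit.valid

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_frame(np.zeros(8), PX)

    def test_nonfinite_profile_rejected(self):
        p = np.ones(32)
        p[3] = np.nan
        with pytest.raises(ValueError):
            fit_frame(p, PX)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        truth = dict(c=30.0 + rng.uniform(-2, 2), w=18.0, a=120.0, b=20.0, s=1.5)
        profile = rng.poisson(model_profile(64, **truth)).astype(float)
        fit = fit_frame(profile, PX)
        assert fit.valid
        c_px, w_px = fit.center_um / PX, fit.extension_um / PX
        oracle = grid_search_rss(
            profile,
            c_range=(c_px - 1.5, c_px + 1.5),
            w_range=(max(w_px - 3.0, 3.0), w_px + 3.0),
            step=0.1,
        )
        assert fit.residual_ss <= oracle + 1e-6


class TestStatisticalConsistency:
    def test_fitted_extension_tracks_simulator_truth(self):
        """Over a long noisy stack, the mean fitted extension matches the
        simulated mean extension and the fitted frame-to-frame spread
        matches the AR fluctuation process's stationary deviation."""
        from nanostain import SimConfig, extract_kymograph, make_molecule_truth, render_stack

        cfg = SimConfig(
            native_extension_um=8.0,
            frames_per_molecule=200,
            extension_fluct_sd_um=0.25,
            center_diffusion_step_um=0.05,
            molecule_extension_sd_um=0.0,
        )
        truth = make_molecule_truth(0.6, cfg)
        stack = render_stack(truth, cfg, seed=17)
        fits = fit_kymograph(extract_kymograph(stack))
        w = np.array([f.extension_um for f in fits if f.valid])
        assert w.size > 190
        n_eff = w.size * (1 - cfg.ar_coeff) / (1 + cfg.ar_coeff)
        se_mean = w.std(ddof=1) / np.sqrt(n_eff)
        assert abs(w.mean() - truth.mean_extension_um) < 3 * se_mean
        # fitted spread = AR spread + fit noise, so it brackets the truth
        se_sd = w.std(ddof=1) / np.sqrt(2 * n_eff)
        assert truth.extension_fluct_sd_um - 3 * se_sd < w.std(ddof=1)
        assert w.std(ddof=1) < 1.3 * truth.extension_fluct_sd_um + 3 * se_sd


class TestAlignKymograph:
    def _kymo_and_fits(self, centers_px, n=64):
        rows = np.stack(
            [model_profile(n, c=c, w=12.0, a=80.0, b=4.0, s=1.0) for c in centers_px]
        )
        kymo = Kymograph(rows, PX, 0.1)
        fits = fit_kymograph(kymo, warm_start=False)
        return kymo, fits

    def test_identical_centers_unchanged(self):
        kymo, fits = self._kymo_and_fits([30.0] * 4)
        out = align_kymograph(kymo, fits)
        assert np.allclose(out.rows, kymo.rows)

    def test_drifting_molecule_rows_coincide_after_alignment(self):
        kymo, fits = self._kymo_and_fits([26.0 + t for t in range(9)])
        out = align_kymograph(kymo, fits)
        for row in out.rows:
            assert np.allclose(row, out.rows[4], atol=1e-6)

    def test_alignment_is_idempotent(self):
        kymo, fits = self._kymo_and_fits([26.0 + t for t in range(9)])
        once = align_kymograph(kymo, fits)
        fits2 = fit_kymograph(once, warm_start=False)
        twice = align_kymograph(once, fits2)
        assert np.allclose(twice.rows, once.rows)

    def test_all_invalid_passthrough_with_warning(self):
        rows = np.full((3, 32), 5.0)
        kymo = Kymograph(rows, PX, 0.1)
        fits = [FrameFit(valid=False)] * 3
        with pytest.warns(UserWarning, match="unaligned"):
            out = align_kymograph(kymo, fits)
        assert np.array_equal(out.rows, rows)

    def test_length_mismatch_rejected(self):
        kymo = Kymograph(np.zeros((3, 32)), PX, 0.1)
        with pytest.raises(ValueError):
            align_kymograph(kymo, [FrameFit()])


class TestSummarizeMolecule:
    @staticmethod
    def _fit(w, intensity=None, valid=True):
        plateau = (intensity / w) if intensity is not None else 50.0
        return FrameFit(
            center_um=5.0, extension_um=w, plateau=plateau, background=1.0,
            blur_sigma_px=1.0, residual_ss=0.0, valid=valid,
        )

    def test_constant_fits(self):
        fits = [self._fit(14.0, intensity=1000.0)] * 200
        s = summarize_molecule(fits)
        assert s.valid
        assert s.mean_extension_um == pytest.approx(14.0)
        assert s.extension_sd_um == 0.0
        assert s.mean_intensity == pytest.approx(1000.0)
        assert s.n_valid_frames == 200

    def test_hand_computed_statistics(self):
        s = summarize_molecule([self._fit(w) for w in (10.0, 12.0, 14.0)])
        assert s.mean_extension_um == pytest.approx(12.0)
        assert s.extension_sd_um == pytest.approx(2.0)

    def test_low_valid_fraction_flagged(self):
        fits = [self._fit(10.0)] * 40 + [self._fit(10.0, valid=False)] * 160
        s = summarize_molecule(fits, min_valid_fraction=0.5)
        assert not s.valid
        assert s.n_valid_frames == 40
        assert s.n_total_frames == 200

    def test_zero_valid_frames_flagged_not_raised(self):
        s = summarize_molecule([self._fit(10.0, valid=False)] * 5)
        assert not s.valid
        assert s.n_valid_frames == 0
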