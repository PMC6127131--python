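import numpy as np
import pytest

from conftest import deterministic_phantom_config
from fetradiomics.io import default_schedule
from fetradiomics.synthesis import (
    ClassTacParams,
    CohortConfig,
    generate_cohort,
    render_subject,
    sample_tac_shape,
    subgroup_i_params,
    subgroup_ii_params,
)
from fetradiomics.uptake import (
    TimeActivityCurve,
    compute_slope,
    compute_standard_params,
    compute_ttp,
    suv_scale,
)


def fit_tac(tbr_curve, schedule):
    tac = TimeActivityCurve(schedule.mid_times, tbr_curve)
    return compute_slope(tac), compute_ttp(tac)


class TestTacShape:
    def test_degenerate_flat_draw_is_monotone(self, schedule):
        p = ClassTacParams(2.0, 0.0, 47.5, 0.0, 0.0, 0.0, heterogeneity=0.0)
        tbr, tgt = sample_tac_shape(p, np.random.default_rng(0), schedule)
        assert np.all(np.diff(tbr) >= -1e-12)
        assert tbr.max() == pytest.approx(tbr[-1])

    def test_wt_like_draw_slope_closure(self, schedule):
        p = ClassTacParams(2.0, 0.0, 28.0, 0.0, -0.3, 0.0, heterogeneity=0.0)
        tbr, tgt = sample_tac_shape(p, np.random.default_rng(1), schedule)
        slope, ttp = fit_tac(tbr, schedule)
        assert slope == pytest.approx(-0.3, abs=0.02)
        assert ttp == 27.5  # mid of the 25-30 min frame containing 28 min

    def test_mut_like_draw_ttp_quantized(self, schedule):
        p = ClassTacParams(2.0, 0.0, 37.0, 0.0, 0.3, 0.0, heterogeneity=0.0)
        tbr, tgt = sample_tac_shape(p, np.random.default_rng(2), schedule)
        slope, ttp = fit_tac(tbr, schedule)
        assert ttp == 37.5  # mid of the 35-40 min frame containing 37 min
        assert slope == pytest.approx(0.3, abs=0.02)

    @pytest.mark.parametrize("params", [*subgroup_i_params().values(), *subgroup_ii_params().values()])
    def test_random_draws_satisfy_closure(self, params, schedule):
        rng = np.random.default_rng(11)
        for _ in range(50):
            tbr, tgt = sample_tac_shape(params, rng, schedule)
            assert tbr.min() > 0
            slope, ttp = fit_tac(tbr, schedule)
            assert slope == pytest.approx(tgt["slope_target_suv_h"], abs=1e-9)
            if not (tgt["ttp_frame_mid_min"] == 47.5 and tgt["slope_target_suv_h"] == 0):
                assert ttp == tgt["ttp_frame_mid_min"]
            w = np.zeros(16)
            w[10:14] = 0.25
            assert w @ tbr == pytest.approx(tgt["tbr_mean_target"], abs=1e-9)

    def test_impossible_draw_raises(self, schedule):
        # enormous negative slope drives the curve negative every time
        p = ClassTacParams(1.9, 0.0, 30.0, 0.0, -50.0, 0.0, heterogeneity=0.0)
        with pytest.raises(ValueError, match="could not draw"):
            sample_tac_shape(p, np.random.default_rng(3), schedule)


class TestRenderSubject:
    def test_no_variation_sources_uniform_tumor(self):
        cfg = deterministic_phantom_config(2.0, 0.0)
        dyn, truth, rec = render_subject(cfg, 0, np.random.default_rng(4))
        m = truth.tumor_mask.voxels
        for f in range(dyn.n_frames):
            vals = dyn.voxels[f][m]
            assert vals.std() == pytest.approx(0.0, abs=1e-12)

    def test_summed_tumor_mean_matches_target_exactly(self):
        cfg = deterministic_phantom_config(2.0, 0.0)
        dyn, truth, rec = render_subject(cfg, 0, np.random.default_rng(5))
        suv = suv_scale(dyn, rec.injected_activity_mbq, rec.body_weight_kg)
        from fetradiomics.uptake import sum_window

        summed = sum_window(suv)
        assert summed.voxels[truth.tumor_mask.voxels].mean() == pytest.approx(2.0, abs=1e-9)

    def test_blur_contracts_intratumoral_variance(self):
        params = {
            0: ClassTacParams(2.2, 0.0, 28.0, 0.0, -0.2, 0.0, heterogeneity=0.35),
            1: ClassTacParams(2.2, 0.0, 28.0, 0.0, -0.2, 0.0, heterogeneity=0.35),
        }
        out = {}
        for fwhm in (3.0, 6.0):
            cfg = CohortConfig(
                n_wt=1, n_mut=1, psf_fwhm_mm=fwhm, noise_sd=0.0,
                bg_variation_sd=0.0, class_params=params,
            )
            dyn, truth, _ = render_subject(cfg, 0, np.random.default_rng(99))
            out[fwhm] = dyn.voxels[11][truth.tumor_mask.voxels].var()
        assert out[6.0] < out[3.0]

    def test_cold_core_reduces_central_uptake(self):
        base = deterministic_phantom_config(2.0, 0.0)
        from dataclasses import replace

        cored = replace(base, core_radius_fraction=0.5, core_uptake_multiplier=0.3)
        dyn_b, truth, _ = render_subject(base, 0, np.random.default_rng(6))
        dyn_c, _, _ = render_subject(cored, 0, np.random.default_rng(6))
        centre = tuple(int(round(c / s)) for c, s in zip(base.tumor_center_mm, base.spacing_mm))
        assert dyn_c.voxels[11][centre] < dyn_b.voxels[11][centre]


class TestGenerateCohort:
    def test_seeded_determinism(self, tmp_path):
        cfg = CohortConfig(n_wt=2, n_mut=2, grid_shape=(24, 24, 16), seed=7,
                           tumor_radius_range_mm=(6.0, 9.0))
        a = generate_cohort(cfg, out_dir=tmp_path / "a")
        b = generate_cohort(cfg, out_dir=tmp_path / "b")
        for va, vb in zip(a.volumes, b.volumes):
            np.testing.assert_array_equal(va.voxels, vb.voxels)
        assert (tmp_path / "a" / "cohort.csv").read_bytes() == (
            tmp_path / "b" / "cohort.csv"
        ).read_bytes()
        assert (tmp_path / "a" / "ground_truth.csv").read_bytes() == (
            tmp_path / "b" / "ground_truth.csv"
        ).read_bytes()

    @pytest.mark.parametrize("n_wt,n_mut", [(41, 15), (17, 11)])
    def test_class_counts(self, n_wt, n_mut):
        cfg = CohortConfig(n_wt=n_wt, n_mut=n_mut)
        labels = [0] * n_wt + [1] * n_mut
        seeds = np.random.SeedSequence(cfg.seed).spawn(len(labels))
        assert len(seeds) == n_wt + n_mut  # counts propagate untouched
        # cheap check on the truth table without rendering: use a tiny grid
        small = CohortConfig(
            n_wt=min(n_wt, 3), n_mut=min(n_mut, 2), grid_shape=(24, 24, 16),
            tumor_radius_range_mm=(6.0, 9.0),
        )
        cohort = generate_cohort(small)
        table = cohort.truth_table()
        assert (table.label == 0).sum() == small.n_wt
        assert (table.label == 1).sum() == small.n_mut


class TestCalibration:
    def test_fitted_slopes_match_configured_means(self, schedule):
        # distributional closure at the TAC level, n=500 per class
        for label, params in subgroup_i_params().items():
            rng = np.random.default_rng(100 + label)
            slopes = []
            for _ in range(500):
                tbr, _ = sample_tac_shape(params, rng, schedule)
                slopes.append(compute_slope(TimeActivityCurve(schedule.mid_times, tbr)))
            slopes = np.asarray(slopes)
            se = slopes.std(ddof=1) / np.sqrt(len(slopes))
            assert abs(slopes.mean() - params.slope_mu) < 2 * se + 1e-9

    def test_parameter_recovery_noise_free(self):
        # rendered, contoured and measured: targets recovered to closure
        for tbr, slope in [(2.2, -0.2), (2.3, 0.2)]:
            cfg = deterministic_phantom_config(tbr, slope)
            dyn, truth, rec = render_subject(cfg, 0, np.random.default_rng(8))
            suv = suv_scale(dyn, rec.injected_activity_mbq, rec.body_weight_kg)
            params, *_ , inc = compute_standard_params(suv, tuple(cfg.ref_center_mm))
            assert inc.included
            assert params.tbr_mean == pytest.approx(tbr, rel=0.01)
            assert params.slope_suv_per_h == pytest.approx(slope, abs=0.02)
            assert params.ttp_min == truth.ttp_frame_mid_min

    def test_heterogeneity_contrast_visible_in_zone_features(self):
        # same seed, same TBR, no noise: the heterogeneous tumor fragments
        # into more zones than the homogeneous one
        from fetradiomics.texture import extract_features
        from fetradiomics.uptake import sum_window

        feats = {}
        for het in (0.0, 0.35):
            cfg = deterministic_phantom_config(2.2, 0.0, heterogeneity=het)
            dyn, truth, rec = render_subject(cfg, 0, np.random.default_rng(12))
            suv = suv_scale(dyn, rec.injected_activity_mbq, rec.body_weight_kg)
            summed = sum_window(suv)
            f, _ = extract_features(summed, truth.tumor_mask, 64)
            feats[het] = f
        assert feats[0.35]["GLNUz"] > feats[0.0]["GLNUz"]
        assert feats[0.35]["ZP"] > feats[0.0]["ZP"]
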