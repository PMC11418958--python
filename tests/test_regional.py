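"""SUVR/rOGI normalisation, FDR, and the voxelwise condition mixed model."""

import warnings

import numpy as np
import pandas as pd
import pytest

from neuroglyc import regional as rg
from neuroglyc import synth


def _phantom(values_by_label: dict[int, float], noise=None, seed=0):
    labels, lookup = synth._phantom_parcellation((16, 16, 10))
    data = np.zeros(labels.shape)
    for lab, val in values_by_label.items():
        data[labels == lab] = val
    if noise:
        data = data + np.random.default_rng(seed).normal(0, noise, labels.shape)
    parc = rg.VoxelImage(labels.astype(float), np.diag([2.0, 2, 2, 1]))
    img = rg.VoxelImage(data, np.diag([2.0, 2, 2, 1]))
    return img, parc, lookup


class TestReferenceSelection:
    def test_toy_table_brute_force(self):
        table = pd.DataFrame({"region": list("ABCD"),
                              "delta": [0.1, -0.05, 3.0, -2.0]})
        ref = rg.select_reference_region(table, 2)
        assert set(ref.labels) == {"A", "B"}
        assert ref.labels[0] == "B"  # smallest |delta| first

    def test_all_regions_degenerate(self):
        table = pd.DataFrame({"region": list("ABC"), "delta": [1.0, 2.0, 3.0]})
        assert len(rg.select_reference_region(table, 3).labels) == 3

    def test_named_stable_regions_selected(self):
        """A table where the three anatomically designated regions carry
        the smallest absolute change returns exactly those three."""
        table = pd.DataFrame({
            "region": ["middle_temporal", "lateral_orbitofrontal",
                       "postcentral", "precuneus", "deep_white"],
            "delta": [0.01, -0.02, 0.03, -0.9, 11.0]})
        ref = rg.select_reference_region(table, 3)
        assert set(ref.labels) == {"middle_temporal", "lateral_orbitofrontal",
                                   "postcentral"}

    def test_too_few_regions(self):
        table = pd.DataFrame({"region": ["A"], "delta": [0.1]})
        with pytest.raises(ValueError, match="only 1"):
            rg.select_reference_region(table, 3)

    def test_regional_delta_unpaired_means(self):
        table = pd.DataFrame({
            "subject": ["s1", "s1", "s2", "s3"],
            "condition": ["eu", "hyper", "eu", "hyper"],
            "region": ["A"] * 4,
            "value": [10.0, 13.0, 12.0, 15.0]})
        out = rg.regional_delta(table)
        assert out.loc[0, "delta"] == pytest.approx(14.0 - 11.0)


class TestSuvr:
    def test_constant_image_is_unity(self):
        img, parc, lookup = _phantom({i: 3.0 for i in range(1, 10)})
        ref = rg.ReferenceRegion(("middle_temporal",))
        suvr = rg.compute_suvr(img, ref, parc, lookup)
        assert np.allclose(suvr.data, 1.0)

    def test_simple_ratio_and_reference_mean_contract(self):
        vals = {i: float(i) for i in range(1, 10)}
        img, parc, lookup = _phantom(vals)
        ref = rg.ReferenceRegion(("middle_temporal",))  # label 2 -> value 2
        suvr = rg.compute_suvr(img, ref, parc, lookup)
        mask = parc.data == 5
        assert np.allclose(suvr.data[mask], 2.5)
        ref_mask = rg.reference_mask(ref, parc, lookup)
        assert suvr.data[ref_mask].mean() == pytest.approx(1.0)

    def test_zero_reference_mean_rejected(self):
        img, parc, lookup = _phantom({i: 0.0 for i in range(1, 10)})
        with pytest.raises(ValueError, match="reference mean"):
            rg.compute_suvr(img, rg.ReferenceRegion(("postcentral",)), parc, lookup)


class TestRogi:
    def test_identical_maps_give_unity(self):
        img, parc, lookup = _phantom({i: float(i) for i in range(1, 10)})
        ref = rg.ReferenceRegion(("precuneus",))
        rogi = rg.compute_rogi(img, img, ref, parc, lookup)
        assert np.allclose(rogi.data[rogi.mask], 1.0)

    def test_doubled_fdg_halves_rogi_locally(self):
        vals = {i: 2.0 for i in range(1, 10)}
        o2, parc, lookup = _phantom(vals)
        fdg_vals = dict(vals)
        fdg_vals[5] = 4.0  # doubled uptake in one non-reference region
        fdg_img, _, _ = _phantom(fdg_vals)
        ref = rg.ReferenceRegion(("middle_temporal",))
        rogi = rg.compute_rogi(o2, fdg_img, ref, parc, lookup)
        assert np.allclose(rogi.data[parc.data == 5], 0.5)
        assert np.allclose(rogi.data[parc.data == 7], 1.0)

    def test_reference_mean_unity_for_random_inputs(self):
        rng = np.random.default_rng(5)
        labels, lookup = synth._phantom_parcellation((16, 16, 10))
        parc = rg.VoxelImage(labels.astype(float), np.diag([2.0, 2, 2, 1]))
        o2 = rg.VoxelImage(rng.uniform(0.5, 2.0, labels.shape), np.diag([2.0, 2, 2, 1]))
        fdg_img = rg.VoxelImage(rng.uniform(0.5, 2.0, labels.shape), np.diag([2.0, 2, 2, 1]))
        ref = rg.ReferenceRegion(("postcentral", "precuneus"))
        rogi = rg.compute_rogi(o2, fdg_img, ref, parc, lookup)
        ref_mask = rg.reference_mask(ref, parc, lookup)
        assert np.nanmean(rogi.data[ref_mask]) == pytest.approx(1.0, abs=1e-12)


class TestFdr:
    def test_hand_executed_step_up(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.5]
        mask = rg.fdr_threshold(p, 0.05)
        assert mask.tolist() == [True, True, True, True, False]

    def test_boundaries(self):
        assert not rg.fdr_threshold([1.0, 1.0, 1.0], 0.05).any()
        assert not rg.fdr_threshold([0.001, 0.01], 0.0).any()

    def test_monotone_in_q_and_dominates_bonferroni(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200) ** 2
        prev = np.zeros(200, bool)
        for q in (0.01, 0.05, 0.1, 0.5):
            mask = rg.fdr_threshold(p, q)
            assert (prev <= mask).all()
            assert (mask >= (p <= q / p.size)).all()  # contains Bonferroni
            prev = mask

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rg.fdr_threshold([0.5, 1.5], 0.05)


class TestRandomInterceptLmm:
    def test_matches_statsmodels_mixedlm(self):
        """Vectorised REML vs the per-response statsmodels fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 8
        cond = np.tile([0.0, 1.0], n)
        subj = np.repeat(np.arange(n), 2)
        X = np.column_stack([np.ones(2 * n), cond])
        Y = (rng.normal(0, 1, (2 * n, 20))
             + np.repeat(rng.normal(0, 1.5, (n, 1)), 2, axis=0)
             + cond[:, None] * rng.normal(0.5, 1, (1, 20)))
        fit = rg.random_intercept_lmm(Y, X, subj)
        for v in range(20):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(Y[:, v], X, groups=subj).fit(reml=True)
            assert fit["beta_1"][v] == pytest.approx(res.fe_params[1], abs=1e-8)
            assert fit["se_1"][v] == pytest.approx(res.bse_fe[1], rel=0.02)

    def test_zero_group_variance_collapses_to_ols(self):
        """With no subject effect the GLS estimate and SE match ordinary
        least squares (the two-sample test) on the same data."""
        rng = np.random.default_rng(3)
        n = 40  # per condition
        cond = np.repeat([0.0, 1.0], n)
        subj = np.arange(2 * n)  # every observation its own subject: sigma_b n/a
        X = np.column_stack([np.ones(2 * n), cond])
        y = rng.normal(0, 1, 2 * n) + 0.5 * cond
        fit = rg.random_intercept_lmm(y[:, None], X, np.tile(np.arange(n), 2))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit["beta_1"][0] == pytest.approx(beta_ols[1], abs=5e-3)


class TestVoxelwiseModel:
    @staticmethod
    def _images(effect=0.0, seed=0, n_sub=4, shape=(4, 4, 2)):
        rng = np.random.default_rng(seed)
        out = []
        for s in range(n_sub):
            b = rng.normal(0, 1)
            for cond in ("eu", "hyper"):
                data = 10 + b + rng.normal(0, 1, shape) \
                    + (effect if cond == "hyper" else 0.0)
                out.append((f"s{s}", cond, rg.VoxelImage(data)))
        return out

    def test_identical_conditions_give_null_result(self):
        rng = np.random.default_rng(1)
        images = []
        for s in range(3):
            data = rng.normal(10, 1, (4, 4, 2))
            images.append((f"s{s}", "eu", rg.VoxelImage(data)))
            images.append((f"s{s}", "hyper", rg.VoxelImage(data.copy())))
        res = rg.voxelwise_condition_model(images, smooth_fwhm_mm=0)
        assert np.allclose(res.effect[res.mask], 0.0)
        assert not res.significant.any()

    def test_paired_effect_equals_mean_difference(self):
        """With a fully paired design the GLS condition effect reduces to
        the mean paired difference at every voxel."""
        images = self._images(effect=2.0, seed=2)
        res = rg.voxelwise_condition_model(images, smooth_fwhm_mm=0)
        eu = np.stack([im.data for _, c, im in images if c == "eu"])
        hy = np.stack([im.data for _, c, im in images if c == "hyper"])
        assert np.allclose(res.effect, (hy - eu).mean(axis=0), atol=1e-8)

    def test_unpaired_subjects_tolerated(self):
        images = self._images(effect=1.0, seed=3)
        images.append(("extra", "eu", rg.VoxelImage(
            np.random.default_rng(9).normal(10, 1, (4, 4, 2)))))
        res = rg.voxelwise_condition_model(images, smooth_fwhm_mm=0)
        assert res.n_obs == 9
        assert np.isfinite(res.effect[res.mask]).all()

    def test_smoothing_constant_image_unchanged(self):
        img = rg.VoxelImage(np.full((6, 6, 6), 3.0), np.diag([2.0, 2, 2, 1]))
        assert np.allclose(rg.smooth_image(img, 5.0).data, 3.0)


class TestBaselineChangeCorrelation:
    def test_exact_antilinearity(self):
        rng = np.random.default_rng(4)
        base = rg.VoxelImage(rng.uniform(1, 3, (5, 5, 2)))
        delta = rg.VoxelImage(-base.data + 7.0)
        assert rg.baseline_change_correlation(base, delta) == pytest.approx(-1.0)

    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(5)
        base = rg.VoxelImage(rng.normal(0, 1, (10, 10, 5)))
        delta = rg.VoxelImage(rng.normal(0, 1, (10, 10, 5)))
        r = rg.baseline_change_correlation(base, delta)
        assert abs(r) < 3.0 / np.sqrt(500)  # null sampling band

    def test_generator_coupling_recovered(self):
        """The phantom's construction (increase concentrated in the
        low-baseline white core) yields a strongly negative coupling."""
        images, parc, lookup, table, truth = synth.gen_regional_images(
            synth.RegionalImageConfig(seed=1))
        eu = np.mean([im.data for _, c, im in images if c == "eu"], axis=0)
        hy = np.mean([im.data for _, c, im in images if c == "hyper"], axis=0)
        r = rg.baseline_change_correlation(rg.VoxelImage(eu),
                                           rg.VoxelImage(hy - eu))
        assert r < -0.9

    def test_zero_variance_rejected(self):
        base = rg.VoxelImage(np.full((3, 3, 3), 2.0))
        delta = rg.VoxelImage(np.random.default_rng(0).normal(size=(3, 3, 3)))
        with pytest.raises(ValueError, match="zero-variance"):
            rg.baseline_change_correlation(base, delta)
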