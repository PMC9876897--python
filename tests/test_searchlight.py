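"""Searchlight machinery: sphere geometry, neural RDMs, partial Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lexload as ll
from lexload.searchlight import _partial_corr_ranked, _tri_ranks

from conftest import random_rdm


def _toy_beta(shape=(8, 8, 8), n_trials=12, seed=0, conditions=("chinese_word",)):
    rng = np.random.default_rng(seed)
    total = n_trials * len(conditions)
    data = rng.normal(size=shape + (total,))
    mask = np.ones(shape, dtype=bool)
    rows = []
    for ci, cond in enumerate(conditions):
        for k in range(n_trials):
            rows.append({"trial_index": ci * n_trials + k, "condition": cond,
                         "item_id": f"it{k:03d}"})
    return ll.BetaVolumeSet(data=data, affine=np.diag([2.0, 2, 2, 1]), mask=mask,
                            trial_table=pd.DataFrame(rows))


class TestVariationFilter:
    def test_constant_voxel_discarded_and_sd_equal_mean_kept(self):
        beta = _toy_beta()
        beta.data[0, 0, 0, :] = 5.0                      # SD 0, mean 5
        beta.data[1, 0, 0, :] = [0.0, 10.0] * 6          # SD == mean for n even
        keep = ll.variation_filter(beta, fraction=1.0)
        assert not keep[0, 0, 0]
        assert keep[1, 0, 0]

    def test_matches_bruteforce(self):
        beta = _toy_beta(shape=(5, 5, 5), seed=1)
        keep = ll.variation_filter(beta, fraction=0.8)
        for idx in np.ndindex(5, 5, 5):
            ts = beta.data[idx]
            assert keep[idx] == (np.std(ts) >= 0.8 * abs(np.mean(ts)))

    def test_all_discarded_raises(self):
        beta = _toy_beta(shape=(4, 4, 4))
        beta.data[:] = 1.0
        with pytest.raises(ValueError, match="0.125"):
            ll.variation_filter(beta)


class TestSphereGeometry:
    def test_tiny_radius_only_center(self):
        offs = ll.sphere_offsets(0.5, np.diag([2.0, 2, 2, 1]))
        assert offs.shape == (1, 3)
        assert np.all(offs == 0)

    def test_lattice_count_on_2mm_grid(self):
        # 6-mm sphere on a 2-mm grid: exactly the offsets with i^2+j^2+k^2 <= 9
        offs = ll.sphere_offsets(6.0, np.diag([2.0, 2, 2, 1]))
        brute = {
            (i, j, k)
            for i in range(-5, 6) for j in range(-5, 6) for k in range(-5, 6)
            if i * i + j * j + k * k <= 9
        }
        assert {tuple(o) for o in offs} == brute

    def test_anisotropic_voxels(self):
        offs = ll.sphere_offsets(6.0, np.diag([3.0, 2, 2, 1]))
        brute = {
            (i, j, k)
            for i in range(-3, 4) for j in range(-4, 5) for k in range(-4, 5)
            if 9 * i * i + 4 * j * j + 4 * k * k <= 36
        }
        assert {tuple(o) for o in offs} == brute

    def test_edge_sphere_is_subset_of_interior(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        aff = np.diag([2.0, 2, 2, 1])
        deep = ll.sphere_indices((4, 4, 4), 6.0, aff, mask)
        edge = ll.sphere_indices((0, 4, 4), 6.0, aff, mask)
        deep_rel = {tuple(c - (4, 4, 4)) for c in deep}
        edge_rel = {tuple(c - (0, 4, 4)) for c in edge}
        assert edge_rel < deep_rel

    def test_center_outside_mask_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        with pytest.raises(ValueError):
            ll.sphere_indices((2, 2, 2), 6.0, np.eye(4), mask)


class TestNeuralRdm:
    def test_identical_and_reversed_columns(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=10)
        P = np.column_stack([col, col, -col])
        rdm = ll.neural_rdm(P)
        assert rdm.values[1, 0] == pytest.approx(0.0)
        assert rdm.values[2, 0] == pytest.approx(2.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(20, 9))
        rdm = ll.neural_rdm(P)
        for i in range(9):
            for j in range(i):
                ri = sps.rankdata(P[:, i])
                rj = sps.rankdata(P[:, j])
                expect = 1 - np.corrcoef(ri, rj)[0, 1]
                assert rdm.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_pattern_gives_nan(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(8, 5))
        P[:, 2] = 3.0
        rdm = ll.neural_rdm(P)
        assert np.isnan(rdm.values[2, 0])
        assert rdm.values[2, 2] == 0.0


class TestPartialSpearman:
    def test_no_controls_equals_plain_spearman(self):
        rng = np.random.default_rng(0)
        a, b = random_rdm(rng, 12), random_rdm(rng, 12)
        rho, p = ll.partial_spearman(a, b, [])
        expect = sps.spearmanr(a.lower_triangle(), b.lower_triangle())
        assert rho == pytest.approx(float(expect.statistic), abs=1e-12)

    def test_target_in_controls_partials_to_zero(self):
        rng = np.random.default_rng(1)
        a, b = random_rdm(rng, 12), random_rdm(rng, 12)
        rho, _ = ll.partial_spearman(a, b, [b])
        assert abs(rho) < 1e-8

    def test_residual_vs_precision_matrix_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            mats = [random_rdm(rng, 10) for _ in range(4)]
            neural, target, c1, c2 = mats
            rho, _ = ll.partial_spearman(neural, target, [c1, c2])
            R = np.corrcoef(np.column_stack([
                _tri_ranks(neural), _tri_ranks(target), _tri_ranks(c1), _tri_ranks(c2)
            ]).T)
            P = np.linalg.inv(R)
            expect = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
            assert rho == pytest.approx(expect, abs=1e-10)

    def test_collinear_controls_rejected(self):
        rng = np.random.default_rng(3)
        a, b, c = random_rdm(rng, 10), random_rdm(rng, 10), random_rdm(rng, 10)
        with pytest.raises(ValueError, match="collinear"):
            ll.partial_spearman(a, b, [c, c])

    def test_permutation_p_close_to_parametric_under_null(self):
        rng = np.random.default_rng(4)
        a, b = random_rdm(rng, 14), random_rdm(rng, 14)
        _, p_par = ll.partial_spearman(a, b, [])
        _, p_perm = ll.partial_spearman(a, b, [], n_perm=400,
                                        rng=np.random.default_rng(5))
        assert abs(p_par - p_perm) < 0.12


class TestFisherZ:
    def test_zero_and_oddness_and_closed_form(self):
        assert ll.fisher_z(0.0) == 0.0
        for r in [0.1, 0.35, 0.8]:
            assert ll.fisher_z(-r) == pytest.approx(-ll.fisher_z(r))
        assert ll.fisher_z(0.5) == pytest.approx(np.arctanh(0.5))

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            z = ll.fisher_z(1.0)
        assert np.isfinite(z)


def _behavioral_for(beta, n_trials, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"it{k:03d}" for k in range(n_trials)]
    out = {}
    for comp in ll.COMPONENTS:
        r = random_rdm(rng, n_trials, comp)
        out[comp] = ll.DissimilarityMatrix(r.values, ids, comp, "chinese_word")
    return out


class TestSearchlightMap:
    def test_no_filtering_when_alpha_one(self):
        beta = _toy_beta(shape=(7, 7, 7), n_trials=12, seed=5)
        behavioral = _behavioral_for(beta, 12)
        maps = ll.searchlight_map(beta, behavioral, "chinese_word", alpha=1.0,
                                  cluster_min=0, min_voxels=2)
        retained = ll.variation_filter(beta)
        finite = np.isfinite(maps["logo"].z)
        np.testing.assert_array_equal(maps["logo"].sig_mask, finite)
        # interior voxels all computed
        assert finite[3, 3, 3]

    def test_invariant_under_monotone_beta_transform(self):
        beta = _toy_beta(shape=(6, 6, 6), n_trials=10, seed=6)
        behavioral = _behavioral_for(beta, 10)
        maps1 = ll.searchlight_map(beta, behavioral, "chinese_word",
                                   min_voxels=2, variation_fraction=1e-9)
        beta2 = ll.BetaVolumeSet(
            data=(beta.data - beta.data.min() + 1.0) ** 3,
            affine=beta.affine, mask=beta.mask,
            trial_table=beta.trial_table, subject=beta.subject)
        maps2 = ll.searchlight_map(beta2, behavioral, "chinese_word",
                                   min_voxels=2, variation_fraction=1e-9)
        np.testing.assert_allclose(maps1["logo"].z, maps2["logo"].z,
                                   atol=1e-10, equal_nan=True)

    def test_invariant_under_trial_relabeling(self):
        beta = _toy_beta(shape=(6, 6, 6), n_trials=10, seed=7)
        behavioral = _behavioral_for(beta, 10)
        maps1 = ll.searchlight_map(beta, behavioral, "chinese_word", min_voxels=2)
        rng = np.random.default_rng(8)
        perm = rng.permutation(10)
        tt = beta.trial_table.copy()
        tt["trial_index"] = perm[tt["trial_index"].to_numpy()]
        beta2 = ll.BetaVolumeSet(data=beta.data[..., np.argsort(perm)],
                                 affine=beta.affine, mask=beta.mask,
                                 trial_table=tt, subject=beta.subject)
        maps2 = ll.searchlight_map(beta2, behavioral, "chinese_word", min_voxels=2)
        np.testing.assert_allclose(maps1["phonology"].z, maps2["phonology"].z,
                                   atol=1e-12, equal_nan=True)

    def test_degenerate_radius_gives_all_nan(self):
        beta = _toy_beta(shape=(5, 5, 5), n_trials=10, seed=9)
        behavioral = _behavioral_for(beta, 10)
        maps = ll.searchlight_map(beta, behavioral, "chinese_word",
                                  radius_mm=0.5, min_voxels=2)
        assert np.all(np.isnan(maps["logo"].z))

    def test_missing_condition_rejected(self):
        beta = _toy_beta(shape=(5, 5, 5), n_trials=10)
        behavioral = _behavioral_for(beta, 10)
        with pytest.raises(ValueError):
            ll.searchlight_map(beta, behavioral, "english_word")

    def test_planted_signal_localizes(self, planted_dataset, planted_maps):
        ds = planted_dataset
        in_region = ds.atlas == 1
        out_region = ds.mask & ~in_region
        med_in, med_out = [], []
        for b in ds.beta:
            z = planted_maps[(b.subject, "chinese_word", "logo")].z
            med_in.append(np.nanmedian(z[in_region]))
            med_out.append(np.nanmedian(z[out_region]))
        assert np.median(med_in) > np.median(med_out) + 0.2
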