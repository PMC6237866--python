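"""Voxel-wise association mapping: GLM statistics, permutation FWE
calibration, and cluster-extent thresholding."""

import numpy as np
import pytest
from scipy import stats

from petkin.errors import ConfigurationError, ContractError
from petkin.mapping import (
    AssociationMap,
    ClusterRecord,
    cluster_threshold,
    fwe_smallvolume,
    subthreshold_coincidence,
    voxelwise_glm,
)

AFFINE_2MM = np.diag([2.0, 2.0, 2.0, 1.0])


def _null_images(rng, n, shape=(8, 8, 8)):
    return [rng.standard_normal(shape) for _ in range(n)]


def _full_mask(shape=(8, 8, 8)):
    return np.ones(shape, dtype=bool)


class TestVoxelwiseGlm:
    def test_matches_linregress_per_voxel(self):
        rng = np.random.default_rng(0)
        imgs = _null_images(rng, 12, (4, 4, 4))
        cov = rng.standard_normal(12)
        amap = voxelwise_glm(imgs, cov, _full_mask((4, 4, 4)),
                            affine=AFFINE_2MM)
        data = np.stack(imgs)
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            y = data[(slice(None),) + idx]
            res = stats.linregress(cov, y)
            t_ref = res.slope / res.stderr
            assert amap.t_voxels[idx] == pytest.approx(t_ref, rel=1e-8)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        imgs = _null_images(rng, 10, (4, 4, 4))
        cov = rng.standard_normal(10)
        perm = rng.permutation(10)
        a = voxelwise_glm(imgs, cov, _full_mask((4, 4, 4)), affine=AFFINE_2MM)
        b = voxelwise_glm([imgs[i] for i in perm], cov[perm],
                          _full_mask((4, 4, 4)), affine=AFFINE_2MM)
        assert np.allclose(a.t_voxels, b.t_voxels)

    def test_zero_variance_covariate_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ConfigurationError):
            voxelwise_glm(_null_images(rng, 6, (3, 3, 3)), np.ones(6),
                          _full_mask((3, 3, 3)))

    def test_too_few_subjects(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ContractError):
            voxelwise_glm(_null_images(rng, 3, (3, 3, 3)),
                          np.array([1.0, 2.0, 3.0]), _full_mask((3, 3, 3)))

    def test_length_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ContractError):
            voxelwise_glm(_null_images(rng, 6, (3, 3, 3)),
                          np.arange(5.0), _full_mask((3, 3, 3)))

    def test_null_t_follows_t_distribution(self):
        """Independent data: the masked t values follow Student t with
        n - 2 degrees of freedom (KS over ~4k voxels)."""
        rng = np.random.default_rng(5)
        n = 14
        amap = voxelwise_glm(_null_images(rng, n, (16, 16, 16)),
                             rng.standard_normal(n),
                             _full_mask((16, 16, 16)), affine=AFFINE_2MM)
        tvals = amap.t_voxels[amap.mask]
        assert stats.kstest(tvals, "t", args=(n - 2,)).pvalue > 0.01

    def test_z_sign_and_magnitude(self):
        rng = np.random.default_rng(6)
        n = 10
        amap = voxelwise_glm(_null_images(rng, n, (6, 6, 6)),
                             rng.standard_normal(n), _full_mask((6, 6, 6)),
                             affine=AFFINE_2MM)
        m = amap.mask
        assert np.all(np.sign(amap.z_voxels[m]) == np.sign(amap.t_voxels[m]))
        # the conversion preserves two-tailed p exactly
        i = (2, 3, 4)
        p_t = 2 * stats.t.sf(abs(amap.t_voxels[i]), n - 2)
        p_z = 2 * stats.norm.sf(abs(amap.z_voxels[i]))
        assert p_t == pytest.approx(p_z, rel=1e-10)

    def test_planted_signal_peaks_at_site(self):
        rng = np.random.default_rng(7)
        cov = rng.standard_normal(16)
        imgs = []
        for ci in cov:
            im = 0.1 * rng.standard_normal((8, 8, 8))
            im[4, 4, 4] += 2.0 * ci
            imgs.append(im)
        amap = voxelwise_glm(imgs, cov, _full_mask((8, 8, 8)),
                             affine=AFFINE_2MM)
        assert np.unravel_index(np.argmax(amap.t_voxels),
                                amap.t_voxels.shape) == (4, 4, 4)


class TestFweSmallvolume:
    def _run(self, seed=0, n=10, signal=0.0, n_perm=1000, alpha=0.05,
             shape=(6, 6, 6), **kw):
        rng = np.random.default_rng(seed)
        cov = rng.standard_normal(n)
        imgs = []
        for ci in cov:
            im = rng.standard_normal(shape)
            im[2, 2, 2] += signal * ci
            imgs.append(im)
        return fwe_smallvolume(imgs, cov, _full_mask(shape), n_perm=n_perm,
                               alpha=alpha, seed=seed, affine=AFFINE_2MM, **kw)

    def test_strong_signal_detected_at_site(self):
        out = self._run(seed=1, signal=5.0)
        assert out["significant_mask"][2, 2, 2]
        assert out["n_significant"] >= 1
        assert out["clusters"][0].peak_xyz_mm == tuple(
            (AFFINE_2MM @ [2, 2, 2, 1])[:3])

    def test_null_rarely_significant(self):
        hits = sum(self._run(seed=s)["n_significant"] > 0 for s in range(40))
        assert hits / 40 <= 0.125   # nominal 0.05, binomial slack at 40 reps

    def test_corrected_p_monotone_in_abs_t(self):
        out = self._run(seed=2, signal=2.0)
        m = out["map"].mask
        t = np.abs(out["map"].t_voxels[m])
        p = out["corrected_p"][m]
        order = np.argsort(t)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_alpha_one_flags_everything(self):
        out = self._run(seed=3, alpha=1.0)
        assert out["n_significant"] == int(out["map"].mask.sum())

    def test_single_voxel_mask_matches_parametric_p(self):
        """With one voxel there is no multiplicity: the permutation p
        converges to the two-tailed parametric p."""
        rng = np.random.default_rng(8)
        n = 12
        cov = rng.standard_normal(n)
        shape = (3, 3, 3)
        mask = np.zeros(shape, dtype=bool)
        mask[1, 1, 1] = True
        imgs = [rng.standard_normal(shape) + 0.8 * ci * mask for ci in cov]
        out = fwe_smallvolume(imgs, cov, mask, n_perm=4000, alpha=0.05,
                              seed=9, affine=AFFINE_2MM)
        t_obs = out["map"].t_voxels[1, 1, 1]
        p_param = 2 * stats.t.sf(abs(t_obs), n - 2)
        p_perm = out["corrected_p"][1, 1, 1]
        assert p_perm == pytest.approx(p_param, abs=0.03)

    def test_identity_permutation_included(self):
        # corrected p can never be below 1/n_perm
        out = self._run(seed=4, signal=10.0)
        assert out["corrected_p"][out["map"].mask].min() >= 1.0 / 1000 - 1e-12

    def test_seed_determinism(self):
        a = self._run(seed=5, signal=1.0)
        b = self._run(seed=5, signal=1.0)
        assert np.array_equal(a["corrected_p"], b["corrected_p"])
        assert a["critical_value"] == b["critical_value"]

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ConfigurationError):
            self._run(n_perm=500)
        with pytest.raises(ConfigurationError):
            self._run(n_perm=1000, alpha=0.0005)

    def test_empty_mask_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ConfigurationError):
            fwe_smallvolume(_null_images(rng, 8, (3, 3, 3)),
                            rng.standard_normal(8),
                            np.zeros((3, 3, 3), dtype=bool))


def _map_from_t(t_img, mask=None, df=19):
    t_img = np.asarray(t_img, dtype=float)
    if mask is None:
        mask = np.ones(t_img.shape, dtype=bool)
    p = stats.t.sf(np.abs(t_img), df)
    z = np.sign(t_img) * stats.norm.isf(np.clip(p, 1e-300, 1.0))
    return AssociationMap(t_img, z, mask, AFFINE_2MM, "trait", df + 2, df)


class TestClusterThreshold:
    def test_extent_filter_at_80mm3(self):
        """2 mm voxels: a 10-voxel blob (80 mm3) survives the default
        extent filter, a 9-voxel blob does not."""
        t = np.zeros((12, 12, 12))
        t[1, 1, 1:11] = 8.0          # 10 voxels, face-connected line
        t[6, 6, 1:10] = 8.0          # 9 voxels
        recs = cluster_threshold(_map_from_t(t))
        assert len(recs) == 1
        assert recs[0].n_voxels == 10
        assert recs[0].size_mm3 == pytest.approx(80.0)

    def test_all_zero_map_yields_no_clusters(self):
        assert cluster_threshold(_map_from_t(np.zeros((6, 6, 6)))) == []

    def test_directions_separated(self):
        t = np.zeros((14, 6, 6))
        t[0:10, 1, 1] = 6.0
        t[0:10, 3, 3] = -6.0
        recs = cluster_threshold(_map_from_t(t))
        assert sorted(r.direction for r in recs) == ["negative", "positive"]
        neg = [r for r in recs if r.direction == "negative"][0]
        assert neg.peak_t == -6.0 and neg.peak_z < 0

    def test_six_connectivity_splits_diagonal(self):
        """Two diagonal 10-voxel sheets touch only at corners: with
        6-connectivity they form separate clusters."""
        t = np.zeros((12, 12, 12))
        t[2, 2, 0:10] = 5.0
        t[3, 3, 0:10] = 5.0
        recs = cluster_threshold(_map_from_t(t))
        assert len(recs) == 2

    def test_height_threshold_is_one_sided_critical_t(self):
        df = 19
        t_crit = stats.t.isf(0.001, df)
        t = np.zeros((12, 6, 6))
        t[0:10, 1, 1] = t_crit + 0.01
        t[0:10, 3, 3] = t_crit - 0.01
        recs = cluster_threshold(_map_from_t(t, df=df))
        assert len(recs) == 1
        assert recs[0].peak_xyz_mm[1:] == (2.0, 2.0)

    def test_peak_is_max_abs_t(self):
        t = np.zeros((12, 6, 6))
        t[0:10, 1, 1] = np.linspace(4.0, 9.0, 10)
        recs = cluster_threshold(_map_from_t(t))
        assert recs[0].peak_t == pytest.approx(9.0)
        assert recs[0].peak_xyz_mm[0] == pytest.approx(9 * 2.0)

    def test_mask_respected(self):
        t = np.zeros((12, 6, 6))
        t[0:10, 1, 1] = 8.0
        mask = np.zeros(t.shape, dtype=bool)
        mask[:, 3, :] = True          # signal lies outside the mask
        assert cluster_threshold(_map_from_t(t, mask=mask)) == []


class TestCoincidence:
    def _rec(self, xyz, z=4.0, direction="positive"):
        return ClusterRecord(peak_xyz_mm=xyz, peak_z=z, peak_t=z,
                             size_mm3=40.0, n_voxels=5, direction=direction)

    def test_shared_peak_grouped(self):
        sets = {"harm_avoidance": [self._rec((2.0, 4.0, 6.0))],
                "self_directedness": [self._rec((2.0, 4.0, 6.0),
                                                direction="negative")],
                "reward_dependence": [self._rec((10.0, 0.0, 0.0))]}
        groups = subthreshold_coincidence(sets)
        assert len(groups) == 1
        assert groups[0]["n_traits"] == 2
        dirs = {m["trait"]: m["direction"] for m in groups[0]["traits"]}
        assert dirs == {"harm_avoidance": "positive",
                        "self_directedness": "negative"}

    def test_tolerance_radius(self):
        sets = {"a": [self._rec((0.0, 0.0, 0.0))],
                "b": [self._rec((0.0, 0.0, 2.0))]}
        assert subthreshold_coincidence(sets) == []
        assert len(subthreshold_coincidence(sets, tolerance_mm=2.0)) == 1

    def test_single_trait_rejected(self):
        with pytest.raises(ContractError):
            subthreshold_coincidence({"a": [self._rec((0, 0, 0))]})

    def test_within_trait_duplicates_not_grouped(self):
        sets = {"a": [self._rec((0.0, 0.0, 0.0)), self._rec((0.0, 0.0, 0.0))],
                "b": [self._rec((9.0, 9.0, 9.0))]}
        assert subthreshold_coincidence(sets) == []
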