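"""Landmark merging, Procrustes superimposition, allometry and shape PCA."""

import numpy as np
import pytest
from scipy import linalg

import cranioscan.morphometrics as mm
from cranioscan.simulate import SimConfig, landmark_template

from conftest import make_config, random_rotation


def _square3d():
    return np.array([[0.5, 0.5, 0.0], [-0.5, 0.5, 0.0],
                     [-0.5, -0.5, 0.0], [0.5, -0.5, 0.0]])


# ---------------------------------------------------------------------------
# merge_views
# ---------------------------------------------------------------------------


class TestMergeViews:
    def test_identity_frames_merge_to_union(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        dorsal = make_config(pts[:5], view="dorsal", ids=[1, 2, 3, 4, 5])
        ventral = make_config(pts[[0, 1, 2, 5]], view="ventral",
                              ids=[1, 2, 3, 6])
        merged, rms = mm.merge_views(dorsal, ventral, {1, 2, 3})
        assert merged.ids == [1, 2, 3, 4, 5, 6]
        assert rms == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(merged.landmarks[6], pts[5], atol=1e-12)

    def test_known_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(size=(8, 3)) * 40
        R = random_rotation(rng)
        t = rng.normal(size=3) * 25
        dorsal = make_config(truth[:6], view="dorsal", ids=range(1, 7))
        ventral_ids = [1, 2, 3, 7, 8]
        ventral = make_config(truth[[0, 1, 2, 6, 7]] @ R + t, view="ventral",
                              ids=ventral_ids)
        merged, rms = mm.merge_views(dorsal, ventral, {1, 2, 3})
        for lid, true_row in zip([7, 8], truth[[6, 7]]):
            np.testing.assert_allclose(merged.landmarks[lid], true_row,
                                       atol=1e-9)
        assert rms < 1e-9

    def test_default_shared_ids(self):
        assert mm.DEFAULT_SHARED_IDS == frozenset({1, 2, 28, 29})

    def test_too_few_or_collinear_shared_fail(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 2.0]])
        a = make_config(pts, view="dorsal")
        b = make_config(pts, view="ventral")
        with pytest.raises(mm.MorphometricsError):
            mm.merge_views(a, b, {1, 2})
        with pytest.raises(mm.MorphometricsError, match="collinear"):
            mm.merge_views(a, b, {1, 2, 3})


# ---------------------------------------------------------------------------
# centroid size
# ---------------------------------------------------------------------------


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        cfg = make_config(_square3d())
        assert mm.centroid_size(cfg) == pytest.approx(np.sqrt(2.0))

    @pytest.mark.parametrize("c", [0.5, 3.0, 17.2])
    def test_homogeneous_in_scale_invariant_to_shift(self, c):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        base = mm.centroid_size(make_config(pts))
        assert mm.centroid_size(make_config(c * pts)) == pytest.approx(c * base)
        assert mm.centroid_size(make_config(pts + [5.0, -3.0, 9.0])) \
            == pytest.approx(base)

    def test_missing_subset_landmark_fails(self):
        cfg = make_config(_square3d())
        with pytest.raises(mm.MorphometricsError):
            mm.centroid_size(cfg, {1, 9})


# ---------------------------------------------------------------------------
# symmetric component
# ---------------------------------------------------------------------------


def _sym_config(rng, n_pairs=4, n_mid=2, perturb=None):
    coords, pairing = [], {}
    for i in range(n_mid):
        coords.append([0.0, rng.normal(), rng.normal()])
        pairing[i + 1] = i + 1
    for j in range(n_pairs):
        left = n_mid + 2 * j + 1
        base = np.array([1 + rng.random(), rng.normal(), rng.normal()])
        coords.append(base * [-1, 1, 1])
        coords.append(base)
        pairing[left] = left + 1
        pairing[left + 1] = left
    coords = np.array(coords)
    if perturb is not None:
        lid, d = perturb
        coords[lid - 1] += d
    return make_config(coords), pairing


class TestSymmetricComponent:
    def test_symmetric_config_is_fixed_point(self):
        cfg, pairing = _sym_config(np.random.default_rng(3))
        out = mm.symmetric_component(cfg, pairing)
        for lid in cfg.ids:
            np.testing.assert_allclose(out.landmarks[lid], cfg.landmarks[lid],
                                       atol=1e-9)

    def test_mirror_image_gives_same_component(self):
        rng = np.random.default_rng(4)
        cfg, pairing = _sym_config(rng, perturb=(3, np.array([0.3, -0.1, 0.2])))
        X = cfg.coords()
        mirrored = X * np.array([-1, 1, 1])
        relabel = {lid: mirrored[cfg.ids.index(pairing[lid])] for lid in cfg.ids}
        cfg_m = make_config([relabel[i] for i in cfg.ids], ids=cfg.ids)
        a = mm.symmetric_component(cfg, pairing, align=False).coords()
        b = mm.symmetric_component(cfg_m, pairing, align=False).coords()
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_half_perturbation_shared_between_pair(self):
        rng = np.random.default_rng(5)
        d = np.array([0.2, 0.4, -0.3])
        clean, pairing = _sym_config(rng)
        pert, _ = _sym_config(np.random.default_rng(5), perturb=(3, d))
        out = mm.symmetric_component(pert, pairing, align=False)
        # landmark 3 (left) keeps half its perturbation; its partner 4 gets
        # the reflected half
        np.testing.assert_allclose(
            out.landmarks[3] - clean.landmarks[3], d / 2, atol=1e-12)
        np.testing.assert_allclose(
            out.landmarks[4] - clean.landmarks[4], d / 2 * [-1, 1, 1],
            atol=1e-12)

    def test_unpaired_id_fails(self):
        cfg, pairing = _sym_config(np.random.default_rng(6))
        del pairing[3]
        with pytest.raises(mm.MorphometricsError):
            mm.symmetric_component(cfg, pairing)


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


class TestGPA:
    def test_identical_configs_have_zero_distances(self):
        pts = np.random.default_rng(7).normal(size=(10, 3))
        samples, mean = mm.gpa([make_config(pts, specimen_id=f"s{i}")
                                for i in range(4)])
        X = np.stack([s.aligned_coords for s in samples])
        assert np.ptp(X, axis=0).max() < 1e-10
        np.testing.assert_allclose(X[0], mean, atol=1e-8)

    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(9, 3)) * 30
        configs = []
        for i in range(5):
            Q = random_rotation(rng)
            c = rng.uniform(0.3, 4.0)
            t = rng.normal(size=3) * 100
            configs.append(make_config(c * pts @ Q + t, specimen_id=f"s{i}"))
        samples, _ = mm.gpa(configs)
        X = np.stack([s.aligned_coords for s in samples])
        assert np.abs(X - X[0]).max() < 1e-8
        # centroid sizes recorded before scaling
        base = mm.centroid_size(configs[0])
        assert samples[0].centroid_size == pytest.approx(base)

    def test_two_triangles_match_closed_form_opa(self):
        # oracle: partial Procrustes distance d^2 = 2 - 2 tr(Sigma) over
        # centered unit-size configs (SVD closed form)
        A = np.array([[0, 0, 0], [4, 0, 0], [1, 3, 0.0]])
        B = np.array([[0, 0, 0], [5, 1, 0], [0, 4, 0.0]])
        Za, Zb = [(X - X.mean(0)) / np.sqrt(((X - X.mean(0)) ** 2).sum())
                  for X in (A, B)]
        U, s, Vt = linalg.svd(Zb.T @ Za)
        d = np.sign(linalg.det(U @ Vt))
        s[-1] *= d
        oracle = np.sqrt(max(2 - 2 * s.sum(), 0.0))
        samples, _ = mm.gpa([make_config(A), make_config(B, specimen_id="s2")])
        X = np.stack([s_.aligned_coords for s_ in samples])
        dist = np.sqrt(((X[0] - X[1]) ** 2).sum())
        assert dist == pytest.approx(oracle, abs=1e-8)

    def test_inconsistent_ids_fail(self):
        a = make_config(np.eye(3), ids=[1, 2, 3])
        b = make_config(np.eye(3), ids=[1, 2, 4], specimen_id="bad")
        with pytest.raises(mm.MorphometricsError, match="bad"):
            mm.gpa([a, b])

    def test_missing_landmark_filter(self):
        a = make_config(np.random.default_rng(1).normal(size=(4, 3)))
        b = make_config(np.eye(3), ids=[1, 2, 3], specimen_id="s2")
        kept, dropped = mm.filter_complete([a, b], [1, 2, 3, 4])
        assert [c.specimen_id for c in kept] == ["s1"]
        assert dropped == ["s2"]


# ---------------------------------------------------------------------------
# allometric regression
# ---------------------------------------------------------------------------


def _planted_allometry(rng, n_groups=5, per_group=6, p=9, slope_scale=0.8):
    slope = rng.normal(size=p) * slope_scale
    shapes, groups, sizes = [], [], []
    for g in range(n_groups):
        mu = rng.normal(size=p)
        for i in range(per_group):
            logcs = rng.uniform(3.0, 5.0)
            shapes.append(mu + slope * logcs)
            sizes.append(np.exp(logcs))
            groups.append((f"b{g}", "M"))
    samples = [
        mm.ShapeSample(f"s{i}", np.asarray(y), float(cs), float(cs))
        for i, (y, cs) in enumerate(zip(shapes, sizes))
    ]
    return samples, groups, slope


class TestAllometricRegression:
    def test_planted_slope_recovered_exactly(self):
        rng = np.random.default_rng(11)
        samples, groups, slope = _planted_allometry(rng)
        fit = mm.allometric_regression(samples, groups, n_perm=199,
                                       rng=np.random.default_rng(0))
        np.testing.assert_allclose(fit.slope, slope, atol=1e-8)
        assert fit.permutation_p == pytest.approx(1.0 / 200.0)
        # residuals carry no within-group size signal
        x = np.log([s.neurocranium_centroid_size for s in samples])
        labels = [g for g in groups]
        for g in set(labels):
            idx = [i for i, l in enumerate(labels) if l == g]
            xc = x[idx] - x[idx].mean()
            R = fit.residuals[idx] - fit.residuals[idx].mean(0)
            assert np.abs(xc @ R).max() < 1e-8

    def test_size_independent_shapes_low_variance_explained(self):
        rng = np.random.default_rng(12)
        samples, groups, _ = _planted_allometry(rng, slope_scale=0.0)
        noisy = [
            mm.ShapeSample(s.specimen_id,
                           s.aligned_coords + rng.normal(size=9),
                           s.centroid_size, s.neurocranium_centroid_size)
            for s in samples
        ]
        fit = mm.allometric_regression(noisy, groups, n_perm=99,
                                       rng=np.random.default_rng(0))
        assert fit.percent_variance < 15.0
        assert fit.permutation_p > 0.01

    def test_within_group_fit_orthogonal_to_remainder(self):
        rng = np.random.default_rng(13)
        samples, groups, _ = _planted_allometry(rng)
        extra = [
            mm.ShapeSample(s.specimen_id,
                           s.aligned_coords + rng.normal(size=9) * 0.3,
                           s.centroid_size, s.neurocranium_centroid_size)
            for s in samples
        ]
        fit = mm.allometric_regression(extra, groups, n_perm=9,
                                       rng=np.random.default_rng(0))
        Y = np.stack([s.aligned_coords for s in extra])
        labels = list(map(tuple, groups))
        Yc = Y.copy()
        for g in set(labels):
            idx = [i for i, l in enumerate(labels) if l == g]
            Yc[idx] -= Yc[idx].mean(0)
        resid_within = Yc - fit.fitted
        assert abs(float(np.sum(resid_within * fit.fitted))) < 1e-8

    def test_zero_size_variance_fails(self):
        samples = [mm.ShapeSample(f"s{i}", np.arange(3.0), 2.0, 2.0)
                   for i in range(4)]
        groups = [("b", "M")] * 4
        with pytest.raises(mm.MorphometricsError):
            mm.allometric_regression(samples, groups, n_perm=9)


# ---------------------------------------------------------------------------
# shape PCA
# ---------------------------------------------------------------------------


class TestShapePCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(14)
        direction = rng.normal(size=6)
        Y = np.outer(rng.normal(size=12), direction)
        space = mm.shape_pca(Y)
        assert space.variance_fractions[0] == pytest.approx(1.0)
        assert np.all(space.variance_fractions[1:] < 1e-12)

    def test_two_spike_spectrum_recovered(self):
        rng = np.random.default_rng(15)
        n, p = 4000, 10
        v1 = np.eye(p)[0]
        v2 = np.eye(p)[1]
        Y = (np.outer(rng.normal(size=n) * 3.0, v1)
             + np.outer(rng.normal(size=n) * 1.5, v2)
             + rng.normal(size=(n, p)) * 0.05)
        space = mm.shape_pca(Y)
        total = 9.0 + 2.25 + p * 0.0025
        np.testing.assert_allclose(
            space.variance_fractions[:2], [9.0 / total, 2.25 / total],
            rtol=0.08)

    def test_variance_fractions_sum_to_one_and_loadings_orthonormal(self):
        Y = np.random.default_rng(16).normal(size=(20, 7))
        space = mm.shape_pca(Y)
        assert space.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        G = space.loadings @ space.loadings.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-9)
        assert np.abs(space.scores.mean(axis=0)).max() < 1e-9
        # sign convention
        for row in space.loadings:
            assert row[np.argmax(np.abs(row))] > 0


# ---------------------------------------------------------------------------
# breed-sex averages and morphs
# ---------------------------------------------------------------------------


class TestAveragesAndMorphs:
    def test_breed_sex_average_values(self):
        import pandas as pd
        scores = np.array([[0.2], [0.4], [0.7]])
        meta = pd.DataFrame({"breed": ["a", "a", "b"], "sex": ["M", "M", "F"]})
        tab = mm.breed_sex_average(scores, meta, np.log([10, 20, 30]))
        row_a = tab[(tab["breed"] == "a")].iloc[0]
        assert row_a["pc1"] == pytest.approx(0.3)
        assert row_a["n_specimens"] == 2
        row_b = tab[(tab["breed"] == "b")].iloc[0]
        assert row_b["pc1"] == pytest.approx(0.7)  # single specimen passes through
        assert row_b["n_specimens"] == 1
        # order invariance
        perm = [2, 0, 1]
        tab2 = mm.breed_sex_average(scores[perm], meta.iloc[perm],
                                    np.log([10, 20, 30])[perm])
        pd.testing.assert_frame_equal(tab, tab2)

    def test_morph_along_pc(self):
        Y = np.random.default_rng(17).normal(size=(10, 9))
        space = mm.shape_pca(Y)
        mean = mm.morph_along_pc(space, 0, 0.0)
        np.testing.assert_allclose(mean.ravel(), space.mean_shape)
        plus = mm.morph_along_pc(space, 0, 2.0)
        minus = mm.morph_along_pc(space, 0, -2.0)
        np.testing.assert_allclose(0.5 * (plus + minus), mean, atol=1e-12)
        with pytest.raises(mm.MorphometricsError):
            mm.morph_along_pc(space, 99, 1.0)

    def test_projection_identity(self):
        Y = np.random.default_rng(18).normal(size=(12, 6))
        space = mm.shape_pca(Y)
        i = 3
        recon = mm.morph_along_pc(space, 0, space.scores[i, 0]).ravel()
        resid = (Y[i] - Y.mean(0)) - (recon - space.mean_shape)
        off_pc = (Y[i] - Y.mean(0)) - space.scores[i, 0] * space.loadings[0]
        np.testing.assert_allclose(np.linalg.norm(resid),
                                   np.linalg.norm(off_pc), atol=1e-10)


# ---------------------------------------------------------------------------
# end-to-end recovery on the generator
# ---------------------------------------------------------------------------


def test_pc1_recovers_planted_trait(study):
    """The full morphometric chain finds the planted deformation axis."""
    by = {}
    for v in study.landmark_views:
        by.setdefault(v.specimen_id, {})[v.view] = v
    merged = [mm.merge_views(d["dorsal"], d["ventral"], {1, 2, 28, 29})[0]
              for d in by.values()]
    sym = [mm.symmetric_component(c, study.pairing) for c in merged]
    samples, _ = mm.gpa(sym, neurocranium_subset=study.neurocranium_subset)
    fit = mm.allometric_regression(samples, [(c.breed, c.sex) for c in merged],
                                   n_perm=49, rng=np.random.default_rng(0))
    space = mm.shape_pca(fit.residuals)
    traits = study.specimen_traits.set_index("specimen_id").loc[
        [s.specimen_id for s in samples], "trait"].to_numpy()
    r = np.corrcoef(space.scores[:, 0], traits)[0, 1]
    assert abs(r) >= 0.95
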