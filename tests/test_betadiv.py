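import numpy as np
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from metadepth.betadiv import (
    DissimilarityMatrix,
    OrdinationResult,
    bray_curtis,
    ordinate,
    procrustes_fit,
    protest,
)
from metadepth.taxprofile import TaxonProfile


def _ord(coords, ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(len(coords)))
    return OrdinationResult(sample_ids=tuple(ids), coordinates=coords, method="pcoa")


def _profile(sid, counts):
    return TaxonProfile(sid, {k: v for k, v in counts.items()})


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        p = _profile("a", {"x": 600, "y": 400})
        d = bray_curtis([p, _profile("b", {"x": 600, "y": 400})], min_reads=0, min_frac=0)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_profiles_one(self):
        d = bray_curtis(
            [_profile("a", {"x": 100}), _profile("b", {"y": 100})],
            min_reads=0,
            min_frac=0,
        )
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # percent vectors (60,40,0) vs (20,40,40): 1 - 2(20+40+0)/200 = 0.4
        a = _profile("a", {"x": 60, "y": 40})
        b = _profile("b", {"x": 20, "y": 40, "z": 40})
        d = bray_curtis([a, b], min_reads=0, min_frac=0)
        assert d.values[0, 1] == pytest.approx(0.4)

    def test_zero_classified_sample_named(self):
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(
                [_profile("ok", {"x": 10}), TaxonProfile("empty", {}, unclassified=5)],
                min_reads=0,
                min_frac=0,
            )

    def test_values_in_unit_interval(self, mock_profile_1m):
        from metadepth.rarefaction import subsample_profile

        subs = [subsample_profile(mock_profile_1m, 50_000, seed=s) for s in range(3)]
        profiles = [mock_profile_1m] + [
            TaxonProfile(f"p{i}", s.counts, s.unclassified) for i, s in enumerate(subs)
        ]
        d = bray_curtis(profiles)
        assert (d.values >= 0).all() and (d.values <= 1).all()
        assert np.allclose(d.values, d.values.T)


class TestDissimilarityMatrix:
    def test_asymmetric_rejected(self):
        bad = np.array([[0.0, 0.3], [0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(("a", "b"), bad)

    def test_nonzero_diagonal_rejected(self):
        bad = np.array([[0.1, 0.3], [0.3, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DissimilarityMatrix(("a", "b"), bad)


class TestOrdinate:
    def test_pcoa_recovers_planted_distances(self):
        """PCoA on Euclidean distances of known 2-D points returns a
        configuration with the same inter-point distances."""
        rng = np.random.default_rng(0)
        points = rng.normal(size=(9, 2))
        d = DissimilarityMatrix(
            tuple(f"s{i}" for i in range(9)), squareform(pdist(points))
        )
        result = ordinate(d, method="pcoa", dims=2)
        assert np.allclose(squareform(pdist(result.coordinates)), d.values, atol=1e-8)

    def test_equidistant_points_stay_equidistant(self):
        d = DissimilarityMatrix(
            ("a", "b", "c"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        )
        result = ordinate(d, method="pcoa", dims=2)
        dists = pdist(result.coordinates)
        assert np.allclose(dists, dists[0], atol=1e-8)

    def test_nmds_near_zero_stress_when_embeddable(self):
        rng = np.random.default_rng(1)
        points = rng.normal(size=(10, 2))
        d = DissimilarityMatrix(
            tuple(f"s{i}" for i in range(10)), squareform(pdist(points))
        )
        result = ordinate(d, method="nmds", dims=2, seed=0, n_starts=8)
        assert result.stress is not None and result.stress < 0.01

    def test_nmds_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(7, 3))
        d = DissimilarityMatrix(
            tuple(f"s{i}" for i in range(7)), squareform(pdist(points))
        )
        a = ordinate(d, method="nmds", dims=2, seed=5, n_starts=4)
        b = ordinate(d, method="nmds", dims=2, seed=5, n_starts=4)
        assert np.allclose(a.coordinates, b.coordinates)

    def test_dims_must_be_below_sample_count(self):
        d = DissimilarityMatrix(("a", "b"), np.array([[0.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="dims"):
            ordinate(d, dims=2)


class TestProcrustes:
    def test_self_comparison_is_one(self):
        x = _ord(np.random.default_rng(3).normal(size=(8, 2)))
        res = procrustes_fit(x, x)
        assert res.correlation == pytest.approx(1.0)
        assert res.rss == pytest.approx(0.0, abs=1e-12)

    def test_rotation_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(10, 2))
        theta = np.deg2rad(37)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        y = _ord(3.0 * coords @ rot + np.array([5.0, -2.0]))
        res = procrustes_fit(_ord(coords), y)
        assert res.correlation == pytest.approx(1.0)
        assert res.rss == pytest.approx(0.0, abs=1e-10)

    def test_reflection_invariance(self):
        coords = np.random.default_rng(5).normal(size=(6, 2))
        reflected = coords @ np.diag([1.0, -1.0])
        res = procrustes_fit(_ord(coords), _ord(reflected))
        assert res.correlation == pytest.approx(1.0)

    def test_matches_scipy_disparity(self):
        """Independent cross-check: scipy's Procrustes disparity m^2
        satisfies correlation = sqrt(1 - m^2)."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 2))
        y = 0.6 * x + rng.normal(scale=0.3, size=(12, 2))
        _, _, disparity = scipy_procrustes(x, y)
        res = procrustes_fit(_ord(x), _ord(y))
        assert res.correlation == pytest.approx(np.sqrt(1 - disparity), abs=1e-10)
        assert res.rss == pytest.approx(disparity, abs=1e-10)

    def test_matches_rotation_grid_search(self):
        """Brute-force oracle: scan rotation angle (and reflection) on a
        fine grid for 3-point 2-D configurations."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(3, 2))
        y = rng.normal(size=(3, 2))
        xc = x - x.mean(0)
        yc = y - y.mean(0)
        xc /= np.sqrt((xc**2).sum())
        yc /= np.sqrt((yc**2).sum())
        # with unit-normalised configurations and the optimal scale for a
        # given rotation R, rss(R) = 1 - trace(R^T yc^T xc)^2; scan theta
        # (and reflection) on a fine grid for the minimum
        m = yc.T @ xc
        thetas = np.linspace(0, 2 * np.pi, 2_000_000, endpoint=False)
        cos_t, sin_t = np.cos(thetas), np.sin(thetas)
        best_sq = 0.0
        for reflect in (1.0, -1.0):
            trace = cos_t * (m[0, 0] + reflect * m[1, 1]) + sin_t * (
                m[1, 0] - reflect * m[0, 1]
            )
            best_sq = max(best_sq, float((trace**2).max()))
        res = procrustes_fit(_ord(x), _ord(y))
        assert res.rss == pytest.approx(1.0 - best_sq, abs=1e-9)

    def test_sample_alignment_by_id(self):
        coords = np.random.default_rng(8).normal(size=(5, 2))
        x = _ord(coords, ids=("a", "b", "c", "d", "e"))
        # same configuration listed in a different row order
        perm = [3, 1, 4, 0, 2]
        y = OrdinationResult(
            sample_ids=tuple(x.sample_ids[i] for i in perm),
            coordinates=coords[perm],
            method="pcoa",
        )
        assert procrustes_fit(x, y).correlation == pytest.approx(1.0)

    def test_id_mismatch_rejected(self):
        x = _ord(np.zeros((3, 2)) + np.arange(3)[:, None], ids=("a", "b", "c"))
        y = _ord(np.zeros((3, 2)) + np.arange(3)[:, None], ids=("a", "b", "z"))
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_fit(x, y)


class TestProtest:
    def test_p_floor_at_999_permutations(self):
        x = _ord(np.random.default_rng(9).normal(size=(12, 2)))
        res = protest(x, x, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(0.001)
        assert res.correlation == pytest.approx(1.0)

    def test_null_rarely_significant(self):
        """Independent random configurations: p > 0.05 in >= 90% of 50 trials."""
        rng = np.random.default_rng(10)
        insignificant = 0
        for trial in range(50):
            x = _ord(rng.normal(size=(10, 2)))
            y = _ord(rng.normal(size=(10, 2)))
            res = protest(x, y, n_perm=199, seed=trial)
            if res.p_value > 0.05:
                insignificant += 1
        assert insignificant >= 45

    def test_null_super_uniform_at_5_percent(self):
        """Across 200 independent null trials the rejection rate at
        alpha = 0.05 does not exceed its binomial noise band."""
        rng = np.random.default_rng(11)
        rejections = 0
        for trial in range(200):
            x = _ord(rng.normal(size=(9, 2)))
            y = _ord(rng.normal(size=(9, 2)))
            if protest(x, y, n_perm=99, seed=trial).p_value <= 0.05:
                rejections += 1
        # binomial(200, 0.05): mean 10, sd ~3.1; allow 4 sd
        assert rejections <= 23

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            x = _ord(rng.normal(size=(6, 2)))
            y = _ord(rng.normal(size=(6, 2)))
            p = protest(x, y, n_perm=49, seed=trial).p_value
            assert 0 < p <= 1
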