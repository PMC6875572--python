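import numpy as np
import pytest

import isonich as iso
from isonich.niche_metrics import IsoPointSet, ellipse_overlap, layman_metrics, sea, sea_b, sea_c


# -- independent brute-force oracles ----------------------------------------

def brute_layman(pts):
    n = len(pts)
    cr = max(p[0] for p in pts) - min(p[0] for p in pts)
    nr = max(p[1] for p in pts) - min(p[1] for p in pts)
    cx = sum(p[0] for p in pts) / n
    cy = sum(p[1] for p in pts) / n
    cd = sum(((p[0] - cx) ** 2 + (p[1] - cy) ** 2) ** 0.5 for p in pts) / n
    nnd = []
    for i in range(n):
        best = min(
            ((pts[i][0] - pts[j][0]) ** 2 + (pts[i][1] - pts[j][1]) ** 2) ** 0.5
            for j in range(n) if j != i
        )
        nnd.append(best)
    mnnd = sum(nnd) / n
    var = sum((d - mnnd) ** 2 for d in nnd) / (n - 1)
    return cr, nr, cd, mnnd, var**0.5, hull_area(pts)


def hull_area(pts):
    """Monotone chain + shoelace; None for degenerate hulls."""
    pts = sorted(set(map(tuple, pts)))
    if len(pts) < 3:
        return None

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return None
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2


class TestLaymanMetrics:
    def test_unit_square_by_symmetry(self):
        ps = IsoPointSet("sq", np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        m = layman_metrics(ps)
        assert m.CR == 1 and m.NR == 1
        assert m.CD == pytest.approx(np.sqrt(2) / 2)
        assert m.MNND == 1 and m.SDNND == 0
        assert m.TA == pytest.approx(1.0)

    def test_coincident_points_have_zero_mnnd(self):
        # NND = (0, 0, sqrt(2)): the coincident pair contributes zeros
        ps = IsoPointSet("dup", np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 0.0]]))
        assert layman_metrics(ps).MNND == pytest.approx(2**0.5 / 3)
        ps2 = IsoPointSet("dup2", np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert layman_metrics(ps2).MNND == 0.0

    def test_matches_brute_force_on_random_sets(self, rng):
        for trial in range(25):
            n = int(rng.integers(3, 13))
            pts = rng.normal(0, 2, (n, 2))
            m = layman_metrics(IsoPointSet(f"t{trial}", pts))
            cr, nr, cd, mnnd, sdnnd, ta = brute_layman([tuple(p) for p in pts])
            assert m.CR == pytest.approx(cr, abs=1e-12)
            assert m.NR == pytest.approx(nr, abs=1e-12)
            assert m.CD == pytest.approx(cd, abs=1e-12)
            assert m.MNND == pytest.approx(mnnd, abs=1e-12)
            assert m.SDNND == pytest.approx(sdnnd, abs=1e-12)
            assert m.TA == pytest.approx(ta, rel=1e-10)

    def test_collinear_points_flag_degenerate_hull(self):
        ps = IsoPointSet("line", np.array([[0, 0], [1, 1], [2, 2]], float))
        m = layman_metrics(ps)
        assert m.TA is None and m.degenerate_hull

    def test_single_point_insufficient(self):
        with pytest.raises(iso.InsufficientDataError):
            layman_metrics(IsoPointSet("one", np.array([[0.0, 0.0]])))

    def test_translation_invariance_except_ranges(self, rng):
        pts = rng.normal(0, 1, (8, 2))
        a = layman_metrics(IsoPointSet("a", pts))
        b = layman_metrics(IsoPointSet("b", pts + np.array([5.0, -3.0])))
        for attr in ("CR", "NR", "CD", "MNND", "SDNND", "TA"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))

    def test_rotation_invariance_of_distance_metrics(self, rng):
        pts = rng.normal(0, 1, (9, 2))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a = layman_metrics(IsoPointSet("a", pts))
        b = layman_metrics(IsoPointSet("b", pts @ rot.T))
        for attr in ("CD", "MNND", "SDNND", "TA"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))


class TestSEA:
    def test_identity_covariance_gives_pi(self, rng):
        # construct points whose sample covariance is exactly I
        raw = rng.normal(size=(40, 2))
        raw -= raw.mean(0)
        chol = np.linalg.cholesky(np.cov(raw.T, ddof=1))
        pts = raw @ np.linalg.inv(chol).T
        assert sea(IsoPointSet("id", pts)) == pytest.approx(np.pi, rel=1e-10)

    def test_sea_c_factor_at_n3(self, rng):
        ps = IsoPointSet("t", rng.normal(size=(3, 2)))
        assert sea_c(ps) == pytest.approx(2 * sea(ps))

    def test_sea_c_converges_to_sea(self, rng):
        ps = IsoPointSet("t", rng.normal(size=(500, 2)))
        assert sea_c(ps) / sea(ps) == pytest.approx(499 / 498)

    def test_determinant_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(0, 1.5, (50, 2))
            s = np.cov(pts.T, ddof=1)
            lam = np.linalg.eigvalsh(s)
            assert sea(IsoPointSet("d", pts)) == pytest.approx(
                np.pi * np.sqrt(lam[0] * lam[1]), rel=1e-10
            )

    def test_translation_and_rotation_invariance(self, rng):
        pts = rng.normal(size=(30, 2))
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        base = sea(IsoPointSet("b", pts))
        assert sea(IsoPointSet("t", pts + 7)) == pytest.approx(base)
        assert sea(IsoPointSet("r", pts @ rot.T)) == pytest.approx(base)

    def test_singular_covariance_gives_zero(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        assert sea(IsoPointSet("sing", pts)) == 0.0


class TestSeaB:
    def test_posterior_concentrates_on_sample_covariance(self, rng):
        # with a vague prior the posterior concentrates on the realized
        # sample covariance; at n=500 the mode tracks pi*sqrt(det S)
        cov = np.array([[2.0, 0.6], [0.6, 0.68]])  # det = 1
        assert np.linalg.det(cov) == pytest.approx(1.0)
        pts = rng.multivariate_normal([0, 0], cov, size=500)
        post = sea_b(IsoPointSet("big", pts), n_draws=4000, seed=5)
        realized = np.pi * np.sqrt(np.linalg.det(np.cov(pts.T, ddof=1)))
        assert post.mode == pytest.approx(realized, rel=0.05)

    def test_fixed_seed_determinism(self, rng):
        pts = rng.normal(size=(30, 2))
        a = sea_b(IsoPointSet("x", pts), n_draws=500, seed=3)
        b = sea_b(IsoPointSet("x", pts), n_draws=500, seed=3)
        np.testing.assert_array_equal(a.sea_b_draws, b.sea_b_draws)

    def test_all_draws_positive_and_pd(self, rng):
        pts = rng.normal(size=(10, 2))
        post = sea_b(IsoPointSet("x", pts), n_draws=300, seed=1)
        assert np.all(post.sea_b_draws > 0)
        assert np.all(np.linalg.eigvalsh(post.sigma_draws) > 0)

    def test_credible_intervals_nested(self, rng):
        pts = rng.normal(size=(25, 2))
        post = sea_b(IsoPointSet("x", pts), n_draws=1000, seed=2)
        (l50, h50), (l75, h75), (l95, h95) = (
            post.credible_intervals[50],
            post.credible_intervals[75],
            post.credible_intervals[95],
        )
        assert l95 <= l75 <= l50 <= h50 <= h75 <= h95


class TestEllipseOverlap:
    def test_identical_ellipses_full_overlap(self):
        sig = np.array([[2.0, 0.3], [0.3, 1.0]])
        area, prop = ellipse_overlap([0, 0], sig, [0, 0], sig)
        lam = np.linalg.eigvalsh(sig)
        assert area == pytest.approx(np.pi * np.sqrt(lam[0] * lam[1]), rel=1e-3)
        assert prop == pytest.approx(1.0, abs=1e-6)

    def test_distant_ellipses_disjoint(self):
        sig = np.eye(2)
        area, prop = ellipse_overlap([0, 0], sig, [1e6, 0], sig)
        assert area == 0.0 and prop == 0.0

    def test_grid_vs_monte_carlo_oracle(self, rng):
        mu_a, mu_b = np.array([0.0, 0.0]), np.array([1.0, 0.5])
        sig_a = np.array([[1.5, 0.4], [0.4, 0.8]])
        sig_b = np.array([[0.9, -0.2], [-0.2, 1.2]])
        area, _ = ellipse_overlap(mu_a, sig_a, mu_b, sig_b)
        # MC hit-count oracle over a bounding box
        lo, hi = np.array([-3.0, -3.0]), np.array([4.0, 4.0])
        n = 600_000
        pts = rng.uniform(lo, hi, (n, 2))
        ia = np.linalg.inv(sig_a)
        ib = np.linalg.inv(sig_b)
        da = np.einsum("ni,ij,nj->n", pts - mu_a, ia, pts - mu_a)
        db = np.einsum("ni,ij,nj->n", pts - mu_b, ib, pts - mu_b)
        mc = np.mean((da <= 1) & (db <= 1)) * np.prod(hi - lo)
        assert area == pytest.approx(mc, rel=0.01)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(iso.ValidationError):
            ellipse_overlap([0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]), [0, 0], np.eye(2))
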