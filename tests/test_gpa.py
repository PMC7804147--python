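import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from faceshape.gpa import (
    DegenerateShapeError,
    bending_energy,
    bending_energy_matrix,
    centroid_size,
    gpa,
    optimal_superimposition,
    preshape,
    procrustes_distance,
    slide_semilandmarks,
    tangent_project,
)
from faceshape.landmark_io import SliderTable

from conftest import brute_force_procrustes, random_similarity


def rotate(coords, theta):
    c, s = np.cos(theta), np.sin(theta)
    return coords @ np.array([[c, -s], [s, c]]).T


class TestCentroidSize:
    def test_unit_square(self):
        # each corner at distance sqrt(1/2) from the center: sum of squares 2
        assert centroid_size([[0, 0], [1, 0], [1, 1], [0, 1]]) == pytest.approx(
            np.sqrt(2), abs=1e-12
        )

    @settings(max_examples=30, deadline=None)
    @given(
        st.floats(-50, 50),
        st.floats(-50, 50),
        st.floats(0.01, 30),
        st.integers(0, 2**31 - 1),
    )
    def test_translation_invariance_and_homogeneity(self, tx, ty, scale, seed):
        coords = np.random.default_rng(seed).normal(size=(6, 2))
        base = centroid_size(coords)
        assert centroid_size(coords + [tx, ty]) == pytest.approx(base, rel=1e-9)
        assert centroid_size(coords * scale) == pytest.approx(base * scale, rel=1e-9)


class TestOptimalSuperimposition:
    def test_recovers_rotation(self, rng):
        target = preshape(rng.normal(size=(5, 2)))
        moving = rotate(target, np.pi / 6)
        _, aligned, rss = optimal_superimposition(moving, target)
        assert rss <= 1e-12
        np.testing.assert_allclose(aligned, target, atol=1e-12)

    def test_reflection_never_used(self, rng):
        target = preshape(np.array([[0.0, 0.0], [2.0, 0.1], [0.5, 1.7]]))
        mirror = target * [1.0, -1.0]  # scalene triangle: mirror is a new shape
        _, _, rss = optimal_superimposition(preshape(mirror), target)
        assert rss > 1e-4

    def test_matches_brute_force_grid(self, rng):
        m = preshape(rng.normal(size=(5, 2)))
        t = preshape(rng.normal(size=(5, 2)))
        _, aligned, rss = optimal_superimposition(m, t)
        d_brute = brute_force_procrustes(m, t)
        assert np.sqrt(rss) == pytest.approx(d_brute, abs=1e-6)

    def test_degenerate_rejected(self):
        flat = np.zeros((4, 2))
        with pytest.raises(DegenerateShapeError):
            optimal_superimposition(flat, np.eye(2).repeat(2, axis=0))


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        a = rng.normal(size=(6, 2))
        b = rng.normal(size=(6, 2))
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12
        )

    def test_brute_force_oracle_many_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            k = rng.integers(5, 9)
            a, b = rng.normal(size=(k, 2)), rng.normal(size=(k, 2))
            assert procrustes_distance(a, b) == pytest.approx(
                brute_force_procrustes(a, b), abs=1e-6
            )

    def test_variants_ordering(self, rng):
        a, b = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        partial = procrustes_distance(a, b, "partial")
        full = procrustes_distance(a, b, "full")
        geo = procrustes_distance(a, b, "geodesic")
        # sin(rho) <= 2 sin(rho/2) <= rho for rho in [0, pi/2]
        assert full <= partial <= geo + 1e-12


class TestGPA:
    def test_orbit_collapse(self, rng):
        base = rng.normal(size=(7, 2))
        dataset = np.stack([random_similarity(base, rng) for _ in range(10)])
        res = gpa(dataset)
        assert res.converged
        spread = np.max(np.abs(res.aligned - res.aligned[0]))
        assert spread < 1e-10
        np.testing.assert_allclose(res.consensus, res.aligned[0], atol=1e-10)

    def test_two_shape_distance_matches_pairwise(self, rng):
        a, b = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        res = gpa(np.stack([a, b]))
        d_aligned = np.linalg.norm(res.aligned[0] - res.aligned[1])
        assert d_aligned == pytest.approx(procrustes_distance(a, b), abs=1e-9)

    def test_idempotence_at_convergence(self, rng):
        dataset = np.stack([rng.normal(size=(6, 2)) for _ in range(5)])
        res = gpa(dataset, tol=1e-12, max_iter=200)
        res2 = gpa(res.aligned, tol=1e-12, max_iter=200)
        assert np.max(np.abs(res2.aligned - res.aligned)) < 1e-8

    def test_tangent_coords_similarity_invariant(self, rng):
        dataset = [rng.normal(size=(8, 2)) for _ in range(6)]
        nuisanced = [random_similarity(c, rng) for c in dataset]
        r1 = gpa(np.stack(dataset), tol=1e-12, max_iter=200)
        r2 = gpa(np.stack(nuisanced), tol=1e-12, max_iter=200)
        # tangent coordinates agree up to a global rotation; compare distances
        d1 = cdist(r1.tangent_coords, r1.tangent_coords)
        d2 = cdist(r2.tangent_coords, r2.tangent_coords)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_consensus_stationarity(self, rng):
        dataset = np.stack([rng.normal(size=(6, 2)) for _ in range(8)])
        res = gpa(dataset, tol=1e-12, max_iter=200)
        mean_tangent = res.tangent_coords.mean(axis=0)
        consensus_tangent = tangent_project(res.consensus, res.consensus)
        np.testing.assert_allclose(mean_tangent, consensus_tangent, atol=1e-9)


class TestTangentProjection:
    def test_consensus_is_fixed_point(self, rng):
        c = preshape(rng.normal(size=(6, 2)))
        out = tangent_project(c, c)
        np.testing.assert_allclose(out, c.ravel(), atol=1e-12)

    def test_small_distance_preserved(self, rng):
        c = preshape(rng.normal(size=(10, 2)))
        # displace orthogonally to the consensus vector, norm 0.01
        d = rng.normal(size=20)
        cv = c.ravel()
        d -= (d @ cv) * cv
        d *= 0.01 / np.linalg.norm(d)
        x = preshape((cv + d).reshape(10, 2))
        theta_opt, aligned, _ = optimal_superimposition(x, c)
        dist = procrustes_distance(x, c)
        t = tangent_project(aligned, c)
        t0 = tangent_project(c, c)
        assert np.linalg.norm(t - t0) == pytest.approx(dist, abs=1e-6)

    def test_idempotent(self, rng):
        c = preshape(rng.normal(size=(6, 2)))
        x = preshape(rng.normal(size=(6, 2)))
        once = tangent_project(x, c)
        twice = tangent_project(once.reshape(6, 2), c)
        np.testing.assert_allclose(once, twice, atol=1e-12)


def tps_energy_quadrature(ref: np.ndarray, disp_component: np.ndarray) -> float:
    """Independent oracle: dense-grid quadrature of the TPS bending integral.

    Fits the thin-plate interpolant of one displacement component through the
    reference points and integrates f_xx^2 + 2 f_xy^2 + f_yy^2 over the plane
    (uniform central disk + log-spaced polar tail).  With the r^2 log(r^2)
    kernel the bending-energy quadratic form equals this integral / (16 pi).
    """
    k = len(ref)
    r2 = cdist(ref, ref, "sqeuclidean")
    kern = np.zeros_like(r2)
    nz = r2 > 0
    kern[nz] = r2[nz] * np.log(r2[nz])
    q = np.column_stack([np.ones(k), ref])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kern
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    w = np.linalg.solve(lmat, np.concatenate([disp_component, np.zeros(3)]))[:k]

    def density(px, py):
        fxx = np.zeros_like(px)
        fyy = np.zeros_like(px)
        fxy = np.zeros_like(px)
        for i in range(k):
            dx, dy = px - ref[i, 0], py - ref[i, 1]
            s = dx * dx + dy * dy
            s = np.where(s == 0, np.nan, s)
            ls = np.log(s)
            fxx += w[i] * (2 * ls + 2 + 4 * dx * dx / s)
            fyy += w[i] * (2 * ls + 2 + 4 * dy * dy / s)
            fxy += w[i] * (4 * dx * dy / s)
        return fxx**2 + 2 * fxy**2 + fyy**2

    h = 0.005
    gx = np.arange(-3 + h / 2, 3, h)
    xg, yg = np.meshgrid(gx, gx)
    vals = density(xg, yg)
    central = np.nansum(vals[xg**2 + yg**2 <= 9]) * h * h
    rr = np.logspace(np.log10(3), np.log10(300), 2000)
    rmid, dr = np.sqrt(rr[:-1] * rr[1:]), np.diff(rr)
    th = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    rg, tg = np.meshgrid(rmid, th)
    tail = np.sum(density(rg * np.cos(tg), rg * np.sin(tg)) * rg * dr[None, :]) * (
        th[1] - th[0]
    )
    return (central + tail) / (16 * np.pi)


class TestBendingEnergy:
    def test_affine_null_space(self, face_template):
        ref = face_template[0].coords
        be = bending_energy_matrix(ref)
        affine = ref @ np.array([[1.2, 0.3], [-0.1, 0.8]]).T + [0.5, -0.2]
        assert bending_energy(affine, ref, be) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_psd(self, face_template):
        be = bending_energy_matrix(face_template[0].coords)
        assert np.max(np.abs(be - be.T)) == 0.0
        assert np.linalg.eigvalsh(be).min() >= -1e-9

    def test_collinear_reference_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(DegenerateShapeError):
            bending_energy_matrix(line)

    def test_matches_quadrature_oracle(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        disp = np.zeros(4)
        disp[2] = 1.0
        be = bending_energy_matrix(ref)
        qform = float(disp @ be @ disp)
        oracle = tps_energy_quadrature(ref, disp)
        assert qform == pytest.approx(oracle, rel=0.01)


class TestSliding:
    def test_zero_at_reference(self, face_template):
        tpl, sliders = face_template
        be = bending_energy_matrix(tpl.coords)
        slid = slide_semilandmarks(tpl.coords, tpl.coords, sliders, be)
        np.testing.assert_allclose(slid, tpl.coords, atol=1e-12)

    def test_restores_tangential_displacement(self, face_template):
        tpl, sliders = face_template
        be = bending_energy_matrix(tpl.coords)
        cfg = tpl.coords.copy()
        b, s, a = sliders.rows[1]
        t = cfg[a] - cfg[b]
        t /= np.linalg.norm(t)
        cfg[s] += 0.01 * t
        slid = slide_semilandmarks(cfg, tpl.coords, sliders, be)
        np.testing.assert_allclose(slid, tpl.coords, atol=1e-8)

    def test_single_slider_matches_grid_search(self, rng, face_template):
        tpl, sliders = face_template
        ref = tpl.coords
        be = bending_energy_matrix(ref)
        one = SliderTable(sliders.rows[:1], n_landmarks=tpl.k)
        cfg = ref + rng.normal(0, 0.01, size=ref.shape)
        b, s, a = one.rows[0]
        t = cfg[a] - cfg[b]
        t /= np.linalg.norm(t)
        # independent oracle: 1-D grid search over the sliding amount
        ws = np.arange(-0.5, 0.5, 1e-5)
        trial = np.repeat(cfg[None, :, :], 1, axis=0)
        energies = np.empty(len(ws))
        d0 = cfg - ref
        for i, wv in enumerate(ws):
            d = d0.copy()
            d[s] += wv * t
            energies[i] = d[:, 0] @ be @ d[:, 0] + d[:, 1] @ be @ d[:, 1]
        w_best = ws[np.argmin(energies)]
        slid = slide_semilandmarks(cfg, ref, one, be)
        w_mod = float((slid[s] - cfg[s]) @ t)
        assert w_mod == pytest.approx(w_best, abs=1e-4)

    def test_energy_never_increases(self, rng, face_template):
        tpl, sliders = face_template
        ref = tpl.coords
        be = bending_energy_matrix(ref)
        for _ in range(10):
            cfg = ref + rng.normal(0, 0.02, size=ref.shape)
            e_pre = bending_energy(cfg, ref, be)
            slid = slide_semilandmarks(cfg, ref, sliders, be)
            e_post = bending_energy(slid, ref, be)
            assert e_post <= e_pre + 1e-12

    def test_coincident_neighbors_named(self, face_template):
        tpl, sliders = face_template
        cfg = tpl.coords.copy()
        b, s, a = sliders.rows[0]
        cfg[a] = cfg[b]
        with pytest.raises(DegenerateShapeError, match="slider row 0"):
            slide_semilandmarks(cfg, tpl.coords, sliders)

    def test_gpa_with_sliding_reduces_energy(self, rng, face_template):
        # the slide-then-realign loop drifts slowly along the outline (a
        # neutral direction of the bending-energy objective), so we assert
        # the substantive contract: sliding lowers total bending energy
        # relative to the unslid superimposition, and output stays finite
        tpl, sliders = face_template
        dataset = np.stack(
            [tpl.coords + rng.normal(0, 0.01, size=tpl.coords.shape) for _ in range(6)]
        )
        plain = gpa(dataset)
        slid = gpa(dataset, sliders=sliders)
        assert np.all(np.isfinite(slid.tangent_coords))
        be_p = bending_energy_matrix(plain.consensus)
        e_plain = sum(bending_energy(c, plain.consensus, be_p) for c in plain.aligned)
        be_s = bending_energy_matrix(slid.consensus)
        e_slid = sum(bending_energy(c, slid.consensus, be_s) for c in slid.aligned)
        assert e_slid < e_plain
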