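"""Biot-Savart loop fields against closed-form oracles; solid harmonics."""

import numpy as np
import pytest

from b0shim import (
    BrainMask,
    FieldMap,
    LoopSpec,
    SHBasisSpec,
    assemble_coil_basis,
    layout_unic51,
    loop_bz_analytic,
    loop_bz_numeric,
    sh_basis,
    sh_term_count,
)
from b0shim.field_basis import GAMMA_BAR_HZ_PER_T, MU0

LOOP95 = LoopSpec((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), 47.5)  # 9.5 cm study loop
CENTER_HZ_PER_A = MU0 / (2 * 0.0475) * GAMMA_BAR_HZ_PER_T  # mu0 I / 2a = 563.2


def _random_points_off_wire(loop, n, rng, lo=20.0, hi=150.0):
    """Points whose distance to the wire circle is in [lo, hi] mm."""
    pts = []
    while len(pts) < n:
        p = np.asarray(loop.center) + rng.normal(0, 60.0, 3)
        rel = p - np.asarray(loop.center)
        nrm = np.asarray(loop.normal)
        z = rel @ nrm
        rho = np.linalg.norm(rel - z * nrm)
        d = np.hypot(rho - loop.radius, z)
        if lo < d < hi:
            pts.append(p)
    return np.asarray(pts)


class TestLoopFieldNumeric:
    def test_center_field_matches_elementary_formula(self):
        val = loop_bz_numeric(LOOP95, [[0.0, 0.0, 0.0]], n_segments=256)[0]
        assert CENTER_HZ_PER_A == pytest.approx(563.2, abs=0.1)
        assert val == pytest.approx(CENTER_HZ_PER_A, rel=1e-3)

    def test_on_axis_at_one_radius(self):
        # mu0 I a^2 / 2(a^2+z^2)^{3/2} at z = a is the center value / 2^{3/2}
        val = loop_bz_numeric(LOOP95, [[0.0, 0.0, 47.5]], n_segments=256)[0]
        assert val == pytest.approx(CENTER_HZ_PER_A / 2**1.5, rel=1e-3)

    def test_two_turns_exactly_doubles_field(self):
        rng = np.random.default_rng(0)
        pts = _random_points_off_wire(LOOP95, 10, rng)
        one = loop_bz_numeric(LOOP95, pts, 64)
        two_turn = LoopSpec(LOOP95.center, LOOP95.normal, LOOP95.radius, turns=2)
        two = loop_bz_numeric(two_turn, pts, 64)
        assert np.array_equal(two, 2.0 * one)

    def test_point_on_wire_rejected(self):
        with pytest.raises(ValueError):
            loop_bz_numeric(LOOP95, [[47.5, 0.0, 0.0]], 64)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            loop_bz_numeric(LOOP95, [[0.0, 0.0, 0.0]], n_segments=4)


class TestLoopFieldOracle:
    def test_analytic_on_axis_reduces_to_elementary_form(self):
        z = np.array([0.0, 10.0, 47.5, 90.0])
        pts = np.stack([np.zeros(4), np.zeros(4), z], axis=1)
        a = 47.5e-3
        expect = (
            MU0 * a**2 / (2.0 * (a**2 + (z * 1e-3) ** 2) ** 1.5)
        ) * GAMMA_BAR_HZ_PER_T
        got = loop_bz_analytic(LOOP95, pts)
        assert np.allclose(got, expect, rtol=1e-12)

    def test_equatorial_far_field_matches_dipole(self):
        # equatorial dipole field: -mu0 m / (4 pi r^3), m = I pi a^2
        a, r = 30.0e-3, 300.0e-3
        loop = LoopSpec((0, 0, 0), (0, 0, 1), 30.0)
        expect = -MU0 * np.pi * a**2 / (4 * np.pi * r**3) * GAMMA_BAR_HZ_PER_T
        got = loop_bz_analytic(loop, [[300.0, 0.0, 0.0]])[0]
        assert got == pytest.approx(expect, rel=0.02)

    def test_numeric_matches_analytic_at_random_points(self):
        rng = np.random.default_rng(42)
        n = np.array([0.3, -0.5, 0.8])
        n /= np.linalg.norm(n)
        loop = LoopSpec((12.0, -8.0, 25.0), tuple(n), 40.0, turns=2)
        pts = _random_points_off_wire(loop, 100, rng)
        num = loop_bz_numeric(loop, pts, 512)
        ana = loop_bz_analytic(loop, pts)
        denom = np.maximum(np.abs(ana), 1e-3 * np.abs(ana).max())
        assert np.max(np.abs(num - ana) / denom) < 1e-3

    def test_numeric_converges_monotonically(self):
        rng = np.random.default_rng(3)
        pts = _random_points_off_wire(LOOP95, 20, rng)
        ana = loop_bz_analytic(LOOP95, pts)
        errs = [
            np.abs(loop_bz_numeric(LOOP95, pts, n) - ana).max()
            for n in (16, 32, 64, 128, 256)
        ]
        assert all(e2 <= e1 for e1, e2 in zip(errs, errs[1:]))


def _cube_basis(n=16, h=6.0, max_degree=5, normalize=True):
    fm = FieldMap(np.zeros((n, n, n)), spacing=(h, h, h),
                  origin=(-(n - 1) * h / 2,) * 3)
    mask = BrainMask(np.ones((n, n, n), bool), spacing=fm.spacing,
                     origin=fm.origin)
    return fm, mask, sh_basis(
        SHBasisSpec(max_degree=max_degree, normalize=normalize), fm, mask
    )


class TestSolidHarmonics:
    @pytest.mark.parametrize("degree,count", [(0, 1), (1, 4), (2, 9), (3, 16),
                                              (4, 25), (5, 36)])
    def test_term_counts(self, degree, count):
        assert sh_term_count(degree) == count
        _, _, basis = _cube_basis(n=6, max_degree=degree)
        assert basis.n_channels == count

    def test_degree_increment_adds_2n_plus_1_terms(self):
        assert sh_term_count(3) - sh_term_count(2) == 7
        assert sh_term_count(4) - sh_term_count(3) == 9
        assert sh_term_count(5) - sh_term_count(4) == 11

    def test_degree_one_m0_column_is_linear_in_z(self):
        fm, mask, basis = _cube_basis(n=8, normalize=False)
        col = basis.values[:, basis.channel_labels.index("sh10c")]
        z = fm.voxel_centers()[mask.data][:, 2]
        zc = (z - z.mean()) / 10.0  # module convention: cm about centroid
        assert np.allclose(col, zc, atol=1e-12)

    def test_degree_zero_is_constant(self):
        _, _, basis = _cube_basis(n=6, normalize=True)
        assert np.allclose(basis.values[:, 0], 1.0)

    def test_columns_are_discretely_harmonic(self):
        # central-difference Laplacian of every unnormalized column
        n, h = 48, 12.0
        fm, mask, basis = _cube_basis(n=n, h=h, normalize=False)
        for c in range(basis.n_channels):
            vol = basis.values[:, c].reshape(n, n, n)
            lap = (
                np.roll(vol, 1, 0) + np.roll(vol, -1, 0)
                + np.roll(vol, 1, 1) + np.roll(vol, -1, 1)
                + np.roll(vol, 1, 2) + np.roll(vol, -1, 2)
                - 6.0 * vol
            ) / h**2
            interior = lap[1:-1, 1:-1, 1:-1]
            assert interior.size >= 1000
            rms = np.sqrt((vol**2).mean())
            assert np.abs(interior).max() < 1e-6 * rms

    def test_gram_matrix_nearly_diagonal_on_spherical_mask(self):
        n, h = 24, 5.0
        fm = FieldMap(np.zeros((n, n, n)), spacing=(h, h, h),
                      origin=(-(n - 1) * h / 2,) * 3)
        centers = fm.voxel_centers()
        r = np.linalg.norm(centers, axis=-1)
        mask = BrainMask(r <= (n / 2 - 1) * h, spacing=fm.spacing,
                         origin=fm.origin)
        basis = sh_basis(SHBasisSpec(max_degree=3), fm, mask)
        g = basis.values.T @ basis.values / basis.values.shape[0]
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 0.01 * np.diag(g).max()

    def test_degenerate_mask_rejected(self):
        fm = FieldMap(np.zeros((1, 1, 1)))
        mask = BrainMask(np.ones((1, 1, 1), bool))
        with pytest.raises(ValueError):
            sh_basis(SHBasisSpec(max_degree=2), fm, mask)


class TestCoilBasis:
    def _small_volume(self):
        n, h = 8, 6.0
        fm = FieldMap(np.zeros((n, n, n)), spacing=(h, h, h),
                      origin=(-(n - 1) * h / 2,) * 3)
        mask = BrainMask(np.ones((n, n, n), bool), spacing=fm.spacing,
                         origin=fm.origin)
        return fm, mask

    def test_unic_basis_has_51_columns(self):
        fm, mask = self._small_volume()
        basis = assemble_coil_basis(layout_unic51(), fm, mask, n_segments=32)
        assert basis.n_channels == 51
        assert basis.values.shape[0] == mask.n_true

    def test_superposition_equals_matrix_vector_product(self):
        fm, mask = self._small_volume()
        loops = [
            LoopSpec((0.0, 0.0, 80.0), (0, 0, 1), 40.0),
            LoopSpec((90.0, 0.0, 0.0), (1, 0, 0), 30.0, turns=2),
        ]
        from b0shim.coil_layouts import CoilLayout

        basis = assemble_coil_basis(CoilLayout("two", loops), fm, mask, 64)
        currents = np.array([1.7, -2.2])
        pts = fm.voxel_centers()[mask.data]
        direct = sum(
            c * loop_bz_numeric(lp, pts, 64) for c, lp in zip(currents, loops)
        )
        assert np.allclose(basis.values @ currents, direct, rtol=1e-12)

    def test_far_field_scales_with_dipole_moment(self):
        # doubling the radius quadruples the dipole moment, hence the far field
        pts = np.array([[0.0, 0.0, 500.0], [300.0, 0.0, 400.0]])
        small = LoopSpec((0, 0, 0), (0, 0, 1), 20.0)
        big = LoopSpec((0, 0, 0), (0, 0, 1), 40.0)
        f_small = loop_bz_numeric(small, pts, 128)
        f_big = loop_bz_numeric(big, pts, 128)
        assert np.allclose(f_big, 4.0 * f_small, rtol=0.05)

    def test_loop_intersecting_mask_rejected(self):
        fm, mask = self._small_volume()
        from b0shim.coil_layouts import CoilLayout

        inside = CoilLayout("bad", [LoopSpec((0, 0, 0), (0, 0, 1), 40.0)])
        with pytest.raises(ValueError):
            assemble_coil_basis(inside, fm, mask, 32)
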