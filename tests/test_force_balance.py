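import numpy as np
import pytest
from scipy.special import iv

from actomotion import (BoundaryCurve, DimensionlessParameters, build_mesh,
                        solve_force_balance, unit_circle)


def rect_curve(w=1.0, hgt=6.0, n=1024, x0=0.0037, y0=0.0021):
    """Counterclockwise rectangle [x0, x0+w] x [y0-hgt/2, y0+hgt/2].

    The small offsets keep the walls off the background grid lines (the
    solver does not rely on grid alignment and the aligned case is
    geometrically degenerate)."""
    per = 2 * (w + hgt)
    s = np.linspace(0, per, n, endpoint=False)
    pts = []
    for q in s:
        if q < w:
            pts.append((q, -hgt / 2))
        elif q < w + hgt:
            pts.append((w, -hgt / 2 + (q - w)))
        elif q < 2 * w + hgt:
            pts.append((w - (q - w - hgt), hgt / 2))
        else:
            pts.append((0.0, hgt / 2 - (q - 2 * w - hgt)))
    return BoundaryCurve(np.array(pts) + [x0, y0], target_spacing=per / n)


class TestZVSlabOracle:
    """1D slab: m linear in x, ZV walls -> alpha u'' - u = -beta c with
    u(0) = u(1) = 0, whose closed form uses hyperbolic cosines.  The 2D
    solver on a tall thin rectangle must match the mid-height profile."""

    alpha, beta, slope = 0.04, 2.0, 0.8
    X0, Y0 = 0.0037, 0.0021

    def exact(self, x):
        # alpha u'' - u = -beta c, u = 0 at both walls: particular solution
        # +beta c corrected by boundary layers of width sqrt(alpha)
        s = np.sqrt(self.alpha)
        return self.beta * self.slope * (
            1.0 - np.cosh((x - self.X0 - 0.5) / s) / np.cosh(0.5 / s))

    def solve(self, h):
        p = DimensionlessParameters(variant="ZV", alpha=self.alpha,
                                    beta=self.beta)
        curve = rect_curve(x0=self.X0, y0=self.Y0)
        mesh = build_mesh(curve, h)
        m = 1.0 + self.slope * mesh.group_pt[:, 0]
        u = solve_force_balance(mesh, m, p)
        mid = np.abs(mesh.group_pt[:, 1] - self.Y0) < 0.5
        return mesh.group_pt[mid, 0], u[mid, 0], u[mid, 1]

    def test_matches_closed_form(self):
        x, ux, uy = self.solve(0.05)
        scale = np.abs(self.exact(x)).max()
        # top/bottom walls are ~2.5 units away: their influence decays as
        # exp(-dist/sqrt(alpha)) ~ 4e-6
        assert np.abs(uy).max() < 1e-3 * scale
        err = np.abs(ux - self.exact(x)).max()
        assert err < 0.01 * scale

    def test_refinement_strongly_reduces_error(self):
        # max-norm error drops by ~3x per mesh halving (between first and
        # second order; the cut-cell Dirichlet flux is the limiting piece)
        errs = []
        for h in (0.1, 0.05):
            x, ux, _ = self.solve(h)
            errs.append(np.abs(ux - self.exact(x)).max())
        assert errs[0] / errs[1] > 2.5


class TestZSRadialOracle:
    """ZS disk with uniform myosin: the radial velocity solves the modified
    Bessel equation, u_r = A I1(r/sqrt(alpha)) with alpha u_r'(R) = -beta m,
    giving centripetal (inward) flow strongest at the rim."""

    @staticmethod
    def exact_radial(r, alpha, beta, m, R=1.0):
        s = np.sqrt(alpha)
        dI1 = 0.5 * (iv(0, R / s) + iv(2, R / s))  # I1'(z)
        A = -beta * m * s / (alpha * dI1)
        return A * iv(1, r / s)

    def test_matches_bessel_solution(self):
        p = DimensionlessParameters(variant="ZS", alpha=0.5, beta=5.0)
        mesh = build_mesh(unit_circle(512), 0.08)
        m_val = 1.3
        u = solve_force_balance(mesh, np.full(mesh.n_groups, m_val), p)
        r = np.hypot(*mesh.group_pt.T)
        er = mesh.group_pt / np.maximum(r, 1e-12)[:, None]
        u_r = np.sum(u * er, axis=1)
        u_t = u[:, 0] * (-er[:, 1]) + u[:, 1] * er[:, 0]
        exact = self.exact_radial(r, 0.5, 5.0, m_val)
        sel = r > 0.1
        assert np.abs(u_t[sel]).max() < 0.05 * np.abs(exact).max()
        err = np.abs(u_r[sel] - exact[sel]).max()
        assert err < 0.05 * np.abs(exact).max()
        # inward at the rim
        assert u_r[r > 0.8].max() < 0.0

    def test_rim_flow_is_inward_on_coarse_mesh(self, circle_mesh):
        p = DimensionlessParameters(variant="ZS", alpha=0.5, beta=5.0)
        u = solve_force_balance(circle_mesh, np.ones(circle_mesh.n_groups), p)
        r = np.hypot(*circle_mesh.group_pt.T)
        u_r = np.sum(u * circle_mesh.group_pt /
                     np.maximum(r, 1e-12)[:, None], axis=1)
        assert u_r[r > 0.8].max() < 0.0


class TestStructuralProperties:
    def test_uniform_myosin_zv_gives_zero_flow(self, circle_mesh):
        p = DimensionlessParameters(variant="ZV")
        u = solve_force_balance(circle_mesh, np.ones(circle_mesh.n_groups), p)
        assert np.abs(u).max() < 1e-12

    def test_linearity_in_myosin(self, circle_mesh, rng):
        p = DimensionlessParameters(variant="ZS")
        m1 = rng.uniform(0, 2, circle_mesh.n_groups)
        m2 = rng.uniform(0, 2, circle_mesh.n_groups)
        u12 = solve_force_balance(circle_mesh, m1 + m2, p)
        u1 = solve_force_balance(circle_mesh, m1, p)
        u2 = solve_force_balance(circle_mesh, m2, p)
        assert np.allclose(u12, u1 + u2, atol=1e-10)

    @pytest.mark.parametrize("variant", ["ZV", "ZS"])
    def test_beta_rescaling_leaves_flow_unchanged(self, circle_mesh, rng,
                                                  variant):
        # (beta, m) -> (beta/c, c m) is an exact invariance of the force
        # balance (contractility only enters through beta*m)
        m = rng.uniform(0.1, 2.0, circle_mesh.n_groups)
        c = 3.7
        p1 = DimensionlessParameters(variant=variant, beta=5.0)
        p2 = DimensionlessParameters(variant=variant, beta=5.0 / c)
        u1 = solve_force_balance(circle_mesh, m, p1)
        u2 = solve_force_balance(circle_mesh, c * m, p2)
        assert np.allclose(u1, u2, atol=1e-12)

    def test_rotational_equivariance_quarter_turn(self, rng):
        # 256 markers are invariant under a quarter turn, so rotating the
        # myosin field by 90 degrees must rotate the flow field exactly
        curve = unit_circle(256)
        mesh = build_mesh(curve, 0.16)
        p = DimensionlessParameters(variant="ZS")
        pts = mesh.group_pt
        m = 1.0 + 0.5 * np.cos(np.arctan2(pts[:, 1], pts[:, 0])) * np.hypot(*pts.T)
        u = solve_force_balance(mesh, m, p)
        # rotate the field: value at x equals old value at R^-1 x
        rot_pts = np.column_stack([pts[:, 1], -pts[:, 0]])  # R^-1 x
        # map rotated collocation points onto groups
        from scipy.spatial import cKDTree
        tree = cKDTree(pts)
        d, idx = tree.query(rot_pts)
        assert d.max() < 1e-9   # the mesh is quarter-turn symmetric
        m_rot = m[idx]
        u_rot = solve_force_balance(mesh, m_rot, p)
        # expected: u_rot(x) = R u(R^-1 x)
        expected = np.column_stack([-u[idx, 1], u[idx, 0]])
        assert np.allclose(u_rot, expected, atol=1e-9)
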