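"""FES reconstruction and PMF projection against closed forms."""

import math

import numpy as np
import pytest

from funnelbind import (HillsRecord, KB, GridSpec, project_pmf,
                        reconstruct_fes, reconstruct_fes_window,
                        set_reference_level)
from funnelbind.fes import CEILING_KT, Pmf, pmf_basin_delta_f

KT = KB * 298.0


def hills_at(centers, heights, gamma=20.0, widths=(0.04, 0.043)):
    n = len(centers)
    return HillsRecord(times=np.arange(1.0, n + 1), centers=centers,
                       widths=[widths] * n, heights=heights, gamma=gamma)


class TestReconstruct:
    def test_single_hill_depth_scaled_by_gamma_factor(self, single_hill):
        # well-tempered inversion: depth = W * gamma/(gamma-1) below far field
        fes = reconstruct_fes(single_hill, cutoff=None)
        i = np.argmin(np.abs(fes.axis1 - 0.5))
        j = np.argmin(np.abs(fes.axis2 - 0.0))
        depth = fes.values[i, j]
        # min is at the hill centre (0 after shift); far field ~ W*20/19
        far = fes.values[fes.sampled].max()
        assert depth == pytest.approx(0.0, abs=1e-9)
        # grid node may be slightly off-centre; compare against the exact
        # Gaussian value at the nearest node
        z, c = fes.axis1[i], fes.axis2[j]
        g = math.exp(-0.5 * (((z - 0.5) / 0.04) ** 2 + (c / 0.043) ** 2))
        assert far - depth == pytest.approx(0.1195 * 20 / 19 * g, rel=1e-9)
        assert 0.1195 * 20 / 19 == pytest.approx(0.12579, abs=5e-6)

    def test_standard_metadynamics_multiplier_is_one(self, single_hill):
        fes_wt = reconstruct_fes(single_hill, cutoff=None)
        fes_std = reconstruct_fes(single_hill, cutoff=None,
                                  heights_prescaled=True)
        span_wt = fes_wt.values[fes_wt.sampled].max()
        span_std = fes_std.values[fes_std.sampled].max()
        assert span_wt == pytest.approx(span_std * 20 / 19, rel=1e-9)

    def test_linearity_two_half_hills_equal_one_full(self):
        full = hills_at([(0.5, 0.0)], [0.1195])
        halves = HillsRecord(times=[1.0, 2.0], centers=[(0.5, 0.0)] * 2,
                             widths=[(0.04, 0.043)] * 2,
                             heights=[0.05975] * 2, gamma=20.0)
        f1 = reconstruct_fes(full, cutoff=None)
        f2 = reconstruct_fes(halves, cutoff=None)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_empty_and_outside_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_fes(HillsRecord(times=[], centers=[], widths=[],
                                        heights=[]))
        bad = hills_at([(5.0, 0.0)], [0.1])
        with pytest.raises(ValueError, match="hill 0"):
            reconstruct_fes(bad)

    def test_unsampled_nodes_carry_ceiling(self, single_hill):
        fes = reconstruct_fes(single_hill)  # 6-sigma cutoff: most nodes empty
        assert not fes.sampled.all()
        ceiling = fes.values[fes.sampled].max() + CEILING_KT * KT
        assert np.all(fes.values[~fes.sampled] == pytest.approx(ceiling))

    def test_window_average_modes(self):
        hills = hills_at([(0.5, 0.0), (0.7, 0.1), (0.9, -0.1)],
                         [0.1, 0.09, 0.08])
        for mode in ("snapshot_mean", "mean_bias"):
            fes = reconstruct_fes_window(hills, t_start=1.0, t_end=3.0,
                                         n_snapshots=3, mode=mode)
            assert np.isfinite(fes.values).all()
            assert fes.values[fes.sampled].min() == pytest.approx(0.0)


class TestProjection:
    def grid_fes(self, values, sampled=None):
        from funnelbind.fes import FreeEnergySurface
        values = np.asarray(values, dtype=float)
        n1, n2 = values.shape
        if sampled is None:
            sampled = np.ones_like(values, dtype=bool)
        return FreeEnergySurface(axis1=np.linspace(0, 2, n1),
                                 axis2=np.linspace(-1, 1, n2),
                                 values=values, sampled=sampled,
                                 T=298.0, gamma=20.0, t_window=(0, 1))

    def test_flat_direction_reduces_to_profile(self):
        f1 = np.linspace(0.0, 3.0, 50)
        fes = self.grid_fes(np.tile(f1[:, None], (1, 20)))
        pmf = project_pmf(fes)
        # separable surface: w(z) = F1(z) + constant
        diff = pmf.w - f1
        np.testing.assert_allclose(diff, diff[0], atol=1e-9)

    def test_two_level_column_closed_form(self):
        # column A: half the c-nodes at 0, half at delta; column B: all 0.
        # The shift-free difference w_A - w_B equals
        # -kT ln(I_A / I_B) with I the trapezoid integral of exp(-beta F);
        # delta -> infinity recovers the lower level + measure ratio.
        beta = 1.0 / KT
        c = np.linspace(-1, 1, 40)
        for delta in (1.0, 50.0):
            vals = np.zeros((4, 40))
            vals[:2, 20:] = delta          # rows 0-1: two-level column
            pmf = project_pmf(self.grid_fes(vals))
            i_a = np.trapezoid(np.exp(-beta * vals[0]), c)
            i_b = np.trapezoid(np.exp(-beta * vals[3]), c)
            expected = -math.log(i_a / i_b) / beta
            assert pmf.w[0] - pmf.w[3] == pytest.approx(expected, rel=1e-9)
        # deep upper level: only the lower half of the measure survives
        assert pmf.w[0] - pmf.w[3] == pytest.approx(
            -math.log(19.5 / 39.0) / beta, abs=1e-6)

    def test_projection_commutes_with_constant_shift(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 3, size=(30, 15))
        p1 = project_pmf(self.grid_fes(vals))
        p2 = project_pmf(self.grid_fes(vals + 7.0))
        np.testing.assert_allclose(p1.w, p2.w, atol=1e-9)

    def test_unsampled_column_flagged(self):
        vals = np.zeros((10, 5))
        sampled = np.ones_like(vals, dtype=bool)
        sampled[3, :] = False
        pmf = project_pmf(self.grid_fes(vals, sampled))
        assert not pmf.sampled[3]
        assert pmf.w[3] > pmf.w[pmf.sampled].max()


class TestReference:
    def make(self, w):
        z = np.linspace(0, 2, 201)
        return Pmf(z=z, w=np.asarray(w, dtype=float),
                   sampled=np.ones(201, dtype=bool), T=298.0)

    def test_constant_pmf_goes_to_zero(self):
        pmf = set_reference_level(self.make(np.full(201, 7.0)))
        np.testing.assert_allclose(pmf.w, 0.0, atol=1e-12)
        assert pmf.referenced

    def test_idempotent(self):
        z = np.linspace(0, 2, 201)
        pmf = set_reference_level(self.make(np.sin(z)))
        again = set_reference_level(pmf)
        np.testing.assert_allclose(pmf.w, again.w, atol=1e-14)

    def test_linear_pmf_mean_subtracted(self):
        z = np.linspace(0, 2, 201)
        pmf = set_reference_level(self.make(3.0 * z))
        sel = (z >= 1.4) & (z <= 1.8)
        assert pmf.w[sel].mean() == pytest.approx(0.0, abs=1e-12)
        # linear: mean over the symmetric node range is the midpoint value
        assert pmf.w[np.argmin(np.abs(z - 1.6))] == pytest.approx(0, abs=1e-9)

    def test_unsampled_reference_range_rejected(self):
        z = np.linspace(0, 2, 201)
        sampled = z < 1.2
        pmf = Pmf(z=z, w=np.zeros(201), sampled=sampled, T=298.0)
        with pytest.raises(ValueError, match="reference range"):
            set_reference_level(pmf)


class TestGridRefinement:
    def test_projection_stable_under_grid_doubling(self):
        # smooth surface: w(z) from a 100-node and a 200-node c-grid agree
        def build(n2):
            from funnelbind.fes import FreeEnergySurface
            z = np.linspace(0, 2, 101)
            c = np.linspace(-1, 1, n2)
            vals = (np.sin(2 * z)[:, None] + 0.5 * np.cos(3 * c)[None, :]) + 2
            return FreeEnergySurface(axis1=z, axis2=c, values=vals,
                                     sampled=np.ones_like(vals, dtype=bool),
                                     T=298.0, gamma=20.0, t_window=(0, 1))
        w1 = project_pmf(build(100)).w
        w2 = project_pmf(build(200)).w
        assert np.max(np.abs(w1 - w2)) < 5e-4


def test_reflect_cv2_matches_brute_force_mirroring():
    # folding hill tails back across the CV2 ends must equal explicitly
    # summing the original plus both mirror-image Gaussians
    rng = np.random.default_rng(3)
    n = 30
    hills = HillsRecord(times=np.arange(1.0, n + 1),
                        centers=np.column_stack([np.full(n, 1.0),
                                                 rng.uniform(-1, 1, n)]),
                        widths=np.tile([0.1, 0.2], (n, 1)),
                        heights=np.full(n, 0.1), gamma=20.0)
    fes = reconstruct_fes(hills, reflect_cv2=True, cutoff=None)
    i = np.argmin(np.abs(fes.axis1 - 1.0))
    zi = fes.axis1[i]          # nearest grid node, not exactly 1.0
    c = fes.axis2
    gz = np.exp(-0.5 * ((zi - 1.0) / 0.1) ** 2)
    v = np.zeros_like(c)
    for cc in hills.centers[:, 1]:
        for m in (cc, -2.0 - cc, 2.0 - cc):
            v += 0.1 * gz * np.exp(-0.5 * ((c - m) / 0.2) ** 2)
    expected = (20 / 19) * (v.max() - v)  # per-column, up to the global shift
    got = fes.values[i, :]
    np.testing.assert_allclose(got - got.min(), expected, atol=1e-9)


def test_basin_delta_f_two_square_wells():
    # analytic check: two flat wells of different depth and equal width
    z = np.linspace(0, 2, 2001)
    w = np.zeros_like(z)
    w[(z >= 0.3) & (z <= 0.5)] = -4.0
    w[(z >= 1.3) & (z <= 1.5)] = -2.0
    pmf = Pmf(z=z, w=w, sampled=np.ones(z.size, dtype=bool), T=298.0)
    got = pmf_basin_delta_f(pmf, divider=1.0, lo=0.0, hi=2.0)
    beta = 1.0 / KT
    left = 0.2 * math.exp(4 * beta) + 0.8
    right = 0.2 * math.exp(2 * beta) + 0.8
    assert got == pytest.approx(-math.log(left / right) / beta, abs=2e-3)
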