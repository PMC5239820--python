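"""Toy-engine physics: determinism, equilibrium sampling, energy
conservation, and the mechanics of the solvent trap."""

import math

import numpy as np
import pytest
from scipy import stats

from funnelbind import (KB, SolventTrapModel, ToyBindingModel, WTParams,
                        simulate_solvent_trap, simulate_wtmetad,
                        unbiased_restraint_series)
from funnelbind.engine import count_bound_visits


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        model = ToyBindingModel()
        runs = [simulate_wtmetad(model, nsteps=20_000, dt=0.01, seed=11)
                for _ in range(2)]
        (t1, h1), (t2, h2) = runs
        np.testing.assert_array_equal(t1.cv1, t2.cv1)
        np.testing.assert_array_equal(h1.centers, h2.centers)
        np.testing.assert_array_equal(h1.heights, h2.heights)

    def test_different_seeds_differ(self):
        model = ToyBindingModel()
        t1, _ = simulate_wtmetad(model, nsteps=5_000, dt=0.01, seed=1)
        t2, _ = simulate_wtmetad(model, nsteps=5_000, dt=0.01, seed=2)
        assert not np.array_equal(t1.cv1, t2.cv1)

    def test_solvent_trap_deterministic(self):
        model = SolventTrapModel()
        a = simulate_solvent_trap(model, True, nsteps=10_000, dt=0.002,
                                  seed=5)
        b = simulate_solvent_trap(model, True, nsteps=10_000, dt=0.002,
                                  seed=5)
        np.testing.assert_array_equal(a.cv1, b.cv1)
        np.testing.assert_array_equal(a.S, b.S)


class TestDynamics:
    def test_zero_temperature_zero_bias_stays_at_minimum(self):
        model = ToyBindingModel(T=0.0)
        traj, _ = simulate_wtmetad(model, nsteps=5_000, dt=0.01, seed=0,
                                   metad=False)
        # the far well's tail shifts the fixed point by ~2e-6 nm
        np.testing.assert_allclose(traj.cv1, model.z1, atol=1e-4)

    def test_equilibrium_marginal_matches_boltzmann(self):
        # shallow single-well landscape: binned chi^2 against exp(-U/kT)
        model = ToyBindingModel(depth1=1.5, depth2=0.0)
        traj, _ = simulate_wtmetad(model, nsteps=400_000, dt=0.01, seed=3,
                                   metad=False, out_stride=0.1)
        z = traj.cv1[1000:]
        edges = np.linspace(0.2, 1.8, 17)
        obs, _ = np.histogram(z, edges)
        centers = 0.5 * (edges[1:] + edges[:-1])
        f = model.free_energy_profile(centers)
        p = np.exp(-(f - f.min()) / (KB * model.T))
        p /= p.sum()
        # frames 0.1 ps apart are correlated; thin to ~independent samples
        n_eff = z.size / 20
        chi2 = np.sum((obs / obs.sum() - p) ** 2 / p) * n_eff
        # 16 bins - 1 dof; generous upper quantile
        assert chi2 < stats.chi2.ppf(0.999, 15) * 2

    def test_energy_conservation_zero_friction_zero_noise(self):
        # BAOAB at T=0, friction=0 reduces to velocity Verlet: bounded drift
        model = ToyBindingModel(T=0.0, friction=0.0)
        m = model.mass
        import funnelbind.engine as eng
        # start displaced from the minimum so there is real oscillation
        kT_proxy = 0.5
        z, c = model.z1 + 0.08, 0.2
        vz = vc = 0.0
        dt = 0.002
        half = 0.5 * dt

        def grad(z, c, h=1e-6):
            dz = (model.potential(z + h, c) - model.potential(z - h, c)) / (2 * h)
            dc = (model.potential(z, c + h) - model.potential(z, c - h)) / (2 * h)
            return dz, dc

        def energy(z, c, vz, vc):
            return model.potential(z, c) + 0.5 * m * (vz**2 + vc**2)

        e0 = energy(z, c, vz, vc)
        energies = []
        gz, gc = grad(z, c)
        for _ in range(100_000):
            vz -= half * gz / m; vc -= half * gc / m
            z += dt * vz; c += dt * vc
            gz, gc = grad(z, c)
            vz -= half * gz / m; vc -= half * gc / m
            energies.append(energy(z, c, vz, vc))
        drift = max(abs(e - e0) for e in energies)
        assert drift < 0.05 * abs(e0 - model.potential(model.z1, 0.0)) + 0.02

    def test_divergence_aborts_with_diagnostic(self):
        model = ToyBindingModel(mass=1e-6)  # absurd mass -> unstable
        with pytest.warns(UserWarning, match="stability"):
            with pytest.raises(RuntimeError, match="diverged"):
                simulate_wtmetad(model, nsteps=20_000, dt=0.01, seed=0)


class TestSolventTrap:
    def test_no_solvent_means_no_restraint_energy(self):
        model = SolventTrapModel(M=0)
        traj = simulate_solvent_trap(model, True, nsteps=5_000, dt=0.002,
                                     seed=0)
        assert np.all(traj.S == 0.0)
        assert np.all(traj.V_S == 0.0)

    def test_restraint_confines_coordination_number(self):
        model = SolventTrapModel()
        traj = simulate_solvent_trap(model, True, nsteps=100_000, dt=0.002,
                                     seed=1)
        r = model.restraint
        onset_width = (KB * model.T / r.k_s) ** 0.25
        assert traj.S.mean() < r.S_0 + 2 * onset_width

    def test_restraint_promotes_binding(self):
        # the dry-state restraint must make bound-state visits more
        # frequent; paired one-sided test over seeds
        model = SolventTrapModel()
        params = WTParams(sigma1=0.1, sigma2=1.0, stride=0.5)
        von, voff = [], []
        for seed in range(5):
            for on, acc in ((True, von), (False, voff)):
                traj = simulate_solvent_trap(model, on, params=params,
                                             nsteps=250_000, dt=0.002,
                                             seed=seed)
                acc.append(count_bound_visits(traj))
        assert stats.wilcoxon(von, voff,
                              alternative="greater").pvalue < 0.05

    def test_hysteresis_signature_without_restraint(self):
        # without the restraint the site is wet (S >= ~1) whenever the
        # ligand is out: solvent occupancy anticorrelates with binding
        model = SolventTrapModel()
        params = WTParams(sigma1=0.1, sigma2=1.0, stride=0.5)
        traj = simulate_solvent_trap(model, False, params=params,
                                     nsteps=250_000, dt=0.002, seed=2)
        bound = traj.cv1 < 1.25
        assert bound.any() and (~bound).any()
        assert traj.S[~bound].mean() > traj.S[bound].mean() + 0.3
        r = np.corrcoef(bound, traj.S)[0, 1]
        assert r < -0.1

    def test_unbiased_series_reports_dry_fraction(self):
        model = SolventTrapModel()
        series, dry = unbiased_restraint_series(model, nsteps=60_000,
                                                dt=0.002, seed=0)
        assert 0.0 <= dry <= 1.0
        assert np.all(series.V_S >= 0.0)
        s2, d2 = unbiased_restraint_series(model, nsteps=60_000, dt=0.002,
                                           seed=0)
        np.testing.assert_array_equal(series.V_S, s2.V_S)

    def test_dry_fraction_limits(self):
        # deep solvent well: site always wet; strong reservoir-only solvent
        # (repulsive site): always dry
        wet, _d = unbiased_restraint_series(
            SolventTrapModel(eps_W=12.0), nsteps=40_000, dt=0.002, seed=0)
        assert _d < 0.02
        _s, d_dry = unbiased_restraint_series(
            SolventTrapModel(eps_W=-6.0), nsteps=40_000, dt=0.002, seed=0)
        assert d_dry > 0.9
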