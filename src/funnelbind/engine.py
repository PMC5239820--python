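"""Langevin toy systems that exercise the full funnel-metadynamics pipeline.

Two model families are provided:

* :class:`ToyBindingModel` — the two collective variables are the literal
  dynamical coordinates: z (nm) plays the role of the projection on the
  binding axis and c in [-1, 1] the orientational cosine.  Well-tempered
  hills are deposited in (z, c) exactly as in a real funnel-metadynamics
  run, and the funnel restraint reduces to its axial walls (a flat-bottom
  confinement on z), which preserves the S* = pi R_cyl^2 standard-state
  bookkeeping as a pure accounting convention.  Every preset has an
  analytic background potential whose free-energy profile is computable by
  quadrature, giving an exact target for parameter-recovery tests.

* :class:`SolventTrapModel` — a 1-D single-file channel holding a ligand
  particle and M "solvent" particles that cannot pass each other.  Solvent
  prefers the binding site whenever the ligand is out, which reproduces the
  trapped-solvent hysteresis mechanism: the ligand cannot re-enter until a
  rare solvent fluctuation vacates the site.  A wall on the solvent
  coordination number S of a virtual site (the dry-state restraint) removes
  the trap.

Dynamics use the BAOAB splitting of Langevin dynamics, which samples
configurations accurately at the large timesteps a toy model permits.
Randomness comes from a counter-based Philox generator keyed by the seed,
so equal seeds give bit-identical trajectories.

Units: kcal/mol, nm, ps; masses in kcal mol^-1 ps^2 nm^-2 (m = 1 gives a
thermal velocity of ~0.77 nm/ps at 298 K).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bias import (KB, CoordinationRestraint, FunnelGeometry, HillsRecord,
                   WTParams, wt_hill_height)

__all__ = [
    "ToyBindingModel",
    "SolventTrapModel",
    "Trajectory",
    "simulate_wtmetad",
    "simulate_solvent_trap",
    "unbiased_restraint_series",
]

_NOISE_BLOCK = 1 << 16


@dataclass
class Trajectory:
    """Uniformly sampled collective-variable output of a toy run."""

    times: np.ndarray
    cv1: np.ndarray
    cv2: np.ndarray | None = None   # orientational CV (binding model)
    S: np.ndarray | None = None     # coordination number (solvent model)
    V_S: np.ndarray | None = None   # restraint energy series, kcal/mol
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("cv1", "cv2", "S", "V_S"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.times):
                raise ValueError(f"{name} length differs from times")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("trajectory times must be uniform")


# ---------------------------------------------------------------------------
# 2-D binding toy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyBindingModel:
    """Analytic background landscape U(z, c) plus Langevin parameters.

    Presets
    -------
    ``double_well``
        Two Gaussian wells of equal width on z, separable from a soft
        quartic confinement in c that keeps the orientational coordinate
        away from its interval ends (where unreflected hills fill the bias
        only slowly); being separable, the confinement leaves the basin
        free-energy difference untouched.  The well depths are set so that
        difference is 2.0 kcal/mol at 298 K, and the exact value is always
        recomputed by quadrature at run time rather than assumed.
    ``binding``
        A single bound minimum of depth 6 kcal/mol at (z_b = 0.5 nm,
        c = -1), mimicking a guest that binds with its axis anti-aligned;
        the landscape is flat for z beyond ~1.2 nm.
    """

    preset: str = "double_well"
    depth1: float = 4.0      # kcal/mol, left well (bound-like)
    depth2: float = 1.677    # kcal/mol, right well (double_well only);
                             # chosen so the basin free-energy difference of
                             # the preset is 2.00 kcal/mol at 298 K
    z1: float = 0.5          # nm
    z2: float = 1.5          # nm
    width: float = 0.2       # nm, common well width; several hill widths,
                             # so the deposition kernel barely broadens it
    c_width: float = 0.35    # orientational well width (binding only)
    c_conf: float = 2.0      # quartic c-confinement scale, kcal/mol (double_well)
    c_conf_width: float = 0.7
    z_lo: float = 0.15       # lower containment wall onset, nm
    k_edge: float = 1.195e5  # containment wall constant, kcal/mol/nm^4
    mass: float = 1.0
    friction: float = 1.0    # 1/ps
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.preset not in ("double_well", "binding"):
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def double_well(cls, **kw) -> "ToyBindingModel":
        return cls(preset="double_well", **kw)

    @classmethod
    def binding(cls, **kw) -> "ToyBindingModel":
        kw.setdefault("depth1", 6.0)
        return cls(preset="binding", **kw)

    # -- analytic potential ------------------------------------------------

    def potential(self, z, c):
        z = np.asarray(z, dtype=float)
        c = np.asarray(c, dtype=float)
        well = -self.depth1 * np.exp(-0.5 * ((z - self.z1) / self.width) ** 2)
        if self.preset == "double_well":
            u = well - self.depth2 * np.exp(
                -0.5 * ((z - self.z2) / self.width) ** 2) \
                + self.c_conf * (c / self.c_conf_width) ** 4
        else:
            u = well * np.exp(-0.5 * ((c + 1.0) / self.c_width) ** 2)
        u = u + self.k_edge * np.maximum(self.z_lo - z, 0.0) ** 4
        return float(u) if np.ndim(u) == 0 else u

    def free_energy_profile(self, z_grid, n_c: int = 201):
        """F(z) = -kB T ln integral dc exp(-beta U(z, c)) by quadrature."""
        beta = 1.0 / (KB * self.T)
        c = np.linspace(-1.0, 1.0, n_c)
        u = self.potential(np.asarray(z_grid)[:, None], c[None, :])
        umin = u.min(axis=1, keepdims=True)
        integ = np.trapezoid(np.exp(-beta * (u - umin)), c, axis=1)
        return umin[:, 0] - np.log(integ) / beta

    def basin_delta_f(self, divider: float = 1.0, lo: float = 0.1,
                      hi: float = 1.9, n: int = 4001) -> float:
        """Quadrature truth for the basin free-energy difference.

        -kB T ln of the ratio of Boltzmann weights of [lo, divider] and
        [divider, hi]; negative when the left (bound-like) basin is lower.
        """
        beta = 1.0 / (KB * self.T)
        z = np.linspace(lo, hi, n)
        f = self.free_energy_profile(z)
        w = np.exp(-beta * (f - f.min()))
        left = np.trapezoid(np.where(z <= divider, w, 0.0), z)
        right = np.trapezoid(np.where(z > divider, w, 0.0), z)
        return float(-math.log(left / right) / beta)

    def max_curvature(self) -> float:
        """Upper bound on |U''| used in the documented stability criterion
        dt^2 max|U''| / mass < 0.1."""
        return max(self.depth1, self.depth2) / self.width**2


class _BiasGrid:
    """Deposited bias and its gradient on a uniform 2-D grid.

    Forces are read back by bilinear interpolation; each hill updates only
    the nodes within ``cutoff`` sigma (truncation below exp(-12.5) of the
    hill height at the default 5).
    """

    def __init__(self, z_min, z_max, dz, c_min, c_max, dc, cutoff=5.0):
        self.z0, self.dz = z_min, dz
        self.c0, self.dc = c_min, dc
        self.zn = np.arange(z_min, z_max + 0.5 * dz, dz)
        self.cn = np.arange(c_min, c_max + 0.5 * dc, dc)
        self.nz, self.nc = self.zn.size, self.cn.size
        self.V = np.zeros((self.nz, self.nc))
        self.dVdz = np.zeros_like(self.V)
        self.dVdc = np.zeros_like(self.V)
        self.cutoff = cutoff

    def deposit(self, zc, cc, s1, s2, h):
        i0 = max(0, int((zc - self.cutoff * s1 - self.z0) / self.dz) + 1)
        i1 = min(self.nz, int((zc + self.cutoff * s1 - self.z0) / self.dz) + 1)
        j0 = max(0, int((cc - self.cutoff * s2 - self.c0) / self.dc) + 1)
        j1 = min(self.nc, int((cc + self.cutoff * s2 - self.c0) / self.dc) + 1)
        dzv = self.zn[i0:i1] - zc
        dcv = self.cn[j0:j1] - cc
        g1 = np.exp(-0.5 * (dzv / s1) ** 2)
        g2 = np.exp(-0.5 * (dcv / s2) ** 2)
        patch = h * np.outer(g1, g2)
        self.V[i0:i1, j0:j1] += patch
        self.dVdz[i0:i1, j0:j1] += patch * (-dzv / s1**2)[:, None]
        self.dVdc[i0:i1, j0:j1] += patch * (-dcv / s2**2)[None, :]

    def interp(self, arr, z, c):
        x = (z - self.z0) / self.dz
        y = (c - self.c0) / self.dc
        try:
            i = int(x)
            j = int(y)
        except (OverflowError, ValueError):
            raise RuntimeError(
                f"trajectory diverged (non-finite coordinate z = {z!r}); "
                "reduce dt or check the model parameters") from None
        if i < 0: i = 0
        elif i > self.nz - 2: i = self.nz - 2
        if j < 0: j = 0
        elif j > self.nc - 2: j = self.nc - 2
        fx = x - i
        fy = y - j
        a = arr[i, j]; b = arr[i + 1, j]; cq = arr[i, j + 1]; d = arr[i + 1, j + 1]
        return (a * (1 - fx) * (1 - fy) + b * fx * (1 - fy)
                + cq * (1 - fx) * fy + d * fx * fy)


def _check_stability(dt: float, friction: float, curvature: float,
                     mass: float) -> None:
    if dt * friction >= 0.1 or dt * dt * curvature / mass >= 0.1:
        warnings.warn(
            f"timestep dt = {dt:g} ps violates the stability guideline "
            "(dt*friction < 0.1 and dt^2 max|U''|/m < 0.1)")


def simulate_wtmetad(model: ToyBindingModel,
                     geom: FunnelGeometry = FunnelGeometry(),
                     params: WTParams | None = None,
                     nsteps: int = 500_000, dt: float = 0.01,
                     seed: int = 0, out_stride: float = 0.2,
                     metad: bool = True):
    """Well-tempered metadynamics run on a 2-D binding toy.

    Hills are deposited every ``params.stride`` ps at the current (z, c)
    with the current grid bias setting the well-tempered height.  The axial
    walls of the funnel (quartic above ``geom.z_wall`` and below the model's
    ``z_lo``) confine z; c reflects at the interval ends +-1 while hills are
    not reflected there.  Returns ``(Trajectory, HillsRecord)``;
    ``metad=False`` runs plain Langevin dynamics with an empty hills record.

    The default toy hill widths are wider than the all-atom protocol's
    (0.1 nm and 0.2) because the toy landscape has no features below that
    scale; deposition height, stride and bias factor keep their standard
    values through ``params``.
    """
    if params is None:
        params = WTParams(sigma1=0.04, sigma2=0.2)
    _check_stability(dt, model.friction, model.max_curvature(), model.mass)

    m = model.mass
    kT = KB * model.T
    a = math.exp(-model.friction * dt)
    b = math.sqrt(kT / m * (1.0 - a * a))
    half = 0.5 * dt

    dw = model.preset == "double_well"
    A1, A2 = model.depth1, model.depth2
    z1w, z2w, w2 = model.z1, model.z2, model.width**2
    cw2 = model.c_width**2
    cc, ccw = model.c_conf, model.c_conf_width
    z_lo, k_edge = model.z_lo, model.k_edge
    z_wall, k_wall = geom.z_wall, geom.k_wall

    def force(z, c):
        # background
        e1 = math.exp(-0.5 * (z - z1w) ** 2 / w2)
        fz = -A1 * e1 * (z - z1w) / w2
        fc = 0.0
        if dw:
            e2 = math.exp(-0.5 * (z - z2w) ** 2 / w2)
            fz -= A2 * e2 * (z - z2w) / w2
            fc = -4.0 * cc * c ** 3 / ccw ** 4
        else:
            g = math.exp(-0.5 * (c + 1.0) ** 2 / cw2)
            fz = -A1 * e1 * g * (z - z1w) / w2
            fc = -A1 * e1 * g * (c + 1.0) / cw2
        # containment walls on z (flat-bottom axial funnel restraint)
        if z < z_lo:
            fz += 4.0 * k_edge * (z_lo - z) ** 3
        if z > z_wall:
            fz -= 4.0 * k_wall * (z - z_wall) ** 3
        return fz, fc

    grid = _BiasGrid(-0.2, 2.2, 0.01, -1.2, 1.2, 0.03) if metad else None
    stride_steps = max(1, round(params.stride / dt))
    out_every = max(1, round(out_stride / dt))

    rng = np.random.Generator(np.random.Philox(key=seed))
    noise = rng.standard_normal((_NOISE_BLOCK, 2))
    ni = 0

    z, c = model.z1, (0.0 if dw else -0.8)
    vz = vc = 0.0
    if model.T > 0:
        vz, vc = math.sqrt(kT / m) * noise[0]
        ni = 1

    fz, fc = force(z, c)
    h_times: list[float] = []
    h_centers: list[tuple[float, float]] = []
    h_heights: list[float] = []
    o_t: list[float] = []
    o_z: list[float] = []
    o_c: list[float] = []

    for step in range(1, nsteps + 1):
        if metad:
            fz_b = fz - grid.interp(grid.dVdz, z, c)
            fc_b = fc - grid.interp(grid.dVdc, z, c)
        else:
            fz_b, fc_b = fz, fc
        vz += half * fz_b / m
        vc += half * fc_b / m
        z += half * vz
        c += half * vc
        if ni >= _NOISE_BLOCK:
            noise = rng.standard_normal((_NOISE_BLOCK, 2))
            ni = 0
        vz = a * vz + b * noise[ni, 0]
        vc = a * vc + b * noise[ni, 1]
        ni += 1
        z += half * vz
        c += half * vc
        # reflecting walls for the bounded orientational variable
        if c > 1.0:
            c = 2.0 - c
            vc = -vc
        elif c < -1.0:
            c = -2.0 - c
            vc = -vc
        fz, fc = force(z, c)
        if metad:
            vz += half * (fz - grid.interp(grid.dVdz, z, c)) / m
            vc += half * (fc - grid.interp(grid.dVdc, z, c)) / m
        else:
            vz += half * fz / m
            vc += half * fc / m

        if metad and step % stride_steps == 0:
            V_here = grid.interp(grid.V, z, c)
            h = wt_hill_height(max(V_here, 0.0), params)
            grid.deposit(z, c, params.sigma1, params.sigma2, h)
            h_times.append(step * dt)
            h_centers.append((z, c))
            h_heights.append(h)
        if step % out_every == 0:
            o_t.append(step * dt)
            o_z.append(z)
            o_c.append(c)
        if step % 1000 == 0 and not (math.isfinite(z) and abs(z) < 10.0):
            raise RuntimeError(
                f"trajectory diverged at step {step} (z = {z!r}); "
                "reduce dt or check the model parameters")

    traj = Trajectory(times=np.array(o_t), cv1=np.array(o_z),
                      cv2=np.array(o_c), seed=seed)
    n = len(h_times)
    hills = HillsRecord(
        times=np.array(h_times),
        centers=np.array(h_centers).reshape(n, 2),
        widths=np.tile([params.sigma1, params.sigma2], (n, 1)),
        heights=np.array(h_heights),
        gamma=params.gamma)
    return traj, hills


# ---------------------------------------------------------------------------
# 1-D solvent-trap toy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolventTrapModel:
    """Single-file channel with a ligand and M trapped-solvent particles.

    The binding site sits in the middle of the channel: the ligand
    approaches from the right (large z) and a solvent reservoir extends to
    the left of the site, standing in for the bulk into which displaced
    water escapes.  The site well at ``z_site`` attracts both the ligand
    (depth ``eps_L``) and the solvent (depth ``eps_W``); the
    inverse-12th-power pair repulsion prevents particle crossing, so a
    solvent particle sitting in the site must be squeezed out into the
    reservoir before the ligand can bind — the trapped-solvent hysteresis
    mechanism.  A ligand-only wall at ``lig_min`` keeps the ligand out of
    the reservoir.  ``restraint`` is the dry-state wall on the coordination
    number of the virtual site at ``z_site``; the toy default is much
    softer than the all-atom wall (k_s = 50 vs 2.39e5 kcal/mol, smoother
    exponents) so that it is integrable at the toy timestep while still
    keeping the site dry.
    """

    M: int = 2
    L_chan: float = 3.0
    z_site: float = 1.0
    lig_min: float = 0.85    # ligand-only wall keeping it out of the reservoir
    site_width: float = 0.2
    eps_L: float = 5.0
    eps_W: float = 3.0
    rep_A: float = 2.0       # pair repulsion scale, kcal/mol at separation d
    rep_d: float = 0.35      # nm
    restraint: CoordinationRestraint = field(
        default_factory=lambda: CoordinationRestraint(
            k_s=50.0, S_0=0.2, n=6, m=12, r_0=0.35))
    mass: float = 1.0
    friction: float = 1.0
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("M must be non-negative")


class _TrapForces:
    """Scalar force field of the solvent-trap channel."""

    def __init__(self, model: SolventTrapModel, with_ligand: bool):
        self.mod = model
        self.with_ligand = with_ligand
        self.rc = 2.0 * model.rep_d
        self.u_shift = model.rep_A * (model.rep_d / self.rc) ** 12

    def site_force(self, z: float, depth: float) -> float:
        m = self.mod
        d = z - m.z_site
        return -depth * math.exp(-0.5 * d * d / m.site_width**2) \
            * d / m.site_width**2

    def wall_force(self, z: float, lo: float = 0.05) -> float:
        m = self.mod
        f = 0.0
        if z < lo:
            f += 4.0 * 1.195e5 * (lo - z) ** 3
        if z > m.L_chan - 0.05:
            f -= 4.0 * 1.195e5 * (z - m.L_chan + 0.05) ** 3
        return f

    def pair_force(self, dz: float) -> float:
        """Force on the first particle of the pair separated by dz."""
        ad = abs(dz)
        if ad >= self.rc or ad == 0.0:
            return 0.0
        m = self.mod
        mag = 12.0 * m.rep_A * (m.rep_d / ad) ** 12 / ad
        return mag if dz > 0 else -mag

    def coordination(self, zs: list[float]) -> tuple[float, list[float]]:
        """S and dS/dz_i for the solvent coordinates."""
        r = self.mod.restraint
        S = 0.0
        dS = []
        for zi in zs:
            d = abs(zi - self.mod.z_site)
            x = d / r.r_0
            if x < 1e-9:
                S += 1.0
                dterm = 0.0
            elif abs(x - 1.0) < 1e-9:
                S += r.n / r.m
                # analytic limit of the derivative at x = 1
                dterm = (r.n * (r.n - r.m)) / (2.0 * r.m) / r.r_0
            else:
                xn = x**r.n
                xm = x**r.m
                den = 1.0 - xm
                S += (1.0 - xn) / den
                dterm = (-r.n * xn / x * den + (1.0 - xn) * r.m * xm / x) \
                    / (den * den) / r.r_0
            dS.append(dterm if zi >= self.mod.z_site else -dterm)
        return S, dS


def _run_trap(model: SolventTrapModel, nsteps: int, dt: float, seed: int,
              out_stride: float, with_ligand: bool, restraint_on: bool,
              params: WTParams | None):
    """Common BAOAB loop of the solvent-trap runs."""
    ff = _TrapForces(model, with_ligand)
    restr = model.restraint
    m = model.mass
    kT = KB * model.T
    a = math.exp(-model.friction * dt)
    b = math.sqrt(kT / m * (1.0 - a * a)) if model.T > 0 else 0.0
    half = 0.5 * dt
    n_part = model.M + (1 if with_ligand else 0)
    if n_part == 0:
        raise ValueError("nothing to simulate: no ligand and M = 0")

    grid = None
    stride_steps = 0
    if params is not None and with_ligand:
        grid = _BiasGrid(-0.1, model.L_chan + 0.1, 0.02, -1.0, 1.0, 1.0)
        stride_steps = max(1, round(params.stride / dt))
    out_every = max(1, round(out_stride / dt))

    rng = np.random.Generator(np.random.Philox(key=seed))
    noise = rng.standard_normal((_NOISE_BLOCK, n_part))
    ni = 0

    # ligand starts unbound at the far end; solvent fills the site and the
    # reservoir to its left (single-file order is preserved by the
    # repulsion); with the dry-state restraint active the solvent must
    # start in the reservoir, outside the restraint zone, or the initial
    # wall energy would be enormous
    pos: list[float] = []
    if with_ligand:
        pos.append(model.L_chan - 0.5)
    z_first = (model.z_site - 1.3 * model.restraint.r_0 if restraint_on
               else model.z_site)
    sol0 = [z_first - 0.35 * k for k in range(model.M)]
    if sol0 and sol0[-1] < 0.12:
        # reservoir too small to stack downward: pack upward from the wall
        sol0 = [0.12 + 0.35 * k for k in range(model.M)]
    pos += sol0
    vel = [0.0] * n_part
    if model.T > 0:
        vel = [math.sqrt(kT / m) * noise[0, k] for k in range(n_part)]
        ni = 1

    def forces(p: list[float]) -> tuple[list[float], float, float]:
        f = [0.0] * n_part
        sol = p[1:] if with_ligand else p
        if with_ligand:
            f[0] = ff.site_force(p[0], model.eps_L) \
                + ff.wall_force(p[0], model.lig_min)
        for k, zk in enumerate(sol):
            idx = k + (1 if with_ligand else 0)
            f[idx] = ff.site_force(zk, model.eps_W) + ff.wall_force(zk)
        for i in range(n_part):
            for j in range(i + 1, n_part):
                fp = ff.pair_force(p[i] - p[j])
                f[i] += fp
                f[j] -= fp
        S, dS = ff.coordination(sol)
        excess = S - restr.S_0
        VS = restr.k_s * excess**4 if excess > 0 else 0.0
        if restraint_on and excess > 0:
            dVdS = 4.0 * restr.k_s * excess**3
            for k in range(model.M):
                idx = k + (1 if with_ligand else 0)
                f[idx] -= dVdS * dS[k]
        return f, S, VS

    f, S, VS = forces(pos)
    h_times: list[float] = []
    h_centers: list[float] = []
    h_heights: list[float] = []
    o_t: list[float] = []
    o_z: list[float] = []
    o_S: list[float] = []
    o_V: list[float] = []

    for step in range(1, nsteps + 1):
        for k in range(n_part):
            fb = f[k]
            if grid is not None and k == 0:
                fb -= grid.interp(grid.dVdz, pos[0], 0.0)
            vel[k] += half * fb / m
            pos[k] += half * vel[k]
        if ni >= _NOISE_BLOCK:
            noise = rng.standard_normal((_NOISE_BLOCK, n_part))
            ni = 0
        for k in range(n_part):
            vel[k] = a * vel[k] + b * noise[ni, k]
            pos[k] += half * vel[k]
        ni += 1
        f, S, VS = forces(pos)
        for k in range(n_part):
            fb = f[k]
            if grid is not None and k == 0:
                fb -= grid.interp(grid.dVdz, pos[0], 0.0)
            vel[k] += half * fb / m

        if grid is not None and step % stride_steps == 0:
            h = wt_hill_height(max(grid.interp(grid.V, pos[0], 0.0), 0.0),
                               params)
            grid.deposit(pos[0], 0.0, params.sigma1, 1.0, h)
            h_times.append(step * dt)
            h_centers.append(pos[0])
            h_heights.append(h)
        if step % out_every == 0:
            o_t.append(step * dt)
            o_z.append(pos[0] if with_ligand else math.nan)
            o_S.append(S)
            o_V.append(VS)
        if step % 1000 == 0 and not all(math.isfinite(p) and abs(p) < 20.0
                                        for p in pos):
            raise RuntimeError(
                f"solvent-trap trajectory diverged at step {step}; "
                "reduce dt or soften the restraint")

    traj = Trajectory(times=np.array(o_t),
                      cv1=np.array(o_z), S=np.array(o_S),
                      V_S=np.array(o_V), seed=seed)
    hills = None
    if grid is not None:
        n = len(h_times)
        hills = HillsRecord(
            times=np.array(h_times),
            centers=np.column_stack([np.array(h_centers), np.zeros(n)]),
            widths=np.tile([params.sigma1, 1.0], (n, 1)),
            heights=np.array(h_heights), gamma=params.gamma)
    return traj, hills


def simulate_solvent_trap(model: SolventTrapModel, restraint_on: bool,
                          params: WTParams | None = None,
                          nsteps: int = 300_000, dt: float = 0.002,
                          seed: int = 0, out_stride: float = 0.1):
    """Metadynamics run of the solvent-trap channel, ligand included.

    Hills (1-D, on the ligand coordinate) are deposited when ``params`` is
    given; ``restraint_on`` switches the dry-state wall on the solvent
    coordination number.  Returns a :class:`Trajectory` carrying the ligand
    coordinate, S, and V(S) series.
    """
    if params is None:
        params = WTParams(sigma1=0.1, sigma2=1.0)
    _check_stability(dt, model.friction,
                     max(model.eps_L, model.eps_W) / model.site_width**2,
                     model.mass)
    traj, _ = _run_trap(model, nsteps, dt, seed, out_stride,
                        with_ligand=True, restraint_on=restraint_on,
                        params=params)
    return traj


def unbiased_restraint_series(model: SolventTrapModel, nsteps: int = 300_000,
                              dt: float = 0.002, seed: int = 0,
                              out_stride: float = 0.1):
    """Unrestrained, unbiased run of the solvent-only channel.

    Emulates the unbiased host-only simulation over which the one-step FEP
    average < exp(-V(S)/kB T) >_0 is taken: no ligand, no bias, no
    restraint force, but V(S) evaluated along the way.  Returns
    ``(RestraintSeries, dry_fraction)`` where the dry fraction is the
    fraction of frames with V(S) = 0 (S below the wall onset).
    """
    from .binding import RestraintSeries

    traj, _ = _run_trap(model, nsteps, dt, seed, out_stride,
                        with_ligand=False, restraint_on=False, params=None)
    series = RestraintSeries(times=traj.times, V_S=traj.V_S,
                             dt_out=out_stride)
    dry = float(np.mean(traj.V_S == 0.0))
    return series, dry


def count_bound_visits(traj: Trajectory, z_bound: float = 1.25,
                       z_unbound: float = 1.8) -> int:
    """Number of distinct entries into the bound region.

    An entry is counted when the ligand coordinate crosses below
    ``z_bound`` after last having been above ``z_unbound`` (two-threshold
    hysteresis avoids double counting boundary jitter).
    """
    visits = 0
    armed = traj.cv1[0] > z_unbound
    for z in traj.cv1:
        if armed and z < z_bound:
            visits += 1
            armed = False
        elif not armed and z > z_unbound:
            armed = True
    return visits
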