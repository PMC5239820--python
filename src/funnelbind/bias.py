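"""Biasing and restraint potentials for funnel metadynamics.

The binding axis of the host is the z axis.  The guest is confined by a
funnel-shaped flat-bottom restraint (a cone that narrows into a cylinder of
radius ``R_cyl`` above the switch point ``z_cc``), a steep quartic wall on z
that keeps the unbound guest from drifting away, and optionally a quartic
wall on a generalized water coordination number S that keeps solvent out of
the binding cavity (the "dry state").  The history-dependent metadynamics
bias is a sum of 2-D Gaussians deposited in (CV 1, CV 2) space with
well-tempered height decay.

Units throughout: energies kcal/mol, lengths nm, times ps, temperatures K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KB",
    "FunnelGeometry",
    "CoordinationRestraint",
    "WTParams",
    "HillsRecord",
    "funnel_radius",
    "funnel_energy",
    "wall_energy",
    "coordination_number",
    "coordination_restraint_energy",
    "wt_hill_height",
    "bias_energy",
]

#: Boltzmann constant in kcal mol^-1 K^-1.
KB = 0.0019872041


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunnelGeometry:
    """Geometry of the funnel restraint and the axial repulsive wall.

    Parameters
    ----------
    z_cc : float
        Axial position (nm) where the cone joins the cylinder.
    R_cyl : float
        Radius (nm) of the cylindrical section; sets the effective
        cross-section S* = pi R_cyl**2 used in the standard-state correction.
    alpha : float
        Cone half-angle in degrees.
    kappa : float
        Funnel force constant, kcal mol^-1 nm^-2.
    z_wall : float
        Onset (nm) of the quartic axial wall.
    k_wall : float
        Axial wall force constant, kcal mol^-1 nm^-4.
    """

    z_cc: float = 1.0
    R_cyl: float = 0.2
    alpha: float = 45.0
    kappa: float = 478.0
    z_wall: float = 1.85
    k_wall: float = 1.195e5

    def __post_init__(self) -> None:
        if not self.z_cc > 0:
            raise ValueError("z_cc must be positive")
        if not self.R_cyl > 0:
            raise ValueError("R_cyl must be positive")
        if not 0 < self.alpha < 90:
            raise ValueError("alpha must be in (0, 90) degrees")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if not self.k_wall > 0:
            raise ValueError("k_wall must be positive")
        if not self.z_wall > self.z_cc:
            raise ValueError("z_wall must lie above z_cc")

    @property
    def tan_alpha(self) -> float:
        return math.tan(math.radians(self.alpha))

    @property
    def s_star(self) -> float:
        """Effective cross-sectional area pi R_cyl**2 (nm^2)."""
        return math.pi * self.R_cyl**2


@dataclass(frozen=True)
class CoordinationRestraint:
    """Quartic wall on a generalized water coordination number S.

    S counts solvent molecules near a virtual atom in the cavity through the
    rational switching function (1 - x**n) / (1 - x**m) with x = r / r_0;
    the wall k_s (S - S_0)**4 activates for S >= S_0 and makes the unbound
    state "dry".
    """

    k_s: float = 2.39e5
    S_0: float = 0.02
    n: int = 16
    m: int = 32
    r_0: float = 0.35

    def __post_init__(self) -> None:
        if not (self.m > self.n > 0):
            raise ValueError("switching exponents must satisfy m > n > 0")
        if not self.r_0 > 0:
            raise ValueError("r_0 must be positive")
        if not self.k_s > 0:
            raise ValueError("k_s must be positive")
        if self.S_0 < 0:
            raise ValueError("S_0 must be non-negative")


@dataclass(frozen=True)
class WTParams:
    """Well-tempered deposition parameters.

    gamma is the bias factor; deposited heights decay as
    W = W0 exp(-V / (kB * (gamma - 1) * T)).  ``gamma = inf`` recovers
    standard (untempered) metadynamics.
    """

    W0: float = 0.1195
    sigma1: float = 0.04
    sigma2: float = 0.043
    stride: float = 1.0
    gamma: float = 20.0
    T: float = 298.0

    def __post_init__(self) -> None:
        if not self.gamma > 1:
            raise ValueError("bias factor gamma must exceed 1")
        if not self.W0 > 0:
            raise ValueError("W0 must be positive")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("Gaussian widths must be positive")
        if not self.stride > 0:
            raise ValueError("stride must be positive")
        if not self.T > 0:
            raise ValueError("T must be positive")

    @property
    def delta_T(self) -> float:
        return (self.gamma - 1.0) * self.T


@dataclass
class HillsRecord:
    """History of deposited Gaussian hills in the 2-D CV space."""

    times: np.ndarray          # (n,) deposition times, ps
    centers: np.ndarray        # (n, 2) hill centres (CV1, CV2)
    widths: np.ndarray         # (n, 2) Gaussian sigmas
    heights: np.ndarray        # (n,) deposited heights, kcal/mol
    gamma: float = 20.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.widths = np.asarray(self.widths, dtype=float).reshape(-1, 2)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.times)
        if not (len(self.centers) == len(self.widths) == len(self.heights) == n):
            raise ValueError("hills arrays must have equal lengths")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError("deposition times must be strictly increasing")
        if n and np.any(self.heights <= 0):
            raise ValueError("hill heights must be positive")
        if n and np.any(self.widths <= 0):
            raise ValueError("hill widths must be positive")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# restraint potentials
# ---------------------------------------------------------------------------

def funnel_radius(z, geom: FunnelGeometry = FunnelGeometry()):
    """Radius R_f(z) of the funnel: a cone below z_cc, a cylinder above.

    R_f(z) = R_cyl + (z_cc - z) tan(alpha) for z < z_cc, else R_cyl.
    Continuous at the switch point and accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    r = geom.R_cyl + np.where(z < geom.z_cc, (geom.z_cc - z) * geom.tan_alpha, 0.0)
    return float(r) if r.ndim == 0 else r


def funnel_energy(r, z, geom: FunnelGeometry = FunnelGeometry()):
    """Flat-bottom funnel potential: kappa (r - R_f(z))**2 outside the funnel.

    Zero everywhere inside (r <= R_f(z)); continuous and once-differentiable
    at the boundary.
    """
    rf = funnel_radius(z, geom)
    excess = np.maximum(np.asarray(r, dtype=float) - rf, 0.0)
    e = geom.kappa * excess**2
    return float(e) if np.ndim(e) == 0 else e


def wall_energy(z, geom: FunnelGeometry = FunnelGeometry()):
    """Quartic axial wall k_wall (z - z_wall)**4 acting above z_wall."""
    excess = np.maximum(np.asarray(z, dtype=float) - geom.z_wall, 0.0)
    e = geom.k_wall * excess**4
    return float(e) if np.ndim(e) == 0 else e


def _switch(x: np.ndarray, n: int, m: int) -> np.ndarray:
    """Rational switching term (1 - x**n)/(1 - x**m) with the removable
    singularity at x = 1 evaluated exactly as n/m."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    sing = np.isclose(x, 1.0, rtol=0.0, atol=1e-12)
    xs = np.where(sing, 0.0, x)  # placeholder, overwritten below
    with np.errstate(over="ignore", invalid="ignore"):
        num = 1.0 - xs**n
        den = 1.0 - xs**m
        ratio = num / den
    # for very large x, x**m overflows to inf; the term tends to 0
    ratio = np.where(np.isfinite(ratio), ratio, 0.0)
    out[...] = np.where(sing, n / m, ratio)
    return out


def coordination_number(distances, restr: CoordinationRestraint = CoordinationRestraint()) -> float:
    """Generalized coordination number S of solvent around the virtual atom.

    S = sum_i (1 - (r_iv/r_0)**n) / (1 - (r_iv/r_0)**m); each term lies in
    [0, 1], tends to 1 as r -> 0 and to 0 as r -> inf, and equals n/m at the
    removable singularity r = r_0.  Empty input gives S = 0.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        return 0.0
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return float(np.sum(_switch(d / restr.r_0, restr.n, restr.m)))


def coordination_restraint_energy(S, restr: CoordinationRestraint = CoordinationRestraint()):
    """Dry-state wall V(S) = k_s (S - S_0)**4 for S >= S_0, else 0."""
    excess = np.maximum(np.asarray(S, dtype=float) - restr.S_0, 0.0)
    e = restr.k_s * excess**4
    return float(e) if np.ndim(e) == 0 else e


# ---------------------------------------------------------------------------
# well-tempered bookkeeping
# ---------------------------------------------------------------------------

def wt_hill_height(V_current: float, params: WTParams) -> float:
    """Well-tempered hill height W0 exp(-V / (kB (gamma-1) T)).

    ``gamma = inf`` gives the standard-metadynamics constant height W0.
    """
    if V_current < 0:
        raise ValueError("bias energy must be non-negative")
    if math.isinf(params.gamma):
        return params.W0
    return params.W0 * math.exp(-V_current / (KB * params.delta_T))


def bias_energy(point, hills: HillsRecord, t: float, cutoff: float | None = 6.0) -> float:
    """Metadynamics bias at ``point`` from all hills deposited at times <= t.

    Parameters
    ----------
    point : (float, float)
        Position in (CV 1, CV 2) space.
    cutoff : float or None
        Per-dimension truncation radius in units of the hill width.  The
        default 6 sigma truncates each Gaussian where its value is below
        exp(-18) of its height; ``None`` disables truncation (exact sum).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if len(hills) == 0:
        return 0.0
    sel = hills.times <= t
    if not np.any(sel):
        return 0.0
    c = hills.centers[sel]
    w = hills.widths[sel]
    h = hills.heights[sel]
    d1 = (point[0] - c[:, 0]) / w[:, 0]
    d2 = (point[1] - c[:, 1]) / w[:, 1]
    if cutoff is not None:
        keep = (np.abs(d1) <= cutoff) & (np.abs(d2) <= cutoff)
        d1, d2, h = d1[keep], d2[keep], h[keep]
    return float(np.sum(h * np.exp(-0.5 * (d1**2 + d2**2))))
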