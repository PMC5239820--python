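"""Standard-state binding free energy from the PMF, and the dry-state
free-energy perturbation correction.

The binding free energy at 1 M standard concentration follows from the
referenced PMF w(z) through

    exp(-beta dG_meta) = C0 S* exp(beta dG_a_site)
                         * integral_site dz exp(-beta w(z)),

with C0 = 1/1.66 nm^-3, S* = pi R_cyl^2 the cross-section of the funnel
cylinder, dG_a_site = 0 for a funnel that leaves the bound guest
unrestrained, and the site taken as z < 0.9 nm.

The cost of the water restraint that defines the dry unbound state is paid
back by one-step exponential averaging over the unrestrained ensemble,

    dG_restr = -kB T ln < exp(-V(S) / kB T) >_0 ,

with the V(S) series first thinned to independent samples using its
statistical inefficiency and the uncertainty taken as the standard
deviation over bootstrap resamples of the thinned set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bias import KB
from .convergence import statistical_inefficiency
from .fes import Pmf

__all__ = [
    "BindingConfig",
    "RestraintSeries",
    "BindingResult",
    "delta_g_meta",
    "site_sensitivity",
    "delta_g_restr",
    "combine",
]


@dataclass(frozen=True)
class BindingConfig:
    """Conventions entering the standard-state formula."""

    C0: float = 1.0 / 1.66          # standard concentration, nm^-3
    S_star: float = math.pi * 0.2**2  # funnel cross-section, nm^2
    site_max: float = 0.9           # site boundary on z, nm
    ref_range: tuple[float, float] = (1.4, 1.8)
    dG_a_site: float = 0.0          # axial-restraint free energy of the bound guest
    T: float = 298.0

    def __post_init__(self) -> None:
        if not self.S_star > 0:
            raise ValueError("S_star must be positive")
        if not self.site_max < self.ref_range[0]:
            raise ValueError("site must end below the reference range")


@dataclass
class RestraintSeries:
    """Uniformly sampled time series of the water-restraint energy V(S)."""

    times: np.ndarray
    V_S: np.ndarray
    dt_out: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.V_S = np.asarray(self.V_S, dtype=float)
        if len(self.times) != len(self.V_S):
            raise ValueError("times and V_S must have equal lengths")
        if np.any(self.V_S < 0):
            raise ValueError("restraint energies must be non-negative")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("times must be uniform")


@dataclass
class BindingResult:
    """Combined binding free energy, kcal/mol."""

    dG_meta: float
    dG_meta_err: float
    dG_bind: float
    dG_bind_err: float
    dG_restr: float | None = None
    dG_restr_err: float | None = None
    dG_emp: float | None = None


def delta_g_meta(pmf: Pmf, cfg: BindingConfig = BindingConfig()) -> float:
    """Standard-state binding free energy from a referenced PMF.

    Trapezoidal quadrature of the Boltzmann factor exp(-beta w) over the
    site z <= site_max on the PMF's own grid.
    """
    if not pmf.referenced:
        raise ValueError("PMF must be referenced first (set_reference_level)")
    beta = 1.0 / (KB * cfg.T)
    sel = pmf.z <= cfg.site_max
    if not np.any(sel):
        raise ValueError("no grid nodes inside the site")
    if not np.any(pmf.sampled[sel]):
        raise ValueError("site is entirely unsampled")
    integral = np.trapezoid(np.exp(-beta * pmf.w[sel]), pmf.z[sel])
    arg = cfg.C0 * cfg.S_star * math.exp(beta * cfg.dG_a_site) * integral
    return float(-math.log(arg) / beta)


def site_sensitivity(pmf: Pmf, cfg: BindingConfig = BindingConfig(),
                     bounds: tuple[float, float] = (0.8, 1.0),
                     n: int = 5) -> float:
    """Largest change in dG_meta when the site boundary varies over ``bounds``.

    The published protocol checks this is below 0.1 kcal/mol; callers can
    query the same number for any PMF.
    """
    from dataclasses import replace
    vals = [delta_g_meta(pmf, replace(cfg, site_max=b))
            for b in np.linspace(bounds[0], bounds[1], n)]
    return float(max(vals) - min(vals))


def delta_g_restr(series: RestraintSeries, T: float = 298.0,
                  n_boot: int = 100, seed: int | None = None,
                  return_g: bool = False):
    """One-step FEP estimate of the water-restraint free energy.

    The series is thinned by ceil(g) frames, where g is its statistical
    inefficiency, so the exponential average runs over effectively
    independent samples; the error is the standard deviation of the
    estimator over ``n_boot`` bootstrap resamples of the thinned set.

    Returns ``(estimate, bootstrap_std)``; with ``return_g=True`` also the
    statistical inefficiency g and the decimation interval g * dt_out in ps.
    """
    v = series.V_S
    if v.size == 0:
        raise ValueError("empty restraint series")
    if np.ptp(v) == 0:
        g = 1.0  # constant series: no correlation information, no thinning
    else:
        g = statistical_inefficiency(v)
    stride = max(1, math.ceil(g))
    ind = v[::stride]
    if ind.size < 10:
        raise ValueError(
            f"only {ind.size} independent samples after thinning by {stride}; "
            "run a longer series")
    beta = 1.0 / (KB * T)

    def estimator(x: np.ndarray) -> float:
        # shift by the minimum for overflow safety; exact for the estimator
        vmin = x.min()
        return vmin - math.log(np.mean(np.exp(-beta * (x - vmin)))) / beta

    est = estimator(ind)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = estimator(rng.choice(ind, size=ind.size, replace=True))
    err = float(boot.std(ddof=1))
    if return_g:
        return est, err, g, g * series.dt_out
    return est, err


def combine(dG_meta: float, dG_restr: float | None = None,
            dG_emp: float | None = None, dG_meta_err: float = 0.0,
            dG_restr_err: float = 0.0) -> BindingResult:
    """Total binding free energy: dG_meta + dG_restr, or the empirical
    variant dG_meta + dG_emp (exactly one correction must be given).

    Errors combine in quadrature; in practice dG_meta dominates and its own
    error is reported alongside.
    """
    if (dG_restr is None) == (dG_emp is None):
        raise ValueError("supply exactly one of dG_restr or dG_emp")
    corr = dG_restr if dG_restr is not None else dG_emp
    err = math.hypot(dG_meta_err, dG_restr_err if dG_restr is not None else 0.0)
    return BindingResult(dG_meta=dG_meta, dG_meta_err=dG_meta_err,
                         dG_bind=dG_meta + corr, dG_bind_err=err,
                         dG_restr=dG_restr, dG_restr_err=(
                             dG_restr_err if dG_restr is not None else None),
                         dG_emp=dG_emp)
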