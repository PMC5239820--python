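# Methods

## Scope and design

funnelbind implements the analysis side of a well-tempered funnel
metadynamics binding-free-energy protocol — bias bookkeeping, free-energy
surface reconstruction, standard-state conversion, the dry-state FEP
correction, convergence statistics, and challenge-style error metrics —
together with two Langevin toy engines that generate every input the
pipeline consumes.  No interface to an MD engine is provided or intended:
the toy systems exist so that each stage can be checked against exact
quadrature or closed-form answers, which an all-atom system never offers.

Units everywhere: energies kcal/mol, lengths nm, times ps, temperatures K,
kB = 0.0019872041 kcal mol⁻¹ K⁻¹.  Masses carry the derived unit
kcal mol⁻¹ ps² nm⁻² (m = 1 gives a thermal velocity of ≈0.77 nm/ps at
298 K).

## Restraint potentials

The funnel is a flat-bottom restraint: zero inside the radius
R_f(z) = R_cyl + (z_cc − z)·tan α for z < z_cc (a straight cone) and
R_cyl above, with quadratic energy κ(r − R_f)² outside.  The cone/cylinder
join is sharp (continuous, with continuous first derivative in r).
Defaults: z_cc = 1.0 nm, R_cyl = 0.2 nm, α = 45°, κ = 478 kcal mol⁻¹ nm⁻².
A quartic wall k_wall (z − z_wall)⁴ with k_wall = 1.195×10⁵
kcal mol⁻¹ nm⁻⁴ caps the axial range; z_wall defaults to 1.85 nm and is
configurable because its appropriate value depends on the size of the
guest.

The water coordination number of the cavity virtual atom is
S = Σᵢ (1 − xᵢⁿ)/(1 − xᵢᵐ) with xᵢ = r_iv/r₀; the removable singularity
at x = 1 is evaluated exactly as n/m rather than left to floating-point
cancellation.  The dry-state wall is k_s (S − S₀)⁴ above S₀.  Analysis
defaults: k_s = 2.39×10⁵ kcal/mol, S₀ = 0.02, n = 16, m = 32,
r₀ = 0.35 nm.

Well-tempered deposition: height W = W0 exp(−V/(kB ΔT)) with
ΔT = (γ−1)T; defaults W0 = 0.1195 kcal/mol, γ = 20, widths 0.04 nm and
0.043, stride 1.0 ps.  γ = ∞ is accepted and reproduces standard
metadynamics (constant height, FES multiplier 1).  Bias evaluation and
reconstruction truncate each Gaussian at 6σ per dimension; the truncation
error is below W0·e⁻¹⁸ ≈ 1.8×10⁻⁹ kcal/mol per hill, and a no-cutoff mode
exists for oracle tests.

CV 2 (an orientational cosine) is treated as a bounded, non-periodic
variable on [−1, 1]; the toy dynamics reflect at the interval ends but
hills are *not* reflected there by default (reconstruction offers a
`reflect_cv2` option that folds hill tails back across the ends).  Bias
convergence immediately next to the ends is otherwise slow, which is why
the double-well preset confines the coordinate away from them (below).

## Toy engines

Dynamics use the BAOAB splitting of Langevin dynamics, chosen for its
configurational accuracy at large timesteps; the documented stability
guideline is dt·friction < 0.1 and dt²·max|U''|/m < 0.1 (a warning is
emitted when violated, divergence aborts with a diagnostic).  Randomness
comes from a counter-based Philox generator keyed by the user seed; equal
seeds give bit-identical trajectories, and every output header records the
seed.

**2-D binding toy.**  The two collective variables are the literal
dynamical coordinates.  The funnel restraint therefore reduces to its
axial walls (the radial coordinate does not exist), and S* = πR_cyl² in
the standard-state formula remains a pure accounting convention — it is
exercised analytically (scaling S* by λ must shift ΔG_meta by
kB T ln(1/λ) exactly) rather than dynamically.  Presets:

- `double_well`: Gaussian wells of common width 0.2 nm at z = 0.5 and
  1.5 nm with depths 4.0 and 1.677 kcal/mol, plus a separable quartic
  confinement 2.0·(c/0.7)⁴ on the orientational coordinate.  The depths
  were chosen once so that the basin free-energy difference (split at
  z = 1 nm) is 2.00 kcal/mol at 298 K; because the Boltzmann width of a
  Gaussian well is w/√(βA), this is *not* simply the depth difference, and
  the exact value is always recomputed by quadrature at run time.  The
  wells are several hill widths wide, so the deposition kernel barely
  broadens them.  The c-confinement is separable and cancels from the
  basin difference; it keeps sampling away from the c = ±1 ends where
  unreflected hills fill slowly.
- `binding` (via `ToyBindingModel.binding()`): a single minimum of depth
  6 kcal/mol at (z = 0.5 nm, c = −1), flat at large z — the topology of a
  host–guest complex whose guest binds with its axis anti-aligned.

Toy hill widths default to σ₁ = 0.04 nm (the all-atom protocol value) and
σ₂ = 0.2 (wider than the all-atom 0.043: the toy landscape has no
orientational features below that scale, and the narrow value would spend
most of the run filling a featureless direction).  The deposition stride
is the protocol's 1.0 ps.  A faster stride was considered and rejected
during the convergence design study: under well-tempered deposition the
bias-fluctuation relaxation time grows with the accumulated-bias level,
which itself grows with the hill-volume rate — so slower deposition keeps
more independent fluctuations inside a fixed averaging window and makes
the window-based error estimate better calibrated.

Metadynamics forces come from an internal bias grid (0.01 nm × 0.03
spacing) updated per hill and read back by bilinear interpolation; the
deposited-height rule reads the current bias from the same grid.  The
grid resolution is a quarter of the smallest hill width, making the
interpolation error a small fraction of a hill height.

**Solvent-trap toy.**  A 1-D single-file channel of length 3 nm with the
binding site (Gaussian well, width 0.2 nm) at z = 1.0 and a reservoir to
its left.  The ligand enters from the right past a ligand-only wall at
z = 0.85; M = 2 solvent particles feel the same site well (depth 3
kcal/mol vs the ligand's 5) and a truncated inverse-12th-power pair
repulsion (2.0 kcal/mol at 0.35 nm) that prevents any particle from
passing another.  A solvent particle in the site must therefore be
squeezed out into the reservoir before the ligand can bind — the
trapped-water mechanism in its minimal form.  The site sits mid-channel
because a site at a closed end would leave displaced solvent nowhere to
go: the restraint would then *block* binding instead of promoting it.

The toy dry-state restraint is softened relative to the analysis defaults
(k_s = 50 kcal/mol, S₀ = 0.2, exponents 6/12): near its onset the
published wall has curvature ≈10⁶ kcal mol⁻¹ nm⁻², far stiffer than any
toy-scale timestep can integrate.  The softened wall still keeps the site
dry (mean S ≈ 0.25 with the restraint on, ≈1.2 without).  The toy is not
tuned to reproduce the published dry-state statistics (2–10 % dry
fraction, a 5–10× visit ratio); it reproduces the qualitative separation —
the restrained runs visit the bound state significantly more often, and
without the restraint site occupancy anticorrelates with binding.

## Reconstruction and projection

Hills are stored as deposited (heights already reduced by the
well-tempered factor, the PLUMED-1.x file convention), so the FES is
−γ/(γ−1) times the summed bias; a flag accepts dialects whose heights are
pre-scaled to the free-energy convention.  The default analysis grid is
200 × 100 nodes over [0, 2] nm × [−1, 1].  Unsampled nodes — those
outside a 6σ footprint of every hill — carry an explicit ceiling (largest
sampled value + 5 kB T) and a False flag; the footprint is geometric, not
a value threshold, so the bookkeeping cannot depend on floating-point
underflow of far Gaussian tails.  Projection onto CV 1 is a trapezoid
Boltzmann average over the CV 2 nodes, stabilised by factoring out the
column minimum; fully-unsampled columns get the ceiling and a flag.
Window-averaged surfaces average min-shifted FES snapshots on a uniform
schedule (the mean-of-snapshots convention); the bias-first alternative is
exposed as `mode="mean_bias"`.

The PMF reference level is the unweighted node mean over 1.4 ≤ z ≤ 1.8 nm
(the unbound plateau); referencing is idempotent and required before the
standard-state integral.

## Standard-state conversion and FEP

ΔG_meta integrates exp(−βw) over z ≤ 0.9 nm by the trapezoid rule on the
PMF's own grid — the Boltzmann factor, not the PMF, is interpolated
linearly within bins.  For smooth PMFs the quadrature is
grid-converged far below the protocol's own 0.1 kcal/mol site-boundary
sensitivity (exposed as `site_sensitivity`, which scans the boundary over
[0.8, 1.0] nm).  A discontinuous test PMF (the square-well oracle) needs a
fine grid: a 5 kcal/mol step contributes an edge-bin error of order
dz·e^{βΔ}, so the bundled oracle uses 5×10⁻⁴ nm spacing where the error is
≈10⁻³ kcal/mol.

ΔG_restr thins the V(S) series by ceil(g) frames (g = statistical
inefficiency, first sample retained), applies the exponential average to
the thinned set (shifted by the minimum for overflow safety — exact, not
approximate), and reports the standard deviation over 100 bootstrap
resamples of the thinned set; fewer than 10 independent samples is an
error advising a longer series.  Both g and the decorrelation time
g·dt_out are reported, since correlated frames would bias the exponential
average's error estimate, not its expectation.

Combination is ΔG_meta + ΔG_restr (or the empirical-offset variant
ΔG_meta + ΔG_emp, with ΔG_emp = 5.86 kcal/mol as used for submissions
lacking a converged restraint term — exactly one correction may be
supplied).  Errors combine in quadrature; in practice the ΔG_meta term
dominates and is reported alongside.

## Convergence statistics

The ΔG_meta(t) (or basin-ΔF(t)) series re-runs the full
reconstruct → project → reference → integrate pipeline at each evaluation
time, with the bias grid accumulated incrementally so the cost is one pass
over the hills.  The final estimate is the mean over the last window W;
its error is max(standard deviation inside the window, |difference of the
last two W-block means|).  "Fluctuation" is read as the standard deviation
(not the SEM) — the conservative reading, since the series is strongly
autocorrelated inside a window.  The default evaluation stride is W/20.

The statistical inefficiency is g = 1 + 2 Σ (1 − t/N) ρ̂(t) with the
empirical autocorrelation summed to its first non-positive lag
(initial-positive-sequence truncation), floored at 1; a constant series
returns 1 with a warning.  For an AR(1) process with coefficient φ the
estimator converges to (1+φ)/(1−φ).

## Error metrics

AvErr, MAD, MADTr and R² (squared Pearson correlation) are computed in
full precision and compared with published tables at 2 decimals.  MADTr
over a combined group subtracts the combined AvErr, not per-host offsets.
Note that MADTr ≤ MAD is not an identity — the mean signed error is not
the L1-optimal translation — although it holds for prediction sets
dominated by a common offset; the guaranteed bound is
MADTr ≤ MAD + |AvErr|.  The equal-affinity dummy predictor reduces MADTr
to the mean absolute deviation of the experimental values from their
mean.  Metric uncertainties come from Monte-Carlo perturbation of the
predictions with their per-system Gaussian errors.  The packaged
octa-acid table carries the OAH-Gu2 reference complex for completeness;
it is excluded from every metric group, which cover the 12 challenge
systems.

Recomputing published metrics from a *printed* (2-decimal) prediction
table can move a metric by one unit in its last digit relative to a
computation from unrounded values; comparisons therefore use a
±0.015 kcal/mol band, the propagation bound of ±0.005 input rounding.

## Problem sizes of the bundled validation runs

The double-well recovery runs 16 ns of toy time (1.6×10⁶ steps at
dt = 0.01 ps) per seed and averages the basin-ΔF series over the final
4 ns window — long enough for several bias-turnover cycles per window,
which is what makes the two-part error estimate a valid per-run error
bound — with 20 seeds for the coverage statistics.  The recovered basin
difference carries a small residual (≈+0.02 kcal/mol, about one combined
standard error) from the finite deposition-kernel resolution.  The solvent-trap
comparisons run 0.5–0.6 ns (2.5–3×10⁵ steps at dt = 2 fs) per condition
and seed.  These sizes were chosen as the smallest at which the respective
estimators are converged on the toy landscapes.

## Known limitations

- The toy engines make no claim of physical realism: no solvent geometry,
  no pressure coupling, no force field.  Passing tests demonstrate the
  correctness of the analysis pipeline and the qualitative trapped-solvent
  mechanism, not the accuracy of any all-atom prediction.
- The flexible-ligand variant of the orientational CV is out of scope;
  only the rigid-axis reading is represented (as a literal coordinate).
- No reweighting estimators: the FES comes from direct bias inversion
  only, as in the protocol this package follows.
- The one-step FEP form assumes the dry state is visited in the
  unrestrained ensemble; systems where it never occurs would need staged
  intermediates, which are not implemented.
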