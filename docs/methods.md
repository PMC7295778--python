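# Methods

## The model

The package studies permeation through a constricted channel pore as
diffusion along a single reaction coordinate: the axial distance *z*
between the permeant species (a K⁺ ion, or the C8 carbon of the blocker
spermine) and a fixed reference group at the base of the selectivity
filter. The synthetic engine replaces the all-atom system with an analytic
free-energy surface

U(z, n) = U₀ + B·exp[−(z−z_c)²/(2w²)] + ½κ·(n − n̄(z))² − qE·u_conv·z

with a single Gaussian barrier of height *B* at the collar position *z_c*,
a continuous hydration-coordination coordinate *n* harmonically coupled
(stiffness κ) to a z-dependent mean n̄(z) that dips from a cavity value to
a collar value over a Gaussian width, and an optional uniform axial
electric field acting on charge *q*. Dynamics are overdamped Langevin
(Euler–Maruyama): x ← x − (D/k_BT)·∂U/∂x·dt + √(2D·dt)·ξ, for *z*, *n*
and the two lateral coordinates, the latter confined by a one-sided
harmonic wall (k_wall = 100 kJ/mol/Å²) beyond the flat-bottom radius — a
differentiable rendering of a flat-bottomed cylindrical restraint.

Assumptions: the coordinate is Markovian and overdamped (no inertial
memory), the coordination coordinate relaxes on the picosecond scale, and
the field enters strictly linearly in *z*. These are idealisations chosen
so that every downstream estimator has an exact, known target.

## Units and constants

Lengths in Å, energies in kJ/mol, time in ps, temperature in K.
k_B = 0.0083144621 kJ/mol/K; 1 e·V/nm = 96.485 kJ/mol/nm, so a field *E*
(V/nm) on charge *q* (e) tilts the landscape by 9.6485·qE kJ/mol/Å.
Harmonic force constants are stored per Å² internally; the conventional
3000 kJ/mol/nm² equals 30 kJ/mol/Å², converted once at the I/O boundary
(config keys and window manifests carry explicit unit suffixes, since
nm/Å mixing is the main foot-gun in this domain).

## Default study conditions

- Umbrella schedule: 101 fixed windows at 0.2 Å spacing spanning
  16.5–36.5 Å, bias constant 30 kJ/mol/Å², T = 303.15 K.
- Per window: dt = 0.01 ps, 2×10⁵ steps (2 ns), samples every 1 ps → 2000
  samples. With D_z = 0.2 Å²/ps the biased relaxation time k_BT/(kD_z) is
  ≈ 0.4 ps, so consecutive samples are effectively decorrelated and no
  burn-in is discarded (windows start at their bias centre; the
  initialisation transient is ~10³ times shorter than the window). These
  sizes are the package's reference desk scale, chosen so that a full
  recovery study runs in tens of seconds while leaving the barrier
  estimate's uncertainty well below the programmed barrier heights.
- Landscape defaults: barrier 6.0 kJ/mol (a 1.0 kJ/mol variant emulates
  the covalently crosslinked pore), centre 22.0 Å, width 1.5 Å.
- Coordination defaults: n̄ falls from 6.5 in the cavity to 3.0 at the
  collar over a 1.5 Å width; κ = 5 kJ/mol per unit² (thermal SD ≈ 0.7).
  The cavity value sits mid-low in the 6–7 range reported for K⁺ in
  solution. It is deliberately non-integer: the within-cutoff water count
  is drawn Poisson with mean equal to the frame's *n*, and a Poisson with
  an integer mean has an exact two-way tie for its mode, so an emulated
  cavity histogram with a robust modal count of six requires a mean
  strictly between 6 and 7. The collar histogram gains one
  hydroxyl-labelled oxygen per frame (transient tyrosine–OH coordination),
  putting the modal total there at 3–4.
- Blocker field study: the blocker dwells in a cytosolic vestibule
  (harmonic confinement at z = 30 Å, k = 0.2 kJ/mol/Å², thermal SD
  ≈ 3.5 Å) against a 15 kJ/mol collar barrier; fields of 0, 25 and
  50 mV/nm drive it inward, and occupancy is scored over 18.0–27.5 Å.
- Flux traces: F(t) = offset + amplitude·e^(−rate·t) + N(0, σ²) on a
  1-minute grid over [−3, 55] min, flat before the protonophore event at
  t = 0; the decay fit window is [0, 35] min (ionophore event at 35 min).

## WHAM implementation

Histogram counts and bias energies are evaluated at bin centres on a
uniform grid (default 100 bins spanning the union of window supports; the
bin width is an explicit choice, not a reconstruction of any particular
tool's default). Iteration runs in log space with running-max subtraction.
Because the self-consistent fixed point converges only linearly, the
solver first minimises the equivalent convex objective
Φ(f) = Σ_b H_b ln Σ_i N_i e^{f_i − w_ib} − Σ_i N_i f_i with L-BFGS
(analytic gradient), then certifies convergence by direct fixed-point
iteration until max_i|Δf_i| < tolerance (default 10⁻⁶) — the reported
iteration metric is always the fixed-point residual. The first window's
free energy is pinned to zero; profiles are referenced min-zero (a
plateau-mean policy is available).

Support checking: windows must form one connected component under
shared-occupied-bin overlap; a split support raises an error naming the
gap, while isolated empty interior bins simply come out at +∞ free
energy. Adjacent windows sharing no occupied bin trigger a warning.

Uncertainty: Bayesian bootstrap with Dirichlet(1,…,1) weights over
complete windows (200 replicates by default), respecting within-window
autocorrelation; per-sample Dirichlet reweighting is available behind a
flag. Each replicate is re-referenced before the per-bin standard
deviation is taken, so the arbitrary additive constant does not inflate
the SEM. Replicates warm-start from the full-data solution. No
integrated-autocorrelation-time correction is applied — the synthetic
sampling interval is chosen to decorrelate, and this is a known
limitation for strongly autocorrelated real data.

2D reweighting assigns each (z, n) sample the weight
1/Σ_j N_j exp[(f_j − w_j(z_b))/k_BT] of its z bin — the same
discretisation the 1D solve uses — so the n-marginal of the 2D PMF is
consistent with the 1D profile by construction (the residual, from
min-zero referencing at different bins, is ≪ 0.01 kJ/mol); samples
outside the z grid are dropped.

The barrier height estimator is max F over a barrier range (19–25 Å)
minus mean F over a cavity reference range (16.5–18.5 Å), with SEMs
combined in quadrature (treating bins as independent, which slightly
overstates the reference-mean term). Note the estimator carries a small
negative bias (~0.1 kJ/mol for the 6 kJ/mol landscape) because the
barrier's Gaussian tail overlaps the reference range.

## Geometry and superposition

Crossing events are sign changes of (z − z_collar) between consecutive
frames; the crossing time is linearly interpolated, and a frame landing
exactly on the plane counts as past it. Couplet symmetrization appends
the swapped pair (D2, D1) for every (D1, D2), making the two diagonal
marginals identical multisets. vdW spacing subtracts one van der Waals
radius per atom (oxygen, Bondi 1.52 Å — a parameter, since the radius
convention behind any published spacing is rarely stated). Superposition
is standard Kabsch (centroid removal, SVD, determinant-sign correction);
residues are paired by chain id and author residue number, insertion
codes are rejected, and the highest-occupancy altloc is kept when reading
PDB files (via gemmi).

## Blocker energetics

Fold ratios are exp(ΔΔG/k_BT) at 303.15 K (the simulation temperature;
at this temperature 10 and 15 kJ/mol round to 50- and 400-fold at one
significant figure). Periodic unwrapping adds the frame's instantaneous
box length to negative coordinates only; a value still negative
afterwards is a data-integrity error. The central-80% interval of an
occupancy density is delimited by the equal-tail 10th/90th sample
percentiles — an explicit convention, since "80% of structures" can be
delimited many ways. Site positions for PMF comparisons are
user-supplied, with defaults symmetric about the collar; both profiles
are re-referenced to the mean over the last 2 Å of shared support (the
bulk, cytosolic end) before differencing.

## Flux analytics

Normalization maps the fluorescence at the protonophore event to 100%
and the post-ionophore floor to 0%. The decay fit F(t) = A·e^{−kt} + C
uses multistart least squares (rate starts spanning 10⁻³–1 min⁻¹); the
offset C is fitted rather than pinned at zero because normalized traces
plateau near but not exactly at the floor before the fit window closes.
Non-convergence is flagged on the result, never raised; a non-positive
rate or vanishing amplitude is flagged "no-flux". Rates are reported in
both min⁻¹ and s⁻¹.

The Dunnett many-to-one test uses pooled-variance t statistics; adjusted
p-values are P(max_j |T_j| ≥ |t_i|) under the joint null, estimated from
≥2×10⁵ Monte-Carlo draws of the equicorrelated multivariate t implied by
the group sizes, with a fixed seed. In the single-comparison limit this
reduces to the two-sided Student t p-value. The family-wise calibration
study computes the Monte-Carlo critical value once and then scores 10⁴
simulated null datasets against it, which is equivalent to thresholding
each adjusted p-value at α but far cheaper.

## What the synthetic data does and does not show

The generator emulates: harmonically biased, decorrelated sampling over a
known landscape; a hydration number that dips at the constriction,
observed through Poisson-sampled oxygen placements with distance decoys
outside the cutoff; field-tilted blocker densities; and exponentially
decaying fluorescence with Gaussian noise. It does not emulate: slow or
correlated degrees of freedom orthogonal to the reaction coordinate,
non-Gaussian force-field noise, window-to-window initialisation
hysteresis, anharmonic bias artefacts, baseline drift or photobleaching
in fluorescence, or heteroscedastic assay noise. Passing recovery tests
therefore demonstrates the correctness of the estimators on data obeying
the model assumptions — not that real MD or assay data meet those
assumptions.

## Numerical choices and degenerate inputs

Euler–Maruyama with dt = 0.01 ps keeps the stability number
k·D·dt/k_BT ≈ 0.02 (variance bias ~1%); a step larger than five barrier
widths raises a stability error suggesting a smaller dt. Zero diffusion
is allowed and freezes the coordinate. The oxygen-count cutoff test is
boundary-inclusive (d ≤ 3.0 Å) — the boundary has measure zero in
continuous data, but the convention is documented and tested. Count
categories above 10 pool into an overflow category. Histogram rows for
unoccupied bins are flagged, not silently zero-filled. Coordination bins
with fewer than 10 frames are flagged low-occupancy.

## Known limitations

Deposited crystal structures are not bundled; the superposition machinery
is validated on synthetic tetramer stand-ins with ground truth known by
construction, and on any user-supplied PDB files. The WHAM solver handles
a single scalar reaction coordinate only (no 2D biasing, no MBAR). The
Brownian engine is a surrogate, not an approximation, of molecular
dynamics: its parameters are chosen for testability, and quantitative
agreement with any particular channel's free-energy surface is not
claimed.
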