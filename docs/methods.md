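# Methods

## Scope and intent

`cphmd` implements the algorithmic core of λ-dynamics constant-pH MD at
desk scale: every piece of machinery that manipulates the titration
coordinates — charge interpolation, the multisite simplex constraint,
buffer-charge neutrality, correction-potential calibration by
thermodynamic integration, biased λ-sampling, and titration-curve
analysis — is implemented and tested in full.  What is deliberately
absent is the production-MD environment around it: there is no force
field beyond point-charge Coulomb (plus optional harmonic tethers), no
water, no mesh Ewald (a direct O(N²) sum with optional minimum-image
periodicity and an ε_RF = ∞ reaction-field kernel stands in), no bonded
terms, no λ-dependent Lennard-Jones, and no barostat.  Those omissions
define what the tests can and cannot show: they validate the constant-pH
*machinery* exactly, not any force field's pKa predictions.

## Extended Hamiltonian

Each titratable group i has one coordinate λ_{i,k} per physical
protonation state k, each with fictitious mass m_λ = 5 amu, and the
constraint Σ_k λ_{i,k} = 1 restricts sampling to the hyperplane joining
the physical states.  State 0 is the shared fully protonated reference;
state k is reached at λ_{i,k} = 1.  A single titratable site is the
two-state special case, and its "titration coordinate" is the value of
the deprotonated-state λ.  Coordinates are never clamped: the
calibration grid runs from −0.1 to 1.1, and every potential term is
smooth on the whole real line.

Charges are linear in λ: q_j(λ) = Σ_k λ_{i,k} q_j^{(k)}, which under
the simplex constraint reduces to (1−λ) q_A + λ q_B for a single site.
Because the Coulomb energy is quadratic in the charges, one evaluation
yields the energy, the atomic forces, and the per-atom electrostatic
potential Φ_i = ∂E/∂q_i, from which every λ-gradient follows as
∂V/∂λ_k = Σ_{i∈group} Δq_i^{(k)} Φ_i with Δq^{(k)} = q^{(k)} − q^{(0)}.
This Δq-form is the directional derivative along the constraint
manifold; it differs from the raw partial by a vector along the
constraint normal, which the projection step removes, so the dynamics
is independent of the choice.  The evaluation-count bookkeeping
(1 per step versus 2 N_sites for the Hamiltonian-interpolation oracle)
is exposed on the result objects and tested.

The Hamiltonian-interpolation scheme is retained as an oracle only.
For chemically uncoupled sites the two schemes agree identically on
group–environment and inter-group interactions (both are products of
affine charge factors); they differ only in the intra-group term, which
is linear in λ under Hamiltonian interpolation but quadratic under
charge interpolation.  `scheme_discrepancy` returns exactly this
difference, zero at the end states by construction.

## λ-potentials

**pH term.**  V^pH(λ) = ΔG_pH σ(λ) with
ΔG_pH = ln(10) k_B T (pKa_ref − pH) and σ a double-logistic step
normalized so σ(0) = 0 and σ(1) = 1 exactly — the end-state contract
holds to machine precision for any steepness.  The kink positions
matter for the *estimator*, not the thermodynamics: frames are
classified at λ < 0.2 / λ > 0.8, and if the step still varies inside
those basins the basin-integrated weights no longer obey the end-state
ratio 10^(pH−pKa), which flattens and (for asymmetric pH grids) can
shift the fitted curve.  The defaults k1 = 100, x0 = 0.25 place the
kinks strictly inside the excluded mid-range; the quadrature oracle
then gives a basin ratio of 10 to 0.02% and a Henderson–Hasselbalch
midpoint exact to < 1e−4 pKa units.  The step also serves its second
purpose of penalizing intermediate λ whenever pKa_ref ≠ pH.

**Bias.**  V^bias(λ) = 16 b λ²(1−λ)², a symmetric double well with
minima of zero at both end states, maximum b at λ = 1/2 (default
b = 5 kJ/mol; 7.5 for coarse-grained-like setups), and quartic growth
outside [0, 1] that confines excursions.  In the multisite
representation every coordinate carries its own bias, so the effective
barrier along a two-state titration path is 2b.

**Correction potential.**  V^MM is a polynomial in the free simplex
coordinates (the deprotonated-state λs; arity n−1), fifth order for a
two-state site and eighth order for a three-state group.  It is fitted
by SVD-based least squares so that −dV^MM/dλ reproduces the mean
gradients of a TI scan; singular values below 1e−10 of the largest are
truncated, which absorbs linear dependencies among the monomial
coefficients (the three-state basis on the simplex-restricted grid is
rank-deficient).  The fit report carries the maximum and RMS residual;
the warning threshold uses the RMS ("fitting error") at 0.5 kJ/mol for
one free coordinate and 1 kJ/mol for two.

## Dynamics

Leapfrog integration with time step 2 fs (λ-only sampling tolerates
this comfortably: the stiffest curvature, from the pH step at extreme
ΔG, gives ω dt ≲ 0.09).  Constraints are linear in λ, so instead of
iterative SHAKE the solver applies the closed-form mass-weighted
least-squares (Lagrange) correction each step; the position projection
keeps Σλ = 1 and the total charge exact to machine precision, and the
velocity components along constraint gradients are removed as in
standard holonomic treatments.  With buffers, one global charge row
ties Σ_k Q_k λ_k plus N_buf Δq_buf λ_buf to its initial value, so
every titration-induced charge change is absorbed equally by all
buffers (−δ/N_buf each).  Requesting the charge constraint without
buffer capacity on a titrating system is a configuration error — it
would freeze titration.

Temperatures are maintained by stochastic velocity rescaling with
separate pools for atoms (τ = 0.5 ps) and λ-coordinates (τ = 2 ps),
both at 300 K by default; the pool's degree-of-freedom count excludes
the constraints.  Initial λ-velocities are Maxwell–Boltzmann draws
projected onto the constraint manifold; all randomness flows from one
integer seed through `numpy.random.Generator`, and repeated runs are
bit-identical.

Two execution paths share this scheme.  `run_md` integrates atoms and
λ together for a single system (used for NVE checks — measured drift
≈ 1e−4 kJ/mol/ps — and for calibration scans with mobile atoms).
`run_lambda_dynamics` propagates many independent walkers (one per
pH value and replica) on frozen atoms, where the Coulomb energy
reduces to an exact quadratic form in the λ DOF vector precomputed
once; its inner loop is a numba-compiled kernel (~3 µs per step for 65
walkers) with a pure-numpy fallback that is used automatically when a
correction polynomial is active or numba is unavailable.

## Calibration

`ti_scan` clamps the λs at each grid point (−0.1 … 1.1, step 0.05; for
a three-state group the two free coordinates are scanned and points
whose eliminated coordinate leaves the window are dropped), lets the
tethered atoms evolve under the thermostat, and averages the
constrained gradient after discarding the first 10% of each window,
with SEMs from samples spaced near the position-autocorrelation time.
With fully frozen atoms the gradient is deterministic and the SEM is
zero.  Atom positions and λs are restored on exit, and every grid
point starts from the fixture's canonical tethered geometry.

The self-consistency loop — scan, fit, install V^MM, re-scan with all
terms at pH = pKa, require interior mean gradients within 2 SEM of
zero — is run with the *same seed* for both scans.  Since V^MM, bias,
and pH terms exert no force on the atoms, the atomic trajectories are
then identical (common random numbers) and the residual isolates the
correction-potential error; with independent seeds the per-point
2-SEM band would be a ~z < 2 coin flip at every one of 19 interior
points even for a perfect correction.  Independent-seed agreement is
tested separately at 3 pooled SEM.

`ti_free_energy` integrates the mean gradients over [0, 1] by the
trapezoid rule (the grid is regular; higher-order rules gain little)
with error propagated from the per-point SEMs, and refuses grids with
gaps larger than twice the nominal spacing.

## Titration analysis

Single-site series: protonated below 0.2, deprotonated above 0.8,
mid-range excluded, S = N_d/(N_p + N_d).  Multisite series: a frame
belongs to state k when λ_k > 0.8 (at most one can, under the
constraint); the macroscopic fraction counts frames in either
deprotonated tautomer over all classified frames, and the microscopic
fraction of tautomer k conditions on frames in the protonated basin or
basin k.  Under this reading each microscopic curve is an exact
two-state Henderson–Hasselbalch titration with the microscopic pKa,
verified against the quadrature oracle.  Campaign fractions are pooled
counts over replicas; errors are SEMs across replicas; the pKa is the
sole free parameter of an unweighted nonlinear least-squares fit with a
95% CI from the t-distribution.

Two estimator properties of the threshold classification are worth
knowing.  First, the macroscopic curve of a three-state group is
slightly flattened, so the fitted macroscopic pKa sits ~0.05–0.1 units
below the analytic combination −log10(10^−pKa_δ + 10^−pKa_ε) of the
microscopic values; the microscopic fits are unaffected.  Second, when
the Coulomb term ramps linearly across the whole λ-line (a fixed
environment charge), the basin average of λ is displaced from the end
state by ~βaσ_λ² and the fitted midpoint shifts by a few hundredths of
a pKa unit relative to the pure end-state free-energy prediction.
Both effects are reproduced by the oracle and documented in the tests;
the ideal reference fixtures used for pKa recovery have zero Coulomb
slope and neither effect.

## Synthetic fixtures and the oracle

The fixtures emulate, at desk scale, the solvated reference compounds
used to calibrate a constant-pH engine: `ideal_site` (one titratable
charge, no environment — the exact correction is zero and the site must
titrate at its reference pKa), `shifted_site` (fixed or harmonically
tethered environment charges giving a closed-form λ-dependent Coulomb
term; tethers, k = 1000 kJ/mol/nm², stand in for the bonded scaffold
and give the gradient samples realistic thermal noise), `his_like`
(three states sharing one atom, charges +1/0/0, microscopic reference
pKas for the two tautomers), and `buffer_bath` (any of the above plus
10 buffers on a 2.5 nm sphere under the charge constraint).  They do
not emulate conformational gating, solvent friction, dielectric
heterogeneity, or charge-transfer coupling between sites — passing
tests certify the machinery, not real-system pKa accuracy.

The quadrature oracle integrates exp(−V_total/k_BT) — including the
bias, exactly the potential the sampler feels — over the constraint
manifold: a line for two states, a plane for three.  Each basin is
integrated in an affine chart in which its boundary is a coordinate
plane (all such charts are unimodular, so the integrals are
comparable), using composite Gauss–Legendre panels; a refinement pass
with more nodes per panel must agree to 1e−6 in every basin fraction.
The oracle shares only the potential evaluators with the dynamics path
and is the ground truth for every statistical assertion.

## Problem sizes and statistical targets

A titration campaign is 13 pH values × 5 replicas, each replica a
single-seeded λ-dynamics walk.  Basin transitions occur roughly every
50–100 ps at the default barrier, which sets the statistical floor:
measured across independent campaigns, the fitted-pKa spread is about
0.03 units at 6 ns/replica and 0.018 at 40 ns/replica.  The test suite
runs 40 ns/replica campaigns and the acceptance script 80 ns/replica,
placing the ±0.05 recovery checks at roughly three to four standard
errors.  TI-based checks use 25 grid points × 8 ps of tethered-atom
dynamics; the oracle-agreement check uses 10 walkers × 1.2 ns at each
of five pH values.

## Known limitations

* Electrostatics is an all-pairs direct sum; no neighbor lists, no
  Ewald reciprocal space, no exclusion rules.
* The exact functional forms of the bias and pH step in production
  constant-pH codes are not published in full; both are implemented to
  their stated contracts (double well with configurable barrier;
  smooth step with an exact end-state free-energy difference), and all
  guarantees tested here target those contracts, not bit-level
  agreement with any particular engine.
* Campaigns support one titratable group per system; multi-group
  systems are fully supported by the dynamics and electrostatics but
  their titration curves must be assembled by the caller.
* The potential-interpolation oracle covers two-state groups only, as
  the multisite case is exactly what the charge-interpolation scheme
  exists to simplify.
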