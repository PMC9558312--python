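# cphmd — desk-scale constant-pH λ-dynamics

`cphmd` is a small, fully tested implementation of the machinery behind
λ-dynamics-based constant-pH molecular dynamics (CpHMD): charge-interpolated
electrostatics for titratable sites, the multisite representation of
chemically coupled protonation states, buffer particles under a collective
charge constraint, thermodynamic-integration calibration of force-field
correction potentials, and titration-curve pKa estimation.

It is aimed at method developers and students who want to study, test, or
extend the *algorithms* of constant-pH MD without a force field or a
production MD engine.  Instead of solvated proteins it operates on small
synthetic point-charge systems whose exact behavior is known in closed form
or computable by brute-force Boltzmann quadrature, so every statistical
claim the sampler makes can be checked against an independent oracle.

## The model

Each titratable group *i* carries one λ-coordinate per physical protonation
state, with fictitious mass *m*<sub>λ</sub> (5 amu), evolving by Newtonian
dynamics alongside the atoms and constrained to the simplex
Σ<sub>k</sub> λ<sub>i,k</sub> = 1.  Partial charges are interpolated
linearly, q<sub>j</sub>(λ) = Σ<sub>k</sub> λ<sub>i,k</sub> q<sub>j</sub><sup>(k)</sup>
(for a single site, (1−λ) q<sub>A</sub> + λ q<sub>B</sub>), so a *single*
electrostatic evaluation yields both the atomic forces and, through the
per-atom potential Φ(**R**<sub>i</sub>, **λ**), every λ-gradient
∂V/∂λ<sub>k</sub> = Σ<sub>i</sub> Δq<sub>i</sub> Φ(**R**<sub>i</sub>, **λ**).
The older alternative — linear interpolation of the end-state Hamiltonians —
is implemented as a verification oracle; it needs 2 N<sub>sites</sub>
evaluations and differs from charge interpolation only in the intra-group
term (linear versus quadratic in λ).

Three analytic terms act on each λ-coordinate:

* **V<sup>MM</sup>** — a polynomial correction (5th order for a two-state
  site, 8th order for a three-state group) fitted to ⟨∂V/∂λ⟩ from a
  thermodynamic-integration scan over λ ∈ [−0.1, 1.1] in steps of 0.05, so
  that the reference compound's landscape is flat;
* **V<sup>bias</sup>** — a symmetric double well, barrier 5 kJ/mol,
  penalizing nonphysical intermediate λ;
* **V<sup>pH</sup>** — a smooth step whose end-state difference is exactly
  ΔG = ln(10) k<sub>B</sub>T (pK<sub>a</sub> − pH), the proton chemical
  potential.

Charge neutrality is maintained by buffer particles whose identical charges
interpolate between −0.5 e and +0.5 e through one collective λ coupled to
the titratable sites by an analytic (Lagrange) charge constraint.

Trajectory frames are classified as protonated (λ < 0.2) or deprotonated
(λ > 0.8); mid-range frames are discarded.  The deprotonated fractions
S(pH) = N<sup>deprot</sup>/(N<sup>prot</sup> + N<sup>deprot</sup>) over a pH
series are fitted to the Henderson–Hasselbalch curve

S(pH) = 1 / (1 + 10<sup>pKa − pH</sup>)

with the pKa as the sole parameter.  For three-state (histidine-like)
groups, macroscopic and per-tautomer microscopic fractions are computed and
fitted separately.

## Worked example

Titrate an ideal glutamate-like site (reference pKa 4.25) at seven pH
values, five replicas of 4 ns λ-dynamics each:

```yaml
# glu.yaml
mode: titrate
system:
  kind: ideal_site
  pKa_refs: [4.25]
pH_values: [2.0, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0]
n_replicas: 5
n_steps: 2000000
seed: 7
output_dir: out
```

```text
$ cphmd titrate glu.yaml
pKa = 4.200 +/- 0.058 (95% CI)
outputs in out
```

The fitted pKa (4.20 ± 0.06) recovers the configured reference within its
confidence interval; `out/titration.csv` holds the per-pH deprotonated
fractions with replica SEMs:

```text
pH,S_mean,S_sem,n_frames_used,n_frames_classified
2.0,0.00223,0.00080,18000,17469
3.0,0.05580,0.01449,18000,17098
3.5,0.16967,0.03039,18000,16892
...
```

At pH 3.0, about 5.6% of classified frames are deprotonated — close to the
ideal-site expectation 1/(1+10^(4.25−3.0)) ≈ 5.3%.  The same library calls
are available in Python (`cphmd.titration.titration_campaign`), and
`cphmd calibrate` / `cphmd analyze` / `cphmd validate` cover correction-
potential fitting, re-analysis of written λ-trajectories, and fast internal
consistency checks.

## Layout

```
src/cphmd/
  model.py              atoms, λ-groups, buffers, charge interpolation
  lambda_potentials.py  V^MM, V^bias, V^pH and derivatives
  electrostatics.py     Coulomb kernels, Φ, λ-gradients, scheme oracle
  dynamics.py           leapfrog, v-rescale, analytic constraint solver
  calibration.py        TI scans and correction-potential fits
  titration.py          fraction estimators, HH fits, campaigns
  fixtures.py           synthetic systems + Boltzmann quadrature oracle
  cli_io.py, cli.py     config schema, file formats, CLI
docs/methods.md         model, defaults, estimator properties, limits
```
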