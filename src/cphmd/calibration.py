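"""Thermodynamic-integration scans and correction-potential fitting.

The correction potential V^MM must cancel the force-field contribution
to the deprotonation free energy of the reference compound, so that at
pH = pKa the site titrates with equal end-state weights.  It is obtained
in two steps:

1. :func:`ti_scan` — hold the lambda coordinates fixed on a grid that
   extends beyond the physical range (-0.1 ... 1.1, step 0.05), run
   dynamics of the atoms at each grid point, and record the ensemble
   average of the constrained gradient dV/dlambda with its standard
   error.  Only the force-field (Coulomb) term is integrated; bias, pH
   and any previously installed correction are excluded by default.
2. :func:`fit_vmm` — least-squares fit of a polynomial V^MM whose
   negative gradient reproduces the mean gradients (fifth order for a
   two-state site, eighth order for a three-state group, with
   rank-deficient monomial bases reduced automatically).

For a multisite group the scan grid covers the (n-1)-dimensional free
simplex coordinates, dropping points whose eliminated coordinate falls
outside the extended range.

:func:`ti_free_energy` integrates the mean gradients over [0, 1] by the
trapezoid rule, propagating the per-point standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import CphmdError, ConfigurationError
from .lambda_potentials import VmmPolynomial, _monomial_exponents, vmm_eval
from .model import TitratableSystem
from .dynamics import (
    ConstraintSet,
    IntegratorSpec,
    MDState,
    RunPotentials,
    _analytic_lambda_gradient,
    _lambda_coulomb_gradient,
    build_constraints,
    md_step,
)
from . import electrostatics as es

__all__ = [
    "TiScanResult",
    "GridSpec",
    "ti_scan",
    "fit_vmm",
    "ti_free_energy",
    "make_simplex_grid",
]

#: fewest integration steps per grid point accepted in strict mode
MIN_STEPS_PER_POINT = 500


@dataclass
class GridSpec:
    """Lambda grid for a TI scan: start/stop/step in each free coordinate."""

    start: float = -0.1
    stop: float = 1.1
    step: float = 0.05


@dataclass
class TiScanResult:
    """Mean constrained lambda-gradients on a grid, with standard errors.

    ``grid`` has shape (n_points, arity) in the free simplex coordinates
    (the deprotonated-state lambdas); ``mean_gradients`` and ``stderr``
    have the same shape.
    """

    grid: np.ndarray
    mean_gradients: np.ndarray
    stderr: np.ndarray
    equilibration_fraction: float = 0.1
    n_samples: int = 0

    def __post_init__(self):
        self.grid = np.atleast_2d(np.asarray(self.grid, dtype=float))
        self.mean_gradients = np.atleast_2d(np.asarray(self.mean_gradients, dtype=float))
        self.stderr = np.atleast_2d(np.asarray(self.stderr, dtype=float))
        if self.grid.shape != self.mean_gradients.shape:
            raise ConfigurationError("grid / gradient shape mismatch")
        if not (self.grid.min() < 0.0 and self.grid.max() > 1.0):
            raise ConfigurationError(
                "TI grid must extend beyond the physical range on both sides"
            )

    @property
    def arity(self) -> int:
        return self.grid.shape[1]


def make_simplex_grid(arity: int, spec: GridSpec = GridSpec()) -> np.ndarray:
    """Free-coordinate grid; multisite points with the eliminated
    coordinate outside the extended range are dropped."""
    axis = np.arange(spec.start, spec.stop + spec.step / 2, spec.step)
    pts = np.array(list(product(axis, repeat=arity)))
    lam0 = 1.0 - pts.sum(axis=1)
    keep = (lam0 >= spec.start - 1e-9) & (lam0 <= spec.stop + 1e-9)
    return pts[keep]


def _constrained_gradient(system: TitratableSystem, pots: RunPotentials) -> np.ndarray:
    """dV/dx_k along the free simplex coordinates at the current state.

    The constrained derivative with the reference coordinate eliminated
    is (dV/dlambda_k - dV/dlambda_0); with buffers, the charge
    constraint ties the buffer lambda to the free coordinates as well.
    """
    sl = system.dof_slices()[0]
    g = system.groups[0]
    lam = system.lambda_vector()
    grad = _analytic_lambda_gradient(system, lam, pots)
    if pots.include_coulomb and system.n_atoms > 0:
        res = es.coulomb(system)
        grad = grad + _lambda_coulomb_gradient(system, res)
    free = grad[sl.start + 1 : sl.stop] - grad[sl.start]
    if system.buffers is not None:
        # d lambda_buf / d x_k from the charge constraint
        dq_states = g.state_charges.sum(axis=1)
        cap = system.buffers.n_buffers * system.buffers.charge_span
        dbuf = -(dq_states[1:] - dq_states[0]) / cap
        free = free + grad[-1] * dbuf
    return free


def ti_scan(
    system: TitratableSystem,
    grid: GridSpec | np.ndarray = GridSpec(),
    per_point_steps: int = 2000,
    seed: int = 0,
    integrator: IntegratorSpec | None = None,
    potentials: RunPotentials | None = None,
    equilibration_fraction: float = 0.1,
    sample_interval: int = 50,
    strict: bool = True,
) -> TiScanResult:
    """Scan the lambda grid, averaging dV/dlambda at each fixed point.

    Atoms evolve (thermostatted) while the lambdas are clamped; with all
    atoms frozen or tether-free the gradient is deterministic and the
    standard error is zero.  ``potentials`` defaults to the bare
    force-field term (no bias, no pH, no V^MM), which is what the
    correction-potential calibration integrates.
    """
    if len(system.groups) != 1:
        raise ConfigurationError("ti_scan supports single-group systems")
    if per_point_steps < MIN_STEPS_PER_POINT:
        msg = (
            f"per_point_steps={per_point_steps} below the configured minimum "
            f"{MIN_STEPS_PER_POINT}"
        )
        if strict:
            raise ConfigurationError(msg)
        warnings.warn(msg, stacklevel=2)
    g = system.groups[0]
    arity = g.n_states - 1
    pts = make_simplex_grid(arity, grid) if isinstance(grid, GridSpec) else np.atleast_2d(grid)
    pots = potentials or RunPotentials(bias=None, pH=None, vmm=[])
    spec = integrator or IntegratorSpec(
        dt=0.002, n_steps=per_point_steps, lambda_thermostat=None, seed=seed
    )

    mobile = any(a.restraint_k > 0 for a in system.atoms) and not spec.freeze_atoms
    sl = system.dof_slices()[0]
    cset = build_constraints(system)
    # canonical geometry: every grid point starts from (and is tethered to)
    # the fixture's reference positions, not wherever the last point ended
    orig_positions = system.positions.copy()
    orig_lambdas = system.lambda_vector().copy()
    means = np.zeros_like(pts)
    sems = np.zeros_like(pts)
    n_samples = 0
    rng_master = np.random.default_rng(seed)
    for ip, x in enumerate(pts):
        full = np.zeros(system.n_lambda_dofs)
        full[sl.start] = 1.0 - x.sum()
        full[sl.start + 1 : sl.stop] = x
        if system.buffers is not None:
            # buffers alone absorb the titration charge at each grid point
            row, cq = cset.jacobian[-1], cset.targets[-1]
            cap = row[-1]
            full[-1] = (cq - row[:-1] @ full[:-1]) / cap
        system.set_lambda_vector(full)
        for a, p in zip(system.atoms, orig_positions):
            a.position = p.copy()
        if not mobile:
            means[ip] = _constrained_gradient(system, pots)
            continue
        # thermostatted atom dynamics with lambdas clamped
        rng = np.random.default_rng(rng_master.integers(2**31))
        state = MDState.initialize(system, rng, constraints=cset)
        state.lambdas = full.copy()
        state.lambda_velocities[:] = 0.0
        lam_spec = IntegratorSpec(
            dt=spec.dt, n_steps=spec.n_steps, atom_thermostat=spec.atom_thermostat,
            lambda_thermostat=None, seed=spec.seed, freeze_atoms=False,
        )
        samples = []
        n_equil = int(equilibration_fraction * per_point_steps)
        for step in range(per_point_steps):
            state = md_step(system, state, lam_spec, pots, cset, rng)
            state.lambdas = full.copy()          # clamp
            state.lambda_velocities[:] = 0.0
            if step >= n_equil and (step + 1) % sample_interval == 0:
                system.set_lambda_vector(full)
                for a, p in zip(system.atoms, state.positions):
                    a.position = p
                samples.append(_constrained_gradient(system, pots))
        samples = np.array(samples)
        means[ip] = samples.mean(axis=0)
        sems[ip] = samples.std(axis=0, ddof=1) / np.sqrt(len(samples))
        n_samples = len(samples)
    # leave the system as we found it (md_step writes through to atoms)
    for a, p in zip(system.atoms, orig_positions):
        a.position = p.copy()
    system.set_lambda_vector(orig_lambdas)
    return TiScanResult(
        grid=pts, mean_gradients=means, stderr=sems,
        equilibration_fraction=equilibration_fraction, n_samples=n_samples,
    )


@dataclass
class VmmFitReport:
    """Diagnostics of a correction-potential fit."""

    max_residual: float
    rms_residual: float
    rank: int
    n_terms: int
    condition: float
    dropped_terms: int = 0


def fit_vmm(scan: TiScanResult, order: int | None = None):
    """Fit V^MM so that -dV^MM/dlambda matches the scanned gradients.

    Defaults to fifth order for one free coordinate and eighth order for
    two (the three-state case).  The monomial gradient design matrix is
    solved by SVD-based least squares; singular values below 1e-10 of
    the largest are truncated, handling linear dependencies among the
    coefficients.  Returns ``(VmmPolynomial, VmmFitReport)``.
    """
    arity = scan.arity
    if order is None:
        order = 5 if arity == 1 else 8
    exps = _monomial_exponents(arity, order)
    n_pts = len(scan.grid)
    if n_pts * arity <= len(exps):
        raise ConfigurationError("underdetermined V^MM fit: more coefficients than data")
    # design: rows = (point, component), columns = monomial gradient
    rows = np.zeros((n_pts * arity, len(exps)))
    for t, e in enumerate(exps):
        for d in range(arity):
            if e[d] == 0:
                continue
            shifted = e.copy()
            shifted[d] -= 1
            rows[d::arity, t] = e[d] * np.prod(scan.grid**shifted, axis=1)
    target = (-scan.mean_gradients).ravel()
    coef, _, rank, sv = np.linalg.lstsq(rows, target, rcond=1e-10)
    poly = VmmPolynomial(arity=arity, order=order, coefficients=coef, exponents=exps)
    _, grads = vmm_eval(scan.grid, poly)
    resid = -grads - scan.mean_gradients
    report = VmmFitReport(
        max_residual=float(np.max(np.abs(resid))),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        rank=int(rank),
        n_terms=len(exps),
        condition=float(sv[0] / sv[-1]) if sv.size and sv[-1] > 0 else np.inf,
    )
    # the fitting-error yardstick: 0.5 kJ/mol for a single site, 1 kJ/mol
    # for the three-state (two free coordinates) case
    threshold = 0.5 if arity == 1 else 1.0
    if report.rms_residual > threshold:
        warnings.warn(
            f"V^MM fitting error (RMS) {report.rms_residual:.3f} kJ/mol exceeds "
            f"{threshold} kJ/mol",
            stacklevel=2,
        )
    return poly, report


def ti_free_energy(scan: TiScanResult) -> tuple[float, float]:
    """Deprotonation free energy over lambda in [0, 1] by trapezoid.

    One-dimensional scans only.  Returns ``(dG, err)`` with the error
    propagated from the per-point standard errors.  Raises if the grid
    leaves a gap larger than twice the nominal spacing inside [0, 1].
    """
    if scan.arity != 1:
        raise ConfigurationError("ti_free_energy requires a one-dimensional scan")
    x = scan.grid[:, 0]
    order = np.argsort(x)
    x = x[order]
    gmean = scan.mean_gradients[order, 0]
    gsem = scan.stderr[order, 0]
    if x.min() > 0.0 or x.max() < 1.0:
        raise CphmdError("grid does not span [0, 1]")
    inside = (x >= -1e-9) & (x <= 1.0 + 1e-9)
    xi, gi, si = x[inside], gmean[inside], gsem[inside]
    all_spacing = np.diff(x)
    nominal = np.min(all_spacing[all_spacing > 1e-12])
    spacing = np.diff(xi)
    if np.any(spacing > 2.0 * nominal + 1e-12):
        raise CphmdError("grid gap inside [0, 1] exceeds twice the nominal spacing")
    dg = float(np.trapezoid(gi, xi))
    w = np.zeros_like(xi)
    w[1:] += spacing / 2
    w[:-1] += spacing / 2
    err = float(np.sqrt(np.sum((w * si) ** 2)))
    return dg, err
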