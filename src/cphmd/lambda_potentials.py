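"""Analytic lambda-dependent potential terms and their derivatives.

Three terms act on every titration coordinate:

``V^MM``
    a fitted polynomial that cancels the force field's intrinsic
    deprotonation free energy, so that the reference compound titrates at
    pH = pKa (see :mod:`cphmd.calibration` for the fit);
``V^bias``
    a symmetric double well that penalizes nonphysical intermediate
    lambda values while leaving the end states at zero energy;
``V^pH``
    a smooth step carrying the proton chemical potential, whose end-state
    difference is exactly ``ln(10) k_B T (pKa_ref - pH)``.

All functions evaluate on arbitrary real lambda (the TI calibration grid
extends to -0.1 and 1.1) and are vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import expit

from .constants import KB, LN10
from .errors import ConfigurationError, ParameterError
from .model import LambdaGroup

__all__ = [
    "PhPotentialSpec",
    "BiasSpec",
    "VmmPolynomial",
    "ph_potential",
    "bias_potential",
    "vmm_eval",
    "total_lambda_force",
]


@dataclass
class PhPotentialSpec:
    """Parameters of the pH-dependent smooth-step potential.

    The step function rises from 0 at lambda = 0 to 1 at lambda = 1, with
    logistic kinks of steepness ``k1`` at ``x0`` and ``1 - x0``.  The
    default kinks (0.25 and 0.75) lie strictly inside the mid-range that
    the frame classifier excludes, so within the physical end basins the
    potential is flat and the basin Boltzmann weights obey the end-state
    contract

        V(1) - V(0) = ln(10) k_B T (pKa_ref - pH),

    which holds exactly by normalization; the interior shape is a
    sampling device, not a thermodynamic statement.
    """

    pKa_ref: float
    pH: float
    k1: float = 100.0
    x0: float = 0.25
    T: float = 300.0

    def __post_init__(self):
        if self.T <= 0:
            raise ParameterError("temperature must be positive")
        if self.k1 <= 0:
            raise ParameterError("k1 must be positive")

    @property
    def delta_g(self) -> float:
        """End-state free-energy difference, kJ/mol."""
        return LN10 * KB * self.T * (self.pKa_ref - self.pH)


def _step(lam, k1, x0):
    """Normalized double-logistic step with s(0) = 0, s(1) = 1 exactly."""
    lam = np.asarray(lam, dtype=float)
    raw = 0.5 * (expit(k1 * (lam - x0)) + expit(k1 * (lam - (1.0 - x0))))
    r0 = 0.5 * (expit(-k1 * x0) + expit(-k1 * (1.0 - x0)))
    r1 = 0.5 * (expit(k1 * (1.0 - x0)) + expit(k1 * x0))
    return (raw - r0) / (r1 - r0)


def _step_deriv(lam, k1, x0):
    lam = np.asarray(lam, dtype=float)
    a = expit(k1 * (lam - x0))
    b = expit(k1 * (lam - (1.0 - x0)))
    r0 = 0.5 * (expit(-k1 * x0) + expit(-k1 * (1.0 - x0)))
    r1 = 0.5 * (expit(k1 * (1.0 - x0)) + expit(k1 * x0))
    return 0.5 * k1 * (a * (1 - a) + b * (1 - b)) / (r1 - r0)


def ph_potential(lam, spec: PhPotentialSpec):
    """pH potential and its derivative at lambda.

    Returns ``(V, dV/dlambda)`` in kJ/mol and kJ/mol per unit lambda.
    The convention V(0) = 0 anchors the protonated end state.
    """
    dg = spec.delta_g
    return dg * _step(lam, spec.k1, spec.x0), dg * _step_deriv(lam, spec.k1, spec.x0)


@dataclass
class BiasSpec:
    """Double-well bias with minima of zero at both end states.

    ``barrier`` is the height of the maximum at lambda = 1/2 in kJ/mol
    (5.0 for all-atom-like, 7.5 for coarse-grained-like setups).
    """

    barrier: float = 5.0

    def __post_init__(self):
        if self.barrier < 0:
            raise ParameterError("bias barrier must be non-negative")


def bias_potential(lam, spec: BiasSpec):
    """Symmetric double-well bias ``b * 16 * lam^2 (1-lam)^2`` and derivative.

    Vanishing derivative at lambda in {0, 1/2, 1}; grows quartically
    outside [0, 1], confining excursions beyond the end states.
    """
    lam = np.asarray(lam, dtype=float)
    b = spec.barrier
    v = 16.0 * b * lam**2 * (1.0 - lam) ** 2
    dv = 32.0 * b * lam * (1.0 - lam) * (1.0 - 2.0 * lam)
    return v, dv


def _monomial_exponents(arity: int, order: int) -> np.ndarray:
    """All non-constant monomial exponent tuples with total degree <= order."""
    exps = [
        e
        for e in product(range(order + 1), repeat=arity)
        if 0 < sum(e) <= order
    ]
    exps.sort(key=lambda e: (sum(e), e))
    return np.array(exps, dtype=int)


@dataclass
class VmmPolynomial:
    """Force-field correction potential as a multivariate polynomial.

    The polynomial is expressed in the *free* simplex coordinates: the
    lambda values of the deprotonated states 1..n-1 of a group, with the
    reference-state coordinate eliminated through sum(lambda) = 1.  A
    two-state site therefore has arity 1 (a polynomial in the titration
    coordinate); a histidine-like three-state group has arity 2.

    ``coefficients[t]`` multiplies the monomial with exponent row
    ``exponents[t]``.  The constant term carries no gradient and is
    omitted; V^MM(0) = 0 by construction.
    """

    arity: int
    order: int
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))
    exponents: np.ndarray | None = None

    def __post_init__(self):
        if self.arity < 1:
            raise ConfigurationError("polynomial arity must be >= 1")
        if self.exponents is None:
            self.exponents = _monomial_exponents(self.arity, self.order)
        self.exponents = np.atleast_2d(np.asarray(self.exponents, dtype=int))
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size == 0:
            self.coefficients = np.zeros(len(self.exponents))
        if len(self.coefficients) != len(self.exponents):
            raise ConfigurationError("coefficient / exponent length mismatch")

    @classmethod
    def zero(cls, arity: int = 1, order: int = 5) -> "VmmPolynomial":
        return cls(arity=arity, order=order)

    @classmethod
    def from_1d_coefficients(cls, coeffs) -> "VmmPolynomial":
        """1-D polynomial ``sum_j c_j lam^j`` from low to high degree, j >= 1."""
        coeffs = np.asarray(coeffs, dtype=float)
        order = len(coeffs)
        exps = np.arange(1, order + 1).reshape(-1, 1)
        return cls(arity=1, order=order, coefficients=coeffs, exponents=exps)

    @property
    def n_terms(self) -> int:
        return len(self.coefficients)


def vmm_eval(lambdas, poly: VmmPolynomial):
    """Evaluate V^MM and its gradient at free-coordinate points.

    ``lambdas`` is a vector of length ``arity`` or an array of shape
    ``(n_points, arity)``.  Returns ``(value, gradient)`` matching the
    input batch shape.
    """
    x = np.asarray(lambdas, dtype=float)
    single = x.ndim <= 1
    x = np.atleast_2d(x)
    if x.shape[-1] != poly.arity:
        raise ConfigurationError(
            f"lambda vector length {x.shape[-1]} does not match polynomial arity {poly.arity}"
        )
    # powers[b, t] = prod_d x[b, d] ** e[t, d]
    powers = np.prod(x[:, None, :] ** poly.exponents[None, :, :], axis=2)
    value = powers @ poly.coefficients
    grad = np.zeros_like(x)
    for d in range(poly.arity):
        e = poly.exponents[:, d]
        mask = e > 0
        if not mask.any():
            continue
        shifted = poly.exponents[mask].copy()
        shifted[:, d] -= 1
        dpow = np.prod(x[:, None, :] ** shifted[None, :, :], axis=2)
        grad[:, d] = dpow @ (poly.coefficients[mask] * e[mask])
    if single:
        return float(value[0]), grad[0]
    return value, grad


def group_free_coords(lambdas: np.ndarray) -> np.ndarray:
    """Free simplex coordinates of a group: drop the reference state 0."""
    return np.asarray(lambdas, dtype=float)[..., 1:]


def total_lambda_force(
    group: LambdaGroup,
    coulomb_gradient,
    vmm: VmmPolynomial | None = None,
    bias: BiasSpec | None = None,
    ph_specs=None,
):
    """Per-coordinate generalized force on a group's lambda coordinates.

    ``coulomb_gradient`` is the per-coordinate electrostatic gradient
    dV^Coul/dlambda_k (zeros if electrostatics are absent).  ``ph_specs``
    is a sequence with one :class:`PhPotentialSpec` or ``None`` per
    coordinate; bias and pH terms act on each coordinate independently.

    Returns ``(force, terms)`` where ``force[k] = -dV_total/dlambda_k``
    and ``terms`` maps each contribution name to its gradient vector for
    diagnostics.
    """
    lam = group.lambdas
    n = group.n_states
    grad_coul = np.asarray(coulomb_gradient, dtype=float)
    if grad_coul.shape != (n,):
        raise ConfigurationError("coulomb gradient length does not match group")
    grad_vmm = np.zeros(n)
    if vmm is not None:
        if vmm.arity != n - 1:
            raise ConfigurationError(
                f"V^MM arity {vmm.arity} does not match group with {n} states"
            )
        _, g = vmm_eval(group_free_coords(lam), vmm)
        grad_vmm[1:] = g
    grad_bias = np.zeros(n)
    if bias is not None:
        _, grad_bias = bias_potential(lam, bias)
    grad_ph = np.zeros(n)
    if ph_specs is not None:
        for k, spec in enumerate(ph_specs):
            if spec is not None:
                _, grad_ph[k] = ph_potential(lam[k], spec)
    terms = {
        "coulomb": grad_coul,
        "vmm": grad_vmm,
        "bias": grad_bias,
        "ph": grad_ph,
    }
    force = -(grad_coul + grad_vmm + grad_bias + grad_ph)
    return force, terms


def ph_specs_for_group(group: LambdaGroup, pH: float, T: float, k1: float = 100.0,
                       x0: float = 0.25) -> list[PhPotentialSpec | None]:
    """Per-coordinate pH potentials from the group's microscopic pKas.

    The shared reference (protonated) coordinate carries no pH term;
    every deprotonated-state coordinate gets a step potential with its
    own microscopic reference pKa.
    """
    specs: list[PhPotentialSpec | None] = []
    for k in range(group.n_states):
        pka = group.reference_pKas[k]
        if k == 0 or pka is None:
            specs.append(None)
        else:
            specs.append(PhPotentialSpec(pKa_ref=pka, pH=pH, k1=k1, x0=x0, T=T))
    return specs
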