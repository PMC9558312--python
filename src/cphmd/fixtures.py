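"""Synthetic toy systems and the brute-force quadrature oracle.

The fixtures stand in, at desk scale, for the solvated reference
compounds (Ala-X-Ala-like) against which a constant-pH engine is
calibrated and validated:

``ideal_site``
    one titratable point charge with no environment — the Coulomb
    lambda-gradient is identically zero, so the exact correction
    potential is V^MM = 0 and the site must titrate at its reference pKa;
``shifted_site``
    adds fixed (optionally harmonically tethered, mobile) environment
    charges, producing a closed-form lambda-dependent Coulomb term and
    hence a predictable pKa shift;
``his_like``
    a three-state multisite group (doubly protonated reference plus two
    singly protonated tautomers) with microscopic reference pKas;
``buffer_bath``
    any of the above plus charge-compensating buffer particles coupled
    through the global charge constraint.

The quadrature oracle integrates exp(-V_total/kT) over the constrained
lambda manifold directly — no dynamics — and is the independent ground
truth for every statistical claim made by the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .errors import ConfigurationError, PrecisionError
from .lambda_potentials import _step, bias_potential, vmm_eval
from .model import (
    Atom,
    BufferSet,
    ElectrostaticsSpec,
    LambdaGroup,
    TitratableSystem,
)
from .dynamics import RunPotentials, _ph_delta_g_matrix, build_constraints
from . import electrostatics as es

__all__ = ["FixtureSpec", "make_fixture", "quadrature_oracle", "OracleResult"]

KINDS = ("ideal_site", "shifted_site", "his_like", "buffer_bath")


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic titratable system.

    ``pKa_refs`` holds the reference pKa of the deprotonated state(s):
    one value for the two-state fixtures, two microscopic values
    (N-delta- and N-epsilon-protonated tautomers) for ``his_like``.
    ``environment_charges`` is a list of ``(position, charge)`` pairs.
    """

    kind: str = "ideal_site"
    pKa_refs: tuple = (4.0,)
    environment_charges: list = field(default_factory=list)
    temperature: float = 300.0
    seed: int = 0
    n_buffers: int = 10
    base: str = "ideal_site"          # for buffer_bath
    mobile_environment: bool = False
    restraint_k: float = 1000.0       # kJ/mol/nm^2 tether for mobile atoms
    site_charge_prot: float = 0.0
    site_charge_deprot: float = -1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown fixture kind {self.kind!r}")


def _site_atom(restraint_k: float = 0.0):
    return Atom(id=0, position=np.zeros(3), mass=12.0, q_A=0.0, q_B=0.0,
                group_id=0, restraint_k=restraint_k)


def _environment_atoms(spec: FixtureSpec, start_id: int) -> list[Atom]:
    atoms = []
    for j, (pos, q) in enumerate(spec.environment_charges):
        atoms.append(
            Atom(
                id=start_id + j,
                position=np.asarray(pos, dtype=float),
                mass=12.0,
                q_A=q,
                restraint_k=spec.restraint_k if spec.mobile_environment else 0.0,
            )
        )
    return atoms


def make_fixture(spec: FixtureSpec) -> TitratableSystem:
    """Build the synthetic system described by ``spec`` (deterministic)."""
    if spec.kind == "buffer_bath":
        base_spec = FixtureSpec(
            kind=spec.base,
            pKa_refs=spec.pKa_refs,
            environment_charges=spec.environment_charges,
            temperature=spec.temperature,
            seed=spec.seed,
            mobile_environment=spec.mobile_environment,
            restraint_k=spec.restraint_k,
            site_charge_prot=spec.site_charge_prot,
            site_charge_deprot=spec.site_charge_deprot,
        )
        system = make_fixture(base_spec)
        rng = np.random.default_rng(spec.seed)
        start = max(a.id for a in system.atoms) + 1
        # buffers on a sphere far enough out not to dominate the site
        radius = 2.5
        buf_ids = []
        for j in range(spec.n_buffers):
            u = rng.normal(size=3)
            u = u / np.linalg.norm(u)
            system.atoms.append(
                Atom(id=start + j, position=radius * u, mass=12.0, q_A=0.0)
            )
            buf_ids.append(start + j)
        system.buffers = BufferSet(atom_ids=buf_ids, collective_lambda=0.5)
        system.total_charge_target = None
        system.__post_init__()
        return system

    if spec.kind in ("ideal_site", "shifted_site"):
        if len(spec.pKa_refs) != 1:
            raise ConfigurationError("two-state fixtures take exactly one pKa_ref")
        site = _site_atom(spec.restraint_k if spec.mobile_environment else 0.0)
        group = LambdaGroup.two_state(
            atom_ids=[0],
            q_prot=[spec.site_charge_prot],
            q_deprot=[spec.site_charge_deprot],
            pKa_ref=spec.pKa_refs[0],
            name="site",
        )
        atoms = [site]
        if spec.kind == "shifted_site":
            env = spec.environment_charges or [((1.0, 0.0, 0.0), 0.05)]
            spec.environment_charges = env
            atoms += _environment_atoms(spec, start_id=1)
        return TitratableSystem(
            atoms=atoms, groups=[group], temperature=spec.temperature,
            electrostatics=ElectrostaticsSpec(),
        )

    # his_like: three-state multisite group, one shared atom
    if len(spec.pKa_refs) != 2:
        raise ConfigurationError("his_like takes two microscopic pKa_refs (HSD, HSE)")
    site = _site_atom(spec.restraint_k if spec.mobile_environment else 0.0)
    group = LambdaGroup(
        atom_ids=[0],
        state_charges=np.array([[1.0], [0.0], [0.0]]),
        reference_pKas=[None, spec.pKa_refs[0], spec.pKa_refs[1]],
        name="his",
    )
    atoms = [site] + _environment_atoms(spec, start_id=1)
    return TitratableSystem(
        atoms=atoms, groups=[group], temperature=spec.temperature,
        electrostatics=ElectrostaticsSpec(),
    )


@dataclass
class OracleResult:
    """Boltzmann basin populations from direct quadrature.

    Populations are normalized over the classified basins only, matching
    the frame-counting estimators (mid-range frames are excluded there
    too).
    """

    P_prot: float
    P_deprot: float
    S_deprot: float
    S_micro: dict | None = None        # state index -> microscopic fraction
    S_macro: float | None = None
    populations: np.ndarray | None = None


def _manifold_chart(system: TitratableSystem, eliminate: int):
    """Affine chart of the constraint manifold for a single-group system.

    The free coordinates are the group's lambda values except coordinate
    ``eliminate``; the eliminated coordinate and (if present) the buffer
    lambda follow from the simplex and charge constraints.  All charts of
    this family are unimodular, so Boltzmann integrals over different
    charts are directly comparable.
    """
    if len(system.groups) != 1:
        raise ConfigurationError("quadrature oracle supports single-group systems")
    sl = system.dof_slices()[0]
    K = system.n_lambda_dofs
    cset = build_constraints(system)
    free_idx = [i for i in range(sl.start, sl.stop) if i != sl.start + eliminate]
    dep_idx = [i for i in range(K) if i not in free_idx]
    Jd = cset.jacobian[:, dep_idx]
    Jf = cset.jacobian[:, free_idx]
    if Jd.shape[0] != Jd.shape[1]:
        raise ConfigurationError("unexpected constraint structure for the oracle")
    Jd_inv = np.linalg.inv(Jd)

    def to_full(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        dep = (cset.targets - x @ Jf.T) @ Jd_inv.T
        full = np.empty(x.shape[:-1] + (K,))
        full[..., free_idx] = x
        full[..., dep_idx] = dep
        return full

    return to_full


def _total_lambda_energy(
    system: TitratableSystem, pots: RunPotentials, full: np.ndarray
) -> np.ndarray:
    """V_total over an array of full lambda DOF vectors (frozen atoms)."""
    flat = full.reshape(-1, full.shape[-1])
    e = np.zeros(len(flat))
    if pots.include_coulomb and system.n_atoms > 0:
        H, glin, c0 = es.quadratic_form(system)
        if np.any(H) or np.any(glin):
            e += 0.5 * np.einsum("bi,ij,bj->b", flat, H, flat) + flat @ glin + c0
    sl = system.dof_slices()[0]
    lam_g = flat[:, sl]
    if pots.bias is not None and pots.bias.barrier != 0.0:
        vb, _ = bias_potential(lam_g, pots.bias)
        e += vb.sum(axis=1)
    dg = _ph_delta_g_matrix(system, pots, 1)[0]
    if np.any(dg != 0.0):
        e += _step(flat, pots.k1, pots.x0) @ dg
    poly = pots.vmm_for(0)
    if poly is not None and np.any(poly.coefficients):
        v, _ = vmm_eval(lam_g[:, 1:], poly)
        e += v
    return e.reshape(full.shape[:-1])


def _panel_gauss(lo: float, hi: float, panel: float, nodes: int):
    """Composite Gauss-Legendre nodes/weights on [lo, hi]."""
    n_panels = max(1, int(np.ceil((hi - lo) / panel)))
    edges = np.linspace(lo, hi, n_panels + 1)
    x0, w0 = np.polynomial.legendre.leggauss(nodes)
    pts = ((edges[1:] + edges[:-1]) / 2)[:, None] + ((edges[1:] - edges[:-1]) / 2)[:, None] * x0
    wts = ((edges[1:] - edges[:-1]) / 2)[:, None] * w0
    return pts.ravel(), wts.ravel()


def quadrature_oracle(
    system: TitratableSystem,
    potentials: RunPotentials,
    thresholds=(0.2, 0.8),
    extent: tuple[float, float] = (-1.5, 2.5),
    nodes: int = 12,
    panel: float = 0.02,
) -> OracleResult:
    """Exact basin populations by numerical Boltzmann integration.

    Integrates ``exp(-V_total/kT)`` over the constrained lambda manifold
    (a line for a two-state site, a plane for a three-state group) with
    atoms frozen.  The bias potential is included: the oracle integrates
    the same total potential the sampler feels.  Each basin (lambda_k
    above the deprotonation threshold; for the protonated basin, the
    reference lambda above it) is integrated in a chart in which its
    boundary is a coordinate plane, using composite Gauss-Legendre
    panels.  A refinement pass with more nodes per panel must agree to
    1e-6 in every basin fraction, else :class:`PrecisionError` is raised.
    """
    g = system.groups[0]
    n_states = g.n_states
    lo, hi_thr = thresholds
    kT = KB * system.temperature

    # common energy offset so all basin integrals share one scale
    chart0 = _manifold_chart(system, eliminate=0)
    if n_states == 2:
        probe = chart0(np.linspace(extent[0], extent[1], 2001)[:, None])
    else:
        ax = np.linspace(extent[0], extent[1], 101)
        X, Y = np.meshgrid(ax, ax)
        probe = chart0(np.column_stack([X.ravel(), Y.ravel()]))
    vmin = float(_total_lambda_energy(system, potentials, probe).min())

    def basin_weight(k: int, nodes_k: int) -> float:
        """Integral of exp(-(V - vmin)/kT) over basin k.

        Basin k >= 1 is {lambda_k > hi}; the protonated basin is
        {lambda_0 > 1 - lo}, which under the simplex constraint equals
        the titration coordinate staying below the lower threshold.
        """
        # chart eliminating some other coordinate, with lambda_k as axis 0
        elim = 1 if k == 0 else 0
        chart = _manifold_chart(system, eliminate=elim)
        axes = [i for i in range(n_states) if i != elim]
        pos = axes.index(k)
        thr = (1.0 - lo) if k == 0 else hi_thr
        u, wu = _panel_gauss(thr, extent[1], panel, nodes_k)
        if n_states == 2:
            x = u[:, None]
            w = wu
            order = [0]
        else:
            v, wv = _panel_gauss(extent[0], extent[1], max(panel, 0.05), nodes_k)
            U, V = np.meshgrid(u, v, indexing="ij")
            x = np.column_stack([U.ravel(), V.ravel()])
            w = np.outer(wu, wv).ravel()
            order = [0, 1]
        # place the basin coordinate on the correct chart axis
        if pos != 0:
            x = x[:, ::-1]
        full = chart(x)
        V_ = _total_lambda_energy(system, potentials, full)
        return float(np.exp(-(V_ - vmin) / kT) @ w)

    def populations(nodes_k: int) -> np.ndarray:
        w = np.array([basin_weight(k, nodes_k) for k in range(n_states)])
        return w / w.sum()

    pops = populations(nodes)
    pops_fine = populations(nodes + 6)
    if np.max(np.abs(pops - pops_fine)) > 1e-6:
        raise PrecisionError("quadrature did not converge under refinement")
    pops = pops_fine

    P_prot = float(pops[0])
    P_deprot = float(pops[1:].sum())
    S = P_deprot / (P_prot + P_deprot)
    result = OracleResult(
        P_prot=P_prot, P_deprot=P_deprot, S_deprot=S, populations=pops
    )
    if n_states > 2:
        result.S_micro = {
            k: float(pops[k] / (pops[0] + pops[k])) for k in range(1, n_states)
        }
        result.S_macro = S
    return result


def oracle_titration(
    system: TitratableSystem,
    potentials: RunPotentials,
    pH_values,
    thresholds=(0.2, 0.8),
):
    """Oracle titration curve(s) and Henderson-Hasselbalch fit(s).

    Returns ``(S_values, fit)`` for a two-state system, or
    ``(S_macro, S_micro_dict, fits_dict)`` for a three-state group, where
    each fit is a :class:`cphmd.titration.HHFit`.
    """
    from .titration import fit_hh

    pH_values = np.asarray(pH_values, dtype=float)
    g = system.groups[0]

    def pots_at(ph):
        return RunPotentials(
            bias=potentials.bias, vmm=potentials.vmm, pH=float(ph),
            k1=potentials.k1, x0=potentials.x0,
            include_coulomb=potentials.include_coulomb,
        )

    if g.n_states == 2:
        S = np.array(
            [quadrature_oracle(system, pots_at(ph), thresholds).S_deprot for ph in pH_values]
        )
        return S, fit_hh(pH_values, S)
    S_macro = np.empty(pH_values.size)
    S_micro = {k: np.empty(pH_values.size) for k in range(1, g.n_states)}
    for i, ph in enumerate(pH_values):
        res = quadrature_oracle(system, pots_at(ph), thresholds)
        S_macro[i] = res.S_macro
        for k in S_micro:
            S_micro[k][i] = res.S_micro[k]
    fits = {"macro": fit_hh(pH_values, S_macro)}
    for k in S_micro:
        fits[k] = fit_hh(pH_values, S_micro[k])
    return S_macro, S_micro, fits
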