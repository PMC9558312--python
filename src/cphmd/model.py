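"""Domain types for titratable systems and lambda-state bookkeeping.

A titratable site is represented in the multisite form: one
:class:`LambdaCoordinate` per physical protonation state of the group,
with the coordinate values constrained to sum to one.  At
``lambda_{i,k} = 1`` the group carries the partial charges of state ``k``;
intermediate points are linear mixtures.  A single titratable site is the
two-state special case (coordinate 0 = protonated, coordinate 1 =
deprotonated), whose titration degree of freedom is the value of the
deprotonated coordinate.

Charges are interpolated linearly:

* non-titratable atoms keep their fixed charge ``q_A``;
* an atom of group *i* carries ``q = sum_k lambda_{i,k} * q^{(k)}``,
  which under the simplex constraint reduces to
  ``(1 - lambda) q_A + lambda q_B`` for a two-state site;
* buffer particles all carry the identical collectively interpolated
  charge ``q_min + lambda_buf * (q_max - q_min)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError

__all__ = [
    "Atom",
    "LambdaCoordinate",
    "LambdaGroup",
    "BufferSet",
    "ElectrostaticsSpec",
    "TitratableSystem",
    "interpolated_charges",
    "total_charge",
]


@dataclass
class Atom:
    """A point particle with per-protonation-state partial charges.

    ``q_A``/``q_B`` are the protonated/deprotonated end-state charges in
    units of e.  Atoms outside any lambda-group must have ``q_A == q_B``.
    ``restraint_k`` is an optional harmonic tether (kJ/mol/nm^2) to the
    atom's initial position; it stands in for the bonded environment that
    keeps reference-state atoms localized.
    """

    id: int
    position: np.ndarray
    mass: float = 12.0
    q_A: float = 0.0
    q_B: float | None = None
    group_id: int | None = None
    restraint_k: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ConfigurationError(f"atom {self.id}: position must be a 3-vector")
        if self.mass <= 0:
            raise ParameterError(f"atom {self.id}: mass must be positive")
        if self.q_B is None:
            self.q_B = self.q_A
        if self.group_id is None and self.q_A != self.q_B:
            raise ConfigurationError(
                f"atom {self.id}: q_A != q_B but atom is not in any lambda-group"
            )


@dataclass
class LambdaCoordinate:
    """One titration degree of freedom.

    The value is deliberately unbounded: the correction, bias, and pH
    potentials confine it, and the TI calibration grid runs from -0.1 to
    1.1, so no hard clamping is ever applied.
    """

    value: float = 0.0
    velocity: float = 0.0
    mass: float = 5.0
    thermostat_group: str = "lambda"
    name: str = ""

    def __post_init__(self):
        if self.mass <= 0:
            raise ParameterError("lambda coordinate mass must be positive")


@dataclass
class LambdaGroup:
    """A titratable group in the multisite representation.

    ``state_charges[k, a]`` is the charge of member atom ``a`` (ordered as
    in ``atom_ids``) when the group is fully in physical state ``k``.
    State 0 is the common (fully protonated) reference state shared by all
    coordinates; every other state is reached at ``lambda_k = 1``.
    ``reference_pKas[k]`` is the microscopic pKa for the transition from
    state 0 to state ``k`` (``None`` for state 0 itself).
    """

    atom_ids: list[int]
    state_charges: np.ndarray
    coordinates: list[LambdaCoordinate] = field(default_factory=list)
    reference_pKas: list[float | None] = field(default_factory=list)
    constrained_sum: float = 1.0
    name: str = ""

    def __post_init__(self):
        self.state_charges = np.atleast_2d(np.asarray(self.state_charges, dtype=float))
        n_states = self.state_charges.shape[0]
        if n_states < 2:
            raise ConfigurationError(f"group {self.name!r}: needs >= 2 states")
        if self.state_charges.shape[1] != len(self.atom_ids):
            raise ConfigurationError(
                f"group {self.name!r}: state_charges shape does not match atom_ids"
            )
        if not self.coordinates:
            self.coordinates = [
                LambdaCoordinate(value=1.0 if k == 0 else 0.0, name=f"{self.name}.{k}")
                for k in range(n_states)
            ]
        if len(self.coordinates) != n_states:
            raise ConfigurationError(
                f"group {self.name!r}: one coordinate per state required"
            )
        if not self.reference_pKas:
            self.reference_pKas = [None] * n_states
        if len(self.reference_pKas) != n_states:
            raise ConfigurationError(
                f"group {self.name!r}: one reference pKa per state required"
            )

    @property
    def n_states(self) -> int:
        return self.state_charges.shape[0]

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([c.value for c in self.coordinates])

    def set_lambdas(self, values) -> None:
        values = np.asarray(values, dtype=float)
        for c, v in zip(self.coordinates, values):
            c.value = float(v)

    def member_charges(self, lambdas=None) -> np.ndarray:
        """State-weighted charges of the member atoms at the given lambdas."""
        lam = self.lambdas if lambdas is None else np.asarray(lambdas, dtype=float)
        return lam @ self.state_charges

    def delta_charges(self, k: int) -> np.ndarray:
        """Per-atom charge difference of state ``k`` relative to state 0.

        For a two-state group and k = 1 this is the classic
        ``dq = q_B - q_A`` entering the charge-interpolation lambda-gradient.
        """
        return self.state_charges[k] - self.state_charges[0]

    @classmethod
    def two_state(cls, atom_ids, q_prot, q_deprot, pKa_ref, name="site") -> "LambdaGroup":
        """Single titratable site in multisite form (2 coordinates)."""
        q_prot = np.atleast_1d(np.asarray(q_prot, dtype=float))
        q_deprot = np.atleast_1d(np.asarray(q_deprot, dtype=float))
        return cls(
            atom_ids=list(atom_ids),
            state_charges=np.vstack([q_prot, q_deprot]),
            reference_pKas=[None, pKa_ref],
            name=name,
        )

    @property
    def titration_index(self) -> int:
        """Index of the deprotonated coordinate of a two-state group."""
        if self.n_states != 2:
            raise ConfigurationError(
                f"group {self.name!r}: titration_index defined for 2-state groups only"
            )
        return 1


@dataclass
class BufferSet:
    """Charge-compensating buffer particles, collectively coupled.

    All buffers always carry the identical charge, interpolated between
    ``q_min`` and ``q_max`` by one collective lambda with its own
    fictitious mass.  Buffers absorb titration-induced charge changes via
    the global charge constraint, keeping the cell neutral.
    """

    atom_ids: list[int]
    q_min: float = -0.5
    q_max: float = 0.5
    collective_lambda: float = 0.5
    velocity: float = 0.0
    mass: float = 5.0
    # recorded metadata only: the toy engine keeps LJ forces off
    lj_sigma: float = 0.25
    lj_epsilon: float = 4.0

    def __post_init__(self):
        if not self.atom_ids:
            raise ConfigurationError("buffer set must contain at least one particle")
        if self.q_max <= self.q_min:
            raise ConfigurationError("buffer q_max must exceed q_min")

    @property
    def n_buffers(self) -> int:
        return len(self.atom_ids)

    @property
    def charge_span(self) -> float:
        return self.q_max - self.q_min

    def charge(self, collective_lambda: float | None = None) -> float:
        lam = self.collective_lambda if collective_lambda is None else collective_lambda
        return self.q_min + lam * self.charge_span


@dataclass
class ElectrostaticsSpec:
    """Electrostatics scheme: direct sum ('plain') or reaction field.

    The reaction-field kernel uses eps_RF = infinity so the energy is
    continuous at the cutoff.  ``box`` enables minimum-image periodicity
    in a cubic box (nm); open boundaries otherwise.
    """

    scheme: str = "plain"
    cutoff: float | None = None
    eps_r: float = 1.0
    box: float | None = None

    def __post_init__(self):
        if self.scheme not in ("plain", "reaction-field"):
            raise ConfigurationError(f"unknown electrostatics scheme {self.scheme!r}")
        if self.scheme == "reaction-field" and self.cutoff is None:
            raise ConfigurationError("reaction-field scheme requires a cutoff")
        if self.eps_r <= 0:
            raise ParameterError("eps_r must be positive")
        if self.box is not None and self.cutoff is not None and self.cutoff > self.box / 2:
            raise ConfigurationError("cutoff must not exceed half the box length")


@dataclass
class TitratableSystem:
    """Atoms, lambda-groups, optional buffers, and global settings."""

    atoms: list[Atom]
    groups: list[LambdaGroup] = field(default_factory=list)
    buffers: BufferSet | None = None
    electrostatics: ElectrostaticsSpec = field(default_factory=ElectrostaticsSpec)
    temperature: float = 300.0
    total_charge_target: float | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        self._validate_membership()
        if self.total_charge_target is None and self.buffers is not None:
            self.total_charge_target = total_charge(self)

    def _validate_membership(self):
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate atom ids")
        buffer_ids = set(self.buffers.atom_ids) if self.buffers else set()
        for gi, g in enumerate(self.groups):
            for aid in g.atom_ids:
                atom = self.atom_by_id(aid)
                if atom.group_id is None:
                    atom.group_id = gi
                elif atom.group_id != gi:
                    raise ConfigurationError(
                        f"atom {aid} assigned to coordinate outside its group"
                    )
                if aid in buffer_ids:
                    raise ConfigurationError(f"atom {aid} is both buffer and titratable")
        for a in self.atoms:
            if a.group_id is not None and a.group_id >= len(self.groups):
                raise ConfigurationError(f"atom {a.id}: group_id out of range")

    def atom_by_id(self, aid: int) -> Atom:
        for a in self.atoms:
            if a.id == aid:
                return a
        raise ConfigurationError(f"unknown atom id {aid}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def atom_index(self, aid: int) -> int:
        for i, a in enumerate(self.atoms):
            if a.id == aid:
                return i
        raise ConfigurationError(f"unknown atom id {aid}")

    # ---- lambda degree-of-freedom vector (group-major, buffer last) ----

    @property
    def n_lambda_dofs(self) -> int:
        n = sum(g.n_states for g in self.groups)
        if self.buffers is not None:
            n += 1
        return n

    def lambda_vector(self) -> np.ndarray:
        parts = [g.lambdas for g in self.groups]
        if self.buffers is not None:
            parts.append(np.array([self.buffers.collective_lambda]))
        return np.concatenate(parts) if parts else np.zeros(0)

    def set_lambda_vector(self, vec) -> None:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_lambda_dofs,):
            raise ConfigurationError("lambda vector length mismatch")
        i = 0
        for g in self.groups:
            g.set_lambdas(vec[i : i + g.n_states])
            i += g.n_states
        if self.buffers is not None:
            self.buffers.collective_lambda = float(vec[i])

    def lambda_masses(self) -> np.ndarray:
        parts = [np.array([c.mass for c in g.coordinates]) for g in self.groups]
        if self.buffers is not None:
            parts.append(np.array([self.buffers.mass]))
        return np.concatenate(parts) if parts else np.zeros(0)

    def dof_slices(self) -> list[slice]:
        """Slice of the lambda DOF vector belonging to each group."""
        out, i = [], 0
        for g in self.groups:
            out.append(slice(i, i + g.n_states))
            i += g.n_states
        return out

    def lambda_names(self) -> list[str]:
        names = []
        for gi, g in enumerate(self.groups):
            for k in range(g.n_states):
                names.append(g.coordinates[k].name or f"g{gi}.{k}")
        if self.buffers is not None:
            names.append("buffer")
        return names


def interpolated_charges(system: TitratableSystem, lambda_vector=None) -> np.ndarray:
    """Per-atom charge vector at the current (or given) lambda values.

    Titratable atoms get the state-weighted sum over their group's
    coordinates, buffers the collectively interpolated charge, everything
    else its fixed ``q_A``.
    """
    if lambda_vector is not None:
        vec = np.asarray(lambda_vector, dtype=float)
    else:
        vec = system.lambda_vector()
    q = np.array([a.q_A for a in system.atoms], dtype=float)
    for sl, g in zip(system.dof_slices(), system.groups):
        member_q = vec[sl] @ g.state_charges
        for aid, qa in zip(g.atom_ids, member_q):
            q[system.atom_index(aid)] = qa
    if system.buffers is not None:
        q_buf = system.buffers.charge(vec[-1])
        for aid in system.buffers.atom_ids:
            q[system.atom_index(aid)] = q_buf
    return q


def total_charge(system: TitratableSystem, lambda_vector=None) -> float:
    """Total interpolated charge of the system including buffers, in e."""
    return float(interpolated_charges(system, lambda_vector).sum())
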