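"""Deprotonated-fraction estimators, Henderson-Hasselbalch fits, campaigns.

Frames are classified by thresholds on the lambda coordinates: a
single-site frame is protonated when the titration lambda is below 0.2
and deprotonated when above 0.8; multisite frames are assigned to the
physical state whose lambda exceeds 0.8 (at most one can, under the
simplex constraint).  Mid-range frames are excluded from the counts.

The macroscopic deprotonated fraction of a multisite group counts
frames deprotonated at either tautomer;  the microscopic fraction of
tautomer k conditions on frames in either the fully protonated basin or
basin k, which makes each microscopic curve an exact two-state
Henderson-Hasselbalch titration with the microscopic pKa.

Fits use nonlinear least squares on S(pH) = 1 / (1 + 10^(pKa - pH))
with the pKa as the only free parameter; the error is the 95%
confidence half-width from the fit covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import NonIdentifiableError, UndefinedFractionError
from .model import TitratableSystem
from .dynamics import IntegratorSpec, LambdaTrajectory, RunPotentials, run_lambda_dynamics

__all__ = [
    "deprot_fraction_single",
    "deprot_fraction_multisite",
    "MultisiteFractions",
    "HHFit",
    "fit_hh",
    "henderson_hasselbalch",
    "TitrationResult",
    "titration_campaign",
]

DEFAULT_THRESHOLDS = (0.2, 0.8)


def deprot_fraction_single(lambda_series, thresholds=DEFAULT_THRESHOLDS):
    """Deprotonated fraction of a single-site lambda time series.

    Returns ``(S, n_prot, n_deprot)`` with
    ``S = N_deprot / (N_prot + N_deprot)``; frames between the
    thresholds are excluded from both counts.
    """
    lam = np.asarray(lambda_series, dtype=float)
    if lam.size == 0:
        raise UndefinedFractionError("empty lambda series")
    lo, hi = thresholds
    n_prot = int((lam < lo).sum())
    n_deprot = int((lam > hi).sum())
    if n_prot + n_deprot == 0:
        raise UndefinedFractionError(
            "no frames outside the mid-range: deprotonated fraction undefined"
        )
    return n_deprot / (n_prot + n_deprot), n_prot, n_deprot


@dataclass
class MultisiteFractions:
    """Frame counts and fractions for a multisite group.

    ``counts[k]`` is the number of frames assigned to physical state k
    (0 = fully protonated).  ``S_micro[k] = N_k / (N_0 + N_k)``.
    """

    counts: np.ndarray
    S_macro: float
    S_micro: dict = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return int(self.counts.sum())


def deprot_fraction_multisite(lambda_series, threshold: float = 0.8) -> MultisiteFractions:
    """Classify multisite frames and compute macro/microscopic fractions.

    ``lambda_series`` has shape (n_frames, n_states), rows on the
    simplex.  A frame belongs to state k when ``lambda_k > threshold``;
    with threshold >= 0.5 at most one coordinate can qualify (guarded).
    """
    lam = np.atleast_2d(np.asarray(lambda_series, dtype=float))
    n_states = lam.shape[1]
    above = lam > threshold
    if np.any(above.sum(axis=1) > 1):
        raise AssertionError(
            "two lambda values above threshold in one frame; impossible under "
            "the simplex constraint with threshold >= 0.5"
        )
    counts = above.sum(axis=0).astype(int)
    n_class = counts.sum()
    if n_class == 0:
        raise UndefinedFractionError("no classifiable frames in multisite series")
    S_macro = counts[1:].sum() / n_class
    S_micro = {}
    for k in range(1, n_states):
        denom = counts[0] + counts[k]
        S_micro[k] = counts[k] / denom if denom else np.nan
    return MultisiteFractions(counts=counts, S_macro=float(S_macro), S_micro=S_micro)


def henderson_hasselbalch(pH, pKa):
    """S(pH) = 1 / (1 + 10^(pKa - pH))."""
    return 1.0 / (1.0 + np.power(10.0, pKa - np.asarray(pH, dtype=float)))


@dataclass
class HHFit:
    """Result of a Henderson-Hasselbalch fit."""

    pKa: float
    ci95: float
    stderr: float
    n_points: int

    def predict(self, pH):
        return henderson_hasselbalch(pH, self.pKa)


def fit_hh(pH_values, S_values, S_errors=None, weighted: bool = False) -> HHFit:
    """Fit the titration curve; pKa is the only free parameter.

    Requires points on both sides of the transition.  With ``weighted``
    and positive ``S_errors``, inverse-variance weighting is applied.
    The 95% confidence half-width uses the t-distribution with n-1
    degrees of freedom.
    """
    pH = np.asarray(pH_values, dtype=float)
    S = np.asarray(S_values, dtype=float)
    ok = np.isfinite(S)
    pH, S = pH[ok], S[ok]
    if pH.size < 3:
        raise NonIdentifiableError("need at least three pH points")
    if S.max() - S.min() < 0.1 or S.min() > 0.95 or S.max() < 0.05:
        raise NonIdentifiableError(
            "titration data lie on a single plateau; pKa not identifiable"
        )
    sigma = None
    if weighted and S_errors is not None:
        sigma = np.clip(np.asarray(S_errors, dtype=float)[ok], 1e-4, None)
    popt, pcov = optimize.curve_fit(
        henderson_hasselbalch, pH, S, p0=[float(np.median(pH))], sigma=sigma,
        absolute_sigma=False,
    )
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    tval = stats.t.ppf(0.975, max(pH.size - 1, 1))
    return HHFit(pKa=float(popt[0]), ci95=tval * stderr, stderr=stderr, n_points=pH.size)


@dataclass
class TitrationResult:
    """Per-pH deprotonated fractions and the fitted pKa."""

    pH_values: np.ndarray
    S_deprot: np.ndarray
    S_err: np.ndarray
    pKa: float
    pKa_ci95: float
    n_replicas: int
    frames_used: np.ndarray          # post-equilibration frames per pH
    frames_discarded: np.ndarray     # equilibration frames per pH
    frames_classified: np.ndarray | None = None
    fit: HHFit | None = None
    micro: dict = field(default_factory=dict)       # tautomer k -> dict with S, S_err, fit
    replica_S: np.ndarray | None = None
    trajectory: LambdaTrajectory | None = None


def _initial_corner_states(system: TitratableSystem, pH_values, n_replicas):
    """Balanced end-state starts: replicas cycle through the corners.

    Starting every walker protonated would bias slowly mixing runs; the
    replicas of each pH therefore cycle deterministically through the
    physical corners of the group.
    """
    g = system.groups[0]
    K = system.n_lambda_dofs
    sl = system.dof_slices()[0]
    B = len(pH_values) * n_replicas
    lam = np.zeros((B, K))
    if system.buffers is not None:
        lam[:, -1] = system.buffers.collective_lambda
    w = 0
    for _ in range(len(pH_values)):
        for r in range(n_replicas):
            corner = r % g.n_states
            lam[w, sl.start + corner] = 1.0
            w += 1
    return lam


def titration_campaign(
    system: TitratableSystem,
    pH_values,
    n_replicas: int = 5,
    n_steps: int = 2_000_000,
    seed: int = 0,
    potentials: RunPotentials | None = None,
    integrator: IntegratorSpec | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    equilibration_fraction: float = 0.1,
    keep_trajectory: bool = False,
) -> TitrationResult:
    """Simulate a full titration and fit the Henderson-Hasselbalch curve.

    One batched lambda-dynamics run propagates every (pH, replica)
    walker simultaneously on the frozen-atom landscape.  Per (pH,
    replica) the deprotonated fraction is computed after discarding the
    equilibration prefix; per-pH means are pooled counts over replicas
    with the SEM taken across replicas.  For a multisite group the
    macroscopic curve is fitted as the headline pKa and each microscopic
    curve is fitted as well.

    Fully reproducible from ``seed``; replicas differ only through the
    integrator's random stream and their starting corner.
    """
    if len(system.groups) != 1:
        raise NotImplementedError("campaigns support single-group systems")
    g = system.groups[0]
    sl = system.dof_slices()[0]
    pH_values = np.asarray(pH_values, dtype=float)
    pots = potentials or RunPotentials()
    pots = RunPotentials(
        bias=pots.bias, vmm=pots.vmm, pH=np.repeat(pH_values, n_replicas),
        k1=pots.k1, x0=pots.x0, include_coulomb=pots.include_coulomb,
    )
    spec = integrator or IntegratorSpec(n_steps=n_steps, seed=seed)
    if spec.n_steps != n_steps or spec.seed != seed:
        spec = IntegratorSpec(
            dt=spec.dt, n_steps=n_steps, atom_thermostat=spec.atom_thermostat,
            lambda_thermostat=spec.lambda_thermostat, seed=seed,
            lambda_output_interval=spec.lambda_output_interval,
        )
    B = pH_values.size * n_replicas
    init = _initial_corner_states(system, pH_values, n_replicas)
    replica_idx = np.tile(np.arange(n_replicas), pH_values.size)
    traj = run_lambda_dynamics(
        system, pots, spec, n_walkers=B, initial_lambdas=init, replica=replica_idx,
    )
    n_frames = traj.lambdas.shape[1]
    n_equil = int(equilibration_fraction * n_frames)

    multisite = g.n_states > 2
    S_mean = np.empty(pH_values.size)
    S_err = np.empty(pH_values.size)
    used = np.zeros(pH_values.size, dtype=int)
    discarded = np.zeros(pH_values.size, dtype=int)
    classified = np.zeros(pH_values.size, dtype=int)
    replica_S = np.full((pH_values.size, n_replicas), np.nan)
    micro_S = {k: np.full(pH_values.size, np.nan) for k in range(1, g.n_states)} if multisite else {}
    micro_err = {k: np.full(pH_values.size, np.nan) for k in range(1, g.n_states)} if multisite else {}
    bad_points = []

    for i in range(pH_values.size):
        walkers = slice(i * n_replicas, (i + 1) * n_replicas)
        series = traj.lambdas[walkers, n_equil:, :]
        discarded[i] = n_replicas * n_equil
        used[i] = n_replicas * (n_frames - n_equil)
        try:
            if multisite:
                per_rep = [
                    deprot_fraction_multisite(series[r, :, sl], thresholds[1])
                    for r in range(n_replicas)
                ]
                pooled = deprot_fraction_multisite(
                    series[:, :, sl].reshape(-1, g.n_states), thresholds[1]
                )
                S_mean[i] = pooled.S_macro
                replica_S[i] = [f.S_macro for f in per_rep]
                classified[i] = pooled.n_classified
                for k in micro_S:
                    micro_S[k][i] = pooled.S_micro[k]
                    vals = np.array([f.S_micro[k] for f in per_rep])
                    micro_err[k][i] = (
                        np.nanstd(vals, ddof=1) / np.sqrt(np.isfinite(vals).sum())
                        if np.isfinite(vals).sum() > 1 else np.nan
                    )
            else:
                tix = sl.start + g.titration_index
                per_rep = [
                    deprot_fraction_single(series[r, :, tix], thresholds)
                    for r in range(n_replicas)
                ]
                S_pooled, n_p, n_d = deprot_fraction_single(
                    series[:, :, tix].ravel(), thresholds
                )
                S_mean[i] = S_pooled
                replica_S[i] = [f[0] for f in per_rep]
                classified[i] = n_p + n_d
            S_err[i] = (
                np.std(replica_S[i], ddof=1) / np.sqrt(n_replicas)
                if n_replicas > 1 else 0.0
            )
        except UndefinedFractionError:
            bad_points.append(pH_values[i])
            S_mean[i] = np.nan
            S_err[i] = np.nan
    if bad_points:
        warnings.warn(
            f"pH points {bad_points} had no classifiable frames and were "
            "excluded from the fit",
            stacklevel=2,
        )
    try:
        fit = fit_hh(pH_values, S_mean, S_err)
    except NonIdentifiableError as exc:
        warnings.warn(f"pKa fit skipped: {exc}", stacklevel=2)
        fit = HHFit(pKa=float("nan"), ci95=float("nan"), stderr=float("nan"),
                    n_points=int(np.isfinite(S_mean).sum()))
    micro = {}
    for k in micro_S:
        try:
            mfit = fit_hh(pH_values, micro_S[k], micro_err[k])
        except NonIdentifiableError as exc:
            warnings.warn(f"microscopic pKa fit skipped (state {k}): {exc}",
                          stacklevel=2)
            mfit = HHFit(pKa=float("nan"), ci95=float("nan"), stderr=float("nan"),
                         n_points=int(np.isfinite(micro_S[k]).sum()))
        micro[k] = {"S": micro_S[k], "S_err": micro_err[k], "fit": mfit}
    return TitrationResult(
        pH_values=pH_values,
        S_deprot=S_mean,
        S_err=S_err,
        pKa=fit.pKa,
        pKa_ci95=fit.ci95,
        n_replicas=n_replicas,
        frames_used=used,
        frames_discarded=discarded,
        frames_classified=classified,
        fit=fit,
        micro=micro,
        replica_S=replica_S,
        trajectory=traj if keep_trajectory else None,
    )
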