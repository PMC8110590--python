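"""Target analysis: fitting a compartmental scheme to a TA surface.

The rate constants of a :class:`~ocpkin.kinetics.KineticScheme` are
optimized in the log domain; at each iterate the compartment populations
come from the analytic kinetic solver and the species-associated spectra
(SAS) are eliminated by per-wavelength linear least squares (variable
projection).  The initial condition places all population in the first
excited compartment (``X2(0) = 1`` for the five-state scheme).

Identifiability caveat: with fully free SAS, the branch rates out of the
hot intermediate are constrained by the data only through the products
``k_c * SAS_c`` — rescaling a branch rate and its SAS in opposite
directions (compensating within the branch total) leaves the model surface
exactly invariant.  The fit therefore pins the identifiable combinations
(the eigen-lifetimes and the branch total) while the branch split follows
the template's starting ratios; the confidence intervals report the flat
directions as very wide.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dataset import TADataset
from .kinetics import (
    BranchingYields,
    IRFModel,
    KineticScheme,
    PopulationTrajectory,
    RateMatrix,
    branching_yields,
    build_rate_matrix,
    eigen_lifetimes,
    solve_populations,
)

__all__ = [
    "TargetKineticModel",
    "TargetFitResults",
    "fit_target",
    "transform_sas_to_dads",
]


@dataclass
class TargetFitResults:
    """Fitted scheme, SAS, populations and diagnostics from a target fit."""

    scheme: KineticScheme
    rates: dict[str, float]  # 1/ps
    rate_stderr: dict[str, float]
    sas: np.ndarray  # (n_compartments, n_wavelengths)
    concentrations: PopulationTrajectory
    yields: BranchingYields | None
    irf: IRFModel
    wavelengths: np.ndarray
    residual: np.ndarray
    rms_residual: float
    converged: bool
    n_iterations: int
    notes: list[str] = field(default_factory=list)

    @property
    def lifetimes(self) -> np.ndarray:
        return eigen_lifetimes(build_rate_matrix(self.scheme))

    @property
    def model_surface(self) -> np.ndarray:
        return self.concentrations.populations.T @ self.sas

    def confidence_intervals(self, n_sigma: float = 2.0) -> dict[str, tuple[float, float]]:
        out = {}
        for name, k in self.rates.items():
            se = self.rate_stderr[name]
            out[name] = (max(k - n_sigma * se, 0.0), k + n_sigma * se)
        return out

    def summary(self) -> str:
        lines = [
            "Target (SAS) fit",
            "=" * 56,
            f"compartments:    {', '.join(self.scheme.compartments)}",
            f"IRF t0 / FWHM:   {self.irf.t0:.5g} ps / {self.irf.fwhm:.5g} ps",
            f"RMS residual:    {self.rms_residual:.5g} mOD",
            f"converged:       {self.converged} ({self.n_iterations} evaluations)",
            "-" * 56,
            f"{'rate':>14} {'value (1/ps)':>14} {'lifetime (ps)':>14} {'std err':>10}",
        ]
        for name, k in self.rates.items():
            se = self.rate_stderr[name]
            se_txt = f"{se:.3g}" if se < 1e3 * k else "unbounded"
            lines.append(f"{name:>14} {k:>14.5g} {1.0 / k:>14.5g} {se_txt:>10}")
        if self.yields is not None:
            y = self.yields
            lines.append("-" * 56)
            lines.append(
                f"branch yields:   phi_S1={y.phi_s1:.3f}  phi_ICT={y.phi_ict:.3f}  "
                f"phi_S*={y.phi_sstar:.3f}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


class TargetKineticModel:
    """Scheme-constrained model of a TA surface.

    Parameters
    ----------
    data : cropped, chirp-corrected :class:`~ocpkin.dataset.TADataset`.
    scheme : template providing topology and starting rates.
    free_rates : iterable of rate names (``"SH->S1"``, ``"S1->S0"``, ...) to
        optimize, or ``"all"`` (default).
    irf : instrument response (fixed unless ``fit_irf=True``).
    branch_policy : ``"tied"`` (default) optimizes the total depopulation
        rate of the branch point while holding the branch fractions at the
        template's split — the split is structurally unidentifiable with
        free SAS, so letting it float only lets it wander along an exactly
        flat direction.  ``"free"`` floats every branch rate independently
        and reports the flat directions through very wide standard errors.
    """

    MAX_ITER = 500
    FTOL = 1e-12

    def __init__(
        self,
        data: TADataset,
        scheme: KineticScheme,
        free_rates="all",
        irf: IRFModel | None = None,
        fit_irf: bool = False,
        branch_policy: str = "tied",
    ) -> None:
        self.data = data
        self.scheme = scheme
        all_names = scheme.rate_names()
        if free_rates == "all":
            self.free_names = list(all_names)
        else:
            self.free_names = list(free_rates)
            unknown = set(self.free_names) - set(all_names)
            if unknown:
                raise ValueError(f"unknown rate names: {sorted(unknown)}")
        self.irf = irf or IRFModel(t0=0.0, fwhm=float(data.meta.get("irf_fwhm_ps", 0.0)))
        self.fit_irf = bool(fit_irf) and self.irf.fwhm > 0
        if branch_policy not in ("tied", "free"):
            raise ValueError("branch_policy must be 'tied' or 'free'")
        # group the free transfers out of a common branch point so that only
        # the (identifiable) total rate is optimized under the tied policy
        self.branch_groups: list[list[str]] = []
        if branch_policy == "tied":
            by_source: dict[str, list[str]] = {}
            for name in self.free_names:
                src, dst = name.split("->")
                if dst != "S0":
                    by_source.setdefault(src, []).append(name)
            for src, names in by_source.items():
                if len(names) > 1:
                    self.branch_groups.append(names)
        grouped = {n for grp in self.branch_groups for n in grp}
        self.solo_names = [n for n in self.free_names if n not in grouped]

    @property
    def _n_theta_rates(self) -> int:
        return len(self.solo_names) + len(self.branch_groups)

    def _unpack(self, theta: np.ndarray) -> tuple[KineticScheme, IRFModel]:
        start = self.scheme.rate_values()
        rates = dict(
            zip(self.solo_names, np.exp(theta[: len(self.solo_names)]))
        )
        for g, grp in enumerate(self.branch_groups):
            total = float(np.exp(theta[len(self.solo_names) + g]))
            tmpl_total = sum(start[n] for n in grp)
            for n in grp:
                rates[n] = total * start[n] / tmpl_total
        scheme = self.scheme.with_rates(rates)
        if self.fit_irf:
            irf = IRFModel(t0=theta[-2], fwhm=float(np.exp(theta[-1])))
        else:
            irf = self.irf
        return scheme, irf

    def _model_parts(
        self, scheme: KineticScheme, irf: IRFModel
    ) -> tuple[PopulationTrajectory, np.ndarray]:
        K = build_rate_matrix(scheme)
        traj = solve_populations(K, scheme.initial_vector(), self.data.delays, irf)
        C = traj.populations.T  # (delays, compartments)
        sas, *_ = np.linalg.lstsq(C, self.data.delta_A, rcond=None)
        return traj, sas

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        scheme, irf = self._unpack(theta)
        traj, sas = self._model_parts(scheme, irf)
        return (self.data.delta_A - traj.populations.T @ sas).ravel()

    def fit(self) -> TargetFitResults:
        start = self.scheme.rate_values()
        theta0 = np.log(
            [start[n] for n in self.solo_names]
            + [sum(start[n] for n in grp) for grp in self.branch_groups]
        )
        if self.fit_irf:
            theta0 = np.concatenate([theta0, [self.irf.t0, np.log(self.irf.fwhm)]])
        sol = least_squares(
            self._residuals,
            theta0,
            method="trf",
            ftol=self.FTOL,
            xtol=1e-12,
            max_nfev=self.MAX_ITER * max(theta0.size, 1),
        )
        scheme, irf = self._unpack(sol.x)
        traj, sas = self._model_parts(scheme, irf)
        residual = self.data.delta_A - traj.populations.T @ sas
        rms = float(np.sqrt(np.mean(residual**2)))

        notes: list[str] = []
        converged = bool(sol.status > 0)
        if not converged:
            notes.append("optimizer hit the iteration cap without converging")

        # linearized covariance at the optimum; tiny singular values mark
        # structurally flat (unidentifiable) directions and blow up the
        # corresponding standard errors rather than failing
        m = residual.size
        p = sol.x.size
        dof = max(m - p - sas.size, 1)
        sigma2 = float(np.sum(residual**2)) / dof
        U, s, Vt = np.linalg.svd(sol.jac, full_matrices=False)
        s_floor = np.finfo(float).eps * max(sol.jac.shape) * (s[0] if s.size else 1.0)
        s_safe = np.maximum(s, s_floor)
        var_theta = sigma2 * np.einsum("ji,j->i", Vt**2, 1.0 / s_safe**2)
        theta_se = np.sqrt(var_theta)

        rates = scheme.rate_values()
        stderr = {}
        for i, name in enumerate(self.solo_names):
            stderr[name] = rates[name] * float(theta_se[i])  # delta method, log domain
        for g, grp in enumerate(self.branch_groups):
            se = float(theta_se[len(self.solo_names) + g])
            for name in grp:  # fractions held fixed: share the total's error
                stderr[name] = rates[name] * se
        for name in set(rates) - set(stderr):
            stderr[name] = 0.0
        wide = sorted(
            n for n in stderr if rates[n] > 0 and stderr[n] > 10 * rates[n]
        )
        if wide:
            notes.append(
                "structurally flat (unidentifiable) rate direction(s): "
                + ", ".join(wide)
                + "; confidence intervals there are effectively unbounded"
            )

        try:
            yields = branching_yields(scheme)
        except ValueError:
            yields = None

        return TargetFitResults(
            scheme=scheme,
            rates=rates,
            rate_stderr=stderr,
            sas=sas,
            concentrations=traj,
            yields=yields,
            irf=irf,
            wavelengths=self.data.wavelengths.copy(),
            residual=residual,
            rms_residual=rms,
            converged=converged,
            n_iterations=int(sol.nfev),
            notes=notes,
        )


def fit_target(
    ds: TADataset,
    scheme_template: KineticScheme,
    free_rates="all",
    irf_guess: IRFModel | None = None,
    fit_irf: bool = False,
    branch_policy: str = "tied",
) -> TargetFitResults:
    """Functional wrapper around :class:`TargetKineticModel`."""
    return TargetKineticModel(
        ds,
        scheme_template,
        free_rates=free_rates,
        irf=irf_guess,
        fit_irf=fit_irf,
        branch_policy=branch_policy,
    ).fit()


def transform_sas_to_dads(
    K: RateMatrix, x0: np.ndarray, sas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert species spectra to decay-associated spectra.

    Writing ``X(t) = V diag(exp(lambda_l t)) V^-1 x0``, the surface
    ``sum_i SAS_i(lambda) X_i(t)`` regroups into
    ``sum_l DADS_l(lambda) exp(lambda_l t)`` with
    ``DADS = (V diag(V^-1 x0))^T @ SAS``.

    Returns ``(lifetimes, dads)`` with rows ordered by ascending lifetime.
    """
    sas = np.asarray(sas, dtype=float)
    if sas.shape[0] != K.n:
        raise ValueError("SAS rows must match the number of compartments")
    from .kinetics import _eig_with_jitter

    lam, V = _eig_with_jitter(K.matrix)
    c = np.linalg.solve(V, np.asarray(x0, dtype=complex))
    A = V * c[np.newaxis, :]  # (compartment, mode)
    dads = np.real(A.T @ sas)
    tau = -1.0 / np.real(lam)
    order = np.argsort(tau)
    return tau[order], dads[order]
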