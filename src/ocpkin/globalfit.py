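"""Global analysis: simultaneous multiexponential fitting of a TA surface.

All wavelengths share a common set of lifetimes; the wavelength-dependent
amplitudes (decay-associated difference spectra, DADS) are eliminated at
every step of the nonlinear optimization by ordinary linear least squares
(variable projection).  Nonlinear parameters are the log-lifetimes and,
optionally, the IRF centre and width.

Usage follows the model/results idiom::

    model = GlobalKineticModel(ds, n_components=3, irf=IRFModel(fwhm=0.026))
    res = model.fit()
    res.lifetimes, res.dads, res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dataset import TADataset
from .kinetics import IRFModel, irf_convolved_exponential

__all__ = ["GlobalKineticModel", "GlobalFitResults", "fit_global"]


def exponential_basis(
    taus: np.ndarray, delays: np.ndarray, irf: IRFModel
) -> np.ndarray:
    """IRF-convolved exponential basis, shape ``(n_delays, n_components)``."""
    C = np.empty((delays.size, taus.size))
    for i, tau in enumerate(taus):
        C[:, i] = irf_convolved_exponential(-1.0 / tau, delays, irf)
    return C


@dataclass
class GlobalFitResults:
    """Lifetimes, DADS and diagnostics from a global fit."""

    lifetimes: np.ndarray  # ps, ascending
    dads: np.ndarray  # (n_components, n_wavelengths), mOD
    irf: IRFModel
    wavelengths: np.ndarray
    delays: np.ndarray
    residual: np.ndarray  # (n_delays, n_wavelengths)
    rms_residual: float
    converged: bool
    n_iterations: int
    notes: list[str] = field(default_factory=list)

    @property
    def model_surface(self) -> np.ndarray:
        C = exponential_basis(self.lifetimes, self.delays, self.irf)
        return C @ self.dads

    def summary(self) -> str:
        lines = [
            "Global (DADS) fit",
            "=" * 48,
            f"components:      {self.lifetimes.size}",
            f"IRF t0 / FWHM:   {self.irf.t0:.5g} ps / {self.irf.fwhm:.5g} ps",
            f"RMS residual:    {self.rms_residual:.5g} mOD",
            f"converged:       {self.converged} ({self.n_iterations} evaluations)",
            "-" * 48,
            f"{'component':>10} {'lifetime (ps)':>14} {'max |DADS| (mOD)':>18}",
        ]
        for i, tau in enumerate(self.lifetimes):
            lines.append(
                f"{i + 1:>10d} {tau:>14.5g} {np.max(np.abs(self.dads[i])):>18.5g}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


class GlobalKineticModel:
    """Shared-lifetime multiexponential model of a TA surface.

    Parameters
    ----------
    data : chirp-corrected :class:`~ocpkin.dataset.TADataset`.
    n_components : number of exponential components (>= 1, <= n_delays / 3).
    irf : starting IRF; ``fit_irf=True`` (default) lets t0 and FWHM float.
    """

    MAX_ITER = 500
    FTOL = 1e-10

    def __init__(
        self,
        data: TADataset,
        n_components: int,
        irf: IRFModel | None = None,
        fit_irf: bool = True,
    ) -> None:
        if n_components < 1:
            raise ValueError("need at least one component")
        if n_components > data.delays.size / 3:
            raise ValueError("too many components for the delay grid")
        self.data = data
        self.n_components = int(n_components)
        self.irf = irf or IRFModel(t0=0.0, fwhm=float(data.meta.get("irf_fwhm_ps", 0.0)))
        self.fit_irf = bool(fit_irf) and self.irf.fwhm > 0

    # ------------------------------------------------------------------
    def _default_tau_guess(self) -> np.ndarray:
        t = self.data.delays
        t_lo = max(float(np.min(t[t > 0], initial=0.01)), 1e-3)
        t_hi = max(float(t[-1]) / 3.0, 10 * t_lo)
        return np.geomspace(2 * t_lo, t_hi, self.n_components)

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, IRFModel]:
        taus = np.exp(theta[: self.n_components])
        if self.fit_irf:
            irf = IRFModel(t0=theta[-2], fwhm=float(np.exp(theta[-1])))
        else:
            irf = self.irf
        return taus, irf

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        taus, irf = self._unpack(theta)
        C = exponential_basis(taus, self.data.delays, irf)
        A, *_ = np.linalg.lstsq(C, self.data.delta_A, rcond=None)
        return (self.data.delta_A - C @ A).ravel()

    def fit(self, tau_guess=None) -> GlobalFitResults:
        taus0 = (
            np.asarray(tau_guess, dtype=float)
            if tau_guess is not None
            else self._default_tau_guess()
        )
        if taus0.size != self.n_components:
            raise ValueError("tau_guess length must equal n_components")
        theta0 = np.log(taus0)
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
        taus, irf = self._unpack(sol.x)
        notes: list[str] = []
        order = np.argsort(taus)
        taus = taus[order]
        ratios = taus[1:] / taus[:-1]
        if np.any(ratios < 1.05):
            msg = (
                "nearly collinear exponentials: lifetime ratio "
                f"{float(np.min(ratios)):.4g} < 1.05"
            )
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        C = exponential_basis(taus, self.data.delays, irf)
        dads, *_ = np.linalg.lstsq(C, self.data.delta_A, rcond=None)
        residual = self.data.delta_A - C @ dads
        converged = bool(sol.status > 0)
        if not converged:
            notes.append("optimizer hit the iteration cap without converging")
        return GlobalFitResults(
            lifetimes=taus,
            dads=dads,
            irf=irf,
            wavelengths=self.data.wavelengths.copy(),
            delays=self.data.delays.copy(),
            residual=residual,
            rms_residual=float(np.sqrt(np.mean(residual**2))),
            converged=converged,
            n_iterations=int(sol.nfev),
            notes=notes,
        )


def fit_global(
    ds: TADataset,
    n_components: int,
    irf_guess: IRFModel | None = None,
    tau_guess=None,
    fit_irf: bool = True,
) -> GlobalFitResults:
    """Functional wrapper around :class:`GlobalKineticModel`."""
    return GlobalKineticModel(ds, n_components, irf_guess, fit_irf=fit_irf).fit(
        tau_guess
    )
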