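"""Photoconversion cycle kinetics and Arrhenius analysis.

The orange <-> red photocycle is modelled as a minimal two-state scheme:
under actinic light the red fraction R obeys
``dR/dt = k_OR (1 - R) - k_RO R`` and in the dark ``dR/dt = -k_RO R``,
solved piecewise in closed form.  The observable is the optical density at
550 nm, ``OD550 = baseline + dOD_max * R(t)``.

Rate constants measured across temperature yield the apparent activation
energy from an ordinary least-squares line in the Arrhenius plot
(ln k versus 1/T): ``E_A = -slope * R_gas`` in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .simulate import GAS_CONSTANT_KCAL

__all__ = [
    "PhotoKineticTrace",
    "ArrheniusResult",
    "ArrheniusModel",
    "simulate_photoconversion",
    "fit_relaxation",
    "fit_conversion",
    "arrhenius_fit",
]


@dataclass
class PhotoKineticTrace:
    """An OD-550 time course with its actinic-light schedule.

    ``schedule`` lists non-overlapping ``(on, off)`` intervals in seconds
    during which the actinic light is on.
    """

    times: np.ndarray  # s, ascending
    od550: np.ndarray  # absorbance units
    temperature: float  # K
    schedule: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od550 = np.asarray(self.od550, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")
        if self.times.shape != self.od550.shape:
            raise ValueError("times and od550 must have the same length")
        last_end = -math.inf
        for on, off in self.schedule:
            if not on < off:
                raise ValueError("schedule interval must satisfy on < off")
            if on < last_end:
                raise ValueError("schedule intervals must not overlap")
            last_end = off

    def light_on(self, t: np.ndarray) -> np.ndarray:
        mask = np.zeros(np.shape(t), dtype=bool)
        for on, off in self.schedule:
            mask |= (t >= on) & (t < off)
        return mask


def _red_fraction(
    times: np.ndarray,
    k_or: float,
    k_ro: float,
    schedule: list[tuple[float, float]],
    r0: float,
) -> np.ndarray:
    """Piecewise closed-form red fraction on an arbitrary time grid."""
    times = np.asarray(times, dtype=float)
    # breakpoints where the light switches
    edges = sorted({t for on, off in schedule for t in (on, off)})
    edges = [e for e in edges if times[0] < e < times[-1]]
    seg_starts = [times[0]] + edges
    seg_ends = edges + [times[-1]]

    def on_at(t: float) -> bool:
        return any(on <= t < off for on, off in schedule)

    out = np.empty_like(times)
    r = r0
    for t0, t1 in zip(seg_starts, seg_ends):
        mask = (times >= t0) & (times <= t1) if t1 == times[-1] else (times >= t0) & (times < t1)
        dt = times[mask] - t0
        if on_at(t0):
            k_tot = k_or + k_ro
            r_inf = k_or / k_tot if k_tot > 0 else 0.0
            out[mask] = r_inf + (r - r_inf) * np.exp(-k_tot * dt)
            r = r_inf + (r - r_inf) * math.exp(-k_tot * (t1 - t0))
        else:
            out[mask] = r * np.exp(-k_ro * dt)
            r = r * math.exp(-k_ro * (t1 - t0))
    return out


def simulate_photoconversion(
    k_or: float,
    k_ro: float,
    schedule: list[tuple[float, float]],
    times: np.ndarray,
    r0: float = 0.0,
    temperature: float = 298.15,
    baseline: float = 0.0,
    dod_max: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> PhotoKineticTrace:
    """Closed-form two-state photoconversion trace.

    ``noise_sigma`` adds i.i.d. Gaussian noise (absorbance units); a seed is
    then required.
    """
    if k_or < 0 or k_ro < 0:
        raise ValueError("rate constants must be >= 0")
    r = _red_fraction(np.asarray(times, dtype=float), k_or, k_ro, schedule, r0)
    od = baseline + dod_max * r
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("noisy simulation requires a seed")
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sigma, size=od.shape)
    return PhotoKineticTrace(times, od, temperature, list(schedule))


def _dark_segment(trace: PhotoKineticTrace) -> np.ndarray:
    """Mask of samples in the dark after the last light interval."""
    if trace.schedule:
        t_off = max(off for _, off in trace.schedule)
        return trace.times >= t_off
    return np.ones_like(trace.times, dtype=bool)


def fit_relaxation(trace: PhotoKineticTrace) -> tuple[float, float]:
    """Single-exponential + offset fit of the dark (relaxation) segment.

    Returns ``(k_RO, standard_error)`` in 1/s.  Raises if the dark segment
    carries no decaying signal.
    """
    mask = _dark_segment(trace)
    t = trace.times[mask]
    y = trace.od550[mask]
    if t.size < 4:
        raise ValueError("no relaxation detected: dark segment too short")
    amp0 = y[0] - y[-1]
    span = np.max(y) - np.min(y)
    if span == 0 or amp0 <= 0.05 * span:
        raise ValueError("no relaxation detected: dark segment is not decaying")
    t0 = t[0]
    k0 = 1.0 / max(t[-1] - t0, 1e-9)
    # crude rate guess from the 1/e point
    target = y[-1] + amp0 / math.e
    below = np.nonzero(y <= target)[0]
    if below.size:
        k0 = 1.0 / max(t[below[0]] - t0, (t[1] - t0))

    def resid(p):
        a, k, c = p
        return a * np.exp(-k * (t - t0)) + c - y

    sol = least_squares(
        resid,
        x0=[amp0, k0, y[-1]],
        bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        method="trf",
    )
    a, k, c = sol.x
    if k <= 0 or a <= 0:
        raise ValueError("no relaxation detected")
    dof = max(t.size - 3, 1)
    sigma2 = float(np.sum(sol.fun**2)) / dof
    cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
    return float(k), float(np.sqrt(cov[1, 1]))


def fit_conversion(trace: PhotoKineticTrace, k_ro: float) -> tuple[float, float]:
    """Fit the forward (orange -> red) rate on the light-on rise.

    ``k_RO`` is held fixed (typically from :func:`fit_relaxation`).  Returns
    ``(k_OR, standard_error)``; a saturated (flat) rise is reported with a
    wide standard error rather than an exception.
    """
    mask = trace.light_on(trace.times)
    t = trace.times[mask]
    y = trace.od550[mask]
    if t.size < 4:
        raise ValueError("no light-on segment in the trace")
    t0 = t[0]
    rise = y[-1] - y[0]
    span = max(np.max(np.abs(y)), 1.0)

    def resid(p):
        log_kor, dod, base = p
        k_or = math.exp(log_kor)
        r = _red_fraction(t, k_or, k_ro, [(t0, t[-1] + 1.0)], r0=0.0)
        return base + dod * r - y

    k0 = max(rise, 1e-6) / max((t[-1] - t0) * max(span, 1e-12), 1e-9)
    sol = least_squares(
        resid, x0=[math.log(max(k0, 1e-6)), max(rise, 1e-6) * 2, y[0]], method="lm"
    )
    k_or = float(math.exp(sol.x[0]))
    dof = max(t.size - 3, 1)
    sigma2 = float(np.sum(sol.fun**2)) / dof
    cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
    se = k_or * float(np.sqrt(max(cov[0, 0], 0.0)))
    # saturated / flat rise: the fitted net rise is indistinguishable from
    # the noise floor, so the rate is unconstrained -> wide interval, not
    # a hard failure
    r_end = _red_fraction(
        np.array([t0, t[-1]]), k_or, k_ro, [(t0, t[-1] + 1.0)], r0=0.0
    )[-1]
    net_rise = abs(float(sol.x[1]) * r_end)
    if net_rise <= 5.0 * math.sqrt(sigma2) or not math.isfinite(se):
        se = math.inf
    return k_or, se


@dataclass
class ArrheniusResult:
    """Activation energy from a ln k versus 1/T line."""

    ea_kcal: float
    ln_a: float
    rates: list[tuple[float, float]]  # (T K, k 1/s)
    rate_stderr: list[float]
    ea_stderr: float
    r_squared: float
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Arrhenius fit",
            "=" * 44,
            f"E_A:             {self.ea_kcal:.4g} +/- {self.ea_stderr:.2g} kcal/mol",
            f"ln(A):           {self.ln_a:.4g}",
            f"R^2:             {self.r_squared:.6f}",
            "-" * 44,
            f"{'T (K)':>10} {'k (1/s)':>12} {'std err':>10}",
        ]
        for (T, k), se in zip(self.rates, self.rate_stderr):
            lines.append(f"{T:>10.2f} {k:>12.5g} {se:>10.2g}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


class ArrheniusModel:
    """OLS of ln k on 1/T over per-temperature rate constants."""

    def __init__(self, rates, stderr=None) -> None:
        rates = [(float(T), float(k)) for T, k in rates]
        if len(rates) < 2:
            raise ValueError("need rates at >= 2 temperatures")
        for T, k in rates:
            if T <= 0 or k <= 0:
                raise ValueError("temperatures and rates must be positive")
        self.rates = rates
        self.stderr = list(stderr) if stderr is not None else [0.0] * len(rates)

    def fit(self) -> ArrheniusResult:
        notes: list[str] = []
        rates = self.rates
        temps = np.array([T for T, _ in rates])
        if np.unique(temps).size != temps.size:
            merged: dict[float, list[float]] = {}
            for T, k in rates:
                merged.setdefault(T, []).append(math.log(k))
            rates = [(T, math.exp(np.mean(lks))) for T, lks in sorted(merged.items())]
            notes.append("duplicate temperatures collapsed to their mean ln k")
            temps = np.array([T for T, _ in rates])
        x = 1.0 / temps
        y = np.log([k for _, k in rates])
        n = x.size
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ beta
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        slope_se = 0.0
        if n > 2:
            sigma2 = ss_res / (n - 2)
            sxx = float(np.sum((x - x.mean()) ** 2))
            slope_se = math.sqrt(sigma2 / sxx)
        return ArrheniusResult(
            ea_kcal=float(-beta[1] * GAS_CONSTANT_KCAL),
            ln_a=float(beta[0]),
            rates=rates,
            rate_stderr=self.stderr[: len(rates)],
            ea_stderr=float(slope_se * GAS_CONSTANT_KCAL),
            r_squared=r2,
            notes=notes,
        )


def arrhenius_fit(rates, stderr=None) -> ArrheniusResult:
    """Functional wrapper around :class:`ArrheniusModel`."""
    return ArrheniusModel(rates, stderr).fit()
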