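"""Steady-state absorption spectra: orange/red decomposition and vibronic structure.

Dark-adapted OCP samples are mixtures of the orange (compact) and red
(photoactivated) spectral forms.  The red fraction is estimated by
subtracting the photoactivated spectrum with the largest scaling factor
that keeps the remainder (the inferred orange spectrum) non-negative over
the carotenoid S0->S2 band, then converting the scale to an area fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

__all__ = [
    "AbsorptionSpectrum",
    "StateDecomposition",
    "decompose_dark_spectrum",
    "vibronic_ratio",
    "read_spectrum",
    "write_spectrum",
]


@dataclass
class AbsorptionSpectrum:
    """Two-column spectrum: wavelengths (nm, ascending) and absorbance (AU)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("axis and absorbance lengths differ")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    def resample(self, wavelengths: np.ndarray) -> "AbsorptionSpectrum":
        return AbsorptionSpectrum(
            wavelengths,
            np.interp(wavelengths, self.wavelengths, self.absorbance),
        )


def read_spectrum(path) -> AbsorptionSpectrum:
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, absorbance)")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wl)
    return AbsorptionSpectrum(wl[order], ab[order])


def write_spectrum(s: AbsorptionSpectrum, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"wavelength_nm": s.wavelengths, "absorbance": s.absorbance}
    ).to_csv(path, index=False, float_format="%.12g")


@dataclass
class StateDecomposition:
    """Result of the orange/red two-state subtraction."""

    scale: float
    fraction_red: float
    fraction_orange: float
    window: tuple[float, float]
    residual: AbsorptionSpectrum  # inferred orange spectrum on the window
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Orange/red spectral decomposition",
            "=" * 44,
            f"window:          {self.window[0]:g}-{self.window[1]:g} nm",
            f"scaling factor:  {self.scale:.6g}",
            f"red fraction:    {self.fraction_red:.4f} ({100 * self.fraction_red:.1f}%)",
            f"orange fraction: {self.fraction_orange:.4f} ({100 * self.fraction_orange:.1f}%)",
        ]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def decompose_dark_spectrum(
    dark: AbsorptionSpectrum,
    red_ref: AbsorptionSpectrum,
    window: tuple[float, float] = (400.0, 600.0),
    epsilon: float | None = None,
) -> StateDecomposition:
    """Subtract the red reference from a dark-adapted spectrum.

    The scaling factor is the largest ``s >= 0`` such that
    ``dark - s * red_ref >= -epsilon`` everywhere in the window (bisection to
    1e-6); the red fraction is ``s * integral(red_ref) / integral(dark)`` over
    the window (trapezoidal), so fractions are area-based.  ``epsilon``
    defaults to 0.5% of the dark-spectrum maximum in the window.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    wmask = (dark.wavelengths >= lo) & (dark.wavelengths <= hi)
    if not wmask.any():
        raise ValueError("window contains no wavelength samples")
    wl = dark.wavelengths[wmask]
    d = dark.absorbance[wmask]
    if not np.array_equal(red_ref.wavelengths, dark.wavelengths):
        red_ref = red_ref.resample(dark.wavelengths)
    r = red_ref.absorbance[wmask]
    if np.max(r) <= 0:
        raise ValueError("red reference has no absorbance in the window")
    if epsilon is None:
        epsilon = 0.005 * float(np.max(d))

    def floor_of(s: float) -> float:
        return float(np.min(d - s * r))

    notes: list[str] = []
    s_hi = 1.0
    while floor_of(s_hi) >= -epsilon and s_hi < 1e9:
        s_hi *= 2.0
    s_lo = 0.0
    if floor_of(0.0) < -epsilon:
        notes.append("dark spectrum already below -epsilon; scale pinned to 0")
        s = 0.0
    else:
        while s_hi - s_lo > 1e-6:
            mid = 0.5 * (s_lo + s_hi)
            if floor_of(mid) >= -epsilon:
                s_lo = mid
            else:
                s_hi = mid
        s = s_lo
    if s == 0.0 and "pinned" not in " ".join(notes):
        notes.append("zero scaling factor: no red contribution detected")

    area_red = float(np.trapezoid(s * r, wl))
    area_dark = float(np.trapezoid(d, wl))
    frac_red = min(max(area_red / area_dark, 0.0), 1.0) if area_dark > 0 else 0.0
    return StateDecomposition(
        scale=s,
        fraction_red=frac_red,
        fraction_orange=1.0 - frac_red,
        window=(lo, hi),
        residual=AbsorptionSpectrum(wl, d - s * r),
        notes=notes,
    )


def vibronic_ratio(
    s: AbsorptionSpectrum, window: tuple[float, float] = (400.0, 600.0)
) -> float:
    """Depth of the vibronic modulation of the S0->S2 band.

    Returns ``(A_peak - A_trough) / A_peak`` for the two highest adjacent
    local maxima in the window (``A_peak`` the higher one, ``A_trough`` the
    minimum between them), or 0 for a structureless band.
    """
    lo, hi = window
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError("window contains no wavelength samples")
    y = s.absorbance[mask]
    (imax,) = argrelextrema(y, np.greater_equal, order=2)
    # collapse plateaus
    peaks = []
    for i in imax:
        if not peaks or i - peaks[-1] > 2:
            peaks.append(int(i))
    if len(peaks) < 2:
        return 0.0
    heights = y[peaks]
    # two highest adjacent maxima
    best = None
    for a, b in zip(peaks[:-1], peaks[1:]):
        pair_height = min(y[a], y[b])
        if best is None or pair_height > best[0]:
            best = (pair_height, a, b)
    _, a, b = best
    trough = float(np.min(y[a : b + 1]))
    peak = float(max(y[a], y[b]))
    if peak <= 0:
        return 0.0
    return max((peak - trough) / peak, 0.0)
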