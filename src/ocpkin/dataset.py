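"""Transient-absorption surfaces: file I/O, cropping and chirp correction.

A :class:`TADataset` holds a delay x wavelength matrix of absorbance changes
(mOD).  The on-disk dialect is a plain CSV whose top-left cell is the literal
``nm\\ps``, first row the delay axis (ps), first column the wavelength axis
(nm) and body the signal in mOD.

The supercontinuum probe arrives earlier at some wavelengths than others
(group-velocity dispersion), so time zero is wavelength dependent.  A
:class:`ChirpModel` is a polynomial t0(lambda) in the reduced variable
``(lambda - lambda_c) / 100 nm``; estimation uses the per-wavelength signal
onset (50% rise to the early-time extremum) and correction re-interpolates
each wavelength column onto the common delay axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TADataset",
    "ChirpModel",
    "read_ta_matrix",
    "write_ta_matrix",
    "crop",
    "estimate_chirp",
    "apply_chirp_correction",
]

_CORNER = "nm\\ps"


@dataclass
class TADataset:
    """A delta-absorbance surface with ascending axes.

    Attributes
    ----------
    wavelengths : probe wavelengths in nm, strictly ascending.
    delays : pump-probe delays in ps, strictly ascending.
    delta_A : signal in mOD, shape ``(n_delays, n_wavelengths)``.
    meta : acquisition metadata (pump wavelength, nominal IRF FWHM, label...).
    warnings : processing notices attached by pipeline stages.
    """

    wavelengths: np.ndarray
    delays: np.ndarray
    delta_A: np.ndarray
    meta: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError("wavelength axis must be a non-empty 1-D array")
        if self.delays.ndim != 1 or self.delays.size == 0:
            raise ValueError("delay axis must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly ascending")
        if self.delta_A.shape != (self.delays.size, self.wavelengths.size):
            raise ValueError(
                f"delta_A shape {self.delta_A.shape} does not match axes "
                f"({self.delays.size}, {self.wavelengths.size})"
            )
        if not np.all(np.isfinite(self.delta_A)):
            raise ValueError("delta_A contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta_A.shape


@dataclass(frozen=True)
class ChirpModel:
    """Polynomial group delay t0(lambda) = sum_j a_j * u^j, u = (lambda - lambda_c)/100."""

    lambda_c: float
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0 or len(self.coefficients) > 5:
            raise ValueError("chirp polynomial order must be 0..4")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("chirp coefficients must be finite")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def t0(self, wavelengths: np.ndarray) -> np.ndarray:
        u = (np.asarray(wavelengths, dtype=float) - self.lambda_c) / 100.0
        return np.polynomial.polynomial.polyval(u, self.coefficients)

    @classmethod
    def zero(cls, lambda_c: float = 550.0) -> "ChirpModel":
        return cls(lambda_c, (0.0,))


class TAParseError(ValueError):
    """Raised for malformed matrix-CSV files."""


def read_ta_matrix(path) -> TADataset:
    """Read a TA surface from the matrix-CSV dialect.

    Axes are sorted ascending (rows/columns permuted together with the body
    if the file is unsorted); duplicate axis values are rejected.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TAParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.name != _CORNER:
        raise TAParseError(
            f"{path}: corner cell must be {_CORNER!r}, got {df.index.name!r}"
        )
    try:
        delays = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TAParseError(f"{path}: non-numeric delay header: {exc}") from exc
    try:
        wavelengths = df.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TAParseError(f"{path}: non-numeric wavelength column: {exc}") from exc
    body = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(body))
    if bad.size:
        r, c = bad[0]
        raise TAParseError(
            f"{path}: non-numeric or missing cell at wavelength row "
            f"{wavelengths[r]:g}, delay column {delays[c]:g}"
        )
    if np.unique(delays).size != delays.size:
        raise TAParseError(f"{path}: duplicate delay values in header")
    if np.unique(wavelengths).size != wavelengths.size:
        raise TAParseError(f"{path}: duplicate wavelength values")
    wi = np.argsort(wavelengths)
    di = np.argsort(delays)
    # file layout is wavelength-rows x delay-columns; the in-memory layout is
    # delays x wavelengths
    return TADataset(
        wavelengths=wavelengths[wi],
        delays=delays[di],
        delta_A=body[np.ix_(wi, di)].T,
    )


def write_ta_matrix(ds: TADataset, path) -> None:
    """Write a TA surface in the matrix-CSV dialect (>= 12 significant digits)."""
    df = pd.DataFrame(
        ds.delta_A.T,
        index=pd.Index(ds.wavelengths, name=_CORNER),
        columns=ds.delays,
    )
    df.to_csv(path, float_format="%.15g")


def crop(
    ds: TADataset,
    lambda_min: float,
    lambda_max: float,
    t_min: float,
    t_max: float,
) -> TADataset:
    """Restrict the surface to closed wavelength/delay windows."""
    if not lambda_min < lambda_max:
        raise ValueError("need lambda_min < lambda_max")
    if not t_min < t_max:
        raise ValueError("need t_min < t_max")
    wmask = (ds.wavelengths >= lambda_min) & (ds.wavelengths <= lambda_max)
    tmask = (ds.delays >= t_min) & (ds.delays <= t_max)
    if not wmask.any() or not tmask.any():
        raise ValueError("crop window contains no grid points")
    return TADataset(
        wavelengths=ds.wavelengths[wmask],
        delays=ds.delays[tmask],
        delta_A=ds.delta_A[np.ix_(tmask, wmask)],
        meta=dict(ds.meta),
        warnings=list(ds.warnings),
    )


def _onset_time(delays: np.ndarray, column: np.ndarray) -> float:
    """Delay at which |signal| first reaches half its early-time extremum.

    The column is lightly smoothed (5-sample moving average) so that noise
    cannot trigger a spuriously early crossing; the crossing itself is
    located by linear interpolation between grid points.
    """
    from scipy.ndimage import uniform_filter1d

    a = np.abs(uniform_filter1d(column, size=min(5, column.size), mode="nearest"))
    ipk = int(np.argmax(a))
    half = 0.5 * a[ipk]
    above = np.nonzero(a[: ipk + 1] >= half)[0]
    i = int(above[0])
    if i == 0:
        return float(delays[0])
    # interpolate the upward crossing between i-1 and i
    f = (half - a[i - 1]) / (a[i] - a[i - 1])
    return float(delays[i - 1] + f * (delays[i] - delays[i - 1]))


def estimate_chirp(
    ds: TADataset, order: int = 2, lambda_c: float | None = None
) -> ChirpModel:
    """Fit a polynomial group delay to per-wavelength signal onsets.

    The onset proxy is parameter-free: the delay where ``|dA|`` first reaches
    50% of its extremum.  Columns with negligible signal (< 5% of the surface
    maximum) are excluded from the fit.
    """
    if order > 4 or order < 0:
        raise ValueError("chirp order must be 0..4")
    peak = np.max(np.abs(ds.delta_A))
    if peak == 0:
        raise ValueError("cannot estimate chirp from an all-zero surface")
    if lambda_c is None:
        lambda_c = float(np.median(ds.wavelengths))
    strong = np.max(np.abs(ds.delta_A), axis=0) >= 0.05 * peak
    if strong.sum() < order + 1:
        raise ValueError("too few wavelengths with signal to fit the chirp")
    onsets = np.array(
        [
            _onset_time(ds.delays, ds.delta_A[:, j])
            for j in np.nonzero(strong)[0]
        ]
    )
    u = (ds.wavelengths[strong] - lambda_c) / 100.0
    coeffs = np.polynomial.polynomial.polyfit(u, onsets, order)
    return ChirpModel(lambda_c, tuple(coeffs))


def apply_chirp_correction(ds: TADataset, chirp: ChirpModel) -> TADataset:
    """Shift every wavelength column by -t0(lambda) onto the common delay axis.

    Uses piecewise-linear interpolation; samples shifted outside the measured
    range are zero-filled and noted in ``warnings``.  A zero model returns
    the dataset unchanged, bitwise.
    """
    t0 = chirp.t0(ds.wavelengths)
    if not np.all(np.isfinite(t0)):
        raise ValueError("chirp model is not finite over the dataset range")
    if np.all(t0 == 0.0):
        return replace(ds)
    span = ds.delays[-1] - ds.delays[0]
    notes = list(ds.warnings)
    if np.max(np.abs(t0)) > 0.5 * span:
        msg = (
            f"chirp shift up to {np.max(np.abs(t0)):.3g} ps exceeds half the "
            f"delay span ({span:.3g} ps)"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    corrected = np.empty_like(ds.delta_A)
    filled = 0
    for j in range(ds.wavelengths.size):
        src = ds.delays + t0[j]
        corrected[:, j] = np.interp(
            src, ds.delays, ds.delta_A[:, j], left=0.0, right=0.0
        )
        filled += int(np.count_nonzero((src < ds.delays[0]) | (src > ds.delays[-1])))
    if filled:
        notes.append(f"{filled} samples shifted out of range were zero-filled")
    return TADataset(
        wavelengths=ds.wavelengths.copy(),
        delays=ds.delays.copy(),
        delta_A=corrected,
        meta=dict(ds.meta),
        warnings=notes,
    )
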