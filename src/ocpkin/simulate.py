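"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* :func:`simulate_ta` — transient-absorption surfaces built from a kinetic
  scheme and per-compartment species spectra, ``dA(t, lambda) =
  sum_i SAS_i(lambda) X_i(t)``, with Gaussian-IRF convolution, optional
  polynomial chirp and additive i.i.d. Gaussian noise;
* :func:`simulate_arrhenius_rates` — rate constants on an Arrhenius line
  with multiplicative log-normal scatter;
* band-shape helpers (:class:`BandSpec`, :func:`make_sas_library`) — Gaussian
  bands with optional vibronic progressions at fixed energy spacing.

Every generator takes a mandatory integer seed; identical configuration and
seed reproduce the output bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ChirpModel, TADataset
from .kinetics import (
    IRFModel,
    KineticScheme,
    build_rate_matrix,
    ocp_five_state_scheme,
    solve_populations,
)

__all__ = [
    "BandSpec",
    "SimulationConfig",
    "make_sas_library",
    "simulate_ta",
    "simulate_arrhenius_rates",
    "ocpww_preset",
    "wt_preset",
    "parallel3_preset",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL = 1.98720425e-3


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorption/ESA band, optionally with a vibronic progression.

    Replicas are spaced by ``vib_spacing_cm`` wavenumbers towards higher
    energy with geometric amplitude decay (factor ``vib_decay`` per step).
    Amplitude is signed: negative bands model ground-state bleaching.
    """

    center_nm: float
    fwhm_nm: float
    amplitude: float
    vib_spacing_cm: float = 0.0
    vib_replicas: int = 0
    vib_decay: float = 0.6

    def __post_init__(self) -> None:
        if not (self.fwhm_nm > 0):
            raise ValueError("band FWHM must be > 0")
        if self.vib_replicas < 0:
            raise ValueError("vibronic replica count must be >= 0")
        if self.vib_replicas > 0 and not (self.vib_spacing_cm > 0):
            raise ValueError("vibronic spacing must be > 0 when replicas are used")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        sigma = self.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        nu0 = 1e7 / self.center_nm  # cm^-1
        for j in range(self.vib_replicas + 1):
            center = 1e7 / (nu0 + j * self.vib_spacing_cm)
            amp = self.amplitude * self.vib_decay**j
            out += amp * np.exp(-((wl - center) ** 2) / (2 * sigma**2))
        return out


@dataclass
class SimulationConfig:
    """Everything needed to synthesize one TA surface, reproducibly."""

    scheme: KineticScheme
    sas_bands: dict[str, list[BandSpec]]
    wavelengths: np.ndarray
    delays: np.ndarray
    irf: IRFModel
    seed: int
    chirp: ChirpModel | None = None
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        if self.wavelengths.size == 0 or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be non-empty ascending")
        if self.delays.size == 0 or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delay grid must be non-empty ascending")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        missing = set(self.scheme.compartments) - set(self.sas_bands)
        if missing:
            raise ValueError(f"no SAS bands given for compartments {sorted(missing)}")


def make_sas_library(
    specs: dict[str, list[BandSpec]],
    wavelengths: np.ndarray,
    compartments: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Evaluate per-compartment band lists on a wavelength grid.

    Returns a matrix of shape ``(n_compartments, n_wavelengths)`` ordered by
    ``compartments`` (or by the dict order when omitted).
    """
    order = compartments if compartments is not None else tuple(specs)
    wl = np.asarray(wavelengths, dtype=float)
    sas = np.zeros((len(order), wl.size))
    for i, name in enumerate(order):
        for band in specs[name]:
            sas[i] += band.evaluate(wl)
    return sas


def simulate_ta(cfg: SimulationConfig) -> TADataset:
    """Synthesize a TA surface from a configuration.

    Populations come from the analytic kinetic solver.  Chirp is applied
    exactly by shifting the IRF centre per wavelength (the measured surface
    has its time zero at ``t0 + chirp(lambda)``), so the distortion carries
    no interpolation error and :func:`~ocpkin.dataset.apply_chirp_correction`
    with the true model inverts it up to interpolation.
    """
    K = build_rate_matrix(cfg.scheme)
    x0 = cfg.scheme.initial_vector()
    sas = make_sas_library(cfg.sas_bands, cfg.wavelengths, cfg.scheme.compartments)

    if cfg.chirp is None or np.all(np.asarray(cfg.chirp.coefficients) == 0.0):
        traj = solve_populations(K, x0, cfg.delays, cfg.irf)
        surface = traj.populations.T @ sas  # (delays, wavelengths)
    else:
        t0 = cfg.chirp.t0(cfg.wavelengths)
        surface = np.empty((cfg.delays.size, cfg.wavelengths.size))
        for j in range(cfg.wavelengths.size):
            irf_j = IRFModel(t0=cfg.irf.t0 + t0[j], fwhm=cfg.irf.fwhm)
            traj = solve_populations(K, x0, cfg.delays, irf_j)
            surface[:, j] = traj.populations.T @ sas[:, j]

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        surface = surface + rng.normal(0.0, cfg.noise_sigma, size=surface.shape)

    meta = dict(cfg.meta)
    meta.setdefault("irf_fwhm_ps", cfg.irf.fwhm)
    meta.setdefault("seed", cfg.seed)
    return TADataset(
        wavelengths=cfg.wavelengths.copy(),
        delays=cfg.delays.copy(),
        delta_A=surface,
        meta=meta,
    )


def simulate_arrhenius_rates(
    ea_kcal: float,
    ln_a: float,
    temps_k,
    rel_sigma: float,
    seed: int,
) -> list[tuple[float, float]]:
    """Rate constants ``k = exp(ln_a - ea / (R T)) * exp(eta)`` with
    ``eta ~ Normal(0, rel_sigma)``, seeded."""
    temps = np.asarray(temps_k, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, rel_sigma, size=temps.size) if rel_sigma > 0 else np.zeros(temps.size)
    k = np.exp(ln_a - ea_kcal / (GAS_CONSTANT_KCAL * temps) + eta)
    return list(zip(temps.tolist(), k.tolist()))


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _default_delays() -> np.ndarray:
    """Dense linear sampling through time zero, log-spaced out to 200 ps.

    10 fs steps over [-1, 1] ps resolve the 26 fs pump and the group-delay
    sweep of the probe; 80 log-spaced points carry the decays out to 200 ps.
    """
    early = np.linspace(-1.0, 1.0, 201)
    late = np.geomspace(1.02, 200.0, 80)
    return np.concatenate([early, late])


def _default_wavelengths() -> np.ndarray:
    return np.arange(400.0, 911.0, 5.0)


def _gsb_bands(amplitude: float, vib_decay: float = 0.6) -> list[BandSpec]:
    """Ground-state bleach: negative vibronic progression of the S0->S2 band."""
    return [
        BandSpec(
            center_nm=497.0,
            fwhm_nm=28.0,
            amplitude=-amplitude,
            vib_spacing_cm=1400.0,
            vib_replicas=2,
            vib_decay=vib_decay,
        )
    ]


def _ocp_sas_bands(sstar_gain: float = 1.0) -> dict[str, list[BandSpec]]:
    """Band placements for the five OCP compartments.

    Gaussian stand-ins for the observed signatures: S2-SM ESA on the red
    edge (>= 860 nm), a broad "mixed state" ESA, the S1-SN ESA near 650 nm,
    ICT ESA above 700 nm and the S* signature near 550-560 nm, each riding on
    a negative vibronic ground-state bleach.
    """
    return {
        "S2": _gsb_bands(6.0)
        + [BandSpec(center_nm=900.0, fwhm_nm=120.0, amplitude=7.0)],
        "SH": _gsb_bands(6.0)
        + [BandSpec(center_nm=620.0, fwhm_nm=160.0, amplitude=5.0)],
        "S1": _gsb_bands(7.0)
        + [BandSpec(center_nm=650.0, fwhm_nm=60.0, amplitude=10.0)],
        "ICT": _gsb_bands(5.0)
        + [BandSpec(center_nm=750.0, fwhm_nm=85.0, amplitude=8.0)],
        "Sstar": _gsb_bands(6.0, vib_decay=0.75)
        + [BandSpec(center_nm=555.0, fwhm_nm=55.0, amplitude=6.0 * sstar_gain)],
    }


def ocpww_preset(seed: int, noise_sigma: float | None = None) -> SimulationConfig:
    """The OCP^WW study condition.

    Lifetimes 0.07 ps (S2), 0.15 ps (S_H), 3.0 ps (S1), 0.34 ps (ICT) and
    9.3 ps (S*); branch fractions 0.50/0.25/0.25 so the S* yield is 25%;
    pump-limited Gaussian IRF of 0.026 ps FWHM.  ``noise_sigma=None`` selects
    SNR 100 (sigma = max |signal| / 100).
    """
    scheme = ocp_five_state_scheme()
    cfg = SimulationConfig(
        scheme=scheme,
        sas_bands=_ocp_sas_bands(),
        wavelengths=_default_wavelengths(),
        delays=_default_delays(),
        irf=IRFModel(t0=0.0, fwhm=0.026),
        seed=seed,
        noise_sigma=0.0,
        meta={"label": "OCPWW synthetic", "pump_nm": 520.0},
    )
    if noise_sigma is None:
        noiseless = simulate_ta(cfg)
        noise_sigma = float(np.max(np.abs(noiseless.delta_A)) / 100.0)
    cfg.noise_sigma = noise_sigma
    return cfg


def wt_preset(seed: int, noise_sigma: float | None = None) -> SimulationConfig:
    """A WT-OCP-like condition: low S* yield (5%), faster ground-state recovery."""
    k_tot = 1 / 0.15
    scheme = ocp_five_state_scheme(
        k1=0.70 * k_tot,
        k_ict=0.25 * k_tot,
        k_sstar=0.05 * k_tot,
        m1=1 / 3.5,
    )
    cfg = SimulationConfig(
        scheme=scheme,
        sas_bands=_ocp_sas_bands(sstar_gain=0.8),
        wavelengths=_default_wavelengths(),
        delays=_default_delays(),
        irf=IRFModel(t0=0.0, fwhm=0.026),
        seed=seed,
        noise_sigma=0.0,
        meta={"label": "WT OCP synthetic", "pump_nm": 520.0},
    )
    if noise_sigma is None:
        noiseless = simulate_ta(cfg)
        noise_sigma = float(np.max(np.abs(noiseless.delta_A)) / 100.0)
    cfg.noise_sigma = noise_sigma
    return cfg


def parallel3_preset(seed: int, noise_sigma: float | None = None) -> SimulationConfig:
    """Three independent compartments with lifetimes 0.3 / 3.0 / 9.3 ps.

    A parallel scheme whose decay-associated spectra equal the species
    spectra scaled by the initial populations, used for global-analysis
    recovery tests.
    """
    scheme = KineticScheme(
        compartments=("fast", "mid", "slow"),
        transfers=[],
        losses=[("fast", 1 / 0.3), ("mid", 1 / 3.0), ("slow", 1 / 9.3)],
        x0={"fast": 1 / 3, "mid": 1 / 3, "slow": 1 / 3},
    )
    bands = {
        "fast": [BandSpec(center_nm=880.0, fwhm_nm=110.0, amplitude=8.0)]
        + _gsb_bands(4.0),
        "mid": [BandSpec(center_nm=650.0, fwhm_nm=60.0, amplitude=10.0)]
        + _gsb_bands(6.0),
        "slow": [BandSpec(center_nm=555.0, fwhm_nm=55.0, amplitude=7.0)]
        + _gsb_bands(5.0, vib_decay=0.75),
    }
    cfg = SimulationConfig(
        scheme=scheme,
        sas_bands=bands,
        wavelengths=_default_wavelengths(),
        delays=_default_delays(),
        irf=IRFModel(t0=0.0, fwhm=0.026),
        seed=seed,
        noise_sigma=0.0,
        meta={"label": "parallel 3-component synthetic"},
    )
    if noise_sigma is None:
        noiseless = simulate_ta(cfg)
        noise_sigma = float(np.max(np.abs(noiseless.delta_A)) / 100.0)
    cfg.noise_sigma = noise_sigma
    return cfg


def orange_red_reference(
    wavelengths: np.ndarray | None = None,
    window: tuple[float, float] = (400.0, 600.0),
):
    """Reference orange and red steady-state spectra (area-normalized).

    Orange: vibronically structured S0->S2 band (0-0 near 497 nm, ~1400 1/cm
    progression); red: broad unstructured band near 530 nm.  Both are scaled
    to unit trapezoidal area over ``window`` so that two-state mixtures have
    area fractions equal to the mixing fractions.
    """
    from .spectra import AbsorptionSpectrum

    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else np.arange(350.0, 701.0, 1.0)
    )
    orange = BandSpec(
        497.0, 32.0, 1.0, vib_spacing_cm=1400.0, vib_replicas=2, vib_decay=0.8
    ).evaluate(wl)
    red = BandSpec(530.0, 120.0, 1.0).evaluate(wl)
    m = (wl >= window[0]) & (wl <= window[1])
    orange /= np.trapezoid(orange[m], wl[m])
    red /= np.trapezoid(red[m], wl[m])
    return AbsorptionSpectrum(wl, orange), AbsorptionSpectrum(wl, red)


def simulate_dark_mixture(
    fraction_red: float,
    seed: int,
    noise_sigma: float = 0.0,
    wavelengths: np.ndarray | None = None,
):
    """A dark-adapted spectrum as an orange/red mixture, plus the red reference.

    Returns ``(dark, red_ref)``; the mixture is by area fraction over the
    default 400-600 nm window.
    """
    from .spectra import AbsorptionSpectrum

    if not (0.0 <= fraction_red <= 1.0):
        raise ValueError("fraction_red must lie in [0, 1]")
    orange, red = orange_red_reference(wavelengths)
    dark = (1.0 - fraction_red) * orange.absorbance + fraction_red * red.absorbance
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dark = dark + rng.normal(0.0, noise_sigma, size=dark.shape)
    return AbsorptionSpectrum(orange.wavelengths, dark), red


PRESETS = {
    "ocpww": ocpww_preset,
    "wt": wt_preset,
    "parallel3": parallel3_preset,
}
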