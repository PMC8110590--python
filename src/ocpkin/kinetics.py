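"""Compartmental first-order kinetics for carotenoid excited-state dynamics.

The central model is the five-state branched scheme used for the Orange
Carotenoid Protein (OCP): photoexcitation populates S2, which decays into a
hot intermediate ("mixed state") S_H; S_H branches into S1, an intramolecular
charge-transfer (ICT) state and the long-lived S* state, each of which decays
to the ground state S0.  The ground state is implicit: conservation reads
``sum(X_i) + X_S0 = 1``.

Populations are solved analytically through the eigendecomposition of the
rate matrix K (convention ``dX/dt = K @ X``), with optional convolution by a
Gaussian instrument response function (IRF) in closed form.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfcx

__all__ = [
    "KineticScheme",
    "RateMatrix",
    "IRFModel",
    "PopulationTrajectory",
    "BranchingYields",
    "ocp_five_state_scheme",
    "build_rate_matrix",
    "eigen_lifetimes",
    "solve_populations",
    "branching_yields",
    "irf_convolved_exponential",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Names of the five excited-state compartments, in solver order.
FIVE_STATE_ORDER = ("S2", "SH", "S1", "ICT", "Sstar")


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: center ``t0`` (ps) and ``fwhm`` (ps).

    ``fwhm == 0`` means a delta-function response (no convolution).
    """

    t0: float = 0.0
    fwhm: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.t0) or not np.isfinite(self.fwhm):
            raise ValueError("IRF parameters must be finite")
        if self.fwhm < 0:
            raise ValueError("IRF FWHM must be >= 0")

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA


@dataclass
class KineticScheme:
    """A first-order compartment graph.

    Parameters
    ----------
    compartments : ordered compartment names (unique).
    transfers : list of ``(source, target, rate)`` inter-compartment flows,
        rates in 1/ps, strictly positive.
    losses : list of ``(source, rate)`` decays to the implicit ground state.
    x0 : initial populations (dimensionless probabilities); missing
        compartments start at zero.
    """

    compartments: tuple[str, ...]
    transfers: list[tuple[str, str, float]] = field(default_factory=list)
    losses: list[tuple[str, float]] = field(default_factory=list)
    x0: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.compartments = tuple(self.compartments)
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("compartment names must be unique")
        names = set(self.compartments)
        for src, dst, k in self.transfers:
            if src == dst:
                raise ValueError(f"self-transfer {src!r} -> {dst!r} rejected")
            if src not in names or dst not in names:
                raise ValueError(f"unknown compartment in transfer {src!r} -> {dst!r}")
            if not (k > 0):
                raise ValueError(f"transfer rate {src}->{dst} must be > 0, got {k}")
        for src, k in self.losses:
            if src not in names:
                raise ValueError(f"unknown compartment in loss {src!r}")
            if not (k > 0):
                raise ValueError(f"loss rate from {src} must be > 0, got {k}")
        for name, p in self.x0.items():
            if name not in names:
                raise ValueError(f"unknown compartment in x0: {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"initial population of {name} outside [0, 1]")
        if sum(self.x0.values()) > 1.0 + 1e-12:
            raise ValueError("initial populations must sum to <= 1")

    @property
    def n(self) -> int:
        return len(self.compartments)

    def initial_vector(self) -> np.ndarray:
        return np.array([self.x0.get(c, 0.0) for c in self.compartments])

    def rate(self, source: str, target: str | None = None) -> float:
        """Rate of ``source -> target`` (or ``source -> ground`` if None)."""
        if target is None:
            for src, k in self.losses:
                if src == source:
                    return k
            raise KeyError(f"no ground loss from {source!r}")
        for src, dst, k in self.transfers:
            if src == source and dst == target:
                return k
        raise KeyError(f"no transfer {source!r} -> {target!r}")

    def with_rates(self, rates: dict[str, float]) -> "KineticScheme":
        """Return a copy with named rates replaced.

        Transfer rates are keyed ``"src->dst"``, ground losses ``"src->S0"``.
        """
        transfers = [
            (s, d, rates.get(f"{s}->{d}", k)) for s, d, k in self.transfers
        ]
        losses = [(s, rates.get(f"{s}->S0", k)) for s, k in self.losses]
        return KineticScheme(self.compartments, transfers, losses, dict(self.x0))

    def rate_names(self) -> list[str]:
        names = [f"{s}->{d}" for s, d, _ in self.transfers]
        names += [f"{s}->S0" for s, _ in self.losses]
        return names

    def rate_values(self) -> dict[str, float]:
        vals = {f"{s}->{d}": k for s, d, k in self.transfers}
        vals.update({f"{s}->S0": k for s, k in self.losses})
        return vals

    # ------------------------------------------------------------------ io
    def to_json(self) -> str:
        return json.dumps(
            {
                "compartments": list(self.compartments),
                "transfers": [[s, d, k] for s, d, k in self.transfers],
                "losses": [[s, k] for s, k in self.losses],
                "x0": dict(self.x0),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "KineticScheme":
        obj = json.loads(text)
        return cls(
            compartments=tuple(obj["compartments"]),
            transfers=[(s, d, float(k)) for s, d, k in obj.get("transfers", [])],
            losses=[(s, float(k)) for s, k in obj.get("losses", [])],
            x0={k: float(v) for k, v in obj.get("x0", {}).items()},
        )


@dataclass(frozen=True)
class RateMatrix:
    """Square rate matrix K with ``dX/dt = K @ X``.

    Columns are source compartments: ``K[i, j] >= 0`` for ``i != j`` is the
    flow j -> i, and ``K[j, j]`` is minus the total outflow from j (including
    the loss to the implicit ground state), so each column sum equals minus
    the ground-loss rate of that compartment.
    """

    matrix: np.ndarray
    compartments: tuple[str, ...]

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("rate matrix must be square")
        if K.shape[0] != len(self.compartments):
            raise ValueError("compartment names do not match matrix size")
        off = K - np.diag(np.diag(K))
        if np.any(off < -1e-15):
            raise ValueError("off-diagonal rate-matrix entries must be >= 0")
        if np.any(K.sum(axis=0) > 1e-12):
            raise ValueError("column sums must be <= 0 (ground loss)")
        object.__setattr__(self, "matrix", K)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def ground_losses(self) -> np.ndarray:
        """Per-compartment ground-loss rates, recovered from column sums."""
        return -self.matrix.sum(axis=0)


@dataclass
class PopulationTrajectory:
    """Compartment populations X(t) plus the implicit ground state."""

    delays: np.ndarray
    populations: np.ndarray  # (n_compartments, n_delays)
    compartments: tuple[str, ...]

    @property
    def ground(self) -> np.ndarray:
        """Recovered ground-state population ``1 - sum_i X_i``."""
        return 1.0 - self.populations.sum(axis=0)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.populations[self.compartments.index(name)]


@dataclass(frozen=True)
class BranchingYields:
    """Branch fractions of the hot intermediate: phi_c = k_c / sum(k)."""

    phi_s1: float
    phi_ict: float
    phi_sstar: float

    def __post_init__(self) -> None:
        for phi in (self.phi_s1, self.phi_ict, self.phi_sstar):
            if not (0.0 < phi < 1.0):
                raise ValueError("branch yields must lie in (0, 1)")
        if abs(self.phi_s1 + self.phi_ict + self.phi_sstar - 1.0) > 1e-12:
            raise ValueError("branch yields must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"S1": self.phi_s1, "ICT": self.phi_ict, "Sstar": self.phi_sstar}


def ocp_five_state_scheme(
    k2: float = 1 / 0.07,
    k1: float | None = None,
    k_ict: float | None = None,
    k_sstar: float | None = None,
    m1: float = 1 / 3.0,
    m_ict: float = 1 / 0.34,
    m_sstar: float = 1 / 9.3,
) -> KineticScheme:
    """Default five-state OCP scheme, S2 -> SH -> {S1, ICT, S*} -> ground.

    Default rates correspond to lifetimes of 0.07 ps (S2), 0.15 ps (S_H,
    total branch depletion), 3.0 ps (S1), 0.34 ps (ICT) and 9.3 ps (S*),
    with branch fractions 0.50 / 0.25 / 0.25 for S1 / ICT / S*; the initial
    condition places all population in S2 (``X2(0) = 1``).
    """
    if k1 is None and k_ict is None and k_sstar is None:
        k_tot = 1 / 0.15
        k1, k_ict, k_sstar = 0.50 * k_tot, 0.25 * k_tot, 0.25 * k_tot
    if k1 is None or k_ict is None or k_sstar is None:
        raise ValueError("provide all three branch rates or none")
    return KineticScheme(
        compartments=FIVE_STATE_ORDER,
        transfers=[
            ("S2", "SH", k2),
            ("SH", "S1", k1),
            ("SH", "ICT", k_ict),
            ("SH", "Sstar", k_sstar),
        ],
        losses=[("S1", m1), ("ICT", m_ict), ("Sstar", m_sstar)],
        x0={"S2": 1.0},
    )


def build_rate_matrix(scheme: KineticScheme) -> RateMatrix:
    """Assemble K from a scheme; columns are sources, rows targets."""
    n = scheme.n
    idx = {c: i for i, c in enumerate(scheme.compartments)}
    K = np.zeros((n, n))
    for src, dst, k in scheme.transfers:
        K[idx[dst], idx[src]] += k
        K[idx[src], idx[src]] -= k
    for src, k in scheme.losses:
        K[idx[src], idx[src]] -= k
    return RateMatrix(K, scheme.compartments)


def eigen_lifetimes(K: RateMatrix) -> np.ndarray:
    """Characteristic lifetimes tau_i = -1/lambda_i, sorted ascending (ps)."""
    lam = np.linalg.eigvals(K.matrix)
    if np.any(np.abs(lam) < 1e-12):
        raise ValueError("non-decaying mode: zero eigenvalue in rate matrix")
    tau = -1.0 / np.real(lam)
    if np.any(tau <= 0):
        raise ValueError("growing mode: positive eigenvalue in rate matrix")
    return np.sort(tau)


def irf_convolved_exponential(
    lam: float, t: np.ndarray, irf: IRFModel
) -> np.ndarray:
    """Exponential ``exp(lam * t) * theta(t)`` convolved with a Gaussian IRF.

    For a delta IRF this is the causal exponential; for a Gaussian of width
    sigma centred at t0 the closed form is

        0.5 * exp(lam*(t - t0) + lam^2 sigma^2 / 2)
            * erfc( (-(t - t0) - lam sigma^2) / (sigma sqrt 2) )

    evaluated in an overflow-safe way via the scaled complementary error
    function erfcx.
    """
    t = np.asarray(t, dtype=float)
    if irf.fwhm == 0.0:
        out = np.zeros_like(t)
        mask = t >= irf.t0
        out[mask] = np.exp(lam * (t[mask] - irf.t0))
        return out
    sigma = irf.sigma
    dt = t - irf.t0
    z = (-dt - lam * sigma * sigma) / (sigma * math.sqrt(2.0))
    # exp(a) * erfc(z) with a = lam*dt + lam^2 sigma^2 / 2.
    # For z >= 0 use erfcx: exp(a - z^2) * erfcx(z) with a - z^2 = -dt^2/(2 sigma^2).
    out = np.empty_like(dt)
    pos = z >= 0
    out[pos] = 0.5 * np.exp(-(dt[pos] ** 2) / (2 * sigma * sigma)) * erfcx(z[pos])
    a = lam * dt[~pos] + 0.5 * lam * lam * sigma * sigma
    from scipy.special import erfc  # local import keeps top import list short

    out[~pos] = 0.5 * np.exp(a) * erfc(z[~pos])
    return out


def _eig_with_jitter(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition; near-degenerate eigenvalues get a tiny relative
    jitter on the matrix (logged) so the eigenvector basis stays well
    conditioned."""
    lam, V = np.linalg.eig(K)
    scale = np.max(np.abs(lam)) if lam.size else 1.0
    order = np.argsort(lam.real)
    lam_sorted = lam[order]
    gaps = np.abs(np.diff(lam_sorted))
    if gaps.size and np.min(gaps) < 1e-9 * scale:
        logger.info(
            "near-degenerate eigenvalues (min gap %.3e); applying relative "
            "1e-9 jitter to resolve the exponential basis",
            float(np.min(gaps)),
        )
        rng = np.random.default_rng(0)  # fixed: deterministic jitter
        jitter = 1.0 + 1e-9 * rng.standard_normal(K.shape[0])
        K = K * jitter[np.newaxis, :]
        lam, V = np.linalg.eig(K)
    return lam, V


def solve_populations(
    K: RateMatrix,
    x0: np.ndarray,
    delays: np.ndarray,
    irf: IRFModel | None = None,
) -> PopulationTrajectory:
    """Analytic populations ``X(t) = V diag(g_i(t)) V^-1 x0``.

    ``g_i`` is the causal exponential of eigenvalue lambda_i, convolved with
    the Gaussian IRF when one is given.  Delays must be ascending.
    """
    irf = irf or IRFModel()
    delays = np.asarray(delays, dtype=float)
    if delays.ndim != 1 or np.any(np.diff(delays) <= 0):
        raise ValueError("delays must be a strictly ascending 1-D grid")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (K.n,):
        raise ValueError("x0 length must match the number of compartments")
    if x0.sum() > 1.0 + 1e-9:
        raise ValueError("initial populations must sum to <= 1")

    lam, V = _eig_with_jitter(K.matrix)
    c = np.linalg.solve(V, x0.astype(complex))
    G = np.empty((K.n, delays.size), dtype=complex)
    for i, li in enumerate(lam):
        if abs(li.imag) > 1e-12 * max(1.0, abs(li.real)):
            # complex pairs cannot arise from a physical acyclic scheme but
            # keep the algebra exact if they do
            G[i] = _complex_convolved(li, delays, irf)
        else:
            G[i] = irf_convolved_exponential(li.real, delays, irf)
    X = (V * c[np.newaxis, :]) @ G
    Xr = np.real(X)
    if np.max(np.abs(np.imag(X))) > 1e-8:
        raise FloatingPointError("population solution has a non-real component")
    return PopulationTrajectory(delays, Xr, K.compartments)


def _complex_convolved(lam: complex, t: np.ndarray, irf: IRFModel) -> np.ndarray:
    if irf.fwhm == 0.0:
        out = np.zeros(t.shape, dtype=complex)
        mask = t >= irf.t0
        out[mask] = np.exp(lam * (t[mask] - irf.t0))
        return out
    from scipy.special import erfc

    sigma = irf.sigma
    dt = t - irf.t0
    z = (-dt - lam * sigma * sigma) / (sigma * math.sqrt(2.0))
    return 0.5 * np.exp(lam * dt + 0.5 * lam * lam * sigma * sigma) * erfc(z)


def branching_yields(scheme: KineticScheme) -> BranchingYields:
    """Branch fractions of the S_H hot intermediate from its outflow rates."""
    ks = {}
    for src, dst, k in scheme.transfers:
        if src == "SH":
            ks[dst] = k
    missing = {"S1", "ICT", "Sstar"} - set(ks)
    if missing:
        raise ValueError(f"scheme lacks SH branch rates to {sorted(missing)}")
    total = ks["S1"] + ks["ICT"] + ks["Sstar"]
    return BranchingYields(
        phi_s1=ks["S1"] / total,
        phi_ict=ks["ICT"] / total,
        phi_sstar=ks["Sstar"] / total,
    )
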