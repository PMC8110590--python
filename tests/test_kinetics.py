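"""Rate-matrix assembly, eigen-lifetimes, analytic populations, yields."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ocpkin.kinetics import (
    BranchingYields,
    IRFModel,
    KineticScheme,
    RateMatrix,
    branching_yields,
    build_rate_matrix,
    eigen_lifetimes,
    ocp_five_state_scheme,
    solve_populations,
)

FIVE_STATE_RATES = dict(
    k2=10.0, k1=2.0, k_ict=1.0, k_sstar=1.0, m1=0.33, m_ict=3.0, m_sstar=0.11
)


class TestRateMatrix:
    def test_single_compartment_ground_loss(self):
        s = KineticScheme(("A",), [], [("A", 1.0)], {"A": 1.0})
        K = build_rate_matrix(s)
        np.testing.assert_allclose(K.matrix, [[-1.0]])

    def test_five_state_diagonal_sums_outflows(self):
        s = ocp_five_state_scheme(**FIVE_STATE_RATES)
        K = build_rate_matrix(s)
        np.testing.assert_allclose(
            np.diag(K.matrix), [-10.0, -4.0, -0.33, -3.0, -0.11]
        )

    def test_column_sums_equal_negative_ground_loss(self):
        s = ocp_five_state_scheme(**FIVE_STATE_RATES)
        K = build_rate_matrix(s)
        np.testing.assert_allclose(
            K.ground_losses(), [0.0, 0.0, 0.33, 3.0, 0.11], atol=1e-14
        )

    def test_self_transfer_rejected(self):
        with pytest.raises(ValueError, match="self-transfer"):
            KineticScheme(("A", "B"), [("A", "A", 1.0)], [("B", 1.0)])

    def test_scheme_json_round_trip(self):
        s = ocp_five_state_scheme()
        back = KineticScheme.from_json(s.to_json())
        assert back.rate_values() == s.rate_values()
        assert back.x0 == s.x0


class TestEigenLifetimes:
    def test_diagonal_matrix_lifetimes(self):
        K = RateMatrix(np.diag([-1.0, -2.0, -4.0]), ("A", "B", "C"))
        np.testing.assert_allclose(eigen_lifetimes(K), [0.25, 0.5, 1.0])

    def test_five_state_lifetimes_are_reciprocal_outflows(self):
        # the matrix is lower-triangular in the order (S2, SH, S1, ICT, S*),
        # so its eigenvalues are the diagonal entries
        s = ocp_five_state_scheme(**FIVE_STATE_RATES)
        tau = eigen_lifetimes(build_rate_matrix(s))
        expected = np.sort([1 / 10.0, 1 / 4.0, 1 / 0.33, 1 / 3.0, 1 / 0.11])
        np.testing.assert_allclose(tau, expected, rtol=1e-12)

    def test_lifetimes_invariant_under_relabeling(self):
        s = ocp_five_state_scheme()
        K = build_rate_matrix(s).matrix
        rng = np.random.default_rng(0)
        perm = rng.permutation(5)
        P = np.eye(5)[perm]
        Kp = RateMatrix(P @ K @ P.T, tuple(np.array(s.compartments)[perm]))
        np.testing.assert_allclose(
            eigen_lifetimes(Kp),
            eigen_lifetimes(build_rate_matrix(s)),
            rtol=1e-9,
        )

    def test_conservative_cycle_raises(self):
        K = np.array([[-1.0, 1.0], [1.0, -1.0]])
        with pytest.raises(ValueError, match="non-decaying"):
            eigen_lifetimes(RateMatrix(K, ("A", "B")))


def random_acyclic_scheme(rng: np.random.Generator, n: int) -> KineticScheme:
    """Random strictly lower-triangular transfer graph with ground losses."""
    names = tuple(f"C{i}" for i in range(n))
    transfers = []
    for j in range(n):
        for i in range(j + 1, n):
            if rng.random() < 0.5:
                transfers.append((names[j], names[i], float(rng.uniform(0.2, 8.0))))
    losses = [(names[i], float(rng.uniform(0.05, 4.0))) for i in range(n)]
    return KineticScheme(names, transfers, losses, {names[0]: 1.0})


class TestPopulations:
    def test_single_exponential_closed_form(self):
        s = KineticScheme(("A",), [], [("A", 1.0)], {"A": 1.0})
        traj = solve_populations(
            build_rate_matrix(s), s.initial_vector(), np.array([0.5, 1.0]), IRFModel()
        )
        assert traj.populations[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_five_state_matches_ode_oracle(self):
        s = ocp_five_state_scheme(**FIVE_STATE_RATES)
        K = build_rate_matrix(s)
        delays = np.geomspace(0.01, 200.0, 200)
        traj = solve_populations(K, s.initial_vector(), delays, IRFModel())
        oracle = solve_ivp(
            lambda t, x: K.matrix @ x,
            (0.0, 200.0),
            s.initial_vector(),
            t_eval=delays,
            rtol=1e-11,
            atol=1e-13,
        )
        assert np.max(np.abs(traj.populations - oracle.y)) < 1e-8

    def test_gaussian_irf_matches_numerical_convolution(self):
        # oracle: quadrature of (delta-IRF ODE solution) * (Gaussian kernel),
        # with the causality discontinuity handled as a quadrature breakpoint
        from scipy.integrate import quad

        s = ocp_five_state_scheme(**FIVE_STATE_RATES)
        K = build_rate_matrix(s)
        irf = IRFModel(t0=0.0, fwhm=0.1)
        sigma = irf.sigma
        tq = np.array([-0.05, 0.0, 0.05, 0.2, 1.0])
        traj = solve_populations(K, s.initial_vector(), tq, irf)

        dense = solve_ivp(
            lambda t, x: K.matrix @ x,
            (0.0, 3.0),
            s.initial_vector(),
            dense_output=True,
            rtol=1e-11,
            atol=1e-13,
        )
        norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
        for i in range(5):
            for j, t in enumerate(tq):
                def integrand(u):
                    tt = t - u
                    return float(dense.sol(tt)[i]) * norm * np.exp(
                        -(u**2) / (2 * sigma**2)
                    ) if tt >= 0 else 0.0

                pts = [t] if abs(t) < 6 * sigma else None
                expected, _ = quad(
                    integrand, -6 * sigma, 6 * sigma, points=pts, limit=200
                )
                assert traj.populations[i, j] == pytest.approx(expected, abs=1e-6)

    def test_populations_causal_before_time_zero(self):
        s = ocp_five_state_scheme()
        traj = solve_populations(
            build_rate_matrix(s),
            s.initial_vector(),
            np.array([-1.0, -0.1, 0.0, 0.1]),
            IRFModel(),
        )
        assert np.all(traj.populations[:, :2] == 0.0)

    def test_conservation_with_implicit_ground_state(self):
        s = ocp_five_state_scheme()
        traj = solve_populations(
            build_rate_matrix(s),
            s.initial_vector(),
            np.geomspace(1e-3, 200.0, 300),
            IRFModel(),
        )
        total = traj.populations.sum(axis=0) + traj.ground
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_acyclic_schemes_match_ode_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        s = random_acyclic_scheme(rng, n)
        K = build_rate_matrix(s)
        delays = np.geomspace(0.02, 50.0, 60)
        traj = solve_populations(K, s.initial_vector(), delays, IRFModel())
        oracle = solve_ivp(
            lambda t, x: K.matrix @ x,
            (0.0, 50.0),
            s.initial_vector(),
            t_eval=delays,
            rtol=1e-11,
            atol=1e-13,
        )
        assert np.max(np.abs(traj.populations - oracle.y)) < 1e-8

    def test_degenerate_rates_are_jittered_not_fatal(self, caplog):
        s = KineticScheme(
            ("A", "B"), [("A", "B", 1.0)], [("A", 1.0), ("B", 2.0)], {"A": 1.0}
        )
        # A's total outflow (2.0) equals B's: degenerate eigenvalues
        with caplog.at_level("INFO", logger="ocpkin.kinetics"):
            traj = solve_populations(
                build_rate_matrix(s), s.initial_vector(), np.array([0.5, 1.0]), IRFModel()
            )
        assert np.all(np.isfinite(traj.populations))
        assert any("jitter" in r.message for r in caplog.records)


class TestBranchingYields:
    def test_equal_rates_split_evenly(self):
        s = ocp_five_state_scheme(k1=1.0, k_ict=1.0, k_sstar=1.0)
        y = branching_yields(s)
        assert (y.phi_s1, y.phi_ict, y.phi_sstar) == (
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
        )

    def test_normalization_identity(self):
        y = branching_yields(ocp_five_state_scheme(k1=0.5, k_ict=0.3, k_sstar=0.2))
        assert (y.phi_s1, y.phi_ict, y.phi_sstar) == (
            pytest.approx(0.5),
            pytest.approx(0.3),
            pytest.approx(0.2),
        )

    def test_quarter_sstar_yield_regime(self):
        # S* receiving 1 of 4 total branch units -> 25% yield
        y = branching_yields(ocp_five_state_scheme(k1=2.0, k_ict=1.0, k_sstar=1.0))
        assert y.phi_sstar == pytest.approx(0.25)
        assert y.phi_s1 + y.phi_ict + y.phi_sstar == 1.0

    def test_missing_branch_rates_raise(self):
        s = KineticScheme(("S2", "SH"), [("S2", "SH", 1.0)], [("SH", 1.0)])
        with pytest.raises(ValueError, match="branch"):
            branching_yields(s)

    def test_invalid_yields_rejected(self):
        with pytest.raises(ValueError):
            BranchingYields(0.5, 0.5, 0.5)
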