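"""Target (SAS) analysis: rate recovery, identifiability, DADS bridge."""

import numpy as np
import pytest

from ocpkin.kinetics import (
    IRFModel,
    KineticScheme,
    build_rate_matrix,
    eigen_lifetimes,
    ocp_five_state_scheme,
    solve_populations,
)
from ocpkin.simulate import make_sas_library, ocpww_preset, simulate_ta
from ocpkin.targetfit import fit_target, transform_sas_to_dads
from ocpkin.globalfit import fit_global


def perturbed_template(scheme: KineticScheme, seed: int) -> KineticScheme:
    """Template with starting rates displaced along identifiable directions:
    independent factors on the S2 decay and the three ground losses, one
    common factor on the branch trio (the split itself is not identifiable
    with free SAS)."""
    true = scheme.rate_values()
    rng = np.random.default_rng(1000 + seed)
    f = rng.uniform(0.7, 1.4, size=5)
    return scheme.with_rates(
        {
            "S2->SH": true["S2->SH"] * f[0],
            "S1->S0": true["S1->S0"] * f[1],
            "ICT->S0": true["ICT->S0"] * f[2],
            "Sstar->S0": true["Sstar->S0"] * f[3],
            "SH->S1": true["SH->S1"] * f[4],
            "SH->ICT": true["SH->ICT"] * f[4],
            "SH->Sstar": true["SH->Sstar"] * f[4],
        }
    )


class TestRateRecovery:
    def test_noiseless_surface_recovers_rates_near_machine_precision(self):
        cfg = ocpww_preset(seed=1, noise_sigma=0.0)
        ds = simulate_ta(cfg)
        res = fit_target(
            ds, perturbed_template(cfg.scheme, 1), irf_guess=IRFModel(0.0, 0.026)
        )
        true = cfg.scheme.rate_values()
        for name, k in res.rates.items():
            assert k == pytest.approx(true[name], rel=1e-4)
        assert res.rms_residual < 1e-8

    def test_noiseless_sas_match_generator_spectra(self):
        cfg = ocpww_preset(seed=1, noise_sigma=0.0)
        ds = simulate_ta(cfg)
        res = fit_target(ds, cfg.scheme, irf_guess=IRFModel(0.0, 0.026))
        sas_true = make_sas_library(
            cfg.sas_bands, cfg.wavelengths, cfg.scheme.compartments
        )
        for i in range(5):
            a, b = res.sas[i], sas_true[i]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos > 0.999

    def test_seeded_recovery_and_sstar_yield(self):
        # per-seed spread of the weakly identified branch total reaches ~10%
        # at SNR 100; the tight 5% bound is asserted on the 10-seed median
        cfg = ocpww_preset(seed=11)
        ds = simulate_ta(cfg)
        res = fit_target(
            ds, perturbed_template(cfg.scheme, 11), irf_guess=IRFModel(0.0, 0.026)
        )
        true = cfg.scheme.rate_values()
        for name, k in res.rates.items():
            assert k == pytest.approx(true[name], rel=0.10)
        assert abs(res.yields.phi_sstar - 0.25) <= 0.02

    def test_median_recovery_over_ten_seeds(self):
        errs: dict[str, list[float]] = {}
        phi_dev = []
        for seed in range(1, 11):
            cfg = ocpww_preset(seed=seed)
            ds = simulate_ta(cfg)
            res = fit_target(
                ds, perturbed_template(cfg.scheme, seed), irf_guess=IRFModel(0.0, 0.026)
            )
            for name, true_k in cfg.scheme.rate_values().items():
                errs.setdefault(name, []).append(abs(res.rates[name] / true_k - 1))
            phi_dev.append(res.yields.phi_sstar - 0.25)
        for name, e in errs.items():
            assert np.median(e) < 0.05, name
        assert abs(np.mean(phi_dev)) < 0.01

    def test_residual_whiteness_on_correct_model(self):
        cfg = ocpww_preset(seed=3)
        ds = simulate_ta(cfg)
        res = fit_target(
            ds, perturbed_template(cfg.scheme, 3), irf_guess=IRFModel(0.0, 0.026)
        )
        r = res.residual
        lag1 = np.mean(
            np.sum(r[:-1] * r[1:], axis=0)
            / np.sqrt(np.sum(r[:-1] ** 2, axis=0) * np.sum(r[1:] ** 2, axis=0))
        )
        assert abs(lag1) < 0.1


class TestIdentifiability:
    def test_branch_split_rescaling_leaves_surface_invariant(self):
        # moving rate from one branch to another while rescaling the SAS is
        # exactly invisible in the data: the structural degeneracy that
        # motivates the tied branch policy
        cfg = ocpww_preset(seed=1, noise_sigma=0.0)
        sas = make_sas_library(cfg.sas_bands, cfg.wavelengths, cfg.scheme.compartments)
        beta = 1.2

        def surface(scheme, sas_m):
            K = build_rate_matrix(scheme)
            traj = solve_populations(K, scheme.initial_vector(), cfg.delays, cfg.irf)
            return traj.populations.T @ sas_m

        base = surface(cfg.scheme, sas)
        true = cfg.scheme.rate_values()
        k1, kict = true["SH->S1"], true["SH->ICT"]
        alt = cfg.scheme.with_rates(
            {"SH->S1": beta * k1, "SH->ICT": kict + k1 * (1 - beta)}
        )
        sas_alt = sas.copy()
        sas_alt[2] /= beta  # S1 row
        sas_alt[3] *= kict / (kict + k1 * (1 - beta))  # ICT row
        np.testing.assert_allclose(surface(alt, sas_alt), base, atol=1e-10)

    def test_free_branch_policy_flags_flat_directions(self):
        cfg = ocpww_preset(seed=2)
        ds = simulate_ta(cfg)
        res = fit_target(
            ds, cfg.scheme, irf_guess=IRFModel(0.0, 0.026), branch_policy="free"
        )
        # the flat branch-split directions must surface as wide errors
        branch_se = [
            res.rate_stderr[n] / res.rates[n]
            for n in ("SH->S1", "SH->ICT", "SH->Sstar")
        ]
        assert max(branch_se) > 10.0
        assert any("flat" in n for n in res.notes)

    def test_yields_consistent_with_fitted_rates(self):
        cfg = ocpww_preset(seed=4)
        ds = simulate_ta(cfg)
        res = fit_target(ds, cfg.scheme, irf_guess=IRFModel(0.0, 0.026))
        k = res.rates
        tot = k["SH->S1"] + k["SH->ICT"] + k["SH->Sstar"]
        assert res.yields.phi_sstar == pytest.approx(k["SH->Sstar"] / tot)


class TestAgreementWithGlobalFit:
    def test_reconstructions_agree_on_noiseless_surface(self):
        cfg = ocpww_preset(seed=1, noise_sigma=0.0)
        ds = simulate_ta(cfg)
        target = fit_target(ds, cfg.scheme, irf_guess=IRFModel(0.0, 0.026))
        n_modes = len(set(np.round(eigen_lifetimes(build_rate_matrix(cfg.scheme)), 12)))
        glob = fit_global(
            ds,
            n_modes,
            irf_guess=IRFModel(0.0, 0.026),
            tau_guess=eigen_lifetimes(build_rate_matrix(cfg.scheme)),
            fit_irf=False,
        )
        assert np.max(np.abs(target.model_surface - glob.model_surface)) < 1e-8


class TestSASToDADS:
    def test_parallel_scheme_dads_are_scaled_sas(self):
        s = KineticScheme(
            ("A", "B"),
            [],
            [("A", 2.0), ("B", 0.5)],
            {"A": 0.5, "B": 0.5},
        )
        K = build_rate_matrix(s)
        sas = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 1.0]])
        tau, dads = transform_sas_to_dads(K, s.initial_vector(), sas)
        np.testing.assert_allclose(tau, [0.5, 2.0])
        np.testing.assert_allclose(dads[0], 0.5 * sas[0])  # tau=0.5 is A
        np.testing.assert_allclose(dads[1], 0.5 * sas[1])

    def test_sequential_scheme_reconstruction_identity(self):
        s = KineticScheme(
            ("A", "B"), [("A", "B", 1.5)], [("B", 0.4)], {"A": 1.0}
        )
        K = build_rate_matrix(s)
        rng = np.random.default_rng(0)
        sas = rng.normal(size=(2, 7))
        tau, dads = transform_sas_to_dads(K, s.initial_vector(), sas)
        t = np.linspace(0.0, 10.0, 50)
        traj = solve_populations(K, s.initial_vector(), t, IRFModel())
        lhs = traj.populations.T @ sas
        rhs = np.exp(-t[:, None] / tau[None, :]) @ dads
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_random_acyclic_schemes_reconstruction_identity(self):
        from test_kinetics import random_acyclic_scheme

        for seed in range(8):
            rng = np.random.default_rng(seed)
            s = random_acyclic_scheme(rng, int(rng.integers(2, 6)))
            K = build_rate_matrix(s)
            sas = rng.normal(size=(s.n, 9))
            tau, dads = transform_sas_to_dads(K, s.initial_vector(), sas)
            t = np.linspace(0.0, 8.0, 40)
            traj = solve_populations(K, s.initial_vector(), t, IRFModel())
            lhs = traj.populations.T @ sas
            rhs = np.exp(-t[:, None] / tau[None, :]) @ dads
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_zero_sas_give_zero_dads(self):
        s = ocp_five_state_scheme()
        K = build_rate_matrix(s)
        _, dads = transform_sas_to_dads(K, s.initial_vector(), np.zeros((5, 4)))
        np.testing.assert_array_equal(dads, np.zeros((5, 4)))
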