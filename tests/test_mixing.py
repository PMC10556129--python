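"""Forward mixing, marginal likelihood, grid oracle, MCMC and weight conversion."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sherdmix import (
    MixtureComposition,
    PipelineConfig,
    SourceReference,
    fa_to_weight_fractions,
    forward_mix,
    grid_posterior,
    marginal_loglik,
    mixing_curve,
    run_mcmc,
)
from sherdmix.mixing import UndefinedProxyError
from sherdmix.types import ValidationError


def simple_source(name, d16, d18, d181, c16, c18, c181, sd=1.0, phi=1.0):
    return SourceReference(
        source_name=name,
        delta_mean={"C16:0": d16, "C18:0": d18, "C18:1": d181},
        delta_sd={"C16:0": sd, "C18:0": sd, "C18:1": sd},
        conc_pct={"C16:0": c16, "C18:0": c18, "C18:1": c181},
        fa_per_dry_weight=phi,
    )


MAIZE = simple_source("maize", -14.5, -16.0, -15.0, 12.0, 2.0, 28.0, phi=0.04)
RUMINANT = simple_source("ruminant", -29.0, -31.0, -30.0, 25.0, 20.0, 35.0, phi=0.60)


class TestForwardMix:
    def test_pure_source_returns_its_signature(self):
        for proxy in ("C16:0", "C18:0", "C18:1"):
            assert forward_mix([1.0, 0.0], [MAIZE, RUMINANT], proxy) == pytest.approx(
                MAIZE.delta_mean[proxy]
            )

    def test_equal_concentrations_reduce_to_linear_mixture(self):
        a = simple_source("a", -20.0, -22.0, -21.0, 10.0, 10.0, 10.0)
        b = simple_source("b", -30.0, -28.0, -29.0, 10.0, 10.0, 10.0)
        f = [0.3, 0.7]
        for proxy in ("C16:0", "C18:0"):
            expected = 0.3 * a.delta_mean[proxy] + 0.7 * b.delta_mean[proxy]
            assert forward_mix(f, [a, b], proxy) == pytest.approx(expected)

    def test_hand_arithmetic_fixture(self):
        """Concentration-weighted mean of the maize/ruminant half-mixture."""
        f = [0.5, 0.5]
        assert forward_mix(f, [MAIZE, RUMINANT], "C16:0") == pytest.approx(-24.30, abs=0.005)
        assert forward_mix(f, [MAIZE, RUMINANT], "C18:0") == pytest.approx(-29.64, abs=0.005)
        delta = forward_mix(f, [MAIZE, RUMINANT], "C18:0") - forward_mix(
            f, [MAIZE, RUMINANT], "C16:0"
        )
        assert delta == pytest.approx(-5.34, abs=0.005)

    def test_all_zero_concentration_is_undefined(self):
        z1 = simple_source("z1", -20.0, -22.0, -21.0, 10.0, 0.0, 10.0)
        z2 = simple_source("z2", -30.0, -28.0, -29.0, 10.0, 0.0, 10.0)
        with pytest.raises(UndefinedProxyError):
            forward_mix([0.5, 0.5], [z1, z2], "C18:0")

    # ruminant's proxy concentrations sum to 80 %, so scales above 1.25
    # would breach the <=100 % invariant of the reference table
    @given(scale=st.floats(min_value=0.01, max_value=1.2), fa=st.floats(min_value=0.0, max_value=1.0))
    def test_invariant_to_common_concentration_rescaling(self, scale, fa):
        scaled = [
            simple_source(
                s.source_name + "_s",
                *[s.delta_mean[p] for p in ("C16:0", "C18:0", "C18:1")],
                *[s.conc_pct[p] * scale for p in ("C16:0", "C18:0", "C18:1")],
            )
            for s in (MAIZE, RUMINANT)
        ]
        f = [fa, 1.0 - fa]
        assert forward_mix(f, scaled, "C16:0") == pytest.approx(
            forward_mix(f, [MAIZE, RUMINANT], "C16:0"), abs=1e-9
        )


class TestMixingCurve:
    def test_endpoints_equal_pure_sources(self):
        curve = mixing_curve(MAIZE, RUMINANT, 10)
        assert len(curve) == 11
        first, last = curve.iloc[0], curve.iloc[-1]
        assert first["f_a"] == 0.0 and last["f_a"] == 1.0
        assert first["d13c_16_0"] == RUMINANT.delta_mean["C16:0"]
        assert last["d13c_16_0"] == MAIZE.delta_mean["C16:0"]
        assert last["delta_18_0_16_0"] == pytest.approx(-1.5)

    def test_identical_sources_give_constant_trajectory(self):
        twin = simple_source("twin", -29.0, -31.0, -30.0, 25.0, 20.0, 35.0)
        curve = mixing_curve(RUMINANT, twin, 5)
        assert np.allclose(curve["delta_18_0_16_0"], -2.0)

    def test_invalid_step_count_rejected(self):
        with pytest.raises(ValidationError):
            mixing_curve(MAIZE, RUMINANT, 0)


class TestMarginalLoglik:
    def test_single_source_single_proxy_closed_form(self, cfg):
        src = simple_source("only", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0, sd=0.8)
        observed = {"C16:0": (-24.5, 0.3)}
        var = 0.8**2 + 0.3**2 + cfg.sigma_model**2
        expected = -0.5 * (np.log(2 * np.pi * var) + (-24.5 + 25.0) ** 2 / var)
        assert marginal_loglik([1.0], [src], observed, cfg) == pytest.approx(expected)

    def test_zero_concentration_source_is_inert(self, cfg):
        ghost = simple_source("ghost", -20.0, -20.0, -20.0, 0.0, 0.0, 0.0)
        observed = {"C16:0": (-24.0, 0.3), "C18:0": (-28.0, 0.3)}
        base = [MAIZE, RUMINANT, ghost]
        ll1 = marginal_loglik([0.5, 0.3, 0.2], base, observed, cfg)
        ll2 = marginal_loglik([0.5 * 5 / 8, 0.3 * 5 / 8, 0.5], base, observed, cfg)
        # only the maize:ruminant ratio matters; the ghost fraction is free
        ll3 = marginal_loglik([0.25, 0.15, 0.6], base, observed, cfg)
        assert ll1 == pytest.approx(ll3, abs=1e-9)
        assert ll1 == pytest.approx(ll2, abs=1e-6)

    def test_matches_monte_carlo_integration(self, cfg, sources3):
        """Average the exact-signature Gaussian density over 10⁶ signature draws."""
        rng = np.random.default_rng(42)
        f = np.array([0.5, 0.2, 0.3])
        observed = {"C16:0": (-23.0, 0.3), "C18:0": (-27.5, 0.3), "C18:1": (-24.0, 0.3)}
        proxies = list(observed)
        n = 1_000_000
        log_draw_liks = np.zeros(n)
        densities = np.ones(n)
        for proxy in proxies:
            c = np.array([s.conc_pct[proxy] for s in sources3])
            dmean = np.array([s.delta_mean[proxy] for s in sources3])
            dsd = np.array([s.delta_sd[proxy] for s in sources3])
            sig = rng.normal(dmean, dsd, size=(n, 3))
            mix = (sig * (f * c)).sum(axis=1) / (f * c).sum()
            y, sd_obs = observed[proxy]
            var = sd_obs**2 + cfg.sigma_model**2
            densities *= np.exp(-0.5 * (y - mix) ** 2 / var) / np.sqrt(2 * np.pi * var)
        mc_mean = densities.mean()
        mc_se = densities.std(ddof=1) / np.sqrt(n)
        exact = np.exp(marginal_loglik(f, sources3, observed, cfg))
        assert abs(exact - mc_mean) <= 3 * mc_se

    def test_zero_variances_reduce_to_forward_prediction(self, sources3):
        cfg = PipelineConfig(sigma_model=0.0)
        tight = [
            dataclasses.replace(s, delta_sd={p: 1e-12 for p in ("C16:0", "C18:0", "C18:1")})
            for s in sources3
        ]
        f = np.array([0.4, 0.4, 0.2])
        sd_obs = 0.3
        observed = {"C16:0": (-23.0, sd_obs)}
        pred = forward_mix(f, tight, "C16:0")
        expected = -0.5 * (np.log(2 * np.pi * sd_obs**2) + (-23.0 - pred) ** 2 / sd_obs**2)
        assert marginal_loglik(f, tight, observed, cfg) == pytest.approx(expected, rel=1e-6)

    def test_requires_at_least_one_proxy(self, cfg, sources3):
        with pytest.raises(ValidationError):
            marginal_loglik([0.3, 0.3, 0.4], sources3, {}, cfg)

    def test_signature_cov_diagonal_matches_diagonal_path(self, cfg, sources3):
        withcov = [
            dataclasses.replace(
                s,
                signature_cov=np.diag(
                    [s.delta_sd[p] ** 2 for p in ("C16:0", "C18:0", "C18:1")]
                ),
            )
            for s in sources3
        ]
        observed = {"C16:0": (-23.0, 0.3), "C18:0": (-27.5, 0.3)}
        f = [0.5, 0.2, 0.3]
        assert marginal_loglik(f, withcov, observed, cfg) == pytest.approx(
            marginal_loglik(f, sources3, observed, cfg), rel=1e-9
        )


class TestGridPosterior:
    def test_masses_normalised(self, cfg, sources3):
        observed = {"C16:0": (-23.0, 0.3), "C18:0": (-27.5, 0.3)}
        gp = grid_posterior(sources3, observed, cfg)
        assert gp.masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(gp.masses >= 0)

    def test_posterior_concentrates_at_observed_vertex(self, sources3):
        cfg = PipelineConfig(sigma_model=0.05, grid_step=0.05)
        tight = [
            dataclasses.replace(s, delta_sd={p: 0.05 for p in ("C16:0", "C18:0", "C18:1")})
            for s in sources3
        ]
        maize = tight[0]
        observed = {p: (maize.delta_mean[p], 0.05) for p in ("C16:0", "C18:0", "C18:1")}
        gp = grid_posterior(tight, observed, cfg)
        near_vertex = gp.lattice[:, 0] >= 1.0 - cfg.grid_step - 1e-12
        assert gp.masses[near_vertex].sum() > 0.95

    def test_symmetry_under_identical_sources(self, cfg):
        a = simple_source("a", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0)
        b = simple_source("b", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0)
        observed = {"C16:0": (-24.0, 0.3)}
        gp = grid_posterior([a, b], observed, cfg)
        masses = {tuple(np.round(p, 9)): m for p, m in zip(gp.lattice, gp.masses)}
        for (fa, fb), mass in masses.items():
            assert mass == pytest.approx(masses[(fb, fa)], rel=1e-9)

    def test_refuses_more_than_four_sources(self, cfg, sources4):
        five = sources4 + [simple_source("extra", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0)]
        with pytest.raises(ValidationError, match="at most 4"):
            grid_posterior(five, {"C16:0": (-24.0, 0.3)}, cfg)

    def test_rejects_non_dividing_step(self, sources3):
        cfg = PipelineConfig(grid_step=0.03)
        with pytest.raises(ValidationError, match="divide"):
            grid_posterior(sources3, {"C16:0": (-24.0, 0.3)}, cfg)


class TestRunMcmc:
    OBS = {"C16:0": (-22.0, 0.3), "C18:0": (-28.0, 0.3), "C18:1": (-24.0, 0.3)}

    def test_same_seed_reproduces_samples(self, sources3, fast_mcmc_cfg):
        a = run_mcmc(sources3, self.OBS, fast_mcmc_cfg)
        b = run_mcmc(sources3, self.OBS, fast_mcmc_cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_different_seed_changes_samples(self, sources3, fast_mcmc_cfg):
        a = run_mcmc(sources3, self.OBS, fast_mcmc_cfg)
        b = run_mcmc(sources3, self.OBS, dataclasses.replace(fast_mcmc_cfg, seed=99))
        assert not np.array_equal(a.samples, b.samples)

    def test_samples_lie_on_simplex(self, sources3, fast_mcmc_cfg):
        post = run_mcmc(sources3, self.OBS, fast_mcmc_cfg)
        flat = post.flat_samples()
        assert np.all(flat >= 0)
        assert np.allclose(flat.sum(axis=1), 1.0, atol=1e-9)
        assert post.rhat.shape == (3,)

    def test_acceptance_rate_in_tuned_band(self, sources3, fast_mcmc_cfg):
        post = run_mcmc(sources3, self.OBS, fast_mcmc_cfg)
        assert 0.15 <= post.acceptance_rate <= 0.45

    def test_proxyless_source_collapses_to_prior(self, sources3, fast_mcmc_cfg):
        """A source contributing no fatty acid keeps its Beta(1, S−1) prior."""
        ghost = simple_source("ghost", -20.0, -20.0, -20.0, 0.0, 0.0, 0.0)
        trio = [sources3[0], sources3[1], ghost]
        cfg = dataclasses.replace(fast_mcmc_cfg, n_iter=4000, n_burn=1500)
        post = run_mcmc(trio, {"C16:0": (-20.0, 0.3)}, cfg)
        k = post.source_names.index("ghost")
        prior_mean = 1.0 / 3.0
        prior_sd = np.sqrt(2.0 / (9.0 * 4.0))
        assert post.mean[k] == pytest.approx(prior_mean, abs=0.04)
        assert post.sd[k] == pytest.approx(prior_sd, abs=0.04)

    def test_degenerate_sources_flagged_non_identifiable(self, fast_mcmc_cfg):
        a = simple_source("a", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0, sd=3.0)
        b = simple_source("b", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0, sd=3.0)
        post = run_mcmc([a, b], {"C16:0": (-25.0, 0.3)}, fast_mcmc_cfg)
        assert post.non_identifiable

    def test_requires_two_sources(self, sources3, fast_mcmc_cfg):
        with pytest.raises(ValidationError):
            run_mcmc(sources3[:1], self.OBS, fast_mcmc_cfg)


class TestWeightConversion:
    def test_equal_fat_contents_leave_fractions_unchanged(self):
        a = simple_source("a", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0, phi=0.2)
        b = simple_source("b", -20.0, -22.0, -21.0, 10.0, 10.0, 10.0, phi=0.2)
        f = np.array([0.3, 0.7])
        assert fa_to_weight_fractions(f, [a, b]) == pytest.approx(f)

    def test_hand_arithmetic_two_sources(self):
        a = simple_source("a", -25.0, -27.0, -26.0, 10.0, 10.0, 10.0, phi=1.0)
        b = simple_source("b", -20.0, -22.0, -21.0, 10.0, 10.0, 10.0, phi=4.0)
        w = fa_to_weight_fractions([0.5, 0.5], [a, b])
        assert w == pytest.approx([0.8, 0.2])

    def test_lean_source_gains_weight_share(self, sources4):
        # maize has the lowest fatty-acid content per dry tissue
        phis = {s.source_name: s.fa_per_dry_weight for s in sources4}
        assert phis["maize"] == min(phis.values())
        f = np.array([0.4, 0.2, 0.2, 0.2])
        w = fa_to_weight_fractions(f, sources4)
        assert w[0] > f[0]

    def test_composition_type_accepted(self, sources4):
        comp = MixtureComposition(
            {"maize": 0.4, "marine": 0.2, "C3_plant": 0.2, "ruminant": 0.2}
        )
        w = fa_to_weight_fractions(comp, sources4)
        assert w.sum() == pytest.approx(1.0)


def test_mixture_composition_enforces_simplex():
    with pytest.raises(ValidationError):
        MixtureComposition({"a": 0.6, "b": 0.6})
    with pytest.raises(ValidationError):
        MixtureComposition({"a": -0.1, "b": 1.1})
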