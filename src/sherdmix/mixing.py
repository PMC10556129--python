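"""Concentration-dependent source mixing of fatty-acid δ13C signatures.

Forward model
-------------
A vessel's fatty-acid pool is a mixture of S food sources with fractions
f (proportions of total fatty acids, Σf = 1). Source i contributes to
proxy fatty acid j in proportion to f_i·c_ij, where c_ij is the
concentration of fatty acid j in source i (% of total fatty acids), so
the expected mixture value is the concentration-weighted mean

    δ_j(f) = Σ_i f_i c_ij δ_ij / Σ_i f_i c_ij .

Sources rich in a fatty acid therefore dominate that proxy: maize kernel
oil is C16:0-rich but nearly devoid of C18:0, which is what drives the
characteristic drop in Δ13C_18:0–16:0 when maize is mixed with C3
animal fats.

Inversion
---------
Source signatures δ_ij are Gaussian with stated means and uncertainties.
Because δ_j(f) is linear in the signatures given f, they marginalise
analytically: each observed proxy is Gaussian with mean Σ_i w_ij δ̄_ij
and variance Σ_i w_ij² σ²_ij + σ²_obs,j + σ²_model, where
w_ij = f_i c_ij / Σ_k f_k c_kj. The posterior over f under a flat
Dirichlet(1) prior is explored two ways: an exhaustive simplex-lattice
quadrature (the oracle) and a random-walk Metropolis sampler in additive
log-ratio coordinates (the workhorse), which must agree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .types import PROXIES, SourceReference, ValidationError


class UndefinedProxyError(ValueError):
    """Raised when every source has zero concentration for a required proxy."""


@dataclass
class MixtureComposition:
    """Source fractions on the fatty-acid basis (simplex to 1e-9)."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        values = np.array(list(self.fractions.values()), dtype=float)
        if np.any(values < -1e-12):
            raise ValidationError("mixture fractions must be >= 0")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"mixture fractions must sum to 1, got {values.sum():.12f}"
            )

    def as_array(self, source_names: list[str]) -> np.ndarray:
        return np.array([self.fractions[name] for name in source_names], dtype=float)


def _source_arrays(sources: list[SourceReference], proxies: tuple[str, ...]):
    """(S, J) arrays of concentrations, signature means and variances."""
    C = np.array([[s.conc_pct[j] for j in proxies] for s in sources], dtype=float)
    D = np.array([[s.delta_mean[j] for j in proxies] for s in sources], dtype=float)
    V = np.array([[s.delta_sd[j] ** 2 for j in proxies] for s in sources], dtype=float)
    return C, D, V


def forward_mix(f, sources: list[SourceReference], proxy: str) -> float:
    """Expected mixture δ13C (‰) for one proxy under fractions ``f``.

    ``f`` is a MixtureComposition or an array aligned with ``sources``.
    Invariant to rescaling all concentrations by a common positive factor.
    """
    if proxy not in PROXIES:
        raise ValidationError(f"unknown proxy {proxy!r}")
    names = [s.source_name for s in sources]
    fa = f.as_array(names) if isinstance(f, MixtureComposition) else np.asarray(f, dtype=float)
    c = np.array([s.conc_pct[proxy] for s in sources], dtype=float)
    d = np.array([s.delta_mean[proxy] for s in sources], dtype=float)
    denom = float(fa @ c)
    if denom <= 0:
        raise UndefinedProxyError(
            f"proxy {proxy}: mixture contributes no fatty acid "
            "(all active sources have zero concentration)"
        )
    return float(fa @ (c * d) / denom)


def mixing_curve(
    source_a: SourceReference, source_b: SourceReference, n_steps: int
) -> pd.DataFrame:
    """Two-source mixing trajectory over f_A = 0 … 1 in ``n_steps`` increments.

    Returns columns f_a, d13c_16_0, d13c_18_0, delta_18_0_16_0 with
    ``n_steps + 1`` rows; the endpoints equal the pure-source values exactly.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    pair = [source_a, source_b]
    rows = []
    for k in range(n_steps + 1):
        fa = k / n_steps
        f = np.array([fa, 1.0 - fa])
        d16 = forward_mix(f, pair, "C16:0")
        d18 = forward_mix(f, pair, "C18:0")
        rows.append(
            {"f_a": fa, "d13c_16_0": d16, "d13c_18_0": d18, "delta_18_0_16_0": d18 - d16}
        )
    return pd.DataFrame(rows)


def _observed_items(observed: dict[str, tuple[float, float]]):
    proxies = tuple(p for p in PROXIES if p in observed)
    if not proxies:
        raise ValidationError("at least one observed proxy is required")
    y = np.array([observed[p][0] for p in proxies], dtype=float)
    obs_var = np.array([observed[p][1] ** 2 for p in proxies], dtype=float)
    return proxies, y, obs_var


def _loglik_batch(
    F: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
    V: np.ndarray,
    y: np.ndarray,
    obs_var: np.ndarray,
    sigma_model: float,
    covs: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Marginal log-likelihood for a batch of compositions F (B, S).

    ``covs`` (per-source J×J signature covariance restricted to the
    observed proxies; entries may be None) switches on the joint
    multivariate evaluation with induced cross-proxy covariance.
    """
    denom = F @ C  # (B, J)
    out = np.full(F.shape[0], -np.inf)
    ok = np.all(denom > 0, axis=1)
    if not np.any(ok):
        return out
    Fok = F[ok]
    W = Fok[:, :, None] * C[None, :, :] / denom[ok][:, None, :]  # (B, S, J)
    mean = np.einsum("bsj,sj->bj", W, D)
    noise = obs_var + sigma_model**2  # (J,)
    if covs is None or all(c is None for c in covs):
        var = np.einsum("bsj,sj->bj", W**2, V) + noise[None, :]
        ll = -0.5 * np.sum(
            np.log(2 * np.pi * var) + (y[None, :] - mean) ** 2 / var, axis=1
        )
    else:
        B, S, J = W.shape
        Sigma = np.zeros((B, J, J))
        for i in range(S):
            cov_i = covs[i] if covs[i] is not None else np.diag(V[i])
            # Cov contribution of source i: diag(w_ij) Σ_i diag(w_ik)
            Sigma += W[:, i, :, None] * cov_i[None, :, :] * W[:, i, None, :]
        Sigma += np.eye(J)[None, :, :] * noise[None, None, :]
        resid = y[None, :] - mean
        L = np.linalg.cholesky(Sigma)
        z = np.linalg.solve(L, resid[:, :, None])[..., 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        ll = -0.5 * (J * np.log(2 * np.pi) + logdet + np.sum(z**2, axis=1))
    out[ok] = ll
    return out


def _prepare(sources, observed, cfg):
    proxies, y, obs_var = _observed_items(observed)
    C, D, V = _source_arrays(sources, proxies)
    idx = [PROXIES.index(p) for p in proxies]
    covs = None
    if any(s.signature_cov is not None for s in sources):
        covs = [
            None if s.signature_cov is None else s.signature_cov[np.ix_(idx, idx)]
            for s in sources
        ]
    return proxies, y, obs_var, C, D, V, covs


def marginal_loglik(
    f,
    sources: list[SourceReference],
    observed: dict[str, tuple[float, float]],
    cfg: PipelineConfig | None = None,
) -> float:
    """Log-likelihood of the observed proxies given fractions ``f``.

    ``observed`` maps proxy → (δ13C value ‰, analytical sd ‰). Source
    signatures are marginalised analytically; with per-source
    ``signature_cov`` supplied the observed proxies are jointly Gaussian
    with the induced cross-proxy covariance.
    """
    cfg = cfg or PipelineConfig()
    names = [s.source_name for s in sources]
    fa = f.as_array(names) if isinstance(f, MixtureComposition) else np.asarray(f, dtype=float)
    _, y, obs_var, C, D, V, covs = _prepare(sources, observed, cfg)
    return float(
        _loglik_batch(fa[None, :], C, D, V, y, obs_var, cfg.sigma_model, covs)[0]
    )


@dataclass
class GridPosterior:
    """Exact-marginalisation posterior on a regular simplex lattice."""

    source_names: list[str]
    lattice: np.ndarray  # (M, S) compositions
    masses: np.ndarray  # (M,) normalised posterior masses
    mean: np.ndarray  # (S,) lattice-marginal posterior means


def grid_posterior(
    sources: list[SourceReference],
    observed: dict[str, tuple[float, float]],
    cfg: PipelineConfig | None = None,
) -> GridPosterior:
    """Brute-force posterior over the simplex lattice with step ``cfg.grid_step``.

    Serves as the independent oracle for the Metropolis sampler. Refuses
    more than 4 sources (combinatorial blow-up).
    """
    cfg = cfg or PipelineConfig()
    S = len(sources)
    if S > 4:
        raise ValidationError("grid_posterior supports at most 4 sources")
    if S < 1:
        raise ValidationError("at least one source required")
    n = round(1.0 / cfg.grid_step)
    if abs(n * cfg.grid_step - 1.0) > 1e-9:
        raise ValidationError(f"grid_step {cfg.grid_step} does not divide 1")

    counts = np.array(
        [
            k + (n - sum(k),)
            for k in itertools.product(range(n + 1), repeat=S - 1)
            if sum(k) <= n
        ],
        dtype=float,
    )
    lattice = counts / n
    _, y, obs_var, C, D, V, covs = _prepare(sources, observed, cfg)
    logpost = _loglik_batch(lattice, C, D, V, y, obs_var, cfg.sigma_model, covs)
    # flat Dirichlet(1) prior: uniform lattice weights
    logpost -= np.max(logpost[np.isfinite(logpost)])
    masses = np.exp(logpost)
    masses /= masses.sum()
    return GridPosterior(
        source_names=[s.source_name for s in sources],
        lattice=lattice,
        masses=masses,
        mean=masses @ lattice,
    )


@dataclass
class PosteriorSummary:
    """Posterior source contributions with convergence diagnostics."""

    source_names: list[str]
    samples: np.ndarray  # (chains, draws, S) retained fractions
    mean: np.ndarray
    sd: np.ndarray
    q2_5: np.ndarray
    q50: np.ndarray
    q97_5: np.ndarray
    rhat: np.ndarray  # split-Rhat per source
    ess: np.ndarray
    acceptance_rate: float
    converged: bool
    non_identifiable: bool
    seed: int
    config: dict = field(default_factory=dict)

    def flat_samples(self) -> np.ndarray:
        return self.samples.reshape(-1, self.samples.shape[-1])

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.source_names,
                "mean": self.mean,
                "sd": self.sd,
                "q2_5": self.q2_5,
                "q50": self.q50,
                "q97_5": self.q97_5,
                "rhat": self.rhat,
                "ess": self.ess,
            }
        )


def _softmax_alr(Z: np.ndarray) -> np.ndarray:
    """Map ALR coordinates (B, S-1) to simplex fractions (B, S)."""
    Zfull = np.concatenate([Z, np.zeros((Z.shape[0], 1))], axis=1)
    Zfull -= Zfull.max(axis=1, keepdims=True)
    expz = np.exp(Zfull)
    return expz / expz.sum(axis=1, keepdims=True)


def run_mcmc(
    sources: list[SourceReference],
    observed: dict[str, tuple[float, float]],
    cfg: PipelineConfig | None = None,
) -> PosteriorSummary:
    """Random-walk Metropolis over additive-log-ratio coordinates.

    Flat Dirichlet(1) prior on the fractions; the log-Jacobian of the ALR
    transform (Σ log f_i) is included in the target. Chains start from
    dispersed points, the proposal scale is tuned during burn-in toward
    20–40 % acceptance and then frozen; all post-burn-in draws are
    retained. The run is flagged non-converged if any split-R̂ > 1.05,
    and non-identifiable when every posterior sd is indistinguishable
    from the prior sd.
    """
    import arviz as az

    cfg = (cfg or PipelineConfig()).validate()
    S = len(sources)
    if S < 2:
        raise ValidationError("run_mcmc requires at least 2 sources")
    _, y, obs_var, C, D, V, covs = _prepare(sources, observed, cfg)
    sigma = cfg.sigma_model

    def log_target(Z: np.ndarray) -> np.ndarray:
        F = _softmax_alr(Z)
        with np.errstate(divide="ignore"):
            log_jac = np.sum(np.log(F), axis=1)  # Dirichlet(1) density x Jacobian
        return _loglik_batch(F, C, D, V, y, obs_var, sigma, covs) + log_jac

    rng = np.random.default_rng(cfg.seed)
    n_chains, K = cfg.n_chains, S - 1
    Z = rng.normal(0.0, 2.0, size=(n_chains, K))  # dispersed starts
    lp = log_target(Z)
    scale = np.full(n_chains, cfg.proposal_scale)

    tune_every = 50
    accepted = np.zeros(n_chains)
    for it in range(cfg.n_burn):
        prop = Z + rng.normal(size=(n_chains, K)) * scale[:, None]
        lp_prop = log_target(prop)
        accept = np.log(rng.random(n_chains)) < lp_prop - lp
        Z[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        accepted += accept
        if (it + 1) % tune_every == 0:
            rate = accepted / tune_every
            scale *= np.exp(rate - 0.3)  # drift toward ~30 % acceptance
            scale = np.clip(scale, 1e-3, 10.0)
            accepted[:] = 0.0

    draws = np.empty((n_chains, cfg.n_iter, S))
    n_accept = 0
    for it in range(cfg.n_iter):
        prop = Z + rng.normal(size=(n_chains, K)) * scale[:, None]
        lp_prop = log_target(prop)
        accept = np.log(rng.random(n_chains)) < lp_prop - lp
        Z[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        n_accept += int(accept.sum())
        draws[:, it, :] = _softmax_alr(Z)

    acceptance_rate = n_accept / (n_chains * cfg.n_iter)
    idata = az.from_dict(posterior={"f": draws})
    rhat = np.asarray(az.rhat(idata)["f"].values, dtype=float)
    ess = np.asarray(az.ess(idata)["f"].values, dtype=float)

    flat = draws.reshape(-1, S)
    q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
    sd = flat.std(axis=0, ddof=1)
    # prior marginal is Beta(1, S-1): detect posteriors that never left it
    prior_sd = np.sqrt((S - 1.0) / (S**2 * (S + 1.0)))
    non_identifiable = bool(np.all(np.abs(sd - prior_sd) < 0.1 * prior_sd))

    return PosteriorSummary(
        source_names=[s.source_name for s in sources],
        samples=draws,
        mean=flat.mean(axis=0),
        sd=sd,
        q2_5=q[0],
        q50=q[1],
        q97_5=q[2],
        rhat=rhat,
        ess=ess,
        acceptance_rate=acceptance_rate,
        converged=bool(np.all(rhat <= 1.05)),
        non_identifiable=non_identifiable,
        seed=cfg.seed,
        config=cfg.to_dict(),
    )


def fa_to_weight_fractions(f, sources: list[SourceReference]) -> np.ndarray:
    """Convert fatty-acid-basis fractions to dry-tissue weight fractions.

    w_i ∝ f_i / φ_i with φ_i the source's fatty-acid content per unit dry
    tissue: lean sources (low φ, e.g. maize kernels) must contribute more
    tissue weight to supply the same share of the fatty-acid pool.
    """
    names = [s.source_name for s in sources]
    fa = f.as_array(names) if isinstance(f, MixtureComposition) else np.asarray(f, dtype=float)
    phi = np.array([s.fa_per_dry_weight for s in sources], dtype=float)
    if np.any(~np.isfinite(phi)) or np.any(phi <= 0):
        raise ValidationError("fa_per_dry_weight must be > 0 for every source")
    w = fa / phi
    total = w.sum()
    if total <= 0:
        raise ValidationError("cannot convert an all-zero composition")
    return w / total
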