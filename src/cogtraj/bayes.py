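"""Bayesian two-group spline trajectory model fitted by Hamiltonian Monte Carlo.

Model
-----
For two groups A and B sharing one restricted-cubic-spline basis in age
(shared knots, so the difference curve lives in the same column space):

    y_i | group g  ~  Normal( x(age_i)ᵀ β_g , σ )        (shared σ)
    β_{g,j}        ~  Cauchy(0, s_β)   on centered, scaled columns
    σ              ~  half-Cauchy(0, s_σ),  sampled as λ = log σ

The heavy-tailed Cauchy priors are weakly informative: they regularize
without forcing the trajectory toward zero. The coefficient scale s_β is
2.5 response-sd units by default (rstanarm-style autoscaling): on a 0-30
cognitive scale the spline coefficients of a full-range decline are tens
of points, and a prior fixed at 2.5 raw points would over-shrink weakly
identified directions (the band tails) and destroy coverage. Design columns (except the
intercept) are centered and scaled by their pooled standard deviation
before sampling; posterior curves undo the transform, so the reported
trajectories are unchanged.

Sampler
-------
HMC with a leapfrog integrator at fixed path length (L steps) and
dual-averaging step-size adaptation to a target acceptance rate of 0.8
during warmup (frozen afterwards). Because the spline basis induces
strongly correlated coefficients, warmup also adapts a dense metric: a
middle warmup window estimates the posterior covariance, whose Cholesky
factor whitens the space for the remaining iterations (equivalent to a
dense mass matrix). Warmup is the first half of the iterations;
post-warmup draws are thinned. Default run
configuration: 8 chains × 10,000 iterations, thin 10 → 4,000 retained
draws. Split R-hat and effective sample size are computed per parameter
(via arviz); R-hat > 1.01 triggers a warning, not a failure.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import arviz as az
import numpy as np

from .cohort import Cohort
from .splines import SplineSpec, place_knots, rcs_design

logger = logging.getLogger("cogtraj")

LogPostFn = Callable[[np.ndarray], tuple[float, np.ndarray]]

#: Energy-error threshold beyond which a trajectory is declared divergent.
DIVERGENCE_ENERGY = 1000.0


@dataclass(frozen=True)
class PriorSpec:
    """Coefficient and noise priors.

    ``coef_scale`` applies per centered/scaled design column; with
    ``autoscale`` (the default, following the rstanarm convention) it is
    further multiplied by the sd of the pooled response, so "2.5" means
    2.5 response-sd units and the prior stays weakly informative on any
    outcome scale. ``family="gaussian"`` (with ``sigma_fixed`` in the
    fit) gives the conjugate variant whose posterior mean has a closed
    form — used for sampler validation.
    """

    coef_scale: float = 2.5
    sigma_scale: float = 5.0
    family: str = "cauchy"
    autoscale: bool = True

    def __post_init__(self) -> None:
        if self.coef_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.family not in ("cauchy", "gaussian"):
            raise ValueError(f"unknown prior family {self.family!r}")

    def scaled_to(self, response_sd: float) -> "PriorSpec":
        """Resolve autoscaling against a concrete response scale."""
        if not self.autoscale:
            return self
        return PriorSpec(
            coef_scale=self.coef_scale * max(response_sd, 1e-12),
            sigma_scale=self.sigma_scale,
            family=self.family,
            autoscale=False,
        )


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 8
    iterations: int = 10_000
    thin: int = 10
    warmup: int | None = None  # default: iterations // 2
    n_leapfrog: int = 20
    target_accept: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need ≥ 2 chains for split-R-hat diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")
        if self.warmup is not None and not (0 < self.warmup < self.iterations):
            raise ValueError("warmup must lie in (0, iterations)")

    @property
    def n_warmup(self) -> int:
        return self.warmup if self.warmup is not None else self.iterations // 2

    @property
    def n_kept_per_chain(self) -> int:
        return (self.iterations - self.n_warmup + self.thin - 1) // self.thin


#: Reduced configuration for interactive/desk use; `paper` is the full run.
MCMC_PRESETS: dict[str, McmcConfig] = {
    "desk": McmcConfig(chains=4, iterations=2000, thin=2),
    "paper": McmcConfig(chains=8, iterations=10_000, thin=10),
}


# ---------------------------------------------------------------------------
# Log posterior and gradient
# ---------------------------------------------------------------------------

def _coef_logprior_and_grad(beta: np.ndarray, priors: PriorSpec):
    s = priors.coef_scale
    if priors.family == "cauchy":
        lp = float(np.sum(-np.log(np.pi * s) - np.log1p((beta / s) ** 2)))
        grad = -2.0 * beta / (s**2 + beta**2)
    else:  # gaussian
        lp = float(np.sum(-0.5 * (beta / s) ** 2 - 0.5 * np.log(2 * np.pi * s**2)))
        grad = -beta / s**2
    return lp, grad


def make_log_posterior(
    design_a: np.ndarray,
    y_a: np.ndarray,
    design_b: np.ndarray,
    y_b: np.ndarray,
    priors: PriorSpec = PriorSpec(),
    sigma_fixed: float | None = None,
) -> tuple[LogPostFn, int]:
    """Build the joint log-posterior density and its exact gradient.

    The state vector is [β_A, β_B] plus, when σ is free, λ = log σ (with
    the Jacobian term of the transform included). Sufficient statistics
    (XᵀX, Xᵀy, yᵀy) are precomputed, so each evaluation costs O(p²)
    regardless of sample size.

    Returns (function, dimension); the function maps θ → (logp, ∇logp).
    """
    groups = []
    for X, y in ((design_a, y_a), (design_b, y_b)):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("design/response dimensions inconsistent")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in design or response")
        groups.append((X.T @ X, X.T @ y, float(y @ y), y.size))
    p = design_a.shape[1]
    if design_b.shape[1] != p:
        raise ValueError("both groups must share one basis (equal column counts)")
    free_sigma = sigma_fixed is None
    dim = 2 * p + (1 if free_sigma else 0)
    s_sigma = priors.sigma_scale
    if not free_sigma and sigma_fixed <= 0:
        raise ValueError("sigma_fixed must be positive")

    def logpost(theta: np.ndarray) -> tuple[float, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if not np.isfinite(theta).all():
            raise ValueError("non-finite parameter state")
        betas = (theta[:p], theta[p : 2 * p])
        if free_sigma:
            lam = theta[-1]
            if abs(lam) > 50.0:  # σ astronomically far from any data scale
                return -np.inf, np.zeros(dim)
            sigma = np.exp(lam)
        else:
            sigma = float(sigma_fixed)
        sig2 = sigma * sigma

        lp = 0.0
        grad = np.zeros(dim)
        dlam = 0.0
        for gi, (beta, (G, h, yty, n)) in enumerate(zip(betas, groups)):
            ssr = yty - 2.0 * beta @ h + beta @ (G @ beta)
            lp += -n * np.log(sigma) - 0.5 * n * np.log(2 * np.pi) - ssr / (2.0 * sig2)
            grad[gi * p : (gi + 1) * p] += (h - G @ beta) / sig2
            dlam += -n + ssr / sig2
            plp, pgrad = _coef_logprior_and_grad(beta, priors)
            lp += plp
            grad[gi * p : (gi + 1) * p] += pgrad
        if free_sigma:
            # half-Cauchy(0, s_sigma) on σ plus log-Jacobian of λ = log σ
            lp += np.log(2.0 / (np.pi * s_sigma)) - np.log1p(sig2 / s_sigma**2) + lam
            dlam += -2.0 * sig2 / (s_sigma**2 + sig2) + 1.0
            grad[-1] = dlam
        return float(lp), grad

    return logpost, dim


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------

def _leapfrog(logpost: LogPostFn, theta, r, grad, eps, n_steps):
    theta, r = theta.copy(), r.copy()
    r = r + 0.5 * eps * grad
    lp = -np.inf
    for step in range(n_steps):
        theta = theta + eps * r
        if not np.isfinite(theta).all():
            return theta, r, -np.inf, grad
        lp, grad = logpost(theta)
        if not np.isfinite(lp):
            return theta, r, lp, grad
        r = r + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return theta, r, lp, grad


def _find_reasonable_step(logpost, theta, grad, lp, rng):
    """Stan-style heuristic: scale ε by 2 until the one-step acceptance
    probability crosses 1/2."""
    eps = 0.1
    r = rng.standard_normal(theta.size)
    h0 = lp - 0.5 * r @ r
    theta1, r1, lp1, _ = _leapfrog(logpost, theta, r, grad, eps, 1)
    h1 = lp1 - 0.5 * r1 @ r1 if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0**direction)
        theta1, r1, lp1, _ = _leapfrog(logpost, theta, r, grad, eps, 1)
        h1 = lp1 - 0.5 * r1 @ r1 if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _DualAveraging:
    """Nesterov dual-averaging of log step size toward a target acceptance."""

    def __init__(self, eps0: float, delta: float):
        self.mu = np.log(10.0 * eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0
        self.delta = delta
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, alpha: float) -> float:
        self.m += 1
        self.h_bar = (1 - 1 / (self.m + self.t0)) * self.h_bar + (
            self.delta - alpha
        ) / (self.m + self.t0)
        log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        eta = self.m ** (-self.kappa)
        self.log_eps_bar = eta * log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def frozen(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _run_chain(logpost, dim, config: McmcConfig, init, rng):
    """One HMC chain with windowed warmup adaptation.

    Warmup proceeds in three windows: (1) step-size adaptation under an
    identity metric; (2) continued adaptation while accumulating draws for
    a dense covariance estimate; (3) the space is whitened with the
    Cholesky factor of that estimate (θ = m + C·u — equivalent to a dense
    mass matrix) and the step size is re-adapted. The frozen step and
    metric are then used for sampling.
    """
    warmup = config.n_warmup
    w1 = max(warmup // 4, 1)
    w2 = max(warmup // 2, 1)  # window [w1, w1+w2) accumulates covariance

    # whitening transform: theta = center + chol @ u
    center = np.zeros(dim)
    chol = np.eye(dim)

    def logpost_u(u):
        lp, grad = logpost(center + chol @ u)
        return lp, chol.T @ grad

    u = np.asarray(init, dtype=float).copy()
    lp, grad = logpost_u(u)
    if not np.isfinite(lp):
        raise ValueError("initial state has non-finite log posterior")

    eps = _find_reasonable_step(logpost_u, u, grad, lp, rng)
    adapt = _DualAveraging(eps, config.target_accept)

    window_draws = np.empty((w2, dim))
    n_window = 0

    kept = np.empty((config.n_kept_per_chain, dim))
    n_kept = 0
    divergences = 0
    accept_sum = 0.0
    n_post = 0

    for it in range(config.iterations):
        r0 = rng.standard_normal(dim)
        h0 = lp - 0.5 * r0 @ r0
        # jitter the step ±20% per iteration: a fixed leapfrog path on a
        # near-Gaussian target is nearly periodic and mixes poorly
        eps_it = eps * rng.uniform(0.8, 1.2)
        u1, r1, lp1, grad1 = _leapfrog(logpost_u, u, r0, grad, eps_it, config.n_leapfrog)
        if np.isfinite(lp1):
            h1 = lp1 - 0.5 * r1 @ r1
            delta_h = h1 - h0
        else:
            delta_h = -np.inf
        divergent = (not np.isfinite(delta_h)) or (delta_h < -DIVERGENCE_ENERGY)
        alpha = 0.0 if divergent else min(1.0, float(np.exp(min(delta_h, 0.0))))
        if not divergent and np.log(rng.uniform()) < delta_h:
            u, lp, grad = u1, lp1, grad1

        if it < warmup:
            eps = adapt.update(alpha)
            if w1 <= it < w1 + w2:
                window_draws[n_window] = center + chol @ u
                n_window += 1
            if it == w1 + w2 - 1 and n_window >= max(2 * dim, 10):
                theta_now = center + chol @ u
                sample = window_draws[:n_window]
                cov = np.cov(sample.T) if dim > 1 else np.atleast_2d(np.var(sample))
                cov = cov + 1e-8 * np.eye(dim)
                try:
                    new_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    new_chol = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-8)))
                center = sample.mean(axis=0)
                chol = new_chol
                u = np.linalg.solve(chol, theta_now - center)
                lp, grad = logpost_u(u)
                eps = _find_reasonable_step(logpost_u, u, grad, lp, rng)
                adapt = _DualAveraging(eps, config.target_accept)
            if it == warmup - 1:
                eps = adapt.frozen
        else:
            n_post += 1
            accept_sum += alpha
            divergences += int(divergent)
            if (it - warmup) % config.thin == 0:
                kept[n_kept] = center + chol @ u
                n_kept += 1

    if n_post and divergences > 0.5 * n_post:
        warnings.warn(
            f"{divergences}/{n_post} post-warmup HMC steps diverged; the posterior "
            "geometry is poorly conditioned — reduce the step target or rescale data",
            RuntimeWarning,
            stacklevel=2,
        )
    return kept[:n_kept], {
        "accept_rate": accept_sum / max(n_post, 1),
        "step_size": eps,
        "divergences": divergences,
    }


def hmc_sample(
    logpost: LogPostFn,
    dim: int,
    config: McmcConfig,
    init: np.ndarray | None = None,
    init_jitter: float = 0.01,
) -> tuple[np.ndarray, dict]:
    """Run ``config.chains`` independent HMC chains.

    Returns (draws, diagnostics): draws has shape
    (chains, kept_per_chain, dim); per-chain seeds are spawned
    deterministically from ``config.seed``, so identical configs give
    identical draws.
    """
    base = np.zeros(dim) if init is None else np.asarray(init, dtype=float)
    if base.size != dim:
        raise ValueError(f"init has size {base.size}, expected {dim}")
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains, infos = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        start = base + init_jitter * rng.standard_normal(dim)
        kept, info = _run_chain(logpost, dim, config, start, rng)
        chains.append(kept)
        infos.append(info)
    draws = np.stack(chains)
    diagnostics = {
        "accept_rate": [i["accept_rate"] for i in infos],
        "step_size": [i["step_size"] for i in infos],
        "divergences": [i["divergences"] for i in infos],
    }
    return draws, diagnostics


def convergence_diagnostics(draws: np.ndarray, names: list[str]) -> dict:
    """Split R-hat and bulk ESS per parameter from (chains, draws, dim)."""
    data = {name: draws[:, :, j] for j, name in enumerate(names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(data))
        ess = az.ess(az.convert_to_dataset(data))
    rhats = {name: float(rhat[name].values) for name in names}
    esses = {name: float(ess[name].values) for name in names}
    return {"rhat": rhats, "ess": esses, "max_rhat": max(rhats.values()), "min_ess": min(esses.values())}


# ---------------------------------------------------------------------------
# Trajectory fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorDraws:
    """Thinned post-warmup draws of the two-group trajectory model.

    ``beta_a``/``beta_b`` are in the centered/scaled column parameterization
    (shape chains × kept × p); ``posterior_curves`` undoes the transform.
    ``sigma`` is None when the fit fixed the noise scale.
    """

    beta_a: np.ndarray
    beta_b: np.ndarray
    sigma: np.ndarray | None
    spec: SplineSpec
    column_means: np.ndarray
    column_scales: np.ndarray
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    age_low: float   # 1st percentile of pooled ages (grid support)
    age_high: float  # 99th percentile
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta_a.shape[0] * self.beta_a.shape[1]

    def flat(self, which: str) -> np.ndarray:
        arr = {"a": self.beta_a, "b": self.beta_b}[which]
        return arr.reshape(-1, arr.shape[-1])


def _standardize(design: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return (design - means) / scales


def _group_masks(cohort: Cohort, group: str, stratum: str):
    df = cohort.to_frame()
    if group == "psen1":
        if stratum != "all":
            raise ValueError("group 'psen1' compares strata; use stratum='all'")
        mask_a, mask_b = df["psen1_carrier"], ~df["psen1_carrier"]
        labels = ("carriers", "noncarriers")
    elif group in ("e4", "e2"):
        if stratum == "carriers":
            base = df["psen1_carrier"]
        elif stratum == "noncarriers":
            base = ~df["psen1_carrier"]
        elif stratum == "all":
            base = np.ones(len(df), dtype=bool)
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        flag = df[f"{group}_positive"]
        mask_a, mask_b = base & flag, base & ~flag
        labels = (f"{stratum}_{group}+", f"{stratum}_{group}-")
    else:
        raise ValueError(f"unknown group {group!r}; use 'psen1', 'e4' or 'e2'")
    return df, np.asarray(mask_a), np.asarray(mask_b), labels


def fit_group_trajectories(
    cohort: Cohort,
    group: str = "psen1",
    stratum: str = "all",
    n_knots: int = 5,
    spec: SplineSpec | None = None,
    priors: PriorSpec = PriorSpec(),
    config: McmcConfig = McmcConfig(),
    sigma_fixed: float | None = None,
) -> PosteriorDraws:
    """Jointly fit both groups' spline trajectories (shared knots, shared σ).

    ``group`` selects the comparison: ``"psen1"`` (carriers vs non-carriers),
    or ``"e4"``/``"e2"`` (allele-positive vs -negative within ``stratum``).
    Knots are placed on the pooled ages of both groups unless ``spec`` is
    given.
    """
    df, mask_a, mask_b, (label_a, label_b) = _group_masks(cohort, group, stratum)
    ages_a, ages_b = df["age"][mask_a].to_numpy(), df["age"][mask_b].to_numpy()
    y_a, y_b = df["mmse"][mask_a].to_numpy(float), df["mmse"][mask_b].to_numpy(float)

    if spec is None:
        spec = place_knots(np.concatenate([ages_a, ages_b]), n_knots)
    k = spec.k
    for label, y in ((label_a, y_a), (label_b, y_b)):
        if y.size < k + 2:
            raise ValueError(
                f"group {label!r} has only {y.size} observations; "
                f"need ≥ {k + 2} for a {k}-knot spline fit"
            )

    X_a, X_b = rcs_design(ages_a, spec), rcs_design(ages_b, spec)
    pooled = np.vstack([X_a, X_b])
    means = pooled.mean(axis=0)
    scales = pooled.std(axis=0)
    means[0], scales[0] = 0.0, 1.0  # leave the intercept column alone
    if (scales <= 0).any():
        raise ValueError("degenerate design: a basis column is constant")
    Xs_a, Xs_b = _standardize(X_a, means, scales), _standardize(X_b, means, scales)

    resolved_priors = priors.scaled_to(float(np.std(np.concatenate([y_a, y_b]))))
    logpost, dim = make_log_posterior(Xs_a, y_a, Xs_b, y_b, resolved_priors, sigma_fixed)
    p = k

    # initialize at lightly ridged least squares; λ at the log residual scale
    init = np.zeros(dim)
    resid_var = 0.0
    for gi, (Xs, y) in enumerate(((Xs_a, y_a), (Xs_b, y_b))):
        beta0 = np.linalg.solve(Xs.T @ Xs + 1e-6 * np.eye(p), Xs.T @ y)
        init[gi * p : (gi + 1) * p] = beta0
        resid_var += float(np.sum((y - Xs @ beta0) ** 2))
    if sigma_fixed is None:
        sigma0 = np.sqrt(resid_var / max(y_a.size + y_b.size - 2 * p, 1))
        init[-1] = np.log(max(sigma0, 1e-2))

    draws, diagnostics = hmc_sample(logpost, dim, config, init=init)
    names = [f"beta_a[{j}]" for j in range(p)] + [f"beta_b[{j}]" for j in range(p)]
    if sigma_fixed is None:
        names.append("log_sigma")
    diagnostics.update(convergence_diagnostics(draws, names))
    if diagnostics["max_rhat"] > 1.01:
        warnings.warn(
            f"split R-hat up to {diagnostics['max_rhat']:.3f} > 1.01: "
            "chains may not have converged; consider more iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    logger.info(
        "fit %s vs %s: accept=%s, step=%s, divergences=%s, max R-hat=%.4f",
        label_a,
        label_b,
        [f"{a:.2f}" for a in diagnostics["accept_rate"]],
        [f"{s:.3g}" for s in diagnostics["step_size"]],
        diagnostics["divergences"],
        diagnostics["max_rhat"],
    )

    pooled_ages = np.concatenate([ages_a, ages_b])
    return PosteriorDraws(
        beta_a=draws[:, :, :p],
        beta_b=draws[:, :, p : 2 * p],
        sigma=np.exp(draws[:, :, -1]) if sigma_fixed is None else None,
        spec=spec,
        column_means=means,
        column_scales=scales,
        label_a=label_a,
        label_b=label_b,
        n_a=y_a.size,
        n_b=y_b.size,
        age_low=float(np.percentile(pooled_ages, 1)),
        age_high=float(np.percentile(pooled_ages, 99)),
        diagnostics=diagnostics,
    )


def posterior_curves(draws: PosteriorDraws, ages) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw mean MMSE curves for both groups on an age grid.

    Returns (curves_a, curves_b), each of shape (n_draws, n_ages); each
    curve is the linear functional x(age)ᵀβ of one retained draw.
    """
    design = rcs_design(np.asarray(ages, dtype=float), draws.spec)
    design = _standardize(design, draws.column_means, draws.column_scales)
    return draws.flat("a") @ design.T, draws.flat("b") @ design.T


# ---------------------------------------------------------------------------
# Fit archives
# ---------------------------------------------------------------------------

def save_fit(draws: PosteriorDraws, path: str | Path) -> None:
    """Persist a fit as a flat .npz bundle (draws + spec + diagnostics)."""
    meta = {
        "spec": draws.spec.to_dict(),
        "label_a": draws.label_a,
        "label_b": draws.label_b,
        "n_a": draws.n_a,
        "n_b": draws.n_b,
        "age_low": draws.age_low,
        "age_high": draws.age_high,
        "diagnostics": draws.diagnostics,
    }
    arrays = {
        "beta_a": draws.beta_a,
        "beta_b": draws.beta_b,
        "column_means": draws.column_means,
        "column_scales": draws.column_scales,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if draws.sigma is not None:
        arrays["sigma"] = draws.sigma
    np.savez_compressed(path, **arrays)


def load_fit(path: str | Path) -> PosteriorDraws:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"].tobytes()).decode())
        return PosteriorDraws(
            beta_a=npz["beta_a"],
            beta_b=npz["beta_b"],
            sigma=npz["sigma"] if "sigma" in npz else None,
            spec=SplineSpec.from_dict(meta["spec"]),
            column_means=npz["column_means"],
            column_scales=npz["column_scales"],
            label_a=meta["label_a"],
            label_b=meta["label_b"],
            n_a=int(meta["n_a"]),
            n_b=int(meta["n_b"]),
            age_low=float(meta["age_low"]),
            age_high=float(meta["age_high"]),
            diagnostics=meta["diagnostics"],
        )
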