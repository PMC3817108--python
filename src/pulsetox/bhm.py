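"""Hierarchical overdispersed-Poisson dose-response model fit by MCMC.

Model, for colony i with dosage d_i and brood count y_i::

    y_i ~ Poisson(mu_i)
    log(mu_i) = alpha + beta * log10(d_i + 1) + lambda_i
    lambda_i ~ Normal(0, sigma_lambda**2)

``lambda`` is a colony-level random effect that absorbs overdispersion; its
posterior SD is the quantity reported as SD(λ).  Priors are vague by default
(Normal(0, 100²) on alpha and beta, Uniform(0, 10) on sigma_lambda) and are
dominated by the likelihood at the study's sample size; all are configurable.

The sampler is Metropolis-within-Gibbs with adaptive random-walk blocks:
(alpha, beta) jointly with a covariance-adapted proposal, all lambda_i in a
vectorised elementwise update (they are conditionally independent),
sigma_lambda on the log scale, plus a translation move along the weakly
identified alpha / mean(lambda) ridge.  Adaptation runs during burn-in only,
so the retained chain is a valid time-homogeneous Markov chain.  The
contract is distributional: any ergodic sampler targeting this posterior is
equivalent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "Posterior",
    "ConvergenceWarning",
    "log_posterior",
    "fit_bhm",
    "convergence_diagnostics",
    "posterior_summary",
    "BayesianPoissonDoseResponse",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when chain diagnostics look unhealthy."""


@dataclass(frozen=True)
class PriorSpec:
    """Priors: Normal on alpha and beta, Uniform(0, sigma_upper) on sigma_lambda."""

    alpha_mean: float = 0.0
    alpha_sd: float = 100.0
    beta_mean: float = 0.0
    beta_sd: float = 100.0
    sigma_upper: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha_sd <= 0 or self.beta_sd <= 0:
            raise ValueError("prior SDs must be > 0")
        if self.sigma_upper <= 0:
            raise ValueError("sigma_upper must be > 0")


@dataclass(frozen=True)
class McmcSettings:
    """Chain lengths and seeding.

    Defaults follow the reporting convention of the original analysis:
    40,000 retained draws per chain after a 7,000-iteration burn-in.
    """

    n_retained: int = 40_000
    burn_in: int = 7_000
    n_chains: int = 2
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_retained", "n_chains", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass(frozen=True)
class Posterior:
    """Retained MCMC draws, shaped (n_chains, n_draws[, n_colonies])."""

    alpha: np.ndarray
    beta: np.ndarray
    sigma_lambda: np.ndarray
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        if self.alpha.ndim != 2 or self.lambdas.ndim != 3:
            raise ValueError("draw arrays must be (chains, draws[, colonies])")
        if np.any(self.sigma_lambda < 0):
            raise ValueError("sigma_lambda draws must be >= 0")

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def stack(self, name: str) -> np.ndarray:
        """All chains concatenated into one 1-D (or 2-D for lambdas) array."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Long draws table: chain, iter, alpha, beta, sigma_lambda."""
        c, d = self.alpha.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d),
                "iter": np.tile(np.arange(d), c),
                "alpha": self.alpha.ravel(),
                "beta": self.beta.ravel(),
                "sigma_lambda": self.sigma_lambda.ravel(),
            }
        )


def _as_arrays(records):
    """(dosage, brood) arrays from ColonyRecord iterables or array pairs."""
    if isinstance(records, tuple) and len(records) == 2:
        d, y = np.asarray(records[0], float), np.asarray(records[1])
    else:
        recs = list(records)
        d = np.array([r.dosage for r in recs], float)
        y = np.array([r.brood for r in recs])
    yf = np.asarray(y, float)
    if np.any(yf < 0) or np.any(yf != np.round(yf)):
        raise ValueError("brood counts must be non-negative integers")
    if np.any(d < 0):
        raise ValueError("dosages must be >= 0")
    return d, yf


def log_posterior(alpha, beta, sigma_lambda, lambdas, records, priors=None):
    """Joint log posterior density (up to nothing — all constants included).

    ``sum_i [y_i*eta_i - exp(eta_i) - log(y_i!)]`` with
    ``eta_i = alpha + beta*log10(d_i+1) + lambda_i``, plus the Normal
    log-density of each lambda_i and the log priors.
    """
    priors = priors or PriorSpec()
    if sigma_lambda <= 0:
        raise ValueError("sigma_lambda must be > 0")
    if sigma_lambda > priors.sigma_upper:
        return -np.inf
    d, y = _as_arrays(records)
    lam = np.asarray(lambdas, float)
    if lam.shape != d.shape:
        raise ValueError("need exactly one lambda per record")
    eta = alpha + beta * np.log10(d + 1.0) + lam
    loglik = float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))
    n = lam.size
    lp_lam = float(
        -0.5 * np.sum(lam**2) / sigma_lambda**2
        - n * math.log(sigma_lambda)
        - 0.5 * n * math.log(2 * math.pi)
    )
    lp = (
        -0.5 * ((alpha - priors.alpha_mean) / priors.alpha_sd) ** 2
        - math.log(priors.alpha_sd) - 0.5 * math.log(2 * math.pi)
        - 0.5 * ((beta - priors.beta_mean) / priors.beta_sd) ** 2
        - math.log(priors.beta_sd) - 0.5 * math.log(2 * math.pi)
        - math.log(priors.sigma_upper)
    )
    return loglik + lp_lam + lp


def _run_chain(L, y, priors, *, n_retained, burn_in, thin, rng,
               beta_fixed=None, init=None):
    """One Metropolis-within-Gibbs chain.  Returns draw arrays.

    The working state is the vector of colony log-means
    ``theta_i = alpha + beta*L_i + lambda_i``: the Poisson likelihood
    depends on theta only, so given theta the coefficients have an exact
    Gaussian conditional (a linear regression of theta on L with noise
    sigma) and sigma an exact truncated inverse-gamma conditional.  Only
    the elementwise theta updates are Metropolis steps, with per-colony
    scales adapted during burn-in.  This mixes well both when sigma is
    near zero and when overdispersion is large.
    """
    n = L.size
    alpha = math.log(y.mean() + 0.5)
    beta = 0.0 if beta_fixed is None else float(beta_fixed)
    sigma = 1.0
    lam = np.zeros(n)
    if init is not None:
        alpha = init.get("alpha", alpha)
        beta = init.get("beta", beta)
        sigma = init.get("sigma_lambda", sigma)
        lam = np.array(init.get("lambdas", lam), float)
    theta = alpha + beta * L + lam

    pa_var = priors.alpha_sd**2
    pb_var = priors.beta_sd**2
    am, bm = priors.alpha_mean, priors.beta_mean
    sum_L = float(L.sum())
    sum_LL = float(L @ L)

    s_th = np.full(n, 1.0)
    acc_th = np.zeros(n)
    s_sig = 0.5
    s_ab = 0.2
    chol_ab = np.eye(2)
    acc_sig = acc_ab = 0
    win = 0
    ab_hist = np.empty((max(burn_in, 1), 2))

    out_a = np.empty(n_retained)
    out_b = np.empty(n_retained)
    out_s = np.empty(n_retained)
    out_l = np.empty((n_retained, n))
    k = 0

    n_iter = burn_in + n_retained * thin
    for it in range(n_iter):
        # --- theta: vectorised elementwise Metropolis
        m = alpha + beta * L
        prop = theta + s_th * rng.standard_normal(n)
        d_vec = (
            y * (prop - theta)
            - (np.exp(prop) - np.exp(theta))
            - ((prop - m) ** 2 - (theta - m) ** 2) / (2 * sigma**2)
        )
        acc = np.log(rng.random(n)) < d_vec
        theta = np.where(acc, prop, theta)
        acc_th += acc

        # --- (alpha, beta) | theta, sigma: exact Gaussian conditional
        v = sigma**2
        if beta_fixed is None:
            prec = np.array(
                [[n / v + 1.0 / pa_var, sum_L / v],
                 [sum_L / v, sum_LL / v + 1.0 / pb_var]]
            )
            rhs = np.array(
                [theta.sum() / v + am / pa_var,
                 float(theta @ L) / v + bm / pb_var]
            )
            cf = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(2)
            alpha, beta = mean + np.linalg.solve(cf.T, z)
        else:
            prec = n / v + 1.0 / pa_var
            mean = (float(np.sum(theta - beta * L)) / v + am / pa_var) / prec
            alpha = mean + rng.standard_normal() / math.sqrt(prec)

        # --- interweaved centered step for the coefficients: hold the
        # residuals lambda fixed and move (alpha, beta) through the
        # likelihood.  Complements the exact draw above, which mixes
        # slowly when sigma is small and theta is pinned to the line.
        lam = theta - (alpha + beta * L)
        step = s_ab * (chol_ab @ rng.standard_normal(2))
        if beta_fixed is not None:
            step[1] = 0.0
        a_p, b_p = alpha + step[0], beta + step[1]
        theta_p = theta + step[0] + step[1] * L
        d = float(np.sum(y * (theta_p - theta) - (np.exp(theta_p) - np.exp(theta))))
        d += ((alpha - am) ** 2 - (a_p - am) ** 2) / (2 * pa_var)
        d += ((beta - bm) ** 2 - (b_p - bm) ** 2) / (2 * pb_var)
        if math.log(rng.random()) < d:
            alpha, beta, theta = a_p, b_p, theta_p
            acc_ab += 1

        # --- sigma | theta, alpha, beta: with a Uniform(0, upper) prior on
        # sigma, sigma^2 is InvGamma((n-1)/2, ssq/2) truncated at upper^2;
        # sample the precision, rejecting the (rare) overflow.
        lam = theta - (alpha + beta * L)
        ssq = float(lam @ lam)
        if ssq > 0 and n >= 2:
            for _ in range(100):
                tau = rng.gamma((n - 1) / 2.0, 2.0 / ssq)
                if tau >= 1.0 / priors.sigma_upper**2:
                    sigma = 1.0 / math.sqrt(tau)
                    break

        # --- interweaved ancillary sigma step: hold u = lambda/sigma fixed
        # and move sigma on the log scale, rescaling lambda through the
        # likelihood.  Breaks the funnel between sigma and the residuals
        # when sigma is small.
        if ssq > 0:
            t_p = math.log(sigma) + s_sig * rng.standard_normal()
            sig_p = math.exp(t_p)
            if sig_p <= priors.sigma_upper:
                m = alpha + beta * L
                theta_p = m + (sig_p / sigma) * lam
                d = float(
                    np.sum(y * (theta_p - theta) - (np.exp(theta_p) - np.exp(theta)))
                )
                d += t_p - math.log(sigma)  # uniform prior on sigma, log scale
                if math.log(rng.random()) < d:
                    sigma = sig_p
                    theta = theta_p
                    lam = theta - m
                    acc_sig += 1

        # --- burn-in-only adaptation of the step sizes
        if it < burn_in:
            ab_hist[it] = (alpha, beta)
            win += 1
            if win == 50:
                s_th *= np.exp(0.4 * (acc_th / 50 - 0.44))
                np.clip(s_th, 1e-3, 50.0, out=s_th)
                s_sig = min(max(s_sig * math.exp(0.5 * (acc_sig / 50 - 0.35)),
                                1e-3), 10.0)
                s_ab = min(max(s_ab * math.exp(0.5 * (acc_ab / 50 - 0.25)),
                               1e-4), 10.0)
                acc_th[:] = 0.0
                acc_sig = acc_ab = 0
                win = 0
            if beta_fixed is None and it >= 400 and it + 1 in (burn_in // 2, burn_in):
                cov = np.cov(ab_hist[(it + 1) // 2: it + 1].T) + 1e-10 * np.eye(2)
                try:
                    chol_ab = np.linalg.cholesky(cov)
                    s_ab = 2.38 / math.sqrt(2)
                except np.linalg.LinAlgError:
                    pass
        else:
            j = it - burn_in
            if j % thin == 0:
                out_a[k] = alpha
                out_b[k] = beta
                out_s[k] = sigma
                out_l[k] = lam
                k += 1

    return out_a[:k], out_b[:k], out_s[:k], out_l[:k]


class BayesianPoissonDoseResponse(BaseEstimator, RegressorMixin):
    """Bayesian hierarchical Poisson dose-response regression.

    scikit-learn style estimator: ``X`` is the dosage (shape ``(n,)`` or
    ``(n, 1)``, µg kg⁻¹), ``y`` the brood count per colony.  ``fit`` runs
    the MCMC and exposes the retained draws as ``posterior_`` together with
    posterior-mean coefficients and convergence diagnostics.

    Parameters mirror :class:`PriorSpec` and :class:`McmcSettings`.
    ``beta_fixed`` pins the slope (e.g. 0 for an intercept-only fit, which
    is also the only valid option when all dosages are identical).

    Attributes
    ----------
    posterior_ : Posterior
    alpha_, beta_, sigma_lambda_ : float
        Posterior means.
    summary_ : pandas.DataFrame
        Means, medians, SDs and central 95% intervals.
    diagnostics_ : pandas.DataFrame
        Split-Rhat and effective sample size per parameter.
    """

    def __init__(
        self,
        *,
        alpha_mean: float = 0.0,
        alpha_sd: float = 100.0,
        beta_mean: float = 0.0,
        beta_sd: float = 100.0,
        sigma_upper: float = 10.0,
        n_retained: int = 40_000,
        burn_in: int = 7_000,
        n_chains: int = 2,
        thin: int = 1,
        beta_fixed: float | None = None,
        random_state: int | None = None,
    ):
        self.alpha_mean = alpha_mean
        self.alpha_sd = alpha_sd
        self.beta_mean = beta_mean
        self.beta_sd = beta_sd
        self.sigma_upper = sigma_upper
        self.n_retained = n_retained
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.thin = thin
        self.beta_fixed = beta_fixed
        self.random_state = random_state

    def _priors(self) -> PriorSpec:
        return PriorSpec(
            alpha_mean=self.alpha_mean,
            alpha_sd=self.alpha_sd,
            beta_mean=self.beta_mean,
            beta_sd=self.beta_sd,
            sigma_upper=self.sigma_upper,
        )

    def fit(self, X, y):
        d = np.asarray(X, float)
        if d.ndim == 2:
            if d.shape[1] != 1:
                raise ValueError("X must be a single dosage column")
            d = d[:, 0]
        d, yf = _as_arrays((d, y))
        if d.size < 2:
            raise ValueError("need at least 2 records")
        if np.unique(d).size < 2 and self.beta_fixed is None:
            raise ValueError(
                "all dosages identical: the slope is unidentifiable; "
                "set beta_fixed=0 for an intercept-only fit"
            )
        priors = self._priors()
        L = np.log10(d + 1.0)
        ss = np.random.SeedSequence(self.random_state)
        draws = [
            _run_chain(
                L, yf, priors,
                n_retained=self.n_retained, burn_in=self.burn_in,
                thin=self.thin, rng=np.random.default_rng(child),
                beta_fixed=self.beta_fixed,
            )
            for child in ss.spawn(self.n_chains)
        ]
        self.posterior_ = Posterior(
            alpha=np.stack([a for a, _, _, _ in draws]),
            beta=np.stack([b for _, b, _, _ in draws]),
            sigma_lambda=np.stack([s for _, _, s, _ in draws]),
            lambdas=np.stack([l for _, _, _, l in draws]),
        )
        self.alpha_ = float(self.posterior_.stack("alpha").mean())
        self.beta_ = float(self.posterior_.stack("beta").mean())
        self.sigma_lambda_ = float(self.posterior_.stack("sigma_lambda").mean())
        self.summary_ = posterior_summary(self.posterior_)
        self.diagnostics_ = convergence_diagnostics(self.posterior_)
        self.n_features_in_ = 1
        bad = self.diagnostics_["flagged"].any()
        if bad:
            warnings.warn(
                "MCMC convergence diagnostics flagged (Rhat > 1.05 or "
                "undefined); inspect diagnostics_ before trusting summaries",
                ConvergenceWarning,
                stacklevel=2,
            )
        return self

    def predict(self, X):
        """Median-colony expected brood at the posterior-median curve."""
        from .curves import credible_band  # local import to avoid cycle

        d = np.asarray(X, float)
        if d.ndim == 2:
            d = d[:, 0]
        return credible_band(self.posterior_, d).point


def fit_bhm(records, priors: PriorSpec | None = None,
            settings: McmcSettings | None = None) -> Posterior:
    """Fit the hierarchical model to colony records; returns the Posterior.

    Thin wrapper over :class:`BayesianPoissonDoseResponse` for record
    collections (uses each record's dosage and brood).
    """
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    d, y = _as_arrays(records)
    est = BayesianPoissonDoseResponse(
        alpha_mean=priors.alpha_mean, alpha_sd=priors.alpha_sd,
        beta_mean=priors.beta_mean, beta_sd=priors.beta_sd,
        sigma_upper=priors.sigma_upper,
        n_retained=settings.n_retained, burn_in=settings.burn_in,
        n_chains=settings.n_chains, thin=settings.thin,
        random_state=settings.seed,
    ).fit(d, y)
    return est.posterior_


def _split_rhat(x: np.ndarray) -> float:
    """Classic split-chain Rhat (variance-ratio formula) for (chains, draws)."""
    c, d = x.shape
    if d < 4:
        return float("nan")
    half = d // 2
    splits = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, nn = splits.shape
    W = splits.var(axis=1, ddof=1).mean()
    if W == 0:
        return float("nan")
    B = nn * splits.mean(axis=1).var(ddof=1)
    var_hat = (nn - 1) / nn * W + B / nn
    return float(math.sqrt(var_hat / W))


def convergence_diagnostics(posterior: Posterior) -> pd.DataFrame:
    """Split-Rhat and effective sample size for alpha, beta, sigma_lambda.

    ``flagged`` is True when Rhat exceeds 1.05 or is undefined (zero
    within-chain variance).  With a single chain Rhat is still computed by
    splitting it, but a warning notes the reduced diagnostic power.
    """
    import arviz as az

    if posterior.n_chains < 2:
        warnings.warn(
            "single chain: split-Rhat has reduced power; ESS still reported",
            ConvergenceWarning,
            stacklevel=2,
        )
    rows = []
    for name in ("alpha", "beta", "sigma_lambda"):
        arr = getattr(posterior, name)
        rhat = _split_rhat(arr)
        ess = float(
            az.ess(az.convert_to_dataset(arr, group="posterior"))["x"].item()
        )
        rows.append(
            {
                "parameter": name,
                "rhat": rhat,
                "ess": ess,
                "flagged": (not np.isfinite(rhat)) or rhat > 1.05,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def posterior_summary(posterior: Posterior) -> pd.DataFrame:
    """Mean, median, SD and central 95% interval for the three parameters."""
    rows = []
    for name in ("alpha", "beta", "sigma_lambda"):
        x = posterior.stack(name)
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "median": float(med),
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                "q2.5": float(lo),
                "q97.5": float(hi),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
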