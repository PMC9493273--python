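"""Bayesian multi-kernel mixed model fitted by Gibbs sampling.

The model is

    y = mu * 1 + sum_t u_t + eps,    u_t ~ N(0, K_t * sigma_t^2),
    eps ~ N(0, I * sigma_e^2),

with one record-level kernel K_t per random term (environment, line,
soil, genomic, and the Hadamard interaction terms).  Each u_t is
reparameterized through the eigendecomposition K_t = Gamma_t Lambda_t
Gamma_tᵀ as u_t = Gamma_t alpha_t with independent coordinates
alpha_tl ~ N(0, lambda_tl * sigma_t^2), which makes every full
conditional univariate Gaussian.  Variances carry scaled-inverse-
chi-square priors and are sampled from their conjugate full
conditionals.  Missing phenotypes are handled by data augmentation:
they are redrawn from the current linear predictor plus residual noise
at every iteration, so masked records contribute no likelihood
information but receive posterior predictions for free.

A deterministic closed-form BLUP solver (:func:`mme_oracle`) with
fixed variances is provided as an independent cross-check of the
sampler.

The scikit-learn estimator wrapper lives in :mod:`soilnorm.estimator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelSet

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "FitResult",
    "fit",
    "mme_oracle",
    "variance_components",
]

EIGEN_TOL = 1e-10  # relative cutoff below which kernel eigenvalues are dropped
JITTER = 1e-8


@dataclass
class PriorSpec:
    """Scaled-inverse-chi-square priors on the variance components.

    By default every term and the residual get ``df`` degrees of
    freedom, and the scales are derived from the observed phenotypic
    variance: the residual prior mode is ``(1 - r2) * var(y)`` and the
    ``T`` random terms share the remaining ``r2 * var(y)`` equally,
    mirroring the usual R2-based elicitation for Bayesian genomic
    models.  Explicit ``df_by_term`` / ``scale_by_term`` entries
    (keyed by term name or ``"R"`` for the residual) override the
    automatic choice.
    """

    df: float = 5.0
    r2: float = 0.5
    df_by_term: dict[str, float] = field(default_factory=dict)
    scale_by_term: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("prior degrees of freedom must be > 0")
        if not 0 < self.r2 < 1:
            raise ValueError("target R2 split must lie in (0, 1)")

    def resolve(self, terms: tuple[str, ...], var_y: float) -> dict[str, tuple[float, float]]:
        """Return {term: (df, scale)} including the residual ``"R"``.

        The scale is chosen so the prior *mode* ``df * Sc / (df + 2)``
        hits the elicited share of ``var_y``.
        """
        var_y = max(var_y, 1e-12)
        out: dict[str, tuple[float, float]] = {}
        T = len(terms)
        for name in (*terms, "R"):
            df = self.df_by_term.get(name, self.df)
            if name in self.scale_by_term:
                sc = self.scale_by_term[name]
            else:
                mode = (1 - self.r2) * var_y if name == "R" else self.r2 * var_y / T
                sc = mode * (df + 2) / df
            if df <= 0 or sc <= 0:
                raise ValueError(f"prior for {name!r} must have df > 0 and scale > 0")
            out[name] = (df, sc)
        return out


@dataclass
class McmcConfig:
    """Chain length settings for the Gibbs sampler."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1 or self.n_iter < 1:
            raise ValueError("n_iter and thin must be positive")


@dataclass
class FitResult:
    """Posterior summaries of one Gibbs fit."""

    model_id: str
    mu: float
    mu_sd: float
    var_components: dict[str, float]
    var_components_sd: dict[str, float]
    effects: dict[str, np.ndarray]  # posterior-mean record-level u_t
    fitted: np.ndarray              # posterior mean of mu + sum_t u_t
    fitted_sd: np.ndarray           # posterior sd of the linear predictor
    fitted_mcse: np.ndarray         # Monte-Carlo s.e. of `fitted`
    y: np.ndarray
    missing_mask: np.ndarray
    n_samples: int
    ess: dict[str, float]           # crude effective sample sizes, sigma2 chains
    samples: dict[str, np.ndarray] | None = None

    @property
    def predictions(self) -> np.ndarray:
        """Posterior-mean predictions for the masked records."""
        return self.fitted[self.missing_mask]

    @property
    def residuals(self) -> np.ndarray:
        """Observed minus fitted, NaN at masked records."""
        r = self.y - self.fitted
        r[self.missing_mask] = np.nan
        return r

    def variance_table(self) -> pd.DataFrame:
        rows = [
            {"term": t, "estimate": self.var_components[t], "sd": self.var_components_sd[t]}
            for t in self.var_components
        ]
        return pd.DataFrame(rows)


def _eigen_bases(kernels: KernelSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Eigendecompose each record-level kernel once, dropping null space."""
    bases = {}
    for term in kernels.terms:
        K = kernels[term].values
        w, V = np.linalg.eigh(K)
        keep = w > EIGEN_TOL * max(w[-1], 1.0)
        if not keep.any():
            raise ValueError(f"kernel {term!r} has no positive eigenvalues")
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError(f"kernel {term!r} is not PSD within tolerance")
        bases[term] = (V[:, keep], w[keep])
    return bases


def _ess(chain: np.ndarray) -> float:
    """Crude autocorrelation-based effective sample size."""
    n = len(chain)
    if n < 10 or np.var(chain) == 0:
        return float(n)
    x = chain - chain.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, n):
        if acf[k] < 0.05:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


def fit(
    y: np.ndarray,
    kernels: KernelSet,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    *,
    fixed_variances: dict[str, float] | None = None,
    fix_mu: float | None = None,
    keep_samples: bool = False,
) -> FitResult:
    """Fit the multi-kernel model by Gibbs sampling.

    Parameters
    ----------
    y
        Phenotypes aligned with the kernels' record axis; NaN marks
        masked records to be predicted.
    fixed_variances
        Optional {term: sigma^2} (``"R"`` for the residual).  Terms
        present here are held fixed instead of sampled — used for
        oracle cross-checks.
    fix_mu
        Pin the intercept at this value instead of sampling it.

    Same seed implies bit-identical output.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    fixed_variances = fixed_variances or {}
    y = np.asarray(y, dtype=float)
    n = kernels.n_records
    if y.shape != (n,):
        raise ValueError(f"y length {y.shape} does not match records {n}")
    miss = ~np.isfinite(y)
    n_obs = int((~miss).sum())
    if n_obs < 2:
        raise ValueError("need at least 2 observed records")
    terms = kernels.terms
    var_y = float(np.var(y[~miss]))
    prior = priors.resolve(terms, var_y)
    bases = _eigen_bases(kernels)
    rng = np.random.default_rng(mcmc.seed)

    # state
    mu = fix_mu if fix_mu is not None else float(np.mean(y[~miss]))
    sigma2 = {}
    for t in (*terms, "R"):
        df_t, sc_t = prior[t]
        sigma2[t] = fixed_variances.get(t, df_t * sc_t / (df_t + 2))
    y_aug = y.copy()
    y_aug[miss] = mu
    alpha = {t: np.zeros(bases[t][1].shape[0]) for t in terms}
    u = {t: np.zeros(n) for t in terms}
    total_u = np.zeros(n)

    n_kept = (mcmc.n_iter - mcmc.burn_in) // mcmc.thin
    acc_mu, acc_mu2 = 0.0, 0.0
    acc_s = {t: 0.0 for t in (*terms, "R")}
    acc_s2 = {t: 0.0 for t in (*terms, "R")}
    acc_u = {t: np.zeros(n) for t in terms}
    acc_eta = np.zeros(n)
    acc_eta2 = np.zeros(n)
    chains = {t: np.empty(n_kept) for t in (*terms, "R")}
    eta_draws = np.empty((n_kept, n)) if keep_samples else None
    # running Monte-Carlo error of the linear predictor via thinned draws
    eta_store = np.empty((n_kept, int(miss.sum()))) if miss.any() else None
    eta_store_all = np.empty((n_kept, n))

    kept = 0
    for it in range(mcmc.n_iter):
        # intercept
        if fix_mu is None:
            resid_mean = float(np.mean(y_aug - total_u))
            mu = resid_mean + rng.normal() * np.sqrt(sigma2["R"] / n)
        # random effects, term by term
        for t in terms:
            V, lam = bases[t]
            ystar = y_aug - mu - (total_u - u[t])
            v = V.T @ ystar
            prec = 1.0 / sigma2["R"] + 1.0 / (lam * sigma2[t])
            mean = (v / sigma2["R"]) / prec
            alpha[t] = mean + rng.normal(size=lam.shape[0]) / np.sqrt(prec)
            new_u = V @ alpha[t]
            total_u += new_u - u[t]
            u[t] = new_u
        # variance components
        for t in terms:
            if t in fixed_variances:
                continue
            df_t, sc_t = prior[t]
            lam = bases[t][1]
            ss = float(np.sum(alpha[t] ** 2 / lam))
            df_post = df_t + lam.shape[0]
            sigma2[t] = (df_t * sc_t + ss) / rng.chisquare(df_post)
        if "R" not in fixed_variances:
            df_r, sc_r = prior["R"]
            eps = y_aug - mu - total_u
            ss = float(eps @ eps)
            sigma2["R"] = (df_r * sc_r + ss) / rng.chisquare(df_r + n)
        # data augmentation for masked records
        if miss.any():
            eta_miss = mu + total_u[miss]
            y_aug[miss] = eta_miss + rng.normal(size=int(miss.sum())) * np.sqrt(sigma2["R"])

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            eta = mu + total_u
            acc_mu += mu
            acc_mu2 += mu * mu
            for t in terms:
                acc_u[t] += u[t]
            for t in (*terms, "R"):
                acc_s[t] += sigma2[t]
                acc_s2[t] += sigma2[t] ** 2
                chains[t][kept] = sigma2[t]
            acc_eta += eta
            acc_eta2 += eta * eta
            eta_store_all[kept] = eta
            if keep_samples:
                eta_draws[kept] = eta
            kept += 1

    if kept == 0:
        raise ValueError("no post-burn-in samples retained; adjust n_iter/thin")

    def _sd(s, s2, k):
        return float(np.sqrt(max(s2 / k - (s / k) ** 2, 0.0)))

    fitted = acc_eta / kept
    fitted_sd = np.sqrt(np.maximum(acc_eta2 / kept - fitted**2, 0.0))
    # Monte-Carlo s.e. of the posterior mean by batch means: thinned
    # draws remain autocorrelated when kernels overlap, so sd/sqrt(K)
    # would understate the error
    n_batches = 20
    if kept >= 2 * n_batches:
        usable = kept - kept % n_batches
        batches = eta_store_all[:usable].reshape(n_batches, usable // n_batches, n)
        bmeans = batches.mean(axis=1)
        fitted_mcse = bmeans.std(axis=0, ddof=1) / np.sqrt(n_batches)
    else:
        fitted_mcse = fitted_sd / np.sqrt(max(kept, 1))
    var_mean = {t: acc_s[t] / kept for t in (*terms, "R")}
    var_sd = {t: _sd(acc_s[t], acc_s2[t], kept) for t in (*terms, "R")}
    ess = {t: _ess(chains[t]) for t in (*terms, "R")}
    return FitResult(
        model_id=kernels.model_id,
        mu=acc_mu / kept,
        mu_sd=_sd(acc_mu, acc_mu2, kept),
        var_components=var_mean,
        var_components_sd=var_sd,
        effects={t: acc_u[t] / kept for t in terms},
        fitted=fitted,
        fitted_sd=fitted_sd,
        fitted_mcse=fitted_mcse,
        y=y,
        missing_mask=miss,
        n_samples=kept,
        ess=ess,
        samples={"eta": eta_draws, **{t: chains[t] for t in chains}} if keep_samples else None,
    )


def mme_oracle(
    y: np.ndarray,
    train_mask: np.ndarray,
    kernels: KernelSet,
    variances: dict[str, float],
) -> np.ndarray:
    """Closed-form BLUP predictions with all variances fixed.

    Builds C = sum_t sigma_t^2 K_t and returns, for every record,

        yhat = C[:, train] (C[train, train] + sigma_e^2 I)^-1
               (y_train - ybar) + ybar

    which is the conditional mean of the joint Gaussian model centered
    at the training average.  Deterministic; used as the independent
    cross-check of the Gibbs sampler.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    y = np.asarray(y, dtype=float)
    n = kernels.n_records
    missing = [t for t in (*kernels.terms, "R") if t not in variances]
    if missing:
        raise ValueError(f"variances missing for terms {missing}")
    if any(v < 0 for v in variances.values()) or variances["R"] <= 0:
        raise ValueError("variances must be nonnegative, residual positive")
    C = np.zeros((n, n))
    for t in kernels.terms:
        C += variances[t] * kernels[t].values
    ybar = float(np.mean(y[train_mask]))
    V = C[np.ix_(train_mask, train_mask)] + variances["R"] * np.eye(int(train_mask.sum()))
    V[np.diag_indices_from(V)] += JITTER
    rhs = np.linalg.solve(V, y[train_mask] - ybar)
    return C[:, train_mask] @ rhs + ybar


def variance_components(result: FitResult) -> pd.DataFrame:
    """Posterior mean and SD of each variance component (residual ``R``)."""
    return result.variance_table()
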