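"""Bayesian multivariate linear mixed-effects model via Gibbs sampling.

The model for the 10-dimensional outcome vector of child *i* of mother *j*::

    Y_ij = beta0 + beta1 * T_ij + beta2' X_ij + b_j + eps_ij
    b_j   ~ MVN(0, Sigma_b)        (mother-level random intercept)
    eps_ij ~ MVN(0, Sigma_e)       (unstructured residual covariance)

with T the binary exposure and X the adjustment covariates.  Conjugate
priors: every fixed-effect coefficient is MVN(0, v0) with a very large v0
(effectively non-informative), and both covariance matrices carry
inverse-Wishart priors IW(nu, S) in the convention where the prior mean is
S / (nu - p - 1) for nu > p + 1.

All four full-conditional updates are conjugate, so the posterior is
explored with a plain Gibbs sweep: stacked coefficients (matrix normal),
per-cluster random intercepts (independent MVNs), then the two covariance
matrices (inverse-Wishart).  Inference is reported as posterior means with
highest-posterior-density (HPD) intervals; an effect is flagged significant
when its 95% HPD interval excludes zero.

Usage follows the statsmodels pattern::

    model = MultivariateMixedLM.from_dataframes(outcome_table, sample_sheet)
    res = model.fit(config=GibbsConfig(n_iter=20000, burn_in=5000, seed=1))
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .cohort import covariate_matrix
from .eaa import OUTCOME_NAMES

__all__ = [
    "MLMEPriors",
    "GibbsConfig",
    "MultivariateMixedLM",
    "MLMEResults",
    "MLMEError",
    "hpd_interval",
    "flag_significance",
    "effective_sample_size",
]


class MLMEError(ValueError):
    pass


@dataclass
class MLMEPriors:
    """Conjugate prior hyperparameters.

    beta_prior_variance : prior variance v0 of each fixed-effect coefficient
        (MVN(0, v0 I)); the default 1e9 is effectively flat.
    iw_df, iw_scale : inverse-Wishart degrees of freedom and scale shared by
        Sigma_b and Sigma_e.  With df equal to the outcome dimension the
        prior mean is undefined — this is accepted as a deliberately weak
        prior; validity only requires df >= dimension.
    """

    beta_prior_variance: float = 1e9
    iw_df: float = 10.0
    iw_scale: np.ndarray | None = None  # defaults to identity at fit time

    def validate(self, p: int) -> np.ndarray:
        if self.beta_prior_variance <= 0:
            raise MLMEError("beta_prior_variance must be positive")
        if self.iw_df < p:
            raise MLMEError(f"iw_df must be >= outcome dimension ({p})")
        scale = np.eye(p) if self.iw_scale is None else np.asarray(self.iw_scale, float)
        if scale.shape != (p, p) or not np.allclose(scale, scale.T):
            raise MLMEError(f"iw_scale must be symmetric {p}x{p}")
        if np.linalg.eigvalsh(scale).min() <= 0:
            raise MLMEError("iw_scale must be positive definite")
        return scale


@dataclass
class GibbsConfig:
    """Sampler settings: sweep count, burn-in, thinning, seed, HPD mass."""

    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 1
    seed: int = 0
    hpd_prob: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise MLMEError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise MLMEError("thin must be >= 1")
        if not (0.0 < self.hpd_prob < 1.0):
            raise MLMEError("hpd_prob must be in (0, 1)")


# ---------------------------------------------------------------------------
# summary statistics on draws
# ---------------------------------------------------------------------------


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(prob * n)`` order
    statistics of the draws; ties go to the lowest start index."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise MLMEError(f"need at least 20 draws for an HPD interval, got {n}")
    if not (0.0 < prob < 1.0):
        raise MLMEError("prob must be in (0, 1)")
    m = math.ceil(prob * n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + m - 1])


def flag_significance(lower, upper):
    """HPD-excludes-zero rule: significant iff lower > 0 or upper < 0."""
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    sig = (lo > 0.0) | (hi < 0.0)
    if isinstance(lower, pd.DataFrame):
        return pd.DataFrame(sig, index=lower.index, columns=lower.columns)
    if isinstance(lower, pd.Series):
        return pd.Series(sig, index=lower.index)
    return sig


def effective_sample_size(chain: np.ndarray) -> float:
    """Autocorrelation-based ESS (initial monotone positive sequence).

    Sums the autocorrelation function in lag pairs, truncating at the first
    non-positive pair and enforcing monotone decrease, which gives a stable
    estimate of the integrated autocorrelation time.  A constant chain has
    no information about mixing and is flagged with NaN.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise MLMEError("chain too short for an ESS estimate")
    xc = x - x.mean()
    var = xc @ xc / n
    if var == 0.0:
        return float("nan")
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    rho = acov / acov[0]
    # Geyer pairs: Gamma_k = rho_{2k} + rho_{2k+1}
    n_pairs = n // 2
    gam = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    tau = 0.0
    prev = np.inf
    for g in gam:
        if g <= 0.0:
            break
        g = min(g, prev)
        tau += g
        prev = g
    iact = max(2.0 * tau - 1.0, 1.0 / n)
    return float(min(n / iact, n))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class MultivariateMixedLM:
    """Multivariate linear mixed model with cluster random intercepts.

    Parameters
    ----------
    endog : (N, p) array
        Outcome matrix (one row per child, one column per outcome).
    exposure : (N,) array of {0, 1}
        Binary exposure indicator.
    exog_covariates : (N, c) array or None
        Adjustment covariates (no constant column; an intercept is added).
    groups : (N,) array
        Cluster (mother) identifier per row.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exposure: np.ndarray,
        exog_covariates: np.ndarray | None,
        groups: Sequence,
        outcome_names: Sequence[str] | None = None,
        covariate_names: Sequence[str] | None = None,
    ) -> None:
        Y = np.asarray(endog, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        T = np.asarray(exposure, dtype=float).ravel()
        N, p = Y.shape
        if T.shape != (N,):
            raise MLMEError("exposure length does not match outcomes")
        if exog_covariates is None:
            X = np.empty((N, 0))
        else:
            X = np.asarray(exog_covariates, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        Z = np.column_stack([np.ones(N), T, X])
        if np.isnan(Y).any() or np.isnan(Z).any():
            raise MLMEError("missing values in outcomes or design")
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise MLMEError("design matrix [1, exposure, covariates] is rank deficient")
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2:
            raise MLMEError("need at least 2 clusters")
        self.endog = Y
        self.design = Z
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.n_obs, self.n_outcomes = N, p
        self.n_coef = Z.shape[1]
        self.outcome_names = list(
            outcome_names
            if outcome_names is not None
            else [f"y{k}" for k in range(p)]
        )
        cov_names = list(
            covariate_names
            if covariate_names is not None
            else [f"x{k}" for k in range(X.shape[1])]
        )
        self.coef_names = ["intercept", "exposure", *cov_names]
        if len(self.coef_names) != self.n_coef or len(self.outcome_names) != p:
            raise MLMEError("name lengths do not match design dimensions")
        # cluster bookkeeping for vectorized random-effect updates
        self._cluster_sizes = np.bincount(codes)
        self._J = len(uniques)

    @classmethod
    def from_dataframes(
        cls, outcomes: pd.DataFrame, sheet: pd.DataFrame
    ) -> "MultivariateMixedLM":
        """Build from an outcome table (child_id, mother_id + 10 outcome
        columns) joined with a sample sheet on child_id."""
        merged = outcomes.merge(
            sheet, on="child_id", how="inner", suffixes=("", "_sheet")
        )
        if len(merged) != len(outcomes) or len(merged) != len(sheet):
            raise MLMEError("child ids of outcome table and sample sheet differ")
        missing = [n for n in OUTCOME_NAMES if n not in merged.columns]
        if missing:
            raise MLMEError(f"outcome table lacks columns {missing}")
        X = covariate_matrix(merged)
        return cls(
            endog=merged[list(OUTCOME_NAMES)].to_numpy(dtype=float),
            exposure=merged["exposed"].to_numpy(),
            exog_covariates=X,
            groups=merged["mother_id"].to_numpy(),
            outcome_names=list(OUTCOME_NAMES),
            covariate_names=["gravida", "sex_male", "season_wet", "epi_prop", "fib_prop"],
        )

    # -- conjugate full-conditional updates ---------------------------------

    def coef_conditional(
        self, b_expanded: np.ndarray, sigma_e_inv: np.ndarray, prior_var: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mean (q, p) and precision (qp, qp) of the coefficient full
        conditional: precision = Sigma_e^-1 (x) Z'Z + I / v0 on the
        column-stacked coefficient vector."""
        Z, Y = self.design, self.endog
        q, p = self.n_coef, self.n_outcomes
        R = Y - b_expanded
        prec = np.kron(sigma_e_inv, Z.T @ Z)
        prec[np.diag_indices_from(prec)] += 1.0 / prior_var
        h = (Z.T @ R @ sigma_e_inv).reshape(-1, order="F")
        mean = np.linalg.solve(prec, h)
        return mean.reshape((q, p), order="F"), prec

    def _update_coefficients(
        self,
        b_expanded: np.ndarray,
        sigma_e_inv: np.ndarray,
        prior_var: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Draw the (q, p) coefficient matrix from its full conditional."""
        q, p = self.n_coef, self.n_outcomes
        mean, prec = self.coef_conditional(b_expanded, sigma_e_inv, prior_var)
        try:
            L = np.linalg.cholesky(prec)
        except np.linalg.LinAlgError as err:
            raise MLMEError("coefficient precision not positive definite") from err
        z = rng.standard_normal(q * p)
        draw = mean.reshape(-1, order="F") + np.linalg.solve(L.T, z)
        return draw.reshape((q, p), order="F")

    def ranef_conditional(
        self, fitted: np.ndarray, sigma_b: np.ndarray, sigma_e: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-cluster conditional means (J, p) and covariances (J, p, p) of
        the random intercepts given coefficients and covariances."""
        resid = self.endog - fitted
        p = self.n_outcomes
        sigma_e_inv = np.linalg.inv(sigma_e)
        sigma_b_inv = np.linalg.inv(sigma_b)
        S = np.zeros((self._J, p))
        np.add.at(S, self.group_codes, resid)
        means = np.empty((self._J, p))
        covs = np.empty((self._J, p, p))
        for n_j in np.unique(self._cluster_sizes):
            mask = self._cluster_sizes == n_j
            Q = n_j * sigma_e_inv + sigma_b_inv
            cov = np.linalg.inv(Q)
            means[mask] = (cov @ sigma_e_inv @ S[mask].T).T
            covs[mask] = cov
        return means, covs

    def _update_random_effects(
        self,
        fitted: np.ndarray,
        sigma_b_inv: np.ndarray,
        sigma_e_inv: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Draw the (J, p) random-intercept matrix: for cluster j,
        precision = n_j Sigma_e^-1 + Sigma_b^-1 and mean
        precision^-1 Sigma_e^-1 * (sum of cluster residuals)."""
        resid = self.endog - fitted
        p = self.n_outcomes
        S = np.zeros((self._J, p))
        np.add.at(S, self.group_codes, resid)
        b = np.empty((self._J, p))
        z = rng.standard_normal((self._J, p))
        for n_j in np.unique(self._cluster_sizes):
            mask = self._cluster_sizes == n_j
            Q = n_j * sigma_e_inv + sigma_b_inv
            try:
                L = np.linalg.cholesky(Q)
            except np.linalg.LinAlgError as err:
                raise MLMEError("random-effect precision not positive definite") from err
            means = np.linalg.solve(Q, (S[mask] @ sigma_e_inv).T).T
            b[mask] = means + np.linalg.solve(L.T, z[mask].T).T
        return b

    @staticmethod
    def _draw_inverse_wishart(
        df: float, scale: np.ndarray, rng: np.random.Generator, what: str
    ) -> np.ndarray:
        scale = 0.5 * (scale + scale.T)
        try:
            return invwishart.rvs(df=df, scale=scale, random_state=rng)
        except np.linalg.LinAlgError as err:
            raise MLMEError(f"{what}: inverse-Wishart scale not positive definite") from err

    # -- sampler ------------------------------------------------------------

    def fit(
        self,
        priors: MLMEPriors | None = None,
        config: GibbsConfig | None = None,
        random_effects: bool = True,
        fix_sigma_e: np.ndarray | None = None,
    ) -> "MLMEResults":
        """Run the Gibbs sampler and summarize the retained draws.

        Initialization is deterministic (per-outcome OLS coefficients, zero
        random effects, identity covariances); all randomness flows from
        ``config.seed``.

        ``random_effects=False`` pins every cluster intercept at zero and
        skips the Sigma_b update (a fixed-effects-only fit);
        ``fix_sigma_e`` holds the residual covariance at a known matrix
        instead of sampling it.  Both are mainly useful for validating the
        sampler against closed forms.
        """
        priors = priors or MLMEPriors()
        config = config or GibbsConfig()
        p, q = self.n_outcomes, self.n_coef
        S0 = priors.validate(p)
        nu0 = priors.iw_df
        rng = np.random.default_rng(config.seed)
        Z, Y = self.design, self.endog
        B = np.linalg.lstsq(Z, Y, rcond=None)[0]
        b = np.zeros((self._J, p))
        sigma_b = np.eye(p)
        if fix_sigma_e is not None:
            fix_sigma_e = np.asarray(fix_sigma_e, dtype=float)
            if fix_sigma_e.shape != (p, p):
                raise MLMEError(f"fix_sigma_e must be {p}x{p}")
        sigma_e = np.eye(p) if fix_sigma_e is None else fix_sigma_e.copy()
        keep = np.arange(config.burn_in, config.n_iter, config.thin)
        n_keep = len(keep)
        chain_B = np.empty((n_keep, q, p))
        chain_sb = np.empty((n_keep, p, p))
        chain_se = np.empty((n_keep, p, p))
        kept = 0
        for it in range(config.n_iter):
            sigma_e_inv = np.linalg.inv(sigma_e)
            sigma_b_inv = np.linalg.inv(sigma_b)
            try:
                B = self._update_coefficients(
                    b[self.group_codes], sigma_e_inv, priors.beta_prior_variance, rng
                )
                fitted = Z @ B
                if random_effects:
                    b = self._update_random_effects(
                        fitted, sigma_b_inv, sigma_e_inv, rng
                    )
                    sigma_b = self._draw_inverse_wishart(
                        nu0 + self._J, S0 + b.T @ b, rng, "Sigma_b"
                    )
                if fix_sigma_e is None:
                    resid = Y - fitted - b[self.group_codes]
                    sigma_e = self._draw_inverse_wishart(
                        nu0 + self.n_obs, S0 + resid.T @ resid, rng, "Sigma_e"
                    )
            except MLMEError as err:
                raise MLMEError(f"iteration {it}: {err}") from err
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                chain_B[kept] = B
                chain_sb[kept] = sigma_b
                chain_se[kept] = sigma_e
                kept += 1
        chains = {"beta": chain_B, "sigma_b": chain_sb, "sigma_e": chain_se}
        return MLMEResults(self, priors, config, chains)


class MLMEResults:
    """Posterior summaries and retained chains from a Gibbs fit.

    Attributes
    ----------
    posterior_mean, hpd_lower, hpd_upper : DataFrame (coefficient x outcome)
    significant : DataFrame of bool, HPD-excludes-zero rule
    chains : dict with ``beta`` (draws, q, p), ``sigma_b``/``sigma_e``
        (draws, p, p)
    """

    def __init__(
        self,
        model: MultivariateMixedLM,
        priors: MLMEPriors,
        config: GibbsConfig,
        chains: dict[str, np.ndarray],
    ) -> None:
        self.model = model
        self.priors = priors
        self.config = config
        self.chains = chains
        beta = chains["beta"]
        idx, cols = model.coef_names, model.outcome_names
        self.posterior_mean = pd.DataFrame(beta.mean(axis=0), index=idx, columns=cols)
        lo = np.empty_like(self.posterior_mean.to_numpy())
        hi = np.empty_like(lo)
        for a in range(beta.shape[1]):
            for c in range(beta.shape[2]):
                lo[a, c], hi[a, c] = hpd_interval(beta[:, a, c], config.hpd_prob)
        self.hpd_lower = pd.DataFrame(lo, index=idx, columns=cols)
        self.hpd_upper = pd.DataFrame(hi, index=idx, columns=cols)
        self.significant = flag_significance(self.hpd_lower, self.hpd_upper)

    @property
    def exposure_summary(self) -> pd.DataFrame:
        """Per-outcome exposure-effect table: posterior mean, HPD bounds and
        the significance flag."""
        return self.summary_frame().query("coefficient == 'exposure'").reset_index(
            drop=True
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for coef in self.model.coef_names:
            for out in self.model.outcome_names:
                rows.append(
                    {
                        "outcome": out,
                        "coefficient": coef,
                        "posterior_mean": self.posterior_mean.loc[coef, out],
                        "hpd_lower": self.hpd_lower.loc[coef, out],
                        "hpd_upper": self.hpd_upper.loc[coef, out],
                        "significant": bool(self.significant.loc[coef, out]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Bayesian multivariate linear mixed model (Gibbs)",
            f"  observations: {self.model.n_obs}   clusters: {self.model._J}   "
            f"outcomes: {self.model.n_outcomes}",
            f"  iterations: {cfg.n_iter}   burn-in: {cfg.burn_in}   "
            f"thin: {cfg.thin}   seed: {cfg.seed}",
            f"  {int(cfg.hpd_prob * 100)}% HPD intervals; "
            "* marks intervals excluding zero",
            "",
            "Exposure effects:",
        ]
        for _, r in self.exposure_summary.iterrows():
            star = "*" if r["significant"] else " "
            lines.append(
                f"  {r['outcome']:<16} {r['posterior_mean']:>8.3f}  "
                f"[{r['hpd_lower']:>7.3f}, {r['hpd_upper']:>7.3f}] {star}"
            )
        return "\n".join(lines)

    def diagnostics(self) -> pd.DataFrame:
        """Per-coefficient effective sample size from the retained chains."""
        beta = self.chains["beta"]
        rows = []
        for a, coef in enumerate(self.model.coef_names):
            for c, out in enumerate(self.model.outcome_names):
                rows.append(
                    {
                        "coefficient": coef,
                        "outcome": out,
                        "n_draws": beta.shape[0],
                        "ess": effective_sample_size(beta[:, a, c]),
                    }
                )
        return pd.DataFrame(rows)

    def trace_plot(self, path: str | Path, coefficient: str = "exposure") -> None:
        """Write a trace-plot grid for one coefficient across all outcomes."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        a = self.model.coef_names.index(coefficient)
        beta = self.chains["beta"]
        p = self.model.n_outcomes
        ncol = min(p, 5)
        nrow = math.ceil(p / ncol)
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False
        )
        for c in range(p):
            ax = axes[c // ncol][c % ncol]
            ax.plot(beta[:, a, c], lw=0.4)
            ax.set_title(self.model.outcome_names[c], fontsize=8)
        for c in range(p, nrow * ncol):
            axes[c // ncol][c % ncol].axis("off")
        fig.suptitle(f"trace: {coefficient}")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)

    def to_csv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, index=False)
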