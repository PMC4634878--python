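"""Bayesian measurement-error regression of log risk ratios on county traits.

Stage 1 delivers, for each county c, posterior draws of a relative risk
ratio R_c.  Those are summarized as ``mu_R[c] = mean(log R_c)`` and
``sigma_R[c] = sd(log R_c)``, and the second stage regresses the latent true
log risk ratio on county covariates while propagating that first-stage
uncertainty::

    Y[c] ~ Normal(mu_R[c], sigma_R[c])     # measurement
    Y[c] ~ Normal(X[c] @ beta, sigma)      # structural model

with ``beta_j ~ Cauchy(0, 5)`` and ``sigma ~ Exponential(1)``.  The two
statements on Y are equivalent to the marginal likelihood
``mu_R[c] ~ Normal(X[c] beta, sqrt(sigma^2 + sigma_R[c]^2))`` with Y[c]
recoverable exactly from its conjugate normal conditional; the sampler uses
the marginal form and draws Y[c] per posterior sample, which is the same
joint posterior with fewer latent dimensions.

Covariates enter as natural logarithms, uncentered by default.  Missing
entries (including zero arrest rates, whose log is undefined) become latent
parameters with a Normal prior matched to the observed entries' moments,
sampled jointly with the coefficients — Bayesian imputation.

Twenty-five candidate models M1..M25 span the intercept-only model up to
all nine predictors; race-specific arrest rates always enter as
white/black pairs.  A robustness re-parameterization replaces each pair
with the pair's sum (logged) and black-minus-white difference (kept on the
natural scale, since it can be negative).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import COVARIATE_COLUMNS
from .sampler import ConvergenceError, NUTSConfig, run_chains

__all__ = [
    "MODEL_GRID",
    "EcoModelSpec",
    "build_model_spec",
    "summarize_log_rr",
    "star_code",
    "MeasurementErrorRegression",
    "fit_eco_model",
    "regression_table",
]

SIGMA_R_FLOOR = 1e-6

#: canonical predictor keys -> (covariate column, table display name)
PREDICTORS = {
    "pop": ("pop_total", "log(Pop.)"),
    "pctb": ("pct_black", "log(Pct. B.)"),
    "inc": ("median_income", "log(Md. In.)"),
    "gini": ("gini", "log(Gini)"),
    "grp": ("racism_proxy", "log(GRP)"),
    "ast_w": ("assault_rate_W", "log(W. Ast)"),
    "ast_b": ("assault_rate_B", "log(B. Ast)"),
    "wps_w": ("weapons_rate_W", "log(W. Wps)"),
    "wps_b": ("weapons_rate_B", "log(B. Wps)"),
}

_CRIME_PAIRS = (("ast_w", "ast_b"), ("wps_w", "wps_b"))

#: covariate sets of the 25 candidate models (intercept is always included)
MODEL_GRID: dict[str, tuple[str, ...]] = {
    "M1": (),
    "M2": ("pop",),
    "M3": ("pop", "pctb"),
    "M4": ("pop", "inc"),
    "M5": ("pop", "gini"),
    "M6": ("pop", "grp"),
    "M7": ("pop", "ast_w", "ast_b"),
    "M8": ("pop", "wps_w", "wps_b"),
    "M9": ("pop", "pctb", "inc"),
    "M10": ("pop", "pctb", "gini"),
    "M11": ("pop", "pctb", "grp"),
    "M12": ("pop", "pctb", "ast_w", "ast_b"),
    "M13": ("pop", "pctb", "wps_w", "wps_b"),
    "M14": ("pop", "pctb", "inc", "gini"),
    "M15": ("pop", "pctb", "inc", "grp"),
    "M16": ("pop", "pctb", "inc", "ast_w", "ast_b"),
    "M17": ("pop", "pctb", "inc", "wps_w", "wps_b"),
    "M18": ("pop", "pctb", "gini", "grp"),
    "M19": ("pop", "pctb", "gini", "ast_w", "ast_b"),
    "M20": ("pop", "pctb", "gini", "wps_w", "wps_b"),
    "M21": ("pop", "pctb", "inc", "grp", "ast_w", "ast_b"),
    "M22": ("pop", "pctb", "inc", "grp", "wps_w", "wps_b"),
    "M23": ("pop", "pctb", "gini", "grp", "ast_w", "ast_b"),
    "M24": ("pop", "pctb", "gini", "grp", "wps_w", "wps_b"),
    "M25": ("pop", "pctb", "inc", "gini", "grp", "ast_w", "ast_b", "wps_w", "wps_b"),
}


@dataclasses.dataclass(frozen=True)
class EcoModelSpec:
    model_id: str
    covariates: tuple[str, ...]
    parameterization: str = "levels"  # or "sum_diff"

    @property
    def term_names(self) -> tuple[str, ...]:
        """Design-matrix column labels after any re-parameterization."""
        names = ["Intercept"]
        if self.parameterization == "levels":
            names += [PREDICTORS[k][1] for k in self.covariates]
        else:
            skip = set()
            for k in self.covariates:
                if k in skip:
                    continue
                pair = _pair_of(k)
                if pair and pair[0] in self.covariates and pair[1] in self.covariates:
                    stem = "Ast" if k.startswith("ast") else "Wps"
                    names += [f"log(Sum {stem})", f"Diff {stem} (B-W)"]
                    skip.update(pair)
                else:
                    names.append(PREDICTORS[k][1])
        return tuple(names)


def _pair_of(key: str) -> tuple[str, str] | None:
    for pair in _CRIME_PAIRS:
        if key in pair:
            return pair
    return None


def build_model_spec(model_id: str, parameterization: str = "levels") -> EcoModelSpec:
    """Look up one of the 25 candidate models by id."""
    if model_id not in MODEL_GRID:
        raise ValueError(f"unknown model id {model_id!r}; expected M1..M25")
    if parameterization not in ("levels", "sum_diff"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return EcoModelSpec(model_id, MODEL_GRID[model_id], parameterization)


def summarize_log_rr(ratio_draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean and sd of log ratio draws per county (the stage-2 outcome).

    Returns a frame with columns fips, mu_R, sigma_R; sigma_R is floored at
    ``SIGMA_R_FLOOR`` so degenerate draws cannot produce a zero-noise
    likelihood.
    """
    rows = []
    for fips, draws in ratio_draws.items():
        draws = np.asarray(draws, dtype=float)
        if draws.size < 2:
            raise ValueError(f"county {fips}: need at least 2 draws")
        if np.any(draws <= 0):
            raise ValueError(f"county {fips}: ratio draws must be positive")
        logs = np.log(draws)
        rows.append({
            "fips": str(fips),
            "mu_R": float(np.mean(logs)),
            "sigma_R": float(max(np.std(logs, ddof=1), SIGMA_R_FLOOR)),
        })
    return pd.DataFrame(rows, columns=["fips", "mu_R", "sigma_R"])


def star_code(beta_draws: np.ndarray) -> str:
    """Significance-style code from the posterior mass opposing the mean sign.

    With p the fraction of draws whose sign opposes the posterior mean:
    ``***`` for p <= 0.01, ``**`` for 0.01 < p <= 0.05, ``*`` for
    0.05 < p <= 0.10, else the empty string.
    """
    draws = np.asarray(beta_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    if draws.mean() >= 0:
        p = float(np.mean(draws < 0))
    else:
        p = float(np.mean(draws > 0))
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.10:
        return "*"
    return ""


def _design_matrix(
    cov: pd.DataFrame, spec: EcoModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build the (possibly incomplete) design matrix on the model scale.

    Returns (X with NaN holes, missing mask, term names).  Zero/negative
    values of logged covariates are treated as missing.
    """
    n = len(cov)
    cols: list[np.ndarray] = [np.ones(n)]
    if spec.parameterization == "levels":
        for key in spec.covariates:
            raw = cov[PREDICTORS[key][0]].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                cols.append(np.where(raw > 0, np.log(np.where(raw > 0, raw, 1.0)), np.nan))
    else:
        skip: set[str] = set()
        for key in spec.covariates:
            if key in skip:
                continue
            pair = _pair_of(key)
            if pair and pair[0] in spec.covariates and pair[1] in spec.covariates:
                w = cov[PREDICTORS[pair[0]][0]].to_numpy(dtype=float)
                b = cov[PREDICTORS[pair[1]][0]].to_numpy(dtype=float)
                total = w + b
                with np.errstate(divide="ignore", invalid="ignore"):
                    cols.append(np.where(total > 0, np.log(np.where(total > 0, total, 1.0)), np.nan))
                cols.append(b - w)
                skip.update(pair)
            else:
                raw = cov[PREDICTORS[key][0]].to_numpy(dtype=float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    cols.append(np.where(raw > 0, np.log(np.where(raw > 0, raw, 1.0)), np.nan))
    X = np.column_stack(cols)
    missing = np.isnan(X)
    return X, missing, list(spec.term_names)


def _make_eco_logp(
    X: np.ndarray,
    missing: np.ndarray,
    mu_R: np.ndarray,
    sigma_R: np.ndarray,
    prior_mean: np.ndarray,
    prior_sd: np.ndarray,
):
    """Marginalized log density over (beta, log sigma, imputed entries)."""
    n, p = X.shape
    miss_idx = np.argwhere(missing)
    n_miss = len(miss_idx)
    var_R = sigma_R**2

    def logp(x: np.ndarray) -> tuple[float, np.ndarray]:
        beta = x[:p]
        if abs(x[p]) > 50.0:  # sigma astronomically far from any data scale
            return -np.inf, np.zeros_like(x)
        sigma = np.exp(x[p])
        xm = x[p + 1 :]
        Xf = X.copy()
        if n_miss:
            Xf[miss_idx[:, 0], miss_idx[:, 1]] = xm

        resid = mu_R - Xf @ beta
        var = sigma**2 + var_R
        lp = float(np.sum(-0.5 * np.log(2 * np.pi * var) - 0.5 * resid**2 / var))
        lp += float(np.sum(-np.log1p((beta / 5.0) ** 2)))      # Cauchy(0,5)
        lp += -sigma + x[p]                                     # Exp(1) + Jacobian
        g_beta = (resid / var) @ Xf - 2.0 * beta / (25.0 + beta**2)
        g_log_sigma = float(sigma**2 * np.sum((resid**2 - var) / var**2)) + 1.0 - sigma

        grad = np.empty_like(x)
        grad[:p] = g_beta
        grad[p] = g_log_sigma
        if n_miss:
            g_xm = (resid / var)[miss_idx[:, 0]] * beta[miss_idx[:, 1]]
            g_xm -= (xm - prior_mean) / prior_sd**2
            lp += float(np.sum(-0.5 * ((xm - prior_mean) / prior_sd) ** 2))
            grad[p + 1 :] = g_xm
        return lp, grad

    return logp, p + 1 + n_miss, miss_idx


class MeasurementErrorRegression(BaseEstimator):
    """Ecological regression with known per-county outcome noise.

    Parameters
    ----------
    model_id
        One of M1..M25, selecting the covariate set.
    parameterization
        ``"levels"`` (default) or ``"sum_diff"`` for the crime-rate
        robustness re-parameterization.
    center
        If True, predictors are centered for sampling and the intercept is
        back-transformed per draw for reporting; priors are applied on the
        sampled (centered) scale.  Default False: fit on the natural scale.
    chains, warmup, draws, seed, target_accept, rhat_threshold
        MCMC layout and convergence contract, as in
        :class:`~countyrisk.hierarchical.ShootingRateModel`.

    Attributes
    ----------
    beta_draws_ : ndarray (n_total, p)
    sigma_draws_ : ndarray (n_total,)
    latent_y_draws_ : ndarray (n_total, C)
    imputed_draws_ : dict[(fips, term), ndarray]
    star_codes_ : dict[term, str]
    summary_ : DataFrame with mean, sd, star per term
    """

    def __init__(
        self,
        model_id: str = "M1",
        parameterization: str = "levels",
        center: bool = False,
        chains: int = 4,
        warmup: int = 500,
        draws: int = 500,
        seed: int = 0,
        target_accept: float = 0.9,
        rhat_threshold: float = 1.02,
    ):
        self.model_id = model_id
        self.parameterization = parameterization
        self.center = center
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.target_accept = target_accept
        self.rhat_threshold = rhat_threshold

    def fit(self, outcomes: pd.DataFrame, covariates: pd.DataFrame):
        """Fit to outcome summaries (fips, mu_R, sigma_R) joined on covariates."""
        spec = build_model_spec(self.model_id, self.parameterization)
        merged = outcomes.merge(covariates, on="fips", how="inner")
        if merged.empty:
            raise ValueError("no counties joined between outcomes and covariates")
        mu_R = merged["mu_R"].to_numpy(dtype=float)
        sigma_R = np.maximum(merged["sigma_R"].to_numpy(dtype=float), SIGMA_R_FLOOR)

        X, missing, names = _design_matrix(merged, spec)
        p = X.shape[1]
        fully_missing = [
            names[j] for j in range(p) if missing[:, j].all()
        ]
        if fully_missing:
            raise ValueError(
                f"covariates {fully_missing} have no observed entries and cannot be imputed"
            )

        col_mean = np.zeros(p)
        col_sd = np.ones(p)
        for j in range(1, p):
            obs = X[~missing[:, j], j]
            col_mean[j] = obs.mean()
            col_sd[j] = obs.std(ddof=1) if obs.size > 1 else 1.0
            if col_sd[j] == 0:
                col_sd[j] = 1.0
        offsets = col_mean.copy() if self.center else np.zeros(p)
        offsets[0] = 0.0
        Xs = X - offsets

        miss_rows = np.argwhere(missing)
        prior_mean = col_mean[miss_rows[:, 1]] - offsets[miss_rows[:, 1]]
        prior_sd = col_sd[miss_rows[:, 1]]
        logp, dim, miss_idx = _make_eco_logp(Xs, missing, mu_R, sigma_R, prior_mean, prior_sd)

        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 17]).spawn(1)[0])
        base = np.zeros(dim)
        base[:p][0] = mu_R.mean()
        base[p] = np.log(max(mu_R.std(ddof=1), 0.1)) if len(mu_R) > 1 else 0.0
        if dim > p + 1:
            base[p + 1 :] = prior_mean
        x0s = [base + 0.1 * rng.normal(size=dim) for _ in range(self.chains)]

        config = NUTSConfig(
            n_warmup=self.warmup, n_draws=self.draws, target_accept=self.target_accept
        )
        raw, stats = run_chains(logp, x0s, self.seed, config)

        n_total = self.chains * self.draws
        beta = raw[:, :, :p].reshape(n_total, p).copy()
        sigma = np.exp(raw[:, :, p].reshape(n_total))
        if self.center:
            # report on the natural scale: intercept absorbs the offsets
            beta[:, 0] -= beta[:, 1:] @ offsets[1:]

        from .hierarchical import _rhat_ess  # shared diagnostics helper

        rhat, ess = _rhat_ess(raw[:, :, : p + 1])
        self.rhat_max_ = float(np.nanmax(rhat))
        self.ess_min_ = float(np.nanmin(ess))

        # imputed covariate entries, reported on the natural (uncentered) scale
        self.imputed_draws_ = {}
        for k, (row, col) in enumerate(miss_idx):
            key = (str(merged["fips"].iloc[row]), names[col])
            self.imputed_draws_[key] = (
                raw[:, :, p + 1 + k].reshape(n_total) + offsets[col]
            )

        # exact conjugate conditional for the latent true log risk ratio
        Xf = np.broadcast_to(Xs, (n_total,) + Xs.shape).copy()
        for k, (row, col) in enumerate(miss_idx):
            Xf[:, row, col] = raw[:, :, p + 1 + k].reshape(n_total)
        pred = np.einsum("ncp,np->nc", Xf, raw[:, :, :p].reshape(n_total, p))
        post_var = 1.0 / (1.0 / sigma_R**2 + 1.0 / sigma[:, None] ** 2)
        post_mean = post_var * (mu_R / sigma_R**2 + pred / sigma[:, None] ** 2)
        y_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 29]).spawn(1)[0])
        self.latent_y_draws_ = post_mean + np.sqrt(post_var) * y_rng.normal(
            size=post_mean.shape
        )

        self.beta_draws_ = beta
        self.sigma_draws_ = sigma
        self.coef_names_ = names
        self.fips_ = [str(f) for f in merged["fips"]]
        self.star_codes_ = {
            name: star_code(beta[:, j]) for j, name in enumerate(names)
        }
        rows = [
            {
                "term": name,
                "mean": float(beta[:, j].mean()),
                "sd": float(beta[:, j].std(ddof=1)),
                "star": self.star_codes_[name],
            }
            for j, name in enumerate(names)
        ]
        rows.append({
            "term": "SD",
            "mean": float(sigma.mean()),
            "sd": float(sigma.std(ddof=1)),
            "star": "",
        })
        self.summary_ = pd.DataFrame(rows)
        self.diagnostics_ = {"rhat_max": self.rhat_max_, "ess_min": self.ess_min_, **stats}
        if self.rhat_max_ > self.rhat_threshold:
            raise ConvergenceError(
                f"max split R-hat {self.rhat_max_:.4f} exceeds threshold "
                f"{self.rhat_threshold}",
                self.diagnostics_,
            )
        return self


def fit_eco_model(
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    model_id: str = "M1",
    parameterization: str = "levels",
    **kwargs,
) -> MeasurementErrorRegression:
    """Functional wrapper over :class:`MeasurementErrorRegression`."""
    est = MeasurementErrorRegression(
        model_id=model_id, parameterization=parameterization, **kwargs
    )
    return est.fit(outcomes, covariates)


def regression_table(
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    model_ids: tuple[str, ...] = tuple(MODEL_GRID),
    parameterization: str = "levels",
    **kwargs,
) -> pd.DataFrame:
    """Fit a grid of models and lay out mean (sd) cells with star codes.

    Mirrors the published table shape: one row per model, columns Intercept,
    SD, then the nine predictors; empty cells for excluded covariates.
    """
    all_terms = ["Intercept", "SD"]
    fits: dict[str, MeasurementErrorRegression] = {}
    for mid in model_ids:
        fits[mid] = fit_eco_model(
            outcomes, covariates, model_id=mid, parameterization=parameterization, **kwargs
        )
        for t in fits[mid].summary_["term"]:
            if t not in all_terms:
                all_terms.append(t)

    rows = []
    for mid in model_ids:
        summary = fits[mid].summary_.set_index("term")
        row = {"Model": mid}
        for term in all_terms:
            if term in summary.index:
                mean, sd = summary.loc[term, "mean"], summary.loc[term, "sd"]
                star = summary.loc[term, "star"]
                row[term] = f"{star}{round(mean, 2)} ({round(sd, 2)})"
            else:
                row[term] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=["Model", *all_terms])
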