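"""Hierarchical binomial model of county-level police-shooting probabilities.

For every county ``c`` with at least one recorded shooting, six binomial
cells are modelled — race (black, hispanic, white) crossed with armed
status (armed, unarmed)::

    S[c, ra] ~ Binomial(N[c, r], theta[c, ra])
    theta[c] = inv_logit(Theta[c])
    Theta[c] ~ MultivariateNormal(mu, Diag(sigma) rho Diag(sigma))

with priors ``mu_d ~ Normal(-14, 4)`` (scale on the logit axis chosen so the
bulk of the prior mass covers per-4-year shooting probabilities between
roughly 1e-9 and 1e-3), ``sigma_d ~ HalfCauchy(0, 5)``, and a uniform prior
over valid correlation matrices ``rho`` (LKJ with shape 1).  Partial pooling
across counties regularizes the sparse counts, keeping posterior risk
ratios finite even when a county recorded zero shootings in a cell.

Sampling uses the non-centered parameterization ``Theta[c] = mu + L z[c]``
with ``L = Diag(sigma) @ cholesky(rho)`` and ``z[c] ~ Normal(0, I)``; the
correlation Cholesky factor is parameterized by canonical partial
correlations so the whole posterior lives on an unconstrained vector
suitable for :mod:`countyrisk.sampler`.  All gradients are analytic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import multivariate_normal

from sklearn.base import BaseEstimator

from .records import CELL_COLUMNS, counts_to_arrays
from .sampler import ConvergenceError, NUTSConfig, run_chains

__all__ = [
    "HyperParams",
    "PosteriorDraws",
    "ShootingRateModel",
    "inv_logit",
    "build_cholesky",
    "log_joint",
]

D = 6  # race x armed cells per county
_N_CORR = D * (D - 1) // 2
_RACE_OF_CELL = np.array([0, 0, 1, 1, 2, 2])  # B,B,H,H,W,W


def inv_logit(x):
    """Numerically stable elementwise logistic function e^x / (1 + e^x)."""
    return expit(np.asarray(x, dtype=float))


def build_cholesky(sigma: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Covariance Cholesky factor ``Diag(sigma) @ cholesky(rho)``.

    Raises ``numpy.linalg.LinAlgError`` when ``rho`` is not positive
    definite.
    """
    sigma = np.asarray(sigma, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return np.diag(sigma) @ np.linalg.cholesky(rho)


@dataclasses.dataclass
class HyperParams:
    """Population-level parameters of the logit-normal random effect."""

    mu: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray

    @property
    def L(self) -> np.ndarray:
        return build_cholesky(self.sigma, self.rho)

    @property
    def cov(self) -> np.ndarray:
        L = self.L
        return L @ L.T


# ---------------------------------------------------------------------------
# correlation-Cholesky transform (canonical partial correlations)
# ---------------------------------------------------------------------------

def _corr_chol_forward(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Map unconstrained ``y`` (length D(D-1)/2) to a correlation Cholesky L.

    Returns (L, tanh(y) per row as a ragged-packed array, log target
    increment).  The increment is the transform's log Jacobian plus the
    uniform (LKJ shape 1) log density over correlation matrices, so adding
    it to a likelihood yields a posterior uniform in ``rho``.
    """
    L = np.zeros((D, D))
    L[0, 0] = 1.0
    z = np.tanh(y)
    logdet = 0.0
    idx = 0
    for i in range(1, D):
        s = 1.0
        for j in range(i):
            zij = z[idx]
            # saturated tanh or an exhausted row norm: the point is outside
            # the numerically representable region, reject it upstream
            if s < 1e-12 or abs(zij) >= 1.0 - 1e-15:
                return L, z, -np.inf
            c = np.sqrt(s)
            L[i, j] = zij * c
            logdet += 0.5 * np.log(s) + np.log1p(-zij * zij)
            s -= L[i, j] ** 2
            idx += 1
        if s < 1e-12:
            return L, z, -np.inf
        L[i, i] = np.sqrt(s)
        logdet += (D - 1 - i) * np.log(L[i, i])  # uniform-correlation density
    return L, z, logdet


def _corr_chol_backward(y: np.ndarray, L: np.ndarray, z: np.ndarray, gL: np.ndarray) -> np.ndarray:
    """Reverse-mode gradient of (transform + log increment) with respect to y.

    ``gL`` is the upstream gradient on the lower triangle of L (diagonal
    included) from the rest of the log density.
    """
    gy = np.zeros_like(y)
    idx = 0
    for i in range(1, D):
        # replay the forward partial sums s_j for this row
        s = np.empty(i + 1)
        s[0] = 1.0
        for j in range(i):
            s[j + 1] = s[j] - L[i, j] ** 2
        row = slice(idx, idx + i)
        zrow = z[row]
        ds = np.zeros(i + 1)
        ds[i] += (gL[i, i] + (D - 1 - i) / L[i, i]) * 0.5 / L[i, i]
        ds[:i] += 0.5 / s[:i]  # d(0.5 log s_j)/ds_j
        dz = np.zeros(i)
        for j in range(i - 1, -1, -1):
            c = np.sqrt(s[j])
            dL = gL[i, j] - 2.0 * L[i, j] * ds[j + 1]
            ds[j] += ds[j + 1]
            dz[j] += dL * c
            ds[j] += dL * zrow[j] * 0.5 / c
            dz[j] += -2.0 * zrow[j] / (1.0 - zrow[j] ** 2)
        gy[row] = dz * (1.0 - zrow**2)
        idx += i
    return gy


# ---------------------------------------------------------------------------
# joint density
# ---------------------------------------------------------------------------

def _binom_constants(S: np.ndarray, N_cell: np.ndarray) -> float:
    return float(np.sum(gammaln(N_cell + 1) - gammaln(S + 1) - gammaln(N_cell - S + 1)))


def log_joint(hyper: HyperParams, theta_unc: np.ndarray, counts: pd.DataFrame) -> float:
    """Joint log density of data, county effects, and hyper-parameters.

    ``theta_unc`` holds the logit-scale county vectors Theta, shape (C, 6),
    aligned with the rows of ``counts``.  Includes the binomial
    coefficients, the multivariate-normal random-effect density, the
    Normal(-14, 4) prior on each mean, the half-Cauchy(0, 5) prior on each
    scale, and the (constant) uniform prior over correlation matrices.
    """
    _, S, N = counts_to_arrays(counts)
    N_cell = N[:, _RACE_OF_CELL]
    theta_unc = np.atleast_2d(np.asarray(theta_unc, dtype=float))
    if theta_unc.shape != S.shape:
        raise ValueError(f"theta_unc shape {theta_unc.shape} != counts shape {S.shape}")

    ll = float(
        np.sum(S * theta_unc - N_cell * np.logaddexp(0.0, theta_unc))
    ) + _binom_constants(S, N_cell)
    ll += float(
        np.sum(multivariate_normal(mean=hyper.mu, cov=hyper.cov).logpdf(theta_unc))
    )
    ll += float(np.sum(-0.5 * ((hyper.mu + 14.0) / 4.0) ** 2 - np.log(4.0 * np.sqrt(2 * np.pi))))
    sigma = np.asarray(hyper.sigma, dtype=float)
    if np.any(sigma < 0):
        return -np.inf
    ll += float(np.sum(np.log(2.0 / (np.pi * 5.0)) - np.log1p((sigma / 5.0) ** 2)))
    return ll


def _make_logp(S: np.ndarray, N: np.ndarray, fixed: HyperParams | None = None):
    """Build the unconstrained log-density-and-gradient closure.

    Parameter layout (free-hyper mode):
      mu (6) | log sigma (6) | corr y (15) | z flattened (C*6)
    Fixed-hyper mode samples only z.
    """
    C = S.shape[0]
    N_cell = N[:, _RACE_OF_CELL]
    const = _binom_constants(S, N_cell)

    if fixed is not None:
        mu0 = np.asarray(fixed.mu, dtype=float)
        L0 = fixed.L

        def logp_fixed(x: np.ndarray) -> tuple[float, np.ndarray]:
            z = x.reshape(C, D)
            theta_unc = mu0 + z @ L0.T
            lp = float(np.sum(S * theta_unc - N_cell * np.logaddexp(0.0, theta_unc))) + const
            lp += -0.5 * float(np.sum(z * z))
            G = S - N_cell * expit(theta_unc)
            gz = G @ L0 - z
            return lp, gz.ravel()

        return logp_fixed, C * D

    dim = D + D + _N_CORR + C * D

    def logp(x: np.ndarray) -> tuple[float, np.ndarray]:
        mu = x[:D]
        log_sigma = x[D : 2 * D]
        y = x[2 * D : 2 * D + _N_CORR]
        z = x[2 * D + _N_CORR :].reshape(C, D)
        sigma = np.exp(log_sigma)

        L_rho, z_pc, corr_term = _corr_chol_forward(y)
        if not np.isfinite(corr_term):
            return -np.inf, np.zeros_like(x)
        L_cov = sigma[:, None] * L_rho
        theta_unc = mu + z @ L_cov.T

        lp = float(np.sum(S * theta_unc - N_cell * np.logaddexp(0.0, theta_unc))) + const
        lp += -0.5 * float(np.sum(z * z))
        lp += float(np.sum(-0.5 * ((mu + 14.0) / 4.0) ** 2))
        # half-Cauchy(0,5) on sigma plus the log|d sigma / d log sigma| Jacobian
        lp += float(np.sum(-np.log1p((sigma / 5.0) ** 2) + log_sigma))
        lp += corr_term

        G = S - N_cell * expit(theta_unc)
        g_mu = G.sum(axis=0) - (mu + 14.0) / 16.0
        g_z = G @ L_cov - z
        M = np.tril(G.T @ z)  # gradient wrt L_cov entries
        g_log_sigma = (M * L_rho).sum(axis=1) * sigma  # chain: dL_cov/dsigma * dsigma/dlog
        g_log_sigma += 1.0 - 2.0 * sigma**2 / (sigma**2 + 25.0)
        gL_rho = sigma[:, None] * M
        g_y = _corr_chol_backward(y, L_rho, z_pc, gL_rho)

        grad = np.concatenate([g_mu, g_log_sigma, g_y, g_z.ravel()])
        return lp, grad

    return logp, dim


# ---------------------------------------------------------------------------
# posterior container and estimator
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PosteriorDraws:
    """Joint posterior draws of the hierarchical model, flattened over chains."""

    fips: list[str]
    mu: np.ndarray       # (n_total, 6)
    sigma: np.ndarray    # (n_total, 6)
    rho: np.ndarray      # (n_total, 6, 6)
    theta: np.ndarray    # (n_total, C, 6), probability scale
    n_chains: int
    n_draws_per_chain: int
    diagnostics: dict
    config: dict

    @property
    def n_total(self) -> int:
        return self.mu.shape[0]

    def county_index(self, fips: str) -> int:
        try:
            return self.fips.index(str(fips).zfill(5))
        except ValueError:
            raise KeyError(f"county {fips} was not part of the fit") from None

    def save(self, prefix: str | Path) -> None:
        """Persist draws as a long-format CSV plus a JSON diagnostics sidecar."""
        prefix = Path(prefix)
        frames = []
        n_per = self.n_draws_per_chain
        chain = np.repeat(np.arange(self.n_chains), n_per)
        iteration = np.tile(np.arange(n_per), self.n_chains)
        for d in range(D):
            frames.append(pd.DataFrame({
                "parameter": f"mu[{d}]", "chain": chain, "iteration": iteration,
                "value": self.mu[:, d],
            }))
            frames.append(pd.DataFrame({
                "parameter": f"sigma[{d}]", "chain": chain, "iteration": iteration,
                "value": self.sigma[:, d],
            }))
        for i in range(D):
            for j in range(i):
                frames.append(pd.DataFrame({
                    "parameter": f"rho[{i},{j}]", "chain": chain,
                    "iteration": iteration, "value": self.rho[:, i, j],
                }))
        for c, f in enumerate(self.fips):
            for d, cell in enumerate(CELL_COLUMNS):
                frames.append(pd.DataFrame({
                    "parameter": f"theta[{f},{cell[2:]}]", "chain": chain,
                    "iteration": iteration, "value": self.theta[:, c, d],
                }))
        pd.concat(frames, ignore_index=True).to_csv(
            prefix.with_suffix(".csv"), index=False
        )
        sidecar = {"diagnostics": self.diagnostics, "config": self.config,
                   "fips": self.fips}
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "PosteriorDraws":
        """Rebuild a posterior store written by :meth:`save`."""
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        long = pd.read_csv(prefix.with_suffix(".csv"))
        long = long.sort_values(["parameter", "chain", "iteration"], kind="stable")
        n_chains = int(long["chain"].max()) + 1
        n_per = int(long["iteration"].max()) + 1
        n_total = n_chains * n_per
        fips = [str(f).zfill(5) for f in sidecar["fips"]]
        series = {p: g["value"].to_numpy() for p, g in long.groupby("parameter")}

        mu = np.column_stack([series[f"mu[{d}]"] for d in range(D)])
        sigma = np.column_stack([series[f"sigma[{d}]"] for d in range(D)])
        rho = np.tile(np.eye(D), (n_total, 1, 1))
        for i in range(D):
            for j in range(i):
                rho[:, i, j] = rho[:, j, i] = series[f"rho[{i},{j}]"]
        theta = np.empty((n_total, len(fips), D))
        for c, f in enumerate(fips):
            for d, cell in enumerate(CELL_COLUMNS):
                theta[:, c, d] = series[f"theta[{f},{cell[2:]}]"]
        return cls(
            fips=fips, mu=mu, sigma=sigma, rho=rho, theta=theta,
            n_chains=n_chains, n_draws_per_chain=n_per,
            diagnostics=sidecar["diagnostics"], config=sidecar["config"],
        )


def _rhat_ess(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split R-hat and bulk ESS for draws shaped (chains, n, k), via arviz."""
    import arviz as az

    ds = az.convert_to_dataset(draws[..., None] if draws.ndim == 2 else draws)
    rhat = az.rhat(ds)["x"].to_numpy()
    ess = az.ess(ds)["x"].to_numpy()
    return np.atleast_1d(rhat), np.atleast_1d(ess)


class ShootingRateModel(BaseEstimator):
    """Partial-pooling binomial model of the six shooting probabilities.

    Parameters
    ----------
    chains, warmup, draws
        MCMC layout; total kept draws are ``chains * draws``.
    seed
        Random seed; fits are bit-reproducible for a fixed seed and config.
    target_accept, max_treedepth
        NUTS tuning knobs.
    rhat_threshold
        Largest admissible split R-hat over mu, sigma, and all county
        probabilities; exceeding it raises :class:`ConvergenceError`.
    fixed_hyper
        Optional :class:`HyperParams` freezing (mu, sigma, rho); only the
        county effects are then sampled.  Used for oracle validation and
        conditional analyses.

    Attributes
    ----------
    posterior_ : PosteriorDraws
    rhat_max_ : float
    ess_min_ : float
    """

    def __init__(
        self,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        target_accept: float = 0.85,
        max_treedepth: int = 10,
        rhat_threshold: float = 1.01,
        fixed_hyper: HyperParams | None = None,
    ):
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.rhat_threshold = rhat_threshold
        self.fixed_hyper = fixed_hyper

    def fit(self, X: pd.DataFrame, y=None):
        """Fit to a county counts frame (columns fips, S_*, N_*)."""
        fips, S, N = counts_to_arrays(X)
        if len(fips) == 0:
            raise ValueError("no counties to fit")
        if np.any(S.sum(axis=1) < 1):
            raise ValueError("every county must have at least one shooting")
        zero_pop_shot = (S > 0) & (N[:, _RACE_OF_CELL] == 0)
        if zero_pop_shot.any():
            c = int(np.argwhere(zero_pop_shot)[0, 0])
            raise ValueError(f"county {fips[c]} has shootings in a zero-population cell")
        C = len(fips)

        logp, dim = _make_logp(S, N, self.fixed_hyper)
        rng = np.random.default_rng(np.random.SeedSequence(self.seed).spawn(1)[0])
        if self.fixed_hyper is None:
            p_hat = (S.sum(axis=0) + 0.5) / (N[:, _RACE_OF_CELL].sum(axis=0) + 1.0)
            mu_init = np.log(p_hat / (1 - p_hat))
            base = np.concatenate([mu_init, np.full(D, np.log(0.5)), np.zeros(_N_CORR + C * D)])
        else:
            base = np.zeros(dim)
        x0s = [base + 0.1 * rng.normal(size=dim) for _ in range(self.chains)]

        config = NUTSConfig(
            n_warmup=self.warmup, n_draws=self.draws,
            target_accept=self.target_accept, max_treedepth=self.max_treedepth,
        )
        raw, stats = run_chains(logp, x0s, self.seed, config)

        if self.fixed_hyper is None:
            mu_ch = raw[:, :, :D]
            sigma_ch = np.exp(raw[:, :, D : 2 * D])
            y_ch = raw[:, :, 2 * D : 2 * D + _N_CORR]
            z_ch = raw[:, :, 2 * D + _N_CORR :].reshape(self.chains, self.draws, C, D)
            rho = np.empty((self.chains, self.draws, D, D))
            theta = np.empty((self.chains, self.draws, C, D))
            for ci in range(self.chains):
                for it in range(self.draws):
                    L_rho, _, _ = _corr_chol_forward(y_ch[ci, it])
                    rho[ci, it] = L_rho @ L_rho.T
                    L_cov = sigma_ch[ci, it][:, None] * L_rho
                    theta[ci, it] = expit(mu_ch[ci, it] + z_ch[ci, it] @ L_cov.T)
            monitor = np.concatenate(
                [mu_ch, sigma_ch, theta.reshape(self.chains, self.draws, C * D)], axis=2
            )
        else:
            hyp = self.fixed_hyper
            z_ch = raw.reshape(self.chains, self.draws, C, D)
            L_cov = hyp.L
            theta = expit(np.asarray(hyp.mu) + z_ch @ L_cov.T)
            mu_ch = np.broadcast_to(
                np.asarray(hyp.mu, float), (self.chains, self.draws, D)
            ).copy()
            sigma_ch = np.broadcast_to(
                np.asarray(hyp.sigma, float), (self.chains, self.draws, D)
            ).copy()
            rho = np.broadcast_to(
                np.asarray(hyp.rho, float), (self.chains, self.draws, D, D)
            ).copy()
            monitor = theta.reshape(self.chains, self.draws, C * D)

        rhat, ess = _rhat_ess(monitor)
        diagnostics = {
            "rhat_max": float(np.nanmax(rhat)),
            "ess_min": float(np.nanmin(ess)),
            **stats,
        }
        n_total = self.chains * self.draws
        self.posterior_ = PosteriorDraws(
            fips=fips,
            mu=mu_ch.reshape(n_total, D),
            sigma=sigma_ch.reshape(n_total, D),
            rho=rho.reshape(n_total, D, D),
            theta=theta.reshape(n_total, C, D),
            n_chains=self.chains,
            n_draws_per_chain=self.draws,
            diagnostics=diagnostics,
            config={
                "chains": self.chains, "warmup": self.warmup, "draws": self.draws,
                "seed": self.seed, "target_accept": self.target_accept,
                "max_treedepth": self.max_treedepth,
                "rhat_threshold": self.rhat_threshold,
                "fixed_hyper": self.fixed_hyper is not None,
            },
        )
        self.rhat_max_ = diagnostics["rhat_max"]
        self.ess_min_ = diagnostics["ess_min"]
        if self.rhat_max_ > self.rhat_threshold:
            raise ConvergenceError(
                f"max split R-hat {self.rhat_max_:.4f} exceeds "
                f"threshold {self.rhat_threshold}",
                diagnostics,
            )
        return self
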