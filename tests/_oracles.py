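"""Independent oracles: deterministic grid/quadrature posteriors.

These never call the package's samplers; they integrate small posteriors
directly so MCMC output can be checked against ground truth.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import binom


def grid_binomial_logit_posterior(
    S: int, N: int, mu: float, sigma: float, n_grid: int = 4001, span: float = 14.0
) -> dict:
    """Posterior of theta for S ~ Binom(N, theta), logit(theta) ~ Normal(mu, sigma).

    Deterministic 1-D grid integration on the logit scale; returns the
    posterior median and equal-tailed 95% interval of theta.
    """
    t = np.linspace(mu - span, mu + span, n_grid)
    log_w = binom.logpmf(S, N, expit(t)) - 0.5 * ((t - mu) / sigma) ** 2
    w = np.exp(log_w - log_w.max())
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    theta = expit(t)
    return {
        "median": float(np.interp(0.5, cdf, theta)),
        "lo": float(np.interp(0.025, cdf, theta)),
        "hi": float(np.interp(0.975, cdf, theta)),
    }


def grid_regression_posterior_mean(
    y: np.ndarray,
    x: np.ndarray | None = None,
    n_grid: int = 161,
    sigma_grid: int = 121,
) -> np.ndarray:
    """Posterior mean of beta for y ~ Normal(X beta, sigma) on a dense grid.

    Intercept-only (x=None, 2-D grid over beta1 x sigma) or single-slope
    (3-D grid over beta1 x beta2 x sigma).  Priors match the ecological
    regression: beta ~ Cauchy(0, 5), sigma ~ Exponential(1).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    c = y.mean()
    s = y.std(ddof=1)
    b1 = np.linspace(c - 8 * s / np.sqrt(n), c + 8 * s / np.sqrt(n), n_grid)
    sg = np.linspace(1e-3, 4 * s, sigma_grid)

    if x is None:
        resid2 = ((y[None, None, :] - b1[:, None, None]) ** 2).sum(-1)
        ll = -n * np.log(sg)[None, :] - 0.5 * resid2 / sg[None, :] ** 2
        lp = ll - np.log1p((b1[:, None] / 5.0) ** 2) - sg[None, :]
        w = np.exp(lp - lp.max())
        return np.array([float((w.sum(1) * b1).sum() / w.sum())])

    # single-slope model: grid over the centered intercept a = b1 + b2*mean(x)
    # (a shear with unit Jacobian) so the rectangular grid is not defeated by
    # the intercept/slope posterior correlation of the uncentered model
    x = np.asarray(x, dtype=float)
    xm = float(x.mean())
    xc = x - xm
    slope_hat = float((xc @ y) / (xc @ xc))
    se = s / np.sqrt(float(xc @ xc))
    a = b1  # y-bar grid doubles as the centered-intercept grid
    b2 = np.linspace(slope_hat - 8 * se, slope_hat + 8 * se, n_grid)
    pred = a[:, None, None] + b2[None, :, None] * xc[None, None, :]
    resid2 = ((y[None, None, :] - pred) ** 2).sum(-1)
    ll = (
        -n * np.log(sg)[None, None, :]
        - 0.5 * resid2[:, :, None] / sg[None, None, :] ** 2
    )
    b1_grid = a[:, None] - b2[None, :] * xm  # natural-scale intercept
    lp = (
        ll
        - np.log1p((b1_grid[:, :, None] / 5.0) ** 2)
        - np.log1p((b2[None, :, None] / 5.0) ** 2)
        - sg[None, None, :]
    )
    w = np.exp(lp - lp.max())
    total = w.sum()
    mean_b1 = float((w.sum(axis=2) * b1_grid).sum() / total)
    mean_b2 = float((w.sum(axis=(0, 2)) * b2).sum() / total)
    return np.array([mean_b1, mean_b2])
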