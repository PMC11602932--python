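"""Analysis models: ANCOVA on change from baseline, MMRM, Rubin pooling.

The estimand is the Active-minus-Control difference in mean change from
baseline at the final timepoint.  Complete (or imputed) data are
analysed with ANCOVA — change regressed on treatment group and baseline
— with marginal (LS) means evaluated at the pooled baseline mean.
Incomplete data can alternatively be analysed directly with a mixed
model for repeated measures (MMRM): outcomes at all post-baseline
timepoints, fixed effects for treatment-by-timepoint and
baseline-by-timepoint, and a single unstructured residual covariance
shared by the arms, fitted by REML.  Multiple-imputation estimates are
combined with Rubin's rules using the Barnard-Rubin small-sample
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .simulate import TrialData

__all__ = [
    "AncovaFit",
    "MmrmFit",
    "PooledResult",
    "fit_ancova",
    "fit_mmrm",
    "pool_rubin",
]


@dataclass(frozen=True)
class AncovaFit:
    """ANCOVA of final change from baseline on arm and baseline."""

    effect: float
    lsmean_control: float
    lsmean_active: float
    se_effect: float
    df_complete: int
    n: int

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.df_complete)
        return self.effect - t * self.se_effect, self.effect + t * self.se_effect

    def p_value(self) -> float:
        return 2 * stats.t.sf(abs(self.effect) / self.se_effect, self.df_complete)


def _extract_frame(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    if isinstance(data, TrialData):
        df, J = data.df, data.J
    else:
        df = data
        J = max(int(c[1:]) for c in df.columns if c.startswith("y") and c[1:].isdigit())
    y0 = df["y0"].to_numpy(dtype=float)
    yJ = df[f"y{J}"].to_numpy(dtype=float)
    arm = (df["arm"] == "A").to_numpy()
    return y0, yJ, arm, J


def fit_ancova(data) -> AncovaFit:
    """OLS of Y_J - Y_0 on intercept, arm and baseline.

    ``data`` is a :class:`TrialData` or a wide DataFrame with no missing
    final outcome.  LS-means are the fitted changes at the pooled mean
    baseline; the effect is their difference, identical to the arm
    coefficient.
    """
    y0, yJ, arm, _ = _extract_frame(data)
    if np.isnan(yJ).any() or np.isnan(y0).any():
        raise ValueError("fit_ancova needs complete baseline and final outcomes")
    if arm.all() or not arm.any():
        raise ValueError("both treatment arms must be present")
    effects, ses, (b0, _, b2) = _ancova_many(y0, arm, yJ[:, None])
    n = y0.size
    ybar0 = y0.mean()
    lsmean_c = float(b0[0] + b2[0] * ybar0)
    return AncovaFit(
        effect=float(effects[0]),
        lsmean_control=lsmean_c,
        lsmean_active=lsmean_c + float(effects[0]),
        se_effect=float(ses[0]),
        df_complete=n - 3,
        n=n,
    )


def _ancova_many(
    y0: np.ndarray, arm_active: np.ndarray, yJ_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Vectorised ANCOVA over many completed copies of the final outcome.

    ``yJ_cols`` has one column per completed dataset; the design
    (intercept, arm, baseline) is shared, so a single factorisation
    serves every copy.  Returns per-copy effects and model-based SEs plus
    the coefficient rows (intercept, arm, baseline).
    """
    n = y0.size
    change = yJ_cols - y0[:, None]
    X = np.column_stack([np.ones(n), arm_active.astype(float), y0])
    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, q.T @ change)  # (3, m)
    resid = change - X @ beta
    sigma2 = (resid * resid).sum(axis=0) / (n - 3)
    xtx_inv = np.linalg.solve(r.T @ r, np.eye(3))
    ses = np.sqrt(sigma2 * xtx_inv[1, 1])
    return beta[1], ses, (beta[0], beta[1], beta[2])


@dataclass
class MmrmFit:
    """REML fit of the repeated-measures model with unstructured covariance."""

    effect_by_timepoint: np.ndarray
    se_by_timepoint: np.ndarray
    lsmeans_by_timepoint: np.ndarray  # (J, 2): control, active adjusted means
    sigma_hat: np.ndarray
    converged: bool
    reml_loglik: float
    reml_loglik_start: float
    df: int
    n: int

    @property
    def effect(self) -> float:
        return float(self.effect_by_timepoint[-1])

    @property
    def se_effect(self) -> float:
        return float(self.se_by_timepoint[-1])

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.df)
        return self.effect - t * self.se_effect, self.effect + t * self.se_effect

    def p_value(self) -> float:
        return 2 * stats.t.sf(abs(self.effect) / self.se_effect, self.df)


def _chol_from_theta(theta: np.ndarray, J: int) -> np.ndarray:
    L = np.zeros((J, J))
    L[np.diag_indices(J)] = np.exp(theta[:J])
    if J > 1:
        L[np.tril_indices(J, -1)] = theta[J:]
    return L


def fit_mmrm(data: TrialData, maxiter: int = 200, tol: float = 1e-8) -> MmrmFit:
    """Fit the MMRM by direct REML maximisation.

    Fixed effects are timepoint, treatment-by-timepoint and
    baseline-by-timepoint (a separate intercept, arm effect and baseline
    slope at every timepoint); the residual covariance is a single
    unstructured J x J matrix parameterised by its log-Cholesky factor,
    which keeps it positive definite.  Patients with at least one
    post-baseline outcome contribute; under monotone missingness each
    contributes its leading observed block.  Non-convergence is flagged
    on the returned fit, not raised.
    """
    J = data.J
    y = data.y_matrix()
    y0 = y[:, 0]
    arm = data.arm_active.astype(float)
    post = y[:, 1:]
    n_obs = (~np.isnan(post)).sum(axis=1)
    # monotone: observed timepoints are 1..k
    keep = n_obs > 0
    post, y0k, armk, n_obs = post[keep], y0[keep], arm[keep], n_obs[keep]
    n_used = int(keep.sum())
    p = 3 * J

    # Per missingness pattern (observed times 1..k) the patient design is the
    # same three regressors u = (1, arm, y0) at every timepoint, so all REML
    # quantities reduce to pattern-level cross-products: M = sum u u',
    # N[t] = sum y_t u and G = sum y y', combined with Sigma^{-1} blocks.
    groups = []
    for k in range(1, J + 1):
        sel = n_obs == k
        if not sel.any():
            continue
        yk = post[sel, :k]
        u = np.column_stack([np.ones(int(sel.sum())), armk[sel], y0k[sel]])
        groups.append((k, int(sel.sum()), u.T @ u, yk.T @ u, yk.T @ yk))

    def suff_stats(Sigma):
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet = 0.0
        for k, nk, M, N, G in groups:
            S = Sigma[:k, :k]
            cf = np.linalg.cholesky(S)
            W = np.linalg.solve(S, np.eye(k))
            logdet += nk * 2 * np.log(np.diag(cf)).sum()
            xtvx[: 3 * k, : 3 * k] += np.kron(W, M)
            xtvy[: 3 * k] += (W @ N).reshape(-1)
            ytvy += float((W * G).sum())
        return xtvx, xtvy, ytvy, logdet

    def neg_reml(theta):
        L = _chol_from_theta(theta, J)
        Sigma = L @ L.T
        try:
            xtvx, xtvy, ytvy, logdet = suff_stats(Sigma)
            beta = np.linalg.solve(xtvx, xtvy)
            quad = ytvy - beta @ xtvy
            sign, logdet_x = np.linalg.slogdet(xtvx)
            if sign <= 0 or quad < 0:
                return 1e12
            return 0.5 * (logdet + logdet_x + quad)
        except np.linalg.LinAlgError:
            return 1e12

    # start from per-timepoint OLS residual variances (diagonal covariance)
    theta0 = np.zeros(J + J * (J - 1) // 2)
    for t in range(J):
        obs = ~np.isnan(post[:, t])
        Xt = np.column_stack([np.ones(obs.sum()), armk[obs], y0k[obs]])
        bt, *_ = np.linalg.lstsq(Xt, post[obs, t], rcond=None)
        r = post[obs, t] - Xt @ bt
        dfree = max(obs.sum() - 3, 1)
        theta0[t] = 0.5 * np.log(max(r @ r / dfree, 1e-8))
    nll0 = neg_reml(theta0)

    res = optimize.minimize(
        neg_reml, theta0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8},
    )
    theta = res.x
    L = _chol_from_theta(theta, J)
    Sigma = L @ L.T
    xtvx, xtvy, _, _ = suff_stats(Sigma)
    beta = np.linalg.solve(xtvx, xtvy)
    cov_beta = np.linalg.solve(xtvx, np.eye(p))
    arm_idx = np.array([3 * t + 1 for t in range(J)])
    ybar0 = float(y0k.mean())
    ls_c = np.array([beta[3 * t] + beta[3 * t + 2] * ybar0 for t in range(J)])
    return MmrmFit(
        effect_by_timepoint=beta[arm_idx],
        se_by_timepoint=np.sqrt(np.diag(cov_beta)[arm_idx]),
        lsmeans_by_timepoint=np.column_stack([ls_c, ls_c + beta[arm_idx]]),
        sigma_hat=Sigma,
        converged=bool(res.success),
        reml_loglik=-float(res.fun),
        reml_loglik_start=-float(nll0),
        df=n_used - 3,
        n=n_used,
    )


@dataclass(frozen=True)
class PooledResult:
    """Rubin's-rules combination of m per-imputation estimates."""

    qbar: float
    W: float
    B: float
    T: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.T)

    @property
    def halfwidth(self) -> float:
        return (self.ci_high - self.ci_low) / 2


def _pool(
    effects: np.ndarray, ses: np.ndarray, df_complete: float, alpha: float, m: int
) -> PooledResult:
    qbar = float(effects.mean())
    W = float((ses ** 2).mean())
    B = float(effects.var(ddof=1))
    T = W + (1 + 1 / m) * B
    if B <= 0 or T <= 0:
        df = float(df_complete)
    else:
        lam = (1 + 1 / m) * B / T
        df_old = (m - 1) / lam ** 2
        df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    se = math.sqrt(T)
    p = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else 0.0
    return PooledResult(
        qbar=qbar, W=W, B=B, T=T, df=df,
        ci_low=qbar - tcrit * se, ci_high=qbar + tcrit * se,
        p_value=float(p), m=m,
    )


def pool_rubin(fits: Sequence[AncovaFit], alpha: float = 0.05) -> PooledResult:
    """Combine per-imputation ANCOVA fits.

    qbar is the mean effect, W the mean squared SE, B the between-copy
    variance of the effects and T = W + (1 + 1/m) B; the reference t
    distribution uses the Barnard-Rubin adjusted degrees of freedom,
    collapsing to the complete-data df when B = 0.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    effects = np.array([f.effect for f in fits])
    ses = np.array([f.se_effect for f in fits])
    df_complete = fits[0].df_complete
    return _pool(effects, ses, df_complete, alpha, m)
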