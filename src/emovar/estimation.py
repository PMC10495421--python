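"""Structured VARX(1) estimation by feasible generalized least squares.

The first-order VARX

    E_t = alpha + Gamma E_{t-1} + B X_t + eps_t,   eps_t ~ N(0, Sigma)

is restricted by expressing its coefficients as functions of the
emotions' appraisal-dimension scores:

    alpha_i   = mu0  + sum_k mu_k  DIM_ik + mu_S  S_i          (base level)
    gamma_ii  = lam0 + sum_k lam_k DIM_ik + lam_S S_i          (carryover)
    gamma_ij  = tau0 + sum_k tau_up_k  DIST_up[i,j,k]
                     + sum_k tau_down_k DIST_down[i,j,k]
                     + tau_S S_i                    (i != j, transitions)

with DIM and S mean-centered across emotions. Substituting these into
the VARX and collecting terms yields a single stacked regression with
4K+6 shared columns plus N*M free exogenous columns, estimated in two
steps: pooled OLS, then GLS reweighting by the inverse of the residual
cross-equation covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, EstimationError
from .types import (
    DimensionScores,
    DistanceTensor,
    EmotionPanel,
    StructuredParams,
    VARCoefficients,
    shared_param_names,
)

# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class StackedDesign:
    """Stacked (destination-major) regression for the structured VARX.

    Rows are ordered equation-major: all T-1 observations of emotion 1,
    then emotion 2, ... so GLS weights of the form Sigma^-1 (x) I apply
    blockwise. ``n_shared`` leading columns are the shared structural
    parameters in :func:`shared_param_names` order; the remaining N*M
    columns are equation-specific exogenous effects beta_{i,m}.
    """

    X: np.ndarray  # (N*(T-1), n_shared + N*M)
    y: np.ndarray  # (N*(T-1),)
    n_emotions: int
    n_obs: int  # T-1, observations per equation
    n_exog: int
    k: int
    colnames: list[str]

    @property
    def n_shared(self) -> int:
        return 4 * self.k + 6


def build_design(
    panel: EmotionPanel, dims: DimensionScores, dist: DistanceTensor
) -> StackedDesign:
    """Build the stacked restricted design from a panel and centered scores.

    For equation i at day t >= 2 the regressors are, in order: the
    base-level block [1, DIM_i1..K, S_i]; the carryover block
    [E_{i,t-1}, DIM_ik * E_{i,t-1}, S_i * E_{i,t-1}]; the transition
    block [sum_{j!=i} E_{j,t-1}, sum_j DIST_up[i,j,k] E_{j,t-1} per k,
    sum_j DIST_down[i,j,k] E_{j,t-1} per k, S_i * sum_{j!=i} E_{j,t-1}];
    then N*M zero/one-interacted exogenous columns.
    """
    if not dims.centered:
        raise EstimationError("dimension scores must be mean-centered")
    if panel.n_days < 2:
        raise EstimationError("panel must contain at least 2 days")
    n, k = dims.n_emotions, dims.n_dims
    if panel.n_emotions != n:
        raise EstimationError("panel and dimension scores disagree on N")
    m = panel.n_exog

    E = panel.freq.to_numpy(dtype=float)
    Elag, Eresp = E[:-1], E[1:]
    Xex = panel.exog.to_numpy(dtype=float)[1:] if m else np.zeros((E.shape[0] - 1, 0))
    t_eff = Elag.shape[0]

    n_shared = 4 * k + 6
    ncol = n_shared + n * m
    X = np.zeros((n * t_eff, ncol))
    y = np.empty(n * t_eff)
    ones = np.ones(t_eff)

    # cross-lag aggregates: for each destination i, Elag @ dist[i, :, k]
    # (diagonal distances are zero, so j != i is automatic there)
    rowsum = Elag.sum(axis=1)
    for i in range(n):
        r = slice(i * t_eff, (i + 1) * t_eff)
        y[r] = Eresp[:, i]
        c = 0
        # mu block
        X[r, c] = ones
        X[r, c + 1 : c + 1 + k] = dims.scores[i]
        X[r, c + 1 + k] = dims.dict_size[i]
        c += k + 2
        # lambda block
        X[r, c] = Elag[:, i]
        X[r, c + 1 : c + 1 + k] = dims.scores[i] * Elag[:, [i]]
        X[r, c + 1 + k] = dims.dict_size[i] * Elag[:, i]
        c += k + 2
        # tau block
        cross = rowsum - Elag[:, i]
        X[r, c] = cross
        X[r, c + 1 : c + 1 + k] = Elag @ dist.up[i]
        X[r, c + 1 + k : c + 1 + 2 * k] = Elag @ dist.down[i]
        X[r, c + 1 + 2 * k] = dims.dict_size[i] * cross
        c += 2 * k + 2
        # equation-specific exogenous columns
        if m:
            X[r, n_shared + i * m : n_shared + (i + 1) * m] = Xex

    colnames = shared_param_names(k) + [
        f"beta_{i + 1}_{j + 1}" for i in range(n) for j in range(m)
    ]
    return StackedDesign(
        X=X, y=y, n_emotions=n, n_obs=t_eff, n_exog=m, k=k, colnames=colnames
    )


# ---------------------------------------------------------------------------
# FGLS estimation
# ---------------------------------------------------------------------------


def _split_params(design: StackedDesign, coef, vcov):
    n, m, ns = design.n_emotions, design.n_exog, design.n_shared
    beta = coef[ns:].reshape(n, m) if m else np.zeros((n, 0))
    se = beta_se = vc = None
    if vcov is not None:
        full_se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        se = full_se[:ns]
        beta_se = full_se[ns:].reshape(n, m) if m else np.zeros((n, 0))
        vc = vcov[:ns, :ns]
    return beta, se, beta_se, vc


def estimate_fgls(
    design: StackedDesign,
    sigma: np.ndarray | None = None,
    iterate: bool = False,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> StructuredParams:
    """Two-step FGLS for the stacked structured design.

    Step 1 fits pooled OLS; step 2 estimates the cross-equation residual
    covariance Sigma-hat (denominator T-1, the per-equation observation
    count after lagging, no degrees-of-freedom correction); step 3
    re-fits by GLS with weight Sigma-hat^-1 (x) I. Standard errors come
    from the GLS covariance (X' (Sigma^-1 (x) I) X)^-1.

    Parameters
    ----------
    sigma
        Optional known error covariance; skips the OLS step's covariance
        estimate and weights by this matrix directly (plain GLS).
    iterate
        Re-estimate Sigma-hat from GLS residuals and re-fit until the
        coefficient vector stabilises (off by default: the two-step
        estimator is the reference procedure).

    Notes
    -----
    If the OLS pass fits the data exactly (noiseless identification),
    the residual covariance is identically zero; the OLS solution is
    then already the GLS solution and is returned with zero Sigma-hat.
    """
    X, y = design.X, design.y
    n, t_eff = design.n_emotions, design.n_obs

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the deficiency via the QR diagonal
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [
            design.colnames[j]
            for j in np.where(diag < 1e-10 * diag.max())[0]
        ]
        raise EstimationError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect columns: {bad or 'unidentified'}"
        )

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef

    if sigma is None:
        scale = max(1.0, float(np.max(np.abs(y))))
        if np.max(np.abs(resid)) < 1e-10 * scale:
            # exact fit: GLS reweighting is a no-op; report zero noise
            vcov = np.zeros((X.shape[1], X.shape[1]))
            beta, se, beta_se, vc = _split_params(design, coef, vcov)
            return StructuredParams(
                k=design.k,
                theta=coef[: design.n_shared],
                beta=beta,
                se=se,
                beta_se=beta_se,
                vcov=vc,
                sigma_hat=np.zeros((n, n)),
            )
        R = resid.reshape(n, t_eff).T  # (T-1, N)
        sigma_hat = R.T @ R / t_eff
    else:
        sigma_hat = np.asarray(sigma, dtype=float)

    for _ in range(max_iter if iterate else 1):
        try:
            L = np.linalg.cholesky(sigma_hat)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                "residual covariance is singular; the system has more "
                "emotions than the sample supports (use more days or "
                "fewer emotions)"
            ) from exc
        A = np.linalg.inv(L)  # whitener: Var(A eps) = I
        # apply (A (x) I) to the stacked vector / each design column
        Yw = (A @ y.reshape(n, t_eff)).reshape(-1)
        Xw = (
            np.einsum("ab,bti->ati", A, X.reshape(n, t_eff, X.shape[1]))
        ).reshape(n * t_eff, X.shape[1])
        new_coef, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        xtx = Xw.T @ Xw
        vcov = np.linalg.inv(xtx)
        if iterate and sigma is None:
            if np.max(np.abs(new_coef - coef)) < tol:
                coef = new_coef
                break
            coef = new_coef
            R = (y - X @ coef).reshape(n, t_eff).T
            sigma_hat = R.T @ R / t_eff
        else:
            coef = new_coef
            break

    beta, se, beta_se, vc = _split_params(design, coef, vcov)
    return StructuredParams(
        k=design.k,
        theta=coef[: design.n_shared],
        beta=beta,
        se=se,
        beta_se=beta_se,
        vcov=vc,
        sigma_hat=sigma_hat,
    )


def expand_coefficients(
    params: StructuredParams, dims: DimensionScores, dist: DistanceTensor
) -> VARCoefficients:
    """Expand shared parameters to full (alpha, Gamma, B, Sigma) matrices."""
    if not dims.centered:
        raise EstimationError("dimension scores must be mean-centered")
    if dims.n_dims != params.k:
        raise EstimationError("dimension count mismatch between params and scores")
    n = dims.n_emotions
    alpha = params.mu0 + dims.scores @ params.mu + params.mu_S * dims.dict_size
    diag = params.lam0 + dims.scores @ params.lam + params.lam_S * dims.dict_size
    gamma = (
        params.tau0
        + np.einsum("ijk,k->ij", dist.up, params.tau_up)
        + np.einsum("ijk,k->ij", dist.down, params.tau_down)
        + params.tau_S * dims.dict_size[:, None]
    )
    gamma[np.arange(n), np.arange(n)] = diag
    sigma = params.sigma_hat if params.sigma_hat is not None else np.zeros((n, n))
    return VARCoefficients(
        alpha=alpha, gamma=gamma, beta=params.beta, sigma=sigma, names=dims.names
    )


# ---------------------------------------------------------------------------
# Pre-estimation diagnostics
# ---------------------------------------------------------------------------


def adf_test(
    series: np.ndarray | pd.Series,
    alpha: float = 0.05,
    exog: np.ndarray | None = None,
):
    """Augmented Dickey-Fuller unit-root test (constant, AIC lag choice).

    Returns ``(statistic, reject)`` where ``reject`` means the unit-root
    null is rejected at ``alpha`` against the MacKinnon critical value.

    ``exog`` (e.g. known step dummies) is partialled out by OLS before
    testing: a permanent level shift left in the series mimics a unit
    root and destroys the test's power, so known breaks should be
    removed first.
    """
    from statsmodels.tsa.stattools import adfuller

    x = np.asarray(series, dtype=float)
    if x.size < 25:
        raise DomainError("series too short for the ADF test (need >= 25)")
    if np.ptp(x) == 0:
        raise DomainError("ADF test undefined for a constant series")
    if exog is not None and np.asarray(exog).size:
        z = np.column_stack([np.ones(x.size), np.asarray(exog, dtype=float)])
        b, *_ = np.linalg.lstsq(z, x, rcond=None)
        x = x - z @ b + x.mean()
    stat, _pvalue, _lags, _nobs, crit, _ = adfuller(x, regression="c", autolag="AIC")
    key = f"{int(round(alpha * 100))}%"
    return float(stat), bool(stat < crit[key])


def _var_lag_fit(E: np.ndarray, Xex: np.ndarray, p: int, t_start: int):
    """OLS fit of an unrestricted VAR(p) with exog on a common sample.

    Returns the residual matrix and per-equation parameter count.
    """
    t, n = E.shape
    Z = []
    for lag in range(1, p + 1):
        Z.append(E[t_start - lag : t - lag])
    Z = np.hstack(Z) if Z else np.empty((t - t_start, 0))
    X = np.hstack([np.ones((t - t_start, 1)), Z, Xex[t_start:]])
    Y = E[t_start:]
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ B, X.shape[1]


def select_lag_order(panel: EmotionPanel, p_max: int = 4):
    """Choose the VAR lag order by information criteria on a common sample.

    Fits unrestricted VAR(p) for p = 1..p_max (with the panel's exog),
    computes multivariate AIC/BIC/HQC from ln|Sigma-hat(p)|, and returns
    ``(p_bic, table)`` where the table has one row per candidate order.
    BIC is the headline selector.
    """
    if p_max < 1:
        raise DomainError("p_max must be >= 1")
    E = panel.freq.to_numpy(dtype=float)
    t, n = E.shape
    if t - p_max <= n * p_max + 1 + panel.n_exog:
        raise EstimationError("insufficient observations for the requested p_max")
    Xex = (
        panel.exog.to_numpy(dtype=float)
        if panel.n_exog
        else np.zeros((t, 0))
    )
    t_eff = t - p_max
    rows = []
    for p in range(1, p_max + 1):
        resid, k_eq = _var_lag_fit(E, Xex, p, p_max)
        sig = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            raise EstimationError("degenerate residual covariance in lag selection")
        n_par = n * k_eq  # total free parameters
        aic = logdet + 2.0 * n_par / t_eff
        bic = logdet + np.log(t_eff) * n_par / t_eff
        hqc = logdet + 2.0 * np.log(np.log(t_eff)) * n_par / t_eff
        rows.append({"p": p, "aic": aic, "bic": bic, "hqc": hqc})
    table = pd.DataFrame(rows).set_index("p")
    return int(table["bic"].idxmin()), table


def granger_tests(panel: EmotionPanel) -> pd.DataFrame:
    """Pairwise Granger-causality p-values from the unrestricted VAR(1).

    Entry (i, j) is the Wald p-value for "source j does not Granger-cause
    destination i", i.e. the lag-j coefficient in equation i is zero.
    The diagonal is reported as NaN (not applicable).
    """
    E = panel.freq.to_numpy(dtype=float)
    t, n = E.shape
    Xex = panel.exog.to_numpy(dtype=float) if panel.n_exog else np.zeros((t, 0))
    X = np.hstack([np.ones((t - 1, 1)), E[:-1], Xex[1:]])
    Y = E[1:]
    xtx_inv = np.linalg.inv(X.T @ X)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    dof = X.shape[0] - X.shape[1]
    from scipy import stats

    pmat = np.full((n, n), np.nan)
    for i in range(n):
        s2 = resid[:, i] @ resid[:, i] / dof
        for j in range(n):
            if i == j:
                continue
            b = B[1 + j, i]
            var_b = s2 * xtx_inv[1 + j, 1 + j]
            w = b * b / var_b
            pmat[i, j] = stats.chi2.sf(w, df=1)
    return pd.DataFrame(pmat, index=panel.names, columns=panel.names)


def wald_symmetry(params: StructuredParams, k: int):
    """Wald test of symmetric transition distances on dimension k.

    H0: tau_up_k == tau_down_k, using the joint GLS covariance of the
    shared parameters; returns ``(chi2, df, p)`` with df = 1. ``k`` is
    1-based to match the dimension labels.
    """
    from scipy import stats

    if params.vcov is None:
        raise EstimationError("wald_symmetry requires a joint parameter covariance")
    if not 1 <= k <= params.k:
        raise DomainError(f"dimension index must be in 1..{params.k}")
    names = params.names
    iu = names.index(f"tau_up_{k}")
    idn = names.index(f"tau_down_{k}")
    diff = params.theta[iu] - params.theta[idn]
    var = params.vcov[iu, iu] + params.vcov[idn, idn] - 2 * params.vcov[iu, idn]
    if var <= 0:
        return 0.0, 1, 1.0
    chi2 = float(diff * diff / var)
    return chi2, 1, float(stats.chi2.sf(chi2, df=1))
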