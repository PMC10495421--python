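"""Post-estimation analytics: durations, shock propagation, distance regressions.

Duration is summarised by the P% duration interval
ln(1 - P/100)/ln(lambda) - 1, the number of days before P% of the
cumulative effect of a shock to a series with carryover lambda has
materialised. Shocks are propagated with impulse-response functions:
the day-0 response embeds co-occurrence through the error covariance
(a shock of delta to emotion i moves emotion j by delta * sigma_ij /
sigma_ii, the conditional-normal expectation), and subsequent days
follow the autoregressive map. Long-term transition is the cumulative
IRF over days 1-29. Contemporaneous and cumulative effects are then
regressed on the asymmetric appraisal distances between emotion pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .types import DimensionScores, DistanceTensor, IRFResult, VARCoefficients

CIRF_START, CIRF_END = 1, 29


def duration_interval(lam: float, p: float = 90.0) -> float:
    """P% duration interval in days for carryover ``lam``.

    Smallest (real-valued) number of days x such that the geometric
    cumulative fraction 1 - lam**(x+1) of a shock's total effect has
    materialised equals P/100: ln(1 - P/100)/ln(lam) - 1.
    """
    if not 0.0 < lam < 1.0:
        raise DomainError("carryover must lie strictly in (0, 1)")
    if not 0.0 < p < 100.0:
        raise DomainError("P must lie strictly in (0, 100)")
    return float(np.log(1.0 - p / 100.0) / np.log(lam) - 1.0)


def shock_vector(sigma: np.ndarray, source: int, delta: float) -> np.ndarray:
    """Day-0 response of all emotions to a shock of ``delta`` at ``source``.

    Under joint normality the expected contemporaneous movement of
    emotion j is delta * sigma_ij / sigma_ii; the source itself moves by
    delta.
    """
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0]
    if sigma.shape != (n, n) or not np.allclose(sigma, sigma.T, atol=1e-8):
        raise DomainError("sigma must be a symmetric square matrix")
    if not 0 <= source < n:
        raise DomainError("source index out of range")
    if sigma[source, source] <= 0:
        raise DomainError("source error variance must be positive")
    vec = delta * sigma[:, source] / sigma[source, source]
    vec[source] = delta
    return vec


def compute_irf(
    coeffs: VARCoefficients,
    shock: np.ndarray,
    horizon: int = 30,
    source: int = 0,
    delta: float | None = None,
) -> IRFResult:
    """Propagate a day-0 shock through the autoregressive map.

    responses[0] = shock; responses[t] = Gamma responses[t-1]. The paths
    are incremental deviations from the unshocked trajectory, so the
    intercept and exogenous terms cancel.
    """
    if horizon < 1:
        raise DomainError("horizon must be >= 1")
    shock = np.asarray(shock, dtype=float)
    n = coeffs.n_emotions
    if shock.shape != (n,):
        raise DomainError("shock vector length must equal the emotion count")
    responses = np.empty((horizon, n))
    responses[0] = shock
    for t in range(1, horizon):
        responses[t] = coeffs.gamma @ responses[t - 1]
    return IRFResult(
        source=source,
        delta=float(shock[source] if delta is None else delta),
        shock=shock,
        responses=responses,
    )


def cumulative_irf(
    irf: IRFResult, t_start: int = CIRF_START, t_end: int = CIRF_END
) -> np.ndarray:
    """Per-destination sum of responses over days t_start..t_end inclusive."""
    if not 0 <= t_start <= t_end:
        raise DomainError("need 0 <= t_start <= t_end")
    if irf.horizon <= t_end:
        raise DomainError(
            f"horizon {irf.horizon} too short for a day-{t_end} cumulative response"
        )
    return irf.responses[t_start : t_end + 1].sum(axis=0)


@dataclass
class ShockStudy:
    """One IRF per source emotion plus destination x source CE/CIRF matrices."""

    irfs: list[IRFResult]
    ce: pd.DataFrame  # rows destination, cols source
    cirf: pd.DataFrame
    deltas: np.ndarray


def run_all_shocks(
    coeffs: VARCoefficients,
    delta_frac: float = 0.10,
    delta_mode: str = "stationary-mean",
    horizon: int = 30,
    xbar: np.ndarray | None = None,
    sample_means: np.ndarray | None = None,
) -> ShockStudy:
    """Shock every source emotion in turn and collect CE and CIRF matrices.

    The shock size for source i is ``delta_frac`` (default 10%) of a
    per-emotion baseline: the model-implied stationary mean
    (I - Gamma)^-1 (alpha + B xbar) by default, or the panel sample mean
    with ``delta_mode='sample-mean'``, or ``delta_frac`` itself as an
    absolute size with ``delta_mode='absolute'``.
    """
    n = coeffs.n_emotions
    if delta_mode == "stationary-mean":
        base = coeffs.stationary_mean(xbar)
        deltas = delta_frac * base
    elif delta_mode == "sample-mean":
        if sample_means is None:
            raise DomainError("sample-mean mode needs the panel sample means")
        deltas = delta_frac * np.asarray(sample_means, dtype=float)
    elif delta_mode == "absolute":
        deltas = np.full(n, delta_frac)
    else:
        raise DomainError(f"unknown delta mode {delta_mode!r}")

    irfs = []
    ce = np.empty((n, n))
    cf = np.empty((n, n))
    for i in range(n):
        shock = shock_vector(coeffs.sigma, i, float(deltas[i]))
        irf = compute_irf(coeffs, shock, horizon=horizon, source=i)
        irfs.append(irf)
        ce[:, i] = irf.ce
        cf[:, i] = cumulative_irf(irf)
    names = coeffs.names
    return ShockStudy(
        irfs=irfs,
        ce=pd.DataFrame(ce, index=names, columns=names),
        cirf=pd.DataFrame(cf, index=names, columns=names),
        deltas=np.asarray(deltas, dtype=float),
    )


def distance_regression(
    effects: pd.DataFrame | np.ndarray,
    dist: DistanceTensor,
    dims: DimensionScores,
    include_size_control: bool = True,
) -> pd.DataFrame:
    """OLS of pairwise effects on asymmetric appraisal distances.

    The effect of source j on destination i (i != j; N(N-1)
    observations) is regressed on a constant, the K upward and K
    downward distances of the pair, and optionally the destination's
    centered dictionary size. Returns a coefficient table with
    conventional OLS standard errors and p-values.
    """
    import statsmodels.api as sm

    eff = np.asarray(effects, dtype=float)
    n = dims.n_emotions
    if eff.shape != (n, n):
        raise DomainError("effects must be a destination x source square matrix")
    k = dims.n_dims
    mask = ~np.eye(n, dtype=bool)
    i_idx, j_idx = np.where(mask)
    y = eff[i_idx, j_idx]
    cols = {}
    for k_ in range(k):
        cols[f"dist_up_{dims.dim_names[k_]}"] = dist.up[i_idx, j_idx, k_]
    for k_ in range(k):
        cols[f"dist_down_{dims.dim_names[k_]}"] = dist.down[i_idx, j_idx, k_]
    if include_size_control:
        sizes = dims.dict_size
        if not dims.centered:
            sizes = sizes - sizes.mean()
        cols["dict_size"] = sizes[i_idx]
    X = pd.DataFrame(cols)
    X = sm.add_constant(X)
    res = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
    )


def duration_table(
    coeffs: VARCoefficients,
    lam0: float,
    lam: np.ndarray,
    dims: DimensionScores,
    p: float = 90.0,
) -> pd.DataFrame:
    """Durations per emotion plus +/- 1 SD profile rows per dimension.

    Per-emotion rows use the expanded carryover gamma_ii; profile rows
    use lambda0 +/- lambda_k * SD(dim_k), the carryover of a hypothetical
    emotion one sample standard deviation above/below average on one
    dimension and average on the rest.
    """
    rows = []
    diag = np.diag(coeffs.gamma)
    for name, lam_i in zip(coeffs.names, diag):
        dur = duration_interval(lam_i, p) if 0 < lam_i < 1 else np.nan
        rows.append({"profile": name, "carryover": lam_i, "duration_days": dur})
    sds = dims.scores.std(axis=0, ddof=1)
    for k_, dim_name in enumerate(dims.dim_names):
        for sign, tag in ((1.0, "+1sd"), (-1.0, "-1sd")):
            lam_prof = lam0 + sign * lam[k_] * sds[k_]
            dur = duration_interval(lam_prof, p) if 0 < lam_prof < 1 else np.nan
            rows.append(
                {
                    "profile": f"{dim_name}_{tag}",
                    "carryover": lam_prof,
                    "duration_days": dur,
                }
            )
    return pd.DataFrame(rows).set_index("profile")
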