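"""Appraisal-dimension space: factor reduction, centering, asymmetric distances.

Emotions are positioned in a K-dimensional appraisal space obtained by
reducing nine survey-rated appraisal dimensions (valence, arousal,
dominance, motivational state, time orientation, agency, certainty,
attentional activity, effort) to K=3 higher-order factors conventionally
labelled valence, arousal and dominance. Transition coefficients of the
structured VAR depend on *asymmetric* distances in that space: the
separation of a destination emotion above or below a source emotion on
each dimension, zero in the other direction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ReductionError
from .types import DimensionScores, DistanceTensor, replace

APPRAISAL_NAMES = [
    "valence",
    "arousal",
    "dominance",
    "motivational_state",
    "time_orientation",
    "agency",
    "certainty",
    "attentional_activity",
    "effort",
]

#: appraisal whose loading anchors the sign (and name) of each factor
FACTOR_ANCHORS = ["valence", "arousal", "dominance"]


def center_scores(raw: DimensionScores) -> DimensionScores:
    """Mean-center dimension scores and dictionary sizes across emotions.

    Idempotent; pairwise differences (hence distances) are unaffected.
    """
    scores = raw.scores - raw.scores.mean(axis=0, keepdims=True)
    dict_size = raw.dict_size - raw.dict_size.mean()
    return replace(raw, scores=scores, dict_size=dict_size, centered=True)


def asymmetric_distances(dims: DimensionScores) -> DistanceTensor:
    """Upward / downward distances between all ordered emotion pairs.

    up[i, j, k] = max(DIM_ik - DIM_jk, 0) and down is its mirror, so on
    every (i, j, k) exactly one of the two is nonzero (or both are zero)
    and their sum is |DIM_ik - DIM_jk|.
    """
    diff = dims.scores[:, None, :] - dims.scores[None, :, :]  # (N, N, K)
    return DistanceTensor(up=np.maximum(diff, 0.0), down=np.maximum(-diff, 0.0))


def reduce_appraisals(
    survey: pd.DataFrame,
    k: int = 3,
    dict_size: Sequence[float] | None = None,
) -> DimensionScores:
    """Reduce mean appraisal ratings (emotions x 9) to K factor scores.

    Principal-axis factoring on the correlation matrix of the appraisal
    columns, varimax rotation, regression-method factor scores. When the
    survey includes the three anchor appraisals and K equals 3, factors
    are matched one-to-one to valence/arousal/dominance by the magnitude
    of the anchor loadings and their signs fixed so the eponymous
    appraisal loads positively; otherwise each factor's sign is fixed by
    its largest-magnitude loading.

    Parameters
    ----------
    survey
        One row per emotion (index = emotion names), one column per
        appraisal dimension.
    k
        Number of higher-order factors to extract; must satisfy k < N.
    dict_size
        Optional per-emotion dictionary sizes carried through into the
        returned scores (defaults to 1 for every emotion).
    """
    from statsmodels.multivariate.factor import Factor

    if survey.shape[0] <= k:
        raise ReductionError("need more emotions than factors")
    x = survey.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ReductionError("survey ratings contain non-finite values")
    corr = np.corrcoef(x, rowvar=False)
    if not np.isfinite(corr).all() or np.linalg.cond(corr) > 1e12:
        raise ReductionError("appraisal correlation matrix is singular")

    try:
        res = Factor(x, n_factor=k, method="pa").fit()
        if k > 1:
            res.rotate("varimax")
        scores = res.factor_scoring(x, method="regression")
    except Exception as exc:  # statsmodels raises bare LinAlgError etc.
        raise ReductionError(f"factor extraction failed: {exc}") from exc
    loadings = np.asarray(res.loadings)

    cols = [str(c) for c in survey.columns]
    order = np.arange(k)
    if k == len(FACTOR_ANCHORS) and all(a in cols for a in FACTOR_ANCHORS):
        anchor_rows = [cols.index(a) for a in FACTOR_ANCHORS]
        # one-to-one factor->anchor assignment maximizing |loading|
        _, order = linear_sum_assignment(-np.abs(loadings[anchor_rows, :]))
        loadings = loadings[:, order]
        scores = scores[:, order]
        signs = np.sign(loadings[anchor_rows, np.arange(k)])
        dim_names = list(FACTOR_ANCHORS)
    else:
        signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
        dim_names = [f"factor_{j + 1}" for j in range(k)]
    signs[signs == 0] = 1.0
    scores = scores * signs

    n = survey.shape[0]
    sizes = np.ones(n) if dict_size is None else np.asarray(dict_size, dtype=float)
    return DimensionScores(
        names=[str(i) for i in survey.index],
        scores=scores,
        dict_size=sizes,
        dim_names=dim_names,
        centered=False,
    )
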