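"""Core data containers shared across the pipeline.

The panel of daily emotion frequencies, the appraisal-dimension scores,
the asymmetric distance tensor, the structured (shared) model parameters
and the expanded VAR coefficient matrices all live here, together with
their plain-text serialisation (CSV / JSON / JSONL).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

EXOG_PREFIX = "X_"


# ---------------------------------------------------------------------------
# EmotionPanel
# ---------------------------------------------------------------------------


@dataclass
class EmotionPanel:
    """T x N matrix of daily emotion relative frequencies plus step dummies.

    ``freq`` is indexed by consecutive calendar days, one column per
    emotion; ``exog`` shares the index and holds 0/1 step dummies whose
    columns are monotone non-decreasing (a dummy switches on once and
    stays on).
    """

    freq: pd.DataFrame
    exog: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exog is None:
            self.exog = pd.DataFrame(index=self.freq.index)
        idx = self.freq.index
        if not isinstance(idx, pd.DatetimeIndex):
            idx = pd.DatetimeIndex(idx)
            self.freq = self.freq.set_axis(idx)
            self.exog = self.exog.set_axis(idx)
        diffs = np.diff(idx.values).astype("timedelta64[D]")
        if len(idx) > 1 and not (diffs == np.timedelta64(1, "D")).all():
            raise ConfigurationError("panel dates must be consecutive days")
        if not np.isfinite(self.freq.to_numpy(dtype=float)).all():
            raise ConfigurationError("panel contains non-finite frequencies")
        if self.exog.shape[1]:
            x = self.exog.to_numpy(dtype=float)
            if not np.isin(x, (0.0, 1.0)).all():
                raise ConfigurationError("exogenous dummies must be 0/1")
            if (np.diff(x, axis=0) < 0).any():
                raise ConfigurationError(
                    "exogenous step dummies must be monotone non-decreasing"
                )

    @property
    def names(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def n_emotions(self) -> int:
        return self.freq.shape[1]

    @property
    def n_days(self) -> int:
        return self.freq.shape[0]

    @property
    def n_exog(self) -> int:
        return self.exog.shape[1]

    def to_csv(self, path: str | Path) -> None:
        out = self.freq.join(self.exog)
        out.index.name = "date"
        out.to_csv(path, date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmotionPanel":
        df = pd.read_csv(path, parse_dates=["date"], index_col="date")
        exog_cols = [c for c in df.columns if c.startswith(EXOG_PREFIX)]
        emo_cols = [c for c in df.columns if c not in exog_cols]
        return cls(freq=df[emo_cols], exog=df[exog_cols])


# ---------------------------------------------------------------------------
# DimensionScores
# ---------------------------------------------------------------------------


@dataclass
class DimensionScores:
    """Per-emotion appraisal-dimension scores plus dictionary sizes.

    When ``centered`` is set, both the score columns and the dictionary
    sizes are stored as deviations from their across-emotion means (the
    form entering the structured model).
    """

    names: list[str]
    scores: np.ndarray  # (N, K)
    dict_size: np.ndarray  # (N,)
    dim_names: list[str] | None = None
    centered: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.dict_size = np.asarray(self.dict_size, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != len(self.names):
            raise ConfigurationError("scores must be N x K with N emotion names")
        if self.dict_size.shape != (len(self.names),):
            raise ConfigurationError("dict_size must have one entry per emotion")
        if not np.isfinite(self.scores).all() or not np.isfinite(self.dict_size).all():
            raise ConfigurationError("dimension scores must be finite")
        if self.dim_names is None:
            self.dim_names = [f"dim_{k + 1}" for k in range(self.scores.shape[1])]
        if self.centered:
            n = len(self.names)
            if (np.abs(self.scores.sum(axis=0)) >= 1e-9 * n).any() or abs(
                self.dict_size.sum()
            ) >= 1e-9 * n:
                raise ConfigurationError("centered scores must have ~zero column sums")
        if not self.centered and (self.dict_size <= 0).any():
            raise ConfigurationError("raw dictionary sizes must be positive")

    @property
    def n_emotions(self) -> int:
        return len(self.names)

    @property
    def n_dims(self) -> int:
        return self.scores.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores, index=self.names, columns=self.dim_names)
        df["dict_size"] = self.dict_size
        df.index.name = "emotion"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, centered: bool = False) -> "DimensionScores":
        df = pd.read_csv(path, index_col="emotion")
        dims = [c for c in df.columns if c != "dict_size"]
        return cls(
            names=list(df.index),
            scores=df[dims].to_numpy(),
            dict_size=df["dict_size"].to_numpy(),
            dim_names=dims,
            centered=centered,
        )


# ---------------------------------------------------------------------------
# DistanceTensor
# ---------------------------------------------------------------------------


@dataclass
class DistanceTensor:
    """Asymmetric appraisal-space distances between ordered emotion pairs.

    ``up[i, j, k]`` is the distance by which destination emotion i sits
    *above* source emotion j on dimension k (zero when it sits below);
    ``down`` is the mirror image, so up[i,j,k] * down[i,j,k] == 0 and
    up[i,j,k] == down[j,i,k].
    """

    up: np.ndarray  # (N, N, K)
    down: np.ndarray  # (N, N, K)

    def __post_init__(self) -> None:
        self.up = np.asarray(self.up, dtype=float)
        self.down = np.asarray(self.down, dtype=float)
        if self.up.shape != self.down.shape or self.up.ndim != 3:
            raise ConfigurationError("distance tensors must share an (N, N, K) shape")


# ---------------------------------------------------------------------------
# StructuredParams
# ---------------------------------------------------------------------------


def shared_param_names(k: int) -> list[str]:
    """Canonical ordering of the 4K+6 shared parameters.

    Base-level block (mu), carryover block (lambda), transition block
    (tau); within each block the intercept first, then the K dimension
    terms, then the dictionary-size control. The tau block carries K
    upward and K downward distance slopes.
    """
    names = ["mu0"] + [f"mu_{k_ + 1}" for k_ in range(k)] + ["mu_S"]
    names += ["lam0"] + [f"lam_{k_ + 1}" for k_ in range(k)] + ["lam_S"]
    names += ["tau0"]
    names += [f"tau_up_{k_ + 1}" for k_ in range(k)]
    names += [f"tau_down_{k_ + 1}" for k_ in range(k)]
    names += ["tau_S"]
    return names


@dataclass
class StructuredParams:
    """Shared coefficients of the dimension-structured VARX(1).

    ``theta`` stacks the 4K+6 shared parameters in the order given by
    :func:`shared_param_names`; ``beta`` holds the free per-equation
    exogenous coefficients. ``vcov`` (when estimated) is the joint GLS
    covariance of ``theta``; ``sigma_hat`` the residual covariance.
    """

    k: int
    theta: np.ndarray
    beta: np.ndarray  # (N, M)
    se: np.ndarray | None = None
    beta_se: np.ndarray | None = None
    vcov: np.ndarray | None = None
    sigma_hat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.theta.shape != (4 * self.k + 6,):
            raise ConfigurationError(
                f"theta must have {4 * self.k + 6} entries for K={self.k}"
            )
        if self.beta.ndim != 2:
            raise ConfigurationError("beta must be an N x M matrix")
        if self.vcov is not None:
            v = np.asarray(self.vcov, dtype=float)
            if v.shape != (self.theta.size, self.theta.size):
                raise ConfigurationError("vcov must match the shared-parameter count")
            if not np.allclose(v, v.T, atol=1e-8):
                raise ConfigurationError("vcov must be symmetric")
            self.vcov = v

    # -- named accessors ----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return shared_param_names(self.k)

    def _idx(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, name: str) -> float:
        return float(self.theta[self._idx(name)])

    @property
    def mu0(self) -> float:
        return self["mu0"]

    @property
    def mu(self) -> np.ndarray:
        return self.theta[1 : 1 + self.k]

    @property
    def mu_S(self) -> float:
        return self["mu_S"]

    @property
    def lam0(self) -> float:
        return self["lam0"]

    @property
    def lam(self) -> np.ndarray:
        o = self.k + 3
        return self.theta[o : o + self.k]

    @property
    def lam_S(self) -> float:
        return self["lam_S"]

    @property
    def tau0(self) -> float:
        return self["tau0"]

    @property
    def tau_up(self) -> np.ndarray:
        o = 2 * self.k + 5
        return self.theta[o : o + self.k]

    @property
    def tau_down(self) -> np.ndarray:
        o = 3 * self.k + 5
        return self.theta[o : o + self.k]

    @property
    def tau_S(self) -> float:
        return self["tau_S"]

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "names": self.names,
            "theta": self.theta.tolist(),
            "beta": self.beta.tolist(),
            "se": None if self.se is None else np.asarray(self.se).tolist(),
            "beta_se": None
            if self.beta_se is None
            else np.asarray(self.beta_se).tolist(),
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
            "sigma_hat": None
            if self.sigma_hat is None
            else np.asarray(self.sigma_hat).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StructuredParams":
        d = json.loads(Path(path).read_text())
        arr = lambda x: None if x is None else np.asarray(x, dtype=float)
        return cls(
            k=d["k"],
            theta=np.asarray(d["theta"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            se=arr(d.get("se")),
            beta_se=arr(d.get("beta_se")),
            vcov=arr(d.get("vcov")),
            sigma_hat=arr(d.get("sigma_hat")),
        )


# ---------------------------------------------------------------------------
# VARCoefficients
# ---------------------------------------------------------------------------


@dataclass
class VARCoefficients:
    """Expanded first-order VARX matrices: intercept, transition, exog, noise."""

    alpha: np.ndarray  # (N,)
    gamma: np.ndarray  # (N, N)
    beta: np.ndarray  # (N, M)
    sigma: np.ndarray  # (N, N)
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.alpha.size
        if self.gamma.shape != (n, n) or self.sigma.shape != (n, n):
            raise ConfigurationError("gamma and sigma must be N x N")
        if self.beta.ndim != 2 or self.beta.shape[0] != n:
            raise ConfigurationError("beta must be N x M")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ConfigurationError("sigma must be symmetric")
        if self.names is None:
            self.names = [f"emotion_{i + 1}" for i in range(n)]

    @property
    def n_emotions(self) -> int:
        return self.alpha.size

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.gamma))))

    def stationary_mean(self, xbar: np.ndarray | None = None) -> np.ndarray:
        """Fixed point (I - Gamma)^-1 (alpha + B xbar) of the deterministic map."""
        n = self.n_emotions
        drive = self.alpha.copy()
        if xbar is not None and self.beta.shape[1]:
            drive = drive + self.beta @ np.asarray(xbar, dtype=float)
        if np.max(np.abs(np.linalg.eigvals(self.gamma))) >= 1.0:
            raise DomainError("stationary mean undefined: spectral radius >= 1")
        return np.linalg.solve(np.eye(n) - self.gamma, drive)


# ---------------------------------------------------------------------------
# IRFResult
# ---------------------------------------------------------------------------


@dataclass
class IRFResult:
    """Impulse-response path of one shocked source emotion.

    ``responses`` holds days 0..H-1 by emotion; day 0 is the shock
    vector itself (the contemporaneous effect, CE), and ``cirf`` sums
    days 1..29 when the horizon reaches that far.
    """

    source: int
    delta: float
    shock: np.ndarray  # (N,)
    responses: np.ndarray  # (H, N)

    def __post_init__(self) -> None:
        self.shock = np.asarray(self.shock, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2 or self.responses.shape[1] != self.shock.size:
            raise ConfigurationError("responses must be H x N matching the shock")
        if not np.allclose(self.responses[0], self.shock):
            raise ConfigurationError("day-0 responses must equal the shock vector")

    @property
    def horizon(self) -> int:
        return self.responses.shape[0]

    @property
    def ce(self) -> np.ndarray:
        return self.responses[0]

    @property
    def cirf(self) -> np.ndarray:
        from .dynamics import cumulative_irf  # local import avoids a cycle

        return cumulative_irf(self)


# ---------------------------------------------------------------------------
# Emotion dictionaries and labeled corpora
# ---------------------------------------------------------------------------


@dataclass
class EmotionDictionaries:
    """Per-emotion unigram and bigram term lists used for lexicon labeling."""

    unigrams: dict[str, set[str]]
    bigrams: dict[str, set[tuple[str, str]]]

    def __post_init__(self) -> None:
        if set(self.unigrams) != set(self.bigrams):
            raise ConfigurationError("unigram and bigram maps must share emotions")
        for emo in self.unigrams:
            self.unigrams[emo] = {u.casefold() for u in self.unigrams[emo]}
            bgs = set()
            for bg in self.bigrams[emo]:
                if len(bg) != 2 or not all(isinstance(w, str) and w for w in bg):
                    raise ConfigurationError("bigrams must be pairs of non-empty tokens")
                bgs.add((bg[0].casefold(), bg[1].casefold()))
            self.bigrams[emo] = bgs
            if any(not u for u in self.unigrams[emo]):
                raise ConfigurationError("unigrams must be non-empty strings")

    @property
    def emotions(self) -> list[str]:
        return sorted(self.unigrams)

    def all_tokens(self) -> set[str]:
        toks: set[str] = set()
        for emo in self.unigrams:
            toks |= self.unigrams[emo]
            for a, b in self.bigrams[emo]:
                toks |= {a, b}
        return toks

    def to_json(self, path: str | Path) -> None:
        payload = {
            emo: {
                "unigrams": sorted(self.unigrams[emo]),
                "bigrams": [list(bg) for bg in sorted(self.bigrams[emo])],
            }
            for emo in self.emotions
        }
        Path(path).write_text(json.dumps(payload, indent=1, ensure_ascii=False))

    @classmethod
    def from_json(cls, path: str | Path) -> "EmotionDictionaries":
        d = json.loads(Path(path).read_text())
        return cls(
            unigrams={e: set(v["unigrams"]) for e, v in d.items()},
            bigrams={e: {tuple(bg) for bg in v["bigrams"]} for e, v in d.items()},
        )


@dataclass
class CorpusRecord:
    date: pd.Timestamp
    tokens: list[str]
    true_labels: np.ndarray | None = None  # planted ground truth, if synthetic


@dataclass
class LabeledCorpus:
    """Dated, pre-lemmatized token lists with optional planted labels."""

    records: list[CorpusRecord]
    emotions: list[str]

    def __len__(self) -> int:
        return len(self.records)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                row = {
                    "date": rec.date.strftime("%Y-%m-%d"),
                    "tokens": rec.tokens,
                }
                if rec.true_labels is not None:
                    row["true_labels"] = [int(v) for v in rec.true_labels]
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")

    @classmethod
    def from_jsonl(
        cls, path: str | Path, emotions: Sequence[str]
    ) -> "LabeledCorpus":
        records = []
        with open(path) as fh:
            for line in fh:
                row = json.loads(line)
                labels = row.get("true_labels")
                records.append(
                    CorpusRecord(
                        date=pd.Timestamp(row["date"]),
                        tokens=list(row["tokens"]),
                        true_labels=None
                        if labels is None
                        else np.asarray(labels, dtype=int),
                    )
                )
        return cls(records=records, emotions=list(emotions))


def replace(obj, **changes):
    """dataclasses.replace that skips __post_init__ re-validation pitfalls."""
    return dataclasses.replace(obj, **changes)
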