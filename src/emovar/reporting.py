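"""End-to-end orchestration and report generation.

``run_pipeline`` strings the stages together — optional labeling and
aggregation, pre-estimation diagnostics, the structured FGLS fit,
duration analytics, the all-source shock study and the CE/CIRF distance
regressions — and writes a machine-readable ``results.json`` alongside
human-readable CSV tables and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dimensions import asymmetric_distances, center_scores
from .dynamics import distance_regression, duration_table, run_all_shocks
from .errors import ConfigurationError, DomainError
from .estimation import (
    adf_test,
    build_design,
    estimate_fgls,
    expand_coefficients,
    granger_tests,
    select_lag_order,
)
from .labeling import corpus_to_panel
from .synth import SimConfig, gen_dimension_scores, gen_structured_params, simulate_panel
from .types import DimensionScores, EmotionDictionaries, EmotionPanel, LabeledCorpus

log = logging.getLogger("emovar")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Inputs may come from files (``panel_path``/``dims_path`` or
    ``corpus_path``+``dicts_path``) or from the synthetic generator
    (``synthetic`` block). CLI flags override YAML values.
    """

    out_dir: str = "results"
    panel_path: str | None = None
    dims_path: str | None = None
    corpus_path: str | None = None
    dicts_path: str | None = None
    k: int = 3
    horizon: int = 30
    duration_p: float = 90.0
    delta_frac: float = 0.10
    delta_mode: str = "stationary-mean"
    seed: int = 0
    p_max: int = 4
    run_diagnostics: bool = True
    write_plots: bool = False
    synthetic: dict | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("K must be >= 1")
        if self.horizon < 2:
            raise ConfigurationError("horizon must be >= 2")
        if not 0 < self.duration_p < 100:
            raise ConfigurationError("duration P must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name: str):
    log.info("stage: %s", name)


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        _stage("synthesize")
        sim = SimConfig(seed=config.seed, **config.synthetic)
        dims = gen_dimension_scores(sim)
        truth, coeffs = gen_structured_params(dims, sim)
        panel = simulate_panel(coeffs, sim)
        return panel, dims
    if config.corpus_path and config.dicts_path:
        _stage("label+aggregate")
        dicts = EmotionDictionaries.from_json(config.dicts_path)
        corpus = LabeledCorpus.from_jsonl(config.corpus_path, dicts.emotions)
        panel = corpus_to_panel(corpus, dicts)
    elif config.panel_path:
        panel = EmotionPanel.from_csv(config.panel_path)
    else:
        raise ConfigurationError(
            "provide a panel CSV, a corpus+dictionaries, or a synthetic block"
        )
    if not config.dims_path:
        raise ConfigurationError("dimension scores CSV is required")
    dims = DimensionScores.from_csv(config.dims_path)
    return panel, dims


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, dims = _load_inputs(config)
    cdims = center_scores(dims) if not dims.centered else dims
    dist = asymmetric_distances(cdims)

    results: dict = {"n_emotions": panel.n_emotions, "n_days": panel.n_days}

    if config.run_diagnostics:
        _stage("diagnostics")
        xex = panel.exog.to_numpy() if panel.n_exog else None
        adf = {
            name: dict(
                zip(("statistic", "reject_unit_root"), adf_test(col, exog=xex))
            )
            for name, col in panel.freq.items()
        }
        p_star, crit_table = select_lag_order(panel, p_max=config.p_max)
        granger = granger_tests(panel)
        crit_table.to_csv(out / "lag_order_criteria.csv")
        granger.to_csv(out / "granger_pvalues.csv")
        results["diagnostics"] = {
            "adf": {k: {"statistic": v["statistic"], "reject": bool(v["reject_unit_root"])} for k, v in adf.items()},
            "selected_lag_order": p_star,
            "granger_rejections_5pct": int((granger.to_numpy() < 0.05).sum()),
        }

    _stage("fit")
    design = build_design(panel, cdims, dist)
    params = estimate_fgls(design)
    params.to_json(out / "params.json")
    results["shared_params"] = dict(zip(params.names, params.theta.tolist()))
    if params.se is not None:
        results["shared_se"] = dict(zip(params.names, params.se.tolist()))
    coeffs = expand_coefficients(params, cdims, dist)
    results["spectral_radius"] = coeffs.spectral_radius()

    _stage("durations")
    durations = duration_table(
        coeffs, params.lam0, params.lam, cdims, p=config.duration_p
    )
    durations.to_csv(out / "durations.csv")
    results["durations"] = durations["duration_days"].round(4).to_dict()

    _stage("shocks")
    xbar = (
        panel.exog.to_numpy(dtype=float).mean(axis=0) if panel.n_exog else None
    )
    study = run_all_shocks(
        coeffs,
        delta_frac=config.delta_frac,
        delta_mode=config.delta_mode,
        horizon=max(config.horizon, 30),
        xbar=xbar,
        sample_means=panel.freq.mean().to_numpy(),
    )
    study.ce.to_csv(out / "ce_matrix.csv")
    study.cirf.to_csv(out / "cirf_matrix.csv")

    _stage("distance regressions")
    ce_reg = distance_regression(study.ce, dist, cdims)
    cirf_reg = distance_regression(study.cirf, dist, cdims)
    ce_reg.to_csv(out / "ce_regression.csv")
    cirf_reg.to_csv(out / "cirf_regression.csv")
    results["ce_regression"] = ce_reg["coef"].to_dict()
    results["cirf_regression"] = cirf_reg["coef"].to_dict()

    if config.write_plots:
        for dim in cdims.dim_names:
            render_heatmap(
                study.cirf,
                cdims,
                dim,
                out / f"cirf_heatmap_{dim}.csv",
                out / f"cirf_heatmap_{dim}.png",
            )

    _stage("write results")
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=1, sort_keys=True))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results


def render_heatmap(
    matrix: pd.DataFrame,
    dims: DimensionScores,
    dimension: str,
    out_csv: str | Path,
    out_png: str | Path | None = None,
) -> pd.DataFrame:
    """Reorder a destination x source matrix by ascending dimension score.

    Rows and columns are permuted simultaneously; the permuted matrix is
    always written as CSV, and optionally rendered as a PNG heatmap.
    """
    if dimension not in dims.dim_names:
        raise DomainError(f"unknown dimension {dimension!r}")
    if list(matrix.index) != list(matrix.columns):
        raise DomainError("heatmap input must be square with matching labels")
    k = dims.dim_names.index(dimension)
    order = [dims.names[i] for i in np.argsort(dims.scores[:, k], kind="stable")]
    permuted = matrix.loc[order, order]
    permuted.to_csv(out_csv)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(permuted.to_numpy(), origin="lower", cmap="coolwarm")
        ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
        ax.set_yticks(range(len(order)), order, fontsize=6)
        ax.set_xlabel("source emotion")
        ax.set_ylabel("destination emotion")
        fig.colorbar(im, ax=ax, label="cumulative response")
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return permuted
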