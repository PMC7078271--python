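"""End-to-end orchestration: cohort → composite → association tables.

``run_pipeline`` executes the full analysis on either a participant CSV
(optionally with a trial-level ASRT CSV to score) or a synthetic cohort,
and writes paper-style outputs: one association table per predictor
(sleep disturbance on the pooled cohort; diary and GSQS on Study 2 via
robust regression), the composite summary, a sleeper-category descriptive
table, the extreme-group comparison, and a run manifest with seeds and
version for reproducibility. Outputs are written atomically: a stage
failure removes partial files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .asrt import DEFAULT_EPOCH_BLOCKS, PatternSequence, classify_triplets, compute_indices
from .cohort import CohortConfig, generate_cohort
from .composite import fit_composite
from .models import OUTCOMES, associate, compare_extreme_groups
from .questionnaires import extreme_groups, sleeper_category_table, validate_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_table", "score_asrt_csv"]

log = logging.getLogger("sleepcog")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``participants_csv`` (real data) or ``synthetic``
    (cohort generator config) must be provided.
    """

    out_dir: str | Path = "results"
    participants_csv: str | Path | None = None
    trials_csv: str | Path | None = None
    synthetic: CohortConfig | None = None
    predictors: tuple[str, ...] = ("sleep_disturbance", "diary", "gsqs")
    estimator_study2: str = "robust_lm"
    bootstrap_B: int = 1000
    seed: int = 0
    epoch_size_blocks: int = DEFAULT_EPOCH_BLOCKS
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.participants_csv is None) == (self.synthetic is None):
            raise ValueError(
                "provide exactly one of participants_csv or synthetic config"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if isinstance(syn, dict):
                for key in ("study_sizes", "covariate_betas"):
                    if key in syn and isinstance(syn[key], list):
                        syn[key] = tuple(syn[key])
                raw["synthetic"] = CohortConfig(**syn)
            else:
                raw["synthetic"] = CohortConfig()
        if "predictors" in raw and isinstance(raw["predictors"], list):
            raw["predictors"] = tuple(raw["predictors"])
        return cls(**raw)


def score_asrt_csv(
    trials: pd.DataFrame,
    pattern: PatternSequence,
    epoch_size_blocks: int = DEFAULT_EPOCH_BLOCKS,
) -> pd.DataFrame:
    """Score a trial-level CSV (one row per trial) into per-participant indices."""
    rows = []
    for pid, stream in trials.groupby("participant_id"):
        stream = stream.sort_values(["block", "trial"]).reset_index(drop=True)
        labels = classify_triplets(stream, pattern)
        idx = compute_indices(stream, labels, epoch_size_blocks=epoch_size_blocks)
        rows.append({"participant_id": pid, **idx.as_dict()})
    return pd.DataFrame(rows)


def render_table(results: pd.DataFrame) -> str:
    """Format an association table the way the result tables are printed.

    Columns β (3 decimals), 95% CI, df, p (2 decimals), BF01 (2 decimals).
    """
    if results.empty:
        raise ValueError("empty results table")
    lines = [f"{'Outcome':<28}{'β':>8}  {'95% CI':<16}{'df':>5}{'p':>7}{'BF01':>8}"]
    for _, row in results.iterrows():
        if not pd.notna(row["ci_low"]) or not pd.notna(row["ci_high"]):
            raise ValueError(f"missing CI for outcome {row['outcome']}")
        ci = f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
        lines.append(
            f"{row['outcome']:<28}{row['beta_std']:>8.3f}  {ci:<16}"
            f"{int(row['df']):>5}{row['p']:>7.2f}{row['bf01']:>8.2f}"
        )
    return "\n".join(lines)


def _plot_associations(data: pd.DataFrame, predictor: str, out_path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcomes = [o for o in OUTCOMES if o in data.columns]
    fig, axes = plt.subplots(3, 4, figsize=(16, 10))
    for ax, outcome in zip(axes.ravel(), outcomes):
        sub = data[[predictor, outcome]].dropna()
        ax.scatter(sub[predictor], sub[outcome], s=8, alpha=0.5)
        if len(sub) > 2:
            import numpy as np

            coef = np.polyfit(sub[predictor], sub[outcome], 1)
            xs = np.linspace(sub[predictor].min(), sub[predictor].max(), 10)
            ax.plot(xs, np.polyval(coef, xs), color="C1")
        ax.set_title(outcome, fontsize=9)
    fig.suptitle(f"Cognitive outcomes vs {predictor}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of result objects.

    Writes, under ``config.out_dir``: ``participants.csv`` (with the
    sleep-disturbance column added), ``composite.json``,
    ``sleeper_categories.csv``, ``associations_<predictor>.csv``,
    ``extreme_groups.csv`` and ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    tmp = Path(tempfile.mkdtemp(prefix="sleepcog_"))
    results: dict = {}
    try:
        stage = "load"
        try:
            if config.synthetic is not None:
                data, truth = generate_cohort(config.synthetic, seed=config.seed)
                truth.to_json(tmp / "truth.json")
            else:
                data = pd.read_csv(config.participants_csv)
                truth = None
            validate_table(data)
        except Exception as err:
            raise PipelineError(stage, err) from err

        if config.trials_csv is not None:
            stage = "asrt"
            try:
                trials = pd.read_csv(config.trials_csv)
                pattern_order = tuple(
                    int(x) for x in trials.attrs.get("pattern", (2, 1, 3, 4))
                )
                indices = score_asrt_csv(
                    trials,
                    PatternSequence(pattern_order),
                    epoch_size_blocks=config.epoch_size_blocks,
                )
                data = data.drop(
                    columns=[c for c in indices.columns if c != "participant_id"],
                    errors="ignore",
                ).merge(indices, on="participant_id", how="left")
            except Exception as err:
                raise PipelineError(stage, err) from err

        stage = "composite"
        try:
            comp_rows = data[["psqi", "ais"]].dropna()
            comp = fit_composite(
                comp_rows["psqi"].to_numpy(), comp_rows["ais"].to_numpy()
            )
            data.loc[comp_rows.index, "sleep_disturbance"] = comp.scores
            results["composite"] = comp
        except Exception as err:
            raise PipelineError(stage, err) from err

        stage = "questionnaires"
        try:
            cats = sleeper_category_table(data)
            good, poor = extreme_groups(data)
            results["sleeper_categories"] = cats
        except Exception as err:
            raise PipelineError(stage, err) from err

        stage = "associations"
        try:
            outcomes = [o for o in OUTCOMES if o in data.columns]
            tables: dict[str, pd.DataFrame] = {}
            for predictor in config.predictors:
                if predictor == "sleep_disturbance":
                    tables[predictor] = associate(
                        data,
                        predictor=predictor,
                        outcomes=outcomes,
                        estimator="lmm_ml",
                        B=config.bootstrap_B,
                        seed=config.seed,
                    )
                elif predictor in ("diary", "gsqs"):
                    study2 = data[data["study"] == 2]
                    if study2[predictor].dropna().empty:
                        log.warning("no %s data; skipping predictor", predictor)
                        continue
                    tables[predictor] = associate(
                        study2,
                        predictor=predictor,
                        outcomes=outcomes,
                        estimator=config.estimator_study2,
                        B=config.bootstrap_B,
                        seed=config.seed,
                    )
                else:
                    tables[predictor] = associate(
                        data,
                        predictor=predictor,
                        outcomes=outcomes,
                        estimator="lmm_ml",
                        B=config.bootstrap_B,
                        seed=config.seed,
                    )
            results["associations"] = tables
            results["extreme_groups"] = compare_extreme_groups(
                data, good, poor, outcomes=outcomes
            )
        except Exception as err:
            raise PipelineError(stage, err) from err

        stage = "write"
        try:
            data.to_csv(tmp / "participants.csv", index=False)
            comp_payload = {
                "eigenvalue_first": comp.eigenvalue_first,
                "variance_explained": comp.variance_explained,
                "loadings": comp.loadings.tolist(),
                "bartlett_chi2": comp.bartlett_chi2,
                "bartlett_df": comp.bartlett_df,
                "bartlett_p": comp.bartlett_p,
                "score_range": [float(comp.scores.min()), float(comp.scores.max())],
            }
            (tmp / "composite.json").write_text(json.dumps(comp_payload, indent=1))
            cats.to_csv(tmp / "sleeper_categories.csv", index=False)
            for predictor, table in tables.items():
                table.to_csv(tmp / f"associations_{predictor}.csv", index=False)
                (tmp / f"associations_{predictor}.txt").write_text(
                    render_table(table) + "\n"
                )
            results["extreme_groups"].to_csv(tmp / "extreme_groups.csv", index=False)
            if config.make_plots and "sleep_disturbance" in data.columns:
                _plot_associations(data, "sleep_disturbance", tmp / "associations.png")
            manifest = {
                "version": __version__,
                "seed": config.seed,
                "bootstrap_B": config.bootstrap_B,
                "predictors": list(tables),
                "n_participants": int(len(data)),
                "config_hash": hashlib.sha256(
                    json.dumps(
                        dataclasses.asdict(config), sort_keys=True, default=str
                    ).encode()
                ).hexdigest()[:16],
            }
            (tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))

            out_dir.mkdir(parents=True, exist_ok=True)
            for item in tmp.iterdir():
                shutil.copy2(item, out_dir / item.name)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, err) from err

        results["data"] = data
        results["truth"] = truth
        results["out_dir"] = out_dir
        return results
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
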