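"""End-to-end orchestration: simulate/ingest -> LPA -> covariates -> cognition -> RF.

Runs the enabled stages in dependency order, persists every intermediate
artifact under the output directory, and emits a consolidated report (JSON and
a human-readable text rendering).  Each stage draws its RNG seed
deterministically from the global seed and the stage name, so toggling one
stage never shifts another's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bifactor import factor_scores, fit_bifactor, fit_indices
from .cohort import (
    COGNITIVE_TESTS,
    GeneratorParams,
    apply_missingness,
    default_params,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from .concomitant import fit_conditional, odds_ratios, report_prevalence
from .distal import run_distal_suite
from .forest import RFConfig, rf_cross_validate
from .mixture import bic, enumerate_classes, fit_lpa, relative_entropy, standardize

log = logging.getLogger("cvprofiles")


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    cohort_csv: str | None = None      # if None, simulate
    n_subjects: int = 727
    seed: int = 1
    out_dir: str = "cvprofiles_out"
    run_enumeration: bool = False      # full BLRT enumeration (slow)
    K: int = 2
    K_max: int = 3
    n_starts: int = 50
    blrt_reps: int = 99
    run_conditional: bool = True
    run_cognition: bool = True
    run_rf: bool = True
    n_tree: int = 1000
    folds: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.K < 1 or self.K_max < 2:
            raise ValueError("invalid class counts")
        if self.folds < 2 or self.n_tree < 1:
            raise ValueError("invalid forest options")


@dataclass
class AnalysisReport:
    config: dict
    version: str
    seeds: dict
    sections: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "seeds": self.seeds,
                "sections": self.sections,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )

    def to_text(self) -> str:
        lines = [f"cvprofiles analysis report (v{self.version})", ""]
        for name, sec in sorted(self.sections.items()):
            lines.append(f"== {name} ==")
            lines.append(json.dumps(sec, indent=2, sort_keys=True,
                                    default=_jsonable))
            lines.append("")
        return "\n".join(lines)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(x)}")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig, params: GeneratorParams | None = None
) -> AnalysisReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: stage_seed(config.seed, s)
        for s in ("simulate", "missingness", "lpa", "blrt", "conditional",
                  "bifactor", "rf")
    }
    report = AnalysisReport(
        config=dataclasses.asdict(config), version=__version__, seeds=seeds
    )

    stage = "input"
    try:
        if config.cohort_csv is None:
            if params is None:
                params = default_params(n_subjects=config.n_subjects)
            cohort = simulate_cohort(params, seed=seeds["simulate"])
            cohort = apply_missingness(cohort, params, seed=seeds["missingness"])
            write_cohort(cohort, out / "cohort.csv", params,
                         seed=seeds["simulate"])
            report.sections["cohort"] = {
                "source": "simulated",
                "n": len(cohort),
                "incomplete_fraction": float(
                    cohort.isna().any(axis=1).mean()
                ),
            }
        else:
            cohort = read_cohort(config.cohort_csv)
            report.sections["cohort"] = {
                "source": str(config.cohort_csv),
                "n": len(cohort),
            }
        log.info("cohort ready: n=%d", len(cohort))

        stage = "lpa"
        X = standardize(cohort)
        if config.run_enumeration:
            enum = enumerate_classes(
                X, K_max=config.K_max, B=config.blrt_reps,
                seed=seeds["blrt"], n_starts=config.n_starts,
            )
            enum.table.to_csv(out / "enumeration.csv", index=False)
            model, post = enum.models[enum.selected_K], enum.posteriors[enum.selected_K]
            report.sections["enumeration"] = {
                "table": enum.table,
                "selected_K": enum.selected_K,
                "rationale": enum.rationale,
            }
        else:
            model, post = fit_lpa(
                X, config.K, n_starts=config.n_starts, seed=seeds["lpa"]
            )
        profile = {
            "K": model.K,
            "prevalence": model.pi,
            "entropy": relative_entropy(post) if model.K > 1 else None,
            "BIC": bic(model, X.n),
            "loglik": model.loglik,
            "q": model.q,
            "class_means_standardized": model.mu,
            "class_means_raw": X.back_transform(model.mu),
            "converged": model.converged,
        }
        report.sections["lpa"] = profile
        with open(out / "lpa_model.json", "w") as fh:
            json.dump(profile, fh, indent=2, sort_keys=True, default=_jsonable)
        labels = post.labels
        lab_df = pd.DataFrame(
            {"subject_id": cohort["subject_id"], "modal_class": labels}
        )
        for k in range(model.K):
            lab_df[f"posterior_{k}"] = post.probs[:, k]
        lab_df.to_csv(out / "posteriors.csv", index=False)

        if config.run_conditional:
            stage = "conditional"
            cmodel, cpost = fit_conditional(
                X, cohort, K=2, n_starts=config.n_starts,
                seed=seeds["conditional"],
            )
            ors = odds_ratios(cmodel)
            ors.to_csv(out / "odds_ratios.csv", index=False)
            report.sections["conditional"] = {
                "odds_ratios": ors,
                "prevalence": report_prevalence(cmodel, cpost, cohort),
                "entropy": relative_entropy(cpost),
                "loglik": cmodel.loglik,
                "converged": cmodel.converged,
            }

        if config.run_cognition:
            stage = "bifactor"
            cog = cohort[COGNITIVE_TESTS]
            bf = fit_bifactor(cog, seed=seeds["bifactor"])
            idx = fit_indices(bf)
            scores = factor_scores(bf, cog)
            scores_out = scores.copy()
            scores_out.insert(
                0, "subject_id", cohort.loc[scores.index, "subject_id"].to_numpy()
            )
            scores_out.to_csv(out / "factor_scores.csv", index=False)
            report.sections["bifactor"] = {
                "fit_indices": dataclasses.asdict(idx),
                "n_complete": bf.n,
                "converged": bf.converged,
                "meets_thresholds": bool(
                    idx.CFI > 0.95 and idx.TLI > 0.95 and idx.RMSEA < 0.05
                ),
            }

            stage = "distal"
            distal = run_distal_suite(
                scores, post, covariates=cohort[["age", "education"]]
            )
            distal.to_csv(out / "distal_results.csv", index=False)
            report.sections["distal"] = {"results": distal}

        if config.run_rf:
            stage = "rf"
            rf = rf_cross_validate(
                X, labels,
                RFConfig(n_tree=config.n_tree, folds=config.folds,
                         seed=seeds["rf"]),
            )
            report.sections["rf_validation"] = {
                "cv_accuracy": rf.cv_accuracy,
                "oob_error": rf.oob_error,
                "importance": rf.importance,
                "ranking": rf.ranking,
                "notes": rf.notes,
            }
            pd.DataFrame(
                {"indicator": list(rf.importance),
                 "mean_decrease_accuracy": list(rf.importance.values())}
            ).to_csv(out / "rf_importance.csv", index=False)
    except Exception as e:  # noqa: BLE001 - annotate failing stage
        partial = out / "report_partial.json"
        partial.write_text(report.to_json())
        raise StageFailure(stage, e) from e

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    return report
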