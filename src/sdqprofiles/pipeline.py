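"""End-to-end analysis pipeline: fit, select, profile, three-step, report.

Every stage writes plain CSV/JSON into the run directory so a run is
fully inspectable; numeric outputs are deterministic given the seed.
Stage timings and messages go to a separate ``run.log`` (excluded from
any byte-level reproducibility comparison, since timings vary).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import profiling, three_step
from .io import DiagnosisGrouping, RunConfig, example_cutoff_config
from .mixture import FitResult, MixtureParams, entropy_r2, posterior, select_model
from .profiling import CutoffConfig
from .records import ModelSpec, SubjectRecord, to_score_array

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NUMERICAL = 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage
        self.cause = exc


def _write_posteriors(fit: FitResult, subjects: list[SubjectRecord], path) -> None:
    P = fit.posterior_matrix
    frame = pd.DataFrame(P, columns=[f"class_{c}" for c in range(P.shape[1])])
    frame.insert(0, "id", [s.id for s in subjects])
    frame["modal_class"] = P.argmax(axis=1)
    frame.to_csv(path, index=False)


def run_pipeline(
    config: RunConfig,
    subjects: list[SubjectRecord],
    out_dir,
    cutoffs: CutoffConfig | None = None,
) -> Path:
    """Run selection, profiling, and the three-step analyses; returns the
    run directory.  On stage failure, earlier outputs are preserved and a
    manifest records which stages completed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.spec
    manifest: dict = {"seed": config.seed, "stages": {}, "files": []}
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("sdqprofiles")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def record(stage: str, files: list[str]) -> None:
        manifest["stages"][stage] = "ok"
        manifest["files"].extend(files)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    def run_stage(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][stage] = f"failed: {exc}"
            with open(out / "manifest.json", "w", encoding="utf-8") as fh:
                json.dump(manifest, fh, indent=1)
            root.removeHandler(handler)
            raise PipelineError(stage, exc) from exc
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
        return result

    try:
        # -- selection -----------------------------------------------------
        def stage_select():
            fit, table = select_model(
                subjects, config.K_range, spec, config.fit_config()
            )
            table.to_csv(out / "selection.csv", index=False)
            fit.params.to_json(out / "model.json")
            _write_posteriors(fit, subjects, out / "posteriors.csv")
            record("select", ["selection.csv", "model.json", "posteriors.csv"])
            return fit

        fit = run_stage("select", stage_select)

        # -- profiling -----------------------------------------------------
        def stage_profile():
            nonlocal cutoffs
            if cutoffs is None:
                if config.cutoff_file is None:
                    raise profiling.ConfigurationError(
                        "no cutoff configuration supplied"
                    )
                cutoffs = CutoffConfig.from_yaml(config.cutoff_file)
            summary = profiling.profile_summary(fit.params, cutoffs)
            summary.to_csv(out / "profile_summary.csv", index=False)
            labels = profiling.label_profiles(
                profiling.band_table(fit.params, cutoffs), spec
            )
            with open(out / "profile_labels.json", "w", encoding="utf-8") as fh:
                json.dump({str(k): v for k, v in labels.items()}, fh, indent=1)
            assignments = three_step.modal_assign(fit)
            tests = profiling.informant_tests(subjects, assignments, spec)
            tests.to_csv(out / "informant_tests.csv", index=False)
            record("profile", ["profile_summary.csv", "profile_labels.json",
                               "informant_tests.csv"])
            return labels

        labels = run_stage("profile", stage_profile)

        # -- three-step ----------------------------------------------------
        def stage_threestep():
            assignments = three_step.modal_assign(fit)
            if fit.params.K < 2:
                pd.DataFrame({"note": ["single-class solution: all prevalences 1"]}
                             ).to_csv(out / "threestep_setting.csv", index=False)
                record("threestep", ["threestep_setting.csv"])
                return
            D = three_step.error_matrix(fit, assignments)
            pd.DataFrame(D.D).to_csv(out / "error_matrix.csv", index=False)

            settings = [s.setting for s in subjects]
            genders = [s.gender for s in subjects]
            dist = three_step.gender_interaction(
                assignments, D, settings, genders,
                min_cell_size=config.min_cell_size,
            )
            dist.theta.to_csv(out / "threestep_setting.csv")
            if dist.gender_theta is not None:
                dist.gender_theta.to_csv(out / "threestep_setting_gender.csv")
            report = three_step.report_prevalence(
                dist, threshold_pct=config.gender_threshold_pct
            )
            report.to_csv(out / "threestep_setting_report.csv")

            grouping = (DiagnosisGrouping.from_yaml(config.grouping_file)
                        if config.grouping_file else DiagnosisGrouping())
            dx_groups = [
                grouping.group(s.diagnoses) if s.setting == "CAMH" else None
                for s in subjects
            ]
            dist_dx = three_step.gender_interaction(
                assignments, D, dx_groups, genders,
                min_cell_size=config.min_cell_size,
            )
            dist_dx.theta.to_csv(out / "threestep_diagnosis.csv")
            report_dx = three_step.report_prevalence(
                dist_dx, threshold_pct=config.gender_threshold_pct,
                min_group_n=config.min_group_n,
            )
            report_dx.to_csv(out / "threestep_diagnosis_report.csv")
            record("threestep", [
                "error_matrix.csv", "threestep_setting.csv",
                "threestep_setting_report.csv", "threestep_diagnosis.csv",
                "threestep_diagnosis_report.csv",
            ])

        run_stage("threestep", stage_threestep)

        # -- comparisons ---------------------------------------------------
        def stage_compare():
            assignments = three_step.modal_assign(fit)
            if fit.params.K < 2:
                record("compare", [])
                return
            D = three_step.error_matrix(fit, assignments)
            for informant in spec.informants:
                ct = profiling.crosstab_total_band(
                    subjects, assignments, D, cutoffs, informant, spec
                )
                ct.to_csv(out / f"crosstab_total_{informant}.csv", index=False)
            record("compare", [f"crosstab_total_{i}.csv" for i in spec.informants])

        run_stage("compare", stage_compare)

        manifest["entropy_r2"] = (
            entropy_r2(fit) if fit.params.K >= 2 else None
        )
        manifest["selected_K"] = fit.params.K
        manifest["labels"] = {str(k): v for k, v in labels.items()}
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def score_cases(
    model_path, subjects: list[SubjectRecord], out_path,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Score new cases with a shipped fitted model.

    Accepts any subset of observed informants/scales per subject; a
    subject with no observed scores receives the model's mixing
    proportions (the prior).
    """
    params = MixtureParams.from_json(model_path)
    rows = []
    for subj in subjects:
        post = posterior(subj, params)
        row = {"id": subj.id}
        for c in range(params.K):
            row[f"class_{c}"] = post.probabilities[c]
        row["modal_class"] = post.modal_class
        if labels:
            row["modal_label"] = labels.get(post.modal_class, "")
        rows.append(row)
    frame = pd.DataFrame(rows)
    if out_path is not None:
        frame.to_csv(out_path, index=False)
    return frame
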