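"""CSV dataset interchange, run configuration and diagnosis grouping.

A dataset is two UTF-8 comma-separated files with header rows:

``subjects.csv``
    columns: id, gender, setting, diagnoses (semicolon-joined labels;
    empty = no recorded diagnoses, the literal ``NA`` = unknown).

``records.csv``
    columns: id, informant, then one column per subscale.  Empty score
    cells mean the score is absent.  At most one row per (id, informant).

Both files carry an optional ``schema_version`` column (constant 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import DataError, InformantRecord, ModelSpec, SubjectRecord

SCHEMA_VERSION = 1

DIAGNOSIS_CANONICAL_ORDER = ("Anxiety/Mood", "CD/ODD", "ADHD", "ASD")


class ValidationError(DataError):
    """Malformed input rows; the message names the offending row."""


def _parse_diagnoses(cell) -> frozenset[str] | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "NA":
        return None
    if text == "":
        return frozenset()
    return frozenset(part.strip() for part in text.split(";") if part.strip())


def read_dataset(
    subjects_path, records_path, spec: ModelSpec | None = None
) -> list[SubjectRecord]:
    """Read and validate a dataset; raises ValidationError with the first
    offending row number on schema violations."""
    spec = spec or ModelSpec()
    subjects_df = pd.read_csv(subjects_path, dtype=str, keep_default_na=False)
    records_df = pd.read_csv(records_path, dtype=str, keep_default_na=False)

    for col in ("id",):
        if col not in subjects_df.columns:
            raise ValidationError(f"subjects file lacks required column {col!r}")
    needed = ["id", "informant", *spec.scales]
    for col in needed:
        if col not in records_df.columns:
            raise ValidationError(f"records file lacks required column {col!r}")

    subjects: dict[str, SubjectRecord] = {}
    for rownum, row in enumerate(subjects_df.itertuples(index=False), start=2):
        sid = str(row.id)
        if sid in subjects:
            raise ValidationError(f"subjects row {rownum}: duplicate subject id {sid!r}")
        gender = getattr(row, "gender", "") or None
        setting = getattr(row, "setting", "") or None
        diagnoses = _parse_diagnoses(getattr(row, "diagnoses", "NA"))
        subjects[sid] = SubjectRecord(
            id=sid, gender=gender, setting=setting, diagnoses=diagnoses
        )

    seen: set[tuple[str, str]] = set()
    for rownum, row in enumerate(records_df.itertuples(index=False), start=2):
        sid = str(row.id)
        if sid not in subjects:
            raise ValidationError(
                f"records row {rownum}: id {sid!r} has no subjects row"
            )
        informant = str(row.informant)
        if informant not in spec.informants:
            raise ValidationError(
                f"records row {rownum}: unknown informant {informant!r}"
            )
        if (sid, informant) in seen:
            raise ValidationError(
                f"records row {rownum}: duplicate (id, informant) ({sid}, {informant})"
            )
        seen.add((sid, informant))
        scores: dict[str, int | None] = {}
        for scale in spec.scales:
            cell = str(getattr(row, scale)).strip()
            if cell == "":
                scores[scale] = None
                continue
            try:
                value = int(cell)
            except ValueError:
                raise ValidationError(
                    f"records row {rownum}: non-integer score {cell!r} for {scale}"
                ) from None
            if not 0 <= value < spec.n_categories:
                raise ValidationError(
                    f"records row {rownum}: score {value} for {scale} outside "
                    f"[0, {spec.n_categories - 1}]"
                )
            scores[scale] = value
        subjects[sid].records.append(InformantRecord(informant=informant, scores=scores))

    return list(subjects.values())


def write_dataset(
    subjects: list[SubjectRecord],
    subjects_path,
    records_path,
    spec: ModelSpec | None = None,
) -> None:
    spec = spec or ModelSpec()
    subject_rows = []
    record_rows = []
    for subj in subjects:
        if subj.diagnoses is None:
            dx = "NA"
        else:
            dx = ";".join(sorted(subj.diagnoses))
        subject_rows.append({
            "id": subj.id,
            "gender": subj.gender or "",
            "setting": subj.setting or "",
            "diagnoses": dx,
            "schema_version": SCHEMA_VERSION,
        })
        for rec in subj.records:
            row = {"id": subj.id, "informant": rec.informant}
            for scale in spec.scales:
                value = rec.scores.get(scale)
                row[scale] = "" if value is None else int(value)
            record_rows.append(row)
    pd.DataFrame(subject_rows).to_csv(subjects_path, index=False)
    pd.DataFrame(
        record_rows, columns=["id", "informant", *spec.scales]
    ).to_csv(records_path, index=False)


def write_truth(truth: np.ndarray, subjects: list[SubjectRecord], path) -> None:
    pd.DataFrame({
        "id": [s.id for s in subjects],
        "true_class": np.asarray(truth, dtype=int),
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diagnosis grouping
# ---------------------------------------------------------------------------


@dataclass
class DiagnosisGrouping:
    """Map a subject's diagnosis label set to one nominal group.

    Default scheme: a single recognized label is its own group; exactly
    two recognized labels form a pairwise group named in canonical order
    ("Anxiety/Mood and ADHD"); three or more recognized labels become
    ``multi_label``; any unrecognized label (alone or mixed) falls into
    ``other_label``; an empty set maps to ``none_label``; an unknown set
    (None) yields no group.
    """

    canonical: tuple[str, ...] = DIAGNOSIS_CANONICAL_ORDER
    multi_label: str = "Multi-problem"
    other_label: str = "Other"
    none_label: str = "None"

    def group(self, diagnoses: frozenset[str] | None) -> str | None:
        if diagnoses is None:
            return None
        if not diagnoses:
            return self.none_label
        recognized = [d for d in self.canonical if d in diagnoses]
        if len(recognized) != len(diagnoses):
            return self.other_label
        if len(recognized) == 1:
            return recognized[0]
        if len(recognized) == 2:
            return f"{recognized[0]} and {recognized[1]}"
        return self.multi_label

    @classmethod
    def from_yaml(cls, path) -> "DiagnosisGrouping":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            canonical=tuple(raw.get("canonical", DIAGNOSIS_CANONICAL_ORDER)),
            multi_label=raw.get("multi_label", "Multi-problem"),
            other_label=raw.get("other_label", "Other"),
            none_label=raw.get("none_label", "None"),
        )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline settings (YAML-serializable)."""

    scales: tuple[str, ...] = ("emotional", "conduct", "hyperactivity",
                               "social", "prosocial")
    informants: tuple[str, ...] = ("self", "parent")
    n_categories: int = 11
    K_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    n_starts: int = 20
    start_iters: int | None = 30
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    parameterization: str = "adjacent"
    cutoff_file: str | None = None
    grouping_file: str | None = None
    gender_threshold_pct: float = 20.0
    min_group_n: int = 100
    min_cell_size: int = 30

    def __post_init__(self):
        if not self.K_range:
            raise ValueError("K_range must be non-empty")
        if self.gender_threshold_pct < 0 or self.min_group_n < 0:
            raise ValueError("thresholds must be >= 0")

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            scales=tuple(self.scales),
            informants=tuple(self.informants),
            n_categories=self.n_categories,
        )

    def fit_config(self, seed: int | None = None):
        from .mixture import FitConfig

        return FitConfig(
            n_starts=self.n_starts,
            start_iters=self.start_iters,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.seed if seed is None else seed,
            parameterization=self.parameterization,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scales", "informants", "K_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        for key in ("scales", "informants", "K_range"):
            raw[key] = list(raw[key])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def example_cutoff_config(spec: ModelSpec | None = None):
    """An illustrative cutoff configuration (NOT authoritative norms).

    Boundaries are placed at plausible positions on the 0-10 subscale
    (0-40 total) range purely so the banding and labelling machinery can
    run end to end; real analyses must supply published cutoff values.
    """
    from .profiling import TOTAL_SCALE, CutoffBands, CutoffConfig

    spec = spec or ModelSpec()
    bands = {}
    for informant in spec.informants:
        for scale in spec.scales:
            if scale in spec.difficulty_scales:
                bands[(informant, scale)] = CutoffBands(3.0, 5.0, high_is_worse=True)
            else:
                bands[(informant, scale)] = CutoffBands(6.0, 5.0, high_is_worse=False)
        bands[(informant, TOTAL_SCALE)] = CutoffBands(15.0, 19.0, high_is_worse=True)
    return CutoffConfig(bands=bands)
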