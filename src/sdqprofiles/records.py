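"""Subject- and informant-level data containers.

The analysis operates on a two-level design: informant reports (the
adolescent's self-report and a parent report) are nested within subjects.
Each report carries ordinal subscale totals -- by default the five SDQ
subscales, each an integer 0-10.  Any report, and any single subscale score
within a report, may be absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_SCALES = ("emotional", "conduct", "hyperactivity", "social", "prosocial")
DEFAULT_INFORMANTS = ("self", "parent")
DEFAULT_N_CATEGORIES = 11

SETTINGS = ("community", "CASC", "CAMH")

MISSING = -1  # sentinel in dense integer score arrays


class DataError(ValueError):
    """Raised when records violate the declared score schema."""


@dataclass(frozen=True)
class ModelSpec:
    """Shape of the measurement design: which scales, informants, categories.

    ``difficulty_scales`` identifies the subscales that measure problems
    (summed into the total-difficulties score); any scale not listed --
    prosocial behaviour by default -- is a strengths scale with reversed
    severity direction.
    """

    scales: tuple[str, ...] = DEFAULT_SCALES
    informants: tuple[str, ...] = DEFAULT_INFORMANTS
    n_categories: int = DEFAULT_N_CATEGORIES

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if len(set(self.scales)) != len(self.scales):
            raise ValueError("duplicate scale names")
        if len(set(self.informants)) != len(self.informants):
            raise ValueError("duplicate informant names")

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def n_informants(self) -> int:
        return len(self.informants)

    @property
    def difficulty_scales(self) -> tuple[str, ...]:
        return tuple(s for s in self.scales if s != "prosocial")

    def scale_index(self, scale: str) -> int:
        try:
            return self.scales.index(scale)
        except ValueError:
            raise KeyError(f"unknown scale {scale!r}") from None

    def informant_index(self, informant: str) -> int:
        try:
            return self.informants.index(informant)
        except ValueError:
            raise KeyError(f"unknown informant {informant!r}") from None

    def restrict_informants(self, informants: tuple[str, ...]) -> "ModelSpec":
        for inf in informants:
            self.informant_index(inf)
        return replace(self, informants=tuple(informants))


@dataclass
class InformantRecord:
    """One informant's subscale scores; individual scores may be None."""

    informant: str
    scores: dict[str, int | None]

    def validate(self, spec: ModelSpec) -> None:
        spec.informant_index(self.informant)
        for scale, value in self.scores.items():
            spec.scale_index(scale)
            if value is None:
                continue
            if not (0 <= int(value) < spec.n_categories):
                raise DataError(
                    f"score {value} for {self.informant}/{scale} outside "
                    f"[0, {spec.n_categories - 1}]"
                )


@dataclass
class SubjectRecord:
    """A subject with up to one record per informant and group covariates."""

    id: str
    records: list[InformantRecord] = field(default_factory=list)
    gender: str | None = None
    setting: str | None = None
    diagnoses: frozenset[str] | None = None

    def validate(self, spec: ModelSpec) -> None:
        seen = set()
        for rec in self.records:
            rec.validate(spec)
            if rec.informant in seen:
                raise DataError(f"subject {self.id}: duplicate informant {rec.informant}")
            seen.add(rec.informant)

    def record_for(self, informant: str) -> InformantRecord | None:
        for rec in self.records:
            if rec.informant == informant:
                return rec
        return None


def to_score_array(subjects: list[SubjectRecord], spec: ModelSpec) -> np.ndarray:
    """Dense integer array (n_subjects, n_informants, n_scales); -1 = missing."""
    X = np.full((len(subjects), spec.n_informants, spec.n_scales), MISSING, dtype=np.int64)
    for n, subj in enumerate(subjects):
        subj.validate(spec)
        for rec in subj.records:
            i = spec.informant_index(rec.informant)
            for scale, value in rec.scores.items():
                if value is not None:
                    X[n, i, spec.scale_index(scale)] = int(value)
    return X


def from_score_array(
    X: np.ndarray,
    spec: ModelSpec,
    ids: list[str] | None = None,
) -> list[SubjectRecord]:
    """Inverse of :func:`to_score_array`; informants with all scores missing
    produce no record."""
    n = X.shape[0]
    if ids is None:
        ids = [f"S{k:06d}" for k in range(n)]
    subjects = []
    for k in range(n):
        records = []
        for i, inf in enumerate(spec.informants):
            row = X[k, i]
            if (row == MISSING).all():
                continue
            scores = {
                scale: (int(row[s]) if row[s] != MISSING else None)
                for s, scale in enumerate(spec.scales)
            }
            records.append(InformantRecord(informant=inf, scores=scores))
        subjects.append(SubjectRecord(id=ids[k], records=records))
    return subjects
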