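"""Interpretation of fitted profiles.

A fitted profile is summarized by its expected mean score per informant
and subscale.  Those means are placed into severity bands (normal /
borderline / abnormal) using external cutoff values -- cutoffs are
supplied by configuration, not shipped as authoritative norms -- and the
band pattern determines an automatic profile label such as
"borderline hyperactivity difficulties".  The module also provides the
paired informant-difference tests per profile, the cross-tabulation of
profiles against total-difficulties banding, and the single-informant
refit comparison.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import three_step
from .mixture import FitConfig, MixtureParams, em_fit, select_model
from .records import MISSING, ModelSpec, SubjectRecord, to_score_array

logger = logging.getLogger(__name__)

TOTAL_SCALE = "total"  # pseudo-scale key for total-difficulties cutoffs


class ConfigurationError(ValueError):
    pass


class Band(enum.IntEnum):
    NORMAL = 0
    BORDERLINE = 1
    ABNORMAL = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass
class CutoffBands:
    """Two ordered boundaries on the severity axis of one scale.

    For a difficulties scale (high = worse) a score <= normal_max is
    normal, <= borderline_max borderline, else abnormal.  For a reversed
    scale (prosocial: low = worse) the boundaries are read from the top:
    score >= normal_min is normal, >= borderline_min borderline, else
    abnormal.  Boundaries are inclusive toward the less severe band.
    """

    normal_bound: float
    borderline_bound: float
    high_is_worse: bool = True

    def classify(self, score: float) -> Band:
        if self.high_is_worse:
            if score <= self.normal_bound:
                return Band.NORMAL
            if score <= self.borderline_bound:
                return Band.BORDERLINE
            return Band.ABNORMAL
        if score >= self.normal_bound:
            return Band.NORMAL
        if score >= self.borderline_bound:
            return Band.BORDERLINE
        return Band.ABNORMAL

    def validate(self) -> None:
        if self.high_is_worse and self.normal_bound > self.borderline_bound:
            raise ConfigurationError("boundaries must satisfy normal <= borderline")
        if not self.high_is_worse and self.normal_bound < self.borderline_bound:
            raise ConfigurationError(
                "reversed scale boundaries must satisfy normal >= borderline"
            )


@dataclass
class CutoffConfig:
    """Per (informant, scale) severity bands, plus total-difficulties bands."""

    bands: dict[tuple[str, str], CutoffBands] = field(default_factory=dict)

    def lookup(self, informant: str, scale: str) -> CutoffBands:
        try:
            return self.bands[(informant, scale)]
        except KeyError:
            raise ConfigurationError(
                f"no cutoff configured for informant={informant!r}, scale={scale!r}"
            ) from None

    def validate(self) -> None:
        for b in self.bands.values():
            b.validate()

    # YAML layout: {informant: {scale: {normal: x, borderline: y,
    #                                   direction: high_worse|low_worse}}}
    @classmethod
    def from_yaml(cls, path) -> "CutoffConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        bands = {}
        for informant, scales in raw.items():
            for scale, entry in scales.items():
                direction = entry.get("direction", "high_worse")
                if direction not in ("high_worse", "low_worse"):
                    raise ConfigurationError(f"bad direction {direction!r}")
                bands[(informant, scale)] = CutoffBands(
                    normal_bound=float(entry["normal"]),
                    borderline_bound=float(entry["borderline"]),
                    high_is_worse=direction == "high_worse",
                )
        config = cls(bands=bands)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        raw: dict = {}
        for (informant, scale), b in self.bands.items():
            raw.setdefault(informant, {})[scale] = {
                "normal": b.normal_bound,
                "borderline": b.borderline_bound,
                "direction": "high_worse" if b.high_is_worse else "low_worse",
            }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def classify_band(score: float, informant: str, scale: str,
                  cutoffs: CutoffConfig) -> Band:
    """Band of a single (mean) score under the configured boundaries."""
    return cutoffs.lookup(informant, scale).classify(score)


def class_means(params: MixtureParams) -> pd.DataFrame:
    """Expected score per (class, informant, scale), plus the expected
    total-difficulties score (sum over the difficulty scales)."""
    means = params.expected_scores()            # (K, I, S)
    spec = params.spec
    rows = []
    for c in range(params.K):
        for i, informant in enumerate(spec.informants):
            row = {"class": c, "informant": informant}
            for s, scale in enumerate(spec.scales):
                row[scale] = means[c, i, s]
            row[TOTAL_SCALE] = sum(
                means[c, i, spec.scale_index(s)] for s in spec.difficulty_scales
            )
            rows.append(row)
    return pd.DataFrame(rows)


def band_table(params: MixtureParams, cutoffs: CutoffConfig) -> pd.DataFrame:
    """class_means() augmented with the band of every mean score."""
    means = class_means(params)
    spec = params.spec
    out = means.copy()
    for scale in list(spec.scales) + [TOTAL_SCALE]:
        out[f"{scale}_band"] = [
            classify_band(row[scale], row["informant"], scale, cutoffs).name.lower()
            for _, row in means.iterrows()
        ]
    return out


def _join_domains(domains: list[str]) -> str:
    if len(domains) == 1:
        return domains[0]
    return ", ".join(domains[:-1]) + " and " + domains[-1]


def label_profiles(bands: pd.DataFrame, spec: ModelSpec,
                   overall_min_domains: int = 4) -> dict[int, str]:
    """Deterministic profile labels from the band pattern.

    A domain counts as affected when either informant's class mean falls
    in the borderline or abnormal band.  All-normal classes are labelled
    "no difficulties"; classes whose worst band is borderline get
    "borderline <domains> difficulties"; classes with any abnormal mean
    get "<domains> difficulties", where the listed domains are those with
    an abnormal band, collapsing to "overall" when at least
    ``overall_min_domains`` domains are affected.  Domains are listed in
    canonical scale order.
    """
    labels = {}
    for c in sorted(bands["class"].unique()):
        sub = bands[bands["class"] == c]
        worst: dict[str, Band] = {}
        for scale in spec.scales:
            col = f"{scale}_band"
            if col in sub:
                worst[scale] = Band(max(Band[v.upper()] for v in sub[col]))
            else:
                worst[scale] = Band.NORMAL
        if all(b == Band.NORMAL for b in worst.values()):
            labels[int(c)] = "no difficulties"
            continue
        abnormal = [s for s in spec.scales if worst[s] == Band.ABNORMAL]
        if not abnormal:
            affected = [s for s in spec.scales if worst[s] == Band.BORDERLINE]
            labels[int(c)] = f"borderline {_join_domains(affected)} difficulties"
            continue
        if len(abnormal) >= overall_min_domains:
            labels[int(c)] = "overall difficulties"
        else:
            labels[int(c)] = f"{_join_domains(abnormal)} difficulties"
    return labels


def profile_summary(params: MixtureParams, cutoffs: CutoffConfig) -> pd.DataFrame:
    """Bands, labels and prevalence per class in one tidy table."""
    bands = band_table(params, cutoffs)
    labels = label_profiles(bands, params.spec)
    bands = bands.copy()
    bands["label"] = bands["class"].map(labels)
    bands["prevalence"] = bands["class"].map(
        {c: params.pi[c] for c in range(params.K)}
    )
    return bands


def informant_tests(
    data: list[SubjectRecord],
    assignments: np.ndarray,
    spec: ModelSpec | None = None,
    informant_pair: tuple[str, str] = ("self", "parent"),
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Paired t tests of informant differences per (cluster, scale).

    Only subjects with both informants' scores observed on a scale enter
    that scale's test.  p values are Bonferroni-corrected by the number of
    scales actually tested within the cluster; significance is flagged at
    the corrected ``alpha``.  Cells with fewer than two complete pairs are
    flagged as skipped.
    """
    spec = spec or ModelSpec()
    X = to_score_array(data, spec)
    a_idx = spec.informant_index(informant_pair[0])
    b_idx = spec.informant_index(informant_pair[1])
    assignments = np.asarray(assignments)

    rows = []
    for c in sorted(set(assignments.tolist())):
        members = np.flatnonzero(assignments == c)
        cluster_rows = []
        for s, scale in enumerate(spec.scales):
            xa = X[members, a_idx, s]
            xb = X[members, b_idx, s]
            ok = (xa != MISSING) & (xb != MISSING)
            n_pairs = int(ok.sum())
            row = {"class": int(c), "scale": scale, "n_pairs": n_pairs}
            if n_pairs < 2:
                row.update(t=np.nan, p=np.nan, p_adjusted=np.nan,
                           significant=False, skipped=True)
            else:
                diffs = xa[ok] - xb[ok]
                if np.all(diffs == diffs[0]) and diffs[0] == 0:
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_rel(xa[ok], xb[ok])
                row.update(t=float(t), p=float(p), skipped=False)
            cluster_rows.append(row)
        n_tested = sum(1 for r in cluster_rows if not r["skipped"])
        for r in cluster_rows:
            if not r["skipped"]:
                r["p_adjusted"] = min(1.0, r["p"] * n_tested)
                r["significant"] = bool(r["p_adjusted"] < alpha)
        rows.extend(cluster_rows)
    return pd.DataFrame(rows)


def total_difficulties_scores(
    data: list[SubjectRecord], spec: ModelSpec, informant: str
) -> np.ndarray:
    """Per subject, the chosen informant's summed difficulty-scale score;
    NaN when any difficulty score (or the record) is missing."""
    X = to_score_array(data, spec)
    i = spec.informant_index(informant)
    idx = [spec.scale_index(s) for s in spec.difficulty_scales]
    sub = X[:, i, idx]
    complete = (sub != MISSING).all(axis=1)
    totals = np.where(complete, sub.sum(axis=1), np.nan)
    return totals.astype(float)


def crosstab_total_band(
    data: list[SubjectRecord],
    assignments: np.ndarray,
    D,
    cutoffs: CutoffConfig,
    informant: str,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Profile prevalence within total-difficulties bands, per setting.

    Subjects missing the chosen informant's difficulty scores are
    excluded (logged).  The borderline and abnormal total bands are
    merged, matching how screening results are conventionally reported.
    Profile prevalences within each (setting, band) cell come from the
    classification-error-corrected estimator.
    """
    spec = spec or ModelSpec()
    totals = total_difficulties_scores(data, spec, informant)
    assignments = np.asarray(assignments)
    keep = ~np.isnan(totals)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("crosstab_total_band: excluded %d subjects lacking %s totals",
                    dropped, informant)

    bands = np.array([
        "normal" if keep[i] and classify_band(
            totals[i], informant, TOTAL_SCALE, cutoffs) == Band.NORMAL
        else "borderline/abnormal"
        for i in range(len(totals))
    ], dtype=object)
    settings = np.array([s.setting for s in data], dtype=object)

    rows = []
    for setting in sorted({s for s in settings[keep] if s is not None}):
        in_setting = keep & (settings == setting)
        n_setting = int(in_setting.sum())
        for band in ("normal", "borderline/abnormal"):
            cell = in_setting & (bands == band)
            n_cell = int(cell.sum())
            if n_cell == 0:
                continue
            groups = np.where(cell, "cell", None)
            dist = three_step.adjusted_distribution(assignments, D, groups)
            row = {
                "setting": setting,
                "band": band,
                "n": n_cell,
                "pct_within_setting": 100.0 * n_cell / n_setting,
            }
            for col in dist.theta.columns:
                row[col] = 100.0 * dist.theta.loc["cell", col]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SingleInformantComparison:
    """Outcome of refitting the model on a single informant's records."""

    informant: str
    selection_table: pd.DataFrame
    crosstab: pd.DataFrame          # rows: full-solution class, cols: single
    merges: list[tuple[tuple[int, ...], int]]
    prevalence_full: np.ndarray
    prevalence_single: np.ndarray


def restrict_to_informant(data: list[SubjectRecord],
                          informant: str) -> list[SubjectRecord]:
    out = []
    for subj in data:
        rec = subj.record_for(informant)
        out.append(SubjectRecord(
            id=subj.id,
            records=[rec] if rec is not None else [],
            gender=subj.gender, setting=subj.setting, diagnoses=subj.diagnoses,
        ))
    return out


def single_informant_comparison(
    data: list[SubjectRecord],
    full_fit,
    K_range,
    informant: str = "self",
    spec: ModelSpec | None = None,
    config: FitConfig | None = None,
    merge_threshold: float = 0.5,
) -> SingleInformantComparison:
    """Refit the model on one informant's records and compare solutions.

    The single-informant solution is selected by BIC over ``K_range`` on
    the restricted data; modal assignments of the two solutions are
    cross-classified.  Full-solution classes are considered merged when
    the majority (``merge_threshold``) of each maps to the same
    single-informant class.
    """
    spec = spec or ModelSpec()
    restricted = restrict_to_informant(data, informant)
    sub_spec = spec.restrict_informants((informant,))
    # keep only the restricted informant's column in the score array
    X = to_score_array(restricted, spec)[:, [spec.informant_index(informant)], :]
    if (X == MISSING).all():
        raise ValueError(f"no observed records for informant {informant!r}")
    single_fit, table = select_model(X, K_range, sub_spec, config)

    full_assign = three_step.modal_assign(full_fit)
    single_assign = three_step.modal_assign(single_fit)
    K_full = full_fit.params.K
    K_single = single_fit.params.K
    ct = np.zeros((K_full, K_single), dtype=int)
    for a, b in zip(full_assign, single_assign):
        ct[a, b] += 1
    crosstab = pd.DataFrame(
        ct,
        index=[f"full_{c}" for c in range(K_full)],
        columns=[f"{informant}_{c}" for c in range(K_single)],
    )

    # classes of the full solution that predominantly land in one
    # single-informant class
    target = {}
    for c in range(K_full):
        row = ct[c]
        if row.sum() == 0:
            continue
        w = int(row.argmax())
        if row[w] / row.sum() >= merge_threshold:
            target.setdefault(w, []).append(c)
    merges = [(tuple(cs), w) for w, cs in sorted(target.items()) if len(cs) > 1]

    return SingleInformantComparison(
        informant=informant,
        selection_table=table,
        crosstab=crosstab,
        merges=merges,
        prevalence_full=np.bincount(full_assign, minlength=K_full) / len(full_assign),
        prevalence_single=np.bincount(single_assign, minlength=K_single)
        / len(single_assign),
    )


def plot_profiles(params: MixtureParams, labels: dict[int, str] | None = None,
                  ax=None):
    """Line plot of mean scale scores per profile, one line per
    (profile, informant) -- the conventional way these profiles are shown."""
    import matplotlib.pyplot as plt

    means = params.expected_scores()
    spec = params.spec
    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 4.5))
    x = np.arange(spec.n_scales)
    styles = ["-", "--", ":", "-."]
    for c in range(params.K):
        name = labels.get(c, f"profile {c}") if labels else f"profile {c}"
        for i, informant in enumerate(spec.informants):
            ax.plot(x, means[c, i], styles[i % len(styles)],
                    label=f"{name} ({informant})")
    ax.set_xticks(x, spec.scales, rotation=30)
    ax.set_ylabel("mean scale score")
    ax.legend(fontsize=7, ncol=2)
    return ax
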