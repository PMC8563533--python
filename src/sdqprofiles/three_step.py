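"""Bias-adjusted profile prevalence by group (the third analysis step).

After the measurement model is fitted and subjects are assigned to their
modal profile, relating the assignment to an external grouping variable
(care setting, diagnosis category, gender) naively ignores that modal
assignment misclassifies subjects whenever posteriors are not degenerate.
The classification error is quantified by the K×K matrix

    D[c, w] = P(assigned class w | true class c)

estimated from the posteriors themselves, and the group-specific class
distribution theta[g] is then recovered by maximum likelihood: within
each group the observed assignment labels are a mixture of the rows of D
with weights theta[g], maximized by EM on the probability simplex.  With
a diagonal D this reduces exactly to the observed assignment proportions.

Modal assignment with maximum-likelihood correction is the standard
recommendation among three-step variants and is what this module
implements; the correction matrix is estimated once on the full
estimation sample and held fixed across groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import FitResult, PosteriorResult

logger = logging.getLogger(__name__)


@dataclass
class ClassificationErrorMatrix:
    """D[c, w] = P(assigned class w | true class c); rows sum to 1."""

    D: np.ndarray

    @property
    def K(self) -> int:
        return self.D.shape[0]

    def validate(self) -> None:
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")
        if np.abs(self.D.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("rows of D must sum to 1")
        if (self.D < 0).any() or (self.D > 1).any():
            raise ValueError("entries of D must lie in [0, 1]")


@dataclass
class GroupClassDistribution:
    """Estimated P(profile | group) after classification-error correction.

    ``theta`` rows are groups, columns classes.  ``gender_theta`` (optional)
    holds per-(group, gender) rows from the interaction analysis, and
    ``unstable`` flags cells whose size fell below the configured minimum.
    """

    theta: pd.DataFrame
    n_g: pd.Series
    se: pd.DataFrame | None = None
    gender_theta: pd.DataFrame | None = None
    gender_n: pd.Series | None = None
    unstable: list = field(default_factory=list)


def modal_assign(posteriors) -> np.ndarray:
    """Assign each subject to its highest-posterior class.

    Ties break toward the lowest class index, so the assignment is
    deterministic.  Accepts a list of PosteriorResult or an (n, K) array.
    """
    P = _posterior_array(posteriors)
    return P.argmax(axis=1)


def _posterior_array(posteriors) -> np.ndarray:
    if isinstance(posteriors, np.ndarray):
        return posteriors
    if isinstance(posteriors, FitResult):
        return posteriors.posterior_matrix
    if len(posteriors) and isinstance(posteriors[0], PosteriorResult):
        return np.vstack([p.probabilities for p in posteriors])
    return np.asarray(posteriors, dtype=float)


def error_matrix(posteriors, assignments: np.ndarray) -> ClassificationErrorMatrix:
    """Posterior-weighted cross-classification of true against assigned class:

        D[c, w] = sum_i p_i(c) 1[w_i = w] / sum_i p_i(c)
    """
    P = _posterior_array(posteriors)
    assignments = np.asarray(assignments)
    if len(P) != len(assignments):
        raise ValueError("posteriors and assignments must have equal length")
    K = P.shape[1]
    if K < 2:
        raise ValueError("error matrix requires K >= 2")
    mass = P.sum(axis=0)                              # (K,)
    if (mass <= 0).any():
        bad = np.flatnonzero(mass <= 0).tolist()
        raise ValueError(f"classes {bad} have zero total posterior mass")
    D = np.zeros((K, K))
    for w in range(K):
        D[:, w] = P[assignments == w].sum(axis=0)
    D /= mass[:, None]
    out = ClassificationErrorMatrix(D=D)
    out.validate()
    return out


def _correct_counts(counts: np.ndarray, D: np.ndarray,
                    tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Maximize sum_w counts[w] log(sum_c theta_c D[c, w]) over the simplex
    by EM; returns theta."""
    K = D.shape[0]
    theta = np.full(K, 1.0 / K)
    total = counts.sum()
    for _ in range(max_iter):
        mix = theta @ D                                # (K,) P(assigned = w)
        mix = np.clip(mix, 1e-300, None)
        # responsibility of true class c for assigned label w
        r = theta[:, None] * D / mix[None, :]          # (K_true, K_assigned)
        new = (r * counts[None, :]).sum(axis=1) / total
        if np.abs(new - theta).max() < tol:
            theta = new
            break
        theta = new
    return theta


def adjusted_distribution(
    assignments: np.ndarray,
    D: ClassificationErrorMatrix | np.ndarray,
    groups,
    se_bootstrap: int = 0,
    seed: int = 0,
) -> GroupClassDistribution:
    """Classification-error-corrected P(profile | group).

    Subjects with an absent group label are excluded (and logged).  An
    empty group yields a NaN row flagged in ``unstable``.  Optional
    nonparametric bootstrap standard errors over subjects within group
    (``se_bootstrap`` replicates, seeded).
    """
    Dm = D.D if isinstance(D, ClassificationErrorMatrix) else np.asarray(D, dtype=float)
    ClassificationErrorMatrix(Dm).validate()
    K = Dm.shape[0]
    assignments = np.asarray(assignments)
    groups = pd.Series(list(groups))
    if len(groups) != len(assignments):
        raise ValueError("groups and assignments must have equal length")

    keep = groups.notna().to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("adjusted_distribution: excluded %d subjects without a group label",
                    n_dropped)

    labels = sorted(set(groups[keep]))
    rows, ns, unstable = {}, {}, []
    rng = np.random.default_rng(seed)
    se_rows = {}
    group_list = list(groups)
    for g in labels:
        in_g = np.array([v == g for v in group_list], dtype=bool)
        members = np.flatnonzero(keep & in_g)
        ns[g] = len(members)
        if len(members) == 0:
            rows[g] = np.full(K, np.nan)
            unstable.append(g)
            continue
        counts = np.bincount(assignments[members], minlength=K).astype(float)
        rows[g] = _correct_counts(counts, Dm)
        if se_bootstrap > 0:
            reps = np.empty((se_bootstrap, K))
            for b in range(se_bootstrap):
                sample = rng.choice(members, size=len(members), replace=True)
                bc = np.bincount(assignments[sample], minlength=K).astype(float)
                reps[b] = _correct_counts(bc, Dm)
            se_rows[g] = reps.std(axis=0, ddof=1)

    cols = [f"class_{c}" for c in range(K)]
    theta = pd.DataFrame(rows, index=cols).T
    se = pd.DataFrame(se_rows, index=cols).T if se_rows else None
    return GroupClassDistribution(
        theta=theta, n_g=pd.Series(ns), se=se, unstable=unstable
    )


def gender_interaction(
    assignments: np.ndarray,
    D: ClassificationErrorMatrix | np.ndarray,
    groups,
    gender,
    min_cell_size: int = 30,
) -> GroupClassDistribution:
    """Corrected class distributions per (group × gender) cell.

    Subjects without observed gender are excluded (logged).  Cells smaller
    than ``min_cell_size`` still receive an estimate but are flagged
    unstable; empty cells get no estimate.  The result also carries the
    overall per-group distribution and a male/female difference table via
    :func:`gender_difference_table`.
    """
    assignments = np.asarray(assignments)
    groups = pd.Series(list(groups))
    gender = pd.Series(list(gender))
    keep = gender.notna().to_numpy() & groups.notna().to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("gender_interaction: excluded %d subjects without gender/group",
                    dropped)

    overall = adjusted_distribution(assignments[keep], D, groups[keep])
    combo = pd.Series(
        [(g, x) if k else None for g, x, k in zip(groups, gender, keep)],
        dtype=object,
    )
    cell_dist = adjusted_distribution(assignments, D, combo)

    unstable = list(cell_dist.unstable)
    for key, n in cell_dist.n_g.items():
        if 0 < n < min_cell_size and key not in unstable:
            unstable.append(key)

    return GroupClassDistribution(
        theta=overall.theta,
        n_g=overall.n_g,
        gender_theta=cell_dist.theta,
        gender_n=cell_dist.n_g,
        unstable=unstable,
    )


def gender_difference_table(dist: GroupClassDistribution,
                            male: str = "M", female: str = "F") -> pd.DataFrame:
    """Tidy per-(group, profile) male/female prevalence and absolute
    difference, in percent."""
    if dist.gender_theta is None:
        raise ValueError("distribution carries no gender cells")
    rows = []
    groups = sorted({g for (g, _x) in dist.gender_theta.index})
    for g in groups:
        for col in dist.gender_theta.columns:
            m = dist.gender_theta.loc[[(g, male)]].iloc[0][col] \
                if (g, male) in dist.gender_theta.index else np.nan
            f = dist.gender_theta.loc[[(g, female)]].iloc[0][col] \
                if (g, female) in dist.gender_theta.index else np.nan
            rows.append({
                "group": g, "profile": col,
                "male_pct": 100 * m, "female_pct": 100 * f,
                "abs_diff_pct": abs(100 * m - 100 * f),
            })
    return pd.DataFrame(rows)


def report_prevalence(
    dist: GroupClassDistribution,
    threshold_pct: float = 20.0,
    min_group_n: int | None = None,
    male: str = "M",
    female: str = "F",
) -> pd.DataFrame:
    """Format prevalence estimates the way the published tables print them.

    Cells show the overall percentage, with "(M/F)" appended only where
    the absolute male/female difference reaches ``threshold_pct``.  Groups
    with fewer than ``min_group_n`` subjects are suppressed entirely.
    """
    table = {}
    for g in dist.theta.index:
        if min_group_n is not None and dist.n_g.get(g, 0) < min_group_n:
            continue
        row = {}
        for col in dist.theta.columns:
            pct = 100 * dist.theta.loc[g, col]
            cell = "" if np.isnan(pct) else f"{pct:.0f}"
            if dist.gender_theta is not None:
                mi, fi = (g, male), (g, female)
                if mi in dist.gender_theta.index and fi in dist.gender_theta.index:
                    mv = 100 * dist.gender_theta.loc[[mi]].iloc[0][col]
                    fv = 100 * dist.gender_theta.loc[[fi]].iloc[0][col]
                    if abs(mv - fv) >= threshold_pct:
                        cell = f"{pct:.0f} ({mv:.0f}/{fv:.0f})"
            row[col] = cell
        table[g] = row
    return pd.DataFrame(table).T
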