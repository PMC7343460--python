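"""Aging-phase ordering, metadata association, clocks and outliers.

Raw cluster labels are relabeled into phases 1..K by ascending median
chronological age.  Within each phase, subjects whose chronological age
exceeds the 3rd quartile by at least one third of the interquartile
range are flagged "young-like" (chronologically old for a young phase,
hence biologically young), and symmetrically "old-like" below the 1st
quartile.  Quartiles use the linear-interpolation (type 7) convention;
the outlier calls depend on it, so it is fixed here.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ClockModel, OmicsMatrix

logger = logging.getLogger("agingphases")


@dataclass
class PhaseAssignment:
    """Subject → phase (1..K) with phases ordered by median age."""

    labels: pd.Series  # index subject_id, values 1..K
    summary: pd.DataFrame  # per phase: n, median_age, mean_age

    @property
    def n_phases(self) -> int:
        return int(self.labels.max())

    def subjects_in(self, phase: int) -> list[str]:
        return list(self.labels.index[self.labels == phase])


@dataclass
class OutlierStatus:
    """Per-subject outlier call and per-phase quartile statistics."""

    labels: pd.Series  # none | young_like | old_like
    stats: pd.DataFrame  # per phase: q1, q3, iqr, threshold


def order_phases(raw_labels: pd.Series, ages: pd.Series) -> PhaseAssignment:
    """Relabel clusters into phases by ascending median chronological age.

    Ties on the median are broken by mean age, then by the smallest
    original label.  Every labeled subject must have an age.
    """
    ages = ages.reindex(raw_labels.index)
    if ages.isna().any():
        missing = list(ages.index[ages.isna()])
        raise ValueError(f"no chronological age for subjects {missing[:5]}")
    stats_rows = []
    for lab, grp in ages.groupby(raw_labels):
        if len(grp) == 0:
            raise ValueError(f"cluster {lab} is empty")
        stats_rows.append((lab, float(grp.median()), float(grp.mean()), len(grp)))
    stats_rows.sort(key=lambda r: (r[1], r[2], r[0]))
    mapping = {old: new + 1 for new, (old, *_rest) in enumerate(stats_rows)}
    labels = raw_labels.map(mapping).rename("phase")
    summary = pd.DataFrame(
        [(mapping[old], n, med, mean) for old, med, mean, n in stats_rows],
        columns=["phase", "n", "median_age", "mean_age"],
    ).set_index("phase").sort_index()
    return PhaseAssignment(labels=labels, summary=summary)


def association_test(values: pd.Series, assignment: PhaseAssignment | pd.Series,
                     method: str = "anova") -> tuple[float, float]:
    """Test whether a per-subject quantity differs across phases.

    ``method`` is ``"anova"`` (one-way F test) or ``"kruskal"``.  With
    identical values everywhere the F statistic is 0 and p = 1.
    """
    labels = assignment.labels if isinstance(assignment, PhaseAssignment) else assignment
    values = values.reindex(labels.index)
    groups = [values[labels == p].to_numpy(float) for p in sorted(labels.unique())]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if method == "anova":
        if any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA requires every group to have >= 2 members")
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:
            return 0.0, 1.0
        stat, p = stats.f_oneway(*groups)
    elif method == "kruskal":
        stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


def apply_linear_clock(matrix: OmicsMatrix, clock: ClockModel) -> pd.Series:
    """Predict molecular age: intercept + Σ coefficient × feature value.

    The matrix scale must match the clock's input scale.  Clock
    features absent from the matrix are dropped with a logged count;
    if none remain it is an error.
    """
    if matrix.scale != clock.input_scale:
        raise ValueError(f"matrix scale {matrix.scale!r} does not match "
                         f"clock input scale {clock.input_scale!r}")
    present = clock.coefficients.index.intersection(matrix.values.index)
    n_missing = len(clock.coefficients) - len(present)
    if len(present) == 0:
        raise ValueError("no clock features present in the matrix")
    if n_missing:
        logger.warning("%d of %d clock feature(s) missing from matrix; dropped",
                       n_missing, len(clock.coefficients))
    coef = clock.coefficients.loc[present]
    pred = clock.intercept + coef @ matrix.values.loc[present]
    return pred.rename("predicted_age")


def classify_age_outliers(assignment: PhaseAssignment, ages: pd.Series) -> OutlierStatus:
    """Flag chronological-age outliers within each phase.

    young_like: age strictly above Q3 with excess >= IQR/3 (the subject
    is chronologically older than its phase, i.e. biologically young);
    old_like symmetrically below Q1.  Quartiles are linear-interpolation
    (type 7).  Phases with fewer than 4 subjects are an error.
    """
    ages = ages.reindex(assignment.labels.index)
    labels = pd.Series("none", index=assignment.labels.index, name="outlier")
    rows = []
    for phase in sorted(assignment.labels.unique()):
        grp = ages[assignment.labels == phase]
        if len(grp) < 4:
            raise ValueError(f"phase {phase} has {len(grp)} subjects; "
                             "quartiles need at least 4")
        q1, q3 = np.quantile(grp.to_numpy(float), [0.25, 0.75])
        iqr = q3 - q1
        thr = iqr / 3.0
        young = (grp > q3) & (grp - q3 >= thr)
        old = (grp < q1) & (q1 - grp >= thr)
        labels[young.index[young]] = "young_like"
        labels[old.index[old]] = "old_like"
        rows.append({"phase": phase, "q1": q1, "q3": q3, "iqr": iqr, "threshold": thr})
    return OutlierStatus(labels=labels, stats=pd.DataFrame(rows).set_index("phase"))


def group_difference_tests(values: pd.Series, groups: pd.Series,
                           method: str = "t_pairwise",
                           adjust: str = "BH") -> pd.DataFrame:
    """All pairwise group comparisons of a per-subject quantity.

    ``method``: ``t_pairwise`` (Welch), ``wilcoxon_one_sided`` or
    ``wilcoxon_two_sided`` (rank-sum, exact for small groups without
    ties).  ``adjust``: ``BH`` or ``none``.  Pairs involving a group
    with fewer than 2 values are skipped with a warning.
    """
    values = values.reindex(groups.index)
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in itertools.combinations(names, 2):
        xa = values[groups == a].to_numpy(float)
        xb = values[groups == b].to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"skipping pair ({a}, {b}): group with < 2 values")
            continue
        if method == "t_pairwise":
            if np.ptp(np.concatenate([xa, xb])) == 0:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        elif method in ("wilcoxon_one_sided", "wilcoxon_two_sided"):
            alternative = "less" if method == "wilcoxon_one_sided" else "two-sided"
            stat, p = stats.mannwhitneyu(xa, xb, alternative=alternative)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"group_a": a, "group_b": b,
                     "statistic": float(stat), "p": float(p)})
    table = pd.DataFrame(rows)
    if adjust == "BH" and len(table):
        table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
    elif adjust == "none":
        table["p_adjusted"] = table["p"] if len(table) else []
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


@dataclass
class LogisticAssociation:
    coefficient: float
    odds_ratio: float
    p: float
    reliable: bool


def logistic_association(outcome: pd.Series, exposure: pd.Series,
                         age: pd.Series | None = None,
                         adjust_for_age: bool = True) -> LogisticAssociation:
    """Age-adjusted logistic regression of a binary outcome on an exposure.

    Fits outcome ~ exposure (+ age) by maximum likelihood and reports
    the exposure's Wald test.  Complete separation is flagged by
    ``reliable=False`` rather than raising.
    """
    import statsmodels.api as sm

    y = outcome.astype(float)
    uniq = set(y.unique())
    if not uniq <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(uniq) < 2:
        raise ValueError("outcome is constant")
    if len(y) < 10:
        raise ValueError("need n >= 10 for logistic association")
    cols = {"exposure": exposure.reindex(y.index).astype(float)}
    if adjust_for_age:
        if age is None:
            raise ValueError("age required when adjust_for_age=True")
        cols["age"] = age.reindex(y.index).astype(float)
    x = sm.add_constant(pd.DataFrame(cols))
    reliable = True
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, x).fit(disp=0)
        except Exception:
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            reliable = False
    coef = float(fit.params["exposure"])
    if not np.isfinite(fit.bse["exposure"]) or abs(coef) > 15:
        reliable = False
    return LogisticAssociation(coefficient=coef, odds_ratio=float(np.exp(coef)),
                               p=float(fit.pvalues["exposure"]), reliable=reliable)


def age_group_assignment(ages: pd.Series, n_groups: int) -> pd.Series:
    """Quantile-bin chronological age into n near-equal-size groups.

    The chronological counterpart to the data-driven phases, used when
    comparing grouping signal strength.
    """
    ranks = ages.rank(method="first")
    groups = pd.qcut(ranks, q=n_groups, labels=range(1, n_groups + 1))
    return groups.astype(int).rename("age_group")
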