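"""Gene-set predictivity: classifier-based pathway importance scoring.

A gene set's *predictivity* is the cross-validated accuracy of a
classifier restricted to that set's genes when predicting the aging
phase of each subject — a measure of how much phase-discriminating
signal the set carries.  Per phase, one-against-all classifiers yield
a per-phase predictivity profile whose shape traces when in the aging
progression the set's signal peaks; hierarchical clustering of the
profiles groups gene sets into succession classes.

Designs follow the study protocol: stratified 5×5-fold repeated CV,
bagged CART forests with ntree=1000 and mtry = set size, and scores
averaged over ``n_reps`` repeated runs differing only by seed.  A
label-permutation mode provides the natural negative control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.model_selection import RepeatedStratifiedKFold

from ._forest import BaggedTreeClassifier
from .io import OmicsMatrix
from .phases import PhaseAssignment

logger = logging.getLogger("agingphases")

OVERALL = "overall_multiclass"
ONE_VS_ALL = "one_vs_all"


@dataclass
class PredictivityResult:
    """Replicate accuracies of one gene set in one mode."""

    gene_set: str
    mode: str  # overall_multiclass | one_vs_all
    phase: int | None
    accuracies: np.ndarray
    chance: float  # majority-class proportion of the labels used
    settings: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


@dataclass
class SuccessionSummary:
    """Hierarchical grouping of gene sets by predictivity profile."""

    profiles: pd.DataFrame  # sets × phases, raw mean predictivity
    linkage_matrix: np.ndarray
    groups: pd.Series  # set -> group id 1..n_groups
    peak_phase: pd.Series  # set -> argmax phase (earliest on ties)


def _design_matrix(expr: OmicsMatrix, genes, labels: pd.Series):
    matched = [g for g in genes if g in expr.values.index]
    if not matched:
        raise ValueError("no genes of the set are present in the expression matrix")
    if len(matched) < len(list(genes)):
        logger.info("%d/%d set gene(s) matched in matrix", len(matched), len(list(genes)))
    if len(matched) == 1:
        logger.warning("singleton gene set after matching")
    y = labels.reindex(expr.subject_ids)
    if y.isna().any():
        raise ValueError("phase labels missing for some subjects")
    x = expr.values.loc[matched].to_numpy(float).T  # subjects × genes
    return np.ascontiguousarray(x, dtype=np.float32), y.to_numpy()


def _check_fold_feasibility(y: np.ndarray, n_splits: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_splits:
        raise ValueError(
            f"smallest class has {counts.min()} members but {n_splits} folds "
            "requested; reduce the fold count")


def _cv_accuracy(x: np.ndarray, y: np.ndarray, n_trees: int,
                 n_splits: int, n_repeats: int, seed: int) -> float:
    """Mean held-out fraction correct over stratified repeated CV."""
    rkf = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                  random_state=seed)
    rng = np.random.default_rng(seed)
    accs = []
    for train, test in rkf.split(x, y):
        clf = BaggedTreeClassifier(n_trees=n_trees,
                                   random_state=int(rng.integers(2**31)))
        clf.fit(x[train], y[train])
        accs.append(float(np.mean(clf.predict(x[test]) == y[test])))
    return float(np.mean(accs))


def _majority_proportion(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / counts.sum())


def pathway_predictivity(expr: OmicsMatrix, genes, labels: PhaseAssignment | pd.Series,
                         n_reps: int = 100, seed: int = 0, n_trees: int = 1000,
                         n_splits: int = 5, n_repeats: int = 5,
                         permute_labels: bool = False,
                         set_name: str = "") -> PredictivityResult:
    """Multiclass predictivity of one gene set.

    Each of the ``n_reps`` replicates runs a full stratified
    ``n_splits``×``n_repeats`` repeated CV of a bagged-tree forest on
    the set's genes; replicates differ only by seed.  With
    ``permute_labels`` the phase labels are shuffled independently per
    replicate (negative-control null).
    """
    y_series = labels.labels if isinstance(labels, PhaseAssignment) else labels
    x, y = _design_matrix(expr, genes, y_series)
    _check_fold_feasibility(y, n_splits)
    master = np.random.default_rng(seed)
    accs = np.empty(n_reps)
    for r in range(n_reps):
        rep_seed = int(master.integers(2**31))
        y_rep = y
        if permute_labels:
            y_rep = np.random.default_rng(rep_seed).permutation(y)
        accs[r] = _cv_accuracy(x, y_rep, n_trees, n_splits, n_repeats, rep_seed)
    return PredictivityResult(
        gene_set=set_name, mode=OVERALL, phase=None, accuracies=accs,
        chance=_majority_proportion(y),
        settings={"n_trees": n_trees, "n_splits": n_splits,
                  "n_repeats": n_repeats, "n_reps": n_reps, "seed": seed,
                  "permuted": permute_labels},
    )


def phase_stratified_predictivity(expr: OmicsMatrix, genes,
                                  labels: PhaseAssignment | pd.Series,
                                  n_reps: int = 100, seed: int = 0,
                                  n_trees: int = 1000, n_splits: int = 5,
                                  n_repeats: int = 5,
                                  set_name: str = "") -> dict[int, PredictivityResult]:
    """One-against-all predictivity per phase.

    For each phase p the labels are binarized (p vs rest) and scored as
    in :func:`pathway_predictivity`; the chance level reported is the
    majority-class (rest) proportion, so the imbalance is explicit.
    """
    y_series = labels.labels if isinstance(labels, PhaseAssignment) else labels
    x, y = _design_matrix(expr, genes, y_series)
    phases = sorted(np.unique(y))
    results: dict[int, PredictivityResult] = {}
    master = np.random.default_rng(seed)
    for phase in phases:
        y_bin = (y == phase).astype(int)
        _check_fold_feasibility(y_bin, n_splits)
        accs = np.empty(n_reps)
        for r in range(n_reps):
            accs[r] = _cv_accuracy(x, y_bin, n_trees, n_splits, n_repeats,
                                   int(master.integers(2**31)))
        results[int(phase)] = PredictivityResult(
            gene_set=set_name, mode=ONE_VS_ALL, phase=int(phase),
            accuracies=accs, chance=_majority_proportion(y_bin),
            settings={"n_trees": n_trees, "n_splits": n_splits,
                      "n_repeats": n_repeats, "n_reps": n_reps, "seed": seed},
        )
    return results


def predictivity_profiles(per_set: dict[str, dict[int, PredictivityResult]]) -> pd.DataFrame:
    """Collect one-vs-all results into a sets × phases mean-accuracy table."""
    rows = {name: {phase: res.mean for phase, res in by_phase.items()}
            for name, by_phase in per_set.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    return df.loc[list(per_set)]


def succession_clustering(profiles: pd.DataFrame, n_groups: int = 3) -> SuccessionSummary:
    """Group gene sets by the shape of their per-phase predictivity.

    Profiles are z-scaled per set (constant profiles skipped with a
    warning), clustered hierarchically (average linkage, Euclidean) and
    the tree cut into ``n_groups``.  The peak phase is the argmax of
    the raw profile, earliest phase on ties.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 gene sets to cluster")
    vals = profiles.to_numpy(float)
    sd = vals.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        import warnings
        warnings.warn(f"{int(flat.sum())} constant profile(s): z-scaling skipped for them")
    scaled = np.where(sd > 0, (vals - vals.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    link = linkage(scaled, method="average", metric="euclidean")
    groups = pd.Series(fcluster(link, t=n_groups, criterion="maxclust"),
                       index=profiles.index, name="group")
    # argmax takes the first maximum, i.e. the earliest phase on ties
    peak = pd.Series([int(profiles.columns[int(np.argmax(row))]) for row in vals],
                     index=profiles.index, name="peak_phase")
    return SuccessionSummary(profiles=profiles, linkage_matrix=link,
                             groups=groups, peak_phase=peak)


@dataclass
class PhaseContrast:
    statistic: float
    p: float
    deltas: pd.Series  # per set: predictivity(phase_b) - predictivity(phase_a)
    method: str
    low_power: bool


def predictivity_phase_contrast(profiles: pd.DataFrame,
                                phase_a: int, phase_b: int) -> PhaseContrast:
    """Paired test for a predictivity decrease from phase_a to phase_b.

    One-sided Wilcoxon signed-rank over per-set deltas
    (``phase_b - phase_a``; alternative: decrease).  With fewer than 5
    sets the exact test is used and flagged low-power.  All-zero deltas
    give p = 1 (no evidence of decrease).
    """
    for p in (phase_a, phase_b):
        if p not in profiles.columns:
            raise ValueError(f"phase {p} not present in profiles")
    deltas = (profiles[phase_b] - profiles[phase_a]).rename("delta")
    low_power = len(deltas) < 5
    if np.allclose(deltas, 0.0):
        return PhaseContrast(statistic=float("nan"), p=1.0, deltas=deltas,
                             method="wilcoxon_signed_rank_exact", low_power=low_power)
    nonzero = deltas[deltas != 0]
    exact_ok = len(nonzero) <= 25 and len(nonzero) == len(np.unique(np.abs(nonzero)))
    method = "exact" if (low_power or exact_ok) else "auto"
    stat, p = stats.wilcoxon(deltas.to_numpy(float), alternative="less",
                             method=method, zero_method="wilcox")
    return PhaseContrast(statistic=float(stat), p=float(p), deltas=deltas,
                         method=f"wilcoxon_signed_rank_{method}", low_power=low_power)
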