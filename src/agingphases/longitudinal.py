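"""Phase classification of follow-up samples and transition summaries.

A forest is trained on the first-timepoint cohort using the union of
the top differential features from every pairwise phase contrast, on
both omics layers, then applied to re-measured subjects.  Performance
on the original cohort is the Hand–Till multiclass AUC under repeated
stratified CV with feature selection re-run inside each training fold
(the leakage guard).  Phase changes between timepoints are summarized
as a transition matrix; backward transitions (against the age
gradient) are flagged prominently.

Feature ranking uses per-feature Welch t tests on the working scales
(log2-TPM / M values): a deliberately simple ranking with the same
top-k contract as count-model or moderated-t rankings.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ._forest import BaggedTreeClassifier
from .io import OmicsMatrix
from .phases import PhaseAssignment

logger = logging.getLogger("agingphases")


def differential_top_features(matrix: OmicsMatrix,
                              labels: PhaseAssignment | pd.Series,
                              top_k: int = 50) -> list[str]:
    """Union of top-k differential features over all pairwise contrasts.

    Per contrast, features are ranked by Welch-t p value (ascending),
    ties by |t| (descending) then feature id; undefined statistics
    (zero variance in both groups) rank last, so the selection is
    deterministic even under the null.  Contrasts with a phase of
    fewer than 2 subjects are skipped with a warning.
    """
    y = labels.labels if isinstance(labels, PhaseAssignment) else labels
    y = y.reindex(matrix.subject_ids)
    phases = sorted(y.dropna().unique())
    if len(phases) < 2:
        raise ValueError("need at least 2 phases")
    vals = matrix.values
    ids = np.array(matrix.feature_ids)
    selected: set[str] = set()
    for a, b in itertools.combinations(phases, 2):
        xa = vals.loc[:, (y == a).to_numpy()].to_numpy(float)
        xb = vals.loc[:, (y == b).to_numpy()].to_numpy(float)
        if xa.shape[1] < 2 or xb.shape[1] < 2:
            warnings.warn(f"contrast ({a}, {b}) skipped: a phase has < 2 subjects")
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        t = np.where(np.isnan(t), 0.0, t)
        order = sorted(range(len(ids)), key=lambda i: (p[i], -abs(t[i]), ids[i]))
        selected.update(ids[order[:top_k]])
    return sorted(selected)


@dataclass
class ClassifierParams:
    n_trees: int = 1000
    top_k: int = 50
    n_splits: int = 5
    n_repeats: int = 5
    seed: int = 0


@dataclass
class PhaseClassifier:
    """A trained phase classifier with its feature provenance."""

    expr_features: list[str]
    meth_features: list[str]
    model: BaggedTreeClassifier
    classes: np.ndarray
    manifest: dict = field(default_factory=dict)


def _stack_features(expr: OmicsMatrix, meth: OmicsMatrix,
                    expr_features: list[str], meth_features: list[str],
                    subjects: list[str]) -> np.ndarray:
    for name, matrix, feats in (("expression", expr, expr_features),
                                ("methylation", meth, meth_features)):
        missing = [f for f in feats if f not in matrix.values.index]
        if missing:
            raise ValueError(f"{name} matrix lacks selected feature(s) {missing[:5]}; "
                             "intersect feature spaces first")
    xe = expr.values.loc[expr_features, subjects].to_numpy(float).T
    xm = meth.values.loc[meth_features, subjects].to_numpy(float).T
    return np.hstack([xe, xm])


def train_phase_classifier(expr: OmicsMatrix, meth: OmicsMatrix,
                           labels: PhaseAssignment | pd.Series,
                           params: ClassifierParams | None = None) -> PhaseClassifier:
    """Train the combined expression + methylation phase forest."""
    params = params or ClassifierParams()
    y = labels.labels if isinstance(labels, PhaseAssignment) else labels
    if list(expr.subject_ids) != list(meth.subject_ids):
        raise ValueError("expression and methylation matrices must share subjects")
    subjects = expr.subject_ids
    y = y.reindex(subjects)
    if y.isna().any():
        raise ValueError("phase labels missing for some subjects")
    expr_feats = differential_top_features(expr, y, params.top_k)
    meth_feats = differential_top_features(meth, y, params.top_k)
    x = _stack_features(expr, meth, expr_feats, meth_feats, subjects)
    model = BaggedTreeClassifier(n_trees=params.n_trees, random_state=params.seed)
    model.fit(x, y.to_numpy())
    return PhaseClassifier(
        expr_features=expr_feats, meth_features=meth_feats, model=model,
        classes=model.classes_,
        manifest={"n_trees": params.n_trees, "top_k": params.top_k,
                  "seed": params.seed, "n_subjects": len(subjects)},
    )


def predict_phases(classifier: PhaseClassifier, expr: OmicsMatrix,
                   meth: OmicsMatrix) -> pd.Series:
    """Apply a trained classifier to (re-measured) subjects."""
    if list(expr.subject_ids) != list(meth.subject_ids):
        raise ValueError("expression and methylation matrices must share subjects")
    x = _stack_features(expr, meth, classifier.expr_features,
                        classifier.meth_features, expr.subject_ids)
    return pd.Series(classifier.model.predict(x), index=expr.subject_ids,
                     name="predicted_phase")


def hand_till_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Multiclass AUC by the Hand–Till mean-of-pairwise construction.

    For each unordered class pair (i, j), A(i|j) is the probability
    that a random class-i sample receives a higher class-i score than a
    random class-j sample (ties count one half); the pair value is
    [A(i|j) + A(j|i)] / 2 and the AUC is the unweighted mean over
    pairs.  Pairs missing a class are skipped with a warning.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    pair_aucs = []
    for ia, ib in itertools.combinations(range(len(classes)), 2):
        mask_a = y_true == classes[ia]
        mask_b = y_true == classes[ib]
        na, nb = int(mask_a.sum()), int(mask_b.sum())
        if na == 0 or nb == 0:
            warnings.warn(f"class pair ({classes[ia]}, {classes[ib]}) skipped: "
                          "a class is absent")
            continue
        both = mask_a | mask_b
        halves = []
        for col, pos_mask in ((ia, mask_a), (ib, mask_b)):
            scores = proba[both, col]
            ranks = stats.rankdata(scores)
            pos = pos_mask[both]
            n_pos, n_neg = int(pos.sum()), int((~pos).sum())
            u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
            halves.append(u / (n_pos * n_neg))
        pair_aucs.append(0.5 * (halves[0] + halves[1]))
    if not pair_aucs:
        raise ValueError("no class pair had both classes present")
    return float(np.mean(pair_aucs))


@dataclass
class AUCResult:
    mean: float
    per_repeat: np.ndarray


def evaluate_classifier_auc(expr: OmicsMatrix, meth: OmicsMatrix,
                            labels: PhaseAssignment | pd.Series,
                            params: ClassifierParams | None = None) -> AUCResult:
    """Cross-validated Hand–Till AUC of the phase classifier.

    Feature selection is re-run on the training subjects of every fold
    so no held-out information leaks into the ranking.  Held-out class
    scores are pooled per repeat; the result averages over repeats.
    """
    params = params or ClassifierParams()
    y = (labels.labels if isinstance(labels, PhaseAssignment) else labels)
    subjects = expr.subject_ids
    y = y.reindex(subjects)
    y_arr = y.to_numpy()
    classes = np.unique(y_arr)
    rng = np.random.default_rng(params.seed)
    per_repeat = []
    for _rep in range(params.n_repeats):
        skf = StratifiedKFold(n_splits=params.n_splits, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        proba = np.zeros((len(subjects), len(classes)))
        for train, test in skf.split(np.zeros(len(subjects)), y_arr):
            tr_ids = [subjects[i] for i in train]
            te_ids = [subjects[i] for i in test]
            expr_tr = expr.with_values(expr.values[tr_ids])
            meth_tr = meth.with_values(meth.values[tr_ids])
            y_tr = y.iloc[train]
            ef = differential_top_features(expr_tr, y_tr, params.top_k)
            mf = differential_top_features(meth_tr, y_tr, params.top_k)
            x_tr = _stack_features(expr, meth, ef, mf, tr_ids)
            x_te = _stack_features(expr, meth, ef, mf, te_ids)
            clf = BaggedTreeClassifier(n_trees=params.n_trees,
                                       random_state=int(rng.integers(2**31)))
            clf.fit(x_tr, y_arr[train])
            cols = [int(np.where(classes == c)[0][0]) for c in clf.classes_]
            proba[np.ix_(test, cols)] = clf.predict_proba(x_te)
        per_repeat.append(hand_till_auc(y_arr, proba, classes))
    per_repeat = np.array(per_repeat)
    return AUCResult(mean=float(per_repeat.mean()), per_repeat=per_repeat)


@dataclass
class TransitionSummary:
    """Phase movements between two timepoints."""

    matrix: pd.DataFrame  # phase_t1 × phase_t2 subject counts
    movers: pd.DataFrame  # subject, phase_t1, phase_t2, direction
    stable_fraction: float
    backward_transitions: list[str]


def phase_transition_summary(t1: pd.Series, t2: pd.Series) -> TransitionSummary:
    """Cross-tabulate phase assignments at two timepoints.

    Counts are over subjects present at both timepoints; movers are
    listed with direction (forward = higher phase at t2) and any
    backward transition is flagged.
    """
    t1_labels = t1.labels if isinstance(t1, PhaseAssignment) else t1
    t2_labels = t2.labels if isinstance(t2, PhaseAssignment) else t2
    shared = t1_labels.index.intersection(t2_labels.index)
    if len(shared) == 0:
        raise ValueError("no shared subjects between timepoints")
    a = t1_labels.loc[shared].astype(int)
    b = t2_labels.loc[shared].astype(int)
    phases = sorted(set(a.unique()) | set(b.unique()))
    matrix = pd.crosstab(a, b).reindex(index=phases, columns=phases, fill_value=0)
    matrix.index.name, matrix.columns.name = "phase_t1", "phase_t2"
    moved = a != b
    movers = pd.DataFrame({
        "subject_id": shared[moved],
        "phase_t1": a[moved].to_numpy(),
        "phase_t2": b[moved].to_numpy(),
    })
    movers["direction"] = np.where(movers["phase_t2"] > movers["phase_t1"],
                                   "forward", "backward")
    backward = movers.loc[movers["direction"] == "backward", "subject_id"].tolist()
    if backward:
        logger.warning("backward phase transition(s): %s", backward)
    return TransitionSummary(
        matrix=matrix, movers=movers,
        stable_fraction=float((~moved).mean()),
        backward_transitions=backward,
    )
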