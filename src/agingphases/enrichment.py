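"""PLAGE single-sample gene-set scores and grouping-signal ANOVA.

PLAGE (pathway level analysis of gene expression) summarizes each gene
set per subject as the first right singular vector of the z-scored
gene-subset matrix.  Because an SVD's sign is arbitrary, scores are
oriented to correlate non-negatively with the set's mean z-scored
expression, making them reproducible across runs and platforms.  When
that correlation is numerically zero the first non-negligible loading
is made positive instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, OmicsMatrix

logger = logging.getLogger("agingphases")


@dataclass
class EnrichmentScores:
    """Gene set × subject pathway-activity matrix.

    Each row is the (unit-norm) first right singular vector of the
    set's z-scored expression submatrix, sign-oriented as documented.
    """

    scores: pd.DataFrame
    collection_name: str = ""
    singleton_sets: tuple[str, ...] = ()


def plage_scores(expr: OmicsMatrix, sets: GeneSetCollection,
                 collection_name: str = "") -> EnrichmentScores:
    """Compute PLAGE activity scores for every gene set.

    Genes are z-scored across subjects (population SD); zero-variance
    genes are dropped with a warning; sets with no matched genes are
    dropped with a warning, singleton sets are scored but flagged.
    """
    if expr.n_subjects < 2:
        raise ValueError("PLAGE needs at least 2 subjects")
    vals = expr.values.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance gene(s) from z-scoring")
    z = pd.DataFrame(
        np.divide(vals - mu, sd, where=sd > 0, out=np.zeros_like(vals)),
        index=expr.values.index, columns=expr.values.columns,
    ).loc[~flat]

    rows = {}
    singletons = []
    for s in sets:
        genes = [g for g in s.genes if g in z.index]
        if not genes:
            warnings.warn(f"gene set {s.name!r}: no genes matched; dropped")
            continue
        if len(genes) == 1:
            singletons.append(s.name)
        sub = z.loc[genes].to_numpy()
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        activity = vt[0]
        reference = sub.mean(axis=0)
        orient = float(activity @ reference)
        # the mean-reference orientation is indeterminate when the leading
        # singular vector is (numerically) orthogonal to the set mean;
        # fall back to a fixed sign convention rather than amplifying
        # floating-point noise into a sign flip
        tol = 1e-9 * max(1.0, float(np.linalg.norm(reference)))
        if abs(orient) <= tol:
            nz = np.nonzero(np.abs(activity) > 1e-12)[0]
            if nz.size and activity[nz[0]] < 0:
                activity = -activity
        elif orient < 0:
            activity = -activity
        rows[s.name] = activity
    if not rows:
        raise ValueError("no gene set matched the expression matrix")
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=expr.subject_ids)
    return EnrichmentScores(scores=scores, collection_name=collection_name,
                            singleton_sets=tuple(singletons))


def grouping_signal_anova(scores: EnrichmentScores,
                          groupings: dict[str, pd.Series],
                          adjust: str = "BH") -> pd.DataFrame:
    """Per-set one-way ANOVA of activity scores under each grouping.

    Returns a tidy table (set, grouping, F, p, p_adjusted) enabling the
    comparison of how strongly alternative subject groupings (e.g.
    aging phases versus chronological age bins) segregate pathway
    activity.  BH adjustment is applied across sets within each
    grouping.  A grouping containing a singleton group is skipped.
    """
    frames = []
    for gname, groups in groupings.items():
        groups = groups.reindex(scores.scores.columns)
        if groups.isna().any():
            raise ValueError(f"grouping {gname!r} does not cover all scored subjects")
        sizes = groups.value_counts()
        if (sizes < 2).any():
            warnings.warn(f"grouping {gname!r} has singleton group(s); skipped")
            continue
        rows = []
        for set_name, vec in scores.scores.iterrows():
            samples = [vec[groups == g].to_numpy(float) for g in sorted(sizes.index)]
            flat = np.concatenate(samples)
            if np.ptp(flat) == 0:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.f_oneway(*samples)
            rows.append({"set": set_name, "grouping": gname,
                         "F": float(stat), "p": float(p)})
        table = pd.DataFrame(rows)
        if adjust == "BH":
            table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
        elif adjust == "none":
            table["p_adjusted"] = table["p"]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        frames.append(table)
    if not frames:
        return pd.DataFrame(columns=["set", "grouping", "F", "p", "p_adjusted"])
    return pd.concat(frames, ignore_index=True)
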