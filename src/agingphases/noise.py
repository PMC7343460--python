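"""Transcriptional noise: inter-subject profile similarity by phase.

Transcriptional noise is measured as the loss of pairwise Pearson
correlation between full omics profiles of subjects in the same phase.
Correlations are computed on the preprocessed full matrices (working
scale, not the MAD-filtered subset).  Because pairs sharing a subject
are not independent, the contrast also reports a subject-level summary
(median correlation of each subject to its same-phase peers) alongside
the pairwise-level test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix
from .phases import PhaseAssignment

WITHIN_PHASE = "within_phase"
ALL_PAIRS = "all_pairs"


@dataclass
class SimilarityByPhase:
    """Within-phase pairwise Pearson correlations of subject profiles."""

    correlations: dict[int, np.ndarray]  # phase -> vector of pair correlations
    pairs: dict[int, list[tuple[str, str]]]
    kind: str
    scope: str

    def pair_count(self, phase: int) -> int:
        return len(self.correlations[phase])


def pairwise_similarity_by_phase(matrix: OmicsMatrix,
                                 assignment: PhaseAssignment | pd.Series,
                                 scope: str = WITHIN_PHASE) -> SimilarityByPhase:
    """Pearson correlation over all features for each subject pair.

    ``within_phase`` groups pairs whose two members share a phase;
    ``all_pairs`` pools every pair under phase 0.  Zero-variance
    profiles are excluded with a warning.
    """
    labels = assignment.labels if isinstance(assignment, PhaseAssignment) else assignment
    labels = labels.reindex(matrix.subject_ids)
    if labels.isna().any():
        raise ValueError("phase labels missing for some subjects")
    vals = matrix.values.to_numpy(float)
    sds = vals.std(axis=0)
    degenerate = sds == 0
    if degenerate.any():
        bad = [s for s, d in zip(matrix.subject_ids, degenerate) if d]
        warnings.warn(f"dropping pairs involving zero-variance profile(s) {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals.T)
    ids = matrix.subject_ids

    correlations: dict[int, np.ndarray] = {}
    pairs: dict[int, list[tuple[str, str]]] = {}
    if scope == WITHIN_PHASE:
        for phase in sorted(labels.unique()):
            members = [i for i, s in enumerate(ids)
                       if labels[s] == phase and not degenerate[i]]
            if len(members) < 2:
                raise ValueError(f"phase {phase} has fewer than 2 usable subjects")
            cs, ps = [], []
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    i, j = members[a], members[b]
                    cs.append(corr[i, j])
                    ps.append((ids[i], ids[j]))
            correlations[int(phase)] = np.array(cs)
            pairs[int(phase)] = ps
    elif scope == ALL_PAIRS:
        members = [i for i in range(len(ids)) if not degenerate[i]]
        cs, ps = [], []
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                cs.append(corr[i, j])
                ps.append((ids[i], ids[j]))
        correlations[0] = np.array(cs)
        pairs[0] = ps
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return SimilarityByPhase(correlations=correlations, pairs=pairs,
                             kind=matrix.kind, scope=scope)


@dataclass
class NoiseContrast:
    pairwise_p: float
    pairwise_statistic: float
    subject_p: float
    subject_statistic: float
    median_a: float
    median_b: float


def noise_contrast(similarity: SimilarityByPhase, phase_a: int, phase_b: int) -> NoiseContrast:
    """Test whether phase_b profiles are less correlated than phase_a's.

    Pairwise level: one-sided rank-sum on the pair correlations
    (alternative: phase_b lower).  Subject level: the same test on each
    subject's median correlation to its same-phase peers, a guard
    against the non-independence of pairs sharing a subject.
    """
    for p in (phase_a, phase_b):
        if p not in similarity.correlations or len(similarity.correlations[p]) < 2:
            raise ValueError(f"phase {p} needs at least 2 pairs")
    ca, cb = similarity.correlations[phase_a], similarity.correlations[phase_b]
    stat_pw, p_pw = stats.mannwhitneyu(ca, cb, alternative="greater")

    def subject_medians(phase: int) -> np.ndarray:
        per_subject: dict[str, list[float]] = {}
        for (a, b), c in zip(similarity.pairs[phase], similarity.correlations[phase]):
            per_subject.setdefault(a, []).append(c)
            per_subject.setdefault(b, []).append(c)
        return np.array([np.median(v) for v in per_subject.values()])

    ma, mb = subject_medians(phase_a), subject_medians(phase_b)
    stat_subj, p_subj = stats.mannwhitneyu(ma, mb, alternative="greater")
    return NoiseContrast(pairwise_p=float(p_pw), pairwise_statistic=float(stat_pw),
                         subject_p=float(p_subj), subject_statistic=float(stat_subj),
                         median_a=float(np.median(ca)), median_b=float(np.median(cb)))
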