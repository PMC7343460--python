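"""Value transforms, MAD feature selection and batch correction.

The canonical order ahead of network fusion is: transform to the
working scale (log2-TPM for expression, M values for methylation),
select the top 10 % most variable features by median absolute
deviation, then remove batch effects with parametric empirical-Bayes
ComBat.  ``combat_then_select`` can swap the last two steps.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import BETA, LOG2_TPM, M_VALUE, RAW_TPM, OmicsMatrix

logger = logging.getLogger("agingphases")

_TRANSFORMS = {
    (RAW_TPM, LOG2_TPM),
    (BETA, M_VALUE),
    (M_VALUE, BETA),
}


def transform_values(matrix: OmicsMatrix, target_scale: str,
                     pseudocount: float = 1.0, eps: float = 1e-6) -> OmicsMatrix:
    """Convert a matrix between measurement scales.

    Supported pairs: raw TPM → log2-TPM (``log2(TPM + pseudocount)``),
    beta → M (``log2(beta / (1 - beta))`` with beta clipped to
    ``[eps, 1 - eps]``), and M → beta (inverse logistic).
    """
    pair = (matrix.scale, target_scale)
    if pair not in _TRANSFORMS:
        raise ValueError(f"unsupported scale conversion {matrix.scale!r} -> {target_scale!r}")
    vals = matrix.values
    if pair == (RAW_TPM, LOG2_TPM):
        out = np.log2(vals + pseudocount)
    elif pair == (BETA, M_VALUE):
        clipped = vals.clip(lower=eps, upper=1.0 - eps)
        out = np.log2(clipped / (1.0 - clipped))
    else:  # m_value -> beta
        out = 1.0 / (1.0 + 2.0 ** (-vals))
    return matrix.with_values(out, scale=target_scale)


def mad_feature_select(matrix: OmicsMatrix, fraction: float = 0.10) -> OmicsMatrix:
    """Keep the ``ceil(fraction * n_features)`` features with largest MAD.

    MAD is the raw median absolute deviation from the feature median
    (no consistency constant — the ranking is scale-free).  Ties are
    broken by lexicographic feature id; the output preserves the input
    feature order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.n_features == 0 or matrix.n_subjects == 0:
        raise ValueError("cannot select features from an empty matrix")
    vals = matrix.values
    med = vals.median(axis=1)
    mad = (vals.sub(med, axis=0)).abs().median(axis=1)
    k = math.ceil(fraction * matrix.n_features)
    order = sorted(matrix.feature_ids, key=lambda f: (-mad[f], f))
    keep = set(order[:k])
    kept = [f for f in matrix.feature_ids if f in keep]
    return matrix.with_values(vals.loc[kept])


def combat_correct(matrix: OmicsMatrix, batch: pd.Series | None = None,
                   parametric: bool = True) -> OmicsMatrix:
    """Remove additive/multiplicative batch effects (parametric ComBat).

    Applies the empirical-Bayes location/scale adjustment: features are
    standardized, per-batch per-feature effects estimated, shrunk
    toward batch-level priors, and the data adjusted and restored.  The
    computation is delegated to scanpy's ComBat implementation (no
    covariate design).  A single-batch matrix is returned unchanged;
    a batch with fewer than two subjects is an error.
    """
    if not parametric:
        raise NotImplementedError("only parametric ComBat is provided")
    if batch is None:
        batch = matrix.batch
    if batch is None:
        raise ValueError("no batch labels supplied")
    batch = batch.reindex(matrix.subject_ids)
    if batch.isna().any():
        raise ValueError("batch labels missing for some subjects")
    sizes = batch.value_counts()
    if len(sizes) == 1:
        return matrix.with_values(matrix.values.copy())
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"batch(es) {small} have fewer than 2 subjects; "
                         "scale adjustment is undefined")

    import anndata
    import scanpy as sc

    adata = anndata.AnnData(
        X=matrix.values.to_numpy(float).T.copy(),
        obs=pd.DataFrame({"batch": pd.Categorical(batch.astype(str))},
                         index=matrix.subject_ids),
        var=pd.DataFrame(index=matrix.feature_ids),
    )
    corrected = sc.pp.combat(adata, key="batch", inplace=False)
    out = pd.DataFrame(np.asarray(corrected).T,
                       index=matrix.feature_ids, columns=matrix.subject_ids)
    return matrix.with_values(out)


def preprocess_layer(matrix: OmicsMatrix, mad_fraction: float = 0.10,
                     combat: bool = True,
                     combat_then_select: bool = False) -> OmicsMatrix:
    """Standard preprocessing for one omics layer ahead of fusion.

    Default order is MAD selection then ComBat; set
    ``combat_then_select`` to correct batches on the full matrix first.
    The matrix must already be on its working scale (log2-TPM /
    M values).
    """
    if matrix.scale not in (LOG2_TPM, M_VALUE):
        raise ValueError("transform to log2_tpm or m_value before preprocessing")
    run_combat = combat and matrix.batch is not None and matrix.batch.nunique() > 1
    if combat_then_select and run_combat:
        matrix = combat_correct(matrix)
    matrix = mad_feature_select(matrix, mad_fraction)
    if not combat_then_select and run_combat:
        matrix = combat_correct(matrix)
    return matrix
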