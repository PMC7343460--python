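"""End-to-end phase discovery: preprocess → fuse → select K → cluster."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fusion import (
    ClusterSelection,
    SimilarityNetwork,
    SNFParams,
    affinity_matrix,
    pairwise_distance,
    select_cluster_number,
    snf_fuse,
    spectral_cluster,
)
from .io import OmicsMatrix
from .phases import PhaseAssignment, order_phases
from .preprocess import preprocess_layer


@dataclass
class PhaseDiscovery:
    fused: SimilarityNetwork
    selection: ClusterSelection | None
    raw_labels: pd.Series
    assignment: PhaseAssignment | None
    n_clusters: int


def discover_phases(layers: list[OmicsMatrix],
                    ages: pd.Series | None = None,
                    params: SNFParams | None = None,
                    mad_fraction: float = 0.10,
                    combat: bool = True,
                    k_range: tuple[int, int] = (2, 8),
                    n_clusters: int | None = None,
                    seed: int = 0) -> PhaseDiscovery:
    """Run the full unsupervised stage on working-scale omics layers.

    Each layer is MAD-filtered and batch-corrected, turned into a
    standardized-Euclidean affinity network, and the networks are fused
    by cross-diffusion.  The cluster number is chosen by eigen-gap over
    ``k_range`` unless fixed via ``n_clusters``.  If chronological ages
    are given the clusters are ordered into phases 1..K by median age.
    """
    params = params or SNFParams()
    affinities = []
    for layer in layers:
        processed = preprocess_layer(layer, mad_fraction=mad_fraction, combat=combat)
        dist = pairwise_distance(processed, standardize=True)
        affinities.append(affinity_matrix(dist, params))
    fused = snf_fuse(affinities, params)
    selection = None
    if n_clusters is None:
        selection = select_cluster_number(fused, k_range)
        n_clusters = selection.best_k
    raw = spectral_cluster(fused, n_clusters, seed=seed)
    assignment = order_phases(raw, ages) if ages is not None else None
    return PhaseDiscovery(fused=fused, selection=selection, raw_labels=raw,
                          assignment=assignment, n_clusters=n_clusters)
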