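"""Approximate two-level survey weights from single-level normalized weights.

Multilevel models of DHS-style data need a weight at each level, but public
survey files ship a single normalized individual weight. The approximation
used here de-normalizes the individual weights (rescaling so they sum to the
population total) and then splits each de-normalized weight D_ij into a
cluster part and a conditional individual part by allocating a share alpha of
its variation to the cluster level:

    level2_j  = (mean of D_ij within cluster j) ** alpha
    level1_ij = D_ij / level2_j

so that level2_j * level1_ij == D_ij for every individual. With alpha = 0.5
the variation is split equally between the two levels. This is a pragmatic
approximation: the defining contract is the alpha-allocation plus the exact
product identity, not a reconstruction of design-based level-2 weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .readiness import ValidationError


def denormalize(
    normalized_weights: np.ndarray | pd.Series,
    total_population: float,
    sample_size: float,
) -> np.ndarray:
    """Scale normalized weights by total_population / sample_size."""
    w = np.asarray(normalized_weights, dtype=float)
    if total_population <= 0 or sample_size <= 0:
        raise ValidationError("population and sample size must be positive")
    if (w <= 0).any():
        raise ValidationError("weights must be positive")
    return w * (total_population / sample_size)


def split_weights(
    denorm_weights: np.ndarray | pd.Series,
    cluster_ids: np.ndarray | pd.Series,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Split de-normalized weights into cluster and conditional-individual parts.

    Returns a frame aligned with the input: columns ``cluster_id``,
    ``level2_weight`` (cluster, = within-cluster mean weight ** alpha) and
    ``level1_weight`` (conditional individual). ``alpha=0`` puts all weight at
    level 1 (every level-2 weight is 1); ``alpha=1`` puts the full
    cluster-mean at level 2.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    d = np.asarray(denorm_weights, dtype=float)
    if (d <= 0).any():
        raise ValidationError("weights must be positive")
    cid = pd.Series(np.asarray(cluster_ids), name="cluster_id")
    if len(cid) != len(d) or len(d) == 0:
        raise ValidationError("weights and cluster ids must align and be non-empty")
    cluster_mean = pd.Series(d).groupby(cid, sort=False).transform("mean").to_numpy()
    level2 = cluster_mean ** alpha
    level1 = d / level2
    return pd.DataFrame(
        {"cluster_id": cid.to_numpy(), "level2_weight": level2, "level1_weight": level1}
    )
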