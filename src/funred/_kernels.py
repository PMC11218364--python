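"""Numeric kernels shared across modules.

Both redundancy indices and both community-diversity measures reduce to the
same two kernels: Shannon entropy of a normalized weight vector and the
Bray-Curtis dissimilarity of two non-negative vectors.  Keeping one
implementation of each guarantees that e.g. the within-community redundancy
index and the community Shannon index can never drift apart numerically.
"""

from __future__ import annotations

import numpy as np

from .core import ValidationError


def shannon_entropy(weights: np.ndarray) -> float:
    """Shannon entropy ``-sum p ln p`` of a non-negative weight vector.

    Weights are normalized to frequencies internally, so the result is
    scale-invariant.  Zero weights contribute nothing (the ``p ln p -> 0``
    limit).  Natural logarithm.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValidationError("entropy of an empty weight vector is undefined")
    if (w < 0).any():
        raise ValidationError("negative weight in entropy input")
    total = w.sum()
    if total <= 0:
        raise ValidationError("entropy of an all-zero weight vector is undefined")
    p = w[w > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 sum(min(x, y)) / (sum x + sum y)``.

    Defined for any pair of equal-length non-negative vectors with at least
    one positive sum each; 0 for identical vectors, 1 for disjoint supports.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(
            f"vector lengths differ: {x.shape} vs {y.shape}"
        )
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative entry in Bray-Curtis input")
    denom = x.sum() + y.sum()
    if denom <= 0:
        raise ValidationError(
            "Bray-Curtis undefined: both vectors sum to zero"
        )
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)
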