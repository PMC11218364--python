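"""Alpha and beta diversity of the OTU table.

These are the community-diversity covariates for the association analyses:
observed OTUs, Shannon index (natural log, same kernel as the
within-community redundancy index), bias-corrected Chao1 richness, Faith's
phylogenetic diversity (rooted convention: the path to the root is
included), and Bray-Curtis beta diversity (same kernel as the
between-community redundancy index).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Set

import numpy as np
import pandas as pd

from ._kernels import bray_curtis as _bray_curtis_kernel
from ._kernels import shannon_entropy
from .core import (
    CommunityProfileSet,
    PhyloTree,
    UsageError,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversityRecord:
    """Alpha diversity of one sample; ``faith_pd`` is None without a tree."""

    sample_id: str
    observed_otus: int
    shannon: float
    chao1: float
    faith_pd: Optional[float] = None


def shannon(counts: Iterable[float]) -> Optional[float]:
    """Shannon index ``-sum p ln p`` of a count vector; None if all zero."""
    w = np.asarray(list(counts), dtype=float)
    if w.size == 0 or w.sum() <= 0:
        logger.warning("Shannon index undefined for an all-zero vector")
        return None
    return shannon_entropy(w)


def chao1(counts: Iterable[float]) -> float:
    """Bias-corrected Chao1 richness estimate.

    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` with F1 = singleton and F2 =
    doubleton counts.  The bias-corrected form is defined even without
    doubletons.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValidationError("Chao1 undefined for an all-zero vector")
    if (c < 0).any() or (c % 1 != 0).any():
        raise ValidationError("Chao1 requires non-negative integer counts")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def observed_otus(counts: Iterable[float]) -> int:
    """Number of OTUs with at least one read."""
    c = np.asarray(list(counts), dtype=float)
    return int((c > 0).sum())


def faith_pd(present_otus: Set[str], tree: PhyloTree) -> float:
    """Faith's phylogenetic diversity of a set of present OTUs.

    Sum of branch lengths in the union of root-to-leaf paths over the
    present leaves (rooted convention: the root's own branch, if any, is
    included).
    """
    tips = {tip.name: tip for tip in tree.tree.tips()}
    missing = set(present_otus) - set(tips)
    if missing:
        raise ValidationError(
            f"OTUs absent from the tree: {sorted(missing)[:5]}"
        )
    if not present_otus:
        return 0.0
    seen: Set[int] = set()
    total = 0.0
    for name in present_otus:
        node = tips[name]
        while node is not None and id(node) not in seen:
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return float(total)


def bray_curtis(x: Iterable[float], y: Iterable[float]) -> Optional[float]:
    """Bray-Curtis dissimilarity of two count/abundance vectors.

    Returns None with a warning when either vector sums to zero.
    """
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.shape != yv.shape:
        raise ValidationError(
            f"vector lengths differ: {xv.size} vs {yv.size}"
        )
    if xv.sum() <= 0 or yv.sum() <= 0:
        logger.warning("Bray-Curtis undefined for a zero-sum vector")
        return None
    return _bray_curtis_kernel(xv, yv)


def alpha_diversity_table(
    profile: CommunityProfileSet, tree: Optional[PhyloTree] = None
) -> pd.DataFrame:
    """All alpha indices per sample as a DataFrame."""
    rows = []
    for i, sid in enumerate(profile.sample_ids):
        counts = profile.counts[i]
        present = {
            otu for otu, c in zip(profile.otu_ids, counts) if c > 0
        }
        pd_value = faith_pd(present, tree) if tree is not None else math.nan
        sh = shannon(counts)
        rows.append(
            {
                "sample_id": sid,
                "observed_otus": observed_otus(counts),
                "shannon": math.nan if sh is None else sh,
                "chao1": chao1(counts),
                "faith_pd": pd_value,
            }
        )
    return pd.DataFrame(rows)


def beta_diversity_table(
    profile: CommunityProfileSet,
    within_environment: Optional[str] = None,
) -> pd.DataFrame:
    """Long-format pairwise Bray-Curtis table (sample_a, sample_b, value).

    With ``within_environment`` set to a metadata field name (e.g.
    ``"environment_level3"``), only pairs sharing that label are emitted.
    """
    if profile.n_samples < 2:
        raise UsageError("need at least 2 samples for beta diversity")
    labels = None
    if within_environment is not None:
        labels = {
            sid: getattr(profile.metadata[sid], within_environment)
            for sid in profile.sample_ids
        }
    rows = []
    for i, j in itertools.combinations(range(profile.n_samples), 2):
        sa, sb = profile.sample_ids[i], profile.sample_ids[j]
        if labels is not None and (not labels[sa] or labels[sa] != labels[sb]):
            continue
        value = bray_curtis(profile.counts[i], profile.counts[j])
        rows.append(
            {
                "sample_a": sa,
                "sample_b": sb,
                "bray_curtis": math.nan if value is None else value,
            }
        )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "bray_curtis"])
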