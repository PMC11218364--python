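"""Functional redundancy indices within and between communities.

For a function whose genes are distributed over taxa with relative
frequencies ``P_i``:

* within-community index = ``-sum_i P_i ln P_i`` (Shannon form).  0 means a
  single encoding taxon (function present but not redundant); the index is
  missing when the function is absent altogether.
* between-community index =
  ``1 - 2 sum_i min(P_Ai, P_Bi) / (sum_i P_Ai + sum_i P_Bi)``
  (Bray-Curtis form).  0 means the two communities encode the function with
  identical taxon frequency profiles; 1 means completely disjoint encoder
  sets.  With per-community normalized frequencies the denominator equals
  2; the full formula is kept so unnormalized inputs stay well-defined.

Edge conventions for pairs: function absent in exactly one community ->
index 1 (disjoint encoders); absent in both -> missing, excluded from
summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import bray_curtis, shannon_entropy
from .abundance import GeneProfile
from .core import (
    LEVELS,
    GenomeCatalog,
    UsageError,
    ValidationError,
)
from .mapping import OtuGenomeMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WithinFRResult:
    """Within-community redundancy of one function in one sample.

    ``fri_a`` is ``None`` iff the function is absent (``n_taxa == 0``);
    0 iff exactly one taxon encodes it; bounded by ``ln(n_taxa)``.
    """

    sample_id: str
    function_name: str
    level: str
    fri_a: Optional[float]
    n_taxa: int


@dataclass(frozen=True)
class BetweenFRResult:
    """Between-community redundancy of one function for one sample pair."""

    sample_a: str
    sample_b: str
    function_name: str
    level: str
    fri_b: Optional[float]


def fri_a(profile: GeneProfile) -> WithinFRResult:
    """Within-community functional redundancy index of one profile."""
    if profile.is_empty:
        return WithinFRResult(
            profile.sample_id, profile.function_name, profile.level, None, 0
        )
    if abs(profile.frequencies.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"profile frequencies sum to {profile.frequencies.sum()}, "
            "expected 1"
        )
    value = shannon_entropy(profile.frequencies)
    return WithinFRResult(
        profile.sample_id,
        profile.function_name,
        profile.level,
        value,
        profile.n_taxa,
    )


def _aligned_frequencies(
    profile_a: GeneProfile, profile_b: GeneProfile
) -> tuple[np.ndarray, np.ndarray]:
    taxa = sorted(set(profile_a.taxa) | set(profile_b.taxa))
    index = {t: i for i, t in enumerate(taxa)}
    fa = np.zeros(len(taxa))
    fb = np.zeros(len(taxa))
    for t, f in zip(profile_a.taxa, profile_a.frequencies):
        fa[index[t]] = f
    for t, f in zip(profile_b.taxa, profile_b.frequencies):
        fb[index[t]] = f
    return fa, fb


def fri_b(profile_a: GeneProfile, profile_b: GeneProfile) -> BetweenFRResult:
    """Between-community functional redundancy index of a sample pair.

    Profiles must describe the same function at the same level; taxon
    vectors are aligned on the union of taxa (absent taxon = 0).
    """
    if profile_a.function_name != profile_b.function_name:
        raise UsageError(
            f"function mismatch: {profile_a.function_name!r} vs "
            f"{profile_b.function_name!r}"
        )
    if profile_a.level != profile_b.level:
        raise UsageError(
            f"level mismatch: {profile_a.level!r} vs {profile_b.level!r}"
        )
    if profile_a.is_empty and profile_b.is_empty:
        value: Optional[float] = None
    elif profile_a.is_empty or profile_b.is_empty:
        value = 1.0
    else:
        fa, fb = _aligned_frequencies(profile_a, profile_b)
        value = bray_curtis(fa, fb)
    return BetweenFRResult(
        profile_a.sample_id,
        profile_b.sample_id,
        profile_a.function_name,
        profile_a.level,
        value,
    )


def aggregate_level(
    profile: GeneProfile,
    level: str,
    otu_map: OtuGenomeMap,
    catalog: GenomeCatalog,
) -> GeneProfile:
    """Merge an OTU-level profile to a coarser taxonomic level.

    Abundances are summed within the coarser lineage label of each OTU's
    assigned genome and frequencies renormalized.  Because merging can only
    pool probability mass, the entropy-form index never increases under
    aggregation.
    """
    if profile.level != "otu":
        raise UsageError(
            f"can only aggregate from otu level, got {profile.level!r}"
        )
    if level not in LEVELS:
        raise ValidationError(f"unknown level {level!r}")
    if level == "otu":
        return profile
    merged: Dict[str, float] = {}
    for otu_id, ab in zip(profile.taxa, profile.gene_abundance):
        genome_id = otu_map.genome_for(otu_id)
        if genome_id is None:
            raise ValidationError(
                f"OTU {otu_id!r} in profile has no genome assignment; "
                "lineage unavailable"
            )
        label = catalog[genome_id].lineage_label(level)
        merged[label] = merged.get(label, 0.0) + float(ab)
    return GeneProfile.from_abundances(
        profile.sample_id, profile.function_name, level, merged
    )


def is_redundant_within(profile: GeneProfile) -> bool:
    """True iff >= 2 taxa encode the function (index > 0).

    Raises on an empty profile: absence is not non-redundancy.
    """
    if profile.is_empty:
        raise UsageError(
            "redundancy is undefined for an absent function (empty profile)"
        )
    return profile.n_taxa >= 2


def fri_b_matrix(
    profiles: Sequence[GeneProfile],
    environments: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise between-community indices.

    All profiles must describe one function at one level.  When
    ``environments`` (sample id -> label) is given, only pairs sharing a
    label are computed; other cells are NaN.  The diagonal is 0 by
    convention.
    """
    if len(profiles) < 2:
        raise UsageError("need at least 2 profiles for a pairwise matrix")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids among profiles")
    n = len(profiles)
    matrix = np.full((n, n), np.nan)
    np.fill_diagonal(matrix, 0.0)
    n_pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        if environments is not None:
            env_i = environments.get(ids[i])
            env_j = environments.get(ids[j])
            if env_i is None or env_i != env_j:
                continue
        res = fri_b(profiles[i], profiles[j])
        v = math.nan if res.fri_b is None else res.fri_b
        matrix[i, j] = matrix[j, i] = v
        n_pairs += 1
    if n_pairs == 0:
        logger.warning("no sample pairs after environment filtering")
    return pd.DataFrame(matrix, index=ids, columns=ids)


def summarize(
    results: pd.DataFrame,
    value_col: str,
    group_col: str,
) -> pd.DataFrame:
    """Per-group distribution summary of a redundancy-index column.

    Returns one row per group with median, 25th/75th and 10th/90th
    percentiles (linear interpolation), the fraction of non-missing values
    that are > 0 (``proportion_redundant``), and the non-missing count
    ``n``.  Groups whose values are all missing are emitted with ``n = 0``
    and NaN statistics.
    """
    if results.empty:
        raise UsageError("cannot summarize an empty results table")
    rows: List[Dict[str, object]] = []
    for group, sub in results.groupby(group_col, sort=True):
        values = sub[value_col].dropna().to_numpy(dtype=float)
        if values.size == 0:
            rows.append(
                {
                    group_col: group,
                    "median": math.nan,
                    "p25": math.nan,
                    "p75": math.nan,
                    "p10": math.nan,
                    "p90": math.nan,
                    "proportion_redundant": math.nan,
                    "n": 0,
                }
            )
            continue
        q10, q25, q50, q75, q90 = np.percentile(
            values, [10, 25, 50, 75, 90], method="linear"
        )
        rows.append(
            {
                group_col: group,
                "median": float(q50),
                "p25": float(q25),
                "p75": float(q75),
                "p10": float(q10),
                "p90": float(q90),
                "proportion_redundant": float((values > 0).mean()),
                "n": int(values.size),
            }
        )
    return pd.DataFrame(rows)
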