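"""High-level orchestration: from validated inputs to result tables.

These functions are the library surface the command-line tool wraps: they
chain rarefaction, gene-profile construction, both redundancy indices,
diversity and the association statistics, and return plain DataFrames in
the long formats the writers expect.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .abundance import (
    DEFAULT_FUNCTION_SETS,
    GeneProfile,
    build_gene_profile,
    gene_per_cell,
)
from .core import (
    CommunityProfileSet,
    FunctionSet,
    GenomeCatalog,
    UsageError,
)
from .mapping import OtuGenomeMap
from .redundancy import fri_a, fri_b


def compute_profiles(
    profile_set: CommunityProfileSet,
    otu_map: OtuGenomeMap,
    catalog: GenomeCatalog,
    functions: Mapping[str, FunctionSet],
    level: str = "otu",
) -> Dict[Tuple[str, str], GeneProfile]:
    """Gene profiles for every (sample, function) at one level."""
    out: Dict[Tuple[str, str], GeneProfile] = {}
    for i, sid in enumerate(profile_set.sample_ids):
        counts = {
            otu: int(c)
            for otu, c in zip(profile_set.otu_ids, profile_set.counts[i])
            if c > 0
        }
        for name, fn in functions.items():
            out[(sid, name)] = build_gene_profile(
                counts, otu_map, catalog, fn, level=level, sample_id=sid
            )
    return out


def within_fr_table(
    profile_set: CommunityProfileSet,
    otu_map: OtuGenomeMap,
    catalog: GenomeCatalog,
    functions: Optional[Mapping[str, FunctionSet]] = None,
    levels: Sequence[str] = ("otu",),
) -> pd.DataFrame:
    """Long table of within-community indices per (sample, function, level)."""
    functions = functions or DEFAULT_FUNCTION_SETS
    rows = []
    for level in levels:
        profiles = compute_profiles(
            profile_set, otu_map, catalog, functions, level=level
        )
        for (sid, fname), profile in profiles.items():
            res = fri_a(profile)
            rows.append(
                {
                    "sample_id": sid,
                    "function_name": fname,
                    "level": level,
                    "fri_a": math.nan if res.fri_a is None else res.fri_a,
                    "n_taxa": res.n_taxa,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "function_name", "level", "fri_a", "n_taxa"]
    )


def between_fr_table(
    profile_set: CommunityProfileSet,
    otu_map: OtuGenomeMap,
    catalog: GenomeCatalog,
    functions: Optional[Mapping[str, FunctionSet]] = None,
    level: str = "otu",
    within_environment: Optional[str] = None,
) -> pd.DataFrame:
    """Long table of between-community indices per (pair, function).

    With ``within_environment`` set to a metadata field name, only sample
    pairs sharing that label are compared (the per-environment pairing
    convention).
    """
    if profile_set.n_samples < 2:
        raise UsageError("need at least 2 samples for pairwise indices")
    functions = functions or DEFAULT_FUNCTION_SETS
    labels = None
    if within_environment is not None:
        labels = {
            sid: getattr(profile_set.metadata[sid], within_environment)
            for sid in profile_set.sample_ids
        }
    profiles = compute_profiles(profile_set, otu_map, catalog, functions, level)
    rows = []
    ids = profile_set.sample_ids
    for sa, sb in itertools.combinations(ids, 2):
        if labels is not None and (not labels[sa] or labels[sa] != labels[sb]):
            continue
        for fname in functions:
            res = fri_b(profiles[(sa, fname)], profiles[(sb, fname)])
            rows.append(
                {
                    "sample_a": sa,
                    "sample_b": sb,
                    "function_name": fname,
                    "level": level,
                    "fri_b": math.nan if res.fri_b is None else res.fri_b,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "function_name", "level", "fri_b"]
    )


def gene_per_cell_table(
    profile_set: CommunityProfileSet,
    otu_map: OtuGenomeMap,
    catalog: GenomeCatalog,
    functions: Optional[Mapping[str, FunctionSet]] = None,
) -> pd.DataFrame:
    """Gene/cell values per (sample, function)."""
    functions = functions or DEFAULT_FUNCTION_SETS
    rows = []
    for i, sid in enumerate(profile_set.sample_ids):
        counts = {
            otu: int(c)
            for otu, c in zip(profile_set.otu_ids, profile_set.counts[i])
            if c > 0
        }
        for name, fn in functions.items():
            gpc = gene_per_cell(counts, otu_map, catalog, fn, sample_id=sid)
            rows.append(
                {
                    "sample_id": sid,
                    "function_name": name,
                    "gene_per_cell": math.nan if gpc.value is None else gpc.value,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "function_name", "gene_per_cell"]
    )


def attach_environment(
    table: pd.DataFrame,
    profile_set: CommunityProfileSet,
    field: str = "environment_level3",
) -> pd.DataFrame:
    """Annotate a results table with environment labels.

    For within tables (``sample_id`` column) one label column is added;
    for between tables both samples' labels are added.
    """
    env = {
        sid: getattr(profile_set.metadata[sid], field)
        for sid in profile_set.sample_ids
    }
    out = table.copy()
    if "sample_id" in out.columns:
        out["environment"] = out["sample_id"].map(env)
    elif {"sample_a", "sample_b"} <= set(out.columns):
        out["environment_a"] = out["sample_a"].map(env)
        out["environment_b"] = out["sample_b"].map(env)
    else:
        raise UsageError("table has neither sample_id nor sample pair columns")
    return out


def parse_function_config(text: str) -> Dict[str, FunctionSet]:
    """Parse a ``name: fam1,fam2,...`` per-line function-set config."""
    out: Dict[str, FunctionSet] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise UsageError(
                f"function config line {lineno}: expected 'name: fam,fam,...'"
            )
        name, fams = line.split(":", 1)
        families = frozenset(
            f.strip() for f in fams.split(",") if f.strip()
        )
        fn = FunctionSet(name.strip(), families)
        if fn.name in out:
            raise UsageError(
                f"function config line {lineno}: duplicate name {fn.name!r}"
            )
        out[fn.name] = fn
    if not out:
        raise UsageError("function config defines no function sets")
    return out


def parse_association_config(text: str) -> list[tuple[str, str, str]]:
    """Parse per-line ``response,covariate,method`` association requests."""
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise UsageError(
                f"association config line {lineno}: expected "
                "'response,covariate,method'"
            )
        out.append((parts[0], parts[1], parts[2]))
    if not out:
        raise UsageError("association config defines no requests")
    return out
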