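"""Readers and writers for every external format the tool touches.

All tabular formats are TSV with a single header row.  BLAST hits are the
standard 12-column tabular dialect (``-outfmt 6``); phylogenies are Newick.
Readers validate eagerly and raise :class:`~funred.core.FormatError` or
:class:`~funred.core.ValidationError` with coordinates rather than silently
coercing.  The sole missing-value token in outputs is ``"NA"``.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import (
    ENVIRONMENT_FIELDS,
    NUMERIC_METADATA_FIELDS,
    CommunityProfileSet,
    FormatError,
    GenomeCatalog,
    GenomeRecord,
    IdentityHit,
    MetadataRecord,
    PhyloTree,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Missing-value token used in every output file.
NA_TOKEN = "NA"


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed TSV: {exc}") from exc


def read_otu_table(
    path: PathLike, orientation: str = "samples_as_rows"
) -> CommunityProfileSet:
    """Read a read-count table into a :class:`CommunityProfileSet`.

    ``orientation`` says what the rows of the file are:
    ``"samples_as_rows"`` (default) or ``"otus_as_rows"``.  The returned
    object has empty metadata; attach metadata with :func:`read_metadata`.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate column id {dup!r}")
    counts = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        for i, v in enumerate(numeric):
            if math.isnan(v) or v < 0 or v != int(v):
                raise FormatError(
                    f"{path}: cell at row {df.index[i]!r}, column {col!r} "
                    f"is not a non-negative integer: {df[col].iloc[i]!r}"
                )
            counts[i, j] = int(v)
    if orientation == "otus_as_rows":
        return CommunityProfileSet(list(df.columns), list(df.index), counts.T)
    return CommunityProfileSet(list(df.index), list(df.columns), counts)


def read_genome_catalog(path: PathLike) -> GenomeCatalog:
    """Read a genome annotation catalog.

    Columns: ``genome_id, phylum, class, genus, n_16S`` then one column per
    GH family holding non-negative integer gene counts.
    """
    df = _read_tsv(path, dtype=str)
    required = ["genome_id", "phylum", "class", "genus", "n_16S"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    family_cols = [c for c in df.columns if c not in required]
    records: List[GenomeRecord] = []
    for _, row in df.iterrows():
        gid = row["genome_id"]
        try:
            n16 = int(row["n_16S"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: genome {gid!r}: n_16S is not an integer: "
                f"{row['n_16S']!r}"
            ) from None
        if n16 < 1:
            raise ValidationError(
                f"{path}: genome {gid!r} has n_16S={n16}; at least one 16S "
                "gene is required (cell abundance divides by this count)"
            )
        gene_counts: Dict[str, int] = {}
        for fam in family_cols:
            raw = row[fam]
            try:
                n = int(raw) if not pd.isna(raw) else 0
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: genome {gid!r}, family {fam!r}: gene count is "
                    f"not an integer: {raw!r}"
                ) from None
            if n < 0:
                raise FormatError(
                    f"{path}: genome {gid!r}, family {fam!r}: negative gene "
                    f"count {n}"
                )
            gene_counts[fam] = n
        records.append(
            GenomeRecord(
                genome_id=gid,
                phylum=row["phylum"],
                class_=row["class"],
                genus=row["genus"],
                rrna16s_copies=n16,
                gene_counts=gene_counts,
            )
        )
    return GenomeCatalog(records)


def write_genome_catalog(catalog: GenomeCatalog, path: PathLike) -> None:
    """Write a catalog in the format :func:`read_genome_catalog` reads."""
    families = sorted(catalog.family_universe)
    rows = []
    for rec in sorted(catalog, key=lambda r: r.genome_id):
        row = {
            "genome_id": rec.genome_id,
            "phylum": rec.phylum,
            "class": rec.class_,
            "genus": rec.genus,
            "n_16S": rec.rrna16s_copies,
        }
        for fam in families:
            row[fam] = rec.gene_counts.get(fam, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_blast_tabular(path: PathLike) -> List[IdentityHit]:
    """Parse BLAST tabular (outfmt 6) hits, preserving row order.

    Columns used: qseqid (OTU), sseqid (genome), pident, bitscore.  Extra
    columns beyond the standard 12 are ignored for interoperability with
    common outfmt-6 variants.
    """
    hits: List[IdentityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                bitscore = float(fields[11])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric pident or bitscore"
                ) from None
            try:
                hits.append(
                    IdentityHit(
                        otu_id=fields[0],
                        genome_id=fields[1],
                        percent_identity=pident,
                        bitscore=bitscore,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return hits


def read_newick(path: PathLike) -> PhyloTree:
    """Read a single rooted Newick tree; absent branch lengths become 0."""
    try:
        # keep underscores literal: OTU ids routinely contain them
        tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"{path}: Newick parse error: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path: PathLike) -> None:
    tree.tree.write(str(path), format="newick")


def read_metadata(path: PathLike) -> Dict[str, MetadataRecord]:
    """Read per-sample metadata; empty cells are missing, never 0.

    Recognized columns: ``sample_id``, the three environment levels and the
    six numeric covariates.  Unrecognized columns are ignored with a logged
    warning.
    """
    df = _read_tsv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    recognized = ("sample_id",) + ENVIRONMENT_FIELDS + NUMERIC_METADATA_FIELDS
    unknown = [c for c in df.columns if c not in recognized]
    if unknown:
        logger.warning("%s: ignoring unrecognized columns %s", path, unknown)
    out: Dict[str, MetadataRecord] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        kwargs: Dict[str, object] = {}
        for col in ENVIRONMENT_FIELDS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = row[col]
        for col in NUMERIC_METADATA_FIELDS:
            if col in df.columns and not pd.isna(row[col]) and row[col] != NA_TOKEN:
                try:
                    kwargs[col] = float(row[col])
                except ValueError:
                    raise FormatError(
                        f"{path}: sample {sid!r}, column {col!r}: "
                        f"non-numeric value {row[col]!r}"
                    ) from None
        try:
            out[sid] = MetadataRecord(**kwargs)  # type: ignore[arg-type]
        except ValidationError as exc:
            raise ValidationError(f"{path}: sample {sid!r}: {exc}") from None
    return out


def write_metadata(metadata: Dict[str, MetadataRecord], path: PathLike) -> None:
    rows = []
    for sid in sorted(metadata):
        rec = metadata[sid]
        row: Dict[str, object] = {"sample_id": sid}
        for col in ENVIRONMENT_FIELDS:
            row[col] = getattr(rec, col)
        for col in NUMERIC_METADATA_FIELDS:
            row[col] = getattr(rec, col)
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g"
    )


def read_gene_abundance_table(
    path: PathLike,
) -> Dict[str, Dict[Tuple[str, str], float]]:
    """Read a metagenome gene-abundance table (e.g. TPM).

    Columns: ``sample_id, taxon_id, family, abundance``.  Duplicate
    (sample, taxon, family) rows are summed.  This is the alternate entry
    path that bypasses OTU->genome mapping and copy-number correction.
    """
    try:
        df = _read_tsv(path)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    required = ["sample_id", "taxon_id", "family", "abundance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out: Dict[str, Dict[Tuple[str, str], float]] = {}
    for _, row in df.iterrows():
        ab = float(row["abundance"])
        if math.isnan(ab) or ab < 0:
            raise ValidationError(
                f"{path}: negative or missing abundance for sample "
                f"{row['sample_id']!r}, taxon {row['taxon_id']!r}, family "
                f"{row['family']!r}: {row['abundance']!r}"
            )
        key = (str(row["taxon_id"]), str(row["family"]))
        per_sample = out.setdefault(str(row["sample_id"]), {})
        per_sample[key] = per_sample.get(key, 0.0) + ab
    return out


def write_results(table: pd.DataFrame, path: PathLike) -> None:
    """Write a results table as TSV.

    Floats are rendered with 12 significant digits, NaN as ``"NA"``, and
    rows are sorted by the non-numeric key columns so output bytes are
    deterministic.
    """
    df = table.copy()
    key_cols = [
        c for c in df.columns
        if not pd.api.types.is_float_dtype(df[c])
    ]
    if key_cols and len(df):
        df = df.sort_values(key_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(
        path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.12g"
    )


def read_results(path: PathLike) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return _read_tsv(path, na_values=[NA_TOKEN], keep_default_na=False)
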