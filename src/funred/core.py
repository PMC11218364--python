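"""Domain types shared by every stage of the functional-redundancy pipeline.

The pipeline relates two sides of a microbial community: the *abundance*
side (a samples x OTUs read-count table plus per-sample metadata) and the
*trait* side (a catalog of sequenced genomes annotated with 16S rRNA gene
copy numbers and per-family glycoside-hydrolase gene counts).  The types
here are thin validated containers; all arithmetic lives in the stage
modules.

Missing numeric metadata is represented as ``None`` — never 0, because 0 is
a legal value for pH, latitude, elevation and salinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode


class FunredError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FunredError):
    """A file does not conform to its declared format."""


class ValidationError(FunredError):
    """A value violates a domain invariant."""


class UsageError(FunredError):
    """The caller combined operations or arguments incorrectly."""


class ConfigError(FunredError):
    """A simulation or run configuration is self-inconsistent."""


#: Taxonomic ranks carried in a genome lineage, coarse to fine.
RANKS: tuple[str, ...] = ("phylum", "class", "genus")

#: Aggregation levels for gene profiles, coarse to fine ("otu" is finest).
LEVELS: tuple[str, ...] = ("phylum", "class", "genus", "otu")


@dataclass(frozen=True)
class GenomeRecord:
    """One sequenced genome: lineage, 16S copy number and GH gene counts.

    ``rrna16s_copies`` is the number of 16S rRNA genes in the genome and is
    used to convert 16S read counts into cell counts; it must be >= 1.
    ``gene_counts`` maps a GH family id (e.g. ``"GH5"``) to the number of
    genes of that family in the genome.
    """

    genome_id: str
    phylum: str
    class_: str
    genus: str
    rrna16s_copies: int
    gene_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValidationError("genome_id must be non-empty")
        for rank in RANKS:
            if not self.lineage_label(rank):
                raise ValidationError(
                    f"genome {self.genome_id!r}: empty {rank} label"
                )
        if int(self.rrna16s_copies) != self.rrna16s_copies or self.rrna16s_copies < 1:
            raise ValidationError(
                f"genome {self.genome_id!r}: rrna16s_copies must be a "
                f"positive integer, got {self.rrna16s_copies!r}"
            )
        for fam, n in self.gene_counts.items():
            if int(n) != n or n < 0:
                raise ValidationError(
                    f"genome {self.genome_id!r}: gene count for {fam!r} must "
                    f"be a non-negative integer, got {n!r}"
                )

    def lineage_label(self, rank: str) -> str:
        """Return the lineage label at ``rank`` ('phylum'|'class'|'genus')."""
        if rank == "phylum":
            return self.phylum
        if rank == "class":
            return self.class_
        if rank == "genus":
            return self.genus
        raise UsageError(f"unknown rank {rank!r}; expected one of {RANKS}")


class GenomeCatalog:
    """A collection of :class:`GenomeRecord` keyed by genome id."""

    def __init__(self, records: Iterable[GenomeRecord]):
        self.records: Dict[str, GenomeRecord] = {}
        for rec in records:
            if rec.genome_id in self.records:
                raise FormatError(f"duplicate genome_id {rec.genome_id!r}")
            self.records[rec.genome_id] = rec

    @property
    def family_universe(self) -> frozenset[str]:
        """Union of GH family ids present across all genomes."""
        fams: set[str] = set()
        for rec in self.records.values():
            fams.update(rec.gene_counts)
        return frozenset(fams)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.records

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        try:
            return self.records[genome_id]
        except KeyError:
            raise ValidationError(
                f"genome {genome_id!r} not present in catalog"
            ) from None

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records.values())


#: Numeric metadata fields, in canonical column order.
NUMERIC_METADATA_FIELDS: tuple[str, ...] = (
    "latitude_deg",
    "longitude_deg",
    "elevation_m",
    "temperature_c",
    "ph",
    "salinity_psu",
)

ENVIRONMENT_FIELDS: tuple[str, ...] = (
    "environment_level1",
    "environment_level2",
    "environment_level3",
)


@dataclass
class MetadataRecord:
    """Per-sample metadata: opaque environment labels and numeric covariates.

    Environment labels follow a three-level habitat ontology (e.g.
    free-living/host-associated at level 1) but are treated as opaque
    grouping strings.  Absent numeric values are ``None``.
    """

    environment_level1: str = ""
    environment_level2: str = ""
    environment_level3: str = ""
    latitude_deg: Optional[float] = None
    longitude_deg: Optional[float] = None
    elevation_m: Optional[float] = None
    temperature_c: Optional[float] = None
    ph: Optional[float] = None
    salinity_psu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ph is not None and not 0.0 <= self.ph <= 14.0:
            raise ValidationError(f"pH {self.ph} outside [0, 14]")
        if self.latitude_deg is not None and not -90.0 <= self.latitude_deg <= 90.0:
            raise ValidationError(f"latitude {self.latitude_deg} outside [-90, 90]")
        if self.longitude_deg is not None and not -180.0 <= self.longitude_deg <= 180.0:
            raise ValidationError(
                f"longitude {self.longitude_deg} outside [-180, 180]"
            )

    def numeric(self, name: str) -> Optional[float]:
        if name not in NUMERIC_METADATA_FIELDS:
            raise UsageError(
                f"unknown numeric metadata field {name!r}; "
                f"expected one of {NUMERIC_METADATA_FIELDS}"
            )
        return getattr(self, name)


class CommunityProfileSet:
    """Samples x OTUs read-count matrix plus per-sample metadata.

    ``counts[i, j]`` is the number of reads of OTU ``otu_ids[j]`` in sample
    ``sample_ids[i]``.  Counts are non-negative integers.  Every sample has
    a metadata entry; samples without supplied metadata get a blank record.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        otu_ids: Sequence[str],
        counts: np.ndarray,
        metadata: Optional[Mapping[str, MetadataRecord]] = None,
    ):
        self.sample_ids = list(sample_ids)
        self.otu_ids = list(otu_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise FormatError(f"duplicate {name} id {x!r}")
                seen.add(x)
        if counts.size and (
            not np.issubdtype(counts.dtype, np.integer)
            or (counts < 0).any()
        ):
            if np.issubdtype(counts.dtype, np.floating):
                bad = np.argwhere((counts % 1 != 0) | (counts < 0) | np.isnan(counts))
                if bad.size:
                    i, j = bad[0]
                    raise FormatError(
                        f"count for sample {self.sample_ids[i]!r}, OTU "
                        f"{self.otu_ids[j]!r} is not a non-negative integer: "
                        f"{counts[i, j]!r}"
                    )
                counts = counts.astype(np.int64)
            else:
                bad = np.argwhere(counts < 0)
                i, j = bad[0]
                raise FormatError(
                    f"negative count for sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}: {counts[i, j]}"
                )
        self.counts = counts.astype(np.int64, copy=False)
        self.metadata: Dict[str, MetadataRecord] = {}
        metadata = metadata or {}
        for sid in self.sample_ids:
            self.metadata[sid] = metadata.get(sid, MetadataRecord())

    def sample_counts(self, sample_id: str) -> pd.Series:
        """Counts of one sample as a Series indexed by OTU id."""
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise UsageError(f"unknown sample id {sample_id!r}") from None
        return pd.Series(self.counts[i], index=self.otu_ids, name=sample_id)

    def totals(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityProfileSet":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityProfileSet(
            [self.sample_ids[i] for i in idx],
            self.otu_ids,
            self.counts[idx],
            {self.sample_ids[i]: self.metadata[self.sample_ids[i]] for i in idx},
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a samples x OTUs DataFrame."""
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.otu_ids
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


@dataclass(frozen=True)
class FunctionSet:
    """A named union of GH families treated as one metabolic function.

    A single family is a valid function set of size one.
    """

    name: str
    families: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", frozenset(self.families))
        if not self.families:
            raise ValidationError(f"function set {self.name!r} has no families")

    @classmethod
    def single(cls, family: str) -> "FunctionSet":
        return cls(family, frozenset({family}))


@dataclass(frozen=True)
class IdentityHit:
    """One OTU-vs-genome alignment hit (the BLAST-tabular essentials)."""

    otu_id: str
    genome_id: str
    percent_identity: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"for hit {self.otu_id!r} vs {self.genome_id!r}"
            )
        if self.bitscore < 0:
            raise ValidationError(
                f"negative bitscore {self.bitscore} for hit "
                f"{self.otu_id!r} vs {self.genome_id!r}"
            )


class PhyloTree:
    """A rooted phylogeny over OTU ids with non-negative branch lengths.

    Missing branch lengths are treated as 0.  Wraps a scikit-bio TreeNode.
    """

    def __init__(self, tree: TreeNode):
        names = [tip.name for tip in tree.tips()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate leaf labels in tree: {sorted(dupes)}"
            )
        for node in tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
            elif node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} at node "
                    f"{node.name!r}"
                )
        self.tree = tree

    @property
    def leaf_names(self) -> list[str]:
        return [tip.name for tip in self.tree.tips()]

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(n.length for n in self.tree.traverse(include_self=True))
        )
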