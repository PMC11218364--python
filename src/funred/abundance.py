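"""From read counts and genome traits to per-taxon gene abundances.

The chain is: rarefy each sample to a fixed depth (default 5000 reads,
without replacement), convert an OTU's reads to estimated cells by
dividing by its genome's 16S rRNA gene copy number, then multiply cells by
the genome's gene count for the function of interest.  The resulting
per-taxon gene abundances, normalized to frequencies ``P_i``, are the
direct operand of both redundancy indices; the companion gene/cell
statistic is the average number of function genes carried per
(genome-mapped) cell.

Function *absence* (no mapped encoder at all) is an empty profile and is
kept distinct from a present-but-not-redundant function (a single encoding
taxon, index 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    LEVELS,
    CommunityProfileSet,
    FunctionSet,
    GenomeCatalog,
    GenomeRecord,
    ValidationError,
)
from .mapping import OtuGenomeMap

logger = logging.getLogger(__name__)

#: Default rarefaction depth (reads per sample).
DEFAULT_RAREFACTION_DEPTH = 5000

#: GH-family unions for the three classical polysaccharide-degrading
#: activities (CAZy-based groupings).
CELLULASES = FunctionSet(
    "cellulases", frozenset({"GH5", "GH6", "GH7", "GH8", "GH12", "GH44", "GH45", "GH48"})
)
XYLANASES = FunctionSet("xylanases", frozenset({"GH10", "GH11", "GH30"}))
CHITINASES = FunctionSet("chitinases", frozenset({"GH18", "GH19", "GH85"}))

DEFAULT_FUNCTION_SETS: Dict[str, FunctionSet] = {
    fs.name: fs for fs in (CELLULASES, XYLANASES, CHITINASES)
}

#: Default prevalence threshold: a family must appear in at least this many
#: samples to be analyzed.
DEFAULT_MIN_PREVALENCE = 125


def rarefy(
    profile: CommunityProfileSet,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
) -> CommunityProfileSet:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning.  Deterministic given ``seed`` (samples are processed in listed
    order with a single generator).
    """
    if depth < 1:
        raise ValidationError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    keep_rows: List[np.ndarray] = []
    keep_ids: List[str] = []
    for i, sid in enumerate(profile.sample_ids):
        row = profile.counts[i]
        total = int(row.sum())
        if total < depth:
            logger.warning(
                "sample %r has %d reads < depth %d; dropped", sid, total, depth
            )
            continue
        if total == depth:
            keep_rows.append(row.copy())
        else:
            keep_rows.append(rng.multivariate_hypergeometric(row, depth))
        keep_ids.append(sid)
    if not keep_ids:
        raise ValidationError("no samples at requested depth")
    counts = np.vstack(keep_rows).astype(np.int64)
    return CommunityProfileSet(
        keep_ids,
        profile.otu_ids,
        counts,
        {sid: profile.metadata[sid] for sid in keep_ids},
    )


def cells_from_reads(reads: float, rrna16s_copies: int) -> float:
    """Estimated cell count: 16S reads divided by 16S gene copies."""
    if rrna16s_copies < 1:
        raise ValidationError(
            f"rrna16s_copies must be >= 1, got {rrna16s_copies}"
        )
    if reads < 0:
        raise ValidationError(f"negative read count {reads}")
    return reads / rrna16s_copies


def function_gene_count(genome: GenomeRecord, fn: FunctionSet) -> int:
    """Number of genes in ``genome`` across the function's families."""
    return int(sum(genome.gene_counts.get(fam, 0) for fam in fn.families))


@dataclass
class GeneProfile:
    """Per-taxon gene abundances of one function in one sample.

    ``gene_abundance[i]`` = estimated cells of taxon i x genes per cell of
    taxon i; ``frequencies`` are those abundances normalized to sum to 1.
    Taxa with zero abundance are omitted, so an *empty* profile means the
    function is absent from the (mapped part of the) community.
    """

    sample_id: str
    function_name: str
    level: str
    taxa: Tuple[str, ...] = ()
    gene_abundance: np.ndarray = field(default_factory=lambda: np.empty(0))
    frequencies: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(
                f"unknown level {self.level!r}; expected one of {LEVELS}"
            )
        self.taxa = tuple(self.taxa)
        self.gene_abundance = np.asarray(self.gene_abundance, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not (
            len(self.taxa)
            == self.gene_abundance.size
            == self.frequencies.size
        ):
            raise ValidationError("taxa/abundance/frequency lengths differ")
        if (self.gene_abundance < 0).any():
            raise ValidationError("negative gene abundance")
        if self.taxa and abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"frequencies sum to {self.frequencies.sum()}, expected 1"
            )

    @classmethod
    def from_abundances(
        cls,
        sample_id: str,
        function_name: str,
        level: str,
        abundances: Mapping[str, float],
    ) -> "GeneProfile":
        """Build a profile from a taxon -> abundance map, dropping zeros."""
        items = sorted(
            (taxon, ab) for taxon, ab in abundances.items() if ab > 0
        )
        if not items:
            return cls(sample_id, function_name, level)
        taxa = tuple(t for t, _ in items)
        values = np.array([ab for _, ab in items], dtype=float)
        return cls(sample_id, function_name, level, taxa, values, values / values.sum())

    @property
    def is_empty(self) -> bool:
        return len(self.taxa) == 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def total_abundance(self) -> float:
        return float(self.gene_abundance.sum())


def _taxon_label(
    otu_id: str, genome: GenomeRecord, level: str
) -> str:
    if level == "otu":
        return otu_id
    return genome.lineage_label(level)


def build_gene_profile(
    counts: Mapping[str, int] | pd.Series,
    otu_map: OtuGenomeMap,
    catalog: GenomeCatalog,
    fn: FunctionSet,
    level: str = "otu",
    sample_id: str = "",
) -> GeneProfile:
    """Gene abundance profile of one function for one sample.

    ``counts`` maps OTU id to read count (one row of the community table).
    Only genome-mapped OTUs contribute; at levels coarser than ``otu``,
    abundances are summed over OTUs sharing the lineage label of their
    assigned genome.
    """
    if level not in LEVELS:
        raise ValidationError(
            f"unknown level {level!r}; expected one of {LEVELS}"
        )
    if isinstance(counts, pd.Series):
        sample_id = sample_id or str(counts.name or "")
        counts = counts.to_dict()
    abundances: Dict[str, float] = {}
    for otu_id, reads in counts.items():
        if reads <= 0:
            continue
        genome_id = otu_map.genome_for(otu_id)
        if genome_id is None:
            continue
        genome = catalog[genome_id]
        genes = function_gene_count(genome, fn)
        if genes == 0:
            continue
        ab = cells_from_reads(reads, genome.rrna16s_copies) * genes
        label = _taxon_label(otu_id, genome, level)
        abundances[label] = abundances.get(label, 0.0) + ab
    return GeneProfile.from_abundances(sample_id, fn.name, level, abundances)


@dataclass(frozen=True)
class GenePerCell:
    """Average number of function genes per genome-mapped cell.

    ``value`` is ``None`` when no mapped OTU has reads (undefined).
    """

    sample_id: str
    function_name: str
    value: Optional[float]


def gene_per_cell(
    counts: Mapping[str, int] | pd.Series,
    otu_map: OtuGenomeMap,
    catalog: GenomeCatalog,
    fn: FunctionSet,
    sample_id: str = "",
) -> GenePerCell:
    """Compute sum(cells_i * genes_i) / sum(cells_i) over mapped OTUs."""
    if isinstance(counts, pd.Series):
        sample_id = sample_id or str(counts.name or "")
        counts = counts.to_dict()
    num = 0.0
    den = 0.0
    for otu_id, reads in counts.items():
        if reads <= 0:
            continue
        genome_id = otu_map.genome_for(otu_id)
        if genome_id is None:
            continue
        genome = catalog[genome_id]
        cells = cells_from_reads(reads, genome.rrna16s_copies)
        num += cells * function_gene_count(genome, fn)
        den += cells
    if den == 0.0:
        logger.warning(
            "sample %r: no genome-mapped OTU with reads; gene/cell undefined",
            sample_id,
        )
        return GenePerCell(sample_id, fn.name, None)
    return GenePerCell(sample_id, fn.name, num / den)


def prevalence_filter(
    presence: pd.DataFrame, min_samples: int = DEFAULT_MIN_PREVALENCE
) -> Tuple[List[str], pd.Series]:
    """Retain functions present in at least ``min_samples`` samples.

    ``presence`` is a functions x samples table, boolean or numeric
    (nonzero = the function has gene abundance in that sample).  Returns
    (retained function names, per-function sample counts of the dropped
    functions).  The boundary is inclusive: exactly ``min_samples`` is
    retained.
    """
    if min_samples < 1:
        raise ValidationError(f"min_samples must be >= 1, got {min_samples}")
    counts = (presence.astype(float) != 0).sum(axis=1)
    retained = [str(f) for f in counts.index[counts >= min_samples]]
    dropped = counts[counts < min_samples]
    if len(dropped):
        logger.info(
            "prevalence filter dropped %d function(s): %s",
            len(dropped),
            dict(dropped),
        )
    return retained, dropped


def profiles_from_gene_table(
    table: Mapping[str, Mapping[Tuple[str, str], float]],
    fn: FunctionSet,
) -> Dict[str, GeneProfile]:
    """Gene profiles straight from a metagenome gene-abundance table.

    ``table`` is the output of :func:`funred.io.read_gene_abundance_table`:
    per sample, (taxon, family) -> abundance.  Families in ``fn`` are summed
    per taxon; copy-number correction does not apply (abundances are already
    per-gene, e.g. TPM).
    """
    out: Dict[str, GeneProfile] = {}
    for sample_id, entries in table.items():
        abundances: Dict[str, float] = {}
        for (taxon, family), ab in entries.items():
            if family in fn.families and ab > 0:
                abundances[taxon] = abundances.get(taxon, 0.0) + ab
        out[sample_id] = GeneProfile.from_abundances(
            sample_id, fn.name, "otu", abundances
        )
    return out
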