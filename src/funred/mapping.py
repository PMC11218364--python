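"""Assign OTUs to sequenced genomes by 16S (V4) sequence identity.

An OTU is linked to a genome when their 16S sequences align at >= 97%
identity (the classical species-level OTU threshold; 97.0 passes, 96.9
does not).  Hits normally come from a precomputed BLAST tabular file; for
desk-scale inputs a built-in global aligner computes identities directly
from FASTA.

Identity convention: global (Needleman-Wunsch) alignment under match +1,
mismatch 0, linear gap -1 — the scoring only selects the alignment —
then identity = 100 x exact matches / alignment columns, gap columns
included in the denominator.  ``N`` never counts as a match.  This mirrors
the BLAST ``pident`` convention at desk scale.

When several genomes clear the threshold for one OTU, the single best is
kept, ordered by (identity, bitscore, lexicographically smallest genome
id); merging or averaging over co-optimal genomes is deliberately not done
so the pipeline stays reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .core import FormatError, IdentityHit, ValidationError
from .io import NA_TOKEN

PathLike = Union[str, Path]

_VALID_SEQ = re.compile(r"^[ACGTN]+$")

#: Default assignment threshold (percent identity).
DEFAULT_IDENTITY_THRESHOLD = 97.0


def _make_aligner() -> PairwiseAligner:
    # match +1, mismatch 0, N scores 0 against everything; linear gap -1.
    # Score ties are broken canonically — most matches, then fewest gap
    # columns — via perturbations far below the integer score granularity
    # (valid for sequences up to ~10^3 bp), so the reported identity is
    # deterministic and symmetric in its arguments.
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for base in "ACGT":
        matrix[base, base] = 1.0 + 1e-4
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -1.0 - 1e-8
    aligner.extend_gap_score = -1.0 - 1e-8
    return aligner


_ALIGNER = _make_aligner()


def _validate_sequence(seq: str, label: str) -> str:
    s = str(seq).upper()
    if not s:
        raise ValidationError(f"{label}: empty sequence")
    if not _VALID_SEQ.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValidationError(
            f"{label}: sequence contains characters outside ACGTN: {bad}"
        )
    return s


def _align_identity(seq_a: str, seq_b: str) -> Tuple[float, int]:
    """Return (percent identity, match count) for one optimal alignment."""
    a = _validate_sequence(seq_a, "sequence A")
    b = _validate_sequence(seq_b, "sequence B")
    alignment = _ALIGNER.align(a, b)[0]
    row_a, row_b = alignment[0], alignment[1]
    matches = sum(
        1
        for ca, cb in zip(row_a, row_b)
        if ca == cb and ca in "ACGT"
    )
    columns = len(row_a)
    return 100.0 * matches / columns, matches


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two nucleotide sequences under global alignment.

    100 x matches / alignment columns (gap columns included); ``N`` never
    matches.  Case-insensitive; symmetric; ``pid(a, a) = 100`` for any
    N-free sequence.
    """
    pid, _ = _align_identity(seq_a, seq_b)
    return pid


def _read_fasta(path: PathLike) -> List[Tuple[str, str]]:
    records: List[Tuple[str, str]] = []
    seen: Set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def hits_from_fasta(otus_path: PathLike, refs_path: PathLike) -> List[IdentityHit]:
    """All-vs-all identity hits between OTU and reference 16S FASTA files.

    One hit per (OTU, reference) pair.  The bitscore field carries the
    alignment match count, a documented proxy sufficient for the
    deterministic tie-breaking in :func:`assign_genomes`.
    """
    otus = _read_fasta(otus_path)
    refs = _read_fasta(refs_path)
    hits: List[IdentityHit] = []
    for otu_id, otu_seq in otus:
        for ref_id, ref_seq in refs:
            pid, matches = _align_identity(otu_seq, ref_seq)
            hits.append(
                IdentityHit(
                    otu_id=otu_id,
                    genome_id=ref_id,
                    percent_identity=pid,
                    bitscore=float(matches),
                )
            )
    return hits


@dataclass
class OtuGenomeMap:
    """Result of OTU->genome assignment at a fixed identity threshold."""

    assignments: Dict[str, str]
    unassigned: Set[str] = field(default_factory=set)
    threshold_pct: float = DEFAULT_IDENTITY_THRESHOLD

    def __post_init__(self) -> None:
        overlap = set(self.assignments) & self.unassigned
        if overlap:
            raise ValidationError(
                f"OTUs both assigned and unassigned: {sorted(overlap)[:5]}"
            )

    @property
    def otu_universe(self) -> Set[str]:
        return set(self.assignments) | self.unassigned

    def genome_for(self, otu_id: str) -> str | None:
        return self.assignments.get(otu_id)


def assign_genomes(
    otu_ids: Sequence[str],
    hits: Iterable[IdentityHit],
    threshold_pct: float = DEFAULT_IDENTITY_THRESHOLD,
) -> OtuGenomeMap:
    """Pick the best genome per OTU among hits at >= ``threshold_pct``.

    Candidate order: highest percent identity, then highest bitscore, then
    lexicographically smallest genome id.  OTUs with no candidate go to
    ``unassigned``.  The result is invariant under permutation of ``hits``.
    """
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValidationError(
            f"threshold {threshold_pct} outside [0, 100]"
        )
    otu_set = set(otu_ids)
    best: Dict[str, IdentityHit] = {}
    for hit in hits:
        if hit.otu_id not in otu_set:
            raise ValidationError(
                f"hit references unknown OTU {hit.otu_id!r}"
            )
        if hit.percent_identity < threshold_pct:
            continue
        cur = best.get(hit.otu_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.otu_id] = hit
    assignments = {otu: h.genome_id for otu, h in best.items()}
    unassigned = otu_set - set(assignments)
    return OtuGenomeMap(
        assignments=assignments,
        unassigned=unassigned,
        threshold_pct=threshold_pct,
    )


def _hit_rank(hit: IdentityHit) -> Tuple[float, float, str]:
    # smaller rank wins: maximize identity then bitscore, minimize genome id
    return (-hit.percent_identity, -hit.bitscore, hit.genome_id)


def write_mapping(mapping: OtuGenomeMap, path: PathLike) -> None:
    """Serialize as 2-column TSV; unassigned OTUs carry genome_id ``NA``."""
    rows = [
        {"otu_id": otu, "genome_id": genome}
        for otu, genome in sorted(mapping.assignments.items())
    ]
    rows += [
        {"otu_id": otu, "genome_id": NA_TOKEN}
        for otu in sorted(mapping.unassigned)
    ]
    pd.DataFrame(rows, columns=["otu_id", "genome_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_mapping(
    path: PathLike, threshold_pct: float = DEFAULT_IDENTITY_THRESHOLD
) -> OtuGenomeMap:
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False
    )
    for col in ("otu_id", "genome_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    assignments: Dict[str, str] = {}
    unassigned: Set[str] = set()
    for _, row in df.iterrows():
        if pd.isna(row["genome_id"]):
            unassigned.add(row["otu_id"])
        else:
            assignments[row["otu_id"]] = row["genome_id"]
    return OtuGenomeMap(assignments, unassigned, threshold_pct)
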