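"""Deterministic generators for every input the pipeline consumes.

The generators emulate the statistical structure of a large amplicon
survey joined to a genome catalog: a catalog of genomes with integer 16S
copy numbers, Poisson gene counts per GH family and a nested 3-level
lineage; Dirichlet-multinomial community read counts with controllable
richness, evenness and between-sample turnover; 16S-like sequences whose
OTU-vs-reference identity is known exactly by construction; metadata
covariates coupled to richness; and a random coalescent-style tree for
phylogenetic diversity.  Every generator is deterministic per seed, and
truth tables are returned alongside each fixture so downstream tests never
re-derive hidden parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import (
    CommunityProfileSet,
    ConfigError,
    GenomeCatalog,
    GenomeRecord,
    IdentityHit,
    MetadataRecord,
    PhyloTree,
)
from . import io as fio
from .mapping import write_mapping, OtuGenomeMap

PathLike = Union[str, Path]

#: Families named after the classical polysaccharide-degradation groupings
#: first, then generic fill-in families.
_TYPICAL_FAMILIES = (
    "GH5", "GH6", "GH7", "GH8", "GH12", "GH44", "GH45", "GH48",  # cellulases
    "GH10", "GH11", "GH30",                                       # xylanases
    "GH18", "GH19", "GH85",                                       # chitinases
)


def family_names(n_families: int) -> List[str]:
    """First ``n_families`` GH family names, typical groupings first."""
    if n_families < 1:
        raise ConfigError("n_families must be >= 1")
    names = list(_TYPICAL_FAMILIES[:n_families])
    k = 1
    while len(names) < n_families:
        candidate = f"GH{k}"
        if candidate not in names:
            names.append(candidate)
        k += 1
    return names


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the desk-scale study conditions the pipeline is
    validated under: 200 samples, per-sample richness drawn from 5-150
    taxa, mid-range evenness and turnover, Poisson(1) gene counts per
    family, 16S copy numbers uniform on 1-15, reads at depth 10000 so that
    rarefaction to 5000 keeps every sample.
    """

    seed: int = 0
    n_samples: int = 200
    n_genomes: int = 200
    n_families: int = 30
    richness_range: Tuple[int, int] = (5, 150)
    evenness: float = 0.5
    gene_count_mean: float = 1.0
    copy_number_range: Tuple[int, int] = (1, 15)
    turnover: float = 0.5
    env_effect: float = 0.8
    read_depth: int = 10000
    seq_length: int = 250
    divergence_mean: float = 3.0
    n_environments: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.richness_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"richness_range {self.richness_range} not ordered")
        if hi > self.n_genomes:
            raise ConfigError(
                f"max richness {hi} exceeds n_genomes {self.n_genomes}"
            )
        clo, chi = self.copy_number_range
        if not (1 <= clo <= chi):
            raise ConfigError(
                f"copy_number_range {self.copy_number_range} not ordered"
            )
        if not 0.0 < self.evenness <= 1.0:
            raise ConfigError(f"evenness {self.evenness} outside (0, 1]")
        if not 0.0 <= self.turnover <= 1.0:
            raise ConfigError(f"turnover {self.turnover} outside [0, 1]")
        if self.gene_count_mean < 0:
            raise ConfigError("gene_count_mean must be >= 0")
        if self.read_depth < 1 or self.n_samples < 1:
            raise ConfigError("read_depth and n_samples must be >= 1")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _genome_ids(cfg: SimulationConfig) -> List[str]:
    width = len(str(cfg.n_genomes))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genomes + 1)]


def otu_id_for(genome_id: str) -> str:
    """OTU id paired with a genome id in synthetic fixtures."""
    return f"OTU_{genome_id}"


def make_catalog(cfg: SimulationConfig) -> GenomeCatalog:
    """Synthetic genome catalog.

    Gene counts per family are Poisson(``gene_count_mean``); 16S copy
    numbers are uniform integers on ``copy_number_range``; lineages come
    from a nested 3-level hierarchy (genus labels determine class and
    phylum by construction, so aggregation is well-defined).
    """
    rng = _rng(cfg, 1)
    families = family_names(cfg.n_families)
    n_phyla = max(2, cfg.n_genomes // 50 + 2)
    records = []
    for gid in _genome_ids(cfg):
        p = rng.integers(1, n_phyla + 1)
        c = rng.integers(1, 4)
        g = rng.integers(1, 5)
        phylum = f"p{p:02d}"
        class_ = f"{phylum}.c{c}"
        genus = f"{class_}.g{g}"
        counts = {
            fam: int(k)
            for fam, k in zip(
                families, rng.poisson(cfg.gene_count_mean, size=len(families))
            )
        }
        copies = int(
            rng.integers(cfg.copy_number_range[0], cfg.copy_number_range[1] + 1)
        )
        records.append(
            GenomeRecord(
                genome_id=gid,
                phylum=phylum,
                class_=class_,
                genus=genus,
                rrna16s_copies=copies,
                gene_counts=counts,
            )
        )
    return GenomeCatalog(records)


def make_communities(
    cfg: SimulationConfig, catalog: GenomeCatalog
) -> Tuple[CommunityProfileSet, pd.DataFrame]:
    """Community read counts plus a per-sample truth table.

    Per sample: a latent environmental covariate z ~ N(0, 1); richness is
    the ``richness_range`` quantile of a mixture correlated with z at
    level ``env_effect`` (0 = uncoupled); the taxon pool mixes a shared
    core (fraction ``1 - turnover``, taken in a fixed core order so
    turnover 0 gives identical pools) with uniform draws from the
    remaining genomes; relative abundances are Dirichlet with
    concentration ``evenness / (1 - evenness)`` (uniform at evenness 1);
    reads are multinomial at ``read_depth``.
    """
    rng = _rng(cfg, 2)
    genome_ids = sorted(catalog.records)
    core_order = list(rng.permutation(genome_ids))
    n = cfg.n_samples
    lo, hi = cfg.richness_range
    z = rng.normal(size=n)
    eps = rng.normal(size=n)
    e = min(max(cfg.env_effect, 0.0), 1.0)
    latent = e * z + math.sqrt(max(0.0, 1.0 - e * e)) * eps
    u = 0.5 * (1.0 + np.vectorize(math.erf)(latent / math.sqrt(2.0)))
    richness = np.clip(np.round(lo + (hi - lo) * u).astype(int), lo, hi)

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    rows: Dict[str, Dict[str, int]] = {}
    truth_rows = []
    for sid, k, z_s in zip(sample_ids, richness, z):
        n_core = int(round((1.0 - cfg.turnover) * k))
        pool = list(core_order[:n_core])
        remaining = [g for g in genome_ids if g not in set(pool)]
        extra = k - n_core
        if extra > 0:
            pool += list(rng.choice(remaining, size=extra, replace=False))
        if cfg.evenness >= 1.0:
            probs = np.full(k, 1.0 / k)
        else:
            conc = cfg.evenness / (1.0 - cfg.evenness)
            probs = rng.dirichlet(np.full(k, conc))
        reads = rng.multinomial(cfg.read_depth, probs)
        rows[sid] = {
            otu_id_for(g): int(r) for g, r in zip(pool, reads) if r > 0
        }
        truth_rows.append(
            {
                "sample_id": sid,
                "richness": int(k),
                "covariate_z": float(z_s),
                "turnover": cfg.turnover,
            }
        )
    otu_ids = sorted({otu for row in rows.values() for otu in row})
    counts = np.zeros((n, len(otu_ids)), dtype=np.int64)
    col = {otu: j for j, otu in enumerate(otu_ids)}
    for i, sid in enumerate(sample_ids):
        for otu, r in rows[sid].items():
            counts[i, col[otu]] = r
    profile = CommunityProfileSet(sample_ids, otu_ids, counts)
    return profile, pd.DataFrame(truth_rows)


def truth_mapping(
    profile: CommunityProfileSet, threshold_pct: float = 97.0
) -> OtuGenomeMap:
    """The by-construction OTU -> genome assignment for a synthetic table."""
    return OtuGenomeMap(
        assignments={
            otu: otu[len("OTU_"):] for otu in profile.otu_ids
        },
        unassigned=set(),
        threshold_pct=threshold_pct,
    )


def make_sequences(
    cfg: SimulationConfig,
    catalog: GenomeCatalog,
    otu_ids: Optional[Sequence[str]] = None,
) -> Tuple[List[Tuple[str, str]], List[Tuple[str, str]], pd.DataFrame]:
    """Reference and OTU 16S-like sequences with known divergences.

    Each OTU sequence is its genome's reference with k substitutions
    (k ~ Poisson(``divergence_mean``), each at a distinct position and to
    a different base), so the true percent identity is exactly
    ``100 (L - k) / L``.  Returns (refs, otus, truth) where truth has
    columns otu_id, genome_id, substitutions, identity.
    """
    rng = _rng(cfg, 3)
    length = cfg.seq_length
    bases = np.array(list("ACGT"))
    refs: List[Tuple[str, str]] = []
    otus: List[Tuple[str, str]] = []
    truth_rows = []
    wanted = None if otu_ids is None else set(otu_ids)
    for gid in sorted(catalog.records):
        seq = "".join(rng.choice(bases, size=length))
        refs.append((gid, seq))
        oid = otu_id_for(gid)
        if wanted is not None and oid not in wanted:
            continue
        k = int(min(rng.poisson(cfg.divergence_mean), length))
        otus.append((oid, mutate_sequence(seq, k, rng)))
        truth_rows.append(
            {
                "otu_id": oid,
                "genome_id": gid,
                "substitutions": k,
                "identity": 100.0 * (length - k) / length,
            }
        )
    return refs, otus, pd.DataFrame(truth_rows)


def mutate_sequence(seq: str, n_substitutions: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_substitutions`` point substitutions to ``seq``."""
    if n_substitutions > len(seq):
        raise ConfigError(
            f"requested {n_substitutions} substitutions exceed sequence "
            f"length {len(seq)}"
        )
    out = list(seq)
    positions = rng.choice(len(seq), size=n_substitutions, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def hits_from_truth(truth: pd.DataFrame) -> List[IdentityHit]:
    """Identity hits at the by-construction identities of a sequence truth.

    A shortcut emulating an aligner's output on the synthetic FASTA pair:
    one hit per OTU against its source genome, at the exact identity
    implied by the prescribed substitution count.
    """
    return [
        IdentityHit(
            otu_id=row["otu_id"],
            genome_id=row["genome_id"],
            percent_identity=float(row["identity"]),
            bitscore=float(row["identity"]),
        )
        for _, row in truth.iterrows()
    ]


def make_metadata(
    cfg: SimulationConfig, truths: pd.DataFrame
) -> Dict[str, MetadataRecord]:
    """Metadata covariates coupled to the latent covariate z.

    pH, temperature and salinity are noisy affine functions of z (and so
    correlate with richness at strength ~``env_effect``); latitude,
    longitude and elevation are uncoupled.  Environment labels partition
    samples into ``n_environments`` contiguous blocks, the first half
    free-living (saline/non-saline), the rest host-associated
    (animal/plant).
    """
    rng = _rng(cfg, 4)
    out: Dict[str, MetadataRecord] = {}
    n = len(truths)
    n_env = max(1, cfg.n_environments)
    block = math.ceil(n / n_env)
    for i, row in truths.reset_index(drop=True).iterrows():
        z = float(row["covariate_z"])
        env_idx = min(int(i) // block, n_env - 1)
        level1 = "free-living" if env_idx < (n_env + 1) // 2 else "host-associated"
        if level1 == "free-living":
            level2 = "saline" if env_idx % 2 == 0 else "non-saline"
        else:
            level2 = "animal" if env_idx % 2 == 0 else "plant"
        out[row["sample_id"]] = MetadataRecord(
            environment_level1=level1,
            environment_level2=level2,
            environment_level3=f"env_{env_idx:02d}",
            latitude_deg=float(rng.uniform(-90, 90)),
            longitude_deg=float(rng.uniform(-180, 180)),
            elevation_m=float(abs(rng.normal(300, 300))),
            temperature_c=float(15.0 - 6.0 * z + rng.normal(0, 2)),
            ph=float(np.clip(7.0 - 1.2 * z + rng.normal(0, 0.3), 0.0, 14.0)),
            salinity_psu=float(max(0.0, 8.0 + 4.0 * z + rng.normal(0, 1))),
        )
    return out


def make_tree(otu_ids: Sequence[str], seed: int = 0) -> PhyloTree:
    """Random coalescent-style rooted tree over the given OTU ids."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    if not otu_ids:
        raise ConfigError("cannot build a tree over zero leaves")
    nodes = [f"{name}:{rng.exponential(0.05):.6f}" for name in otu_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        nodes.append(f"({b},{a}):{rng.exponential(0.05):.6f}")
    tree = TreeNode.read(
        [nodes[0] + ";"], format="newick", convert_underscores=False
    )
    return PhyloTree(tree)


def make_turnover_gradient(
    cfg: SimulationConfig,
    turnovers: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> Tuple[CommunityProfileSet, pd.DataFrame, GenomeCatalog]:
    """Concatenated community sets spanning a turnover gradient.

    One catalog is shared; ``cfg.n_samples`` is split evenly across the
    turnover values, so pairwise comparisons span the full range of
    compositional overlap.
    """
    catalog = make_catalog(cfg)
    per = max(2, cfg.n_samples // len(turnovers))
    sample_ids: List[str] = []
    otu_union: set[str] = set()
    pieces = []
    truths = []
    for b, t in enumerate(turnovers):
        sub = replace(cfg, n_samples=per, turnover=float(t), seed=cfg.seed + b + 1)
        profile, truth = make_communities(sub, catalog)
        renamed = [f"T{b}_{sid}" for sid in profile.sample_ids]
        truth = truth.assign(
            sample_id=renamed, turnover=float(t)
        )
        pieces.append((renamed, profile))
        truths.append(truth)
        sample_ids += renamed
        otu_union.update(profile.otu_ids)
    otu_ids = sorted(otu_union)
    col = {otu: j for j, otu in enumerate(otu_ids)}
    counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
    row = 0
    for renamed, profile in pieces:
        for i, _ in enumerate(renamed):
            for j, otu in enumerate(profile.otu_ids):
                if profile.counts[i, j]:
                    counts[row, col[otu]] = profile.counts[i, j]
            row += 1
    combined = CommunityProfileSet(sample_ids, otu_ids, counts)
    return combined, pd.concat(truths, ignore_index=True), catalog


def write_fasta(records: Sequence[Tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def simulate_bundle(cfg: SimulationConfig, outdir: PathLike) -> Dict[str, Path]:
    """Emit the full input bundle for a pipeline run into ``outdir``.

    Writes catalog.tsv, otu_table.tsv, refs.fasta, otus.fasta, tree.nwk,
    metadata.tsv, mapping_truth.tsv and the two truth tables.  Byte-level
    deterministic per seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = make_catalog(cfg)
    profile, truth_samples = make_communities(cfg, catalog)
    refs, otus, truth_otus = make_sequences(cfg, catalog, profile.otu_ids)
    metadata = make_metadata(cfg, truth_samples)
    tree = make_tree(profile.otu_ids, seed=cfg.seed)

    paths = {
        "catalog": outdir / "catalog.tsv",
        "otu_table": outdir / "otu_table.tsv",
        "refs_fasta": outdir / "refs.fasta",
        "otus_fasta": outdir / "otus.fasta",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "truth_otus": outdir / "truth_otus.tsv",
        "mapping_truth": outdir / "mapping_truth.tsv",
    }
    fio.write_genome_catalog(catalog, paths["catalog"])
    profile.to_dataframe().rename_axis("sample_id").to_csv(
        paths["otu_table"], sep="\t"
    )
    write_fasta(refs, paths["refs_fasta"])
    write_fasta(otus, paths["otus_fasta"])
    fio.write_newick(tree, paths["tree"])
    fio.write_metadata(metadata, paths["metadata"])
    truth_samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    truth_otus.to_csv(paths["truth_otus"], sep="\t", index=False)
    write_mapping(truth_mapping(profile), paths["mapping_truth"])
    return paths
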