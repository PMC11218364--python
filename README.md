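# funred

Quantify **functional redundancy** (FR) of gene functions in prokaryotic
communities — how many taxonomically distinct organisms encode the same
metabolic function within a community, and how different the encoding taxa
are between communities. The package targets carbohydrate-degradation
functions described by CAZy glycoside-hydrolase (GH) families (cellulases,
xylanases, chitinases, or any single family), but works for any named
union of gene families.

It is intended for microbial ecologists with an OTU table from 16S
amplicon data plus an annotated genome catalog (or, alternatively, a
metagenome gene-abundance table), who want per-sample and per-pair
redundancy indices and their relationships with community diversity and
environmental factors.

## The indices

For a function whose genes are distributed over taxa with relative
frequencies *P&#8342;* within one community:

* **Within-community index** (Shannon form):
  FRI<sub>a</sub> = −Σᵢ *P*ᵢ ln *P*ᵢ.
  0 means a single encoding taxon (present but not redundant); missing
  means the function is absent; the maximum is ln (number of encoders).
* **Between-community index** (Bray–Curtis form), for communities A and B
  aligned on the union of their encoding taxa:
  FRI<sub>b</sub> = 1 − 2 Σᵢ min(*P*<sub>A,i</sub>, *P*<sub>B,i</sub>) /
  (Σᵢ *P*<sub>A,i</sub> + Σᵢ *P*<sub>B,i</sub>).
  0 = identical encoder profiles, 1 = completely disjoint encoder sets.

The supporting pipeline: OTU→genome assignment by 16S (V4) identity at
the ≥ 97% threshold, 16S-copy-number-corrected cell abundance, per-taxon
gene abundance and the gene/cell statistic, taxonomic aggregation
(OTU/genus/class/phylum), alpha and beta diversity, and the association
statistics (Spearman/Pearson, Wilcoxon rank tests, multiple regression
with adjusted R², pairwise Δ-environment analyses). See
`docs/methods.md` for the full model description.

## Worked example

```python
from funred import (
    FunctionSet, GenomeCatalog, GenomeRecord, OtuGenomeMap,
    build_gene_profile, gene_per_cell, fri_a, fri_b,
)

catalog = GenomeCatalog([
    # genome, phylum, class, genus, 16S copies, gene counts
    GenomeRecord("G1", "p1", "c1", "g1", 2, {"GH5": 4}),
    GenomeRecord("G2", "p1", "c1", "g2", 1, {"GH5": 0}),
])
otu_map = OtuGenomeMap({"O1": "G1", "O2": "G2"})
fn = FunctionSet.single("GH5")
counts = {"O1": 100, "O2": 50}          # reads per OTU in one sample

print(gene_per_cell(counts, otu_map, catalog, fn).value)
profile = build_gene_profile(counts, otu_map, catalog, fn, sample_id="S1")
print(profile.taxa, fri_a(profile).fri_a)
```

prints

```
2.0
('O1',) 0.0
```

O1's 100 reads over 2 rRNA copies are 50 cells carrying 4 GH5 genes each;
O2's 50 reads over 1 copy are 50 cells carrying none — so the community
averages (50·4 + 50·0)/100 = **2.0 GH5 genes per cell**, and because only
one taxon encodes the function, FRI<sub>a</sub> = **0.0** (present but
not redundant). With gene abundances 6 : 3 : 1 over three taxa the index
is 0.8979…, and two communities whose encoder frequencies are
(0.5, 0.5, 0) and (0.25, 0.25, 0.5) have FRI<sub>b</sub> = 0.5.

## Command line

```sh
funred simulate --out inputs --seed 1        # synthetic input bundle
funred map --otus inputs/otus.fasta --refs inputs/refs.fasta \
           --otu-table inputs/otu_table.tsv --out mapping.tsv
funred diversity --otu-table inputs/otu_table.tsv --tree inputs/tree.nwk \
           --out-dir diversity
funred fr  --otu-table inputs/otu_table.tsv --catalog inputs/catalog.tsv \
           --mapping mapping.tsv --metadata inputs/metadata.tsv \
           --out-dir fr
funred associate --within fr/within.tsv --between fr/between.tsv \
           --alpha diversity/alpha.tsv --beta diversity/beta.tsv \
           --metadata inputs/metadata.tsv --spec associations.cfg \
           --out associations.tsv
```

or `funred all --out run --seed 1` for the whole chain on a fresh
synthetic bundle. All inputs and outputs are plain TSV/FASTA/Newick;
`NA` is the sole missing-value token. Real-data users supply their own
OTU table, genome catalog and BLAST tabular hit file in place of the
simulated bundle.

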