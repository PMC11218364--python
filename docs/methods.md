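# Methods

## The two indices

`funred` quantifies functional redundancy (FR) of a gene function — a
glycoside-hydrolase (GH) family, or a named union of families such as the
cellulases — in prokaryotic communities.

For one community, let `P_i` be the relative frequency of the function's
genes contributed by taxon `i` (that taxon's gene abundance divided by the
community's total gene abundance for the function). The
**within-community index** is the Shannon entropy of that distribution,

    FRI_a = − Σ_i P_i ln P_i        (natural log)

It is 0 when a single taxon encodes the function (present but not
redundant), grows with the number and evenness of encoders, and is bounded
by `ln(number of encoding taxa)`. When no taxon encodes the function the
index is *missing*, which is deliberately distinct from 0: absence and
non-redundant presence answer different questions, and the
present-vs-redundant proportions reported by `summarize` depend on the
distinction.

For two communities A and B with encoder frequency vectors aligned on the
union of their taxa, the **between-community index** is the Bray–Curtis
dissimilarity of those vectors,

    FRI_b = 1 − 2 Σ_i min(P_Ai, P_Bi) / (Σ_i P_Ai + Σ_i P_Bi)

0 means the same taxa encode the function with identical frequencies; 1
means completely disjoint encoder sets. Frequencies are normalized per
community, so the denominator equals 2; the full formula is kept so that
unnormalized inputs remain well-defined. Edge conventions: function absent
in exactly one community of a pair → 1 (disjoint encoders); absent in both
→ missing, excluded from summaries.

Both indices share their numeric kernels (`_kernels.py`) with the
community Shannon index and Bray–Curtis beta diversity, so the
"redundancy is diversity of encoders" analogy is exact in code, not just
in prose, and is pinned by tests.

## Pipeline

1. **Rarefaction** — every sample is subsampled without replacement to a
   fixed depth (default 5000 reads); shallower samples are dropped with a
   warning. Rarefaction happens before genome mapping–dependent
   computations and before diversity, so all downstream statistics see the
   same depth-controlled counts.
2. **OTU → genome assignment** — an OTU is linked to a sequenced genome
   when their 16S (V4) sequences align at ≥ 97% identity, the classical
   species-level threshold (97.0 passes, 96.9 fails). Hits normally come
   from a BLAST tabular file; a built-in global aligner (match +1,
   mismatch 0, linear gap −1; identity = matches / alignment columns, gap
   columns included, `N` never matches) serves desk-scale FASTA inputs.
   When several genomes clear the threshold the single best is kept —
   highest identity, then highest bitscore, then lexicographically
   smallest genome id. Merging or averaging co-optimal genomes was the
   open alternative; single-best was chosen for reproducibility and is
   noted as a modelling choice, not a biological claim. Score ties inside
   the aligner are broken canonically (most matches, then fewest gap
   columns) so reported identity is deterministic and symmetric.
3. **Gene abundance** — an OTU's reads are divided by its genome's 16S
   rRNA gene copy number to estimate cells, then multiplied by the
   genome's gene count for the function. Unassigned OTUs contribute
   nothing to gene abundance or to gene/cell (their gene content is
   unknown; no hidden-state prediction is attempted) but are retained for
   the community diversity indices. The companion statistic
   `gene/cell = Σ cells_i·g_i / Σ cells_i` averages over mapped cells
   only.
4. **Taxonomic aggregation** — profiles built at OTU level can be merged
   to genus, class or phylum through the assigned genome's lineage.
   Merging only pools probability mass, so `FRI_a` is monotone
   non-increasing from OTU to phylum; this is tested exactly on nested
   random fixtures.
5. **Diversity** — observed OTUs; Shannon (natural log, same kernel as
   `FRI_a`); Chao1 in the bias-corrected form
   `S_obs + F1(F1−1)/(2(F2+1))`, chosen so doubleton-free samples are
   defined; Faith's PD in the rooted convention (sum of branch lengths on
   the union of root-to-leaf paths, root path included); Bray–Curtis beta
   diversity, optionally restricted to within-environment pairs.
6. **Associations** — Spearman (tie-corrected, Pearson on mid-ranks, t
   approximation with n−2 df) and Pearson correlations on complete cases;
   Wilcoxon signed-rank for paired comparisons (zero differences dropped)
   and Mann–Whitney U for two groups, with exact enumeration of all rank
   assignments at combined n ≤ 10 and the tie-corrected normal
   approximation otherwise; OLS with intercept reporting
   `adjusted R² = 1 − (1−R²)(n−1)/(n−p−1)`; absolute pairwise metadata
   deltas (Δtemperature, ΔpH, Δsalinity) for pair-level analyses. No
   multiple-testing correction gates anything; a Benjamini–Hochberg
   q-value column is emitted for reference. Pair-level correlations
   (FRI_b vs beta diversity or Δ-variables) treat pairs as independent
   observations; pair non-independence is a known caveat of that design.

## Synthetic data

The generators emulate the structure of a large amplicon survey joined to
a genome catalog; they define the study conditions the package is
validated under.

* **Catalog** — gene counts per GH family are Poisson(`gene_count_mean`,
  default 1), 16S copy numbers uniform integers on 1–15 (the realistic
  prokaryotic range), lineages from a nested 3-level hierarchy. Family
  names start with the classical cellulase/xylanase/chitinase groupings
  so the default function sets apply.
* **Communities** — 200 samples by default; per-sample richness is drawn
  from 5–150 via a latent covariate `z ~ N(0,1)` correlated with richness
  at strength `env_effect` (default 0.8); the taxon pool mixes a shared
  core (fraction `1 − turnover`) with uniform draws; relative abundances
  are Dirichlet with concentration `evenness/(1−evenness)` (default
  evenness 0.5 → flat Dirichlet, a realistically uneven community);
  reads are multinomial at depth 10000 so rarefaction to 5000 keeps all
  samples. The Dirichlet-multinomial model is the simplest one with a
  controllable evenness knob; nothing is assumed about real abundance
  distributions.
* **Sequences** — each OTU sequence is its genome's 250-mer reference
  with `k ~ Poisson(3)` substitutions at distinct positions, so the true
  identity is exactly `100(250−k)/250` and the 97% boundary is exercised
  (about 1% of OTUs fall below it).
* **Metadata** — pH, temperature and salinity are noisy affine functions
  of `z` (so they correlate with richness at ~`env_effect`); latitude,
  longitude and elevation are uncoupled; environment labels partition
  samples into contiguous blocks under a free-living/host-associated
  two-level scheme.
* **Turnover gradient** — for pair-level analyses a bundle concatenates
  sub-cohorts at turnover 0, 0.25, 0.5, 0.75 and 1 over one catalog, so
  pairwise compositional overlap spans its full range.

Everything is deterministic per seed (independent seeded generator
streams per stage; no dict-order dependence), and truth tables are
emitted with every fixture.

What the generator does **not** emulate: real phylogenetic signal in gene
content (gene counts are independent of lineage), chimeras and
sequencing error, compositional structure beyond Dirichlet-multinomial,
spatial autocorrelation of metadata. Passing the recovery tests therefore
shows that the pipeline's statistics faithfully recover couplings that
are present by construction — not that such couplings exist in any real
data set.

## Problem sizes and numerical choices

The recovery checks run 200-sample cohorts (within-community) and
40-sample turnover gradients (~780 pairs, between-community) across five
seeds; the byte-determinism check runs the full command-line pipeline
twice at 10 samples × 40 genomes. These sizes make every distributional
property measurable while keeping the whole suite under a minute of
compute.

* Quantiles use linear interpolation (NumPy default, type 7).
* Frequencies must sum to 1 within 1e-9; entropy/Bray–Curtis oracle
  agreement is asserted at 1e-12.
* Missing metadata is `None` (never 0 — pH 0 is legal); the sole missing
  token in output files is `NA`; floats are written with 12 significant
  digits and rows sorted by key columns, so outputs are byte-stable.
* Exact Mann–Whitney enumeration is capped at combined n ≤ 10
  (C(10,5) = 252 assignments); beyond that the normal approximation with
  tie correction is used, which already agrees with enumeration to ~0.02
  at n ≈ 10.

## Known limitations

* Gene content of unassigned OTUs is unknown and treated as absent, so
  gene/cell and the indices describe the genome-mapped fraction of the
  community.
* The indices inherit compositionality from relative frequencies; they
  say nothing about absolute encoder biomass.
* Pair-level statistics ignore the dependence between pairs sharing a
  sample.
* The built-in aligner is a desk-scale stand-in for a production aligner
  on real survey data; users with large data should supply BLAST tabular
  hits.
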