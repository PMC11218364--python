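"""The two redundancy indices and their exact invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funred.abundance import GeneProfile
from funred.core import (
    GenomeCatalog,
    GenomeRecord,
    UsageError,
    ValidationError,
)
from funred.mapping import OtuGenomeMap
from funred.redundancy import (
    aggregate_level,
    fri_a,
    fri_b,
    fri_b_matrix,
    is_redundant_within,
    summarize,
)

from oracles import bray_curtis_oracle, entropy_oracle


def profile_of(abundances, sample="S", fn="f", level="otu"):
    return GeneProfile.from_abundances(
        sample, fn, level, {f"t{i}": a for i, a in enumerate(abundances)}
    )


positive_abundances = st.lists(
    st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
    min_size=1,
    max_size=30,
)


class TestWithinIndex:
    def test_single_taxon_not_redundant(self):
        res = fri_a(profile_of([5.0]))
        assert res.fri_a == 0.0
        assert res.n_taxa == 1

    def test_uniform_four_taxa_is_ln4(self):
        res = fri_a(profile_of([2.0, 2.0, 2.0, 2.0]))
        assert res.fri_a == pytest.approx(math.log(4), abs=1e-12)

    def test_worked_631_example(self):
        res = fri_a(profile_of([6.0, 3.0, 1.0]))
        assert res.fri_a == pytest.approx(0.8979457248567798, abs=1e-9)

    def test_absent_function_is_missing_not_zero(self):
        res = fri_a(GeneProfile("S", "f", "otu"))
        assert res.fri_a is None
        assert res.n_taxa == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 20))
            ab = rng.uniform(0.01, 100.0, size=k)
            res = fri_a(profile_of(ab))
            assert res.fri_a == pytest.approx(entropy_oracle(ab), abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(positive_abundances, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_and_permutation_invariance(self, abundances, factor):
        base = fri_a(profile_of(abundances)).fri_a
        scaled = fri_a(profile_of([a * factor for a in abundances])).fri_a
        permuted = fri_a(profile_of(sorted(abundances, reverse=True))).fri_a
        assert scaled == pytest.approx(base, abs=1e-9)
        assert permuted == pytest.approx(base, abs=1e-9)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(positive_abundances)
    def test_bounded_by_log_richness(self, abundances):
        res = fri_a(profile_of(abundances))
        assert 0.0 <= res.fri_a <= math.log(res.n_taxa) + 1e-9

    def test_inconsistent_frequencies_rejected(self):
        p = profile_of([1.0, 1.0])
        p.frequencies = np.array([0.9, 0.3])
        with pytest.raises(ValidationError):
            fri_a(p)


class TestBetweenIndex:
    def test_identical_profiles_give_zero(self):
        a = profile_of([3.0, 1.0], sample="A")
        b = profile_of([3.0, 1.0], sample="B")
        assert fri_b(a, b).fri_b == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_taxa_give_one(self):
        a = GeneProfile.from_abundances("A", "f", "otu", {"x": 1.0})
        b = GeneProfile.from_abundances("B", "f", "otu", {"y": 1.0})
        assert fri_b(a, b).fri_b == 1.0

    def test_worked_half_overlap_example(self):
        a = GeneProfile.from_abundances(
            "A", "f", "otu", {"t1": 0.5, "t2": 0.5}
        )
        b = GeneProfile.from_abundances(
            "B", "f", "otu", {"t1": 0.25, "t2": 0.25, "t3": 0.5}
        )
        assert fri_b(a, b).fri_b == pytest.approx(0.5, abs=1e-12)

    def test_absent_in_one_is_one_absent_in_both_is_missing(self):
        present = profile_of([1.0, 2.0], sample="A")
        empty_a = GeneProfile("A", "f", "otu")
        empty_b = GeneProfile("B", "f", "otu")
        assert fri_b(present, empty_b).fri_b == 1.0
        assert fri_b(empty_a, empty_b).fri_b is None

    def test_function_mismatch_rejected(self):
        a = profile_of([1.0], fn="f1")
        b = profile_of([1.0], fn="f2")
        with pytest.raises(UsageError):
            fri_b(a, b)

    def test_symmetry_bounds_and_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            taxa = [f"t{i}" for i in range(int(rng.integers(1, 12)))]
            pa = {
                t: float(rng.uniform(0, 5))
                for t in taxa
                if rng.random() < 0.7
            }
            pb = {
                t: float(rng.uniform(0, 5))
                for t in taxa
                if rng.random() < 0.7
            }
            a = GeneProfile.from_abundances("A", "f", "otu", pa)
            b = GeneProfile.from_abundances("B", "f", "otu", pb)
            ab, ba = fri_b(a, b).fri_b, fri_b(b, a).fri_b
            if ab is None:
                assert ba is None
                continue
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 0.0 <= ab <= 1.0
            if not a.is_empty and not b.is_empty:
                union = sorted(set(a.taxa) | set(b.taxa))
                fa = np.array([dict(zip(a.taxa, a.frequencies)).get(t, 0.0) for t in union])
                fb = np.array([dict(zip(b.taxa, b.frequencies)).get(t, 0.0) for t in union])
                assert ab == pytest.approx(bray_curtis_oracle(fa, fb), abs=1e-12)
                disjoint = not set(a.taxa) & set(b.taxa)
                assert (ab == 1.0) == disjoint


class TestAggregation:
    def _nested_setup(self, rng, n_genomes=50):
        genomes = []
        for i in range(n_genomes):
            p = int(rng.integers(1, 4))
            c = int(rng.integers(1, 3))
            g = int(rng.integers(1, 4))
            genomes.append(
                GenomeRecord(
                    f"G{i}",
                    f"p{p}",
                    f"p{p}.c{c}",
                    f"p{p}.c{c}.g{g}",
                    1,
                    {"GH5": 1},
                )
            )
        catalog = GenomeCatalog(genomes)
        otu_map = OtuGenomeMap({f"O{i}": f"G{i}" for i in range(n_genomes)})
        return catalog, otu_map

    def test_entropy_merge_worked_example(self, rng):
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "p.c", "g1", 1, {"GH5": 1}),
                GenomeRecord("G2", "p", "p.c", "g1", 1, {"GH5": 1}),
                GenomeRecord("G3", "p", "p.c", "g2", 1, {"GH5": 1}),
            ]
        )
        otu_map = OtuGenomeMap({"O1": "G1", "O2": "G2", "O3": "G3"})
        otu = GeneProfile.from_abundances(
            "S", "f", "otu", {"O1": 4.0, "O2": 4.0, "O3": 2.0}
        )
        assert fri_a(otu).fri_a == pytest.approx(1.0549201679861442, abs=1e-9)
        genus = aggregate_level(otu, "genus", otu_map, catalog)
        assert dict(zip(genus.taxa, genus.gene_abundance)) == {
            "g1": 8.0, "g2": 2.0
        }
        assert fri_a(genus).fri_a == pytest.approx(0.5004024235381879, abs=1e-9)
        phylum = aggregate_level(otu, "phylum", otu_map, catalog)
        assert fri_a(phylum).fri_a == 0.0

    def test_bijective_merge_preserves_index(self, rng):
        catalog, otu_map = self._nested_setup(rng)
        # one OTU per genus: pick OTUs with distinct genera
        seen = {}
        for i in range(50):
            genus = catalog[f"G{i}"].genus
            if genus not in seen:
                seen[genus] = f"O{i}"
        otu = GeneProfile.from_abundances(
            "S", "f", "otu", {o: float(i + 1) for i, o in enumerate(seen.values())}
        )
        genus = aggregate_level(otu, "genus", otu_map, catalog)
        assert fri_a(genus).fri_a == pytest.approx(fri_a(otu).fri_a, abs=1e-12)

    def test_monotone_under_nesting_1000_fixtures(self, rng):
        catalog, otu_map = self._nested_setup(rng)
        for _ in range(1000):
            k = int(rng.integers(1, 30))
            otus = rng.choice(50, size=k, replace=False)
            otu = GeneProfile.from_abundances(
                "S", "f", "otu",
                {f"O{i}": float(rng.uniform(0.1, 10)) for i in otus},
            )
            values = {"otu": fri_a(otu).fri_a}
            total = otu.total_abundance
            for level in ("genus", "class", "phylum"):
                agg = aggregate_level(otu, level, otu_map, catalog)
                values[level] = fri_a(agg).fri_a
                assert agg.total_abundance == pytest.approx(total, rel=1e-12)
            assert (
                values["phylum"]
                <= values["class"] + 1e-12
            )
            assert values["class"] <= values["genus"] + 1e-12
            assert values["genus"] <= values["otu"] + 1e-12

    def test_aggregating_non_otu_profile_rejected(self, rng):
        catalog, otu_map = self._nested_setup(rng)
        genus = GeneProfile.from_abundances("S", "f", "genus", {"g": 1.0})
        with pytest.raises(UsageError):
            aggregate_level(genus, "phylum", otu_map, catalog)


class TestRedundancyClassification:
    def test_two_taxa_redundant_one_not(self):
        assert is_redundant_within(profile_of([1.0, 1.0]))
        assert not is_redundant_within(profile_of([5.0]))

    def test_level_dependence(self):
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "c", "g", 1, {"GH5": 1}),
                GenomeRecord("G2", "p", "c", "g", 1, {"GH5": 1}),
            ]
        )
        otu_map = OtuGenomeMap({"O1": "G1", "O2": "G2"})
        otu = GeneProfile.from_abundances(
            "S", "f", "otu", {"O1": 1.0, "O2": 1.0}
        )
        assert is_redundant_within(otu)
        genus = aggregate_level(otu, "genus", otu_map, catalog)
        assert not is_redundant_within(genus)

    def test_empty_profile_rejected(self):
        with pytest.raises(UsageError):
            is_redundant_within(GeneProfile("S", "f", "otu"))


class TestPairMatrixAndSummaries:
    def test_three_samples_symmetric_matrix(self, rng):
        profiles = [
            profile_of(rng.uniform(1, 5, size=3), sample=f"S{i}")
            for i in range(3)
        ]
        m = fri_b_matrix(profiles)
        assert m.shape == (3, 3)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_environment_filter_restricts_pairs(self, rng):
        profiles = [
            profile_of(rng.uniform(1, 5, size=3), sample=f"S{i}")
            for i in range(5)
        ]
        envs = {"S0": "a", "S1": "a", "S2": "b", "S3": "b", "S4": "b"}
        m = fri_b_matrix(profiles, environments=envs)
        off_diag = ~np.isnan(m.values) & ~np.eye(5, dtype=bool)
        assert off_diag.sum() == 2 * (1 + 3)  # symmetric: 1 a-pair + 3 b-pairs

    def test_summarize_quantiles_and_proportion(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "group": ["g"] * 3 + ["h"],
                "value": [0.0, 1.0, 2.0, math.nan],
            }
        )
        out = summarize(df, "value", "group").set_index("group")
        assert out.loc["g", "median"] == 1.0
        assert out.loc["g", "proportion_redundant"] == pytest.approx(2 / 3)
        assert out.loc["g", "n"] == 3
        assert out.loc["h", "n"] == 0
        assert math.isnan(out.loc["h", "median"])

    def test_summarize_single_value_collapses_quantiles(self):
        import pandas as pd

        df = pd.DataFrame({"group": ["g"], "value": [0.7]})
        out = summarize(df, "value", "group").iloc[0]
        assert (
            out["p10"] == out["p25"] == out["median"] == out["p75"]
            == out["p90"] == 0.7
        )
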