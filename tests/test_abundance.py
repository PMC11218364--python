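"""Rarefaction, copy-number correction, gene profiles and gene/cell."""

import numpy as np
import pandas as pd
import pytest

from funred.abundance import (
    CELLULASES,
    CHITINASES,
    GeneProfile,
    build_gene_profile,
    cells_from_reads,
    function_gene_count,
    gene_per_cell,
    prevalence_filter,
    profiles_from_gene_table,
    rarefy,
)
from funred.core import (
    CommunityProfileSet,
    FunctionSet,
    GenomeCatalog,
    GenomeRecord,
    ValidationError,
)
from funred.mapping import OtuGenomeMap


class TestRarefy:
    def test_exact_depth_unchanged(self):
        ps = CommunityProfileSet(
            ["S1"], ["O1", "O2"], np.array([[4990, 10]])
        )
        out = rarefy(ps, depth=5000, seed=1)
        assert (out.counts == ps.counts).all()

    def test_below_depth_dropped_with_warning(self, caplog):
        ps = CommunityProfileSet(
            ["S1", "S2"], ["O1"], np.array([[4999], [6000]])
        )
        with caplog.at_level("WARNING"):
            out = rarefy(ps, depth=5000, seed=1)
        assert out.sample_ids == ["S2"]
        assert "S1" in caplog.text

    def test_all_samples_below_depth_error(self):
        ps = CommunityProfileSet(["S1"], ["O1"], np.array([[10]]))
        with pytest.raises(ValidationError, match="no samples"):
            rarefy(ps, depth=5000, seed=1)

    def test_deterministic_given_seed(self):
        ps = CommunityProfileSet(
            ["S1"], ["O1", "O2", "O3"], np.array([[500, 300, 200]])
        )
        a = rarefy(ps, depth=100, seed=7)
        b = rarefy(ps, depth=100, seed=7)
        assert (a.counts == b.counts).all()

    def test_draw_matches_hypergeometric_expectation(self):
        # mean O1 count over many seeds vs the hypergeometric mean 9.0
        ps = CommunityProfileSet(["S1"], ["O1", "O2"], np.array([[90, 10]]))
        draws = np.array(
            [rarefy(ps, depth=10, seed=s).counts[0, 0] for s in range(2000)]
        )
        var = 10 * 0.9 * 0.1 * (90 / 99)
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - 9.0) < 3 * se

    def test_depth_preserved_per_sample(self):
        ps = CommunityProfileSet(
            ["S1"], ["O1", "O2", "O3"], np.array([[500, 300, 200]])
        )
        out = rarefy(ps, depth=123, seed=0)
        assert out.counts.sum() == 123


class TestCellsFromReads:
    @pytest.mark.parametrize(
        "reads,copies,expected",
        [(100, 2, 50.0), (0, 5, 0.0), (7, 3, 7 / 3)],
    )
    def test_division(self, reads, copies, expected):
        assert cells_from_reads(reads, copies) == pytest.approx(expected)

    def test_zero_copies_rejected(self):
        with pytest.raises(ValidationError):
            cells_from_reads(10, 0)


class TestFunctionGeneCount:
    def test_sum_over_families(self):
        g = GenomeRecord("G", "p", "c", "g", 1, {"GH5": 2, "GH6": 1})
        assert function_gene_count(g, CELLULASES) == 3

    def test_disjoint_families_give_zero(self):
        g = GenomeRecord("G", "p", "c", "g", 1, {"GH18": 4})
        assert function_gene_count(g, CELLULASES) == 0

    def test_chitinase_grouping(self):
        g = GenomeRecord("G", "p", "c", "g", 1, {"GH18": 1, "GH85": 2})
        assert function_gene_count(g, CHITINASES) == 3


class TestBuildGeneProfile:
    def test_worked_two_otu_example(self, tiny_map):
        # O1: 100 reads / 2 copies x 4 genes = 200; O2 carries no GH5/GH6
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "c", "g1", 2, {"GH5": 4}),
                GenomeRecord("G2", "p", "c", "g2", 1, {"GH5": 0}),
                GenomeRecord("G3", "p", "c", "g3", 1, {}),
            ]
        )
        fn = FunctionSet.single("GH5")
        profile = build_gene_profile(
            {"O1": 100, "O2": 50}, tiny_map, catalog, fn, sample_id="S1"
        )
        assert profile.taxa == ("O1",)
        assert profile.gene_abundance.tolist() == [200.0]
        assert profile.frequencies.tolist() == [1.0]

    def test_absent_function_gives_empty_profile(self, tiny_map):
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "c", "g", 1, {"GH99": 1}),
                GenomeRecord("G2", "p", "c", "g", 1, {}),
                GenomeRecord("G3", "p", "c", "g", 1, {}),
            ]
        )
        profile = build_gene_profile(
            {"O1": 10, "O2": 5}, tiny_map, catalog, FunctionSet.single("GH5")
        )
        assert profile.is_empty

    def test_genus_aggregation_sums_abundance(self, tiny_map):
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "c", "gX", 1, {"GH5": 1}),
                GenomeRecord("G2", "p", "c", "gX", 1, {"GH5": 1}),
                GenomeRecord("G3", "p", "c", "gY", 1, {}),
            ]
        )
        fn = FunctionSet.single("GH5")
        counts = {"O1": 4, "O2": 4}
        otu_level = build_gene_profile(counts, tiny_map, catalog, fn)
        genus_level = build_gene_profile(
            counts, tiny_map, catalog, fn, level="genus"
        )
        assert otu_level.n_taxa == 2
        assert genus_level.taxa == ("gX",)
        assert genus_level.gene_abundance.tolist() == [8.0]
        assert genus_level.total_abundance == pytest.approx(
            otu_level.total_abundance
        )

    def test_missing_genome_in_catalog_rejected(self, tiny_map):
        catalog = GenomeCatalog(
            [GenomeRecord("G1", "p", "c", "g", 1, {"GH5": 1})]
        )
        with pytest.raises(ValidationError, match="G2"):
            build_gene_profile(
                {"O2": 5}, tiny_map, catalog, FunctionSet.single("GH5")
            )

    def test_unmapped_otus_contribute_nothing(self, tiny_catalog, tiny_map):
        fn = FunctionSet.single("GH5")
        with_unmapped = build_gene_profile(
            {"O1": 10, "O4": 1000}, tiny_map, tiny_catalog, fn
        )
        without = build_gene_profile({"O1": 10}, tiny_map, tiny_catalog, fn)
        assert with_unmapped.taxa == without.taxa
        assert np.allclose(
            with_unmapped.gene_abundance, without.gene_abundance
        )

    def test_frequencies_sum_to_one(self, tiny_catalog, tiny_map, rng):
        fn = FunctionSet("both", frozenset({"GH5", "GH6", "GH18"}))
        for _ in range(50):
            counts = {
                otu: int(rng.integers(0, 100))
                for otu in ("O1", "O2", "O3", "O4")
            }
            p = build_gene_profile(counts, tiny_map, tiny_catalog, fn)
            if not p.is_empty:
                assert p.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unit_copy_number_equals_raw_reads(self, tiny_map):
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "c", "g1", 1, {"GH5": 3}),
                GenomeRecord("G2", "p", "c", "g2", 1, {"GH5": 2}),
                GenomeRecord("G3", "p", "c", "g3", 1, {}),
            ]
        )
        fn = FunctionSet.single("GH5")
        p = build_gene_profile({"O1": 10, "O2": 20}, tiny_map, catalog, fn)
        assert dict(zip(p.taxa, p.gene_abundance)) == {
            "O1": 30.0, "O2": 40.0
        }


class TestGenePerCell:
    def test_worked_example(self, tiny_map):
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "c", "g1", 2, {"GH5": 4}),
                GenomeRecord("G2", "p", "c", "g2", 1, {"GH5": 0}),
                GenomeRecord("G3", "p", "c", "g3", 1, {}),
            ]
        )
        fn = FunctionSet.single("GH5")
        gpc = gene_per_cell({"O1": 100, "O2": 50}, tiny_map, catalog, fn)
        # (50 cells x 4 genes + 50 cells x 0 genes) / 100 cells
        assert gpc.value == pytest.approx(2.0)

    def test_single_otu_equals_its_gene_count(self, tiny_map):
        catalog = GenomeCatalog(
            [GenomeRecord("G1", "p", "c", "g", 3, {"GH5": 7})]
        )
        m = OtuGenomeMap({"O1": "G1"})
        fn = FunctionSet.single("GH5")
        for reads in (1, 10, 99999):
            assert gene_per_cell(
                {"O1": reads}, m, catalog, fn
            ).value == pytest.approx(7.0)

    def test_zero_gene_community_gives_zero(self, tiny_map):
        catalog = GenomeCatalog(
            [
                GenomeRecord("G1", "p", "c", "g1", 1, {}),
                GenomeRecord("G2", "p", "c", "g2", 1, {}),
                GenomeRecord("G3", "p", "c", "g3", 1, {}),
            ]
        )
        fn = FunctionSet.single("GH5")
        assert gene_per_cell({"O1": 5, "O2": 5}, tiny_map, catalog, fn).value == 0.0

    def test_no_mapped_reads_is_missing(self, tiny_catalog, tiny_map):
        fn = FunctionSet.single("GH5")
        gpc = gene_per_cell({"O4": 100}, tiny_map, tiny_catalog, fn)
        assert gpc.value is None

    def test_invariant_under_uniform_read_scaling(self, tiny_catalog, tiny_map):
        fn = FunctionSet("all", frozenset({"GH5", "GH6", "GH18"}))
        base = gene_per_cell(
            {"O1": 10, "O2": 20, "O3": 30}, tiny_map, tiny_catalog, fn
        ).value
        for factor in (2, 7, 100):
            scaled = gene_per_cell(
                {"O1": 10 * factor, "O2": 20 * factor, "O3": 30 * factor},
                tiny_map,
                tiny_catalog,
                fn,
            ).value
            assert scaled == pytest.approx(base, rel=1e-12)


class TestPrevalenceFilter:
    def test_inclusive_boundary(self):
        presence = pd.DataFrame(
            {
                f"S{i}": {"rare": i < 2, "at_cut": i < 125, "common": True}
                for i in range(300)
            }
        )
        retained, dropped = prevalence_filter(presence, min_samples=125)
        assert retained == ["at_cut", "common"]
        assert dropped.to_dict() == {"rare": 2}

    def test_threshold_one_keeps_all_observed(self):
        presence = pd.DataFrame(
            {"S1": {"a": True, "b": False}, "S2": {"a": False, "b": True}}
        )
        retained, dropped = prevalence_filter(presence, min_samples=1)
        assert retained == ["a", "b"]
        assert dropped.empty


class TestGeneTableEntryPath:
    def test_profiles_from_metagenome_table(self):
        table = {
            "S1": {("T1", "GH5"): 10.0, ("T1", "GH6"): 5.0, ("T2", "GH5"): 5.0},
            "S2": {("T1", "GH18"): 3.0},
        }
        fn = FunctionSet("cellulase-like", frozenset({"GH5", "GH6"}))
        profiles = profiles_from_gene_table(table, fn)
        p1 = profiles["S1"]
        assert dict(zip(p1.taxa, p1.gene_abundance)) == {
            "T1": 15.0, "T2": 5.0
        }
        assert profiles["S2"].is_empty
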