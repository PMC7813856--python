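import numpy as np
import pandas as pd
import pytest

from scfa_resilience import (
    DEFAULT_GENE_GROUPS,
    UNCLASSIFIED_AT_LEVEL,
    GeneGroupDefinition,
    collapse_to_level,
    extract_gene_group,
    mapped_fraction,
    normalize_to_cpm,
    scfa_relative_abundance,
)
from scfa_resilience.groups import COMMUNITY_LEVEL, NormalizationError

from conftest import make_table

BUTYRATE = next(d for d in DEFAULT_GENE_GROUPS if d.group_name == "butyrate")
ACETATE = next(d for d in DEFAULT_GENE_GROUPS if d.group_name == "acetate")


class TestNormalizeToCpm:
    def test_forced_scaling(self):
        t = make_table(
            {"UNMAPPED": [200.0], "G1: x|g__A": [300.0]}, ["s1"]
        )
        out = normalize_to_cpm(t)
        assert out.data["s1"].sum() == pytest.approx(1e6)
        assert out.data.loc["G1: x|g__A", "s1"] == pytest.approx(300.0 * 2000)

    def test_identity_when_already_cpm(self):
        t = make_table({"UNMAPPED": [4e5], "G1: x|g__A": [6e5]}, ["s1"])
        out = normalize_to_cpm(t)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_ratios_within_sample_unchanged(self, rng):
        rows = {f"G{i}: x|g__T{i}": rng.uniform(1, 9, 3).tolist() for i in range(6)}
        t = make_table(rows, ["a", "b", "c"])
        out = normalize_to_cpm(t)
        before = t.data.to_numpy()
        after = out.data.to_numpy()
        # every pairwise ratio of features within a sample is preserved
        np.testing.assert_allclose(
            before / before[0], after / after[0], rtol=1e-12
        )

    def test_idempotent(self, simple_table):
        once = normalize_to_cpm(simple_table)
        twice = normalize_to_cpm(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_community_total_rows_not_double_counted(self, simple_table):
        # grand total must use strata (60) + unclassified... the G1 community
        # row duplicates its strata and must not inflate the denominator
        out = normalize_to_cpm(simple_table)
        mask = out.gene_total_mask()
        assert out.data.loc[mask].sum()["s1"] == pytest.approx(1e6)

    def test_zero_total_sample_raises(self):
        t = make_table({"G1: x|g__A": [0.0, 1.0]}, ["dead", "ok"])
        with pytest.raises(NormalizationError, match="dead"):
            normalize_to_cpm(t)


class TestMappedFraction:
    def test_forced_arithmetic(self):
        t = make_table(
            {"UNMAPPED": [250000.0], "G1: x|g__A": [750000.0]}, ["s1"]
        )
        assert mapped_fraction(t)["s1"] == pytest.approx(0.75)

    def test_degenerate_values(self):
        t = make_table({"UNMAPPED": [0.0, 10.0], "G1: x|g__A": [5.0, 0.0]},
                       ["all_mapped", "none_mapped"])
        frac = mapped_fraction(t)
        assert frac["all_mapped"] == 1.0
        assert frac["none_mapped"] == 0.0

    def test_missing_unmapped_row_is_an_error(self):
        t = make_table({"G1: x|g__A": [5.0]}, ["s1"])
        with pytest.raises(Exception, match="UNMAPPED"):
            mapped_fraction(t)


class TestExtractGeneGroup:
    def test_butyrate_combines_buk_and_but(self):
        t = make_table(
            {
                "UNMAPPED": [1.0],
                "b1: butyrate kinase|g__Clostridium": [2.0],
                "b2: butyryl-CoA: acetate CoA transferase|g__Roseburia": [3.0],
                "a1: acetate kinase|g__Bacteroides": [4.0],
            },
            ["s1"],
        )
        sub = extract_gene_group(t, BUTYRATE)
        assert sorted(k.gene_name for k in sub.features) == [
            "butyrate kinase",
            "butyryl-CoA: acetate CoA transferase",
        ]

    def test_matching_is_exact_not_substring(self):
        t = make_table(
            {"a2: phosphoacetate kinase homolog|g__X": [1.0]}, ["s1"]
        )
        assert extract_gene_group(t, ACETATE).n_features == 0

    def test_case_and_whitespace_folding(self):
        t = make_table({"a1: Acetate  Kinase|g__X": [1.0]}, ["s1"])
        assert extract_gene_group(t, ACETATE).n_features == 1

    def test_regex_escape_hatch(self):
        t = make_table({"a2: acetate kinase 2|g__X": [1.0]}, ["s1"])
        rx = GeneGroupDefinition("acetate", ("acetate kinase",), regex=True)
        assert extract_gene_group(t, rx).n_features == 1

    def test_empty_group_is_legal(self):
        t = make_table({"z: something else|g__X": [1.0]}, ["s1"])
        sub = extract_gene_group(t, ACETATE)
        assert sub.n_features == 0
        assert sub.samples == ["s1"]

    def test_group_sum_bounded_by_sample_total(self, simple_table):
        norm = normalize_to_cpm(simple_table)
        sub = extract_gene_group(norm, ACETATE)
        strat = sub.data.loc[sub.gene_total_mask()]
        assert (strat.sum() <= norm.grand_totals() + 1e-9).all()


class TestCollapseToLevel:
    def test_species_aggregate_to_genus(self):
        t = make_table(
            {
                "G1: x|g__Bacteroides.s__B_a": [3.0],
                "G1: x|g__Bacteroides.s__B_b": [5.0],
            },
            ["s1"],
        )
        m = collapse_to_level(t, "genus")
        assert m.data.loc["Bacteroides", "s1"] == 8.0

    def test_missing_genus_goes_to_unclassified_bucket(self):
        t = make_table({"G1: x|s__Lachnospiraceae_bacterium_X": [4.0]}, ["s1"])
        at_genus = collapse_to_level(t, "genus")
        assert at_genus.data.loc[UNCLASSIFIED_AT_LEVEL, "s1"] == 4.0
        at_species = collapse_to_level(t, "species")
        assert at_species.data.loc["Lachnospiraceae_bacterium_X", "s1"] == 4.0

    def test_unclassified_stratum_goes_to_bucket(self, simple_table):
        m = collapse_to_level(simple_table, "genus")
        assert m.data.loc[UNCLASSIFIED_AT_LEVEL, "s1"] == 10.0

    def test_column_sums_conserved(self, rng):
        rows = {}
        for i in range(20):
            g = f"g__T{rng.integers(0, 6)}"
            s = f"s__T{rng.integers(0, 6)}_sp{i}"
            rows[f"G{i}: x|{g}.{s}"] = rng.uniform(0, 5, 4).tolist()
        rows["G0: x|unclassified"] = rng.uniform(0, 5, 4).tolist()
        t = make_table(rows, list("abcd"))
        for level in ("phylum", "genus", "species", COMMUNITY_LEVEL):
            m = collapse_to_level(t, level)
            np.testing.assert_allclose(
                m.data.sum().to_numpy(), t.data.sum().to_numpy(), rtol=1e-12
            )

    def test_species_then_genus_matches_direct_genus_collapse(self, rng):
        rows = {}
        genus_of = {}
        for i in range(12):
            g = f"T{rng.integers(0, 4)}"
            sp = f"{g}_sp{i}"
            genus_of[sp] = g
            rows[f"G1: x|g__{g}.s__{sp}"] = rng.uniform(0, 5, 3).tolist()
        t = make_table(rows, list("abc"))
        direct = collapse_to_level(t, "genus").classified()
        via_species = collapse_to_level(t, "species").classified()
        regrouped = via_species.groupby(
            via_species.index.map(genus_of)
        ).sum()
        pd.testing.assert_frame_equal(
            direct.sort_index(), regrouped.sort_index(), check_names=False
        )

    def test_unknown_rank_rejected(self, simple_table):
        with pytest.raises(ValueError, match="strain"):
            collapse_to_level(simple_table, "strain")


class TestScfaRelativeAbundance:
    def _matrices(self, totals):
        mats = []
        for name, vals in totals.items():
            t = make_table({f"{name}_g: {name}|g__A": vals}, ["s1"])
            mats.append(collapse_to_level(t, COMMUNITY_LEVEL, name))
        return mats

    def test_forced_arithmetic(self):
        shares = scfa_relative_abundance(
            self._matrices({"acetate": [60.0], "butyrate": [20.0],
                            "propionate": [20.0]})
        )
        assert shares.loc["s1"].tolist() == pytest.approx([0.6, 0.2, 0.2])

    def test_single_nonzero_group(self):
        shares = scfa_relative_abundance(
            self._matrices({"acetate": [7.0], "butyrate": [0.0],
                            "propionate": [0.0]})
        )
        assert shares.loc["s1"].tolist() == pytest.approx([1.0, 0.0, 0.0])

    def test_all_zero_sample_flagged_missing(self):
        shares = scfa_relative_abundance(
            self._matrices({"acetate": [0.0], "butyrate": [0.0]})
        )
        assert shares.loc["s1"].isna().all()
        assert shares.attrs["missing_samples"] == ["s1"]
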