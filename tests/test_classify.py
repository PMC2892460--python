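import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pleionet import io as pio
from pleionet.classify import (
    ConfigurationError,
    assign_min_similarity,
    classify_all,
    classify_by_disease_count,
    essential_enrichment_table,
    mark_essential,
    split_phenosim_phenodiv,
)


def _table(pairs):
    return pio.DiseaseAssociationTable(pd.DataFrame(
        [(g, d, "") for g, d in pairs],
        columns=["gene_id", "disease_id", "disease_name"]))


class TestDiseaseCountSplit:
    def test_specific_and_shared(self):
        c = classify_by_disease_count(_table([
            ("G1", "D1"), ("G2", "D1"), ("G2", "D2"), ("G2", "D3")]))
        assert c.df.loc["G1", "gene_class"] == "specific"
        assert c.df.loc["G2", "gene_class"] == "shared"
        assert c.df.loc["G2", "disease_count"] == 3

    def test_partition_exact(self):
        pairs = [("G1", "D1"), ("G2", "D2"), ("G3", "D3"),
                 ("G4", "D1"), ("G4", "D2"), ("G5", "D1"), ("G5", "D3")]
        c = classify_by_disease_count(_table(pairs))
        counts = c.class_counts()
        assert counts["specific"] == 3 and counts["shared"] == 2
        assert c.genes_in_class("specific") | c.genes_in_class("shared") == set(c.df.index)

    def test_empty_table_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_by_disease_count(_table([]))


class TestMinSimilarity:
    def test_min_over_pairs(self, toy_sims):
        c = classify_by_disease_count(_table(
            [("G4", "D1"), ("G4", "D2"), ("G4", "D4")]))
        c = assign_min_similarity(c, _table(
            [("G4", "D1"), ("G4", "D2"), ("G4", "D4")]), toy_sims)
        # pair scores {0.5, 0.2, 0.9} -> minimum 0.2
        assert c.df.loc["G4", "min_similarity"] == pytest.approx(0.2)

    def test_unscored_pair_leaves_gene_unscored(self, toy_sims):
        assoc = _table([("G9", "D1"), ("G9", "D7")])  # D1-D7 not in table
        c = assign_min_similarity(classify_by_disease_count(assoc), assoc, toy_sims)
        assert np.isnan(c.df.loc["G9", "min_similarity"])
        assert c.n_unscored_shared == 1

    def test_specific_gene_never_scored(self, toy_sims):
        assoc = _table([("G1", "D1")])
        c = assign_min_similarity(classify_by_disease_count(assoc), assoc, toy_sims)
        assert np.isnan(c.df.loc["G1", "min_similarity"])

    def test_per_disease_mode_uses_disease_means(self, toy_sims):
        assoc = _table([("G4", "D1"), ("G4", "D2"), ("G4", "D4")])
        c = assign_min_similarity(classify_by_disease_count(assoc), assoc,
                                  toy_sims, mode="per_disease")
        # per-disease means: D1 (0.5+0.2)/2=0.35, D2 (0.5+0.9)/2=0.7, D4 0.55
        assert c.df.loc["G4", "min_similarity"] == pytest.approx(0.35)


def _scored(scores):
    df = pd.DataFrame({
        "disease_count": [2] * len(scores),
        "gene_class": ["shared"] * len(scores),
        "min_similarity": scores,
        "is_essential": False,
        "is_disease_gene": True,
    }, index=[f"G{i}" for i in range(len(scores))])
    from pleionet.classify import ClassifiedGenes
    return ClassifiedGenes(df)


class TestPhenoSplit:
    def test_median_rule(self):
        c = split_phenosim_phenodiv(_scored([0.1, 0.2, 0.4, 0.5]), cutoff="median")
        assert c.resolved_cutoff == pytest.approx(0.3)
        counts = c.class_counts()
        assert counts["phenodiv"] == 2 and counts["phenosim"] == 2

    def test_score_equal_to_cutoff_is_phenosim(self):
        c = split_phenosim_phenodiv(_scored([0.33, 0.1]), cutoff=0.33)
        assert c.df.iloc[0]["gene_class"] == "phenosim"
        assert c.df.iloc[1]["gene_class"] == "phenodiv"

    def test_single_scored_gene_is_phenosim(self):
        c = split_phenosim_phenodiv(_scored([0.7]), cutoff="median")
        assert c.df.iloc[0]["gene_class"] == "phenosim"

    def test_no_scored_genes_is_config_error(self):
        with pytest.raises(ConfigurationError):
            split_phenosim_phenodiv(_scored([np.nan]), cutoff="median")

    @given(st.floats(min_value=0, max_value=1))
    @settings(deadline=None, max_examples=30)
    def test_phenosim_set_non_increasing_in_cutoff(self, cutoff):
        scores = [0.05, 0.2, 0.33, 0.4, 0.66, 0.9]
        lo = split_phenosim_phenodiv(_scored(scores), cutoff=cutoff)
        hi = split_phenosim_phenodiv(_scored(scores), cutoff=min(1.0, cutoff + 0.1))
        assert hi.genes_in_class("phenosim") <= lo.genes_in_class("phenosim")


class TestEssential:
    def test_axes(self):
        assoc = _table([("G1", "D1"), ("G2", "D2")])
        c = mark_essential(classify_by_disease_count(assoc),
                           pio.GeneSet({"G1", "G3"}, "ess"))
        assert c.genes_in_class("essential_disease") == {"G1"}
        assert c.genes_in_class("essential_nondisease") == {"G3"}
        assert not c.df.loc["G2", "is_essential"]

    def test_empty_essential_set(self):
        assoc = _table([("G1", "D1")])
        c = mark_essential(classify_by_disease_count(assoc), pio.GeneSet(set(), "ess"))
        assert not c.df["is_essential"].any()

    def test_enrichment_table_counts(self):
        assoc = _table([(f"G{i}", "D1") for i in range(1, 5)]
                       + [(f"H{i}", "D1") for i in range(1, 5)]
                       + [(f"H{i}", "D2") for i in range(1, 5)])
        c = mark_essential(classify_by_disease_count(assoc),
                           pio.GeneSet({"H1", "H2", "G1"}, "ess"))
        assert essential_enrichment_table(c, "shared", "specific") == [[2, 2], [1, 3]]

    def test_enrichment_table_empty_class_errors(self):
        assoc = _table([("G1", "D1")])
        c = mark_essential(classify_by_disease_count(assoc), pio.GeneSet(set(), "e"))
        with pytest.raises(ConfigurationError):
            essential_enrichment_table(c, "shared", "specific")

    def test_planted_essentiality_recovered_as_odds_ratio(self):
        # essentiality planted at twice the rate in shared genes
        rng = np.random.default_rng(5)
        pairs, essential = [], set()
        for i in range(300):
            g = f"S{i:03d}"
            pairs.append((g, f"D{i}a"))
            if rng.random() < 0.2:
                essential.add(g)
        for i in range(300):
            g = f"M{i:03d}"
            pairs += [(g, f"E{i}a"), (g, f"E{i}b")]
            if rng.random() < 0.4:
                essential.add(g)
        c = mark_essential(classify_by_disease_count(_table(pairs)),
                           pio.GeneSet(essential, "ess"))
        t = essential_enrichment_table(c, "shared", "specific")
        odds = (t[0][0] * t[1][1]) / (t[0][1] * t[1][0])
        assert odds > 1


def test_classification_invariant_to_row_order_and_duplicates(toy_assoc, toy_sims):
    ess = pio.GeneSet({"G2"}, "ess")
    base = classify_all(toy_assoc, toy_sims, ess, cutoff=0.33)
    shuffled = pio.DiseaseAssociationTable(
        pd.concat([toy_assoc.df.iloc[::-1], toy_assoc.df.iloc[:2]])
        .drop_duplicates(["gene_id", "disease_id"]).reset_index(drop=True))
    other = classify_all(shuffled, toy_sims, ess, cutoff=0.33)
    pd.testing.assert_frame_equal(base.df.sort_index(), other.df.sort_index())
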