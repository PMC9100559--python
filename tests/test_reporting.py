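"""Assessment merging, category tables, group summaries and bias diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from oracles import ray_casting_contains
from treerisk import reporting
from treerisk.qc import LAT, LON

# Published per-category counts for the world's tree species: official Red
# List column and model-prediction column of the five-class assessment.
RL_COUNTS = {"LC": 16349, "NT": 1953, "VU": 4864, "EN": 4836, "CR": 2498}
PRED_COUNTS = {"LC": 11670, "NT": 4, "VU": 3569, "EN": 4248, "CR": 2200}
N_UNIVERSE = 58429


def build_universe():
    """Synthetic species universe reproducing the published per-category
    label and prediction counts exactly."""
    labels, predictions, universe = [], [], []
    i = 0
    for cat, n in RL_COUNTS.items():
        for _ in range(n):
            sp = f"sp_{i:06d}"
            universe.append(sp)
            labels.append({"species": sp, "category": cat})
            i += 1
    for cat, n in PRED_COUNTS.items():
        for _ in range(n):
            sp = f"sp_{i:06d}"
            universe.append(sp)
            predictions.append({"species": sp, "predicted_class": cat})
            i += 1
    while i < N_UNIVERSE:
        universe.append(f"sp_{i:06d}")
        i += 1
    return pd.DataFrame(labels), pd.DataFrame(predictions), universe


class TestMergeAssessments:
    def test_three_species_example(self):
        labels = pd.DataFrame({"species": ["A"], "category": ["LC"]})
        preds = pd.DataFrame({"species": ["B"], "predicted_class": ["EN"]})
        out = reporting.merge_assessments(labels, preds, ["A", "B", "C"])
        by_sp = out.set_index("species")
        assert by_sp.loc["A", ["status", "source"]].tolist() == ["LC", "rl_label"]
        assert by_sp.loc["B", ["status", "source"]].tolist() == ["EN", "prediction"]
        assert by_sp.loc["C", "source"] == "not_evaluated"

    def test_label_precedence_over_prediction(self):
        labels = pd.DataFrame({"species": ["A"], "category": ["VU"]})
        preds = pd.DataFrame({"species": ["A"], "predicted_class": ["LC"]})
        out = reporting.merge_assessments(labels, preds, ["A"])
        assert out.loc[0, "status"] == "VU"
        assert out.loc[0, "source"] == "rl_label"

    def test_data_deficient_receives_prediction(self):
        labels = pd.DataFrame({"species": ["A"], "category": ["DD"]})
        preds = pd.DataFrame({"species": ["A"], "predicted_class": ["EN"]})
        out = reporting.merge_assessments(labels, preds, ["A"])
        assert out.loc[0, ["status", "source"]].tolist() == ["EN", "prediction"]

    def test_prediction_outside_universe_rejected(self):
        preds = pd.DataFrame({"species": ["ghost"], "predicted_class": ["EN"]})
        with pytest.raises(ValueError, match="universe"):
            reporting.merge_assessments(pd.DataFrame({"species": [], "category": []}), preds, ["A"])

    def test_universe_appears_exactly_once(self):
        labels, preds, universe = build_universe()
        out = reporting.merge_assessments(labels, preds, universe)
        assert len(out) == N_UNIVERSE
        assert out["species"].is_unique


class TestCategoryTable:
    def test_published_five_class_merge(self):
        labels, preds, universe = build_universe()
        merged = reporting.merge_assessments(labels, preds, universe)
        table = reporting.category_table(merged).set_index("category")
        # merged counts are the sum of label and prediction counts
        assert table.loc["LC", "merged_count"] == 28019
        assert table.loc["NT", "merged_count"] == 1957
        assert table.loc["VU", "merged_count"] == 8433
        assert table.loc["EN", "merged_count"] == 9084
        assert table.loc["CR", "merged_count"] == 4698
        assert table.loc["NE/DD", "merged_count"] == 6238
        # percentages over the RL-labeled / assessed totals
        assert table.loc["LC", "rl_pct"] == 53.6
        assert table.loc["NT", "rl_pct"] == 6.4
        assert table.loc["VU", "rl_pct"] == 15.9
        assert table.loc["EN", "rl_pct"] == 15.9
        assert table.loc["CR", "rl_pct"] == 8.2
        assert table.loc["LC", "merged_pct"] == 53.7
        assert table.loc["NT", "merged_pct"] == 3.7
        assert table.loc["VU", "merged_pct"] == 16.2
        assert table.loc["EN", "merged_pct"] == 17.4
        assert table.loc["CR", "merged_pct"] == 9.0

    def test_published_binary_merge(self):
        # the binary model's published prediction counts (11,000 / 10,691)
        # come from the separately trained binary network, not from folding
        # the 5-class prediction column
        binary_rl = {"not_threatened": 18302, "possibly_threatened": 12198}
        binary_pred = {"not_threatened": 11000, "possibly_threatened": 10691}
        labels, predictions, universe = [], [], []
        i = 0
        # official labels carry Red List categories; LC/VU stand in for the
        # two groups and statuses are folded after merging
        for cat, n in (("LC", binary_rl["not_threatened"]), ("VU", binary_rl["possibly_threatened"])):
            for _ in range(n):
                sp = f"sp_{i:06d}"
                universe.append(sp)
                labels.append({"species": sp, "category": cat})
                i += 1
        for cat, n in binary_pred.items():
            for _ in range(n):
                sp = f"sp_{i:06d}"
                universe.append(sp)
                predictions.append({"species": sp, "predicted_class": cat})
                i += 1
        while i < N_UNIVERSE:
            universe.append(f"sp_{i:06d}")
            i += 1
        merged = reporting.merge_assessments(
            pd.DataFrame(labels), pd.DataFrame(predictions), universe
        )
        fold = {"LC": "not_threatened", "VU": "possibly_threatened"}
        merged["status"] = merged["status"].map(lambda c: fold.get(c, c))
        table = reporting.category_table(
            merged, categories=("not_threatened", "possibly_threatened")
        ).set_index("category")
        assert table.loc["not_threatened", "rl_count"] == 18302
        assert table.loc["not_threatened", "rl_pct"] == 60.0
        assert table.loc["possibly_threatened", "rl_pct"] == 40.0
        assert table.loc["not_threatened", "pred_count"] == 11000
        assert table.loc["not_threatened", "pred_pct"] == 50.7
        assert table.loc["possibly_threatened", "pred_pct"] == 49.3
        assert table.loc["not_threatened", "merged_count"] == 29302
        assert table.loc["not_threatened", "merged_pct"] == 56.1
        assert table.loc["possibly_threatened", "merged_count"] == 22889
        assert table.loc["possibly_threatened", "merged_pct"] == 43.9

    def test_single_category_is_hundred_percent(self):
        labels = pd.DataFrame({"species": ["a", "b"], "category": ["CR", "CR"]})
        merged = reporting.merge_assessments(labels, pd.DataFrame({"species": [], "predicted_class": []}), ["a", "b"])
        table = reporting.category_table(merged).set_index("category")
        assert table.loc["CR", "rl_pct"] == 100.0
        assert table.loc["CR", "merged_pct"] == 100.0

    def test_empty_predictions_merged_equals_rl(self):
        labels = pd.DataFrame({"species": ["a", "b"], "category": ["LC", "EN"]})
        merged = reporting.merge_assessments(labels, pd.DataFrame({"species": [], "predicted_class": []}), ["a", "b"])
        table = reporting.category_table(merged)
        assert (table["pred_count"][:-1] == 0).all()
        assert (table["merged_count"] == table["rl_count"]).all()


def make_assessment(rows):
    return pd.DataFrame(rows, columns=["species", "status", "source", "confidence"])


class TestTaxonSummaries:
    def test_ranking_by_count_and_conservation(self):
        rows = [(f"s{i}", "EN", "rl_label", np.nan) for i in range(5)]
        rows += [(f"t{i}", "EN", "prediction", 0.9) for i in range(3)]
        rows += [("u0", "LC", "rl_label", np.nan)]
        assessment = make_assessment(rows)
        taxonomy = pd.DataFrame(
            {
                "species": [r[0] for r in rows],
                "genus": "g",
                "family": ["fam1"] * 5 + ["fam2"] * 3 + ["fam2"],
                "order": "o",
            }
        )
        summary, by_count, by_prop = reporting.summarize_by_taxon(assessment, taxonomy)
        assert list(by_count["group"][:2]) == ["fam1", "fam2"]
        assert summary["n_species"].sum() == len(rows)
        s = summary.set_index("group")
        assert s.loc["fam1", "n_threatened_rl"] == 5
        assert s.loc["fam2", "n_threatened_pred"] == 3

    def test_small_families_excluded_from_proportion_ranking(self):
        rows = [(f"s{i}", "CR", "rl_label", np.nan) for i in range(3)]  # tiny, 100% threatened
        rows += [(f"b{i}", "VU" if i < 8 else "LC", "rl_label", np.nan) for i in range(12)]
        assessment = make_assessment(rows)
        taxonomy = pd.DataFrame(
            {"species": [r[0] for r in rows], "genus": "g", "family": ["tiny"] * 3 + ["big"] * 12, "order": "o"}
        )
        summary, _, by_prop = reporting.summarize_by_taxon(assessment, taxonomy, min_group_size=10)
        assert "tiny" not in set(by_prop["group"])
        assert list(by_prop["group"]) == ["big"]

    def test_unmapped_species_grouped_unknown(self):
        assessment = make_assessment([("x", "LC", "rl_label", np.nan)])
        taxonomy = pd.DataFrame({"species": [], "genus": [], "family": [], "order": []})
        summary, _, _ = reporting.summarize_by_taxon(assessment, taxonomy)
        assert list(summary["group"]) == ["unknown"]


class TestSpatialSummaries:
    def test_assignment_matches_ray_casting(self, world, clean_dataset):
        occ, _, _ = clean_dataset
        sub = occ.head(300)
        assigned = reporting.assign_countries(sub, world.countries)
        rings = [list(p.exterior.coords[:-1]) for p in world.countries]
        for sp, grp in sub.groupby("species"):
            expected = set()
            for lon, lat in zip(grp[LON], grp[LAT]):
                for cid, ring in enumerate(rings):
                    if ray_casting_contains(ring, lon, lat):
                        expected.add(cid)
                        break
            assert assigned[sp] == expected

    def test_country_summary_suppression_and_multicountry(self):
        rows = [(f"s{i}", "EN", "rl_label", np.nan) for i in range(6)] + [("t0", "LC", "rl_label", np.nan)]
        assessment = make_assessment(rows)
        mapping = {f"s{i}": {0} for i in range(6)}
        mapping["t0"] = {0, 1}  # occurs in both countries
        out = reporting.country_threat_summary(assessment, mapping, min_assessed=5).set_index("country")
        assert out.loc[0, "n_assessed"] == 7
        assert out.loc[0, "fraction_threatened"] == pytest.approx(6 / 7)
        assert out.loc[1, "n_assessed"] == 1
        assert np.isnan(out.loc[1, "fraction_threatened"])  # below min_assessed

    def test_per_country_accuracy_trivial_and_brute_force(self):
        species = [f"s{i}" for i in range(6)]
        correct = np.array([True, True, False, True, False, True])
        mapping = {sp: {0} for sp in species}
        acc = reporting.per_country_accuracy(species, correct, mapping)
        assert acc[0] == pytest.approx(correct.mean())
        mapping["s0"] = {0, 1}
        mapping["s2"] = {1}
        acc = reporting.per_country_accuracy(species, correct, mapping)
        assert acc[1] == pytest.approx(1 / 2)  # s0 correct, s2 wrong

    def test_adding_unevaluated_species_never_changes_fraction(self):
        rows = [("a", "EN", "rl_label", np.nan), ("b", "LC", "prediction", 0.8)]
        assessment = make_assessment(rows)
        mapping = {"a": {0}, "b": {0}}
        base = reporting.country_threat_summary(assessment, mapping, min_assessed=1)
        rows.append(("c", "NE", "not_evaluated", np.nan))
        mapping["c"] = {0}
        more = reporting.country_threat_summary(make_assessment(rows), mapping, min_assessed=1)
        assert base.loc[0, "fraction_threatened"] == more.loc[0, "fraction_threatened"]


class TestBiasDiagnostics:
    def test_fully_labeled_degenerate(self):
        taxonomy = pd.DataFrame(
            {"species": [f"s{i}" for i in range(10)], "genus": "g", "family": ["f1"] * 5 + ["f2"] * 5, "order": "o"}
        )
        flags = pd.Series(True, index=taxonomy["species"])
        out = reporting.bias_diagnostics(flags, taxonomy)
        assert np.all(out["family"]["fractions"] == 1.0)

    def test_random_labeling_uncorrelated_with_size(self):
        rng = np.random.default_rng(3)
        n = 600
        species = [f"s{i}" for i in range(n)]
        fam_sizes = rng.integers(5, 60, 25)
        fams = np.repeat([f"f{j}" for j in range(25)], fam_sizes)[:n]
        taxonomy = pd.DataFrame({"species": species, "genus": "g", "family": fams[:n], "order": "o"})
        flags = pd.Series(rng.random(n) < 0.5, index=species)
        out = reporting.bias_diagnostics(flags, taxonomy)
        rho = out["family"]["size_rank_correlation"]
        # null permutation bound for |spearman rho| at n_groups ~ 25
        null = [
            abs(spearmanr(rng.permutation(25), np.arange(25)).statistic) for _ in range(500)
        ]
        assert abs(rho) <= np.quantile(null, 0.999)

    def test_constructed_negative_signal_detected(self):
        rng = np.random.default_rng(8)
        species, countries, flags = [], {}, {}
        for c in range(20):
            size = 5 + 10 * c
            p_label = 0.9 - 0.035 * c  # richer countries less assessed
            for i in range(size):
                sp = f"c{c}_s{i}"
                species.append(sp)
                countries[sp] = {c}
                flags[sp] = bool(rng.random() < p_label)
        out = reporting.bias_diagnostics(pd.Series(flags), species_countries=countries)
        assert out["country"]["size_rank_correlation"] < -0.5
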