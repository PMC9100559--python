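"""Merged assessment tables and taxonomic / spatial threat summaries.

Red List labels take precedence over model predictions: a species with
an official category keeps it, Data Deficient and unevaluated species
receive the model's prediction when features exist, and the remainder
stay not-evaluated. On top of the merged table this module computes the
per-category count table, family/order rankings of threatened species,
per-country and per-biome summaries, per-country prediction accuracy,
and the taxonomic/geographic assessment-bias diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
import shapely

from .model import FIVE_CLASSES
from .qc import LAT, LON

THREATENED_STATUSES = {"VU", "EN", "CR", "possibly_threatened"}
NOT_THREATENED_STATUSES = {"LC", "NT", "not_threatened"}

SOURCE_RL = "rl_label"
SOURCE_PREDICTION = "prediction"
SOURCE_NOT_EVALUATED = "not_evaluated"


def is_threatened(status) -> bool:
    return status in THREATENED_STATUSES


def merge_assessments(
    rl_labels: pd.DataFrame, predictions: pd.DataFrame, species_universe: list[str]
) -> pd.DataFrame:
    """Merge official labels and predictions over a species universe.

    ``rl_labels`` has columns (species, category); ``predictions`` has
    (species, predicted_class[, confidence]). An official category among
    the five classes always wins; DD counts as unlabeled. Returns one row
    per universe species with columns (species, status, source,
    confidence).
    """
    universe = list(species_universe)
    missing = set(predictions["species"]) - set(universe)
    if missing:
        raise ValueError(f"{len(missing)} predicted species absent from the universe, e.g. {sorted(missing)[:3]}")

    label_map = {
        sp: cat for sp, cat in zip(rl_labels["species"], rl_labels["category"]) if cat in FIVE_CLASSES
    }
    pred_map = dict(zip(predictions["species"], predictions["predicted_class"]))
    conf_map = (
        dict(zip(predictions["species"], predictions["confidence"]))
        if "confidence" in predictions.columns
        else {}
    )

    rows = []
    for sp in universe:
        if sp in label_map:
            rows.append((sp, label_map[sp], SOURCE_RL, np.nan))
        elif sp in pred_map:
            rows.append((sp, pred_map[sp], SOURCE_PREDICTION, conf_map.get(sp, np.nan)))
        else:
            rows.append((sp, "NE", SOURCE_NOT_EVALUATED, np.nan))
    return pd.DataFrame(rows, columns=["species", "status", "source", "confidence"])


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def category_table(assessment: pd.DataFrame, categories: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-category counts and percentages by source (rl / prediction / merged).

    Percentage denominators are per column: RL percentages over all
    RL-labeled species, prediction percentages over all predicted
    species, merged percentages over all assessed species. Not-evaluated
    species are reported as a separate NE/DD row without percentages.
    """
    rl = assessment[assessment["source"] == SOURCE_RL]
    pred = assessment[assessment["source"] == SOURCE_PREDICTION]
    n_rl, n_pred = len(rl), len(pred)
    n_assessed = n_rl + n_pred
    if categories is None:
        categories = tuple(
            c for c in list(FIVE_CLASSES) + ["not_threatened", "possibly_threatened"]
            if (assessment["status"] == c).any()
        )
    rows = []
    for cat in categories:
        c_rl = int((rl["status"] == cat).sum())
        c_pred = int((pred["status"] == cat).sum())
        c_merged = c_rl + c_pred
        rows.append(
            {
                "category": cat,
                "rl_count": c_rl,
                "rl_pct": _round_half_away(100.0 * c_rl / n_rl, 1) if n_rl else np.nan,
                "pred_count": c_pred,
                "pred_pct": _round_half_away(100.0 * c_pred / n_pred, 1) if n_pred else np.nan,
                "merged_count": c_merged,
                "merged_pct": _round_half_away(100.0 * c_merged / n_assessed, 1) if n_assessed else np.nan,
            }
        )
    n_ne = int((assessment["source"] == SOURCE_NOT_EVALUATED).sum())
    rows.append(
        {
            "category": "NE/DD",
            "rl_count": n_ne,
            "rl_pct": np.nan,
            "pred_count": n_ne,
            "pred_pct": np.nan,
            "merged_count": n_ne,
            "merged_pct": np.nan,
        }
    )
    return pd.DataFrame(rows)


def _group_summary(assessment: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    df = assessment.copy()
    df["group"] = groups.reindex(df["species"]).fillna("unknown").to_numpy()
    rows = []
    for g, grp in df.groupby("group", sort=True):
        assessed = grp[grp["source"] != SOURCE_NOT_EVALUATED]
        thr = assessed["status"].map(is_threatened)
        rows.append(
            {
                "group": g,
                "n_species": len(grp),
                "n_assessed": len(assessed),
                "n_not_evaluated": len(grp) - len(assessed),
                "n_threatened": int(thr.sum()),
                "n_threatened_rl": int((thr & (assessed["source"] == SOURCE_RL)).sum()),
                "n_threatened_pred": int((thr & (assessed["source"] == SOURCE_PREDICTION)).sum()),
                "n_not_threatened": int((~thr).sum()),
                "n_not_threatened_rl": int((~thr & (assessed["source"] == SOURCE_RL)).sum()),
                "n_not_threatened_pred": int((~thr & (assessed["source"] == SOURCE_PREDICTION)).sum()),
                "fraction_threatened": float(thr.mean()) if len(assessed) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_by_taxon(
    assessment: pd.DataFrame, taxonomy: pd.DataFrame, level: str = "family", min_group_size: int = 10
):
    """Per-taxon threat summary plus the two rankings: by threatened count,
    and by threatened proportion among groups with more than
    ``min_group_size`` assessed species. Ties break on group name."""
    groups = taxonomy.set_index("species")[level]
    summary = _group_summary(assessment, groups)
    by_count = summary.sort_values(["n_threatened", "group"], ascending=[False, True]).reset_index(drop=True)
    eligible = summary[summary["n_assessed"] > min_group_size]
    by_proportion = eligible.sort_values(
        ["fraction_threatened", "group"], ascending=[False, True]
    ).reset_index(drop=True)
    return summary, by_count, by_proportion


def assign_polygons(cleaned: pd.DataFrame, polygons) -> dict[str, set[int]]:
    """species -> set of polygon ids containing >= 1 cleaned record.
    Records in no polygon are ignored for assignment."""
    pts = shapely.points(cleaned[LON].to_numpy(dtype=float), cleaned[LAT].to_numpy(dtype=float))
    species = cleaned["species"].to_numpy()
    out: dict[str, set[int]] = {sp: set() for sp in np.unique(species)}
    for pid, poly in enumerate(polygons):
        inside = shapely.covers(poly, pts)
        for sp in np.unique(species[inside]):
            out[sp].add(pid)
    return out


def assign_countries(cleaned: pd.DataFrame, country_polygons) -> dict[str, set[int]]:
    return assign_polygons(cleaned, country_polygons)


def country_threat_summary(
    assessment: pd.DataFrame,
    species_countries: dict[str, set[int]],
    min_assessed: int = 5,
    country_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-country threatened counts and (suppressed below ``min_assessed``)
    threatened fractions. A species occurring in several countries counts
    once in each."""
    status = assessment.set_index("species")["status"]
    source = assessment.set_index("species")["source"]
    all_ids = sorted({c for cs in species_countries.values() for c in cs})
    rows = []
    for cid in all_ids:
        members = [sp for sp, cs in species_countries.items() if cid in cs and sp in status.index]
        assessed = [sp for sp in members if source[sp] != SOURCE_NOT_EVALUATED]
        n_thr = sum(is_threatened(status[sp]) for sp in assessed)
        frac = n_thr / len(assessed) if len(assessed) >= min_assessed else np.nan
        rows.append(
            {
                "country": country_names[cid] if country_names else cid,
                "n_species": len(members),
                "n_assessed": len(assessed),
                "n_threatened": int(n_thr),
                "fraction_threatened": frac,
            }
        )
    return pd.DataFrame(rows)


def per_country_accuracy(
    species: list[str], correct: np.ndarray, species_countries: dict[str, set[int]]
) -> pd.Series:
    """Cross-validation accuracy per country: the fraction of labeled species
    occurring in the country whose held-out prediction was correct."""
    correct = np.asarray(correct, dtype=bool)
    totals: dict[int, int] = {}
    hits: dict[int, int] = {}
    for sp, ok in zip(species, correct):
        for cid in species_countries.get(sp, ()):
            totals[cid] = totals.get(cid, 0) + 1
            hits[cid] = hits.get(cid, 0) + int(ok)
    return pd.Series({cid: hits[cid] / totals[cid] for cid in sorted(totals)}, name="accuracy")


def bias_diagnostics(
    labeled_flags: pd.Series,
    taxonomy: pd.DataFrame | None = None,
    species_countries: dict[str, set[int]] | None = None,
    species_biomes: dict[str, set[int]] | None = None,
) -> dict:
    """Assessment-coverage bias diagnostics.

    ``labeled_flags`` maps species -> bool (has a usable label). For each
    grouping level (genus/family/order/country/biome) the per-group
    assessed fraction distribution is summarized (quantiles and 95%
    range) along with the Spearman rank correlation between group size
    and assessed fraction — a systematic bias would show up as a strong
    correlation or a bimodal fraction distribution.
    """
    out: dict[str, dict] = {}

    def summarize(level: str, groups_per_species: dict[str, list]):
        sizes, fracs = [], []
        groups: dict = {}
        for sp, gs in groups_per_species.items():
            for g in gs:
                groups.setdefault(g, []).append(bool(labeled_flags.get(sp, False)))
        for flags in groups.values():
            sizes.append(len(flags))
            fracs.append(float(np.mean(flags)))
        sizes_arr = np.asarray(sizes, dtype=float)
        fracs_arr = np.asarray(fracs, dtype=float)
        if len(fracs_arr) >= 2 and np.std(fracs_arr) > 0 and np.std(sizes_arr) > 0:
            rho = float(spearmanr(sizes_arr, fracs_arr).statistic)
        else:
            rho = float("nan")
        out[level] = {
            "n_groups": len(fracs_arr),
            "fractions": fracs_arr,
            "quantiles": {
                q: float(np.quantile(fracs_arr, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)
            },
            "range_95": (float(np.quantile(fracs_arr, 0.025)), float(np.quantile(fracs_arr, 0.975))),
            "size_rank_correlation": rho,
        }

    if taxonomy is not None:
        for level in ("genus", "family", "order"):
            summarize(level, {sp: [g] for sp, g in zip(taxonomy["species"], taxonomy[level])})
    if species_countries is not None:
        summarize("country", {sp: sorted(cs) for sp, cs in species_countries.items()})
    if species_biomes is not None:
        summarize("biome", {sp: sorted(bs) for sp, bs in species_biomes.items()})
    return out
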