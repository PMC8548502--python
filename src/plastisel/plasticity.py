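"""Classifying heat-induced expression plasticity as adaptive or
maladaptive, per lineage.

A candidate gene is a positive regulator if its expression correlates
positively with heat tolerance (CT_MAX), negative otherwise. Its
heat-induced plasticity is the common-garden 25->32 degC log-fold change
within a lineage. Plasticity whose direction is congruent with higher
CT_MAX is adaptive:

    positive regulator, upregulated at 32 degC   -> adaptive
    positive regulator, downregulated at 32 degC -> maladaptive
    negative regulator, downregulated at 32 degC -> adaptive
    negative regulator, upregulated at 32 degC   -> maladaptive

|lfc| <= epsilon is called indeterminate (epsilon defaults to 0, so only
exact-zero changes are indeterminate). This is a congruence rule, not a
fitness measurement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .stats import two_proportion_test, welch_t_test

__all__ = [
    "classify_gene",
    "classify_cohort",
    "summarize_calls",
    "plasticity_proportion_tests",
    "plasticity_magnitude_test",
]


def classify_gene(regulator_class: str, lfc_25_to_32: float,
                  epsilon: float = 0.0) -> str:
    """Apply the congruence rule to one gene; returns 'adaptive',
    'maladaptive' or 'indeterminate'."""
    if regulator_class not in ("positive", "negative"):
        raise ValidationError(
            f"regulator_class must be 'positive' or 'negative', "
            f"got {regulator_class!r}")
    if abs(lfc_25_to_32) <= epsilon:
        return "indeterminate"
    up = lfc_25_to_32 > 0
    if regulator_class == "positive":
        return "adaptive" if up else "maladaptive"
    return "maladaptive" if up else "adaptive"


def classify_cohort(gs_table: pd.DataFrame, lfc_forest: pd.Series,
                    lfc_urban: pd.Series, epsilon: float = 0.0) -> pd.DataFrame:
    """One call per candidate gene per lineage.

    ``gs_table`` is the full-cohort gene-significance table with
    ``candidate`` and ``regulator_class`` columns; the LFC series are the
    per-lineage common-garden 25->32 degC log-fold changes. Regulator
    classes come from the full cohort for both lineages.
    """
    candidates = gs_table.index[gs_table["candidate"].astype(bool)]
    if len(candidates) == 0:
        raise ValidationError("no candidate genes to classify")
    rows = []
    for lineage, lfc in (("forest", lfc_forest), ("urban", lfc_urban)):
        missing = [g for g in candidates if g not in lfc.index]
        if missing:
            raise ValidationError(
                f"candidates absent from {lineage} LFC table: {missing[:5]}")
        for gene in candidates:
            cls = gs_table.at[gene, "regulator_class"]
            value = float(lfc.at[gene])
            rows.append({
                "gene_id": gene,
                "lineage": lineage,
                "regulator_class": cls,
                "lfc_25_to_32": value,
                "call": classify_gene(cls, value, epsilon=epsilon),
            })
    return pd.DataFrame(rows)


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Counts and proportions by lineage, call, and (class x direction)."""
    out: dict = {}
    for lineage, sub in calls.groupby("lineage"):
        determinate = sub[sub["call"] != "indeterminate"]
        n_det = len(determinate)
        n_mal = int((determinate["call"] == "maladaptive").sum())
        n_ad = n_det - n_mal
        entry = {
            "n": int(len(sub)),
            "n_determinate": n_det,
            "n_indeterminate": int(len(sub) - n_det),
            "n_maladaptive": n_mal,
            "n_adaptive": n_ad,
            "prop_maladaptive": n_mal / n_det if n_det else float("nan"),
            "prop_adaptive": n_ad / n_det if n_det else float("nan"),
            "by_class_direction": {},
        }
        for cls in ("positive", "negative"):
            csub = determinate[determinate["regulator_class"] == cls]
            n_cls = len(csub)
            n_up = int((csub["lfc_25_to_32"] > 0).sum())
            entry["by_class_direction"][cls] = {
                "n": n_cls,
                "n_up": n_up,
                "n_down": n_cls - n_up,
                "prop_up": n_up / n_cls if n_cls else float("nan"),
                "prop_down": (n_cls - n_up) / n_cls if n_cls else float("nan"),
            }
        out[lineage] = entry
    return out


def plasticity_proportion_tests(calls: pd.DataFrame) -> dict:
    """Within-lineage exact binomial tests of the maladaptive fraction
    against 0.5, and forest-vs-urban comparisons: an exact binomial test of
    the urban adaptive count against the forest adaptive proportion, plus
    the two-sample equality-of-proportions chi-square with continuity
    correction. Indeterminate calls are excluded (count reported)."""
    summary = summarize_calls(calls)
    report: dict = {"summary": summary, "within_lineage": {}, "between_lineage": {}}
    for lineage, entry in summary.items():
        n_det, n_mal = entry["n_determinate"], entry["n_maladaptive"]
        if n_det == 0:
            raise ValidationError(f"no determinate calls for {lineage}")
        test = sps.binomtest(n_mal, n_det, p=0.5, alternative="two-sided")
        report["within_lineage"][lineage] = {
            "n": n_det, "n_maladaptive": n_mal,
            "prop_maladaptive": entry["prop_maladaptive"],
            "binomial_p": float(test.pvalue),
        }
    if {"forest", "urban"} <= set(summary):
        f, u = summary["forest"], summary["urban"]
        exact = sps.binomtest(u["n_adaptive"], u["n_determinate"],
                              p=f["prop_adaptive"], alternative="two-sided")
        prop = two_proportion_test(f["n_maladaptive"], f["n_determinate"],
                                   u["n_maladaptive"], u["n_determinate"])
        report["between_lineage"] = {
            "exact_binomial_p_adaptive": float(exact.pvalue),
            "two_proportion": prop,
        }
    return report


def plasticity_magnitude_test(lfc_forest: pd.Series, lfc_urban: pd.Series,
                              candidate_ids) -> dict:
    """Welch two-sample t-test of |LFC| magnitudes (forest vs urban) over
    the candidate genes: tests whether the urban lineage shows attenuated
    heat-induced plasticity."""
    ids = [g for g in candidate_ids
           if g in lfc_forest.index and g in lfc_urban.index]
    if len(ids) < 2:
        raise ValidationError("need at least 2 candidate genes per group")
    res = welch_t_test(np.abs(lfc_forest.loc[ids].to_numpy()),
                       np.abs(lfc_urban.loc[ids].to_numpy()))
    res["n"] = len(ids)
    res["mean_abs_lfc_forest"] = res.pop("mean_x")
    res["mean_abs_lfc_urban"] = res.pop("mean_y")
    return res
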