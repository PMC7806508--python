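"""Immunohistochemistry Histoscores and diagnostic-accuracy statistics.

The Histoscore of a sample is sum(i * pct_i) over staining intensities
i in {0..3}, where pct_i is the percent of tumor cells at intensity i;
range 0-300, binned absent / low (1-100) / intermediate (101-200) /
strong (201-300).  Positivity calls feed marker-vs-ATC 2x2 contingency
tables pooled across cohorts, from which sensitivity, specificity,
PPV/NPV (Mercaldo logit CIs at sample prevalence) and the diagnostic odds
ratio (log-method CI, Haldane-Anscombe 0.5 correction on zero cells) are
computed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

INTENSITY_COLS = [f"pct_intensity_{i}" for i in range(4)]


def histoscore(percent_at_intensity: Sequence[float]) -> float:
    """H = sum_i i * pct_i over intensities 0..3; range [0, 300]."""
    pct = np.asarray(percent_at_intensity, dtype=float)
    if pct.shape != (4,):
        raise ValueError("expected four intensity percentages (intensities 0..3)")
    if np.any(pct < 0):
        raise ValueError("intensity percentages must be non-negative")
    if abs(pct.sum() - 100.0) > 1e-9:
        raise ValueError(f"intensity percentages must sum to 100, got {pct.sum()}")
    return float(np.dot(np.arange(4), pct))


def classify_histoscore(h: float) -> str:
    """Bin a Histoscore: 0 absent, (0,100] low, (100,200] intermediate, (200,300] strong."""
    if not (0.0 <= h <= 300.0):
        raise ValueError(f"Histoscore {h} outside [0, 300]")
    if h == 0:
        return "absent"
    if h <= 100:
        return "low"
    if h <= 200:
        return "intermediate"
    return "strong"


def call_positive(h: float, threshold: float | None = None) -> bool:
    """Positivity call; default rule is any detectable staining (H > 0).

    A numeric ``threshold`` switches to H >= threshold, e.g. 101 to count
    only intermediate-or-strong expression as positive.
    """
    if threshold is None:
        return h > 0
    return h >= threshold


def add_histoscores(records: pd.DataFrame) -> pd.DataFrame:
    """Annotate IHC records with ``histoscore`` and ``histoscore_class``."""
    out = records.copy()
    scores = [histoscore(row) for row in out[INTENSITY_COLS].to_numpy()]
    out["histoscore"] = scores
    out["histoscore_class"] = [classify_histoscore(h) for h in scores]
    return out


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 marker-vs-disease table: TP = marker-positive ATC, FP = positive non-ATC."""

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_diseased(self) -> float:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> float:
        return self.fp + self.tn

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.fp + self.tn

    def corrected(self) -> "ContingencyTable":
        """Haldane-Anscombe: add 0.5 to every cell iff any cell is zero."""
        if min(self.tp, self.fn, self.fp, self.tn) == 0:
            return ContingencyTable(self.tp + 0.5, self.fn + 0.5, self.fp + 0.5, self.tn + 0.5)
        return self


def build_contingency(
    data: pd.DataFrame,
    marker: str,
    disease_class: str = "ATC",
    exclude_classes: Iterable[str] = ("NT",),
    positivity_threshold: float | None = None,
) -> ContingencyTable:
    """Pool cohorts into a marker-vs-ATC 2x2 table.

    Accepts either per-sample records (columns ``tumor_class``, ``marker``
    and intensity percentages or a precomputed ``histoscore``) or a
    cohort-count table (columns ``tumor_class``, ``marker``, ``n_total``,
    ``n_positive``).  Normal-tissue samples are excluded by default: the
    diagnostic comparison is ATC against the other carcinomas.
    """
    sub = data[data["marker"] == marker]
    if sub.empty:
        raise ValueError(f"marker {marker!r} absent from records")
    sub = sub[~sub["tumor_class"].isin(set(exclude_classes))]
    if {"n_total", "n_positive"} <= set(sub.columns):
        pos = sub.groupby(sub["tumor_class"] == disease_class)["n_positive"].sum()
        tot = sub.groupby(sub["tumor_class"] == disease_class)["n_total"].sum()
        tp = float(pos.get(True, 0))
        fn = float(tot.get(True, 0) - tp)
        fp = float(pos.get(False, 0))
        tn = float(tot.get(False, 0) - fp)
    else:
        if "histoscore" not in sub.columns:
            sub = add_histoscores(sub)
        calls = sub["histoscore"].map(lambda h: call_positive(h, positivity_threshold))
        diseased = sub["tumor_class"] == disease_class
        tp = float((calls & diseased).sum())
        fn = float((~calls & diseased).sum())
        fp = float((calls & ~diseased).sum())
        tn = float((~calls & ~diseased).sum())
    return ContingencyTable(tp, fn, fp, tn)


def dor_with_ci(table: ContingencyTable, alpha: float = 0.05) -> dict:
    """Diagnostic odds ratio (TP*TN)/(FN*FP) with a log-method CI.

    Zero cells trigger the Haldane-Anscombe +0.5 correction on all four
    cells for both the point estimate and the CI.
    """
    if table.n_diseased == 0 and table.n_nondiseased == 0:
        raise ValueError("empty table: DOR undefined")
    if (table.tp + table.fp == 0) and (table.fn + table.tn == 0):
        raise ValueError("both test margins empty: DOR undefined")
    corr = table.corrected()
    dor = (corr.tp * corr.tn) / (corr.fn * corr.fp)
    z = norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / corr.tp + 1 / corr.fn + 1 / corr.fp + 1 / corr.tn)
    lo, hi = np.exp(np.log(dor) - z * se), np.exp(np.log(dor) + z * se)
    return {
        "dor": float(dor),
        "ci": (float(lo), float(hi)),
        "correction_applied": corr is not table,
    }


def sens_spec_with_ci(table: ContingencyTable, alpha: float = 0.05) -> dict:
    """Sensitivity and specificity with Wilson score CIs."""
    out = {}
    for key, k, n in (
        ("sensitivity", table.tp, table.n_diseased),
        ("specificity", table.tn, table.n_nondiseased),
    ):
        if n == 0:
            out[key] = {"value": np.nan, "ci": (np.nan, np.nan), "undefined": True}
            continue
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        out[key] = {"value": k / n, "ci": (float(lo), float(hi)), "undefined": False}
    return out


def ppv_npv_with_ci(
    table: ContingencyTable, prevalence: float | None = None, alpha: float = 0.05
) -> dict:
    """Predictive values at a given prevalence with standard-logit CIs.

    PPV = se*pi / (se*pi + (1-sp)(1-pi)); NPV = sp(1-pi) / ((1-se)pi + sp(1-pi)).
    Default prevalence is the sample prevalence (TP+FN)/total, at which the
    point estimates reduce to the column proportions TP/(TP+FP) and
    TN/(TN+FN).  CIs use the logit transform with the standard variance
    (Mercaldo); degenerate sensitivity or specificity (0 or 1) triggers the
    0.5 cell correction for the CI and is flagged.
    """
    if prevalence is None:
        prevalence = table.n_diseased / table.total
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0, 1)")
    z = norm.ppf(1 - alpha / 2)

    def compute(t: ContingencyTable) -> tuple[float, float, float, float]:
        se_ = t.tp / t.n_diseased
        sp_ = t.tn / t.n_nondiseased
        pi = prevalence
        ppv = se_ * pi / (se_ * pi + (1 - sp_) * (1 - pi))
        npv = sp_ * (1 - pi) / ((1 - se_) * pi + sp_ * (1 - pi))
        return se_, sp_, ppv, npv

    se_raw, sp_raw, ppv, npv = compute(table)
    corrected = se_raw in (0.0, 1.0) or sp_raw in (0.0, 1.0)
    ci_table = (
        ContingencyTable(table.tp + 0.5, table.fn + 0.5, table.fp + 0.5, table.tn + 0.5)
        if corrected
        else table
    )
    se_, sp_, ppv_ci_pt, npv_ci_pt = compute(ci_table)
    n1, n0 = ci_table.n_diseased, ci_table.n_nondiseased

    def logit_ci(point: float, var: float) -> tuple[float, float]:
        lg = np.log(point / (1 - point))
        lo, hi = lg - z * np.sqrt(var), lg + z * np.sqrt(var)
        return float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi)))

    var_ppv = (1 - se_) / (se_ * n1) + sp_ / ((1 - sp_) * n0)
    var_npv = se_ / ((1 - se_) * n1) + (1 - sp_) / (sp_ * n0)
    return {
        "ppv": {"value": float(ppv), "ci": logit_ci(ppv_ci_pt, var_ppv)},
        "npv": {"value": float(npv), "ci": logit_ci(npv_ci_pt, var_npv)},
        "prevalence": float(prevalence),
        "correction_applied": corrected,
    }


def diagnostic_report(
    data: pd.DataFrame,
    markers: Iterable[str] | None = None,
    disease_class: str = "ATC",
    exclude_classes: Iterable[str] = ("NT",),
    positivity_threshold: float | None = None,
    alpha: float = 0.05,
) -> dict:
    """Per-marker diagnostic metrics from records or cohort counts.

    Returns ``{marker: {"table": ..., "sensitivity": ..., "specificity": ...,
    "ppv": ..., "npv": ..., "dor": ...}}``; an empty marker list yields an
    empty report.
    """
    if markers is None:
        markers = sorted(data["marker"].unique())
    report: dict[str, dict] = {}
    for marker in markers:
        table = build_contingency(
            data, marker, disease_class, exclude_classes, positivity_threshold
        )
        ss = sens_spec_with_ci(table, alpha)
        pn = ppv_npv_with_ci(table, alpha=alpha)
        dor = dor_with_ci(table, alpha)
        report[marker] = {
            "table": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
            "sensitivity": ss["sensitivity"],
            "specificity": ss["specificity"],
            "ppv": pn["ppv"],
            "npv": pn["npv"],
            "prevalence": pn["prevalence"],
            "dor": dor,
        }
    return report


def load_published_cohort_counts() -> pd.DataFrame:
    """Bundled positivity counts for IGF2BP1, MAGEA3 and MYC.

    Three thyroid-carcinoma cohorts (an RNA-seq test cohort and two tissue
    microarrays) with, per cohort, tumor class and marker, the number of
    samples and the number showing detectable protein expression.
    """
    ref = importlib.resources.files("atcmark") / "data" / "published_ihc_counts.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
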