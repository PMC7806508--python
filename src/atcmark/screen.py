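"""ATC-exclusive marker screen: de novo filter, RSD ranking, CT annotation.

The screen nominates genes that are effectively silent outside ATC
(mean FPM in non-ATC samples < 1), strongly induced in ATC (> 50-fold),
significant (FDR <= 0.01), and then ranks the survivors by increasing
relative standard deviation (RSD = sd/mean of FPM across ATC samples) so
that the most *consistently* induced genes come first.  The top-K table
mirrors a marker report: gene, log2FC, FDR, RSD, cancer-testis flag, rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .expression import NBExactTest


@dataclass
class ScreenThresholds:
    """Cutoffs of the de novo screen.

    Inequalities follow the printed conventions: non-ATC mean FPM strictly
    below ``max_noatc_mean_fpm``, fold change strictly above
    ``min_fold_change``, FDR at most ``max_fdr``.
    """

    max_noatc_mean_fpm: float = 1.0
    min_fold_change: float = 50.0
    max_fdr: float = 0.01
    top_k: int = 20

    def validate(self) -> None:
        if min(self.max_noatc_mean_fpm, self.min_fold_change, self.max_fdr) <= 0:
            raise ValueError("screen thresholds must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")


def compute_rsd(fpm: pd.DataFrame, atc_sample_ids: Sequence[str]) -> pd.Series:
    """Per-gene relative standard deviation of FPM across ATC samples.

    rsd_g = sd(FPM_g; ddof=1) / mean(FPM_g) over the ATC columns.  Genes
    with zero ATC mean have an undefined RSD and come back as NaN; they are
    excluded from ranking downstream.
    """
    atc = list(atc_sample_ids)
    if len(atc) < 2:
        raise ValueError("RSD needs at least two ATC samples")
    sub = fpm.loc[:, atc]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    rsd[mean == 0] = np.nan
    rsd.name = "rsd"
    return rsd


def de_novo_filter(de: pd.DataFrame, thresholds: ScreenThresholds | None = None) -> pd.Index:
    """Genes passing the de novo expression screen.

    ``de`` must carry ``mean_fpm_ref`` (non-ATC group mean FPM),
    ``log2_fold_change`` (prior-offset, so finite for de novo genes) and
    ``fdr``.  The fold-change criterion is evaluated on the same
    prior-offset ratio as the DE log2FC, not on the raw ratio, which is
    unstable when the non-ATC mean is near zero.
    """
    thresholds = thresholds or ScreenThresholds()
    thresholds.validate()
    if de.empty:
        return de.index
    fold = 2.0 ** de["log2_fold_change"]
    keep = (
        (de["mean_fpm_ref"] < thresholds.max_noatc_mean_fpm)
        & (fold > thresholds.min_fold_change)
        & (de["fdr"] <= thresholds.max_fdr)
    )
    return de.index[keep]


def rank_markers(
    candidates: pd.DataFrame,
    rsd: pd.Series,
    top_k: int = 20,
    ct_gene_list: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Rank screened candidates by increasing RSD; annotate CT membership.

    Genes with undefined RSD (zero ATC mean) are dropped before ranking;
    a candidate simply absent from ``rsd`` is an error.  Ties break by
    ascending FDR, then lexicographic gene id.  Returns the top-K table
    with columns ``log2_fold_change``, ``fdr``, ``rsd``,
    ``is_cancer_testis`` and ``rank`` (1..K).
    """
    missing = candidates.index.difference(rsd.index)
    if len(missing):
        raise ValueError(f"RSD missing for candidate genes: {list(missing[:5])}")
    ct = set(ct_gene_list or [])
    tab = candidates.copy()
    tab["rsd"] = rsd.reindex(tab.index)
    tab = tab[tab["rsd"].notna()]
    # stable sort on gene id first so (rsd, fdr) ties break lexicographically
    tab = tab.sort_index(kind="mergesort").sort_values(by=["rsd", "fdr"], kind="mergesort")
    tab = tab.head(int(top_k))
    tab["is_cancer_testis"] = [g in ct for g in tab.index]
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def screen_markers(
    de: pd.DataFrame,
    fpm: pd.DataFrame,
    atc_sample_ids: Sequence[str],
    thresholds: ScreenThresholds | None = None,
    ct_gene_list: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Full screen: de novo filter, then RSD ranking of the survivors."""
    thresholds = thresholds or ScreenThresholds()
    candidates = de.loc[de_novo_filter(de, thresholds)]
    rsd = compute_rsd(fpm, atc_sample_ids)
    return rank_markers(candidates, rsd, thresholds.top_k, ct_gene_list)


class DeNovoMarkerScreen(SelectorMixin, BaseEstimator):
    """The whole marker-discovery chain as a feature selector.

    ``fit(X, y)`` takes (n_samples, n_genes) counts and per-sample class
    labels, runs TMM normalization, common-dispersion estimation, the NB
    exact test of ``test_group`` against everything else, the de novo
    expression filter and the RSD ranking.  ``get_support()`` marks the
    top-K markers; ``records_`` holds the ranked marker table.
    """

    def __init__(
        self,
        test_group: str = "ATC",
        max_noatc_mean_fpm: float = 1.0,
        min_fold_change: float = 50.0,
        max_fdr: float = 0.01,
        top_k: int = 20,
        ct_gene_list: Iterable[str] | None = None,
    ):
        self.test_group = test_group
        self.max_noatc_mean_fpm = max_noatc_mean_fpm
        self.min_fold_change = min_fold_change
        self.max_fdr = max_fdr
        self.top_k = top_k
        self.ct_gene_list = ct_gene_list

    def fit(self, X, y):
        X_df = pd.DataFrame(X)
        y = np.asarray(y)
        de_est = NBExactTest(test_group=self.test_group).fit(X_df, y)
        counts = X_df.T
        factors = pd.Series(de_est.norm_factors_, index=counts.columns)
        from .expression import compute_fpm  # local to avoid cycle at import

        fpm = compute_fpm(counts, factors)
        atc_cols = list(counts.columns[np.asarray(y) == self.test_group])
        thresholds = ScreenThresholds(
            self.max_noatc_mean_fpm, self.min_fold_change, self.max_fdr, self.top_k
        )
        self.de_results_ = de_est.results_
        self.dispersion_ = de_est.dispersion_
        self.records_ = screen_markers(
            de_est.results_, fpm, atc_cols, thresholds, self.ct_gene_list
        )
        self.selected_genes_ = list(self.records_.index)
        self.n_features_in_ = counts.shape[0]
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self._support = np.asarray(counts.index.isin(self.selected_genes_))
        return self

    def _get_support_mask(self):
        return self._support
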