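"""Count normalization and negative-binomial differential expression.

Implements trimmed-mean-of-M-values (TMM) between-sample normalization,
FPM computation on effective library sizes, common-dispersion estimation
by profile maximum likelihood, the two-group NB exact test, BH adjustment
and a PCA embedding for cohort QC.

Count matrices are pandas DataFrames with genes as rows and samples as
columns; the sklearn-style estimators at the bottom of the module accept
the transposed (samples x genes) orientation instead, following the
(n_samples, n_features) convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _as_count_frame(counts) -> pd.DataFrame:
    df = pd.DataFrame(counts)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers in count matrix")
    arr = df.to_numpy()
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return df


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Raw TMM factor of one column against the reference column.

    Uses genes expressed in both samples; log-ratios M and abundances A
    are doubly trimmed (30%/5% by default) and the surviving M are
    averaged with inverse-asymptotic-variance (delta-method) weights.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return np.nan
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return np.nan
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0**f)


def tmm_norm_factors(
    counts,
    reference: str | int | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    Parameters
    ----------
    counts : DataFrame, genes x samples.
    reference : sample id / positional index, or None to pick the column
        whose upper quartile of scaled counts is closest to the mean upper
        quartile.

    Returns
    -------
    Series of positive factors indexed by sample; effective library size is
    the raw column total times the factor.
    """
    df = _as_count_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    arr = df.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    zero_cols = np.flatnonzero(lib == 0)
    if zero_cols.size:
        raise ValueError(f"sample {df.columns[zero_cols[0]]!r} has an all-zero count column")

    if reference is None:
        q75 = np.quantile(arr / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    elif isinstance(reference, (int, np.integer)) and reference not in df.columns:
        ref_idx = int(reference)
    else:
        ref_idx = int(df.columns.get_loc(reference))

    factors = np.ones(df.shape[1])
    for j in range(df.shape[1]):
        if j == ref_idx:
            continue
        f = _tmm_pair_factor(arr[:, j], arr[:, ref_idx], lib[j], lib[ref_idx], logratio_trim, sum_trim)
        if np.isnan(f):
            logger.warning(
                "no genes survive TMM trimming for sample %r; factor set to 1", df.columns[j]
            )
            f = 1.0
        factors[j] = f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def compute_fpm(counts, factors: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per million of effective library size.

    FPM[g, s] = counts[g, s] / (libsize_s * factor_s) * 1e6.  With all
    factors equal to 1 every column sums to one million.
    """
    df = _as_count_frame(counts)
    lib = df.sum(axis=0).to_numpy(dtype=float)
    if factors is None:
        f = np.ones(df.shape[1])
    else:
        f = pd.Series(factors).reindex(df.columns).to_numpy(dtype=float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("normalization factors must be positive and aligned to samples")
    eff = lib * f
    if np.any(eff == 0):
        raise ValueError("zero effective library size")
    return df / eff * 1e6


def effective_library_sizes(counts, factors: pd.Series | None = None) -> pd.Series:
    df = _as_count_frame(counts)
    lib = df.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * pd.Series(factors).reindex(df.columns)
    return lib


# ---------------------------------------------------------------------------
# dispersion estimation and the exact test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Pooled NB log-likelihood with Var = mu + phi mu^2 (continuous in y)."""
    mask = mu > 0
    y, mu = y[mask], mu[mask]
    if phi < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _scaled_counts(counts: pd.DataFrame, factors: pd.Series | None) -> tuple[np.ndarray, float]:
    """Counts rescaled (mean-preserving) to a common effective library size."""
    arr = counts.to_numpy(dtype=float)
    eff = effective_library_sizes(counts, factors).to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(eff))))
    return arr * (common / eff), common


def estimate_common_dispersion(
    counts,
    groups,
    factors: pd.Series | None = None,
    bounds: tuple[float, float] = (1e-6, 5.0),
) -> float:
    """Common NB dispersion phi by Cox-Reid adjusted profile likelihood.

    Counts are first scaled to a common effective library size; for each
    candidate phi the group means are profiled out (the NB mean MLE under a
    common dispersion is the sample mean) and the pooled log-likelihood,
    penalized by half the log Fisher information of each profiled mean
    (Cox-Reid, which removes the downward bias of plain profile ML), is
    maximized over phi on ``bounds``.
    """
    df = _as_count_frame(counts)
    groups = pd.Series(np.asarray(groups), index=df.columns)
    sizes = groups.value_counts()
    if df.shape[1] < 2 or (sizes < 2).all():
        raise ValueError("dispersion is unidentifiable without a group of at least two samples")
    scaled, _ = _scaled_counts(df, factors)

    group_masks = [groups.to_numpy() == g for g in sizes.index]
    ys, mus, ns = [], [], []
    for mask in group_masks:
        if mask.sum() < 2:
            continue
        y = scaled[:, mask]
        mu = np.broadcast_to(y.mean(axis=1, keepdims=True), y.shape)
        ys.append(y.ravel())
        mus.append(mu.ravel())
        ns.append(np.full(y.shape[0], mask.sum()))
    y_all = np.concatenate(ys)
    mu_all = np.concatenate(mus)
    # one profiled mean per (gene, group); its Fisher info is n / (mu (1 + phi mu))
    mean_mu = np.concatenate([m[:: int(n[0])] for m, n in zip(mus, ns)])
    mean_n = np.concatenate(ns)
    pos = mean_mu > 0
    mean_mu, mean_n = mean_mu[pos], mean_n[pos]

    def nll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        cr = -0.5 * np.sum(np.log(mean_n / (mean_mu * (1.0 + phi * mean_mu))))
        return -(_nb_loglik(y_all, mu_all, phi) + cr)

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(np.exp(res.x))
    # likelihood flat / decreasing at the lower bound means "no overdispersion"
    if nll(np.log(bounds[0])) <= res.fun:
        phi = bounds[0]
    return phi


def _exact_test_pvalue(a_obs: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for a single gene.

    Conditions the group-A total on the overall total t.  With equal
    per-sample means and a common dispersion the conditional law of the
    group-A total is free of the mean: negative hypergeometric for phi > 0
    (NB sums share the success probability), binomial in the Poisson limit
    phi = 0.  The two-sided p sums the conditional probabilities of all
    splits no more likely than the observed one (tie-inclusive), capped
    at 1.
    """
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi < 1e-12:
        p_a = n_a / (n_a + n_b)
        logp = (
            gammaln(t + 1) - gammaln(a + 1) - gammaln(t - a + 1)
            + a * np.log(p_a) + (t - a) * np.log1p(-p_a)
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            gammaln(a + r_a) - gammaln(a + 1)
            + gammaln(t - a + r_b) - gammaln(t - a + 1)
        )
        logp -= logsumexp(logp)
    thresh = logp[a_obs] + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[logp <= thresh]))))


def nb_exact_test(
    counts,
    groups,
    dispersion: float,
    factors: pd.Series | None = None,
    pair: tuple[str, str] | None = None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Two-group NB exact test with TMM-equalized library sizes.

    Parameters
    ----------
    counts : DataFrame, genes x samples.
    groups : per-sample labels with exactly two levels.
    dispersion : common NB dispersion phi (>= 0).
    pair : (test, reference) group labels; fold changes are test/reference.
        Defaults to the two labels in sorted order.
    prior_count : per-group count offset (at the common library size) used
        for finite log2 fold changes of genes absent in one group.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2_fold_change``,
    ``p_value``, ``fdr``, ``mean_fpm``, ``mean_fpm_test``, ``mean_fpm_ref``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    df = _as_count_frame(counts)
    groups = pd.Series(np.asarray(groups), index=df.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exact test needs exactly two groups, got {levels}")
    if pair is None:
        pair = (levels[0], levels[1])
    test_g, ref_g = pair
    if set(pair) != set(levels):
        raise ValueError(f"pair {pair} does not match group labels {levels}")
    mask_a = (groups == test_g).to_numpy()
    mask_b = (groups == ref_g).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    scaled, common = _scaled_counts(df, factors)
    pseudo = np.rint(scaled).astype(np.int64)
    tot_a = pseudo[:, mask_a].sum(axis=1)
    tot_b = pseudo[:, mask_b].sum(axis=1)

    pvals = np.array(
        [
            _exact_test_pvalue(int(ta), int(ta + tb), n_a, n_b, dispersion)
            for ta, tb in zip(tot_a, tot_b)
        ]
    )

    fpm = compute_fpm(df, factors)
    mean_a = fpm.loc[:, mask_a].mean(axis=1)
    mean_b = fpm.loc[:, mask_b].mean(axis=1)
    prior_fpm = prior_count * 1e6 / common
    log2fc = np.log2((mean_a + prior_fpm) / (mean_b + prior_fpm))

    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "mean_fpm": fpm.mean(axis=1),
            "mean_fpm_test": mean_a,
            "mean_fpm_ref": mean_b,
        },
        index=df.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

def pca_embed(
    fpm, n_components: int = 2, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(FPM + pseudocount), genes centered.

    Returns per-sample coordinates (samples x components) and the
    explained-variance fractions in decreasing order.
    """
    df = pd.DataFrame(fpm)
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > min(df.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    x = np.log2(df.to_numpy(dtype=float).T + pseudocount)  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=df.columns, columns=cols), pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

class TMMNormalizer(TransformerMixin, BaseEstimator):
    """TMM normalization as a transformer over (n_samples, n_genes) counts.

    ``fit`` learns per-sample normalization factors against an
    automatically chosen reference column; ``transform`` returns FPM on
    effective library sizes.  Note that factors are per *sample*, so
    ``transform`` must be called with the same samples used in ``fit``.
    """

    def __init__(self, logratio_trim: float = 0.3, sum_trim: float = 0.05):
        self.logratio_trim = logratio_trim
        self.sum_trim = sum_trim

    def fit(self, X, y=None):
        counts = pd.DataFrame(X).T  # genes x samples internally
        self.norm_factors_ = tmm_norm_factors(
            counts, logratio_trim=self.logratio_trim, sum_trim=self.sum_trim
        ).to_numpy()
        self.library_sizes_ = counts.sum(axis=0).to_numpy(dtype=float)
        self.n_features_in_ = counts.shape[0]
        return self

    def transform(self, X):
        counts = pd.DataFrame(X).T
        if counts.shape != (self.n_features_in_, len(self.norm_factors_)):
            raise ValueError("transform expects the matrix the factors were fitted on")
        factors = pd.Series(self.norm_factors_, index=counts.columns)
        return compute_fpm(counts, factors).T


class NBExactTest(BaseEstimator):
    """Fit-shaped NB differential expression: TMM, dispersion, exact test.

    ``fit(X, y)`` takes an (n_samples, n_genes) count matrix and per-sample
    class labels; every label different from ``test_group`` is pooled into
    the comparator ("rest", e.g. noATC).  Fitted attributes:

    - ``norm_factors_`` : per-sample TMM factors
    - ``dispersion_`` : common NB dispersion
    - ``results_`` : per-gene DataFrame (log2_fold_change, p_value, fdr, ...)
    """

    def __init__(self, test_group: str = "ATC", rest_label: str = "noATC",
                 dispersion: float | None = None, prior_count: float = 0.125):
        self.test_group = test_group
        self.rest_label = rest_label
        self.dispersion = dispersion
        self.prior_count = prior_count

    def fit(self, X, y):
        counts = pd.DataFrame(X).T
        y = np.asarray(y)
        if len(y) != counts.shape[1]:
            raise ValueError("y must give one class label per sample")
        if self.test_group not in y:
            raise ValueError(f"no samples labelled {self.test_group!r}")
        two = np.where(y == self.test_group, self.test_group, self.rest_label)
        factors = tmm_norm_factors(counts)
        if self.dispersion is None:
            self.dispersion_ = estimate_common_dispersion(counts, two, factors)
        else:
            self.dispersion_ = float(self.dispersion)
        self.norm_factors_ = factors.to_numpy()
        self.results_ = nb_exact_test(
            counts, two, self.dispersion_, factors,
            pair=(self.test_group, self.rest_label), prior_count=self.prior_count,
        )
        self.n_features_in_ = counts.shape[0]
        return self
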