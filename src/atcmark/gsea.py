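"""Preranked gene-set enrichment analysis (weighted KS running sum).

Genes are ranked by descending fold change; each gene set accumulates
|score|^p / sum(|score|^p over hits) at its members and loses
1/(N - N_hits) elsewhere.  The enrichment score (ES) is the signed
extremum of that running sum.  Significance comes from a gene-set
permutation null (random same-size sets), with NES = ES divided by the
mean |null ES| of matching sign, and q-values by the standard pooled-null
FDR procedure.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def rank_by_fold_change(de: pd.DataFrame, score_col: str = "log2_fold_change") -> pd.Series:
    """Ranking scores sorted descending; ties break by ascending gene id."""
    if de.index.has_duplicates:
        dup = de.index[de.index.duplicated()][:5]
        raise ValueError(f"duplicate gene ids in DE table: {list(dup)}")
    scores = de[score_col].astype(float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    # stable sort on gene id first, then on -score, gives deterministic ties
    return scores.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")


def enrichment_score(
    ranked: pd.Series, gene_set: Sequence[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and running-sum profile of one gene set on a ranked list.

    The set is intersected with the ranked universe first; an empty or
    universe-covering intersection is degenerate (the miss decrement is
    undefined) and raises.
    """
    n = len(ranked)
    hits = ranked.index.isin(set(gene_set))
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set is empty or covers the whole universe after intersection")
    scores = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hit_sum = scores[hits].sum()
    if hit_sum == 0:
        # all hit scores zero: fall back to unweighted increments
        incr = np.where(hits, 1.0 / n_hits, 0.0)
    else:
        incr = np.where(hits, scores / hit_sum, 0.0)
    incr = incr - np.where(hits, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(incr)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es(
    ranked: pd.Series, set_size: int, n_permutations: int, rng: np.random.Generator,
    weight: float,
) -> np.ndarray:
    n = len(ranked)
    scores = np.abs(ranked.to_numpy(dtype=float)) ** weight
    miss_base = np.empty(n)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        idx = rng.choice(n, size=set_size, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        hit_sum = scores[idx].sum()
        if hit_sum == 0:
            incr = np.where(hit, 1.0 / set_size, -1.0 / (n - set_size))
        else:
            incr = np.where(hit, scores / hit_sum, -1.0 / (n - set_size))
        running = np.cumsum(incr, out=miss_base)
        out[i] = running[np.argmax(np.abs(running))]
    return out


def _normalize(es: float | np.ndarray, null: np.ndarray) -> np.ndarray:
    """ES / mean(|null ES| of matching sign); NaN when that sign is absent."""
    es = np.atleast_1d(np.asarray(es, dtype=float))
    pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
    neg_mean = -null[null < 0].mean() if (null < 0).any() else np.nan
    out = np.where(es >= 0, es / pos_mean, es / neg_mean)
    return out


def nes_and_q(
    ranked: pd.Series,
    collection: Mapping[str, Sequence[str]],
    n_permutations: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Per-set ES, NES, nominal p and permutation q-values.

    Gene-set permutation: for each set size the null is the ES of random
    same-size gene sets.  NES normalizes observed and null ES by the mean
    null |ES| of matching sign; the nominal p is the matching-sign null
    tail (add-one), and q follows the standard GSEA FDR: the fraction of
    pooled null NES at least as extreme, divided by the fraction of
    observed NES at least as extreme, clipped to [0, 1] and made monotone.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    universe = set(ranked.index)

    kept: dict[str, list[str]] = {}
    for name, members in collection.items():
        inter = sorted(set(members) & universe)
        if min_size <= len(inter) <= max_size and len(inter) < len(ranked):
            kept[name] = inter

    rows = []
    null_nes_pool: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in kept.items():
        es, running = enrichment_score(ranked, members, weight)
        size = len(members)
        if size not in null_cache:
            null_cache[size] = _null_es(ranked, size, n_permutations, rng, weight)
        null = null_cache[size]
        same_sign = null[null >= 0] if es >= 0 else null[null <= 0]
        if same_sign.size == 0:
            nes, p = np.nan, np.nan
        else:
            nes = float(_normalize(es, null)[0])
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (same_sign.size + 1)
        null_nes_pool.append(_normalize(null, null))
        # leading edge: hits up to the ES extremum (from the top for ES>0)
        hits = ranked.index.isin(set(members))
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            leading = list(ranked.index[: peak + 1][hits[: peak + 1]])
        else:
            leading = list(ranked.index[peak:][hits[peak:]])
        rows.append(
            {"name": name, "size": size, "es": es, "nes": nes, "p_value": p,
             "leading_edge": ",".join(leading)}
        )

    res = pd.DataFrame(rows)
    if res.empty:
        res["q_value"] = []
        return res

    pooled = np.concatenate(null_nes_pool)
    pooled = pooled[np.isfinite(pooled)]
    obs = res["nes"].to_numpy()
    q = np.full(len(res), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = np.mean(pooled >= nes) if pooled.size else np.nan
            obs_frac = np.mean(obs[np.isfinite(obs)] >= nes)
        else:
            null_frac = np.mean(pooled <= nes) if pooled.size else np.nan
            obs_frac = np.mean(obs[np.isfinite(obs)] <= nes)
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    # q-value convention: each set takes the smallest estimated FDR over all
    # cutoffs that include it, i.e. cumulative min from least to most extreme
    for sign in (1, -1):
        idx = np.where(np.isfinite(obs) & ((obs >= 0) if sign == 1 else (obs < 0)))[0]
        order = idx[np.argsort(sign * obs[idx], kind="mergesort")]
        q[order] = np.minimum.accumulate(q[order])
    res["q_value"] = q
    res = res[["name", "size", "es", "nes", "p_value", "q_value", "leading_edge"]]
    return res.sort_values("nes", ascending=False, kind="mergesort").reset_index(drop=True)
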