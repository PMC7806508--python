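import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

import atcmark as am
from atcmark.expression import _exact_test_pvalue


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def tmm_pair_oracle(obs, ref, logratio_trim=0.3, sum_trim=0.05):
    """Direct pure-Python TMM factor: explicit M, A, weights, rank trims."""
    n_o, n_r = sum(obs), sum(ref)
    rows = [(o, r) for o, r in zip(obs, ref) if o > 0 and r > 0]
    m = [math.log2((o / n_o) / (r / n_r)) for o, r in rows]
    a = [0.5 * math.log2((o / n_o) * (r / n_r)) for o, r in rows]
    w = [(n_o - o) / (n_o * o) + (n_r - r) / (n_r * r) for o, r in rows]
    if max(abs(x) for x in m) < 1e-6:
        return 1.0
    n = len(m)

    def ranks(v):
        order = sorted(range(n), key=lambda i: v[i])
        r = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and v[order[j + 1]] == v[order[i]]:
                j += 1
            for k in range(i, j + 1):
                r[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rm, ra = ranks(m), ranks(a)
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    keep = [i for i in range(n) if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a]
    f = sum(m[i] / w[i] for i in keep) / sum(1.0 / w[i] for i in keep)
    return 2.0**f


def exact_test_oracle(ya, yb, phi):
    """Exhaustive enumeration of the conditional two-sided p for one gene.

    Splits of the total follow a binomial (Poisson limit) or the
    normalized product of two NB pmfs sharing one success probability.
    """
    n_a, n_b = len(ya), len(yb)
    t, a_obs = sum(ya) + sum(yb), sum(ya)
    if t == 0:
        return 1.0
    if phi == 0:
        probs = [binom.pmf(k, t, n_a / (n_a + n_b)) for k in range(t + 1)]
    else:
        r_a, r_b = n_a / phi, n_b / phi
        raw = [nbinom.pmf(k, r_a, 0.37) * nbinom.pmf(t - k, r_b, 0.37) for k in range(t + 1)]
        s = sum(raw)
        probs = [x / s for x in raw]
    po = probs[a_obs]
    return min(1.0, sum(x for x in probs if x <= po * (1 + 1e-9)))


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]})
        f = am.tmm_norm_factors(counts)
        assert np.allclose(f, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(5, 11))
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(n_genes, 3)), columns=["a", "b", "c"]
        )
        f = am.tmm_norm_factors(counts, reference="a")
        raw = np.array(
            [1.0]
            + [
                tmm_pair_oracle(counts[c].tolist(), counts["a"].tolist())
                for c in ["b", "c"]
            ]
        )
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, atol=1e-12, rtol=0)

    def test_geometric_mean_is_one(self, small_cohort):
        _, counts, _, _ = small_cohort
        f = am.tmm_norm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)
        assert (f > 0).all()

    def test_all_zero_column_is_an_error(self):
        counts = pd.DataFrame({"s1": [5, 1], "s2": [0, 0]})
        with pytest.raises(ValueError, match="s2"):
            am.tmm_norm_factors(counts)


class TestFPM:
    def test_single_count_column(self):
        counts = pd.DataFrame({"s": [1, 0, 0]})
        fpm = am.compute_fpm(counts)
        assert fpm["s"].tolist() == [1e6, 0.0, 0.0]

    def test_columns_sum_to_one_million_with_unit_factors(self, small_cohort):
        _, counts, _, _ = small_cohort
        fpm = am.compute_fpm(counts)
        assert np.allclose(fpm.sum(axis=0), 1e6)

    def test_doubling_a_sample_leaves_its_fpm_unchanged(self, small_cohort):
        _, counts, _, _ = small_cohort
        doubled = counts.copy()
        doubled.iloc[:, 0] *= 2
        a = am.compute_fpm(counts, am.tmm_norm_factors(counts))
        b = am.compute_fpm(doubled, am.tmm_norm_factors(doubled))
        # M and A are scale-free but the doubled sample's precision weights
        # shrink, so the factor moves slightly: equal up to that effect
        assert np.allclose(a.iloc[:, 0], b.iloc[:, 0], rtol=0.01)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(7)
        mu = np.exp(rng.normal(4, 1, 1000))
        counts = pd.DataFrame(rng.poisson(mu[:, None], size=(1000, 12)))
        grp = np.array(["A"] * 6 + ["B"] * 6)
        assert am.estimate_common_dispersion(counts, grp) < 1e-3

    def test_recovers_known_dispersion_within_20pct(self):
        rng = np.random.default_rng(7)
        mu = np.exp(rng.normal(4, 1, 2000))
        r = 1 / 0.2
        counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 12)))
        grp = np.array(["A"] * 6 + ["B"] * 6)
        est = am.estimate_common_dispersion(counts, grp)
        assert est == pytest.approx(0.2, rel=0.2)

    def test_constant_counts_mean_no_overdispersion(self):
        counts = pd.DataFrame(np.full((50, 6), 20))
        grp = np.array(["A"] * 3 + ["B"] * 3)
        # estimate collapses to the optimizer's lower bound: no overdispersion
        assert am.estimate_common_dispersion(counts, grp) < 1e-5

    def test_single_sample_is_an_error(self):
        counts = pd.DataFrame({"s1": [3, 4]})
        with pytest.raises(ValueError):
            am.estimate_common_dispersion(counts, ["A"])


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_all_zero_gene_has_p_one(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 0], [50, 60, 55, 45]], columns=list("abcd")
        )
        res = am.nb_exact_test(counts, ["A", "A", "B", "B"], 0.1)
        assert res["p_value"].iloc[0] == 1.0

    @pytest.mark.parametrize(
        "ya,yb,phi",
        [
            ([3, 5], [1, 2], 0.0),
            ([3, 5], [1, 2], 0.2),
            ([0, 0], [4, 6], 0.1),
            ([10, 8], [2, 1], 0.05),
            ([7], [7, 7, 7], 0.3),
        ],
    )
    def test_matches_enumeration_oracle(self, ya, yb, phi):
        p_kernel = _exact_test_pvalue(sum(ya), sum(ya) + sum(yb), len(ya), len(yb), phi)
        assert p_kernel == pytest.approx(exact_test_oracle(ya, yb, phi), abs=1e-10)

    def test_public_surface_matches_oracle_with_equalized_libraries(self):
        # filler gene makes every column total 100 so no rescaling occurs
        ya, yb = [3, 5], [1, 2]
        gene = ya + yb
        filler = [100 - c for c in gene]
        counts = pd.DataFrame([gene, filler], columns=list("abcd"))
        res = am.nb_exact_test(counts, ["A", "A", "B", "B"], 0.2, pair=("A", "B"))
        assert res["p_value"].iloc[0] == pytest.approx(exact_test_oracle(ya, yb, 0.2), abs=1e-10)

    def test_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(42)
        phi, n = 0.1, 2000
        mu = np.exp(rng.normal(3.5, 1.0, n))
        r = 1 / phi
        counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 28)))
        grp = np.array(["A"] * 10 + ["B"] * 18)
        res = am.nb_exact_test(counts, grp, phi)
        assert 0.03 <= (res["p_value"] < 0.05).mean() <= 0.07

    def test_negative_dispersion_and_empty_group_rejected(self):
        counts = pd.DataFrame([[1, 2, 3, 4]], columns=list("abcd"))
        with pytest.raises(ValueError):
            am.nb_exact_test(counts, ["A", "A", "B", "B"], -0.1)
        with pytest.raises(ValueError):
            am.nb_exact_test(counts, ["A", "A", "A", "A"], 0.1)

    def test_spiked_markers_reach_screen_fdr(self, small_cohort, small_de):
        _, _, _, truth = small_cohort
        spiked = truth.loc[truth["role"] == "spiked_marker", "gene_id"]
        assert (small_de.results_.loc[spiked, "fdr"] <= 0.01).all()


# ---------------------------------------------------------------------------
# BH and PCA
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(am.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert am.bh_fdr([0.03]) == pytest.approx([0.03])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_order_invariance_and_dominates_p(self, pvals, rnd):
        p = np.array(pvals)
        fdr = am.bh_fdr(p)
        assert (fdr >= p - 1e-12).all()
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        assert np.allclose(am.bh_fdr(p[perm]), fdr[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            am.bh_fdr([0.5, 1.5])


class TestPCA:
    def test_identical_samples_coincide(self):
        fpm = pd.DataFrame({"s1": [5.0, 1.0, 2.0], "s2": [5.0, 1.0, 2.0], "s3": [9.0, 0.0, 1.0]})
        coords, _ = am.pca_embed(fpm, n_components=2)
        assert np.allclose(coords.loc["s1"], coords.loc["s2"], atol=1e-9)

    def test_explained_variance_fractions(self, small_cohort):
        _, counts, _, _ = small_cohort
        _, evr = am.pca_embed(am.compute_fpm(counts), n_components=5)
        assert evr.sum() <= 1 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_classes_separate_on_pc1(self, small_cohort):
        _, counts, sheet, _ = small_cohort
        coords, _ = am.pca_embed(am.compute_fpm(counts, am.tmm_norm_factors(counts)))
        atc = sheet["class"].to_numpy() == "ATC"
        pc1 = coords["PC1"].to_numpy()
        between = abs(pc1[atc].mean() - pc1[~atc].mean())
        within = max(pc1[atc].std(), pc1[~atc].std())
        assert between > within

    def test_too_many_components_rejected(self):
        fpm = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            am.pca_embed(fpm, n_components=4)


class TestEstimatorContracts:
    def test_clone_and_get_params(self):
        from sklearn.base import clone

        for est in (am.TMMNormalizer(), am.NBExactTest(test_group="ATC"), am.DeNovoMarkerScreen()):
            cl = clone(est)
            assert cl.get_params() == est.get_params()

    def test_tmm_normalizer_transform_matches_function(self, small_cohort):
        _, counts, _, _ = small_cohort
        norm = am.TMMNormalizer().fit(counts.T)
        direct = am.compute_fpm(counts, am.tmm_norm_factors(counts))
        assert np.allclose(norm.transform(counts.T).to_numpy(), direct.T.to_numpy())
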