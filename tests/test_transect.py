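import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import gammaln

from rhizotransfer.transect import (
    TukeyKramer,
    compact_letter_display,
    fit_lmm_lrt,
    normality_homoscedasticity_screen,
    pairwise_species_regression,
    per_species_distance_lrt,
    tukey_kramer,
)


# ---------------------------------------------------------------------------
# independent studentized-range oracle (numerical quadrature)


def studentized_range_sf_quadrature(q, k, df):
    """P(Q > q) for the studentized range by direct double quadrature.

    Outer integral over the scale s = sqrt(chi2_df / df), inner over the
    location of the minimum; independent of scipy's implementation.
    """

    def inner(s):
        def f(z):
            return (
                k
                * stats.norm.pdf(z)
                * (stats.norm.cdf(z) - stats.norm.cdf(z - q * s)) ** (k - 1)
            )

        v, _ = quad(f, -9, 9, epsabs=1e-11, epsrel=1e-11, limit=200)
        return v

    def outer(s):
        log_f = (
            np.log(2.0)
            + (df / 2.0) * np.log(df / 2.0)
            - gammaln(df / 2.0)
            + (df - 1.0) * np.log(s)
            - df * s * s / 2.0
        )
        return np.exp(log_f) * inner(s)

    cdf, _ = quad(outer, 1e-8, 10, epsabs=1e-9, epsrel=1e-9, limit=200)
    return 1.0 - cdf


class TestTukeyKramer:
    def test_two_groups_equal_n_matches_pooled_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 8)
        values = np.concatenate([a, b])
        groups = np.array(["A"] * 8 + ["B"] * 8)
        tk = TukeyKramer().fit(values, groups)
        # with k=2 the studentized range reduces to |t|*sqrt(2)
        t, p = stats.ttest_ind(a, b)
        assert tk.pvalues_.loc["A", "B"] == pytest.approx(p, rel=1e-9)

    def test_all_means_equal_single_letter(self):
        values = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        groups = np.array(["A", "A", "B", "B", "C", "C"])
        pmat, letters = tukey_kramer(values, groups)
        assert (pmat.values == 1.0).all()
        assert set(letters["letters"]) == {"a"}

    @pytest.mark.parametrize("q,k,df", [(2.0, 3, 12), (3.5, 3, 12), (2.8, 4, 20), (1.2, 5, 8)])
    def test_matches_quadrature_oracle(self, q, k, df):
        impl = stats.studentized_range.sf(q, k, df)
        oracle = studentized_range_sf_quadrature(q, k, df)
        assert impl == pytest.approx(oracle, abs=1e-6)

    def test_balanced_case_p_values_against_oracle(self):
        rng = np.random.default_rng(1)
        data = {g: rng.normal(m, 1.0, 6) for g, m in [("A", 0.0), ("B", 0.8), ("C", 2.0)]}
        values = np.concatenate(list(data.values()))
        groups = np.repeat(list(data), 6)
        tk = TukeyKramer().fit(values, groups)
        k, df = 3, len(values) - 3
        s2 = tk.s2_
        for a, b in itertools.combinations(data, 2):
            q = abs(data[a].mean() - data[b].mean()) / np.sqrt(s2 / 6)
            assert tk.pvalues_.loc[a, b] == pytest.approx(
                studentized_range_sf_quadrature(q, k, df), abs=1e-6
            )

    def test_equal_n_reduces_to_classical_tukey_hsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 18) + np.repeat([0.0, 0.5, 1.5], 6)
        groups = np.repeat(["A", "B", "C"], 6)
        tk = TukeyKramer().fit(values, groups)
        hsd = pairwise_tukeyhsd(values, groups)
        for (a, b), p in zip(itertools.combinations(["A", "B", "C"], 2), hsd.pvalues):
            assert tk.pvalues_.loc[a, b] == pytest.approx(p, abs=1e-6)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 15)
        groups = rng.choice(["A", "B", "C"], 15)
        p1 = TukeyKramer().fit(values, groups).pvalues_
        perm = np.argsort(rng.random(15))
        p2 = TukeyKramer().fit(values[perm], groups[perm]).pvalues_
        pd.testing.assert_frame_equal(p1.sort_index(axis=0).sort_index(axis=1),
                                      p2.sort_index(axis=0).sort_index(axis=1))

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            TukeyKramer().fit([1.0, 2.0], ["A", "B"])


class TestCompactLetterDisplay:
    @staticmethod
    def _check_consistency(pmat, letters, alpha):
        """Independent checker: sharing a letter <=> not significant."""
        for a, b in itertools.combinations(pmat.index, 2):
            share = set(letters[a]) & set(letters[b])
            if pmat.loc[a, b] < alpha:
                assert not share, (a, b)
            else:
                assert share, (a, b)

    def test_letters_consistent_with_p_matrix_fuzzed(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            k = rng.integers(2, 7)
            labels = [chr(65 + i) for i in range(k)]
            pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
            for a, b in itertools.combinations(labels, 2):
                p = rng.random()
                pmat.loc[a, b] = pmat.loc[b, a] = p
            letters = compact_letter_display(pmat, alpha=0.3)
            self._check_consistency(pmat, letters, alpha=0.3)

    def test_chain_pattern_needs_two_letters(self):
        # A != C significant, but A~B and B~C: classic a / ab / b pattern
        labels = ["A", "B", "C"]
        pmat = pd.DataFrame(1.0, index=labels, columns=labels)
        pmat.loc["A", "C"] = pmat.loc["C", "A"] = 0.01
        letters = compact_letter_display(pmat, alpha=0.05)
        assert letters == {"A": "a", "B": "ab", "C": "b"}


class TestLmmLrt:
    def test_constant_response_all_stats_zero(self, noisy_tables):
        plant, _, _ = noisy_tables
        plant = plant.copy()
        plant["d15n"] = 1.234
        for r in fit_lmm_lrt(plant, "d15n"):
            assert r.statistic == 0.0 and r.p_value == 1.0 and r.singular

    def test_strong_distance_effect_detected(self, noisy_tables):
        plant, _, _ = noisy_tables
        results = {r.effect: r for r in fit_lmm_lrt(plant, "d15n")}
        assert results["distance"].p_value < 1e-4
        assert results["species"].p_value < 1e-4
        assert results["distance"].df == 7
        assert results["species"].df == 2
        assert results["species:distance"].df == 14
        assert all(r.statistic >= 0 for r in results.values())

    def test_affine_rescaling_invariance(self, noisy_tables):
        plant, _, _ = noisy_tables
        scaled = plant.copy()
        scaled["d15n"] = 3.0 * scaled["d15n"] - 7.0
        a = {r.effect: r.statistic for r in fit_lmm_lrt(plant, "d15n")}
        b = {r.effect: r.statistic for r in fit_lmm_lrt(scaled, "d15n")}
        for eff in a:
            assert a[eff] == pytest.approx(b[eff], rel=1e-4, abs=1e-4)

    def test_per_species_restriction(self, noisy_tables):
        plant, _, _ = noisy_tables
        res = per_species_distance_lrt(plant, "LC", "d15n")
        assert res.effect == "distance|LC"
        assert res.df == 7
        assert res.p_value < 1e-4  # LC reference is far more enriched than transect
        with pytest.raises(ValueError, match="ZZ"):
            per_species_distance_lrt(plant, "ZZ", "d15n")

    def test_diagnostics_reported_not_gating(self, noisy_tables):
        plant, _, _ = noisy_tables
        out = normality_homoscedasticity_screen(plant, "d15n")
        assert {"shapiro_w", "shapiro_p", "levene_w", "levene_p"} <= set(out)
        assert 0 <= out["shapiro_p"] <= 1


class TestPairwiseRegression:
    @staticmethod
    def _paired_plants(x, y, sx="LC", sy="SG"):
        rows = []
        dists = [0, 20, 50, 100, 150, 300, 500]
        cells = [(b, d) for d in dists for b in range(1, 7)][: len(x)]
        for (b, d), xi in zip(cells, x):
            rows.append({"species": sx, "block": b, "distance": d, "n_pct": 1.0, "d15n": xi})
        for (b, d), yi in zip(cells, y):
            rows.append({"species": sy, "block": b, "distance": d, "n_pct": 1.0, "d15n": yi})
        return pd.DataFrame(rows)

    def test_identity_relation(self):
        x = np.linspace(-1, 3, 12)
        df = self._paired_plants(x, x)
        res = pairwise_species_regression(df).iloc[0]
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["r2"] == pytest.approx(1.0)

    def test_constant_y_zero_slope(self):
        x = np.linspace(-1, 3, 10)
        df = self._paired_plants(x, np.full(10, 2.0))
        res = pairwise_species_regression(df).iloc[0]
        assert res["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_matched_pairs(self):
        df = self._paired_plants([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            pairwise_species_regression(df)

    def test_known_slope_recovered_on_average(self):
        root = np.random.default_rng(5)
        slopes = []
        for _ in range(200):
            rng = np.random.default_rng(root.integers(0, 2**31))
            x = rng.normal(1.0, 1.0, 42)
            y = 0.8 * x + rng.normal(0, 0.5, 42)
            res = pairwise_species_regression(self._paired_plants(x, y)).iloc[0]
            slopes.append(res["slope"])
        # se of the mean slope ~ (0.5/sqrt(41))/sqrt(200) ~ 0.006
        assert np.mean(slopes) == pytest.approx(0.8, abs=0.03)
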