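import numpy as np
import pandas as pd
import pytest

from carballoc import metkit


class TestMedianNormalize:
    def table(self, values, batch=None):
        df = pd.DataFrame({"abundance": values})
        if batch is not None:
            df["batch"] = batch
        return df

    def test_direct_formula(self):
        out = metkit.median_normalize(self.table([1.0, 2.0, 3.0]))
        assert list(out["abundance"]) == [0.5, 1.0, 1.5]

    def test_idempotent(self):
        once = metkit.median_normalize(self.table([1.0, 2.0, 3.0]))
        twice = metkit.median_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_scale_invariance(self):
        a = metkit.median_normalize(self.table([1.0, 2.0, 3.0]))
        b = metkit.median_normalize(self.table([10.0, 20.0, 30.0]))
        pd.testing.assert_frame_equal(a, b)

    def test_per_batch(self):
        out = metkit.median_normalize(
            self.table([1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                       batch=list("aaabbb")),
            batch_col="batch",
        )
        assert list(out["abundance"]) == [0.5, 1.0, 1.5, 0.5, 1.0, 1.5]

    def test_zero_median_error(self):
        with pytest.raises(ValueError, match="median"):
            metkit.median_normalize(self.table([0.0, 0.0, 1.0]))

    def test_impute_minimum(self):
        df = pd.DataFrame(
            {"metabolite": ["m", "m", "m"], "abundance": [2.0, np.nan, 5.0]}
        )
        out = metkit.impute_minimum(df)
        assert list(out["abundance"]) == [2.0, 2.0, 5.0]


class TestPca:
    def test_rank_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        mat = pd.DataFrame(np.outer(v, [1.0, -2.0, 0.5]))
        _, frac = metkit.pca_summary(mat)
        assert frac[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        _, frac = metkit.pca_summary(pd.DataFrame(rng.normal(size=(30, 6))))
        assert frac.sum() == pytest.approx(1.0)

    def test_closed_form_two_variables(self):
        # construct exact sample correlation r=0.8 -> eigenvalues (1±r)/2
        rng = np.random.default_rng(1)
        n, r = 200, 0.8
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)  # exact orthogonalization
        z2 /= z2.std()
        b = r * z1 + np.sqrt(1 - r**2) * z2
        mat = pd.DataFrame({"x": z1, "y": b})
        _, frac = metkit.pca_summary(mat)
        assert frac[0] == pytest.approx((1 + r) / 2, abs=1e-12)

    def test_constant_matrix_error(self):
        with pytest.raises(ValueError, match="constant"):
            metkit.pca_summary(pd.DataFrame(np.ones((5, 3))))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            metkit.pca_summary(pd.DataFrame(np.ones((2, 3))))


def letters_consistent(values_by_group, alpha=0.05):
    """Brute-force check: share a letter iff pair not significant."""
    res = metkit.anova_tukey_letters(values_by_group, alpha=alpha)
    letters = dict(zip(res["group"], res["letters"]))
    pairs = metkit.tukey_pairwise(values_by_group, alpha=alpha)
    for row in pairs.itertuples(index=False):
        share = bool(set(letters[row.group_a]) & set(letters[row.group_b]))
        if row.significant:
            assert not share, (row.group_a, row.group_b)
        else:
            assert share, (row.group_a, row.group_b)


class TestAnovaTukeyLetters:
    def test_identical_groups_one_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        res = metkit.anova_tukey_letters(
            {"a": base, "b": base + 1e-12, "c": base}
        )
        assert set(res["letters"]) == {"a"}

    def test_spec_example_two_letter_groups(self):
        rng = np.random.default_rng(1)
        groups = {
            "g1": rng.normal(0, 0.1, 6),
            "g2": rng.normal(0, 0.1, 6),
            "g3": rng.normal(10, 0.1, 6),
        }
        res = metkit.anova_tukey_letters(groups).set_index("group")
        assert res.at["g1", "letters"] == res.at["g2", "letters"] == "a"
        assert res.at["g3", "letters"] == "b"
        letters_consistent(groups)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        groups = {
            "x": rng.normal(0, 1, 5),
            "y": rng.normal(2, 1, 5),
            "z": rng.normal(4, 1, 5),
        }
        res1 = metkit.anova_tukey_letters(groups).set_index("group")
        reordered = {k: groups[k] for k in ["z", "x", "y"]}
        res2 = metkit.anova_tukey_letters(reordered).set_index("group")
        for g in groups:
            assert res1.at[g, "letters"] == res2.at[g, "letters"]

    def test_statsmodels_pvalue_agreement(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(0, 1, 7),
            "b": rng.normal(1, 1, 7),
            "c": rng.normal(3, 1, 7),
        }
        mine = metkit.tukey_pairwise(groups)["p"].to_numpy()
        vals = np.concatenate([groups[g] for g in "abc"])
        labs = np.repeat(list("abc"), 7)
        theirs = pairwise_tukeyhsd(vals, labs).pvalues
        assert mine == pytest.approx(theirs, abs=1e-6)

    def test_random_fixture_consistency(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            k = int(rng.integers(3, 6))
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 3), 1.0,
                                    int(rng.integers(3, 7)))
                for i in range(k)
            }
            letters_consistent(groups)

    def test_zero_variance_equal_means(self):
        res = metkit.anova_tukey_letters(
            {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}
        )
        assert set(res["letters"]) == {"a"}


class TestWelch:
    def test_identical_samples(self):
        t, df, p = metkit.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == pytest.approx(1.0)

    def test_formula_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, df, p = metkit.welch_t(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_expected = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert t == pytest.approx(t_expected)
        assert df == pytest.approx(df_expected)
        from scipy import stats

        assert p == pytest.approx(
            float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 8)
        t1, _, p1 = metkit.welch_t(a, b)
        t2, _, p2 = metkit.welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_equal_means(self):
        t, df, p = metkit.welch_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_permutation_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.0, 1.5, 8)
        _, _, p = metkit.welch_t(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        n_perm = 100_000
        idx = np.array([rng.permutation(16) for _ in range(n_perm)])
        perm = pooled[idx]
        diffs = np.abs(perm[:, :8].mean(1) - perm[:, 8:].mean(1))
        p_perm = (diffs >= obs - 1e-12).mean()
        assert abs(p - p_perm) < 0.02


class TestSummaries:
    def planted_table(self):
        rows = []
        rng = np.random.default_rng(0)
        for geno in ("P1", "P2"):
            for cat, mets in (
                ("carbohydrates", ["c1", "c2", "c3", "c4", "c5"]),
                ("lipids", ["l1"]),
            ):
                for m in mets:
                    changing = geno == "P2" and cat == "carbohydrates"
                    for t in range(4):
                        level = (t + 1.0) * 3 if changing else 1.0
                        for r in range(3):
                            rows.append(
                                (m, cat, geno, f"T{t + 1}", r,
                                 level + rng.normal(0, 0.05))
                            )
        return pd.DataFrame(
            rows, columns=["metabolite", "category", "genotype",
                           "timepoint", "replicate", "abundance"],
        )

    def test_planted_counts(self):
        summary = metkit.diff_metabolite_summary(self.planted_table())
        assert summary.at["P2", "carbohydrates"] == 5
        assert summary.at["P1", "carbohydrates"] == 0
        assert summary.at["P2", "lipids"] == 0

    def test_partition_property(self):
        table = self.planted_table()
        summary = metkit.diff_metabolite_summary(table)
        rows = []
        for (geno, met), sub in table.groupby(["genotype", "metabolite"]):
            from scipy import stats

            groups = [g["abundance"].to_numpy()
                      for _, g in sub.groupby("timepoint")]
            rows.append(stats.f_oneway(*groups).pvalue < 0.05)
        assert summary.to_numpy().sum() == sum(rows)

    def test_all_flat_zero(self):
        table = self.planted_table()
        table["abundance"] = 1.0 + np.random.default_rng(1).normal(
            0, 0.01, len(table)
        )
        # still could have accidental hits; use huge noise-free flat table
        table["abundance"] = np.tile([1.0, 1.1, 0.9], len(table) // 3)
        summary = metkit.diff_metabolite_summary(table)
        assert summary.to_numpy().sum() == 0


class TestBrix:
    def make(self, slope=2.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows_b, rows_s = [], []
        for geno in ("P1", "P2"):
            for t in range(5):
                total = 10 + 3 * t
                rows_b.append((geno, f"T{t + 1}",
                               slope * total + rng.normal(0, noise)))
                for met, fracn in (("sucrose", 0.7), ("glucose", 0.2),
                                   ("fructose", 0.1)):
                    for r in range(2):
                        rows_s.append((met, geno, f"T{t + 1}", r,
                                       fracn * total))
        brix = pd.DataFrame(rows_b, columns=["genotype", "timepoint", "brix"])
        sugars = pd.DataFrame(
            rows_s, columns=["metabolite", "genotype", "timepoint",
                             "replicate", "abundance"],
        )
        return brix, sugars

    def test_proportional(self):
        brix, sugars = self.make()
        r = metkit.brix_sugar_correlation(brix, sugars)
        assert np.allclose(r.to_numpy(), 1.0)

    def test_anti_proportional(self):
        brix, sugars = self.make(slope=-2.0)
        r = metkit.brix_sugar_correlation(brix, sugars)
        assert np.allclose(r.to_numpy(), -1.0)

    def test_noisy_proportional(self):
        brix, sugars = self.make(noise=2.0, seed=3)
        r = metkit.brix_sugar_correlation(brix, sugars)
        assert (r > 0.9).all()

    def test_too_few_points(self):
        brix, sugars = self.make()
        brix = brix[brix["timepoint"].isin(["T1", "T2"])]
        r = metkit.brix_sugar_correlation(brix, sugars)
        assert r.isna().all()
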