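"""Correlation, regression, ANOVA and gender tests vs from-definition oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazentropy import (
    analyze_dataset,
    descriptives_by_type,
    ols_fit,
    oneway_anova,
    pearson,
    two_sample_test,
)
from gazentropy.errors import DomainError, ValidationError


def pearson_oracle(x, y):
    """Pearson r and its two-tailed t-transform p, from the definitions."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
    n = x.size
    t = r * math.sqrt((n - 2) / (1 - r**2))
    from scipy.stats import t as tdist

    return r, 2 * tdist.sf(abs(t), n - 2)


def slope_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc = x - x.mean()
    return ((y - y.mean()) * xc).sum() / (xc**2).sum()


def anova_oracle(groups):
    """Between/within decomposition written out directly."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestPearsonAndOLS:
    def test_perfect_positive_line(self):
        x = np.array([1.0, 2, 4, 7, 11])
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.array([0.0, 1, 2, 5])
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_exact_line_fit(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fit = ols_fit(x, 3 * x - 2)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(-2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_from_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        r, p = pearson(x, y)
        r0, p0 = pearson_oracle(x, y)
        assert r == pytest.approx(r0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)
        fit = ols_fit(x, y)
        assert fit.slope == pytest.approx(slope_oracle(x, y), abs=1e-10)
        # internal identities of simple regression
        assert fit.r2 == pytest.approx(fit.r**2, abs=1e-9)
        assert fit.p == pytest.approx(p, abs=1e-12)

    @given(st.integers(0, 10**6), st.floats(0.1, 50), st.floats(-100, 100))
    def test_r_invariant_to_positive_affine_rescaling(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r0, _ = pearson(x, y)
        r1, _ = pearson(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        f, p = oneway_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_groups_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        f, p_f = oneway_anova([a, b])
        # pooled-variance two-sample t, written out independently
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert f == pytest.approx(t**2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_decomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(m, 1, int(rng.integers(3, 12))) for m in (0, 0.5, 1.2)]
        f, _ = oneway_anova(groups)
        assert f == pytest.approx(anova_oracle(groups), abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            oneway_anova([[1, 2, 3]])


class TestTwoSample:
    def test_identical_samples(self):
        t, p = two_sample_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_huge_shift_separates(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        t, p = two_sample_test(a, a + 10)
        assert p < 1e-10

    def test_tiny_sample_rejected(self):
        with pytest.raises(DomainError):
            two_sample_test([1.0], [1.0, 2.0])


class TestDescriptives:
    def _trials(self, rows):
        return pd.DataFrame(rows, columns=["participant", "gender", "task_type", "question_id", "rt_s", "he_bits"])

    def test_constant_he_gives_zero_sd(self):
        df = self._trials(
            [["P1", "F", 1, "q", 2.0, 16.0], ["P2", "M", 1, "q", 3.0, 16.0]]
        )
        d = descriptives_by_type(df)
        assert d.loc[0, "he_sd"] == 0.0
        assert d.loc[0, "n"] == 2

    def test_single_trial_sd_missing(self):
        d = descriptives_by_type(self._trials([["P1", "F", 2, "q", 2.0, 16.0]]))
        assert np.isnan(d.loc[0, "he_sd"])

    def test_missing_type_omitted(self):
        d = descriptives_by_type(
            self._trials([["P1", "F", 1, "q", 2.0, 16.0], ["P2", "M", 1, "q", 3.0, 15.0]])
        )
        assert list(d["task_type"]) == [1]


class TestAnalyzeDataset:
    def _dataset(self, seed=0, n_per_type=30):
        rng = np.random.default_rng(seed)
        rows = []
        for t, (m, s, b, a) in {1: (16.46, 0.92, 5.0, -75), 2: (16.05, 0.5, 1.5, -20), 3: (16.18, 0.65, 3.0, -44)}.items():
            he = rng.normal(m, s, n_per_type)
            rt = np.abs(a + b * he + rng.normal(0, 2, n_per_type)) + 0.1
            for i in range(n_per_type):
                rows.append(
                    {
                        "participant": f"P{i % 8:02d}",
                        "gender": "F" if i % 2 else "M",
                        "task_type": t,
                        "question_id": f"T{t}Q{i % 8}",
                        "rt_s": rt[i],
                        "he_bits": he[i],
                    }
                )
        return pd.DataFrame(rows)

    def test_bundle_structure(self):
        trials = self._dataset()
        ratings = pd.DataFrame(
            {"participant": ["P1"] * 3, "task_type": [1, 2, 3], "rating": [2, 4, 6]}
        )
        ratings = pd.concat([ratings] * 4, ignore_index=True)
        res = analyze_dataset(trials, ratings)
        assert set(res.per_type) == {1, 2, 3}
        assert res.overall.n == len(trials)
        assert res.anova is not None
        assert ("type1", "he_bits") in res.gender_tests
        for fit in [res.overall, *res.per_type.values()]:
            assert fit.r2 == pytest.approx(fit.r**2, abs=1e-9)

    def test_single_type_dataset(self):
        trials = self._dataset()
        trials = trials[trials.task_type == 2].reset_index(drop=True)
        res = analyze_dataset(trials)
        assert set(res.per_type) == {2}

    def test_row_order_invariance(self):
        trials = self._dataset()
        shuffled = trials.sample(frac=1.0, random_state=99).reset_index(drop=True)
        a = analyze_dataset(trials)
        b = analyze_dataset(shuffled)
        for fa, fb in zip([a.overall, *a.per_type.values()], [b.overall, *b.per_type.values()]):
            for attr in ("slope", "intercept", "r", "r2", "p"):
                assert getattr(fa, attr) == pytest.approx(getattr(fb, attr), abs=1e-10)
            assert fa.n == fb.n

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            analyze_dataset(pd.DataFrame(columns=["task_type", "rt_s", "he_bits"]))
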