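import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from deshade import (
    anova_letters,
    correlate_vi_lnc,
    pearson_r,
    select_sensitive,
    significance_stars,
    vi_standard_error,
)


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            r, p = pearson_r(x, y)
            # oracle: covariance formula plus the t transform with n-2 df
            xm, ym = x - x.mean(), y - y.mean()
            r0 = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            t0 = r0 * np.sqrt(18 / (1 - r0**2))
            p0 = 2 * sps.t.sf(abs(t0), 18)
            assert r == pytest.approx(r0, abs=1e-12)
            assert p == pytest.approx(p0, rel=1e-9)

    def test_hand_five_point_dataset(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        # by hand: sum(xm*ym) = 2.8+2.4+0-0.4+7.2 = 12, sum(xm^2) = 10,
        # sum(ym^2) = 21.2, so r = 12 / sqrt(10 * 21.2)
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(12 / np.sqrt(10 * 21.2), abs=1e-12)

    def test_independent_data_r_near_zero_p_uniformish(self):
        rng = np.random.default_rng(9)
        rs, ps = [], []
        for _ in range(200):
            x, y = rng.normal(size=(2, 50))
            r, p = pearson_r(x, y)
            rs.append(r)
            ps.append(p)
        assert abs(np.mean(rs)) < 0.05
        assert 0.35 < np.mean(ps) < 0.65  # uniform p-values average 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson_r(np.arange(2.0), np.arange(2.0))


class TestStars:
    @pytest.mark.parametrize(
        "p,expected", [(0.001, "**"), (0.0099, "**"), (0.01, "*"), (0.049, "*"), (0.05, ""), (0.9, "")]
    )
    def test_thresholds_exact(self, p, expected):
        assert significance_stars(p) == expected


class TestStandardError:
    def test_constant_column_zero(self):
        table = pd.DataFrame({"A": [0.5] * 4, "lnc": [1, 2, 3, 4]})
        assert vi_standard_error(table)["A"] == 0.0

    def test_two_point_column(self):
        table = pd.DataFrame({"A": [0.0, 2.0]})
        assert vi_standard_error(table)["A"] == pytest.approx(1.0)


class TestCorrelationReport:
    def test_long_format_ordered_by_abs_r(self):
        rng = np.random.default_rng(12)
        lnc = rng.uniform(25, 55, 40)
        table = pd.DataFrame(
            {
                "strong": lnc * 2 + rng.normal(0, 1, 40),
                "weak": rng.normal(0, 1, 40),
                "lnc": lnc,
            },
            index=[f"s{i}" for i in range(40)],
        )
        table.attrs["levels"] = [4]
        table.attrs["method"] = "GFSG"
        report = correlate_vi_lnc([table])
        assert list(report.columns) == ["class", "method", "index", "r", "p", "stars", "n"]
        assert report.iloc[0]["index"] == "strong"
        assert report.iloc[0]["stars"] == "**"
        assert report["r"].abs().is_monotonic_decreasing
        assert (report["n"] == 40).all()
        assert report.iloc[0]["method"] == "GFSG"

    def test_missing_rows_dropped_pairwise(self):
        lnc = np.linspace(25, 55, 20)
        a = lnc + np.sin(np.arange(20))
        a[:5] = np.nan
        table = pd.DataFrame({"A": a, "lnc": lnc}, index=[f"s{i}" for i in range(20)])
        report = correlate_vi_lnc([table])
        assert report.iloc[0]["n"] == 15


class TestAnovaLetters:
    def test_three_separated_groups_get_abc(self):
        rng = np.random.default_rng(5)
        groups = {
            "high": rng.normal(10, 0.1, 8),
            "mid": rng.normal(5, 0.1, 8),
            "low": rng.normal(1, 0.1, 8),
        }
        out = anova_letters(groups)
        assert list(out["group"]) == ["high", "mid", "low"]
        assert list(out["letters"]) == ["a", "b", "c"]

    def test_identical_groups_share_a(self):
        groups = {g: np.array([1.0, 1.0, 1.0]) for g in "xyz"}
        out = anova_letters(groups)
        assert set(out["letters"]) == {"a"}

    def test_overlapping_pair_shares_letter(self):
        rng = np.random.default_rng(6)
        groups = {
            "a1": rng.normal(10.0, 0.3, 10),
            "a2": rng.normal(10.1, 0.3, 10),
            "b": rng.normal(5.0, 0.3, 10),
            "c": rng.normal(1.0, 0.3, 10),
        }
        out = anova_letters(groups).set_index("group")
        assert set(out.loc["a1", "letters"]) & set(out.loc["a2", "letters"])
        assert not set(out.loc["a1", "letters"]) & set(out.loc["b", "letters"])

    @pytest.mark.parametrize("method", ["tukey", "lsd"])
    def test_letters_encode_significance_graph(self, method):
        """Validity oracle: groups share a letter iff the post-hoc test does
        not separate them (checked against the raw pairwise p matrix)."""
        rng = np.random.default_rng(7)
        for trial in range(8):
            g = int(rng.integers(2, 6))
            means = rng.uniform(0, 8, g)
            groups = {
                f"g{i}": rng.normal(means[i], 0.8, 12) for i in range(g)
            }
            out = anova_letters(groups, method=method).set_index("group")
            arrays = [groups[f"g{i}"] for i in range(g)]
            if method == "tukey":
                pmat = np.asarray(sps.tukey_hsd(*arrays).pvalue)
            else:
                n = np.array([len(v) for v in arrays])
                m = np.array([v.mean() for v in arrays])
                ss = sum(((v - v.mean()) ** 2).sum() for v in arrays)
                df = int(n.sum() - g)
                mse = ss / df
                pmat = np.ones((g, g))
                for i, j in itertools.combinations(range(g), 2):
                    se = np.sqrt(mse * (1 / n[i] + 1 / n[j]))
                    t = (m[i] - m[j]) / se
                    pmat[i, j] = pmat[j, i] = 2 * sps.t.sf(abs(t), df)
            for i, j in itertools.combinations(range(g), 2):
                share = bool(
                    set(out.loc[f"g{i}", "letters"]) & set(out.loc[f"g{j}", "letters"])
                )
                significant = pmat[i, j] < 0.05
                assert share != significant, (trial, i, j)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            anova_letters({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})
        with pytest.raises(ValueError, match="2 groups"):
            anova_letters({"a": np.array([1.0, 2.0])})


class TestSelectSensitive:
    def _report(self, rows):
        return pd.DataFrame(rows, columns=["class", "method", "index", "r", "p", "stars", "n"])

    def test_all_insignificant_gives_empty_set(self):
        rows = [("c", "OS", f"i{k}", 0.5, 0.2, "", 30) for k in range(5)]
        sens = select_sensitive(self._report(rows))
        assert sens.per_class["c"] == []

    def test_zero_magnitude_threshold_equals_significance_filter(self):
        rows = [
            ("c", "OS", "a", 0.1, 0.01, "*", 30),
            ("c", "OS", "b", 0.9, 0.2, "", 30),
        ]
        sens = select_sensitive(self._report(rows), min_abs_r=0.0)
        assert sens.per_class["c"] == ["a"]

    def test_engineered_cohort_counts_14_15_12(self):
        """Three classes engineered so exactly 14 / 15 / 12 indices pass the
        p<0.05, |r|>=0.2 screen."""
        from deshade import INDEX_NAMES

        rng = np.random.default_rng(404)
        n = 80
        lnc = rng.uniform(25, 55, n)
        tables = []
        for n_sensitive in (14, 15, 12):
            cols = {}
            for k, name in enumerate(INDEX_NAMES):
                if k < n_sensitive:  # strong linear association
                    cols[name] = 0.05 * lnc + rng.normal(0, 0.3, n)
                else:  # pure noise
                    cols[name] = rng.normal(0, 1, n)
            table = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
            table["lnc"] = lnc
            tables.append(table)
        report = correlate_vi_lnc(tables, class_names=["2-3", "2-4", "2-5"])
        sens = select_sensitive(report)
        assert sens.counts == {"2-3": 14, "2-4": 15, "2-5": 12}
        assert sum(1 for _ in sens.all_pairs()) == 41
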