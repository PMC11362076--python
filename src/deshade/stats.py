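"""Correlation screening, standard errors, ANOVA letter tables, sensitivity.

Associates vegetation-index tables with leaf nitrogen content: per-index
Pearson correlations with significance stars, across-sample standard
errors, one-way ANOVA with compact-letter displays for group comparisons,
and selection of the "sensitive" indices eligible as model features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import INDEX_NAMES

__all__ = [
    "pearson_r",
    "significance_stars",
    "correlate_vi_lnc",
    "vi_standard_error",
    "anova_letters",
    "SensitiveSet",
    "select_sensitive",
]


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Two-sided significance annotation: ** for p<0.01, * for p<0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _index_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "lnc"]


def correlate_vi_lnc(
    tables: list[pd.DataFrame],
    lnc: pd.Series | None = None,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format correlation report over one or more VI tables.

    Each table is a ``build_vi_table`` result (rows = sample_id).  LNC is
    taken from the table's own ``lnc`` column unless an explicit series
    (indexed by sample_id) is given.  Missing rows are dropped pairwise per
    index and the per-cell n reported.  The report is ordered by |r|
    descending.
    """
    records = []
    for i, table in enumerate(tables):
        if class_names is not None:
            cls = class_names[i]
        else:
            lv = table.attrs.get("levels")
            cls = "all" if lv is None else "+".join(str(v) for v in lv)
        method = table.attrs.get("method", "OS")
        if lnc is not None:
            y_full = lnc.reindex(table.index)
        elif "lnc" in table.columns:
            y_full = table["lnc"]
        else:
            raise ValueError("no LNC available: table lacks an lnc column")
        for name in _index_columns(table):
            pair = pd.DataFrame({"x": table[name], "y": y_full}).dropna()
            n = len(pair)
            if n < 3 or pair["x"].nunique() < 2 or pair["y"].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = pearson_r(pair["x"].values, pair["y"].values)
            records.append(
                {
                    "class": cls,
                    "method": method,
                    "index": name,
                    "r": r,
                    "p": p,
                    "stars": significance_stars(p) if np.isfinite(p) else "",
                    "n": n,
                }
            )
    report = pd.DataFrame(records)
    return report.reindex(report["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def vi_standard_error(table: pd.DataFrame) -> pd.Series:
    """Across-sample standard error SD/sqrt(n) per index column."""
    cols = _index_columns(table)
    values = table[cols]
    n = values.notna().sum()
    se = values.std(ddof=1) / np.sqrt(n)
    return se.fillna(0.0)


# ---------------------------------------------------------------------------
# ANOVA + compact letter display
# ---------------------------------------------------------------------------

def _pairwise_pvalues(groups: list[np.ndarray], method: str) -> np.ndarray:
    g = len(groups)
    pmat = np.ones((g, g))
    if method == "tukey":
        res = sps.tukey_hsd(*groups)
        pmat = np.asarray(res.pvalue)
    elif method == "lsd":
        # Fisher's LSD: pooled-variance t-tests, no correction
        n = np.array([len(v) for v in groups])
        means = np.array([v.mean() for v in groups])
        ss = sum(((v - v.mean()) ** 2).sum() for v in groups)
        df = int(n.sum() - g)
        mse = ss / df
        for i in range(g):
            for j in range(i + 1, g):
                se = np.sqrt(mse * (1 / n[i] + 1 / n[j]))
                t = (means[i] - means[j]) / se if se > 0 else 0.0
                p = 2 * sps.t.sf(abs(t), df)
                pmat[i, j] = pmat[j, i] = p
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return pmat


def compact_letter_display(significant: np.ndarray, order: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` is True when groups i and j differ; ``order``
    lists group indices by descending mean.  Returns one lowercase letter
    string per group (original indexing), such that two groups share a
    letter iff they are not significantly different from every other member
    of that letter's clique... more precisely: significant pairs never
    share a letter and non-significant pairs share at least one.
    """
    g = significant.shape[0]
    columns: list[set[int]] = [set(range(g))]
    for i in range(g):
        for j in range(i + 1, g):
            if not significant[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.append(col - {i})
                columns.append(col - {j})
            # absorb: drop empties, duplicates, and proper subsets
            unique: list[set[int]] = []
            for c in columns:
                if c and c not in unique:
                    unique.append(c)
            columns = [c for c in unique if not any(c < other for other in unique)]
    # order letters so 'a' goes to the column holding the highest mean
    rank = {idx: pos for pos, idx in enumerate(order)}
    columns.sort(key=lambda c: min(rank[i] for i in c))
    letters = [""] * g
    for letter_pos, col in enumerate(columns):
        letter = chr(ord("a") + letter_pos)
        for i in col:
            letters[i] += letter
    return ["".join(sorted(s)) for s in letters]


def anova_letters(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    method: str = "tukey",
) -> pd.DataFrame:
    """One-way ANOVA with pairwise post-hoc comparisons and letter codes.

    Groups sharing a lowercase letter are not significantly different at
    ``alpha``; letters are assigned in descending-mean order.  The post-hoc
    test defaults to Tukey's HSD; Fisher's LSD is available via
    ``method="lsd"``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
    means = np.array([a.mean() for a in arrays])
    f_stat, f_p = sps.f_oneway(*arrays)
    if np.ptp(np.concatenate(arrays)) == 0:
        significant = np.zeros((len(arrays), len(arrays)), dtype=bool)
    else:
        pmat = _pairwise_pvalues(arrays, method)
        significant = pmat < alpha
    np.fill_diagonal(significant, False)
    order = np.argsort(-means, kind="stable")
    letters = compact_letter_display(significant, order)
    out = pd.DataFrame(
        {
            "group": names,
            "n": [len(a) for a in arrays],
            "mean": means,
            "letters": letters,
        }
    ).sort_values("mean", ascending=False, kind="stable").reset_index(drop=True)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    out.attrs["alpha"] = alpha
    out.attrs["posthoc"] = method
    return out


# ---------------------------------------------------------------------------
# sensitive-index selection
# ---------------------------------------------------------------------------

@dataclass
class SensitiveSet:
    """Per class: the indices passing the significance + magnitude screen."""

    per_class: dict[str, list[str]] = field(default_factory=dict)
    alpha: float = 0.05
    min_abs_r: float = 0.2

    @property
    def counts(self) -> dict[str, int]:
        return {cls: len(v) for cls, v in self.per_class.items()}

    def all_pairs(self) -> list[tuple[str, str]]:
        return [(cls, name) for cls, names in self.per_class.items() for name in names]


def select_sensitive(
    report: pd.DataFrame, alpha: float = 0.05, min_abs_r: float = 0.2
) -> SensitiveSet:
    """Retain indices with p < alpha and |r| >= min_abs_r, per class.

    The defaults mirror the screening rule used to shortlist model features:
    a significant correlation of at least moderate magnitude (|r| > 0.2).
    """
    selected: dict[str, list[str]] = {}
    for cls, sub in report.groupby("class", sort=False):
        keep = sub[(sub["p"] < alpha) & (sub["r"].abs() >= min_abs_r)]
        # preserve canonical registry order for readability
        names = [n for n in INDEX_NAMES if n in set(keep["index"])]
        names += [n for n in keep["index"] if n not in names]
        selected[str(cls)] = names
    return SensitiveSet(selected, alpha=alpha, min_abs_r=min_abs_r)
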