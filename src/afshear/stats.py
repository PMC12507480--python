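"""Normality-gated group comparisons, Spearman correlations, and summary
tables.

The decision tree: Shapiro-Wilk per group; if every group is consistent
with normality (p > 0.05) use Welch's t-test (between groups) or
repeated-measures ANOVA (within), otherwise Mann-Whitney U (between) or
Friedman (within).  Bonferroni adjustment is ``min(1, m p)`` with the
family size ``m`` declared by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "bonferroni",
    "gated_compare",
    "spearman",
    "build_summary",
]


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    design: str  # "between" or "within"
    test: str
    normal: bool
    shapiro_p: tuple[float, ...]
    statistic: float
    p_value: float
    p_adjusted: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r_s: float
    p_value: float
    n: int


def bonferroni(p: float, m: int) -> float:
    """Family-wise adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def _shapiro_all_normal(groups: list[np.ndarray], alpha: float = 0.05):
    ps = []
    for g in groups:
        if g.size < 3:
            raise ValueError("need >= 3 observations per group for the normality gate")
        if np.ptp(g) == 0:
            ps.append(0.0)  # constant data: not normal, take the rank branch
            continue
        ps.append(float(sstats.shapiro(g).pvalue))
    return all(p > alpha for p in ps), tuple(ps)


def gated_compare(
    values,
    groups=None,
    design: str = "between",
    variable: str = "value",
    family_size: int = 1,
) -> ComparisonResult:
    """Normality-gated comparison.

    ``between``: ``values`` and ``groups`` are flat arrays; exactly two
    group labels.  ``within``: ``values`` is an (n_subjects, k_conditions)
    matrix of repeated measures (no missing cells; unbalanced designs are
    rejected).
    """
    if design == "between":
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        labels = pd.unique(groups)
        if labels.size != 2:
            raise ValueError("between design requires exactly two groups")
        a = values[groups == labels[0]]
        b = values[groups == labels[1]]
        normal, ps = _shapiro_all_normal([a, b])
        if normal:
            res = sstats.ttest_ind(a, b, equal_var=False)
            test = "welch-t"
        else:
            res = sstats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney-u"
        stat, p = float(res.statistic), float(res.pvalue)
        means = (float(np.mean(a)), float(np.mean(b)))
        sds = (float(np.std(a, ddof=1)), float(np.std(b, ddof=1)))
    elif design == "within":
        mat = np.asarray(values, dtype=float)
        if mat.ndim != 2 or mat.shape[1] < 2:
            raise ValueError("within design requires an (n_subjects, k) matrix")
        if np.any(~np.isfinite(mat)):
            raise ValueError("within design requires balanced repeated measures")
        conditions = [mat[:, j] for j in range(mat.shape[1])]
        normal, ps = _shapiro_all_normal(conditions)
        if normal:
            import pingouin as pg

            n, k = mat.shape
            long = pd.DataFrame(
                {
                    "y": mat.ravel(),
                    "subject": np.repeat(np.arange(n), k),
                    "condition": np.tile(np.arange(k), n),
                }
            )
            aov = pg.rm_anova(
                data=long, dv="y", within="condition", subject="subject"
            )
            stat, p = float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])
            test = "rm-anova"
        else:
            res = sstats.friedmanchisquare(*conditions)
            stat, p = float(res.statistic), float(res.pvalue)
            test = "friedman"
        means = tuple(float(np.mean(c)) for c in conditions)
        sds = tuple(float(np.std(c, ddof=1)) for c in conditions)
    else:
        raise ValueError("design must be 'between' or 'within'")
    return ComparisonResult(
        variable=variable,
        design=design,
        test=test,
        normal=normal,
        shapiro_p=ps,
        statistic=stat,
        p_value=p,
        p_adjusted=bonferroni(p, family_size),
        group_means=means,
        group_sds=sds,
    )


def spearman(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with tie-corrected ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    res = sstats.spearmanr(x, y)
    return CorrelationResult(
        pair=pair, r_s=float(res.statistic), p_value=float(res.pvalue), n=x.size
    )


def build_summary(
    results: pd.DataFrame,
    value_cols: list[str] | None = None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Mean +/- SD per group x orientation with significance flags.

    ``results`` is tidy with columns ``group``, ``orientation`` and one or
    more numeric value columns.  Per value column the table carries the
    cell summaries, a ``*`` flag for the between-group contrast within each
    orientation, and a ``#`` flag for the between-orientation contrast
    within each group.  A ratio row (mean G2 / mean G1 per group) is
    appended for modulus-like columns.
    """
    if value_cols is None:
        value_cols = [
            c
            for c in results.columns
            if c not in ("group", "orientation", "sample_id")
            and pd.api.types.is_numeric_dtype(results[c])
        ]
    groups = list(pd.unique(results["group"]))
    orients = list(pd.unique(results["orientation"]))
    m = family_size if family_size is not None else len(value_cols) * len(orients)
    rows = []
    for col in value_cols:
        row: dict = {"variable": col}
        for orient in orients:
            sub = results[results["orientation"] == orient]
            for g in groups:
                vals = sub.loc[sub["group"] == g, col].dropna()
                cell = f"{orient}/{g}"
                if vals.empty:
                    row[cell] = "unavailable"
                    continue
                sd = vals.std(ddof=1) if vals.size > 1 else 0.0
                row[cell] = f"{vals.mean():.1f} ± {sd:.1f}"
            # between-group contrast within orientation
            if len(groups) == 2:
                a = sub.loc[sub["group"] == groups[0], col].dropna()
                b = sub.loc[sub["group"] == groups[1], col].dropna()
                if a.size >= 3 and b.size >= 3:
                    cmp_res = gated_compare(
                        np.concatenate([a, b]),
                        np.array([groups[0]] * a.size + [groups[1]] * b.size),
                        design="between",
                        variable=col,
                        family_size=m,
                    )
                    row[f"{orient} *"] = "*" if cmp_res.significant else ""
        # between-orientation contrast within group
        if len(orients) == 2:
            for g in groups:
                sub = results[results["group"] == g]
                a = sub.loc[sub["orientation"] == orients[0], col].dropna()
                b = sub.loc[sub["orientation"] == orients[1], col].dropna()
                if a.size >= 3 and b.size >= 3:
                    cmp_res = gated_compare(
                        np.concatenate([a, b]),
                        np.array([orients[0]] * a.size + [orients[1]] * b.size),
                        design="between",
                        variable=col,
                        family_size=m,
                    )
                    row[f"{g} #"] = "#" if cmp_res.significant else ""
        rows.append(row)
    summary = pd.DataFrame(rows)
    # orientation ratio row per modulus-like column
    if "G1" in orients and "G2" in orients:
        for col in value_cols:
            if "modulus" not in col and "kpa" not in col.lower():
                continue
            row = {"variable": f"{col} ratio G2/G1"}
            for g in groups:
                sub = results[results["group"] == g]
                m1 = sub.loc[sub["orientation"] == "G1", col].dropna().mean()
                m2 = sub.loc[sub["orientation"] == "G2", col].dropna().mean()
                row[f"G1/{g}"] = ""
                row[f"G2/{g}"] = f"{m2 / m1:.1f}" if m1 else "unavailable"
            summary = pd.concat([summary, pd.DataFrame([row])], ignore_index=True)
    return summary
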