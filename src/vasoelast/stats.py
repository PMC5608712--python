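"""Cohort statistics: group summaries, t tests, one-way ANOVA with post
hoc comparisons, and modulus-remodeling correlations.

Findings are reported as mean +/- SEM.  Two-group comparisons use the
equal-variance Student's t test (Welch available per flag); the
four-group comparison is a one-way ANOVA followed by pairwise post hoc t
tests only when the ANOVA reaches significance.  Correlations are
Pearson's r with exact t-transform p-values; pairs with missing values
(unmeasurable sham intima) are excluded pairwise.  No multiple-testing
correction is applied by default, mirroring the source procedure; a
Bonferroni option exists and logs a note when used.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class StatResult:
    """One comparison or correlation."""

    name: str
    statistic: float
    df: float
    p_value: float
    summaries: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    kind: str = "t"   # "t" | "anova" | "pearson"

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def mean_sem(values) -> tuple[float, float, int]:
    """(mean, SEM, n) with SEM = SD/sqrt(n); n = 1 yields SEM 0 (flagged)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        raise ValueError("empty group")
    if n == 1:
        log.warning("SEM of a single observation reported as 0")
        return float(v[0]), 0.0, 1
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n)), n


def summarize_groups(
    table: pd.DataFrame, metric: str, group_col: str = "group"
) -> pd.DataFrame:
    """Per-group mean +/- SEM of a metric column."""
    rows = []
    for name, sub in table.groupby(group_col, sort=False):
        m, s, n = mean_sem(sub[metric])
        rows.append({group_col: name, "mean": m, "sem": s, "n": n})
    return pd.DataFrame(rows)


def two_group_test(a, b, equal_var: bool = True, name: str = "t-test") -> StatResult:
    """Two-sided Student's t test (equal-variance pooled by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(stat):  # identical constant samples
        stat, p = 0.0, 1.0
    return StatResult(
        name=name,
        statistic=stat,
        df=df,
        p_value=p,
        summaries={"a": mean_sem(a), "b": mean_sem(b)},
        kind="t",
    )


def anova_posthoc(
    table: pd.DataFrame,
    metric: str,
    groups: list[str],
    group_col: str = "group",
    bonferroni: bool = False,
) -> list[StatResult]:
    """One-way ANOVA over four groups, pairwise post hoc t tests if p < 0.05.

    Returns the ANOVA result first, followed by any post hoc results.
    """
    if len(groups) < 4:
        raise ValueError("the factorial design has four experimental groups")
    samples = []
    for g in groups:
        v = table.loc[table[group_col] == g, metric].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
        samples.append(v)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # identical constant groups make F undefined; handled below
        _warnings.simplefilter("ignore")
        F, p = sps.f_oneway(*samples)
    if not np.isfinite(F):  # all groups identical constants
        F, p = 0.0, 1.0
    k = len(groups)
    n_tot = sum(s.size for s in samples)
    out = [
        StatResult(
            name=f"ANOVA[{metric}]",
            statistic=float(F),
            df=float(k - 1),
            p_value=float(p),
            summaries={g: mean_sem(s) for g, s in zip(groups, samples)},
            kind="anova",
        )
    ]
    out[0].summaries["_df_within"] = (float(n_tot - k), 0.0, n_tot)
    if p < SIGNIFICANCE_LEVEL:
        pairs = list(itertools.combinations(range(k), 2))
        correction = len(pairs) if bonferroni else 1
        if bonferroni:
            log.info("applying Bonferroni correction over %d post hoc contrasts", len(pairs))
        for i, j in pairs:
            r = two_group_test(
                samples[i], samples[j], name=f"{groups[i]} vs {groups[j]} [{metric}]"
            )
            r.p_value = min(1.0, r.p_value * correction)
            out.append(r)
    return out


def pearson(x, y, name: str = "pearson") -> StatResult:
    """Pearson correlation with pairwise missing-value exclusion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    r, p = sps.pearsonr(x[ok], y[ok])
    return StatResult(
        name=name, statistic=float(r), df=float(ok.sum() - 2), p_value=float(p),
        summaries={"n": (float(ok.sum()), 0.0, int(ok.sum()))}, kind="pearson",
    )


def modulus_correlations(
    table: pd.DataFrame,
    modulus_col: str = "wall_modulus_kpa",
    targets: tuple[str, ...] = (
        "intima_volume_um3",
        "im_ratio",
        "strain_pct",
        "media_volume_um3",
        "adventitia_volume_um3",
    ),
    strict: bool = True,
) -> list[StatResult]:
    """Pearson r of the reconstructed modulus against remodeling measures.

    A pair with fewer than 3 complete observations raises when ``strict``
    and is skipped with a log note otherwise.
    """
    out = []
    for col in targets:
        if col not in table:
            continue
        try:
            out.append(
                pearson(table[modulus_col], table[col], name=f"{modulus_col} vs {col}")
            )
        except ValueError:
            if strict:
                raise
            log.info("skipping correlation %s vs %s: fewer than 3 complete pairs",
                     modulus_col, col)
    return out


def results_frame(results: list[StatResult]) -> pd.DataFrame:
    """Flatten StatResults for CSV/markdown reporting."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "kind": r.kind,
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "significant": bool(r.p_value < SIGNIFICANCE_LEVEL),
            }
            for r in results
        ]
    )
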