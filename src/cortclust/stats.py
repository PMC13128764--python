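"""Group-comparison test battery with multiple-testing correction.

Continuous variables are compared with Welch's unpaired t-test (two
groups) or one-way ANOVA (more than two); categorical variables with a
chi-square test, Yates-corrected for 2x2 tables.  Every test has a
summary-statistic entry point (mean/SD/n per group) because the source
tables print only group moments.  The battery's p-values are corrected
with the Benjamini-Hochberg step-up procedure by default; Bonferroni and
a fixed threshold are available behind the same ``alpha_policy`` switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "TestBattery",
    "BHResult",
    "welch_t",
    "welch_t_raw",
    "oneway_anova",
    "oneway_anova_from_summary",
    "chi_square_2xk",
    "bh_adjust",
    "run_battery",
    "battery_to_frame",
]


@dataclass
class TestResult:
    variable: str
    test_kind: str              # "t_test" | "anova" | "chi_square"
    statistic: float
    p_value: float
    group_summaries: list
    n_per_group: tuple
    df: object = None
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class BHResult:
    significant: np.ndarray
    adjusted_alpha: float
    n_rejected: int


@dataclass
class TestBattery:
    """Ordered test results plus the single corrected threshold."""

    results: list
    q: float
    policy: str
    adjusted_alpha: float
    significant_flags: np.ndarray

    @property
    def m(self) -> int:
        return len(self.results)


def _summ(s):
    """Accept (mean, sd, n) tuples or {'mean','sd','n'} dicts."""
    if isinstance(s, dict):
        return float(s["mean"]), float(s["sd"]), int(s["n"])
    mean, sd, n = s
    return float(mean), float(sd), int(n)


# ---------------------------------------------------------------------------
# two-sample t


def welch_t(summary_a, summary_b, *, equal_var: bool = False,
            sd_ddof: int = 1, variable: str = "") -> TestResult:
    """Unpaired two-sample t-test from group summary statistics.

    Welch's form (unequal variances, Welch-Satterthwaite df) by default;
    ``equal_var=True`` gives the pooled-variance Student form.
    ``sd_ddof=0`` declares the supplied SDs to be population-convention
    (numpy-default) values, as printed by pipelines that tabulate
    ``np.std`` output; they are rescaled to sample SDs before testing.
    """
    m1, s1, n1 = _summ(summary_a)
    m2, s2, n2 = _summ(summary_b)
    if sd_ddof == 0:
        s1 *= np.sqrt(n1 / (n1 - 1))
        s2 *= np.sqrt(n2 / (n2 - 1))
    elif sd_ddof != 1:
        raise ValueError("sd_ddof must be 0 or 1")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if s1 == 0.0 and s2 == 0.0:
        p = 1.0 if m1 == m2 else 0.0
        return TestResult(variable, "t_test", 0.0 if m1 == m2 else np.inf, p,
                          [summary_a, summary_b], (n1, n2), degenerate=True,
                          note="zero variance in both groups")
    if equal_var:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        a, b = s1**2 / n1, s2**2 / n2
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    t = (m1 - m2) / se
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(variable, "t_test", float(t), p,
                      [summary_a, summary_b], (n1, n2), df=float(df))


def welch_t_raw(a, b, *, equal_var: bool = False, variable: str = "") -> TestResult:
    """Raw-data entry point; reduces to :func:`welch_t` via group moments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    return welch_t((a.mean(), a.std(ddof=1), a.size),
                   (b.mean(), b.std(ddof=1), b.size),
                   equal_var=equal_var, variable=variable)


# ---------------------------------------------------------------------------
# one-way ANOVA


def oneway_anova_from_summary(means, sds, ns, *, sd_ddof: int = 1,
                              variable: str = "") -> TestResult:
    """Classic one-way ANOVA F test from per-group means/SDs/sizes.

    ``sd_ddof=0`` treats the supplied SDs as population-convention values
    (see :func:`welch_t`)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if means.size < 2:
        raise ValueError("need at least two groups")
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    if sd_ddof == 0:
        sds = sds * np.sqrt(ns / (ns - 1))
    elif sd_ddof != 1:
        raise ValueError("sd_ddof must be 0 or 1")
    N = int(ns.sum())
    k = means.size
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    summaries = [{"mean": m, "sd": s, "n": int(n)} for m, s, n in zip(means, sds, ns)]
    if ssw == 0.0 and ssb == 0.0:
        return TestResult(variable, "anova", 0.0, 1.0, summaries, tuple(ns),
                          df=(k - 1, N - k), degenerate=True,
                          note="all values identical")
    if ssw == 0.0:
        return TestResult(variable, "anova", np.inf, 0.0, summaries, tuple(ns),
                          df=(k - 1, N - k), degenerate=True,
                          note="zero within-group variance")
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = float(sps.f.sf(F, k - 1, N - k))
    return TestResult(variable, "anova", float(F), p, summaries, tuple(ns),
                      df=(k - 1, N - k))


def oneway_anova(groups, *, variable: str = "") -> TestResult:
    """Raw-data one-way ANOVA; agrees exactly with the summary entry point."""
    cleaned = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[~np.isnan(g)]
        if g.size >= 2:
            cleaned.append(g)
    if len(cleaned) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    return oneway_anova_from_summary(
        [g.mean() for g in cleaned],
        [g.std(ddof=1) for g in cleaned],
        [g.size for g in cleaned],
        variable=variable,
    )


# ---------------------------------------------------------------------------
# chi-square


def chi_square_2xk(table, *, variable: str = "") -> TestResult:
    """Pearson chi-square on a contingency table of counts.

    2x2 tables get the Yates continuity correction; larger tables the
    plain Pearson statistic.  A zero row/column margin leaves the test
    undefined (p = NaN, flagged degenerate).
    """
    table = np.asarray(table)
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        table = np.asarray(table, dtype=float)
        if (table < 0).any() or not np.allclose(table, np.rint(table)):
            raise ValueError("table must hold non-negative integer counts")
        table = np.rint(table).astype(int)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    n_per_group = tuple(int(r) for r in table.sum(axis=1))
    summaries = [
        {"count": int(row[0]), "n": int(row.sum()),
         "pct": 100.0 * row[0] / row.sum() if row.sum() else np.nan}
        for row in table
    ]
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult(variable, "chi_square", np.nan, np.nan, summaries,
                          n_per_group, degenerate=True, note="zero margin")
    correction = table.shape == (2, 2)
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=correction)
    return TestResult(variable, "chi_square", float(chi2), float(p), summaries,
                      n_per_group, df=int(dof),
                      note="yates" if correction else "pearson")


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values, q: float = 0.05) -> BHResult:
    """Benjamini-Hochberg step-up over an ordered battery of p-values.

    Sorts ascending, finds the largest rank i with p(i) <= (i/m) q, and
    declares the i smallest p-values significant.  ``adjusted_alpha`` is
    the single threshold (i/m) q the battery is compared against; when
    nothing passes it falls back to the smallest critical value q/m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(p[order] <= crit)
    if passing.size == 0:
        return BHResult(np.zeros(m, dtype=bool), q / m, 0)
    i = int(passing[-1]) + 1
    flags = np.zeros(m, dtype=bool)
    flags[order[:i]] = True
    return BHResult(flags, float(i / m * q), i)


def _fixed_policy_alpha(policy: str, q: float, m: int) -> float:
    if policy == "bonferroni":
        return q / m
    if policy.startswith("fixed:"):
        return float(policy.split(":", 1)[1])
    raise ValueError(f"unknown alpha policy {policy!r}")


def apply_alpha_policy(p_values, policy: str = "bh", q: float = 0.05):
    """Significance flags + single threshold under bh|bonferroni|fixed:<x>."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    flags = np.zeros(p.size, dtype=bool)
    if policy == "bh":
        res = bh_adjust(np.where(ok, p, 1.0), q)
        flags = res.significant & ok
        return flags, res.adjusted_alpha
    alpha = _fixed_policy_alpha(policy, q, int(ok.sum()) or 1)
    flags[ok] = p[ok] <= alpha
    return flags, alpha


# ---------------------------------------------------------------------------
# battery over a covariate table

CONTINUOUS_VARS = (
    "age", "length_of_stay", "descent_velocity", "initial_cortisol",
    "nadir_cortisol", "ki67", "max_diameter_cm", "tumor_volume_cm3",
    "knosp_grade",
)
CATEGORICAL_VARS = (
    "male", "macroadenoma", "apoplexy", "crooke_hyaline",
    "piecemeal_resection", "iop_csf_leak", "postop_complication",
    "postop_csf_leak",
)


def run_battery(covariates: pd.DataFrame, labels, *,
                continuous=CONTINUOUS_VARS, categorical=CATEGORICAL_VARS,
                extra_results=(), q: float = 0.05,
                policy: str = "bh") -> TestBattery:
    """Compare covariates across groups and correct the whole battery.

    Welch t (2 groups) / one-way ANOVA (>2) for continuous variables,
    chi-square for flags; ``extra_results`` (e.g. per-timepoint trajectory
    tests) are appended so the correction spans the full battery, the way
    the published analysis pooled its 58 tests.
    """
    labels = np.asarray(labels)
    group_ids = np.unique(labels)
    if group_ids.size < 2:
        raise ValueError("need at least two groups")
    results: list[TestResult] = []
    for var in continuous:
        if var not in covariates.columns:
            continue
        groups = [covariates.loc[labels == g, var].to_numpy(dtype=float)
                  for g in group_ids]
        groups = [g[~np.isnan(g)] for g in groups]
        if sum(g.size >= 2 for g in groups) < 2:
            results.append(TestResult(var, "anova", np.nan, np.nan, [],
                                      tuple(g.size for g in groups),
                                      degenerate=True, note="insufficient data"))
            continue
        if group_ids.size == 2:
            results.append(welch_t_raw(groups[0], groups[1], variable=var))
        else:
            results.append(oneway_anova(groups, variable=var))
    for var in categorical:
        if var not in covariates.columns:
            continue
        table = np.array([
            [int(covariates.loc[labels == g, var].sum()),
             int((~covariates.loc[labels == g, var].astype(bool)).sum())]
            for g in group_ids
        ])
        results.append(chi_square_2xk(table, variable=var))
    results = list(results) + list(extra_results)
    p = np.array([r.p_value for r in results], dtype=float)
    flags, alpha = apply_alpha_policy(p, policy=policy, q=q)
    return TestBattery(results, q=q, policy=policy, adjusted_alpha=alpha,
                       significant_flags=flags)


def battery_to_frame(battery: TestBattery) -> pd.DataFrame:
    """Tables-style rendering: group summaries, p (4 decimals), stars."""
    rows = []
    for r, sig in zip(battery.results, battery.significant_flags):
        row = {"variable": r.variable, "test": r.test_kind}
        for j, s in enumerate(r.group_summaries):
            if isinstance(s, dict) and "mean" in s:
                row[f"group{j}"] = f"{s['mean']:.1f} ± {s['sd']:.1f}"
            elif isinstance(s, dict):
                row[f"group{j}"] = f"{s['count']} ({s['pct']:.1f}%)"
            else:
                m, sd, n = _summ(s)
                row[f"group{j}"] = f"{m:.1f} ± {sd:.1f}"
        row["p_value"] = np.nan if np.isnan(r.p_value) else round(r.p_value, 4)
        row["significant"] = "*" if sig else ""
        rows.append(row)
    return pd.DataFrame(rows)
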