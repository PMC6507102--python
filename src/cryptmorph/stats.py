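"""Nested ANOVA and Tukey HSD for hierarchical cohort designs.

Images are replicates within mice, and mice within cohorts, so testing
the cohort effect against the image-level residual would pseudoreplicate.
The nested one-way ANOVA therefore tests the cohort mean square against
the mouse-within-cohort mean square; for balanced designs this is
algebraically identical to a classical one-way ANOVA on per-mouse means.
Unbalanced designs use sequential (type-I) sums of squares with the same
error stratum.

The depth analysis is a split-plot: depth stacks (one location on one
mouse) are whole plots carrying all five acquisition depths, so depth
and cohort x depth are tested against the within-stack residual while
cohort keeps the mouse-level error term.

Tukey's HSD operates on per-mouse means (the experimental unit) with the
studentized range distribution and the mouse-stratum degrees of freedom;
flags follow the * (p < 0.05) / ** (p < 0.01) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class DesignError(ValueError):
    """The table cannot support the requested analysis."""


@dataclass(frozen=True)
class FactorTest:
    """One tested factor: F statistic, degrees of freedom, p-value."""

    name: str
    ss: float
    df_num: int
    df_den: int
    ms: float
    ms_error: float
    F: float
    p: float


@dataclass
class NestedAnovaResult:
    """Factor tests plus error-stratum bookkeeping."""

    factors: list[FactorTest]
    strata: dict[str, tuple[float, int]] = field(default_factory=dict)  # name -> (SS, df)
    degenerate: bool = False

    def __getitem__(self, name: str) -> FactorTest:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.factors])


@dataclass(frozen=True)
class TukeyComparison:
    group_i: str
    group_j: str
    mean_diff: float
    q: float
    p_adj: float
    flag: str


@dataclass
class TukeyResult:
    comparisons: list[TukeyComparison]
    ms_error: float
    df_error: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])


def significance_flag(p: float) -> str:
    """Map an adjusted p-value to the ns / * / ** convention."""
    if np.isnan(p):
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _scoped_codes(*series) -> tuple[np.ndarray, int]:
    """Integer codes for the tuple key formed by the given columns."""
    idx = pd.MultiIndex.from_arrays([np.asarray(s) for s in series])
    codes, uniques = pd.factorize(idx)
    return codes, len(uniques)


def _group_ss(values: np.ndarray, codes: np.ndarray, grand_mean: float) -> float:
    """Sum over groups of n_g * (mean_g - grand_mean)^2."""
    n = np.bincount(codes)
    s = np.bincount(codes, weights=values)
    keep = n > 0
    return float(np.sum(n[keep] * (s[keep] / n[keep] - grand_mean) ** 2))


def _prepare(table: pd.DataFrame, response: str, cols: tuple[str, ...]):
    for c in (*cols, response):
        if c not in table.columns:
            raise DesignError(f"table lacks required column {c!r}")
    sub = table.loc[:, [*cols, response]].dropna(subset=[response])
    vals = sub[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DesignError("responses must be finite")
    return sub, vals


def nested_oneway_anova(
    table: pd.DataFrame, response: str = "value"
) -> NestedAnovaResult:
    """Nested one-way ANOVA: cohort tested against mouse(cohort).

    Expects columns ``cohort``, ``mouse`` and the response.  Requires at
    least two cohorts and at least two mice in every cohort (otherwise
    the mouse-stratum denominator has no degrees of freedom).  A table
    with zero within-mouse variance and zero mouse variance is flagged
    degenerate (p = NaN, no rejection).
    """
    sub, vals = _prepare(table, response, ("cohort", "mouse"))
    cohorts = sub["cohort"].astype(str)
    # mouse ids scoped to cohort via tuple keys (plain string concat could collide)
    c_codes, c_labels = pd.factorize(cohorts)
    m_codes, m = _scoped_codes(cohorts, sub["mouse"])
    a = len(c_labels)
    n_total = len(vals)
    if a < 2:
        raise DesignError("need at least two cohorts")
    mice_per_cohort = (
        pd.Series(m_codes, index=cohorts.to_numpy()).groupby(level=0).nunique()
    )
    if (mice_per_cohort < 2).any():
        bad = list(mice_per_cohort[mice_per_cohort < 2].index)
        raise DesignError(f"cohorts with a single mouse have no error df: {bad}")

    grand = vals.mean()
    ss_total = float(np.sum((vals - grand) ** 2))
    ss_cohort = _group_ss(vals, c_codes, grand)
    ss_mouse_total = _group_ss(vals, m_codes, grand)
    ss_mouse = ss_mouse_total - ss_cohort  # mouse within cohort (sequential)
    ss_within = ss_total - ss_mouse_total

    df_c, df_m, df_w = a - 1, m - a, n_total - m
    ms_c = ss_cohort / df_c
    ms_m = ss_mouse / df_m if df_m > 0 else float("nan")

    degenerate = not (ms_m > 0)
    if degenerate:
        F = p = float("nan")
    else:
        F = ms_c / ms_m
        p = float(sps.f.sf(F, df_c, df_m))
    return NestedAnovaResult(
        factors=[
            FactorTest("cohort", ss_cohort, df_c, df_m, ms_c, ms_m, F, p),
        ],
        strata={
            "cohort": (ss_cohort, df_c),
            "mouse(cohort)": (ss_mouse, df_m),
            "within": (ss_within, df_w),
        },
        degenerate=degenerate,
    )


def _mouse_means(table: pd.DataFrame, response: str) -> pd.DataFrame:
    sub, _ = _prepare(table, response, ("cohort", "mouse"))
    return (
        sub.groupby(["cohort", "mouse"], sort=False, observed=True)[response]
        .mean()
        .reset_index()
    )


def tukey_posthoc(
    table: pd.DataFrame, response: str = "value"
) -> TukeyResult:
    """Tukey-Kramer HSD over cohorts, on per-mouse means.

    The mouse is the experimental unit: group means are unweighted means
    of per-mouse means, the error mean square is the pooled within-cohort
    variance of mouse means (df = total mice - cohorts), and adjusted
    p-values come from the studentized range distribution.  With exactly
    two cohorts this reduces to the two-sample pooled t-test via
    ``q = t * sqrt(2)``.
    """
    mm = _mouse_means(table, response)
    groups = mm.groupby("cohort", sort=False, observed=True)[response]
    names = list(groups.groups)
    k = len(names)
    if k < 2:
        raise DesignError("Tukey needs at least two cohorts")
    means = groups.mean()
    ns = groups.size()
    ss_err = float(((mm[response] - mm["cohort"].map(means)) ** 2).sum())
    df_err = int(len(mm) - k)
    if df_err <= 0:
        raise DesignError("no error degrees of freedom for Tukey")
    ms_err = ss_err / df_err

    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            diff = float(means[gi] - means[gj])
            if ms_err > 0:
                se = np.sqrt(ms_err / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_err))
            else:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else 0.0
            comparisons.append(
                TukeyComparison(gi, gj, diff, float(q), p, significance_flag(p))
            )
    return TukeyResult(comparisons, ms_error=ms_err, df_error=df_err)


def depth_twoway_anova(
    table: pd.DataFrame, response: str = "value"
) -> NestedAnovaResult:
    """Split-plot two-way ANOVA: cohort x depth with nested stacks.

    Expects columns ``cohort``, ``mouse``, ``stack``, ``depth_um`` and
    the response, with exactly one observation per (stack, depth) and
    every stack carrying the full depth set.  Cohort is tested against
    mouse(cohort); depth and cohort x depth against the within-stack
    residual.  A single-depth table falls back to the nested one-way
    analysis.
    """
    sub, vals = _prepare(
        table, response, ("cohort", "mouse", "stack", "depth_um")
    )
    depths = np.sort(sub["depth_um"].unique())
    if len(depths) == 1:
        return nested_oneway_anova(sub, response)

    cohorts = sub["cohort"].astype(str)
    mouse_col = sub["mouse"].astype(str)
    stack_col = sub["stack"].astype(str)
    s_codes, s = _scoped_codes(cohorts, mouse_col, stack_col)
    stack_keys = list(zip(cohorts, mouse_col, stack_col))

    counts = (
        sub.assign(_stack=s_codes)
        .groupby("_stack", observed=True)["depth_um"]
        .agg(["nunique", "size"])
    )
    stack_names = dict(zip(s_codes, stack_keys))
    bad = counts.index[
        (counts["nunique"] != len(depths)) | (counts["size"] != len(depths))
    ].tolist()
    if bad:
        names = sorted("/".join(stack_names[b]) for b in bad)
        raise DesignError(
            f"stacks missing depth planes (need one image at each of "
            f"{[float(d) for d in depths]}): {names}"
        )
    c_codes, c_labels = pd.factorize(cohorts)
    m_codes, m = _scoped_codes(cohorts, mouse_col)
    d_codes, d_labels = pd.factorize(sub["depth_um"])
    cd_codes, _ = _scoped_codes(cohorts, sub["depth_um"])
    a, d = len(c_labels), len(d_labels)
    n_total = len(vals)

    grand = vals.mean()
    ss_total = float(np.sum((vals - grand) ** 2))
    ss_c = _group_ss(vals, c_codes, grand)
    ss_m = _group_ss(vals, m_codes, grand) - ss_c
    ss_s = _group_ss(vals, s_codes, grand) - ss_c - ss_m
    ss_d = _group_ss(vals, d_codes, grand)
    ss_cd = _group_ss(vals, cd_codes, grand) - ss_c - ss_d
    ss_resid = ss_total - (ss_c + ss_m + ss_s + ss_d + ss_cd)

    df_c, df_m, df_s = a - 1, m - a, s - m
    df_d = d - 1
    df_cd = (a - 1) * (d - 1)
    df_resid = n_total - 1 - (df_c + df_m + df_s + df_d + df_cd)
    if df_m <= 0:
        raise DesignError("cohort test needs >= 2 mice per cohort")
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom for the depth tests")

    ms_m = ss_m / df_m
    ms_resid = ss_resid / df_resid
    degenerate = not (ms_m > 0 and ms_resid > 0)

    def _test(name, ss, dfn, ms_err, df_err):
        ms = ss / dfn
        if degenerate or not ms_err > 0:
            return FactorTest(name, ss, dfn, df_err, ms, ms_err, float("nan"), float("nan"))
        F = ms / ms_err
        return FactorTest(name, ss, dfn, df_err, ms, ms_err, F, float(sps.f.sf(F, dfn, df_err)))

    return NestedAnovaResult(
        factors=[
            _test("cohort", ss_c, df_c, ms_m, df_m),
            _test("depth", ss_d, df_d, ms_resid, df_resid),
            _test("cohort:depth", ss_cd, df_cd, ms_resid, df_resid),
        ],
        strata={
            "cohort": (ss_c, df_c),
            "mouse(cohort)": (ss_m, df_m),
            "stack(mouse)": (ss_s, df_s),
            "depth": (ss_d, df_d),
            "cohort:depth": (ss_cd, df_cd),
            "residual": (ss_resid, df_resid),
        },
        degenerate=degenerate,
    )


def per_depth_cohort_tests(
    table: pd.DataFrame, response: str = "value"
) -> dict[float, tuple[NestedAnovaResult, TukeyResult]]:
    """Cohort comparison at each acquisition depth separately.

    Mirrors comparing cohorts at a fixed depth: the table is sliced per
    depth and each slice gets the nested one-way ANOVA plus Tukey HSD.
    """
    out = {}
    for depth, sub in table.groupby("depth_um", sort=True, observed=True):
        out[float(depth)] = (
            nested_oneway_anova(sub, response),
            tukey_posthoc(sub, response),
        )
    return out


def per_cohort_depth_tests(
    table: pd.DataFrame, response: str = "value"
) -> dict[str, tuple[NestedAnovaResult, TukeyResult]]:
    """Depth comparison within each cohort (stacks as blocks).

    Within a cohort every stack contributes one value per depth, so
    depth is a within-stack factor: F = MS_depth / MS(depth x stack
    residual), and Tukey compares depth means with that residual and
    n = number of stacks per depth.
    """
    out = {}
    for cohort, sub0 in table.groupby("cohort", sort=False, observed=True):
        sub, vals = _prepare(sub0, response, ("mouse", "stack", "depth_um"))
        s_codes, s = _scoped_codes(sub["mouse"], sub["stack"])
        d_codes, d_labels = pd.factorize(sub["depth_um"])
        d = len(d_labels)
        if d < 2 or s < 2:
            raise DesignError(
                f"cohort {cohort!r} needs >= 2 depths and >= 2 stacks"
            )
        grand = vals.mean()
        ss_total = float(np.sum((vals - grand) ** 2))
        ss_d = _group_ss(vals, d_codes, grand)
        ss_s = _group_ss(vals, s_codes, grand)
        ss_resid = ss_total - ss_d - ss_s
        df_d, df_s = d - 1, s - 1
        df_resid = len(vals) - 1 - df_d - df_s
        if df_resid <= 0:
            raise DesignError(f"cohort {cohort!r}: no residual df")
        ms_d = ss_d / df_d
        ms_resid = ss_resid / df_resid
        if ms_resid > 0:
            F = ms_d / ms_resid
            p = float(sps.f.sf(F, df_d, df_resid))
            degenerate = False
        else:
            F = p = float("nan")
            degenerate = True
        anova = NestedAnovaResult(
            factors=[FactorTest("depth", ss_d, df_d, df_resid, ms_d, ms_resid, F, p)],
            strata={
                "depth": (ss_d, df_d),
                "stack": (ss_s, df_s),
                "residual": (ss_resid, df_resid),
            },
            degenerate=degenerate,
        )
        # Tukey across depths with the within-stack residual
        comparisons = []
        d_means = {
            float(lab): vals[d_codes == i].mean() for i, lab in enumerate(d_labels)
        }
        n_per = {
            float(lab): int((d_codes == i).sum()) for i, lab in enumerate(d_labels)
        }
        d_sorted = sorted(d_means)
        for i in range(len(d_sorted)):
            for j in range(i + 1, len(d_sorted)):
                di, dj = d_sorted[i], d_sorted[j]
                diff = float(d_means[di] - d_means[dj])
                if ms_resid > 0:
                    se = np.sqrt(ms_resid / 2.0 * (1.0 / n_per[di] + 1.0 / n_per[dj]))
                    q = abs(diff) / se
                    p_adj = float(sps.studentized_range.sf(q, d, df_resid))
                else:
                    q, p_adj = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
                comparisons.append(
                    TukeyComparison(
                        str(di), str(dj), diff, float(q), p_adj, significance_flag(p_adj)
                    )
                )
        out[str(cohort)] = (anova, TukeyResult(comparisons, ms_resid, df_resid))
    return out


def run_feature_screen(
    summaries: pd.DataFrame,
    features: list[str] | None = None,
    statistics: tuple[str, ...] = ("mean", "sd"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nested one-way ANOVA + Tukey per (feature, statistic) pair.

    ``summaries`` is the per-image summary table with hierarchy columns
    and ``<feature>_mean`` / ``<feature>_sd`` responses.  Returns an
    ANOVA table (one row per screen) and a Tukey table (one row per
    pairwise comparison).  P-values are not corrected across the
    feature screens; each screen stands on its own.
    """
    from .morphometry import FEATURE_COLUMNS

    features = features or FEATURE_COLUMNS
    anova_rows = []
    tukey_rows = []
    for feat in features:
        for stat in statistics:
            col = f"{feat}_{stat}"
            if col not in summaries.columns:
                raise DesignError(f"summary table lacks column {col!r}")
            res = nested_oneway_anova(summaries, response=col)
            tk = tukey_posthoc(summaries, response=col)
            t = res["cohort"]
            anova_rows.append(
                dict(
                    feature=feat,
                    statistic=stat,
                    F=t.F,
                    df_num=t.df_num,
                    df_den=t.df_den,
                    p=t.p,
                    degenerate=res.degenerate,
                )
            )
            for cmp_ in tk.comparisons:
                tukey_rows.append(
                    dict(
                        feature=feat,
                        statistic=stat,
                        group_i=cmp_.group_i,
                        group_j=cmp_.group_j,
                        mean_diff=cmp_.mean_diff,
                        q=cmp_.q,
                        p_adj=cmp_.p_adj,
                        flag=cmp_.flag,
                    )
                )
    return pd.DataFrame(anova_rows), pd.DataFrame(tukey_rows)


def simulate_nested_table(
    rng: np.random.Generator,
    n_cohorts: int = 5,
    mice_per_cohort: int = 4,
    images_per_mouse: int = 5,
    cohort_effects: dict[int, float] | None = None,
    mouse_sd: float = 0.5,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate a response table from the nested variance-component model.

    ``y = cohort effect + mouse effect (SD mouse_sd) + noise (SD
    noise_sd)``.  Used for null calibration and power studies of the
    nested ANOVA; cohort effects default to zero (the null).
    """
    rows = []
    effects = cohort_effects or {}
    for c in range(n_cohorts):
        for m in range(mice_per_cohort):
            mouse_eff = rng.normal(0.0, mouse_sd)
            y = (
                effects.get(c, 0.0)
                + mouse_eff
                + rng.normal(0.0, noise_sd, images_per_mouse)
            )
            for i, v in enumerate(y):
                rows.append(
                    dict(cohort=f"c{c}", mouse=f"m{m}", image=i, value=float(v))
                )
    return pd.DataFrame(rows)


def simulate_depth_table(
    rng: np.random.Generator,
    n_cohorts: int = 5,
    mice_per_cohort: int = 4,
    stacks_per_mouse: int = 2,
    depths: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0),
    shift: float = 0.0,
    shift_cohort: int = 0,
    shift_depth: float | None = None,
    mouse_sd: float = 0.5,
    stack_sd: float = 0.3,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate a depth-resolved table (one value per stack x depth).

    ``shift`` adds a fixed offset to ``shift_cohort``; with
    ``shift_depth`` set the offset applies at that single depth only
    (a localized effect, otherwise at all depths).
    """
    rows = []
    for c in range(n_cohorts):
        for m in range(mice_per_cohort):
            mouse_eff = rng.normal(0.0, mouse_sd)
            for s in range(stacks_per_mouse):
                stack_eff = rng.normal(0.0, stack_sd)
                for d in depths:
                    v = mouse_eff + stack_eff + rng.normal(0.0, noise_sd)
                    if c == shift_cohort and shift and (
                        shift_depth is None or d == shift_depth
                    ):
                        v += shift
                    rows.append(
                        dict(
                            cohort=f"c{c}",
                            mouse=f"m{m}",
                            stack=f"s{s}",
                            depth_um=float(d),
                            value=float(v),
                        )
                    )
    return pd.DataFrame(rows)
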