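"""Cohort stratification and group statistics for LDAEP treatment-response
analysis.

Stratifications: responder (>50% BDI reduction, strict), remitter
(post-treatment BDI < 10, strict), and a median split of the pretreatment
N1/P2 LDAEP into low/high groups. Statistics: two-sample t (pooled, Welch,
or variance-gated auto), paired t, Pearson chi-square without continuity
correction, group-vs-total relative odds, Cohen's d, Pearson correlation,
a sex-covariate general linear model, and a Kolmogorov–Smirnov normality
report. All p-values are two-tailed; no multiple-testing adjustment is
applied (the report counts the tests run).

The t, chi-square, d, and odds computations are closed-form in this module;
scipy supplies only the reference distributions (and serves as the
independent oracle in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

RESPONDER_REDUCTION_PCT: float = 50.0
REMITTER_BDI_CUTOFF: int = 10


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class GroupComparison:
    """One table cell: a statistic with df, two-tailed p, and descriptives."""

    kind: str  # t_pooled | t_welch | t_paired | chi2 | F | d | r | odds_vs_total
    value: float
    df: float
    p: float
    groups: tuple[GroupSummary, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0) and not math.isnan(self.p):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class ResponseStatus:
    responder: bool
    remitter: bool
    bdi_change_pct: float


def _summarize(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        n, mean, sd = x
        return GroupSummary(int(n), float(mean), float(sd))
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("group needs >= 2 raw values or an (n, mean, sd) triple")
    return GroupSummary(len(arr), float(arr.mean()), float(arr.std(ddof=1)))


def classify_response(bdi_pre: float, bdi_post: float) -> ResponseStatus:
    """Responder iff strictly >50% BDI reduction; remitter iff post < 10."""
    if bdi_pre <= 0:
        raise ValueError("percent change undefined for baseline BDI <= 0")
    change = 100.0 * (bdi_pre - bdi_post) / bdi_pre
    return ResponseStatus(
        responder=change > RESPONDER_REDUCTION_PCT,
        remitter=bdi_post < REMITTER_BDI_CUTOFF,
        bdi_change_pct=change,
    )


def median_split(values) -> np.ndarray:
    """Label each value 'low' (strictly below the sample median) or 'high'.

    With the interpolated median and distinct values, odd n yields
    floor(n/2) low and ceil(n/2) high. Order-invariant. All-identical
    values cannot be split.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need >= 2 values")
    if np.ptp(v) == 0:
        raise ValueError("degenerate split: all values identical")
    med = np.median(v)
    return np.where(v < med, "low", "high")


def two_sample_t(group_a, group_b, mode: str = "auto") -> GroupComparison:
    """Two-sample t from raw values or (n, mean, sd) summaries.

    pooled: classical equal-variance t, df = n_a + n_b - 2.
    welch: unequal-variance t with Welch–Satterthwaite fractional df.
    auto: Welch iff an F-test of variance equality rejects at 0.05.
    """
    a, b = _summarize(group_a), _summarize(group_b)
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 per group")
    if a.sd < 0 or b.sd < 0:
        raise ValueError("sd must be >= 0")
    if mode == "auto":
        mode = "welch" if _variances_differ(a, b) else "pooled"
    diff = a.mean - b.mean
    if mode == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        kind = "t_pooled"
    elif mode == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        if se == 0:
            df = a.n + b.n - 2
        else:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        kind = "t_welch"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if se == 0:
        if diff == 0:
            raise ValueError("t undefined: zero variance and equal means")
        raise ValueError("t undefined: zero variance in both groups")
    t = diff / se
    p = 2.0 * sstats.t.sf(abs(t), df)
    return GroupComparison(kind, t, float(df), float(p), (a, b))


def _variances_differ(a: GroupSummary, b: GroupSummary, alpha: float = 0.05) -> bool:
    """Two-tailed F-test of variance equality (the gate for 'auto' t mode)."""
    if a.sd == 0 and b.sd == 0:
        return False
    if a.sd == 0 or b.sd == 0:
        return True
    if a.sd >= b.sd:
        f, dfn, dfd = (a.sd / b.sd) ** 2, a.n - 1, b.n - 1
    else:
        f, dfn, dfd = (b.sd / a.sd) ** 2, b.n - 1, a.n - 1
    p = 2.0 * min(sstats.f.sf(f, dfn, dfd), sstats.f.cdf(f, dfn, dfd))
    return p < alpha


def paired_t(pre, post) -> GroupComparison:
    """Paired t = one-sample t on within-subject differences, df = n - 1."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D and equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = pre - post
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return GroupComparison("t_paired", 0.0, float(n - 1), 1.0,
                                   (_summarize(pre), _summarize(post)))
        raise ValueError("t undefined: zero-variance nonzero differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), n - 1)
    return GroupComparison("t_paired", float(t), float(n - 1), float(p),
                           (_summarize(pre), _summarize(post)))


def chi_square_2x2(table) -> GroupComparison:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction (Yates would not reproduce the reference statistics)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("table must be 2x2 nonnegative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n == 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal: chi-square undefined")
    expected = row @ col / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(sstats.chi2.sf(chi2, 1))
    return GroupComparison("chi2", chi2, 1.0, p,
                           extra={"observed": obs, "expected": expected})


def relative_odds(group_counts: tuple[int, int],
                  total_counts: tuple[int, int]) -> GroupComparison:
    """Ratio of the within-group odds of an event to the whole-sample odds.

    This group-vs-total definition is what reproduces the reference study's
    printed odds ratios from its counts; the conventional cross-product
    odds ratio of the group against the rest of the sample is also returned
    in ``extra['conventional_or']``. The log-scale CI is a delta-method
    approximation treating the two odds as independent (labelled as such —
    the overlap makes it conservative).
    """
    ge, gn = group_counts
    te, tn = total_counts
    if min(ge, gn, te, tn) <= 0:
        raise ValueError(
            "zero cell: apply an explicit continuity adjustment before calling"
        )
    ratio = (ge / gn) / (te / tn)
    se_log = math.sqrt(1.0 / ge + 1.0 / gn + 1.0 / te + 1.0 / tn)
    lo = math.exp(math.log(ratio) - 1.96 * se_log)
    hi = math.exp(math.log(ratio) + 1.96 * se_log)
    z = math.log(ratio) / se_log
    p = 2.0 * sstats.norm.sf(abs(z))
    # conventional OR: group vs the complement of the group within the total
    oe, on = te - ge, tn - gn
    conv = (ge / gn) / (oe / on) if min(oe, on) > 0 else math.nan
    return GroupComparison(
        "odds_vs_total", float(ratio), math.nan, float(p),
        extra={"ci95_log_approx": (lo, hi), "conventional_or": conv},
    )


def cohens_d(group_a, group_b) -> GroupComparison:
    """|mean difference| / pooled SD (n-1 weights)."""
    a, b = _summarize(group_a), _summarize(group_b)
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if sp2 == 0:
        raise ValueError("Cohen's d undefined: zero pooled SD")
    d = abs(a.mean - b.mean) / math.sqrt(sp2)
    return GroupComparison("d", float(d), float(a.n + b.n - 2), math.nan, (a, b))


def pearson_r(x, y) -> GroupComparison:
    """Pearson correlation with its two-tailed t-based p, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    r, p = sstats.pearsonr(x, y)
    return GroupComparison("r", float(r), float(len(x) - 2), float(p))


def glm_group_sex(outcome, group, sex) -> GroupComparison:
    """Linear model outcome ~ group + sex; F and p for the group term.

    This is the sex-covariate adjustment for group differences in LDAEP.
    Requires a non-singular design (raises on rank deficiency).
    """
    import statsmodels.api as sm
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "y": np.asarray(outcome, dtype=float),
        "group": np.asarray(group).astype(str),
        "sex": np.asarray(sex).astype(str),
    })
    if len(df) < 3:
        raise ValueError("need >= 3 subjects")
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    if df["group"].nunique() < 2:
        raise ValueError("need >= 2 group levels")
    import statsmodels.formula.api as smf

    model = smf.ols("y ~ C(group) + C(sex)", data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design (collinear group/sex)")
    aov = anova_lm(model, typ=2)
    F = float(aov.loc["C(group)", "F"])
    p = float(aov.loc["C(group)", "PR(>F)"])
    return GroupComparison(
        "F", F, float(aov.loc["C(group)", "df"]), p,
        extra={"df_resid": float(model.df_resid)},
    )


def ks_normality(values) -> GroupComparison:
    """One-sample KS statistic against N(sample mean, sample sd).

    A report/gate only — methods are never switched on its outcome. Note
    the plug-in parameters make the p-value anti-conservative (classical
    KS, as used in legacy clinical software, not Lilliefors).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 5:
        raise ValueError("need >= 5 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("KS undefined for constant values")
    stat, p = sstats.kstest(v, "norm", args=(v.mean(), sd))
    return GroupComparison("ks", float(stat), float(len(v)), float(p))


# --------------------------------------------------------------------------
# summary tables
# --------------------------------------------------------------------------

def stratify_cohort(cohort: pd.DataFrame,
                    slope_column: str = "slope_n1p2") -> pd.DataFrame:
    """Add responder/remitter flags, percent BDI change, and the low/high
    median-split labels of the pretreatment N1/P2 LDAEP."""
    out = cohort.copy()
    status = [classify_response(r.bdi_pre, r.bdi_post) for r in out.itertuples()]
    out["bdi_change_pct"] = [s.bdi_change_pct for s in status]
    out["responder"] = [s.responder for s in status]
    out["remitter"] = [s.remitter for s in status]
    out["ldaep_group"] = median_split(out[slope_column].to_numpy())
    return out


def _mean_sd_row(values: np.ndarray) -> str:
    return f"{np.mean(values):.2f} ± {np.std(values, ddof=1):.2f}"


def _compare_row(a: np.ndarray, b: np.ndarray):
    try:
        cmp = two_sample_t(a, b, mode="auto")
        return cmp, f"{cmp.p:.3f}"
    except ValueError:
        return None, "n/a"


def build_summary_tables(strat: pd.DataFrame,
                         slope_columns: dict[str, str] | None = None):
    """Render response-group and LDAEP-group summary tables.

    ``strat`` is a stratified cohort (see :func:`stratify_cohort`) that may
    carry LDAEP slope columns named in ``slope_columns`` (display label ->
    column). Returns ``{'response': DataFrame, 'ldaep_group': DataFrame,
    'comparisons': DataFrame}``; rows whose stratum is empty or degenerate
    are marked not-computable ('n/a').
    """
    if slope_columns is None:
        slope_columns = {
            k: c for k, c in
            (("N1", "slope_n1"), ("P2", "slope_p2"), ("N1/P2", "slope_n1p2"))
            if c in strat.columns
        }
    tables = {}
    comparisons = []

    for split_name, flag, labels in (
        ("response", strat["responder"].to_numpy(), ("nonresponder", "responder")),
        ("ldaep_group", (strat["ldaep_group"] == "high").to_numpy(), ("low", "high")),
    ):
        ga, gb = strat[~flag], strat[flag]
        rows = []

        def add_numeric(name, col):
            a, b = ga[col].to_numpy(float), gb[col].to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                rows.append((name, "n/a", "n/a", "n/a", "n/a"))
                return
            cmp, ptxt = _compare_row(a, b)
            rows.append((
                name, _mean_sd_row(a), _mean_sd_row(b),
                f"{cmp.value:.3f} ({cmp.kind})" if cmp else "n/a", ptxt,
            ))
            if cmp:
                comparisons.append((split_name, name, cmp))

        def add_counts(name, series_a, series_b, level):
            ca = (int((series_a == level).sum()), int((series_a != level).sum()))
            cb = (int((series_b == level).sum()), int((series_b != level).sum()))
            tbl = np.array([ca, cb])
            try:
                cmp = chi_square_2x2(tbl)
                stat_txt, ptxt = f"{cmp.value:.3f} (chi2)", f"{cmp.p:.3f}"
                comparisons.append((split_name, name, cmp))
            except ValueError:
                stat_txt, ptxt = "n/a", "n/a"
            rows.append((name, f"{ca[0]}/{ca[1]}", f"{cb[0]}/{cb[1]}",
                         stat_txt, ptxt))

        add_numeric("Age (years)", "age")
        add_counts("Sex (male/female)", ga["sex"], gb["sex"], "M")
        add_counts("First-/Recurrent-episode", ga["episode"], gb["episode"], "first")
        add_counts("Nonsmoker/smoker", 1 - ga["smoker"], 1 - gb["smoker"], 1)
        for label, col in slope_columns.items():
            add_numeric(f"Pretreatment {label} LDAEP (µV/dB)", col)
        add_numeric("Pretreatment BDI score", "bdi_pre")
        add_numeric("Post-treatment BDI score", "bdi_post")
        add_numeric("BDI change (%)", "bdi_change_pct")
        if split_name == "ldaep_group":
            add_counts("Responder/nonresponder", ga["responder"], gb["responder"], True)
            rows.append((
                "Responder rate (%)",
                f"{100.0 * ga['responder'].mean():.1f}",
                f"{100.0 * gb['responder'].mean():.1f}",
                "", "",
            ))
        tables[split_name] = pd.DataFrame(
            rows, columns=["variable", labels[0], labels[1], "statistic", "p"]
        )

    tables["comparisons"] = pd.DataFrame(
        [
            {
                "split": s, "variable": v, "kind": c.kind, "value": c.value,
                "df": c.df, "p": c.p,
                "groups": "; ".join(
                    f"n={g.n}, mean={g.mean:.3f}, sd={g.sd:.3f}" for g in c.groups
                ),
            }
            for s, v, c in comparisons
        ]
    )
    tables["n_tests"] = len(comparisons)
    return tables
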