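"""Group-comparison statistics: ANCOVA with partial eta squared, Bonferroni
post hoc contrasts of covariate-adjusted means, demographics tests (one-way
ANOVA, chi-square) and two-rater ICC.

The ANCOVA fits y ~ group + covariates by OLS (group dummy-coded against the
first group in canonical order, sex coded female=1/male=0 upstream) and tests
the group effect with a Wald partial F on the dummy coefficients — identical
to a Type III factor test, which for a single factor plus covariates also
coincides with Type II. Effect size is partial eta squared,
eta_p^2 = F*df1 / (F*df1 + df2). Post hoc comparisons contrast the
covariate-adjusted (estimated marginal) means using the pooled model error
variance, Bonferroni-adjusted (p_adj = min(1, m * p_raw), m = 3 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AncovaFit",
    "AncovaResult",
    "PosthocResult",
    "IccResult",
    "fit_ancova",
    "ancova_group_test",
    "partial_eta_squared",
    "bonferroni_adjust",
    "bonferroni_posthoc",
    "assemble_pattern",
    "one_way_anova",
    "chi_square_test",
    "icc_two_rater",
    "build_results_table",
    "demographics_table",
]


@dataclass
class PosthocResult:
    """Bonferroni-adjusted pairwise comparisons and the table-style pattern."""

    pairwise_p_raw: dict[tuple[str, str], float]
    pairwise_p_adj: dict[tuple[str, str], float]
    pattern: str


@dataclass
class AncovaFit:
    """A fitted ANCOVA: statsmodels results plus design metadata."""

    results: object
    groups: list[str]
    n_covariates: int
    adjusted_means: dict[str, float]
    param_index: dict[str, int]  # group name -> dummy column (ref group absent)


@dataclass
class AncovaResult:
    roi: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    adjusted_means: dict[str, float]
    posthoc: PosthocResult | None = None


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    flagged: bool = False


def bonferroni_adjust(p_raw: float, m: int = 3) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, m * p_raw)


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be >= 0 and dfs positive")
    return F * df1 / (F * df1 + df2)


def _as_covariate_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=np.float64), list(covariates.columns)
    arr = np.asarray(covariates, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{i}" for i in range(arr.shape[1])]


def fit_ancova(y, group, covariates=None, group_order=None) -> AncovaFit:
    """OLS fit of y ~ group + covariates with treatment-coded group dummies."""
    y = np.asarray(y, dtype=np.float64)
    group = np.asarray(group)
    levels = list(group_order) if group_order is not None else sorted(pd.unique(group))
    if set(pd.unique(group)) - set(levels):
        raise ValueError("group contains labels outside group_order")
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups")
    cov, cov_names = _as_covariate_matrix(covariates)
    n = len(y)
    n_cov = cov.shape[1] if cov.size else 0
    if n <= k + n_cov + 1:
        raise ValueError("too few observations for the requested design")

    cols = [np.ones(n)]
    names = ["intercept"]
    param_index: dict[str, int] = {}
    for g in levels[1:]:
        param_index[g] = len(cols)
        cols.append((group == g).astype(np.float64))
        names.append(f"group[{g}]")
    for j in range(n_cov):
        cols.append(cov[:, j])
        names.append(cov_names[j])
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad, r = [], 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()

    cov_means = cov.mean(axis=0) if n_cov else np.empty(0)
    base = res.params[0] + float(cov_means @ res.params[k:]) if n_cov else res.params[0]
    adj = {levels[0]: float(base)}
    for g in levels[1:]:
        adj[g] = float(base + res.params[param_index[g]])
    return AncovaFit(
        results=res, groups=levels, n_covariates=n_cov,
        adjusted_means=adj, param_index=param_index,
    )


def _omnibus(fit: AncovaFit) -> tuple[float, int, int, float]:
    res = fit.results
    p_tot = len(res.params)
    R = np.zeros((len(fit.groups) - 1, p_tot))
    for row, g in enumerate(fit.groups[1:]):
        R[row, fit.param_index[g]] = 1.0
    ft = res.f_test(R)
    return float(ft.fvalue), len(fit.groups) - 1, int(res.df_resid), float(ft.pvalue)


def assemble_pattern(
    labels: list[str],
    means: dict[str, float],
    sig_pairs: set[frozenset],
    omnibus_significant: bool,
) -> str:
    """Table-style post hoc pattern string.

    '>' or '<' joins significantly different groups, ',' joins groups whose
    pairwise test is non-significant; empty when the omnibus test (or every
    pair) is non-significant. Letters keep their canonical order: the string
    is rendered so the first canonical label leads, flipping to '<' when that
    label sits in the lowest block (e.g. 'a < b, c').
    """
    if not omnibus_significant or not sig_pairs:
        return ""
    by_mean = sorted(labels, key=lambda g: means[g], reverse=True)
    g1, g2, g3 = (by_mean + [None, None])[:3] if len(by_mean) == 3 else (None, None, None)
    if g1 is None:  # general k: list significant pairs
        parts = []
        for a, b in combinations(labels, 2):
            if frozenset((a, b)) in sig_pairs:
                hi, lo = (a, b) if means[a] >= means[b] else (b, a)
                parts.append(f"{hi} > {lo}")
        return "; ".join(parts)

    def sig(a, b):
        return frozenset((a, b)) in sig_pairs

    if sig(g1, g2) and sig(g2, g3) and sig(g1, g3):
        blocks = [[g1], [g2], [g3]]
    elif sig(g1, g3) and sig(g2, g3) and not sig(g1, g2):
        blocks = [[g1, g2], [g3]]
    elif sig(g1, g2) and sig(g1, g3) and not sig(g2, g3):
        blocks = [[g1], [g2, g3]]
    elif sig(g1, g3) and not sig(g1, g2) and not sig(g2, g3):
        blocks = [[g1], [g3]]
    elif sig(g1, g2) and not sig(g1, g3):
        blocks = [[g1], [g2]]
    elif sig(g2, g3) and not sig(g1, g3):
        blocks = [[g2], [g3]]
    else:
        blocks = []
    if not blocks:
        return ""
    first = min(labels)  # canonical first letter, e.g. group 'a'
    if any(first in b for b in blocks) and first in blocks[-1]:
        blocks = blocks[::-1]
        sep = " < "
    else:
        sep = " > "
    return sep.join(", ".join(sorted(b)) for b in blocks)


def bonferroni_posthoc(fit: AncovaFit, alpha: float = 0.05, m: int = 3) -> PosthocResult:
    """Pairwise contrasts of adjusted means with Bonferroni adjustment.

    Each pair's contrast uses the fitted model's pooled error variance
    (EMMEANS-style t test on the dummy-coefficient difference).
    """
    res = fit.results
    p_tot = len(res.params)
    raw: dict[tuple[str, str], float] = {}
    for a, b in combinations(fit.groups, 2):
        c = np.zeros(p_tot)
        if a in fit.param_index:
            c[fit.param_index[a]] = 1.0
        if b in fit.param_index:
            c[fit.param_index[b]] -= 1.0
        tt = res.t_test(c)
        raw[(a, b)] = float(tt.pvalue)
    adj = {pair: bonferroni_adjust(p, m) for pair, p in raw.items()}
    _, _, _, omni_p = _omnibus(fit)
    sig_pairs = {frozenset(pair) for pair, p in adj.items() if p < alpha}
    pattern = assemble_pattern(fit.groups, fit.adjusted_means, sig_pairs, omni_p < alpha)
    return PosthocResult(pairwise_p_raw=raw, pairwise_p_adj=adj, pattern=pattern)


def ancova_group_test(
    y, group, covariates=None, group_order=None,
    roi: str = "", alpha: float = 0.05, posthoc_m: int = 3,
) -> AncovaResult:
    """Omnibus group ANCOVA plus Bonferroni post hoc on adjusted means."""
    fit = fit_ancova(y, group, covariates=covariates, group_order=group_order)
    F, df1, df2, p = _omnibus(fit)
    return AncovaResult(
        roi=roi,
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        partial_eta_sq=partial_eta_squared(F, df1, df2),
        adjusted_means=fit.adjusted_means,
        posthoc=bonferroni_posthoc(fit, alpha=alpha, m=posthoc_m),
    )


def one_way_anova(y, group) -> tuple[float, float]:
    """Classical between/within one-way ANOVA F and p."""
    y = np.asarray(y, dtype=np.float64)
    group = np.asarray(group)
    samples = [y[group == g] for g in pd.unique(group)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >=2 groups with >=2 observations each")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    F, p = sps.f_oneway(*samples)
    return float(F), float(p)


def chi_square_test(contingency) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a counts table."""
    table = np.asarray(contingency, dtype=np.float64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def icc_two_rater(ratings_a, ratings_b) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed via pingouin's intraclass_corr (ICC2 row) with its F-based 95%
    CI. Zero between-subject variance is flagged as undefined.
    """
    import pingouin as pg

    a = np.asarray(ratings_a, dtype=np.float64)
    b = np.asarray(ratings_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D vectors")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 rated subjects")
    subject_means = (a + b) / 2.0
    if np.ptp(subject_means) == 0:
        return IccResult(icc=np.nan, ci_low=np.nan, ci_high=np.nan, flagged=True)
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "score": np.concatenate([a, b]),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):  # degenerate MSE=0 case
        tab = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
    tab = tab.set_index("Type")
    # two-way random, absolute agreement, single measure: labelled ICC2 or ICC(A,1)
    key = "ICC2" if "ICC2" in tab.index else "ICC(A,1)"
    row = tab.loc[key]
    ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
    lo, hi = row[ci_col]
    icc = float(row["ICC"])
    if icc == 1.0 and not (np.isfinite(lo) and np.isfinite(hi)):
        lo = hi = 1.0  # degenerate interval under perfect agreement (MSE = 0)
    return IccResult(icc=icc, ci_low=float(lo), ci_high=float(hi))


# --- table assembly ----------------------------------------------------------


def _mean_sd_str(mean: float, sd: float) -> str:
    """Table-style 'mean (SD)' with 1 dp for magnitudes >= 10, else 3 sig."""
    dp = 1 if abs(mean) >= 10 else 3
    return f"{mean:.{dp}f} ({sd:.{dp}f})"


def _sex_code(sex: pd.Series) -> np.ndarray:
    return (sex.astype(str).str.upper().str.startswith("F")).to_numpy(dtype=np.float64)


def build_results_table(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    analysis_kind: str,
    feature_col: str = "contrast",
    group_order=None,
    alpha: float = 0.05,
    posthoc_m: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI (and lobe-row) ANCOVA table in the published layout.

    analysis_kind='volume': y = volume_cc, covariates age, sex, education, TBV.
    analysis_kind='texture': y = feature_col, covariates age, sex, education
    and the row's regional volume. Returns (wide table, long stats table).
    """
    from .phantom import GROUP_ORDER

    if analysis_kind not in ("volume", "texture"):
        raise ValueError("analysis_kind must be 'volume' or 'texture'")
    if group_order is None:
        group_order = [g for g in GROUP_ORDER if g in set(subjects["group"])]
    need = {"age", "sex", "education", "subject_id", "group"}
    missing = need - set(subjects.columns)
    if missing:
        raise ValueError(f"subjects table lacks columns: {sorted(missing)}")
    subj_cols = subjects[["subject_id", "group", "age", "sex", "education"]]
    df = features.merge(subj_cols, on="subject_id", how="inner", validate="many_to_one")
    orphans = set(features["subject_id"]) - set(subjects["subject_id"])
    if orphans:
        raise ValueError(f"feature rows with no subject record: {sorted(orphans)}")

    letters = {g: chr(ord("a") + i) for i, g in enumerate(group_order)}
    rows, long_rows = [], []
    roi_order = features["roi"].drop_duplicates().tolist()
    for roi_name in roi_order:
        sub = df[df["roi"] == roi_name]
        lobe = sub["lobe"].iloc[0]
        lobe_row = bool(sub["lobe_row"].iloc[0]) if "lobe_row" in sub else False
        if lobe in ("csf", "other"):
            continue  # stats tables cover grey-matter rows only
        y = sub["volume_cc"] if analysis_kind == "volume" else sub[feature_col]
        y = y.to_numpy(dtype=np.float64)
        if not np.isfinite(y).all():
            continue  # flagged feature records never enter the model silently
        cov = pd.DataFrame(
            {
                "age": sub["age"].to_numpy(dtype=np.float64),
                "sex": _sex_code(sub["sex"]),
                "education": sub["education"].to_numpy(dtype=np.float64),
            }
        )
        if analysis_kind == "volume":
            if "tbv_cc" not in sub:
                raise ValueError("features table lacks tbv_cc needed as covariate")
            cov["tbv"] = sub["tbv_cc"].to_numpy(dtype=np.float64)
        else:
            cov["regional_volume"] = sub["volume_cc"].to_numpy(dtype=np.float64)
        grp = sub["group"].map(letters).to_numpy()
        result = ancova_group_test(
            y, grp, covariates=cov,
            group_order=[letters[g] for g in group_order],
            roi=roi_name, alpha=alpha, posthoc_m=posthoc_m,
        )
        row = {"roi": roi_name, "lobe": lobe, "lobe_row": lobe_row}
        for g in group_order:
            vals = y[(sub["group"] == g).to_numpy()]
            row[f"mean_{letters[g]}"] = vals.mean()
            row[f"sd_{letters[g]}"] = vals.std(ddof=1)
            row[f"mean_sd_{letters[g]}"] = _mean_sd_str(vals.mean(), vals.std(ddof=1))
        row.update(
            F=result.F, df1=result.df1, df2=result.df2, p=result.p,
            partial_eta_sq=result.partial_eta_sq, pattern=result.posthoc.pattern,
        )
        rows.append(row)
        for (ga, gb), praw in result.posthoc.pairwise_p_raw.items():
            long_rows.append(
                {
                    "roi": roi_name,
                    "kind": analysis_kind,
                    "pair": f"{ga}-{gb}",
                    "p_raw": praw,
                    "p_adj": result.posthoc.pairwise_p_adj[(ga, gb)],
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(long_rows)


def demographics_table(subjects: pd.DataFrame, group_order=None) -> pd.DataFrame:
    """Per-group demographic summaries with ANOVA / chi-square p values."""
    from .phantom import GROUP_ORDER

    if group_order is None:
        group_order = [g for g in GROUP_ORDER if g in set(subjects["group"])]
    rows = []
    for col, label in (("age", "Age, years"), ("education", "Education, years"),
                       ("mmse", "MMSE, points"), ("tbv_cc", "Total brain volume, cc")):
        if col not in subjects or subjects[col].isna().all():
            continue
        y = subjects[col].to_numpy(dtype=np.float64)
        F, p = one_way_anova(y, subjects["group"].to_numpy())
        row = {"variable": label, "statistic": F, "p": p, "test": "one-way ANOVA"}
        for g in group_order:
            v = subjects.loc[subjects["group"] == g, col]
            row[g] = f"{v.mean():.1f} ({v.std(ddof=1):.1f})"
        rows.append(row)
    counts = []
    for g in group_order:
        s = subjects.loc[subjects["group"] == g, "sex"]
        counts.append([int((_sex_code(s) == 1).sum()), int((_sex_code(s) == 0).sum())])
    table = np.array(counts).T  # 2 x k: female / male
    chi2, p = chi_square_test(table)
    row = {"variable": "Sex, female, %", "statistic": chi2, "p": p, "test": "chi-square"}
    for g, (f, m) in zip(group_order, counts):
        row[g] = f"{100 * f / (f + m):.1f}"
    rows.append(row)
    return pd.DataFrame(rows)
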