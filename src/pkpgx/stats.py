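"""Association statistics: normality gate, univariate screen, multivariate
linear regression, paired pharmacodynamic tests and incidence tests.

The cascade mirrors a classical exploratory candidate-gene workflow.
Continuous outcomes pass a Shapiro-Wilk normality gate (raw scale, then
natural-log scale); the gate's verdict routes each outcome x predictor
comparison to a pooled t-test / one-way ANOVA with Bonferroni post hoc
(parametric) or Mann-Whitney / Kruskal-Wallis (nonparametric). Predictors
univariately significant at alpha enter an ordinary-least-squares
multivariate model on the gate-chosen scale, reported as the
non-standardized beta, the multivariate p-value and the model R^2.
Incidence comparisons use Pearson's chi-square, switching to Fisher's
exact test when any expected cell count drops below 5.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GateResult",
    "UnivariateResult",
    "MultivariateResult",
    "ContingencyResult",
    "PairedResult",
    "normality_gate",
    "univariate",
    "multivariate",
    "paired_change",
    "incidence_test",
    "association_cascade",
    "describe",
]

ALPHA = 0.05


@dataclass
class GateResult:
    route: str  # "normal-raw" | "normal-log" | "nonparametric"
    p_raw: float
    p_log: float | None = None

    @property
    def parametric(self) -> bool:
        return self.route in ("normal-raw", "normal-log")

    @property
    def log_scale(self) -> bool:
        return self.route == "normal-log"


@dataclass
class UnivariateResult:
    outcome: str
    predictor: str
    test: str
    p_uv: float
    descriptives: pd.DataFrame  # level, n, mean, sd (original scale)
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class MultivariateResult:
    outcome: str
    predictors: list[str]
    terms: pd.DataFrame  # term, beta, p_mv
    r_squared: float
    log_scale: bool
    dropped: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.predictors) == 0


@dataclass
class PairedResult:
    mean_change: float
    sd_change: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class ContingencyResult:
    table: np.ndarray
    test: str  # "chi2" | "fisher"
    p: float


def describe(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Per-level 'mean (standard deviation)' descriptives on the original scale."""
    df = pd.DataFrame({"value": values, "group": groups})
    out = (
        df.groupby("group", sort=True)["value"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
        .rename(columns={"group": "level"})
    )
    out["formatted"] = [
        f"{m:.2f} ({s:.2f})" if np.isfinite(s) else f"{m:.2f} (—)"
        for m, s in zip(out["mean"], out["sd"])
    ]
    return out


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def normality_gate(values: Sequence[float], alpha: float = ALPHA) -> GateResult:
    """Shapiro-Wilk on the raw values; on rejection, retry on ln(values).

    Values containing zeros or negatives skip the log retry and go straight
    to the nonparametric route.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("normality gate needs n >= 3")
    if np.ptp(x) == 0.0:
        return GateResult("nonparametric", p_raw=0.0)
    p_raw = float(sps.shapiro(x).pvalue)
    if p_raw >= alpha:
        return GateResult("normal-raw", p_raw=p_raw)
    if np.any(x <= 0):
        return GateResult("nonparametric", p_raw=p_raw)
    p_log = float(sps.shapiro(np.log(x)).pvalue)
    if p_log >= alpha:
        return GateResult("normal-log", p_raw=p_raw, p_log=p_log)
    return GateResult("nonparametric", p_raw=p_raw, p_log=p_log)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def _transformed(x: np.ndarray, gate: GateResult) -> np.ndarray:
    return np.log(x) if gate.log_scale else x


def univariate(
    values: Sequence[float],
    groups: Sequence,
    gate: GateResult,
    outcome: str = "outcome",
    predictor: str = "predictor",
    welch: bool = False,
) -> UnivariateResult:
    """Two-group or k-group comparison on the gate-chosen route.

    Parametric: pooled t-test (two groups) or one-way ANOVA with
    Bonferroni-adjusted pairwise t-tests (k > 2). Nonparametric:
    Mann-Whitney or Kruskal-Wallis with Bonferroni-adjusted pairwise
    Mann-Whitney post hoc. Descriptives are always reported on the
    original scale. A parametric request with any group of n < 2 falls
    back to the nonparametric route with a warning.
    """
    x = np.asarray(values, float)
    g = np.asarray([str(v) for v in groups])
    ok = np.isfinite(x)
    x, g = x[ok], g[ok]
    levels = sorted(set(g))
    if len(levels) < 2:
        raise ValueError("univariate comparison needs >= 2 non-empty groups")
    desc = describe(x, g)
    warnings: list[str] = []
    parametric = gate.parametric
    if parametric and min((g == lv).sum() for lv in levels) < 2:
        parametric = False
        warnings.append("group with n < 2: fell back to nonparametric route")
    samples = [x[g == lv] for lv in levels]
    t_samples = [_transformed(s, gate) for s in samples] if parametric else samples

    pairwise: dict[tuple[str, str], float] = {}
    if np.ptp(x) == 0.0:  # all observations identical across groups
        test, p = ("degenerate", 1.0)
    elif len(levels) == 2:
        if parametric:
            test = "welch-t" if welch else "t-test"
            p = float(sps.ttest_ind(*t_samples, equal_var=not welch).pvalue)
        else:
            test = "mann-whitney"
            p = float(sps.mannwhitneyu(*samples, alternative="two-sided").pvalue)
    else:
        n_pairs = len(levels) * (len(levels) - 1) // 2
        if parametric:
            test = "anova"
            p = float(sps.f_oneway(*t_samples).pvalue)
            for (i, a), (j, b) in itertools.combinations(enumerate(levels), 2):
                raw = float(sps.ttest_ind(t_samples[i], t_samples[j], equal_var=True).pvalue)
                pairwise[(a, b)] = min(1.0, raw * n_pairs)
        else:
            test = "kruskal-wallis"
            p = float(sps.kruskal(*samples).pvalue)
            for (i, a), (j, b) in itertools.combinations(enumerate(levels), 2):
                if np.ptp(np.concatenate([samples[i], samples[j]])) == 0.0:
                    raw = 1.0
                else:
                    raw = float(
                        sps.mannwhitneyu(samples[i], samples[j], alternative="two-sided").pvalue
                    )
                pairwise[(a, b)] = min(1.0, raw * n_pairs)
    if math.isnan(p):
        p, test = 1.0, test + " (degenerate)"
    return UnivariateResult(outcome, predictor, test, p, desc, pairwise, warnings)


# ---------------------------------------------------------------------------
# Multivariate regression
# ---------------------------------------------------------------------------

def _design_matrix(
    df: pd.DataFrame, predictors: Sequence[str], references: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    cols = {}
    term_map: dict[str, list[str]] = {}
    for pred in predictors:
        series = df[pred]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            cols[pred] = series.astype(float)
            term_map[pred] = [pred]
            continue
        series = series.astype(str)
        levels = sorted(series.unique())
        ref = references.get(pred, levels[0])
        term_map[pred] = []
        for lv in levels:
            if lv == ref:
                continue
            name = f"{pred}[{lv}]"
            cols[name] = (series == lv).astype(float)
            term_map[pred].append(name)
    return pd.DataFrame(cols, index=df.index), term_map


def multivariate(
    df: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    gate: GateResult,
    references: Mapping[str, str] | None = None,
) -> MultivariateResult:
    """OLS of the (possibly log-transformed) outcome on the selected predictors.

    Categorical predictors are dummy-coded against their reference level.
    Perfectly collinear columns are dropped (with a warning entry) and the
    model refitted. Returns per-term beta and p_mv plus model R^2.
    """
    if not predictors:
        return MultivariateResult(outcome, [], pd.DataFrame(columns=["term", "beta", "p_mv"]), math.nan, gate.log_scale)
    data = df.dropna(subset=[outcome, *predictors])
    y = data[outcome].astype(float).to_numpy()
    if gate.log_scale:
        if np.any(y <= 0):
            raise ValueError("log transform undefined for non-positive outcome")
        y = np.log(y)
    X, _ = _design_matrix(data, predictors, references or {})
    dropped: list[str] = []
    # drop constant columns, then iteratively remove collinear ones
    for col in list(X.columns):
        if X[col].nunique() <= 1:
            X = X.drop(columns=col)
            dropped.append(col)
    while len(X.columns) > 0:
        mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
        if np.linalg.matrix_rank(mat) == mat.shape[1]:
            break
        victim = str(X.columns[-1])
        X = X.drop(columns=victim)
        dropped.append(victim)
    if len(X.columns) == 0:
        return MultivariateResult(outcome, [], pd.DataFrame(columns=["term", "beta", "p_mv"]), math.nan, gate.log_scale, dropped)
    if len(data) <= len(X.columns) + 2:
        raise ValueError("too few observations for the multivariate model")
    model = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
    terms = pd.DataFrame(
        {
            "term": list(X.columns),
            "beta": model.params[1:],
            "p_mv": model.pvalues[1:],
        }
    )
    return MultivariateResult(
        outcome, list(predictors), terms, float(model.rsquared), gate.log_scale, dropped
    )


# ---------------------------------------------------------------------------
# Paired pharmacodynamic tests
# ---------------------------------------------------------------------------

def paired_change(baseline: Sequence[float], followup: Sequence[float]) -> PairedResult:
    """Paired t-test on followup - baseline, reported as mean (SD) change.

    A zero-variance nonzero change is degenerate (p below machine floor)
    and flagged rather than raised; a zero-variance zero change gives p=1.
    """
    b = np.asarray(baseline, float)
    f = np.asarray(followup, float)
    if b.shape != f.shape:
        raise ValueError("baseline and followup must be equal length")
    ok = np.isfinite(b) & np.isfinite(f)
    diff = f[ok] - b[ok]
    n = len(diff)
    if n < 3:
        raise ValueError("paired test needs n >= 3")
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedResult(0.0, 0.0, 1.0, n)
        return PairedResult(mean, 0.0, 5e-324, n, degenerate=True)
    p = float(sps.ttest_rel(f[ok], b[ok]).pvalue)
    return PairedResult(mean, sd, p, n)


# ---------------------------------------------------------------------------
# Incidence tests
# ---------------------------------------------------------------------------

def expected_counts(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def incidence_test(table) -> ContingencyResult:
    """Chi-square or Fisher exact test of a 2 x k event-count table.

    Fisher's exact test (two-sided, the sum of hypergeometric
    probabilities no larger than the observed table's) is used for 2 x 2
    tables with any expected count below 5; Pearson's chi-square
    (uncorrected) otherwise. Wider tables always use chi-square; merge
    levels to 2 x 2 first when their expected counts are small.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("incidence_test expects a 2 x k table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("empty margin in contingency table")
    small = bool(np.any(expected_counts(t) < 5))
    if t.shape == (2, 2) and small:
        p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
        return ContingencyResult(t, "fisher", p)
    chi2 = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(t, "chi2", float(chi2.pvalue))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2 x 2 table, regardless of cell sizes."""
    return float(sps.fisher_exact(np.asarray(table), alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Cascade orchestration
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    outcome: str
    gate: GateResult
    univariate: list[UnivariateResult]
    multivariate: MultivariateResult

    def significant_predictors(self, alpha: float = ALPHA) -> list[str]:
        return [u.predictor for u in self.univariate if u.p_uv < alpha]


def association_cascade(
    df: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    alpha: float = ALPHA,
    references: Mapping[str, str] | None = None,
) -> CascadeResult:
    """Run gate -> univariate screen -> multivariate model for one outcome.

    Predictor columns with fewer than two observed levels are skipped. The
    multivariate model includes exactly the univariately significant
    predictors (p_uv < alpha); with none, no model is fitted.
    """
    data = df.dropna(subset=[outcome])
    gate = normality_gate(data[outcome])
    uni: list[UnivariateResult] = []
    for pred in predictors:
        sub = data.dropna(subset=[pred])
        if sub[pred].astype(str).nunique() < 2:
            continue
        uni.append(univariate(sub[outcome], sub[pred], gate, outcome, pred))
    selected = [u.predictor for u in uni if u.p_uv < alpha]
    if selected:
        mv = multivariate(data, outcome, selected, gate, references)
    else:
        mv = MultivariateResult(outcome, [], pd.DataFrame(columns=["term", "beta", "p_mv"]), math.nan, gate.log_scale)
    return CascadeResult(outcome, gate, uni, mv)
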