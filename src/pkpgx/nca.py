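"""Non-compartmental pharmacokinetic analysis.

Estimates the standard single-dose exposure metrics from a plasma
concentration-time profile: Cmax and tmax read directly off the observed
curve, AUC to the last quantifiable sample by the linear trapezoidal rule,
the terminal elimination rate constant Ke (lambda-z) by log-linear
regression over an automatically selected terminal tail, the half-life
t1/2 = ln2/Ke, and the extrapolated AUC to infinity AUCt + Clast/Ke.
Dose- and dose/weight-normalised variants (X/D, X/DW with DW = dose/weight)
are attached for cross-dose, cross-subject comparison.

Profiles come from crossover bioequivalence periods; per-subject
aggregation across test (T) and reference (R) formulations supports two
policies: the arithmetic mean of all periods (``mean_TR``) or the
reference periods only (``reference_only``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConcentrationProfile",
    "NCAResult",
    "NonEvaluableProfile",
    "preprocess_bloq",
    "cmax_tmax",
    "auc_trapezoidal",
    "terminal_slope",
    "extrapolate_auc",
    "normalize",
    "run_nca",
    "aggregate_formulations",
]

#: AUCt integration cut-off (h); samples after this time do not enter AUCt.
DEFAULT_AUC_END = 48.0

#: Extrapolated fraction above which AUCinf is flagged as poorly determined.
EXTRAPOLATION_WARN_PCT = 20.0


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject x drug x period concentration-time series.

    ``concentrations`` holds quantified values in ng/mL; samples below the
    lower limit of quantification (LLOQ) are flagged in ``bloq`` and their
    concentration entry is ignored. Times are hours post dose; the first
    sample is the pre-dose draw at t=0.
    """

    subject_id: str
    drug: str
    period: int
    formulation: str  # "T" or "R"
    dose_mg: float
    weight_kg: float
    times: np.ndarray
    concentrations: np.ndarray
    bloq: np.ndarray
    lloq: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        b = np.asarray(self.bloq, dtype=bool)
        if t.ndim != 1 or t.shape != c.shape or t.shape != b.shape:
            raise ValueError("times, concentrations and bloq must be 1-D and equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            # canonical order: strictly increasing time
            order = np.argsort(t, kind="stable")
            t, c, b = t[order], c[order], b[order]
            if np.any(np.diff(t) <= 0):
                raise ValueError("duplicate sampling times in profile")
        if len(t) and t[0] < 0:
            raise ValueError("negative sampling time")
        if self.dose_mg <= 0 or self.weight_kg <= 0:
            raise ValueError("dose and weight must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "bloq", b)


class NonEvaluableProfile(Exception):
    """Raised when a profile cannot yield NCA parameters; carries the reason."""


@dataclass
class NCAResult:
    subject_id: str
    drug: str
    period: int | None
    formulation: str | None
    dose_mg: float
    weight_kg: float
    cmax: float
    tmax: float
    auc_t: float
    auc_inf: float
    ke: float
    t_half: float
    n_lambda_points: int
    adj_r2_lambda: float
    pct_extrapolated: float
    extrapolation_flag: bool = False
    # normalised variants, filled by normalize()
    auc_inf_d: float = math.nan
    cmax_d: float = math.nan
    auc_inf_dw: float = math.nan
    cmax_dw: float = math.nan


# ---------------------------------------------------------------------------
# BLOQ handling
# ---------------------------------------------------------------------------

def preprocess_bloq(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Apply the below-quantification (BLOQ) cleaning rules.

    Leading BLOQ samples (everything before the first quantifiable sample,
    including the mandatory pre-dose draw) are set to concentration 0 and
    retained, so the absorption-phase trapezoids start from zero. BLOQ
    samples embedded between quantifiable ones are excluded. Trailing BLOQ
    samples are truncated: the series ends at the last quantifiable sample.

    A profile with no quantifiable sample is returned with all samples
    removed; downstream :func:`run_nca` reports it non-evaluable.
    """
    t, c, b = profile.times, profile.concentrations, profile.bloq
    quant = ~b
    if not quant.any():
        return replace(profile, times=t[:0], concentrations=c[:0], bloq=b[:0])
    first = int(np.argmax(quant))
    last = len(t) - 1 - int(np.argmax(quant[::-1]))
    keep = np.zeros(len(t), dtype=bool)
    keep[: first + 1] = True          # leading BLOQ -> zeros
    mid = np.arange(first, last + 1)
    keep[mid] = quant[mid]            # embedded BLOQ dropped
    new_c = np.where(b, 0.0, c)[keep]
    return replace(profile, times=t[keep], concentrations=new_c, bloq=np.zeros(keep.sum(), bool))


# ---------------------------------------------------------------------------
# Primary parameters
# ---------------------------------------------------------------------------

def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximum observed concentration and its time; ties go to the earliest time."""
    c = profile.concentrations[~profile.bloq]
    t = profile.times[~profile.bloq]
    if len(c) == 0 or np.max(c) <= 0:
        raise NonEvaluableProfile("no quantifiable concentration")
    i = int(np.argmax(c))  # argmax returns the first maximum -> earliest time
    return float(c[i]), float(t[i])


def auc_trapezoidal(profile: ConcentrationProfile, end_time: float = DEFAULT_AUC_END) -> float:
    """Linear trapezoidal AUC up to the last retained sample at or before ``end_time``."""
    mask = profile.times <= end_time + 1e-12
    t = profile.times[mask]
    c = profile.concentrations[mask]
    if len(t) < 2:
        raise NonEvaluableProfile("fewer than 2 samples for AUC")
    return float(np.trapezoid(c, t))


def _ols_loglinear(t: np.ndarray, logc: np.ndarray) -> tuple[float, float]:
    """Slope and adjusted R^2 of the OLS line logc ~ t."""
    n = len(t)
    tm, lm = t.mean(), logc.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (logc - lm)))
    syy = float(np.sum((logc - lm) ** 2))
    slope = sxy / sxx
    if syy == 0.0:  # perfectly flat log-concentrations
        return slope, 1.0
    r2 = (sxy * sxy) / (sxx * syy)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, adj


def terminal_slope(
    profile: ConcentrationProfile,
    method: str = "best_adj_r2",
    min_points: int = 3,
) -> tuple[float, int, float]:
    """Terminal elimination rate constant Ke (lambda-z).

    Fits ordinary least squares to ln(C) vs t over a terminal tail of
    quantifiable points strictly after tmax. ``best_adj_r2`` (default)
    scans all tails of ``min_points`` or more samples and keeps the one
    with the highest adjusted R^2 (ties to the longer tail);
    ``fixed_last_3`` uses the final three points. Ke is the negated slope
    and must be positive (declining terminal phase).

    Returns (Ke, number of points used, adjusted R^2).
    """
    _, tmax = cmax_tmax(profile)
    mask = (~profile.bloq) & (profile.times > tmax) & (profile.concentrations > 0)
    t = profile.times[mask]
    c = profile.concentrations[mask]
    if len(t) < min_points:
        raise NonEvaluableProfile(f"fewer than {min_points} post-tmax points for lambda-z")
    logc = np.log(c)
    if method == "fixed_last_3":
        candidates = [len(t) - 3]
    elif method == "best_adj_r2":
        candidates = range(0, len(t) - min_points + 1)  # longest first: wins ties
    else:
        raise ValueError(f"unknown lambda-z method: {method!r}")
    best: tuple[float, int, float] | None = None
    for start in candidates:
        slope, adj = _ols_loglinear(t[start:], logc[start:])
        if slope >= 0:
            continue
        if best is None or adj > best[2] + 1e-12:
            best = (-slope, len(t) - start, adj)
    if best is None:
        raise NonEvaluableProfile("no declining terminal phase (Ke <= 0)")
    return best


def extrapolate_auc(auc_t: float, c_last: float, ke: float) -> tuple[float, float, bool]:
    """AUC to infinity: AUCt + Clast/Ke.

    Returns (AUCinf, percent extrapolated, warning flag for >20% extrapolation).
    """
    if ke <= 0:
        raise NonEvaluableProfile("non-positive Ke")
    if c_last < 0:
        raise ValueError("negative last concentration")
    auc_inf = auc_t + c_last / ke
    pct = 100.0 * (auc_inf - auc_t) / auc_inf if auc_inf > 0 else 0.0
    return auc_inf, pct, pct > EXTRAPOLATION_WARN_PCT


def normalize(result: NCAResult, dose_mg: float | None = None, weight_kg: float | None = None) -> NCAResult:
    """Attach dose- and dose/weight-normalised exposure metrics.

    X/D = X / dose; X/DW = X / (dose/weight) = X * weight / dose, with dose
    in mg and weight in kg (units ng*h*kg/mL*mg for AUCinf/DW).
    """
    dose = result.dose_mg if dose_mg is None else dose_mg
    weight = result.weight_kg if weight_kg is None else weight_kg
    if dose <= 0 or weight <= 0:
        raise ValueError("dose and weight must be positive")
    result.auc_inf_d = result.auc_inf / dose
    result.cmax_d = result.cmax / dose
    result.auc_inf_dw = result.auc_inf * weight / dose
    result.cmax_dw = result.cmax * weight / dose
    return result


def run_nca(
    profile: ConcentrationProfile,
    auc_end: float = DEFAULT_AUC_END,
    lambda_method: str = "best_adj_r2",
) -> NCAResult:
    """Full NCA on one profile: BLOQ cleaning, Cmax/tmax, AUCt, Ke, AUCinf, t1/2."""
    clean = preprocess_bloq(profile)
    if len(clean.times) == 0:
        raise NonEvaluableProfile("all samples below the limit of quantification")
    cmax, tmax = cmax_tmax(clean)
    auc_t = auc_trapezoidal(clean, end_time=auc_end)
    ke, n_pts, adj_r2 = terminal_slope(clean, method=lambda_method)
    in_window = clean.times <= auc_end + 1e-12
    c_last = float(clean.concentrations[in_window][-1])
    auc_inf, pct, flag = extrapolate_auc(auc_t, c_last, ke)
    result = NCAResult(
        subject_id=profile.subject_id,
        drug=profile.drug,
        period=profile.period,
        formulation=profile.formulation,
        dose_mg=profile.dose_mg,
        weight_kg=profile.weight_kg,
        cmax=cmax,
        tmax=tmax,
        auc_t=auc_t,
        auc_inf=auc_inf,
        ke=ke,
        t_half=math.log(2) / ke,
        n_lambda_points=n_pts,
        adj_r2_lambda=adj_r2,
        pct_extrapolated=pct,
        extrapolation_flag=flag,
    )
    return normalize(result)


# ---------------------------------------------------------------------------
# Crossover aggregation
# ---------------------------------------------------------------------------

_AGG_FIELDS = (
    "cmax", "tmax", "auc_t", "auc_inf", "ke", "t_half",
    "pct_extrapolated", "auc_inf_d", "cmax_d", "auc_inf_dw", "cmax_dw",
)


def aggregate_formulations(results: Sequence[NCAResult], policy: str) -> NCAResult:
    """Collapse one subject's per-period results for one drug to a single row.

    ``mean_TR`` takes the arithmetic mean of every parameter across all T and
    R periods (drugs whose T formulation was bioequivalent to R);
    ``reference_only`` averages over R periods only (drug where it was not).
    """
    if not results:
        raise ValueError("no results to aggregate")
    subj = {r.subject_id for r in results}
    drugs = {r.drug for r in results}
    if len(subj) != 1 or len(drugs) != 1:
        raise ValueError("aggregate_formulations expects one subject and one drug")
    if policy == "mean_TR":
        pool = list(results)
    elif policy == "reference_only":
        pool = [r for r in results if r.formulation == "R"]
        if not pool:
            raise ValueError(f"no reference-formulation period for subject {subj.pop()}")
    else:
        raise ValueError(f"unknown aggregation policy: {policy!r}")
    out = NCAResult(
        subject_id=results[0].subject_id,
        drug=results[0].drug,
        period=None,
        formulation=None if policy == "mean_TR" else "R",
        dose_mg=float(np.mean([r.dose_mg for r in pool])),
        weight_kg=results[0].weight_kg,
        cmax=0.0, tmax=0.0, auc_t=0.0, auc_inf=0.0, ke=0.0, t_half=0.0,
        n_lambda_points=int(round(np.mean([r.n_lambda_points for r in pool]))),
        adj_r2_lambda=float(np.mean([r.adj_r2_lambda for r in pool])),
        pct_extrapolated=0.0,
        extrapolation_flag=any(r.extrapolation_flag for r in pool),
    )
    for name in _AGG_FIELDS:
        setattr(out, name, float(np.mean([getattr(r, name) for r in pool])))
    return out
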