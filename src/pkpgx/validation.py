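"""Simulation-based validation studies.

Self-contained checks of the pipeline against independent oracles and
known simulation truth: trapezoidal AUC versus the closed-form
one-compartment integral, the Fisher exact test versus brute-force
hypergeometric enumeration, covariate effect-sign recovery through the
full simulate -> NCA -> cascade chain, and type-I calibration of the
cascade under the null configuration. The acceptance script and the test
suite both drive these functions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import nca, stats, synth

__all__ = [
    "fisher_enumeration",
    "fisher_sweep",
    "trapezoid_vs_analytic",
    "simulate_nca_cohort",
    "effect_sign_recovery",
    "null_calibration",
]


# ---------------------------------------------------------------------------
# Exact-test oracle
# ---------------------------------------------------------------------------

def fisher_enumeration(table) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Sums, over all 2x2 tables with the observed margins, the
    point probabilities no larger than the observed table's (with a tiny
    relative tolerance against floating-point ties). Independent of any
    statistics library.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1.0 + 1e-9):
            total += px
    return min(total, 1.0)


def fisher_sweep(
    seed: int = 0, exhaustive_total: int = 25, n_random: int = 500, max_total: int = 200
) -> float:
    """Max |fisher_exact - enumeration| over many 2x2 tables.

    Exhausts every table with grand total up to ``exhaustive_total`` and
    adds ``n_random`` random tables with totals up to ``max_total``.
    """
    worst = 0.0
    for n in range(2, exhaustive_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    t = [[a, b], [c, d]]
                    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                        continue
                    worst = max(worst, abs(stats.fisher_exact_2x2(t) - fisher_enumeration(t)))
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        n = int(rng.integers(4, max_total + 1))
        cuts = np.sort(rng.integers(0, n + 1, size=3))
        a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
        d = n - a - b - c
        t = [[a, b], [c, d]]
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        worst = max(worst, abs(stats.fisher_exact_2x2(t) - fisher_enumeration(t)))
    return worst


# ---------------------------------------------------------------------------
# AUC oracle
# ---------------------------------------------------------------------------

def trapezoid_vs_analytic(n_points: int = 200, t_end: float = 72.0) -> float:
    """Relative error of the trapezoidal AUC against the analytic integral.

    Dense, noise-free one-compartment profiles for all three drugs; the
    analytic AUC over [0, t_end] is D/CL times the completed fraction of
    the exponential terms. Returns the worst relative error.
    """
    worst = 0.0
    for drug, base in synth.DRUG_PARAMS.items():
        params = synth.PKTrueParameters(drug=drug, **base)
        dose = {"valsartan": 160.0, "olmesartan": 40.0, "hydrochlorothiazide": 12.5}[drug]
        t = np.linspace(0.0, t_end, n_points)
        c = synth.one_compartment_conc(params, dose, t)
        ke, ka, tlag = params.ke, params.ka, params.tlag
        tau = t_end - tlag
        c0 = dose * 1000.0 / params.v_f
        analytic = c0 * ka / (ka - ke) * (
            (1.0 - math.exp(-ke * tau)) / ke - (1.0 - math.exp(-ka * tau)) / ka
        )
        numeric = float(np.trapezoid(c, t))
        worst = max(worst, abs(numeric - analytic) / analytic)
    return worst


# ---------------------------------------------------------------------------
# Cohort-level studies
# ---------------------------------------------------------------------------

def simulate_nca_cohort(
    drug: str,
    dose: float,
    n_subjects: int,
    master_seed: int,
    effects: tuple[synth.CovariateEffect, ...] | None = None,
    error_cv: float = 0.15,
) -> pd.DataFrame:
    """One single-period cohort for one drug, run through NCA.

    Returns a per-subject frame with sex, the transporter genotypes, the
    true CYP2D6 phenotype and the NCA outcomes; the truth used to check
    recovery is the simulator's, never the estimate's.
    """
    cfg = synth.CohortConfig(
        n_subjects=n_subjects,
        effect_sizes=effects if effects is not None else synth.default_effects(),
        master_seed=master_seed,
        error_cv=error_cv,
    )
    subjects = synth.sample_demographics(cfg)
    genotypes = synth.sample_genotypes(
        subjects, cfg.variant_freqs, cfg.star_freqs, cfg.cyp2d6_cn_dist, cfg.master_seed
    )
    rows = []
    for idx, subject in enumerate(subjects):
        params = synth.assign_pk_parameters(
            subject, genotypes[subject.id], drug, cfg.effect_sizes,
            cfg.iiv_sd, cfg.master_seed, idx,
        )
        rng = synth.derive_rng(cfg.master_seed, "profiles", idx, 0, 1)
        profile = synth.simulate_profile(
            params, dose, cfg.schedule, synth.LLOQ[drug], error_cv, rng,
            subject_id=subject.id, weight_kg=subject.weight_kg,
        )
        try:
            res = nca.run_nca(profile)
        except nca.NonEvaluableProfile:
            continue
        geno = genotypes[subject.id]
        rows.append(
            {
                "subject": subject.id,
                "sex": subject.sex,
                "rs1045642": "/".join(sorted(geno.calls["rs1045642"])),
                "rs34059508": "/".join(sorted(geno.calls["rs34059508"])),
                "cyp2d6": geno.phenotypes["CYP2D6"],
                "tmax": res.tmax,
                "t_half": res.t_half,
                "auc_inf_dw": res.auc_inf_dw,
            }
        )
    return pd.DataFrame(rows)


_EFFECT_CHECKS = {
    # effect name -> (drug, dose, outcome, grouping fn, expected sign of
    # mean(outcome | effect group) - mean(outcome | reference group))
    "abcb1_tmax": ("valsartan", 160.0, "tmax",
                   lambda df: df["rs1045642"] == "T/T", +1),
    "slc22a1_auc": ("hydrochlorothiazide", 12.5, "auc_inf_dw",
                    lambda df: df["rs34059508"].str.contains("A"), +1),
    "cyp2d6_thalf": ("valsartan", 160.0, "t_half",
                     lambda df: df["cyp2d6"] == "PM", +1),
    "sex_auc": ("valsartan", 160.0, "auc_inf_dw",
                lambda df: df["sex"] == "female", -1),
}

#: Per-drug cohort sizes of the emulated pooled study.
PAPER_N = {"valsartan": 26, "hydrochlorothiazide": 58, "olmesartan": 37}


def effect_sign_recovery(
    n_reps: int = 200, n_subjects: int = 200, master_seed: int = 1,
    detection_n: dict[str, int] | None = None,
) -> dict[str, dict[str, float]]:
    """Recovery of injected covariate-effect signs through the full chain.

    For each replicate, simulates one valsartan and one hydrochlorothiazide
    cohort of ``n_subjects`` with the default effects on, runs NCA and asks
    whether the group-mean contrast on the relevant outcome has the
    injected sign. Also reruns each check at the emulated per-drug study
    size and records how often the univariate cascade detects it
    (p_uv < 0.05). Returns per-effect ``sign_recovery_pct`` and
    ``detection_at_study_n_pct``.
    """
    detection_n = dict(PAPER_N) if detection_n is None else detection_n
    hits = {name: 0 for name in _EFFECT_CHECKS}
    valid = {name: 0 for name in _EFFECT_CHECKS}
    detect = {name: 0 for name in _EFFECT_CHECKS}
    detect_valid = {name: 0 for name in _EFFECT_CHECKS}
    for rep in range(n_reps):
        frames = {
            drug: simulate_nca_cohort(drug, dose, n_subjects, master_seed * 100000 + rep * 10 + k)
            for k, (drug, dose) in enumerate(
                [("valsartan", 160.0), ("hydrochlorothiazide", 12.5)]
            )
        }
        small = {
            drug: simulate_nca_cohort(
                drug, dose, detection_n[drug], master_seed * 100000 + rep * 10 + 5 + k
            )
            for k, (drug, dose) in enumerate(
                [("valsartan", 160.0), ("hydrochlorothiazide", 12.5)]
            )
        }
        for name, (drug, _dose, outcome, grouping, sign) in _EFFECT_CHECKS.items():
            df = frames[drug]
            mask = grouping(df)
            if mask.sum() >= 1 and (~mask).sum() >= 1:
                valid[name] += 1
                contrast = df.loc[mask, outcome].mean() - df.loc[~mask, outcome].mean()
                if np.sign(contrast) == sign:
                    hits[name] += 1
            sdf = small[drug]
            smask = grouping(sdf)
            if smask.sum() >= 2 and (~smask).sum() >= 2:
                detect_valid[name] += 1
                group = np.where(smask, "effect", "reference")
                gate = stats.normality_gate(sdf[outcome])
                uni = stats.univariate(sdf[outcome], group, gate)
                if uni.p_uv < 0.05:
                    detect[name] += 1
    return {
        name: {
            "sign_recovery_pct": 100.0 * hits[name] / max(valid[name], 1),
            "valid_replicates": valid[name],
            "detection_at_study_n_pct": 100.0 * detect[name] / max(detect_valid[name], 1),
            "detection_valid_replicates": detect_valid[name],
        }
        for name in _EFFECT_CHECKS
    }


def null_calibration(
    n_reps: int = 500, master_seed: int = 2, n_subjects: int = 26,
) -> dict[str, float]:
    """Cascade type-I rate with every effect off.

    Per replicate, a covariate-free valsartan cohort; the cascade compares
    weight-corrected exposure between sexes and tmax between rs1045642 T/T
    and the rest. Returns the fraction of replicates with p_uv < 0.05 per
    test (both should sit near the nominal 5%).
    """
    tests = {"sex_on_auc": 0, "genotype_on_tmax": 0}
    valid = {"sex_on_auc": 0, "genotype_on_tmax": 0}
    for rep in range(n_reps):
        df = simulate_nca_cohort(
            "valsartan", 160.0, n_subjects, master_seed * 100000 + rep, effects=(),
        )
        checks = {
            "sex_on_auc": ("auc_inf_dw", df["sex"] == "female"),
            "genotype_on_tmax": ("tmax", df["rs1045642"] == "T/T"),
        }
        for name, (outcome, mask) in checks.items():
            if mask.sum() < 2 or (~mask).sum() < 2:
                continue
            valid[name] += 1
            gate = stats.normality_gate(df[outcome])
            uni = stats.univariate(df[outcome], np.where(mask, "a", "b"), gate)
            if uni.p_uv < 0.05:
                tests[name] += 1
    return {
        name: 100.0 * tests[name] / max(valid[name], 1) for name in tests
    } | {f"{name}_valid": float(valid[name]) for name in valid}
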