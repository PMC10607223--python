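"""End-to-end pipeline: table I/O, stage orchestration and reporting.

Chains the four analysis stages — simulate (optional), per-profile NCA
with crossover aggregation, genotype-to-phenotype translation, and the
association / safety statistics — over schema-validated TSV/CSV tables,
writing one output table per stage plus a human-readable report whose
numbers are all recomputable from the stage tables.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import nca, pgx, stats, synth

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_concentrations",
    "read_demographics",
    "read_genotypes",
    "read_safety",
    "profiles_from_frame",
    "nca_table",
    "phenotypes_from_tables",
    "association_tables",
    "safety_tables",
    "run_pipeline",
]

log = logging.getLogger("pkpgx")

#: Per-drug crossover aggregation policy: arithmetic mean of both
#: formulations where T was bioequivalent to R, reference periods only
#: for olmesartan where it was not.
DEFAULT_POLICIES: dict[str, str] = {
    "valsartan": "mean_TR",
    "hydrochlorothiazide": "mean_TR",
    "olmesartan": "reference_only",
}

CONC_COLUMNS = [
    "subject", "drug", "period", "formulation", "dose_mg", "weight_kg",
    "time_h", "conc_ng_ml", "bloq_flag",
]

EXIT_VALIDATION = 2
EXIT_STAGE = 3


class SchemaError(ValueError):
    """Input table fails schema validation; message carries file and rows."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "pkpgx_out"
    seed: int = 0
    simulate: bool = True
    n_subjects: int = 64
    concentrations: str | None = None
    demographics: str | None = None
    genotypes: str | None = None
    cyp2d6_cn: str | None = None
    safety: str | None = None
    policies: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_POLICIES))
    lambda_method: str = "best_adj_r2"
    alpha: float = 0.05
    null_effects: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for drug, policy in self.policies.items():
            if policy not in ("mean_TR", "reference_only"):
                raise ValueError(f"unknown aggregation policy {policy!r} for {drug}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")


def read_concentrations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CONC_COLUMNS, path)
    key = ["subject", "drug", "period", "time_h"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise SchemaError(f"{path}: duplicate subject/drug/period/time rows at lines {rows}")
    if (df["dose_mg"] <= 0).any() or (df["weight_kg"] <= 0).any():
        raise SchemaError(f"{path}: non-positive dose or weight")
    log.info("read %d concentration rows from %s", len(df), path)
    return df


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["subject", "sex", "age", "height_m", "weight_kg", "trial"], path)
    if df["subject"].duplicated().any():
        raise SchemaError(f"{path}: duplicate subject rows")
    log.info("read %d demographic rows from %s", len(df), path)
    return df


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["subject", "rsid", "allele1", "allele2"], path)
    dup = df.duplicated(subset=["subject", "rsid"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicate subject/rsid rows at lines {rows}")
    log.info("read %d genotype rows from %s", len(df), path)
    return df


def read_safety(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["subject"], path)
    log.info("read %d safety rows from %s", len(df), path)
    return df


# ---------------------------------------------------------------------------
# NCA stage
# ---------------------------------------------------------------------------

def profiles_from_frame(df: pd.DataFrame) -> list[nca.ConcentrationProfile]:
    """Group a long concentration table into per-period profiles."""
    profiles = []
    lloq_by_drug = dict(synth.LLOQ)
    for (subject, drug, period, formulation), sub in df.groupby(
        ["subject", "drug", "period", "formulation"], sort=True
    ):
        sub = sub.sort_values("time_h")
        bloq = sub["bloq_flag"].astype(int).to_numpy().astype(bool)
        conc = pd.to_numeric(sub["conc_ng_ml"], errors="coerce").to_numpy(float)
        profiles.append(
            nca.ConcentrationProfile(
                subject_id=str(subject), drug=str(drug), period=int(period),
                formulation=str(formulation), dose_mg=float(sub["dose_mg"].iloc[0]),
                weight_kg=float(sub["weight_kg"].iloc[0]),
                times=sub["time_h"].to_numpy(float), concentrations=conc,
                bloq=bloq, lloq=lloq_by_drug.get(str(drug), 0.0),
            )
        )
    return profiles


def nca_table(
    profiles: Sequence[nca.ConcentrationProfile],
    policies: Mapping[str, str] | None = None,
    lambda_method: str = "best_adj_r2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run NCA per period, aggregate per subject x drug by policy.

    Returns (aggregated results, non-evaluable log). Every subject x drug
    in the input appears in exactly one of the two frames.
    """
    policies = dict(DEFAULT_POLICIES) if policies is None else policies
    per_period: dict[tuple[str, str], list[nca.NCAResult]] = {}
    failures: list[dict] = []
    for profile in profiles:
        key = (profile.subject_id, profile.drug)
        try:
            res = nca.run_nca(profile, lambda_method=lambda_method)
        except nca.NonEvaluableProfile as exc:
            failures.append(
                {"subject": profile.subject_id, "drug": profile.drug,
                 "period": profile.period, "reason": str(exc)}
            )
            continue
        per_period.setdefault(key, []).append(res)
    rows = []
    for (subject, drug), results in sorted(per_period.items()):
        policy = policies.get(drug, "mean_TR")
        try:
            agg = nca.aggregate_formulations(results, policy)
        except ValueError as exc:
            failures.append({"subject": subject, "drug": drug, "period": None, "reason": str(exc)})
            continue
        rows.append(
            {
                "subject": subject, "drug": drug, "policy": policy,
                "dose_mg": agg.dose_mg, "weight_kg": agg.weight_kg,
                "cmax": agg.cmax, "tmax": agg.tmax, "auc_t": agg.auc_t,
                "auc_inf": agg.auc_inf, "ke": agg.ke, "t_half": agg.t_half,
                "pct_extrapolated": agg.pct_extrapolated,
                "auc_inf_d": agg.auc_inf_d, "cmax_d": agg.cmax_d,
                "auc_inf_dw": agg.auc_inf_dw, "cmax_dw": agg.cmax_dw,
            }
        )
    nca_df = pd.DataFrame(rows)
    fail_df = pd.DataFrame(failures, columns=["subject", "drug", "period", "reason"])
    log.info("NCA: %d subject x drug results, %d non-evaluable", len(nca_df), len(fail_df))
    return nca_df, fail_df


# ---------------------------------------------------------------------------
# Phenotype stage
# ---------------------------------------------------------------------------

def phenotypes_from_tables(
    genotypes: pd.DataFrame, cyp2d6_cn: pd.DataFrame | None = None
) -> pd.DataFrame:
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    for _, row in genotypes.iterrows():
        calls.setdefault(str(row["subject"]), {})[str(row["rsid"])] = (
            str(row["allele1"]), str(row["allele2"]),
        )
    cns = {}
    if cyp2d6_cn is not None:
        cns = dict(zip(cyp2d6_cn["subject"].astype(str), cyp2d6_cn["cyp2d6_cn"].astype(int)))
    # only genes whose defining loci are on the panel
    panel = set(genotypes["rsid"].astype(str))
    genes = [g for g, t in pgx.load_definitions().items() if t.rsids <= panel]
    return pgx.phenotype_table(calls, cns, genes=sorted(genes))


#: Transporter genotype predictors analysed for every drug, and the merged
#: codings (reference genotype against carriers).
GENOTYPE_PREDICTORS = ["rs1045642", "rs1128503", "rs2032582", "rs2273697",
                       "rs2231142", "rs12208357", "rs34059508", "rs72552763"]
PK_OUTCOMES = ["auc_inf_dw", "cmax_dw", "tmax", "t_half"]


def _merged_analysis_table(
    nca_df: pd.DataFrame,
    demographics: pd.DataFrame,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    safety: pd.DataFrame | None,
) -> pd.DataFrame:
    geno_wide = (
        genotypes.assign(
            genotype=lambda d: [
                "/".join(sorted((a, b))) for a, b in zip(d["allele1"], d["allele2"])
            ]
        )
        .pivot(index="subject", columns="rsid", values="genotype")
        .reset_index()
    )
    phen_wide = (
        phenotypes.pivot(index="subject", columns="gene", values="phenotype")
        .add_prefix("phen_")
        .reset_index()
    )
    df = nca_df.merge(demographics, on="subject", how="left", suffixes=("", "_demo"))
    df = df.merge(geno_wide, on="subject", how="left")
    df = df.merge(phen_wide, on="subject", how="left")
    if safety is not None:
        df = df.merge(safety, on="subject", how="left")
    return df


def association_tables(
    merged: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate + multivariate association results per drug and outcome.

    Predictors: sex, biogeographic origin, trial, transporter genotypes and
    available phenotype columns. Returns (univariate frame, multivariate
    frame).
    """
    uni_rows, mv_rows = [], []
    for drug, sub in merged.groupby("drug"):
        predictors = ["sex", "origin", "trial"]
        predictors += [c for c in GENOTYPE_PREDICTORS if c in sub.columns]
        predictors += [c for c in sub.columns if c.startswith("phen_")]
        usable = []
        for pred in predictors:
            vals = sub[pred].dropna().astype(str)
            vals = vals[vals != "indeterminate"]
            if vals.nunique() >= 2 and vals.value_counts().iloc[1] >= 2:
                usable.append(pred)
        for outcome in PK_OUTCOMES:
            if outcome not in sub.columns or sub[outcome].dropna().shape[0] < 3:
                continue
            clean = sub.copy()
            for pred in usable:
                clean.loc[clean[pred].astype(str) == "indeterminate", pred] = np.nan
            result = stats.association_cascade(clean, outcome, usable, alpha=alpha)
            for u in result.univariate:
                for _, lv in u.descriptives.iterrows():
                    uni_rows.append(
                        {
                            "drug": drug, "outcome": outcome, "predictor": u.predictor,
                            "level": lv["level"], "n": lv["n"],
                            "mean_sd": lv["formatted"], "test": u.test,
                            "p_uv": u.p_uv, "route": result.gate.route,
                        }
                    )
            if not result.multivariate.empty:
                for _, term in result.multivariate.terms.iterrows():
                    mv_rows.append(
                        {
                            "drug": drug, "outcome": outcome, "term": term["term"],
                            "beta": term["beta"], "p_mv": term["p_mv"],
                            "r_squared": result.multivariate.r_squared,
                            "scale": "log" if result.multivariate.log_scale else "raw",
                        }
                    )
    uni = pd.DataFrame(uni_rows, columns=["drug", "outcome", "predictor", "level", "n",
                                          "mean_sd", "test", "p_uv", "route"])
    mv = pd.DataFrame(mv_rows, columns=["drug", "outcome", "term", "beta", "p_mv",
                                        "r_squared", "scale"])
    return uni, mv


def safety_tables(merged_any: pd.DataFrame, safety: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ADR incidence tests and paired haemodynamic tests.

    ``merged_any`` must contain one row per subject with demographic and
    genotype columns; ``safety`` the per-subject ADR flags and BP/HR/QTc
    measurements.
    """
    df = merged_any.merge(safety, on="subject", how="inner")
    adr_cols = [c for c in safety.columns if c.startswith("adr_")]
    df["adr_any"] = df[adr_cols].max(axis=1) if adr_cols else 0
    incid_rows = []
    group_cols = [c for c in ["sex", "origin", "trial", *GENOTYPE_PREDICTORS] if c in df.columns]
    for adr in ["adr_any", *adr_cols]:
        for pred in group_cols:
            sub = df.dropna(subset=[pred])
            levels = sorted(sub[pred].astype(str).unique())
            if len(levels) < 2:
                continue
            counts = np.array(
                [
                    [
                        int((sub.loc[sub[pred].astype(str) == lv, adr] > 0).sum()),
                        int((sub.loc[sub[pred].astype(str) == lv, adr] == 0).sum()),
                    ]
                    for lv in levels
                ]
            ).T  # 2 x k: events / non-events
            try:
                res = stats.incidence_test(counts)
            except ValueError:
                continue
            pct = 100.0 * counts[0] / counts.sum(axis=0)
            incid_rows.append(
                {
                    "adr": adr.removeprefix("adr_"), "predictor": pred,
                    "levels": "|".join(levels),
                    "events": "|".join(map(str, counts[0])),
                    "totals": "|".join(map(str, counts.sum(axis=0))),
                    "pct": "|".join(f"{v:.1f}" for v in pct),
                    "test": res.test, "p": res.p,
                }
            )
    paired_rows = []
    for name, base, follow in [
        ("sbp_t3h", "sbp_basal", "sbp_t3h"), ("sbp_t6h", "sbp_basal", "sbp_t6h"),
        ("dbp_t3h", "dbp_basal", "dbp_t3h"), ("dbp_t6h", "dbp_basal", "dbp_t6h"),
        ("hr_t3h", "hr_basal", "hr_t3h"), ("hr_t6h", "hr_basal", "hr_t6h"),
        ("qtc_t6h", "qtc_basal", "qtc_t6h"),
    ]:
        if base not in df.columns or follow not in df.columns:
            continue
        res = stats.paired_change(df[base], df[follow])
        paired_rows.append(
            {
                "measure": name, "n": res.n,
                "mean_change": res.mean_change, "sd_change": res.sd_change,
                "p": res.p, "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(incid_rows), pd.DataFrame(paired_rows)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _report_text(
    nca_df: pd.DataFrame, uni: pd.DataFrame, mv: pd.DataFrame,
    incid: pd.DataFrame, paired: pd.DataFrame, failures: pd.DataFrame,
    alpha: float,
) -> str:
    lines = ["# Pharmacokinetic-pharmacogenetic analysis report", ""]
    for drug, sub in nca_df.groupby("drug"):
        lines.append(f"## {drug} (n = {len(sub)})")
        lines.append("parameter\tmean (standard deviation)")
        for col, label in [
            ("auc_inf", "AUCinf (ng*h/mL)"), ("cmax", "Cmax (ng/mL)"),
            ("auc_inf_dw", "AUCinf/DW (ng*h*kg/mL*mg)"),
            ("cmax_dw", "Cmax/DW (ng*kg/mL*mg)"),
            ("tmax", "tmax (h)"), ("t_half", "t1/2 (h)"),
        ]:
            lines.append(f"{label}\t{sub[col].mean():.2f} ({sub[col].std(ddof=1):.2f})")
        lines.append("")
        drug_uni = uni[uni["drug"] == drug]
        sig = drug_uni[drug_uni["p_uv"] < alpha]
        if len(sig):
            lines.append("univariately significant predictors (descriptives per level):")
            for (outcome, pred), block in sig.groupby(["outcome", "predictor"]):
                p = block["p_uv"].iloc[0]
                lines.append(f"  {outcome} ~ {pred} (p_uv = {p:.3f})")
                for _, row in drug_uni[
                    (drug_uni["outcome"] == outcome) & (drug_uni["predictor"] == pred)
                ].iterrows():
                    lines.append(f"    {row['level']}\tn={row['n']}\t{row['mean_sd']}")
        drug_mv = mv[mv["drug"] == drug]
        if len(drug_mv):
            lines.append("multivariate model terms:")
            for _, row in drug_mv.iterrows():
                lines.append(
                    f"  {row['outcome']} ~ {row['term']}: beta = {row['beta']:.3f}, "
                    f"p_mv = {row['p_mv']:.3f}, R^2 = {row['r_squared']:.3f} ({row['scale']} scale)"
                )
        lines.append("")
    if len(incid):
        lines.append("## ADR incidence")
        for _, row in incid.iterrows():
            lines.append(
                f"{row['adr']} by {row['predictor']} [{row['levels']}]: "
                f"{row['events']} of {row['totals']} ({row['pct']} %), "
                f"{row['test']} p = {row['p']:.3f}"
            )
        lines.append("")
    if len(paired):
        lines.append("## Haemodynamics (paired change from basal)")
        for _, row in paired.iterrows():
            lines.append(
                f"{row['measure']}: {row['mean_change']:.2f} ({row['sd_change']:.2f}), "
                f"n = {row['n']}, p = {row['p']:.3g}"
            )
        lines.append("")
    if len(failures):
        lines.append("## Non-evaluable profiles")
        for _, row in failures.iterrows():
            lines.append(f"{row['subject']} {row['drug']} period {row['period']}: {row['reason']}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute simulate -> NCA -> phenotype -> associate -> report.

    Returns a mapping of artifact name to written path. Deterministic for a
    fixed configuration (incl. seed).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate:
            cohort_cfg = (
                synth.null_config(n_subjects=config.n_subjects, master_seed=config.seed)
                if config.null_effects
                else synth.CohortConfig(n_subjects=config.n_subjects, master_seed=config.seed)
            )
            cohort = synth.generate_cohort(cohort_cfg)
            paths.update(cohort.write_tables(outdir / "simulated"))
            conc = read_concentrations(paths["concentrations"])
            demo = read_demographics(paths["demographics"])
            geno = read_genotypes(paths["genotypes"])
            cn = pd.read_csv(paths["cyp2d6_cn"], sep="\t")
            safety = read_safety(paths["safety"])
        else:
            if not (config.concentrations and config.demographics and config.genotypes):
                raise SchemaError("non-simulated run needs concentrations, demographics and genotypes paths")
            conc = read_concentrations(config.concentrations)
            demo = read_demographics(config.demographics)
            geno = read_genotypes(config.genotypes)
            cn = pd.read_csv(config.cyp2d6_cn, sep="\t") if config.cyp2d6_cn else None
            safety = read_safety(config.safety) if config.safety else None
    except SchemaError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageFailure("read_tables", exc) from exc

    # --- NCA --------------------------------------------------------------
    try:
        profiles = profiles_from_frame(conc)
        nca_df, failures = nca_table(profiles, config.policies, config.lambda_method)
    except Exception as exc:
        raise StageFailure("nca", exc) from exc
    nca_path = outdir / "nca_results.tsv"
    nca_df.to_csv(nca_path, sep="\t", index=False)
    failures.to_csv(outdir / "nca_non_evaluable.tsv", sep="\t", index=False)
    paths["nca_results"] = str(nca_path)

    # --- phenotypes -------------------------------------------------------
    try:
        phen = phenotypes_from_tables(geno, cn)
    except Exception as exc:
        raise StageFailure("pgx", exc) from exc
    phen_path = outdir / "phenotypes.tsv"
    phen.to_csv(phen_path, sep="\t", index=False)
    paths["phenotypes"] = str(phen_path)

    # --- associations -----------------------------------------------------
    try:
        merged = _merged_analysis_table(nca_df, demo, geno, phen, None)
        uni, mv = association_tables(merged, alpha=config.alpha)
        if safety is not None:
            subject_cols = merged.drop_duplicates("subject")
            incid, paired = safety_tables(subject_cols, safety)
        else:
            incid = pd.DataFrame()
            paired = pd.DataFrame()
    except Exception as exc:
        raise StageFailure("associate", exc) from exc
    uni.to_csv(outdir / "associations_univariate.tsv", sep="\t", index=False)
    mv.to_csv(outdir / "associations_multivariate.tsv", sep="\t", index=False)
    incid.to_csv(outdir / "safety_incidence.tsv", sep="\t", index=False)
    paired.to_csv(outdir / "paired_haemodynamics.tsv", sep="\t", index=False)
    paths["associations_univariate"] = str(outdir / "associations_univariate.tsv")
    paths["associations_multivariate"] = str(outdir / "associations_multivariate.tsv")
    paths["safety_incidence"] = str(outdir / "safety_incidence.tsv")

    report = _report_text(nca_df, uni, mv, incid, paired, failures, config.alpha)
    report_path = outdir / "report.txt"
    report_path.write_text(report)
    paths["report"] = str(report_path)
    log.info("pipeline complete: %d artifacts in %s", len(paths), outdir)
    return paths
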