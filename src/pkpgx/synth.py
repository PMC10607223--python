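"""Synthetic crossover-trial cohort generator.

Simulates the data structure of a pooled candidate-gene study across seven
single-dose crossover bioequivalence trials of valsartan, olmesartan and
hydrochlorothiazide: per-sex demographics truncated to the trials'
eligibility window, Hardy-Weinberg genotypes at the panel's transporter
variants and star-allele pharmacogenes, one-compartment first-order
absorption PK with log-normal between-subject variability and configurable
multiplicative covariate effects, LLOQ-censored concentration-time
profiles with proportional log-normal assay error, and exposure-linked
adverse-reaction and blood-pressure/heart-rate/QTc records.

All randomness derives from one master seed through a documented counter
scheme (``derive_rng``), so any stage can be regenerated independently and
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nca import ConcentrationProfile
from .pgx import cyp2d6_phenotype, function_phenotype

__all__ = [
    "CohortConfig",
    "Subject",
    "PKTrueParameters",
    "CovariateEffect",
    "AdrModel",
    "BPModel",
    "SafetyRecord",
    "SimulatedCohort",
    "derive_rng",
    "sample_demographics",
    "sample_genotypes",
    "assign_pk_parameters",
    "simulate_profile",
    "simulate_safety",
    "generate_cohort",
    "DEFAULT_SCHEDULE",
    "DRUG_PARAMS",
    "LLOQ",
    "TRIAL_DESIGNS",
    "VARIANT_FREQS",
    "STAR_FREQS",
    "default_effects",
    "null_config",
]

# ---------------------------------------------------------------------------
# Study-condition constants
# ---------------------------------------------------------------------------

#: Sampling schedule (h): 17 draws from pre-dose to 48 h, dense through the
#: absorption window (tmax 1-5 h) with at least three terminal-phase points.
DEFAULT_SCHEDULE: tuple[float, ...] = (
    0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0,
    24.0, 36.0, 48.0,
)

#: Lower limits of quantification (ng/mL) of the bioanalytical assays.
LLOQ: dict[str, float] = {
    "hydrochlorothiazide": 1.01,
    "olmesartan": 2.51,
    "valsartan": 20.02,
}

#: Base one-compartment population parameters per drug for a 71-kg adult:
#: apparent clearance CL/F (L/h), apparent volume V/F (L), first-order
#: absorption rate ka (1/h) and absorption lag (h). Chosen so that
#: noise-free NCA of the simulated profiles lands near the study-scale
#: exposure means (HCTZ 12.5 mg AUCinf ~594 ng*h/mL, valsartan 160 mg
#: ~27,400 ng*h/mL, olmesartan 40 mg ~5,900 ng*h/mL); see docs/methods.md
#: for why a one-compartment model cannot also match the multiphasic
#: terminal half-lives.
DRUG_PARAMS: dict[str, dict[str, float]] = {
    "valsartan": {"cl_f": 5.85, "v_f": 50.9, "ka": 2.2, "tlag": 0.3},
    "olmesartan": {"cl_f": 6.80, "v_f": 56.7, "ka": 2.0, "tlag": 0.3},
    "hydrochlorothiazide": {"cl_f": 21.1, "v_f": 140.0, "ka": 2.2, "tlag": 0.25},
}

#: Reference body weight (kg) for the proportional CL/V scaling.
REFERENCE_WEIGHT = 71.0

#: Trial catalogue: drug -> dose (mg) per trial, crossover period layout and
#: enrolment of the pooled pharmacogenetic sub-cohort.
TRIAL_DESIGNS: dict[int, dict] = {
    1: {"doses": {"valsartan": 160.0}, "periods": ("T", "T", "R", "R"), "n": 6},
    2: {"doses": {"valsartan": 160.0, "hydrochlorothiazide": 25.0}, "periods": ("T", "T", "R", "R"), "n": 4},
    3: {"doses": {"valsartan": 160.0, "hydrochlorothiazide": 12.5}, "periods": ("T", "T", "R", "R"), "n": 8},
    4: {"doses": {"valsartan": 320.0, "hydrochlorothiazide": 25.0}, "periods": ("T", "T", "R", "R"), "n": 8},
    5: {"doses": {"olmesartan": 40.0, "hydrochlorothiazide": 25.0}, "periods": ("T", "R"), "n": 12},
    6: {"doses": {"olmesartan": 40.0, "hydrochlorothiazide": 12.5}, "periods": ("T", "R"), "n": 10},
    7: {"doses": {"olmesartan": 40.0, "hydrochlorothiazide": 12.5}, "periods": ("T", "R"), "n": 16},
}

#: European-population allele frequencies at the transporter loci
#: (tri-allelic rs2032582 carries three alleles).
VARIANT_FREQS: dict[str, dict[str, float]] = {
    "rs1045642": {"T": 0.518, "C": 0.482},
    "rs2032582": {"T": 0.410, "G": 0.573, "A": 0.017},
    "rs1128503": {"T": 0.416, "C": 0.584},
    "rs2273697": {"G": 0.796, "A": 0.204},
    "rs2231142": {"C": 0.896, "A": 0.104},
    "rs12208357": {"C": 0.937, "T": 0.063},
    "rs34059508": {"G": 0.980, "A": 0.020},
    "rs72552763": {"GAT": 0.816, "delGAT": 0.184},
}

#: European star-allele (haplotype) frequencies per pharmacogene; the
#: reference *1 takes the remaining mass. Sampling haplotypes keeps the
#: derived per-locus variant calls internally consistent.
STAR_FREQS: dict[str, dict[str, float]] = {
    "CYP2D6": {"*3": 0.016, "*4": 0.185, "*6": 0.011, "*7": 0.0001, "*8": 0.0001,
               "*9": 0.028, "*10": 0.016, "*14": 0.0001, "*17": 0.004, "*41": 0.092},
    "SLCO1B1": {"*5": 0.0001, "*15": 0.150, "*37": 0.253},
    "CYP3A5": {"*3": 0.924, "*6": 0.0001},
    "CYP2C9": {"*2": 0.127, "*3": 0.076},
    "CYP2C19": {"*2": 0.147, "*3": 0.002, "*4": 0.002, "*17": 0.215},
    "CYP2B6": {"*4": 0.409, "*5": 0.116, "*6": 0.233, "*7": 0.025, "*9": 0.015},
    "CYP2A6": {"*9": 0.071},
    "CYP2C8": {"*2": 0.004, "*3": 0.118, "*4": 0.058},
    "CYP3A4": {"*2": 0.0001, "*6": 0.0001, "*20": 0.0009, "*22": 0.037},
    "UGT1A1": {"*80": 0.314},
}

#: Star-allele -> defining variant calls, for emitting per-locus genotypes
#: consistent with the sampled haplotypes (mirror of the bundled
#: definition table; the reference haplotype carries the reference allele
#: at every locus).
_GENE_LOCI: dict[str, dict[str, str]] = {
    # gene -> {rsid: reference allele}
    "CYP2D6": {"rs35742686": "A", "rs3892097": "G", "rs5030655": "T",
               "rs5030867": "A", "rs5030865": "G", "rs5030656": "TCT",
               "rs1065852": "C", "rs28371706": "C", "rs28371725": "G"},
    "SLCO1B1": {"rs4149056": "T", "rs2306283": "A"},
    "CYP3A5": {"rs776746": "A", "rs10264272": "G"},
    "CYP2C9": {"rs1799853": "C", "rs1057910": "A"},
    "CYP2C19": {"rs4244285": "G", "rs4986893": "G", "rs28399504": "A", "rs12248560": "C"},
    "CYP2B6": {"rs2279343": "A", "rs3745274": "G", "rs3211371": "C"},
    "CYP2A6": {"rs28399433": "T"},
    "CYP2C8": {"rs11572103": "A", "rs10509681": "A", "rs1058930": "C"},
    "CYP3A4": {"rs55785340": "T", "rs46464389": "delA", "rs67666821": "delA", "rs35599367": "C"},
    "UGT1A1": {"rs887829": "C"},
}

_STAR_VARIANTS: dict[str, dict[str, dict[str, str]]] = {
    "CYP2D6": {"*3": {"rs35742686": "delA"}, "*4": {"rs3892097": "A", "rs1065852": "T"},
               "*6": {"rs5030655": "delT"}, "*7": {"rs5030867": "C"},
               "*8": {"rs5030865": "T"}, "*9": {"rs5030656": "delTCT"},
               "*10": {"rs1065852": "T"}, "*14": {"rs5030865": "A"},
               "*17": {"rs28371706": "T"}, "*41": {"rs28371725": "A"}},
    "SLCO1B1": {"*5": {"rs4149056": "C"}, "*15": {"rs4149056": "C", "rs2306283": "G"},
                "*37": {"rs2306283": "G"}},
    "CYP3A5": {"*3": {"rs776746": "G"}, "*6": {"rs10264272": "A"}},
    "CYP2C9": {"*2": {"rs1799853": "T"}, "*3": {"rs1057910": "C"}},
    "CYP2C19": {"*2": {"rs4244285": "A"}, "*3": {"rs4986893": "A"},
                "*4": {"rs28399504": "G"}, "*17": {"rs12248560": "T"}},
    "CYP2B6": {"*4": {"rs2279343": "G"}, "*5": {"rs3211371": "T"},
               "*6": {"rs2279343": "G", "rs3745274": "T"},
               "*7": {"rs2279343": "G", "rs3745274": "T", "rs3211371": "T"},
               "*9": {"rs3745274": "T"}},
    "CYP2A6": {"*9": {"rs28399433": "G"}},
    "CYP2C8": {"*2": {"rs11572103": "T"}, "*3": {"rs10509681": "G"}, "*4": {"rs1058930": "G"}},
    "CYP3A4": {"*2": {"rs55785340": "C"}, "*6": {"rs46464389": "A"},
               "*20": {"rs67666821": "A"}, "*22": {"rs35599367": "T"}},
    "UGT1A1": {"*80": {"rs887829": "T"}},
}


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffect:
    """Multiplicative covariate effect on one PK parameter of one drug.

    ``selector`` is declarative: ("sex", "female"), ("genotype", rsid,
    "T/T"), ("carrier", rsid, "A") or ("phenotype", gene, "PM"). A
    ``parameter`` of "ke" multiplies the elimination rate at fixed
    clearance (i.e. divides V/F), leaving total exposure unchanged.
    """

    name: str
    drug: str
    parameter: str  # cl_f | v_f | ka | ke
    multiplier: float
    selector: tuple

    def applies(self, subject: "Subject", genotype: "GenotypeProfile") -> bool:
        kind = self.selector[0]
        if kind == "sex":
            return subject.sex == self.selector[1]
        if kind == "genotype":
            rsid, want = self.selector[1], self.selector[2]
            pair = genotype.calls.get(rsid)
            if pair is None:
                raise KeyError(f"effect {self.name!r} needs genotype at {rsid}")
            return "/".join(sorted(pair)) == "/".join(sorted(want.split("/")))
        if kind == "carrier":
            rsid, allele = self.selector[1], self.selector[2]
            pair = genotype.calls.get(rsid)
            if pair is None:
                raise KeyError(f"effect {self.name!r} needs genotype at {rsid}")
            return allele in pair
        if kind == "phenotype":
            gene, cat = self.selector[1], self.selector[2]
            got = genotype.phenotypes.get(gene)
            if got is None:
                raise KeyError(f"effect {self.name!r} needs {gene} phenotype")
            return got == cat
        raise ValueError(f"unknown selector kind {kind!r}")


def default_effects() -> tuple[CovariateEffect, ...]:
    """Covariate effects encoding the associations the cohort emulates."""
    return (
        # slower valsartan absorption with the ABCB1 rs1045642 reference genotype
        CovariateEffect("abcb1_valsartan_ka", "valsartan", "ka", 0.5,
                        ("genotype", "rs1045642", "T/T")),
        # reduced hepatic uptake -> lower apparent clearance of hydrochlorothiazide
        CovariateEffect("slc22a1_hctz_cl", "hydrochlorothiazide", "cl_f", 0.76,
                        ("carrier", "rs34059508", "A")),
        # slower valsartan elimination in CYP2D6 poor metabolizers (exposure unchanged)
        CovariateEffect("cyp2d6_valsartan_ke", "valsartan", "ke", 0.65,
                        ("phenotype", "CYP2D6", "PM")),
        # lower weight-corrected valsartan exposure in women
        CovariateEffect("sex_valsartan_cl", "valsartan", "cl_f", 1.35,
                        ("sex", "female")),
        # faster hydrochlorothiazide elimination in women at fixed clearance
        CovariateEffect("sex_hctz_ke", "hydrochlorothiazide", "ke", 1.12,
                        ("sex", "female")),
    )


@dataclass(frozen=True)
class AdrModel:
    """Per-term logistic ADR model: logit p = intercept + slope * z(log AUCinf)."""

    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {
            "headache": -0.75, "dizziness": -3.05,
            "postural_dizziness": -3.5, "nausea": -3.5,
        }
    )
    slope: float = 1.0


@dataclass(frozen=True)
class BPModel:
    """Basal haemodynamics and post-dose changes (mean, SD).

    Changes are followup minus basal; the exposure coefficient shifts the
    blood-pressure change per SD of standardized log exposure.
    """

    basal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sbp": (116.0, 11.0), "dbp": (65.0, 8.0),
            "hr": (62.0, 9.0), "qtc": (395.8, 24.1),
        }
    )
    delta: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sbp_t3h": (-5.5, 10.0), "sbp_t6h": (-7.0, 11.0),
            "dbp_t3h": (-6.8, 7.0), "dbp_t6h": (-8.6, 7.0),
            "hr_t3h": (3.0, 8.0), "hr_t6h": (10.0, 9.0),
            "qtc_t6h": (12.5, 18.0),
        }
    )
    exposure_coef_bp: float = -1.5


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated pooled cohort."""

    n_subjects: int = 64
    sex_ratio: float = 27 / 64  # fraction women
    trial_assignments: Mapping[int, dict] = field(default_factory=lambda: dict(TRIAL_DESIGNS))
    demographic_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "male": {"age": (24.57, 4.39), "height": (1.78, 0.08), "weight": (78.77, 10.38)},
            "female": {"age": (31.15, 10.69), "height": (1.62, 0.05), "weight": (60.56, 7.57)},
        }
    )
    age_range: tuple[float, float] = (18.0, 55.0)
    bmi_range: tuple[float, float] = (18.5, 30.0)
    variant_freqs: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: dict(VARIANT_FREQS))
    star_freqs: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: dict(STAR_FREQS))
    cyp2d6_cn_dist: Mapping[int, float] = field(default_factory=lambda: {2: 1.0})
    effect_sizes: tuple[CovariateEffect, ...] = field(default_factory=default_effects)
    # between-subject log-normal variability (SD of log) per PK parameter
    iiv_sd: Mapping[str, float] = field(
        default_factory=lambda: {"cl_f": 0.25, "v_f": 0.20, "ka": 0.35}
    )
    # within-subject between-period variability (SD of log), default none
    iov_sd: float = 0.0
    error_cv: float = 0.15
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    adr_model: AdrModel = field(default_factory=AdrModel)
    bp_model: BPModel = field(default_factory=BPModel)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.error_cv < 0:
            raise ValueError("error_cv must be >= 0")
        for rsid, freqs in self.variant_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 5e-3:
                raise ValueError(f"allele frequencies at {rsid} sum to {total}, not 1")
        for trial, design in self.trial_assignments.items():
            if any(d <= 0 for d in design["doses"].values()):
                raise ValueError(f"non-positive dose in trial {trial}")


def null_config(**overrides) -> CohortConfig:
    """Configuration with every covariate effect off and no exposure-ADR link."""
    defaults = dict(
        effect_sizes=(),
        adr_model=AdrModel(slope=0.0),
        bp_model=BPModel(exposure_coef_bp=0.0),
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subject:
    id: str
    sex: str  # "male" | "female"
    age: float
    height_m: float
    weight_kg: float
    trial: int
    origin: str  # self-reported biogeographic origin label

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2


@dataclass
class GenotypeProfile:
    subject_id: str
    calls: dict[str, tuple[str, str]]  # rsid -> unordered allele pair
    star_truth: dict[str, tuple[str, str]]  # gene -> simulated diplotype
    cyp2d6_cn: int = 2
    phenotypes: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PKTrueParameters:
    drug: str
    cl_f: float  # L/h
    v_f: float   # L
    ka: float    # 1/h
    tlag: float  # h

    @property
    def ke(self) -> float:
        return self.cl_f / self.v_f

    def __post_init__(self) -> None:
        if min(self.cl_f, self.v_f, self.ka) <= 0 or self.tlag < 0:
            raise ValueError("PK parameters must be positive (tlag >= 0)")
        if abs(self.ka - self.ke) < 1e-9:
            raise ValueError("degenerate ka == ke")


@dataclass
class SafetyRecord:
    subject_id: str
    adrs: dict[str, bool]
    sbp: dict[str, float]  # basal / t3h / t6h
    dbp: dict[str, float]
    hr: dict[str, float]
    qtc: dict[str, float]  # basal / t6h


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

_STAGE_CODES = {
    "demographics": 1, "genotypes": 2, "pk_params": 3, "profiles": 4,
    "safety": 5,
}


def derive_rng(master_seed: int, stage: str, *indices: int) -> np.random.Generator:
    """Independent generator for (stage, index...) under one master seed.

    The entropy pool is [master_seed, stage code, indices...], so re-running
    one stage in isolation reproduces exactly the draws of a full run.
    """
    code = _STAGE_CODES[stage]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), code, *map(int, indices)]))


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_tries: int = 10000) -> float:
    if lo >= hi:
        raise ValueError("impossible truncation bounds")
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(f"truncated normal ({mean}, {sd}) on [{lo}, {hi}] did not converge")


def sample_demographics(config: CohortConfig) -> list[Subject]:
    """Draw the cohort roster: sex, age, height, weight, trial, origin.

    Ages are truncated to the eligibility window and weight is re-drawn
    until BMI falls inside the admissible range. Trial membership follows
    the configured enrolment counts, recycled proportionally when
    ``n_subjects`` differs from the catalogue total.
    """
    rng = derive_rng(config.master_seed, "demographics")
    n = config.n_subjects
    n_women = int(round(config.sex_ratio * n))
    sexes = np.array(["female"] * n_women + ["male"] * (n - n_women))
    rng.shuffle(sexes)
    # proportional trial allocation
    trials = list(config.trial_assignments)
    weights = np.array([config.trial_assignments[t]["n"] for t in trials], float)
    counts = np.floor(weights / weights.sum() * n).astype(int)
    remainder = n - counts.sum()
    frac_order = np.argsort(-(weights / weights.sum() * n - counts))
    for i in range(remainder):
        counts[frac_order[i % len(trials)]] += 1
    trial_pool = np.repeat(trials, counts)
    rng.shuffle(trial_pool)

    subjects = []
    for i in range(n):
        sex = str(sexes[i])
        params = config.demographic_params[sex]
        age = _truncated_normal(rng, *params["age"], *config.age_range)
        for _ in range(10000):
            height = _truncated_normal(rng, *params["height"], 1.40, 2.10)
            weight = _truncated_normal(rng, *params["weight"], 35.0, 140.0)
            bmi = weight / height**2
            if config.bmi_range[0] <= bmi <= config.bmi_range[1]:
                break
        else:  # pragma: no cover
            raise ValueError("could not sample admissible BMI")
        origin = "European" if rng.random() < 43 / 64 else "Other"
        subjects.append(
            Subject(
                id=f"S{i + 1:03d}", sex=sex, age=age, height_m=height,
                weight_kg=weight, trial=int(trial_pool[i]), origin=origin,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _sample_locus(rng: np.random.Generator, freqs: Mapping[str, float]) -> tuple[str, str]:
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles], float)
    p = p / p.sum()
    pick = rng.choice(len(alleles), size=2, p=p)
    return (alleles[pick[0]], alleles[pick[1]])


def sample_genotypes(
    subjects: Sequence[Subject],
    variant_freqs: Mapping[str, Mapping[str, float]] | None = None,
    star_freqs: Mapping[str, Mapping[str, float]] | None = None,
    cyp2d6_cn_dist: Mapping[int, float] | None = None,
    master_seed: int = 0,
) -> dict[str, GenotypeProfile]:
    """Hardy-Weinberg genotypes, independent across loci and genes.

    Stand-alone transporter loci are sampled allele-wise per rsID. Star-
    allele genes are sampled haplotype-wise from star-allele frequencies
    (*1 absorbs the remaining mass) and the implied per-locus variant calls
    are emitted, so the diplotype caller sees internally consistent data;
    haplotype-level HWE implies locus-level HWE marginally. CYP2D6 copy
    number is drawn from ``cyp2d6_cn_dist`` (default: always 2).
    """
    variant_freqs = dict(VARIANT_FREQS) if variant_freqs is None else variant_freqs
    star_freqs = dict(STAR_FREQS) if star_freqs is None else star_freqs
    cn_dist = {2: 1.0} if cyp2d6_cn_dist is None else dict(cyp2d6_cn_dist)
    for rsid, freqs in variant_freqs.items():
        if abs(sum(freqs.values()) - 1.0) > 5e-3:
            raise ValueError(f"allele frequencies at {rsid} do not sum to 1")
    cns = sorted(cn_dist)
    cn_p = np.array([cn_dist[c] for c in cns], float)
    cn_p = cn_p / cn_p.sum()

    out: dict[str, GenotypeProfile] = {}
    for idx, subject in enumerate(subjects):
        rng = derive_rng(master_seed, "genotypes", idx)
        calls: dict[str, tuple[str, str]] = {}
        for rsid in sorted(variant_freqs):
            calls[rsid] = _sample_locus(rng, variant_freqs[rsid])
        star_truth: dict[str, tuple[str, str]] = {}
        for gene in sorted(star_freqs):
            freqs = dict(star_freqs[gene])
            rest = 1.0 - sum(freqs.values())
            if rest < -1e-9:
                raise ValueError(f"star-allele frequencies for {gene} exceed 1")
            freqs["*1"] = max(rest, 0.0)
            hap = _sample_locus(rng, freqs)
            star_truth[gene] = tuple(sorted(hap, key=lambda a: (len(a), a)))
            for rsid, ref in _GENE_LOCI[gene].items():
                pair = tuple(
                    _STAR_VARIANTS[gene].get(h, {}).get(rsid, ref) for h in hap
                )
                calls[rsid] = pair
        cn = int(cns[rng.choice(len(cns), p=cn_p)])
        profile = GenotypeProfile(subject.id, calls, star_truth, cyp2d6_cn=cn)
        profile.phenotypes = _true_phenotypes(profile)
        out[subject.id] = profile
    return out


def _true_phenotypes(profile: GenotypeProfile) -> dict[str, str]:
    phen = {}
    for gene, diplo in profile.star_truth.items():
        if gene == "CYP2D6":
            phen[gene] = cyp2d6_phenotype(diplo, profile.cyp2d6_cn).category
        else:
            phen[gene] = function_phenotype(gene, diplo).category
    return phen


# ---------------------------------------------------------------------------
# PK parameters and profiles
# ---------------------------------------------------------------------------

def assign_pk_parameters(
    subject: Subject,
    genotype: GenotypeProfile,
    drug: str,
    effect_sizes: Sequence[CovariateEffect] = (),
    iiv_sd: Mapping[str, float] | None = None,
    master_seed: int = 0,
    subject_index: int = 0,
) -> PKTrueParameters:
    """Individual one-compartment parameters for one subject and drug.

    Population values are scaled proportionally with body weight
    (CL ~ wt/71, V ~ wt/71, so dose/weight correction removes body-size
    effects exactly and half-life is weight-free), multiplied by every
    applicable covariate effect, then jittered with log-normal
    between-subject variability. With all effect multipliers at 1 the
    parameter distribution is covariate-free apart from the weight scaling.
    """
    if drug not in DRUG_PARAMS:
        raise KeyError(f"unknown drug {drug!r}")
    iiv = {"cl_f": 0.0, "v_f": 0.0, "ka": 0.0} if iiv_sd is None else dict(iiv_sd)
    base = DRUG_PARAMS[drug]
    wt = subject.weight_kg / REFERENCE_WEIGHT
    values = {
        "cl_f": base["cl_f"] * wt,
        "v_f": base["v_f"] * wt,
        "ka": base["ka"],
        "tlag": base["tlag"],
    }
    for effect in effect_sizes:
        if effect.drug != drug or not effect.applies(subject, genotype):
            continue
        if effect.parameter == "ke":
            # multiply elimination rate at fixed clearance
            values["v_f"] /= effect.multiplier
        elif effect.parameter in ("cl_f", "v_f", "ka"):
            values[effect.parameter] *= effect.multiplier
        else:
            raise ValueError(f"effect on unknown parameter {effect.parameter!r}")
    drug_code = sorted(DRUG_PARAMS).index(drug)
    rng = derive_rng(master_seed, "pk_params", subject_index, drug_code)
    for name in ("cl_f", "v_f", "ka"):
        sd = iiv.get(name, 0.0)
        if sd > 0:
            values[name] *= math.exp(rng.normal(0.0, sd))
    # exclude the degenerate equal-rate case by construction
    if abs(values["ka"] - values["cl_f"] / values["v_f"]) < 1e-6:
        values["ka"] *= 1.05
    return PKTrueParameters(drug=drug, **values)


def one_compartment_conc(
    params: PKTrueParameters, dose_mg: float, times: np.ndarray
) -> np.ndarray:
    """Noise-free concentrations (ng/mL) of the oral one-compartment model."""
    ke, ka, tlag = params.ke, params.ka, params.tlag
    if abs(ka - ke) < 1e-12:
        raise ValueError("degenerate ka == ke")
    t = np.asarray(times, float)
    if np.any(t < 0):
        raise ValueError("negative times")
    dt = np.maximum(t - tlag, 0.0)
    c0 = dose_mg * 1000.0 / params.v_f  # mg -> ng/mL with V in L
    c = c0 * ka / (ka - ke) * (np.exp(-ke * dt) - np.exp(-ka * dt))
    return np.where(t > tlag, c, 0.0)


def simulate_profile(
    params: PKTrueParameters,
    dose_mg: float,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    lloq: float | None = None,
    error_cv: float = 0.15,
    rng: np.random.Generator | None = None,
    subject_id: str = "S000",
    period: int = 1,
    formulation: str = "R",
    weight_kg: float = REFERENCE_WEIGHT,
) -> ConcentrationProfile:
    """LLOQ-censored noisy concentration-time profile for one period.

    The structural curve is multiplied by i.i.d. log-normal proportional
    error with coefficient of variation ``error_cv``; samples below the
    assay LLOQ are flagged below-quantification, and the pre-dose sample is
    below-quantification by design (single dose, no carry-over).
    """
    t = np.asarray(schedule, float)
    if t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("schedule must start at 0 and strictly increase")
    if dose_mg < 0:
        raise ValueError("negative dose")
    if lloq is None:
        lloq = LLOQ[params.drug]
    rng = np.random.default_rng(0) if rng is None else rng
    c = one_compartment_conc(params, dose_mg, t) if dose_mg > 0 else np.zeros_like(t)
    if error_cv > 0:
        sigma = math.sqrt(math.log(1.0 + error_cv**2))
        c = c * np.exp(rng.normal(0.0, sigma, size=len(t)))
    bloq = (c < lloq) | (t == 0.0)
    return ConcentrationProfile(
        subject_id=subject_id, drug=params.drug, period=period,
        formulation=formulation, dose_mg=dose_mg if dose_mg > 0 else 1.0,
        weight_kg=weight_kg, times=t, concentrations=np.where(bloq, np.nan, c),
        bloq=bloq, lloq=lloq,
    )


# ---------------------------------------------------------------------------
# Safety
# ---------------------------------------------------------------------------

def simulate_safety(
    subject: Subject,
    exposure_z: float,
    adr_model: AdrModel,
    bp_model: BPModel,
    rng: np.random.Generator,
) -> SafetyRecord:
    """ADR labels and haemodynamic records for one subject.

    Each ADR term is an independent Bernoulli draw on the logit scale with
    the subject's standardized log exposure as the linear predictor.
    Blood-pressure/HR changes at t3h and t6h and the QTc change at t6h are
    normal draws around the configured means, with the exposure
    coefficient shifting the BP changes.
    """
    adrs = {}
    for term, intercept in adr_model.intercepts.items():
        if math.isinf(intercept) and intercept < 0:
            p = 0.0
        else:
            logit = intercept + adr_model.slope * exposure_z
            p = 1.0 / (1.0 + math.exp(-logit))
        adrs[term] = bool(rng.random() < p)
    basal = {k: rng.normal(*v) for k, v in bp_model.basal.items()}
    d = {k: rng.normal(*v) for k, v in bp_model.delta.items()}
    bp_shift = bp_model.exposure_coef_bp * exposure_z
    sbp = {"basal": basal["sbp"], "t3h": basal["sbp"] + d["sbp_t3h"] + bp_shift,
           "t6h": basal["sbp"] + d["sbp_t6h"] + bp_shift}
    dbp = {"basal": basal["dbp"], "t3h": basal["dbp"] + d["dbp_t3h"] + bp_shift,
           "t6h": basal["dbp"] + d["dbp_t6h"] + bp_shift}
    hr = {"basal": basal["hr"], "t3h": basal["hr"] + d["hr_t3h"],
          "t6h": basal["hr"] + d["hr_t6h"]}
    qtc = {"basal": basal["qtc"], "t6h": basal["qtc"] + d["qtc_t6h"]}
    return SafetyRecord(subject.id, adrs, sbp, dbp, hr, qtc)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Full synthetic dataset plus simulation ground truth."""

    config: CohortConfig
    subjects: list[Subject]
    genotypes: dict[str, GenotypeProfile]
    profiles: list[ConcentrationProfile]
    safety: list[SafetyRecord]
    true_params: dict[tuple[str, str], PKTrueParameters]  # (subject, drug)

    def demographics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": s.id, "sex": s.sex, "age": round(s.age, 1),
                "height_m": round(s.height_m, 3), "weight_kg": round(s.weight_kg, 1),
                "bmi": round(s.bmi, 2), "trial": s.trial, "origin": s.origin,
            }
            for s in self.subjects
        )

    def genotype_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            g = self.genotypes[s.id]
            for rsid in sorted(g.calls):
                a1, a2 = sorted(g.calls[rsid])
                rows.append({"subject": s.id, "rsid": rsid, "allele1": a1, "allele2": a2})
        return pd.DataFrame(rows)

    def cn_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": s.id, "cyp2d6_cn": self.genotypes[s.id].cyp2d6_cn}
            for s in self.subjects
        )

    def concentration_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            for t, c, b in zip(p.times, p.concentrations, p.bloq):
                rows.append(
                    {
                        "subject": p.subject_id, "drug": p.drug, "period": p.period,
                        "formulation": p.formulation, "dose_mg": p.dose_mg,
                        "weight_kg": round(p.weight_kg, 1), "time_h": t,
                        "conc_ng_ml": "" if b else round(float(c), 4),
                        "bloq_flag": int(b),
                    }
                )
        return pd.DataFrame(rows)

    def safety_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.safety:
            row: dict = {"subject": rec.subject_id}
            for term, hit in rec.adrs.items():
                row[f"adr_{term}"] = int(hit)
            for name, series in (("sbp", rec.sbp), ("dbp", rec.dbp), ("hr", rec.hr), ("qtc", rec.qtc)):
                for tp, val in series.items():
                    row[f"{name}_{tp}"] = round(val, 1)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tables(self, outdir) -> dict[str, str]:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("concentrations", self.concentration_frame()),
            ("demographics", self.demographics_frame()),
            ("genotypes", self.genotype_frame()),
            ("cyp2d6_cn", self.cn_frame()),
            ("safety", self.safety_frame()),
        ):
            sep = "," if name == "concentrations" else "\t"
            ext = "csv" if name == "concentrations" else "tsv"
            path = outdir / f"{name}.{ext}"
            frame.to_csv(path, sep=sep, index=False)
            paths[name] = str(path)
        return paths


def generate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Simulate the whole pooled cohort under one configuration."""
    config = CohortConfig() if config is None else config
    subjects = sample_demographics(config)
    genotypes = sample_genotypes(
        subjects, config.variant_freqs, config.star_freqs,
        config.cyp2d6_cn_dist, config.master_seed,
    )
    profiles: list[ConcentrationProfile] = []
    true_params: dict[tuple[str, str], PKTrueParameters] = {}
    log_auc: dict[str, dict[str, float]] = {}
    for idx, subject in enumerate(subjects):
        design = config.trial_assignments[subject.trial]
        for drug, dose in design["doses"].items():
            params = assign_pk_parameters(
                subject, genotypes[subject.id], drug, config.effect_sizes,
                config.iiv_sd, config.master_seed, idx,
            )
            true_params[(subject.id, drug)] = params
            drug_code = sorted(DRUG_PARAMS).index(drug)
            for per, formulation in enumerate(design["periods"], start=1):
                rng = derive_rng(config.master_seed, "profiles", idx, drug_code, per)
                period_params = params
                if config.iov_sd > 0:
                    period_params = replace(
                        params, cl_f=params.cl_f * math.exp(rng.normal(0, config.iov_sd))
                    )
                profiles.append(
                    simulate_profile(
                        period_params, dose, config.schedule, LLOQ[drug],
                        config.error_cv, rng, subject_id=subject.id,
                        period=per, formulation=formulation,
                        weight_kg=subject.weight_kg,
                    )
                )
            log_auc.setdefault(drug, {})[subject.id] = math.log(dose * 1000.0 / params.cl_f)
    # standardized log exposure, averaged over the subject's drugs
    zscores: dict[str, list[float]] = {s.id: [] for s in subjects}
    for drug, by_subject in log_auc.items():
        vals = np.array(list(by_subject.values()))
        mu, sd = vals.mean(), vals.std(ddof=0) or 1.0
        for sid, v in by_subject.items():
            zscores[sid].append((v - mu) / sd)
    safety = []
    for idx, subject in enumerate(subjects):
        rng = derive_rng(config.master_seed, "safety", idx)
        z = float(np.mean(zscores[subject.id])) if zscores[subject.id] else 0.0
        safety.append(simulate_safety(subject, z, config.adr_model, config.bp_model, rng))
    return SimulatedCohort(config, subjects, genotypes, profiles, safety, true_params)
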