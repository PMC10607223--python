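"""Star-allele diplotype calling and phenotype translation.

Per-subject variant calls (unphased allele pairs per rsID) are matched
against bundled PharmVar-style allele-definition tables to produce a
star-allele diplotype per pharmacogene. Diplotypes are then mapped to the
phenotype categories used as association predictors: the CYP2D6 activity
score with copy-number handling (UM/NM/IM/PM), qualitative function
lookups for the other CYP enzymes and UGT1A1, and the transporter
normal/decreased/poor function classes for SLCO1B1 (NF/DF/PF).

Phasing is unobservable from unphased genotypes, so when several
diplotypes are consistent with the observed allele counts the caller
prefers the one built from alleles defined by the most variants (the
"nested allele" rule, e.g. SLCO1B1 *1/*15 over *5/*37) and flags the
alternatives as ambiguity diagnostics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AlleleDefinitionTable",
    "DiplotypeCall",
    "PhenotypeAssignment",
    "load_definitions",
    "load_functions",
    "call_diplotype",
    "cyp2d6_phenotype",
    "function_phenotype",
    "phenotype_table",
    "analysis_groups",
    "GroupingRule",
]

INDETERMINATE = "indeterminate"

#: CYP2D6 activity-score bins (CPIC-style): score -> metabolizer category.
CYP2D6_SCORE_BINS = (
    (0.0, 0.0, "PM"),
    (0.0, 1.0, "IM"),
    (1.0, 2.25, "NM"),
    (2.25, float("inf"), "UM"),
)

#: Qualitative phenotype rules per gene: sorted pair of function classes -> category.
_FUNCTION_RULES: dict[str, dict[tuple[str, str], str]] = {
    "SLCO1B1": {
        ("normal", "normal"): "NF",
        ("decreased", "normal"): "DF",
        ("decreased", "decreased"): "PF",
    },
    "CYP3A5": {
        ("normal", "normal"): "NM",
        ("none", "normal"): "IM",
        ("none", "none"): "PM",
    },
    "CYP3A4": {
        ("normal", "normal"): "NM",
        ("decreased", "normal"): "IM",
        ("none", "normal"): "IM",
        ("decreased", "decreased"): "PM",
        ("decreased", "none"): "PM",
        ("none", "none"): "PM",
    },
    "CYP2C9": {
        # activity-score style collapsed to classes: 2 -> NM, 1-1.5 -> IM, <=0.5 -> PM
        ("normal", "normal"): "NM",
        ("decreased", "normal"): "IM",
        ("none", "normal"): "IM",
        ("decreased", "decreased"): "IM",
        ("decreased", "none"): "PM",
        ("none", "none"): "PM",
    },
    "CYP2C19": {
        ("normal", "normal"): "NM",
        ("increased", "normal"): "RM",
        ("increased", "increased"): "UM",
        ("none", "normal"): "IM",
        ("increased", "none"): "IM",
        ("none", "none"): "PM",
    },
    "CYP2B6": {
        ("normal", "normal"): "NM",
        ("increased", "normal"): "RM",
        ("increased", "increased"): "RM",
        ("decreased", "normal"): "IM",
        ("decreased", "increased"): "IM",
        ("decreased", "decreased"): "PM",
    },
    "CYP2A6": {
        ("normal", "normal"): "normal",
        ("decreased", "normal"): "intermediate",
        ("decreased", "decreased"): "poor",
    },
    "CYP2C8": {
        ("normal", "normal"): "normal",
        ("decreased", "normal"): "intermediate",
        ("decreased", "decreased"): "poor",
    },
    "UGT1A1": {
        ("normal", "normal"): "NM",
        ("decreased", "normal"): "IM",
        ("decreased", "decreased"): "PM",
    },
}


@dataclass(frozen=True)
class AlleleDefinitionTable:
    """Defining variants per star allele for one gene.

    ``alleles`` maps star-allele name to {rsid: variant allele}; the
    reference allele (*1) is the empty mapping. ``rsids`` is the full set of
    loci that define any allele of the gene.
    """

    gene: str
    alleles: Mapping[str, Mapping[str, str]]
    rsids: frozenset[str]

    def variant_count(self, allele: str) -> int:
        return len(self.alleles[allele])


@dataclass
class DiplotypeCall:
    gene: str
    diplotype: tuple[str, str]  # sorted pair, or (INDETERMINATE, INDETERMINATE)
    ambiguous: bool = False
    alternatives: list[tuple[str, str]] = field(default_factory=list)
    note: str = ""

    @property
    def label(self) -> str:
        if self.diplotype[0] == INDETERMINATE:
            return INDETERMINATE
        return "/".join(self.diplotype)


@dataclass
class PhenotypeAssignment:
    gene: str
    diplotype: str
    category: str
    activity_score: float | None = None


def _read_data_tsv(name: str) -> pd.DataFrame:
    with resources.files("pkpgx.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)


def load_definitions() -> dict[str, AlleleDefinitionTable]:
    """Bundled allele-definition tables, keyed by gene."""
    df = _read_data_tsv("star_allele_definitions.tsv")
    tables: dict[str, AlleleDefinitionTable] = {}
    for gene, sub in df.groupby("gene"):
        alleles: dict[str, dict[str, str]] = {"*1": {}}
        for allele, rows in sub.groupby("allele"):
            alleles[allele] = dict(zip(rows["rsid"], rows["variant_allele"]))
        rsids = frozenset(sub["rsid"])
        tables[gene] = AlleleDefinitionTable(gene=gene, alleles=alleles, rsids=rsids)
    return tables


def load_functions() -> dict[str, dict[str, tuple[str, float | None]]]:
    """Per-allele (function class, activity value) lookups, keyed by gene."""
    df = _read_data_tsv("allele_function.tsv")
    out: dict[str, dict[str, tuple[str, float | None]]] = {}
    for _, row in df.iterrows():
        act = None if pd.isna(row.get("activity")) else float(row["activity"])
        out.setdefault(row["gene"], {})[row["allele"]] = (row["function"], act)
    return out


_DEFINITIONS = None
_FUNCTIONS = None


def _definitions() -> dict[str, AlleleDefinitionTable]:
    global _DEFINITIONS
    if _DEFINITIONS is None:
        _DEFINITIONS = load_definitions()
    return _DEFINITIONS


def _functions() -> dict[str, dict[str, tuple[str, float | None]]]:
    global _FUNCTIONS
    if _FUNCTIONS is None:
        _FUNCTIONS = load_functions()
    return _FUNCTIONS


# ---------------------------------------------------------------------------
# Diplotype calling
# ---------------------------------------------------------------------------

def _pair_sort_key(defs: AlleleDefinitionTable, pair: tuple[str, str]):
    # nested-allele preference: pairs containing the allele defined by the
    # most variants rank first; ties broken by total variant count, then name
    counts = sorted((defs.variant_count(a) for a in pair), reverse=True)
    return (-counts[0], -(counts[0] + counts[1]), pair)


def call_diplotype(
    gene: str,
    variant_calls: Mapping[str, tuple[str, str] | None],
    definitions: Mapping[str, AlleleDefinitionTable] | None = None,
) -> DiplotypeCall:
    """Resolve the star-allele pair consistent with observed allele counts.

    ``variant_calls`` maps rsID to an unordered allele pair (or None for an
    explicitly missing call). Every combination of two defined alleles
    (including the implicit reference *1) whose summed defining-variant
    counts reproduce the observed variant-allele counts at every defining
    locus is a candidate; the nested-allele rule picks the winner and any
    other candidates are reported as alternatives. Missing calls at defining
    loci, or counts no pair can produce, yield an indeterminate call.
    """
    defs = (definitions or _definitions())[gene]
    missing = [rs for rs in defs.rsids if variant_calls.get(rs) is None]
    if missing:
        return DiplotypeCall(
            gene, (INDETERMINATE, INDETERMINATE),
            note=f"missing calls at {sorted(missing)}",
        )
    # observed count of each allele's defining variant allele, per locus
    obs: dict[str, dict[str, int]] = {}
    for rs in defs.rsids:
        a1, a2 = variant_calls[rs]
        counts: dict[str, int] = {}
        for a in (a1, a2):
            counts[a] = counts.get(a, 0) + 1
        obs[rs] = counts

    def implied(pair: tuple[str, str]) -> dict[str, dict[str, int]]:
        acc: dict[str, dict[str, int]] = {rs: {} for rs in defs.rsids}
        for allele in pair:
            for rs, var in defs.alleles[allele].items():
                acc[rs][var] = acc[rs].get(var, 0) + 1
        return acc

    def consistent(pair: tuple[str, str]) -> bool:
        imp = implied(pair)
        for rs in defs.rsids:
            for var, n in imp[rs].items():
                if obs[rs].get(var, 0) != n:
                    return False
            # variant alleles observed but not implied must be absent
            for var, n in obs[rs].items():
                if var not in imp[rs] and _is_variant_allele(defs, rs, var) and n > 0:
                    return False
        return True

    names = sorted(defs.alleles)
    candidates = [
        tuple(sorted(p))
        for p in itertools.combinations_with_replacement(names, 2)
        if consistent(tuple(sorted(p)))
    ]
    candidates = sorted(set(candidates), key=lambda p: _pair_sort_key(defs, p))
    if not candidates:
        return DiplotypeCall(
            gene, (INDETERMINATE, INDETERMINATE),
            note="allele counts inconsistent with any defined diplotype",
        )
    best = candidates[0]
    return DiplotypeCall(
        gene, best,
        ambiguous=len(candidates) > 1,
        alternatives=candidates[1:],
    )


def _is_variant_allele(defs: AlleleDefinitionTable, rsid: str, allele: str) -> bool:
    return any(v.get(rsid) == allele for v in defs.alleles.values())


# ---------------------------------------------------------------------------
# Phenotype translation
# ---------------------------------------------------------------------------

def cyp2d6_phenotype(diplotype: tuple[str, str] | str, copy_number: int = 2) -> PhenotypeAssignment:
    """CYP2D6 metabolizer category from the activity score.

    The score sums the two alleles' activity values; copy-number events
    rescale it: a whole-gene deletion (copy number 1) leaves the remaining
    (higher-activity) allele, copy number 0 scores 0, and each extra copy
    beyond two duplicates the higher-activity allele.
    """
    if isinstance(diplotype, str):
        diplotype = tuple(diplotype.split("/"))  # type: ignore[assignment]
    if copy_number < 0 or int(copy_number) != copy_number:
        raise ValueError("copy number must be a non-negative integer")
    if diplotype[0] == INDETERMINATE:
        return PhenotypeAssignment("CYP2D6", INDETERMINATE, INDETERMINATE, None)
    funcs = _functions()["CYP2D6"]
    try:
        acts = [funcs[a][1] for a in diplotype]
    except KeyError as exc:
        raise KeyError(f"no activity value for CYP2D6 allele {exc}") from exc
    if any(a is None for a in acts):
        raise ValueError("CYP2D6 allele without activity value")
    if copy_number == 0:
        score = 0.0
    elif copy_number == 1:
        score = max(acts)  # hemizygous: the surviving copy
    else:
        score = sum(acts) + (copy_number - 2) * max(acts)
    for lo, hi, cat in CYP2D6_SCORE_BINS:
        if (score == 0.0 and cat == "PM") or (lo < score <= hi):
            break
    else:  # pragma: no cover - bins span [0, inf)
        cat = INDETERMINATE
    label = "/".join(diplotype) + (f" (CN={copy_number})" if copy_number != 2 else "")
    return PhenotypeAssignment("CYP2D6", label, cat, score)


def function_phenotype(gene: str, diplotype: tuple[str, str] | str) -> PhenotypeAssignment:
    """Qualitative phenotype from the two alleles' function classes."""
    if isinstance(diplotype, str):
        diplotype = tuple(diplotype.split("/"))  # type: ignore[assignment]
    if gene not in _FUNCTION_RULES:
        raise KeyError(f"no phenotype rules for gene {gene!r}")
    if diplotype[0] == INDETERMINATE:
        return PhenotypeAssignment(gene, INDETERMINATE, INDETERMINATE)
    funcs = _functions()[gene]
    try:
        classes = tuple(sorted(funcs[a][0] for a in diplotype))
    except KeyError as exc:
        raise KeyError(f"no function class for {gene} allele {exc}") from exc
    cat = _FUNCTION_RULES[gene].get(classes)
    if cat is None:
        return PhenotypeAssignment(gene, "/".join(diplotype), INDETERMINATE)
    return PhenotypeAssignment(gene, "/".join(diplotype), cat)


def phenotype_table(
    genotypes: Mapping[str, Mapping[str, tuple[str, str] | None]],
    copy_numbers: Mapping[str, int] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Call diplotypes and phenotypes for a cohort.

    ``genotypes`` maps subject id -> {rsid: allele pair}; ``copy_numbers``
    maps subject id -> CYP2D6 copy number (default 2). Returns one row per
    subject x gene with diplotype, category and (for CYP2D6) activity score.
    """
    defs = _definitions()
    genes = list(genes) if genes is not None else sorted(defs)
    rows = []
    for subject, calls in genotypes.items():
        for gene in genes:
            dc = call_diplotype(gene, calls, defs)
            if gene == "CYP2D6":
                cn = int((copy_numbers or {}).get(subject, 2))
                if dc.diplotype[0] == INDETERMINATE:
                    pa = PhenotypeAssignment(gene, INDETERMINATE, INDETERMINATE, None)
                else:
                    pa = cyp2d6_phenotype(dc.diplotype, cn)
            else:
                pa = function_phenotype(gene, dc.diplotype)
            rows.append(
                {
                    "subject": subject,
                    "gene": gene,
                    "diplotype": dc.label,
                    "phenotype": pa.category,
                    "activity_score": pa.activity_score,
                    "ambiguous": dc.ambiguous,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analysis grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupingRule:
    """Merge categorical levels into an analysis coding.

    ``mapping`` sends source levels to merged labels; unmapped levels keep
    their own label. ``reference`` names the reference level of the merged
    coding (e.g. genotype T/T against the merged T/G+G/A+G/G group).
    """

    source: str
    name: str
    mapping: Mapping[str, str]
    reference: str | None = None


def analysis_groups(
    table: pd.DataFrame,
    rules: Sequence[GroupingRule] = (),
    min_group_n: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Emit merged predictor columns alongside the full categorical coding.

    Returns the augmented table and a list of warnings for merged groups
    smaller than ``min_group_n``.
    """
    out = table.copy()
    warnings: list[str] = []
    for rule in rules:
        if rule.source not in out.columns:
            raise KeyError(f"grouping rule references unknown column {rule.source!r}")
        levels = set(out[rule.source].dropna().astype(str))
        unknown = set(rule.mapping) - levels
        if unknown:
            raise KeyError(
                f"grouping rule {rule.name!r} references unknown levels {sorted(unknown)}"
            )
        col = out[rule.source].astype(str).map(lambda v: rule.mapping.get(v, v))
        out[rule.name] = col
        for level, n in col.value_counts().items():
            if n < min_group_n:
                warnings.append(f"{rule.name}: group {level!r} has n={n} < {min_group_n}")
    return out, warnings
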