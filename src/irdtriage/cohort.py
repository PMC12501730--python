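"""Per-patient case solving and cohort-level summary statistics.

A panel report lists patient-variant rows; turning those into "n patients
molecularly diagnosed" requires an explicit genotype rule.  The rule used
here (documented, and echoed per patient in the output) is:

a. a homozygous or hemizygous P/LP record solves the patient;
b. two or more heterozygous P/LP records in one gene with autosomal
   recessive inheritance solve the patient as a presumed compound
   heterozygote (phase is assumed in trans and flagged as assumed —
   panel tables carry no phasing);
c. one heterozygous P/LP record in a gene with autosomal dominant
   inheritance solves the patient.

Patients whose only P/LP records are single heterozygous hits in
recessive-only genes remain unsolved carriers; this is exactly how a
97-row variant table can correspond to a smaller diagnosed-patient count.

Percentages are rounded half-up (two decimals for shares, nearest integer
for the headline diagnostic yield) to match how diagnostic studies print
them.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .acmg import Classification, CombinerConfig, classify
from .variant_model import (
    ConsequenceType,
    VariantRecord,
    Zygosity,
    normalize_hgvs_text,
)

__all__ = [
    "SolvingRule",
    "SolvedCase",
    "CohortSummary",
    "round_half_up",
    "solve_cases",
    "diagnostic_yield",
    "pathogenicity_distribution",
    "variant_type_distribution",
    "gene_distribution",
    "recurrence",
    "flag_novel",
    "NovelMatchError",
    "reconstruct_counts_from_percentages",
    "build_summary",
    "render_summary",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), like printed clinical tables."""
    q = Decimal(1).scaleb(-ndigits)
    out = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(out) if ndigits else int(out)


def _pct(num: int, den: int) -> float:
    return round_half_up(100.0 * num / den, 2) if den else 0.0


class SolvingRule(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    COMPOUND_HET_AR = "compound_het_AR"
    HETEROZYGOUS_AD = "heterozygous_AD"


@dataclass
class SolvedCase:
    patient_id: str
    solving_rule: SolvingRule
    solving_records: list[VariantRecord]
    phase_assumed: bool = False  # True for presumed compound heterozygotes


def _is_causal_class(rec: VariantRecord, engine: Optional[CombinerConfig]) -> bool:
    if engine is None:
        # trust the reported classification when present
        return rec.reported_class in ("P", "LP")
    return classify(rec.criteria, engine) >= Classification.LP


def solve_cases(
    records: Sequence[VariantRecord],
    engine_config: Optional[CombinerConfig] = None,
) -> tuple[list[SolvedCase], list[str]]:
    """Apply the case-solving rule; returns (solved cases, unsolved carrier ids).

    Only P/LP records count — by reported class when ``engine_config`` is
    None, otherwise by the engine's own classification.  Rules are tried in
    the order homozygous/hemizygous, compound het, dominant het; a patient
    is solved by the first that applies.
    """
    by_patient: dict[str, list[VariantRecord]] = defaultdict(list)
    for rec in records:
        if _is_causal_class(rec, engine_config):
            by_patient[rec.patient_id].append(rec)

    solved: list[SolvedCase] = []
    carriers: list[str] = []
    for pid in by_patient:
        recs = by_patient[pid]
        case = _solve_one(pid, recs)
        if case is not None:
            solved.append(case)
        else:
            carriers.append(pid)
    return solved, carriers


def _solve_one(pid: str, recs: list[VariantRecord]) -> Optional[SolvedCase]:
    # rule (a): homozygous or hemizygous causal genotype
    for rec in recs:
        if rec.zygosity is Zygosity.HOMOZYGOUS:
            return SolvedCase(pid, SolvingRule.HOMOZYGOUS, [rec])
        if rec.zygosity is Zygosity.HEMIZYGOUS:
            return SolvedCase(pid, SolvingRule.HEMIZYGOUS, [rec])
    # rule (b): >=2 heterozygous records in one AR-capable gene
    by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    for rec in recs:
        if rec.zygosity is Zygosity.HETEROZYGOUS:
            by_gene[rec.gene].append(rec)
    for gene, group in by_gene.items():
        if len(group) >= 2 and any("AR" in r.inheritance_modes for r in group):
            return SolvedCase(pid, SolvingRule.COMPOUND_HET_AR, group, phase_assumed=True)
    # rule (c): heterozygous record in an AD-capable gene
    for rec in recs:
        if rec.zygosity is Zygosity.HETEROZYGOUS and "AD" in rec.inheritance_modes:
            return SolvedCase(pid, SolvingRule.HETEROZYGOUS_AD, [rec])
    return None


def diagnostic_yield(
    solved: Sequence[SolvedCase], n_cohort: int
) -> tuple[int, float, int]:
    """(n_solved, raw percentage, integer-rounded percentage) of the cohort."""
    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    n_solved = len({c.patient_id for c in solved})
    if n_solved > n_cohort:
        raise ValueError("more solved patients than cohort members")
    raw = 100.0 * n_solved / n_cohort
    return n_solved, round_half_up(raw, 2), int(round_half_up(raw, 0))


def pathogenicity_distribution(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Counts and two-decimal percentages per reported class."""
    classed = [r for r in records if r.reported_class is not None]
    counts = pd.Series([r.reported_class for r in classed]).value_counts() if classed else pd.Series(dtype=int)
    rows = [
        {"class": cls, "count": int(counts.get(cls, 0)), "pct": _pct(int(counts.get(cls, 0)), len(classed))}
        for cls in ("P", "LP", "VUS", "LB", "B")
        if counts.get(cls, 0) or cls in ("P", "LP")
    ]
    return pd.DataFrame(rows, columns=["class", "count", "pct"])


def variant_type_distribution(
    records: Sequence[VariantRecord],
    splice_window: int = 20,
    expected: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Counts and percentages per consequence class.

    When an ``expected`` count table is supplied (e.g. the totals a report
    printed), any class whose computed count differs is flagged in the
    ``divergent`` column — divergence is surfaced, never reconciled away.
    """
    cons = [r.consequence(splice_window).value for r in records]
    counts = pd.Series(cons).value_counts() if cons else pd.Series(dtype=int)
    seen = {c.value for c in ConsequenceType}
    keys = [c.value for c in ConsequenceType if counts.get(c.value, 0) > 0]
    if expected:
        keys += [k for k in expected if k not in keys and k in seen]
    rows = []
    for key in keys:
        n = int(counts.get(key, 0))
        row = {"consequence": key, "count": n, "pct": _pct(n, len(cons))}
        if expected is not None:
            exp = expected.get(key)
            row["expected"] = exp
            row["divergent"] = exp is not None and exp != n
        rows.append(row)
    cols = ["consequence", "count", "pct"] + (["expected", "divergent"] if expected is not None else [])
    return pd.DataFrame(rows, columns=cols)


def gene_distribution(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Per-gene variant-row and distinct-patient counts, descending; ties alphabetical."""
    rows_per_gene: dict[str, int] = defaultdict(int)
    patients_per_gene: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        rows_per_gene[rec.gene] += 1
        patients_per_gene[rec.gene].add(rec.patient_id)
    frame = pd.DataFrame(
        [
            {"gene": g, "n_variant_rows": rows_per_gene[g], "n_patients": len(patients_per_gene[g])}
            for g in rows_per_gene
        ],
        columns=["gene", "n_variant_rows", "n_patients"],
    )
    return frame.sort_values(
        ["n_variant_rows", "gene"], ascending=[False, True], ignore_index=True
    )


def recurrence(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Distinct-patient count per (gene, normalized cDNA); duplicates count once."""
    patients: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in records:
        patients[(rec.gene, rec.normalized_cdna)].add(rec.patient_id)
    frame = pd.DataFrame(
        [
            {"gene": g, "cdna": c, "n_patients": len(p)}
            for (g, c), p in patients.items()
        ],
        columns=["gene", "cdna", "n_patients"],
    )
    return frame.sort_values(
        ["n_patients", "gene", "cdna"], ascending=[False, True, True], ignore_index=True
    )


class NovelMatchError(ValueError):
    """A novel-list row failed to match exactly one cohort record."""


def flag_novel(
    records: Sequence[VariantRecord],
    novel_list: Iterable[tuple[str, str, str]],
) -> list[VariantRecord]:
    """Set the novelty flag by matching (patient_id, gene, normalized cDNA).

    Every novel-list entry must match exactly one record; unmatched or
    multiply-matched entries raise :class:`NovelMatchError` naming them —
    a silent drop would corrupt the novelty count.
    """
    index: dict[tuple[str, str, str], list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        index[(rec.patient_id, rec.gene, rec.normalized_cdna)].append(i)
    problems = []
    hits: set[int] = set()
    for pid, gene, cdna in novel_list:
        key = (pid, gene, normalize_hgvs_text(cdna))
        matched = index.get(key, [])
        if len(matched) != 1:
            problems.append(f"{key}: {len(matched)} matches")
        else:
            hits.add(matched[0])
    if problems:
        raise NovelMatchError("novel-list reconciliation failed: " + "; ".join(problems))
    for i, rec in enumerate(records):
        rec.novel = i in hits
    return list(records)


def reconstruct_counts_from_percentages(
    group_table: Sequence[tuple[int, float]],
) -> int:
    """Recover an absolute count from per-subgroup (n, percentage) rows.

    Each subgroup contributes ``round_half_up(n * pct / 100)``; summing the
    per-subgroup integers reproduces the count a table's percentages encode.
    """
    total = 0
    for n, pct in group_table:
        if not 0 <= pct <= 100:
            raise ValueError(f"percentage {pct} outside [0, 100]")
        total += int(round_half_up(n * pct / 100.0, 0))
    return total


@dataclass
class CohortSummary:
    n_cohort: int
    solved: list[SolvedCase]
    carriers: list[str]
    n_solved: int
    yield_pct_raw: float
    yield_pct_rounded: int
    pathogenicity: pd.DataFrame
    variant_types: pd.DataFrame
    genes: pd.DataFrame
    recurrence_table: pd.DataFrame
    n_variants: int = 0
    n_novel: int = 0


def build_summary(
    records: Sequence[VariantRecord],
    n_cohort: int,
    splice_window: int = 20,
    expected_types: Optional[dict[str, int]] = None,
) -> CohortSummary:
    """Compose the full cohort summary from a reported-variant table."""
    solved, carriers = solve_cases(records)
    n_solved, raw, rounded = diagnostic_yield(solved, n_cohort)
    return CohortSummary(
        n_cohort=n_cohort,
        solved=solved,
        carriers=carriers,
        n_solved=n_solved,
        yield_pct_raw=raw,
        yield_pct_rounded=rounded,
        pathogenicity=pathogenicity_distribution(records),
        variant_types=variant_type_distribution(records, splice_window, expected_types),
        genes=gene_distribution(records),
        recurrence_table=recurrence(records),
        n_variants=len(records),
        n_novel=sum(r.novel for r in records),
    )


def render_summary(summary: CohortSummary) -> str:
    """Deterministic plain-text report mirroring the headline panels."""
    lines = [
        "Cohort summary",
        "==============",
        f"cohort size\t{summary.n_cohort}",
        f"reported variants\t{summary.n_variants}",
        f"novel variants\t{summary.n_novel}",
        f"solved patients\t{summary.n_solved}",
        f"diagnostic yield\t{summary.yield_pct_raw:.2f}%\t(rounded {summary.yield_pct_rounded}%)",
        f"unsolved carriers\t{len(summary.carriers)}",
        "",
        "Pathogenicity classification",
    ]
    for _, r in summary.pathogenicity.iterrows():
        lines.append(f"{r['class']}\t{r['count']}\t{r['pct']:.2f}%")
    lines += ["", "Variant types"]
    for _, r in summary.variant_types.iterrows():
        line = f"{r['consequence']}\t{r['count']}\t{r['pct']:.2f}%"
        if "divergent" in summary.variant_types.columns and bool(r.get("divergent")):
            line += f"\t[differs from supplied expected count {int(r['expected'])}]"
        lines.append(line)
    lines += ["", "Top genes (variant rows / patients)"]
    for _, r in summary.genes.head(10).iterrows():
        lines.append(f"{r['gene']}\t{r['n_variant_rows']}\t{r['n_patients']}")
    lines.append(f"distinct genes\t{len(summary.genes)}")
    return "\n".join(lines) + "\n"
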