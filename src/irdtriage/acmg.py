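"""ACMG/AMP evidence combination into a five-tier classification.

Two modes are provided.  ``richards`` applies the guideline's rule table
at face-value strengths (no strength modulation: PM2 counts as moderate,
PVS1 is never downgraded, because panel reports print only the bare
tokens).  ``points`` applies the Bayesian points convention: exponents of
a strength ladder summed with sign, benign stand-alone evidence
short-circuiting to Benign.

A reconciliation helper compares engine output against classifications a
report printed; discordances are a measured quantity, never silently
absorbed, because commercial scoring engines apply internal strength
adjustments a published token string does not expose.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import pandas as pd

from .variant_model import (
    CriteriaSet,
    EvidenceCategory,
    EvidenceStrength,
    VariantRecord,
    format_criteria,
)

__all__ = [
    "Classification",
    "CombinerMode",
    "ConflictPolicy",
    "CombinerConfig",
    "combine_richards",
    "combine_points",
    "classify",
    "ReconciliationReport",
    "reconcile_with_reported",
]


class Classification(enum.IntEnum):
    """Five-tier pathogenicity call, ordered by strength toward pathogenic."""

    B = 0
    LB = 1
    VUS = 2
    LP = 3
    P = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class CombinerMode(str, enum.Enum):
    RICHARDS = "richards"
    POINTS = "points"


class ConflictPolicy(str, enum.Enum):
    """What to do when pathogenic and benign combinations both fire."""

    STRICT = "strict"  # conflicting evidence -> VUS
    PATHOGENIC_DOMINANT = "pathogenic_dominant"  # keep the pathogenic-side call


DEFAULT_POINT_WEIGHTS: dict[EvidenceStrength, int] = {
    EvidenceStrength.VERY_STRONG: 8,
    EvidenceStrength.STRONG: 4,
    EvidenceStrength.MODERATE: 2,
    EvidenceStrength.SUPPORTING: 1,
}
# benign-side magnitudes; BA1 (stand-alone) disqualifies rather than scores
DEFAULT_BENIGN_WEIGHTS: dict[EvidenceStrength, int] = {
    EvidenceStrength.STRONG: -4,
    EvidenceStrength.SUPPORTING: -1,
}
# thresholds partition the integers: P >= 10, LP 6..9, VUS 0..5, LB -6..-1, B <= -7
DEFAULT_POINT_THRESHOLDS: dict[str, int] = {"P": 10, "LP": 6, "VUS": 0, "LB": -6}


@dataclass
class CombinerConfig:
    mode: CombinerMode = CombinerMode.RICHARDS
    conflict_policy: ConflictPolicy = ConflictPolicy.PATHOGENIC_DOMINANT
    point_weights: dict[EvidenceStrength, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_POINT_WEIGHTS)
    )
    benign_point_weights: dict[EvidenceStrength, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_BENIGN_WEIGHTS)
    )
    point_thresholds: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_POINT_THRESHOLDS)
    )


def _strength_counts(criteria: CriteriaSet, category: EvidenceCategory):
    counts = {s: 0 for s in EvidenceStrength}
    for code in criteria:
        if code.category is category:
            counts[code.strength] += 1
    return counts


def _pathogenic_tier(criteria: CriteriaSet) -> Classification:
    """Pathogenic-side rule table; returns P, LP or VUS ignoring benign codes."""
    c = _strength_counts(criteria, EvidenceCategory.PATHOGENIC)
    pvs = c[EvidenceStrength.VERY_STRONG]
    ps = c[EvidenceStrength.STRONG]
    pm = c[EvidenceStrength.MODERATE]
    pp = c[EvidenceStrength.SUPPORTING]
    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    if pathogenic:
        return Classification.P
    likely = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    return Classification.LP if likely else Classification.VUS


def _benign_tier(criteria: CriteriaSet) -> Classification:
    """Benign-side rule table; returns B, LB or VUS ignoring pathogenic codes."""
    c = _strength_counts(criteria, EvidenceCategory.BENIGN)
    ba = c[EvidenceStrength.STAND_ALONE]
    bs = c[EvidenceStrength.STRONG]
    bp = c[EvidenceStrength.SUPPORTING]
    if ba >= 1 or bs >= 2:
        return Classification.B
    if (bs == 1 and bp >= 1) or bp >= 2:
        return Classification.LB
    return Classification.VUS


def combine_richards(
    criteria: CriteriaSet,
    conflict_policy: ConflictPolicy = ConflictPolicy.PATHOGENIC_DOMINANT,
) -> Classification:
    """Combine evidence codes by the guideline rule table.

    Conflicting evidence: under the ``strict`` policy, any co-occurrence of
    pathogenic-side and benign-side codes is contradictory and yields VUS.
    Under ``pathogenic_dominant`` a firing pathogenic-side combination wins
    over benign evidence — which is how panel reports that print e.g. BS2
    alongside a Pathogenic call have evidently resolved the conflict.
    """
    path = _pathogenic_tier(criteria)
    ben = _benign_tier(criteria)
    path_fired = path is not Classification.VUS
    ben_fired = ben is not Classification.VUS
    has_path = any(c.category is EvidenceCategory.PATHOGENIC for c in criteria)
    has_ben = any(c.category is EvidenceCategory.BENIGN for c in criteria)
    if conflict_policy is ConflictPolicy.STRICT and has_path and has_ben:
        # contradictory evidence categories -> uncertain significance
        return Classification.VUS
    if path_fired:
        return path
    if ben_fired:
        return ben
    return Classification.VUS


def combine_points(
    criteria: CriteriaSet, config: Optional[CombinerConfig] = None
) -> tuple[int, Classification]:
    """Sum signed evidence points and classify by threshold bands.

    Benign stand-alone evidence (BA1) short-circuits to Benign regardless
    of any pathogenic points.
    """
    config = config or CombinerConfig(mode=CombinerMode.POINTS)
    total = 0
    stand_alone_benign = False
    for code in criteria:
        if code.category is EvidenceCategory.PATHOGENIC:
            total += config.point_weights[code.strength]
        elif code.strength is EvidenceStrength.STAND_ALONE:
            stand_alone_benign = True
        else:
            total += config.benign_point_weights[code.strength]
    if stand_alone_benign:
        return (total, Classification.B)
    t = config.point_thresholds
    if total >= t["P"]:
        cls = Classification.P
    elif total >= t["LP"]:
        cls = Classification.LP
    elif total >= t["VUS"]:
        cls = Classification.VUS
    elif total >= t["LB"]:
        cls = Classification.LB
    else:
        cls = Classification.B
    return (total, cls)


def classify(criteria: CriteriaSet, config: Optional[CombinerConfig] = None) -> Classification:
    """Classify under the configured mode (rule table by default)."""
    config = config or CombinerConfig()
    if config.mode is CombinerMode.POINTS:
        return combine_points(criteria, config)[1]
    return combine_richards(criteria, config.conflict_policy)


@dataclass
class ReconciliationReport:
    """Engine-vs-reported comparison for a batch of records."""

    rows: pd.DataFrame  # patient_id, gene, cdna, criteria, engine_class, reported_class, concordant, detail
    n_concordant: int
    n_discordant: int
    n_uninformative: int

    @property
    def discordant_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["concordant"] == False]  # noqa: E712

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def reconcile_with_reported(
    records: Sequence[VariantRecord], config: Optional[CombinerConfig] = None
) -> ReconciliationReport:
    """Compare the engine's classification with each record's reported class.

    Records without a reported class are listed as uninformative and counted
    in neither bucket.  The aggregate satisfies
    ``n_concordant + n_discordant + n_uninformative == len(records)``.
    """
    config = config or CombinerConfig()
    rows = []
    n_con = n_dis = n_unk = 0
    for rec in records:
        if config.mode is CombinerMode.POINTS:
            total, engine = combine_points(rec.criteria, config)
            detail = f"points={total}"
        else:
            engine = combine_richards(rec.criteria, config.conflict_policy)
            detail = f"rule_table/{config.conflict_policy.value}"
        if rec.reported_class is None:
            concordant = None
            n_unk += 1
        else:
            concordant = engine.name == rec.reported_class
            n_con += concordant
            n_dis += not concordant
        rows.append(
            {
                "patient_id": rec.patient_id,
                "gene": rec.gene,
                "cdna": rec.normalized_cdna,
                "criteria": format_criteria(rec.criteria),
                "engine_class": engine.name,
                "reported_class": rec.reported_class or "",
                "concordant": concordant,
                "detail": detail,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "gene", "cdna", "criteria",
            "engine_class", "reported_class", "concordant", "detail",
        ],
    )
    return ReconciliationReport(frame, n_con, n_dis, n_unk)
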