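"""Step-wise triage of annotated panel calls.

The cascade mirrors a clinical rare-variant workflow: read-support (VAF)
filter, population-frequency filter against up to three databases,
ClinVar benign exclusion, then consequence-class selection (including the
splice-window rule for intronic calls and the splice-predictor rescue for
synonymous calls).  Every stage is an independent predicate over a single
call, so the surviving set does not depend on stage order; the funnel
report records per-stage removals for auditability.

Boundary conventions are inclusive except where the source wording says
"below": VAF exactly 15% is analyzed, a QC ratio of exactly 1.8 or 2.2
passes, but a population frequency equal to the 0.1% threshold is removed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .acmg import Classification, CombinerConfig, classify
from .variant_model import ConsequenceType, VariantRecord

__all__ = [
    "ClinvarAssertion",
    "SplicePrediction",
    "AnnotatedCall",
    "SampleQC",
    "QCResult",
    "CascadeConfig",
    "SynonymousRescue",
    "FunnelStage",
    "FunnelReport",
    "qc_sample",
    "filter_vaf",
    "filter_population_frequency",
    "filter_clinvar",
    "filter_consequence_class",
    "run_cascade",
    "report_clinically_relevant",
    "STAGE_NAMES",
]


class ClinvarAssertion(str, enum.Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"
    CONFLICTING = "conflicting"
    NONE = "none"


class SplicePrediction(str, enum.Enum):
    AFFECTS = "affects"
    NO_EFFECT = "no_effect"
    UNAVAILABLE = "unavailable"


@dataclass
class AnnotatedCall:
    """A pre-triage call: variant record plus the annotations the filters use."""

    core: VariantRecord
    variant_fraction: Optional[float] = None
    freq_gnomad: Optional[float] = None
    freq_1000g: Optional[float] = None
    freq_esp: Optional[float] = None
    clinvar_assertion: ClinvarAssertion = ClinvarAssertion.NONE
    splice_pred_mt: SplicePrediction = SplicePrediction.UNAVAILABLE
    splice_pred_hsf: SplicePrediction = SplicePrediction.UNAVAILABLE
    consequence: Optional[ConsequenceType] = None

    def __post_init__(self) -> None:
        for name in ("variant_fraction", "freq_gnomad", "freq_1000g", "freq_esp"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def call_id(self) -> str:
        return f"{self.core.patient_id}:{self.core.gene}:{self.core.normalized_cdna}"

    def frequencies(self) -> list[float]:
        return [
            f for f in (self.freq_gnomad, self.freq_1000g, self.freq_esp) if f is not None
        ]

    def get_consequence(self, splice_window: int = 20) -> ConsequenceType:
        if self.consequence is not None:
            return self.consequence
        return self.core.consequence(splice_window)


@dataclass(frozen=True)
class SampleQC:
    """Spectrophotometric DNA-quality readings for one sample."""

    a260_280: float
    a260_230: float
    mass_ng: float  # in the standard 15 uL input volume

    def __post_init__(self) -> None:
        if min(self.a260_280, self.a260_230, self.mass_ng) < 0:
            raise ValueError("sample QC values must be non-negative")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def qc_sample(qc: SampleQC) -> QCResult:
    """Accept a DNA sample iff both purity ratios lie in [1.8, 2.2] and mass >= 100 ng."""
    reasons = []
    if not 1.8 <= qc.a260_280 <= 2.2:
        reasons.append(f"a260_280={qc.a260_280} outside [1.8, 2.2]")
    if not 1.8 <= qc.a260_230 <= 2.2:
        reasons.append(f"a260_230={qc.a260_230} outside [1.8, 2.2]")
    if qc.mass_ng < 100:
        reasons.append(f"mass_ng={qc.mass_ng} below 100")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


class SynonymousRescue(str, enum.Enum):
    # all_predictors: remove only when every available predictor says no_effect
    ALL_PREDICTORS = "all_predictors"
    # any_predictor: one no_effect prediction suffices to remove
    ANY_PREDICTOR = "any_predictor"


@dataclass
class CascadeConfig:
    vaf_min: float = 0.15
    vaf_max: float = 1.0
    maf_threshold: float = 0.001
    splice_window: int = 20
    synonymous_rescue: SynonymousRescue = SynonymousRescue.ALL_PREDICTORS
    missing_frequency_passes: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.vaf_min <= self.vaf_max <= 1:
            raise ValueError("require 0 <= vaf_min <= vaf_max <= 1")
        if not 0 < self.maf_threshold < 1:
            raise ValueError("maf_threshold must lie in (0, 1)")


Removal = tuple[AnnotatedCall, str]


def filter_vaf(
    calls: Sequence[AnnotatedCall], config: Optional[CascadeConfig] = None
) -> tuple[list[AnnotatedCall], list[Removal]]:
    """Keep calls with variant fraction in [vaf_min, vaf_max], inclusive."""
    config = config or CascadeConfig()
    kept, removed = [], []
    for call in calls:
        vf = call.variant_fraction
        if vf is None:
            removed.append((call, "missing_vaf"))
        elif config.vaf_min <= vf <= config.vaf_max:
            kept.append(call)
        else:
            removed.append((call, f"vaf={vf} outside [{config.vaf_min}, {config.vaf_max}]"))
    return kept, removed


def filter_population_frequency(
    calls: Sequence[AnnotatedCall], config: Optional[CascadeConfig] = None
) -> tuple[list[AnnotatedCall], list[Removal]]:
    """Keep rare calls: max frequency over available databases strictly below threshold.

    Calls absent from every database are kept when
    ``missing_frequency_passes`` (a triage for rare disease must not discard
    unobserved variants).
    """
    config = config or CascadeConfig()
    kept, removed = [], []
    for call in calls:
        freqs = call.frequencies()
        if not freqs:
            if config.missing_frequency_passes:
                kept.append(call)
            else:
                removed.append((call, "no_population_frequency"))
        elif max(freqs) < config.maf_threshold:
            kept.append(call)
        else:
            removed.append(
                (call, f"max_maf={max(freqs)} >= {config.maf_threshold}")
            )
    return kept, removed


def filter_clinvar(
    calls: Sequence[AnnotatedCall], config: Optional[CascadeConfig] = None
) -> tuple[list[AnnotatedCall], list[Removal]]:
    """Remove calls asserted Benign or Likely benign in ClinVar.

    Conflicting interpretations and absent assertions are kept; only an
    unambiguous benign assertion excludes a call.
    """
    kept, removed = [], []
    for call in calls:
        if call.clinvar_assertion in (
            ClinvarAssertion.BENIGN,
            ClinvarAssertion.LIKELY_BENIGN,
        ):
            removed.append((call, f"clinvar={call.clinvar_assertion.value}"))
        else:
            kept.append(call)
    return kept, removed


_SELECTED = {
    ConsequenceType.MISSENSE,
    ConsequenceType.NONSENSE,
    ConsequenceType.FRAMESHIFT,
    ConsequenceType.INFRAME_INDEL,
    ConsequenceType.DELINS,
    ConsequenceType.DELETION,
    ConsequenceType.DUPLICATION,
    ConsequenceType.SPLICE_SITE,
}


def _synonymous_removed(call: AnnotatedCall, rescue: SynonymousRescue) -> bool:
    preds = [
        p
        for p in (call.splice_pred_mt, call.splice_pred_hsf)
        if p is not SplicePrediction.UNAVAILABLE
    ]
    if not preds:
        return False  # nothing predicted: keep conservatively
    if rescue is SynonymousRescue.ALL_PREDICTORS:
        return all(p is SplicePrediction.NO_EFFECT for p in preds)
    return any(p is SplicePrediction.NO_EFFECT for p in preds)


def filter_consequence_class(
    calls: Sequence[AnnotatedCall], config: Optional[CascadeConfig] = None
) -> tuple[list[AnnotatedCall], list[Removal]]:
    """Select coding-relevant consequence classes.

    Missense, nonsense, frameshift, in-frame indels/delins/deletions/
    duplications and near-junction (splice-window) intronic calls pass.
    Synonymous calls are removed only when the splice predictors agree there
    is no splicing effect (per ``synonymous_rescue``); deeper intronic calls
    are removed.
    """
    config = config or CascadeConfig()
    kept, removed = [], []
    for call in calls:
        cons = call.get_consequence(config.splice_window)
        if cons in _SELECTED:
            kept.append(call)
        elif cons is ConsequenceType.SYNONYMOUS:
            if _synonymous_removed(call, config.synonymous_rescue):
                removed.append((call, "synonymous_no_splice_effect"))
            else:
                kept.append(call)
        else:
            removed.append((call, f"consequence={cons.value}"))
    return kept, removed


STAGE_NAMES = ("vaf", "frequency", "clinvar", "consequence")

_STAGE_FUNCS: dict[str, Callable] = {
    "vaf": filter_vaf,
    "frequency": filter_population_frequency,
    "clinvar": filter_clinvar,
    "consequence": filter_consequence_class,
}


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    removed: list[tuple[str, str]] = field(default_factory=list)  # (call_id, reason)


@dataclass
class FunnelReport:
    """Per-stage accounting of the triage cascade."""

    stages: list[FunnelStage]

    @property
    def n_input(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_survivors(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def validate(self) -> None:
        removed_total = 0
        for i, st in enumerate(self.stages):
            if st.n_out > st.n_in:
                raise AssertionError(f"stage {st.name}: n_out > n_in")
            if st.n_in - st.n_out != len(st.removed):
                raise AssertionError(f"stage {st.name}: removal ledger mismatch")
            if i > 0 and st.n_in != self.stages[i - 1].n_out:
                raise AssertionError(f"stage {st.name}: funnel discontinuity")
            removed_total += len(st.removed)
        if self.stages and removed_total + self.n_survivors != self.n_input:
            raise AssertionError("removed + survivors does not partition the input")

    def to_rows(self) -> list[dict]:
        return [
            {
                "stage": st.name,
                "n_in": st.n_in,
                "n_out": st.n_out,
                "n_removed": st.n_in - st.n_out,
                "removed_ids": ";".join(cid for cid, _ in st.removed),
                "reasons": ";".join(r for _, r in st.removed),
            }
            for st in self.stages
        ]


def run_cascade(
    calls: Sequence[AnnotatedCall],
    config: Optional[CascadeConfig] = None,
    stage_order: Sequence[str] = STAGE_NAMES,
) -> tuple[list[AnnotatedCall], FunnelReport]:
    """Apply the triage stages in order and return survivors plus the funnel.

    The stages are independent predicates, so the survivor *set* is
    invariant under any ``stage_order`` permutation; only the per-stage
    removal attribution changes.
    """
    config = config or CascadeConfig()
    if sorted(stage_order) != sorted(STAGE_NAMES):
        raise ValueError(f"stage_order must be a permutation of {STAGE_NAMES}")
    current = list(calls)
    stages: list[FunnelStage] = []
    for name in stage_order:
        kept, removed = _STAGE_FUNCS[name](current, config)
        stages.append(
            FunnelStage(
                name=name,
                n_in=len(current),
                n_out=len(kept),
                removed=[(c.call_id, reason) for c, reason in removed],
            )
        )
        current = kept
    report = FunnelReport(stages)
    report.validate()
    return current, report


def report_clinically_relevant(
    survivors: Sequence[AnnotatedCall],
    engine_config: Optional[CombinerConfig] = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, Classification]]]:
    """Classify survivors and keep the reportable (P / LP) records.

    Returns ``(reportable, non_reportable)`` where each non-reportable entry
    carries the class that excluded it (B, LB or VUS).
    """
    engine_config = engine_config or CombinerConfig()
    reportable: list[VariantRecord] = []
    non_reportable: list[tuple[VariantRecord, Classification]] = []
    for call in survivors:
        cls = classify(call.core.criteria, engine_config)
        if cls >= Classification.LP:
            reportable.append(call.core)
        else:
            non_reportable.append((call.core, cls))
    return reportable, non_reportable
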