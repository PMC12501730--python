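"""Seeded synthetic cohorts with planted ground truth.

The generator emulates the *shape* of a diagnostic-panel output — a
cohort in which roughly three quarters of patients carry a causal
genotype, each patient also carries background calls constructed to fail
exactly one named triage filter, and trios segregate consistently — so
that every pipeline stage (cascade, classification, case solving,
segregation) can be tested against constructed, not sampled, truth.

Fates are planted, not emergent: a ``fails_frequency`` record is given a
population frequency well above threshold (2-10x) and clean values for
every other filter, a survivor is given a frequency well below threshold
(or none), and so on, deliberately avoiding the filter boundaries so that
recovery is exact by construction.  Empirical distributions (criteria
strings, genes and their inheritance modes, zygosity mix) default to the
packaged 97-row fixture, which is what ties the simulation to the study
conditions it emulates.

Everything derives from ``numpy.random.default_rng(seed)``; a fixed seed
gives byte-identical output across platforms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .acmg import Classification, ConflictPolicy, combine_richards
from .cascade import AnnotatedCall, CascadeConfig, ClinvarAssertion, SplicePrediction
from .fixtures import load_table2
from .segregation import Genotype, Sex, TrioGenotypes
from .variant_model import (
    CdnaChange,
    CriteriaSet,
    EditKind,
    ProteinChange,
    ProteinKind,
    VariantRecord,
    Zygosity,
    parse_cdna,
    parse_protein,
)

__all__ = [
    "PlantedFate",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_table2_like",
]


class PlantedFate(str, enum.Enum):
    SURVIVOR = "survivor"
    FAILS_VAF = "fails_vaf"
    FAILS_FREQUENCY = "fails_frequency"
    FAILS_CLINVAR = "fails_clinvar"
    FAILS_CONSEQUENCE = "fails_consequence"


_FAIL_FATES = [
    PlantedFate.FAILS_VAF,
    PlantedFate.FAILS_FREQUENCY,
    PlantedFate.FAILS_CLINVAR,
    PlantedFate.FAILS_CONSEQUENCE,
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the study conditions.

    ``solved_rate`` defaults to 0.74 (the diagnostic yield of the cohort the
    generator emulates) and ``consanguinity_rate`` to 0.734; the criteria
    pool and gene pool default to the packaged fixture's empirical sets.
    """

    seed: int = 0
    n_patients: int = 94
    solved_rate: float = 0.74
    carrier_rate: float = 0.08  # unsolved patients given a lone het AR record
    background_mean: float = 3.0  # Poisson mean of background calls per patient
    stage_failure_mix: dict[str, float] = field(
        default_factory=lambda: {
            "vaf": 0.25, "frequency": 0.25, "clinvar": 0.25, "consequence": 0.25,
        }
    )
    consanguinity_rate: float = 0.734
    criteria_pool: Optional[list[CriteriaSet]] = None  # default: fixture strings
    gene_pool: Optional[list[tuple[str, frozenset]]] = None  # (symbol, modes)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    def __post_init__(self) -> None:
        for name in ("solved_rate", "carrier_rate", "consanguinity_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if sum(self.stage_failure_mix.values()) > 1 + 1e-9:
            raise ValueError("stage_failure_mix proportions sum above 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for exact-recovery assertions."""

    record_fates: dict[str, PlantedFate]  # call_id -> fate
    solved_patients: dict[str, str]  # patient_id -> solving rule name
    consanguineous: set[str]

    def planted_survivor_ids(self) -> set[str]:
        return {
            cid for cid, fate in self.record_fates.items()
            if fate is PlantedFate.SURVIVOR
        }


def _fixture_pools() -> tuple[list[CriteriaSet], list[tuple[str, frozenset]]]:
    records = load_table2()
    criteria = [r.criteria for r in records]
    genes: dict[str, frozenset] = {}
    for r in records:
        genes.setdefault(r.gene, r.inheritance_modes)
    return criteria, sorted(genes.items())


def _causal_pool(criteria_pool: Sequence[CriteriaSet]) -> list[CriteriaSet]:
    """Criteria sets whose face-value rule-table class is P/LP under both policies."""
    pool = [
        c
        for c in criteria_pool
        if combine_richards(c, ConflictPolicy.STRICT) >= Classification.LP
    ]
    if not pool:
        raise ValueError("criteria pool contains no P/LP set; cannot plant solved cases")
    return pool


_BASES = "ACGT"


def _random_substitution(rng: np.random.Generator, intronic_offset: int = 0) -> CdnaChange:
    pos = int(rng.integers(1, 9000))
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    off = f"{intronic_offset:+d}" if intronic_offset else ""
    return parse_cdna(f"c.{pos}{off}{ref}>{alt}")


_AA = ["Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Leu", "Ser", "Val"]


def _random_protein(rng: np.random.Generator, kind: str) -> ProteinChange:
    pos = int(rng.integers(1, 2000))
    ref, alt = rng.choice(_AA, size=2, replace=False)
    if kind == "missense":
        return parse_protein(f"p.{ref}{pos}{alt}")
    if kind == "synonymous":
        return parse_protein(f"p.{ref}{pos}{ref}")
    if kind == "nonsense":
        return parse_protein(f"p.{ref}{pos}*")
    raise ValueError(kind)


def _make_call(
    core: VariantRecord,
    rng: np.random.Generator,
    fate: PlantedFate,
    cfg: SimulationConfig,
) -> AnnotatedCall:
    """Dress a record with annotations that violate exactly the planted filter."""
    cc = cfg.cascade
    # clean values first (pass every filter)
    vaf = (
        float(rng.uniform(0.85, 1.0))
        if core.zygosity is not Zygosity.HETEROZYGOUS
        else float(rng.uniform(0.35, 0.65))
    )
    freq = None if rng.random() < 0.5 else float(rng.uniform(0, cc.maf_threshold / 2))
    clinvar = ClinvarAssertion.NONE
    mt = hsf = SplicePrediction.UNAVAILABLE

    if fate is PlantedFate.FAILS_VAF:
        vaf = float(rng.uniform(0.01, cc.vaf_min * 0.66))
    elif fate is PlantedFate.FAILS_FREQUENCY:
        freq = float(rng.uniform(2 * cc.maf_threshold, 10 * cc.maf_threshold))
    elif fate is PlantedFate.FAILS_CLINVAR:
        clinvar = (
            ClinvarAssertion.BENIGN
            if rng.random() < 0.5
            else ClinvarAssertion.LIKELY_BENIGN
        )
    elif fate is PlantedFate.FAILS_CONSEQUENCE:
        mt = hsf = SplicePrediction.NO_EFFECT  # synonymous, predicted silent

    return AnnotatedCall(
        core=core,
        variant_fraction=vaf,
        freq_gnomad=freq,
        freq_1000g=None,
        freq_esp=None,
        clinvar_assertion=clinvar,
        splice_pred_mt=mt,
        splice_pred_hsf=hsf,
    )


def generate_cohort(
    config: Optional[SimulationConfig] = None,
) -> tuple[list[AnnotatedCall], dict[str, TrioGenotypes], GroundTruth]:
    """Generate (annotated calls, trios, planted truth) for one seeded cohort."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    criteria_pool, gene_pool = cfg.criteria_pool, cfg.gene_pool
    if criteria_pool is None or gene_pool is None:
        fc, fg = _fixture_pools()
        criteria_pool = criteria_pool or fc
        gene_pool = gene_pool or fg
    causal_pool = _causal_pool(criteria_pool)
    ar_genes = [(g, m) for g, m in gene_pool if "AR" in m]
    ad_genes = [(g, m) for g, m in gene_pool if "AD" in m]
    xlr_genes = [(g, m) for g, m in gene_pool if "XLR" in m]
    ar_only = [(g, m) for g, m in ar_genes if "AD" not in m]
    if not ar_genes or not ad_genes:
        raise ValueError("gene pool must contain AR and AD capable genes")

    calls: list[AnnotatedCall] = []
    trios: dict[str, TrioGenotypes] = {}
    truth = GroundTruth({}, {}, set())

    fail_names = list(cfg.stage_failure_mix)
    fail_probs = np.array([cfg.stage_failure_mix[n] for n in fail_names], dtype=float)
    fail_probs = fail_probs / fail_probs.sum()

    def pick_criteria(pool):
        return pool[int(rng.integers(len(pool)))]

    def causal_record(pid, gene, modes, zygosity) -> VariantRecord:
        return VariantRecord(
            patient_id=pid,
            gene=gene,
            cdna=_random_substitution(rng),
            protein=_random_protein(rng, "missense"),
            zygosity=zygosity,
            criteria=pick_criteria(causal_pool),
            inheritance_modes=modes,
        )

    for i in range(cfg.n_patients):
        pid = f"S{i + 1:04d}"
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        if rng.random() < cfg.consanguinity_rate:
            truth.consanguineous.add(pid)
        u = rng.random()
        causal: list[VariantRecord] = []
        if u < cfg.solved_rate:
            # choose a solving rule; hemizygous only for male probands
            choices = ["homozygous", "compound_het_AR", "heterozygous_AD"]
            if xlr_genes and sex is Sex.MALE:
                choices.append("hemizygous")
            rule = choices[int(rng.integers(len(choices)))]
            if rule == "homozygous":
                g, m = ar_genes[int(rng.integers(len(ar_genes)))]
                causal = [causal_record(pid, g, m, Zygosity.HOMOZYGOUS)]
                trios[pid] = TrioGenotypes(Genotype.HOM_ALT, Genotype.HET, Genotype.HET, sex)
            elif rule == "hemizygous":
                g, m = xlr_genes[int(rng.integers(len(xlr_genes)))]
                causal = [causal_record(pid, g, m, Zygosity.HEMIZYGOUS)]
                trios[pid] = TrioGenotypes(
                    Genotype.HEMI_ALT, Genotype.HET, Genotype.HEMI_REF, Sex.MALE
                )
            elif rule == "compound_het_AR":
                g, m = ar_genes[int(rng.integers(len(ar_genes)))]
                causal = [
                    causal_record(pid, g, m, Zygosity.HETEROZYGOUS),
                    causal_record(pid, g, m, Zygosity.HETEROZYGOUS),
                ]
                trios[pid] = TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HOM_REF, sex)
            else:  # heterozygous_AD
                g, m = ad_genes[int(rng.integers(len(ad_genes)))]
                causal = [causal_record(pid, g, m, Zygosity.HETEROZYGOUS)]
                trios[pid] = TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HOM_REF, sex)
            truth.solved_patients[pid] = rule
        elif u < cfg.solved_rate + cfg.carrier_rate and ar_only:
            # unsolved carrier: one heterozygous P/LP record in an AR-only gene
            g, m = ar_only[int(rng.integers(len(ar_only)))]
            causal = [causal_record(pid, g, m, Zygosity.HETEROZYGOUS)]

        for rec in causal:
            call = _make_call(rec, rng, PlantedFate.SURVIVOR, cfg)
            truth.record_fates[call.call_id] = PlantedFate.SURVIVOR
            calls.append(call)

        n_bg = int(rng.poisson(cfg.background_mean))
        for b in range(n_bg):
            fate = PlantedFate(
                f"fails_{fail_names[int(rng.choice(len(fail_names), p=fail_probs))]}"
            )
            gene = f"BG{int(rng.integers(1, 400)):03d}"
            if fate is PlantedFate.FAILS_CONSEQUENCE:
                protein = _random_protein(rng, "synonymous")
            else:
                protein = _random_protein(rng, "missense")
            rec = VariantRecord(
                patient_id=pid,
                gene=gene,
                cdna=_random_substitution(rng),
                protein=protein,
                zygosity=Zygosity.HETEROZYGOUS,
                criteria=CriteriaSet(frozenset()),
                inheritance_modes=frozenset({"AR"}),
            )
            call = _make_call(rec, rng, fate, cfg)
            if call.call_id in truth.record_fates:
                continue  # vanishingly rare id collision: skip rather than overwrite
            truth.record_fates[call.call_id] = fate
            calls.append(call)

    return calls, trios, truth


def generate_table2_like(seed: int, n_rows: int) -> list[VariantRecord]:
    """Sample schema-valid variant rows from the fixture's empirical distributions.

    Zygosity, criteria string, inheritance modes and consequence shape are
    drawn jointly from a fixture row (preserving their dependence); gene and
    positions are resampled, so rows are novel but distributionally faithful.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    fixture = load_table2()
    genes = sorted({r.gene for r in fixture})
    out = []
    for i in range(n_rows):
        template = fixture[int(rng.integers(len(fixture)))]
        gene = genes[int(rng.integers(len(genes)))]
        kind = template.protein.kind
        if kind is ProteinKind.UNKNOWN:
            if template.cdna.edit_kind is EditKind.SUBSTITUTION:
                off = template.cdna.start_offset or -2
                cdna = _random_substitution(rng, intronic_offset=off)
            else:
                cdna = template.cdna
            protein = parse_protein("p.?")
        else:
            cdna = _random_substitution(rng)
            protein = _random_protein(
                rng,
                {
                    ProteinKind.SUBSTITUTION: "missense",
                    ProteinKind.NONSENSE: "nonsense",
                    ProteinKind.SYNONYMOUS: "synonymous",
                    ProteinKind.FRAMESHIFT: "missense",  # placeholder, replaced below
                }[kind],
            )
            if kind is ProteinKind.FRAMESHIFT:
                pos = int(rng.integers(1, 2000))
                ref, alt = rng.choice(_AA, size=2, replace=False)
                protein = parse_protein(f"p.{ref}{pos}{alt}fs*{int(rng.integers(2, 80))}")
        zyg = template.zygosity
        modes = template.inheritance_modes
        if zyg is Zygosity.HEMIZYGOUS and "XLR" not in modes:
            modes = modes | {"XLR"}
        out.append(
            VariantRecord(
                patient_id=f"R{i + 1:04d}",
                gene=gene,
                cdna=cdna,
                protein=protein,
                zygosity=zyg,
                criteria=template.criteria,
                reported_class=template.reported_class,
                inheritance_modes=modes,
            )
        )
    return out
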