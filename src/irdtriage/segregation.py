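"""Trio genotype consistency checks.

Formalizes the segregation step of a panel workflow: given the proband's
causal genotype and parental genotypes from confirmatory sequencing, is
the observed transmission compatible with the variant's inheritance mode?
The verdict is purely genotypic — consanguinity and sibling genotypes are
carried as annotation, never as evidence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .variant_model import VariantRecord, Zygosity

__all__ = [
    "Genotype",
    "Sex",
    "TrioGenotypes",
    "SegregationVerdict",
    "check_trio_consistency",
    "batch_segregate",
]


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    HEMI_REF = "hemi_ref"
    UNAVAILABLE = "unavailable"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


_HEMI = {Genotype.HEMI_ALT, Genotype.HEMI_REF}


@dataclass(frozen=True)
class TrioGenotypes:
    proband: Genotype
    mother: Genotype = Genotype.UNAVAILABLE
    father: Genotype = Genotype.UNAVAILABLE
    proband_sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        if self.proband in _HEMI and self.proband_sex is Sex.FEMALE:
            raise ValueError("hemizygous proband genotype requires a male proband")
        if self.mother in _HEMI:
            raise ValueError("maternal genotype cannot be hemizygous")


class SegregationVerdict(str, enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    POSSIBLE_DE_NOVO = "possible_de_novo"
    UNINFORMATIVE = "uninformative"


_CARRIES_ALT = {Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT}


def check_trio_consistency(
    variant: VariantRecord, trio: TrioGenotypes
) -> tuple[SegregationVerdict, str]:
    """Check one proband genotype against parental genotypes.

    Recessive homozygotes need one alternate allele from each parent;
    dominant heterozygotes need a carrier parent (both parents reference →
    possible de novo); X-linked hemizygous males need a carrier mother.
    Any required relative with an unavailable genotype makes the trio
    uninformative rather than guessing.
    """
    modes = variant.inheritance_modes
    zyg = variant.zygosity

    if zyg is Zygosity.HOMOZYGOUS:
        verdicts = []
        for label, gt in (("mother", trio.mother), ("father", trio.father)):
            if gt is Genotype.UNAVAILABLE:
                verdicts.append((label, None))
            elif gt in _CARRIES_ALT:
                verdicts.append((label, True))
            else:
                verdicts.append((label, False))
        if any(v is False for _, v in verdicts):
            bad = ", ".join(l for l, v in verdicts if v is False)
            return (
                SegregationVerdict.INCONSISTENT,
                f"homozygous proband but {bad} carries no alternate allele",
            )
        if any(v is None for _, v in verdicts):
            missing = ", ".join(l for l, v in verdicts if v is None)
            return (SegregationVerdict.UNINFORMATIVE, f"genotype unavailable: {missing}")
        return (SegregationVerdict.CONSISTENT, "both parents carry the alternate allele")

    if zyg is Zygosity.HEMIZYGOUS:
        if trio.mother is Genotype.UNAVAILABLE:
            return (SegregationVerdict.UNINFORMATIVE, "maternal genotype unavailable")
        if trio.mother in _CARRIES_ALT:
            return (SegregationVerdict.CONSISTENT, "mother carries the alternate allele")
        return (
            SegregationVerdict.POSSIBLE_DE_NOVO,
            "mother is reference homozygous; X-linked variant may be de novo",
        )

    # heterozygous proband
    if "AD" in modes or not modes:
        parents = [g for g in (trio.mother, trio.father) if g is not Genotype.UNAVAILABLE]
        if any(g in _CARRIES_ALT for g in parents):
            return (SegregationVerdict.CONSISTENT, "a parent carries the alternate allele")
        if len(parents) == 2:
            return (
                SegregationVerdict.POSSIBLE_DE_NOVO,
                "both parents are reference homozygous",
            )
        return (SegregationVerdict.UNINFORMATIVE, "a parental genotype is unavailable")
    # heterozygous in a recessive-only gene: carrier state, nothing to confirm
    if trio.mother is Genotype.UNAVAILABLE and trio.father is Genotype.UNAVAILABLE:
        return (SegregationVerdict.UNINFORMATIVE, "no parental genotypes")
    if any(g in _CARRIES_ALT for g in (trio.mother, trio.father)):
        return (SegregationVerdict.CONSISTENT, "a parent carries the alternate allele")
    if Genotype.UNAVAILABLE in (trio.mother, trio.father):
        return (SegregationVerdict.UNINFORMATIVE, "a parental genotype is unavailable")
    return (
        SegregationVerdict.POSSIBLE_DE_NOVO,
        "both parents are reference homozygous",
    )


def batch_segregate(
    records: Sequence[VariantRecord],
    trios: Mapping[str, TrioGenotypes],
) -> pd.DataFrame:
    """Per-record verdicts; records without a trio are uninformative."""
    rows = []
    for rec in records:
        trio = trios.get(rec.patient_id)
        if trio is None:
            verdict, why = SegregationVerdict.UNINFORMATIVE, "no trio genotypes"
        else:
            verdict, why = check_trio_consistency(rec, trio)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "gene": rec.gene,
                "cdna": rec.normalized_cdna,
                "zygosity": rec.zygosity.value,
                "verdict": verdict.value,
                "explanation": why,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "gene", "cdna", "zygosity", "verdict", "explanation"],
    )
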