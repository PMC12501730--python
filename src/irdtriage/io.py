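"""Readers and writers for the tab-separated schemas and minimal VCF input.

All tables are UTF-8, LF, one header row; lines starting with ``#`` are
comments.  Reading then writing preserves the schema columns byte for
byte; unknown extra columns are preserved on read and trigger a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cascade import AnnotatedCall, ClinvarAssertion, SplicePrediction
from .segregation import Genotype, Sex, TrioGenotypes
from .variant_model import (
    VariantRecord,
    Zygosity,
    format_criteria,
    parse_cdna,
    parse_criteria_string,
    parse_protein,
)

__all__ = [
    "SchemaError",
    "RECORD_COLUMNS",
    "CALL_COLUMNS",
    "read_records_tsv",
    "write_records_tsv",
    "read_calls_tsv",
    "write_calls_tsv",
    "read_trios_tsv",
    "read_vcf_minimal",
]


class SchemaError(ValueError):
    """A table does not conform to the documented schema."""


RECORD_COLUMNS = [
    "patient_id", "gene", "transcript", "cdna", "protein",
    "zygosity", "criteria", "reported_class", "inheritance", "novel", "dann",
]
_MANDATORY_RECORD = ["patient_id", "gene", "cdna", "protein", "zygosity", "criteria"]

_CALL_EXTRA = [
    "vaf", "freq_gnomad", "freq_1000g", "freq_esp",
    "clinvar", "splice_mt", "splice_hsf",
]
CALL_COLUMNS = RECORD_COLUMNS + _CALL_EXTRA

_MISSING = {"", "na", "n/a", "none", "nan", "n", "-", "—", "."}


def _opt_float(value) -> Optional[float]:
    s = str(value).strip()
    if s.lower() in _MISSING:
        return None
    return float(s)


def _opt_str(value) -> Optional[str]:
    s = str(value).strip()
    return None if s.lower() in _MISSING else s


def _read_table(path, mandatory: Sequence[str], known: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: unknown column(s) preserved: {', '.join(unknown)}", stacklevel=2)
    return frame


def _record_from_row(row: dict) -> VariantRecord:
    zyg = str(row["zygosity"]).strip().lower()
    try:
        zygosity = Zygosity(zyg)
    except ValueError:
        raise SchemaError(f"unknown zygosity value {row['zygosity']!r}") from None
    modes = frozenset(
        m.strip().upper()
        for m in str(row.get("inheritance", "") or "").replace(";", ",").split(",")
        if m.strip()
    )
    novel_raw = str(row.get("novel", "") or "").strip().lower()
    return VariantRecord(
        patient_id=str(row["patient_id"]).strip(),
        gene=str(row["gene"]).strip(),
        transcript=_opt_str(row.get("transcript", "")),
        cdna=parse_cdna(str(row["cdna"])),
        protein=parse_protein(str(row["protein"])),
        zygosity=zygosity,
        criteria=parse_criteria_string(str(row["criteria"])),
        reported_class=_opt_str(row.get("reported_class", "")),
        inheritance_modes=modes,
        novel=novel_raw in {"1", "true", "yes"},
        dann_score=_opt_float(row.get("dann", "")),
    )


def read_records_tsv(path: Union[str, Path]) -> list[VariantRecord]:
    """Read a variant-record table (one row per patient-variant pair)."""
    frame = _read_table(path, _MANDATORY_RECORD, RECORD_COLUMNS)
    return [_record_from_row(row) for row in frame.to_dict("records")]


def _record_to_row(rec: VariantRecord) -> dict:
    return {
        "patient_id": rec.patient_id,
        "gene": rec.gene,
        "transcript": rec.transcript or "",
        "cdna": rec.normalized_cdna,
        "protein": rec.protein.raw_text,
        "zygosity": rec.zygosity.value,
        "criteria": format_criteria(rec.criteria),
        "reported_class": rec.reported_class or "",
        "inheritance": ",".join(sorted(rec.inheritance_modes)),
        "novel": "true" if rec.novel else "false",
        "dann": "" if rec.dann_score is None else repr(rec.dann_score),
    }


def write_records_tsv(records: Sequence[VariantRecord], path: Union[str, Path]) -> None:
    frame = pd.DataFrame([_record_to_row(r) for r in records], columns=RECORD_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def _call_from_row(row: dict) -> AnnotatedCall:
    clinvar_raw = _opt_str(row.get("clinvar", ""))
    clinvar = ClinvarAssertion(clinvar_raw.lower()) if clinvar_raw else ClinvarAssertion.NONE

    def pred(key: str) -> SplicePrediction:
        raw = _opt_str(row.get(key, ""))
        return SplicePrediction(raw.lower()) if raw else SplicePrediction.UNAVAILABLE

    return AnnotatedCall(
        core=_record_from_row(row),
        variant_fraction=_opt_float(row.get("vaf", "")),
        freq_gnomad=_opt_float(row.get("freq_gnomad", "")),
        freq_1000g=_opt_float(row.get("freq_1000g", "")),
        freq_esp=_opt_float(row.get("freq_esp", "")),
        clinvar_assertion=clinvar,
        splice_pred_mt=pred("splice_mt"),
        splice_pred_hsf=pred("splice_hsf"),
    )


def read_calls_tsv(path: Union[str, Path]) -> list[AnnotatedCall]:
    """Read an annotated-call table (records plus triage annotations)."""
    frame = _read_table(path, _MANDATORY_RECORD, CALL_COLUMNS)
    return [_call_from_row(row) for row in frame.to_dict("records")]


def write_calls_tsv(calls: Sequence[AnnotatedCall], path: Union[str, Path]) -> None:
    rows = []
    for call in calls:
        row = _record_to_row(call.core)
        row.update(
            {
                "vaf": "" if call.variant_fraction is None else repr(call.variant_fraction),
                "freq_gnomad": "" if call.freq_gnomad is None else repr(call.freq_gnomad),
                "freq_1000g": "" if call.freq_1000g is None else repr(call.freq_1000g),
                "freq_esp": "" if call.freq_esp is None else repr(call.freq_esp),
                "clinvar": call.clinvar_assertion.value,
                "splice_mt": call.splice_pred_mt.value,
                "splice_hsf": call.splice_pred_hsf.value,
            }
        )
        rows.append(row)
    frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_trios_tsv(path: Union[str, Path]) -> dict[str, TrioGenotypes]:
    """Read trio genotypes keyed by patient_id.

    Columns: patient_id, proband_gt, mother_gt, father_gt, sex.
    """
    frame = _read_table(
        path,
        ["patient_id", "proband_gt", "mother_gt", "father_gt"],
        ["patient_id", "proband_gt", "mother_gt", "father_gt", "sex"],
    )
    trios = {}
    for row in frame.to_dict("records"):
        sex_raw = _opt_str(row.get("sex", ""))
        trios[str(row["patient_id"]).strip()] = TrioGenotypes(
            proband=Genotype(str(row["proband_gt"]).strip().lower()),
            mother=Genotype(str(row["mother_gt"]).strip().lower()),
            father=Genotype(str(row["father_gt"]).strip().lower()),
            proband_sex=Sex(sex_raw.lower()) if sex_raw else Sex.UNKNOWN,
        )
    return trios


# INFO/FORMAT keys the minimal VCF reader understands
_VCF_INFO_FREQS = {"GNOMAD_AF": "freq_gnomad", "KG_AF": "freq_1000g", "ESP_AF": "freq_esp"}
_CLNSIG_MAP = {
    "benign": ClinvarAssertion.BENIGN,
    "likely_benign": ClinvarAssertion.LIKELY_BENIGN,
    "uncertain_significance": ClinvarAssertion.VUS,
    "vus": ClinvarAssertion.VUS,
    "likely_pathogenic": ClinvarAssertion.LIKELY_PATHOGENIC,
    "pathogenic": ClinvarAssertion.PATHOGENIC,
    "conflicting": ClinvarAssertion.CONFLICTING,
}


def read_vcf_minimal(path: Union[str, Path]) -> list[AnnotatedCall]:
    """Ingest a minimally annotated single-sample VCF into annotated calls.

    Understands INFO keys GNOMAD_AF, KG_AF, ESP_AF (per-allele), CLNSIG,
    CSQTYPE (consequence vocabulary of :class:`ConsequenceType`), SPLICE_MT,
    SPLICE_HSF, GENE, CDNA, PROT, CRIT, MOI and the FORMAT field VAF.
    Multi-allelic sites are split into one call per alternate allele.
    Absent keys leave the corresponding fields absent.
    """
    from cyvcf2 import VCF

    from .variant_model import ConsequenceType

    def per_allele(value, i: int, n_alt: int):
        if value is None:
            return None
        if isinstance(value, (tuple, list)):
            return value[i] if i < len(value) else None
        return value  # single value shared across alleles

    calls: list[AnnotatedCall] = []
    vcf = VCF(str(path))
    try:
        sample_id = vcf.samples[0] if vcf.samples else "sample"
        for variant in vcf:
            n_alt = len(variant.ALT)
            info = dict(variant.INFO)
            vaf = None
            try:
                fmt = variant.format("VAF")
                if fmt is not None:
                    vaf = float(fmt[0][0])
            except KeyError:
                vaf = None
            for i, alt in enumerate(variant.ALT):
                kw = {}
                for key, field_name in _VCF_INFO_FREQS.items():
                    raw = per_allele(info.get(key), i, n_alt)
                    kw[field_name] = float(raw) if raw is not None else None
                clnsig = info.get("CLNSIG")
                clinvar = (
                    _CLNSIG_MAP.get(str(clnsig).strip().lower(), ClinvarAssertion.NONE)
                    if clnsig is not None
                    else ClinvarAssertion.NONE
                )

                def pred(key: str) -> SplicePrediction:
                    raw = info.get(key)
                    return (
                        SplicePrediction(str(raw).strip().lower())
                        if raw is not None
                        else SplicePrediction.UNAVAILABLE
                    )

                cons = info.get("CSQTYPE")
                core = _record_from_row(
                    {
                        "patient_id": sample_id,
                        "gene": info.get("GENE", f"{variant.CHROM}:{variant.POS}"),
                        "cdna": info.get("CDNA", f"c.{variant.POS}{variant.REF}>{alt}"),
                        "protein": info.get("PROT", "p.?"),
                        "zygosity": info.get("ZYG", "heterozygous"),
                        "criteria": info.get("CRIT", ""),
                        "inheritance": info.get("MOI", ""),
                    }
                )
                calls.append(
                    AnnotatedCall(
                        core=core,
                        variant_fraction=vaf,
                        clinvar_assertion=clinvar,
                        splice_pred_mt=pred("SPLICE_MT"),
                        splice_pred_hsf=pred("SPLICE_HSF"),
                        consequence=ConsequenceType(str(cons).strip().lower())
                        if cons is not None
                        else None,
                        **kw,
                    )
                )
    finally:
        vcf.close()
    return calls
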