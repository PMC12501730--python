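"""Packaged cohort fixtures transcribed from the published study tables.

Three tables ship with the package: subgroup demographics (one row per
clinical subgroup plus the cohort total), the 97-row reported-variant
table, and the 28-row novel-variant list.  They contain only variant- and
group-level data, no raw patient data.  Each file is integrity-checked
against a row count and a SHA-256 checksum so that transcription drift is
caught immediately rather than silently shifting every downstream count.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .variant_model import (
    VariantRecord,
    Zygosity,
    parse_cdna,
    parse_criteria_string,
    parse_protein,
)

__all__ = [
    "FixtureIntegrityError",
    "NovelRow",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_fixture",
    "COHORT_SIZE",
]

COHORT_SIZE = 94

_EXPECTED = {
    "table1.tsv": ("0a5af1c5f40d87dec375e50b2ec99ddfd596e32c6416e5a5132b07d70a0a40ad", 8 + 1),  # 8 subgroups + Total
    "table2.tsv": ("876b779da6f8e29e061dfded65706d77f70c9fc5f8253cfd7b3b06246da9fe27", 97),
    "table3.tsv": ("6909d6bac984de999318e025c12fe43e24c3042d3e4234ede76ff3d4df187794", 28),
}


class FixtureIntegrityError(RuntimeError):
    """Fixture content does not match its recorded checksum or row count."""


def _fixture_path(name: str) -> Path:
    return Path(resources.files("irdtriage").joinpath("data", name))


def _checked_frame(name: str) -> pd.DataFrame:
    path = _fixture_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected_digest, expected_rows = _EXPECTED[name]
    if digest != expected_digest:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != expected {expected_digest}"
        )
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if len(frame) != expected_rows:
        raise FixtureIntegrityError(
            f"{name}: {len(frame)} rows, expected {expected_rows}"
        )
    return frame


_ABSENT = {"", "n", "n/a", "na", "—", "-"}


def _opt_float(raw: str) -> Optional[float]:
    s = raw.strip()
    return None if s.lower() in _ABSENT else float(s)


def load_table1() -> pd.DataFrame:
    """Subgroup demographics: n, age/onset mean+-SD, printed percentages.

    The subgroup n's (excluding the Total row) must sum to the cohort size.
    Percentages are carried exactly as printed, for count reconstruction;
    no per-patient demographics are fabricated from them.
    """
    frame = _checked_frame("table1.tsv")
    num_cols = [c for c in frame.columns if c != "group"]
    frame[num_cols] = frame[num_cols].apply(pd.to_numeric)
    subgroups = frame[frame["group"] != "Total"]
    if int(subgroups["n"].sum()) != COHORT_SIZE:
        raise FixtureIntegrityError("subgroup sizes do not sum to the cohort size")
    return frame


def load_table2() -> list[VariantRecord]:
    """The 97 reported patient-variant rows (gene, HGVS, zygosity, criteria, class, mode)."""
    frame = _checked_frame("table2.tsv")
    records = []
    for row in frame.to_dict("records"):
        modes = frozenset(m.strip() for m in row["inheritance"].split(",") if m.strip())
        records.append(
            VariantRecord(
                patient_id=row["patient_id"],
                gene=row["gene"],
                cdna=parse_cdna(row["cdna"]),
                protein=parse_protein(row["protein"]),
                zygosity=Zygosity(row["zygosity"].strip().lower()),
                criteria=parse_criteria_string(row["criteria"]),
                reported_class=row["reported_class"].strip(),
                inheritance_modes=modes,
                dann_score=_opt_float(row["dann"]),
            )
        )
    return records


@dataclass(frozen=True)
class NovelRow:
    """One novel-variant listing: enough identity to match a cohort record."""

    patient_id: str
    gene: str
    transcript: str
    cdna: str
    protein: str
    zygosity: str
    reported_class: str
    dann_score: Optional[float]

    @property
    def match_key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.gene, self.cdna)


def load_table3() -> list[NovelRow]:
    """The 28 novel-variant rows; transcripts kept verbatim (punctuation included)."""
    frame = _checked_frame("table3.tsv")
    return [
        NovelRow(
            patient_id=row["patient_id"],
            gene=row["gene"],
            transcript=row["transcript"],
            cdna=row["cdna"],
            protein=row["protein"],
            zygosity=row["zygosity"].strip().lower(),
            reported_class=row["reported_class"].strip(),
            dann_score=_opt_float(row["dann"]),
        )
        for row in frame.to_dict("records")
    ]


def load_fixture(name: str):
    """Load a fixture by name: ``table1``, ``table2`` or ``table3``."""
    loaders = {"table1": load_table1, "table2": load_table2, "table3": load_table3}
    if name not in loaders:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(loaders)}")
    return loaders[name]()
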