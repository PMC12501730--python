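"""Domain model for panel-reported sequence variants.

Covers a deliberately small slice of HGVS nomenclature — the coding-DNA
("c.") and protein ("p.") descriptions that appear in diagnostic-panel
reports: substitutions, deletions, duplications, insertions and
deletion-insertions, with optional intronic offsets.  Genomic,
mitochondrial and inversion syntax is out of scope, as is validation
against a reference sequence.

Published tables routinely swap the ASCII hyphen in intronic offsets for
an en-dash (and scatter non-breaking spaces), so every parser here
normalizes unicode dashes and whitespace before matching.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "HgvsParseError",
    "EditKind",
    "CdnaChange",
    "ProteinKind",
    "ProteinChange",
    "ConsequenceType",
    "EvidenceCode",
    "CriteriaSet",
    "CriteriaParseError",
    "Zygosity",
    "VariantRecord",
    "normalize_hgvs_text",
    "parse_cdna",
    "parse_protein",
    "classify_consequence",
    "parse_criteria_string",
    "format_criteria",
    "EVIDENCE_CODES",
]


class HgvsParseError(ValueError):
    """Raised when a variant description cannot be parsed."""


# en dash, em dash, figure dash, horizontal bar, minus sign, hyphen (U+2010/11)
_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")
_SPACES = dict.fromkeys(map(ord, " \t   "), None)


def normalize_hgvs_text(text: str) -> str:
    """Map unicode dash variants to '-' and strip all whitespace."""
    return text.translate(_DASHES).translate(_SPACES)


class EditKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    DELINS = "delins"
    INSERTION = "insertion"


@dataclass(frozen=True)
class CdnaChange:
    """A coding-DNA change, e.g. ``c.12067-2A>G`` or ``c.802-8_810delinsGC``.

    Positions are (anchor, offset) pairs: the anchor is the 1-based coding
    position as printed, the offset is the signed intronic offset (0 for
    exonic positions).  Single-position edits carry identical start and end.

    ``raw_text`` preserves the input typography for provenance and is
    excluded from equality: two parses describing the same edit compare
    equal even when one was printed with an en-dash.
    """

    raw_text: str = field(compare=False)
    edit_kind: EditKind
    start_anchor: int
    start_offset: int
    end_anchor: int
    end_offset: int
    ref_bases: str = ""
    alt_bases: str = ""

    def __post_init__(self) -> None:
        if (self.start_anchor, self.start_offset) > (self.end_anchor, self.end_offset):
            raise HgvsParseError(
                f"{self.raw_text!r}: start position follows end position"
            )
        if self.edit_kind is EditKind.SUBSTITUTION and not (
            len(self.ref_bases) == len(self.alt_bases) == 1
        ):
            raise HgvsParseError(
                f"{self.raw_text!r}: substitution requires one ref and one alt base"
            )

    @property
    def is_intronic(self) -> bool:
        return self.start_offset != 0 or self.end_offset != 0

    @property
    def min_intronic_offset(self) -> int:
        """Smallest |offset| over the edit span (0 when either end is exonic)."""
        return min(abs(self.start_offset), abs(self.end_offset))

    def format(self) -> str:
        """Canonical ASCII rendering (dash-normalized raw text round-trips)."""
        def pos(anchor: int, offset: int) -> str:
            if offset == 0:
                return str(anchor)
            return f"{anchor}{offset:+d}"

        span = pos(self.start_anchor, self.start_offset)
        if (self.start_anchor, self.start_offset) != (self.end_anchor, self.end_offset):
            span += "_" + pos(self.end_anchor, self.end_offset)
        k = self.edit_kind
        if k is EditKind.SUBSTITUTION:
            body = f"{span}{self.ref_bases}>{self.alt_bases}"
        elif k is EditKind.DELETION:
            body = f"{span}del{self.ref_bases}"
        elif k is EditKind.DUPLICATION:
            body = f"{span}dup{self.ref_bases}"
        elif k is EditKind.DELINS:
            body = f"{span}delins{self.alt_bases}"
        else:
            body = f"{span}ins{self.alt_bases}"
        return "c." + body


_POS = r"(\d+)([+-]\d+)?"
_CDNA_RE = re.compile(
    rf"^c\.{_POS}(?:_{_POS})?"
    r"(?:"
    r"(?P<ref>[ACGT])>(?P<alt>[ACGT])"
    r"|delins(?P<delins>[ACGT]+)"
    r"|del(?P<del>[ACGT]*)"
    r"|dup(?P<dup>[ACGT]*)"
    r"|ins(?P<ins>[ACGT]+)"
    r")$"
)


def parse_cdna(text: str) -> CdnaChange:
    """Parse a coding-DNA description into a :class:`CdnaChange`.

    Unicode dashes and stray whitespace are normalized first, so table
    typography such as ``c.12067–2A>G`` (en-dash) parses identically to
    ``c.12067-2A>G``.

    Raises
    ------
    HgvsParseError
        If the prefix is not ``c.`` or the position/edit syntax is not part
        of the supported subset.
    """
    norm = normalize_hgvs_text(text)
    if not norm.startswith("c."):
        raise HgvsParseError(f"unsupported prefix in {text!r}: expected 'c.'")
    m = _CDNA_RE.match(norm)
    if m is None:
        raise HgvsParseError(f"cannot parse coding-DNA description {text!r}")
    sa, so, ea, eo = m.group(1), m.group(2), m.group(3), m.group(4)
    start = (int(sa), int(so) if so else 0)
    end = (int(ea), int(eo) if eo else 0) if ea else start
    if m.group("ref"):
        kind, ref, alt = EditKind.SUBSTITUTION, m.group("ref"), m.group("alt")
    elif m.group("delins") is not None:
        kind, ref, alt = EditKind.DELINS, "", m.group("delins")
    elif m.group("del") is not None:
        kind, ref, alt = EditKind.DELETION, m.group("del"), ""
    elif m.group("dup") is not None:
        kind, ref, alt = EditKind.DUPLICATION, m.group("dup"), ""
    else:
        kind, ref, alt = EditKind.INSERTION, "", m.group("ins")
    return CdnaChange(
        raw_text=text,
        edit_kind=kind,
        start_anchor=start[0],
        start_offset=start[1],
        end_anchor=end[0],
        end_offset=end[1],
        ref_bases=ref,
        alt_bases=alt,
    )


class ProteinKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    UNKNOWN = "unknown"


_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp "
    "Tyr Val Sec Pyl Xaa".split()
)
_AA_ALT = {"Ter": "*", "*": "*", **{a: a for a in _AA3}}
_AA_RE = "|".join(["Ter", r"\*"] + _AA3)
_PROTEIN_RE = re.compile(
    rf"^p\.(?P<ref>{_AA_RE})(?P<pos>\d+)"
    rf"(?:(?P<alt>{_AA_RE})?(?P<fs>fs(?:(?:Ter|\*)(?P<fsdist>\d+))?)?)?$"
)


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level change, e.g. ``p.Gly1961Glu``, ``p.Arg675*``, ``p.?``.

    ``raw_text`` keeps the input typography and is excluded from equality.
    """

    raw_text: str = field(compare=False)
    kind: ProteinKind
    residue_position: Optional[int] = None
    ref_residue: Optional[str] = None
    alt_residue: Optional[str] = None
    fs_stop_distance: Optional[int] = None


def parse_protein(text: str) -> ProteinChange:
    """Parse a protein description, tolerating parentheses and stray spaces.

    ``*`` and ``Ter`` denote the same stop symbol; ``fs*N`` and ``fsTerN``
    the same frameshift syntax.  ``p.?`` (unknown effect) and em/en dashes or
    an empty string (no protein annotation) map to kind ``unknown``.
    """
    norm = normalize_hgvs_text(text)
    if norm.startswith("(") and norm.endswith(")"):
        norm = norm[1:-1]
    if norm in {"", "-", "p.?"}:
        return ProteinChange(raw_text=text, kind=ProteinKind.UNKNOWN)
    if not norm.startswith("p."):
        raise HgvsParseError(f"unsupported prefix in {text!r}: expected 'p.'")
    m = _PROTEIN_RE.match(norm)
    if m is None:
        raise HgvsParseError(f"cannot parse protein description {text!r}")
    ref = _AA_ALT[m.group("ref")]
    pos = int(m.group("pos"))
    alt = _AA_ALT[m.group("alt")] if m.group("alt") else None
    if m.group("fs"):
        dist = int(m.group("fsdist")) if m.group("fsdist") else None
        return ProteinChange(text, ProteinKind.FRAMESHIFT, pos, ref, alt, dist)
    if alt is None:
        raise HgvsParseError(f"missing alternate residue in {text!r}")
    if alt == "*":
        kind = ProteinKind.NONSENSE
    elif alt == ref:
        kind = ProteinKind.SYNONYMOUS
    else:
        kind = ProteinKind.SUBSTITUTION
    return ProteinChange(text, kind, pos, ref, alt)


class ConsequenceType(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    DELINS = "delins"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    INTRONIC_OTHER = "intronic_other"
    UNKNOWN = "unknown"


def classify_consequence(
    cdna: CdnaChange, protein: ProteinChange, splice_window: int = 20
) -> ConsequenceType:
    """Assign a single consequence class to a parsed variant.

    Protein-level evidence takes precedence over the DNA edit kind: a
    delins whose annotated protein effect is a stop gain counts as
    nonsense.  Only when the protein effect is unknown does the DNA
    description decide — substitutions at intronic offsets within
    ``splice_window`` of a junction are splice-site candidates; other
    intronic substitutions are plain intronic; non-substitution edits keep
    their DNA edit kind (an intronic deletion stays a deletion).
    """
    if protein.kind is ProteinKind.FRAMESHIFT:
        return ConsequenceType.FRAMESHIFT
    if protein.kind is ProteinKind.NONSENSE:
        return ConsequenceType.NONSENSE
    if protein.kind is ProteinKind.SUBSTITUTION:
        return ConsequenceType.MISSENSE
    if protein.kind is ProteinKind.SYNONYMOUS:
        return ConsequenceType.SYNONYMOUS
    # protein unknown: fall back to the DNA description
    if cdna.edit_kind is EditKind.SUBSTITUTION:
        off = cdna.start_offset
        if off != 0 and abs(off) <= splice_window:
            return ConsequenceType.SPLICE_SITE
        if off != 0:
            return ConsequenceType.INTRONIC_OTHER
        return ConsequenceType.UNKNOWN
    if cdna.edit_kind is EditKind.DELINS:
        return ConsequenceType.DELINS
    if cdna.edit_kind is EditKind.DELETION:
        return ConsequenceType.DELETION
    if cdna.edit_kind is EditKind.DUPLICATION:
        return ConsequenceType.DUPLICATION
    return ConsequenceType.UNKNOWN


class EvidenceCategory(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class EvidenceStrength(enum.IntEnum):
    """Ordered ACMG evidence strengths (higher = stronger)."""

    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5


@dataclass(frozen=True)
class EvidenceCode:
    """One ACMG evidence token, e.g. PVS1 or BS2.

    The token alone determines category (pathogenic vs benign), strength
    and index; exactly 28 tokens exist in the guideline vocabulary.
    """

    token: str
    category: EvidenceCategory
    strength: EvidenceStrength
    index: int


def _build_vocabulary() -> dict[str, EvidenceCode]:
    P, B = EvidenceCategory.PATHOGENIC, EvidenceCategory.BENIGN
    S = EvidenceStrength
    spec = [
        ("PVS", S.VERY_STRONG, P, [1]),
        ("PS", S.STRONG, P, [1, 2, 3, 4]),
        ("PM", S.MODERATE, P, [1, 2, 3, 4, 5, 6]),
        ("PP", S.SUPPORTING, P, [1, 2, 3, 4, 5]),
        ("BA", S.STAND_ALONE, B, [1]),
        ("BS", S.STRONG, B, [1, 2, 3, 4]),
        ("BP", S.SUPPORTING, B, [1, 2, 3, 4, 5, 6, 7]),
    ]
    vocab = {}
    for prefix, strength, cat, indices in spec:
        for i in indices:
            tok = f"{prefix}{i}"
            vocab[tok] = EvidenceCode(tok, cat, strength, i)
    assert len(vocab) == 28
    return vocab


EVIDENCE_CODES: dict[str, EvidenceCode] = _build_vocabulary()


class CriteriaParseError(ValueError):
    """Raised when an ACMG criteria string contains an unknown token."""


_TOKEN_RE = re.compile("|".join(sorted(EVIDENCE_CODES, key=len, reverse=True)))


@dataclass(frozen=True)
class CriteriaSet:
    """An unordered set of ACMG evidence codes with canonical formatting."""

    codes: frozenset[EvidenceCode]

    @classmethod
    def of(cls, *tokens: str) -> "CriteriaSet":
        return cls(frozenset(EVIDENCE_CODES[t] for t in tokens))

    def tokens(self) -> frozenset[str]:
        return frozenset(c.token for c in self.codes)

    def __contains__(self, token: str) -> bool:
        return token in self.tokens()

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)


def parse_criteria_string(text: str) -> CriteriaSet:
    """Parse a separator-free concatenation of ACMG tokens, e.g. ``PVS1PM2PS4PP5``.

    Duplicate tokens collapse into the set with a warning; any substring not
    consumed by the 28-token vocabulary raises :class:`CriteriaParseError`
    naming the residue.
    """
    norm = normalize_hgvs_text(text)
    codes: list[EvidenceCode] = []
    pos = 0
    while pos < len(norm):
        m = _TOKEN_RE.match(norm, pos)
        if m is None:
            raise CriteriaParseError(
                f"unrecognized token at {norm[pos:]!r} in criteria string {text!r}"
            )
        codes.append(EVIDENCE_CODES[m.group(0)])
        pos = m.end()
    if len(codes) != len(set(codes)):
        warnings.warn(f"duplicate evidence tokens in {text!r} collapsed", stacklevel=2)
    return CriteriaSet(frozenset(codes))


def format_criteria(criteria: CriteriaSet) -> str:
    """Canonical rendering: pathogenic before benign, strongest first, index ascending."""
    def key(c: EvidenceCode):
        return (c.category is not EvidenceCategory.PATHOGENIC, -int(c.strength), c.index)

    return "".join(c.token for c in sorted(criteria.codes, key=key))


class Zygosity(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    HEMIZYGOUS = "hemizygous"


VALID_MODES = frozenset({"AD", "AR", "XLR"})


@dataclass
class VariantRecord:
    """One patient-variant pair as reported by a diagnostic panel."""

    patient_id: str
    gene: str
    cdna: CdnaChange
    protein: ProteinChange
    zygosity: Zygosity
    criteria: CriteriaSet
    reported_class: Optional[str] = None  # P, LP, VUS, LB, B
    inheritance_modes: frozenset[str] = frozenset()
    novel: bool = False
    dann_score: Optional[float] = None  # annotation only, never used in computation
    transcript: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.gene:
            raise ValueError("gene must be non-empty")
        bad = set(self.inheritance_modes) - VALID_MODES
        if bad:
            raise ValueError(f"unknown inheritance modes: {sorted(bad)}")
        if self.zygosity is Zygosity.HEMIZYGOUS and "XLR" not in self.inheritance_modes:
            raise ValueError(
                f"{self.patient_id}/{self.gene}: hemizygous zygosity requires an "
                "X-linked recessive inheritance mode"
            )

    @property
    def normalized_cdna(self) -> str:
        return normalize_hgvs_text(self.cdna.raw_text)

    def consequence(self, splice_window: int = 20) -> ConsequenceType:
        return classify_consequence(self.cdna, self.protein, splice_window)
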