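import pytest
from hypothesis import given
from hypothesis import strategies as st

from irdtriage.variant_model import (
    EVIDENCE_CODES,
    CdnaChange,
    ConsequenceType,
    CriteriaParseError,
    EditKind,
    EvidenceCategory,
    EvidenceStrength,
    HgvsParseError,
    ProteinKind,
    classify_consequence,
    format_criteria,
    normalize_hgvs_text,
    parse_cdna,
    parse_criteria_string,
    parse_protein,
)


class TestParseCdna:
    @pytest.mark.parametrize(
        "text, kind, start, end, ref, alt",
        [
            ("c.3244G>T", EditKind.SUBSTITUTION, (3244, 0), (3244, 0), "G", "T"),
            # en-dash typography as found in published tables
            ("c.12067–2A>G", EditKind.SUBSTITUTION, (12067, -2), (12067, -2), "A", "G"),
            ("c.9_10dupGG", EditKind.DUPLICATION, (9, 0), (10, 0), "GG", ""),
            ("c.802–8_810delinsGC", EditKind.DELINS, (802, -8), (810, 0), "", "GC"),
            ("c.871delT", EditKind.DELETION, (871, 0), (871, 0), "T", ""),
            ("c.269del", EditKind.DELETION, (269, 0), (269, 0), "", ""),
            ("c.1356+3_1356+6del", EditKind.DELETION, (1356, 3), (1356, 6), "", ""),
            ("c.3228+13G>A", EditKind.SUBSTITUTION, (3228, 13), (3228, 13), "G", "A"),
            ("c.461_464delinsTGGTCT", EditKind.DELINS, (461, 0), (464, 0), "", "TGGTCT"),
            ("c.45_46insAT", EditKind.INSERTION, (45, 0), (46, 0), "", "AT"),
        ],
    )
    def test_supported_syntax(self, text, kind, start, end, ref, alt):
        c = parse_cdna(text)
        assert c.edit_kind is kind
        assert (c.start_anchor, c.start_offset) == start
        assert (c.end_anchor, c.end_offset) == end
        assert (c.ref_bases, c.alt_bases) == (ref, alt)

    @pytest.mark.parametrize(
        "text",
        ["g.123A>T", "p.Arg37*", "c.123A>U", "c.A>T", "c.12-xA>G", "c.", "c.10_5del"],
    )
    def test_rejects_bad_syntax(self, text):
        with pytest.raises(HgvsParseError):
            parse_cdna(text)

    def test_rejection_names_the_prefix(self):
        with pytest.raises(HgvsParseError, match="prefix"):
            parse_cdna("g.123A>T")

    @pytest.mark.parametrize(
        "text",
        ["c.3244G>T", "c.12067–2A>G", "c.802–8_810delinsGC", "c.9_10dupGG", "c.269del"],
    )
    def test_format_round_trip(self, text):
        c = parse_cdna(text)
        assert c.format() == normalize_hgvs_text(text)
        assert parse_cdna(c.format()) == c

    def test_fixture_round_trip(self, table2_records):
        """Every cohort variant string survives parse -> format -> parse."""
        for rec in table2_records:
            c = rec.cdna
            assert c.format() == normalize_hgvs_text(c.raw_text)
            reparsed = parse_cdna(c.format())
            assert reparsed.edit_kind is c.edit_kind
            assert reparsed.format() == c.format()


class TestParseProtein:
    @pytest.mark.parametrize(
        "text, kind, pos, ref, alt, fs",
        [
            ("(p.Glu4Glyfs*41)", ProteinKind.FRAMESHIFT, 4, "Glu", "Gly", 41),
            ("(p.Ser2043ArgfsTer6)", ProteinKind.FRAMESHIFT, 2043, "Ser", "Arg", 6),
            ("(p.?)", ProteinKind.UNKNOWN, None, None, None, None),
            ("p.Gly706Gly", ProteinKind.SYNONYMOUS, 706, "Gly", "Gly", None),
            # stray internal space as printed in one table row
            ("p.Arg 4192Gly", ProteinKind.SUBSTITUTION, 4192, "Arg", "Gly", None),
            ("(p.Arg675*)", ProteinKind.NONSENSE, 675, "Arg", "*", None),
            ("p.Trp3955Ter", ProteinKind.NONSENSE, 3955, "Trp", "*", None),
            ("—", ProteinKind.UNKNOWN, None, None, None, None),
        ],
    )
    def test_supported_syntax(self, text, kind, pos, ref, alt, fs):
        p = parse_protein(text)
        assert p.kind is kind
        assert p.residue_position == pos
        assert p.ref_residue == ref
        assert p.alt_residue == alt
        assert p.fs_stop_distance == fs

    def test_star_and_ter_are_the_same_stop(self):
        assert parse_protein("p.Arg37*").kind is parse_protein("p.Arg37Ter").kind

    @pytest.mark.parametrize("text", ["c.100A>G", "p.Xyz12Arg", "p.Arg12"])
    def test_rejects_bad_syntax(self, text):
        with pytest.raises(HgvsParseError):
            parse_protein(text)


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "cdna, protein, expected",
        [
            # protein-level evidence wins over the DNA edit kind
            ("c.1744_1751delinsT", "(p.Ile582*)", ConsequenceType.NONSENSE),
            ("c.802–8_810delinsGC", "(p.?)", ConsequenceType.DELINS),
            ("c.12067–2A>G", "(p.?)", ConsequenceType.SPLICE_SITE),
            ("c.5882G>A", "(p.Gly1961Glu)", ConsequenceType.MISSENSE),
            ("c.9_10dupGG", "(p.Glu4Glyfs*41)", ConsequenceType.FRAMESHIFT),
            ("c.2118G>T", "(p.Gly706Gly)", ConsequenceType.SYNONYMOUS),
            ("c.1356+3_1356+6del", "(p.?)", ConsequenceType.DELETION),
            ("c.3228+13G>A", "(p.?)", ConsequenceType.SPLICE_SITE),
            ("c.100+35A>G", "(p.?)", ConsequenceType.INTRONIC_OTHER),
            ("c.100A>G", "(p.?)", ConsequenceType.UNKNOWN),
        ],
    )
    def test_classification(self, cdna, protein, expected):
        assert classify_consequence(parse_cdna(cdna), parse_protein(protein)) is expected

    def test_window_never_converts_protein_decided_classes(self, table2_records):
        """Shrinking the splice window only moves protein-unknown intronic calls."""
        for rec in table2_records:
            wide = classify_consequence(rec.cdna, rec.protein, splice_window=20)
            narrow = classify_consequence(rec.cdna, rec.protein, splice_window=2)
            if rec.protein.kind is not ProteinKind.UNKNOWN:
                assert wide is narrow
            elif wide is not narrow:
                assert wide is ConsequenceType.SPLICE_SITE
                assert narrow is ConsequenceType.INTRONIC_OTHER


class TestCriteriaGrammar:
    def test_vocabulary_is_exactly_28_tokens(self):
        assert len(EVIDENCE_CODES) == 28
        assert {c.category for c in EVIDENCE_CODES.values()} == set(EvidenceCategory)

    @pytest.mark.parametrize(
        "text, tokens",
        [
            ("PVS1PM2PS4PP5", {"PVS1", "PM2", "PS4", "PP5"}),
            ("PVS1PM3PM2BS2PP5", {"PVS1", "PM3", "PM2", "BS2", "PP5"}),
            ("", set()),
        ],
    )
    def test_parses_concatenated_tokens(self, text, tokens):
        assert parse_criteria_string(text).tokens() == frozenset(tokens)

    def test_rejects_unknown_residue_by_name(self):
        with pytest.raises(CriteriaParseError, match="PX9"):
            parse_criteria_string("PM2PX9")

    def test_duplicates_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            s = parse_criteria_string("PM2PM2")
        assert s.tokens() == frozenset({"PM2"})

    def test_canonical_ordering(self):
        s = parse_criteria_string("PM2PVS1")
        assert format_criteria(s) == "PVS1PM2"
        assert format_criteria(parse_criteria_string("")) == ""
        # benign after pathogenic, strength descending, index ascending
        s = parse_criteria_string("BP4BS2PP1PM2PS1PVS1BA1PP3")
        assert format_criteria(s) == "PVS1PS1PM2PP1PP3BA1BS2BP4"

    def test_fixture_strings_round_trip(self, table2_records):
        for rec in table2_records:
            assert parse_criteria_string(format_criteria(rec.criteria)).codes == rec.criteria.codes

    @given(st.lists(st.sampled_from(sorted(EVIDENCE_CODES)), max_size=8))
    def test_token_concatenations_always_parse(self, tokens):
        text = "".join(tokens)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = parse_criteria_string(text)
        assert s.tokens() == frozenset(tokens)

    @given(st.text(alphabet="PVSMBA1234567890", max_size=12))
    def test_fuzzed_strings_parse_or_fail_locally(self, text):
        """Arbitrary strings over the token alphabet never crash the parser."""
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = parse_criteria_string(text)
        except CriteriaParseError as exc:
            assert "unrecognized token" in str(exc)
        else:
            assert s.tokens() <= set(EVIDENCE_CODES)


class TestVariantRecordInvariants:
    def test_hemizygous_requires_xlr(self, table2_records):
        from irdtriage.variant_model import VariantRecord, Zygosity

        template = table2_records[0]
        with pytest.raises(ValueError, match="hemizygous"):
            VariantRecord(
                patient_id="X1",
                gene="RS1",
                cdna=template.cdna,
                protein=template.protein,
                zygosity=Zygosity.HEMIZYGOUS,
                criteria=template.criteria,
                inheritance_modes=frozenset({"AR"}),
            )

    def test_substitution_needs_single_bases(self):
        with pytest.raises(HgvsParseError):
            CdnaChange(
                raw_text="bad",
                edit_kind=EditKind.SUBSTITUTION,
                start_anchor=1,
                start_offset=0,
                end_anchor=1,
                end_offset=0,
                ref_bases="AT",
                alt_bases="G",
            )

    def test_strength_order(self):
        assert EvidenceStrength.SUPPORTING < EvidenceStrength.MODERATE < EvidenceStrength.STRONG < EvidenceStrength.VERY_STRONG
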