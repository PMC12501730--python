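import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from irdtriage.cascade import (
    STAGE_NAMES,
    AnnotatedCall,
    CascadeConfig,
    ClinvarAssertion,
    SampleQC,
    SplicePrediction,
    SynonymousRescue,
    filter_clinvar,
    filter_consequence_class,
    filter_population_frequency,
    filter_vaf,
    qc_sample,
    report_clinically_relevant,
    run_cascade,
)
from irdtriage.synthetic import PlantedFate, SimulationConfig, generate_cohort
from irdtriage.variant_model import (
    VariantRecord,
    Zygosity,
    parse_cdna,
    parse_criteria_string,
    parse_protein,
)


def make_call(
    cdna="c.100A>G",
    protein="p.Arg34Gly",
    vaf=0.5,
    gnomad=None,
    kg=None,
    esp=None,
    clinvar=ClinvarAssertion.NONE,
    mt=SplicePrediction.UNAVAILABLE,
    hsf=SplicePrediction.UNAVAILABLE,
    patient="T1",
    gene="GENE1",
    criteria="",
):
    core = VariantRecord(
        patient_id=patient,
        gene=gene,
        cdna=parse_cdna(cdna),
        protein=parse_protein(protein),
        zygosity=Zygosity.HETEROZYGOUS,
        criteria=parse_criteria_string(criteria),
        inheritance_modes=frozenset({"AR"}),
    )
    return AnnotatedCall(
        core=core,
        variant_fraction=vaf,
        freq_gnomad=gnomad,
        freq_1000g=kg,
        freq_esp=esp,
        clinvar_assertion=clinvar,
        splice_pred_mt=mt,
        splice_pred_hsf=hsf,
    )


class TestSampleQC:
    @pytest.mark.parametrize(
        "ratios, passed",
        [
            ((1.9, 2.0, 150), True),
            ((1.7, 2.0, 150), False),
            ((1.8, 2.2, 100), True),  # boundaries inclusive
            ((1.9, 2.3, 150), False),
            ((1.9, 2.0, 99.9), False),
        ],
    )
    def test_thresholds(self, ratios, passed):
        result = qc_sample(SampleQC(*ratios))
        assert result.passed is passed

    def test_failure_names_the_offending_ratio(self):
        result = qc_sample(SampleQC(1.7, 2.0, 150))
        assert any("a260_280" in r for r in result.reasons)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            SampleQC(-0.1, 2.0, 100)


class TestIndividualFilters:
    @pytest.mark.parametrize("vaf, kept", [(0.14, False), (0.15, True), (0.5, True), (1.0, True)])
    def test_vaf_boundaries(self, vaf, kept):
        kept_calls, removed = filter_vaf([make_call(vaf=vaf)])
        assert bool(kept_calls) is kept

    def test_missing_vaf_routed_with_reason(self):
        _, removed = filter_vaf([make_call(vaf=None)])
        assert removed[0][1] == "missing_vaf"

    @pytest.mark.parametrize(
        "freqs, kept",
        [
            ((0.0005, None, None), True),
            ((0.0005, 0.002, None), False),  # max over databases decides
            ((None, None, None), True),  # unobserved variants pass
            ((0.001, None, None), False),  # threshold itself removed ("below")
        ],
    )
    def test_frequency_rule(self, freqs, kept):
        g, k, e = freqs
        kept_calls, _ = filter_population_frequency([make_call(gnomad=g, kg=k, esp=e)])
        assert bool(kept_calls) is kept

    def test_missing_frequency_can_be_configured_to_fail(self):
        config = CascadeConfig(missing_frequency_passes=False)
        kept, removed = filter_population_frequency([make_call()], config)
        assert not kept and removed[0][1] == "no_population_frequency"

    @pytest.mark.parametrize(
        "assertion, kept",
        [
            (ClinvarAssertion.BENIGN, False),
            (ClinvarAssertion.LIKELY_BENIGN, False),
            (ClinvarAssertion.CONFLICTING, True),
            (ClinvarAssertion.NONE, True),
            (ClinvarAssertion.PATHOGENIC, True),
        ],
    )
    def test_clinvar_rule(self, assertion, kept):
        kept_calls, _ = filter_clinvar([make_call(clinvar=assertion)])
        assert bool(kept_calls) is kept

    @pytest.mark.parametrize(
        "call, kept",
        [
            (make_call(), True),  # missense
            (make_call(protein="p.Arg34*"), True),  # nonsense
            (make_call(cdna="c.100-2A>G", protein="p.?"), True),  # splice site
            (make_call(cdna="c.100+35A>G", protein="p.?"), False),  # deep intronic
            (make_call(protein="p.Gly34Gly", mt=SplicePrediction.NO_EFFECT, hsf=SplicePrediction.NO_EFFECT), False),
            (make_call(protein="p.Gly34Gly", mt=SplicePrediction.AFFECTS, hsf=SplicePrediction.NO_EFFECT), True),
            (make_call(protein="p.Gly34Gly"), True),  # no predictions: keep
        ],
    )
    def test_consequence_selection(self, call, kept):
        kept_calls, _ = filter_consequence_class([call])
        assert bool(kept_calls) is kept

    def test_any_predictor_rescue_mode(self):
        call = make_call(
            protein="p.Gly34Gly",
            mt=SplicePrediction.AFFECTS,
            hsf=SplicePrediction.NO_EFFECT,
        )
        config = CascadeConfig(synonymous_rescue=SynonymousRescue.ANY_PREDICTOR)
        kept, removed = filter_consequence_class([call], config)
        assert not kept and removed[0][1] == "synonymous_no_splice_effect"

    def test_frequency_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            make_call(gnomad=1.5)


class TestRunCascade:
    def build_constructed_batch(self):
        """One call per planted failure mode plus one clean call."""
        return [
            make_call(patient="A", vaf=0.05),
            make_call(patient="B", gnomad=0.02),
            make_call(patient="C", clinvar=ClinvarAssertion.LIKELY_BENIGN),
            make_call(
                patient="D",
                protein="p.Gly34Gly",
                mt=SplicePrediction.NO_EFFECT,
                hsf=SplicePrediction.NO_EFFECT,
            ),
            make_call(patient="E", cdna="c.100+35A>G", protein="p.?"),
            make_call(patient="CLEAN"),
        ]

    def test_each_stage_removes_its_planted_call(self):
        survivors, funnel = run_cascade(self.build_constructed_batch())
        assert [c.core.patient_id for c in survivors] == ["CLEAN"]
        removed_by_stage = {st.name: len(st.removed) for st in funnel.stages}
        assert removed_by_stage == {"vaf": 1, "frequency": 1, "clinvar": 1, "consequence": 2}

    def test_empty_input(self):
        survivors, funnel = run_cascade([])
        assert survivors == [] and funnel.n_input == 0 and funnel.n_survivors == 0

    def test_all_clean_input_survives(self):
        calls = [make_call(patient=f"P{i}") for i in range(7)]
        survivors, funnel = run_cascade(calls)
        assert len(survivors) == 7 and funnel.n_survivors == 7

    def test_funnel_conservation_on_synthetic_batch(self):
        calls, _, _ = generate_cohort(SimulationConfig(seed=11, n_patients=40))
        survivors, funnel = run_cascade(calls)
        removed = sum(len(st.removed) for st in funnel.stages)
        assert removed + len(survivors) == len(calls)
        funnel.validate()

    def test_survivor_set_invariant_under_all_stage_orders(self):
        calls, _, _ = generate_cohort(SimulationConfig(seed=13, n_patients=25))
        reference = None
        for order in itertools.permutations(STAGE_NAMES):
            survivors, _ = run_cascade(calls, stage_order=order)
            ids = {c.call_id for c in survivors}
            if reference is None:
                reference = ids
            assert ids == reference

    def test_bad_stage_order_rejected(self):
        with pytest.raises(ValueError):
            run_cascade([], stage_order=("vaf", "vaf", "clinvar", "consequence"))

    @given(st.floats(min_value=0.15, max_value=0.6), st.floats(min_value=0.0001, max_value=0.001))
    def test_tightening_thresholds_never_grows_survivors(self, vaf_min, maf):
        calls, _, _ = generate_cohort(SimulationConfig(seed=17, n_patients=15))
        base, _ = run_cascade(calls)
        tight, _ = run_cascade(calls, CascadeConfig(vaf_min=vaf_min, maf_threshold=maf))
        assert {c.call_id for c in tight} <= {c.call_id for c in base}

    def test_planted_fates_recovered_exactly(self):
        calls, _, truth = generate_cohort(SimulationConfig(seed=19, n_patients=60))
        survivors, funnel = run_cascade(calls)
        assert {c.call_id for c in survivors} == truth.planted_survivor_ids()
        stage_for_fate = {
            PlantedFate.FAILS_VAF: "vaf",
            PlantedFate.FAILS_FREQUENCY: "frequency",
            PlantedFate.FAILS_CLINVAR: "clinvar",
            PlantedFate.FAILS_CONSEQUENCE: "consequence",
        }
        removed_at = {
            cid: st.name for st in funnel.stages for cid, _ in st.removed
        }
        for cid, fate in truth.record_fates.items():
            if fate is not PlantedFate.SURVIVOR:
                assert removed_at[cid] == stage_for_fate[fate]


class TestClinicalReporting:
    def test_plp_survivors_are_reportable(self):
        survivors = [
            make_call(patient="R1", criteria="PVS1PM2"),  # LP
            make_call(patient="R2", criteria=""),  # VUS
            make_call(patient="R3", criteria="BA1"),  # B
        ]
        reportable, non_reportable = report_clinically_relevant(survivors)
        assert [r.patient_id for r in reportable] == ["R1"]
        assert {r.patient_id: c.name for r, c in non_reportable} == {"R2": "VUS", "R3": "B"}
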