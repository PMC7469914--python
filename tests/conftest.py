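import pytest

from drugtrader.interaction_store import (
    AdverseReactionMatrix,
    Candidate,
    CandidateDataset,
    DrugDiseaseMatrix,
    DrugTargetMatrix,
    EffectLabel,
    HTTargetSet,
    TargetRelation,
)

INH, IND, AGO, ANT = (
    EffectLabel.INH,
    EffectLabel.IND,
    EffectLabel.AGO,
    EffectLabel.ANT,
)


@pytest.fixture
def small_dataset() -> CandidateDataset:
    """Three candidates over two main targets, one adverse pair.

    d1 covers T1 at zero side effects, d2 and d3 cover T2 at 2 and 4 side
    effects; d2-d3 is an adverse pair.  Hand arithmetic: {d1} scores 1,
    {d1, d3} scores 2 - 4/2 = 0.
    """
    return CandidateDataset(
        given_drug="GIVEN",
        main_targets=HTTargetSet([("T1", INH), ("T2", AGO)]),
        candidates=[
            Candidate("d1", frozenset({"T1"}), 0),
            Candidate("d2", frozenset({"T2"}), 2),
            Candidate("d3", frozenset({"T2"}), 4),
        ],
        adverse_pairs={("d2", "d3")},
    )


@pytest.fixture
def rule_fixture():
    """Twelve-drug matrices exercising all five admission rules.

    The disease target set derives to {(ACE, INH), (AT1R, ANT)} from the two
    indicated drugs.  One drug per rule template is admitted; the excluded
    drugs are an agonist of AT1R where antagonism is required (the
    exact-function counter-example), a drug behind a relation whose effect
    does not match, a drug on an unrelated target, and a drug acting on ACE
    with the wrong effect.
    """
    drugs = [
        "CANDESARTAN", "ANGIOTENSIN2", "CAPTOPRIL", "D_E_A", "D_P_B",
        "D_P_C", "D_E_D", "D_DECOY", "D_NOWHERE", "D_WRONGEFF",
        "GIV1", "GIV2",
    ]
    targets = ["ACE", "AT1R", "E_a", "P_b", "P_c", "E_d", "E_e", "U1"]
    classes = {
        "ACE": "enzyme", "AT1R": "protein", "E_a": "enzyme", "P_b": "protein",
        "P_c": "protein", "E_d": "enzyme", "E_e": "enzyme", "U1": "protein",
    }
    cells = {
        ("CANDESARTAN", "AT1R"): ANT,
        ("ANGIOTENSIN2", "AT1R"): AGO,
        ("CAPTOPRIL", "ACE"): INH,
        ("D_E_A", "E_a"): INH,
        ("D_P_B", "P_b"): AGO,
        ("D_P_C", "P_c"): INH,
        ("D_E_D", "E_d"): IND,
        ("D_DECOY", "E_e"): INH,
        ("D_NOWHERE", "U1"): INH,
        ("D_WRONGEFF", "ACE"): AGO,
        ("GIV1", "AT1R"): ANT,
        ("GIV2", "ACE"): INH,
    }
    dt = DrugTargetMatrix(drugs, targets, cells, classes)
    ddi = DrugDiseaseMatrix(
        drugs, ["HT", "OTHER"], {("GIV1", "HT"), ("GIV2", "HT"), ("D_NOWHERE", "OTHER")}
    )
    ddar = AdverseReactionMatrix(drugs, set())
    relations = [
        TargetRelation("E_a", "enzyme", "AT1R", "protein", ANT),  # rule 2
        TargetRelation("P_b", "protein", "ACE", "enzyme", INH),  # rule 3
        TargetRelation("P_c", "protein", "AT1R", "protein", ANT),  # rule 4
        TargetRelation("E_d", "enzyme", "ACE", "enzyme", INH),  # rule 5
        TargetRelation("E_e", "enzyme", "AT1R", "protein", AGO),  # effect mismatch
    ]
    expected_admitted = {
        "CANDESARTAN", "CAPTOPRIL", "D_E_A", "D_P_B", "D_P_C", "D_E_D",
        "GIV1", "GIV2",
    }
    return ddi, dt, ddar, relations, expected_admitted
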