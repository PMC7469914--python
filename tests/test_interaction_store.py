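import pytest

from drugtrader.interaction_store import (
    AdverseReactionMatrix,
    Candidate,
    CandidateDataset,
    DrugTargetMatrix,
    EffectLabel,
    EmptyInstanceError,
    HTTargetSet,
    ValidationError,
    build_candidate_dataset,
    load_matrices,
    save_matrices,
)
from drugtrader.synthetic_data import dataset_to_matrices, generate, preset_spec

INH, AGO, ANT = EffectLabel.INH, EffectLabel.AGO, EffectLabel.ANT


def _write(tmp_path, name, lines):
    (tmp_path / name).write_text("\n".join(lines) + "\n")


def _write_empty_siblings(tmp_path, *skip):
    headers = {
        "drug_target.tsv": "drug\ttarget\ttarget_class\teffect",
        "drug_disease.tsv": "drug\tdisease",
        "ddar.tsv": "drug_a\tdrug_b",
        "target_relations.tsv": "source\tsource_class\tsink\tsink_class\teffect",
    }
    for name, header in headers.items():
        if name not in skip:
            _write(tmp_path, name, [header])


class TestLoadMatrices:
    def test_three_row_drug_target_parse(self, tmp_path):
        _write_empty_siblings(tmp_path, "drug_target.tsv")
        _write(
            tmp_path,
            "drug_target.tsv",
            [
                "drug\ttarget\ttarget_class\teffect",
                "d1\tt1\tprotein\tINH",
                "d1\tt2\tprotein\tAGO",
                "d2\tt1\tprotein\tINH",
            ],
        )
        _, dt, _, _ = load_matrices(tmp_path)
        assert dt.drugs == ["d1", "d2"]
        assert dt.targets == ["t1", "t2"]
        assert len(dt.cells) == 3
        assert dt.effect("d1", "t2") is AGO
        assert dt.effect("d2", "t2") is EffectLabel.NONE

    def test_header_only_files_yield_empty_valid_matrices(self, tmp_path):
        _write_empty_siblings(tmp_path)
        ddi, dt, ddar, relations = load_matrices(tmp_path)
        assert dt.drugs == [] and dt.cells == {}
        assert ddi.pairs == set() and ddar.pairs == set() and relations == []

    def test_unknown_effect_label_cites_line(self, tmp_path):
        _write_empty_siblings(tmp_path, "drug_target.tsv")
        _write(
            tmp_path,
            "drug_target.tsv",
            ["drug\ttarget\ttarget_class\teffect", "d1\tt1\tprotein\tBLOCKS"],
        )
        with pytest.raises(ValidationError, match=r"BLOCKS.*line 2"):
            load_matrices(tmp_path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_matrices(tmp_path)

    def test_round_trip_reproduces_cells(self, tmp_path):
        dataset = generate(preset_spec("CAR", seed=5))
        ddi, dt, ddar = dataset_to_matrices(dataset)
        save_matrices(tmp_path, ddi, dt, ddar)
        ddi2, dt2, ddar2, _ = load_matrices(tmp_path)
        assert dt2.cells == dt.cells
        assert ddi2.pairs == ddi.pairs
        assert ddar2.pairs == ddar.pairs


class TestAdverseReactionMatrix:
    def test_pairs_canonicalized_symmetric(self):
        m = AdverseReactionMatrix(["a", "b", "c"], {("c", "a"), ("a", "b")})
        assert m.adverse("a", "c") and m.adverse("c", "a")
        assert m.pairs == {("a", "b"), ("a", "c")}

    def test_self_pair_rejected(self):
        with pytest.raises(ValidationError):
            AdverseReactionMatrix(["a"], {("a", "a")})

    def test_restriction_preserves_symmetry(self):
        m = AdverseReactionMatrix(["a", "b", "c"], {("a", "b"), ("b", "c")})
        r = m.restricted(["b", "c"])
        assert r.pairs == {("b", "c")}
        assert r.adverse("c", "b")


class TestHTTargetSet:
    def test_requires_nonempty_unique_real_effects(self):
        with pytest.raises(ValidationError):
            HTTargetSet([])
        with pytest.raises(ValidationError):
            HTTargetSet([("t", INH), ("t", INH)])
        with pytest.raises(ValidationError):
            HTTargetSet([("t", EffectLabel.NONE)])

    def test_conflicting_effects_for_one_target_allowed(self):
        ht = HTTargetSet([("t", INH), ("t", AGO)])
        assert ht.required("t") == {INH, AGO}
        assert ht.targets() == ["t"]


class TestBuildCandidateDataset:
    @pytest.fixture
    def dt(self):
        cells = {
            ("GIVEN", "T1"): ANT,
            ("dA", "T1"): ANT,  # matches required effect
            ("dA", "X1"): INH,
            ("dB", "T1"): AGO,  # wrong effect: excluded
            ("dC", "T1"): ANT,
            ("dC", "X1"): INH,
            ("dC", "X2"): INH,
        }
        return DrugTargetMatrix(
            ["GIVEN", "dA", "dB", "dC"], ["T1", "X1", "X2"], cells
        )

    def test_effect_matched_candidates_only(self, dt):
        ht = HTTargetSet([("T1", ANT)])
        ddar = AdverseReactionMatrix(dt.drugs, set())
        ds = build_candidate_dataset("GIVEN", ht, dt, ddar, {"dA", "dB", "dC"})
        assert ds.drug_names == ["dA", "dC"]
        assert ds.m <= len(dt.drugs) - 1

    def test_se_is_total_minus_covered(self, dt):
        ht = HTTargetSet([("T1", ANT)])
        ddar = AdverseReactionMatrix(dt.drugs, set())
        ds = build_candidate_dataset("GIVEN", ht, dt, ddar, {"dA", "dC"})
        se = {c.drug: c.se for c in ds.candidates}
        assert se == {"dA": 1, "dC": 2}

    def test_absent_given_drug_is_lookup_error(self, dt):
        ht = HTTargetSet([("T1", ANT)])
        with pytest.raises(KeyError):
            build_candidate_dataset("nope", ht, dt, AdverseReactionMatrix(dt.drugs, set()), set())

    def test_no_matching_candidates_is_empty_instance(self, dt):
        ht = HTTargetSet([("T1", ANT)])
        ddar = AdverseReactionMatrix(dt.drugs, set())
        with pytest.raises(EmptyInstanceError):
            build_candidate_dataset("GIVEN", ht, dt, ddar, {"dB"})

    def test_nicardipine_shaped_instance(self):
        """A pool of 40 candidates over 4 main targets, matching the
        published Nicardipine instance shape (15 targets, 4 main, 40
        candidates)."""
        ds = generate(preset_spec("NIC"))
        assert ds.m == 40
        assert ds.main_targets.n == 4

    def test_se_matches_brute_force_recount_from_matrices(self):
        dataset = generate(preset_spec("ATE", seed=11))
        ddi, dt, ddar = dataset_to_matrices(dataset)
        required = dict(dataset.main_targets.entries)
        ht = HTTargetSet(list(dataset.main_targets.entries))
        rebuilt = build_candidate_dataset(
            dataset.given_drug, ht, dt, ddar, set(dataset.drug_names)
        )
        for cand in rebuilt.candidates:
            hits = dt.targets_of(cand.drug)
            covered = {t for t, r in required.items() if hits.get(t) is r}
            assert cand.covered == covered
            assert cand.se == len(hits) - len(covered)


class TestCandidateDataset:
    def test_candidate_must_cover_something(self):
        with pytest.raises(ValidationError):
            Candidate("d", frozenset(), 0)

    def test_coverage_outside_main_set_rejected(self):
        with pytest.raises(ValidationError):
            CandidateDataset(
                "g",
                HTTargetSet([("T1", INH)]),
                [Candidate("d", frozenset({"T9"}), 0)],
            )

    def test_adverse_pairs_canonicalized(self, small_dataset):
        assert small_dataset.adverse_pairs == {("d2", "d3")}
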