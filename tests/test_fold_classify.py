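"""Fold classification, PFAM filtering, and dimer sequence preparation."""

import pytest
from hypothesis import given, settings, strategies as st

from memqa.errors import ConfigError, DomtblParseError, SequenceError
from memqa.fold_classify import (
    PfamHit,
    classify_fold,
    load_reference_library,
    parse_domtbl,
    pfam_filter,
    prepare_dimer_sequence,
    verdict_from_score,
)
from memqa.structure_io import write_structure
from memqa.synthetic_data import (
    DISORDERED_LINKER_126,
    generate_coil,
    perturb_structure,
    write_fixture_domtbl,
)


class TestVerdict:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (1.0, "same_fold"),
            (0.5, "same_fold"),   # boundary included
            (0.49, "twilight"),
            (0.31, "twilight"),
            (0.3, "unrelated"),   # boundary included
            (0.05, "unrelated"),
        ],
    )
    def test_thresholds(self, score, expected):
        assert verdict_from_score(score) == expected


class TestClassifyFold:
    def test_library_member_classifies_to_itself(self, reference_library):
        ref = reference_library[1]
        assignment = classify_fold(ref.structure, reference_library)
        assert assignment.best_fold == ref.fold_name
        assert assignment.best_score == 1.0
        assert assignment.verdict == "same_fold"
        assert set(assignment.scores) == {r.fold_name for r in reference_library}

    def test_perturbed_copy_recovers_fold(self, reference_library):
        ref = reference_library[4]
        query = perturb_structure(ref.structure, 77, noise_sigma=0.5)
        assignment = classify_fold(query, reference_library)
        assert assignment.best_fold == ref.fold_name
        assert assignment.best_score > 0.5
        assert assignment.verdict == "same_fold"

    def test_random_coil_is_unrelated(self, reference_library):
        assignment = classify_fold(generate_coil(60, 42), reference_library)
        assert assignment.verdict == "unrelated"

    def test_empty_library_rejected(self, reference_library):
        with pytest.raises(ConfigError):
            classify_fold(reference_library[0].structure, [])

    def test_best_score_is_max(self, reference_library):
        assignment = classify_fold(generate_coil(60, 8), reference_library)
        assert assignment.best_score == max(assignment.scores.values())
        assert all(0 < v <= 1 for v in assignment.scores.values())


class TestPfamFilter:
    GRID = [
        # E-values x coverage grid on a 100-position profile
        PfamHit("t_e4_c089", "P", 100, 1e-4, 1, 89),
        PfamHit("t_e4_c090", "P", 100, 1e-4, 11, 100),
        PfamHit("t_e4_c100", "P", 100, 1e-4, 1, 100),
        PfamHit("t_e3_c089", "P", 100, 1e-3, 1, 89),
        PfamHit("t_e3_c090", "P", 100, 1e-3, 11, 100),
        PfamHit("t_e3_c100", "P", 100, 1e-3, 1, 100),
        PfamHit("t_e2_c089", "P", 100, 1e-2, 1, 89),
        PfamHit("t_e2_c090", "P", 100, 1e-2, 11, 100),
        PfamHit("t_e2_c100", "P", 100, 1e-2, 1, 100),
    ]

    def test_grid_selection(self):
        kept = {h.target_id for h in pfam_filter(self.GRID)}
        assert kept == {"t_e4_c090", "t_e4_c100", "t_e3_c090", "t_e3_c100"}

    def test_coverage_exactly_90_percent_kept(self):
        hit = PfamHit("t", "P", 100, 1e-4, 11, 100)
        assert pfam_filter([hit]) == [hit]

    def test_coverage_89_rejected(self):
        assert pfam_filter([PfamHit("t", "P", 100, 1e-4, 12, 100)]) == []

    def test_e_value_boundary_inclusive(self):
        assert len(pfam_filter([PfamHit("t", "P", 100, 1e-3, 1, 100)])) == 1
        assert pfam_filter([PfamHit("t", "P", 100, 1.01e-3, 1, 100)]) == []

    def test_dedup_keeps_lowest_e(self):
        hits = [
            PfamHit("t", "A", 100, 1e-4, 1, 100),
            PfamHit("t", "B", 100, 1e-6, 1, 100),
        ]
        kept = pfam_filter(hits)
        assert len(kept) == 1
        assert kept[0].hmm_name == "B"

    @given(st.permutations(GRID))
    @settings(max_examples=20, deadline=None)
    def test_order_independent_and_idempotent(self, shuffled):
        kept = pfam_filter(shuffled)
        assert kept == pfam_filter(self.GRID)
        assert pfam_filter(kept) == kept


class TestParseDomtbl:
    def test_comment_only_file(self, tmp_path):
        path = tmp_path / "comments.domtbl"
        path.write_text("# nothing here\n# at all\n")
        assert parse_domtbl(path) == []

    def test_truncated_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.domtbl"
        path.write_text("# header\nshort line only\n")
        with pytest.raises(DomtblParseError, match=":2:"):
            parse_domtbl(path)

    def test_full_sequence_evalue_option(self, tmp_path):
        hits = [PfamHit("q", "P", 50, 1e-5, 1, 50)]
        path = tmp_path / "one.domtbl"
        write_fixture_domtbl(hits, path)
        full = parse_domtbl(path, e_value_field="full")
        assert full[0].e_value == pytest.approx(1e-5, rel=1e-6)


class TestPrepareDimerSequence:
    def test_basic_concatenation(self):
        construct = prepare_dimer_sequence("AAA", "CCC", "GG")
        assert construct.sequence == "AAAGGCCC"
        assert construct.range_a == (1, 3)
        assert construct.range_linker == (4, 5)
        assert construct.range_b == (6, 8)

    def test_empty_linker(self):
        construct = prepare_dimer_sequence("AC", "DE", "")
        assert construct.sequence == "ACDE"
        assert construct.range_linker is None
        assert construct.range_b == (3, 4)

    def test_126_residue_linker_fixture(self):
        assert len(DISORDERED_LINKER_126) == 126
        construct = prepare_dimer_sequence("A" * 10, "C" * 20, DISORDERED_LINKER_126)
        assert len(construct.sequence) == 10 + 126 + 20

    def test_invalid_character_rejected(self):
        with pytest.raises(SequenceError):
            prepare_dimer_sequence("AAZ1", "CCC", "")


class TestLoadReferenceLibrary:
    def test_yaml_config_round_trip(self, tmp_path, reference_library):
        import yaml

        entries = []
        for ref in reference_library[:3]:
            path = tmp_path / f"{ref.fold_name}.pdb"
            write_structure(ref.structure, path)
            entries.append({"name": ref.fold_name, "path": path.name})
        cfg = tmp_path / "library.yaml"
        cfg.write_text(yaml.safe_dump({"folds": entries}))
        loaded = load_reference_library(cfg)
        assert [r.fold_name for r in loaded] == [r.fold_name for r in reference_library[:3]]
        assert all(len(r.structure) > 0 for r in loaded)

    def test_missing_folds_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("{}")
        with pytest.raises(ConfigError):
            load_reference_library(cfg)
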