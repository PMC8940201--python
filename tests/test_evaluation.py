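"""MCC and confusion-tally contracts under the negative-control design."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annotran.annotate_core import AnnotationRecord
from annotran.evaluation import (
    RANKS,
    ConfusionCounts,
    EvaluationError,
    GroundTruthEntry,
    TaxAssignment,
    classification_rate,
    functional_confusion,
    mcc,
    rank_recovery,
    read_classification_table,
    read_ground_truth,
    taxonomic_confusion,
    write_classification_table,
    write_ground_truth,
)

from conftest import reference_mcc

counts_st = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 10_000),
    fp=st.integers(0, 10_000),
    tn=st.integers(0, 10_000),
    fn=st.integers(0, 10_000),
)


class TestMcc:
    def test_perfect_classification_is_exactly_one(self):
        assert mcc(ConfusionCounts(tp=60, tn=40)) == 1.0

    def test_all_errors_is_exactly_minus_one(self):
        assert mcc(ConfusionCounts(fp=30, fn=70)) == -1.0

    def test_symmetric_case_is_zero(self):
        assert mcc(ConfusionCounts(25, 25, 25, 25)) == 0.0

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=10)) == 0.0
        assert mcc(ConfusionCounts()) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(counts_st)
    def test_matches_textbook_formula_and_range(self, counts):
        value = mcc(counts)
        assert value == pytest.approx(
            reference_mcc(counts.tp, counts.fp, counts.tn, counts.fn), abs=1e-12
        )
        assert -1.0 <= value <= 1.0

    @settings(max_examples=100, deadline=None)
    @given(counts_st, st.integers(1, 50))
    def test_swap_and_scale_invariance(self, counts, k):
        swapped = ConfusionCounts(tp=counts.tn, fp=counts.fn,
                                  tn=counts.tp, fn=counts.fp)
        scaled = ConfusionCounts(k * counts.tp, k * counts.fp,
                                 k * counts.tn, k * counts.fn)
        assert mcc(swapped) == pytest.approx(mcc(counts), abs=1e-12)
        assert mcc(scaled) == pytest.approx(mcc(counts), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


def truth_entry(read_id, species=None, nc=False, ids=frozenset()):
    lineage = {"species": species, "genus": species + "_g"} if species else {}
    return GroundTruthEntry(read_id, nc, lineage, frozenset(ids))


def assignment(read_id, species=None):
    if species is None:
        return TaxAssignment(read_id, classified=False)
    return TaxAssignment(read_id, True, {"species": species, "genus": species + "_g"})


class TestTaxonomicConfusion:
    def test_per_read_cells(self):
        truth = [
            truth_entry("tp", "Escherichia coli"),
            truth_entry("fp", "Escherichia coli"),
            truth_entry("fn", "Escherichia coli"),
            truth_entry("nc_fp", nc=True),
            truth_entry("nc_tn", nc=True),
            truth_entry("absent", "Escherichia coli"),  # missing from predictions
        ]
        preds = [
            assignment("tp", "Escherichia coli"),
            assignment("fp", "Wrong species"),
            assignment("fn"),
            assignment("nc_fp", "Anything at all"),
            assignment("nc_tn"),
        ]
        counts = taxonomic_confusion(preds, truth, "species")
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 2, 1, 2)
        assert counts.total == len(truth)

    def test_whitespace_normalised_match(self):
        truth = [truth_entry("r", "Escherichia  coli")]
        preds = [assignment("r", " Escherichia coli ")]
        assert taxonomic_confusion(preds, truth, "species").tp == 1

    def test_partial_lineage_unclassified_at_empty_rank(self):
        truth = [truth_entry("r", "Sp")]
        preds = [TaxAssignment("r", True, {"genus": "Sp_g", "species": ""})]
        assert taxonomic_confusion(preds, truth, "species").fn == 1
        assert taxonomic_confusion(preds, truth, "genus").tp == 1

    def test_unknown_prediction_read_errors(self):
        with pytest.raises(EvaluationError, match="ghost"):
            taxonomic_confusion(
                [assignment("ghost", "X")], [truth_entry("r", "X")], "species"
            )

    def test_unknown_rank_rejected(self):
        with pytest.raises(EvaluationError):
            taxonomic_confusion([], [truth_entry("r", "X")], "subspecies")

    def test_random_planted_scenario_matches_hand_tally(self):
        """500 reads with known per-read outcomes reproduce the tally."""
        rng = np.random.default_rng(41)
        truth, preds = [], []
        expected = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for i in range(500):
            rid = f"r{i}"
            cell = ("tp", "fp", "tn", "fn")[int(rng.integers(4))]
            expected[cell] += 1
            if cell in ("tn",):
                truth.append(truth_entry(rid, nc=True))
                preds.append(assignment(rid))
            elif cell == "tp":
                truth.append(truth_entry(rid, f"sp{i % 20}"))
                preds.append(assignment(rid, f"sp{i % 20}"))
            elif cell == "fn":
                truth.append(truth_entry(rid, f"sp{i % 20}"))
                if rng.random() < 0.5:
                    preds.append(assignment(rid))  # explicit U row
                # else omitted from predictions entirely
            else:  # fp: half misassigned real reads, half classified NCs
                if rng.random() < 0.5:
                    truth.append(truth_entry(rid, f"sp{i % 20}"))
                    preds.append(assignment(rid, "wrong"))
                else:
                    truth.append(truth_entry(rid, nc=True))
                    preds.append(assignment(rid, f"sp{i % 20}"))
        counts = taxonomic_confusion(preds, truth, "species")
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (
            expected["tp"], expected["fp"], expected["tn"], expected["fn"]
        )


def record(read_id, ids=None):
    if ids is None:
        return AnnotationRecord(read_id=read_id, status="unknown")
    return AnnotationRecord(read_id=read_id, status="annotated",
                            functional_ids=frozenset(ids),
                            source_subject_id="S")


class TestFunctionalConfusion:
    def test_one_shared_id_is_tp(self):
        truth = [truth_entry("r", "sp", ids={"GO:1", "GO:2"})]
        counts = functional_confusion([record("r", {"GO:2", "GO:9"})], truth)
        assert counts.tp == 1

    def test_disjoint_is_fp_missing_is_fn(self):
        truth = [truth_entry("a", "sp", ids={"GO:1"}),
                 truth_entry("b", "sp", ids={"GO:1"})]
        counts = functional_confusion(
            [record("a", {"GO:9"}), record("b")], truth
        )
        assert (counts.fp, counts.fn) == (1, 1)

    def test_nc_reads(self):
        truth = [truth_entry("nc1", nc=True), truth_entry("nc2", nc=True)]
        counts = functional_confusion([record("nc1", {"GO:9"}), record("nc2")], truth)
        assert (counts.fp, counts.tn) == (1, 1)

    def test_absent_read_counts_as_unannotated(self):
        truth = [truth_entry("r", "sp", ids={"GO:1"}), truth_entry("nc", nc=True)]
        counts = functional_confusion([], truth)
        assert (counts.fn, counts.tn) == (1, 1)

    def test_map_all_records_merged_by_union(self):
        truth = [truth_entry("r", "sp", ids={"GO:2"})]
        counts = functional_confusion(
            [record("r", {"GO:1"}), record("r", {"GO:2"})], truth
        )
        assert counts.tp == 1

    def test_planted_scenario_partition(self):
        rng = np.random.default_rng(43)
        truth, annotations = [], []
        expected = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for i in range(400):
            rid = f"r{i}"
            cell = ("tp", "fp", "tn", "fn")[int(rng.integers(4))]
            expected[cell] += 1
            if cell == "tp":
                truth.append(truth_entry(rid, "sp", ids={"GO:1", "GO:2"}))
                annotations.append(record(rid, {"GO:2", "GO:50"}))
            elif cell == "fp":
                truth.append(truth_entry(rid, "sp", ids={"GO:1"}))
                annotations.append(record(rid, {"GO:99"}))
            elif cell == "fn":
                truth.append(truth_entry(rid, "sp", ids={"GO:1"}))
                annotations.append(record(rid))
            else:
                truth.append(truth_entry(rid, nc=True))
        counts = functional_confusion(annotations, truth)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (
            expected["tp"], expected["fp"], expected["tn"], expected["fn"]
        )
        assert counts.total == len(truth)


class TestRankRecoveryAndRate:
    def test_three_of_four_species(self):
        truth = [truth_entry(f"r{i}", f"sp{i % 4}") for i in range(8)]
        preds = [assignment(f"r{i}", f"sp{i % 4}") for i in range(8) if i % 4 != 3]
        rec = rank_recovery(preds, truth, "species")
        assert (rec.n_true_taxa, rec.n_recovered, rec.proportion_pct) == (4, 3, 75)

    def test_no_reads_classified_is_zero(self):
        truth = [truth_entry("r0", "sp0"), truth_entry("r1", "sp1")]
        rec = rank_recovery([], truth, "species")
        assert rec.proportion_pct == 0

    def test_wrong_label_does_not_recover(self):
        truth = [truth_entry("r0", "sp0")]
        rec = rank_recovery([assignment("r0", "sp1")], truth, "species")
        assert rec.n_recovered == 0

    def test_planted_20_species_13_recoverable(self):
        truth = [truth_entry(f"r{i}", f"sp{i:02d}") for i in range(20)]
        preds = [assignment(f"r{i}", f"sp{i:02d}") for i in range(13)]
        assert rank_recovery(preds, truth, "species").proportion_pct == 65

    def test_monotone_in_added_tp_reads(self):
        truth = [truth_entry(f"r{i}", f"sp{i % 10}") for i in range(30)]
        last = -1
        preds = []
        for i in range(30):
            preds.append(assignment(f"r{i}", f"sp{i % 10}"))
            pct = rank_recovery(preds, truth, "species").proportion_pct
            assert pct >= last
            last = pct

    def test_zero_true_taxa_errors(self):
        with pytest.raises(EvaluationError):
            rank_recovery([], [truth_entry("r", nc=True)], "species")

    def test_classification_rate_rounding(self):
        preds = [assignment(f"r{i}", "sp") for i in range(2129)]
        preds += [assignment(f"u{i}") for i in range(507429 - 2129)]
        assert classification_rate(preds) == 0.42

    def test_classification_rate_edges(self):
        assert classification_rate([assignment("r")] * 10) == 0.00
        assert classification_rate([assignment("r", "sp")] * 3) == 100.00
        with pytest.raises(EvaluationError):
            classification_rate([])


class TestTableRoundTrip:
    def test_ground_truth_and_classification_io(self, tmp_path):
        truth = [
            truth_entry("r0", "Escherichia coli", ids={"GO:1", "GO:2"}),
            truth_entry("nc0", nc=True),
        ]
        preds = [assignment("r0", "Escherichia coli"), assignment("nc0")]
        write_ground_truth(truth, tmp_path / "t.tsv")
        write_classification_table(preds, tmp_path / "p.tsv")
        truth2 = read_ground_truth(tmp_path / "t.tsv")
        preds2 = read_classification_table(tmp_path / "p.tsv")
        c1 = taxonomic_confusion(preds, truth, "species")
        c2 = taxonomic_confusion(preds2, truth2, "species")
        assert c1 == c2
        assert truth2[0].expected_functional_ids == {"GO:1", "GO:2"}
        assert truth2[1].is_negative_control
        assert not preds2[1].classified

    def test_bad_flag_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("read_id\tclassified\nr0\tX\n")
        with pytest.raises(EvaluationError):
            read_classification_table(tmp_path / "p.tsv")
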