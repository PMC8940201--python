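"""Benchmark scoring with negative controls: MCC, rank recovery,
classification rate.

The scoring design follows the negative-control (NC) idea: NC reads are
drawn from shuffled sequences and simulate organisms absent from every
reference, so the correct behaviour of a classifier or annotator is to
leave them unassigned.  Per read, at a given taxonomic rank (or for the
functional-ID sets):

* TP — a non-NC read assigned its true label (functional: the assigned ID
  set intersects the expected set);
* FP — any read, NC or not, assigned a non-empty incorrect label (every
  assignment to an NC read is incorrect);
* FN — a non-NC read left unassigned;
* TN — an NC read left unassigned.

Every read in the ground truth contributes to exactly one cell, so
TP + FP + TN + FN equals the number of truth entries.  The Matthews
correlation coefficient then summarises the four counts in [-1, 1]:

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the conventional value 0 when any denominator factor is zero.

Reads present in the truth but absent from the assignment table are scored
as unclassified, since classifiers commonly omit unclassified reads from
their output.  Taxon labels are compared as exact strings after whitespace
normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotate_core import AnnotationRecord

__all__ = [
    "RANKS",
    "ConfusionCounts",
    "TaxAssignment",
    "GroundTruthEntry",
    "RankRecovery",
    "EvaluationError",
    "mcc",
    "taxonomic_confusion",
    "functional_confusion",
    "rank_recovery",
    "classification_rate",
    "read_classification_table",
    "read_ground_truth",
    "write_ground_truth",
    "write_classification_table",
    "evaluate_taxonomic",
    "evaluate_functional",
    "format_report",
]

#: Fixed rank ladder reported by the pipeline, coarsest to finest.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class EvaluationError(ValueError):
    """Inconsistent or degenerate evaluation input."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class TaxAssignment:
    """Predicted lineage for one read at the fixed ranks."""

    read_id: str
    classified: bool
    lineage: Mapping[str, str] = field(default_factory=dict)

    def label_at(self, rank: str) -> str:
        if not self.classified:
            return ""
        return _normalise(self.lineage.get(rank, ""))


@dataclass(frozen=True)
class GroundTruthEntry:
    """True label set for one read; NC entries carry no lineage or IDs."""

    read_id: str
    is_negative_control: bool = False
    true_lineage: Mapping[str, str] = field(default_factory=dict)
    expected_functional_ids: frozenset[str] = frozenset()

    def label_at(self, rank: str) -> str:
        return _normalise(self.true_lineage.get(rank, ""))


@dataclass(frozen=True)
class RankRecovery:
    rank: str
    n_true_taxa: int
    n_recovered: int

    @property
    def proportion_pct(self) -> int:
        """Recovered share as a percentage rounded to the nearest integer."""
        return round(100.0 * self.n_recovered / self.n_true_taxa)


def _normalise(label: str) -> str:
    return " ".join(label.split())


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when undefined."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    num = tp * tn - fp * fn
    root = math.isqrt(denom_sq)
    if root * root == denom_sq:  # exact when the product is a perfect square
        return num / root
    return num / math.sqrt(denom_sq)


def _assignments_by_read(
    assignments: Iterable[TaxAssignment],
) -> dict[str, TaxAssignment]:
    by_read: dict[str, TaxAssignment] = {}
    for a in assignments:
        by_read[a.read_id] = a
    return by_read


def _check_reads_known(
    predicted_ids: Iterable[str], truth_ids: set[str], what: str
) -> None:
    unknown = [r for r in predicted_ids if r not in truth_ids]
    if unknown:
        raise EvaluationError(
            f"{len(unknown)} {what} read id(s) absent from the ground truth, "
            f"e.g. {unknown[0]!r}"
        )


def taxonomic_confusion(
    assignments: Iterable[TaxAssignment],
    truth: Iterable[GroundTruthEntry],
    rank: str,
) -> ConfusionCounts:
    """Per-read confusion tally at one rank (see module docstring for rules).

    A partial lineage — classified at genus but empty at species — counts
    as unclassified at the empty ranks.
    """
    if rank not in RANKS:
        raise EvaluationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    truth = list(truth)
    by_read = _assignments_by_read(assignments)
    _check_reads_known(by_read, {t.read_id for t in truth}, "assignment")

    tp = fp = tn = fn = 0
    for entry in truth:
        assignment = by_read.get(entry.read_id)
        predicted = assignment.label_at(rank) if assignment is not None else ""
        if entry.is_negative_control:
            if predicted:
                fp += 1
            else:
                tn += 1
        else:
            if not predicted:
                fn += 1
            elif predicted == entry.label_at(rank) and entry.label_at(rank):
                tp += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def functional_confusion(
    annotations: Iterable[AnnotationRecord],
    truth: Iterable[GroundTruthEntry],
) -> ConfusionCounts:
    """Per-read confusion tally for functional-ID assignment.

    A TP needs only one expected ID in the assigned set.  Multiple records
    per read (map-all output) are merged by union of their annotated ID
    sets before scoring.
    """
    truth = list(truth)
    assigned: dict[str, set[str]] = {}
    for record in annotations:
        assigned.setdefault(record.read_id, set())
        if record.is_annotated:
            assigned[record.read_id].update(record.functional_ids)
    _check_reads_known(assigned, {t.read_id for t in truth}, "annotation")

    tp = fp = tn = fn = 0
    for entry in truth:
        ids = assigned.get(entry.read_id, set())
        expected = entry.expected_functional_ids
        if entry.is_negative_control or not expected:
            # nothing should be assigned to NC reads (or to reads with no
            # expected IDs, which the file format permits)
            if ids:
                fp += 1
            else:
                tn += 1
        else:
            if not ids:
                fn += 1
            elif ids & expected:
                tp += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def rank_recovery(
    assignments: Iterable[TaxAssignment],
    truth: Iterable[GroundTruthEntry],
    rank: str,
) -> RankRecovery:
    """How many distinct true taxa at ``rank`` gained at least one TP read."""
    truth = list(truth)
    by_read = _assignments_by_read(assignments)
    true_taxa = {
        e.label_at(rank) for e in truth
        if not e.is_negative_control and e.label_at(rank)
    }
    if not true_taxa:
        raise EvaluationError(f"no true taxa at rank {rank!r}; proportion undefined")
    recovered: set[str] = set()
    for entry in truth:
        if entry.is_negative_control:
            continue
        assignment = by_read.get(entry.read_id)
        if assignment is None:
            continue
        predicted = assignment.label_at(rank)
        if predicted and predicted == entry.label_at(rank):
            recovered.add(predicted)
    return RankRecovery(rank=rank, n_true_taxa=len(true_taxa), n_recovered=len(recovered))


def classification_rate(assignments: Sequence[TaxAssignment]) -> float:
    """Percentage of reads with ``classified`` set, rounded to 2 decimals."""
    if not assignments:
        raise EvaluationError("classification rate undefined for empty input")
    n_classified = sum(1 for a in assignments if a.classified)
    return round(100.0 * n_classified / len(assignments), 2)


# ---------------------------------------------------------------------------
# Table I/O


def read_classification_table(path: str | Path) -> list[TaxAssignment]:
    """Read the classification TSV: read_id, C/U flag, then the 7 ranks.

    A header line is required and skipped.  Kaiju-style: unclassified reads
    may carry empty rank columns or omit them entirely.
    """
    assignments: list[TaxAssignment] = []
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.strip():
            raise EvaluationError(f"{path}: missing header line")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise EvaluationError(f"{path}:{lineno}: expected >=2 columns")
            read_id, flag = fields[0], fields[1].strip().upper()
            if flag not in ("C", "U"):
                raise EvaluationError(
                    f"{path}:{lineno}: classified flag must be C or U, got {flag!r}"
                )
            classified = flag == "C"
            labels = fields[2 : 2 + len(RANKS)]
            lineage = {
                rank: labels[i].strip() if i < len(labels) else ""
                for i, rank in enumerate(RANKS)
            }
            if not classified:
                lineage = {}
            assignments.append(TaxAssignment(read_id, classified, lineage))
    return assignments


def read_ground_truth(path: str | Path) -> list[GroundTruthEntry]:
    """Read the ground-truth TSV: read_id, is_nc (0/1), 7 ranks, expected IDs."""
    entries: list[GroundTruthEntry] = []
    n_cols = 2 + len(RANKS) + 1
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.strip():
            raise EvaluationError(f"{path}: missing header line")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < n_cols:
                fields = fields + [""] * (n_cols - len(fields))
            read_id = fields[0]
            is_nc = fields[1].strip() == "1"
            lineage = {
                rank: fields[2 + i].strip() for i, rank in enumerate(RANKS)
            }
            ids = frozenset(
                v.strip() for v in fields[2 + len(RANKS)].split(";") if v.strip()
            )
            if is_nc:
                lineage, ids = {}, frozenset()
            entries.append(GroundTruthEntry(read_id, is_nc, lineage, ids))
    return entries


def write_ground_truth(entries: Iterable[GroundTruthEntry], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("read_id\tis_nc\t" + "\t".join(RANKS) + "\texpected_functional_ids\n")
        for e in entries:
            out.write(
                "\t".join(
                    [
                        e.read_id,
                        "1" if e.is_negative_control else "0",
                        *[e.true_lineage.get(r, "") for r in RANKS],
                        ";".join(sorted(e.expected_functional_ids)),
                    ]
                )
                + "\n"
            )


def write_classification_table(
    assignments: Iterable[TaxAssignment], path: str | Path
) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("read_id\tclassified\t" + "\t".join(RANKS) + "\n")
        for a in assignments:
            out.write(
                "\t".join(
                    [
                        a.read_id,
                        "C" if a.classified else "U",
                        *[a.lineage.get(r, "") if a.classified else "" for r in RANKS],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Report assembly


def evaluate_taxonomic(
    assignments: Sequence[TaxAssignment],
    truth: Sequence[GroundTruthEntry],
    ranks: Sequence[str] = RANKS,
) -> dict:
    """Confusion counts, MCC and recovery per rank, plus classification rate."""
    report: dict = {"mode": "taxonomic", "ranks": {}}
    for rank in ranks:
        counts = taxonomic_confusion(assignments, truth, rank)
        entry = {
            "tp": counts.tp,
            "fp": counts.fp,
            "tn": counts.tn,
            "fn": counts.fn,
            "mcc": mcc(counts),
        }
        try:
            rec = rank_recovery(assignments, truth, rank)
            entry["n_true_taxa"] = rec.n_true_taxa
            entry["n_recovered"] = rec.n_recovered
            entry["recovery_pct"] = rec.proportion_pct
        except EvaluationError:
            pass
        report["ranks"][rank] = entry
    if assignments:
        report["classification_rate_pct"] = classification_rate(assignments)
    return report


def evaluate_functional(
    annotations: Sequence[AnnotationRecord],
    truth: Sequence[GroundTruthEntry],
) -> dict:
    counts = functional_confusion(annotations, truth)
    return {
        "mode": "functional",
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
        "mcc": mcc(counts),
    }


def format_report(report: dict) -> str:
    """Human-readable rendering of an evaluation report."""
    lines: list[str] = [f"mode: {report['mode']}"]
    if report["mode"] == "taxonomic":
        lines.append(
            f"{'rank':<13}{'TP':>7}{'FP':>7}{'TN':>7}{'FN':>7}{'MCC':>9}{'recovery':>10}"
        )
        for rank, e in report["ranks"].items():
            recovery = (
                f"{e['recovery_pct']}%" if "recovery_pct" in e else "n/a"
            )
            lines.append(
                f"{rank:<13}{e['tp']:>7}{e['fp']:>7}{e['tn']:>7}{e['fn']:>7}"
                f"{e['mcc']:>9.4f}{recovery:>10}"
            )
        if "classification_rate_pct" in report:
            lines.append(
                f"classification rate: {report['classification_rate_pct']:.2f}%"
            )
    else:
        lines.append(
            f"TP={report['tp']} FP={report['fp']} TN={report['tn']} FN={report['fn']}"
        )
        lines.append(f"MCC: {report['mcc']:.4f}")
    return "\n".join(lines)
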