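"""Annotation transfer: filter alignment hits, pick the best mappable hit
per read, emit functional IDs or "Unknown".

The algorithm is a single linear pass over a grouped alignment file.  For
each read (query group):

1. drop hits failing any set threshold (e-value ≤, bit score ≥, percent
   identity ≥, alignment length ≥ — all comparisons inclusive);
2. rank the survivors by bit score descending, then e-value ascending, then
   percent identity descending, then original file order;
3. walk the ranked list and transfer the functional-ID set of the first
   subject present in the mapping store ("best mappable hit").  A
   ``strict_best`` option instead considers only the single top-ranked hit.

A read with no passing hit, or none mappable, is assigned the literal label
``"Unknown"``; such records can be suppressed (``omit_unknown``) and a
``map_all`` mode maps every passing hit independently instead of only the
best one.  The default minimum percent identity is 80, chosen so that only
reasonably close homologs transfer annotations; all other thresholds are
unset by default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .alignment_io import (
    AlignmentHit,
    ParseStats,
    QueryGroup,
    group_by_query,
    parse_alignment_table,
)
from .annotation_store import AnnotationStore

__all__ = [
    "UNKNOWN_LABEL",
    "FilterThresholds",
    "AnnotateOptions",
    "AnnotationRecord",
    "RunSummary",
    "passes_filters",
    "rank_hits",
    "annotate_group",
    "annotate_stream",
    "annotate_file",
    "format_record",
    "read_annotation_table",
    "OUTPUT_HEADER",
]

UNKNOWN_LABEL = "Unknown"

OUTPUT_HEADER = (
    "#read_id\tstatus\tfunctional_ids\tsubject_id\tpident\tlength\tevalue\tbitscore"
)


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive hit-filtering thresholds; ``None`` means the check always passes."""

    max_e_value: float | None = None
    min_bit_score: float | None = None
    min_percent_identity: float | None = 80.0
    min_alignment_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("max_e_value", "min_bit_score", "min_percent_identity",
                     "min_alignment_length"):
            value = getattr(self, name)
            if value is not None and not (float("-inf") < float(value) < float("inf")):
                raise ValueError(f"{name} must be finite, got {value!r}")
        pid = self.min_percent_identity
        if pid is not None and not 0.0 <= pid <= 100.0:
            raise ValueError(f"min_percent_identity {pid} outside [0, 100]")

    def as_dict(self) -> dict[str, float | int | None]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AnnotateOptions:
    """Output-shaping switches; all independent and combinable."""

    omit_unknown: bool = False
    map_all: bool = False
    strict_best: bool = False

    def as_dict(self) -> dict[str, bool]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AnnotationRecord:
    """Transfer result for one read (or one hit in map-all mode)."""

    read_id: str
    status: str  # "annotated" | "unknown"
    functional_ids: frozenset[str] = frozenset()
    source_subject_id: str = ""
    percent_identity: float | None = None
    alignment_length: int | None = None
    e_value: float | None = None
    bit_score: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("annotated", "unknown"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "annotated" and (
            not self.functional_ids or not self.source_subject_id
        ):
            raise ValueError("annotated records need functional IDs and a subject")
        if self.status == "unknown" and self.functional_ids:
            raise ValueError("unknown records carry no functional IDs")

    @property
    def is_annotated(self) -> bool:
        return self.status == "annotated"


@dataclass
class RunSummary:
    """Per-run tallies plus every resolved parameter, for reproducibility."""

    reads_seen: int = 0
    reads_annotated: int = 0
    reads_unknown: int = 0
    records_written: int = 0
    rows_skipped: int = 0
    thresholds: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def passes_filters(hit: AlignmentHit, thresholds: FilterThresholds) -> bool:
    """True iff the hit meets every set threshold (inclusive comparisons)."""
    t = thresholds
    if t.max_e_value is not None and hit.e_value > t.max_e_value:
        return False
    if t.min_bit_score is not None and hit.bit_score < t.min_bit_score:
        return False
    if t.min_percent_identity is not None and hit.percent_identity < t.min_percent_identity:
        return False
    if t.min_alignment_length is not None and hit.alignment_length < t.min_alignment_length:
        return False
    return True


def rank_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Stable sort: bit score ↓, e-value ↑, percent identity ↓, file order."""
    return sorted(
        hits,
        key=lambda h: (-h.bit_score, h.e_value, -h.percent_identity),
    )


def _unknown_record(read_id: str) -> AnnotationRecord:
    return AnnotationRecord(read_id=read_id, status="unknown")


def _annotated_record(read_id: str, hit: AlignmentHit, ids: frozenset[str]) -> AnnotationRecord:
    return AnnotationRecord(
        read_id=read_id,
        status="annotated",
        functional_ids=ids,
        source_subject_id=hit.subject_id,
        percent_identity=hit.percent_identity,
        alignment_length=hit.alignment_length,
        e_value=hit.e_value,
        bit_score=hit.bit_score,
    )


def annotate_group(
    group: QueryGroup,
    store: AnnotationStore,
    thresholds: FilterThresholds = FilterThresholds(),
    options: AnnotateOptions = AnnotateOptions(),
) -> list[AnnotationRecord]:
    """Annotate one read's hits.

    Default mode returns exactly one record: annotated from the best
    mappable passing hit, else unknown (dropped when ``omit_unknown``).
    ``map_all`` returns one record per passing hit, each mapped
    independently.  ``strict_best`` disables the fallback through the ranked
    list: only the top-ranked passing hit is tried.
    """
    ranked = rank_hits(h for h in group.hits if passes_filters(h, thresholds))

    records: list[AnnotationRecord]
    if options.map_all:
        records = []
        for hit in ranked:
            ids = store.lookup(hit.subject_id)
            if ids is None:
                records.append(_unknown_record(group.query_id))
            else:
                records.append(_annotated_record(group.query_id, hit, ids))
        if not records:
            records = [_unknown_record(group.query_id)]
    else:
        candidates = ranked[:1] if options.strict_best else ranked
        chosen: AnnotationRecord | None = None
        for hit in candidates:
            ids = store.lookup(hit.subject_id)
            if ids is not None:
                chosen = _annotated_record(group.query_id, hit, ids)
                break
        records = [chosen if chosen is not None else _unknown_record(group.query_id)]

    if options.omit_unknown:
        records = [r for r in records if r.is_annotated]
    return records


def annotate_stream(
    groups: Iterable[QueryGroup],
    store: AnnotationStore,
    thresholds: FilterThresholds = FilterThresholds(),
    options: AnnotateOptions = AnnotateOptions(),
    summary: RunSummary | None = None,
) -> Iterator[AnnotationRecord]:
    """Annotate a stream of query groups, updating ``summary`` in place."""
    for group in groups:
        records = annotate_group(group, store, thresholds, options)
        if summary is not None:
            summary.reads_seen += 1
            if any(r.is_annotated for r in records):
                summary.reads_annotated += 1
            else:
                summary.reads_unknown += 1
            summary.records_written += len(records)
        yield from records


def format_record(record: AnnotationRecord) -> str:
    """One output TSV line; functional IDs sorted and ";"-joined for byte
    stability."""
    if record.is_annotated:
        return "\t".join(
            (
                record.read_id,
                "annotated",
                ";".join(sorted(record.functional_ids)),
                record.source_subject_id,
                f"{record.percent_identity:g}",
                str(record.alignment_length),
                f"{record.e_value:g}",
                f"{record.bit_score:g}",
            )
        )
    return "\t".join((record.read_id, UNKNOWN_LABEL, "", "", "", "", "", ""))


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read back the TSV written by :func:`annotate_file`."""
    records: list[AnnotationRecord] = []
    with open(path, "rt", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            read_id, status = fields[0], fields[1]
            if status == UNKNOWN_LABEL:
                records.append(_unknown_record(read_id))
            else:
                records.append(
                    AnnotationRecord(
                        read_id=read_id,
                        status="annotated",
                        functional_ids=frozenset(fields[2].split(";")),
                        source_subject_id=fields[3],
                        percent_identity=float(fields[4]),
                        alignment_length=int(fields[5]),
                        e_value=float(fields[6]),
                        bit_score=float(fields[7]),
                    )
                )
    return records


def annotate_file(
    alignment_path: str | Path,
    store: AnnotationStore,
    thresholds: FilterThresholds = FilterThresholds(),
    options: AnnotateOptions = AnnotateOptions(),
    output_path: str | Path | None = None,
    *,
    strict_parse: bool = False,
    on_regrouping: str = "error",
    write_summary: bool = True,
) -> RunSummary:
    """Single-pass annotation of a whole alignment file.

    Writes one record per line to ``output_path`` (TSV, ``#``-prefixed
    header) and, unless disabled, a JSON run summary next to it at
    ``<output>.summary.json``.  Memory use is bounded by the largest single
    query group.
    """
    stats = ParseStats()
    summary = RunSummary(
        thresholds=thresholds.as_dict(), options=options.as_dict()
    )
    hits = parse_alignment_table(alignment_path, strict=strict_parse, stats=stats)
    groups = group_by_query(hits, on_regrouping=on_regrouping)
    records = annotate_stream(groups, store, thresholds, options, summary)

    if output_path is None:
        for _ in records:
            pass
    else:
        output_path = Path(output_path)
        with open(output_path, "wt", encoding="utf-8") as out:
            out.write(OUTPUT_HEADER + "\n")
            for record in records:
                out.write(format_record(record) + "\n")
    summary.rows_skipped = stats.rows_skipped
    if output_path is not None and write_summary:
        Path(str(output_path) + ".summary.json").write_text(summary.to_json())
    return summary
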