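"""Streaming reader for BLAST/DIAMOND 12-column tabular alignments.

The only dialect accepted is the tab-separated 12-column ``outfmt 6`` report
(DIAMOND's default output)::

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore

Extra columns beyond the twelfth are tolerated and dropped.  Input may be
plain text or gzip-compressed; compression is detected from the file's magic
bytes, never from its name.  Rows are yielded in file order and can be
grouped into per-query blocks with :func:`group_by_query`, which holds at
most one query's hits in memory at a time.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "AlignmentHit",
    "QueryGroup",
    "ParseStats",
    "AlignmentFormatError",
    "NonContiguousQueryError",
    "parse_alignment_table",
    "group_by_query",
]

GZIP_MAGIC = b"\x1f\x8b"


class AlignmentFormatError(ValueError):
    """A data row could not be parsed as 12-column tabular output."""


class NonContiguousQueryError(ValueError):
    """A query id reappeared after hits for a different query."""


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """One row of a 12-column tabular alignment.

    Coordinates are 1-based inclusive as printed by BLAST; no conversion is
    performed.  ``alignment_length`` counts alignment columns, not query
    bases.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def validate(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise AlignmentFormatError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise AlignmentFormatError(f"negative e-value {self.e_value}")
        if self.alignment_length < 1:
            raise AlignmentFormatError(
                f"alignment length {self.alignment_length} < 1"
            )
        if self.q_start < 1 or self.q_end < 1:
            raise AlignmentFormatError("query coordinates must be >= 1")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise AlignmentFormatError("negative mismatch/gap-open count")


@dataclass(frozen=True, slots=True)
class QueryGroup:
    """All consecutive hits sharing one query id, in file order."""

    query_id: str
    hits: tuple[AlignmentHit, ...]

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class ParseStats:
    """Row tallies updated in place while the hit stream is consumed."""

    rows_read: int = 0
    rows_skipped: int = 0
    skipped_lines: list[int] = field(default_factory=list)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _parse_row(fields: list[str]) -> AlignmentHit:
    hit = AlignmentHit(
        query_id=fields[0],
        subject_id=fields[1],
        percent_identity=float(fields[2]),
        alignment_length=int(fields[3]),
        mismatches=int(fields[4]),
        gap_opens=int(fields[5]),
        q_start=int(fields[6]),
        q_end=int(fields[7]),
        s_start=int(fields[8]),
        s_end=int(fields[9]),
        e_value=float(fields[10]),
        bit_score=float(fields[11]),
    )
    hit.validate()
    return hit


def parse_alignment_table(
    path: str | Path,
    *,
    strict: bool = False,
    stats: ParseStats | None = None,
) -> Iterator[AlignmentHit]:
    """Yield :class:`AlignmentHit` rows from an outfmt-6 file, in file order.

    Parameters
    ----------
    path
        Plain or gzip-compressed tab-separated file.
    strict
        If true, a malformed row (fewer than 12 columns, unparsable
        numerics, out-of-range values) raises :class:`AlignmentFormatError`
        naming the line number.  Otherwise malformed rows are skipped and
        tallied in ``stats``.
    stats
        Optional :class:`ParseStats` mutated as rows are consumed.
    """
    if stats is None:
        stats = ParseStats()
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                if strict:
                    raise AlignmentFormatError(
                        f"{path}:{lineno}: expected >=12 tab-separated "
                        f"columns, found {len(fields)}"
                    )
                stats.rows_skipped += 1
                stats.skipped_lines.append(lineno)
                continue
            try:
                hit = _parse_row(fields[:12])
            except (ValueError, AlignmentFormatError) as exc:
                if strict:
                    raise AlignmentFormatError(
                        f"{path}:{lineno}: {exc}"
                    ) from exc
                stats.rows_skipped += 1
                stats.skipped_lines.append(lineno)
                continue
            stats.rows_read += 1
            yield hit


def group_by_query(
    hits: Iterable[AlignmentHit],
    *,
    on_regrouping: str = "error",
) -> Iterator[QueryGroup]:
    """Group a hit stream into one :class:`QueryGroup` per maximal run.

    BLAST and DIAMOND emit all hits for a query contiguously, so a single
    pass buffering only the current query suffices.  If a query id reappears
    after a different query (non-contiguous input), policy ``"error"``
    (default) raises :class:`NonContiguousQueryError`; policy ``"merge"``
    buffers the whole stream and merges groups in first-appearance order —
    documented as breaking the streaming memory contract.
    """
    if on_regrouping not in ("error", "merge"):
        raise ValueError(f"unknown regrouping policy: {on_regrouping!r}")

    if on_regrouping == "merge":
        buffered: dict[str, list[AlignmentHit]] = {}
        for hit in hits:
            buffered.setdefault(hit.query_id, []).append(hit)
        for query_id, group_hits in buffered.items():
            yield QueryGroup(query_id, tuple(group_hits))
        return

    seen: set[str] = set()
    current_id: str | None = None
    current: list[AlignmentHit] = []
    for hit in hits:
        if hit.query_id != current_id:
            if current_id is not None:
                yield QueryGroup(current_id, tuple(current))
                seen.add(current_id)
            if hit.query_id in seen:
                raise NonContiguousQueryError(
                    f"query {hit.query_id!r} reappeared after a different "
                    "query; input is not grouped (use the merge policy for "
                    "hand-edited files)"
                )
            current_id = hit.query_id
            current = [hit]
        else:
            current.append(hit)
    if current_id is not None:
        yield QueryGroup(current_id, tuple(current))
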