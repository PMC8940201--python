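"""Shared fixtures and an independent brute-force reference annotator.

The reference implementation here deliberately avoids the package's
streaming machinery: it loads the whole alignment file with plain string
operations, groups rows in a dict, sorts each group with an explicitly
spelled-out key and maps subjects against a plain in-memory dictionary.
Tests compare the package's streaming output against it byte for byte.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pytest

from annotran.annotation_store import MappingDictionaryFile, build_store


# ---------------------------------------------------------------------------
# Brute-force reference annotation (independent of annotran.annotate_core)


def reference_annotate_lines(
    alignment_text: str,
    mapping: dict[str, set[str]],
    *,
    max_e_value: float | None = None,
    min_bit_score: float | None = None,
    min_percent_identity: float | None = 80.0,
    min_alignment_length: int | None = None,
    omit_unknown: bool = False,
    map_all: bool = False,
    strict_best: bool = False,
) -> list[str]:
    """Whole-file in-memory annotation; returns output TSV data lines."""
    # parse
    rows = []
    for line in alignment_text.splitlines():
        if not line:
            continue
        f = line.split("\t")
        if len(f) < 12:
            continue
        try:
            rows.append(
                (f[0], f[1], float(f[2]), int(f[3]), float(f[10]), float(f[11]))
            )
        except ValueError:
            continue
    # group preserving first-appearance order (input is assumed grouped)
    groups: dict[str, list] = {}
    for row in rows:
        groups.setdefault(row[0], []).append(row)

    def passes(row) -> bool:
        _, _, pid, length, ev, bs = row
        if max_e_value is not None and ev > max_e_value:
            return False
        if min_bit_score is not None and bs < min_bit_score:
            return False
        if min_percent_identity is not None and pid < min_percent_identity:
            return False
        if min_alignment_length is not None and length < min_alignment_length:
            return False
        return True

    def fmt_annotated(read, row, ids) -> str:
        _, subject, pid, length, ev, bs = row
        return "\t".join(
            (read, "annotated", ";".join(sorted(ids)), subject,
             f"{pid:g}", str(length), f"{ev:g}", f"{bs:g}")
        )

    def fmt_unknown(read) -> str:
        return "\t".join((read, "Unknown", "", "", "", "", "", ""))

    out: list[str] = []
    for read, group in groups.items():
        passing = [r for r in group if passes(r)]
        indexed = list(enumerate(passing))
        indexed.sort(key=lambda p: (-p[1][5], p[1][4], -p[1][2], p[0]))
        ranked = [r for _, r in indexed]
        if map_all:
            records = []
            for row in ranked:
                if row[1] in mapping:
                    records.append(fmt_annotated(read, row, mapping[row[1]]))
                else:
                    records.append(fmt_unknown(read))
            if not records:
                records = [fmt_unknown(read)]
        else:
            candidates = ranked[:1] if strict_best else ranked
            chosen = None
            for row in candidates:
                if row[1] in mapping:
                    chosen = fmt_annotated(read, row, mapping[row[1]])
                    break
            records = [chosen if chosen is not None else fmt_unknown(read)]
        if omit_unknown:
            records = [r for r in records if "\tannotated\t" in r]
        out.extend(records)
    return out


def reference_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Textbook MCC, written directly from the formula."""
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


# ---------------------------------------------------------------------------
# Random grouped alignment text (test-local generator, not the package's)


def random_alignment_text(
    rng: np.random.Generator,
    n_reads: int,
    subjects: list[str],
    max_hits: int = 5,
) -> str:
    """Grouped outfmt-6 text with arbitrary (not planted) hit parameters."""
    lines = []
    for i in range(n_reads):
        read = f"q{i:05d}"
        for _ in range(int(rng.integers(1, max_hits + 1))):
            subject = subjects[int(rng.integers(len(subjects)))]
            pid = round(float(rng.uniform(40, 100)), 1)
            length = int(rng.integers(30, 200))
            ev = float(f"{10.0 ** -float(rng.uniform(0, 60)):.3g}")
            bs = round(float(rng.uniform(40, 400)), 1)
            mism = int(length * (100 - pid) / 100)
            lines.append(
                f"{read}\t{subject}\t{pid:g}\t{length}\t{mism}\t0\t1\t{length}"
                f"\t1\t{length}\t{ev:g}\t{bs:g}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture()
def small_mapping(tmp_path: Path):
    """A 40-key dictionary file, its oracle mapping, and a built store."""
    from annotran.synthetic_data import make_dictionary_fixture

    dict_path = tmp_path / "dict.tsv"
    _, oracle = make_dictionary_fixture(40, 2, seed=7, path=dict_path)
    store, _ = build_store(MappingDictionaryFile(dict_path), tmp_path / "store.db")
    yield store, oracle
    store.close()
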