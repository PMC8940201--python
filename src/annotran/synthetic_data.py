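"""Generators for fully predictable test inputs.

Everything the annotate + evaluate workflow consumes can be generated here
at desk scale with known ground truth:

* :func:`shuffle_windows` — negative-control sequences built by permuting
  residues within non-overlapping windows (default width 500), which
  destroys homology while preserving local composition, so shuffled reads
  remain realistically alignable but belong to no reference organism;
* :func:`simulate_reads` — reads drawn from named source sequences under a
  supplied or lognormal abundance profile, with i.i.d. substitutions and an
  optional negative-control fraction, plus a complete truth table;
* :func:`make_dictionary_fixture` — a mapping-dictionary file together with
  its in-memory oracle, including planted duplicate keys;
* :func:`make_alignment_fixture` — a tabular alignment file with a planted,
  fully predictable annotation outcome per read, plus the expected
  annotation records.

All generators draw from one ``numpy.random.default_rng`` (PCG64) seeded
explicitly, so outputs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate_core import AnnotationRecord, FilterThresholds
from .evaluation import RANKS, GroundTruthEntry

__all__ = [
    "SimulatedRead",
    "shuffle_windows",
    "random_sources",
    "lognormal_profile",
    "simulate_reads",
    "make_dictionary_fixture",
    "make_alignment_fixture",
    "write_fasta",
    "write_alignment_rows",
    "default_lineage",
    "PlantedOutcome",
]

DNA_ALPHABET = ("A", "C", "G", "T")
_DNA_SET = frozenset(DNA_ALPHABET)

#: Planted per-read annotate outcomes understood by make_alignment_fixture.
PlantedOutcome = ("clean", "sub_threshold", "unmappable_best", "no_hit")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    source_id: str
    is_negative_control: bool = False


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shuffle_windows(
    sequence: str,
    window_size: int = 500,
    seed: int | np.random.Generator = 0,
    *,
    allow_non_dna: bool = False,
) -> str:
    """Permute residues uniformly within consecutive non-overlapping windows.

    The final window may be shorter than ``window_size``.  Output length and
    per-window residue multisets equal the input's.  Non-DNA characters
    raise unless ``allow_non_dna`` (for protein or ambiguity codes).
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    if not allow_non_dna and not _DNA_SET.issuperset(sequence):
        bad = sorted(set(sequence) - _DNA_SET)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    rng = _rng(seed)
    out: list[str] = []
    for start in range(0, len(sequence), window_size):
        window = list(sequence[start : start + window_size])
        rng.shuffle(window)
        out.append("".join(window))
    return "".join(out)


def random_sources(
    n_sources: int,
    length: int,
    seed: int | np.random.Generator = 0,
    *,
    prefix: str = "src",
) -> dict[str, str]:
    """Uniform-composition random DNA source sequences, named ``prefix_i``."""
    rng = _rng(seed)
    bases = np.array(DNA_ALPHABET)
    return {
        f"{prefix}_{i}": "".join(rng.choice(bases, size=length))
        for i in range(n_sources)
    }


def lognormal_profile(
    source_ids: Sequence[str],
    sigma: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Normalised lognormal abundance weights (mu fixed at 0).

    Only relative abundances matter downstream, so the profile is
    parameterised by sigma alone and normalised to sum to 1.
    """
    rng = _rng(seed)
    weights = rng.lognormal(mean=0.0, sigma=sigma, size=len(source_ids))
    weights = weights / weights.sum()
    return dict(zip(source_ids, weights))


def default_lineage(source_id: str) -> dict[str, str]:
    """Deterministic toy lineage: species is the source id, coarser ranks
    are derived labels (each source its own clade)."""
    lineage = {rank: f"{source_id}_{rank}" for rank in RANKS}
    lineage["species"] = source_id
    lineage["superkingdom"] = "Bacteria"
    return lineage


def _mutate(read: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return read
    hit = rng.random(read.size) < rate
    if not hit.any():
        return read
    bases = np.array(DNA_ALPHABET)
    read = read.copy()
    for i in np.flatnonzero(hit):
        choices = bases[bases != read[i]]
        read[i] = rng.choice(choices)
    return read


def simulate_reads(
    sources: Mapping[str, str],
    n_reads: int,
    *,
    profile: Mapping[str, float] | None = None,
    lognormal_sigma: float = 2.0,
    read_length: int = 150,
    substitution_rate: float = 0.0,
    nc_fraction: float = 0.0,
    seed: int = 0,
    nc_window_size: int = 500,
    lineages: Mapping[str, Mapping[str, str]] | None = None,
    functional_ids: Mapping[str, Iterable[str]] | None = None,
) -> tuple[list[SimulatedRead], list[GroundTruthEntry]]:
    """Draw reads from sources and emit a complete ground-truth table.

    Non-NC reads come from the sources at uniformly random positions with
    i.i.d. substitutions at ``substitution_rate``; negative-control reads
    come from window-shuffled copies of the same sources and carry no true
    lineage or expected IDs.  Per-source expected functional IDs default to
    two deterministic GO-style identifiers per source.
    """
    if not sources:
        raise ValueError("at least one source sequence is required")
    if not 0.0 <= nc_fraction < 1.0:
        raise ValueError(f"nc_fraction must be in [0, 1), got {nc_fraction}")
    too_short = [k for k, s in sources.items() if len(s) < read_length]
    if len(too_short) == len(sources):
        raise ValueError(f"read_length {read_length} exceeds every source length")
    usable = {k: s for k, s in sources.items() if len(s) >= read_length}

    rng = np.random.default_rng(seed)
    source_ids = list(usable)
    if profile is None:
        profile = lognormal_profile(source_ids, lognormal_sigma, rng)
    else:
        profile = {k: v for k, v in profile.items() if k in usable}
        if not profile or min(profile.values()) <= 0:
            raise ValueError("profile weights must be positive over usable sources")
    weights = np.array([profile[k] for k in source_ids], dtype=float)
    weights = weights / weights.sum()

    if lineages is None:
        lineages = {k: default_lineage(k) for k in source_ids}
    if functional_ids is None:
        functional_ids = {
            k: {f"GO:{2 * i + 1:07d}", f"GO:{2 * i + 2:07d}"}
            for i, k in enumerate(source_ids)
        }

    n_nc = int(round(n_reads * nc_fraction))
    n_real = n_reads - n_nc
    shuffled = {
        k: shuffle_windows(usable[k], nc_window_size, rng) for k in source_ids
    }

    reads: list[SimulatedRead] = []
    truth: list[GroundTruthEntry] = []

    def draw(pool: Mapping[str, str], read_id: str, is_nc: bool) -> None:
        src = source_ids[rng.choice(len(source_ids), p=weights)]
        seq = pool[src]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        arr = np.array(list(seq[start : start + read_length]))
        arr = _mutate(arr, substitution_rate, rng)
        reads.append(SimulatedRead(read_id, "".join(arr), src, is_nc))
        if is_nc:
            truth.append(GroundTruthEntry(read_id, is_negative_control=True))
        else:
            truth.append(
                GroundTruthEntry(
                    read_id,
                    is_negative_control=False,
                    true_lineage=dict(lineages[src]),
                    expected_functional_ids=frozenset(functional_ids[src]),
                )
            )

    for i in range(n_real):
        draw(usable, f"read_{i:06d}", False)
    for i in range(n_nc):
        draw(shuffled, f"nc_{i:06d}", True)
    return reads, truth


def make_dictionary_fixture(
    n_keys: int,
    ids_per_key: int = 2,
    seed: int = 0,
    path: str | Path | None = None,
    *,
    duplicate_fraction: float = 0.05,
) -> tuple[list[str], dict[str, set[str]]]:
    """A two-column TSV mapping dictionary plus its in-memory oracle.

    About ``duplicate_fraction`` of the keys get a second line with extra
    IDs, exercising union-merge.  Returns the file lines (also written to
    ``path`` when given) and the oracle key→ID-set mapping.
    """
    if n_keys < 0:
        raise ValueError("n_keys must be >= 0")
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    oracle: dict[str, set[str]] = {}
    go_counter = 1
    for i in range(n_keys):
        key = f"WP_{i:06d}.1"
        ids = {f"GO:{go_counter + j:07d}" for j in range(ids_per_key)}
        go_counter += ids_per_key
        lines.append(f"{key}\t{';'.join(sorted(ids))}")
        oracle[key] = set(ids)
        if rng.random() < duplicate_fraction:
            extra = {f"GO:{go_counter:07d}"}
            go_counter += 1
            lines.append(f"{key}\t{';'.join(sorted(extra))}")
            oracle[key] |= extra
    order = rng.permutation(len(lines))
    lines = [lines[i] for i in order]
    if path is not None:
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return lines, oracle


# ---------------------------------------------------------------------------
# Alignment fixtures with planted outcomes


def _fmt_row(
    query: str,
    subject: str,
    pident: float,
    length: int,
    evalue: float,
    bitscore: float,
    rng: np.random.Generator,
) -> str:
    mism = int(round(length * (100.0 - pident) / 100.0))
    qs = int(rng.integers(1, 50))
    return "\t".join(
        (
            query,
            subject,
            f"{pident:g}",
            str(length),
            str(mism),
            "0",
            str(qs),
            str(qs + length - 1),
            "1",
            str(length),
            f"{evalue:g}",
            f"{bitscore:g}",
        )
    )


def _passing_params(
    t: FilterThresholds, rng: np.random.Generator, bitscore: float
) -> tuple[float, int, float]:
    lo_pid = t.min_percent_identity if t.min_percent_identity is not None else 60.0
    pident = round(float(rng.uniform(lo_pid, 100.0)), 1)
    pident = max(pident, lo_pid)  # rounding must not dip below the threshold
    length = int((t.min_alignment_length or 60) + rng.integers(0, 60))
    max_e = t.max_e_value if t.max_e_value is not None else 1e-5
    evalue = float(f"{max_e * 10.0 ** -float(rng.uniform(0, 20)):.3g}")
    if t.min_bit_score is not None:
        bitscore = max(bitscore, t.min_bit_score)
    return pident, length, evalue


def _failing_params(
    t: FilterThresholds, rng: np.random.Generator
) -> tuple[float, int, float, float]:
    """Parameters violating one (random) set threshold. Requires >=1 set."""
    settable = []
    if t.min_percent_identity is not None and t.min_percent_identity >= 1.0:
        settable.append("pident")
    if t.max_e_value is not None:
        settable.append("evalue")
    if t.min_bit_score is not None:
        settable.append("bitscore")
    if t.min_alignment_length is not None and t.min_alignment_length > 1:
        settable.append("length")
    if not settable:
        raise ValueError(
            "sub_threshold outcome requires at least one violable threshold"
        )
    which = settable[int(rng.integers(len(settable)))]
    pident = round(float(rng.uniform(60.0, 100.0)), 1)
    length = 60 + int(rng.integers(0, 60))
    evalue = float(f"{10.0 ** -float(rng.uniform(10, 30)):.3g}")
    bitscore = round(float(rng.uniform(50.0, 300.0)), 1)
    if which == "pident":
        # rounding a value <= min-0.5 moves it by at most 0.05, so it stays
        # strictly below the threshold
        pident = round(float(rng.uniform(0.0, t.min_percent_identity - 0.5)), 1)
    elif which == "evalue":
        evalue = float(f"{t.max_e_value * 10.0 ** float(rng.uniform(1, 5)):.3g}")
    elif which == "bitscore":
        bitscore = round(t.min_bit_score - float(rng.uniform(0.5, 50.0)), 1)
    else:
        length = int(rng.integers(1, t.min_alignment_length))
    # keep the other fields passing-compatible so only the chosen one fails
    if which != "pident" and t.min_percent_identity is not None:
        pident = max(pident, t.min_percent_identity)
    if which != "evalue" and t.max_e_value is not None:
        evalue = min(evalue, t.max_e_value)
    if which != "bitscore" and t.min_bit_score is not None:
        bitscore = max(bitscore, t.min_bit_score)
    if which != "length" and t.min_alignment_length is not None:
        length = max(length, t.min_alignment_length)
    return pident, length, evalue, bitscore


def make_alignment_fixture(
    outcomes: Mapping[str, str],
    key_to_ids: Mapping[str, Iterable[str]],
    thresholds: FilterThresholds = FilterThresholds(),
    seed: int = 0,
    alignment_path: str | Path | None = None,
    *,
    subject_for_read: Mapping[str, str] | None = None,
) -> tuple[list[str], list[AnnotationRecord]]:
    """Build an outfmt-6 alignment file with a planted outcome per read.

    ``outcomes`` maps read id → one of ``clean`` (best passing hit maps
    through the store), ``sub_threshold`` (hits present but all below
    threshold), ``unmappable_best`` (top passing hit has no store entry, a
    lower-ranked passing hit does — exercises the best-mappable fallback),
    ``no_hit`` (read absent from the file).  Returns the file rows and the
    expected default-mode annotation records for every read that appears in
    the file, in file order.  Reads are emitted in ``outcomes`` order, so
    the file is query-grouped.
    """
    mappable = list(key_to_ids)
    needs_keys = any(o in ("clean", "unmappable_best") for o in outcomes.values())
    if needs_keys and not mappable:
        raise ValueError("planted outcomes require at least one store key")
    rng = np.random.default_rng(seed)
    rows: list[str] = []
    expected: list[AnnotationRecord] = []

    def parse_back(row: str) -> tuple[float, int, float, float]:
        f = row.split("\t")
        return float(f[2]), int(f[3]), float(f[10]), float(f[11])

    for read_id, outcome in outcomes.items():
        if outcome not in PlantedOutcome:
            raise ValueError(f"unknown planted outcome {outcome!r} for {read_id}")
        if outcome == "no_hit":
            continue
        if outcome == "sub_threshold":
            for _ in range(int(rng.integers(1, 4))):
                pid, length, ev, bs = _failing_params(thresholds, rng)
                rows.append(_fmt_row(read_id, f"SUB_{read_id}", pid, length, ev, bs, rng))
            expected.append(AnnotationRecord(read_id=read_id, status="unknown"))
            continue

        # clean / unmappable_best: build a ranked ladder of passing hits
        # with strictly decreasing bit scores
        top_bit = round(float(rng.uniform(200.0, 400.0)), 1)
        if thresholds.min_bit_score is not None:
            top_bit = max(top_bit, thresholds.min_bit_score + 100.0)
        if subject_for_read and read_id in subject_for_read:
            chosen_key = subject_for_read[read_id]
        else:
            chosen_key = mappable[int(rng.integers(len(mappable)))]

        read_rows: list[str] = []
        if outcome == "unmappable_best":
            pid, length, ev = _passing_params(thresholds, rng, top_bit)
            read_rows.append(
                _fmt_row(read_id, f"MISSING_{read_id}", pid, length, ev, top_bit, rng)
            )
            chosen_bit = round(top_bit - float(rng.uniform(5.0, 20.0)), 1)
        else:
            chosen_bit = top_bit
        if thresholds.min_bit_score is not None:
            chosen_bit = max(chosen_bit, thresholds.min_bit_score)
        pid, length, ev = _passing_params(thresholds, rng, chosen_bit)
        chosen_row = _fmt_row(read_id, chosen_key, pid, length, ev, chosen_bit, rng)
        read_rows.append(chosen_row)
        # trailing lower-ranked passing hits (mappable or not) and, when a
        # threshold exists to violate, some sub-threshold noise
        next_bit = chosen_bit
        for _ in range(int(rng.integers(0, 3))):
            next_bit = round(next_bit - float(rng.uniform(5.0, 15.0)), 1)
            if thresholds.min_bit_score is not None and next_bit < thresholds.min_bit_score:
                break
            pid2, len2, ev2 = _passing_params(thresholds, rng, next_bit)
            subj = (
                mappable[int(rng.integers(len(mappable)))]
                if rng.random() < 0.5
                else f"OTHER_{read_id}_{int(rng.integers(100))}"
            )
            read_rows.append(_fmt_row(read_id, subj, pid2, len2, ev2, next_bit, rng))
        try:
            for _ in range(int(rng.integers(0, 3))):
                pid3, len3, ev3, bs3 = _failing_params(thresholds, rng)
                read_rows.append(
                    _fmt_row(read_id, f"SUB_{read_id}", pid3, len3, ev3, bs3, rng)
                )
        except ValueError:
            pass  # no threshold set; noise hits would all pass
        rows.extend(read_rows)
        cpid, clen, cev, cbs = parse_back(chosen_row)
        expected.append(
            AnnotationRecord(
                read_id=read_id,
                status="annotated",
                functional_ids=frozenset(key_to_ids[chosen_key]),
                source_subject_id=chosen_key,
                percent_identity=cpid,
                alignment_length=clen,
                e_value=cev,
                bit_score=cbs,
            )
        )

    if alignment_path is not None:
        Path(alignment_path).write_text(
            "\n".join(rows) + ("\n" if rows else "")
        )
    return rows, expected


# ---------------------------------------------------------------------------
# Writers


def write_fasta(
    sequences: Mapping[str, str] | Iterable[SimulatedRead],
    path: str | Path,
) -> None:
    """Write sources (mapping) or simulated reads to FASTA."""
    if isinstance(sequences, Mapping):
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sequences.items()
        ]
    else:
        records = [
            SeqRecord(
                Seq(r.sequence),
                id=r.read_id,
                description=f"source={r.source_id} nc={int(r.is_negative_control)}",
            )
            for r in sequences
        ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path, quality: int = 35) -> None:
    """FASTQ with a constant quality character (quality is irrelevant
    downstream of alignment)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_alignment_rows(rows: Iterable[str], path: str | Path) -> None:
    rows = list(rows)
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))
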