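"""Persistent key→functional-ID-set store built from plain-text dictionaries.

A mapping dictionary is a tab-separated UTF-8 text file, one key and one
value field per line (e.g. a protein accession and a ";"-joined list of GO
IDs).  :func:`build_store` compiles such a file into an embedded SQLite
database so that lookups against dictionaries with millions of keys cost a
B-tree probe instead of a linear scan.  Duplicate keys are merged by set
union — the UniProt ID-mapping export maps one accession to many GO IDs
across lines — so the merged value set a key returns is independent of line
order.

Absence is meaningful: :meth:`AnnotationStore.lookup` returns ``None`` for a
key never inserted, which downstream becomes an "Unknown" annotation.  An
empty set cannot occur.
"""

from __future__ import annotations

import datetime
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "MappingDictionaryFile",
    "AnnotationStore",
    "StoreIntegrityError",
    "build_store",
    "open_store",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")
_SCHEMA = """
CREATE TABLE IF NOT EXISTS mapping (key TEXT PRIMARY KEY, ids TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS metadata (name TEXT PRIMARY KEY, value TEXT NOT NULL);
"""


class StoreIntegrityError(RuntimeError):
    """The store file is missing, corrupted, or not an annotation store."""


@dataclass(frozen=True)
class MappingDictionaryFile:
    """Description of a plain-text mapping dictionary.

    Columns are 1-based.  Lines starting with ``#`` are comments; a single
    header line may be skipped with ``skip_header``.  ``strip_versions``
    removes a trailing ``.N`` accession version from every key at build time
    (and must then also be used at lookup time, which the store records and
    applies automatically).
    """

    path: str | Path
    key_column: int = 1
    value_column: int = 2
    value_separator: str = ";"
    skip_header: bool = False
    strip_versions: bool = False

    def __post_init__(self) -> None:
        if self.key_column == self.value_column:
            raise ValueError("key_column and value_column must differ")
        if self.key_column < 1 or self.value_column < 1:
            raise ValueError("column indices are 1-based")
        if self.value_separator == "\t" or len(self.value_separator) != 1:
            raise ValueError("value_separator must be a single non-tab character")


@dataclass
class BuildReport:
    """Tallies and provenance recorded by :func:`build_store`."""

    n_keys: int = 0
    n_lines: int = 0
    n_invalid_lines: int = 0
    warnings: list[str] = field(default_factory=list)


def _strip_key(key: str, strip_versions: bool) -> str:
    key = key.strip()
    if strip_versions:
        key = _VERSION_SUFFIX.sub("", key)
    return key


def read_dictionary(dictionary: MappingDictionaryFile) -> tuple[dict[str, set[str]], BuildReport]:
    """Parse a mapping dictionary into an in-memory key→ID-set mapping.

    This is also the brute-force reference the store is tested against.
    """
    report = BuildReport()
    mapping: dict[str, set[str]] = {}
    need = max(dictionary.key_column, dictionary.value_column)
    first_data_line = True
    with open(dictionary.path, "rt", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            if first_data_line and dictionary.skip_header:
                first_data_line = False
                continue
            first_data_line = False
            report.n_lines += 1
            fields = line.split("\t")
            if len(fields) < need:
                report.n_invalid_lines += 1
                continue
            key = _strip_key(fields[dictionary.key_column - 1], dictionary.strip_versions)
            raw_values = fields[dictionary.value_column - 1]
            values = {
                v.strip()
                for v in raw_values.split(dictionary.value_separator)
                if v.strip()
            }
            if not key or not values:
                report.n_invalid_lines += 1
                continue
            mapping.setdefault(key, set()).update(values)
    report.n_keys = len(mapping)
    if report.n_keys == 0:
        report.warnings.append("dictionary produced zero valid entries; store is empty")
    return mapping, report


class AnnotationStore:
    """Read handle over a built store; supports ``in`` and context-manager use."""

    def __init__(self, store_path: str | Path):
        self.store_path = Path(store_path)
        if not self.store_path.exists():
            raise StoreIntegrityError(f"store file not found: {self.store_path}")
        try:
            self._conn = sqlite3.connect(self.store_path)
            self._meta = dict(
                self._conn.execute("SELECT name, value FROM metadata").fetchall()
            )
        except sqlite3.DatabaseError as exc:
            raise StoreIntegrityError(
                f"{self.store_path} is not a valid annotation store: {exc}"
            ) from exc
        if "n_keys" not in self._meta:
            raise StoreIntegrityError(
                f"{self.store_path} lacks build metadata; was the build interrupted?"
            )
        self._strip_versions = self._meta.get("strip_versions") == "1"
        self._separator = self._meta.get("value_separator", ";")

    @property
    def n_keys(self) -> int:
        return int(self._meta["n_keys"])

    @property
    def build_metadata(self) -> dict[str, str]:
        return dict(self._meta)

    def lookup(self, key: str) -> frozenset[str] | None:
        """Return the merged value set for ``key``, or ``None`` if absent."""
        key = _strip_key(key, self._strip_versions)
        try:
            row = self._conn.execute(
                "SELECT ids FROM mapping WHERE key = ?", (key,)
            ).fetchone()
        except sqlite3.DatabaseError as exc:
            raise StoreIntegrityError(f"store query failed: {exc}") from exc
        if row is None:
            return None
        return frozenset(row[0].split(self._separator))

    def __contains__(self, key: str) -> bool:
        return self.lookup(key) is not None

    def keys(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT key FROM mapping")]

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "AnnotationStore":
        return self

    def __exit__(self, *exc_info) -> None:
        self.close()


def build_store(
    dictionary: MappingDictionaryFile,
    store_path: str | Path,
) -> tuple[AnnotationStore, BuildReport]:
    """Compile a mapping dictionary into a persistent on-disk store.

    Rebuilding over an existing store replaces it atomically enough for
    single-writer use (the file is truncated first).  Zero valid lines yield
    an empty store with a warning in the report, not an error.
    """
    mapping, report = read_dictionary(dictionary)
    store_path = Path(store_path)
    store_path.parent.mkdir(parents=True, exist_ok=True)
    if store_path.exists():
        store_path.unlink()
    conn = sqlite3.connect(store_path)
    try:
        conn.executescript(_SCHEMA)
        sep = dictionary.value_separator
        conn.executemany(
            "INSERT INTO mapping (key, ids) VALUES (?, ?)",
            ((key, sep.join(sorted(ids))) for key, ids in mapping.items()),
        )
        meta = {
            "source_path": str(dictionary.path),
            "build_timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "value_separator": sep,
            "strip_versions": "1" if dictionary.strip_versions else "0",
            "backend": f"sqlite3 {sqlite3.sqlite_version}",
            "n_keys": str(report.n_keys),
            "n_invalid_lines": str(report.n_invalid_lines),
        }
        conn.executemany(
            "INSERT INTO metadata (name, value) VALUES (?, ?)", meta.items()
        )
        conn.commit()
    finally:
        conn.close()
    return AnnotationStore(store_path), report


def open_store(store_path: str | Path) -> AnnotationStore:
    """Open an existing store for lookups."""
    return AnnotationStore(store_path)
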