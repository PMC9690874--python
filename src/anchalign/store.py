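"""The subalignment knowledge base.

Four relations back the heuristic aligner:

* ``seq_data(id, seq)`` — every input sequence;
* ``sample_seq(id, seq)`` — the current z-sized random sample;
* ``aligned_subseq(id, subseq)`` — deduplicated *gapless* versions of
  subalignment rows: the strings actually searched for in new sequences
  ('-ACA', 'A-CA', 'AC-A', 'ACA-' and 'ACA' all bind to 'ACA');
* ``lookup(id, subseq_a_id, subseq_b_id, aligned_a, aligned_b, score)`` —
  the stored subalignments (gapped rows + score) referencing the gapless
  strings.

The lookup table is populated by optimally aligning every unordered pair
of the sample, sliding a k-column window over each alignment, and keeping
the windows whose score clears the threshold (default ceil(k/2)*match).

Storage is a contract (:class:`StorageBackend`); the default backend is
SQLite (embedded, file- or memory-resident) and :class:`MemoryBackend` is a
plain-dict implementation with identical behaviour used in tests.
"""

from __future__ import annotations

import math
import sqlite3
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from random import Random
from typing import Iterable, NamedTuple, Sequence as TSequence

from .errors import (
    DuplicateIdError,
    InvalidSequenceError,
    ParameterError,
    StateError,
)
from .pairwise import PairwiseAlignment, exact_align
from .scoring import GAP, FixedScoring, Scoring, rescore_alignment, validate_dna

__all__ = [
    "Sequence",
    "LookupConfig",
    "LookupRow",
    "BuildResult",
    "StorageBackend",
    "SQLiteBackend",
    "MemoryBackend",
    "SubalignmentStore",
    "extract_window_subalignments",
    "max_subseq_count",
    "table_size_estimate",
]


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence (alphabet A/C/G/T)."""

    id: str
    seq: str


@dataclass(frozen=True)
class LookupConfig:
    """Parameters of the lookup-table build.

    ``k`` is the subalignment length in alignment columns, ``z`` the sample
    size, ``threshold`` the minimum window score to store (``None`` means
    the default ceil(k/2)*match).  ``strict`` switches the threshold test
    from ``score >= threshold`` (default, keeps boundary windows) to
    ``score > threshold``.
    """

    k: int
    z: int
    scheme: Scoring = field(default_factory=FixedScoring)
    threshold: int | None = None
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        if self.z < 2:
            raise ParameterError("z must be >= 2")

    @property
    def resolved_threshold(self) -> int:
        if self.threshold is not None:
            return self.threshold
        return math.ceil(self.k / 2) * self.scheme.match

    def keeps(self, score: int) -> bool:
        t = self.resolved_threshold
        return score > t if self.strict else score >= t


class LookupRow(NamedTuple):
    id: int
    subseq_a_id: int
    subseq_b_id: int
    aligned_a: str
    aligned_b: str
    score: int


class BuildResult(NamedTuple):
    n_lookup_rows: int
    n_subseq_rows: int
    n_pair_alignments: int


def max_subseq_count(k: int) -> int:
    """Capacity bound for aligned_subseq: count of non-empty gapless DNA
    strings of length <= k, i.e. sum_{r=1..k} 4^r = 4*(4^k - 1)/3."""
    return 4 * (4**k - 1) // 3


def table_size_estimate(z: int, h_avg: int) -> int:
    """Order-of-magnitude size estimate z^2 * h_avg for the lookup tables:
    z sequences give O(z^2) sample pairs, each alignment splitting into
    O(h_avg) windows."""
    return z * z * h_avg


def extract_window_subalignments(
    aln: PairwiseAlignment, config: LookupConfig
) -> list[tuple[str, str, int]]:
    """Slide a k-column window over an optimal alignment and keep the
    high-scoring subalignments.

    One window per column offset 0..(L-k).  A window is kept iff its score
    (rescored under the config scheme, so affine gap runs are priced
    window-locally) clears the threshold and neither de-gapped row is
    empty.  Duplicates on (aligned_a, aligned_b) are dropped, first
    occurrence wins.  An alignment shorter than k columns yields no
    windows.
    """
    k = config.k
    length = aln.n_columns
    out: list[tuple[str, str, int]] = []
    seen: set[tuple[str, str]] = set()
    for off in range(length - k + 1):
        wa = aln.row_a[off : off + k]
        wb = aln.row_b[off : off + k]
        if (wa, wb) in seen:
            continue
        sa = wa.replace(GAP, "")
        sb = wb.replace(GAP, "")
        if not sa or not sb:
            continue
        score = rescore_alignment(wa, wb, config.scheme)
        if not config.keeps(score):
            continue
        seen.add((wa, wb))
        out.append((wa, wb, score))
    return out


class StorageBackend(ABC):
    """Relational persistence contract for the four tables.

    Implementations must behave identically; :class:`SubalignmentStore`
    contains the domain logic and treats the backend as dumb storage with
    uniqueness constraints.
    """

    @abstractmethod
    def insert_sequences(self, records: Iterable[tuple[str, str]]) -> int: ...

    @abstractmethod
    def fetch_sequences(self) -> list[tuple[str, str]]: ...

    @abstractmethod
    def count_sequences(self) -> int: ...

    @abstractmethod
    def replace_sample(self, records: Iterable[tuple[str, str]]) -> None: ...

    @abstractmethod
    def fetch_sample(self) -> list[tuple[str, str]]: ...

    @abstractmethod
    def clear_lookup(self) -> None:
        """Empty aligned_subseq and lookup (a rebuild starts fresh)."""

    @abstractmethod
    def get_or_create_subseq(self, subseq: str) -> int: ...

    @abstractmethod
    def insert_lookup(
        self, a_id: int, b_id: int, aligned_a: str, aligned_b: str, score: int
    ) -> bool:
        """Insert unless a row with the same (aligned_a, aligned_b) exists;
        return whether a row was inserted."""

    @abstractmethod
    def fetch_subseqs(self) -> list[tuple[int, str]]: ...

    @abstractmethod
    def fetch_lookup(self) -> list[LookupRow]: ...


class SQLiteBackend(StorageBackend):
    """Embedded-SQL backend (default).  ``path=':memory:'`` keeps the
    database in RAM; any other path persists it on disk."""

    def __init__(self, path: str = ":memory:") -> None:
        self._con = sqlite3.connect(path)
        self._con.executescript(
            """
            CREATE TABLE IF NOT EXISTS seq_data (
                id TEXT PRIMARY KEY, seq TEXT NOT NULL);
            CREATE TABLE IF NOT EXISTS sample_seq (
                id TEXT PRIMARY KEY, seq TEXT NOT NULL);
            CREATE TABLE IF NOT EXISTS aligned_subseq (
                id INTEGER PRIMARY KEY,
                subseq TEXT NOT NULL UNIQUE);
            CREATE TABLE IF NOT EXISTS lookup (
                id INTEGER PRIMARY KEY,
                subseq_a_id INTEGER NOT NULL REFERENCES aligned_subseq(id),
                subseq_b_id INTEGER NOT NULL REFERENCES aligned_subseq(id),
                aligned_a TEXT NOT NULL,
                aligned_b TEXT NOT NULL,
                score INTEGER NOT NULL,
                UNIQUE (aligned_a, aligned_b));
            CREATE INDEX IF NOT EXISTS idx_lookup_pair
                ON lookup (subseq_a_id, subseq_b_id);
            """
        )

    def insert_sequences(self, records):
        records = list(records)
        try:
            with self._con:
                self._con.executemany(
                    "INSERT INTO seq_data (id, seq) VALUES (?, ?)", records
                )
        except sqlite3.IntegrityError as exc:
            raise DuplicateIdError(f"duplicate sequence id: {exc}") from exc
        return len(records)

    def fetch_sequences(self):
        cur = self._con.execute("SELECT id, seq FROM seq_data ORDER BY id")
        return cur.fetchall()

    def count_sequences(self):
        return self._con.execute("SELECT COUNT(*) FROM seq_data").fetchone()[0]

    def replace_sample(self, records):
        with self._con:
            self._con.execute("DELETE FROM sample_seq")
            self._con.executemany(
                "INSERT INTO sample_seq (id, seq) VALUES (?, ?)", records
            )

    def fetch_sample(self):
        cur = self._con.execute("SELECT id, seq FROM sample_seq ORDER BY id")
        return cur.fetchall()

    def clear_lookup(self):
        with self._con:
            self._con.execute("DELETE FROM lookup")
            self._con.execute("DELETE FROM aligned_subseq")

    def get_or_create_subseq(self, subseq):
        row = self._con.execute(
            "SELECT id FROM aligned_subseq WHERE subseq = ?", (subseq,)
        ).fetchone()
        if row is not None:
            return row[0]
        with self._con:
            cur = self._con.execute(
                "INSERT INTO aligned_subseq (subseq) VALUES (?)", (subseq,)
            )
        return cur.lastrowid

    def insert_lookup(self, a_id, b_id, aligned_a, aligned_b, score):
        with self._con:
            cur = self._con.execute(
                "INSERT OR IGNORE INTO lookup "
                "(subseq_a_id, subseq_b_id, aligned_a, aligned_b, score) "
                "VALUES (?, ?, ?, ?, ?)",
                (a_id, b_id, aligned_a, aligned_b, score),
            )
        return cur.rowcount == 1

    def fetch_subseqs(self):
        cur = self._con.execute("SELECT id, subseq FROM aligned_subseq ORDER BY id")
        return cur.fetchall()

    def fetch_lookup(self):
        cur = self._con.execute(
            "SELECT id, subseq_a_id, subseq_b_id, aligned_a, aligned_b, score "
            "FROM lookup ORDER BY id"
        )
        return [LookupRow(*row) for row in cur.fetchall()]

    def close(self) -> None:
        self._con.close()


class MemoryBackend(StorageBackend):
    """Pure-python dict backend, behaviourally identical to SQLite."""

    def __init__(self) -> None:
        self._seqs: dict[str, str] = {}
        self._sample: dict[str, str] = {}
        self._subseq_by_str: dict[str, int] = {}
        self._lookup: list[LookupRow] = []
        self._lookup_keys: set[tuple[str, str]] = set()

    def insert_sequences(self, records):
        records = list(records)
        staged = dict(self._seqs)
        for sid, seq in records:
            if sid in staged:
                raise DuplicateIdError(f"duplicate sequence id: {sid!r}")
            staged[sid] = seq
        self._seqs = staged
        return len(records)

    def fetch_sequences(self):
        return sorted(self._seqs.items())

    def count_sequences(self):
        return len(self._seqs)

    def replace_sample(self, records):
        self._sample = dict(records)

    def fetch_sample(self):
        return sorted(self._sample.items())

    def clear_lookup(self):
        self._subseq_by_str.clear()
        self._lookup.clear()
        self._lookup_keys.clear()

    def get_or_create_subseq(self, subseq):
        if subseq not in self._subseq_by_str:
            self._subseq_by_str[subseq] = len(self._subseq_by_str) + 1
        return self._subseq_by_str[subseq]

    def insert_lookup(self, a_id, b_id, aligned_a, aligned_b, score):
        key = (aligned_a, aligned_b)
        if key in self._lookup_keys:
            return False
        self._lookup_keys.add(key)
        self._lookup.append(
            LookupRow(len(self._lookup) + 1, a_id, b_id, aligned_a, aligned_b, score)
        )
        return True

    def fetch_subseqs(self):
        return sorted(
            ((i, s) for s, i in self._subseq_by_str.items()), key=lambda t: t[0]
        )

    def fetch_lookup(self):
        return list(self._lookup)


class SubalignmentStore:
    """Domain facade over a storage backend.

    Typical life cycle: :meth:`load_sequences` (or :meth:`load_fasta`),
    :meth:`draw_sample`, :meth:`build_lookup`; then hand the store to
    :func:`anchalign.heuristic.heuristic_align`.
    """

    def __init__(self, backend: StorageBackend | None = None) -> None:
        self.backend = backend if backend is not None else SQLiteBackend()
        self.last_build: BuildResult | None = None

    # -- seq_data ---------------------------------------------------------

    def load_sequences(self, records: Iterable[tuple[str, str] | Sequence]) -> int:
        """Persist (id, seq) records into seq_data; returns the count.

        Ids must be new and unique; sequences must be non-empty A/C/G/T
        strings (inputs containing N are rejected — degenerate bases are
        out of scope)."""
        rows: list[tuple[str, str]] = []
        seen: set[str] = set()
        for rec in records:
            sid, seq = (rec.id, rec.seq) if isinstance(rec, Sequence) else rec
            if sid in seen:
                raise DuplicateIdError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
            if not seq:
                raise InvalidSequenceError(f"empty sequence for id {sid!r}")
            validate_dna(seq)
            rows.append((sid, seq))
        return self.backend.insert_sequences(rows)

    def load_fasta(self, path) -> int:
        from .fasta import read_fasta

        return self.load_sequences(read_fasta(path))

    def sequences(self) -> list[Sequence]:
        return [Sequence(i, s) for i, s in self.backend.fetch_sequences()]

    # -- sample_seq -------------------------------------------------------

    def draw_sample(self, z: int, seed: int) -> list[Sequence]:
        """Uniform random z-subset of seq_data, without replacement,
        deterministic under ``seed``; persisted in sample_seq."""
        n = self.backend.count_sequences()
        if z <= 0 or z > n:
            raise ParameterError(f"sample size z={z} must satisfy 0 < z <= {n}")
        records = self.backend.fetch_sequences()
        chosen = Random(seed).sample(records, z)
        chosen.sort(key=lambda t: t[0])
        self.backend.replace_sample(chosen)
        return [Sequence(i, s) for i, s in chosen]

    def sample(self) -> list[Sequence]:
        return [Sequence(i, s) for i, s in self.backend.fetch_sample()]

    # -- lookup build -----------------------------------------------------

    def build_lookup(self, config: LookupConfig) -> BuildResult:
        """Populate aligned_subseq and lookup from the current sample.

        Every unordered sample pair (z*(z-1)/2 of them) is optimally
        aligned under the config scheme; k-column windows clearing the
        threshold are stored with their gapless strings.  Rebuilding with
        the same sample and config yields identical tables."""
        sample = self.backend.fetch_sample()
        if not sample:
            raise StateError("sample_seq is empty; call draw_sample first")
        self.backend.clear_lookup()
        n_pairs = 0
        n_rows = 0
        for i in range(len(sample)):
            for j in range(i + 1, len(sample)):
                aln = exact_align(sample[i][1], sample[j][1], config.scheme)
                n_pairs += 1
                for wa, wb, score in extract_window_subalignments(aln, config):
                    a_id = self.backend.get_or_create_subseq(wa.replace(GAP, ""))
                    b_id = self.backend.get_or_create_subseq(wb.replace(GAP, ""))
                    if self.backend.insert_lookup(a_id, b_id, wa, wb, score):
                        n_rows += 1
        result = BuildResult(n_rows, len(self.backend.fetch_subseqs()), n_pairs)
        self.last_build = result
        return result

    def subseqs(self) -> list[tuple[int, str]]:
        return self.backend.fetch_subseqs()

    def lookup_rows(self) -> list[LookupRow]:
        return self.backend.fetch_lookup()
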