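"""Strand-aware 5' read-start profiles from aligned-read records.

A *5' profile* counts, for every (reference, strand, position), how many
sequenced fragments begin there.  On the forward strand a fragment's 5' end
is the leftmost aligned base of its informative read; on the reverse strand
it is the rightmost aligned base.  Soft-clipped bases are excluded: the
5' end is taken from the aligned span only, because clipped bases are not
genome-supported.

Coordinates are 1-based and inclusive throughout this module (SAM
convention); the BEDGraph writer in :mod:`fragexcess.io` converts to
0-based half-open intervals at the boundary.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Strand = str  # "+" or "-"
Key = tuple[str, Strand]  # (reference, strand)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read, reduced to the fields the pipeline needs.

    ``leftmost``/``rightmost`` are the 1-based first and last *aligned*
    reference bases (soft clips excluded, deletions/introns spanned).
    ``is_unique`` is False for secondary/supplementary or otherwise
    multi-mapping alignments; such records never enter a profile.
    """

    reference: str
    leftmost: int
    rightmost: int
    strand: Strand
    is_paired: bool = False
    is_read2: bool = False
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.leftmost < 1 or self.rightmost < self.leftmost:
            raise ValueError(
                f"invalid aligned span [{self.leftmost}, {self.rightmost}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class FivePrimeProfile:
    """Sparse per-(reference, strand, position) counts of fragment 5' ends.

    Counts are stored columnar: for each (reference, strand) a sorted
    array of positions and a parallel array of positive counts.  Zero
    counts are never stored, and ``total_reads`` always equals the sum of
    all stored counts.

    Parameters
    ----------
    data
        Mapping ``(reference, strand) -> (positions, counts)`` of integer
        arrays, or a flat mapping ``(reference, strand, position) -> count``.
    references
        Optional declared reference space.  When two profiles with
        declared, differing reference sets are merged an error is raised;
        undeclared profiles merge freely.
    """

    def __init__(
        self,
        data: Mapping | None = None,
        references: Iterable[str] | None = None,
    ) -> None:
        self._data: dict[Key, tuple[np.ndarray, np.ndarray]] = {}
        self.references: frozenset[str] | None = (
            frozenset(references) if references is not None else None
        )
        if data:
            first_key = next(iter(data))
            if len(first_key) == 3:  # flat (ref, strand, pos) -> count
                grouped: dict[Key, list[tuple[int, int]]] = {}
                for (ref, strand, pos), count in data.items():
                    grouped.setdefault((ref, strand), []).append((pos, count))
                for key, pairs in grouped.items():
                    pairs.sort()
                    pos = np.array([p for p, _ in pairs], dtype=np.int64)
                    cnt = np.array([c for _, c in pairs], dtype=np.int64)
                    self._set_arrays(key, pos, cnt)
            else:
                for key, (pos, cnt) in data.items():
                    pos = np.asarray(pos, dtype=np.int64)
                    cnt = np.asarray(cnt, dtype=np.int64)
                    order = np.argsort(pos, kind="stable")
                    self._set_arrays(key, pos[order], cnt[order])

    def _set_arrays(self, key: Key, pos: np.ndarray, cnt: np.ndarray) -> None:
        if np.any(cnt < 0):
            raise ValueError("negative counts are not allowed")
        keep = cnt > 0
        pos, cnt = pos[keep], cnt[keep]
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError(f"duplicate or unsorted positions for {key}")
        if np.any(pos < 1):
            raise ValueError("positions must be >= 1")
        if pos.size:
            self._data[key] = (pos, cnt)

    # -- mapping-style access ------------------------------------------------

    @property
    def total_reads(self) -> int:
        return int(sum(int(cnt.sum()) for _, cnt in self._data.values()))

    @property
    def n_positions(self) -> int:
        return int(sum(pos.size for pos, _ in self._data.values()))

    def keys(self) -> list[Key]:
        return sorted(self._data)

    def arrays(self, key: Key) -> tuple[np.ndarray, np.ndarray]:
        """(positions, counts) for one (reference, strand); empty if absent."""
        if key in self._data:
            return self._data[key]
        empty = np.array([], dtype=np.int64)
        return empty, empty

    def observed_references(self) -> frozenset[str]:
        return frozenset(ref for ref, _ in self._data)

    def as_dict(self) -> dict[tuple[str, Strand, int], int]:
        """Flat sparse mapping (reference, strand, position) -> count."""
        out: dict[tuple[str, Strand, int], int] = {}
        for (ref, strand), (pos, cnt) in sorted(self._data.items()):
            for p, c in zip(pos.tolist(), cnt.tolist()):
                out[(ref, strand, p)] = c
        return out

    def __getitem__(self, key: tuple[str, Strand, int]) -> int:
        ref, strand, position = key
        pos, cnt = self.arrays((ref, strand))
        i = np.searchsorted(pos, position)
        if i < pos.size and pos[i] == position:
            return int(cnt[i])
        return 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FivePrimeProfile):
            return NotImplemented
        if self.keys() != other.keys():
            return False
        return all(
            np.array_equal(self._data[k][0], other._data[k][0])
            and np.array_equal(self._data[k][1], other._data[k][1])
            for k in self._data
        )

    def __repr__(self) -> str:
        return (
            f"FivePrimeProfile(n_positions={self.n_positions}, "
            f"total_reads={self.total_reads})"
        )

    def collapse_strands(self) -> "FivePrimeProfile":
        """Sum counts over strands, yielding a strand-collapsed profile.

        All collapsed counts are reported on the forward strand.
        """
        out = FivePrimeProfile(references=self.references)
        refs = {ref for ref, _ in self._data}
        for ref in refs:
            parts = [self.arrays((ref, s)) for s in ("+", "-")]
            pos = np.concatenate([p for p, _ in parts])
            cnt = np.concatenate([c for _, c in parts])
            upos, inv = np.unique(pos, return_inverse=True)
            ucnt = np.bincount(inv, weights=cnt).astype(np.int64)
            out._set_arrays((ref, "+"), upos, ucnt)
        return out


# -- per-record operations ---------------------------------------------------


def five_prime_position(record: AlignmentRecord) -> tuple[str, Strand, int]:
    """Genomic 5'-end coordinate of the fragment an informative read reports.

    Forward-strand reads start at their leftmost aligned base, reverse-strand
    reads at their rightmost.
    """
    if record.strand == "+":
        return record.reference, "+", record.leftmost
    return record.reference, "-", record.rightmost


def select_informative_reads(
    records: Iterable[AlignmentRecord], layout: str
) -> list[AlignmentRecord]:
    """Keep only the reads whose 5' end marks a sequenced-fragment start.

    With a paired layout only read-2 records are informative (their 5' end
    coincides with the fragment 5' end), whether or not the mate aligned.
    With a single-end layout every record is informative.  Multi-mapping
    records are always dropped.
    """
    if layout not in ("paired", "single"):
        raise ValueError(f"layout must be 'paired' or 'single', got {layout!r}")
    records = list(records)
    unique = [r for r in records if r.is_unique]
    if layout == "single":
        return unique
    kept = [r for r in unique if r.is_read2]
    if records and not kept:
        logger.warning(
            "paired layout but no read-2 records found among %d records; "
            "suspicious library",
            len(records),
        )
    return kept


# -- library-level operations ------------------------------------------------


def library_rng(seed: int, library_name: str) -> np.random.Generator:
    """Child RNG stream for one library, stable under library addition.

    The stream is keyed by a CRC32 hash of the library name, so adding or
    reordering libraries does not perturb the sample drawn for the others.
    """
    key = zlib.crc32(library_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def undersample(
    libraries: Sequence[Sequence[AlignmentRecord]],
    fraction: float = 0.9,
    *,
    seed: int,
    names: Sequence[str] | None = None,
) -> list[list[AlignmentRecord]]:
    """Equalize sequencing depth across libraries by random subsampling.

    Every library is reduced, uniformly without replacement, to
    ``floor(fraction x smallest library size)`` records.  This removes
    depth as a confounder before the two strains' profiles are compared.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if any(len(lib) == 0 for lib in libraries):
        raise ValueError("all libraries must be non-empty")
    target = int(np.floor(fraction * min(len(lib) for lib in libraries)))
    if target == 0:
        raise ValueError("degenerate depth: undersampling target is 0 reads")
    if names is None:
        names = [f"library_{i}" for i in range(len(libraries))]
    out = []
    for lib, name in zip(libraries, names):
        rng = library_rng(seed, name)
        idx = rng.choice(len(lib), size=target, replace=False)
        idx.sort()
        out.append([lib[i] for i in idx])
    return out


def build_profile(
    records: Iterable[AlignmentRecord],
    references: Iterable[str] | None = None,
) -> FivePrimeProfile:
    """Accumulate 5'-end counts of already-filtered records into a profile."""
    grouped: dict[Key, list[int]] = {}
    n = 0
    for record in records:
        ref, strand, pos = five_prime_position(record)
        grouped.setdefault((ref, strand), []).append(pos)
        n += 1
    profile = FivePrimeProfile(references=references)
    for key, positions in grouped.items():
        pos, cnt = np.unique(np.asarray(positions, dtype=np.int64), return_counts=True)
        profile._set_arrays(key, pos, cnt.astype(np.int64))
    assert profile.total_reads == n
    return profile


def merge_replicates(profiles: Sequence[FivePrimeProfile]) -> FivePrimeProfile:
    """Position-wise sum of replicate profiles into one per-strain profile."""
    if not profiles:
        raise ValueError("need at least one profile to merge")
    declared = [p.references for p in profiles if p.references is not None]
    if declared and any(d != declared[0] for d in declared[1:]):
        raise ValueError("profiles declare mismatched reference names")
    merged = FivePrimeProfile(references=declared[0] if declared else None)
    keys = sorted(set().union(*(p.keys() for p in profiles)))
    for key in keys:
        parts = [p.arrays(key) for p in profiles]
        pos = np.concatenate([p for p, _ in parts])
        cnt = np.concatenate([c for _, c in parts])
        upos, inv = np.unique(pos, return_inverse=True)
        ucnt = np.bincount(inv, weights=cnt).astype(np.int64)
        merged._set_arrays(key, upos, ucnt)
    return merged
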