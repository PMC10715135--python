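"""Readers and writers: SAM, alignment-TSV fixtures, BEDGraph, counts tables.

SAM coordinates follow the SAM specification (1-based, CIGAR-derived
aligned span; soft clips excluded from the span).  BEDGraph output is
0-based half-open, converted at this boundary only.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .profiles import AlignmentRecord, FivePrimeProfile

TSV_COLUMNS = [
    "reference", "leftmost", "rightmost", "strand",
    "is_paired", "is_read2", "is_unique",
]


# -- SAM ---------------------------------------------------------------------


def read_sam(path: str | Path, min_mapq: int | None = None) -> list[AlignmentRecord]:
    """Load mapped reads from a SAM/BAM file as AlignmentRecords.

    Uniqueness is taken from the secondary/supplementary flags; pass
    ``min_mapq`` to additionally treat low-MAPQ alignments as non-unique
    (off by default).
    """
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for i, read in enumerate(handle):
            if read.is_unmapped:
                continue
            if read.reference_end is None:
                raise ValueError(
                    f"{path}: record {i + 1} has no aligned span (missing CIGAR?)"
                )
            unique = not (read.is_secondary or read.is_supplementary)
            if min_mapq is not None and read.mapping_quality < min_mapq:
                unique = False
            records.append(
                AlignmentRecord(
                    reference=read.reference_name,
                    leftmost=read.reference_start + 1,
                    rightmost=read.reference_end,  # 0-based excl == 1-based incl
                    strand="-" if read.is_reverse else "+",
                    is_paired=read.is_paired,
                    is_read2=read.is_read2,
                    is_unique=unique,
                )
            )
    return records


def write_sam(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    reference_lengths: dict[str, int],
) -> None:
    """Write records as minimal SAM (header SQ lines, flags, CIGAR only).

    A paired read-2 record immediately followed by its read-1 mate is
    written as one proper pair sharing a template name; any other paired
    record is written with its mate flagged unmapped.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in sorted(reference_lengths.items())],
    }
    ref_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}

    def segment(rec: AlignmentRecord, qname: str) -> pysam.AlignedSegment:
        seg = pysam.AlignedSegment()
        seg.query_name = qname
        seg.reference_id = ref_ids[rec.reference]
        seg.reference_start = rec.leftmost - 1
        seg.cigartuples = [(0, rec.rightmost - rec.leftmost + 1)]
        seg.mapping_quality = 60 if rec.is_unique else 0
        flag = 0
        if rec.strand == "-":
            flag |= 0x10
        if rec.is_paired:
            flag |= 0x1
            flag |= 0x80 if rec.is_read2 else 0x40
        if not rec.is_unique:
            flag |= 0x100
        seg.flag = flag
        return seg

    with pysam.AlignmentFile(str(path), "w", header=header) as handle:
        i = 0
        pair_id = 0
        while i < len(records):
            rec = records[i]
            mate = records[i + 1] if i + 1 < len(records) else None
            if (
                rec.is_paired and rec.is_read2
                and mate is not None and mate.is_paired and not mate.is_read2
            ):
                qname = f"pair{pair_id}"
                pair_id += 1
                seg2, seg1 = segment(rec, qname), segment(mate, qname)
                for seg, other, other_rec in ((seg2, seg1, mate), (seg1, seg2, rec)):
                    seg.flag |= 0x2
                    if other_rec.strand == "-":
                        seg.flag |= 0x20
                    seg.next_reference_id = other.reference_id
                    seg.next_reference_start = other.reference_start
                handle.write(seg2)
                handle.write(seg1)
                i += 2
            else:
                seg = segment(rec, f"read{pair_id}")
                pair_id += 1
                if rec.is_paired:
                    seg.flag |= 0x8  # mate unmapped
                handle.write(seg)
                i += 1


# -- alignment TSV fixture format -------------------------------------------


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Read the documented TSV fixture format (see TSV_COLUMNS)."""
    records = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(
            (line for line in handle if not line.startswith("#")), delimiter="\t"
        )
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader):
            try:
                records.append(
                    AlignmentRecord(
                        reference=row["reference"],
                        leftmost=int(row["leftmost"]),
                        rightmost=int(row["rightmost"]),
                        strand=row["strand"],
                        is_paired=_parse_bool(row["is_paired"]),
                        is_read2=_parse_bool(row["is_read2"]),
                        is_unique=_parse_bool(row["is_unique"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: bad record at data row {i + 1}: {exc}")
    return records


def write_alignment_tsv(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.reference, r.leftmost, r.rightmost, r.strand,
                int(r.is_paired), int(r.is_read2), int(r.is_unique),
            ])


def _parse_bool(token: str) -> bool:
    token = token.strip().lower()
    if token in ("1", "true", "t", "yes"):
        return True
    if token in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"not a boolean: {token!r}")


def read_alignments(path: str | Path, min_mapq: int | None = None) -> list[AlignmentRecord]:
    """Dispatch on extension: .sam/.bam via pysam, .tsv via the fixture format."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam"):
        return read_sam(path, min_mapq=min_mapq)
    if suffix in (".tsv", ".txt"):
        return read_alignment_tsv(path)
    raise ValueError(f"unrecognized alignment file extension: {path}")


# -- BEDGraph ----------------------------------------------------------------

STRAND_SUFFIX = {"+": "plus", "-": "minus"}


def write_bedgraph(profile: FivePrimeProfile, prefix: str | Path) -> list[Path]:
    """Write one 4-column BEDGraph per strand: ``<prefix>.plus.bedgraph``
    and ``<prefix>.minus.bedgraph`` (0-based half-open intervals)."""
    paths = []
    for strand, suffix in STRAND_SUFFIX.items():
        path = Path(f"{prefix}.{suffix}.bedgraph")
        with open(path, "w") as handle:
            for ref in sorted(profile.observed_references()):
                positions, counts = profile.arrays((ref, strand))
                for pos, count in zip(positions.tolist(), counts.tolist()):
                    handle.write(f"{ref}\t{pos - 1}\t{pos}\t{count}\n")
        paths.append(path)
    return paths


def read_bedgraph_pair(
    plus_path: str | Path, minus_path: str | Path
) -> FivePrimeProfile:
    """Rebuild a profile from its per-strand BEDGraph files.

    Multi-base intervals are expanded to per-base counts.
    """
    flat: dict[tuple[str, str, int], int] = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path) as handle:
            for line in handle:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                ref, start, end, value = line.split("\t")
                for pos in range(int(start) + 1, int(end) + 1):
                    flat[(ref, strand, pos)] = flat.get((ref, strand, pos), 0) + int(value)
    return FivePrimeProfile(flat)


# -- decay tables ------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, list[float]]:
    """Counts table: columns gene, length_bp, then one column per chase
    time point with the time (min) in the header, e.g. ``0 1 3 9`` or
    ``t0 t1 t3 t9``.  Returns the table and the parsed times."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["gene", "length_bp"]:
        raise ValueError(f"{path}: first columns must be 'gene' and 'length_bp'")
    times = []
    for col in df.columns[2:]:
        token = str(col).strip().lstrip("tT")
        try:
            times.append(float(token))
        except ValueError:
            raise ValueError(f"{path}: cannot parse time from column {col!r}")
    if len(times) < 3:
        raise ValueError(f"{path}: need at least 3 time points")
    return df, times


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    """qPCR Ct table: columns sample, gene, ct, time."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"sample", "gene", "ct", "time"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# -- flat key=value config ---------------------------------------------------


def parse_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
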