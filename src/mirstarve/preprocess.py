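"""Raw read cleanup: 5' hexamer trim, 3' adapter removal, length selection,
and collapsing of identical sequences into unique reads with counts.

The pipeline order is fixed: hexamer -> adapter -> length filter -> collapse.
A library-prep artifact (the hexamer ACATCG) sits at the 5' end of ~6-8% of
reads and is removed once, at the terminus only.  The 3' adapter is found by
the best un-gapped alignment of an adapter *prefix* to the read's 3' portion
(minimum 8 nt overlap, at most 10% mismatches), including a full internal
match; the read is cut at the alignment start.  Reads with no detectable
adapter are kept as-is — the 16-28 nt length filter is the only discard gate,
besides empty-after-trim reads and reads containing N (which the aligner
cannot score; they are dropped and logged).
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

HEXAMER = "ACATCG"
ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTGC"
MIN_LEN = 16
MAX_LEN = 28


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read sequence with its total observed count."""

    uid: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("unique read count must be >= 1")


@dataclass
class PreprocessStats:
    """Per-stage read totals; conservation of reads is asserted by tests."""

    raw: int = 0
    hexamer_trimmed: int = 0
    adapter_trimmed: int = 0
    with_n: int = 0
    empty_after_trim: int = 0
    length_filtered_out: int = 0
    kept: int = 0
    unique: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def trim_hexamer(read: RawRead, hexamer: str = HEXAMER, max_trims: int = 1) -> RawRead:
    """Remove up to `max_trims` leading occurrences of the artifact hexamer."""
    seq, qual, n = read.sequence, read.quality, 0
    while n < max_trims and seq.startswith(hexamer):
        seq = seq[len(hexamer):]
        qual = qual[len(hexamer):]
        n += 1
    if n == 0:
        return read
    return RawRead(read.read_id, seq, qual)


def find_adapter_start(
    sequence: str,
    adapter: str = ADAPTER,
    min_overlap: int = 8,
    max_mm_rate: float = 0.1,
) -> int | None:
    """Leftmost read position where an adapter prefix aligns without gaps.

    A position i qualifies when the overlap min(len(read)-i, len(adapter)) is
    at least `min_overlap` and the mismatch count over the overlap is at most
    floor(overlap * max_mm_rate).  The leftmost qualifying start wins: it
    corresponds to the longest adapter match (including a full internal one).
    Returns None when nothing qualifies.
    """
    n = len(sequence)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        allowed = int(overlap * max_mm_rate)
        window = sequence[i:i + overlap]
        mm = 0
        for a, b in zip(window, adapter):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        else:
            return i
    return None


def trim_adapter(
    read: RawRead,
    adapter: str = ADAPTER,
    min_overlap: int = 8,
    max_mm_rate: float = 0.1,
) -> RawRead:
    """Cut the read at the best 3' adapter alignment; unchanged if none found."""
    start = find_adapter_start(read.sequence, adapter, min_overlap, max_mm_rate)
    if start is None:
        return read
    return RawRead(read.read_id, read.sequence[:start], read.quality[:start])


def length_filter(
    reads: Iterable[RawRead], lo: int = MIN_LEN, hi: int = MAX_LEN
) -> Iterator[RawRead]:
    """Keep reads with lo <= length <= hi (both ends inclusive)."""
    for read in reads:
        if lo <= len(read.sequence) <= hi:
            yield read


def collapse(reads: Iterable[RawRead]) -> list[UniqueRead]:
    """One UniqueRead per distinct sequence; counts sum to the input total.

    Ordering (hence uid assignment) is deterministic: descending count, then
    lexicographic sequence — the "tally" collapsing convention.
    """
    tally = Counter(read.sequence for read in reads)
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        UniqueRead(uid=f"r{i}", sequence=seq, count=count)
        for i, (seq, count) in enumerate(ordered, start=1)
    ]


def clean_reads(
    reads: Iterable[RawRead],
    hexamer: str = HEXAMER,
    adapter: str = ADAPTER,
    min_overlap: int = 8,
    max_mm_rate: float = 0.1,
    lo: int = MIN_LEN,
    hi: int = MAX_LEN,
    hexamer_max_trims: int = 1,
    stats: PreprocessStats | None = None,
) -> Iterator[RawRead]:
    """Full cleanup stream (everything before collapsing), updating stats."""
    stats = stats if stats is not None else PreprocessStats()
    for read in reads:
        stats.raw += 1
        trimmed = trim_hexamer(read, hexamer, hexamer_max_trims)
        if trimmed is not read:
            stats.hexamer_trimmed += 1
        cut = trim_adapter(trimmed, adapter, min_overlap, max_mm_rate)
        if cut is not trimmed:
            stats.adapter_trimmed += 1
        if "N" in cut.sequence:
            stats.with_n += 1
            continue
        if not cut.sequence:
            stats.empty_after_trim += 1
            continue
        if not (lo <= len(cut.sequence) <= hi):
            stats.length_filtered_out += 1
            continue
        stats.kept += 1
        yield cut


def preprocess_reads(
    reads: Iterable[RawRead], stats: PreprocessStats | None = None, **kwargs
) -> tuple[list[UniqueRead], PreprocessStats]:
    """Clean and collapse a read stream; returns (unique reads, stage totals)."""
    stats = stats if stats is not None else PreprocessStats()
    unique = collapse(clean_reads(reads, stats=stats, **kwargs))
    stats.unique = len(unique)
    return unique, stats


# ---------------------------------------------------------------------------
# FASTQ / collapsed-FASTA I/O


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq(source: str | Path | TextIO) -> Iterator[RawRead]:
    """Plain 4-line FASTQ records (gzip-aware when given a path)."""
    handle = _open_text(source) if isinstance(source, (str, Path)) else source
    try:
        while True:
            header = handle.readline()
            if not header:
                break
            seq = handle.readline().strip()
            handle.readline()  # separator line
            qual = handle.readline().strip()
            yield RawRead(header[1:].split()[0], seq.upper(), qual)
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def write_collapsed_fasta(unique: Iterable[UniqueRead], handle: TextIO) -> None:
    """Tally-dialect FASTA: header `>uid_count`."""
    for u in unique:
        handle.write(f">{u.uid}_{u.count}\n{u.sequence}\n")


def read_collapsed_fasta(source: str | Path | TextIO) -> list[UniqueRead]:
    handle = _open_text(source) if isinstance(source, (str, Path)) else source
    out: list[UniqueRead] = []
    uid = None
    try:
        for line in handle:
            line = line.strip()
            if line.startswith(">"):
                uid, count = line[1:].rsplit("_", 1)
                count = int(count)
            elif line:
                out.append(UniqueRead(uid=uid, sequence=line.upper(), count=count))
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return out


def run_preprocess(
    fastq_path: str | Path,
    out_fasta: str | Path,
    report_path: str | Path | None = None,
    **kwargs,
) -> PreprocessStats:
    unique, stats = preprocess_reads(parse_fastq(fastq_path), **kwargs)
    with open(out_fasta, "w") as fh:
        write_collapsed_fasta(unique, fh)
    if report_path is not None:
        Path(report_path).write_text(stats.to_json())
    return stats
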