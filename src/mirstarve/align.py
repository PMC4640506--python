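"""End-to-end multi-mapping of collapsed reads against the reference catalog.

Semantics: un-gapped, full-length placements with at most `max_mm`
substitutions (no indels), every qualifying location reported and then capped
at `max_hits` (default 100) in a deterministic order — (mismatches,
feature_id, offset, strand).  Reads exceeding the cap keep their first
`max_hits` hits and are flagged, not discarded.

Transcript-space features (mature, hairpin, ncRNA, coding) are matched on the
given strand only; genome-class features are additionally searched with the
reverse complement of the read (reported as strand '-'), since an intergenic
fragment can come off either genomic strand.  Setting `both_strands=True`
extends reverse-complement search to every class.

The search uses pigeonhole seeding: a read aligned with <= k mismatches must
contain at least one of k+1 disjoint exact segments, so exact occurrences of
those segments in the concatenated reference text nominate candidate offsets,
which are then verified by direct mismatch counting.  This is exhaustive —
tests assert set-equality with a brute-force sliding-window oracle.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .preprocess import UniqueRead
from .refdb import ReferenceIndex

MAX_MISMATCHES = 2
MAX_HITS = 100

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    uid: str
    feature_id: str
    seq_class: str
    offset: int  # 0-based start on the feature
    strand: str  # '+' or '-'
    mismatches: int

    def sort_key(self):
        return (self.mismatches, self.feature_id, self.offset, self.strand)


@dataclass
class HitSet:
    uid: str
    hits: list[AlignmentHit] = field(default_factory=list)
    overflow: bool = False

    @property
    def mapped(self) -> bool:
        return bool(self.hits)


class SeedIndex:
    """Concatenated reference text with per-feature spans and seed search."""

    def __init__(self, index: ReferenceIndex, separator_len: int = 30):
        self.index = index
        sep = "#" * separator_len
        parts: list[str] = []
        self._starts: list[int] = []   # global start of each feature
        self._feats: list = []
        pos = 0
        for feat in index:
            self._starts.append(pos)
            self._feats.append(feat)
            parts.append(feat.sequence)
            parts.append(sep)
            pos += len(feat.sequence) + separator_len
        self.text = "".join(parts)

    def locate(self, global_pos: int):
        """Feature containing `global_pos`, or None if in a separator."""
        i = bisect_right(self._starts, global_pos) - 1
        if i < 0:
            return None, None
        feat = self._feats[i]
        off = global_pos - self._starts[i]
        if off >= len(feat.sequence):
            return None, None
        return feat, off

    def candidate_starts(self, read_seq: str, max_mm: int) -> set[int]:
        """Global start positions nominated by exact seed occurrences."""
        n_parts = max_mm + 1
        L = len(read_seq)
        base, extra = divmod(L, n_parts)
        candidates: set[int] = set()
        part_start = 0
        for p in range(n_parts):
            part_len = base + (1 if p < extra else 0)
            seed = read_seq[part_start:part_start + part_len]
            pos = self.text.find(seed)
            while pos != -1:
                candidates.add(pos - part_start)
                pos = self.text.find(seed, pos + 1)
            part_start += part_len
        return candidates


def _count_mismatches(text: str, start: int, read_seq: str, limit: int) -> int:
    mm = 0
    for i, base in enumerate(read_seq):
        if text[start + i] != base:
            mm += 1
            if mm > limit:
                return mm
    return mm


def map_read(
    read: UniqueRead,
    seed_index: SeedIndex,
    max_mm: int = MAX_MISMATCHES,
    max_hits: int = MAX_HITS,
    both_strands: bool = False,
) -> HitSet:
    """Every end-to-end placement with <= max_mm substitutions, capped/flagged.

    An unmapped read returns an empty hit list (a valid outcome).
    """
    text = seed_index.text
    L = len(read.sequence)
    found: dict[tuple[str, int, str], int] = {}

    def scan(query: str, strand: str, class_filter) -> None:
        for gstart in seed_index.candidate_starts(query, max_mm):
            if gstart < 0 or gstart + L > len(text):
                continue
            feat, off = seed_index.locate(gstart)
            if feat is None or off + L > len(feat.sequence):
                continue
            if class_filter is not None and feat.seq_class not in class_filter:
                continue
            mm = _count_mismatches(text, gstart, query, max_mm)
            if mm <= max_mm:
                key = (feat.feature_id, off, strand)
                if key not in found or mm < found[key]:
                    found[key] = mm

    scan(read.sequence, "+", None)
    rc_classes = None if both_strands else {"genome"}
    scan(revcomp(read.sequence), "-", rc_classes)

    hits = sorted(
        (
            AlignmentHit(
                uid=read.uid,
                feature_id=fid,
                seq_class=seed_index.index[fid].seq_class,
                offset=off,
                strand=strand,
                mismatches=mm,
            )
            for (fid, off, strand), mm in found.items()
        ),
        key=AlignmentHit.sort_key,
    )
    overflow = len(hits) > max_hits
    return HitSet(uid=read.uid, hits=hits[:max_hits], overflow=overflow)


@dataclass
class MappingSummary:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    overflow: int = 0


def map_all(
    reads: Sequence[UniqueRead],
    index: ReferenceIndex | SeedIndex,
    max_mm: int = MAX_MISMATCHES,
    max_hits: int = MAX_HITS,
    both_strands: bool = False,
) -> tuple[list[HitSet], MappingSummary]:
    """One HitSet per read, order-preserving, with mapped/unmapped totals."""
    seed_index = index if isinstance(index, SeedIndex) else SeedIndex(index)
    summary = MappingSummary()
    out: list[HitSet] = []
    for read in reads:
        hs = map_read(read, seed_index, max_mm=max_mm, max_hits=max_hits,
                      both_strands=both_strands)
        summary.total += 1
        if hs.mapped:
            summary.mapped += 1
        else:
            summary.unmapped += 1
        if hs.overflow:
            summary.overflow += 1
        out.append(hs)
    return out, summary


# ---------------------------------------------------------------------------
# interoperability output


def write_hits_tsv(hitsets: Iterable[HitSet], handle: TextIO) -> None:
    handle.write("uid\tfeature_id\tclass\toffset\tstrand\tmismatches\n")
    for hs in hitsets:
        for h in hs.hits:
            handle.write(
                f"{h.uid}\t{h.feature_id}\t{h.seq_class}\t{h.offset}\t"
                f"{h.strand}\t{h.mismatches}\n"
            )


def read_hits_tsv(source) -> dict[str, list[AlignmentHit]]:
    import io
    from pathlib import Path

    handle = open(source) if isinstance(source, (str, Path)) else source
    hits: dict[str, list[AlignmentHit]] = {}
    header = handle.readline()
    for line in handle:
        uid, fid, cls, off, strand, mm = line.rstrip("\n").split("\t")
        hits.setdefault(uid, []).append(
            AlignmentHit(uid, fid, cls, int(off), strand, int(mm))
        )
    if isinstance(source, (str, Path)):
        handle.close()
    return hits


def write_sam(
    hitsets: Iterable[HitSet],
    reads: dict[str, UniqueRead],
    index: ReferenceIndex,
    handle: TextIO,
) -> None:
    """Minimal SAM: one line per hit, NM = mismatches, NH = reported hits."""
    handle.write("@HD\tVN:1.6\tSO:unsorted\n")
    for feat in index:
        handle.write(f"@SQ\tSN:{feat.feature_id}\tLN:{len(feat.sequence)}\n")
    for hs in hitsets:
        read = reads[hs.uid]
        if not hs.hits:
            handle.write(f"{hs.uid}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence}\t*\n")
            continue
        nh = len(hs.hits)
        for i, h in enumerate(hs.hits):
            flag = 0 if h.strand == "+" else 16
            if i > 0:
                flag |= 256  # secondary
            seq = read.sequence if h.strand == "+" else revcomp(read.sequence)
            handle.write(
                f"{hs.uid}\t{flag}\t{h.feature_id}\t{h.offset + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{h.mismatches}\tNH:i:{nh}\n"
            )
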