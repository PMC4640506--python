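"""Hierarchical class assignment and fractional counting of multi-mappers.

Each unique read is first assigned to a single sequence class by preference:

    mature > hairpin > ncRNA > coding > intergenic (genome)

A hit on a hairpin that falls entirely inside an extended-mature interval is
re-classified as a hit on that mature feature before the preference is taken
(reads on a hairpin proper are those outside the annotated mature regions —
mostly loop byproducts of miRNA biogenesis).  The read's observed count is
then divided equally among its retained locations *within* the winning class;
a read whose divided count drops below 1 contributes nothing anywhere.
Counts are kept as exact rationals until export so conservation holds to the
last unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .align import AlignmentHit, HitSet
from .preprocess import UniqueRead
from .refdb import ReferenceIndex

#: preference order; genome-backed assignments are reported as "intergenic"
CLASS_PREFERENCE = ("mature", "hairpin", "ncRNA", "coding", "genome")
ASSIGNED_CLASSES = ("mature", "hairpin", "ncRNA", "coding", "intergenic", "unmapped")


@dataclass(frozen=True)
class ClassAssignment:
    uid: str
    assigned_class: str  # one of ASSIGNED_CLASSES
    retained_hits: tuple[AlignmentHit, ...] = ()


def _reclassify_hairpin_hit(
    hit: AlignmentHit, index: ReferenceIndex, read_len: int, containment: str
) -> AlignmentHit:
    """Mature re-classification of a hairpin hit inside an extended interval.

    `containment` is "full" (hit entirely inside one extended-mature interval;
    the strict complement of "outside the mature regions") or "any" (any
    overlap).  When the hit is contained only in the union of overlapping
    intervals, the interval with the largest overlap wins (ties: smaller
    start, then mature id).
    """
    feat = index[hit.feature_id]
    lo, hi = hit.offset, hit.offset + read_len
    best = None
    for region in feat.mature_regions:
        if containment == "full":
            inside = region.start <= lo and hi <= region.end
        else:
            inside = lo < region.end and region.start < hi
        if inside:
            overlap = min(hi, region.end) - max(lo, region.start)
            key = (-overlap, region.start, region.mature_id)
            if best is None or key < best[0]:
                best = (key, region)
    if best is None:
        return hit
    region = best[1]
    return AlignmentHit(
        uid=hit.uid,
        feature_id=region.mature_id,
        seq_class="mature",
        offset=hit.offset - region.start,
        strand=hit.strand,
        mismatches=hit.mismatches,
    )


def resolve_class(
    hitset: HitSet,
    index: ReferenceIndex,
    read_len: int,
    mature_containment: str = "full",
) -> ClassAssignment:
    """Assign the highest-preference class present among the hits.

    Hairpin hits lying inside extended-mature intervals become mature hits
    first (de-duplicated against direct mature hits); the retained hits are
    exactly the distinct locations in the winning class.  Genome-class wins
    are reported as "intergenic".  An empty hit set is "unmapped".
    """
    if not hitset.hits:
        return ClassAssignment(uid=hitset.uid, assigned_class="unmapped")

    seen: dict[tuple[str, int, str], AlignmentHit] = {}
    for hit in hitset.hits:
        if hit.seq_class == "hairpin":
            hit = _reclassify_hairpin_hit(hit, index, read_len, mature_containment)
        key = (hit.feature_id, hit.offset, hit.strand)
        if key not in seen or hit.mismatches < seen[key].mismatches:
            seen[key] = hit

    by_class: dict[str, list[AlignmentHit]] = {}
    for hit in seen.values():
        by_class.setdefault(hit.seq_class, []).append(hit)

    for seq_class in CLASS_PREFERENCE:
        if seq_class in by_class:
            retained = tuple(sorted(by_class[seq_class], key=AlignmentHit.sort_key))
            label = "intergenic" if seq_class == "genome" else seq_class
            return ClassAssignment(hitset.uid, label, retained)
    raise AssertionError("unreachable: hits with no known class")


def partition_counts(
    assignment: ClassAssignment, read_count: int
) -> list[tuple[str, Fraction]]:
    """Equal division of the read's count over its retained locations.

    Distinct locations — (feature, offset) pairs — each receive
    read_count / n_locations; if that share is below 1 the entire read is
    ignored.  Per-feature totals sum the shares of its locations.
    """
    if assignment.assigned_class == "unmapped":
        raise ValueError("cannot partition an unmapped read")
    n = len(assignment.retained_hits)
    share = Fraction(read_count, n)
    if share < 1:
        return []
    per_feature: dict[str, Fraction] = {}
    for hit in assignment.retained_hits:
        per_feature[hit.feature_id] = per_feature.get(hit.feature_id, 0) + share
    return sorted(per_feature.items())


@dataclass
class LibraryTally:
    """Bookkeeping for one library's tabulation (exact rationals)."""

    label: str
    collapsed_total: int = 0                       # sum of unique-read counts
    class_totals: dict[str, Fraction] = field(
        default_factory=lambda: {c: Fraction(0) for c in ASSIGNED_CLASSES}
    )
    dropped_subunit: int = 0                       # reads lost to the <1 rule
    unmapped: int = 0


class CountTable:
    """Per-feature fractional counts per library (rows: feature, class)."""

    def __init__(
        self,
        counts: Mapping[str, Mapping[str, Fraction]],
        feature_classes: Mapping[str, str],
        tallies: Mapping[str, LibraryTally],
    ):
        self.counts = {f: dict(libs) for f, libs in counts.items()}
        self.feature_classes = dict(feature_classes)
        self.tallies = dict(tallies)
        self.libraries = list(tallies)

    def value(self, feature_id: str, library: str) -> Fraction:
        return self.counts.get(feature_id, {}).get(library, Fraction(0))

    def library_total(self, library: str, classes: Sequence[str] | None = None) -> Fraction:
        total = Fraction(0)
        for fid, libs in self.counts.items():
            if classes is None or self.feature_classes[fid] in classes:
                total += libs.get(library, Fraction(0))
        return total

    def to_frame(self, decimals: int = 4) -> pd.DataFrame:
        """Float export (rationals rounded to `decimals` places)."""
        rows = []
        for fid in sorted(self.counts):
            row = {"feature_id": fid, "class": self.feature_classes[fid]}
            for lib in self.libraries:
                row[lib] = round(float(self.value(fid, lib)), decimals)
            rows.append(row)
        return pd.DataFrame(rows, columns=["feature_id", "class", *self.libraries])

    def to_tsv(self, handle: TextIO, decimals: int = 4) -> None:
        self.to_frame(decimals).to_csv(handle, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        libs = [c for c in frame.columns if c not in ("feature_id", "class")]
        counts, classes = {}, {}
        tallies = {lib: LibraryTally(label=lib) for lib in libs}
        for _, row in frame.iterrows():
            fid = row["feature_id"]
            classes[fid] = row["class"]
            counts[fid] = {
                lib: Fraction(row[lib]).limit_denominator(10**6) for lib in libs
            }
        for lib in libs:
            tallies[lib].class_totals = {c: Fraction(0) for c in ASSIGNED_CLASSES}
            for fid in counts:
                tallies[lib].class_totals[classes[fid]] += counts[fid][lib]
        return cls(counts, classes, tallies)


def build_count_table(
    per_library: Mapping[str, Sequence[tuple[ClassAssignment, int]]],
    index: ReferenceIndex,
) -> CountTable:
    """Tabulate (assignment, read count) pairs for each labeled library.

    Rows exist for every feature with a nonzero value in any library; zeros
    are filled for the other libraries.  Library labels must be unique.
    """
    if len(set(per_library)) != len(list(per_library)):
        raise ValueError("library label collision")

    counts: dict[str, dict[str, Fraction]] = {}
    classes: dict[str, str] = {}
    tallies: dict[str, LibraryTally] = {}

    for label, assignments in per_library.items():
        tally = LibraryTally(label=label)
        for assignment, read_count in assignments:
            tally.collapsed_total += read_count
            if assignment.assigned_class == "unmapped":
                tally.unmapped += read_count
                tally.class_totals["unmapped"] += read_count
                continue
            shares = partition_counts(assignment, read_count)
            if not shares:
                tally.dropped_subunit += read_count
                continue
            for fid, share in shares:
                counts.setdefault(fid, {})[label] = (
                    counts.get(fid, {}).get(label, Fraction(0)) + share
                )
                hit_class = assignment.assigned_class
                classes.setdefault(fid, "mature" if hit_class == "mature" else hit_class)
                tally.class_totals[hit_class] += share
        tallies[label] = tally

    # fill zeros so every row covers every library
    for fid in counts:
        for label in per_library:
            counts[fid].setdefault(label, Fraction(0))
    return CountTable(counts, classes, tallies)


def quantify_libraries(
    hitsets_per_library: Mapping[str, Sequence[HitSet]],
    reads_per_library: Mapping[str, Sequence[UniqueRead]],
    index: ReferenceIndex,
    mature_containment: str = "full",
) -> CountTable:
    """Convenience: resolve classes and tabulate in one step."""
    per_library = {}
    for label, hitsets in hitsets_per_library.items():
        reads = {r.uid: r for r in reads_per_library[label]}
        pairs = []
        for hs in hitsets:
            read = reads[hs.uid]
            assignment = resolve_class(
                hs, index, len(read.sequence), mature_containment
            )
            pairs.append((assignment, read.count))
        per_library[label] = pairs
    return build_count_table(per_library, index)


def class_composition(table: CountTable) -> pd.DataFrame:
    """Per-library read-class fractions over all collapsed reads.

    Fractions cover {mature, hairpin, ncRNA, coding, intergenic, unmapped}
    plus the sub-unit-dropped remainder folded into "dropped", summing to 1.
    """
    rows = {}
    for lib, tally in table.tallies.items():
        denom = tally.collapsed_total
        if denom == 0:
            raise ValueError(f"library {lib} has no reads")
        fractions = {
            cls: float(tally.class_totals[cls] / denom) for cls in ASSIGNED_CLASSES
        }
        fractions["dropped"] = tally.dropped_subunit / denom
        rows[lib] = fractions
    return pd.DataFrame(rows).T[list(ASSIGNED_CLASSES) + ["dropped"]]


def top_mirna_shares(table: CountTable, n: int = 10) -> pd.DataFrame:
    """Each mature miRNA's share (%) of all miRNA-mapped reads, per library.

    Rows are the top-n features by mean share across libraries, descending.
    """
    mature = [f for f, c in table.feature_classes.items() if c == "mature"]
    if not mature:
        raise ValueError("no mature features in the table")
    data = {}
    for lib in table.libraries:
        total = table.library_total(lib, classes=("mature",))
        data[lib] = {
            fid: float(table.value(fid, lib) / total) * 100.0 if total else 0.0
            for fid in mature
        }
    frame = pd.DataFrame(data)
    frame["mean_share"] = frame.mean(axis=1)
    frame = frame.sort_values("mean_share", ascending=False).drop(columns="mean_share")
    return frame.head(n)


def composition_to_json(table: CountTable) -> str:
    return json.dumps(
        {lib: row.to_dict() for lib, row in class_composition(table).iterrows()},
        indent=2,
    )
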