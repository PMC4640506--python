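"""Class-labeled reference catalog for small-RNA read mapping.

The mapping target is a concatenated, transcript-space catalog of five
sequence classes: extended mature miRNAs, miRNA hairpins, non-coding
transcripts, coding transcripts and the genome (the genome class backs the
"intergenic" call).  Mature miRNA annotations live on their hairpin and are
extended by 3 nt at the 5' end and 5 nt at the 3' end (clipped at the hairpin
boundaries) so that slightly offset isomiR reads still map end-to-end inside
the mature feature.  Hairpin features remember where their extended matures
sit, because reads on a hairpin are later re-classified as mature when they
fall entirely inside an extended-mature interval.

Coordinates are 0-based, half-open everywhere internally; GFF3 input/output
is the only 1-based boundary.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEQ_CLASSES = ("mature", "hairpin", "ncRNA", "coding", "genome")

#: default extension of annotated matures, 5' and 3' (nt)
MATURE_EXT5 = 3
MATURE_EXT3 = 5

INDEX_FORMAT_VERSION = 1


class ReferenceError(ValueError):
    """Inconsistent or invalid reference input."""


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA located on its hairpin (0-based, half-open)."""

    hairpin_id: str
    mature_id: str
    start: int
    end: int
    arm: str = "?"  # {5p, 3p, ?}, informational only

    def validate(self, hairpin_len: int) -> None:
        if not (0 <= self.start < self.end <= hairpin_len):
            raise ReferenceError(
                f"mature {self.mature_id}: coordinates [{self.start},{self.end}) "
                f"invalid on hairpin {self.hairpin_id} of length {hairpin_len}"
            )


@dataclass(frozen=True)
class MatureRegion:
    """Extended-mature interval on a hairpin, keyed to the mature feature."""

    start: int
    end: int
    mature_id: str


@dataclass(frozen=True)
class ReferenceFeature:
    feature_id: str
    seq_class: str
    sequence: str
    parent_hairpin: str | None = None
    # populated on hairpin features only (extended coordinates on the hairpin)
    mature_regions: tuple[MatureRegion, ...] = ()

    def __post_init__(self) -> None:
        if self.seq_class not in SEQ_CLASSES:
            raise ReferenceError(f"unknown sequence class {self.seq_class!r}")
        if not self.sequence:
            raise ReferenceError(f"feature {self.feature_id} has empty sequence")
        if self.seq_class == "mature" and self.parent_hairpin is None:
            raise ReferenceError(f"mature feature {self.feature_id} lacks a parent hairpin")

    def __len__(self) -> int:
        return len(self.sequence)


def extend_mature(
    hairpin_seq: str,
    ann: MatureAnnotation,
    ext5: int = MATURE_EXT5,
    ext3: int = MATURE_EXT3,
) -> ReferenceFeature:
    """Extended mature feature: hairpin_seq[max(0, start-ext5):min(L, end+ext3)].

    Extension is clipped at the hairpin boundaries, never wrapped.
    """
    ann.validate(len(hairpin_seq))
    lo = max(0, ann.start - ext5)
    hi = min(len(hairpin_seq), ann.end + ext3)
    return ReferenceFeature(
        feature_id=ann.mature_id,
        seq_class="mature",
        sequence=hairpin_seq[lo:hi],
        parent_hairpin=ann.hairpin_id,
    )


def extended_interval(
    ann: MatureAnnotation, hairpin_len: int, ext5: int = MATURE_EXT5, ext3: int = MATURE_EXT3
) -> MatureRegion:
    ann.validate(hairpin_len)
    return MatureRegion(
        start=max(0, ann.start - ext5),
        end=min(hairpin_len, ann.end + ext3),
        mature_id=ann.mature_id,
    )


class ReferenceIndex:
    """Ordered collection of ReferenceFeature with unique ids.

    Duplicate *sequences* across classes are allowed (class preference
    resolves them downstream); duplicate feature ids are an error.
    """

    def __init__(self, features: Iterable[ReferenceFeature]):
        self._features: dict[str, ReferenceFeature] = {}
        for feat in features:
            if feat.feature_id in self._features:
                raise ReferenceError(f"duplicate feature id {feat.feature_id!r}")
            self._features[feat.feature_id] = feat

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self):
        return iter(self._features.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._features

    def __getitem__(self, feature_id: str) -> ReferenceFeature:
        return self._features[feature_id]

    def features_of_class(self, seq_class: str) -> list[ReferenceFeature]:
        return [f for f in self if f.seq_class == seq_class]

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in SEQ_CLASSES}
        for f in self:
            out[f.seq_class] += 1
        return out

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": INDEX_FORMAT_VERSION,
            "features": [
                {
                    "feature_id": f.feature_id,
                    "seq_class": f.seq_class,
                    "sequence": f.sequence,
                    "parent_hairpin": f.parent_hairpin,
                    "mature_regions": [
                        [r.start, r.end, r.mature_id] for r in f.mature_regions
                    ],
                }
                for f in self
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReferenceIndex":
        if payload.get("format_version") != INDEX_FORMAT_VERSION:
            raise ReferenceError("unsupported index format version")
        feats = [
            ReferenceFeature(
                feature_id=d["feature_id"],
                seq_class=d["seq_class"],
                sequence=d["sequence"],
                parent_hairpin=d.get("parent_hairpin"),
                mature_regions=tuple(
                    MatureRegion(int(a), int(b), m) for a, b, m in d.get("mature_regions", [])
                ),
            )
            for d in payload["features"]
        ]
        return cls(feats)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceIndex":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_fasta(self, handle) -> None:
        """All features as one wrapped FASTA stream, class in the description."""
        records = [
            SeqRecord(Seq(f.sequence), id=f.feature_id, description=f"class={f.seq_class}")
            for f in self
        ]
        SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------------------
# input parsing


def read_fasta(source: str | Path | io.TextIOBase) -> list[tuple[str, str]]:
    """(id, sequence) pairs; `source` is a path or an open text handle."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(source, "fasta")]


def read_mature_gff(source: str | Path | io.TextIOBase) -> list[MatureAnnotation]:
    """Mature annotations from a miRBase-style GFF3 (ID/Parent attributes).

    GFF3 is 1-based inclusive; converted to 0-based half-open here.
    """
    text = (
        Path(source).read_text()
        if isinstance(source, (str, Path))
        else source.read()
    )
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    anns = []
    for feat in db.all_features():
        if feat.featuretype not in ("miRNA", "mature_miRNA", "miRNA_mature"):
            continue
        parents = feat.attributes.get("Parent", [])
        parent = parents[0] if parents else feat.seqid
        arm = feat.attributes.get("arm", ["?"])[0]
        anns.append(
            MatureAnnotation(
                hairpin_id=feat.seqid,
                mature_id=feat.id,
                start=feat.start - 1,
                end=feat.end,
                arm=arm,
            )
        )
    return anns


def write_mature_gff(anns: Sequence[MatureAnnotation], handle) -> None:
    handle.write("##gff-version 3\n")
    for a in anns:
        handle.write(
            f"{a.hairpin_id}\tmirstarve\tmiRNA\t{a.start + 1}\t{a.end}\t.\t+\t.\t"
            f"ID={a.mature_id};Parent={a.hairpin_id};arm={a.arm}\n"
        )


# ---------------------------------------------------------------------------
# assembly


def build_reference(
    hairpins: Sequence[tuple[str, str]],
    matures: Sequence[MatureAnnotation],
    ncrna: Sequence[tuple[str, str]] = (),
    coding: Sequence[tuple[str, str]] = (),
    genome: Sequence[tuple[str, str]] = (),
    ext5: int = MATURE_EXT5,
    ext3: int = MATURE_EXT3,
) -> ReferenceIndex:
    """Assemble the five-class concatenated reference.

    Every input sequence appears exactly once with its class label; hairpin
    features record their extended-mature intervals for the later
    hairpin-vs-mature region test.  A mature annotation pointing at an absent
    hairpin is a consistency error.
    """
    hairpin_seqs = dict(hairpins)
    if len(hairpin_seqs) != len(hairpins):
        raise ReferenceError("duplicate hairpin ids in input")

    by_hairpin: dict[str, list[MatureAnnotation]] = {}
    for ann in matures:
        if ann.hairpin_id not in hairpin_seqs:
            raise ReferenceError(
                f"mature {ann.mature_id} references absent hairpin {ann.hairpin_id}"
            )
        by_hairpin.setdefault(ann.hairpin_id, []).append(ann)

    features: list[ReferenceFeature] = []
    for ann in matures:
        features.append(extend_mature(hairpin_seqs[ann.hairpin_id], ann, ext5, ext3))
    for hp_id, seq in hairpins:
        regions = tuple(
            sorted(
                (extended_interval(a, len(seq), ext5, ext3) for a in by_hairpin.get(hp_id, [])),
                key=lambda r: (r.start, r.mature_id),
            )
        )
        features.append(
            ReferenceFeature(hp_id, "hairpin", seq, mature_regions=regions)
        )
    features.extend(ReferenceFeature(i, "ncRNA", s) for i, s in ncrna)
    features.extend(ReferenceFeature(i, "coding", s) for i, s in coding)
    features.extend(ReferenceFeature(i, "genome", s) for i, s in genome)

    index = ReferenceIndex(features)
    _check_mature_substrings(index)
    return index


def _check_mature_substrings(index: ReferenceIndex) -> None:
    for feat in index.features_of_class("mature"):
        hairpin = index[feat.parent_hairpin]
        if feat.sequence not in hairpin.sequence:
            raise ReferenceError(
                f"mature {feat.feature_id} is not a substring of hairpin "
                f"{feat.parent_hairpin}"
            )


def merged_regions(regions: Sequence[MatureRegion]) -> list[tuple[int, int]]:
    """Union of extended-mature intervals (overlaps merged)."""
    merged: list[tuple[int, int]] = []
    for r in sorted(regions, key=lambda r: r.start):
        if merged and r.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], r.end))
        else:
            merged.append((r.start, r.end))
    return merged
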