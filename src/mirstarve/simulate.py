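"""Synthetic reference and two-library sRNA-seq read generator.

Emulates the structure of a C. elegans L4 starvation sRNA-seq experiment at
desk scale: a toy reference (random miRNA hairpins with one or two embedded
matures, non-coding and coding transcripts, one genome contig embedding
everything with intergenic spacers) and two single-end 36-cycle libraries,
"well_fed" and "starved".  Reads are feature fragments 16-28 nt with the 3'
sequencing adapter read through, an artificial 5' hexamer on ~7% of reads,
rare substitutions, and per-feature counts drawn negative-binomially
(variance mu + phi*mu^2, phi = 0.1 — the common-dispersion convention of the
downstream test).  A designated subset of miRNAs carries known fold changes
between the libraries; everything is recorded in a ground-truth object so
every pipeline stage can be scored.

Determinism: all randomness flows from integer-seeded numpy Generators
(per-purpose streams derived from the config seed), so a given seed yields
byte-identical output across platforms.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import ADAPTER, HEXAMER
from .refdb import (
    MatureAnnotation,
    ReferenceIndex,
    build_reference,
    extended_interval,
    write_mature_gff,
)

READ_CLASSES = ("mature", "hairpin_loop", "ncRNA", "coding", "intergenic")

DEFAULT_CLASS_MIX = {
    # shaped after the observed library composition: ~90% of cleaned reads
    # map to mature miRNAs, the rest scatter over loops/transcripts/intergenic
    "mature": 0.90,
    "hairpin_loop": 0.01,
    "ncRNA": 0.04,
    "coding": 0.03,
    "intergenic": 0.02,
}

LIB_WELL_FED = "well_fed"
LIB_STARVED = "starved"


@dataclass
class SimulationConfig:
    seed: int
    n_mirnas: int = 20
    n_ncrna: int = 5
    n_coding: int = 5
    reads_per_library: int = 50_000
    hexamer_fraction: float = 0.07
    adapter: str = ADAPTER
    hexamer: str = HEXAMER
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    dispersion: float = 0.1
    perturbed: tuple[tuple[str, float], ...] = ()
    dominant_mirna_share: float | None = None
    second_mirna_share: float | None = None
    baseline_overrides: Mapping[str, float] = field(default_factory=dict)
    read_length: int = 36
    mean_substitutions: float = 0.05  # Poisson mean per read, capped at 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mix must sum to 1, got {total}")
        for fid, fc in self.perturbed:
            if fc <= 0:
                raise ValueError(f"fold change for {fid} must be > 0")


@dataclass
class SimulatedReference:
    hairpins: list[tuple[str, str]]
    matures: list[MatureAnnotation]
    ncrna: list[tuple[str, str]]
    coding: list[tuple[str, str]]
    genome: list[tuple[str, str]]
    loop_regions: dict[str, tuple[int, int]]      # hairpin -> usable loop interval
    spacer_intervals: list[tuple[int, int]]       # intergenic stretches on the contig

    def build_index(self) -> ReferenceIndex:
        return build_reference(
            self.hairpins, self.matures, self.ncrna, self.coding, self.genome
        )

    def hairpin_seq(self, hairpin_id: str) -> str:
        return dict(self.hairpins)[hairpin_id]


@dataclass
class ReadProvenance:
    read_id: str
    source_id: str
    seq_class: str
    hexamer: bool
    insert: str


@dataclass
class GroundTruth:
    """Expected proportions, true fold changes and per-read provenance."""

    source_class: dict[str, str]
    proportions: dict[str, dict[str, float]]       # library -> source -> prop
    true_fc: dict[str, float]                      # mature id -> B/A fold change
    provenance: dict[str, list[ReadProvenance]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "source_class": self.source_class,
            "proportions": self.proportions,
            "true_fc": self.true_fc,
            "n_reads": {lib: len(v) for lib, v in self.provenance.items()},
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# reference construction

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(cfg_seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, zlib.crc32(purpose.encode())])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def make_reference(cfg: SimulationConfig) -> SimulatedReference:
    """Random hairpins (one or two matures each), transcripts and a genome
    contig embedding every feature between intergenic spacers.

    Deterministic given the config seed.  Hairpins are 55-90 nt, matures
    20-23 nt; every hairpin keeps a >= 16 nt stretch outside its
    extended-mature intervals so loop reads can always be drawn.
    """
    rng = _rng(cfg.seed, "reference")
    hairpins: list[tuple[str, str]] = []
    matures: list[MatureAnnotation] = []
    loop_regions: dict[str, tuple[int, int]] = {}

    for i in range(1, cfg.n_mirnas + 1):
        hp_id = f"sim-mir-{i}"
        lead = int(rng.integers(3, 6))
        m1_len = int(rng.integers(20, 24))
        two_arms = bool(rng.random() < 0.5)
        if two_arms:
            loop_len = int(rng.integers(24, 31))       # loop stays >= 16 after extension
            m2_len = int(rng.integers(20, 24))
            tail = int(rng.integers(3, 6))
            L = lead + m1_len + loop_len + m2_len + tail
        else:
            loop_len = int(rng.integers(30, 43))
            tail = 0
            m2_len = 0
            L = max(55, lead + m1_len + loop_len)
        seq = _random_seq(rng, L)
        hairpins.append((hp_id, seq))
        m1 = MatureAnnotation(hp_id, f"sim-miR-{i}-5p", lead, lead + m1_len, arm="5p")
        matures.append(m1)
        ext1 = extended_interval(m1, L)
        if two_arms:
            m2_start = lead + m1_len + loop_len
            m2 = MatureAnnotation(hp_id, f"sim-miR-{i}-3p", m2_start, m2_start + m2_len, arm="3p")
            matures.append(m2)
            ext2 = extended_interval(m2, L)
            loop_regions[hp_id] = (ext1.end, ext2.start)
        else:
            loop_regions[hp_id] = (ext1.end, L)

    ncrna = [
        (f"sim-ncRNA-{i}", _random_seq(rng, int(rng.integers(60, 301))))
        for i in range(1, cfg.n_ncrna + 1)
    ]
    coding = [
        (f"sim-gene-{i}", _random_seq(rng, int(rng.integers(300, 1501))))
        for i in range(1, cfg.n_coding + 1)
    ]

    # one contig: spacer + feature + spacer + ... + spacer
    pieces: list[str] = []
    spacers: list[tuple[int, int]] = []
    pos = 0
    embedded = [s for _, s in hairpins] + [s for _, s in ncrna] + [s for _, s in coding]
    for feat_seq in embedded:
        gap = _random_seq(rng, int(rng.integers(80, 201)))
        spacers.append((pos, pos + len(gap)))
        pieces.append(gap)
        pos += len(gap)
        pieces.append(feat_seq)
        pos += len(feat_seq)
    gap = _random_seq(rng, int(rng.integers(80, 201)))
    spacers.append((pos, pos + len(gap)))
    pieces.append(gap)
    genome = [("sim-chrI", "".join(pieces))]

    return SimulatedReference(
        hairpins=hairpins,
        matures=matures,
        ncrna=ncrna,
        coding=coding,
        genome=genome,
        loop_regions=loop_regions,
        spacer_intervals=spacers,
    )


# ---------------------------------------------------------------------------
# abundance model


def assign_truth(cfg: SimulationConfig, ref: SimulatedReference) -> GroundTruth:
    """Per-source expected read proportions for both libraries.

    Within the mature class, baseline weights come from (in order of
    precedence) explicit overrides, the dominant/second shares, then a
    log-uniform background normalized to the remainder.  The starved library
    multiplies perturbed matures by their fold change and renormalizes within
    the class, so the class mix itself is unchanged between libraries.
    """
    rng = _rng(cfg.seed, "abundance")
    mature_ids = [m.mature_id for m in ref.matures]
    perturbed = dict(cfg.perturbed)
    unknown = set(perturbed) - set(mature_ids)
    if unknown:
        raise ValueError(f"perturbed ids not in reference: {sorted(unknown)}")

    weights: dict[str, float] = dict(cfg.baseline_overrides)
    remaining = [m for m in mature_ids if m not in weights]
    if cfg.dominant_mirna_share is not None and remaining:
        weights[remaining.pop(0)] = cfg.dominant_mirna_share
    if cfg.second_mirna_share is not None and remaining:
        weights[remaining.pop(0)] = cfg.second_mirna_share
    residual = 1.0 - sum(weights.values())
    if residual < 0:
        raise ValueError("mature baseline weights exceed 1")
    if remaining:
        raw = np.exp(rng.uniform(np.log(1.0), np.log(50.0), size=len(remaining)))
        raw = raw / raw.sum() * residual
        weights.update(dict(zip(remaining, raw)))

    def class_weights(ids: Sequence[str], log_hi: float = 20.0) -> dict[str, float]:
        if not ids:
            return {}
        raw = np.exp(rng.uniform(0.0, np.log(log_hi), size=len(ids)))
        return dict(zip(ids, raw / raw.sum()))

    loop_w = {hp: 1.0 / len(ref.hairpins) for hp, _ in ref.hairpins}
    nc_w = class_weights([i for i, _ in ref.ncrna])
    cod_w = class_weights([i for i, _ in ref.coding])

    source_class: dict[str, str] = {}
    props_a: dict[str, float] = {}
    props_b: dict[str, float] = {}

    def spread(cls: str, within: Mapping[str, float], fc: Mapping[str, float] | None = None):
        mix = cfg.class_mix.get(cls, 0.0)
        if mix == 0 or not within:
            return
        w_a = dict(within)
        w_b = {k: v * (fc.get(k, 1.0) if fc else 1.0) for k, v in within.items()}
        tot_a, tot_b = sum(w_a.values()), sum(w_b.values())
        for k in within:
            source_class[k] = cls
            props_a[k] = mix * w_a[k] / tot_a
            props_b[k] = mix * w_b[k] / tot_b

    spread("mature", weights, perturbed)
    spread("hairpin_loop", loop_w)
    spread("ncRNA", nc_w)
    spread("coding", cod_w)
    if cfg.class_mix.get("intergenic", 0.0) > 0:
        source_class["intergenic"] = "intergenic"
        props_a["intergenic"] = cfg.class_mix["intergenic"]
        props_b["intergenic"] = cfg.class_mix["intergenic"]

    return GroundTruth(
        source_class=source_class,
        proportions={LIB_WELL_FED: props_a, LIB_STARVED: props_b},
        true_fc={m: perturbed.get(m, 1.0) for m in mature_ids},
    )


# ---------------------------------------------------------------------------
# read generation


def _draw_counts(
    rng: np.random.Generator, props: np.ndarray, depth: int, phi: float
) -> np.ndarray:
    mu = props * depth
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + np.where(mu > 0, mu, 1.0))
    counts = rng.negative_binomial(r, p)
    counts[mu == 0] = 0
    return counts


def _mature_insert(rng, ref: SimulatedReference, ann: MatureAnnotation) -> str:
    hp = ref.hairpin_seq(ann.hairpin_id)
    ext = extended_interval(ann, len(hp))
    start = ann.start + int(rng.integers(-1, 2))
    end = ann.end + int(rng.integers(-1, 2))
    start = max(ext.start, max(0, start))
    end = min(ext.end, min(len(hp), end))
    return hp[start:end]


def _substitute(rng, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_library(
    cfg: SimulationConfig,
    ref: SimulatedReference,
    truth: GroundTruth,
    label: str,
) -> list[str]:
    """FASTQ lines for one library; per-read provenance goes into `truth`.

    Each read: feature fragment + (optional 5' hexamer) + 3' adapter,
    truncated to the 36-cycle read length.  Per-feature counts are NB draws
    at the configured dispersion around proportion * depth.
    """
    rng = _rng(cfg.seed, f"library:{label}")
    props = truth.proportions[label]
    sources = sorted(props)
    counts = _draw_counts(
        rng, np.array([props[s] for s in sources]), cfg.reads_per_library, cfg.dispersion
    )

    anns = {m.mature_id: m for m in ref.matures}
    ncrna = dict(ref.ncrna)
    coding = dict(ref.coding)
    genome_seq = ref.genome[0][1]

    jobs = np.repeat(np.arange(len(sources)), counts)
    rng.shuffle(jobs)

    lines: list[str] = []
    provenance: list[ReadProvenance] = []
    qual = "I" * cfg.read_length
    for i, src_idx in enumerate(jobs):
        source = sources[src_idx]
        cls = truth.source_class[source]
        if cls == "mature":
            insert = _mature_insert(rng, ref, anns[source])
        elif cls == "hairpin_loop":
            a, b = ref.loop_regions[source]
            length = int(rng.integers(16, min(28, b - a) + 1))
            off = int(rng.integers(a, b - length + 1))
            insert = ref.hairpin_seq(source)[off:off + length]
        elif cls in ("ncRNA", "coding"):
            seq = ncrna[source] if cls == "ncRNA" else coding[source]
            length = int(rng.integers(16, min(28, len(seq)) + 1))
            off = int(rng.integers(0, len(seq) - length + 1))
            insert = seq[off:off + length]
        else:  # intergenic
            a, b = ref.spacer_intervals[int(rng.integers(0, len(ref.spacer_intervals)))]
            length = int(rng.integers(16, min(28, b - a) + 1))
            off = int(rng.integers(a, b - length + 1))
            insert = genome_seq[off:off + length]

        insert = _substitute(rng, insert, min(2, int(rng.poisson(cfg.mean_substitutions))))
        hexed = bool(rng.random() < cfg.hexamer_fraction)
        raw = (cfg.hexamer if hexed else "") + insert + cfg.adapter
        if len(raw) < cfg.read_length:
            raw += _random_seq(rng, cfg.read_length - len(raw))
        raw = raw[:cfg.read_length]

        read_id = f"{label}.{i + 1}|src={source}|cls={cls}|hex={int(hexed)}"
        lines.append(f"@{read_id}\n{raw}\n+\n{qual}\n")
        provenance.append(ReadProvenance(read_id, source, cls, hexed, insert))

    truth.provenance[label] = provenance
    return lines


def write_scenario(
    cfg: SimulationConfig,
    ref: SimulatedReference,
    truth: GroundTruth,
    outdir: str | Path,
    libraries: Sequence[str] = (LIB_WELL_FED, LIB_STARVED),
) -> dict[str, Path]:
    """Standard-format bundle: FASTA/GFF3 reference, per-library FASTQ,
    truth.json.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def fasta(name: str, seqs: Sequence[tuple[str, str]]) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            for sid, seq in seqs:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        paths[name] = path

    fasta("hairpins.fa", ref.hairpins)
    fasta("ncrna.fa", ref.ncrna)
    fasta("coding.fa", ref.coding)
    fasta("genome.fa", ref.genome)
    with open(outdir / "matures.gff3", "w") as fh:
        write_mature_gff(ref.matures, fh)
    paths["matures.gff3"] = outdir / "matures.gff3"

    for label in libraries:
        lines = simulate_library(cfg, ref, truth, label)
        path = outdir / f"{label}.fastq"
        path.write_text("".join(lines))
        paths[f"{label}.fastq"] = path

    (outdir / "truth.json").write_text(truth.to_json())
    paths["truth.json"] = outdir / "truth.json"
    return paths


# ---------------------------------------------------------------------------
# the study-shaped scenario

#: true fold changes of the upregulated miRNA cluster (starved / well-fed):
#: the published fold changes of the seven-member miR-35..41-3p family
CLUSTER_FOLD_CHANGES = (8.6, 10.2, 15.4, 15.4, 17.6, 20.1, 20.2)
#: true fold changes of the two downregulated matures (published: -7.9, -13.0)
DOWN_FOLD_CHANGES = (1 / 7.9, 1 / 13.0)
#: well-fed baseline shares (of the mature pool) for the perturbed features
CLUSTER_BASELINES = (0.003, 0.004, 0.005, 0.006, 0.005, 0.004, 0.003)
DOWN_BASELINES = (0.012, 0.016)


def paper_shaped_scenario(
    seed: int = 42, reads_per_library: int = 150_000
) -> tuple[SimulationConfig, SimulatedReference, GroundTruth]:
    """Two-library scenario shaped like the starvation experiment.

    60 miRNA hairpins; one dominant mature near a 50% share of the miRNA pool
    and a second near 19%; a 7-member clustered family truly up 6.5-20x in
    the starved library; two matures truly down ~8-13x; everything else null.
    """
    base = SimulationConfig(seed=seed, n_mirnas=60, n_ncrna=8, n_coding=8,
                            reads_per_library=reads_per_library)
    ref = make_reference(base)

    first_mature = {}
    for m in ref.matures:
        first_mature.setdefault(m.hairpin_id, m.mature_id)

    dominant = first_mature["sim-mir-1"]
    second = first_mature["sim-mir-2"]
    cluster = [first_mature[f"sim-mir-{i}"] for i in range(10, 17)]
    downs = [first_mature[f"sim-mir-{i}"] for i in (20, 21)]

    overrides = {dominant: 0.50, second: 0.19}
    overrides.update(dict(zip(cluster, CLUSTER_BASELINES)))
    overrides.update(dict(zip(downs, DOWN_BASELINES)))
    perturbed = tuple(zip(cluster, CLUSTER_FOLD_CHANGES)) + tuple(
        zip(downs, DOWN_FOLD_CHANGES)
    )

    cfg = SimulationConfig(
        seed=seed,
        n_mirnas=60,
        n_ncrna=8,
        n_coding=8,
        reads_per_library=reads_per_library,
        perturbed=perturbed,
        baseline_overrides=overrides,
    )
    truth = assign_truth(cfg, ref)
    return cfg, ref, truth
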