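"""End-to-end driver: simulated (or on-disk) two-library experiment through
cleanup, mapping, fractional counting and differential expression."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from . import align, diffexp, preprocess, quantify
from .refdb import ReferenceIndex
from .simulate import (
    LIB_STARVED,
    LIB_WELL_FED,
    GroundTruth,
    SimulatedReference,
    SimulationConfig,
    simulate_library,
)


@dataclass
class PipelineResult:
    index: ReferenceIndex
    prep_stats: dict[str, preprocess.PreprocessStats]
    unique_reads: dict[str, list[preprocess.UniqueRead]]
    hitsets: dict[str, list[align.HitSet]]
    mapping: dict[str, align.MappingSummary]
    table: quantify.CountTable
    de: diffexp.DEOutcome

    @property
    def composition(self) -> pd.DataFrame:
        return quantify.class_composition(self.table)

    def top_shares(self, n: int = 10) -> pd.DataFrame:
        return quantify.top_mirna_shares(self.table, n=n)


def run_two_library_pipeline(
    fastq_lines: dict[str, list[str]],
    index: ReferenceIndex,
    de_config: diffexp.DEConfig | None = None,
) -> PipelineResult:
    """Clean, collapse, map, classify, count and test two labeled libraries."""
    if len(fastq_lines) != 2:
        raise ValueError("exactly two libraries expected")
    seed_index = align.SeedIndex(index)
    prep_stats, unique_reads, hitsets, mapping = {}, {}, {}, {}
    for label, lines in fastq_lines.items():
        reads = preprocess.parse_fastq(io.StringIO("".join(lines)))
        unique, stats = preprocess.preprocess_reads(reads)
        prep_stats[label] = stats
        unique_reads[label] = unique
        hitsets[label], mapping[label] = align.map_all(unique, seed_index)

    table = quantify.quantify_libraries(hitsets, unique_reads, index)
    de = diffexp.run_de(table, de_config)
    return PipelineResult(
        index=index,
        prep_stats=prep_stats,
        unique_reads=unique_reads,
        hitsets=hitsets,
        mapping=mapping,
        table=table,
        de=de,
    )


def run_simulated_experiment(
    cfg: SimulationConfig,
    ref: SimulatedReference,
    truth: GroundTruth,
    de_config: diffexp.DEConfig | None = None,
    libraries: tuple[str, str] = (LIB_WELL_FED, LIB_STARVED),
) -> PipelineResult:
    """Simulate both libraries and push them through the full pipeline."""
    fastq = {label: simulate_library(cfg, ref, truth, label) for label in libraries}
    return run_two_library_pipeline(fastq, ref.build_index(), de_config)
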