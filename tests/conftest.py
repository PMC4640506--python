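"""Shared fixtures: a tiny handcrafted reference and the full synthetic
two-library starvation scenario (run once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from mirstarve.pipeline import PipelineResult, run_simulated_experiment
from mirstarve.refdb import MatureAnnotation, build_reference
from mirstarve.simulate import paper_shaped_scenario

SCENARIO_SEED = 42


@pytest.fixture()
def tiny_reference():
    """Two hairpins (one mature each), one ncRNA, one coding, one contig.

    Sequences are fixed so tests can reason about exact placements; the
    genome embeds both hairpins plus unique intergenic spacers.
    """
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def rand(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()

    hp1 = rand(70)
    hp2 = rand(64)
    matures = [
        MatureAnnotation("hp-1", "miR-1", 5, 27, arm="5p"),
        MatureAnnotation("hp-2", "miR-2", 38, 60, arm="3p"),
    ]
    ncrna = [("nc-1", rand(120))]
    coding = [("gene-1", rand(400))]
    spacer1, spacer2, spacer3 = rand(90), rand(90), rand(90)
    genome = [("chr-1", spacer1 + hp1 + spacer2 + hp2 + spacer3)]
    index = build_reference(
        [("hp-1", hp1), ("hp-2", hp2)], matures, ncrna, coding, genome
    )
    return index


@pytest.fixture(scope="session")
def scenario():
    """The study-shaped two-library scenario (60 miRNAs, 150k reads/library)."""
    return paper_shaped_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario_result(scenario) -> PipelineResult:
    """The full pipeline run on the study-shaped scenario (run once)."""
    cfg, ref, truth = scenario
    return run_simulated_experiment(cfg, ref, truth)
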