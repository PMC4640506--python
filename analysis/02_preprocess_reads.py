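#!/usr/bin/env python
"""Clean and collapse both simulated libraries.

Hexamer trim -> 3' adapter removal -> 16-28 nt filter -> collapse to unique
reads.  Reads scratch/sim/*.fastq (from 01), writes collapsed FASTA next to
them and the per-stage totals to results/prep_stats.json.
"""

import json
from pathlib import Path

from mirstarve.preprocess import run_preprocess

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    simdir = ROOT / "scratch" / "sim"
    stats = {}
    for lib in ("well_fed", "starved"):
        fq = simdir / f"{lib}.fastq"
        out = simdir / f"{lib}.collapsed.fa"
        stats[lib] = run_preprocess(fq, out).__dict__
        s = stats[lib]
        print(f"{lib}: {s['raw']} raw -> {s['kept']} kept "
              f"({s['unique']} unique; {s['hexamer_trimmed']} hexamer-trimmed, "
              f"{s['length_filtered_out']} outside 16-28 nt)")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "prep_stats.json").write_text(json.dumps(stats, indent=2))


if __name__ == "__main__":
    main()
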