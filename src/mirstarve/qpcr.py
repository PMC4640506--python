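"""Efficiency-corrected relative quantification from qPCR crossing points.

The relative expression ratio of a target assay against a reference assay
between two conditions (control vs treated) is

    ratio = E_t ** (Ct_control,t - Ct_treated,t)
          / E_r ** (Ct_control,r - Ct_treated,r)

where E is the per-cycle amplification factor (2 = perfect doubling).  With
E = 2 for both assays this is the familiar 2**(-ddCt).  No efficiencies were
measured in the starvation validation experiments, so E defaults to 2 and is
overridable per assay.  Replicate aggregation computes one ratio per
biological replicate (from replicate-mean Cts) and reports mean +/- SEM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Sequence, TextIO

import pandas as pd

DEFAULT_EFFICIENCY = 2.0


@dataclass
class QpcrAssay:
    name: str
    ct_control: float
    ct_treated: float
    efficiency: float = DEFAULT_EFFICIENCY
    replicate_cts_control: tuple[float, ...] = ()
    replicate_cts_treated: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (1.0 <= self.efficiency <= 2.2):
            raise ValueError(
                f"assay {self.name}: efficiency {self.efficiency} outside [1, 2.2]"
            )
        if self.ct_control <= 0 or self.ct_treated <= 0:
            raise ValueError(f"assay {self.name}: Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        """Ct_control - Ct_treated (positive = more template when treated)."""
        return self.ct_control - self.ct_treated

    @classmethod
    def from_replicates(
        cls,
        name: str,
        cts_control: Sequence[float],
        cts_treated: Sequence[float],
        efficiency: float = DEFAULT_EFFICIENCY,
    ) -> "QpcrAssay":
        return cls(
            name=name,
            ct_control=mean(cts_control),
            ct_treated=mean(cts_treated),
            efficiency=efficiency,
            replicate_cts_control=tuple(cts_control),
            replicate_cts_treated=tuple(cts_treated),
        )


def pfaffl_ratio(target: QpcrAssay, reference: QpcrAssay) -> float:
    """Efficiency-corrected expression ratio of target, normalized to reference."""
    for assay in (target, reference):
        if assay.efficiency <= 1.0 and assay.delta_ct != 0:
            warnings.warn(
                f"assay {assay.name}: efficiency <= 1 cannot discriminate "
                "template amounts",
                stacklevel=2,
            )
    return (target.efficiency ** target.delta_ct) / (
        reference.efficiency ** reference.delta_ct
    )


@dataclass
class RatioSummary:
    target: str
    reference: str
    ratios: tuple[float, ...]
    mean_ratio: float
    sem: float | None  # None with a single replicate
    direction: str     # up / down / unchanged vs 1.0

    def as_row(self) -> dict:
        return {
            "target": self.target,
            "reference": self.reference,
            "n_replicates": len(self.ratios),
            "ratio": self.mean_ratio,
            "sem": self.sem if self.sem is not None else float("nan"),
            "direction": self.direction,
        }


def replicate_summary(
    replicate_pairs: Sequence[tuple[QpcrAssay, QpcrAssay]]
) -> RatioSummary:
    """Mean ratio +/- SEM over independent (target, reference) replicates."""
    if not replicate_pairs:
        raise ValueError("no replicates supplied")
    ratios = tuple(pfaffl_ratio(t, r) for t, r in replicate_pairs)
    m = mean(ratios)
    sem = stdev(ratios) / math.sqrt(len(ratios)) if len(ratios) >= 2 else None
    direction = "up" if m > 1.0 else ("down" if m < 1.0 else "unchanged")
    target, reference = replicate_pairs[0][0].name, replicate_pairs[0][1].name
    return RatioSummary(target, reference, ratios, m, sem, direction)


# ---------------------------------------------------------------------------
# TSV interface: columns assay, condition, replicate, Ct, efficiency


def read_ct_table(source: str | TextIO) -> pd.DataFrame:
    frame = pd.read_csv(source, sep="\t")
    required = {"assay", "condition", "replicate", "Ct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if "efficiency" not in frame.columns:
        frame["efficiency"] = DEFAULT_EFFICIENCY
    return frame


def summarize_ct_table(
    frame: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str = "control",
    treated_condition: str = "treated",
) -> RatioSummary:
    """One Pfaffl ratio per biological replicate shared by both assays."""
    pairs = []
    reps = sorted(
        set(frame.loc[frame["assay"] == target, "replicate"])
        & set(frame.loc[frame["assay"] == reference, "replicate"])
    )
    if not reps:
        raise ValueError("no shared replicates between target and reference")
    for rep in reps:
        assays = {}
        for name in (target, reference):
            sub = frame[(frame["assay"] == name) & (frame["replicate"] == rep)]
            ctrl = sub.loc[sub["condition"] == control_condition, "Ct"]
            trt = sub.loc[sub["condition"] == treated_condition, "Ct"]
            if ctrl.empty or trt.empty:
                raise ValueError(
                    f"assay {name} replicate {rep}: missing a condition"
                )
            assays[name] = QpcrAssay.from_replicates(
                name, tuple(ctrl), tuple(trt),
                efficiency=float(sub["efficiency"].iloc[0]),
            )
        pairs.append((assays[target], assays[reference]))
    return replicate_summary(pairs)


def write_ratio_tsv(summaries: Iterable[RatioSummary], handle: TextIO) -> None:
    pd.DataFrame([s.as_row() for s in summaries]).to_csv(handle, sep="\t", index=False)
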