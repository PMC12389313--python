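"""Risk classification of interaction scores and combination-level labels.

An overall interaction score in [0, 1] maps to a categorical severity:
High at or above 0.75, Moderate in [0.5, 0.75), Low below 0.5.  A
multi-drug combination inherits the most severe label among its
constituent pairs (High > Moderate > Low > Unknown); a single-drug
"combination" has no pairs and is labeled None.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .freq_mining import DrugCombination
from .io_model import RiskLevel, RiskTable

__all__ = [
    "RiskThresholds",
    "classify_score",
    "aggregate_combination_risk",
    "label_combinations",
    "write_labeled_combinations",
]


@dataclass(frozen=True)
class RiskThresholds:
    """Score cut-points: High at ``high_min`` and above, Moderate at ``moderate_min``."""

    high_min: float = 0.75
    moderate_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.moderate_min < self.high_min <= 1.0:
            raise ValueError(
                f"require 0 < moderate_min < high_min <= 1, got "
                f"moderate_min={self.moderate_min}, high_min={self.high_min}"
            )


def classify_score(score: float, t: RiskThresholds = RiskThresholds()) -> RiskLevel:
    """Map an overall interaction score in [0, 1] to High / Moderate / Low."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score}")
    if score >= t.high_min:
        return RiskLevel.HIGH
    if score >= t.moderate_min:
        return RiskLevel.MODERATE
    return RiskLevel.LOW


def aggregate_combination_risk(pair_levels: Iterable[RiskLevel]) -> RiskLevel:
    """Most severe label among a combination's pairs; None when there are no pairs."""
    levels = list(pair_levels)
    if not levels:
        return RiskLevel.NONE
    return max(levels, key=lambda lv: lv.severity)


def label_combinations(
    combos: Sequence[DrugCombination], risks: RiskTable
) -> list[tuple[DrugCombination, RiskLevel]]:
    """Attach the aggregated pairwise risk label to each combination."""
    out = []
    for combo in combos:
        pair_levels = [
            risks.get(a, b) for a, b in combinations(combo.drugs, 2)
        ]
        out.append((combo, aggregate_combination_risk(pair_levels)))
    return out


def write_labeled_combinations(
    labeled: Sequence[tuple[DrugCombination, RiskLevel]],
    path: str | Path,
    scores: Sequence[float] | None = None,
    sep: str = "\t",
) -> None:
    """Write COMBINATION / SIZE / FREQUENCY / [SCORE] / RISK_LEVEL rows."""
    rows = []
    for i, (combo, level) in enumerate(labeled):
        row = {
            "COMBINATION": "|".join(combo.drugs),
            "SIZE": combo.size,
            "FREQUENCY": combo.frequency,
            "RISK_LEVEL": level.value,
        }
        if scores is not None:
            row["SCORE"] = scores[i]
        rows.append(row)
    cols = ["COMBINATION", "SIZE", "FREQUENCY"]
    if scores is not None:
        cols.append("SCORE")
    cols.append("RISK_LEVEL")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
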