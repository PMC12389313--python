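"""Frequent drug-combination mining.

Each admission's de-duplicated drug set is expanded into all unordered
combinations of one to four drugs; frequencies are counted corpus-wide
(one admission contributes at most once per combination), filtered at a
minimum support of four occurrences, and capped at the 30,000 most
frequent combinations.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_model import AdmissionDrugSet

__all__ = [
    "MiningConfig",
    "DrugCombination",
    "enumerate_combinations",
    "count_combination_frequencies",
    "select_high_frequency",
    "merge_admissions_per_subject",
    "write_combinations",
    "read_combinations",
]

CombinationCounter = Counter  # keys: canonical drug tuples, values: admission counts


@dataclass(frozen=True)
class MiningConfig:
    """Mining parameters: combination size ceiling, support floor, ranking cap."""

    max_combo_size: int = 4
    min_frequency: int = 4
    top_n: int = 30_000

    def __post_init__(self) -> None:
        if self.max_combo_size < 1:
            raise ValueError("max_combo_size must be >= 1")
        if self.min_frequency < 1:
            raise ValueError("min_frequency must be >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class DrugCombination:
    """A canonical (lexicographically sorted) 1–4-drug tuple with its support count."""

    drugs: tuple[str, ...]
    frequency: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.drugs) <= 4:
            raise ValueError(f"combination size must be 1–4, got {len(self.drugs)}")
        if any(a >= b for a, b in zip(self.drugs, self.drugs[1:])):
            raise ValueError(f"drugs must be strictly increasing: {self.drugs}")
        if self.frequency < 0:
            raise ValueError("frequency must be non-negative")

    @property
    def size(self) -> int:
        return len(self.drugs)


def enumerate_combinations(
    drugs: AdmissionDrugSet | Iterable[str],
    config: MiningConfig = MiningConfig(),
) -> set[tuple[str, ...]]:
    """All canonical subsets of size 1..max_combo_size of one admission's drugs."""
    pool = sorted(drugs.drugs if isinstance(drugs, AdmissionDrugSet) else set(drugs))
    if not pool:
        raise ValueError("cannot enumerate combinations of an empty drug set")
    out: set[tuple[str, ...]] = set()
    for k in range(1, min(config.max_combo_size, len(pool)) + 1):
        out.update(itertools.combinations(pool, k))
    return out


def count_combination_frequencies(
    admissions: Sequence[AdmissionDrugSet],
    config: MiningConfig = MiningConfig(),
) -> CombinationCounter:
    """Count, per combination, the number of admissions containing it."""
    if not admissions:
        raise ValueError("no admissions to mine")
    counter: CombinationCounter = Counter()
    for adm in admissions:
        counter.update(enumerate_combinations(adm, config))
    return counter


def select_high_frequency(
    counter: CombinationCounter,
    config: MiningConfig = MiningConfig(),
) -> list[DrugCombination]:
    """Filter at the support floor, rank, and cap.

    Ordering is frequency descending with lexicographic tuple order as the
    deterministic tie-break; the support filter is applied before the
    top-N cap.
    """
    qualifying = [
        DrugCombination(drugs=combo, frequency=freq)
        for combo, freq in counter.items()
        if freq >= config.min_frequency
    ]
    qualifying.sort(key=lambda c: (-c.frequency, c.drugs))
    return qualifying[: config.top_n]


def merge_admissions_per_subject(
    admissions: Sequence[AdmissionDrugSet],
) -> list[AdmissionDrugSet]:
    """Collapse each subject's admissions into one union drug set.

    Sensitivity helper for counting per patient instead of per admission.
    """
    merged: dict[str, set[str]] = {}
    for adm in admissions:
        merged.setdefault(adm.subject_id, set()).update(adm.drugs)
    return [
        AdmissionDrugSet(subject_id=s, hadm_id=s, drugs=frozenset(d))
        for s, d in sorted(merged.items())
    ]


def write_combinations(
    combos: Sequence[DrugCombination], path: str | Path, sep: str = "\t"
) -> None:
    """Write ranked combinations as COMBINATION / SIZE / FREQUENCY rows."""
    rows = [
        {"COMBINATION": "|".join(c.drugs), "SIZE": c.size, "FREQUENCY": c.frequency}
        for c in combos
    ]
    pd.DataFrame(rows, columns=["COMBINATION", "SIZE", "FREQUENCY"]).to_csv(
        path, sep=sep, index=False
    )


def read_combinations(path: str | Path, sep: str = "\t") -> list[DrugCombination]:
    df = pd.read_csv(path, sep=sep, dtype={"COMBINATION": str})
    missing = [c for c in ("COMBINATION", "FREQUENCY") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        DrugCombination(
            drugs=tuple(row["COMBINATION"].split("|")), frequency=int(row["FREQUENCY"])
        )
        for _, row in df.iterrows()
    ]
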