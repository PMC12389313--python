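"""Seeded generators for every input the pipeline consumes.

The generators emulate the shape of the real inputs — hospitalization
prescription records with a heavy-tailed (Zipf) co-prescription
frequency curve, a drug→target-gene map with plantable overlap blocks, a
pairwise DDI severity table whose label mixture is dominated by Moderate
and Unknown, and docking runs whose mode 1 is the reference pose — while
planting known structure (frequent combinations, substitute pairs) so
every downstream stage has a recoverable ground truth.

All randomness flows from a single spec-level seed through a named
``numpy`` generator; identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import AdmissionDrugSet, DockingMode, DrugGeneMap, RiskLevel, RiskTable

__all__ = [
    "CohortSpec",
    "RiskMixSpec",
    "GeneOverlapBlock",
    "gen_cohort",
    "gen_drug_gene_map",
    "gen_risk_table",
    "gen_docking_modes",
]

# label mixture matching the skew of curated DDI severity annotations:
# most assessed pairs are Moderate, a large minority cannot be assessed
DEFAULT_RISK_MIX: dict[RiskLevel, float] = {
    RiskLevel.MODERATE: 21829 / 30000,
    RiskLevel.UNKNOWN: 6127 / 30000,
    RiskLevel.HIGH: 1840 / 30000,
    RiskLevel.LOW: 107 / 30000,
    RiskLevel.NONE: 97 / 30000,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic prescription corpus.

    ``planted_combos`` lists (drug tuple, target frequency) pairs; each
    planted tuple is injected into at least that many admissions.
    Background drugs are drawn with Zipf-like popularity weights
    (rank^-zipf_exponent) so the mined combination-frequency curve decays
    heavy-tailed.
    """

    n_subjects: int = 200
    admissions_per_subject: tuple[int, int] = (1, 3)
    drug_universe_size: int = 60
    planted_combos: tuple[tuple[tuple[str, ...], int], ...] = ()
    background_set_size: tuple[int, int] = (3, 10)
    zipf_exponent: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.drug_universe_size < 1:
            raise ValueError("cohort must have at least one subject and one drug")
        lo, hi = self.background_set_size
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid background_set_size range: {self.background_set_size}")
        for combo, freq in self.planted_combos:
            if not 1 <= len(combo) <= 4:
                raise ValueError(f"planted combo size must be 1–4: {combo}")
            if freq < 1:
                raise ValueError(f"planted frequency must be >= 1: {combo} -> {freq}")
            if len(combo) > hi:
                raise ValueError(
                    f"planted combo {combo} exceeds the admission size bound {hi}"
                )


@dataclass(frozen=True)
class RiskMixSpec:
    """Mixture over severity labels for generated pairwise risk tables."""

    proportions: Mapping[RiskLevel, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_MIX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("proportions must be non-negative")


@dataclass(frozen=True)
class GeneOverlapBlock:
    """A planted substitute pair: both drugs get ``set_size`` targets, ``overlap`` shared."""

    drug_a: str
    drug_b: str
    overlap: int
    set_size: int = 10

    def __post_init__(self) -> None:
        if self.overlap < 0 or self.set_size < 1:
            raise ValueError("overlap must be >= 0 and set_size >= 1")
        if self.overlap > self.set_size:
            raise ValueError(
                f"overlap {self.overlap} exceeds set size {self.set_size}"
            )

    @property
    def expected_jaccard(self) -> float:
        return self.overlap / (2 * self.set_size - self.overlap)


def drug_universe(size: int) -> list[str]:
    """Canonical synthetic drug names (already normalized)."""
    return [f"drug-{i:03d}" for i in range(1, size + 1)]


def gen_cohort(spec: CohortSpec) -> list[AdmissionDrugSet]:
    """Generate per-admission drug sets with planted frequent combinations."""
    rng = np.random.default_rng(spec.seed)
    universe = np.array(drug_universe(spec.drug_universe_size))
    ranks = np.arange(1, len(universe) + 1, dtype=float)
    weights = ranks ** (-spec.zipf_exponent)
    weights /= weights.sum()

    lo_adm, hi_adm = spec.admissions_per_subject
    lo_sz, hi_sz = spec.background_set_size
    admissions: list[tuple[str, str, set[str]]] = []
    for s in range(1, spec.n_subjects + 1):
        n_adm = int(rng.integers(lo_adm, hi_adm + 1))
        for h in range(1, n_adm + 1):
            size = int(rng.integers(lo_sz, min(hi_sz, len(universe)) + 1))
            drugs = set(
                rng.choice(universe, size=size, replace=False, p=weights).tolist()
            )
            admissions.append((f"subj-{s:04d}", f"hadm-{s:04d}-{h}", drugs))

    for combo, freq in spec.planted_combos:
        if freq > len(admissions):
            raise ValueError(
                f"planted frequency {freq} exceeds the {len(admissions)} admissions generated"
            )
        chosen = rng.choice(len(admissions), size=freq, replace=False)
        for idx in chosen:
            admissions[idx][2].update(combo)

    return [
        AdmissionDrugSet(subject_id=s, hadm_id=h, drugs=frozenset(d))
        for s, h, d in admissions
    ]


def gen_drug_gene_map(
    universe: Sequence[str],
    genes_per_drug: tuple[int, int] = (2, 8),
    shared_gene_blocks: Sequence[GeneOverlapBlock] = (),
    seed: int = 0,
) -> DrugGeneMap:
    """Assign random target-gene sets, then overwrite planted overlap blocks.

    Drugs in a planted block receive freshly minted gene sets with exactly
    the requested overlap, so the block's Jaccard similarity is
    ``overlap / (2*set_size - overlap)`` by construction.
    """
    lo, hi = genes_per_drug
    if not 0 <= lo <= hi:
        raise ValueError(f"invalid genes_per_drug range: {genes_per_drug}")
    rng = np.random.default_rng(seed)
    pool = np.array([f"GENE{i:04d}" for i in range(1, max(3 * hi, 2 * len(universe)) + 1)])
    mapping: dict[str, set[str]] = {}
    for drug in universe:
        k = int(rng.integers(lo, hi + 1))
        mapping[drug] = set(rng.choice(pool, size=k, replace=False).tolist()) if k else set()

    serial = 0
    for block in shared_gene_blocks:
        shared = {f"PLANT{seed % 1000:03d}S{serial}N{j}" for j in range(block.overlap)}
        serial += 1
        uniq = block.set_size - block.overlap
        mapping[block.drug_a] = shared | {f"UA{serial}N{j}" for j in range(uniq)}
        mapping[block.drug_b] = shared | {f"UB{serial}N{j}" for j in range(uniq)}
    return DrugGeneMap(mapping)


def gen_risk_table(
    universe: Sequence[str],
    mix: RiskMixSpec = RiskMixSpec(),
    n_pairs: int | None = None,
) -> RiskTable:
    """Label random drug pairs by the severity mixture; deterministic per seed."""
    rng = np.random.default_rng(mix.seed)
    drugs = sorted(set(universe))
    all_pairs = [
        (drugs[i], drugs[j])
        for i in range(len(drugs))
        for j in range(i + 1, len(drugs))
    ]
    if n_pairs is None:
        n_pairs = len(all_pairs)
    if n_pairs > len(all_pairs):
        raise ValueError(
            f"requested {n_pairs} pairs but only {len(all_pairs)} exist"
        )
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    levels = list(mix.proportions.keys())
    probs = np.array([mix.proportions[lv] for lv in levels], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(levels), size=n_pairs, p=probs)
    table = RiskTable()
    for idx, lv_idx in zip(chosen, draws):
        a, b = all_pairs[int(idx)]
        table.set(a, b, levels[int(lv_idx)])
    return table


def gen_docking_modes(
    n_modes: int = 9,
    affinity_range: tuple[float, float] = (-12.0, -4.0),
    rmsd_range: tuple[float, float] = (0.0, 8.0),
    seed: int = 0,
) -> list[DockingMode]:
    """Generate one docking run; mode 1 is the reference pose.

    Mode 1 carries the most favorable (most negative) affinity and
    RMSD 0; later modes have weaker affinities and increasing RMSD, the
    usual ordering of docking-program output.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    lo_a, hi_a = min(affinity_range), max(affinity_range)
    lo_r, hi_r = rmsd_range
    if lo_r < 0:
        raise ValueError("RMSD range must be non-negative")
    rng = np.random.default_rng(seed)
    affinities = np.sort(rng.uniform(lo_a, hi_a, size=n_modes))  # ascending = strongest first
    if n_modes == 1:
        rmsds = np.array([0.0])
    else:
        rmsds = np.concatenate(
            [[0.0], np.sort(rng.uniform(max(lo_r, 1e-3), hi_r, size=n_modes - 1))]
        )
    return [
        DockingMode(mode_index=i + 1, affinity=float(a), rmsd=float(r))
        for i, (a, r) in enumerate(zip(affinities, rmsds))
    ]
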