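"""Greedy low-risk substitute recommendation (the GRDC core).

Each candidate drug is scored against an input combination as a weighted
sum of three components:

    total = alpha_freq * frequency_score
          + beta_gene * gene_overlap
          + gamma_risk * risk_penalty

* frequency_score — how often the candidate co-occurs with the input
  drugs in the mined corpus: the summed counts of every 2–3-drug tuple
  formed by the candidate together with one or two input drugs.
* gene_overlap — the summed shared-target counts between the candidate
  and each input drug.
* risk_penalty — a non-positive sum of severity penalties over the
  candidate's interaction labels with each input drug
  (High −10, Moderate −5, Low −1; Unknown and None cost nothing).

Default weights are alpha_freq = 1.0, beta_gene = 2.0, gamma_risk = 1.0.
Candidates are ranked by total score (descending, lexicographic
tie-break) and additionally reported on a min–max normalized 0–100 scale
over the scored pool.  When substituting a risky drug, candidates whose
own risk toward the remaining combination exceeds the risky drug's are
filtered out.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .freq_mining import CombinationCounter
from .io_model import DrugGeneMap, RiskLevel, RiskTable

__all__ = [
    "RecommendationWeights",
    "PenaltyTable",
    "CandidateScore",
    "frequency_score",
    "gene_overlap_score",
    "risk_penalty",
    "total_score",
    "jaccard_similarity",
    "recommend_candidates",
    "recommend_substitute",
    "write_recommendations",
]


@dataclass(frozen=True)
class RecommendationWeights:
    """Weights of the frequency, gene-overlap, and risk-penalty terms."""

    alpha_freq: float = 1.0
    beta_gene: float = 2.0
    gamma_risk: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha_freq, self.beta_gene, self.gamma_risk) < 0:
            raise ValueError("recommendation weights must be non-negative")


DEFAULT_PENALTIES: dict[RiskLevel, float] = {
    RiskLevel.HIGH: -10.0,
    RiskLevel.MODERATE: -5.0,
    RiskLevel.LOW: -1.0,
    RiskLevel.UNKNOWN: 0.0,
    RiskLevel.NONE: 0.0,
}


@dataclass(frozen=True)
class PenaltyTable:
    """Per-severity penalty points; all non-positive, harsher with severity."""

    penalties: Mapping[RiskLevel, float] = field(
        default_factory=lambda: dict(DEFAULT_PENALTIES)
    )

    def __post_init__(self) -> None:
        p = self.penalties
        if any(v > 0 for v in p.values()):
            raise ValueError("penalties must be non-positive")
        if not (
            p[RiskLevel.HIGH] < p[RiskLevel.MODERATE] < p[RiskLevel.LOW] <= 0
        ):
            raise ValueError("penalties must grow strictly harsher with severity")

    def __getitem__(self, level: RiskLevel) -> float:
        return self.penalties.get(level, 0.0)


@dataclass(frozen=True)
class CandidateScore:
    """Score decomposition for one candidate drug (recomputable from its parts)."""

    candidate: str
    frequency_score: float
    gene_overlap: float
    risk_penalty: float
    total: float
    normalized_score: int = 0
    similarity: float = 0.0
    shared_genes: int = 0
    substitute_risk: RiskLevel = RiskLevel.NONE


def frequency_score(
    candidate: str,
    input_combo: Iterable[str],
    counter: CombinationCounter,
) -> float:
    """Summed corpus counts of the candidate's 2–3-drug tuples with the input.

    For every non-empty subset S of the input with |S| <= 2, the count of
    the canonical tuple S ∪ {candidate} is accumulated; absent tuples
    count zero.
    """
    combo = sorted(set(input_combo))
    if candidate in combo:
        raise ValueError(f"candidate {candidate!r} is already in the input combination")
    score = 0.0
    for k in (1, 2):
        for subset in itertools.combinations(combo, k):
            key = tuple(sorted((candidate, *subset)))
            score += counter.get(key, 0)
    return score


def gene_overlap_score(
    candidate: str, input_combo: Iterable[str], genes: DrugGeneMap
) -> float:
    """Summed shared-target counts between the candidate and each input drug."""
    cand_genes = genes.genes(candidate)
    return float(
        sum(len(cand_genes & genes.genes(d)) for d in set(input_combo))
    )


def risk_penalty(
    candidate: str,
    input_combo: Iterable[str],
    risks: RiskTable,
    p: PenaltyTable = PenaltyTable(),
) -> float:
    """Accumulated severity penalty over the candidate's pairs with the input."""
    return float(sum(p[risks.get(candidate, d)] for d in set(input_combo)))


def total_score(
    parts: tuple[float, float, float],
    w: RecommendationWeights = RecommendationWeights(),
) -> float:
    """Weighted sum of (frequency_score, gene_overlap, risk_penalty)."""
    freq, gene, risk = parts
    return w.alpha_freq * freq + w.beta_gene * gene + w.gamma_risk * risk


def jaccard_similarity(a: str, b: str, genes: DrugGeneMap) -> float:
    """Target-gene Jaccard index |A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    ga, gb = genes.genes(a), genes.genes(b)
    union = ga | gb
    if not union:
        return 0.0
    return len(ga & gb) / len(union)


def _normalize_0_100(totals: Sequence[float]) -> list[int]:
    """Min–max rescale totals to integers 0–100, rounding half-up.

    A pool with a single candidate, or all-equal totals, maps to 100.
    """
    lo, hi = min(totals), max(totals)
    if hi == lo:
        return [100] * len(totals)
    return [
        int(math.floor(100.0 * (t - lo) / (hi - lo) + 0.5)) for t in totals
    ]


def recommend_candidates(
    input_combo: Iterable[str],
    universe: Iterable[str],
    counter: CombinationCounter,
    genes: DrugGeneMap,
    risks: RiskTable,
    w: RecommendationWeights = RecommendationWeights(),
    p: PenaltyTable = PenaltyTable(),
    k: int | None = 10,
) -> list[CandidateScore]:
    """Score every candidate in the universe and return the top k.

    Ranking is by total score descending, ties broken lexicographically on
    the drug name.  ``normalized_score`` is min–max rescaled to 0–100 over
    the full scored pool (before truncation to k).
    """
    combo = sorted(set(input_combo))
    pool = sorted(set(universe) - set(combo))
    if not pool:
        return []
    scored = []
    for cand in pool:
        parts = (
            frequency_score(cand, combo, counter),
            gene_overlap_score(cand, combo, genes),
            risk_penalty(cand, combo, risks, p),
        )
        scored.append((cand, parts, total_score(parts, w)))
    norm = _normalize_0_100([t for _, _, t in scored])
    results = [
        CandidateScore(
            candidate=cand,
            frequency_score=parts[0],
            gene_overlap=parts[1],
            risk_penalty=parts[2],
            total=tot,
            normalized_score=ns,
        )
        for (cand, parts, tot), ns in zip(scored, norm)
    ]
    results.sort(key=lambda c: (-c.total, c.candidate))
    return results if k is None else results[:k]


def _risk_toward(drug: str, context: Iterable[str], risks: RiskTable) -> RiskLevel:
    """Most severe interaction label of a drug against a set of context drugs."""
    levels = [risks.get(drug, d) for d in set(context)]
    if not levels:
        return RiskLevel.NONE
    return max(levels, key=lambda lv: lv.severity)


def recommend_substitute(
    risky_drug: str,
    context_combo: Iterable[str],
    counter: CombinationCounter,
    genes: DrugGeneMap,
    risks: RiskTable,
    w: RecommendationWeights = RecommendationWeights(),
    p: PenaltyTable = PenaltyTable(),
    universe: Iterable[str] | None = None,
    k: int | None = 10,
) -> list[CandidateScore]:
    """Rank safe substitutes for one risky drug within its combination.

    Candidates are scored against the remaining context
    (``context_combo`` minus the risky drug) and kept only when their own
    risk toward that context does not exceed the risky drug's; each
    result carries the gene-set Jaccard similarity and shared-target
    count with the drug being replaced.
    """
    context = set(context_combo)
    if risky_drug not in context:
        raise ValueError(f"{risky_drug!r} is not part of the input combination")
    remaining = sorted(context - {risky_drug})
    original_risk = _risk_toward(risky_drug, remaining, risks)

    if universe is None:
        universe = {d for key in counter for d in key} | set(genes.drugs())
    pool = sorted(set(universe) - context)

    ranked = recommend_candidates(
        remaining or [], pool, counter, genes, risks, w, p, k=None
    ) if remaining else _score_unconstrained(pool, genes)
    out = []
    for cand in ranked:
        substitute_risk = _risk_toward(cand.candidate, remaining, risks)
        if substitute_risk.severity > original_risk.severity:
            continue
        cand_genes = genes.genes(cand.candidate)
        out.append(
            CandidateScore(
                candidate=cand.candidate,
                frequency_score=cand.frequency_score,
                gene_overlap=cand.gene_overlap,
                risk_penalty=cand.risk_penalty,
                total=cand.total,
                normalized_score=cand.normalized_score,
                similarity=jaccard_similarity(cand.candidate, risky_drug, genes),
                shared_genes=len(cand_genes & genes.genes(risky_drug)),
                substitute_risk=substitute_risk,
            )
        )
    return out if k is None else out[:k]


def _score_unconstrained(pool: Sequence[str], genes: DrugGeneMap) -> list[CandidateScore]:
    # degenerate single-drug combination: no context remains, all parts zero
    return [
        CandidateScore(
            candidate=c,
            frequency_score=0.0,
            gene_overlap=0.0,
            risk_penalty=0.0,
            total=0.0,
            normalized_score=100,
        )
        for c in pool
    ]


def write_recommendations(
    risky_drug: str,
    original_risk: RiskLevel,
    recs: Sequence[CandidateScore],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write a substitute report: one row per recommended candidate."""
    rows = [
        {
            "RISK_DRUG": risky_drug,
            "SUBSTITUTE": r.candidate,
            "SIMILARITY": round(r.similarity, 2),
            "SHARED_GENES": r.shared_genes,
            "SCORE": r.normalized_score,
            "ORIGINAL_RISK": original_risk.value,
            "SUBSTITUTE_RISK": r.substitute_risk.value,
        }
        for r in recs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "RISK_DRUG",
            "SUBSTITUTE",
            "SIMILARITY",
            "SHARED_GENES",
            "SCORE",
            "ORIGINAL_RISK",
            "SUBSTITUTE_RISK",
        ],
    ).to_csv(path, sep=sep, index=False)
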