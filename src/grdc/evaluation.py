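"""Top-k recommendation metrics and the leave-one-drug-out evaluation harness.

Per evaluation case with held-out relevant drugs R and ranked
recommendations, on the top-k list T:

    precision@k = |T ∩ R| / k          recall@k = |T ∩ R| / |R|
    f1@k = harmonic mean of the two    hit@k = 1 if |T ∩ R| >= 1 else 0

``evaluate_model`` splits admissions 80/20 (seeded), trains the
combination counter on the training split, and for each test admission
with at least two drugs holds one drug out as ground truth and
recommends from the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .freq_mining import MiningConfig, count_combination_frequencies
from .io_model import AdmissionDrugSet, DrugGeneMap, RiskTable
from .recommender import PenaltyTable, RecommendationWeights, recommend_candidates

__all__ = ["EvalCase", "TopKMetrics", "topk_metrics", "evaluate_model"]


@dataclass(frozen=True)
class EvalCase:
    """One evaluation instance: visible context, held-out truth, ranked output."""

    input_drugs: frozenset[str]
    relevant_drugs: frozenset[str]
    recommended: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.relevant_drugs:
            raise ValueError("each case needs at least one relevant drug")
        if self.relevant_drugs & self.input_drugs:
            raise ValueError("relevant drugs must be disjoint from the input context")
        if len(set(self.recommended)) != len(self.recommended):
            raise ValueError("recommended list contains duplicates")


class TopKMetrics(NamedTuple):
    precision: float
    recall: float
    f1: float
    hit: float


def topk_metrics(cases: Sequence[EvalCase], k: int) -> TopKMetrics:
    """Mean precision/recall/F1/hit at k over the cases."""
    if not cases:
        raise ValueError("no evaluation cases")
    if k < 1:
        raise ValueError("k must be >= 1")
    precisions, recalls, f1s, hits = [], [], [], []
    for case in cases:
        top = set(case.recommended[:k])
        n_hit = len(top & case.relevant_drugs)
        prec = n_hit / k
        rec = n_hit / len(case.relevant_drugs)
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
        hits.append(1.0 if n_hit >= 1 else 0.0)
    n = len(cases)
    return TopKMetrics(
        precision=sum(precisions) / n,
        recall=sum(recalls) / n,
        f1=sum(f1s) / n,
        hit=sum(hits) / n,
    )


def evaluate_model(
    admissions: Sequence[AdmissionDrugSet],
    split_fraction: float = 0.8,
    seed: int = 0,
    k: int = 10,
    genes: DrugGeneMap | None = None,
    risks: RiskTable | None = None,
    weights: RecommendationWeights = RecommendationWeights(),
    penalties: PenaltyTable = PenaltyTable(),
    mining: MiningConfig = MiningConfig(min_frequency=1),
    random_holdout: bool = False,
) -> TopKMetrics:
    """Train/test split, leave-one-drug-out per test admission, mean metrics.

    The held-out drug is the lexicographically last one by default, or a
    seeded uniform draw with ``random_holdout``.  Deterministic given the
    seed.
    """
    if len(admissions) < 5:
        raise ValueError("need at least 5 admissions to evaluate")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(admissions))
    n_train = int(round(split_fraction * len(admissions)))
    train = [admissions[i] for i in order[:n_train]]
    test = [admissions[i] for i in order[n_train:]]
    if not train or not test:
        raise ValueError("split produced an empty partition")

    counter = count_combination_frequencies(train, mining)
    genes = genes or DrugGeneMap()
    risks = risks or RiskTable()
    universe = sorted({d for a in train for d in a.drugs})

    cases = []
    for adm in test:
        drugs = sorted(adm.drugs)
        if len(drugs) < 2:
            continue
        held_out = (
            drugs[int(rng.integers(len(drugs)))] if random_holdout else drugs[-1]
        )
        context = frozenset(adm.drugs - {held_out})
        recs = recommend_candidates(
            context, universe, counter, genes, risks, weights, penalties, k=k
        )
        cases.append(
            EvalCase(
                input_drugs=context,
                relevant_drugs=frozenset({held_out}),
                recommended=tuple(r.candidate for r in recs),
            )
        )
    if not cases:
        raise ValueError("no test admission has >= 2 drugs; nothing to evaluate")
    return topk_metrics(cases, k)
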