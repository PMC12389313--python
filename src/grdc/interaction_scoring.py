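"""Docking-derived drug-interaction scoring.

A docking run reports ranked poses (modes), each with a binding free
energy (affinity, kcal/mol; more negative = stronger binding) and an RMSD
(Å) to the reference mode-1 conformation.  Affinities and RMSDs are
min–max rescaled within the run to [0, 1], combined linearly into a
per-mode score

    score_mode = alpha * normalized_affinity + beta * inverse_normalized_rmsd

with alpha > beta > 0 and alpha + beta = 1, and pooled into pair, triple
and quadruple composite scores.  For three and four drugs the composite is

    gamma * mean(individual drug scores) + (1 - gamma) * mean(pairwise scores)

with gamma = 0.5 by default.

Normalization orientation
-------------------------
In the default ``strength`` orientation the most negative affinity in a
run maps to 1 (strongest binding scores highest) and the smallest RMSD
maps to 1.  The ``literal`` orientation instead maps the *largest*
affinity to 1, i.e. a plain min–max rescale of the raw values; it is kept
for comparison but inverts the meaning of the risk ranking.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

from .io_model import DockingMode

__all__ = [
    "EnergyComponents",
    "ModeScoreWeights",
    "CompositeMix",
    "ScoringConfig",
    "load_scoring_config",
    "rmsd",
    "binding_free_energy",
    "normalize_modes",
    "mode_score",
    "pair_overall_score",
    "pair_interaction_score",
    "triple_overall_score",
    "quad_overall_score",
    "drug_score_from_modes",
    "combination_overall_score",
]

Orientation = Literal["strength", "literal"]


@dataclass(frozen=True)
class EnergyComponents:
    """Terms of the binding free energy decomposition, all in kcal/mol.

    ``U_*`` are average potential energies and ``W_*`` solvation free
    energies of the protein–ligand complex (PL), protein (P) and ligand
    (L); ``dS_config`` is the configurational entropy change in
    kcal/(mol·K) so that ``T * dS_config`` is an energy.
    """

    U_PL: float
    U_P: float
    U_L: float
    W_PL: float
    W_P: float
    W_L: float
    T: float = 298.0
    dS_config: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")


@dataclass(frozen=True)
class ModeScoreWeights:
    """Affinity weight ``alpha`` and RMSD weight ``beta``; alpha > beta > 0, summing to 1."""

    alpha: float = 0.7
    beta: float = 0.3

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ValueError(
                f"require alpha > beta > 0, got alpha={self.alpha}, beta={self.beta}"
            )
        if not math.isclose(self.alpha + self.beta, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"alpha + beta must equal 1, got {self.alpha + self.beta}"
            )


@dataclass(frozen=True)
class CompositeMix:
    """Mixing weight between individual-drug and pairwise-interaction means."""

    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class ScoringConfig:
    weights: ModeScoreWeights = ModeScoreWeights()
    mix: CompositeMix = CompositeMix()
    orientation: Orientation = "strength"


def load_scoring_config(path: str | Path) -> ScoringConfig:
    """Load alpha/beta/gamma/orientation from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = data or {}
    return ScoringConfig(
        weights=ModeScoreWeights(
            alpha=float(data.get("alpha", 0.7)), beta=float(data.get("beta", 0.3))
        ),
        mix=CompositeMix(gamma=float(data.get("gamma", 0.5))),
        orientation=data.get("orientation", "strength"),
    )


# ---------------------------------------------------------------------------
# structural / energetic primitives


def rmsd(target: Sequence[Sequence[float]], reference: Sequence[Sequence[float]]) -> float:
    """Root mean square deviation (Å) between two corresponding coordinate sets.

    ``sqrt(mean_i ||x_i - x_ref,i||^2)`` over N atoms in fixed
    correspondence; both sets must have the same atom count and order.
    """
    x = np.asarray(target, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"coordinate shapes differ: {x.shape} vs {ref.shape}")
    if x.size == 0:
        raise ValueError("coordinate sets must contain at least one atom")
    if x.ndim == 1:  # allow a single 3-vector per atom set
        x = x[None, :]
        ref = ref[None, :]
    return float(np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1))))


def binding_free_energy(e: EnergyComponents) -> float:
    """ΔG° = U_PL − U_P − U_L + W_PL − W_P − W_L − T·ΔS_config (kcal/mol)."""
    return (
        e.U_PL - e.U_P - e.U_L + e.W_PL - e.W_P - e.W_L - e.T * e.dS_config
    )


# ---------------------------------------------------------------------------
# mode normalization and scoring


def normalize_modes(
    modes: Sequence[DockingMode], orientation: Orientation = "strength"
) -> list[tuple[float, float]]:
    """Per-mode (normalized_affinity, inverse_normalized_rmsd), each in [0, 1].

    Within one run, affinity and RMSD are min–max rescaled.  In the
    ``strength`` orientation the most negative affinity maps to 1; in the
    ``literal`` orientation the largest does.  The mode with the smallest
    RMSD always gets inverse_normalized_rmsd = 1.  When a run is
    degenerate (all equal, e.g. a single mode), both values are 1: the
    sole mode is its own optimum.
    """
    if not modes:
        raise ValueError("at least one docking mode required")
    affs = np.array([m.affinity for m in modes], dtype=float)
    rmsds = np.array([m.rmsd for m in modes], dtype=float)

    a_span = affs.max() - affs.min()
    if a_span == 0:
        norm_aff = np.ones_like(affs)
    elif orientation == "strength":
        norm_aff = (affs.max() - affs) / a_span
    elif orientation == "literal":
        norm_aff = (affs - affs.min()) / a_span
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")

    r_span = rmsds.max() - rmsds.min()
    if r_span == 0:
        inv_rmsd = np.ones_like(rmsds)
    else:
        inv_rmsd = 1.0 - (rmsds - rmsds.min()) / r_span

    return [(float(a), float(r)) for a, r in zip(norm_aff, inv_rmsd)]


def mode_score(
    pair: tuple[float, float], w: ModeScoreWeights = ModeScoreWeights()
) -> float:
    """Linear blend of normalized affinity and inverse-normalized RMSD."""
    norm_aff, inv_rmsd = pair
    for name, v in (("normalized affinity", norm_aff), ("inverse normalized RMSD", inv_rmsd)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return w.alpha * norm_aff + w.beta * inv_rmsd


def drug_score_from_modes(
    modes: Sequence[DockingMode],
    w: ModeScoreWeights = ModeScoreWeights(),
    orientation: Orientation = "strength",
) -> float:
    """Score of a drug's docking run: the mode-1 score after normalization."""
    normalized = normalize_modes(modes, orientation=orientation)
    by_index = {m.mode_index: nm for m, nm in zip(modes, normalized)}
    if 1 not in by_index:
        raise ValueError("docking run lacks the reference mode 1")
    return mode_score(by_index[1], w)


def pair_overall_score(s1: float, s2: float) -> float:
    """Two-drug combination score: the mean of the two drug scores."""
    for s in (s1, s2):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"drug score must lie in [0, 1], got {s}")
    return (s1 + s2) / 2.0


def pair_interaction_score(
    modes_xy: Sequence[DockingMode],
    w: ModeScoreWeights = ModeScoreWeights(),
    orientation: Orientation = "strength",
) -> float:
    """Interaction score of a drug pair from its own pairwise docking run."""
    if not modes_xy:
        raise ValueError("pairwise docking run is empty")
    return drug_score_from_modes(modes_xy, w, orientation=orientation)


def triple_overall_score(
    individual: tuple[float, float, float],
    pairwise: tuple[float, float, float],
    mix: CompositeMix = CompositeMix(),
) -> float:
    """Composite score for three drugs.

    ``gamma * mean(S_A, S_B, S_C) + (1-gamma) * mean(I_AB, I_AC, I_BC)``.
    """
    return _composite(individual, pairwise, 3, 3, mix)


def quad_overall_score(
    individual: tuple[float, float, float, float],
    pairwise: tuple[float, float, float, float, float, float],
    mix: CompositeMix = CompositeMix(),
) -> float:
    """Composite score for four drugs: gamma-blend of the 4 individual and 6 pairwise means."""
    return _composite(individual, pairwise, 4, 6, mix)


def _composite(
    individual: Sequence[float],
    pairwise: Sequence[float],
    n_ind: int,
    n_pair: int,
    mix: CompositeMix,
) -> float:
    if len(individual) != n_ind:
        raise ValueError(f"expected {n_ind} individual scores, got {len(individual)}")
    if len(pairwise) != n_pair:
        raise ValueError(f"expected {n_pair} pairwise scores, got {len(pairwise)}")
    for s in (*individual, *pairwise):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {s}")
    return mix.gamma * (sum(individual) / n_ind) + (1.0 - mix.gamma) * (
        sum(pairwise) / n_pair
    )


def combination_overall_score(
    drugs: Sequence[str],
    drug_modes: Mapping[str, Sequence[DockingMode]],
    pair_modes: Mapping[tuple[str, str], Sequence[DockingMode]] | None = None,
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Overall interaction score of a 2–4-drug combination from docking runs.

    Individual scores come from each drug's run; pairwise interaction
    scores from the pair's own run when available, otherwise the mean of
    the two individual scores (with a warning).
    """
    drugs = sorted(set(drugs))
    if not 2 <= len(drugs) <= 4:
        raise ValueError(f"combination must contain 2–4 distinct drugs, got {len(drugs)}")
    pair_modes = pair_modes or {}
    w, orient = config.weights, config.orientation
    individual = {
        d: drug_score_from_modes(drug_modes[d], w, orientation=orient) for d in drugs
    }
    pair_scores = []
    for a, b in itertools.combinations(drugs, 2):
        run = pair_modes.get((a, b)) or pair_modes.get((b, a))
        if run:
            pair_scores.append(pair_interaction_score(run, w, orientation=orient))
        else:
            warnings.warn(
                f"no pairwise docking run for ({a}, {b}); "
                "falling back to the mean of the individual scores",
                stacklevel=2,
            )
            pair_scores.append(pair_overall_score(individual[a], individual[b]))
    if len(drugs) == 2:
        return pair_overall_score(individual[drugs[0]], individual[drugs[1]])
    if len(drugs) == 3:
        return triple_overall_score(
            tuple(individual[d] for d in drugs), tuple(pair_scores), config.mix
        )
    return quad_overall_score(
        tuple(individual[d] for d in drugs), tuple(pair_scores), config.mix
    )
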