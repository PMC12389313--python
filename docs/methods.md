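# Methods

## The recommendation model

`grdc` treats substitute recommendation as a scoring problem over a
candidate universe. Given an input combination *D* (the drugs a patient is
already on, minus the drug being replaced), every other drug *c* observed
in the corpus receives

    Total(c) = α_freq · Freq(c, D) + β_gene · Gene(c, D) + γ_risk · Risk(c, D)

* **Freq(c, D)** — the summed corpus frequencies of every tuple
  `{c} ∪ S` for non-empty `S ⊆ D` with `|S| ≤ 2`, i.e. all 2–3-drug
  combinations the candidate forms with the input. Raw admission counts are
  used, not normalized frequencies: the term is meant to dominate only when
  a candidate is genuinely co-prescribed with the input drugs at scale, and
  min–max normalization of the final totals (below) absorbs the scale.
* **Gene(c, D)** — Σ over d ∈ D of |targets(c) ∩ targets(d)|: mechanistic
  plausibility via shared target genes. Counts, not Jaccard, so overlap
  with several input drugs accumulates.
* **Risk(c, D)** — Σ over d ∈ D of penalty(severity(c, d)) with
  penalty(High) = −10, penalty(Moderate) = −5, penalty(Low) = −1 and 0 for
  Unknown/None. Unknown costs nothing because an unassessed pair is not
  evidence of danger; the penalty for it is configurable through
  `PenaltyTable` if a more conservative stance is wanted.

Default weights α_freq = 1.0, β_gene = 2.0, γ_risk = 1.0. Ranking is by
total descending with lexicographic tie-break (determinism over aesthetics:
ties are rare and any stable rule would do). The reported 0–100 score is a
min–max rescale of the totals over the scored pool, rounded half-up;
degenerate pools (one candidate, or all totals equal) report 100. This
makes the reported score invariant under affine transformations of the
totals, so re-weighting that preserves order also preserves the display.

When replacing a risky drug, candidates are additionally filtered: the
substitute's own worst-case severity toward the remaining combination must
not exceed the replaced drug's. Each surviving candidate carries the
target-gene Jaccard similarity |∩|/|∪| to the replaced drug (defined 0 when
both gene sets are empty) and the shared-gene count. Jaccard captures
mechanistic similarity only at the target-identity level; directionality
(agonist vs antagonist), expression level, and downstream pathway effects
are outside the model.

## Mining

The mining unit is the hospitalization (admission), not the patient: drug
sets are de-duplicated within an admission, and one admission contributes
at most once to any combination's count. `merge_admissions_per_subject`
provides the per-patient union variant for sensitivity checks.
Combinations are unordered, canonicalized as sorted tuples, sizes 1–4.
Singleton "combinations" are retained — they carry the frequency signal for
the recommender's 2-tuple terms and label as risk None (no pairs exist).
The support floor (default 4) is applied before the top-N cap (default
30,000); both are `MiningConfig` parameters. Enumeration is exhaustive
(`itertools.combinations`) rather than an Apriori-style miner: admission
drug sets are small (tens of drugs), so Σ_k C(n,k) for k ≤ 4 is cheap and
exactness lets tests compare against brute force.

## Docking-derived interaction scores

Within one docking run, affinities and RMSDs are min–max rescaled.
The default orientation maps the *most negative* affinity (strongest
binding) to 1, because the score must reward binding strength for the risk
ranking to be coherent; the `literal` orientation, which maps the largest
affinity to 1, is kept behind a flag for comparison. The smallest RMSD
always maps to 1. Degenerate runs (single mode, or all values equal)
normalize to 1.0 — the sole mode is its own optimum — which avoids a 0/0
without special-casing callers.

Per-mode score: `α·norm_affinity + β·inv_norm_rmsd` with α > β > 0 and
α + β = 1; defaults 0.7/0.3. The constraint expresses that binding free
energy is the primary signal and pose-stability (RMSD) auxiliary; the exact
split is configurable (`ModeScoreWeights`, or a YAML/JSON config via
`load_scoring_config`).

A drug's (or drug pair's) score is the mode-1 score of its run. Composites:
two drugs average their individual scores; three and four drugs blend
`γ·mean(individual) + (1−γ)·mean(pairwise)` with γ = 0.5 by default, where
the pairwise terms come from the pair's own docking run when present and
fall back to the mean of the two individual scores (with a warning)
otherwise. The binding free energy decomposition
`ΔG° = U_PL − U_P − U_L + W_PL − W_P − W_L − T·ΔS_config` is provided as
arithmetic over user-supplied components (T in K, default 298; ΔS_config in
kcal/(mol·K) so the T·ΔS term is kcal/mol); computing those components by
simulation is out of scope.

Score → severity: High at 0.75 and above, Moderate in [0.5, 0.75), Low
below 0.5; closed boundaries at the lower edge of each band. A multi-drug
combination takes the maximum severity over its pairs
(High > Moderate > Low > Unknown); the order is extended downward with
None below Unknown so that single-drug entries, which have no pairs, rank
below every assessed pair. When both a computed score and a curated table
entry exist for a pair, the curated table wins — database annotations
encode clinical evidence the docking proxy does not.

## Evaluation protocol

`evaluate_model` splits admissions 80/20 with a seeded permutation, builds
the frequency counter on the training split, and for each test admission
with ≥ 2 drugs holds out one drug — the lexicographically last by default
(deterministic), or a seeded uniform draw with `random_holdout` — and asks
the recommender to rank candidates given the remainder. Metrics are the
standard top-k definitions: precision@k = |hits|/k,
recall@k = |hits|/|relevant|, F1 their harmonic mean (0 when both are 0),
hit@k the indicator of ≥ 1 hit, averaged over cases. With a single held-out
drug per case, precision@k ≤ hit@k holds per case by construction; the
test suite asserts this and the other metric identities as properties. The
protocol measures co-prescription predictability, not clinical correctness
— a recommender that memorizes popular drugs scores well on it, which is
exactly what makes it a useful sanity harness and a poor clinical endpoint.

## Synthetic data: what it does and does not emulate

`gen_cohort` draws each admission's drugs without replacement with
popularity weights rank^(−s) (Zipf exponent s, default 1.2), which
reproduces the decaying, heavy-tailed rank-frequency curve characteristic
of co-prescription data; planted combinations are injected into a chosen
number of admissions so mining has a recoverable ground truth. Defaults
(200 subjects, 1–3 admissions each, 60-drug universe, 3–10 drugs per
admission) keep full-pipeline tests in the seconds range while leaving
thousands of distinct combinations.

`gen_risk_table` draws severity labels from a mixture dominated by Moderate
(~73%) and Unknown (~20%), with High ~6% and Low/None under 1% — the skew
of curated DDI severity resources. `gen_drug_gene_map` assigns each drug a
uniform number of targets from a shared gene pool and overwrites planted
substitute pairs with sets of exact overlap, so the expected Jaccard
`overlap/(2·size − overlap)` is known by construction. `gen_docking_modes`
emits mode 1 as the reference pose (most favorable affinity, RMSD 0) with
weaker, higher-RMSD modes after it.

None of the generators simulate pharmacology: drug identities are labels,
gene sets have no biology, severity labels are independent of the gene
structure, and admissions have no diagnoses, doses, or time structure.
Passing tests on synthetic data therefore demonstrate algorithmic
correctness (counting, ranking, filtering, aggregation, recovery of planted
signal) — not clinical validity of the recommendations.

All randomness flows from explicit seeds through `numpy.random.default_rng`
instances; no global random state is touched, and identical seeds give
byte-identical outputs.

## Numerical and edge-case choices

* Drug-name normalization: lowercase → strip bracketed content (round,
  square, curly; nested handled innermost-out) → delete characters outside
  `[a-z0-9 -]` → collapse whitespace. Idempotent by construction; names
  that normalize to nothing are rejected with the offending input named.
* Absent risk-table pair ⇒ Unknown; absent gene-map drug ⇒ empty set;
  both are contracts, not errors.
* File dialect: comma-separated UTF-8 with header; tab accepted via
  `sep="\t"` / `--tab`. Writers emit sorted, bit-stable output.
* Multi-ingredient drug strings ("sodium chloride 0.9%") stay single
  tokens; no ingredient splitting is attempted.
* Identifiers (subject, admission) are opaque strings, never parsed.

## Known limitations

* The frequency term uses raw counts, so corpus size shifts the balance
  between the frequency and gene terms; the defaults were chosen for
  corpora where interesting co-prescription counts are O(10–100).
* The docking-score path assumes docking output is trustworthy; no pose
  quality control beyond the RMSD term is applied.
* The substitute filter compares worst-case pair severities only; it does
  not re-score the full combination after substitution.
* Evaluation ground truth is held-out co-prescription, with the caveats
  noted above.
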