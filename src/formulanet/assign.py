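"""Iterative multi-round formula assignment.

Each round: every unresolved monoisotopic feature's candidates are
connected to the current reaction network, filtered by the degree
cut-off, and scored; a feature whose top total score is strictly best
receives that (adduct, formula) as its unique assignment. Newly assigned
formulas then join the network as new seed nodes (with their reaction
edges recomputed), and the next round re-evaluates the features that are
still unresolved — both those with no connected candidate and those that
ended in a score tie. The loop stops when a round assigns nothing new or
``max_rounds`` is reached; assignments are never revoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .candidates import CandidateSet, generate_candidates
from .formula import ElementRules, Formula, ion_isotope_pattern
from .isotopes import DEFAULT_ADDUCTS
from .network import (
    ReactionNetwork,
    ReactionTable,
    build_initial_network,
    connect_candidates,
    degree_filter,
)
from .scoring import ScoredCandidate, ScoreWeights, score_candidates

UNIQUE = "unique"
AMBIGUOUS = "ambiguous-tie"
UNASSIGNED = "unassigned"

#: Score ties closer than this are treated as exact (floating-point guard).
TIE_EPS = 1e-12


@dataclass
class FeatureAssignment:
    feature_id: object
    mz: float
    status: str = UNASSIGNED
    adduct: str | None = None
    formula: Formula | None = None
    round_index: int | None = None
    ppm_error: float | None = None
    degree: int | None = None
    scores: tuple[float, float, float, float] | None = None
    candidates: list[ScoredCandidate] = field(default_factory=list)
    n_candidates: int = 0


@dataclass
class AssignmentResult:
    """Per-feature outcomes plus per-round unique-assignment counts."""

    features: dict[object, FeatureAssignment]
    rounds: list[int] = field(default_factory=list)

    @property
    def unique_count(self) -> int:
        return sum(1 for f in self.features.values() if f.status == UNIQUE)

    def by_status(self, status: str) -> list[FeatureAssignment]:
        return [f for f in self.features.values() if f.status == status]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for fa in self.features.values():
            s = fa.scores or (None, None, None, None)
            rows.append({
                "feature_id": fa.feature_id,
                "mz": fa.mz,
                "status": fa.status,
                "adduct": fa.adduct,
                "formula": str(fa.formula) if fa.formula else None,
                "ppm_error": fa.ppm_error,
                "degree": fa.degree,
                "score_degree": s[0],
                "score_mz": s[1],
                "score_iso": s[2],
                "score_total": s[3],
                "round": fa.round_index,
                "n_candidates": fa.n_candidates,
            })
        return pd.DataFrame(rows)


def _evaluate_feature(
    fa: FeatureAssignment,
    cand_set: CandidateSet,
    exp_iso,
    net: ReactionNetwork,
    reactions: ReactionTable,
    cutoff: int,
    weights: ScoreWeights,
    tol_ppm: float,
    tol_int: float,
    inclusive: bool,
    mz_mode: str,
    pattern_cache: dict,
) -> tuple[str, list[ScoredCandidate]]:
    connected, _ = connect_candidates(net, cand_set, reactions)
    retained = degree_filter(connected, cutoff, inclusive=inclusive)
    if not retained:
        return UNASSIGNED, []
    for c in retained:
        key = (c.formula, c.adduct)
        if key not in pattern_cache:
            pattern_cache[key] = ion_isotope_pattern(c.formula, c.adduct)
    scored = score_candidates(
        retained, fa.mz, exp_iso, pattern_cache, weights, tol_ppm, tol_int,
        mz_mode,
    )
    if len(scored) == 1 or scored[0].total > scored[1].total + TIE_EPS:
        return UNIQUE, scored
    return AMBIGUOUS, scored


def assign_round(
    result: AssignmentResult,
    candidate_sets: dict,
    iso_shells: dict,
    net: ReactionNetwork,
    reactions: ReactionTable,
    cutoff: int = 3,
    weights: ScoreWeights = ScoreWeights(),
    tol_ppm: float = 2.0,
    tol_int: float = 5.0,
    round_index: int = 1,
    inclusive_cutoff: bool = True,
    rescore_ambiguous: bool = True,
    mz_mode: str = "tolerance",
    pattern_cache: dict | None = None,
) -> list[Formula]:
    """Run one assignment round in place; returns the newly unique formulas."""
    pattern_cache = {} if pattern_cache is None else pattern_cache
    new_formulas = []
    for fid, fa in result.features.items():
        if fa.status == UNIQUE:
            continue
        if fa.status == AMBIGUOUS and not rescore_ambiguous:
            continue
        status, scored = _evaluate_feature(
            fa, candidate_sets[fid], iso_shells.get(fid), net, reactions,
            cutoff, weights, tol_ppm, tol_int, inclusive_cutoff, mz_mode,
            pattern_cache,
        )
        fa.candidates = scored
        fa.status = status
        if status == UNIQUE:
            top = scored[0]
            fa.adduct = top.candidate.adduct
            fa.formula = top.candidate.formula
            fa.round_index = round_index
            fa.ppm_error = top.candidate.ppm_error
            fa.degree = top.candidate.degree
            fa.scores = (top.s_degree, top.s_mz, top.s_iso, top.total)
            new_formulas.append(top.candidate.formula)
    return new_formulas


def iterative_assign(
    features: pd.DataFrame,
    seeds,
    reactions: ReactionTable,
    rules: ElementRules | None = None,
    adducts=DEFAULT_ADDUCTS,
    tol_ppm: float = 2.0,
    tol_int: float = 5.0,
    cutoff: int = 3,
    weights: ScoreWeights = ScoreWeights(),
    max_rounds: int = 20,
    inclusive_cutoff: bool = True,
    rescore_ambiguous: bool = True,
    mz_mode: str = "tolerance",
    net: ReactionNetwork | None = None,
) -> AssignmentResult:
    """Assign formulas to monoisotopic features by iterative network growth.

    ``features`` needs columns ``mz`` and optionally ``iso_mz``/``iso_ratio``
    (the observed M+1 shell; NaN when absent); the index is the feature id.
    ``seeds`` is the known-formula universe (ignored when a prebuilt ``net``
    is given). Candidates are enumerated once per feature; rounds proceed
    until no feature gains a unique assignment. Deterministic for fixed
    inputs: candidate and feature orderings are canonical.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    rules = rules or ElementRules()
    if net is None:
        net = build_initial_network(seeds, reactions, rules)
    result = AssignmentResult(features={
        fid: FeatureAssignment(feature_id=fid, mz=float(row["mz"]))
        for fid, row in features.iterrows()
    })
    candidate_sets = {}
    iso_shells = {}
    for fid, row in features.iterrows():
        cs = generate_candidates(
            float(row["mz"]), adducts, tol_ppm, rules, feature_id=fid
        )
        candidate_sets[fid] = cs
        result.features[fid].n_candidates = len(cs)
        iso_mz = row.get("iso_mz")
        iso_ratio = row.get("iso_ratio")
        if iso_mz is not None and iso_ratio is not None and pd.notna(iso_mz) \
                and pd.notna(iso_ratio):
            iso_shells[fid] = (float(iso_mz), float(iso_ratio))
    pattern_cache: dict = {}
    for round_index in range(1, max_rounds + 1):
        new_formulas = assign_round(
            result, candidate_sets, iso_shells, net, reactions, cutoff,
            weights, tol_ppm, tol_int, round_index, inclusive_cutoff,
            rescore_ambiguous, mz_mode, pattern_cache,
        )
        result.rounds.append(len(new_formulas))
        if not new_formulas:
            break
        net.add_formulas(
            dict.fromkeys(new_formulas), reactions, origin=f"round-{round_index}"
        )
    return result
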