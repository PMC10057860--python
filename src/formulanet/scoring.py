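"""Candidate ranking: weighted combination of network degree, mass
accuracy and isotope-pattern similarity.

The total score of a connected candidate is

    score = w_degree . S_degree - w_mz . S_mz + w_iso . S_iso

where S_degree is the candidate's network degree normalized by the
largest degree among the same feature's candidates (in (0, 1]), S_mz is
the ppm mass error normalized by the mass tolerance (0 at a perfect
match, 1 at the tolerance boundary; it enters with a minus sign, a pure
penalty), and S_iso in [0, 1] compares the experimental M+1 shell with
the prediction, half on m/z agreement and half on relative intensity.
Default weights (0.5, 0.3, 0.2) are those found optimal on reference
standard mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formula import IsotopePattern
from .network import ConnectedCandidate


@dataclass(frozen=True)
class ScoreWeights:
    w_degree: float = 0.5
    w_mz: float = 0.3
    w_iso: float = 0.2

    def __post_init__(self):
        if min(self.w_degree, self.w_mz, self.w_iso) < 0:
            raise ValueError("weights must be non-negative")


def score_mz(
    mz_exp: float,
    mz_theo: float,
    tol_ppm: float = 2.0,
    mode: str = "tolerance",
) -> float:
    """Mass-accuracy penalty term.

    ``mode='tolerance'`` (default): |ppm error| / tol_ppm, i.e. 0 for a
    perfect match and 1 at the tolerance boundary, commensurate with the
    other unit-interval terms. ``mode='doubled_ppm'`` gives the raw
    alternative 2e6.|dm|/mz with no tolerance normalization.
    """
    if mz_exp <= 0 or mz_theo <= 0:
        raise ValueError("m/z values must be positive")
    rel = abs(mz_exp - mz_theo) / mz_exp
    if mode == "tolerance":
        return rel * 1e6 / tol_ppm
    if mode == "doubled_ppm":
        return rel * 2e6
    raise ValueError(f"unknown score_mz mode {mode!r}")


def score_iso(
    pattern_exp: IsotopePattern | tuple[float, float] | None,
    pattern_theo: IsotopePattern,
    tol_ppm: float = 2.0,
    tol_int: float = 5.0,
) -> float:
    """Isotope-pattern similarity on the M+1 shell, in [0, 1].

    0.5.S_mz + 0.5.S_int with S_mz = 1 - (ppm error / tol_ppm) and
    S_int = 1 - (|int_E - int_T| / int_T) / tol_int, each floored at 0;
    ``tol_int`` = 5.0 is the 500% relative-intensity tolerance. With no
    detected experimental M+1 the score is 0 (no isotope evidence).
    """
    theo = pattern_theo.shell(1)
    if pattern_exp is None or theo is None:
        return 0.0
    if isinstance(pattern_exp, IsotopePattern):
        exp = pattern_exp.shell(1)
        if exp is None:
            return 0.0
    else:
        exp = pattern_exp
    mz_e, int_e = exp
    mz_t, int_t = theo
    s_mz = max(0.0, 1.0 - abs(mz_e - mz_t) / mz_t * 1e6 / tol_ppm)
    s_int = max(0.0, 1.0 - (abs(int_e - int_t) / int_t) / tol_int)
    return 0.5 * s_mz + 0.5 * s_int


def score_degree(candidates: list[ConnectedCandidate]) -> list[float]:
    """Per-candidate degree normalized by the feature's maximum degree.

    A lone candidate scores 1; ties all score 1. Identity matches with a
    zero-degree node score 0 on this term (their retention is handled by
    the degree filter, not the score).
    """
    if not candidates:
        return []
    top = max(c.degree for c in candidates)
    if top == 0:
        return [1.0 for _ in candidates]
    return [c.degree / top for c in candidates]


def total_score(
    s_degree: float, s_mz: float, s_iso: float, weights: ScoreWeights
) -> float:
    """Weighted combination; the mass term is subtracted (pure penalty)."""
    return (
        weights.w_degree * s_degree
        - weights.w_mz * s_mz
        + weights.w_iso * s_iso
    )


@dataclass(frozen=True)
class ScoredCandidate:
    candidate: ConnectedCandidate
    s_degree: float
    s_mz: float
    s_iso: float
    total: float


def score_candidates(
    connected: list[ConnectedCandidate],
    mz_exp: float,
    exp_iso: tuple[float, float] | None,
    theo_patterns: dict,
    weights: ScoreWeights = ScoreWeights(),
    tol_ppm: float = 2.0,
    tol_int: float = 5.0,
    mz_mode: str = "tolerance",
) -> list[ScoredCandidate]:
    """Score one feature's connected candidates.

    ``exp_iso`` is the feature's observed (m/z, relative intensity) M+1
    shell, or None when no isotope peak was detected. ``theo_patterns``
    maps each candidate formula to its predicted :class:`IsotopePattern`
    (of the ionized composition). Returns candidates sorted by descending
    total score with a deterministic composition/adduct tie-break for
    stable output ordering (ties still count as ties for assignment).
    """
    degrees = score_degree(connected)
    out = []
    for cand, s_deg in zip(connected, degrees):
        s_m = score_mz(mz_exp, cand.mz_theo, tol_ppm, mode=mz_mode)
        s_i = score_iso(exp_iso, theo_patterns[cand.formula, cand.adduct],
                        tol_ppm, tol_int)
        out.append(
            ScoredCandidate(cand, s_deg, s_m, s_i,
                            total_score(s_deg, s_m, s_i, weights))
        )
    out.sort(key=lambda s: (-s.total, s.candidate.formula.counts,
                            s.candidate.adduct))
    return out
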