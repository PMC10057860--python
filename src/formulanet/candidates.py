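"""Exhaustive molecular-formula candidate enumeration from accurate mass.

For an observed ion m/z and each configured adduct, every CHNOPS
composition whose theoretical ion m/z lies within the ppm tolerance and
which passes the elemental plausibility rules is returned. Enumeration is
complete over the integer lattice of element counts: heteroatoms and
carbon are expanded as staged numpy lattices pruned by cumulative mass,
and the hydrogen count is solved last inside the residual mass window
(which is narrower than one hydrogen mass for any ppm-scale tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formula import ElementRules, Formula, check_constraints
from .isotopes import (
    ADDUCT_MASS,
    DEFAULT_ADDUCTS,
    ELECTRON_MASS,
    ELEMENTS,
    MONOISOTOPIC_MASS,
)

# Heteroatom expansion order: heaviest first keeps intermediate lattices small.
_STAGED = ("P", "S", "N", "O", "C")


@dataclass(frozen=True)
class Candidate:
    adduct: str
    formula: Formula
    mz_theo: float
    ppm_error: float


@dataclass(frozen=True)
class CandidateSet:
    feature_id: object
    mz: float
    candidates: tuple[Candidate, ...]

    def __len__(self) -> int:
        return len(self.candidates)

    def formulas(self) -> set[tuple[str, Formula]]:
        return {(c.adduct, c.formula) for c in self.candidates}


def _enumerate_window(lo: float, hi: float, rules: ElementRules) -> np.ndarray:
    """All CHNOPS count vectors with monoisotopic mass in [lo, hi].

    Returns an (n, 6) int array in ELEMENTS order (C, H, N, O, P, S),
    before plausibility filtering other than per-element max counts and
    the mass window itself.
    """
    if hi < lo:
        return np.empty((0, 6), dtype=np.int64)
    mass = np.zeros(1)
    cols: dict[str, np.ndarray] = {}
    for el in _STAGED:
        m_el = MONOISOTOPIC_MASS[el]
        cmax = int(math.floor(hi / m_el))
        if el not in rules.allowed_elements:
            cmax = 0
        cap = rules.max_counts.get(el)
        if cap is not None:
            cmax = min(cmax, cap)
        counts = np.arange(cmax + 1)
        new_mass = (mass[:, None] + counts[None, :] * m_el).ravel()
        keep = new_mass <= hi
        reps = cmax + 1
        for name in cols:
            cols[name] = np.repeat(cols[name], reps)[keep]
        cols[el] = np.tile(counts, mass.size)[keep]
        mass = new_mass[keep]
    # Solve hydrogen in the residual window.
    m_h = MONOISOTOPIC_MASS["H"]
    if "H" in rules.allowed_elements:
        h_lo = np.ceil((lo - mass) / m_h - 1e-9).astype(np.int64)
        h_hi = np.floor((hi - mass) / m_h + 1e-9).astype(np.int64)
        np.clip(h_lo, 0, None, out=h_lo)
        h_cap = rules.max_counts.get("H")
        if h_cap is not None:
            np.minimum(h_hi, h_cap, out=h_hi)
    else:
        inside = (mass >= lo) & (mass <= hi)
        h_lo = np.where(inside, 0, 1).astype(np.int64)
        h_hi = np.zeros_like(h_lo)
    n_h = h_hi - h_lo + 1
    valid = n_h > 0
    n_h = n_h[valid]
    if n_h.size == 0:
        return np.empty((0, 6), dtype=np.int64)
    base = {el: cols[el][valid] for el in _STAGED}
    h_start = h_lo[valid]
    # Expand rows with more than one admissible H count (only possible for
    # tolerances wider than ~1 Da).
    rows = np.repeat(np.arange(n_h.size), n_h)
    offsets = np.arange(rows.size) - np.repeat(np.cumsum(n_h) - n_h, n_h)
    out = np.empty((rows.size, 6), dtype=np.int64)
    order = {el: i for i, el in enumerate(ELEMENTS)}
    for el in _STAGED:
        out[:, order[el]] = base[el][rows]
    out[:, order["H"]] = h_start[rows] + offsets
    return out


def _apply_rules(counts: np.ndarray, rules: ElementRules) -> np.ndarray:
    """Vectorized plausibility mask mirroring :func:`check_constraints`."""
    idx = {el: i for i, el in enumerate(ELEMENTS)}
    keep = counts.sum(axis=1) > 0
    for el, lo in rules.min_counts.items():
        keep &= counts[:, idx[el]] >= lo
    c = counts[:, idx["C"]]
    h = counts[:, idx["H"]]
    has_c = c > 0
    ratio_ok = ~has_c | (
        (h >= rules.hc_ratio[0] * c - 1e-12) & (h <= rules.hc_ratio[1] * c + 1e-12)
    )
    keep &= ratio_ok
    if rules.rdbe_range is not None:
        r = c - h / 2 + counts[:, idx["N"]] / 2 + 1
        keep &= (r >= rules.rdbe_range[0]) & (r <= rules.rdbe_range[1])
    return keep


def generate_candidates(
    mz: float,
    adducts=DEFAULT_ADDUCTS,
    tol_ppm: float = 2.0,
    rules: ElementRules | None = None,
    feature_id=None,
) -> CandidateSet:
    """Enumerate every plausible (adduct, formula) hypothesis for an ion.

    For each adduct the target neutral monoisotopic mass is
    ``mz + m_e - m_adduct``; a formula qualifies when its theoretical ion
    m/z is within ``tol_ppm`` of the observed m/z (tolerance measured on
    the observed value), its neutral mass lies inside the configured mass
    range, and it passes :func:`formulanet.formula.check_constraints`.
    The result is deterministic and independent of adduct list order.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    rules = rules or ElementRules()
    if not rules.allowed_elements:
        raise ValueError("empty allowed-element set")
    masses = np.array([MONOISOTOPIC_MASS[el] for el in ELEMENTS])
    out = []
    for adduct in adducts:
        if adduct not in ADDUCT_MASS:
            raise KeyError(f"unknown adduct {adduct!r}")
        shift = ADDUCT_MASS[adduct] - ELECTRON_MASS
        lo = max(mz * (1 - tol_ppm * 1e-6) - shift, rules.mass_range[0])
        hi = min(mz * (1 + tol_ppm * 1e-6) - shift, rules.mass_range[1])
        counts = _enumerate_window(lo, hi, rules)
        if counts.size == 0:
            continue
        counts = counts[_apply_rules(counts, rules)]
        mz_theo = counts @ masses + shift
        ppm = (mz_theo - mz) / mz * 1e6
        inside = np.abs(ppm) <= tol_ppm + 1e-12
        for row, mt, p in zip(counts[inside], mz_theo[inside], ppm[inside]):
            out.append(Candidate(adduct, Formula(row.tolist()), float(mt), float(p)))
    out.sort(key=lambda c: (c.formula.counts, c.adduct))
    return CandidateSet(feature_id=feature_id, mz=float(mz), candidates=tuple(out))


def candidate_count_profile(
    mz_list,
    adducts=DEFAULT_ADDUCTS,
    tol_ppm: float = 2.0,
    rules: ElementRules | None = None,
) -> list[int]:
    """Number of candidates per observed m/z; monotone in tol_ppm."""
    return [
        len(generate_candidates(mz, adducts, tol_ppm, rules)) for mz in mz_list
    ]
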