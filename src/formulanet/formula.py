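"""Molecular-formula algebra over the CHNOPS alphabet.

The :class:`Formula` is the universal currency of the package: peak
annotation hypotheses, reaction-network nodes and reaction differences are
all element-count vectors over (C, H, N, O, P, S). Ordinary formulas have
non-negative counts; *difference* formulas (the result of subtracting two
formulas, or a reaction's elemental change) may carry negative counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .isotopes import (
    ADDUCT_MASS,
    ELECTRON_MASS,
    ELEMENTS,
    ISOTOPES,
    MONOISOTOPIC_MASS,
)

_ELEMENT_INDEX = {el: i for i, el in enumerate(ELEMENTS)}
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class FormulaError(ValueError):
    """Malformed formula text or an element outside the CHNOPS alphabet."""


class Formula:
    """Immutable element-count vector over (C, H, N, O, P, S).

    Supports addition and subtraction (componentwise); subtraction may
    produce negative counts, representing an elemental difference such as
    the change effected by a biochemical reaction.
    """

    __slots__ = ("counts",)

    def __init__(self, counts=None, **kw: int):
        if counts is None:
            counts = kw
        elif kw:
            raise TypeError("pass either a mapping/sequence or keyword counts")
        if isinstance(counts, dict):
            bad = set(counts) - set(ELEMENTS)
            if bad:
                raise FormulaError(f"unknown element(s): {sorted(bad)}")
            vec = tuple(int(counts.get(el, 0)) for el in ELEMENTS)
        else:
            vec = tuple(int(c) for c in counts)
            if len(vec) != len(ELEMENTS):
                raise FormulaError(f"expected {len(ELEMENTS)} counts, got {len(vec)}")
        object.__setattr__(self, "counts", vec)

    # -- construction ------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse Hill-notation text such as ``"C6H12O6"`` into a Formula.

        Multi-digit counts and implicit 1 are supported; repeated element
        tokens are summed. Raises :class:`FormulaError` on empty input,
        unknown element symbols, or malformed text.
        """
        if not text or not text.strip():
            raise FormulaError("empty formula string")
        text = text.strip()
        counts = [0] * len(ELEMENTS)
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or m.start() != pos or not m.group(1):
                raise FormulaError(f"malformed formula {text!r} at position {pos}")
            sym, num = m.group(1), m.group(2)
            if sym not in _ELEMENT_INDEX:
                raise FormulaError(f"unknown element {sym!r} in {text!r}")
            try:
                counts[_ELEMENT_INDEX[sym]] += int(num) if num else 1
            except ValueError:
                raise FormulaError(f"malformed count in {text!r}") from None
            pos = m.end()
        return cls(counts)

    # -- algebra -----------------------------------------------------------

    def __add__(self, other: "Formula") -> "Formula":
        return Formula([a + b for a, b in zip(self.counts, other.counts)])

    def __sub__(self, other: "Formula") -> "Formula":
        return Formula([a - b for a, b in zip(self.counts, other.counts)])

    def __neg__(self) -> "Formula":
        return Formula([-a for a in self.counts])

    def __getitem__(self, element: str) -> int:
        return self.counts[_ELEMENT_INDEX[element]]

    def __eq__(self, other) -> bool:
        return isinstance(other, Formula) and self.counts == other.counts

    def __hash__(self) -> int:
        return hash(self.counts)

    def __bool__(self) -> bool:
        return any(self.counts)

    @property
    def is_difference(self) -> bool:
        """True if any element count is negative."""
        return any(c < 0 for c in self.counts)

    @property
    def atom_count(self) -> int:
        return sum(abs(c) for c in self.counts)

    def as_dict(self) -> dict[str, int]:
        return {el: c for el, c in zip(ELEMENTS, self.counts) if c != 0}

    def canonical_difference(self) -> tuple[int, ...]:
        """Sign-normalized count tuple: the first non-zero count is positive.

        Two formulas a, b match a reaction difference d iff
        ``(a - b).canonical_difference() == d.canonical_difference()``;
        matching is undirected, so d and -d are the same key.
        """
        for c in self.counts:
            if c > 0:
                return self.counts
            if c < 0:
                return tuple(-x for x in self.counts)
        return self.counts

    # -- formatting --------------------------------------------------------

    def __str__(self) -> str:
        """Hill notation: C first, H second, remaining elements alphabetical
        (for carbon-free formulas all elements are alphabetical, which for
        CHNOPS coincides with the same order). Negative counts are written
        with a leading minus on the count."""
        parts = []
        for el in ELEMENTS:
            c = self[el]
            if c == 0:
                continue
            if c == 1:
                parts.append(el)
            else:
                parts.append(f"{el}{c}")
        return "".join(parts) or "0"

    def __repr__(self) -> str:
        return f"Formula({self})"

    # -- mass --------------------------------------------------------------

    def monoisotopic_mass(self) -> float:
        """Exact mass of the all-lightest-isotope species, Da."""
        if self.is_difference:
            raise ValueError(f"negative counts in {self}; not a molecular species")
        return sum(c * MONOISOTOPIC_MASS[el] for el, c in zip(ELEMENTS, self.counts))

    def mass_shift(self) -> float:
        """Signed monoisotopic mass of a difference formula, Da."""
        return sum(c * MONOISOTOPIC_MASS[el] for el, c in zip(ELEMENTS, self.counts))


def parse_formula(text: str) -> Formula:
    """Module-level alias for :meth:`Formula.parse`."""
    return Formula.parse(text)


def monoisotopic_mass(f: Formula) -> float:
    return f.monoisotopic_mass()


def formula_difference(a: Formula, b: Formula) -> Formula:
    """Componentwise a - b; the result may carry negative counts."""
    return a - b


def ion_mz(f: Formula, adduct: str) -> float:
    """m/z of the singly charged positive ion [M+X]+.

    The electron removed on ionization is accounted for: m/z =
    neutral monoisotopic mass + adduct atom mass - electron mass. Without
    the electron correction the theoretical m/z is biased by ~+0.55 mDa,
    which alone exceeds a 2 ppm window above m/z ~ 270.
    """
    try:
        add = ADDUCT_MASS[adduct]
    except KeyError:
        raise KeyError(
            f"unknown adduct {adduct!r}; configured adducts: {sorted(ADDUCT_MASS)}"
        ) from None
    return f.monoisotopic_mass() + add - ELECTRON_MASS


# -- isotope patterns ------------------------------------------------------


@dataclass(frozen=True)
class IsotopePattern:
    """Shell-aggregated isotope envelope.

    ``entries`` is an ordered list of (m/z, relative intensity) with the
    monoisotopic peak first at relative intensity exactly 1. Shell k
    (M+k) aggregates every isotopologue whose nominal mass exceeds the
    monoisotopic species by k; its m/z is the abundance-weighted mean
    isotopologue mass within the shell.
    """

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self):
        mzs = [mz for mz, _ in self.entries]
        if sorted(mzs) != mzs:
            raise ValueError("isotope pattern entries must be m/z-ordered")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def shell(self, k: int) -> tuple[float, float] | None:
        """(m/z, relative intensity) of the M+k entry, or None if absent."""
        if k < len(self.entries):
            return self.entries[k]
        return None


def _element_shell_dist(element: str) -> list[tuple[int, float, float]]:
    """Single-atom (shell, probability, mass offset from lightest) triples."""
    isos = ISOTOPES[element]
    m0 = isos[0][0]
    out = []
    for mass, abundance in isos:
        shell = round(mass - m0)
        out.append((shell, abundance, mass - m0))
    return out


def isotope_pattern(f: Formula, max_shells: int = 2) -> IsotopePattern:
    """Predicted isotope envelope of a neutral or ionized composition.

    Aggregates isotopologues into nominal-mass shells M, M+1, ... M+k
    (k = ``max_shells``) by exact convolution of the per-element isotope
    distributions, which is equivalent to the polynomial expansion of the
    abundance multinomials. Intensities are reported relative to the
    monoisotopic peak; shell m/z is the abundance-weighted mean mass of
    the isotopologues inside the shell.

    Aggregation (rather than fully resolved fine structure) matches what a
    centroided Orbitrap spectrum presents at the M+1/M+2 scale, and is what
    the isotope-similarity score compares.
    """
    if max_shells < 1:
        raise ValueError("max_shells must be >= 1")
    if f.is_difference or not f:
        raise ValueError(f"cannot compute isotope pattern of {f!r}")
    n_shells = max_shells + 1
    # prob[k] = probability of shell k; wmass[k] = prob-weighted mean offset * prob
    prob = [1.0] + [0.0] * max_shells
    wmass = [0.0] * n_shells
    for el, count in zip(ELEMENTS, f.counts):
        if count == 0:
            continue
        dist = _element_shell_dist(el)
        if len(dist) == 1:  # monoisotopic element (P)
            continue
        for _ in range(count):
            new_p = [0.0] * n_shells
            new_w = [0.0] * n_shells
            for shell, p_iso, dm in dist:
                if p_iso == 0.0:
                    continue
                for k in range(n_shells - shell):
                    if prob[k] == 0.0:
                        continue
                    new_p[k + shell] += prob[k] * p_iso
                    new_w[k + shell] += wmass[k] * p_iso + prob[k] * p_iso * dm
            prob, wmass = new_p, new_w
    mono_mass = f.monoisotopic_mass()
    mono_p = prob[0]
    entries = []
    for k in range(n_shells):
        if prob[k] <= 0.0:
            continue
        mean_offset = wmass[k] / prob[k]
        entries.append((mono_mass + mean_offset, prob[k] / mono_p))
    return IsotopePattern(tuple(entries))


def ion_isotope_pattern(f: Formula, adduct: str, max_shells: int = 2) -> IsotopePattern:
    """Isotope envelope of the adduct ion [M+X]+, on the ion m/z axis.

    The pattern is computed for the ionized composition: a proton adduct
    contributes one extra hydrogen to the envelope; Na and K are
    effectively monoisotopic at the M+1 shell and only shift the axis.
    """
    comp = f + Formula(H=1) if adduct == "[M+H]+" else f
    neutral = isotope_pattern(comp, max_shells)
    shift = ion_mz(f, adduct) - comp.monoisotopic_mass()
    return IsotopePattern(tuple((mz + shift, ri) for mz, ri in neutral.entries))


# -- elemental constraints -------------------------------------------------


@dataclass(frozen=True)
class ElementRules:
    """Constraints a chemically plausible candidate formula must satisfy.

    Defaults encode the serum-metabolome search space: CHNOPS elements,
    H/C ratio in [0.4, 5.1] (applied only when carbon is present), and a
    neutral monoisotopic mass between 50 and 800 Da. Optional per-element
    count bounds and an RDBE (ring-plus-double-bond equivalents) window
    can tighten the space further; RDBE filtering is off by default.
    """

    allowed_elements: frozenset[str] = frozenset(ELEMENTS)
    hc_ratio: tuple[float, float] = (0.4, 5.1)
    mass_range: tuple[float, float] = (50.0, 800.0)
    min_counts: dict = field(default_factory=dict)
    max_counts: dict = field(default_factory=dict)
    rdbe_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.hc_ratio[0] > self.hc_ratio[1]:
            raise ValueError("H/C ratio bounds out of order")
        if not (0 < self.mass_range[0] <= self.mass_range[1]):
            raise ValueError("mass bounds must be positive and ordered")
        object.__setattr__(self, "allowed_elements", frozenset(self.allowed_elements))


def rdbe(f: Formula) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + N/2 + 1 (O, S, P ignored
    in the standard valence-II convention for P-as-phosphate)."""
    return f["C"] - f["H"] / 2 + f["N"] / 2 + 1


def check_constraints(f: Formula, rules: ElementRules) -> tuple[bool, str]:
    """Test a candidate formula against :class:`ElementRules`.

    Returns (ok, reason); reason is "" when ok. The H/C ratio test is
    skipped for carbon-free formulas, where the ratio is undefined.
    """
    for el, c in zip(ELEMENTS, f.counts):
        if c < 0:
            return False, f"negative {el} count"
        if c > 0 and el not in rules.allowed_elements:
            return False, f"element {el} not allowed"
        lo = rules.min_counts.get(el, 0)
        hi = rules.max_counts.get(el)
        if c < lo:
            return False, f"{el} count {c} < {lo}"
        if hi is not None and c > hi:
            return False, f"{el} count {c} > {hi}"
    if not f:
        return False, "empty formula"
    if f["C"] > 0:
        ratio = f["H"] / f["C"]
        if not (rules.hc_ratio[0] <= ratio <= rules.hc_ratio[1]):
            return False, f"H/C ratio {ratio:.3f} outside {rules.hc_ratio}"
    mass = f.monoisotopic_mass()
    if not (rules.mass_range[0] <= mass <= rules.mass_range[1]):
        return False, f"mass {mass:.4f} outside {rules.mass_range}"
    if rules.rdbe_range is not None:
        r = rdbe(f)
        if not (rules.rdbe_range[0] <= r <= rules.rdbe_range[1]):
            return False, f"RDBE {r:.1f} outside {rules.rdbe_range}"
    return True, ""
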