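"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the package's vectorized/staged implementations:
candidate enumeration is scalar nested loops; network edges come from
all-pairs difference comparison.
"""

import itertools
import math

from formulanet.formula import Formula, check_constraints
from formulanet.isotopes import ADDUCT_MASS, ELECTRON_MASS, MONOISOTOPIC_MASS


def naive_candidates(mz, adducts, tol_ppm, rules):
    """Scalar nested loops over C, N, O, P, S with an innermost solved
    hydrogen range; every candidate re-checked through the scalar
    constraint function."""
    m = MONOISOTOPIC_MASS
    found = set()
    for adduct in adducts:
        shift = ADDUCT_MASS[adduct] - ELECTRON_MASS
        lo = max(mz * (1 - tol_ppm * 1e-6) - shift, rules.mass_range[0])
        hi = min(mz * (1 + tol_ppm * 1e-6) - shift, rules.mass_range[1])
        if hi < lo:
            continue
        for c in range(int(hi / m["C"]) + 1):
            mc = c * m["C"]
            if mc > hi:
                break
            for n in range(int((hi - mc) / m["N"]) + 1):
                mn = mc + n * m["N"]
                for o in range(int((hi - mn) / m["O"]) + 1):
                    mo = mn + o * m["O"]
                    for p in range(int((hi - mo) / m["P"]) + 1):
                        mp = mo + p * m["P"]
                        for s in range(int((hi - mp) / m["S"]) + 1):
                            ms = mp + s * m["S"]
                            h_lo = max(0, math.ceil((lo - ms) / m["H"] - 1e-9))
                            h_hi = math.floor((hi - ms) / m["H"] + 1e-9)
                            for h in range(h_lo, h_hi + 1):
                                f = Formula({"C": c, "H": h, "N": n,
                                             "O": o, "P": p, "S": s})
                                ok, _ = check_constraints(f, rules)
                                if ok:
                                    found.add((adduct, f))
    return found


def brute_force_edges(formulas, reactions):
    """O(n^2) oracle: compare every pair's signed difference (up to sign)
    with the reaction table."""
    keys = {d.canonical_difference() for d in reactions.differences}
    edges = set()
    for a, b in itertools.combinations(formulas, 2):
        if (a - b).canonical_difference() in keys:
            edges.add(frozenset((a, b)))
    return edges
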