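"""Synthetic study generation: seed universes, ground-truth spectra,
blanks, QC replicates and decoy formulas.

The generator emulates a direct-infusion serum-metabolomics acquisition:
a universe of known metabolite formulas grown so that it is densely
connected under the biochemical reaction table (as real metabolomes
are), truth metabolites drawn from the reaction neighborhood of that
universe, three positive adduct types, Gaussian ppm-scale mass error,
M+1/M+2 isotopologue peaks with multiplicative intensity error, uniform
chemical-noise peaks, solvent-blank contaminants and pooled-QC
replicates, all split into overlapping spectral-stitching windows.
Everything is reproducible bit-for-bit from the integer RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formula import (
    ElementRules,
    Formula,
    check_constraints,
    ion_isotope_pattern,
    ion_mz,
)
from .isotopes import DEFAULT_ADDUCTS, MONOISOTOPIC_MASS
from .network import ReactionNetwork, ReactionTable, build_initial_network
from .peaks import DEFAULT_WINDOWS, WindowScheme

_MAX_TRIES = 20000


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_formula(
    rng: np.random.Generator,
    rules: ElementRules,
    target_mass: float | None = None,
) -> Formula:
    """One random formula satisfying the element rules.

    Without a target, composition ranges are sampled freely and rejected
    against the rules. With ``target_mass``, heteroatom counts are drawn
    first and hydrogen is rounded to land within ~0.5 Da of the target,
    which is how mass-matched decoys are produced.
    """
    lo, hi = rules.mass_range
    m = {el: MONOISOTOPIC_MASS[el] for el in "CHNOPS"}
    for _ in range(_MAX_TRIES):
        tgt = target_mass if target_mass is not None else rng.uniform(lo, hi)
        c = int(rng.integers(max(1, int(tgt // 30)), max(2, int(tgt // 12.5))))
        p = int(rng.integers(0, 3)) if tgt > 150 else int(rng.integers(0, 2))
        s = int(rng.integers(0, 3)) if tgt > 110 else 0
        n = int(rng.integers(0, 6))
        rest = tgt - c * m["C"] - p * m["P"] - s * m["S"] - n * m["N"]
        if rest < 0:
            continue
        o = int(rng.integers(0, int(rest // m["O"]) + 1))
        rest -= o * m["O"]
        h = int(round(rest / m["H"]))
        if h < 0:
            continue
        f = Formula(C=c, H=h, N=n, O=o, P=p, S=s)
        ok, _ = check_constraints(f, rules)
        if ok:
            return f
    raise RuntimeError("could not draw a valid random formula")


def make_seed_universe(
    n: int,
    reactions: ReactionTable,
    rules: ElementRules | None = None,
    connectivity: float = 3.0,
    rng_seed=0,
) -> list[Formula]:
    """Grow a seed formula universe with a target network mean degree.

    A fraction of members (set by ``connectivity``) are produced by
    applying a random reaction difference to an existing member, so the
    induced reaction network forms dense clusters like a real metabolome;
    the rest are drawn uniformly from the constrained formula space. The
    returned list is prefix-closed: any leading slice is itself a valid
    (smaller, nested) universe grown with the same process.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rules = rules or ElementRules()
    rng = _rng(rng_seed)
    if connectivity < 0:
        raise ValueError("connectivity must be >= 0")
    # Growth steps favor a handful of common transformations so members
    # form homologous lattice-like clusters (as real metabolomes do);
    # the map from target mean degree to grow probability was fitted once
    # on simulated universes (see docs/methods.md).
    p_grow = (
        min(0.95, (math.log(connectivity) + 1.74) / 3.92)
        if connectivity > 0
        else 0.0
    )
    p_grow = max(0.0, p_grow)
    n_common = min(6, len(reactions))
    members: list[Formula] = []
    seen: set[Formula] = set()

    def _add(f: Formula) -> bool:
        if f in seen:
            return False
        seen.add(f)
        members.append(f)
        return True

    n_roots = max(2, n // 100)
    while len(members) < n_roots:
        _add(random_formula(rng, rules))
    tries = 0
    diffs = reactions.differences
    while len(members) < n:
        tries += 1
        if tries > _MAX_TRIES * max(1, n // 100):
            raise RuntimeError("universe growth stalled; relax connectivity")
        if rng.random() < p_grow:
            base = members[int(rng.integers(len(members)))]
            if rng.random() < 0.8:
                diff = diffs[int(rng.integers(n_common))]
            else:
                diff = diffs[int(rng.integers(len(diffs)))]
            cand = base + diff if rng.random() < 0.5 else base - diff
            if cand.is_difference or not cand:
                continue
            ok, _ = check_constraints(cand, rules)
            # seeds only need element/mass validity, but keeping them
            # plausible makes them usable as truth metabolites too
            if ok:
                _add(cand)
        else:
            _add(random_formula(rng, rules))
    return members


def make_truths(
    universe: list[Formula],
    reactions: ReactionTable,
    n: int,
    rules: ElementRules | None = None,
    adducts=DEFAULT_ADDUCTS,
    min_degree: int = 3,
    frac_novel: float = 0.0,
    min_sep_ppm: float = 10.0,
    windows: WindowScheme = DEFAULT_WINDOWS,
    rng_seed=0,
    net: ReactionNetwork | None = None,
) -> pd.DataFrame:
    """Draw ground-truth metabolites from the reaction neighborhood of the
    seed universe.

    Each truth is one reaction step from a universe member (it may itself
    be a member: real samples contain many database-known metabolites).
    Novel truths (absent from the universe) must reach ``min_degree``
    network neighbors, emulating the dense reaction context of genuine
    endogenous metabolites; ``frac_novel`` forces at least that fraction
    to be novel. Each truth is given one adduct; ion m/z values are kept
    ``min_sep_ppm`` apart and inside the acquisition span so features are
    resolvable in a direct-infusion spectrum.
    """
    rules = rules or ElementRules()
    rng = _rng(rng_seed)
    if net is None:
        net = build_initial_network(universe, reactions, rules)
    uni = set(universe)
    span = windows.span
    rows = []
    taken_mz: list[float] = []
    n_novel_req = int(round(frac_novel * n))

    def _try_add(need_novel: bool) -> bool:
        base = universe[int(rng.integers(len(universe)))]
        diff = reactions.differences[int(rng.integers(len(reactions)))]
        cand = base + diff if rng.random() < 0.5 else base - diff
        if cand.is_difference or not cand:
            return False
        ok, _ = check_constraints(cand, rules)
        if not ok:
            return False
        novel = cand not in uni
        if need_novel and not novel:
            return False
        degree = len(net.reaction_neighbors(cand, reactions))
        if novel and degree < min_degree:
            return False
        if any(cand == r["formula"] for r in rows):
            return False
        adduct = adducts[int(rng.integers(len(adducts)))]
        mz = ion_mz(cand, adduct)
        if not (span[0] <= mz <= span[1]):
            return False
        if any(abs(mz - t) / t * 1e6 < min_sep_ppm for t in taken_mz):
            return False
        taken_mz.append(mz)
        rows.append({
            "formula": cand, "adduct": adduct, "mz_ion": mz,
            "in_universe": not novel, "degree": degree,
        })
        return True

    tries = 0
    while len(rows) < n:
        tries += 1
        if tries > _MAX_TRIES * max(1, n // 20):
            raise RuntimeError("truth sampling stalled; check parameters")
        need_novel = sum(not r["in_universe"] for r in rows) < n_novel_req
        _try_add(need_novel)
    df = pd.DataFrame(rows)
    df["formula_str"] = df["formula"].map(str)
    return df.sort_values("mz_ion", ignore_index=True)


def make_decoys(
    n: int,
    universe: list[Formula],
    rules: ElementRules | None = None,
    rng_seed=0,
    exclusion: set | None = None,
) -> list[Formula]:
    """Random valid formulas absent from the universe, with the mass
    distribution matched to the universe by sampling each decoy's target
    mass from a random universe member."""
    if n < 1:
        raise ValueError("need n >= 1")
    rules = rules or ElementRules()
    rng = _rng(rng_seed)
    excluded = set(universe) | (exclusion or set())
    out: list[Formula] = []
    seen: set[Formula] = set()
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > _MAX_TRIES * max(1, n // 10):
            raise RuntimeError("decoy sampling exhausted")
        target = universe[int(rng.integers(len(universe)))].monoisotopic_mass()
        f = random_formula(rng, rules, target_mass=target)
        if f in excluded or f in seen:
            continue
        seen.add(f)
        out.append(f)
    return out


# -- spectra ---------------------------------------------------------------


def _split_windows(
    peaks: pd.DataFrame, windows: WindowScheme
) -> list[pd.DataFrame]:
    """Assign each peak to every acquisition window containing it (peaks in
    overlap regions appear in both scans, exercising the stitch)."""
    out = []
    mz = peaks["mz"].to_numpy()
    for lo, hi in windows:
        out.append(peaks.loc[(mz >= lo) & (mz <= hi)].reset_index(drop=True))
    return out


def make_spectrum(
    truth: pd.DataFrame,
    intensities: np.ndarray,
    windows: WindowScheme = DEFAULT_WINDOWS,
    ppm_sd: float = 0.7,
    iso_int_cv: float = 0.2,
    noise_mz: np.ndarray | None = None,
    noise_intensity: np.ndarray | None = None,
    noise_floor: float = 1e3,
    rng_seed=0,
) -> list[pd.DataFrame]:
    """Emit one sample's per-window centroid scans.

    Every truth ion appears at its theoretical m/z perturbed by a
    multiplicative Gaussian error of ``ppm_sd`` ppm, with M+1 (and, when
    above the noise floor, M+2) isotopologues at the predicted relative
    intensity perturbed by ``iso_int_cv``; the isotopologue m/z error is
    shared with the parent (calibration-like) plus a small independent
    component. Noise peaks are passed in as arrays so that the same noise
    species recur across samples. S/N is intensity / ``noise_floor``.
    """
    if ppm_sd < 0:
        raise ValueError("ppm_sd must be >= 0")
    rng = _rng(rng_seed)
    mzs, ints = [], []
    for (_, row), inten in zip(truth.iterrows(), intensities):
        eps = rng.normal(0.0, ppm_sd) * 1e-6
        mzs.append(row["mz_ion"] * (1 + eps))
        ints.append(inten)
        pattern = ion_isotope_pattern(row["formula"], row["adduct"])
        for shell_k in (1, 2):
            shell = pattern.shell(shell_k)
            if shell is None:
                continue
            s_mz, s_ri = shell
            s_int = inten * s_ri * max(0.05, 1 + rng.normal(0.0, iso_int_cv))
            if s_int < noise_floor:
                continue
            eps_extra = rng.normal(0.0, 0.2) * 1e-6
            mzs.append(s_mz * (1 + eps + eps_extra))
            ints.append(s_int)
    if noise_mz is not None:
        mzs.extend(noise_mz.tolist())
        ints.extend(noise_intensity.tolist())
    peaks = pd.DataFrame({"mz": mzs, "intensity": ints})
    peaks["snr"] = peaks["intensity"] / noise_floor
    peaks = peaks.sort_values("mz", ignore_index=True)
    return _split_windows(peaks, windows)


@dataclass
class SyntheticStudy:
    """A complete in-silico acquisition with known ground truth."""

    universe: list[Formula]
    truth: pd.DataFrame
    samples: dict[str, list[pd.DataFrame]]
    roles: dict[str, str]
    windows: WindowScheme
    decoys: list[Formula] = field(default_factory=list)
    rng_seed: int | None = None
    params: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write peak-list CSVs, a manifest, the seed list, and the truth
        table into a directory (the formats the preprocessing CLI reads)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for name, scans in self.samples.items():
            merged = []
            for w_idx, scan in enumerate(scans):
                scan = scan.assign(window=w_idx)
                merged.append(scan)
            pd.concat(merged, ignore_index=True).to_csv(
                out / f"{name}.csv", index=False
            )
            manifest.append({"file": f"{name}.csv", "role": self.roles[name]})
        pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
        with open(out / "seeds.txt", "w") as fh:
            for f in self.universe:
                fh.write(f"{f}\n")
        self.truth.drop(columns=["formula"]).rename(
            columns={"formula_str": "formula"}
        ).to_csv(out / "truth.csv", index=False)
        if self.decoys:
            with open(out / "decoys.txt", "w") as fh:
                for f in self.decoys:
                    fh.write(f"{f}\n")
        with open(out / "windows.csv", "w") as fh:
            fh.write("low,high\n")
            for lo, hi in self.windows:
                fh.write(f"{lo},{hi}\n")


def make_study(
    rng_seed: int = 0,
    n_universe: int = 2000,
    n_truth: int = 200,
    connectivity: float = 3.0,
    ppm_sd: float = 0.7,
    iso_int_cv: float = 0.2,
    n_noise: int = 500,
    n_contaminants: int = 50,
    n_samples: int = 3,
    n_qc: int = 2,
    n_blank: int = 1,
    frac_novel: float = 0.0,
    min_truth_degree: int = 3,
    n_decoys: int = 0,
    sample_cv: float = 0.25,
    qc_cv: float = 0.10,
    reactions: ReactionTable | None = None,
    rules: ElementRules | None = None,
    windows: WindowScheme = DEFAULT_WINDOWS,
    adducts=DEFAULT_ADDUCTS,
) -> SyntheticStudy:
    """Generate a full study: replicate samples, a solvent blank and
    pooled-QC injections over a shared truth panel.

    Truth ions carry log-uniform base intensities (1e5..1e7, S/N 100+);
    noise peaks are log-uniform (2e3..1e5) so a fraction falls under the
    S/N>10 filter, and a third of them are made irreproducible (high QC
    variance, sporadic presence) to exercise the RSD filter. Contaminant
    peaks appear in the blank at full strength and are removed by blank
    reduction. All randomness derives from ``rng_seed``.
    """
    reactions = reactions or ReactionTable.default()
    rules = rules or ElementRules()
    rng = _rng(rng_seed)
    universe = make_seed_universe(
        n_universe, reactions, rules, connectivity, rng_seed=rng
    )
    net = build_initial_network(universe, reactions, rules)
    truth = make_truths(
        universe, reactions, n_truth, rules, adducts, min_truth_degree,
        frac_novel, windows=windows, rng_seed=rng, net=net,
    )
    span = windows.span
    noise_floor = 1e3
    base_int = 10 ** rng.uniform(5, 7, size=len(truth))
    noise_mz = rng.uniform(span[0], span[1], size=n_noise)
    noise_int = 10 ** rng.uniform(np.log10(2e3), 5, size=n_noise)
    flaky = rng.random(n_noise) < (1 / 3)
    contam_mz = rng.uniform(span[0], span[1], size=n_contaminants)
    contam_int = 10 ** rng.uniform(5, 6, size=n_contaminants)

    def _noise_arrays(role: str):
        if role == "blank":
            sub = rng.random(n_noise) < 0.2
            mz = np.concatenate([noise_mz[sub], contam_mz])
            inten = np.concatenate([0.5 * noise_int[sub], contam_int])
            return mz, inten * np.exp(rng.normal(0, 0.1, mz.size))
        cv = qc_cv if role == "qc" else 0.3
        present = np.ones(n_noise, dtype=bool)
        present[flaky] = rng.random(flaky.sum()) < 0.5
        jitter = np.exp(rng.normal(0, cv, n_noise))
        jitter[flaky] *= np.exp(rng.normal(0, 0.6, flaky.sum()))
        mz = np.concatenate([noise_mz[present], contam_mz])
        inten = np.concatenate(
            [(noise_int * jitter)[present],
             contam_int * np.exp(rng.normal(0, cv, n_contaminants))]
        )
        return mz, inten

    samples: dict[str, list[pd.DataFrame]] = {}
    roles: dict[str, str] = {}

    def _emit(name: str, role: str, truth_df: pd.DataFrame, cv: float):
        n_mz, n_int = _noise_arrays(role)
        factors = np.exp(rng.normal(0, cv, len(truth_df))) if len(truth_df) else []
        samples[name] = make_spectrum(
            truth_df,
            base_int[: len(truth_df)] * factors if len(truth_df) else np.array([]),
            windows, ppm_sd, iso_int_cv, n_mz, n_int, noise_floor, rng_seed=rng,
        )
        roles[name] = role

    for i in range(n_samples):
        _emit(f"sample_{i + 1}", "sample", truth, sample_cv)
    for i in range(n_blank):
        _emit(f"blank_{i + 1}", "blank", truth.iloc[0:0], 0.0)
    for i in range(n_qc):
        _emit(f"qc_{i + 1}", "qc", truth, qc_cv)

    decoys = (
        make_decoys(n_decoys, universe, rules, rng_seed=rng) if n_decoys else []
    )
    return SyntheticStudy(
        universe=universe,
        truth=truth,
        samples=samples,
        roles=roles,
        windows=windows,
        decoys=decoys,
        rng_seed=rng_seed if isinstance(rng_seed, int) else None,
        params={
            "n_universe": n_universe, "n_truth": n_truth,
            "connectivity": connectivity, "ppm_sd": ppm_sd,
            "iso_int_cv": iso_int_cv, "n_noise": n_noise,
            "frac_novel": frac_novel, "min_truth_degree": min_truth_degree,
        },
    )
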