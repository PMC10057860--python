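"""Assignment-run evaluation: coverage/accuracy against ground truth,
target-decoy pass rates, and the plain m/z database-search baseline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .assign import UNIQUE, AssignmentResult
from .formula import Formula, ion_mz
from .isotopes import DEFAULT_ADDUCTS
from .network import ReactionNetwork, ReactionTable


@dataclass
class EvaluationReport:
    """Coverage/accuracy of an assignment run on truth-bearing features.

    coverage = uniquely assigned truth features / all truth features;
    accuracy = correctly assigned (formula AND adduct) / uniquely assigned
    truth features. Accuracy is None (reported as NA) when nothing was
    assigned. ``per_round`` holds the cumulative unique count after each
    round, over all features.
    """

    n_truth: int
    n_matched: int
    n_unique: int
    n_correct: int
    coverage_pct: float
    accuracy_pct: float | None
    per_round: list[int]

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2)

    def __str__(self) -> str:
        acc = "NA" if self.accuracy_pct is None else f"{self.accuracy_pct:.1f}%"
        return (
            f"truth features: {self.n_truth} (matched in table: {self.n_matched})\n"
            f"uniquely assigned: {self.n_unique}  correct: {self.n_correct}\n"
            f"coverage: {self.coverage_pct:.1f}%  accuracy: {acc}"
        )


def match_truth_features(
    features: pd.DataFrame, truth: pd.DataFrame, tol_ppm: float = 2.0
) -> pd.Series:
    """Map each truth ion to the nearest feature within ``tol_ppm``.

    ``features`` has a ``mz`` column indexed by feature id; ``truth`` has
    ``mz_ion``. Returns a Series indexed like ``truth`` holding feature
    ids (NaN where no feature matches).
    """
    mz = features["mz"].to_numpy()
    ids = features.index.to_numpy()
    out = []
    for t in truth["mz_ion"].to_numpy():
        if mz.size == 0:
            out.append(np.nan)
            continue
        j = int(np.argmin(np.abs(mz - t)))
        out.append(ids[j] if abs(mz[j] - t) / t * 1e6 <= tol_ppm else np.nan)
    return pd.Series(out, index=truth.index)


def coverage_accuracy(
    result: AssignmentResult,
    truth: pd.DataFrame,
    feature_map: pd.Series | None = None,
    features: pd.DataFrame | None = None,
    tol_ppm: float = 2.0,
) -> EvaluationReport:
    """Score an assignment run against a ground-truth table.

    ``truth`` needs ``formula_str`` (or ``formula``), ``adduct`` and
    ``mz_ion`` columns. Truth ions with no matching feature in the run
    count against coverage (the pipeline lost them). Both the formula and
    the adduct must match for a correct assignment.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    if feature_map is None:
        if features is None:
            features = pd.DataFrame(
                {"mz": {fid: fa.mz for fid, fa in result.features.items()}}
            )
        feature_map = match_truth_features(features, truth, tol_ppm)
    fcol = "formula_str" if "formula_str" in truth.columns else "formula"
    n_truth = len(truth)
    n_matched = int(feature_map.notna().sum())
    n_unique = n_correct = 0
    for idx, row in truth.iterrows():
        fid = feature_map.loc[idx]
        if pd.isna(fid):
            continue
        fa = result.features.get(fid)
        if fa is None or fa.status != UNIQUE:
            continue
        n_unique += 1
        truth_formula = row[fcol]
        if not isinstance(truth_formula, str):
            truth_formula = str(truth_formula)
        if str(fa.formula) == truth_formula and fa.adduct == row["adduct"]:
            n_correct += 1
    coverage = 100.0 * n_unique / n_truth
    accuracy = 100.0 * n_correct / n_unique if n_unique else None
    cum = list(np.cumsum(result.rounds)) if result.rounds else []
    return EvaluationReport(
        n_truth=n_truth,
        n_matched=n_matched,
        n_unique=n_unique,
        n_correct=n_correct,
        coverage_pct=coverage,
        accuracy_pct=accuracy,
        per_round=[int(c) for c in cum],
    )


def target_decoy(
    known: list[Formula],
    decoys: list[Formula],
    net: ReactionNetwork,
    reactions: ReactionTable,
    cutoff: int = 3,
    inclusive: bool = True,
) -> tuple[float, float]:
    """Network-filter pass rates (%) for known vs decoy formulas.

    A formula passes when its connection degree into the network meets the
    cut-off, or when it is itself a network node (identity), mirroring the
    candidate degree filter. Specific networks pass knowns at a much
    higher rate than mass-matched decoys.
    """
    if not known or not decoys:
        raise ValueError("both formula lists must be non-empty")

    def rate(formulas):
        n_pass = 0
        for f in formulas:
            degree = len(net.reaction_neighbors(f, reactions))
            ok = degree > cutoff if not inclusive else degree >= cutoff
            if ok or f in net:
                n_pass += 1
        return 100.0 * n_pass / len(formulas)

    return rate(known), rate(decoys)


def database_search_baseline(
    features: pd.DataFrame,
    seeds: list[Formula],
    adducts=DEFAULT_ADDUCTS,
    tol_ppm: float = 2.0,
) -> pd.DataFrame:
    """Direct m/z lookup of features against the seed formula list.

    For each feature, counts the (seed, adduct) ion m/z values within
    ``tol_ppm``; a feature is 'unique' iff exactly one matches. This is
    the database-dependent method the network approach is compared with.
    """
    ion_mzs, labels = [], []
    for f in seeds:
        for a in adducts:
            ion_mzs.append(ion_mz(f, a))
            labels.append((f, a))
    order = np.argsort(ion_mzs)
    ion_arr = np.asarray(ion_mzs)[order]
    labels = [labels[i] for i in order]
    rows = []
    for fid, row in features.iterrows():
        mz = float(row["mz"])
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(ion_arr, mz - tol, side="left")
        hi = np.searchsorted(ion_arr, mz + tol, side="right")
        hits = {labels[i] for i in range(lo, hi)}
        rec = {"feature_id": fid, "mz": mz, "n_matches": len(hits),
               "unique": len(hits) == 1, "formula": None, "adduct": None}
        if len(hits) == 1:
            (f, a), = hits
            rec["formula"] = str(f)
            rec["adduct"] = a
        rows.append(rec)
    return pd.DataFrame(rows).set_index("feature_id")
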