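"""End-to-end orchestration: preprocessing chain and full assignment runs.

The preprocessing order follows the acquisition logic: per-sample window
stitching and S/N filtering, cross-sample alignment, blank reduction,
optional IS normalization, QC RSD filtering, then monoisotopic flagging.
Only monoisotopic features enter candidate generation and assignment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assign import AssignmentResult, iterative_assign
from .formula import ElementRules
from .isotopes import DEFAULT_ADDUCTS
from .network import ReactionTable, build_initial_network
from .peaks import (
    DEFAULT_WINDOWS,
    FeatureTable,
    WindowScheme,
    align_peaks,
    blank_reduction,
    filter_noise,
    flag_monoisotopic,
    normalize_by_is,
    read_manifest,
    read_peaks_csv,
    rsd_qc_filter,
    stitch_windows,
)
from .scoring import ScoreWeights

log = logging.getLogger("formulanet")


@dataclass
class RunParams:
    """All tunable knobs of a run, with the defaults used throughout."""

    tol_ppm: float = 2.0
    align_ppm: float = 5.0
    snr_min: float = 10.0
    blank_ratio: float = 3.0
    rsd_max: float = 30.0
    tol_int: float = 5.0
    adducts: tuple = DEFAULT_ADDUCTS
    cutoff: int = 3
    inclusive_cutoff: bool = True
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    max_rounds: int = 20
    rules: ElementRules = field(default_factory=ElementRules)
    mz_mode: str = "tolerance"
    rescore_ambiguous: bool = True

    def validate(self) -> None:
        for name in ("tol_ppm", "align_ppm", "tol_int"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


def preprocess_scans(
    scans_by_sample: dict[str, list[pd.DataFrame]],
    roles: dict[str, str],
    windows: WindowScheme = DEFAULT_WINDOWS,
    params: RunParams | None = None,
    is_mzs: dict[str, float] | None = None,
) -> FeatureTable:
    """Per-window scans for several samples -> QC-filtered monoisotopic
    feature table. Logs every filter's in/out feature counts."""
    params = params or RunParams()
    params.validate()
    merged = {}
    for name, scans in scans_by_sample.items():
        spectrum = stitch_windows(scans, windows)
        n0 = len(spectrum)
        spectrum = filter_noise(spectrum, params.snr_min)
        log.info("%s: stitched %d peaks, %d after S/N > %g",
                 name, n0, len(spectrum), params.snr_min)
        merged[name] = spectrum
    table = align_peaks(merged, params.align_ppm, roles)
    log.info("aligned: %d features", len(table))
    if table.by_role("blank"):
        n0 = len(table)
        table = blank_reduction(table, params.blank_ratio)
        log.info("blank reduction: %d -> %d", n0, len(table))
    if is_mzs:
        table = normalize_by_is(table, is_mzs, params.align_ppm)
        log.info("IS-normalized against %d standards", len(is_mzs))
    if len(table.by_role("qc")) >= 2:
        n0 = len(table)
        table = rsd_qc_filter(table, params.rsd_max)
        log.info("QC RSD < %g%%: %d -> %d", params.rsd_max, n0, len(table))
    table = flag_monoisotopic(table, params.tol_ppm)
    n_mono = int(table.df["is_monoisotopic"].sum())
    log.info("monoisotopic features: %d / %d", n_mono, len(table))
    return table


def monoisotopic_features(table: FeatureTable) -> pd.DataFrame:
    """The assignment input: monoisotopic rows with mz and observed M+1."""
    df = table.df
    if "is_monoisotopic" in df.columns:
        df = df.loc[df["is_monoisotopic"]]
    cols = [c for c in ("mz", "iso_mz", "iso_ratio") if c in df.columns]
    return df[cols].copy()


def assign_table(
    table: FeatureTable,
    seeds,
    reactions: ReactionTable,
    params: RunParams | None = None,
) -> AssignmentResult:
    params = params or RunParams()
    params.validate()
    features = monoisotopic_features(table)
    return iterative_assign(
        features,
        seeds,
        reactions,
        rules=params.rules,
        adducts=params.adducts,
        tol_ppm=params.tol_ppm,
        tol_int=params.tol_int,
        cutoff=params.cutoff,
        weights=params.weights,
        max_rounds=params.max_rounds,
        inclusive_cutoff=params.inclusive_cutoff,
        rescore_ambiguous=params.rescore_ambiguous,
        mz_mode=params.mz_mode,
    )


def load_study_dir(
    data_dir: str | Path,
) -> tuple[dict[str, list[pd.DataFrame]], dict[str, str], WindowScheme]:
    """Read a directory written by :meth:`SyntheticStudy.write` (or hand-
    assembled in the same layout): per-sample peak CSVs with a ``window``
    column, ``manifest.csv`` and ``windows.csv``."""
    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "manifest.csv")
    wdf = pd.read_csv(data_dir / "windows.csv")
    windows = WindowScheme(tuple(zip(wdf["low"], wdf["high"])))
    scans_by_sample, roles = {}, {}
    for fname, role in manifest.items():
        df = read_peaks_csv(data_dir / fname)
        if "window" not in df.columns:
            raise ValueError(f"{fname}: peak list needs a 'window' column")
        scans = [
            df.loc[df["window"] == i, ["mz", "intensity", "snr"]].reset_index(drop=True)
            for i in range(len(windows))
        ]
        name = Path(fname).stem
        scans_by_sample[name] = scans
        roles[name] = role
    return scans_by_sample, roles, windows


def provenance(params: RunParams, rng_seed=None) -> dict:
    """Machine-readable run record: config hash, package version, seed."""
    from . import __version__

    blob = json.dumps(
        {k: repr(v) for k, v in vars(params).items()}, sort_keys=True
    ).encode()
    return {
        "formulanet_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "rng_seed": rng_seed,
    }
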