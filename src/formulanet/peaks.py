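"""Direct-infusion peak processing: window stitching, noise filtering,
cross-sample alignment, blank reduction, IS normalization, QC filtering and
monoisotopic-feature flagging.

Peak lists are pandas DataFrames with columns ``mz``, ``intensity`` and
optionally ``snr``. A processed study is held in a :class:`FeatureTable`:
one row per aligned feature (strictly increasing consensus m/z), one
intensity column per sample, plus per-feature QC metadata. Sample roles
(``sample`` / ``blank`` / ``qc``) come from a manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Mass gap between successive isotopologue shells (13C - 12C), Da.
ISOTOPE_SPACING = 1.003354835

ROLES = ("sample", "blank", "qc")


@dataclass(frozen=True)
class WindowScheme:
    """Ordered acquisition windows (low, high) m/z; neighbors may overlap."""

    windows: tuple[tuple[float, float], ...]

    def __post_init__(self):
        ws = tuple((float(a), float(b)) for a, b in self.windows)
        if any(a >= b for a, b in ws):
            raise ValueError("each window needs low < high")
        if any(ws[i][0] >= ws[i + 1][0] for i in range(len(ws) - 1)):
            raise ValueError("windows must be ordered by low bound")
        object.__setattr__(self, "windows", ws)

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def span(self) -> tuple[float, float]:
        return (self.windows[0][0], self.windows[-1][1])

    def effective_bounds(self) -> list[tuple[float, float]]:
        """Non-overlapping retention ranges, splitting each overlap at its
        midpoint. Window i retains [eff_lo, eff_hi): peaks at or above the
        midpoint of an overlap belong to the later window."""
        out = []
        for i, (lo, hi) in enumerate(self.windows):
            eff_lo = lo
            if i > 0 and self.windows[i - 1][1] > lo:
                eff_lo = 0.5 * (lo + self.windows[i - 1][1])
            eff_hi = hi
            if i + 1 < len(self.windows) and self.windows[i + 1][0] < hi:
                eff_hi = 0.5 * (hi + self.windows[i + 1][0])
            out.append((eff_lo, eff_hi))
        return out


#: The spectral-stitching scheme used for serum acquisition (m/z 65-609,
#: nine overlapping SIM-style windows).
DEFAULT_WINDOWS = WindowScheme(
    (
        (65, 235),
        (225, 315),
        (305, 355),
        (345, 395),
        (385, 435),
        (425, 475),
        (465, 515),
        (505, 562),
        (552, 609),
    )
)


def stitch_windows(scans: list[pd.DataFrame], scheme: WindowScheme) -> pd.DataFrame:
    """Merge per-window centroid scans into one spectrum.

    Each scan must contain only peaks inside its declared window (error
    otherwise). In an overlap region each peak is retained from exactly one
    window, split at the overlap midpoint; the result is sorted by m/z.
    """
    if len(scans) != len(scheme):
        raise ValueError(f"expected {len(scheme)} scans, got {len(scans)}")
    kept = []
    bounds = scheme.effective_bounds()
    last = len(scans) - 1
    for i, (scan, (lo, hi), (eff_lo, eff_hi)) in enumerate(
        zip(scans, scheme, bounds)
    ):
        if scan.empty:
            continue
        mz = scan["mz"].to_numpy(float)
        if ((mz < lo) | (mz > hi)).any():
            bad = mz[(mz < lo) | (mz > hi)][0]
            raise ValueError(f"peak at m/z {bad} outside window {i} [{lo}, {hi}]")
        mask = (mz >= eff_lo) & ((mz < eff_hi) | ((i == last) & (mz <= eff_hi)))
        kept.append(scan.loc[mask])
    if not kept:
        return pd.DataFrame(columns=["mz", "intensity"])
    out = pd.concat(kept, ignore_index=True)
    return out.sort_values("mz", kind="stable", ignore_index=True)


def filter_noise(peaks: pd.DataFrame, snr_min: float = 10.0) -> pd.DataFrame:
    """Retain peaks with S/N strictly greater than ``snr_min``."""
    if "snr" not in peaks.columns:
        raise ValueError("peak list has no 'snr' column; cannot noise-filter")
    return peaks.loc[peaks["snr"] > snr_min].reset_index(drop=True)


@dataclass
class FeatureTable:
    """Aligned cross-sample feature table.

    ``df`` has one row per feature with a strictly increasing ``mz``
    column, one intensity column per sample (0 where the sample did not
    contribute a peak), and optional metadata columns (``rsd_qc``,
    ``is_monoisotopic``, ``iso_mz``, ``iso_ratio``). ``roles`` maps each
    sample column to 'sample' | 'blank' | 'qc'.
    """

    df: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self):
        for s, r in self.roles.items():
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r} for sample {s!r}")
            if s not in self.df.columns:
                raise ValueError(f"sample {s!r} missing from table")

    @property
    def sample_names(self) -> list[str]:
        return list(self.roles)

    def by_role(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]

    def __len__(self) -> int:
        return len(self.df)

    def intensities(self, role: str) -> pd.DataFrame:
        return self.df[self.by_role(role)]

    def subset(self, mask) -> "FeatureTable":
        return replace(self, df=self.df.loc[mask].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="feature_id")


def align_peaks(
    samples: dict[str, pd.DataFrame],
    tol_ppm: float = 5.0,
    roles: dict[str, str] | None = None,
) -> FeatureTable:
    """Greedy single-linkage m/z clustering of peaks across samples.

    All peaks are pooled and walked in ascending m/z; a peak joins the
    open cluster iff it lies within ``tol_ppm`` of the cluster's running
    intensity-weighted mean m/z, otherwise it opens a new cluster. Each
    cluster becomes one feature (consensus m/z = final weighted mean); a
    sample contributes at most its most intense peak to a feature.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    roles = roles or {name: "sample" for name in samples}
    frames = []
    for name, df in samples.items():
        if df.empty:
            continue
        frames.append(pd.DataFrame({
            "mz": df["mz"].to_numpy(float),
            "intensity": df["intensity"].to_numpy(float),
            "sample": name,
        }))
    if not frames:
        cols = {"mz": pd.Series(dtype=float)}
        cols.update({s: pd.Series(dtype=float) for s in samples})
        return FeatureTable(pd.DataFrame(cols), roles=roles)
    pool = pd.concat(frames, ignore_index=True).sort_values(
        "mz", kind="stable", ignore_index=True
    )
    mzs = pool["mz"].to_numpy()
    ints = pool["intensity"].to_numpy()
    labels = np.empty(len(pool), dtype=np.int64)
    cluster = -1
    mean = w = 0.0
    for i in range(len(pool)):
        if cluster < 0 or (mzs[i] - mean) / mean * 1e6 > tol_ppm:
            cluster += 1
            mean, w = mzs[i], max(ints[i], 1e-30)
        else:
            wi = max(ints[i], 1e-30)
            mean = (mean * w + mzs[i] * wi) / (w + wi)
            w += wi
        labels[i] = cluster
    pool["cluster"] = labels
    w_int = pool["intensity"].clip(lower=1e-30)
    num = (pool["mz"] * w_int).groupby(labels).sum()
    consensus = num / w_int.groupby(labels).sum()
    best = pool.loc[pool.groupby(["cluster", "sample"])["intensity"].idxmax()]
    wide = best.pivot(index="cluster", columns="sample", values="intensity")
    wide = wide.reindex(columns=list(samples), fill_value=np.nan).fillna(0.0)
    out = pd.DataFrame({"mz": consensus})
    for s in samples:
        out[s] = wide[s] if s in wide.columns else 0.0
    out = out.fillna(0.0).sort_values("mz", ignore_index=True)
    return FeatureTable(out, roles=roles)


def blank_reduction(table: FeatureTable, ratio_min: float = 3.0) -> FeatureTable:
    """Drop features not sufficiently above the blank background: a feature
    is retained iff mean sample intensity >= ratio_min x mean blank
    intensity (features absent from blanks are always retained)."""
    blanks = table.by_role("blank")
    if not blanks:
        raise ValueError("no blank samples in table")
    samples = table.by_role("sample") or table.by_role("qc")
    mean_s = table.df[samples].mean(axis=1)
    mean_b = table.df[blanks].mean(axis=1)
    return table.subset((mean_s >= ratio_min * mean_b).to_numpy())


def normalize_by_is(
    table: FeatureTable, is_mzs: dict[str, float], tol_ppm: float = 5.0
) -> FeatureTable:
    """Divide each feature's intensities by its internal standard's.

    ``is_mzs`` maps IS names to their ion m/z. Each IS must match a feature
    (within ``tol_ppm``) with non-zero intensity in every sample; each
    feature is normalized by the IS nearest in m/z. The IS features
    themselves are dropped from the output.
    """
    mz = table.df["mz"].to_numpy()
    is_rows: dict[str, int] = {}
    for name, target in is_mzs.items():
        idx = int(np.argmin(np.abs(mz - target)))
        if abs(mz[idx] - target) / target * 1e6 > tol_ppm:
            raise ValueError(f"internal standard {name!r} (m/z {target}) not found")
        is_rows[name] = idx
    for name, idx in is_rows.items():
        for s in table.sample_names:
            if table.df.at[idx, s] <= 0:
                raise ValueError(
                    f"internal standard {name!r} missing from sample {s!r}"
                )
    is_names = list(is_rows)
    is_feature_mz = np.array([mz[is_rows[n]] for n in is_names])
    nearest = np.argmin(np.abs(mz[:, None] - is_feature_mz[None, :]), axis=1)
    df = table.df.copy()
    for s in table.sample_names:
        is_int = np.array([df.at[is_rows[n], s] for n in is_names])
        df[s] = df[s].to_numpy() / is_int[nearest]
    df = df.drop(index=list(is_rows.values())).reset_index(drop=True)
    return replace(table, df=df, normalized=True)


def rsd_qc_filter(table: FeatureTable, rsd_max: float = 30.0) -> FeatureTable:
    """Keep features whose QC-replicate RSD (100.sd/mean, sample sd) is
    below ``rsd_max``; features absent from QC cannot demonstrate
    repeatability and are dropped. Adds an ``rsd_qc`` column."""
    qc = table.by_role("qc")
    if len(qc) < 2:
        raise ValueError("need at least 2 QC samples for the RSD filter")
    vals = table.df[qc]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    rsd = 100.0 * sd / mean.where(mean > 0)
    out = replace(table, df=table.df.assign(rsd_qc=rsd))
    return out.subset((rsd < rsd_max).fillna(False).to_numpy())


def flag_monoisotopic(
    table: FeatureTable, tol_ppm: float = 2.0, ratio_slack: float = 1.5
) -> FeatureTable:
    """Identify monoisotopic features and attach their observed M+1 shells.

    A feature is flagged non-monoisotopic when another feature sits one
    isotope spacing (13C - 12C) below it within ``tol_ppm`` and the
    intensity ratio is consistent with an M+1 isotopologue: the ratio must
    not exceed ``ratio_slack`` times the largest M+1 fraction any CHNOPS
    formula at that mass could plausibly show (carbon-dominated, ~1.1% per
    carbon). Monoisotopic features gain ``iso_mz``/``iso_ratio`` columns
    holding the matched experimental M+1 peak, used by the isotope
    similarity score; only monoisotopic features enter formula assignment.
    """
    df = table.df
    mz = df["mz"].to_numpy()
    ref = table.by_role("sample") or table.sample_names
    mean_int = df[ref].mean(axis=1).to_numpy()
    n = len(df)
    is_mono = np.ones(n, dtype=bool)
    iso_mz = np.full(n, np.nan)
    iso_ratio = np.full(n, np.nan)
    for i in range(n):
        target = mz[i] - ISOTOPE_SPACING
        j = int(np.argmin(np.abs(mz - target))) if n else -1
        if j < 0 or abs(mz[j] - target) / mz[i] * 1e6 > tol_ppm:
            continue
        if mean_int[j] <= 0:
            continue
        ratio = mean_int[i] / mean_int[j]
        max_c = (mz[i] - ISOTOPE_SPACING) / 12.0
        plausible = 0.0115 * max_c + 0.05
        if ratio <= ratio_slack * plausible:
            is_mono[i] = False
            iso_mz[j] = mz[i]
            iso_ratio[j] = ratio
    out = df.assign(is_monoisotopic=is_mono, iso_mz=iso_mz, iso_ratio=iso_ratio)
    return replace(table, df=out)


# -- file I/O --------------------------------------------------------------


def read_peaks_csv(path: str | Path) -> pd.DataFrame:
    """Read a centroid peak list CSV with columns mz,intensity[,snr,window]."""
    df = pd.read_csv(path)
    missing = {"mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a sample manifest CSV (columns: file, role)."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            role = row["role"].strip().lower()
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} in manifest")
            out[row["file"].strip()] = role
    return out
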