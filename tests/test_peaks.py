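"""Peak processing: stitching, noise filter, alignment, blank reduction,
IS normalization, QC RSD filter and monoisotopic flagging."""

import numpy as np
import pandas as pd
import pytest

from formulanet.peaks import (
    FeatureTable,
    WindowScheme,
    align_peaks,
    blank_reduction,
    filter_noise,
    flag_monoisotopic,
    normalize_by_is,
    rsd_qc_filter,
    stitch_windows,
)


def peaks_df(mzs, intensities=None, snr=None):
    df = pd.DataFrame({"mz": list(mzs)})
    df["intensity"] = intensities if intensities is not None else 1000.0
    if snr is not None:
        df["snr"] = snr
    return df


class TestStitch:
    def test_overlap_midpoint_rule(self):
        scheme = WindowScheme(((225, 315), (305, 355)))
        # peak at 310 recorded in both windows; overlap midpoint is 310,
        # so it belongs to (and is kept once from) the later window
        merged = stitch_windows(
            [peaks_df([260.0, 310.0]), peaks_df([310.0, 340.0])], scheme
        )
        assert merged["mz"].tolist() == [260.0, 310.0, 340.0]

    def test_below_midpoint_taken_from_earlier_window(self):
        scheme = WindowScheme(((225, 315), (305, 355)))
        merged = stitch_windows(
            [peaks_df([308.0], [111.0]), peaks_df([308.0, 340.0], [222.0, 1.0])],
            scheme,
        )
        assert merged.loc[merged["mz"] == 308.0, "intensity"].tolist() == [111.0]

    def test_non_overlapping_concatenates_sorted(self):
        scheme = WindowScheme(((100, 200), (200, 300)))
        merged = stitch_windows(
            [peaks_df([150.0, 120.0]), peaks_df([250.0])], scheme
        )
        assert merged["mz"].tolist() == [120.0, 150.0, 250.0]

    def test_empty_scans(self):
        scheme = WindowScheme(((100, 200), (200, 300)))
        assert stitch_windows([peaks_df([]), peaks_df([])], scheme).empty

    def test_peak_outside_window_rejected(self):
        scheme = WindowScheme(((100, 200),))
        with pytest.raises(ValueError, match="outside window"):
            stitch_windows([peaks_df([250.0])], scheme)

    def test_dedup_against_brute_force(self):
        rng = np.random.default_rng(8)
        scheme = WindowScheme(((65, 235), (225, 315), (305, 355)))
        all_mz = rng.uniform(65, 355, size=400)
        scans = [
            peaks_df(sorted(all_mz[(all_mz >= lo) & (all_mz <= hi)]))
            for lo, hi in scheme
        ]
        merged = stitch_windows(scans, scheme)
        # oracle: the union of window contents with duplicates removed
        expected = sorted(set(np.concatenate(
            [s["mz"].to_numpy() for s in scans]
        )))
        assert merged["mz"].tolist() == expected


class TestNoiseFilter:
    def test_strictly_greater_than_threshold(self):
        out = filter_noise(peaks_df([1, 2, 3], snr=[5, 10, 11]), 10)
        assert out["snr"].tolist() == [11]

    def test_zero_threshold_keeps_positive_snr(self):
        out = filter_noise(peaks_df([1, 2], snr=[0.5, 0.0]), 0)
        assert out["snr"].tolist() == [0.5]

    def test_empty_input(self):
        assert filter_noise(peaks_df([], snr=[]), 10).empty

    def test_missing_snr_column_errors(self):
        with pytest.raises(ValueError, match="snr"):
            filter_noise(peaks_df([100.0]), 10)


class TestAlign:
    def test_close_peaks_merge(self):
        table = align_peaks(
            {"a": peaks_df([200.0000]), "b": peaks_df([200.0005])}, tol_ppm=5
        )
        assert len(table) == 1

    def test_distant_peaks_split(self):
        table = align_peaks(
            {"a": peaks_df([200.000]), "b": peaks_df([200.010])}, tol_ppm=5
        )
        assert len(table) == 2

    def test_single_sample_identity(self):
        mzs = [100.0, 150.0, 200.0]
        table = align_peaks({"a": peaks_df(mzs)}, tol_ppm=5)
        assert table.df["mz"].tolist() == mzs

    def test_sample_contributes_most_intense_peak(self):
        table = align_peaks(
            {"a": peaks_df([200.0000, 200.0004], [10.0, 99.0])}, tol_ppm=5
        )
        assert len(table) == 1
        assert table.df["a"].tolist() == [99.0]

    def test_sample_order_invariance_for_disjoint_clusters(self):
        a, b = peaks_df([100.0, 300.0]), peaks_df([200.0, 400.0])
        t1 = align_peaks({"a": a, "b": b}, tol_ppm=5)
        t2 = align_peaks({"b": b, "a": a}, tol_ppm=5)
        assert t1.df["mz"].tolist() == t2.df["mz"].tolist()

    def test_feature_count_bounded_by_peaks(self):
        rng = np.random.default_rng(9)
        samples = {
            f"s{i}": peaks_df(np.sort(rng.uniform(100, 500, 50)))
            for i in range(3)
        }
        table = align_peaks(samples, tol_ppm=5)
        assert len(table) <= 150
        mzs = table.df["mz"].to_numpy()
        assert (np.diff(mzs) > 0).all()


def _table(sample, blank=None, qc=None, mzs=None):
    n = len(sample)
    data = {"mz": mzs or list(100.0 + 10 * np.arange(n)), "s1": sample}
    roles = {"s1": "sample"}
    if blank is not None:
        data["b1"] = blank
        roles["b1"] = "blank"
    if qc is not None:
        for i, col in enumerate(np.array(qc, dtype=float).T):
            data[f"q{i + 1}"] = col
            roles[f"q{i + 1}"] = "qc"
    return FeatureTable(pd.DataFrame(data), roles=roles)


class TestBlankReduction:
    def test_threshold_cases(self):
        table = _table([300.0, 100.0, 50.0], blank=[100.0, 100.0, 0.0])
        out = blank_reduction(table, ratio_min=3)
        # 300 >= 3x100 kept; 100 < 3x100 dropped; blank-absent kept
        assert out.df["s1"].tolist() == [300.0, 50.0]

    def test_requires_blank(self):
        with pytest.raises(ValueError, match="blank"):
            blank_reduction(_table([100.0]), ratio_min=3)


class TestISNormalization:
    def test_ratio_and_scale_invariance(self):
        df = pd.DataFrame({
            "mz": [100.0, 150.0],
            "s1": [1000.0, 500.0],
            "s2": [3000.0, 1500.0],  # s2 is s1 globally scaled by 3
        })
        table = FeatureTable(df, roles={"s1": "sample", "s2": "sample"})
        out = normalize_by_is(table, {"IS1": 150.0})
        assert out.normalized
        assert len(out) == 1  # the IS feature itself is dropped
        assert out.df["s1"].tolist() == [2.0]
        assert out.df["s2"].tolist() == [2.0]

    def test_missing_is_errors(self):
        table = _table([100.0, 200.0])
        with pytest.raises(ValueError, match="not found"):
            normalize_by_is(table, {"IS1": 999.0})

    def test_is_absent_in_one_sample_named(self):
        df = pd.DataFrame({
            "mz": [100.0, 150.0],
            "s1": [1000.0, 500.0],
            "s2": [900.0, 0.0],
        })
        table = FeatureTable(df, roles={"s1": "sample", "s2": "sample"})
        with pytest.raises(ValueError, match="IS1.*s2"):
            normalize_by_is(table, {"IS1": 150.0})


class TestRsdFilter:
    def test_constant_feature_retained(self):
        out = rsd_qc_filter(_table([1.0], qc=[[100.0, 100.0, 100.0]]), 30)
        assert len(out) == 1
        assert out.df["rsd_qc"].tolist() == [0.0]

    def test_variable_feature_removed(self):
        # sd([100, 200]) / mean = 70.71/150 = 47.1% > 30%
        out = rsd_qc_filter(_table([1.0], qc=[[100.0, 200.0]]), 30)
        assert len(out) == 0

    def test_scale_invariance(self):
        qc = [[120.0, 100.0, 95.0]]
        a = rsd_qc_filter(_table([1.0], qc=qc), 30)
        b = rsd_qc_filter(_table([1.0], qc=[[7 * v for v in qc[0]]]), 30)
        assert a.df["rsd_qc"].tolist() == pytest.approx(b.df["rsd_qc"].tolist())

    def test_requires_two_qc(self):
        with pytest.raises(ValueError, match="QC"):
            rsd_qc_filter(_table([1.0], qc=[[100.0]]), 30)


class TestMonoisotopicFlag:
    def test_isotopologue_flagged_and_attached(self):
        # a plausible M/M+1 pair (6.9% ratio at m/z 181) plus an unrelated peak
        df = pd.DataFrame({
            "mz": [181.070665, 182.074020, 250.000000],
            "s1": [1e6, 6.9e4, 5e5],
        })
        table = FeatureTable(df, roles={"s1": "sample"})
        out = flag_monoisotopic(table).df
        assert out["is_monoisotopic"].tolist() == [True, False, True]
        assert out.loc[0, "iso_mz"] == pytest.approx(182.074020)
        assert out.loc[0, "iso_ratio"] == pytest.approx(0.069)

    def test_equal_intensity_pair_not_flagged(self):
        # 1:1 intensity cannot be an isotopologue of a small molecule
        df = pd.DataFrame({
            "mz": [181.070665, 182.074020],
            "s1": [1e6, 1e6],
        })
        table = FeatureTable(df, roles={"s1": "sample"})
        assert flag_monoisotopic(table).df["is_monoisotopic"].all()
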