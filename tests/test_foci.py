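import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vsxscan.foci import axis_difference, dioptric_distance, find_foci, summarize_eye
from vsxscan.refraction import SpherocylRx, rx_to_power_vector


def cloud_from(points):
    """points: iterable of (sphere, cylinder, axis, vsx)."""
    rows = []
    for s, c, a, v in points:
        rx = SpherocylRx.normalized(s, c, a)
        pv = rx_to_power_vector(rx)
        rows.append(
            (rx.sphere_D, rx.cylinder_D, rx.axis_deg, pv.M, pv.J0, pv.J45, v,
             math.log10(v) if v > 0 else -np.inf, "C")
        )
    return pd.DataFrame(
        rows, columns=["sphere", "cylinder", "axis", "M", "J0", "J45", "vsx", "log_vsx", "stage"]
    )


def line_cloud(vsx_profile, cyl=-1.0, axis=90.0):
    """1-D chain of lattice-adjacent points with a prescribed VSX profile."""
    return cloud_from(
        [(-2.0 + 0.25 * i, cyl, axis, v) for i, v in enumerate(vsx_profile)]
    )


class TestFindFoci:
    def test_unimodal_cloud_single_focus(self):
        prof = [0.02, 0.05, 0.09, 0.12, 0.09, 0.05, 0.02]
        foci = find_foci(line_cloud(prof))
        assert len(foci) == 1
        assert foci[0].peak_vsx == pytest.approx(0.12)

    def test_two_peaks_with_deep_valley(self):
        """Peaks 0.09 and 0.07 with a 0.03 valley; 0.03 < (2/3)*0.09 = 0.06
        so the superlevel set splits into exactly two foci."""
        prof = [0.02, 0.09, 0.03, 0.07, 0.02]
        foci = find_foci(line_cloud(prof))
        assert len(foci) == 2
        assert foci[0].peak_vsx == pytest.approx(0.09)
        assert foci[1].peak_vsx == pytest.approx(0.07)

    def test_raised_valley_merges_foci(self):
        """Valley raised to 0.07 >= 0.06: one connected focus."""
        prof = [0.02, 0.09, 0.07, 0.07, 0.02]
        foci = find_foci(line_cloud(prof))
        assert len(foci) == 1

    def test_single_point_cloud(self):
        foci = find_foci(cloud_from([(0.0, -1.0, 10.0, 0.2)]))
        assert len(foci) == 1 and foci[0].n_members == 1

    def test_axis_wraparound_connectivity(self):
        """Points at axis 177.5 and 0 are lattice neighbours (180 == 0)."""
        pts = [(0.0, -1.0, 177.5, 0.1), (0.0, -1.0, 0.0, 0.1)]
        assert len(find_foci(cloud_from(pts))) == 1

    def test_partition_property(self):
        """Members partition the superlevel set: disjoint, covering."""
        rng = np.random.default_rng(2)
        pts = []
        for i in range(10):
            for j in range(6):
                pts.append((0.25 * i, -0.25 * (j + 1), 45.0, float(rng.uniform(0.01, 0.1))))
        cloud = cloud_from(pts)
        foci = find_foci(cloud)
        members = np.concatenate([f.member_index for f in foci])
        assert len(members) == len(set(members))
        thresh = (2.0 / 3.0) * cloud.vsx.max()
        assert set(members) == set(np.where(cloud.vsx >= thresh)[0])

    def test_focus_nesting_in_threshold(self):
        """Raising the threshold refines the partition: every focus at a
        higher threshold is contained in exactly one focus at a lower one.
        (The raw focus COUNT is not monotone - a ridge can split.)"""
        prof = [0.02, 0.09, 0.03, 0.07, 0.02, 0.05, 0.01]
        cloud = line_cloud(prof)
        lo = find_foci(cloud, threshold_fraction=0.3)
        hi = find_foci(cloud, threshold_fraction=0.8)
        lo_sets = [set(f.member_index) for f in lo]
        for f in hi:
            containers = [s for s in lo_sets if set(f.member_index) <= s]
            assert len(containers) == 1


class TestDioptricDistance:
    def test_identical_prescriptions(self):
        f = find_foci(cloud_from([(0.0, -1.0, 10.0, 0.2)]))[0]
        assert dioptric_distance(f, f) == 0.0

    def test_printed_focus_pair(self):
        """The keratoconic example pair (-11.5 -7.25 x 177.5) and
        (+1 -8.0 x 50) lies 13.55 D apart in power-vector space."""
        d = dioptric_distance(
            SpherocylRx(-11.5, -7.25, 177.5), SpherocylRx(1.0, -8.0, 50.0)
        )
        assert d == pytest.approx(13.55, abs=0.01)

    def test_pure_sphere_pair(self):
        assert dioptric_distance(
            SpherocylRx(-10.0, 0.0, 0.0), SpherocylRx(-8.0, 0.0, 0.0)
        ) == pytest.approx(2.0, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        s=st.tuples(st.floats(-15, 10), st.floats(-15, 10), st.floats(-15, 10)),
        c=st.tuples(st.floats(-10, 0), st.floats(-10, 0), st.floats(-10, 0)),
        a=st.tuples(st.floats(0, 179), st.floats(0, 179), st.floats(0, 179)),
    )
    def test_metric_properties(self, s, c, a):
        rx = [SpherocylRx.normalized(s[i], c[i], a[i]) for i in range(3)]
        d01 = dioptric_distance(rx[0], rx[1])
        d10 = dioptric_distance(rx[1], rx[0])
        assert d01 == pytest.approx(d10, abs=1e-12)
        assert d01 >= 0
        d02 = dioptric_distance(rx[0], rx[2])
        d12 = dioptric_distance(rx[1], rx[2])
        assert d02 <= d01 + d12 + 1e-9


class TestAxisDifference:
    def test_printed_pair_unfolded_and_folded(self):
        d = axis_difference(SpherocylRx(-11.5, -7.25, 177.5), SpherocylRx(1.0, -8.0, 50.0))
        assert d["unfolded"] == pytest.approx(127.5)
        assert d["folded"] == pytest.approx(52.5)

    def test_equal_axes(self):
        d = axis_difference(SpherocylRx(0, -1, 30.0), SpherocylRx(1, -2, 30.0))
        assert d["unfolded"] == 0.0

    def test_both_conventions_reported(self):
        d = axis_difference(SpherocylRx(0, -1, 10.0), SpherocylRx(0, -1, 170.0))
        assert d["unfolded"] == pytest.approx(160.0)
        assert d["folded"] == pytest.approx(20.0)

    def test_zero_cylinder_undefined(self):
        d = axis_difference(SpherocylRx(1.0, 0.0, 0.0), SpherocylRx(0, -1, 30.0))
        assert d["unfolded"] is None and d["folded"] is None


class TestMergeConnectedFoci:
    def _foci_for(self, prof):
        return find_foci(line_cloud(prof)), line_cloud(prof)

    def test_merges_when_fine_path_stays_above_threshold(self):
        from vsxscan.foci import merge_connected_foci

        prof = [0.02, 0.09, 0.03, 0.07, 0.02]
        foci, cloud = self._foci_for(prof)
        assert len(foci) == 2
        # an evaluator that reveals the valley was a sampling artifact
        merged = merge_connected_foci(foci, lambda rx: 0.08, 0.06)
        assert len(merged) == 1
        assert merged[0].peak_vsx == pytest.approx(0.09)
        assert len(merged[0].member_index) == sum(
            1 for v in prof if v >= (2 / 3) * max(prof)
        )

    def test_keeps_genuinely_separated_foci(self):
        from vsxscan.foci import merge_connected_foci

        prof = [0.02, 0.09, 0.03, 0.07, 0.02]
        foci, _ = self._foci_for(prof)
        merged = merge_connected_foci(foci, lambda rx: 0.01, 0.06)
        assert len(merged) == 2


class _FakeScan:
    def __init__(self, cloud, best_rx, best_vsx):
        self.cloud = cloud
        self.best_rx = best_rx
        self.best_vsx = best_vsx
        self.low_ceiling_warning = False


class TestSummarizeEye:
    def test_two_peak_summary(self):
        prof = [0.02, 0.09, 0.03, 0.07, 0.02]
        cloud = line_cloud(prof)
        scan = _FakeScan(cloud, SpherocylRx(-1.75, -1.0, 90.0), 0.09)
        rec = summarize_eye({"spectacle": scan})["spectacle"]
        assert rec["n_foci"] == 2
        assert rec["focus_distance_D"] == pytest.approx(0.5, abs=1e-9)
        assert rec["axis_difference_deg"]["unfolded"] == 0.0

    def test_below_threshold_cloud_still_reports_best(self):
        cloud = line_cloud([0.002, 0.004, 0.003])
        scan = _FakeScan(cloud, SpherocylRx(-1.75, -1.0, 90.0), 0.004)
        scan.low_ceiling_warning = True
        rec = summarize_eye({"spectacle": scan})["spectacle"]
        assert rec["best_vsx"] == 0.004
        assert rec["low_ceiling_warning"]
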