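"""Degree formula, binning and the per-vessel plane-sweep maximum."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vesselquant as vq
from vesselquant.involvement import (
    CATEGORIES,
    DegenerateFormulaError,
    bin_degree,
    involvement_degree,
    quantify_vessel,
    quantify_volume,
    report_from_degrees,
)


class TestDegreeFormula:
    @pytest.mark.parametrize(
        "frac,expected", [(0.0, 0.0), (0.25, 90.0), (0.5, 180.0), (0.75, 270.0), (1.0, 360.0)]
    )
    def test_fraction_mode_is_proportional(self, frac, expected):
        assert involvement_degree(frac * 80.0, 80.0) == pytest.approx(expected)

    def test_literal_mode_matches_printed_expression(self):
        # TV/(TV+(TV-V)) * 360: agrees with fraction mode at full contact
        assert involvement_degree(80.0, 80.0, mode="literal") == pytest.approx(360.0)
        # below half contact the printed expression goes negative
        assert involvement_degree(20.0, 80.0, mode="literal") == pytest.approx(-180.0)

    def test_literal_mode_degenerate_at_half_contact(self):
        with pytest.raises(DegenerateFormulaError):
            involvement_degree(40.0, 80.0, mode="literal")

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            involvement_degree(1.0, 0.0)
        with pytest.raises(ValueError):
            involvement_degree(5.0, 4.0)
        with pytest.raises(ValueError):
            involvement_degree(1.0, 4.0, mode="nonsense")


class TestBinning:
    def test_worked_example_89_degrees(self):
        # sub-quarter arterial contact maps into the first nonzero group
        assert bin_degree(89.0) == "0–90"

    @pytest.mark.parametrize(
        "deg,cat",
        [
            (0.0, "0"),
            (0.001, "0–90"),
            (90.0, "0–90"),
            (90.001, "90–180"),
            (180.0, "90–180"),
            (270.0, "180–270"),
            (270.001, "270–360"),
            (360.0, "270–360"),
        ],
    )
    def test_right_closed_boundaries(self, deg, cat):
        assert bin_degree(deg) == cat

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 360.1):
            with pytest.raises(ValueError):
                bin_degree(bad)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 360, allow_nan=False))
    def test_every_degree_has_a_category(self, deg):
        assert bin_degree(deg) in CATEGORIES


class TestQuantifyVessel:
    def test_recovers_quarter_wrap(self, single_vessel_phantom):
        vol, truth = single_vessel_phantom(90.0)
        vi = quantify_vessel(vol, "SMA")
        assert vi.max_degrees == pytest.approx(90.0, abs=10.0)
        assert vi.category in ("0–90", "90–180")
        assert vi.argmax_plane is not None

    def test_no_contact_phantom(self, single_vessel_phantom):
        vol, _ = single_vessel_phantom(0.0)
        vi = quantify_vessel(vol, "SMA")
        assert vi.max_degrees == 0.0
        assert vi.category == "0"

    def test_full_encasement(self, single_vessel_phantom):
        vol, _ = single_vessel_phantom(360.0)
        vi = quantify_vessel(vol, "SMA")
        assert vi.max_degrees == pytest.approx(360.0, abs=10.0)
        assert vi.category == "270–360"

    def test_monotone_in_wrap_angle(self, single_vessel_phantom):
        vals = []
        for theta in (45.0, 120.0, 200.0, 300.0):
            vol, _ = single_vessel_phantom(theta, shape=64, extent_slices=14)
            vals.append(quantify_vessel(vol, "SMA").max_degrees)
        for lo, hi in zip(vals, vals[1:]):
            assert lo <= hi + 2.0  # discretisation slack

    def test_unknown_vessel_raises(self, single_vessel_phantom):
        vol, _ = single_vessel_phantom(90.0)
        with pytest.raises(vq.LabelConsistencyError):
            quantify_vessel(vol, "aorta")


class TestQuantifyVolume:
    def test_multi_vessel_report(self):
        vol, truth = vq.make_multi_vessel_phantom({"SMA": 90.0, "SMV": 270.0})
        rep = quantify_volume(vol)
        assert rep["SMA"].max_degrees == pytest.approx(90.0, abs=10.0)
        assert rep["SMV"].max_degrees == pytest.approx(270.0, abs=10.0)
        for v in ("CeTr", "HA", "PV"):
            assert rep[v].max_degrees == 0.0
            assert not rep[v].absent  # present, just uninvolved

    def test_absent_vessel_flagged(self, single_vessel_phantom):
        vol, _ = single_vessel_phantom(90.0)  # only SMA exists
        rep = quantify_volume(vol)
        assert rep["PV"].absent
        assert rep["PV"].max_degrees == 0.0
        assert rep["PV"].category == "0"
        assert not rep["SMA"].absent

    def test_no_tumor_volume_all_zero(self):
        vol, _ = vq.make_multi_vessel_phantom({})
        rep = quantify_volume(vol)
        assert all(rep[v].max_degrees == 0.0 for v in vq.VESSELS)
        assert all(rep[v].category == "0" for v in vq.VESSELS)

    def test_degrees_within_bounds_and_contact_leq_circumference(self):
        vol, _ = vq.make_multi_vessel_phantom(
            {"CeTr": 45.0, "SMA": 200.0, "PV": 330.0}, jitter_prob=0.1, seed=5
        )
        rep = quantify_volume(vol)
        for v in vq.VESSELS:
            vi = rep[v]
            assert 0.0 <= vi.max_degrees <= 360.0
            if vi.measurement is not None:
                m = vi.measurement
                assert 0.0 <= m.contact_TV <= m.circumference_V + 1e-9
                assert (m.contact_TV == 0.0) == (m.degrees == 0.0)


class TestResolutionAndRotation:
    def test_finer_voxels_stay_within_tolerance(self, single_vessel_phantom):
        theta = 135.0
        vol_lo, _ = single_vessel_phantom(theta, shape=96, spacing=0.5)
        vol_hi, _ = single_vessel_phantom(theta, shape=192, spacing=0.25)
        err_lo = abs(quantify_vessel(vol_lo, "SMA").max_degrees - theta)
        err_hi = abs(quantify_vessel(vol_hi, "SMA").max_degrees - theta)
        assert err_hi <= max(err_lo, 5.0)

    def test_axis_permutation_invariance(self, single_vessel_phantom):
        vol, _ = single_vessel_phantom(135.0, shape=64, extent_slices=14)
        base = quantify_vessel(vol, "SMA").max_degrees
        for perm in ((1, 2, 0), (2, 0, 1), (0, 2, 1)):
            pvol = vq.LabelVolume(
                np.transpose(vol.voxels, perm),
                tuple(vol.spacing[p] for p in perm),
                vol.label_map,
            )
            assert quantify_vessel(pvol, "SMA").max_degrees == pytest.approx(base, abs=2.0)


def test_report_from_degrees_consistency():
    rep = report_from_degrees({"SMA": 120.0})
    assert rep["SMA"].category == "90–180"
    assert rep["PV"].max_degrees == 0.0
    with pytest.raises(ValueError):
        report_from_degrees({"SMA": 400.0})
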