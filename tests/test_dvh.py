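"""Unit and property tests of the DVH model and the MADD."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosegain.dvh import (
    FRACTION,
    GY,
    ML,
    PERCENT,
    ReferenceDose,
    StructureDVH,
    differential_volumes,
    madd,
    mean_dose,
    read_dvh_csv,
    read_tps_export,
    to_absolute,
    to_relative,
    write_dvh_csv,
)
from dosegain.errors import DegenerateStructureError, InvalidDVHError, UnitError


def make_dvh(doses, volumes, total=None, unit=PERCENT, vol_unit=FRACTION, role="OAR"):
    return StructureDVH.from_points(
        "heart", doses, volumes, role=role, total_volume=total,
        dose_unit=unit, volume_unit=vol_unit,
    )


def dvh_from_voxels(voxels, grid=0.1, role="OAR"):
    """Independent DVH construction: cumulative fraction >= each grid dose."""
    voxels = np.asarray(voxels, dtype=float)
    grid_doses = np.arange(0.0, voxels.max() + grid, grid)
    volumes = np.array([(voxels >= d).mean() for d in grid_doses])
    keep = volumes > 0
    keep[0] = True
    return make_dvh(grid_doses[keep], volumes[keep], total=1.0, role=role)


class TestValidation:
    def test_rejects_increasing_volumes(self):
        with pytest.raises(InvalidDVHError):
            StructureDVH("heart", "OAR", np.array([0.0, 10.0]),
                         np.array([0.5, 1.0]), total_volume=0.5)

    def test_rejects_negative_doses(self):
        with pytest.raises(InvalidDVHError):
            make_dvh([-1.0, 5.0], [1.0, 0.5])

    def test_duplicate_doses_merged_keeping_smaller_volume(self):
        dvh = make_dvh([0.0, 10.0, 10.0, 20.0], [1.0, 0.8, 0.6, 0.1])
        assert dvh.doses.tolist() == [0.0, 10.0, 20.0]
        assert dvh.volumes.tolist() == [1.0, 0.6, 0.1]

    def test_truncated_export_is_anchored_at_zero_dose(self):
        dvh = make_dvh([5.0, 10.0], [0.7, 0.2], total=1.0)
        assert dvh.doses[0] == 0.0
        assert dvh.volumes[0] == 1.0


class TestUnitConversion:
    def test_prescription_maps_to_100_percent(self):
        dvh = make_dvh([47.25], [1.0], unit=GY)
        rel = to_relative(dvh, 47.25)
        assert rel.doses.tolist() == [100.0]
        assert rel.dose_unit == PERCENT

    def test_linear_scaling(self):
        dvh = make_dvh([0.0, 23.625, 47.25], [1.0, 0.5, 0.1], unit=GY)
        rel = to_relative(dvh, 47.25)
        np.testing.assert_allclose(rel.doses, [0.0, 50.0, 100.0])
        np.testing.assert_array_equal(rel.volumes, dvh.volumes)

    def test_round_trip_recovers_doses(self, rng):
        doses = np.sort(rng.uniform(0.0, 50.0, 40))
        doses = np.unique(doses)
        volumes = np.sort(rng.uniform(0.0, 1.0, doses.size))[::-1]
        volumes[0] = 1.0
        dvh = make_dvh(doses, volumes, unit=GY)
        back = to_absolute(to_relative(dvh, 47.25), 47.25)
        np.testing.assert_allclose(back.doses, dvh.doses, rtol=1e-12)

    def test_non_positive_prescription_rejected(self):
        dvh = make_dvh([10.0], [1.0], unit=GY)
        with pytest.raises(ValueError):
            to_relative(dvh, 0.0)


class TestDifferentialVolumes:
    def test_single_point_carries_all_volume(self):
        doses, dv = differential_volumes(make_dvh([10.0], [1.0]))
        assert doses.tolist() == [10.0]
        assert dv.tolist() == [1.0]

    def test_two_equal_strips(self):
        doses, dv = differential_volumes(make_dvh([0.0, 10.0, 20.0], [1.0, 0.5, 0.0]))
        assert list(zip(doses.tolist(), dv.tolist())) == [
            (0.0, 0.5), (10.0, 0.5), (20.0, 0.0)
        ]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=30), st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation(self, n_points, seed):
        r = np.random.default_rng(seed)
        doses = np.unique(np.round(r.uniform(0, 120, n_points), 6))
        volumes = np.sort(r.uniform(0, 1, doses.size))[::-1]
        volumes[0] = 1.0
        dvh = make_dvh(doses, volumes)
        _, dv = differential_volumes(dvh)
        assert dv.sum() == pytest.approx(dvh.total_volume, rel=1e-9)


class TestMADD:
    def test_zero_for_all_volume_at_reference(self):
        dvh = make_dvh([42.0], [1.0])
        assert madd(dvh, ReferenceDose(42.0)) == 0.0

    def test_reduces_to_mean_dose_at_zero_reference(self):
        # half the volume at 10%, half at 30% -> mean dose 20%
        dvh = make_dvh([10.0, 30.0], [1.0, 0.5])
        assert madd(dvh, ReferenceDose(0.0)) == pytest.approx(20.0)
        assert mean_dose(dvh) == pytest.approx(20.0)

    def test_voxel_oracle(self, rng):
        """DVH-path MADD equals the voxel-level mean |D - A| within one grid width."""
        grid = 0.1
        voxels = np.concatenate([
            rng.normal(95.0, 6.0, 800).clip(0),
            rng.exponential(2.0, 9200),
        ])
        dvh = dvh_from_voxels(voxels, grid=grid)
        for a in (0.0, 7.5, 100.0):
            oracle = np.abs(voxels - a).mean()
            assert madd(dvh, ReferenceDose(a)) == pytest.approx(oracle, abs=grid)

    def test_unit_mismatch_rejected(self):
        dvh = make_dvh([10.0], [1.0], unit=GY)
        with pytest.raises(UnitError):
            madd(dvh, ReferenceDose(0.0, PERCENT))

    def test_zero_volume_structure_rejected(self):
        dvh = StructureDVH("heart", "OAR", np.array([1.0]), np.array([0.0]),
                           total_volume=0.0)
        with pytest.raises(DegenerateStructureError):
            madd(dvh, ReferenceDose(0.0))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.0, max_value=120.0),
        st.floats(min_value=0.0, max_value=120.0),
    )
    def test_scale_equivariance_and_translation_bound(self, seed, k, a1, a2):
        r = np.random.default_rng(seed)
        doses = np.unique(np.round(r.uniform(0, 110, 20), 4))
        volumes = np.sort(r.uniform(0, 1, doses.size))[::-1]
        volumes[0] = 1.0
        dvh = make_dvh(doses, volumes)
        m1 = madd(dvh, ReferenceDose(a1))
        # scaling doses and reference by k scales the deviation by k
        scaled = make_dvh(doses * k, volumes)
        assert madd(scaled, ReferenceDose(a1 * k)) == pytest.approx(k * m1, rel=1e-9)
        # moving the reference by d moves the deviation by at most d
        m2 = madd(dvh, ReferenceDose(a2))
        assert abs(m1 - m2) <= abs(a1 - a2) + 1e-9

    def test_volume_unit_independence(self, rng):
        doses = np.unique(np.round(rng.uniform(0, 110, 25), 4))
        fractions = np.sort(rng.uniform(0, 1, doses.size))[::-1]
        fractions[0] = 1.0
        v0_ml = 731.4
        as_fraction = make_dvh(doses, fractions, total=1.0)
        as_ml = make_dvh(doses, fractions * v0_ml, total=v0_ml, vol_unit=ML)
        a = ReferenceDose(17.0)
        assert madd(as_ml, a) == pytest.approx(madd(as_fraction, a), rel=1e-12)


class TestIO:
    def test_csv_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "dvhs.csv"
        write_dvh_csv(small_cohort.dvhs, path)
        loaded, unit = read_dvh_csv(path)
        assert unit == PERCENT
        assert set(loaded) == set(small_cohort.dvhs)
        key = next(iter(loaded))
        for name, dvh in loaded[key].items():
            orig = small_cohort.dvhs[key][name]
            np.testing.assert_allclose(dvh.doses, orig.doses)
            np.testing.assert_allclose(dvh.volumes, orig.volumes)

    def test_tps_export_parser_handles_absolute_and_relative_volumes(self):
        text = """
Patient: anonymous
Structure: heart
Dose [Gy]  Volume [mL]
0.0    461.0
10.0   50.0
20.0   1.0

Structure: breast_left
Dose [Gy]  Ratio of Total Structure Volume [%]
0.0    100.0
40.0   98.0
47.25  50.0
"""
        parsed = read_tps_export(io.StringIO(text))
        assert parsed["heart"].volume_unit == ML
        assert parsed["heart"].total_volume == pytest.approx(461.0)
        assert parsed["breast_left"].volume_unit == FRACTION
        assert parsed["breast_left"].volumes[0] == pytest.approx(1.0)
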