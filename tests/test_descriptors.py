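import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rollcompact.descriptors import (
    DESCRIPTOR_COLUMNS, InvalidMeasurementError, PowderRawMeasurements,
    PSDHistogram, angle_of_repose, bulk_and_tapped_density, compute_descriptors,
    homogeneity_index, hygroscopicity, packing_indices, powder_solid_fraction,
    psd_summary, true_density,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestDensities:
    @pytest.mark.parametrize("m,va,vc,expected", [
        (100.0, 200.0, 160.0, (0.500, 0.625)),
        (100.0, 150.0, 150.0, (100 / 150, 100 / 150)),  # no tap consolidation
    ])
    def test_bulk_and_tapped(self, m, va, vc, expected):
        da, dc = bulk_and_tapped_density(m, va, vc)
        assert da == pytest.approx(expected[0])
        assert dc == pytest.approx(expected[1])
        assert dc >= da

    @pytest.mark.parametrize("m,va,vc", [(0, 100, 80), (10, 0, 0), (10, 80, 100)])
    def test_degenerate_inputs_rejected(self, m, va, vc):
        with pytest.raises(InvalidMeasurementError):
            bulk_and_tapped_density(m, va, vc)

    def test_true_density(self):
        assert true_density(3.0, 10.0, 8.0) == pytest.approx(1.5)
        with pytest.raises(InvalidMeasurementError):
            true_density(3.0, 8.0, 10.0)


class TestPackingIndices:
    def test_hand_example(self):
        ie, ic, ih = packing_indices(0.500, 0.625)
        assert ie == pytest.approx(0.400)
        assert ic == pytest.approx(20.0)
        assert ih == pytest.approx(1.25)

    def test_identical_densities(self):
        assert packing_indices(0.7, 0.7) == pytest.approx((0.0, 0.0, 1.0))

    def test_zero_divisor_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            packing_indices(0.0, 0.5)
        with pytest.raises(InvalidMeasurementError):
            packing_indices(0.8, 0.5)  # tapped below bulk

    @given(da=st.floats(0.05, 2.0), rel=st.floats(1.0, 2.0), c=st.floats(0.1, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_carr_hausner_scale_invariant_and_consistent(self, da, rel, c):
        """IC and IH ignore a common density rescaling; IC = 100(1 - 1/IH)."""
        dc = da * rel
        _, ic1, ih1 = packing_indices(da, dc)
        _, ic2, ih2 = packing_indices(c * da, c * dc)
        assert ic1 == pytest.approx(ic2, abs=1e-9)
        assert ih1 == pytest.approx(ih2, rel=1e-12)
        assert abs(ic1 - 100.0 * (1.0 - 1.0 / ih1)) < 1e-12 * 100
        assert ih1 >= 1.0 and ic1 >= 0.0


class TestFlowAndMoisture:
    @pytest.mark.parametrize("h,r,expected", [
        (50.0, 100.0, 45.0),          # tan = 1
        (0.0, 50.0, 0.0),             # flat pile
        (25.0, 100.0, math.degrees(math.atan(0.5))),
    ])
    def test_angle_of_repose(self, h, r, expected):
        assert angle_of_repose(h, r) == pytest.approx(expected)
        assert 0.0 <= angle_of_repose(h, r) < 90.0

    def test_angle_of_repose_bad_cone(self):
        with pytest.raises(InvalidMeasurementError):
            angle_of_repose(10.0, 0.0)

    def test_hygroscopicity(self):
        assert hygroscopicity(10.0, 11.0, 11.2) == pytest.approx(20.0)
        assert hygroscopicity(10.0, 11.0, 11.0) == 0.0
        assert hygroscopicity(10.0, 11.0, 10.9) < 0  # mass loss allowed
        with pytest.raises(InvalidMeasurementError):
            hygroscopicity(10.0, 10.0, 11.0)


class TestSolidFraction:
    def test_hand_example(self):
        sfp, eps = powder_solid_fraction(0.5, 1.5)
        assert sfp == pytest.approx(1 / 3)
        assert eps == pytest.approx(2 / 3)

    def test_fully_dense(self):
        assert powder_solid_fraction(1.5, 1.5) == (1.0, 0.0)

    def test_inconsistent_density_warns_not_clamps(self):
        with pytest.warns(UserWarning):
            sfp, eps = powder_solid_fraction(2.0, 1.5)
        assert sfp > 1.0 and eps < 0.0  # audit trail preserved

    @given(da=st.floats(0.01, 3.0), dt=st.floats(0.01, 3.0))
    @settings(max_examples=100, derandomize=True)
    def test_partition_of_unity(self, da, dt):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sfp, eps = powder_solid_fraction(da, dt)
        assert sfp + eps == 1.0  # exact, not approximate


class TestPSD:
    def test_span(self, simple_psd):
        psd = PSDHistogram(simple_psd.bin_edges, simple_psd.frequency, 10.0, 50.0, 150.0)
        span, _ = psd_summary(psd)
        assert span == pytest.approx(2.8)

    def test_monodisperse_span_zero(self, simple_psd):
        psd = PSDHistogram(simple_psd.bin_edges, simple_psd.frequency, 80.0, 80.0, 80.0)
        assert psd_summary(psd)[0] == 0.0

    def test_fines_interpolated_on_cumulative_curve(self, simple_psd):
        # cumulative curve hits 30% exactly at the 50 um edge
        _, pf = psd_summary(simple_psd)
        assert pf == pytest.approx(30.0)

    def test_all_fines(self):
        psd = PSDHistogram(np.array([0.0, 20.0, 40.0]), np.array([60.0, 40.0]),
                           5.0, 15.0, 35.0)
        assert psd_summary(psd)[1] == pytest.approx(100.0)

    def test_invalid_histograms_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            PSDHistogram(np.array([0.0, 10.0]), np.array([90.0]), 1, 2, 3)  # sum != 100
        with pytest.raises(InvalidMeasurementError):
            PSDHistogram(np.array([0.0, 10.0, 5.0]), np.array([50.0, 50.0]), 1, 2, 3)


class TestHomogeneityIndex:
    def test_single_bin_is_unity(self):
        psd = PSDHistogram(np.array([0.0, 50.0, 100.0, 150.0]),
                           np.array([0.0, 100.0, 0.0]), 60, 75, 90)
        assert homogeneity_index(psd) == pytest.approx(1.0)

    def test_two_equal_bins_tie_takes_smaller_diameter(self):
        # bins mean diameters 5 and 15; majority = lower bin; the literal
        # neighbor-weighted sum gives 50/(100 + (15-5)*50)
        psd = PSDHistogram(np.array([0.0, 10.0, 20.0, 30.0]),
                           np.array([50.0, 50.0, 0.0]), 3, 10, 17)
        assert homogeneity_index(psd) == pytest.approx(50.0 / 600.0)

    def test_spreading_mass_decreases_index(self):
        edges = np.linspace(0, 120, 7)
        base = np.array([0.0, 0.0, 100.0, 0.0, 0.0, 0.0])
        vals = []
        for moved in (0.0, 10.0, 20.0, 30.0):
            f = base.copy()
            f[2] -= moved
            f[4] += moved  # move mass two bins away, fixed total
            psd = PSDHistogram(edges, f, 30, 50, 70)
            vals.append(homogeneity_index(psd))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_farther_bins_penalized_more(self):
        edges = np.linspace(0, 120, 7)
        near = np.array([0.0, 10.0, 90.0, 0.0, 0.0, 0.0])
        far = np.array([10.0, 0.0, 90.0, 0.0, 0.0, 0.0])
        mk = lambda f: PSDHistogram(edges, f, 30, 50, 70)
        assert homogeneity_index(mk(near)) > homogeneity_index(mk(far))


class TestDescriptorVector:
    def _raw(self, simple_psd):
        return PowderRawMeasurements(
            sample_mass=100.0, bulk_volume=200.0, tapped_volume=160.0,
            tablet_hardness=120.0, cone_height=25.0, cone_diameter=100.0,
            flow_time=12.0, moisture_loss_pct=3.5,
            hygro_weights=(10.0, 11.0, 11.2),
            true_density_mass=3.0, true_density_volumes=(10.0, 8.0),
            psd=simple_psd, cohesiveness=0.4, springiness=0.3,
            springiness_coeff=0.6,
        )

    def test_full_vector(self, simple_psd):
        vec = compute_descriptors(self._raw(simple_psd))
        assert set(vec) == set(DESCRIPTOR_COLUMNS)
        assert vec["Da"] == pytest.approx(0.5)
        assert vec["Dt"] == pytest.approx(1.5)
        assert vec["SFp"] + vec["epsP"] == 1.0
        assert vec["IC"] == pytest.approx(20.0)
        assert vec["Hpct"] == pytest.approx(20.0)
        # measured-only descriptors pass through unchanged
        assert vec["Icd"] == 120.0 and vec["tflow"] == 12.0 and vec["Co"] == 0.4

    def test_csv_round_trip_at_6_digits(self, simple_psd, tmp_path):
        vec = compute_descriptors(self._raw(simple_psd))
        df = pd.DataFrame([vec])
        path = tmp_path / "desc.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        back = pd.read_csv(path).astype(float)
        df6 = df.map(lambda v: float(f"{v:.6g}"))
        pd.testing.assert_frame_equal(back, df6, check_exact=True)
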