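import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tldose.calibration import CalibrationCurve
from tldose.dose import (
    DoseError,
    GroupKermaStat,
    MassEnergyCoefficientSet,
    PipelineConfig,
    SliceKerma,
    group_stats,
    load_coefficients,
    organ_dose,
    run_pipeline,
    slice_dose,
    slice_weighted_kerma,
)
from tldose.phantom import FractionRow, OrganFractionTable
from tldose.synth import NoiseModel, TruthScenario, generate_readings


def gstat(mean, var, slc=1, gid="g"):
    return GroupKermaStat(group_id=gid, slice_index=slc, mean_kerma=mean, variance=var, n_chips=3)


class TestGroupStats:
    def test_identical_chips_floored(self):
        stat = group_stats([1.0, 1.0, 1.0], variance_floor_frac=0.01)
        assert stat.mean_kerma == 1.0
        assert stat.floored
        assert stat.variance == pytest.approx((0.01 * 1.0) ** 2)

    def test_sample_variance_hand_oracle(self):
        # var of (0.9, 1.0, 1.1) = (0.01 + 0 + 0.01)/2 = 0.01
        stat = group_stats([0.9, 1.0, 1.1])
        assert stat.mean_kerma == pytest.approx(1.0)
        assert stat.variance == pytest.approx(0.01)
        assert not stat.floored

    def test_single_value_uses_floor(self):
        stat = group_stats([2.0], variance_floor_frac=0.01)
        assert stat.mean_kerma == 2.0
        assert stat.variance == pytest.approx((0.01 * 2.0) ** 2)
        assert stat.floored

    def test_empty_group_rejected(self):
        with pytest.raises(DoseError):
            group_stats([])


class TestSliceWeightedKerma:
    def test_two_group_hand_oracle(self):
        # (100*1 + 25*2) / 125 = 1.2; var = 1/125
        sk = slice_weighted_kerma([gstat(1.0, 0.01), gstat(2.0, 0.04)])
        assert sk.kerma == pytest.approx(1.2, rel=1e-12)
        assert sk.variance == pytest.approx(1.0 / 125.0, rel=1e-12)

    def test_single_group_identity(self):
        sk = slice_weighted_kerma([gstat(3.0, 0.02)])
        assert sk.kerma == 3.0
        assert sk.variance == pytest.approx(0.02)

    def test_mixed_slices_rejected(self):
        with pytest.raises(DoseError, match="slices"):
            slice_weighted_kerma([gstat(1.0, 0.01, slc=1), gstat(1.0, 0.01, slc=2)])

    def test_zero_variance_rejected(self):
        with pytest.raises(DoseError, match="positive"):
            slice_weighted_kerma([gstat(1.0, 0.0)])

    def test_empty_rejected(self):
        with pytest.raises(DoseError):
            slice_weighted_kerma([])

    @given(
        means=st.lists(st.floats(0.1, 100), min_size=2, max_size=8),
        var=st.floats(1e-4, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_equal_variances_reduce_to_arithmetic_mean(self, means, var):
        groups = [gstat(m, var, gid=f"g{i}") for i, m in enumerate(means)]
        sk = slice_weighted_kerma(groups)
        assert sk.kerma == pytest.approx(float(np.mean(means)), rel=1e-9)

    @given(
        stats=st.lists(
            st.tuples(st.floats(0.1, 100), st.floats(1e-6, 10.0)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_convexity(self, stats):
        groups = [gstat(m, v, gid=f"g{i}") for i, (m, v) in enumerate(stats)]
        sk = slice_weighted_kerma(groups)
        means = [g.mean_kerma for g in groups]
        assert min(means) - 1e-9 <= sk.kerma <= max(means) + 1e-9

    @given(
        stats=st.lists(
            st.tuples(st.floats(0.1, 100), st.floats(1e-6, 10.0)),
            min_size=2,
            max_size=6,
        ),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, stats, seed):
        groups = [gstat(m, v, gid=f"g{i}") for i, (m, v) in enumerate(stats)]
        shuffled = list(groups)
        np.random.default_rng(seed).shuffle(shuffled)
        a = slice_weighted_kerma(groups)
        b = slice_weighted_kerma(shuffled)
        assert a.kerma == pytest.approx(b.kerma, rel=1e-12)
        assert a.variance == pytest.approx(b.variance, rel=1e-12)

    @given(
        stats=st.lists(
            st.tuples(st.floats(0.1, 100), st.floats(1e-6, 10.0)),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_naive_summation_oracle(self, stats):
        """Independent oracle: plain-Python loop over the defining formula."""
        groups = [gstat(m, v, gid=f"g{i}") for i, (m, v) in enumerate(stats)]
        num = 0.0
        den = 0.0
        for m, v in stats:
            num += m / v
            den += 1.0 / v
        sk = slice_weighted_kerma(groups)
        assert sk.kerma == pytest.approx(num / den, rel=1e-12)
        assert sk.variance == pytest.approx(1.0 / den, rel=1e-12)


class TestSliceDose:
    def test_lung_120kv_hand_oracle(self, coeffs_120):
        d, var = slice_dose(SliceKerma(1, 10.0, 0.0), coeffs_120["lung"])
        assert d == pytest.approx(10.0 * 0.0365 / 0.0339, rel=1e-12)
        assert d == pytest.approx(10.767, abs=5e-4)

    def test_thyroid_80kv_hand_oracle(self, coeffs_80):
        d, _ = slice_dose(SliceKerma(1, 10.0, 0.0), coeffs_80["thyroid"])
        assert d == pytest.approx(10.0 * 0.0610 / 0.0521, rel=1e-12)
        assert d == pytest.approx(11.708, abs=5e-4)

    def test_zero_kerma(self, coeffs_120):
        d, var = slice_dose(SliceKerma(1, 0.0, 0.0), coeffs_120["lung"])
        assert d == 0.0 and var == 0.0

    def test_variance_scales_by_ratio_squared(self, coeffs_120):
        ratio = coeffs_120["lung"].ratio
        _, var = slice_dose(SliceKerma(1, 5.0, 0.04), coeffs_120["lung"])
        assert var == pytest.approx(0.04 * ratio**2, rel=1e-12)

    def test_organ_mismatch_rejected(self, coeffs_120):
        with pytest.raises(DoseError, match="organ"):
            slice_dose(SliceKerma(1, 1.0, 0.0), coeffs_120["lung"], organ="thyroid")

    def test_voltage_mismatch_rejected(self, coeffs_120):
        with pytest.raises(DoseError, match="kV"):
            slice_dose(SliceKerma(1, 1.0, 0.0), coeffs_120["lung"], tube_voltage="80")


class TestCoefficients:
    def test_packaged_values(self, coeffs_120, coeffs_80):
        assert coeffs_120["lung"].mu_en_rho_organ == 0.0365
        assert coeffs_120["thyroid"].mu_en_rho_organ == 0.0402
        assert coeffs_120["lung"].mu_en_rho_air == 0.0339
        assert coeffs_80["lung"].mu_en_rho_organ == 0.0557
        assert coeffs_80["thyroid"].mu_en_rho_organ == 0.0610
        assert coeffs_80["thyroid"].mu_en_rho_air == 0.0521

    def test_unknown_voltage(self):
        with pytest.raises(DoseError, match="140"):
            load_coefficients(140)

    def test_nonpositive_coefficient_rejected(self):
        with pytest.raises(DoseError):
            MassEnergyCoefficientSet("120", "lung", 0.0, 0.03)


def two_slice_table():
    return OrganFractionTable(
        phantom_id="t",
        organ="lung",
        rows=[FractionRow(1, 0.4, 1), FractionRow(2, 0.6, 1)],
    )


class TestOrganDose:
    def test_weighted_sum_hand_oracle(self):
        result = organ_dose({1: (10.0, 0.0), 2: (20.0, 0.0)}, two_slice_table())
        assert result.dose == pytest.approx(16.0, rel=1e-12)

    def test_uniform_dose_is_identity(self, adult_layout):
        table = adult_layout.tables["lung"]
        per_slice = {r.slice_index: (7.5, 0.0) for r in table.rows}
        result = organ_dose(per_slice, table)
        assert result.dose == pytest.approx(7.5, rel=1e-12)

    def test_missing_slice_listed(self, adult_layout):
        table = adult_layout.tables["lung"]
        per_slice = {r.slice_index: (1.0, 0.0) for r in table.rows if r.slice_index != 15}
        with pytest.raises(DoseError, match="15"):
            organ_dose(per_slice, table)

    def test_sigma_from_fraction_weighted_variances(self):
        result = organ_dose({1: (10.0, 4.0), 2: (20.0, 9.0)}, two_slice_table())
        assert result.sigma == pytest.approx(math.sqrt(0.16 * 4.0 + 0.36 * 9.0), rel=1e-12)

    @given(
        doses=st.lists(st.floats(0.0, 50.0), min_size=9, max_size=9),
    )
    @settings(max_examples=50, deadline=None)
    def test_brute_force_summation_oracle(self, doses, adult_layout):
        table = adult_layout.tables["lung"]
        per_slice = {
            r.slice_index: (doses[i], 0.0) for i, r in enumerate(table.rows)
        }
        expected = sum(r.fraction * per_slice[r.slice_index][0] for r in table.rows)
        result = organ_dose(per_slice, table)
        assert result.dose == pytest.approx(expected, abs=1e-12, rel=1e-12)


class TestRunPipeline:
    def _scenario(self, adult_layout, adult_protocols, coeffs_120, curve, dose=14.30):
        coeffs = {"lung": coeffs_120["lung"]}
        return TruthScenario.flat(adult_layout, adult_protocols["STD"], dose, coeffs, curve)

    def test_noise_free_recovery(self, adult_layout, adult_protocols, coeffs_120, exact_curve):
        sc = self._scenario(adult_layout, adult_protocols, coeffs_120, exact_curve)
        readings, bg, truth = generate_readings(
            sc, NoiseModel(chip_cv=0.0, background_tl=100.0, seed=0)
        )
        result = run_pipeline(
            readings, bg, exact_curve, adult_layout, {"lung": coeffs_120["lung"]}
        )
        assert result["lung"].dose == pytest.approx(14.30, rel=1e-12)
        assert truth["organ_doses_mGy"]["lung"] == pytest.approx(14.30)

    def test_missing_slice_error_names_slice(
        self, adult_layout, adult_protocols, coeffs_120, exact_curve
    ):
        sc = self._scenario(adult_layout, adult_protocols, coeffs_120, exact_curve)
        readings, bg, _ = generate_readings(sc, NoiseModel(chip_cv=0.0, seed=0))
        readings = [r for r in readings if r.slice_index != 15]
        with pytest.raises(DoseError, match="15"):
            run_pipeline(readings, bg, exact_curve, adult_layout, {"lung": coeffs_120["lung"]})

    def test_missing_coefficients_rejected(
        self, adult_layout, adult_protocols, coeffs_120, exact_curve
    ):
        sc = self._scenario(adult_layout, adult_protocols, coeffs_120, exact_curve)
        readings, bg, _ = generate_readings(sc, NoiseModel(chip_cv=0.0, seed=0))
        with pytest.raises(DoseError, match="coefficient"):
            run_pipeline(readings, bg, exact_curve, adult_layout, {})

    def test_linearity_dose_and_sigma_double(
        self, adult_layout, adult_protocols, coeffs_120, exact_curve
    ):
        coeffs = {"lung": coeffs_120["lung"]}
        noise = NoiseModel(chip_cv=0.05, seed=11)
        sc1 = self._scenario(adult_layout, adult_protocols, coeffs_120, exact_curve, dose=5.0)
        sc2 = self._scenario(adult_layout, adult_protocols, coeffs_120, exact_curve, dose=10.0)
        r1, b1, _ = generate_readings(sc1, noise)
        r2, b2, _ = generate_readings(sc2, noise)
        res1 = run_pipeline(r1, b1, exact_curve, adult_layout, coeffs)
        res2 = run_pipeline(r2, b2, exact_curve, adult_layout, coeffs)
        # same seed => identical relative noise => strict scaling
        assert res2["lung"].dose == pytest.approx(2 * res1["lung"].dose, rel=1e-9)
        assert res2["lung"].sigma == pytest.approx(2 * res1["lung"].sigma, rel=1e-9)

    def test_two_sigma_coverage_over_replicates(
        self, adult_layout, adult_protocols, coeffs_120, exact_curve
    ):
        coeffs = {"lung": coeffs_120["lung"]}
        sc = self._scenario(adult_layout, adult_protocols, coeffs_120, exact_curve)
        hits = 0
        n = 60
        for seed in range(n):
            noise = NoiseModel(chip_cv=0.05, background_tl=100.0, background_cv=0.02, seed=seed)
            readings, bg, _ = generate_readings(sc, noise)
            res = run_pipeline(readings, bg, exact_curve, adult_layout, coeffs)
            if abs(res["lung"].dose - 14.30) <= 2 * res["lung"].sigma:
                hits += 1
        # ~95% nominal with a generous allowance for the small sample
        assert hits / n >= 0.85

    def test_provenance_records_all_slices(
        self, adult_layout, adult_protocols, coeffs_120, exact_curve
    ):
        sc = self._scenario(adult_layout, adult_protocols, coeffs_120, exact_curve)
        readings, bg, _ = generate_readings(sc, NoiseModel(chip_cv=0.02, seed=3))
        res = run_pipeline(readings, bg, exact_curve, adult_layout, {"lung": coeffs_120["lung"]})
        slices = res.provenance["organs"]["lung"]["slices"]
        assert [s["slice"] for s in slices] == list(range(11, 20))
        assert sum(len(s["groups"]) for s in slices) == 40

    def test_pediatric_two_organs(
        self, pediatric_layout, pediatric_protocols, coeffs_120, exact_curve
    ):
        coeffs = {"lung": coeffs_120["lung"], "thyroid": coeffs_120["thyroid"]}
        sc = TruthScenario.flat(
            pediatric_layout,
            pediatric_protocols["PED120"],
            {"lung": 6.12, "thyroid": 6.84},
            coeffs,
            exact_curve,
        )
        readings, bg, _ = generate_readings(sc, NoiseModel(chip_cv=0.0, seed=0))
        res = run_pipeline(readings, bg, exact_curve, pediatric_layout, coeffs)
        assert res["lung"].dose == pytest.approx(6.12, rel=1e-12)
        assert res["thyroid"].dose == pytest.approx(6.84, rel=1e-12)
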