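"""Standard-curve efficiency fitting and ddCt relative quantification."""

import numpy as np
import pandas as pd
import pytest

from refstab.errors import (
    InputValidationError,
    InsufficientDataError,
    InvalidCurveError,
)
from refstab.quant import (
    fit_standard_curve,
    normalization_factor,
    relative_expression,
)
from refstab.simulate import generate_dilution_series

from conftest import make_ct


class TestStandardCurve:
    def test_perfect_doubling_slope(self):
        x, y = generate_dilution_series(amplification_factor=2.0, n_points=5)
        fit = fit_standard_curve(x, y)
        assert fit.slope == pytest.approx(-1 / np.log10(2), abs=1e-9)
        assert fit.efficiency_percent == pytest.approx(100.0, abs=1e-9)
        assert fit.amplification_factor == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_minus_3_45_gives_94_9_percent(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        y = 20.0 - 3.45 * x
        fit = fit_standard_curve(x, y)
        assert fit.efficiency_percent == pytest.approx(94.9, abs=0.05)

    def test_generator_inverse_recovers_factor_exactly(self):
        x, y = generate_dilution_series(amplification_factor=1.95, n_points=6)
        fit = fit_standard_curve(x, y)
        assert fit.efficiency_percent == pytest.approx(95.0, abs=1e-9)

    def test_positive_slope_rejected(self):
        with pytest.raises(InvalidCurveError):
            fit_standard_curve([0, -1, -2], [20, 23, 26][::-1])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_standard_curve([0, -1], [20, 23])


class TestNormalizationFactor:
    def test_single_rg_is_its_quantity_row(self):
        ct = make_ct([[20, 21, 22]], genes=["R"])
        nf = normalization_factor(ct, ["R"])
        np.testing.assert_allclose(nf.to_numpy(), [1, 0.5, 0.25])

    def test_two_identical_rgs_equal_either_row(self):
        ct = make_ct([[20, 21, 22], [20, 21, 22]], genes=["R1", "R2"])
        nf = normalization_factor(ct, ["R1", "R2"])
        np.testing.assert_allclose(nf.to_numpy(), [1, 0.5, 0.25])

    def test_geometric_mean_of_two_rgs(self):
        # quantities A (1, .5, .25) and C (1, 1, .5)
        ct = make_ct([[20, 21, 22], [20, 20, 21]], genes=["A", "C"])
        nf = normalization_factor(ct, ["A", "C"])
        np.testing.assert_allclose(
            nf.to_numpy(), [1.0, np.sqrt(0.5), np.sqrt(0.125)], rtol=1e-12
        )

    def test_unknown_rg_rejected(self):
        ct = make_ct([[20, 21, 22]], genes=["R"])
        with pytest.raises(InputValidationError, match="X"):
            normalization_factor(ct, ["X"])


class TestRelativeExpression:
    def test_target_covarying_with_rg_gives_unit_folds(self):
        ct = make_ct([[20, 21, 22]], genes=["R"])
        nf = normalization_factor(ct, ["R"])
        target = pd.Series([23.0, 24.0, 25.0], index=["S1", "S2", "S3"])
        res = relative_expression(target, nf, calibrator=["S1"])
        np.testing.assert_allclose(res.fold_change.to_numpy(), 1.0, rtol=1e-12)

    def test_one_cycle_shift_in_treated_doubles_fold(self):
        samples = ["C1", "C2", "T1", "T2"]
        rg = make_ct([[20, 20, 20, 20]], genes=["R"], samples=samples)
        nf = normalization_factor(rg, ["R"])
        target = pd.Series([25, 25, 24, 24], index=samples, dtype=float)
        res = relative_expression(target, nf, calibrator=["C1", "C2"])
        np.testing.assert_allclose(res.fold_change[["T1", "T2"]], 2.0,
                                   rtol=1e-12)
        np.testing.assert_allclose(res.fold_change[["C1", "C2"]].mean(), 1.0,
                                   rtol=1e-12)

    def test_fold_changes_invariant_to_per_sample_rescaling(self, rng):
        values = rng.uniform(18, 28, size=(3, 8))
        target_row = rng.uniform(22, 30, size=8)
        samples = [f"S{j}" for j in range(8)]
        genes = ["R1", "R2", "R3"]
        ct = make_ct(values, genes=genes, samples=samples)
        target = pd.Series(target_row, index=samples)
        base = relative_expression(
            target, normalization_factor(ct, genes), calibrator=samples[:3]
        )
        loading = rng.normal(0, 1.5, size=8)  # cycles added to every gene
        ct2 = make_ct(values + loading[None, :], genes=genes, samples=samples)
        shifted = relative_expression(
            target + loading, normalization_factor(ct2, genes),
            calibrator=samples[:3],
        )
        np.testing.assert_allclose(base.fold_change.to_numpy(),
                                   shifted.fold_change.to_numpy(), rtol=1e-9)

    def test_unstable_rg_biases_fold_by_its_programmed_shift(self):
        # an RG shifted down by s cycles in treated inflates NF by 2^s there,
        # deflating the apparent fold by exactly 2^-s (here s=1 -> fold 0.5)
        samples = ["C1", "C2", "T1", "T2"]
        stable = make_ct([[20, 20, 20, 20]], genes=["R"], samples=samples)
        bad = make_ct([[20, 20, 19, 19]], genes=["R"], samples=samples)
        target = pd.Series([25, 25, 25, 25], index=samples, dtype=float)
        good = relative_expression(
            target, normalization_factor(stable, ["R"]), calibrator=["C1", "C2"]
        )
        biased = relative_expression(
            target, normalization_factor(bad, ["R"]), calibrator=["C1", "C2"]
        )
        np.testing.assert_allclose(good.fold_change[["T1", "T2"]], 1.0,
                                   rtol=1e-12)
        np.testing.assert_allclose(biased.fold_change[["T1", "T2"]], 0.5,
                                   rtol=1e-12)

    def test_geometric_calibrator_aggregation(self):
        samples = ["C1", "C2", "T1"]
        rg = make_ct([[20, 20, 20]], genes=["R"], samples=samples)
        nf = normalization_factor(rg, ["R"])
        target = pd.Series([24.0, 26.0, 25.0], index=samples)
        res = relative_expression(target, nf, calibrator=["C1", "C2"],
                                  aggregation="geometric")
        # geometric mean of calibrator ratios -> calibrator geomean fold = 1
        assert np.exp(np.log(res.fold_change[["C1", "C2"]]).mean()) == \
            pytest.approx(1.0, rel=1e-12)

    def test_missing_calibrator_sample_rejected(self):
        rg = make_ct([[20, 21]], genes=["R"])
        nf = normalization_factor(rg, ["R"])
        target = pd.Series([22.0, 23.0], index=["S1", "S2"])
        with pytest.raises(InputValidationError, match="S9"):
            relative_expression(target, nf, calibrator=["S9"])

    def test_programmed_upregulation_recovered_under_multi_rg(self, rng):
        # 3 stage groups; target 4x up (2 cycles down) in stage 3
        samples = [f"st{g}_r{r}" for g in (1, 2, 3) for r in (1, 2, 3)]
        rgs = ["R1", "R2"]
        base = rng.uniform(20, 24, size=(2, 1))
        loading = rng.normal(0, 0.3, size=9)
        noise = rng.normal(0, 0.05, size=(2, 9))
        ct = make_ct(base + loading[None, :] + noise, genes=rgs,
                     samples=samples)
        target_base = 26.0 + loading + rng.normal(0, 0.05, 9)
        target_base[6:] -= 2.0  # stage 3: 4-fold up
        target = pd.Series(target_base, index=samples)
        res = relative_expression(
            target, normalization_factor(ct, rgs), calibrator=samples[:3]
        )
        stage3 = res.fold_change[samples[6:]].mean()
        assert stage3 == pytest.approx(4.0, rel=0.15)
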