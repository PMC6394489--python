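"""Covariate model and parameter container behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trastupk as tp
from trastupk.parameters import (REFERENCE_ALBU, REFERENCE_SGOT,
                                 REFERENCE_WT, TumorType)


class TestLinearClearance:
    @pytest.mark.parametrize("tumor, expected", [
        ("MBC", 0.127), ("EBC", 0.127), ("HV", 0.127),
        ("AGC", 0.176), ("OTHER", 0.148),
    ])
    def test_typical_by_tumor_type(self, pp, tumor, expected):
        cov = tp.CovariateVector(tumor_type=tumor)
        assert tp.linear_clearance(cov, pp) == pytest.approx(expected)

    def test_albumin_effect_published_magnitude(self, pp):
        """Albumin 4.7 g/dL lowers linear CL by 14.9% vs the reference."""
        ref = tp.linear_clearance(tp.TYPICAL_BC, pp)
        hi = tp.linear_clearance(tp.CovariateVector(albu=4.7), pp)
        assert hi / ref == pytest.approx((4.7 / 4.0) ** -0.998)
        assert 100 * (1 - hi / ref) == pytest.approx(14.9, abs=0.05)

    def test_weight_proportionality_with_unit_exponent(self, pp):
        pp1 = pp.replace(wt_exp=1.0)
        ref = tp.linear_clearance(tp.CovariateVector(wt=66.0), pp1)
        dbl = tp.linear_clearance(tp.CovariateVector(wt=132.0), pp1)
        assert dbl == pytest.approx(2.0 * ref)

    def test_monotone_in_covariates(self, pp):
        ref = tp.linear_clearance(tp.TYPICAL_BC, pp)
        assert tp.linear_clearance(tp.CovariateVector(wt=80), pp) > ref
        assert tp.linear_clearance(tp.CovariateVector(sgot=40), pp) > ref
        assert tp.linear_clearance(tp.CovariateVector(albu=4.5), pp) < ref
        assert tp.linear_clearance(tp.CovariateVector(lmet=True), pp) > ref

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(wt=st.floats(30, 150), sgot=st.floats(5, 200),
           albu=st.floats(1.5, 6.0))
    def test_multiplicative_joint_equals_product_of_ratios(self, wt, sgot,
                                                           albu):
        """Joint covariate changes factor into individual ratios."""
        pp = tp.PopulationParameters()
        ref = tp.linear_clearance(tp.TYPICAL_BC, pp)
        joint = tp.linear_clearance(
            tp.CovariateVector(wt=wt, sgot=sgot, albu=albu), pp) / ref
        parts = (tp.linear_clearance(tp.CovariateVector(wt=wt), pp) / ref
                 * tp.linear_clearance(tp.CovariateVector(sgot=sgot), pp) / ref
                 * tp.linear_clearance(tp.CovariateVector(albu=albu), pp) / ref)
        assert joint == pytest.approx(parts, rel=1e-12)

    def test_rejects_bad_inputs(self, pp):
        with pytest.raises(ValueError, match="strictly positive"):
            tp.CovariateVector(wt=-1.0)
        with pytest.raises(ValueError, match="tumor type"):
            tp.CovariateVector(tumor_type="LUNG")


class TestCentralVolume:
    def test_typical_values(self, pp):
        assert tp.central_volume(tp.TYPICAL_BC, pp) == pytest.approx(2.62)
        assert tp.central_volume(tp.TYPICAL_AGC, pp) == pytest.approx(3.63)

    def test_lognormal_random_effect(self, pp):
        v = tp.central_volume(tp.TYPICAL_BC, pp, eta_vc=math.log(2))
        assert v == pytest.approx(5.24)


class TestKmWithShed:
    def test_reference_level_gives_typical_km(self, pp):
        pps = pp.replace(shed_enabled=True)
        assert tp.km_with_shed(pps, 1.0) == pytest.approx(8.92)

    def test_power_law(self, pp):
        pps = pp.replace(shed_enabled=True)
        assert tp.km_with_shed(pps, 2.0) == pytest.approx(8.92 * 2 ** -0.771)

    def test_zero_exponent_removes_dependence(self, pp):
        pps = pp.replace(shed_enabled=True, shed_km_exp=0.0)
        assert tp.km_with_shed(pps, 5.0) == pytest.approx(8.92)

    def test_disabled_or_invalid_rejected(self, pp):
        with pytest.raises(ValueError, match="disabled"):
            tp.km_with_shed(pp, 1.0)
        with pytest.raises(ValueError, match="positive"):
            tp.km_with_shed(pp.replace(shed_enabled=True), 0.0)


class TestTotalClearance:
    def test_published_value_at_cmax(self, typical_bc):
        assert tp.total_clearance_at(182.0, typical_bc) == \
            pytest.approx(0.173, abs=5e-4)

    def test_half_saturation_at_km(self, typical_bc):
        v = tp.total_clearance_at(typical_bc.km, typical_bc)
        assert v == pytest.approx(typical_bc.cl
                                  + typical_bc.vmax / (2 * typical_bc.km))

    def test_limits_and_monotonicity(self, typical_bc):
        lo = typical_bc.cl
        hi = typical_bc.cl + typical_bc.vmax / typical_bc.km
        grid = np.logspace(-3, 6, 40)
        vals = [tp.total_clearance_at(c, typical_bc) for c in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(lo < v <= hi for v in vals)
        assert tp.total_clearance_at(1e9, typical_bc) == pytest.approx(lo, rel=1e-4)
        with pytest.raises(ValueError):
            tp.total_clearance_at(-1.0, typical_bc)


class TestContainers:
    def test_missing_covariates_imputed_to_reference(self):
        cov = tp.CovariateVector()
        assert (cov.wt, cov.sgot, cov.albu) == \
            (REFERENCE_WT, REFERENCE_SGOT, REFERENCE_ALBU)
        assert cov.lmet is False and cov.tumor_type is TumorType.MBC

    def test_typical_subject_from_reference_covariates(self, pp, typical_bc):
        assert (typical_bc.cl, typical_bc.vc, typical_bc.q, typical_bc.vp,
                typical_bc.vmax, typical_bc.km) == \
            (0.127, 2.62, 0.544, 2.97, 8.81, 8.92)

    def test_omega_matrix_structure(self, pp):
        om = pp.omega_matrix()
        assert om[0, 1] == om[1, 0] == 0.0230
        assert np.all(np.linalg.eigvalsh(om) > 0)
        assert om[2, 3] == 0.0

    def test_invalid_parameters_rejected(self, pp):
        with pytest.raises(ValueError):
            pp.replace(km=-1.0)
        with pytest.raises(ValueError):
            pp.replace(omega_cl_vc_cov=1.0)  # would break PSD

    def test_default_yaml_matches_code_defaults(self, pp, tmp_path):
        loaded = tp.load_default_parameters()
        assert loaded == pp
        path = tmp_path / "params.yaml"
        tp.parameters_to_yaml(pp.replace(km=5.0), path)
        back = tp.parameters_from_yaml(path)
        assert back.km == 5.0 and back.cl_bc == pp.cl_bc
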