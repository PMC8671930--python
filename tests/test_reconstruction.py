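"""Inversion of the eight sensitivity-analysis reporting media."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import voihbp as v
from voihbp.datamodel import UnivariateRow
from voihbp.errors import InsufficientDataError, ReconstructionError, ReconstructionWarning
from voihbp.fixtures import InterventionTruth, render_payload

Z95 = float(stats.norm.ppf(0.975))


def make_truth(mu_c=100.0, mu_e=2.0, sd_c=50.0, sd_e=0.5, rho=0.0, medium="mean_se"):
    return InterventionTruth("t", "", mu_c, mu_e, sd_c, sd_e, rho, 1000.0, 1.0, medium)


class TestMeanSE:
    def test_identity_mapping(self):
        ju = v.from_mean_se(30.0, 0.2, rho=0.0)
        assert (ju.sd_cost, ju.sd_benefit, ju.correlation) == (30.0, 0.2, 0.0)
        assert ju.family == "bivariate_normal"

    def test_point_mass(self):
        ju = v.from_mean_se(0.0, 0.0, rho=0.0)
        assert ju.sd_cost == 0.0 and ju.sd_benefit == 0.0

    def test_absent_rho_uses_pooled_average(self):
        pooled = v.PooledUncertainty(0.25, 1.0, 1.0, 0.5, 0.5, 2)
        ju = v.from_mean_se(30.0, 0.2, rho=None, pooled=pooled)
        assert ju.correlation == 0.25

    def test_absent_rho_without_pool_warns_and_defaults_zero(self):
        with pytest.warns(ReconstructionWarning):
            ju = v.from_mean_se(30.0, 0.2)
        assert ju.correlation == 0.0

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            v.from_mean_se(-1.0, 0.2, rho=0.0)


class TestMeanCI:
    def test_95pct_interval_width(self):
        # sd = (160 - 40) / (2 * 1.959964)
        ju = v.from_mean_ci((40.0, 160.0), (1.0, 1.0), level=0.95, rho=0.0)
        assert ju.sd_cost == pytest.approx(120.0 / (2 * Z95), rel=1e-9)
        assert ju.sd_cost == pytest.approx(30.61, abs=0.01)

    def test_zero_width_interval_is_degenerate(self):
        ju = v.from_mean_ci((5.0, 5.0), (1.0, 1.0), rho=0.0)
        assert ju.sd_cost == 0.0 and ju.sd_benefit == 0.0

    def test_interquartile_level(self):
        # at level 0.5 the z value is the upper quartile 0.67449
        ju = v.from_mean_ci((-1.0, 1.0), (0.0, 0.0), level=0.50, rho=0.0)
        assert ju.sd_cost == pytest.approx(1.0 / 0.674490, rel=1e-5)

    def test_agrees_with_mean_se_at_matching_width(self):
        sd = 120.0 / (2 * Z95)
        a = v.from_mean_ci((40.0, 160.0), (0.8, 1.2), rho=0.3)
        b = v.from_mean_se(sd, 0.4 / (2 * Z95), rho=0.3)
        assert a.sd_cost == pytest.approx(b.sd_cost, rel=1e-12)
        assert a.sd_benefit == pytest.approx(b.sd_benefit, rel=1e-12)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            v.from_mean_ci((160.0, 40.0), (1.0, 2.0), rho=0.0)


class TestRawPairs:
    def test_hand_computed_sample_moments(self):
        ju = v.from_raw_pairs([(0.0, 0.0), (2.0, 1.0), (4.0, 2.0)])
        assert ju.sd_cost == pytest.approx(2.0)
        assert ju.sd_benefit == pytest.approx(1.0)
        assert ju.correlation == pytest.approx(1.0)

    def test_moment_recovery_from_large_sample(self, rng):
        n = 10_000
        z = rng.standard_normal((2, n))
        dc = 50.0 * z[0]
        de = 0.5 * (-0.3 * z[0] + np.sqrt(1 - 0.09) * z[1])
        ju = v.from_raw_pairs(list(zip(dc, de)))
        assert ju.sd_cost == pytest.approx(50.0, rel=0.05)
        assert ju.sd_benefit == pytest.approx(0.5, rel=0.05)
        assert ju.correlation == pytest.approx(-0.3, abs=0.05)

    def test_constant_margin_degenerates_with_warning(self):
        with pytest.warns(ReconstructionWarning):
            ju = v.from_raw_pairs([(0.0, 1.0), (2.0, 1.0), (4.0, 1.0)])
        assert ju.sd_benefit == 0.0 and ju.correlation == 0.0
        assert "degenerate_margin" in ju.diagnostics

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            v.from_raw_pairs([(0.0, 0.0), (1.0, 1.0)])

    def test_empirical_mode_retains_sample(self):
        pairs = [(0.0, 0.0), (2.0, 1.0), (4.0, 2.0), (1.0, 0.4)]
        ju = v.from_raw_pairs(pairs, mode="empirical")
        assert ju.family == "empirical"
        assert ju.sample.shape == (4, 2)


class TestUnivariateTable:
    def row(self, dc_low, dc_high, de_low, de_high, pid="p1"):
        return UnivariateRow(
            param_id=pid, dc_low=dc_low, dc_high=dc_high, de_low=de_low, de_high=de_high
        )

    def test_single_parameter_closed_form(self):
        ju = v.from_univariate_table([self.row(80.0, 120.0, 0.9, 1.1)])
        assert ju.sd_cost == pytest.approx(40.0 / np.sqrt(12), rel=1e-12)
        assert ju.sd_benefit == pytest.approx(0.2 / np.sqrt(12), rel=1e-12)
        assert ju.correlation == pytest.approx(1.0)

    def test_opposing_movement_gives_negative_unit_correlation(self):
        ju = v.from_univariate_table([self.row(80.0, 120.0, 1.1, 0.9)])
        assert ju.correlation == pytest.approx(-1.0)

    def test_orthogonal_parameters_are_uncorrelated(self):
        ju = v.from_univariate_table(
            [self.row(80.0, 120.0, 1.0, 1.0, "p1"), self.row(100.0, 100.0, 0.9, 1.1, "p2")]
        )
        assert ju.correlation == 0.0
        assert ju.sd_cost == pytest.approx(40.0 / np.sqrt(12), rel=1e-12)
        assert ju.sd_benefit == pytest.approx(0.2 / np.sqrt(12), rel=1e-12)

    def test_interval95_convention(self):
        ju = v.from_univariate_table(
            [self.row(80.0, 120.0, 0.9, 1.1)], range_convention="interval95"
        )
        assert ju.sd_cost == pytest.approx(20.0 / Z95, rel=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            v.from_univariate_table([])


class TestTornadoICER:
    def test_cost_attribution_closed_form(self):
        ju = v.from_tornado_icer(60.0, [(40.0, 80.0)], delta_e_base=2.0)
        assert ju.sd_cost == pytest.approx(2.0 * 40.0 / np.sqrt(12), rel=1e-12)
        assert ju.sd_cost == pytest.approx(23.09, abs=0.01)
        assert ju.sd_benefit == 0.0 and ju.correlation == 0.0

    def test_interval95_convention(self):
        ju = v.from_tornado_icer(
            60.0, [(40.0, 80.0)], delta_e_base=2.0, range_convention="interval95"
        )
        assert ju.sd_cost == pytest.approx((20.0 / Z95) * 2.0, rel=1e-9)
        assert ju.sd_cost == pytest.approx(20.41, abs=0.01)

    def test_zero_width_bars_give_point_mass(self):
        ju = v.from_tornado_icer(60.0, [(60.0, 60.0)], delta_e_base=2.0)
        assert ju.sd_cost == 0.0 and ju.sd_benefit == 0.0

    def test_benefit_attribution_spans_icer_interval(self):
        base, de = 60.0, 2.0
        ju = v.from_tornado_icer(base, [(40.0, 80.0)], de, attribution="benefit")
        assert ju.sd_cost == 0.0 and ju.sd_benefit > 0
        sd_icer = 40.0 / np.sqrt(12)
        dc = base * de
        implied_span = dc / (de - Z95 * ju.sd_benefit) - dc / (de + Z95 * ju.sd_benefit)
        assert implied_span == pytest.approx(2 * Z95 * sd_icer, rel=1e-9)

    def test_zero_benefit_rejected(self):
        with pytest.raises(ValueError):
            v.from_tornado_icer(60.0, [(40.0, 80.0)], delta_e_base=0.0)


class TestICERHistogram:
    def test_recovery_from_rendered_histogram(self):
        truth = make_truth(medium="icer_histogram")
        p = render_payload(truth, seed=11)
        ju = v.from_icer_histogram(p.bin_edges, p.counts, (100.0, 2.0), rho_fixed=0.0)
        assert ju.sd_cost == pytest.approx(50.0, rel=0.10)
        assert ju.sd_benefit == pytest.approx(0.5, rel=0.10)

    def test_single_occupied_bin_gives_near_point_mass(self):
        ju = v.from_icer_histogram(
            [49.0, 50.0, 51.0, 52.0], [0.0, 100.0, 0.0], (101.0, 2.0), rho_fixed=0.0
        )
        assert ju.sd_cost < 2.0 and ju.sd_benefit < 0.05

    def test_non_unimodal_shape_reports_large_residual(self):
        truth = make_truth(medium="icer_histogram")
        p = render_payload(truth, seed=11)
        scrambled = tuple(reversed(p.counts))
        ju = v.from_icer_histogram(p.bin_edges, scrambled, (100.0, 2.0), rho_fixed=0.0)
        assert ju.fit_residual > 1e-3
        assert "poor_fit" in ju.diagnostics

    def test_malformed_histogram_rejected(self):
        with pytest.raises(ValueError):
            v.from_icer_histogram([0.0, 1.0], [1.0, 2.0], (100.0, 2.0))
        with pytest.raises(ValueError):
            v.from_icer_histogram([0.0, 1.0, 2.0], [0.0, 0.0], (100.0, 2.0))


class TestICERCDF:
    def test_recovery_from_exact_cdf_points(self):
        truth = make_truth(medium="icer_cdf")
        p = render_payload(truth)
        ju = v.from_icer_cdf(p.points, (100.0, 2.0), rho_fixed=0.0)
        assert ju.sd_cost == pytest.approx(50.0, rel=0.10)
        assert ju.sd_benefit == pytest.approx(0.5, rel=0.10)

    def test_three_quantile_points(self):
        t = np.array([50.0 - 50.0, 50.0, 50.0 + 50.0])
        q = v.icer_ratio_cdf(t, 100.0, 2.0, 50.0, 0.5, 0.0)
        ju = v.from_icer_cdf(list(zip(t, q)), (100.0, 2.0), rho_fixed=0.0)
        assert ju.sd_cost == pytest.approx(50.0, rel=0.15)
        assert ju.sd_benefit == pytest.approx(0.5, rel=0.15)

    def test_step_cdf_gives_point_mass(self):
        ju = v.from_icer_cdf(
            [(49.9, 0.0), (50.0, 1.0), (50.1, 1.0)], (100.0, 2.0), rho_fixed=0.0
        )
        assert ju.sd_cost < 0.5 and ju.sd_benefit < 0.01

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            v.from_icer_cdf([(1.0, 0.5), (2.0, 0.3), (3.0, 0.9)], (100.0, 2.0))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            v.from_icer_cdf([(1.0, 0.1), (2.0, 0.9)], (100.0, 2.0))

    def test_agrees_with_histogram_of_same_distribution(self):
        truth = make_truth(medium="icer_histogram")
        hist = render_payload(truth, medium="icer_histogram", seed=5)
        cdf = render_payload(truth, medium="icer_cdf")
        ju_h = v.from_icer_histogram(hist.bin_edges, hist.counts, (100.0, 2.0), 0.0)
        ju_c = v.from_icer_cdf(cdf.points, (100.0, 2.0), 0.0)
        assert ju_h.sd_cost == pytest.approx(ju_c.sd_cost, rel=0.10)
        assert ju_h.sd_benefit == pytest.approx(ju_c.sd_benefit, rel=0.10)


class TestCEAC:
    def test_recovery_from_three_lambdas(self):
        lam = np.array([0.0, 61.0, 200.0])
        p = v.ceac_probability(lam, 100.0, 2.0, 50.0, 0.5, 0.3)
        ju = v.from_ceac(list(zip(lam, p)), (100.0, 2.0))
        assert ju.sd_cost == pytest.approx(50.0, rel=0.05)
        assert ju.sd_benefit == pytest.approx(0.5, rel=0.05)
        assert ju.correlation == pytest.approx(0.3, abs=0.05)

    def test_zero_lambda_probability_is_phi_of_minus_cost_ratio(self):
        p = v.ceac_probability(np.array([0.0]), 0.0, 2.0, 50.0, 0.5, 0.0)
        assert p[0] == pytest.approx(0.5)
        p2 = v.ceac_probability(np.array([0.0]), 100.0, 2.0, 50.0, 0.5, 0.0)
        assert p2[0] == pytest.approx(float(stats.norm.cdf(-2.0)), rel=1e-9)

    def test_flat_ceac_is_unidentifiable(self):
        with pytest.raises(ReconstructionError):
            v.from_ceac([(0.0, 1.0), (61.0, 1.0), (200.0, 1.0)], (100.0, 2.0))

    def test_too_few_distinct_lambdas(self):
        with pytest.raises(InsufficientDataError):
            v.from_ceac([(0.0, 0.1), (0.0, 0.2), (61.0, 0.9)], (100.0, 2.0))


class TestDispatch:
    def test_mean_ci_record_matches_direct_call(self, record):
        ev = v.datamodel.MeanCIPayload(
            ci_cost=(40.0, 160.0), ci_benefit=(1.0, 2.0), level=0.95, rho=0.2
        )
        rec = record.model_copy(update={"evidence": ev})
        ju = v.reconstruct(rec)
        direct = v.from_mean_ci((40.0, 160.0), (1.0, 2.0), 0.95, 0.2)
        assert ju.sd_cost == direct.sd_cost and ju.correlation == direct.correlation
        assert ju.provenance == "reconstructed"

    def test_pairs_mode_is_honoured(self, record):
        ev = v.datamodel.PairsPayload(
            pairs=((0.0, 0.0), (2.0, 1.0), (4.0, 2.0), (1.0, 0.6))
        )
        rec = record.model_copy(update={"evidence": ev})
        assert v.reconstruct(rec, pairs_mode="empirical").family == "empirical"
        assert v.reconstruct(rec, pairs_mode="parametric").family == "bivariate_normal"

    def test_errors_are_tagged_with_intervention_id(self, record):
        ev = v.datamodel.PairsPayload(pairs=((0.0, 0.0), (1.0, 1.0), (2.0, 2.0)))
        rec = record.model_copy(update={"id": "X9", "evidence": ev, })
        bad = rec.model_copy(update={"evidence": v.datamodel.UnivariatePayload(rows=())})
        with pytest.raises(InsufficientDataError, match="X9"):
            v.reconstruct(bad)

    def test_absent_evidence_is_not_reconstructable(self, record):
        with pytest.raises(ValueError, match="imputation"):
            v.reconstruct(record)


class TestInvariants:
    """Reconstructed parameters always satisfy the distribution constraints."""

    @given(
        lo_c=st.floats(-1e3, 1e3),
        w_c=st.floats(0, 1e3),
        lo_e=st.floats(-10, 10),
        w_e=st.floats(0, 10),
        level=st.floats(0.05, 0.99),
        rho=st.floats(-1, 1),
    )
    def test_mean_ci_bounds(self, lo_c, w_c, lo_e, w_e, level, rho):
        ju = v.from_mean_ci((lo_c, lo_c + w_c), (lo_e, lo_e + w_e), level, rho)
        assert ju.sd_cost >= 0 and ju.sd_benefit >= 0
        assert -1 <= ju.correlation <= 1

    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100),
                st.floats(-100, 100),
                st.floats(-5, 5),
                st.floats(-5, 5),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_univariate_bounds(self, raw_rows):
        rows = [
            UnivariateRow(param_id=f"p{i}", dc_low=a, dc_high=b, de_low=c, de_high=d)
            for i, (a, b, c, d) in enumerate(raw_rows)
        ]
        ju = v.from_univariate_table(rows)
        assert ju.sd_cost >= 0 and ju.sd_benefit >= 0
        assert -1 <= ju.correlation <= 1

    @given(
        st.lists(
            st.tuples(st.floats(-1e4, 1e4), st.floats(-50, 50)), min_size=3, max_size=40
        )
    )
    def test_raw_pairs_bounds(self, pairs):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ReconstructionWarning)
            ju = v.from_raw_pairs(pairs)
        assert ju.sd_cost >= 0 and ju.sd_benefit >= 0
        assert -1 <= ju.correlation <= 1
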