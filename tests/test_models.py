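"""EQD2 correction, Poisson-LQ TCP, gEUD, LKB and relative-seriality NTCP."""

import math

import numpy as np
import pytest
from scipy import integrate

from radbio import (
    DoseVolumeHistogram,
    DVHValidationError,
    FractionationScheme,
    LKBParams,
    SerialityParams,
    TCPParams,
    dvh_from_dose_list,
    eqd2,
    eqd2_correct_dvh,
    eud,
    evaluate_plan,
    lkb_ntcp,
    poisson_response,
    seriality_ntcp,
    summary_metrics,
    tcp_from_dvh,
    uniform_dvh,
)
from conftest import random_differential_dvh


class TestEQD2:
    def test_two_gray_identity(self):
        for d_total in (10.0, 45.0, 60.0):
            for ab in (1.3, 3.0, 10.0):
                assert eqd2(d_total, 2.0, ab) == pytest.approx(d_total)

    def test_published_conversion(self):
        # 6.5 Gy at 12 Gy per fraction, alpha/beta 10 -> 11.9 Gy
        assert round(eqd2(6.5, 12.0, 10.0), 1) == 11.9

    def test_hand_value(self):
        assert eqd2(60.0, 12.0, 10.0) == pytest.approx(110.0)

    def test_linear_in_total_dose(self):
        assert eqd2(30.0, 12.0, 10.0) * 2 == pytest.approx(eqd2(60.0, 12.0, 10.0))

    def test_invalid_alpha_beta(self):
        with pytest.raises(ValueError):
            eqd2(60.0, 12.0, 0.0)


class TestEQD2DVH:
    def test_uniform_60_in_5_fractions(self, scheme):
        out = eqd2_correct_dvh(uniform_dvh(60.0, bin_width_gy=0.01), scheme, 10.0)
        assert summary_metrics(out)["mean_gy"] == pytest.approx(110.0, abs=0.05)
        assert float(out.volume.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_two_gray_per_bin_identity(self):
        # 30 fractions of 2 Gy: every bin's per-fraction dose is D/30
        dvh = uniform_dvh(60.0, bin_width_gy=0.01)
        out = eqd2_correct_dvh(dvh, FractionationScheme(60.0, 30), 10.0)
        # only the 60 Gy bin is populated, and 60/30 = 2 Gy/fx maps to itself
        assert summary_metrics(out)["mean_gy"] == pytest.approx(60.0, abs=0.05)

    def test_monotone_and_volume_conserving(self, rng, scheme):
        for _ in range(10):
            dvh = random_differential_dvh(rng)
            out = eqd2_correct_dvh(dvh, scheme, 3.0)
            assert np.all(np.diff(out.dose_edges) > 0)
            np.testing.assert_allclose(out.volume, dvh.volume)

    def test_zero_fractions_rejected(self, scheme):
        with pytest.raises(ValueError):
            eqd2_correct_dvh(uniform_dvh(60.0), FractionationScheme(60.0, -1), 10.0)


MARTEL_30 = TCPParams(84.5, 1.5, 10.0)


class TestPoissonResponse:
    def test_half_probability_at_d50(self, registry):
        for params in registry.tcp.values():
            assert poisson_response(params.d50_eqd2_gy, params) == pytest.approx(0.5)

    def test_sigmoid_limits(self):
        assert poisson_response(0.0, MARTEL_30) < 1e-6
        assert poisson_response(1e4, MARTEL_30) > 1 - 1e-12

    def test_frozen_closed_form_value(self):
        # 2^(-exp(e*1.5*(1 - 110/84.5))) evaluated to high precision
        assert poisson_response(110.0, MARTEL_30) == pytest.approx(
            0.8166802608619775, abs=1e-12
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            poisson_response(-1.0, MARTEL_30)


class TestTCPFromDVH:
    def test_single_bin_equals_pointwise(self):
        dvh = uniform_dvh(90.0)
        assert tcp_from_dvh(dvh, MARTEL_30) == pytest.approx(
            poisson_response(summary_metrics(dvh)["mean_gy"], MARTEL_30), abs=1e-12
        )

    def test_uniform_d50_gives_half(self, registry):
        for params in registry.tcp.values():
            dvh = uniform_dvh(params.d50_eqd2_gy)
            assert tcp_from_dvh(dvh, params) == pytest.approx(0.5, abs=1e-12)

    def test_two_bin_hand_product(self):
        # doses chosen so P = 0.9 and 0.4; TCP = sqrt(0.9*0.4) = 0.6
        def dose_for(p):
            # invert the Kallman form analytically
            return MARTEL_30.d50_eqd2_gy * (
                1 - math.log(-math.log(p) / math.log(2)) / (math.e * MARTEL_30.gamma)
            )

        d_hi, d_lo = dose_for(0.9), dose_for(0.4)
        dvh = dvh_from_dose_list([d_lo, d_hi])
        assert tcp_from_dvh(dvh, MARTEL_30) == pytest.approx(0.6, abs=1e-9)

    def test_brute_force_voxel_product(self, rng):
        for _ in range(5):
            doses = rng.uniform(40.0, 120.0, size=80)
            dvh = dvh_from_dose_list(doses)
            brute = float(
                np.prod(poisson_response(doses, MARTEL_30) ** (1.0 / doses.size))
            )
            assert tcp_from_dvh(dvh, MARTEL_30) == pytest.approx(brute, abs=1e-9)

    def test_unnormalised_volumes_rejected(self):
        dvh = DoseVolumeHistogram(
            "x", np.array([0.0, 50.0, 60.0]), np.array([0.2, 0.3]), "differential"
        )
        with pytest.raises(DVHValidationError):
            tcp_from_dvh(dvh, MARTEL_30)

    def test_eud_reduction_variant(self):
        dvh = uniform_dvh(110.0)
        assert tcp_from_dvh(dvh, MARTEL_30, method="eud") == pytest.approx(
            tcp_from_dvh(dvh, MARTEL_30), abs=1e-6
        )


class TestEUD:
    def test_n_one_is_mean_dose(self, rng):
        dvh = random_differential_dvh(rng)
        assert eud(dvh, 1.0) == pytest.approx(summary_metrics(dvh)["mean_gy"], abs=1e-9)

    def test_uniform_invariant_in_n(self):
        dvh = uniform_dvh(42.0)
        for n in (0.1, 0.5, 1.0):
            assert eud(dvh, n) == pytest.approx(42.0, abs=1e-9)

    def test_hand_generalized_mean(self):
        dvh = dvh_from_dose_list([10.0] * 5 + [20.0] * 5)
        assert eud(dvh, 0.5) == pytest.approx(math.sqrt(250.0), abs=1e-9)

    def test_non_increasing_in_n_and_bounded(self, rng):
        for _ in range(10):
            dvh = random_differential_dvh(rng)
            m = summary_metrics(dvh)
            hot_center = float(dvh.bin_centers[np.nonzero(dvh.volume > 1e-12)[0][-1]])
            values = [eud(dvh, n) for n in (1e-3, 0.1, 0.3, 0.6, 1.0)]
            assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
            assert m["min_gy"] - 1e-6 <= values[-1] <= m["max_gy"] + 1e-6
            assert all(v <= m["max_gy"] + 1e-6 for v in values)
            # n -> 0+ approaches the hottest populated dose
            assert values[0] >= 0.95 * hot_center

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            eud(uniform_dvh(10.0), 0.0)


LUNG_KWA = LKBParams(30.5, 1.0, 0.3, 1.3, "lung")


class TestLKB:
    def test_anchor_points(self, registry):
        for params in registry.lkb.values():
            assert lkb_ntcp(params.d50_gy, params) == pytest.approx(0.5, abs=1e-12)
            assert lkb_ntcp(params.d50_gy * (1 + params.m_slope), params) == pytest.approx(
                0.8413447460685429, abs=1e-9
            )

    def test_deep_lower_tail(self):
        assert lkb_ntcp(0.0, LKBParams(30.5, 1.0, 0.05, 1.3)) < 1e-12

    def test_matches_probit_quadrature(self):
        # closed-form CDF vs numerical integration of the probit integrand
        for t in np.linspace(-6.0, 6.0, 25):
            eud_gy = LUNG_KWA.d50_gy * (1 + LUNG_KWA.m_slope * t)
            if eud_gy < 0:
                continue
            quad, _ = integrate.quad(
                lambda u: math.exp(-(u**2) / 2.0) / math.sqrt(2 * math.pi),
                -12.0,
                t,
            )
            assert lkb_ntcp(eud_gy, LUNG_KWA) == pytest.approx(quad, abs=1e-7)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LKBParams(30.5, 1.0, -0.1, 1.3)
        with pytest.raises(ValueError):
            lkb_ntcp(-1.0, LUNG_KWA)


CORD = SerialityParams(68.6, 1.9, 4.0, 3.0, "cord")


class TestSeriality:
    def test_uniform_d50_gives_half_any_s(self, registry):
        for params in registry.seriality.values():
            dvh = uniform_dvh(params.d50_gy)
            assert seriality_ntcp(dvh, params) == pytest.approx(0.5, abs=1e-9)
        for s in (0.5, 1.0, 2.0, 10.0):
            params = SerialityParams(68.6, 1.9, s, 3.0)
            assert seriality_ntcp(uniform_dvh(68.6), params) == pytest.approx(
                0.5, abs=1e-9
            )

    def test_s_one_uniform_collapses_to_response(self):
        params = SerialityParams(68.6, 1.9, 1.0, 3.0)
        tcp_params = TCPParams(68.6, 1.9, 3.0)
        for dose in (30.0, 68.6, 90.0):
            assert seriality_ntcp(uniform_dvh(dose), params) == pytest.approx(
                poisson_response(dose, tcp_params), abs=1e-6
            )

    def test_two_bin_hand_value(self):
        # independently evaluated: [1 - sqrt((1-0.8^2)(1-0.2^2))]^(1/2)
        def dose_for(p, params):
            return params.d50_gy * (
                1 - math.log(-math.log(p) / math.log(2)) / (math.e * params.gamma)
            )

        params = SerialityParams(68.6, 1.9, 2.0, 3.0)
        dvh = dvh_from_dose_list([dose_for(0.8, params), dose_for(0.2, params)])
        expected = math.sqrt(1.0 - math.sqrt((1 - 0.64) * (1 - 0.04)))
        assert expected == pytest.approx(0.641968, abs=1e-5)
        assert seriality_ntcp(dvh, params) == pytest.approx(expected, abs=1e-9)

    def test_invalid_s(self):
        with pytest.raises(ValueError):
            SerialityParams(68.6, 1.9, -1.0, 3.0)


class TestMonotonicity:
    """Pointwise dose increases never decrease any response probability."""

    def test_tcp_and_ntcp_monotone_under_dose_scaling(self, rng, scheme):
        lkb = LUNG_KWA
        ser = CORD
        for _ in range(8):
            dvh = random_differential_dvh(rng)
            hotter = dvh.with_scaled_doses(1.07)
            t0 = tcp_from_dvh(eqd2_correct_dvh(dvh, scheme, 10.0), MARTEL_30)
            t1 = tcp_from_dvh(eqd2_correct_dvh(hotter, scheme, 10.0), MARTEL_30)
            assert t1 >= t0 - 1e-12
            e0 = eud(eqd2_correct_dvh(dvh, scheme, lkb.alpha_beta_gy), lkb.n_volume)
            e1 = eud(eqd2_correct_dvh(hotter, scheme, lkb.alpha_beta_gy), lkb.n_volume)
            assert lkb_ntcp(e1, lkb) >= lkb_ntcp(e0, lkb) - 1e-12
            s0 = seriality_ntcp(eqd2_correct_dvh(dvh, scheme, ser.alpha_beta_gy), ser)
            s1 = seriality_ntcp(eqd2_correct_dvh(hotter, scheme, ser.alpha_beta_gy), ser)
            assert s1 >= s0 - 1e-12

    def test_probabilities_in_unit_interval(self, rng, scheme):
        for _ in range(8):
            dvh = random_differential_dvh(rng)
            corr = eqd2_correct_dvh(dvh, scheme, 3.0)
            assert 0.0 <= tcp_from_dvh(corr, MARTEL_30) <= 1.0
            assert 0.0 <= seriality_ntcp(corr, CORD) <= 1.0
            assert 0.0 <= lkb_ntcp(eud(corr, 0.5), LUNG_KWA) <= 1.0


class TestEvaluatePlan:
    def test_ptv_only_plan(self, scheme):
        dvhs = {"ptv": uniform_dvh(60.0)}
        ev = evaluate_plan(dvhs, scheme, {"martel_30mo": MARTEL_30}, {})
        assert set(ev.tcp) == {"martel_30mo"}
        assert ev.ntcp == {}

    def test_determinism(self, scheme):
        dvhs = {"ptv": uniform_dvh(60.0)}
        a = evaluate_plan(dvhs, scheme, {"m": MARTEL_30}, {})
        b = evaluate_plan(dvhs, scheme, {"m": MARTEL_30}, {})
        assert a.tcp == b.tcp and a.metrics == b.metrics

    def test_missing_ptv_raises(self, scheme):
        with pytest.raises(DVHValidationError):
            evaluate_plan({"lung": uniform_dvh(5.0)}, scheme, {}, {})

    def test_missing_oar_skipped_with_warning(self, scheme, registry):
        dvhs = {"ptv": uniform_dvh(60.0)}
        with pytest.warns(UserWarning, match="missing"):
            ev = evaluate_plan(
                dvhs, scheme, {}, {"lung_lkb.kwa": registry.lkb["lung_lkb.kwa"]}
            )
        assert ev.ntcp == {}
        assert any("skipped" in w for w in ev.warnings)

    def test_lung_parameter_set_ordering(self, scheme, registry, rng):
        """For typical low-dose lung DVHs Burman predicts the smallest and
        Seppenwoolde the largest complication probability."""
        sets = {
            k: registry.lkb[k]
            for k in ("lung_lkb.burman", "lung_lkb.kwa", "lung_lkb.seppenwoolde_ab1.3")
        }
        edges = np.arange(0.0, 30.1, 0.5)
        for _ in range(5):
            # decaying lung-like differential DVH, mean a few Gy
            w = np.exp(-edges[:-1] / rng.uniform(3.0, 8.0))
            dvh = DoseVolumeHistogram("lung", edges, w / w.sum(), "differential")
            ev = evaluate_plan(
                {"ptv": uniform_dvh(60.0), "lung": dvh}, scheme, {}, sets
            )
            assert (
                ev.ntcp["lung_lkb.burman"]
                <= ev.ntcp["lung_lkb.kwa"] + 1e-12
                <= ev.ntcp["lung_lkb.seppenwoolde_ab1.3"] + 2e-12
            )
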