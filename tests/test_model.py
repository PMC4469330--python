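"""Core carrier-cycle flux law and time-course integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import carrierflux as cf
from carrierflux.model import FACE_EXT, FACE_INT


class TestFaceOccupancy:
    def test_empty_face_is_all_free(self):
        occ = cf.face_occupancy({}, {"A": 100.0})
        assert occ.p0 == 1.0 and occ.loaded == 0.0

    def test_half_saturation_at_K(self):
        occ = cf.face_occupancy({"A": 1129.0}, {"A": 1129.0})
        assert occ.p["A"] == pytest.approx(0.5)
        assert occ.p0 == pytest.approx(0.5)

    def test_two_equal_substrates_split_evenly(self):
        occ = cf.face_occupancy({"A": 1129.0, "B": 1129.0}, {"A": 1129.0, "B": 1129.0})
        assert occ.p["A"] == pytest.approx(1 / 3)
        assert occ.p["B"] == pytest.approx(1 / 3)
        assert occ.p0 == pytest.approx(1 / 3)

    def test_infinite_K_never_binds(self):
        occ = cf.face_occupancy({"A": 1e6}, {"A": math.inf})
        assert occ.p["A"] == 0.0 and occ.p0 == 1.0

    @pytest.mark.parametrize(
        "conc,K",
        [({"A": -1.0}, {"A": 10.0}), ({"A": 1.0}, {"A": 0.0}), ({"A": 1.0}, {"A": -5.0})],
    )
    def test_domain_errors(self, conc, K):
        with pytest.raises(ValueError):
            cf.face_occupancy(conc, K)

    @given(
        concs=st.lists(st.floats(0, 1e4), min_size=1, max_size=4),
        ks=st.lists(st.floats(1.0, 1e5), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, concs, ks):
        names = [f"s{i}" for i in range(len(concs))]
        occ = cf.face_occupancy(dict(zip(names, concs)), dict(zip(names, ks)))
        total = occ.p0 + sum(occ.p.values())
        assert total == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= v <= 1.0 for v in occ.p.values())


class TestCarrierDistribution:
    def test_identical_faces_split_evenly(self):
        occ = cf.face_occupancy({"A": 300.0}, {"A": 1129.0})
        for h in (0.0, 0.04, 1.0):
            assert cf.carrier_distribution(occ, occ, h) == pytest.approx((0.5, 0.5))

    def test_obligate_zero_trans_piles_up_inside(self):
        # fully loaded outside, empty inside, h = 0: the carrier accumulates
        # at the inside face and influx stalls
        occ_out = cf.FaceOccupancy(p={"A": 1.0}, p0=0.0)
        occ_in = cf.FaceOccupancy(p={}, p0=1.0)
        assert cf.carrier_distribution(occ_out, occ_in, 0.0) == (0.0, 1.0)

    def test_hand_solved_asymmetric_case(self):
        # theta_ext*(0.5 + 0.04*0.5) = (1-theta_ext)*0.04  =>  theta_ext = 0.04/0.56
        occ_out = cf.FaceOccupancy(p={"A": 0.5}, p0=0.5)
        occ_in = cf.FaceOccupancy(p={}, p0=1.0)
        theta = cf.carrier_distribution(occ_out, occ_in, 0.04)
        assert theta[0] == pytest.approx(0.04 / 0.56)
        assert theta[0] + theta[1] == 1.0

    def test_double_degenerate_convention(self):
        empty = cf.FaceOccupancy(p={}, p0=1.0)
        assert cf.carrier_distribution(empty, empty, 0.0) == (0.5, 0.5)

    def test_negative_h_rejected(self):
        empty = cf.FaceOccupancy(p={}, p0=1.0)
        with pytest.raises(ValueError):
            cf.carrier_distribution(empty, empty, -0.1)


def _state(ext_u, int_u, tracer=7.5, v_in=0.26, v_out=39.74):
    return cf.AssayState(
        conc={
            ("tracer", FACE_EXT): tracer,
            ("tracer", FACE_INT): 0.0,
            ("serine", FACE_EXT): ext_u,
            ("serine", FACE_INT): int_u,
        },
        v_in=v_in,
        v_out=v_out,
    )


class TestNetFlux:
    def test_symmetric_state_has_zero_flux(self, pred_params):
        st_sym = cf.AssayState(
            conc={("serine", FACE_EXT): 250.0, ("serine", FACE_INT): 250.0},
            v_in=0.26,
            v_out=39.74,
        )
        flux = cf.net_flux(st_sym, pred_params)
        assert flux["serine"] == pytest.approx(0.0, abs=1e-15)

    def test_obligate_empty_interior_transports_nothing(self):
        params = cf.prediction_params(h=0.0)
        flux = cf.net_flux(_state(250.0, 0.0), params)
        assert flux["tracer"] == 0.0 and flux["serine"] == 0.0

    @given(
        ext_u=st.floats(0, 2000),
        int_u=st.floats(0, 2000),
        h=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_face_swap(self, ext_u, int_u, h):
        params = cf.prediction_params(h=h)
        s = _state(ext_u, int_u)
        f, g = cf.net_flux(s, params), cf.net_flux(s.swapped(), params)
        for sub in f:
            assert f[sub] + g[sub] == pytest.approx(0.0, abs=1e-12)


class TestSimulateUptake:
    def test_single_time_returns_initial_state(self, pred_params):
        s = _state(250.0, 1000.0)
        tc = cf.simulate_uptake(s, pred_params, [0.0])
        assert tc.times.tolist() == [0.0]
        assert tc.trace("tracer", FACE_INT)[0] == 0.0
        assert tc.trace("serine", FACE_EXT)[0] == 250.0

    def test_times_must_start_at_zero(self, pred_params):
        with pytest.raises(ValueError):
            cf.simulate_uptake(_state(0, 0), pred_params, [1.0, 2.0])

    def test_tracer_only_equilibrates_to_external_concentration(self):
        # passive symmetric carrier: intravesicular tracer converges to the
        # external value (v_out >> v_in keeps the outside nearly constant)
        params = cf.prediction_params(h=0.5)
        tc = cf.simulate_uptake(_state(0.0, 0.0), params, [0.0, 5000.0])
        final = tc.trace("tracer", FACE_INT)[-1]
        ext_final = tc.trace("tracer", FACE_EXT)[-1]
        assert final == pytest.approx(ext_final, rel=1e-4)
        assert final == pytest.approx(7.5 * 39.74 / 40.0, rel=1e-3)

    def test_engines_agree(self, pred_params):
        times = np.concatenate([[0.0], np.geomspace(0.25, 500.0, 25)])
        s = _state(50.0, 1000.0, v_out=399.74)
        a = cf.simulate_uptake(s, pred_params, times, engine="compiled")
        b = cf.simulate_uptake(s, pred_params, times, engine="scipy")
        tra, trb = a.trace("tracer"), b.trace("tracer")
        assert np.max(np.abs(tra[1:] - trb[1:]) / trb[1:]) < 1e-5

    def test_unknown_engine_rejected(self, pred_params):
        with pytest.raises(ValueError):
            cf.simulate_uptake(_state(0, 0), pred_params, [0.0, 1.0], engine="nope")

    @given(
        h=st.floats(0, 1),
        ext_u=st.floats(0, 1500),
        int_u=st.floats(0, 1500),
    )
    @settings(max_examples=25, deadline=None)
    def test_mass_conserved_and_nonnegative(self, h, ext_u, int_u):
        params = cf.prediction_params(h=h)
        tc = cf.simulate_uptake(_state(ext_u, int_u), params, np.linspace(0, 50, 11))
        assert tc.conc.min() >= 0.0
        for sub in ("tracer", "serine"):
            amt = tc.total_amount(sub)
            if amt[0] > 0:
                assert np.ptp(amt) / amt[0] < 1e-7

    def test_overshoot_under_outward_gradient(self, long_horizon_timecourses):
        om = cf.overshoot_metrics(long_horizon_timecourses["4b"])
        assert om.is_overshoot
        assert 0.0 < om.peak_time < 5000.0
        assert om.peak_value > om.final_value


class TestOvershootMetrics:
    def test_toy_trace_arithmetic(self):
        tc = cf.TimeCourse(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            conc=np.column_stack([np.zeros(4), [0.0, 10.0, 6.0, 5.0]]),
            substrates=("tracer",),
            v_in=0.26,
            v_out=39.74,
        )
        m = cf.overshoot_metrics(tc)
        assert m.peak_value == 10.0 and m.peak_time == 1.0
        assert m.final_value == 5.0 and m.ratio == 2.0
        assert m.is_overshoot

    def test_monotone_trace_is_not_overshoot(self):
        tc = cf.TimeCourse(
            times=np.arange(4.0),
            conc=np.column_stack([np.zeros(4), [0.0, 1.0, 2.0, 3.0]]),
            substrates=("tracer",),
            v_in=0.26,
            v_out=39.74,
        )
        assert not cf.overshoot_metrics(tc).is_overshoot

    def test_constant_trace_reports_ratio_one(self):
        tc = cf.TimeCourse(
            times=np.arange(3.0),
            conc=np.full((3, 2), 4.0),
            substrates=("tracer",),
            v_in=0.26,
            v_out=39.74,
        )
        m = cf.overshoot_metrics(tc)
        assert m.ratio == 1.0 and not m.is_overshoot
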