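import dataclasses
import math

import numpy as np
import pytest

from bicnn import dynamics as dyn
from bicnn import microcircuit as mc

TINY_SPECS = [
    mc.PopulationSpec("mf", 10, mc.GRANULAR, 4.0),
    mc.PopulationSpec("gr", 20, mc.GRANULAR, 2.0),
    mc.PopulationSpec("Go", 2, mc.GRANULAR, 8.0),
    mc.PopulationSpec("ba", 4, mc.MOLECULAR, 3.0),
    mc.PopulationSpec("Pk", 2, mc.MOLECULAR, 8.0),
]
TINY_RATIOS = {
    ("mf", "gr"): (2, 4),
    ("mf", "Go"): (3, 1),
    ("gr", "Go"): (5, 1),
    ("Go", "gr"): (1, 10),
    ("gr", "ba"): (4, 1),
    ("gr", "Pk"): (6, 1),
    ("ba", "Pk"): (2, 1),
    ("Pk", "ba"): (1, 2),
    ("ba", "Go"): (2, 1),
}


@pytest.fixture(scope="module")
def tiny_net():
    net, _table, _positions = mc.build_hemisphere(
        rng_seed=3, specs=TINY_SPECS, ratios=TINY_RATIOS
    )
    return net


class TestEncodeMossy:
    def test_zero_signals_center(self):
        v = dyn.encode_mossy(dyn.MossySignals())
        assert v.shape == (562,)
        assert (v == 0.5).all()

    def test_fullscale_maps_to_one(self):
        v = dyn.encode_mossy(dyn.MossySignals(phi_ref=math.pi))
        assert v[0] == pytest.approx(1.0)
        assert v[1] == pytest.approx(0.5)

    def test_roundrobin_replication(self):
        sig = dyn.MossySignals(phi_ref=1.0, theta_e=-0.1, efference=0.3)
        v = dyn.encode_mossy(sig)
        assert (v[0::7] == v[0]).all()
        assert (v[6::7] == v[6]).all()

    def test_clipping(self):
        v = dyn.encode_mossy(dyn.MossySignals(phi_e=100.0, theta_e=-100.0))
        assert v[4] == 1.0 and v[2] == 0.0

    def test_invertible_on_range(self):
        scales = dyn.MossyScales()
        sig = dyn.MossySignals(phi_ref=0.7, phi_dot_ref=-2.0, theta_e=0.1,
                               theta_dot_e=1.0, phi_e=-0.5, phi_dot_e=3.0,
                               efference=-0.4)
        v = dyn.encode_mossy(sig, scales)
        back = (v[:7] - 0.5) * 2.0 * scales.as_array()
        assert back == pytest.approx(sig.as_array())

    def test_bad_scale_rejected(self):
        with pytest.raises(ValueError):
            dyn.encode_mossy(dyn.MossySignals(),
                             dataclasses.replace(dyn.MossyScales(), phi_e=0.0))


class TestComputeCf:
    UNIT = dyn.CfParams(error_gain=1.0, w_p=1.0, w_v=0.0)

    def test_zero_error_spontaneous(self):
        pair = dyn.compute_cf(0.0, 0.0)
        assert pair.cf_left == 0.05
        assert pair.cf_right == 0.05

    def test_positive_raw_floors_right(self):
        pair = dyn.compute_cf(0.30, 0.0, self.UNIT)
        assert pair.cf_left == pytest.approx(0.35)
        assert pair.cf_right == 0.0

    def test_negative_raw(self):
        pair = dyn.compute_cf(-0.02, 0.0, self.UNIT)
        assert pair.cf_left == pytest.approx(0.03)
        assert pair.cf_right == pytest.approx(0.07)

    def test_caps_at_one(self):
        pair = dyn.compute_cf(5.0, 0.0, self.UNIT)
        assert pair.cf_left == 1.0 and pair.cf_right == 0.0

    def test_velocity_component(self):
        params = dyn.CfParams(error_gain=1.0, w_p=1.0, w_v=0.1)
        pair = dyn.compute_cf(0.1, 0.5, params)
        assert pair.cf_left == pytest.approx(0.05 + 0.15)

    def test_absolute_mode(self):
        pair = dyn.compute_cf(-0.2, 0.0, self.UNIT, absolute=True)
        assert pair.cf_left == pytest.approx(0.25)
        assert pair.cf_right == pytest.approx(0.25)

    def test_asymmetric_spontaneous(self):
        params = dyn.CfParams(cf_spont_left=0.08, cf_spont_right=0.01,
                              error_gain=1.0, w_v=0.0)
        pair = dyn.compute_cf(0.0, 0.0, params)
        assert (pair.cf_left, pair.cf_right) == (0.08, 0.01)


class TestPfPkPlasticity:
    PARAMS = dyn.PlasticityParams()

    def test_ltd_branch(self):
        w = np.array([1e-3])
        out = dyn.update_pf_pk(w, np.array([0.5]), cf=0.1, params=self.PARAMS)
        assert out[0] - w[0] == pytest.approx(-2e-7)

    def test_ltd_at_saturated_rates(self):
        w = np.array([1e-3])
        out = dyn.update_pf_pk(w, np.array([1.0]), cf=1.0, params=self.PARAMS)
        assert out[0] - w[0] == pytest.approx(-4e-6)

    def test_ltp_branch(self):
        w = np.array([1e-3])
        out = dyn.update_pf_pk(w, np.array([0.5]), cf=0.02, params=self.PARAMS)
        assert out[0] - w[0] == pytest.approx(1.5e-7)

    def test_quiescent_at_spontaneous(self):
        w = np.random.default_rng(0).uniform(0, 1e-3, size=(3, 4))
        out = dyn.update_pf_pk(w, np.full((3, 4), 0.7), cf=0.05,
                               params=self.PARAMS)
        assert np.array_equal(out, w)

    def test_clip_at_zero(self):
        w = np.array([1e-7])
        out = dyn.update_pf_pk(w, np.array([1.0]), cf=1.0, params=self.PARAMS)
        assert out[0] == 0.0

    def test_clip_at_wmax(self):
        params = dyn.PlasticityParams(w_max=1e-3)
        w = np.array([1e-3 - 1e-8])
        out = dyn.update_pf_pk(w, np.array([1.0]), cf=0.0, params=params)
        assert out[0] == 1e-3

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            dyn.PlasticityParams(gamma_ltd=1e-6)


class TestPkVnPlasticity:
    PARAMS = dyn.PlasticityParams()

    def test_centered_rate_no_change(self):
        w = np.array([0.05])
        out = dyn.update_pk_vn(w, np.array([0.5]), vn=0.9, params=self.PARAMS)
        assert np.array_equal(out, w)

    def test_same_sign_potentiates(self):
        w = np.array([0.05])
        out = dyn.update_pk_vn(w, np.array([0.7]), vn=0.5, params=self.PARAMS)
        assert out[0] - w[0] == pytest.approx(1e-5)

    def test_opposite_sign_depresses(self):
        w = np.array([0.05])
        out = dyn.update_pk_vn(w, np.array([0.7]), vn=-0.5, params=self.PARAMS)
        assert out[0] - w[0] == pytest.approx(-1e-5)

    def test_clip_range(self):
        w = np.array([0.0, 2.0 / 15])
        out = dyn.update_pk_vn(w, np.array([0.0, 1.0]), vn=1.0,
                               params=self.PARAMS)
        assert out[0] == 0.0 and out[1] == 2.0 / 15


class TestBicnnOutput:
    def test_cancellation(self):
        pk = np.array([0.3, 0.6, 0.9])
        w = np.full(3, 1 / 3)
        assert dyn.bicnn_output(pk, pk, w, w) == 0.0

    def test_bounds_attained(self):
        w = np.full(4, 0.25)
        assert dyn.bicnn_output(np.zeros(4), np.ones(4), w, w) == 1.0
        assert dyn.bicnn_output(np.ones(4), np.zeros(4), w, w) == -1.0

    def test_mean_difference(self):
        w = np.full(5, 0.2)
        out = dyn.bicnn_output(np.full(5, 0.4), np.full(5, 0.6), w, w)
        assert out == pytest.approx(0.2)

    def test_unicnn_centered(self):
        w = np.full(5, 0.2)
        assert dyn.unicnn_output(np.full(5, 0.5), w) == 0.0
        assert dyn.unicnn_output(np.ones(5), w) == 1.0


class TestHemisphereStep:
    def test_rest_is_fixed_point(self, tiny_net):
        stepper = dyn.HemisphereStepper(tiny_net)
        state = stepper.create_state()
        mf = np.full(10, 0.5)
        for _ in range(5):
            stepper.step(state, mf)
        assert (state.rates == 0.5).all()

    def test_rates_bounded(self, tiny_net):
        stepper = dyn.HemisphereStepper(tiny_net)
        state = stepper.create_state()
        rng = np.random.default_rng(0)
        for _ in range(50):
            stepper.step(state, rng.uniform(0, 1, size=10))
            assert (state.rates >= 0).all() and (state.rates <= 1).all()

    def test_zeroed_weights_all_half(self, tiny_net):
        zeroed = dataclasses.replace(tiny_net, W=np.zeros_like(tiny_net.W))
        stepper = dyn.HemisphereStepper(zeroed)
        state = stepper.create_state()
        state.w_pf_pk[:] = 0.0
        stepper.step(state, np.random.default_rng(1).uniform(0, 1, size=10))
        assert (state.rates[10:] == 0.5).all()

    def test_mirrored_states_identical(self, tiny_net):
        stepper = dyn.HemisphereStepper(tiny_net)
        a = stepper.create_state("left")
        b = stepper.create_state("right")
        rng = np.random.default_rng(2)
        for _ in range(10):
            mf = rng.uniform(0, 1, size=10)
            stepper.step(a, mf)
            stepper.step(b, mf)
        assert np.array_equal(a.rates, b.rates)

    def test_shape_mismatch_rejected(self, tiny_net):
        stepper = dyn.HemisphereStepper(tiny_net)
        state = stepper.create_state()
        with pytest.raises(ValueError):
            stepper.step(state, np.full(7, 0.5))

    @pytest.mark.parametrize("rate_tau", [0.0, 0.1])
    def test_naive_oracle_agreement(self, tiny_net, rate_tau):
        stepper = dyn.HemisphereStepper(tiny_net, rate_tau=rate_tau)
        fast = stepper.create_state()
        slow = stepper.create_state()
        rng = np.random.default_rng(4)
        for _ in range(10):
            mf = rng.uniform(0, 1, size=10)
            stepper.step(fast, mf)
            dyn.step_hemisphere_naive(tiny_net, slow, mf, rate_tau=rate_tau)
            np.testing.assert_allclose(fast.rates, slow.rates, rtol=0, atol=1e-12)

    def test_functional_wrapper(self, tiny_net):
        state = dyn.create_state(tiny_net)
        out = dyn.step_hemisphere(tiny_net, state, np.full(10, 0.5))
        assert out is state


class TestPlasticityQuiescence:
    def test_pinned_cf_and_zero_vn_freeze_weights(self, tiny_net):
        stepper = dyn.HemisphereStepper(tiny_net)
        state = stepper.create_state()
        # clip bound scales with the population: [0, 2/n_pk]
        params = dataclasses.replace(
            dyn.PlasticityParams(), w_pkvn_max=2.0 / stepper.n_pk)
        w_pf0 = state.w_pf_pk.copy()
        w_vn0 = state.w_pk_vn.copy()
        rng = np.random.default_rng(5)
        for _ in range(20):
            stepper.step(state, rng.uniform(0, 1, size=10))
            state.w_pf_pk = dyn.update_pf_pk(
                state.w_pf_pk, stepper.pf_rates(state), 0.05, params)
            state.w_pk_vn = dyn.update_pk_vn(
                state.w_pk_vn, stepper.pk_rates(state), 0.0, params)
        assert np.array_equal(state.w_pf_pk, w_pf0)
        assert np.array_equal(state.w_pk_vn, w_vn0)

    def test_drift_flips_at_spontaneous_rate(self):
        params = dyn.PlasticityParams()
        w = np.array([1e-3])
        pf = np.array([0.8])
        below = dyn.update_pf_pk(w, pf, 0.049, params)[0] - w[0]
        above = dyn.update_pf_pk(w, pf, 0.051, params)[0] - w[0]
        assert below > 0 > above
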