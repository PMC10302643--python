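import numpy as np
import pytest

from kinetree.energy import (
    BOLTZMANN_J_PER_K,
    GAS_CONSTANT_KCAL,
    PLANCK_J_S,
    EnergyHeadParams,
    backward_batch,
    eyring_energy_from_rate,
    eyring_prefactor,
    eyring_rate_from_energy,
    forward,
    forward_batch,
    init_head_params,
)
from kinetree.errors import ConstraintError
from kinetree.substrate import HammettVector

T_ROOM = 298.15
# R*T*ln(kB*T/h) at 298.15 K for k = 1/s, evaluated independently with
# 50-digit arithmetic
E_A_FOR_UNIT_RATE = 17.453169561770013


class TestEyring:
    def test_zero_barrier_gives_attempt_frequency(self):
        assert eyring_rate_from_energy(0.0, T_ROOM) == pytest.approx(
            BOLTZMANN_J_PER_K * T_ROOM / PLANCK_J_S
        )

    def test_barrier_rt_gives_one_over_e(self):
        rt = GAS_CONSTANT_KCAL * T_ROOM
        assert eyring_rate_from_energy(rt, T_ROOM) == pytest.approx(
            eyring_prefactor(T_ROOM) / np.e, rel=1e-12
        )

    def test_unit_rate_barrier_matches_high_precision_value(self):
        assert eyring_energy_from_rate(1.0, T_ROOM) == pytest.approx(
            E_A_FOR_UNIT_RATE, rel=1e-12
        )

    def test_round_trip_identity(self):
        energies = np.linspace(-5, 40, 10)
        temps = np.linspace(250, 450, 10)
        for t in temps:
            back = eyring_energy_from_rate(eyring_rate_from_energy(energies, t), t)
            np.testing.assert_allclose(back, energies, rtol=1e-10, atol=1e-10)

    def test_monotone_decreasing_in_barrier(self, rng):
        e = np.sort(rng.uniform(-10, 50, size=(100, 2)), axis=1)
        k = eyring_rate_from_energy(e, 310.0)
        assert np.all(k[:, 0] > k[:, 1])

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            eyring_energy_from_rate(0.0, T_ROOM)
        with pytest.raises(ValueError):
            eyring_energy_from_rate(-1.0, T_ROOM)
        with pytest.raises(ValueError):
            eyring_rate_from_energy(np.inf, T_ROOM)
        with pytest.raises(ValueError):
            eyring_prefactor(-5.0)


def head(rng, n_slots=3):
    return init_head_params(rng, n_slots)


class TestForward:
    def test_all_zero_inputs_give_half_sigmoids(self, rng):
        p = head(rng)
        dec = forward(np.zeros(3), HammettVector(0.0, 0.0), p)
        assert dec.dG_total == pytest.approx(0.5 * p.w_final.sum(), rel=1e-12)
        assert dec.dG_L == pytest.approx(0.5 * p.w_final[1])
        assert dec.dG_LS == pytest.approx(0.5 * p.w_final[0])

    def test_zero_final_weights_give_attempt_frequency_rate(self, rng):
        p = head(rng)
        p.w_final[:] = 0.0
        dec = forward(np.array([0.3, -0.2, 1.0]), HammettVector(0.5, 0.0), p)
        assert dec.dG_total == 0.0
        assert dec.k_pred == pytest.approx(eyring_prefactor(T_ROOM))

    def test_matches_hand_rolled_forward(self, rng):
        p = head(rng)
        g = rng.normal(size=3)
        hv = HammettVector(0.2, 0.0)
        dec = forward(g, hv, p, temperature_K=305.0)
        x1 = np.concatenate([[hv.sigma_meta, hv.sigma_para], g])
        s = lambda z: 1.0 / (1.0 + np.exp(-z))
        dls = p.w_final[0] * s(float(x1 @ p.w_h1))
        dl = p.w_final[1] * s(float(g @ p.w_h2))
        assert dec.dG_LS == pytest.approx(dls, rel=1e-12)
        assert dec.dG_L == pytest.approx(dl, rel=1e-12)
        assert dec.k_pred == pytest.approx(
            eyring_rate_from_energy(dls + dl, 305.0), rel=1e-12
        )

    def test_additivity_exact_and_components_bounded(self, rng):
        for _ in range(200):
            p = head(rng)
            g = rng.normal(scale=3, size=(5, 3))
            hv = rng.normal(scale=0.5, size=(5, 2))
            res = forward_batch(g, hv, p, T_ROOM)
            assert np.all(res["dG_total"] == res["dG_L"] + res["dG_LS"])
            assert np.all((res["dG_L"] >= 0) & (res["dG_L"] <= p.w_final[1]))
            assert np.all((res["dG_LS"] >= 0) & (res["dG_LS"] <= p.w_final[0]))

    def test_corrupt_params_refused(self, rng):
        p = head(rng)
        p.w_h2[0] = -0.1
        with pytest.raises(ConstraintError):
            forward_batch(np.zeros((1, 3)), np.zeros((1, 2)), p, T_ROOM)
        p = head(rng)
        p.w_final[1] = -1.0
        with pytest.raises(ConstraintError):
            forward(np.zeros(3), HammettVector(0, 0), p)

    def test_head_gradients_match_finite_differences(self, rng):
        p = head(rng, n_slots=4)
        g = rng.normal(size=(6, 4))
        hv = rng.normal(scale=0.5, size=(6, 2))
        weights = rng.normal(size=6)

        def loss():
            return float(weights @ forward_batch(g, hv, p, T_ROOM)["dG_total"])

        res = forward_batch(g, hv, p, T_ROOM, keep_cache=True)
        d1, d2, df, dg = backward_batch(weights, res["cache"], p)
        eps = 1e-6
        for arr, grad in [(p.w_h1, d1), (p.w_h2, d2), (p.w_final, df)]:
            for i in range(arr.size):
                arr[i] += eps
                up = loss()
                arr[i] -= 2 * eps
                dn = loss()
                arr[i] += eps
                np.testing.assert_allclose(grad[i], (up - dn) / (2 * eps), atol=1e-6)


def test_projection_clips_constrained_weights(rng):
    p = head(rng)
    p.w_h2 -= 10.0
    p.w_final -= 100.0
    p.project()
    assert np.all(p.w_h2 >= 0) and np.all(p.w_final >= 0)


def test_head_shape_validation():
    with pytest.raises(ValueError):
        EnergyHeadParams(w_h1=np.ones(4), w_h2=np.ones(3), w_final=np.ones(2))
    with pytest.raises(ValueError):
        EnergyHeadParams(w_h1=np.ones(5), w_h2=np.ones(3), w_final=np.ones(3))
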