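"""Network construction, membrane dynamics, damage, and the simulator loop."""

import numpy as np
import pytest

from spikeplane.network import (
    IB,
    LTS,
    DamageMask,
    DriveConfig,
    MembraneState,
    NetworkConfig,
    NeuronParams,
    apply_damage,
    build_topology,
    integrate_step,
    resting_state,
    simulate,
)


class TestNeuronParams:
    def test_presets_match_table(self):
        assert (IB.a, IB.b, IB.c, IB.d) == (0.02, 0.2, -55.0, 4.0)
        assert (LTS.a, LTS.b, LTS.c, LTS.d) == (0.02, 0.25, -65.0, 2.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(a=0.0, b=0.2, c=-65.0, d=2.0)
        with pytest.raises(ValueError):
            NeuronParams(a=0.02, b=0.2, c=35.0, d=2.0)


class TestRestingState:
    def test_ib_rests_at_minus_seventy(self):
        v, u = resting_state(IB)
        assert v == pytest.approx(-70.0, abs=1e-9)
        assert u == pytest.approx(-14.0, abs=1e-9)

    def test_lts_rest_within_physiological_range(self):
        v, _ = resting_state(LTS)
        assert -70.0 < v < -60.0

    @pytest.mark.parametrize("params", [IB, LTS])
    def test_fixed_point_zeroes_both_derivatives(self, params):
        v, u = resting_state(params)
        dv = 0.04 * v * v + 5 * v + 140 - u
        du = params.a * (params.b * v - u)
        assert abs(dv) < 1e-9 and abs(du) < 1e-9

    def test_no_resting_state_raises(self):
        with pytest.raises(ValueError):
            resting_state(NeuronParams(a=0.02, b=0.6, c=-65.0, d=2.0))


class TestTopology:
    def test_default_out_degree_and_connection_probability(self):
        cfg = NetworkConfig()
        syn = build_topology(cfg, np.random.default_rng(7))
        degrees = np.bincount(syn.pre[: cfg.n_exc * cfg.m_out], minlength=cfg.n_exc)
        assert (degrees == 50).all()
        assert degrees[0] / cfg.n_total == 0.05

    def test_structural_invariants(self, small_net):
        syn = build_topology(small_net, np.random.default_rng(0))
        assert not (syn.pre == syn.post).any()  # no self-connections
        exc_rows = syn.pre < small_net.n_exc
        lo, hi = small_net.delay_range_exc
        assert ((syn.delay[exc_rows] >= lo) & (syn.delay[exc_rows] <= hi)).all()
        assert (syn.delay[~exc_rows] == small_net.delay_inh).all()
        assert (syn.post[~exc_rows] < small_net.n_exc).all()  # inh targets excitatory
        # distinct targets per neuron
        for j in range(small_net.n_total):
            targets = syn.post[j * syn.m_out : (j + 1) * syn.m_out]
            assert len(np.unique(targets)) == syn.m_out
        assert (syn.w[exc_rows] == small_net.w_exc_init).all()
        assert (syn.w[~exc_rows] == small_net.w_inh_init).all()

    def test_pure_excitatory_population(self):
        cfg = NetworkConfig(n_total=50, n_exc=50, n_inh=0, m_out=5, delay_range_exc=(2, 6))
        syn = build_topology(cfg, np.random.default_rng(1))
        assert ((syn.delay >= 2) & (syn.delay <= 6)).all()

    def test_determinism(self, small_net):
        a = build_topology(small_net, np.random.default_rng(3))
        b = build_topology(small_net, np.random.default_rng(3))
        for field in ("pre", "post", "w", "delay"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_too_many_targets_rejected(self):
        cfg = NetworkConfig(n_total=10, n_exc=8, n_inh=2, m_out=10)
        with pytest.raises(ValueError):
            build_topology(cfg, np.random.default_rng(0))


class TestDamage:
    def test_empty_mask(self, small_net):
        mask = apply_damage(small_net, 0, np.random.default_rng(0))
        assert mask.n_damaged == 0

    def test_full_scale_damage_is_excitatory_only(self):
        cfg = NetworkConfig()
        mask = apply_damage(cfg, 300, np.random.default_rng(0))
        assert mask.n_damaged == 300
        assert (mask.indices < cfg.n_exc).all()
        assert len(np.unique(mask.indices)) == 300

    def test_determinism(self, small_net):
        a = apply_damage(small_net, 20, np.random.default_rng(5))
        b = apply_damage(small_net, 20, np.random.default_rng(5))
        assert np.array_equal(a.indices, b.indices)

    def test_excess_damage_rejected(self, small_net):
        with pytest.raises(ValueError):
            apply_damage(small_net, small_net.n_exc + 1, np.random.default_rng(0))


def _single_state(v, u, i=0.0):
    return MembraneState(
        v=np.array([v], float), u=np.array([u], float), I=np.array([i], float)
    )


class TestIntegrateStep:
    def _arrays(self, p):
        return tuple(np.array([getattr(p, k)]) for k in "abcd")

    def test_fixed_point_is_stationary(self):
        a, b, c, d = self._arrays(IB)
        state = _single_state(-70.0, -14.0)
        fired, rec = integrate_step(state, a, b, c, d)
        assert fired.size == 0
        assert state.v[0] == pytest.approx(-70.0, abs=1e-9)
        assert state.u[0] == pytest.approx(-14.0, abs=1e-9)

    def test_spike_is_reset_and_clamped(self):
        a, b, c, d = self._arrays(IB)
        state = _single_state(31.0, -14.0)
        fired, rec = integrate_step(state, a, b, c, d)
        assert fired.tolist() == [0]
        assert rec[0] == 30.0
        assert state.v[0] == IB.c
        # u was advanced by one Euler step from -14 and then incremented by d

    def test_damaged_neuron_is_skipped(self):
        a, b, c, d = self._arrays(IB)
        state = _single_state(31.0, -14.0, i=100.0)
        fired, rec = integrate_step(state, a, b, c, d, damaged=np.array([True]))
        assert fired.size == 0
        assert state.v[0] == 31.0 and state.u[0] == -14.0

    def test_non_finite_state_raises(self):
        a, b, c, d = self._arrays(IB)
        state = _single_state(np.nan, -14.0)
        with pytest.raises(FloatingPointError):
            integrate_step(state, a, b, c, d)


class TestSimulate:
    def test_uncoupled_network_relaxes_to_rest(self, small_net):
        from dataclasses import replace

        cfg = replace(small_net, w_exc_init=0.0, w_inh_init=0.0)
        v0 = np.full(cfg.n_total, -60.0)
        res = simulate(
            cfg, 1000, drive=DriveConfig(kind="none"), rng_topology=0, rng_drive=1, v_init=v0
        )
        assert len(res.raster) == 0
        v_end = res.v_mv[-1]
        rests = np.array(
            [resting_state(IB)[0]] * cfg.n_exc + [resting_state(LTS)[0]] * cfg.n_inh
        )
        assert np.abs(v_end - rests).max() < 1e-3

    def test_activity_in_physiological_band(self, small_net, stdp_params):
        res = simulate(small_net, 10_000, plasticity=stdp_params, rng_topology=2, rng_drive=3)
        rates = np.bincount(res.raster.neurons, minlength=small_net.n_total) / 10.0
        assert len(res.raster) > 0
        assert 0.1 <= rates.mean() <= 100.0

    def test_determinism(self, small_net, stdp_params):
        runs = [
            simulate(small_net, 2000, plasticity=stdp_params, rng_topology=4, rng_drive=5)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].raster.times, runs[1].raster.times)
        assert np.array_equal(runs[0].raster.neurons, runs[1].raster.neurons)
        assert np.array_equal(runs[0].v_mv, runs[1].v_mv)
        assert np.array_equal(runs[0].synapses.w, runs[1].synapses.w)

    def test_raster_and_reset_invariants(self, small_net, stdp_params):
        dmg = apply_damage(small_net, 10, np.random.default_rng(6))
        res = simulate(
            small_net, 3000, plasticity=stdp_params, damage=dmg, rng_topology=6, rng_drive=7
        )
        assert len(res.raster) > 0
        assert (res.raster.times >= 0).all() and (res.raster.times < 3000).all()
        assert not np.isin(res.raster.neurons, dmg.indices).any()
        # stored traces clamp the spike peak and the damaged clamp holds
        for t, i in zip(res.raster.times[:200], res.raster.neurons[:200]):
            assert res.v_mv[t, i] == 30.0
        assert (res.v_mv[:, dmg.indices] == res.v_mv[0, dmg.indices]).all()

    def test_weights_stay_bounded(self, small_net, stdp_params):
        res = simulate(small_net, 5000, plasticity=stdp_params, rng_topology=8, rng_drive=9)
        exc = res.synapses.pre < small_net.n_exc
        assert (res.synapses.w[exc] >= 0).all()
        assert (res.synapses.w[exc] <= stdp_params.w_max).all()
        assert (res.synapses.w[~exc] == small_net.w_inh_init).all()  # inhibitory static

    def test_damage_reduces_expected_spike_count(self, small_net, stdp_params):
        totals = {0: [], 40: []}
        for seed in range(5):
            for n_dam in totals:
                dmg = apply_damage(small_net, n_dam, np.random.default_rng([50, seed]))
                res = simulate(
                    small_net,
                    3000,
                    plasticity=stdp_params,
                    damage=dmg,
                    rng_topology=seed,
                    rng_drive=100 + seed,
                )
                totals[n_dam].append(len(res.raster))
        assert np.mean(totals[40]) <= np.mean(totals[0])

    def test_short_duration_rejected(self, small_net):
        with pytest.raises(ValueError):
            simulate(small_net, 500)
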