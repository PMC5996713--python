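import numpy as np
import pytest

from effconn import lif
from effconn.graphs import enumerate_dags
from effconn.lif import (
    CircuitParameters,
    ExternalInputParameters,
    InterCircuitParameters,
    SimulationSettings,
    build_connectivity,
    generate_nn_dataset,
    ou_rate_series,
    simulate,
)

CAT1 = enumerate_dags(1)
NO_EXT = ExternalInputParameters(nu0=0.0, ou_sigma=0.0)


def tiny_circuit(n=60, **kw):
    return CircuitParameters(n_neurons=n, **kw)


class TestParameterValidation:
    def test_rise_must_be_below_decay(self):
        with pytest.raises(ValueError):
            CircuitParameters(tau_rA=3.0, tau_dA=2.0)

    def test_reset_below_threshold(self):
        with pytest.raises(ValueError):
            CircuitParameters(v_res=20.0, v_thr=18.0)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            CircuitParameters(p_conn_intra=1.5)
        with pytest.raises(ValueError):
            InterCircuitParameters(p_conn_inter=-0.1)

    def test_inter_efficacy_order(self):
        with pytest.raises(ValueError):
            InterCircuitParameters(j_int_low=0.2, j_int_high=0.1)

    def test_lfp_dt_multiple_of_dt(self):
        with pytest.raises(ValueError):
            SimulationSettings(dt=0.3, lfp_dt=1.0)

    def test_dt_too_coarse_for_gaba_rise(self, catalog):
        settings = SimulationSettings(dt=0.25, duration=10.0, lfp_dt=0.5)
        with pytest.raises(ValueError, match="tau_rG"):
            simulate(catalog[0], tiny_circuit(), settings=settings, seed=0)

    def test_latency_must_align_to_dt(self, catalog):
        circ = tiny_circuit(tau_L=0.13)
        with pytest.raises(ValueError, match="multiple"):
            simulate(catalog[0], circ, settings=SimulationSettings(duration=5.0), seed=0)


class TestOuRateSeries:
    def test_zero_sigma_constant(self):
        settings = SimulationSettings(duration=100.0)
        rate = ou_rate_series(ExternalInputParameters(ou_sigma=0.0), settings,
                              np.random.default_rng(0))
        assert np.all(rate == 2.0)

    def test_stationary_sd(self):
        settings = SimulationSettings(duration=60_000.0)
        params = ExternalInputParameters(nu0=100.0, ou_tau=16.0, ou_sigma=0.4)
        rate = ou_rate_series(params, settings, np.random.default_rng(1))
        noise = rate - 100.0  # nu0 large enough that rectification never binds
        assert noise.std() == pytest.approx(0.4, rel=0.05)

    def test_autocorrelation_matches_ou_closed_form(self):
        settings = SimulationSettings(duration=120_000.0)
        params = ExternalInputParameters(nu0=100.0, ou_tau=8.0, ou_sigma=0.5)
        rate = ou_rate_series(params, settings, np.random.default_rng(2))
        n = rate - 100.0
        n = n - n.mean()
        for k_ms in (2.0, 8.0):
            k = int(k_ms / settings.dt)
            rho = (n[:-k] @ n[k:]) / (len(n) - k) / n.var()
            assert rho == pytest.approx(np.exp(-k_ms / 8.0), abs=0.04)

    def test_rectification_nonnegative(self):
        settings = SimulationSettings(duration=5000.0)
        params = ExternalInputParameters(nu0=0.0, ou_sigma=5.0)
        rate = ou_rate_series(params, settings, np.random.default_rng(3))
        assert rate.min() >= 0.0


class TestConnectivity:
    def test_empty_config_no_inter_synapses(self, catalog):
        table = build_connectivity(
            catalog[0], tiny_circuit(200), InterCircuitParameters(),
            SimulationSettings(), np.random.default_rng(0),
        )
        assert table.n_inter_synapses() == 0

    def test_intra_count_binomial(self, catalog):
        n = 200
        table = build_connectivity(
            catalog[0], tiny_circuit(n), InterCircuitParameters(),
            SimulationSettings(), np.random.default_rng(1),
        )
        mean = 3 * n * (n - 1) * 0.2
        sd = np.sqrt(3 * n * (n - 1) * 0.2 * 0.8)
        assert abs(table.n_intra_synapses() - mean) < 4 * sd

    def test_univariate_inter_structure(self, univariate_config):
        n = 100
        circ = tiny_circuit(n)
        table = build_connectivity(
            univariate_config, circ, InterCircuitParameters(),
            SimulationSettings(), np.random.default_rng(2),
        )
        src_circ = np.repeat(table.circuit_id, np.diff(table.indptr))
        src_idx = np.repeat(np.arange(3 * n), np.diff(table.indptr))
        inter = table.circuit_id[table.targets] != src_circ
        assert inter.sum() > 0
        # all inter synapses go X -> Y, from excitatory senders
        assert np.all(src_circ[inter] == 0)
        assert np.all(table.circuit_id[table.targets[inter]] == 1)
        assert not np.any(table.is_inhibitory[src_idx[inter]])
        # receivers include both classes
        assert table.is_inhibitory[table.targets[inter]].any()
        assert (~table.is_inhibitory[table.targets[inter]]).any()

    def test_j_int_drawn_within_bounds(self, chain_config):
        inter = InterCircuitParameters(j_int_low=0.05, j_int_high=0.1)
        table = build_connectivity(
            chain_config, tiny_circuit(50), inter,
            SimulationSettings(), np.random.default_rng(3),
        )
        assert set(table.j_int_per_edge) == {(0, 1), (1, 2)}
        for v in table.j_int_per_edge.values():
            assert 0.05 <= v <= 0.1


class TestSimulateOracles:
    def test_no_input_silence(self, catalog):
        settings = SimulationSettings(duration=200.0)
        ts, rec = simulate(
            catalog[0], tiny_circuit(40), ext=NO_EXT, settings=settings,
            seed=0, record_spikes=True,
        )
        assert len(rec.times) == 0
        assert np.all(ts.values == 0.0)

    def test_subthreshold_decay_closed_form(self):
        # single neuron, no input: V(T) = V0 exp(-T / tau_m)
        circ = CircuitParameters(n_neurons=1, p_conn_intra=0.0)
        T = 40.0
        settings = SimulationSettings(duration=T)
        _, _, v_final = simulate(
            CAT1[0], circ, ext=NO_EXT, settings=settings, seed=0,
            v_init=10.0, return_state=True,
        )
        expected = 10.0 * np.exp(-T / circ.tau_m_exc)
        assert v_final[0] == pytest.approx(expected, rel=1e-3)

    def test_synaptic_kernel_peak_time(self):
        # one presynaptic spike; I_A peaks tau_L + tdta after it, with
        # tdta = (tau_dA tau_rA / (tau_dA - tau_rA)) ln(tau_dA / tau_rA)
        circ = CircuitParameters(
            n_neurons=3, frac_excitatory=2 / 3, p_conn_intra=1.0,
            j_exc=(1e-4, 1e-4), j_inh=(1e-4, 1e-4),
        )
        settings = SimulationSettings(duration=10.0, lfp_dt=0.05)
        v0 = np.array([25.0, 0.0, 0.0])
        ts, _ = simulate(CAT1[0], circ, ext=NO_EXT, settings=settings, seed=0, v_init=v0)
        lfp = ts.values[0]
        k = int(np.argmax(lfp))
        # sub-sample refinement by parabolic interpolation
        y0, y1, y2 = lfp[k - 1], lfp[k], lfp[k + 1]
        delta = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
        t_peak = (k + delta + 1) * settings.lfp_dt
        tdta = (circ.tau_dA * circ.tau_rA / (circ.tau_dA - circ.tau_rA)) * np.log(
            circ.tau_dA / circ.tau_rA
        )
        assert t_peak == pytest.approx(circ.tau_L + tdta, rel=1e-3)

    def test_lfp_nonnegative(self, univariate_config):
        settings = SimulationSettings(duration=300.0)
        ts, _ = simulate(univariate_config, tiny_circuit(80), settings=settings, seed=4)
        assert ts.values.min() >= 0.0
        assert np.isfinite(ts.values).all()

    def test_seed_determinism(self, chain_config):
        settings = SimulationSettings(duration=250.0)
        a, _ = simulate(chain_config, tiny_circuit(60), settings=settings, seed=11)
        b, _ = simulate(chain_config, tiny_circuit(60), settings=settings, seed=11)
        c, _ = simulate(chain_config, tiny_circuit(60), settings=settings, seed=12)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_lfp_shape_and_names(self, catalog):
        settings = SimulationSettings(duration=500.0)
        ts, _ = simulate(catalog[0], tiny_circuit(40), settings=settings, seed=0)
        assert ts.values.shape == (3, 500)
        assert ts.channel_names == ("X", "Y", "Z")
        assert ts.sampling_interval == 1.0


class TestGenerateDataset:
    def test_balanced_and_deterministic(self, catalog):
        circ = tiny_circuit(30)
        settings = SimulationSettings(duration=120.0)
        ds1 = generate_nn_dataset(catalog, 1, circ, settings=settings, seed=5)
        ds2 = generate_nn_dataset(catalog, 1, circ, settings=settings, seed=5)
        assert len(ds1) == 25
        assert np.bincount(ds1.labels).tolist() == [1] * 25
        assert ds1.labels.tolist() == ds2.labels.tolist()
        for a, b in zip(ds1, ds2):
            assert np.array_equal(a.timeseries.values, b.timeseries.values)
        assert ds1.metadata == ds2.metadata

    def test_example_count_arithmetic(self, catalog):
        circ = tiny_circuit(20)
        settings = SimulationSettings(duration=60.0)
        ds = generate_nn_dataset(catalog, 2, circ, settings=settings, seed=0)
        assert len(ds) == 50

    def test_n_per_config_validated(self, catalog):
        with pytest.raises(ValueError):
            generate_nn_dataset(catalog, 0, tiny_circuit(10), seed=0)
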