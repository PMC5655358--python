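import numpy as np
import pytest

from sdglu import SDModel, baseline_protocol, perfusion_protocol, simulate
from sdglu.model import S
from sdglu.simulation import action_potential_waveform, uptake_decomposition


@pytest.fixture(scope="module")
def short_baseline(model):
    return simulate(model, baseline_protocol(), 30_000.0, rtol=1e-7)


@pytest.fixture(scope="module")
def short_perfusion(model):
    """Ninety seconds of perfusion: ignition and early SD."""
    return simulate(model, perfusion_protocol(), 90_000.0, rtol=1e-6)


class TestBaselineStability:
    def test_state_stays_at_rest(self, short_baseline):
        V = short_baseline.V
        assert np.max(np.abs(V - V[0])) < 0.1 * 0.001 * abs(V[0]) + 1e-3

    def test_conservation_drift_negligible(self, short_baseline):
        drift = short_baseline.conservation_drift()
        for key, val in drift.items():
            assert val < 1e-8, key


class TestDeterminism:
    def test_identical_runs_identical_hashes(self, model):
        a = simulate(model, baseline_protocol(), 5_000.0, rtol=1e-7)
        b = simulate(model, baseline_protocol(), 5_000.0, rtol=1e-7)
        assert a.state_hash() == b.state_hash()


class TestTrajectoryExport:
    def test_frame_has_documented_columns(self, short_baseline):
        df = short_baseline.to_frame()
        for col in ("t_ms", "V_mV", "k_e_mM", "na_n_mM", "G_c_mM", "G_e_mM",
                    "omega_n_um3", "omega_e_um3", "dNK_fmol"):
            assert col in df.columns
        assert len(df) == len(short_baseline.t)

    def test_time_grid_strictly_increasing(self, short_perfusion):
        assert np.all(np.diff(short_perfusion.t) > 0)

    def test_slow_variable_is_sum_of_parts(self, short_perfusion):
        lhs = short_perfusion.delta_n_k
        rhs = short_perfusion.delta_n_glia_k + short_perfusion.delta_n_bath_k
        assert np.allclose(lhs, rhs, rtol=0, atol=1e-12)


class TestConservationAlongSD:
    def test_totals_conserved_through_ignition(self, short_perfusion):
        """Glutamate, per-ion closed-system totals, and volume drift by less
        than 1e-6 relative across the SD ignition transient."""
        drift = short_perfusion.conservation_drift()
        for key, val in drift.items():
            assert val < 1e-6, (key, val)

    def test_pools_and_gates_stay_in_range(self, short_perfusion):
        y = short_perfusion.y
        assert np.all(y[:, [S.N, S.H, S.SNA, S.R_NMDA, S.R_AMPA]] >= -1e-9)
        assert np.all(y[:, [S.N, S.H, S.SNA, S.R_NMDA, S.R_AMPA]] <= 1.0 + 1e-9)
        assert np.all(y[:, S.GLU_I:] >= -1e-12)
        assert np.all(short_perfusion.omega_e > 0)


class TestUptakeDecomposition:
    def test_pathways_non_decreasing_and_account_for_buffered(self, short_perfusion):
        df = uptake_decomposition(short_perfusion)
        for col in ("cleft_to_neuron", "cleft_to_glia", "ecs_to_neuron", "ecs_to_glia"):
            assert np.all(np.diff(df[col].to_numpy()) >= -1e-12)
        total = (df["cleft_to_neuron"] + df["cleft_to_glia"]
                 + df["ecs_to_neuron"] + df["ecs_to_glia"])
        reconstructed = total - df["recycled"]
        scale = max(df["buffered"].abs().max(), 1e-9)
        assert np.max(np.abs(reconstructed - df["buffered"])) < 2e-2 * scale

    def test_glial_uptake_dominates_neuronal_from_cleft(self, short_perfusion):
        df = uptake_decomposition(short_perfusion)
        late = df.iloc[-1]
        assert late["cleft_to_glia"] > late["cleft_to_neuron"]

    def test_zero_uptake_protocol_clears_nothing(self, model):
        from sdglu.protocols import impaired_uptake

        traj = simulate(model, impaired_uptake(baseline_protocol(), 0.0), 10_000.0,
                        rtol=1e-7)
        df = uptake_decomposition(traj)
        assert float(df.iloc[-1][["cleft_to_neuron", "cleft_to_glia",
                                  "ecs_to_neuron", "ecs_to_glia"]].abs().max()) == 0.0


class TestReleaseCalibration:
    def test_one_ap_releases_three_thousand_molecules(self, model):
        """The frozen R_max reproduces the one-AP calibration: integrating
        the release flux over a simulated action potential yields 3,000
        molecules per synapse."""
        from sdglu.constants import amount_from_molecules
        from sdglu.glutamate import release_flux

        t, V = action_potential_waveform(model)
        p = model.release
        flux = np.array([release_flux(v, p.N_max, p) for v in V])
        released = np.trapezoid(flux, t)
        assert released == pytest.approx(amount_from_molecules(3000.0), rel=0.01)

    def test_waveform_is_a_single_spike(self, model):
        t, V = action_potential_waveform(model)
        assert V.max() > 0.0
        assert V[-1] < -60.0


class TestGuards:
    def test_negative_t_end_rejected(self, model):
        with pytest.raises(ValueError):
            simulate(model, baseline_protocol(), -1.0)


class TestTimescaleOrdering:
    def test_slow_pools_are_the_slowest_state_group(self, short_perfusion):
        """Normalized by each group's dynamic range, the combined glial+bath
        K+ pool moves more slowly than the membrane, ion, and glutamate
        groups both at rest and through SD ignition."""
        tr = short_perfusion
        dt = np.diff(tr.t)

        def normalized_rate(series):
            """Peak rate of change in units of the series' own range."""
            rng = np.ptp(series)
            if rng == 0:
                return 0.0
            return float(np.max(np.abs(np.diff(series)) / dt) / rng)

        slow = normalized_rate(tr.delta_n_k)
        fast_groups = {
            "membrane": normalized_rate(tr.V),
            "gates": normalized_rate(tr.y[:, S.N]),
            "ions": normalized_rate(tr.concentration("k_e")),
            "glutamate": normalized_rate(tr.G_c),
        }
        for name, rate in fast_groups.items():
            assert slow < rate, (name, slow, rate)
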