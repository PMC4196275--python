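import numpy as np
import pytest

from cisclock.grn_model import GrnModel, canonical_initial_state
from cisclock.interfaces import PsmConfig, RunConfig
from cisclock.simulation import run_simulation
from cisclock.sync_metrics import estimate_period_amplitude
from cisclock.tissue import (
    GradientSpec, GrowthOptions, PsmTissue, advance_growth, build_tissue,
    gradient_modifier, neighbor_mean,
)


class TestGeometry:
    @pytest.mark.parametrize("shape,mode,interior", [
        ((9,), "von_neumann", 2),
        ((7, 7), "von_neumann", 4),
        ((7, 7, 7), "von_neumann", 6),
        ((7, 7), "extended", 8),
        ((5, 5, 5), "extended", 26),
    ])
    def test_interior_neighbor_counts(self, shape, mode, interior):
        t = build_tissue(shape, mode)
        counts = t.neighbor_counts()
        center = t.cell_index(tuple(s // 2 for s in shape))
        assert counts[center] == interior
        assert counts.max() == interior  # no wrap: nobody exceeds interior

    def test_corner_and_edge_reduction(self):
        t = build_tissue((4, 4))
        assert t.neighbor_counts()[t.cell_index((0, 0))] == 2
        assert t.neighbor_counts()[t.cell_index((0, 1))] == 3

    @pytest.mark.parametrize("shape,mode", [
        ((5,), "von_neumann"), ((3, 4), "von_neumann"),
        ((3, 3, 3), "von_neumann"), ((3, 4), "extended"),
        ((3, 3, 3), "extended"),
    ])
    def test_symmetry_and_no_self(self, shape, mode):
        t = build_tissue(shape, mode)
        for i, nbs in enumerate(t.neighbor_lists):
            assert i not in nbs
            for j in nbs:
                assert i in t.neighbor_lists[j]

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            build_tissue((0, 3))
        with pytest.raises(ValueError):
            build_tissue((2, 2, 2, 2))
        with pytest.raises(ValueError):
            build_tissue((3, 3), "hexagonal")


class TestNeighborMean:
    def test_uniform_field(self):
        t = build_tissue((4, 4))
        np.testing.assert_allclose(neighbor_mean(t, np.full(16, 3.5)), 3.5)

    def test_chain_average(self):
        t = build_tissue((3,))
        np.testing.assert_allclose(neighbor_mean(t, np.array([1.0, 2.0, 3.0])),
                                   [2.0, 2.0, 2.0])

    def test_isolated_cell_returns_zero(self):
        t = build_tissue((1,))
        assert neighbor_mean(t, np.array([7.0]))[0] == 0.0

    def test_wrong_length_rejected(self):
        t = build_tissue((3,))
        with pytest.raises(ValueError):
            neighbor_mean(t, np.zeros(4))


class TestGradient:
    def test_maximal_at_posterior_and_monotone(self):
        spec = GradientSpec(amplitude=0.5, length_scale=5.0)
        d = np.arange(0, 30.0)
        f = gradient_modifier(d, spec)
        assert f[0] == pytest.approx(1.5)
        assert np.all(np.diff(f) <= 0)
        assert f[-1] == pytest.approx(1.0, abs=0.01)

    def test_zero_amplitude_is_identity(self):
        spec = GradientSpec(amplitude=0.0)
        assert gradient_modifier(12.0, spec) == 1.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GradientSpec(amplitude=-1.0)
        with pytest.raises(ValueError):
            GradientSpec(length_scale=0.0)


class TestGrowth:
    def _psm(self, **kw):
        growth = GrowthOptions(cell_cycle_min=30.0, mitosis_shutdown_min=kw.pop("shutdown", 20.0),
                               division_noise_percent=kw.pop("noise", 0.0),
                               jitter_min=kw.pop("jitter", 0.0), **kw)
        return PsmTissue(4, cross_section=(2, 2), growth=growth)

    def test_division_duplicates_posterior_row_and_conserves_state(self):
        psm = self._psm(shutdown=0.0)
        rng = np.random.default_rng(0)
        states = np.arange(16 * 13, dtype=float).reshape(16, 13)
        mothers = states[psm.row_cells(3)].copy()
        new_states, events = advance_growth(psm, states, clock=30.0, rng=rng)
        assert len(events) == 1
        assert psm.axial_length == 5
        assert new_states.shape[0] == 20
        np.testing.assert_array_equal(new_states[psm.row_cells(4)], mothers)
        np.testing.assert_array_equal(new_states[psm.row_cells(3)], mothers)

    def test_no_division_before_schedule(self):
        psm = self._psm()
        states = np.zeros((16, 13))
        new_states, events = advance_growth(psm, states, clock=29.9,
                                            rng=np.random.default_rng(0))
        assert events == [] and new_states.shape == (16, 13)

    def test_mitosis_window_gates_transcription(self):
        psm = self._psm(shutdown=20.0)
        states = np.zeros((16, 13))
        advance_growth(psm, states, clock=30.0, rng=np.random.default_rng(0))
        gate_mid = psm.transcription_gate(40.0)
        gate_after = psm.transcription_gate(50.1)
        dividing = np.concatenate([psm.row_cells(3), psm.row_cells(4)])
        assert np.all(gate_mid[dividing] == 0.0)
        assert np.all(np.delete(gate_mid, dividing) == 1.0)
        assert np.all(gate_after == 1.0)

    def test_growth_capped_at_max_length(self):
        growth = GrowthOptions(cell_cycle_min=10.0, jitter_min=0.0, max_length=5)
        psm = PsmTissue(4, cross_section=(2, 2), growth=growth)
        states = np.zeros((16, 13))
        states, _ = advance_growth(psm, states, clock=10.0, rng=np.random.default_rng(0))
        states, events = advance_growth(psm, states, clock=1000.0,
                                        rng=np.random.default_rng(0))
        assert psm.axial_length == 5 and events == []

    def test_division_noise_only_scales_up(self):
        psm = PsmTissue(4, cross_section=(2, 2),
                        growth=GrowthOptions(cell_cycle_min=30.0, jitter_min=0.0,
                                             division_noise_percent=100.0))
        base = canonical_initial_state(GrnModel())
        states = np.tile(base, (16, 1))
        new_states, _ = advance_growth(psm, states, clock=30.0,
                                       rng=np.random.default_rng(1))
        daughters = np.concatenate([psm.row_cells(3), psm.row_cells(4)])
        ratio = new_states[daughters] / base
        assert np.all(ratio >= 1.0) and np.all(ratio <= 2.0)
        untouched = np.delete(np.arange(20), daughters)
        np.testing.assert_array_equal(new_states[untouched],
                                      np.tile(base, (len(untouched), 1)))


class TestWaveSlowing:
    def test_anterior_cells_oscillate_slower_than_posterior(self):
        # FGF8-gradient coupling: posterior cells see faster HES7 decay and a
        # shorter period; anterior cells slow down (the wave mechanism)
        cfg = RunConfig(steps=20000, noise_percent=0.0, neighborhood="extended",
                        psm=PsmConfig(enabled=True, initial_length=12,
                                      cell_cycle_min=1e6,  # no divisions: pure gradient
                                      gradient_amplitude=0.5,
                                      gradient_length_scale=4.0))
        trace = run_simulation(cfg)
        V = trace.matrix("hes7.mC")
        n_cross = 21
        anterior = V[:, :n_cross].mean(axis=1)
        posterior = V[:, -n_cross:].mean(axis=1)
        pa_ant = estimate_period_amplitude(anterior, dt=1.0, burn_in_min=400)
        pa_post = estimate_period_amplitude(posterior, dt=1.0, burn_in_min=400)
        assert pa_ant.period >= pa_post.period
        assert pa_ant.period > pa_post.period * 1.02
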