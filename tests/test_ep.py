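"""Ionic model dynamics, FEM assembly oracles, and tissue-level physics."""

import numpy as np
import pytest

from lapwsim import courtemanche
from lapwsim.courtemanche import (
    GATE_IDX,
    IV,
    courtemanche_rhs,
    initial_state,
    ionic_step,
    step_nodes,
)
from lapwsim.ep import (
    SimulationConfig,
    StimulusProtocol,
    assemble,
    select_stimulus_nodes,
    simulate,
    stability_limit,
)


def run_single_cell(duration_ms, dt, stim_amplitude=0.0, stim_duration=0.0):
    S = initial_state()[None, :].copy()
    n = int(round(duration_ms / dt))
    V = np.empty(n)
    ist = np.zeros(1)
    for k in range(n):
        ist[0] = stim_amplitude if k * dt < stim_duration else 0.0
        step_nodes(S, dt, ist)
        V[k] = S[0, IV]
    return np.arange(1, n + 1) * dt, V


class TestCourtemanche:
    def test_resting_state_is_stationary(self):
        dy = courtemanche_rhs(initial_state())
        assert abs(dy[IV]) < 0.02

    def test_quiescent_cell_stays_at_rest_for_one_second(self):
        _, V = run_single_cell(1000.0, 0.01)
        assert np.max(np.abs(V - initial_state()[IV])) < 0.5

    def test_stimulated_action_potential_shape(self):
        # clinical-strength stimulus: 25 pA/pF for 2.5 ms
        t, V = run_single_cell(600.0, 0.005, stim_amplitude=25.0, stim_duration=2.5)
        v_rest = initial_state()[IV]
        v_peak = V.max()
        assert v_peak > 0.0
        v90 = v_peak - 0.9 * (v_peak - v_rest)
        i_peak = int(V.argmax())
        below = np.flatnonzero(V[i_peak:] <= v90)
        apd90 = t[i_peak + below[0]] - t[i_peak]
        assert 250.0 <= apd90 <= 350.0

    def test_gates_at_steady_state_have_zero_derivative(self):
        y = initial_state()
        inf = np.zeros(courtemanche.NSTATE)
        tau = np.ones(courtemanche.NSTATE)
        dy = np.zeros(courtemanche.NSTATE)
        courtemanche._cell_rates(y, 0.0, inf, tau, dy)
        y_clamped = y.copy()
        for g in GATE_IDX:
            y_clamped[g] = inf[g]
        d = courtemanche_rhs(y_clamped)
        assert np.max(np.abs(d[list(GATE_IDX)])) < 1e-12

    def test_ionic_step_matches_forward_euler_as_dt_vanishes(self):
        y = initial_state()
        y[IV] = -60.0  # off-rest so gates actually move
        dy = courtemanche_rhs(y, 0.0)
        for dt in (1e-3, 1e-4):
            stepped, _ = ionic_step(y, dt)
            euler = y + dt * dy
            # Rush–Larsen deviates from Euler at O(dt²)
            assert np.max(np.abs(stepped - euler)) < 20.0 * dt**2 + 1e-12

    def test_step_halving_consistency_at_rest(self):
        y = initial_state()
        full, _ = ionic_step(y, 0.02)
        half, _ = ionic_step(y, 0.01)
        half2, _ = ionic_step(half, 0.01)
        assert abs(full[IV] - half2[IV]) < 1e-3

    def test_gates_remain_in_unit_interval_through_an_ap(self):
        S = initial_state()[None, :].copy()
        ist = np.zeros(1)
        for k in range(20000):
            ist[0] = 25.0 if k * 0.02 < 2.5 else 0.0
            step_nodes(S, 0.02, ist)
        gates = S[0, list(GATE_IDX)]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ionic_step(initial_state(), -0.1)
        bad = initial_state()
        bad[IV] = np.nan
        with pytest.raises(ValueError):
            courtemanche_rhs(bad)


class TestAssembly:
    def test_single_tet_matches_hand_assembled_stiffness(self):
        from lapwsim.geometry import VolumeMesh

        # reference tet with mm coordinates chosen to give cm-unit edges of 1
        mesh = VolumeMesh(
            10.0 * np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
            np.array([[0, 1, 2, 3]]),
        )
        sigma = 2.0
        tensors = sigma * np.eye(3)[None, :, :]
        mass, K, active = assemble(mesh, tensors, SimulationConfig())
        # analytic P1 gradients on the unit tet: ∇φ0 = (-1,-1,-1), ∇φi = e_i
        grads = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        K_hand = (1.0 / 6.0) * sigma * grads @ grads.T
        assert np.allclose(K.toarray(), K_hand, atol=1e-12)
        assert np.allclose(mass, (1.0 / 6.0) / 4.0)

    def test_row_sums_vanish(self, slab_20mm, slab_20mm_field):
        from lapwsim.fibers import ConductivitySet, conductivity_tensor

        tensors = conductivity_tensor(slab_20mm_field, ConductivitySet())
        _, K, _ = assemble(slab_20mm, tensors, SimulationConfig())
        row_sums = np.abs(np.asarray(K.sum(axis=1))).max()
        assert row_sums < 1e-10 * np.abs(K.data).max()

    def test_lumped_mass_sums_to_active_volume(self, slab_20mm, slab_20mm_field):
        from lapwsim.fibers import ConductivitySet, conductivity_tensor
        from lapwsim.fibrosis import FibrosisSpec, apply_percolation, generate_pattern

        pattern = generate_pattern(
            slab_20mm, slab_20mm_field, FibrosisSpec(type="diffuse", density=0.35, seed=0)
        )
        tagged = apply_percolation(slab_20mm, pattern)
        tensors = conductivity_tensor(slab_20mm_field, ConductivitySet())
        mass, _, _ = assemble(tagged, tensors, SimulationConfig())
        active_volume_cm3 = (
            tagged.signed_volumes()[tagged.element_subdomain == 1].sum() / 1000.0
        )
        assert mass.sum() == pytest.approx(active_volume_cm3, rel=1e-9)


class TestStimulusSelection:
    def test_single_early_electrode_wins(self, small_slab):
        electrodes = np.array([[2.0, 5.0, 3.3], [8.0, 5.0, 3.3]])
        lats = np.array([10.0, 20.0])
        nodes = select_stimulus_nodes(small_slab, electrodes, lats, window=2.0)
        assert len(nodes) > 0
        assert np.all(small_slab.vertices[nodes][:, 0] < 5.0)

    def test_equal_lats_make_all_eligible(self, small_slab):
        electrodes = np.array([[2.0, 5.0, 3.3], [8.0, 5.0, 3.3]])
        nodes = select_stimulus_nodes(small_slab, electrodes, np.array([5.0, 5.0]))
        xs = small_slab.vertices[nodes][:, 0]
        assert xs.min() < 5.0 < xs.max()

    def test_exclusive_box_rejected(self, small_slab):
        electrodes = np.array([[2.0, 5.0, 3.3]])
        with pytest.raises(ValueError, match="empty"):
            select_stimulus_nodes(
                small_slab,
                electrodes,
                np.array([5.0]),
                box=((50.0, 50.0, 50.0), (60.0, 60.0, 60.0)),
            )


class TestSimulate:
    def test_rest_stays_rest_without_stimulus(self, small_slab, small_slab_tensors):
        cfg = SimulationConfig(dt=0.01, duration=100.0, stimuli=[])
        res = simulate(small_slab, small_slab_tensors, cfg)
        v_rest = initial_state()[IV]
        assert np.max(np.abs(res.vm - v_rest)) < 0.5

    def test_pure_diffusion_conserves_lumped_integral(self, small_slab, small_slab_tensors):
        cfg = SimulationConfig(dt=0.01, duration=50.0, stimuli=[])
        rng = np.random.default_rng(0)
        v0 = -81.18 + 10.0 * rng.random(len(np.unique(small_slab.tets)))
        res = simulate(
            small_slab, small_slab_tensors, cfg, disable_ionic=True, initial_vm=v0
        )
        totals = res.vm @ res.node_volumes_cm3
        assert np.max(np.abs(totals - totals[0])) < 1e-8 * abs(totals[0])

    def test_planar_wave_isochrones_and_cv(self, small_slab, small_slab_tensors):
        from lapwsim.fibers import measure_cv

        cfg = SimulationConfig(
            dt=0.01,
            duration=80.0,
            stimuli=[StimulusProtocol(box_min=(-1, -1, -1), box_max=(1.01, 11, 3.4))],
        )
        res = simulate(small_slab, small_slab_tensors, cfg)
        v = small_slab.vertices
        lat = res.lat
        assert np.all(np.isfinite(lat[res.active_nodes]))
        # isochrones are x-planes: LAT correlates tightly with x and the
        # slice means increase monotonically downstream of the stimulus
        act = res.active_nodes
        r = np.corrcoef(v[act, 0], lat[act])[0, 1]
        assert r > 0.97
        means = [lat[np.abs(v[:, 0] - x) < 0.1].mean() for x in range(2, 11, 2)]
        assert np.all(np.diff(means) > 0)
        start = np.flatnonzero(np.abs(v[:, 0] - 2) < 0.1)
        end = np.flatnonzero(np.abs(v[:, 0] - 8) < 0.1)
        m = measure_cv(v, lat, start, end)
        assert m.cv > 5.0  # physiological propagation, not numerical creep

    def test_stability_bound_enforced(self, small_slab, small_slab_tensors):
        cfg = SimulationConfig(dt=5.0, duration=10.0, stimuli=[])
        limit = stability_limit(small_slab, small_slab_tensors, cfg)
        assert limit < 5.0
        with pytest.raises(ValueError, match="stability"):
            simulate(small_slab, small_slab_tensors, cfg)

    def test_fibrotic_nodes_carry_no_state(self, small_slab, small_slab_field):
        from lapwsim.fibers import ConductivitySet, conductivity_tensor
        from lapwsim.fibrosis import FibrosisSpec, apply_percolation, generate_pattern

        pattern = generate_pattern(
            small_slab, small_slab_field, FibrosisSpec(type="compact", density=0.6, seed=2)
        )
        tagged = apply_percolation(small_slab, pattern)
        tensors = conductivity_tensor(small_slab_field, ConductivitySet())
        cfg = SimulationConfig(
            dt=0.01,
            duration=40.0,
            stimuli=[StimulusProtocol(box_min=(-1, -1, -1), box_max=(1.01, 11, 3.4))],
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = simulate(tagged, tensors, cfg)
        n_total = len(tagged.vertices)
        inactive = np.setdiff1d(np.arange(n_total), res.active_nodes)
        assert res.vm.shape[1] == len(res.active_nodes) < n_total
        assert np.all(np.isnan(res.lat[inactive]))
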