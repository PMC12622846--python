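import math

import numpy as np
import pytest

import twindom as td

from twindom.engine import (
    EventDraws,
    apply_gyrase,
    apply_topoI,
    bind_rnap,
    effective_initiation_rate,
    elongate_all,
    is_stalled,
    step,
    terminate_if_due,
    topo_channel_rates,
)
from twindom.state import init_state, sigma_of


def make_draws(seed=0):
    return EventDraws(np.random.default_rng(seed))


class TestInitiationRate:
    def test_occluded_promoter_silent(self):
        cfg = td.make_config()
        state = init_state(cfg)
        bind_rnap(state, cfg)
        # freshly bound RNAP sits at D_up - w/2: promoter occluded
        assert state.x[0] == pytest.approx(cfg.D_up - cfg.w / 2)
        assert effective_initiation_rate(state, cfg) == 0.0

    def test_half_maximal_at_sigmoid_midpoint(self):
        cfg = td.make_config(k_i=0.05, sigma_i=-0.04, sigma_start=-0.04)
        state = init_state(cfg)
        assert effective_initiation_rate(state, cfg) == pytest.approx(0.025)

    def test_direct_evaluation(self):
        cfg = td.make_config(k_i=0.05, sigma_i=-0.04, beta_i=0.005, sigma_start=-0.03)
        state = init_state(cfg)
        assert effective_initiation_rate(state, cfg) == pytest.approx(
            0.05 / (1 + math.e**2), rel=1e-12
        )

    def test_constant_mode_ignores_sigma(self):
        cfg = td.make_config(k_i=0.05, sigma_start=-0.01, sc_dependent_initiation=False)
        state = init_state(cfg)
        assert effective_initiation_rate(state, cfg) == 0.05


class TestBindRnap:
    def test_binding_splits_proportionally(self):
        cfg = td.make_config(D=10_000.0, L=1000.0, w=30.0, sigma_start=-0.05)
        state = init_state(cfg)
        bind_rnap(state, cfg)
        assert state.x == [9985.0]
        assert len(state.Lk) == 2
        assert sigma_of(state.Lk[0], 9985.0) == pytest.approx(-0.05)
        assert sigma_of(state.Lk[1], 21_000.0 - 9985.0) == pytest.approx(-0.05)
        assert sum(state.Lk) == pytest.approx(state.Lk_initial)

    def test_double_binding_impossible_without_elongation(self):
        cfg = td.make_config()
        state = init_state(cfg)
        bind_rnap(state, cfg)
        bind_rnap(state, cfg)  # occluded: ignored with a warning
        assert state.n_rnaps == 1
        assert state.initiations == 1


class TestStallingAndElongation:
    def _single_rnap_state(self, cfg, sigma_up, sigma_down):
        state = init_state(cfg)
        x = cfg.D_up + cfg.L / 2
        state.x = [x]
        state.birth = [0.0]
        state.Lk = [
            (1 + sigma_up) * x / cfg.h,
            (1 + sigma_down) * (cfg.total_length - x) / cfg.h,
        ]
        return state

    @pytest.mark.parametrize(
        "s_up,s_down,expected",
        [
            (-0.07, 0.0, True),  # upstream breach
            (-0.05, 0.05, False),  # both within bounds
            (-0.05, 0.063, True),  # downstream breach
            (-0.062, 0.0, False),  # exactly at threshold: not stalled (strict)
        ],
    )
    def test_stall_thresholds(self, s_up, s_down, expected):
        cfg = td.make_config()
        state = self._single_rnap_state(cfg, s_up, s_down)
        assert is_stalled(state, 0, cfg) is expected

    def test_twin_domain_stretch_arithmetic(self):
        # relaxed single RNAP at 5250 advancing 525 bp: upstream sigma -> -1/11.
        # Stalling is disabled so the pure fixed-Lk stretch arithmetic is isolated
        # (the deficit crosses the default threshold after ~350 bp).
        cfg = td.make_config(D_up=5250.0, D_down=5250.0, L=1000.0, sigma_s=10.0)
        state = init_state(cfg)
        state.x = [5250.0]
        state.birth = [0.0]
        state.Lk = [5250.0 / 10.5, (cfg.total_length - 5250.0) / 10.5]
        total_before = sum(state.Lk)
        for _ in range(525):
            elongate_all(state, cfg)
        assert state.x == [5775.0]
        s_up = sigma_of(state.Lk[0], 5775.0)
        s_down = sigma_of(state.Lk[1], cfg.total_length - 5775.0)
        assert s_up == pytest.approx(-0.0909, abs=1e-4)
        assert s_down > 0.0
        assert sum(state.Lk) == pytest.approx(total_before)  # conservation

    def test_twin_domain_sign_property(self):
        cfg = td.make_config(sigma_start=0.0)
        state = init_state(cfg)
        bind_rnap(state, cfg)
        for n_moves in range(1, 200):
            elongate_all(state, cfg)
            s_up = sigma_of(state.Lk[0], state.x[0])
            s_down = sigma_of(state.Lk[1], cfg.total_length - state.x[0])
            assert s_up < 0.0 < s_down

    def test_stalled_rnap_stays_put_neighbors_move(self):
        cfg = td.make_config()
        state = init_state(cfg)
        x1, x2 = cfg.D_up + 100.0, cfg.D_up + 500.0
        state.x = [x1, x2]
        state.birth = [0.0, 0.0]
        # stall the trailing RNAP with an extreme upstream deficit
        state.Lk = [
            (1 - 0.10) * x1 / cfg.h,
            (x2 - x1) / cfg.h,
            (cfg.total_length - x2) / cfg.h,
        ]
        elongate_all(state, cfg)
        assert state.x == [x1, x2 + 1.0]

    def test_blocked_by_leading_footprint(self):
        cfg = td.make_config()
        state = init_state(cfg)
        x2 = cfg.D_up + 500.0
        x1 = x2 - cfg.w  # gap exactly w: trailing cannot move unless leader does
        state.x = [x1, x2]
        state.birth = [0.0, 0.0]
        state.Lk = [x1 / cfg.h, (x2 - x1) / cfg.h, (cfg.total_length - x2) / cfg.h]
        # stall the leader via a huge downstream excess
        state.Lk[2] = (1 + 0.1) * (cfg.total_length - x2) / cfg.h
        elongate_all(state, cfg)
        assert state.x == [x1, x2]  # leader stalled, trailer blocked


class TestTermination:
    def test_terminator_removal_and_merge(self):
        cfg = td.make_config(sigma_start=-0.03)
        draws = make_draws()
        state = init_state(cfg)
        term = cfg.D_up + cfg.L
        state.x = [term]
        state.birth = [0.0]
        lk_up = (1 - 0.05) * term / cfg.h
        lk_down = (1 + 0.02) * (cfg.total_length - term) / cfg.h
        state.Lk = [lk_up, lk_down]
        state.time = 100.0
        terminate_if_due(state, cfg, draws)
        assert state.n_rnaps == 0
        assert len(state.Lk) == 1  # single domain-spanning segment restored
        assert state.Lk[0] == pytest.approx(lk_up + lk_down)  # length-weighted merge
        assert state.terminations == 1
        assert state.rna_count == 1
        assert state.decay_heap[0] > 100.0
        assert state.transit_times == [100.0]


class TestTopoisomerases:
    def test_channel_rates_at_midpoint(self):
        cfg = td.make_config(sigma_start=-0.04)  # TopoI sigmoid midpoint
        state = init_state(cfg)
        tIu, tId, gu, gd = topo_channel_rates(state, cfg)
        k_T = cfg.topoI.max_rate
        assert tIu + tId == pytest.approx(k_T * (cfg.D_up + cfg.D_down) / 2)

    def test_gyrase_channel_closed_below_threshold(self):
        cfg = td.make_config(sigma_start=-0.12)
        state = init_state(cfg)
        _, _, gu, gd = topo_channel_rates(state, cfg)
        assert gu == 0.0 and gd == 0.0

    def test_topoI_event_arithmetic(self):
        cfg = td.make_config(sigma_start=0.0)
        state = init_state(cfg)
        apply_topoI(state, "up")
        assert sigma_of(state.Lk[0], cfg.total_length) == pytest.approx(5e-4)
        assert state.topoI_events == 1

    def test_gyrase_called_below_threshold_is_an_error(self):
        cfg = td.make_config(sigma_start=-0.12)
        state = init_state(cfg)
        with pytest.raises(RuntimeError):
            apply_gyrase(state, "up", make_draws(), cfg)

    def test_gyrase_cycles_capped_at_sigma_rho(self):
        cfg = td.make_config(sigma_start=-0.109)
        state = init_state(cfg)
        before = state.Lk[0]
        apply_gyrase(state, "up", make_draws(3), cfg)
        # 21 kb domain: one cycle shifts sigma by -0.001, so at most 2 cycles
        # fit before the segment reaches sigma_rho = -0.11
        assert state.gyrase_cycles <= 2
        assert sigma_of(state.Lk[0], cfg.total_length) >= cfg.sigma_rho - 2 * 2 * 10.5 / cfg.total_length
        assert before - state.Lk[0] == pytest.approx(2.0 * state.gyrase_cycles)

    def test_geometric_cycle_mean(self):
        draws = make_draws(7)
        n = 50_000
        mean = sum(draws.geometric(4.0) for _ in range(n)) / n
        assert mean == pytest.approx(4.0, rel=0.03)


class TestStepAndRun:
    def test_null_dynamics(self):
        cfg = td.make_config(k_i=0.0, k_T=0.0, k_G=0.0)
        state = init_state(cfg)
        lk_before = list(state.Lk)
        step(state, cfg, make_draws())
        assert state.time == pytest.approx(cfg.dt)
        assert state.Lk == lk_before
        assert state.n_rnaps == 0

    def test_event_channel_poisson_mean(self):
        # With enormous barriers sigma stays constant, so TopoI events over a
        # window of T seconds are Poisson with mean k_T * fT(sigma) * (D_up+D_down) * T.
        cfg = td.make_config(
            D=1e9, k_i=0.0, k_T=0.5e-9, k_G=0.0, sigma_start=-0.04, n_steps=5000
        )
        from twindom.kinetics import sigmoid_rate

        expected_rate = sigmoid_rate(cfg.topoI, -0.04) * 2e9  # = 0.5/s
        traj = td.run(cfg, seed=5)
        T = cfg.n_steps * cfg.dt
        lam = expected_rate * T
        assert abs(traj.counters["topoI_events"] - lam) < 5 * math.sqrt(lam)

    def test_deterministic_replay(self):
        cfg = td.make_config(n_steps=4000)
        a = td.run(cfg, seed=42)
        b = td.run(cfg, seed=42)
        assert np.array_equal(a.rna, b.rna)
        assert np.array_equal(a.sigma_up, b.sigma_up)
        assert np.array_equal(a.termination_times, b.termination_times)
        c = td.run(cfg, seed=43)
        assert not np.array_equal(a.sigma_up, c.sigma_up)

    def test_no_source_no_rna(self):
        cfg = td.make_config(k_i=0.0, n_steps=3000)
        traj = td.run(cfg, seed=2)
        assert traj.rna.max() == 0
        assert traj.counters["initiations"] == 0

    def test_lk_ledger_and_tiling_through_active_run(self):
        # sigma_i = -0.03 keeps initiation active once sigma relaxes to the
        # topoisomerase balance point near -0.03
        cfg = td.make_config(k_i=0.2, sigma_i=-0.03, n_steps=6000, record_events=True)
        draws = make_draws(9)
        state = init_state(cfg)
        for _ in range(cfg.n_steps):
            step(state, cfg, draws)
            assert state.total_Lk() == pytest.approx(state.expected_total_Lk(), abs=1e-6)
            assert len(state.Lk) == state.n_rnaps + 1  # segments tile the domain
            assert all(a < b for a, b in zip(state.x, state.x[1:]))
        assert state.initiations > 5  # the run actually exercised all channels
        assert state.topoI_events > 0 and state.gyrase_cycles > 0
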