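import numpy as np
import pytest

from gatewalk import (ConfigError, ModelConfig, WalkerState, open_probability,
                      potential_m1, potential_m2, simulate,
                      step_probabilities)
from gatewalk.core_models import (_uniforms, move_probability,
                                  update_boundaries_m1, update_drift_m2)
from gatewalk.event_detection import extract_dwells

from oracle_walk import (expected_mean_dwell, stationary_distribution,
                         walk_reference)


class TestPotentials:
    def test_barrier_height_is_the_published_one(self, m1_cfg):
        st = m1_cfg.initial_state()
        assert potential_m1(0.0, m1_cfg, st) - potential_m1(-1.5, m1_cfg, st) \
            == pytest.approx(1.0)

    def test_flat_outside_barrier_without_drift(self, m1_cfg):
        st = m1_cfg.initial_state()
        for x in np.linspace(st.b1, -1.5, 12):
            assert potential_m1(float(x), m1_cfg, st) == pytest.approx(0.0)

    def test_drift_ramp_value(self):
        cfg = ModelConfig.model1(f_d=0.40)
        st = WalkerState(rc=-1, b1=-7, b2=7)
        assert potential_m1(-4.0, cfg, st) == pytest.approx(3 * 0.40)

    def test_m2_bare_tent_without_drift(self, m2_cfg):
        st = m2_cfg.initial_state()
        assert potential_m2(0.0, m2_cfg, st) - potential_m2(-1.5, m2_cfg, st) \
            == pytest.approx(0.2)

    def test_m2_mirror_symmetry_about_threshold(self, m2_cfg):
        st = m2_cfg.initial_state()
        st.drift_slope = 0.15
        for xp in (0.5, 1.5, 4.0, 10.0):
            assert potential_m2(-xp, m2_cfg, st) == \
                pytest.approx(potential_m2(xp, m2_cfg, st))

    def test_m2_outer_ramp_value(self):
        cfg = ModelConfig.model2(tp=0, b1=-18, b2=18)
        st = WalkerState(rc=-1, b1=-18, b2=18, drift_slope=0.20)
        assert potential_m2(-10.0, cfg, st) == pytest.approx(8 * 0.20)

    def test_continuity_at_segment_joins(self):
        cfg = ModelConfig.model1(f_d=-0.3)
        st = cfg.initial_state()
        eps = 1e-9
        for x in (-1.5, 0.0, 1.5):
            below = potential_m1(x - eps, cfg, st)
            above = potential_m1(x + eps, cfg, st)
            assert below == pytest.approx(above, abs=1e-6)

    def test_out_of_range_is_an_error(self, m1_cfg):
        st = m1_cfg.initial_state()
        with pytest.raises(ValueError):
            potential_m1(st.b2 + 1.0, m1_cfg, st)


class TestStepProbabilities:
    @pytest.mark.parametrize("du,expected_p", [(0.0, 0.5), (2.0, 0.0),
                                               (0.4, 0.4), (-0.4, 0.6)])
    def test_linear_rule(self, du, expected_p):
        p, q = step_probabilities(du)
        assert p == pytest.approx(expected_p)
        assert p + q == pytest.approx(1.0)

    def test_probability_conservation_over_range(self):
        for du in np.linspace(-2, 2, 41):
            p, q = step_probabilities(float(du))
            assert 0 <= p <= 1
            assert p + q == pytest.approx(1.0)

    def test_clamped_with_warning_beyond_validity(self):
        with pytest.warns(UserWarning):
            p, q = step_probabilities(3.0)
        assert (p, q) == (0.0, 1.0)


class TestSlowUpdates:
    def test_boundary_moves_are_synchronized(self, m1_cfg, rng):
        st = WalkerState(rc=-1, b1=-7, b2=7)
        for _ in range(200):
            st = update_boundaries_m1(st, m1_cfg, rng)
            assert st.b1 == -st.b2
            assert 2 <= st.b2 <= m1_cfg.b_max
            assert st.b1 <= st.rc <= st.b2

    def test_expand_rejected_at_bmax(self, m1_cfg):
        class Up:
            def random(self):
                return 0.0  # always draws "expand"
        st = WalkerState(rc=1, b1=-14, b2=14)
        st2 = update_boundaries_m1(st, m1_cfg, Up())
        assert (st2.b1, st2.b2) == (-14, 14)

    def test_shrink_moves_both_sides(self, m1_cfg):
        class Down:
            def random(self):
                return 0.9
        st = WalkerState(rc=7, b1=-7, b2=7)
        st2 = update_boundaries_m1(st, m1_cfg, Down())
        assert (st2.b1, st2.b2) == (-6, 6)
        assert st2.rc == 6  # clamped with the shrinking edge

    def test_boundary_halfwidth_is_uniform_in_the_long_run(self, m1_cfg, rng):
        # reflected unbiased walk on {2..14}: stationary law is uniform.
        # Oracle: brute-force stationary vector of the 13-state chain.
        P = np.zeros((13, 13))
        for i in range(13):
            P[i, min(i + 1, 12)] += 0.5
            P[i, max(i - 1, 0)] += 0.5
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi /= pi.sum()
        assert pi == pytest.approx(np.full(13, 1 / 13), abs=1e-10)
        st = WalkerState(rc=1, b1=-7, b2=7)
        counts = np.zeros(13)
        for _ in range(40_000):
            st = update_boundaries_m1(st, m1_cfg, rng)
            counts[st.b2 - 2] += 1
        freq = counts / counts.sum()
        assert np.max(np.abs(freq - 1 / 13)) < 0.02

    def test_drift_reflects_exactly_at_the_limit(self, m2_cfg):
        class Down:
            def random(self):
                return 0.9
        st = WalkerState(rc=-1, b1=-18, b2=18, drift_slope=0.0)
        for _ in range(45):
            st = update_drift_m2(st, m2_cfg, Down())
        assert st.drift_slope == pytest.approx(-0.20, abs=0)

    def test_drift_clamped_at_max(self, m2_cfg):
        class Up:
            def random(self):
                return 0.0
        st = WalkerState(rc=-1, b1=-18, b2=18, drift_slope=0.20)
        st2 = update_drift_m2(st, m2_cfg, Up())
        assert st2.drift_slope == pytest.approx(0.20)


class TestMoveProbability:
    def test_flat_region_symmetric(self, m1_cfg):
        st = WalkerState(rc=-4, b1=-7, b2=7)
        assert move_probability(m1_cfg, st) == pytest.approx(0.5)

    def test_crossing_gated_by_half_step_into_barrier(self, m1_cfg):
        st = WalkerState(rc=-1, b1=-7, b2=7)
        # dU = u_barrier / 3 for the half-step into the 1.0 kT peak
        assert move_probability(m1_cfg, st) == pytest.approx(0.5 - (1.0 / 3) / 4)
        st_open = WalkerState(rc=1, b1=-7, b2=7)
        assert move_probability(m1_cfg, st_open) == \
            pytest.approx(1 - (0.5 - (1.0 / 3) / 4))


class TestSimulate:
    def test_identical_seeds_reproduce_bit_for_bit(self, m1_cfg):
        a = simulate(m1_cfg, 50_000, seed=42)
        b = simulate(m1_cfg, 50_000, seed=42)
        assert np.array_equal(a.states, b.states)

    def test_kernel_matches_pure_python_reference(self):
        for cfg in (ModelConfig.model1(f_d=0.2), ModelConfig.model2(tp=-7),
                    ModelConfig.model1(f_d=0.0).frozen()):
            u = _uniforms(7, 20_000, cfg.period)
            got = simulate(cfg, 20_000, seed=7)
            want = walk_reference(cfg, 20_000, u)
            assert np.array_equal(got.states, want)

    def test_symmetric_models_are_unbiased(self):
        # Model 1 without drift and Model 2 with centred threshold must
        # both give open probability 1/2 within a few SD
        po1 = [open_probability(simulate(ModelConfig.model1(), 2_000_000, s))
               for s in range(3)]
        po2 = [open_probability(simulate(ModelConfig.model2(), 2_000_000, s))
               for s in range(3)]
        assert abs(np.mean(po1) - 0.5) < 0.03
        assert abs(np.mean(po2) - 0.5) < 0.05

    def test_mirror_equivariance_of_drift(self):
        # negating the drift swaps open and closed statistics
        pos, negs = [], []
        for s in range(3):
            pos.append(open_probability(
                simulate(ModelConfig.model1(f_d=0.4), 2_000_000, s)))
            negs.append(open_probability(
                simulate(ModelConfig.model1(f_d=-0.4), 2_000_000, s + 100)))
        assert np.mean(pos) + np.mean(negs) == pytest.approx(1.0, abs=0.04)

    def test_occupancy_matches_exact_chain_on_small_lattice(self):
        cfg = ModelConfig.model1(b_max=4, f_d=0.2).frozen()
        gt = simulate(cfg, 400_000, seed=5, record_paths=True)
        nodes, pi = stationary_distribution(cfg)
        rc = gt.rc_path
        # batch-means standard error per node (the walk is autocorrelated)
        batches = np.array_split(rc, 40)
        for x, target in zip(nodes, pi):
            shares = [np.mean(b == x) for b in batches]
            se = np.std(shares) / np.sqrt(len(shares))
            assert abs(np.mean(shares) - target) < 3 * se + 1e-4

    def test_mean_dwell_matches_exact_chain_on_small_lattice(self):
        cfg = ModelConfig.model1(b_max=4, f_d=0.0).frozen()
        gt = simulate(cfg, 400_000, seed=6)
        ds = extract_dwells(gt)
        for state in (0, 1):
            want = expected_mean_dwell(cfg, state)
            dur = ds.of_state(state)
            se = dur.std() / np.sqrt(len(dur))
            assert abs(dur.mean() - want) < 3 * se

    def test_side_channels_aligned_and_consistent(self, m2_cfg):
        gt = simulate(m2_cfg, 10_000, seed=3, record_paths=True)
        assert len(gt.rc_path) == len(gt.states) == len(gt.drift_path)
        assert np.array_equal(gt.states, (gt.rc_path > m2_cfg.tp))
        assert np.max(np.abs(gt.drift_path)) <= m2_cfg.drift_max + 1e-12
        assert not np.any(gt.rc_path == m2_cfg.tp)

    def test_burn_in_drops_samples(self, m1_cfg):
        gt = simulate(m1_cfg, 1_000, seed=0, burn_in=500)
        assert len(gt) == 1_000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(model_id=3)
        with pytest.raises(ConfigError):
            ModelConfig.model2(tp=18)
        with pytest.raises(ConfigError):
            ModelConfig.model1(f_d=5.0)
        with pytest.raises(ConfigError):
            simulate(ModelConfig.model1(), 0)
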