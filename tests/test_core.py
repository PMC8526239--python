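"""Optimizer mechanics: schedules, coefficient draws, update rules, runs."""

from types import SimpleNamespace

import numpy as np
import pytest

from msbgwo.core import (
    LeaderTriple,
    OptimizerConfig,
    Wolf,
    control_param,
    draw_coefficients,
    leader_guided_position,
    pair_master_slave,
    rank_and_split,
    run_optimizer,
    slave_learning_step,
)


def make_wolf(bits, fitness=None):
    return Wolf(position=np.asarray(bits, dtype=np.int8), fitness=fitness)


def triple(alpha, beta, delta):
    return LeaderTriple(
        make_wolf(alpha, 0.1), make_wolf(beta, 0.2), make_wolf(delta, 0.3)
    )


# ---------------------------------------------------------------- schedules

@pytest.mark.parametrize(
    "t, T, schedule, expected",
    [
        (0, 100, "nonlinear", 2.0),
        (100, 100, "nonlinear", 0.0),
        (50, 100, "nonlinear", 1.5),
        (0, 100, "linear", 2.0),
        (100, 100, "linear", 0.0),
        (50, 100, "linear", 1.0),
    ],
)
def test_control_param_values(t, T, schedule, expected):
    assert control_param(t, T, schedule) == pytest.approx(expected)


def test_control_param_nonlinear_dominates_linear_and_decays():
    T = 1000
    lin = np.array([control_param(t, T, "linear") for t in range(T + 1)])
    non = np.array([control_param(t, T, "nonlinear") for t in range(T + 1)])
    assert np.all(non >= lin)
    assert np.all(np.diff(lin) <= 0) and np.all(np.diff(non) <= 0)


@pytest.mark.parametrize("t, T", [(-1, 10), (11, 10), (0, 0)])
def test_control_param_rejects_bad_indices(t, T):
    with pytest.raises(ValueError):
        control_param(t, T, "linear")


# ----------------------------------------------------------- coefficients

def test_draw_coefficients_zero_a_gives_zero_A():
    rng = np.random.default_rng(0)
    A, C = draw_coefficients(0.0, 8, rng)
    np.testing.assert_array_equal(A, np.zeros(8))
    assert np.all((C >= 0) & (C <= 2))


def test_draw_coefficients_extreme_draws(scripted_rng):
    rng = scripted_rng([np.ones(3), np.ones(3)])
    A, C = draw_coefficients(2.0, 3, rng)
    np.testing.assert_allclose(A, [2, 2, 2])
    np.testing.assert_allclose(C, [2, 2, 2])


def test_draw_coefficients_range_property():
    rng = np.random.default_rng(1)
    draws = [draw_coefficients(1.0, 100, rng) for _ in range(100)]
    A = np.concatenate([a for a, _ in draws])
    C = np.concatenate([c for _, c in draws])
    assert np.all((A >= -1) & (A <= 1))
    assert np.all((C >= 0) & (C <= 2))
    assert A.std() > 0.3  # fresh randomness actually consumed


def test_draw_coefficients_rejects_negative_a():
    with pytest.raises(ValueError):
        draw_coefficients(-0.5, 4, np.random.default_rng(0))


# ------------------------------------------------------------ update rules

def test_leader_update_fixed_point_at_a_zero():
    x_star = np.array([1, 0, 1, 1], dtype=np.int8)
    leaders = triple(x_star, x_star, x_star)
    out = leader_guided_position(x_star, leaders, 0.0, np.random.default_rng(0))
    np.testing.assert_allclose(out, x_star.astype(float))


def test_leader_update_hand_worked_scalar_case(scripted_rng):
    # a=1, r1=0.75 -> A=0.5; r2=0.5 -> C=1, for each of the three guides:
    # D = |1*1 - 0| = 1, X_i = 1 - 0.5 = 0.5, mean = 0.5
    rng = scripted_rng([[0.75], [0.5]] * 3)
    leaders = triple([1], [1], [1])
    out = leader_guided_position(np.array([0]), leaders, 1.0, rng)
    np.testing.assert_allclose(out, [0.5])


def test_leader_update_dimension_mismatch():
    leaders = triple([1, 0], [0, 1], [1, 1])
    with pytest.raises(ValueError, match="dimension"):
        leader_guided_position(np.array([0, 1, 0]), leaders, 1.0,
                               np.random.default_rng(0))


def _oracle_leader_guided(x, leaders, a, rng):
    """Independent scalar-loop evaluation of the three-guide update."""
    d = len(x)
    parts = []
    for lead in (leaders.alpha, leaders.beta, leaders.delta):
        r1 = rng.random(d)
        r2 = rng.random(d)
        part = np.empty(d)
        for j in range(d):
            A = 2 * a * r1[j] - a
            C = 2 * r2[j]
            dist = abs(C * float(lead.position[j]) - float(x[j]))
            part[j] = float(lead.position[j]) - A * dist
        parts.append(part)
    return (parts[0] + parts[1] + parts[2]) / 3.0


def _oracle_slave_step(xm, xs, omega, a, rng):
    d = len(xm)
    r1 = rng.random(d)
    r2 = rng.random(d)
    xn = np.empty(d)
    for j in range(d):
        A4 = 2 * a * r1[j] - a
        C4 = 2 * r2[j]
        dl = omega * abs(C4 * float(xm[j]) - float(xs[j]))
        xn[j] = float(xm[j]) - A4 * dl
    thresholds = rng.random(d)
    bits = np.array(
        [1 if 1 / (1 + np.exp(-10 * (v - 0.5))) > t else 0
         for v, t in zip(xn, thresholds)],
        dtype=np.int8,
    )
    return bits, xn


def test_update_rules_match_scalar_oracle():
    meta = np.random.default_rng(42)
    for _ in range(120):
        d = int(meta.integers(1, 5))
        a = float(meta.uniform(0, 2))
        omega = float(meta.uniform(0, 1))
        seed = int(meta.integers(0, 2**31))
        x = meta.integers(0, 2, d).astype(np.int8)
        masks = [meta.integers(0, 2, d).astype(np.int8) for _ in range(4)]
        leaders = triple(masks[0], masks[1], masks[2])

        got = leader_guided_position(x, leaders, a, np.random.default_rng(seed))
        want = _oracle_leader_guided(x, leaders, a, np.random.default_rng(seed))
        np.testing.assert_allclose(got, want, atol=1e-12)

        m, s = make_wolf(masks[3]), make_wolf(x)
        got_bits, got_xn = slave_learning_step(
            m, s, omega, a, np.random.default_rng(seed)
        )
        want_bits, want_xn = _oracle_slave_step(
            masks[3], x, omega, a, np.random.default_rng(seed)
        )
        np.testing.assert_allclose(got_xn, want_xn, atol=1e-12)
        np.testing.assert_array_equal(got_bits, want_bits)


def test_slave_step_omega_zero_targets_master():
    m, s = make_wolf([1, 0, 1]), make_wolf([0, 1, 0])
    _, xn = slave_learning_step(m, s, 0.0, 1.5, np.random.default_rng(3))
    np.testing.assert_allclose(xn, [1, 0, 1])


def test_slave_step_coincident_positions(scripted_rng):
    # C4 = 1 forces D_L = 0 whatever omega; thresholds still consumed
    rng = scripted_rng([[0.3, 0.9], [0.5, 0.5], [0.5, 0.5]])
    m = make_wolf([1, 0])
    _, xn = slave_learning_step(m, make_wolf([1, 0]), 0.7, 2.0, rng)
    np.testing.assert_allclose(xn, [1.0, 0.0])


def test_slave_step_hand_worked_case(scripted_rng):
    # a=1, r1=1 -> A4=1; r2=0.5 -> C4=1; omega=0.1, X_M=1, X_S=0:
    # D_L=0.1, X_n=0.9, S(0.9)=0.982; threshold 0.5 -> bit 1
    rng = scripted_rng([[1.0], [0.5], [0.5]])
    bits, xn = slave_learning_step(make_wolf([1]), make_wolf([0]), 0.1, 1.0, rng)
    np.testing.assert_allclose(xn, [0.9])
    np.testing.assert_array_equal(bits, [1])


def test_slave_step_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        slave_learning_step(make_wolf([1, 0]), make_wolf([1]), 0.1, 1.0,
                            np.random.default_rng(0))


# --------------------------------------------------------- ranking/pairing

def test_rank_and_split_orders_by_fitness():
    pop = [make_wolf([1], f) for f in (0.3, 0.1, 0.4, 0.2)]
    masters, slaves = rank_and_split(pop)
    assert [w.fitness for w in masters] == [0.1, 0.2]
    assert [w.fitness for w in slaves] == [0.3, 0.4]


def test_rank_and_split_stable_on_ties():
    pop = [make_wolf([i], 0.5) for i in range(4)]
    masters, slaves = rank_and_split(pop)
    assert masters == pop[:2] and slaves == pop[2:]


def test_rank_and_split_minimal_and_errors():
    pop = [make_wolf([1], 0.2), make_wolf([0], 0.1)]
    masters, slaves = rank_and_split(pop)
    assert len(masters) == len(slaves) == 1
    with pytest.raises(ValueError, match="even"):
        rank_and_split(pop + [make_wolf([1], 0.3)])
    with pytest.raises(ValueError, match="evaluated"):
        rank_and_split([make_wolf([1]), make_wolf([0])])


@pytest.mark.parametrize(
    "n, expected",
    [
        (10, [(0, 5), (1, 6), (2, 7), (3, 8), (4, 9)]),
        (2, [(0, 1)]),
        (6, [(0, 3), (1, 4), (2, 5)]),
    ],
)
def test_pair_master_slave_examples(n, expected):
    assert pair_master_slave(n) == expected


def test_pair_master_slave_rejects_odd_or_tiny():
    for n in (0, 1, 3, 7):
        with pytest.raises(ValueError):
            pair_master_slave(n)


# ------------------------------------------------------------- config/runs

def test_optimizer_config_validation():
    with pytest.raises(ValueError):
        OptimizerConfig(n_wolves=5)
    with pytest.raises(ValueError):
        OptimizerConfig(n_iterations=0)
    with pytest.raises(ValueError):
        OptimizerConfig(omega=1.5)
    with pytest.raises(ValueError):
        OptimizerConfig(variant="GWO3")
    assert OptimizerConfig(variant="MSBGWO").resolved_schedule == "nonlinear"
    assert OptimizerConfig(variant="BGWO2").resolved_schedule == "linear"
    assert OptimizerConfig(variant="BGWO2", schedule="nonlinear").resolved_schedule == "nonlinear"


class CountingFitness:
    """Cheap deterministic fitness: prefers masks matching a target."""

    def __init__(self, target):
        self.target = np.asarray(target, dtype=np.int8)
        self.masks_seen = []

    def __call__(self, dataset, mask):
        mask = np.asarray(mask)
        self.masks_seen.append(mask.copy())
        value = float(np.sum(mask != self.target)) / len(self.target)
        return SimpleNamespace(fitness=value)


def stub_dataset(d):
    return SimpleNamespace(n_features=d)


def test_run_optimizer_deterministic_and_monotone():
    target = np.zeros(12, dtype=np.int8)
    target[:4] = 1
    cfg = OptimizerConfig(n_wolves=6, n_iterations=30, seed=7)
    traces = [
        run_optimizer(stub_dataset(12), cfg, CountingFitness(target))
        for _ in range(2)
    ]
    np.testing.assert_array_equal(traces[0].best_mask, traces[1].best_mask)
    np.testing.assert_array_equal(traces[0].convergence, traces[1].convergence)
    assert traces[0].n_evaluations == traces[1].n_evaluations
    conv = traces[0].convergence
    assert len(conv) == 30
    assert np.all(np.diff(conv) <= 0)
    assert traces[0].best_fitness == conv[-1]


def test_run_optimizer_population_masks_stay_binary():
    fitness = CountingFitness(np.ones(9, dtype=np.int8))
    cfg = OptimizerConfig(n_wolves=4, n_iterations=15, seed=3)
    run_optimizer(stub_dataset(9), cfg, fitness)
    for mask in fitness.masks_seen:
        assert mask.dtype == np.int8
        assert set(np.unique(mask)).issubset({0, 1})


def test_bgwo2_ignores_omega():
    target = np.zeros(10, dtype=np.int8)
    target[::2] = 1
    traces = [
        run_optimizer(
            stub_dataset(10),
            OptimizerConfig(n_wolves=4, n_iterations=20, seed=11,
                            variant="BGWO2", omega=om),
            CountingFitness(target),
        )
        for om in (0.0, 0.1, 1.0)
    ]
    for t in traces[1:]:
        np.testing.assert_array_equal(traces[0].convergence, t.convergence)
        np.testing.assert_array_equal(traces[0].best_mask, t.best_mask)


def test_minimal_run_completes_one_pairing():
    fitness = CountingFitness(np.array([1, 1, 0]))
    cfg = OptimizerConfig(n_wolves=2, n_iterations=1, seed=0)
    trace = run_optimizer(stub_dataset(3), cfg, fitness)
    # init (2) + population update (2) + one slave re-evaluation (1)
    assert trace.n_evaluations == 5
    assert len(trace.convergence) == 1


def test_fitness_failure_is_annotated():
    def broken(dataset, mask):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="iteration"):
        run_optimizer(stub_dataset(5),
                      OptimizerConfig(n_wolves=2, n_iterations=1, seed=0),
                      broken)
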