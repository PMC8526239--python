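"""Grey-wolf population optimizer with the master-slave learning scheme.

Two variants of the binary grey wolf optimizer are provided:

* ``BGWO2`` — the baseline: every wolf moves toward the three best
  solutions found so far (alpha, beta, delta) under a linearly decaying
  encircling coefficient ``a``, and the continuous update is binarized
  with a fixed 0.5 threshold.
* ``MSBGWO`` — the master-slave variant: same leader-guided update but
  under a quadratic (slower-decaying, hence more exploratory) schedule
  for ``a``; additionally, each iteration the population is sorted by
  fitness, the fitter half become masters, and each wolf of the weaker
  half takes a small randomized step toward its assigned master before
  being re-binarized with per-dimension random thresholds.

Fitness is minimized.  All randomness flows through one seeded
``numpy.random.Generator`` per run, consumed in a fixed documented
order, so runs replay bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from msbgwo.transfer import FIXED_HALF, PER_DIM_RANDOM, binarize

VARIANT_MSBGWO = "MSBGWO"
VARIANT_BGWO2 = "BGWO2"
SCHEDULE_LINEAR = "linear"
SCHEDULE_NONLINEAR = "nonlinear"


@dataclass
class Wolf:
    """A candidate solution: a binary feature mask plus bookkeeping.

    ``last_continuous`` is the pre-binarization state from the most
    recent update (None before the first update).
    """

    position: np.ndarray
    fitness: Optional[float] = None
    last_continuous: Optional[np.ndarray] = None


@dataclass
class LeaderTriple:
    """Best-so-far alpha/beta/delta snapshots, ordered by fitness."""

    alpha: Wolf
    beta: Wolf
    delta: Wolf

    def update(self, wolves: Sequence[Wolf]) -> None:
        """Fold newly evaluated wolves into the best-so-far hierarchy."""
        for w in wolves:
            if w.fitness is None:
                raise ValueError("cannot update leaders with an unevaluated wolf")
            snap = Wolf(position=w.position.copy(), fitness=w.fitness)
            if snap.fitness < self.alpha.fitness:
                self.alpha, self.beta, self.delta = snap, self.alpha, self.beta
            elif snap.fitness < self.beta.fitness:
                self.beta, self.delta = snap, self.beta
            elif snap.fitness < self.delta.fitness:
                self.delta = snap


@dataclass
class OptimizerConfig:
    """Run settings for either optimizer variant.

    Parameters
    ----------
    n_wolves : int
        Population size N; must be even and >= 2 (the master-slave
        pairing splits the pack in halves).  Default 10.
    n_iterations : int
        Iteration budget T >= 1.  Default 100.
    omega : float
        Learning coefficient in [0, 1] scaling the master-slave step;
        only the MSBGWO variant uses it.  Default 0.1.
    variant : str
        ``"MSBGWO"`` or ``"BGWO2"``.
    schedule : str or None
        Decay schedule for the encircling coefficient; ``None`` picks
        the variant's own schedule (nonlinear for MSBGWO, linear for
        BGWO2).
    seed : int
        Seed for the single per-run random generator.
    """

    n_wolves: int = 10
    n_iterations: int = 100
    omega: float = 0.1
    variant: str = VARIANT_MSBGWO
    schedule: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_wolves < 2 or self.n_wolves % 2 != 0:
            raise ValueError(f"n_wolves must be even and >= 2, got {self.n_wolves}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if self.variant not in (VARIANT_MSBGWO, VARIANT_BGWO2):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.schedule not in (None, SCHEDULE_LINEAR, SCHEDULE_NONLINEAR):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    @property
    def resolved_schedule(self) -> str:
        if self.schedule is not None:
            return self.schedule
        return SCHEDULE_NONLINEAR if self.variant == VARIANT_MSBGWO else SCHEDULE_LINEAR


@dataclass
class RunTrace:
    """Outcome of one optimizer run."""

    best_mask: np.ndarray
    best_fitness: float
    convergence: np.ndarray  # best-so-far fitness after each iteration, length T
    n_evaluations: int = 0


def control_param(t: int, T: int, schedule: str = SCHEDULE_LINEAR) -> float:
    """Encircling coefficient ``a`` at iteration ``t`` of ``T``.

    linear:    a = 2 - 2 t / T
    nonlinear: a = 2 (1 - t^2 / T^2)

    Both decay from 2 at t=0 to 0 at t=T; the quadratic stays above the
    linear one throughout, lengthening the exploratory phase.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not 0 <= t <= T:
        raise ValueError(f"iteration index t={t} outside [0, {T}]")
    if schedule == SCHEDULE_LINEAR:
        return 2.0 - 2.0 * t / T
    if schedule == SCHEDULE_NONLINEAR:
        return 2.0 * (1.0 - (t * t) / (T * T))
    raise ValueError(f"unknown schedule {schedule!r}")


def draw_coefficients(a: float, D: int, rng: np.random.Generator):
    """Draw one (A, C) coefficient vector pair.

    A = 2 a r1 - a with r1 ~ U(0,1)^D, so A lies in [-a, a];
    C = 2 r2 with r2 ~ U(0,1)^D, so C lies in [0, 2].

    Consumes 2 D uniforms from ``rng`` (r1 first, then r2).
    """
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a}")
    r1 = rng.random(D)
    r2 = rng.random(D)
    return 2.0 * a * r1 - a, 2.0 * r2


def leader_guided_position(
    position: np.ndarray,
    leaders: LeaderTriple,
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous position update toward the alpha/beta/delta leaders.

    For each leader L in (alpha, beta, delta) with its own fresh
    coefficient pair (A_i, C_i):

        D_L = | C_i * X_L - X |
        X_i = X_L - A_i * D_L

    and the new continuous position is (X_1 + X_2 + X_3) / 3.  All
    arithmetic is element-wise.  Coefficients are drawn in leader order
    alpha, beta, delta (r1 then r2 for each), consuming 6 D uniforms.
    """
    x = np.asarray(position, dtype=float)
    parts = []
    for leader in (leaders.alpha, leaders.beta, leaders.delta):
        lx = np.asarray(leader.position, dtype=float)
        if lx.shape != x.shape:
            raise ValueError(
                f"dimension mismatch: wolf has {x.shape}, leader has {lx.shape}"
            )
        A, C = draw_coefficients(a, x.shape[0], rng)
        d = np.abs(C * lx - x)
        parts.append(lx - A * d)
    return (parts[0] + parts[1] + parts[2]) / 3.0


def rank_and_split(population: Sequence[Wolf]):
    """Sort ascending by fitness (stable) and split into halves.

    Returns ``(masters, slaves)``: the fitter half first.  Ties keep
    their prior order, so re-ranking an already-sorted pack is a no-op.
    """
    n = len(population)
    if n % 2 != 0:
        raise ValueError(f"population size must be even, got {n}")
    for w in population:
        if w.fitness is None:
            raise ValueError("rank_and_split requires every wolf to be evaluated")
    ordered = sorted(population, key=lambda w: w.fitness)  # Timsort: stable
    half = n // 2
    return ordered[:half], ordered[half:]


def pair_master_slave(n_wolves: int):
    """Master-slave index pairs into the fitness-sorted population.

    With the pack sorted best-first, master m (0-based, m = 0..N/2-1)
    is paired with slave m + N/2, the classic 1-based rule S = M + N/2.
    Every wolf appears in exactly one pair.
    """
    if n_wolves < 2 or n_wolves % 2 != 0:
        raise ValueError(f"population size must be even and >= 2, got {n_wolves}")
    half = n_wolves // 2
    return [(m, m + half) for m in range(half)]


def slave_learning_step(
    master: Wolf,
    slave: Wolf,
    omega: float,
    a: float,
    rng: np.random.Generator,
):
    """Move a slave toward its master and re-binarize.

    D_L = omega * | C4 * X_M - X_S |   (a fraction of the master-slave
    distance), X_n = X_M - A4 * D_L, then X_n is binarized with one
    uniform threshold per dimension.  The new mask replaces the slave's
    unconditionally — no greedy acceptance.

    Consumes 2 D uniforms for (A4, C4) then D threshold uniforms.

    Returns ``(mask, continuous)``.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    xm = np.asarray(master.position, dtype=float)
    xs = np.asarray(slave.position, dtype=float)
    if xm.shape != xs.shape:
        raise ValueError(
            f"dimension mismatch: master has {xm.shape}, slave has {xs.shape}"
        )
    A4, C4 = draw_coefficients(a, xm.shape[0], rng)
    d_l = omega * np.abs(C4 * xm - xs)
    x_n = xm - A4 * d_l
    mask = binarize(x_n, PER_DIM_RANDOM, rng)
    return mask, x_n


def _init_leaders(population: Sequence[Wolf]) -> LeaderTriple:
    ordered = sorted(population, key=lambda w: w.fitness)
    # packs smaller than 3 repeat their worst member to fill the triple
    picks = [ordered[min(i, len(ordered) - 1)] for i in range(3)]
    snaps = [Wolf(position=w.position.copy(), fitness=w.fitness) for w in picks]
    return LeaderTriple(*snaps)


def run_optimizer(
    dataset,
    cfg: OptimizerConfig,
    fitness: Callable,
) -> RunTrace:
    """Run one seeded optimization and return its trace.

    Parameters
    ----------
    dataset : msbgwo.data.Dataset
        Normalized two-class dataset with D >= 2 features.
    cfg : OptimizerConfig
    fitness : callable
        ``fitness(dataset, mask) -> FitnessReport``; lower fitness is
        better.  Failures propagate annotated with the iteration index.

    Returns
    -------
    RunTrace
        Best mask/fitness ever observed plus the per-iteration
        best-so-far convergence series (non-increasing by construction).

    Notes
    -----
    Per iteration t = 1..T: (i) compute ``a`` from the variant's
    schedule; (ii) move every wolf with the leader-guided update and
    binarize at the fixed 0.5 threshold; (iii) re-evaluate and fold into
    the best-so-far leaders; (iv) MSBGWO only: sort, pair masters with
    slaves, apply the learning step to every slave, re-evaluate slaves;
    (v) record the best-so-far fitness.
    """
    D = dataset.n_features
    if D < 2:
        raise ValueError(f"dataset must have >= 2 features, got {D}")
    rng = np.random.default_rng(cfg.seed)
    n_evals = 0

    def _evaluate(wolf: Wolf, t: int) -> None:
        nonlocal n_evals
        try:
            wolf.fitness = float(fitness(dataset, wolf.position).fitness)
        except Exception as exc:  # annotate with iteration context
            raise RuntimeError(f"fitness evaluation failed at iteration {t}") from exc
        n_evals += 1

    # Bernoulli(0.5) initialization; empty masks are re-drawn because the
    # wrapper fitness is undefined on the empty subset.
    population = []
    for _ in range(cfg.n_wolves):
        bits = (rng.random(D) < 0.5).astype(np.int8)
        while not bits.any():
            bits = (rng.random(D) < 0.5).astype(np.int8)
        population.append(Wolf(position=bits))
    for w in population:
        _evaluate(w, 0)

    leaders = _init_leaders(population)
    best = Wolf(position=leaders.alpha.position.copy(), fitness=leaders.alpha.fitness)
    convergence = np.empty(cfg.n_iterations, dtype=float)

    schedule = cfg.resolved_schedule
    pairs = pair_master_slave(cfg.n_wolves)
    for t in range(1, cfg.n_iterations + 1):
        a = control_param(t, cfg.n_iterations, schedule)

        # whole-population leader-guided update, deterministic 0.5 threshold
        for w in population:
            cont = leader_guided_position(w.position, leaders, a, rng)
            w.last_continuous = cont
            w.position = binarize(cont, FIXED_HALF)
            _evaluate(w, t)
        leaders.update(population)

        if cfg.variant == VARIANT_MSBGWO:
            masters, slaves = rank_and_split(population)
            ordered = masters + slaves
            for m_idx, s_idx in pairs:
                master, slave = ordered[m_idx], ordered[s_idx]
                mask, cont = slave_learning_step(master, slave, cfg.omega, a, rng)
                slave.position = mask
                slave.last_continuous = cont
                _evaluate(slave, t)
            population = ordered
            leaders.update(slaves)

        if leaders.alpha.fitness < best.fitness:
            best = Wolf(
                position=leaders.alpha.position.copy(),
                fitness=leaders.alpha.fitness,
            )
        convergence[t - 1] = best.fitness

    return RunTrace(
        best_mask=best.position,
        best_fitness=best.fitness,
        convergence=convergence,
        n_evaluations=n_evals,
    )
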