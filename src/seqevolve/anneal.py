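"""Simulated-annealing optimizer over fixed-backbone sequence space.

Geometric cooling with the stock parameters N_TRIES = 200,
ITERS_FIXED_T = 2000, K = 1.0, T_INITIAL = 5000, MU_T = 1.002 and
T_MIN = 0.005: the temperature ladder T -> T/MU_T is walked until T_MIN,
running ITERS_FIXED_T Metropolis iterations at each level, which makes a
default run >1.3e7 iterations (6915 levels x 2000). N_TRIES is carried in
the schedule for fidelity to the stock parameter set, but the iteration
count follows levels x ITERS_FIXED_T — treating it as an extra multiplier
would contradict the published per-run iteration count.

A single MT19937 stream (classic seeding, see :mod:`seqevolve.rng`) drives
the start sequence, the move proposals and the acceptance draws, so a run
is bit-reproducible across platforms for a fixed seed; one run per start
sequence suffices. Moves are single-point substitutions with the
replacement drawn from the background frequency table conditioned on
differing from the current residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, SeqEvolveError
from .fitness import EnergyModel, FitnessState, StructureContext
from .fixtures import default_frequency_table, shuffle_sequence
from .rng import DEFAULT_SEED, make_rng
from .structio import AA_INDEX, AMINO_ACIDS, Structure, sequence_identity

START_MODES = ("native", "shuffled", "random")


@dataclass
class Schedule:
    """Cooling-schedule control parameters (GSL-style)."""

    n_tries: int = 200
    iters_fixed_t: int = 2000
    k: float = 1.0
    t_initial: float = 5000.0
    mu_t: float = 1.002
    t_min: float = 0.005

    def __post_init__(self) -> None:
        if self.mu_t <= 1.0:
            raise ValueError("mu_t must be > 1")
        if not (0 < self.t_min < self.t_initial):
            raise ValueError("need 0 < t_min < t_initial")
        if min(self.n_tries, self.iters_fixed_t) < 1 or self.k <= 0:
            raise ValueError("n_tries, iters_fixed_t and k must be positive")


@dataclass
class TrajectoryRecord:
    """One sampled point of an annealing run."""

    step: int
    temperature: float
    fitness: float
    best_fitness: float
    identity: float


def temperature_levels(schedule: Schedule) -> np.ndarray:
    """All temperatures visited: T_0 = t_initial, T_{n+1} = T_n / mu_t > t_min."""
    levels = []
    t = schedule.t_initial
    while t > schedule.t_min:
        levels.append(t)
        t /= schedule.mu_t
    return np.array(levels)


def total_iterations(schedule: Schedule) -> int:
    """Metropolis iterations of a full run: levels x iters_fixed_t."""
    return len(temperature_levels(schedule)) * schedule.iters_fixed_t


def _conditional_cumsums(probs: np.ndarray) -> np.ndarray:
    """Row r: cumulative distribution over replacements given current aa r."""
    n = len(probs)
    out = np.empty((n, n))
    for r in range(n):
        p = probs.copy()
        p[r] = 0.0
        p /= p.sum()
        np.cumsum(p, out=out[r])
        out[r, -1] = 1.0
    return out


def propose_move(seq: str, rng: np.random.Generator, freq_table=None) -> str:
    """One-position substitution; replacement background-distributed, != current."""
    table = freq_table or default_frequency_table()
    cond = _conditional_cumsums(table.probs())
    pos = int(rng.integers(len(seq)))
    cur = AA_INDEX[seq[pos]]
    new = int(np.searchsorted(cond[cur], rng.random(), side="right"))
    return seq[:pos] + AMINO_ACIDS[new] + seq[pos + 1:]


def metropolis_accept(delta_fitness: float, temperature: float, k: float,
                      rng: np.random.Generator) -> bool:
    """Accept uphill moves always; downhill with prob exp(delta/(k T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_fitness >= 0:
        return True
    return rng.random() < math.exp(delta_fitness / (k * temperature))


def _restricted_probs(table, alphabet: str | None) -> np.ndarray:
    probs = table.probs()
    if alphabet is not None:
        mask = np.zeros(20, dtype=bool)
        for aa in alphabet:
            mask[AA_INDEX[aa]] = True
        probs = np.where(mask, probs, 0.0)
        if probs.sum() <= 0:
            raise SeqEvolveError("alphabet excludes every amino acid")
        probs /= probs.sum()
    return probs


def anneal(structure: Structure, model: EnergyModel,
           start_mode: str = "random", schedule: Schedule | None = None,
           seed: int = DEFAULT_SEED, record_every: int = 1000,
           native: str | None = None, alphabet: str | None = None,
           context: StructureContext | None = None
           ) -> tuple[str, list[TrajectoryRecord]]:
    """Evolve a sequence for the target backbone; returns (best, trajectory).

    ``start_mode`` is one of native / shuffled / random; ``alphabet``
    optionally restricts moves (and random starts) to a subset of residues.
    The returned sequence is the best scored at any point of the run.
    """
    if start_mode not in START_MODES:
        raise SeqEvolveError(
            f"start_mode must be one of {START_MODES}, got {start_mode!r}")
    if not model.calibrated:
        raise CalibrationError("model has no normalizers; calibrate first")
    schedule = schedule or Schedule()
    native = native if native is not None else structure.sequence
    rng = make_rng(seed)

    probs = _restricted_probs(model.freq_table, alphabet)
    cond = _conditional_cumsums(probs)
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    length = len(structure)

    if start_mode == "native":
        seq = native
    elif start_mode == "shuffled":
        seq = shuffle_sequence(native, rng)
    else:
        idx = np.searchsorted(cum, rng.random(length), side="right")
        seq = "".join(AMINO_ACIDS[i] for i in idx)

    state = FitnessState(seq, structure, model, context)
    cur_fit = state.fitness
    best_fit = cur_fit
    best_aa = state.aa.copy()
    scale = state._scale

    trajectory: list[TrajectoryRecord] = []

    def record(step: int, temp: float) -> None:
        trajectory.append(TrajectoryRecord(
            step=step, temperature=temp, fitness=cur_fit,
            best_fitness=best_fit,
            identity=sequence_identity(state.sequence, native)))

    step = 0
    levels = temperature_levels(schedule)
    record(0, float(levels[0]))
    inv_k = 1.0 / schedule.k
    for temp in levels:
        # refresh accumulated raws once per level to bound float drift
        state.reset(state.sequence)
        cur_fit = state.fitness
        for _ in range(schedule.iters_fixed_t):
            step += 1
            pos = int(rng.integers(length))
            cur = int(state.aa[pos])
            new = int(np.searchsorted(cond[cur], rng.random(), side="right"))
            d = state.term_deltas(pos, new)
            delta = float(scale @ d)
            if delta >= 0 or rng.random() < math.exp(delta * inv_k / temp):
                state.apply_deltas(pos, new, d)
                cur_fit += delta
                if cur_fit > best_fit:
                    best_fit = cur_fit
                    best_aa = state.aa.copy()
            if step % record_every == 0:
                record(step, float(temp))
    if step % record_every != 0:
        record(step, float(levels[-1]))

    best_seq = "".join(AMINO_ACIDS[i] for i in best_aa)
    return best_seq, trajectory
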