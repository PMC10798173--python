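"""Oddball stimulus timelines with controlled temporal variability.

A session is a set of blocks of ~2 Hz tone sequences in which the
stimulus-onset asynchrony (SOA) between consecutive tones is drawn from a
quantized Gaussian distribution.  All conditions share a 500 ms mean SOA and
differ only in the standard deviation of the distribution (0 ms = periodic,
up to 150 ms).  Rare cued target tones, which the simulated listener must
classify as standard or deviant pitch, are embedded under hard placement
constraints (no target in the first 10 trials, 4-10 standards between
consecutive targets).

The target-gap sampler draws uniformly over the set of *feasible* gap
compositions.  With 56 targets and gaps bounded in [4, 10] an unconstrained
uniform gap draw would need 451+ trials on average, which does not fit a
410-trial block; sampling uniformly over feasible bounded compositions (via
dynamic-programming composition counts) honours every hard constraint while
keeping the placement maximally non-informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence as _Seq

import numpy as np

__all__ = [
    "ALLOWED_STDS",
    "ConditionSpec",
    "DiscreteSOADistribution",
    "Trial",
    "Block",
    "Session",
    "build_soa_distribution",
    "sample_target_gaps",
    "build_block",
    "build_session",
    "sample_block_order",
]

#: Condition labels used throughout: the nominal STD (ms) of the SOA distribution.
ALLOWED_STDS = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0)

N_TRIALS = 410
N_TARGETS = 56
GAP_MIN = 4
GAP_MAX = 10
PREFIX_MIN = 10


class InvalidConditionError(ValueError):
    """Raised for SOA condition parameters outside the experimental design."""


class InfeasibleCompositionError(ValueError):
    """Raised when no gap composition satisfies the placement constraints."""


@dataclass(frozen=True)
class ConditionSpec:
    """One temporal-variability condition: a quantized Gaussian SOA distribution.

    Parameters
    ----------
    std_soa
        Nominal standard deviation of the SOA distribution in ms; one of
        ``ALLOWED_STDS``.  0 denotes the periodic condition (point mass).
    mean_soa
        Mean SOA in ms (500 in the experimental design).
    grid_min, grid_max, grid_step
        The discrete support: grid points from 100 to 900 ms every 25 ms,
        symmetric about the mean.
    """

    std_soa: float
    mean_soa: float = 500.0
    grid_min: float = 100.0
    grid_max: float = 900.0
    grid_step: float = 25.0

    def __post_init__(self) -> None:
        if self.std_soa not in ALLOWED_STDS:
            raise InvalidConditionError(
                f"std_soa must be one of {ALLOWED_STDS}, got {self.std_soa!r}"
            )
        if (self.grid_min + self.grid_max) / 2.0 != self.mean_soa:
            raise InvalidConditionError("grid must be symmetric about mean_soa")
        n_steps = (self.grid_max - self.grid_min) / self.grid_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise InvalidConditionError("grid span must be a multiple of grid_step")

    @property
    def label(self) -> str:
        return "periodic" if self.std_soa == 0 else f"gauss{self.std_soa:g}"

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class DiscreteSOADistribution:
    """Probability mass function of SOAs on the condition grid."""

    support: np.ndarray
    probs: np.ndarray

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs))

    def var(self) -> float:
        m = self.mean()
        return float(np.sum(self.probs * (self.support - m) ** 2))

    def std(self) -> float:
        return math.sqrt(self.var())

    def mass_at(self, x: float) -> float:
        """Probability mass at grid point ``x`` (0 if off-grid)."""
        hit = np.isclose(self.support, x)
        return float(self.probs[hit].sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.support), size=n, p=self.probs)
        return self.support[idx]


@dataclass(frozen=True)
class Trial:
    """One stimulus in a block; ``soa_ms`` is the interval since the previous
    tone onset (None for the first trial)."""

    index: int  # 1-based within block
    soa_ms: float | None
    is_target: bool
    is_deviant: bool

    def __post_init__(self) -> None:
        if self.is_deviant and not self.is_target:
            raise ValueError("is_deviant requires is_target")


@dataclass
class Block:
    condition: ConditionSpec
    trials: list[Trial]
    seed_info: dict = field(default_factory=dict)

    @property
    def target_indices(self) -> np.ndarray:
        return np.array([t.index for t in self.trials if t.is_target], dtype=int)

    @property
    def soa_array(self) -> np.ndarray:
        """SOA per trial, indexed by 1-based trial index; entry 0 and trial 1 are NaN."""
        out = np.full(len(self.trials) + 1, np.nan)
        for t in self.trials:
            if t.soa_ms is not None:
                out[t.index] = t.soa_ms
        return out

    def validate(self) -> None:
        trials = self.trials
        if len(trials) != N_TRIALS:
            raise AssertionError(f"block has {len(trials)} trials, expected {N_TRIALS}")
        tidx = self.target_indices
        if len(tidx) != N_TARGETS:
            raise AssertionError(f"block has {len(tidx)} targets, expected {N_TARGETS}")
        if (tidx <= PREFIX_MIN).any():
            raise AssertionError("target within the first 10 trials")
        gaps = np.diff(tidx) - 1
        if ((gaps < GAP_MIN) | (gaps > GAP_MAX)).any():
            raise AssertionError("inter-target gap outside [4, 10]")
        if trials[0].soa_ms is not None:
            raise AssertionError("first trial must carry an undefined SOA")
        if any(t.soa_ms is None for t in trials[1:]):
            raise AssertionError("undefined SOA on a non-initial trial")
        soas = np.array([t.soa_ms for t in trials[1:]], dtype=float)
        grid = self.condition.grid
        off = np.abs(soas[:, None] - grid[None, :]).min(axis=1)
        if (off > 1e-9).any():
            raise AssertionError("SOA off the condition grid")


@dataclass
class Session:
    subject_id: str
    blocks: list[Block]

    def validate(self) -> None:
        if len(self.blocks) != 12:
            raise AssertionError("session must hold 12 blocks")
        stds = [b.condition.std_soa for b in self.blocks]
        for c in ALLOWED_STDS:
            if stds.count(c) != 2:
                raise AssertionError(f"condition {c} must appear in exactly 2 blocks")
        if any(a == b for a, b in zip(stds, stds[1:])):
            raise AssertionError("consecutive blocks share a condition")
        for b in self.blocks:
            b.validate()
        for c in ALLOWED_STDS:
            n = sum(len(b.target_indices) for b in self.blocks if b.condition.std_soa == c)
            if n != 2 * N_TARGETS:
                raise AssertionError("pooled condition must hold 112 targets")


def build_soa_distribution(spec: ConditionSpec) -> DiscreteSOADistribution:
    """Quantized Gaussian SOA distribution on the condition grid.

    The Gaussian density with the condition's mean and nominal STD is
    evaluated at each grid point and renormalized.  The grid is symmetric
    about the mean, so the analytic mean of the returned distribution is
    exactly ``mean_soa``; truncation to [100, 900] ms shrinks the realized
    STD slightly below nominal for the widest condition.
    """
    grid = spec.grid
    if spec.std_soa == 0:
        probs = np.where(grid == spec.mean_soa, 1.0, 0.0)
    else:
        z = (grid - spec.mean_soa) / spec.std_soa
        probs = np.exp(-0.5 * z * z)
        probs = probs / probs.sum()
    return DiscreteSOADistribution(support=grid, probs=probs)


_COUNT_CACHE: dict = {}


def _composition_counts_cached(bounds: tuple, total: int) -> list[list[int]]:
    key = (bounds, total)
    if key not in _COUNT_CACHE:
        _COUNT_CACHE[key] = _composition_counts(list(bounds), total)
    return _COUNT_CACHE[key]


def _composition_counts(bounds: list[tuple[int, int]], total: int) -> list[list[int]]:
    """counts[i][s] = number of ways to fill parts i.. with sum s (exact ints)."""
    n = len(bounds)
    counts: list[list[int]] = [[0] * (total + 1) for _ in range(n + 1)]
    counts[n][0] = 1
    for i in range(n - 1, -1, -1):
        lo, hi = bounds[i]
        nxt = counts[i + 1]
        row = counts[i]
        for s in range(total + 1):
            acc = 0
            for v in range(lo, min(hi, s) + 1):
                acc += nxt[s - v]
            row[s] = acc
    return counts


def sample_target_gaps(
    n_targets: int,
    n_trials: int,
    prefix_min: int,
    rng: np.random.Generator,
    gap_min: int = GAP_MIN,
    gap_max: int = GAP_MAX,
    prefix_max: int | None = None,
    tail_max: int | None = None,
) -> tuple[int, list[int], int]:
    """Sample (prefix, inter-target gaps, tail) uniformly over feasible compositions.

    The standards total ``n_trials - n_targets`` and are split into a prefix
    (before the first target, at least ``prefix_min``), ``n_targets - 1``
    gaps each in [gap_min, gap_max], and a tail after the last target.  The
    prefix is bounded above at ``prefix_min + (gap_max - gap_min)`` and the
    tail at ``gap_max`` unless overridden.  Sampling is exact: a
    dynamic-programming count of bounded compositions drives sequential
    conditional draws, so every feasible composition is equiprobable.
    """
    if prefix_max is None:
        prefix_max = prefix_min + (gap_max - gap_min)
    if tail_max is None:
        tail_max = gap_max
    total = n_trials - n_targets
    bounds = [(prefix_min, prefix_max)]
    bounds += [(gap_min, gap_max)] * (n_targets - 1)
    bounds += [(0, tail_max)]
    if total < 0:
        raise InfeasibleCompositionError("more targets than trials")
    counts = _composition_counts_cached(tuple(bounds), total)
    if counts[0][total] == 0:
        raise InfeasibleCompositionError(
            f"no composition of {total} standards under bounds {bounds[0]}, "
            f"{n_targets - 1} gaps in [{gap_min},{gap_max}], tail <= {tail_max}"
        )
    parts: list[int] = []
    remaining = total
    for i, (lo, hi) in enumerate(bounds):
        values = [v for v in range(lo, min(hi, remaining) + 1)]
        weights = np.array(
            [counts[i + 1][remaining - v] for v in values], dtype=float
        )
        probs = weights / weights.sum()
        v = int(rng.choice(values, p=probs))
        parts.append(v)
        remaining -= v
    assert remaining == 0
    return parts[0], parts[1:-1], parts[-1]


def build_block(
    spec: ConditionSpec,
    rng: np.random.Generator,
    n_trials: int = N_TRIALS,
    n_targets: int = N_TARGETS,
    prefix_min: int = PREFIX_MIN,
) -> Block:
    """Generate one block: SOA stream, target placement, deviant identities.

    Targets and standards draw their SOA from the same condition
    distribution; each target is a deviant with probability 0.5.
    """
    dist = build_soa_distribution(spec)
    prefix, gaps, _tail = sample_target_gaps(n_targets, n_trials, prefix_min, rng)
    target_set = set()
    pos = prefix + 1
    target_set.add(pos)
    for g in gaps:
        pos += g + 1
        target_set.add(pos)
    soas = dist.sample(n_trials - 1, rng)
    deviant_draws = rng.random(n_targets) < 0.5
    trials: list[Trial] = []
    t_i = 0
    for idx in range(1, n_trials + 1):
        is_target = idx in target_set
        is_deviant = bool(deviant_draws[t_i]) if is_target else False
        if is_target:
            t_i += 1
        trials.append(
            Trial(
                index=idx,
                soa_ms=None if idx == 1 else float(soas[idx - 2]),
                is_target=is_target,
                is_deviant=is_deviant,
            )
        )
    block = Block(condition=spec, trials=trials)
    block.validate()
    return block


def sample_block_order(
    rng: np.random.Generator,
    conditions: _Seq[float] = ALLOWED_STDS,
    blocks_per_condition: int = 2,
    max_tries: int = 10_000,
) -> list[float]:
    """Pseudo-random block order: uniform over orderings of the condition
    multiset that never repeat a condition in consecutive blocks.

    Rejection sampling from uniform multiset shuffles is exactly uniform over
    the admissible orders.
    """
    pool = np.repeat(np.asarray(conditions, dtype=float), blocks_per_condition)
    for _ in range(max_tries):
        order = rng.permutation(pool)
        if not np.any(order[1:] == order[:-1]):
            return [float(c) for c in order]
    raise RuntimeError("failed to sample an admissible block order")


def build_session(
    subject_id: str,
    rng: np.random.Generator,
    conditions: _Seq[float] = ALLOWED_STDS,
) -> Session:
    """Generate a 12-block session: 2 blocks per condition, no immediate repeats."""
    order = sample_block_order(rng, conditions)
    blocks = []
    for k, std in enumerate(order):
        spec = ConditionSpec(std_soa=std)
        block = build_block(spec, rng)
        block.seed_info = {"block_position": k + 1}
        blocks.append(block)
    session = Session(subject_id=subject_id, blocks=blocks)
    session.validate()
    return session
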