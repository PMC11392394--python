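"""Pair-based Monte Carlo scarcity engine.

A capacity of c = n/20 beds per patient is simulated per replicate by
randomly permuting the cohort, cutting it into blocks of twenty, pairing
consecutive patients within each block (ten pairs), and then:

* if n > 10 — the first n-10 pairs both receive beds and each remaining pair
  is contested (the higher-priority member wins);
* if n = 10 — every pair is contested;
* if n < 10 — the first n pairs are contested and the last 10-n pairs receive
  no beds.

Patients denied a bed are assumed not to survive; allocated patients realise
their scarcity-free outcome. A final short block (cohort size not divisible
by twenty) forms floor(m/2) pairs plus an optional singleton and receives
round(c*m) beds by the same first-pairs-double / last-pairs-zero scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Encounter, cohort_to_frame
from .protocols import ColoradoTable, PROTOCOL_NAMES, compute_bands

__all__ = [
    "CAPACITY_GRID",
    "SimulationConfig",
    "AllocationResult",
    "allocate_block",
    "simulate_replicate",
    "run_simulation",
    "capacity_sweep",
    "default_replicates",
]

BLOCK = 20
CAPACITY_GRID = tuple(n / BLOCK for n in range(1, BLOCK))


def default_replicates(capacity: float) -> int:
    """1000 replicates at half capacity, 250 elsewhere."""
    return 1000 if abs(capacity - 0.5) < 1e-12 else 250


def _beds_per_block(capacity: float) -> int:
    n = capacity * BLOCK
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 or not 1 <= n_int <= BLOCK - 1:
        raise ValueError(
            f"capacity {capacity} is not on the n/20 grid with 1 <= n <= 19"
        )
    return n_int


@dataclass
class SimulationConfig:
    protocol: str
    capacity: float
    replicates: int | None = None
    seed: int | np.random.SeedSequence = 0
    colorado_table: ColoradoTable | None = None

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOL_NAMES:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        _beds_per_block(self.capacity)
        if self.replicates is None:
            self.replicates = default_replicates(self.capacity)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class AllocationResult:
    """Per-replicate allocation indicators plus realised outcomes.

    ``allocation`` has shape (replicates, n_encounters). Realised survival is
    ``allocation & survived``; realised life-years are the annotated life
    expectancy for allocated survivors and zero otherwise.
    """

    protocol: str
    capacity: float
    allocation: np.ndarray
    survived: np.ndarray
    life_expectancy: np.ndarray | None
    cohort: pd.DataFrame = field(repr=False)

    @property
    def replicates(self) -> int:
        return self.allocation.shape[0]

    @property
    def n_encounters(self) -> int:
        return self.allocation.shape[1]

    @property
    def realized_survival(self) -> np.ndarray:
        return self.allocation & self.survived[None, :]

    @property
    def realized_life_years(self) -> np.ndarray:
        if self.life_expectancy is None:
            raise ValueError(
                "cohort not annotated with life expectancy; run annotate_cohort first"
            )
        return self.realized_survival * self.life_expectancy[None, :]


def _decide_pairs(
    bands: np.ndarray, tiebreak: np.ndarray, left: np.ndarray, right: np.ndarray
) -> np.ndarray:
    """Winner of each (left, right) pair by lexicographic (band, tiebreak)."""
    right_wins = (bands[right] < bands[left]) | (
        (bands[right] == bands[left]) & (tiebreak[right] < tiebreak[left])
    )
    return np.where(right_wins, right, left)


def _allocate_from_permutation(
    bands: np.ndarray,
    tiebreak: np.ndarray,
    perm: np.ndarray,
    capacity: float,
) -> np.ndarray:
    """Allocation decisions for one replicate given a cohort permutation."""
    n_beds = _beds_per_block(capacity)
    size = perm.size
    alloc = np.zeros(size, dtype=bool)
    n_blocks, remainder = divmod(size, BLOCK)

    if n_blocks:
        idx = perm[: n_blocks * BLOCK].reshape(n_blocks, BLOCK // 2, 2)
        winners = _decide_pairs(bands, tiebreak, idx[..., 0], idx[..., 1])
        if n_beds >= 10:
            double = n_beds - 10
            if double:
                alloc[idx[:, :double, :].ravel()] = True
            alloc[winners[:, double:].ravel()] = True
        else:
            alloc[winners[:, :n_beds].ravel()] = True

    if remainder:
        rem = perm[n_blocks * BLOCK:]
        beds = min(remainder, int(math.floor(capacity * remainder + 0.5)))
        full_pairs, singleton = divmod(remainder, 2)
        n_pairs = full_pairs + singleton  # singleton competes as its own pair
        if beds > 0:
            pair_idx = rem[: full_pairs * 2].reshape(full_pairs, 2)
            winners = (
                _decide_pairs(bands, tiebreak, pair_idx[:, 0], pair_idx[:, 1])
                if full_pairs
                else np.zeros(0, dtype=perm.dtype)
            )
            if beds >= n_pairs:
                extra = beds - n_pairs
                if extra:  # double-bed pairs come first; extra <= full_pairs
                    alloc[pair_idx[:extra].ravel()] = True
                alloc[winners] = True
                if singleton:
                    alloc[rem[-1]] = True
            else:
                k = min(beds, full_pairs)
                alloc[winners[:k]] = True
                if singleton and beds > full_pairs:
                    alloc[rem[-1]] = True
    return alloc


def allocate_block(
    block: Sequence[Encounter],
    n_beds: int,
    protocol: str,
    rng: np.random.Generator,
    colorado_table: ColoradoTable | None = None,
) -> np.ndarray:
    """Allocate ``n_beds`` beds within one block of exactly twenty encounters.

    Pairs are formed by a fresh random permutation; returns a boolean vector
    aligned with the block's input order.
    """
    if len(block) != BLOCK:
        raise ValueError(f"block must contain exactly {BLOCK} encounters, got {len(block)}")
    if not 1 <= n_beds <= BLOCK - 1:
        raise ValueError(f"n_beds must lie in [1, {BLOCK - 1}], got {n_beds}")
    bands = compute_bands(block, protocol, colorado_table)
    perm = rng.permutation(BLOCK)
    tiebreak = rng.random(BLOCK)
    return _allocate_from_permutation(bands, tiebreak, perm, n_beds / BLOCK)


def simulate_replicate(
    cohort: Sequence[Encounter],
    config: SimulationConfig,
    rng: np.random.Generator,
    bands: np.ndarray | None = None,
) -> np.ndarray:
    """One replicate: permute, partition into blocks, allocate.

    Returns a boolean allocation vector aligned with the cohort order.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    if bands is None:
        bands = compute_bands(cohort, config.protocol, config.colorado_table)
    perm = rng.permutation(len(cohort))
    tiebreak = rng.random(len(cohort))
    return _allocate_from_permutation(bands, tiebreak, perm, config.capacity)


def run_simulation(cohort: Sequence[Encounter], config: SimulationConfig) -> AllocationResult:
    """Run all replicates with independent per-replicate RNG substreams."""
    bands = compute_bands(cohort, config.protocol, config.colorado_table)
    survived = np.array([e.survived for e in cohort], dtype=bool)
    le = [e.life_expectancy for e in cohort]
    life_expectancy = (
        np.array(le, dtype=float) if all(v is not None for v in le) else None
    )

    master = (
        config.seed
        if isinstance(config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed)
    )
    streams = master.spawn(config.replicates)
    allocation = np.empty((config.replicates, len(cohort)), dtype=bool)
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        allocation[r] = simulate_replicate(cohort, config, rng, bands=bands)
    return AllocationResult(
        protocol=config.protocol,
        capacity=config.capacity,
        allocation=allocation,
        survived=survived,
        life_expectancy=life_expectancy,
        cohort=cohort_to_frame(cohort),
    )


def capacity_sweep(
    cohort: Sequence[Encounter],
    protocol: str,
    capacities: Sequence[float] = CAPACITY_GRID,
    replicates_map: Mapping[float, int] | None = None,
    seed: int | np.random.SeedSequence = 0,
    colorado_table: ColoradoTable | None = None,
) -> dict[float, AllocationResult]:
    """One run per capacity, each with a distinct seed substream."""
    master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    # Distinct substream per capacity, keyed by grid position so the same
    # capacity gets the same stream regardless of sweep composition.
    results: dict[float, AllocationResult] = {}
    for capacity in capacities:
        n_beds = _beds_per_block(capacity)
        reps = (replicates_map or {}).get(capacity) or default_replicates(capacity)
        sub_seed = np.random.SeedSequence(
            entropy=master.entropy, spawn_key=tuple(master.spawn_key) + (n_beds,)
        )
        config = SimulationConfig(
            protocol=protocol,
            capacity=capacity,
            replicates=reps,
            seed=sub_seed,
            colorado_table=colorado_table,
        )
        results[capacity] = run_simulation(cohort, config)
    return results
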