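"""Asynchronous main loop, generation clock and census recording.

One simulation proceeds in *culling cycles*. Within a cycle, occupied sites
are selected uniformly at random (with replacement, serial asynchronous
updating); the selected cell first attempts to divide and then — if it
carries the plasmid — attempts to conjugate, so a cell may do both in one
step. When occupancy reaches ``floor(0.95·edge²)`` a census row (the six
type counts plus the generation clock) is recorded and the population is
culled down to ``floor(0.5·edge²)``. The run stops after ``n_cull_events``
culls.

The generation clock is the cumulative base-2 logarithm of population
expansion: each cycle contributes ``log2(N_fill / N_start)``, the number of
population doublings it took to refill the grid. With the default 0.95/0.5
fractions every steady cycle contributes ``log2(1.9) ≈ 0.926`` generations,
and 1073 cycles amount to ≈1000 generations regardless of grid size.

Two engines produce bit-identical results from the same seed: ``"numba"``
(default, compiled fused loop) and ``"python"`` (reference composition of
the :mod:`plasmidlattice.dynamics` kernels; use for small grids only).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynamics
from .lattice import CellType, Lattice, MutationLocus, SimulationParams, init_lattice

__all__ = [
    "CensusRecord",
    "CensusSeries",
    "run_simulation",
    "generations_elapsed",
    "write_census_csv",
    "read_census_csv",
    "CENSUS_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Census CSV schema, one row per fill event.
CENSUS_COLUMNS = [
    "replicate_id",
    "condition_id",
    "mutation_locus",
    "cycle_index",
    "generations",
    "n_recipient",
    "n_donor",
    "n_transconjugant",
    "n_seg_adapted",
    "n_seg_nonadapted",
    "n_seg_donor",
]

_COUNT_COLUMNS = CENSUS_COLUMNS[5:]


@dataclass(frozen=True)
class CensusRecord:
    """Counts of the six bacterial types at one grid-fill event."""

    cycle_index: int  # 1-based
    counts: np.ndarray  # six entries, type codes 1..6
    generations: float  # cumulative clock at the fill instant


@dataclass(frozen=True)
class CensusSeries:
    """Full census of one run: one record per fill event, plus final state."""

    params: SimulationParams
    counts: np.ndarray  # (n_records, 6) int64
    generations: np.ndarray  # (n_records,) cumulative clock
    final_counts: np.ndarray  # (6,) after the last cull

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def records(self) -> list[CensusRecord]:
        return [
            CensusRecord(i + 1, self.counts[i], float(self.generations[i]))
            for i in range(len(self))
        ]

    def to_dataframe(self, replicate_id: int = 0, condition_id: int = 0) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "replicate_id": np.full(n, replicate_id, dtype=np.int64),
                "condition_id": np.full(n, condition_id, dtype=np.int64),
                "mutation_locus": [self.params.mutation_locus.value] * n,
                "cycle_index": np.arange(1, n + 1, dtype=np.int64),
                "generations": self.generations,
                "n_recipient": self.counts[:, 0],
                "n_donor": self.counts[:, 1],
                "n_transconjugant": self.counts[:, 2],
                "n_seg_adapted": self.counts[:, 3],
                "n_seg_nonadapted": self.counts[:, 4],
                "n_seg_donor": self.counts[:, 5],
            }
        )


class ExtinctionError(RuntimeError):
    """Raised when the whole population dies out mid-run."""


def _run_python(lattice: Lattice, params: SimulationParams, rng) -> CensusSeries:
    """Reference engine: the dynamics kernels composed step by step."""
    n_cycles = params.n_cull_events
    counts_out = np.zeros((n_cycles, 6), dtype=np.int64)
    gen_out = np.zeros(n_cycles, dtype=np.float64)
    fill, target = params.fill_threshold, params.cull_target
    cycles = 0
    generations = 0.0
    cycle_start = lattice.occupied_count

    def record_and_cull() -> None:
        nonlocal cycles, generations, cycle_start
        counts_out[cycles] = lattice.type_counts[1:7]
        generations += math.log2(lattice.occupied_count / cycle_start)
        gen_out[cycles] = generations
        dynamics.cull(lattice, params, rng)
        cycles += 1
        cycle_start = lattice.occupied_count
        logger.debug("cycle %d/%d: %.2f generations", cycles, n_cycles, generations)

    while cycles < n_cycles:
        if lattice.occupied_count <= 0:
            raise ExtinctionError("population went extinct")
        if lattice.occupied_count >= fill:
            record_and_cull()
            continue
        u = rng.random_sample()
        idx = int(u * lattice.occupied_count)
        if idx >= lattice.occupied_count:
            idx = lattice.occupied_count - 1
        site = lattice.coords(int(lattice.occupied_sites[idx]))
        out = dynamics.attempt_growth(lattice, site, params, rng)
        if out.kind is dynamics.EventKind.BIRTH and lattice.occupied_count >= fill:
            # the birth filled the grid: census/cull takes precedence and
            # the focal cell forfeits its conjugation opportunity
            record_and_cull()
            continue
        if lattice.state(*site).plasmid_bearing:
            dynamics.attempt_conjugation(lattice, site, params, rng)

    return CensusSeries(params, counts_out, gen_out, lattice.type_counts[1:7].copy())


def _run_numba(lattice: Lattice, params: SimulationParams, loop_seed: int) -> CensusSeries:
    from ._kernel import STATUS_EXTINCT, run_kernel

    n_cycles = params.n_cull_events
    counts_out = np.zeros((n_cycles, 6), dtype=np.int64)
    gen_out = np.zeros(n_cycles, dtype=np.float64)
    status, n_occ = run_kernel(
        lattice.types,
        lattice.cost,
        lattice.countdown,
        lattice.occupied_sites,
        lattice.position_of,
        lattice.occupied_count,
        lattice.type_counts,
        lattice.edge,
        params.psi_max,
        params.gamma_max,
        params.theta,
        params.theta1,
        params.theta2,
        params.b,
        params.c,
        params.adaptation_time,
        params.segregation_prob,
        params.fill_threshold,
        params.cull_target,
        n_cycles,
        params.mutation_locus is MutationLocus.PLASMID,
        loop_seed,
        counts_out,
        gen_out,
    )
    lattice.occupied_count = int(n_occ)
    if status == STATUS_EXTINCT:
        raise ExtinctionError("population went extinct")
    return CensusSeries(params, counts_out, gen_out, lattice.type_counts[1:7].copy())


def run_simulation(
    params: SimulationParams,
    engine: str = "numba",
    return_lattice: bool = False,
):
    """Run one full simulation and return its :class:`CensusSeries`.

    The seed governs both the initial placement and the event loop. The
    two engines share the placement code and consume loop draws in the same
    order, so they are interchangeable and bit-identical; ``"python"`` is
    the reference implementation and practical only for small grids.
    """
    rng = np.random.RandomState(params.seed)
    lattice = init_lattice(params, rng)
    loop_seed = int(rng.randint(0, 2**31 - 1))
    logger.info(
        "run: edge=%d pop=%d locus=%s seed=%d engine=%s",
        params.edge,
        params.initial_population,
        params.mutation_locus.value,
        params.seed,
        engine,
    )
    if engine == "python":
        series = _run_python(lattice, params, np.random.RandomState(loop_seed))
    elif engine == "numba":
        series = _run_numba(lattice, params, loop_seed)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    logger.info(
        "done: %d cycles, %.1f generations",
        len(series),
        series.generations[-1] if len(series) else 0.0,
    )
    if return_lattice:
        return series, lattice
    return series


def generations_elapsed(series: CensusSeries) -> float:
    """Total generations over a run, from the log2 population-expansion clock.

    Recomputed from the census itself: the first cycle expands from the
    initial population, every later cycle from the post-cull population, and
    each contributes ``log2(N_fill / N_start)``.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    fills = series.counts.sum(axis=1)
    if (fills <= 0).any():
        raise ValueError("census contains a zero population")
    start0 = series.params.initial_population
    if start0 <= 0:
        raise ValueError("initial population is zero")
    total = math.log2(fills[0] / start0)
    target = series.params.cull_target
    for n_fill in fills[1:]:
        total += math.log2(n_fill / target)
    return total


def write_census_csv(
    series: CensusSeries,
    path,
    replicate_id: int = 0,
    condition_id: int = 0,
) -> None:
    """Write the census as RFC-4180 CSV (UTF-8), one row per fill event."""
    df = series.to_dataframe(replicate_id=replicate_id, condition_id=condition_id)
    df.to_csv(path, index=False, encoding="utf-8")


def read_census_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"census file {path} lacks columns: {sorted(missing)}")
    return df


def series_from_dataframe(df: pd.DataFrame, params: SimulationParams) -> CensusSeries:
    """Rebuild a :class:`CensusSeries` from a census table (one replicate)."""
    df = df.sort_values("cycle_index")
    counts = df[_COUNT_COLUMNS].to_numpy(dtype=np.int64)
    return CensusSeries(
        params,
        counts,
        df["generations"].to_numpy(dtype=np.float64),
        counts[-1].copy() if len(counts) else np.zeros(6, dtype=np.int64),
    )
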