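"""Periodic lattice, cell states and simulation parameters.

The habitat is a toroidal ``edge × edge`` grid. Every site is either empty or
holds exactly one bacterium. Six bacterial types are tracked:

====  =================  =========================================
code  name               description
====  =================  =========================================
1     RECIPIENT          plasmid-free cell, never carried the plasmid
2     DONOR              original plasmid-bearing cell, adapted (cost ``c``)
3     TRANSCONJUGANT     cell that received the plasmid by conjugation;
                         pays cost ``b`` until its amelioration countdown
                         reaches zero, then cost ``c``
4     SEG_ADAPTED        adapted transconjugant that lost the plasmid
5     SEG_NONADAPTED     non-adapted transconjugant that lost the plasmid
6     SEG_DONOR          donor that lost the plasmid
====  =================  =========================================

Two neighbourhoods are defined around each site, both with toroidal
wraparound: the *local* neighbourhood (the 8 sites of the 3×3 Moore block,
into which a cell can divide or conjugate) and the *nutrient* neighbourhood
(the full 7×7 block of 49 sites, whose empty-space fraction stands in for
nutrient availability).

Coordinates are 0-based internally; logs and CSV output present them 1-based.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellType",
    "MutationLocus",
    "SiteState",
    "SimulationParams",
    "Lattice",
    "LOCAL_OFFSETS",
    "init_lattice",
    "local_neighbors",
    "empty_fraction_nutrient",
]


class CellType(enum.IntEnum):
    """Site contents. ``EMPTY`` is 0; bacterial types are 1–6."""

    EMPTY = 0
    RECIPIENT = 1
    DONOR = 2
    TRANSCONJUGANT = 3
    SEG_ADAPTED = 4
    SEG_NONADAPTED = 5
    SEG_DONOR = 6


#: Types that carry the conjugative plasmid.
PLASMID_BEARING = frozenset({CellType.DONOR, CellType.TRANSCONJUGANT})
#: Types eligible to receive the plasmid.
PLASMID_FREE = frozenset(
    {CellType.RECIPIENT, CellType.SEG_ADAPTED, CellType.SEG_NONADAPTED, CellType.SEG_DONOR}
)


class MutationLocus(enum.Enum):
    """Replicon on which compensatory (cost-ameliorating) mutations arise.

    ``CHROMOSOME``: amelioration belongs to the host lineage; a transferred
    plasmid always restarts at the initial cost ``b`` with a full countdown.
    ``PLASMID``: amelioration travels with the plasmid; a transferred plasmid
    carries its current cost and its current countdown.
    """

    PLASMID = "plasmid"
    CHROMOSOME = "chromosome"


# Fixed scan order of the 8 Moore neighbours: row-major over the 3×3 block
# excluding the centre. Both simulation engines rely on this exact order.
LOCAL_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

#: Half-width and site count of the nutrient (7×7) neighbourhood.
NUTRIENT_RADIUS = 3
NUTRIENT_SITES = (2 * NUTRIENT_RADIUS + 1) ** 2  # 49, focal site included


@dataclass(frozen=True)
class SiteState:
    """Snapshot of one lattice site.

    ``plasmid_cost`` is the current growth-rate reduction paid by the cell
    (0 for empty or plasmid-free sites). ``countdown`` is the number of
    divisions remaining until amelioration; 0 means adapted. For
    plasmid-locus simulations the countdown is a property of the plasmid
    copy resident in the cell, for chromosome-locus simulations it is a
    property of the host cell — the stored representation is identical.
    """

    cell_type: CellType
    plasmid_cost: float = 0.0
    countdown: int = 0

    def __post_init__(self) -> None:
        if self.cell_type in (CellType.EMPTY, *PLASMID_FREE):
            if self.plasmid_cost != 0.0 or self.countdown != 0:
                raise ValueError(
                    f"{self.cell_type.name} sites carry no plasmid cost or countdown"
                )
        if not (0.0 <= self.plasmid_cost < 1.0):
            raise ValueError("plasmid_cost must lie in [0, 1)")
        if self.countdown < 0:
            raise ValueError("countdown must be non-negative")

    @property
    def plasmid_bearing(self) -> bool:
        return self.cell_type in PLASMID_BEARING


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set for a single simulation condition.

    Defaults are the reference configuration: a 1000×1000 grid seeded with
    10 donors and 9990 recipients, growth saturating above a nutrient
    fraction ``theta`` = 0.8, conjugation switching on between ``theta1`` =
    0.2 and ``theta2`` = 0.3, and a resource-renewal cycle that culls the
    population to 50% whenever 95% of sites are occupied, repeated
    ``n_cull_events`` = 1073 times (≈1000 generations).
    """

    edge: int = 1000
    max_fill_fraction: float = 0.95
    remaining_fraction: float = 0.5
    psi_max: float = 1.0
    gamma_max: float = 1.0
    theta: float = 0.8
    theta1: float = 0.2
    theta2: float = 0.3
    b: float = 0.2
    c: float = 0.0
    adaptation_time: int = 70
    segregation_prob: float = 0.001
    n_donors: int = 10
    n_recipients: int = 9990
    mutation_locus: MutationLocus = MutationLocus.CHROMOSOME
    n_cull_events: int = 1073
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge < 3:
            raise ValueError("edge must be >= 3 (neighbourhoods must be proper)")
        if not (0.0 <= self.c <= self.b < 1.0):
            raise ValueError("costs must satisfy 0 <= c <= b < 1")
        if not (0.0 < self.theta1 < self.theta2 <= self.theta <= 1.0):
            raise ValueError("thresholds must satisfy 0 < theta1 < theta2 <= theta <= 1")
        if not (0.0 < self.psi_max <= 1.0):
            raise ValueError("psi_max must lie in (0, 1]")
        if not (0.0 <= self.gamma_max <= 1.0):
            raise ValueError("gamma_max must lie in [0, 1]")
        if not (0.0 <= self.segregation_prob <= 1.0):
            raise ValueError("segregation_prob must lie in [0, 1]")
        if not (0.0 < self.remaining_fraction < self.max_fill_fraction <= 1.0):
            raise ValueError("need 0 < remaining_fraction < max_fill_fraction <= 1")
        if self.n_donors < 0 or self.n_recipients < 0:
            raise ValueError("population counts must be non-negative")
        if self.n_donors + self.n_recipients == 0:
            raise ValueError("initial population must not be empty")
        if self.n_donors + self.n_recipients > self.edge**2:
            raise ValueError("initial population exceeds grid capacity")
        if self.adaptation_time < 0 or self.n_cull_events < 0:
            raise ValueError("adaptation_time and n_cull_events must be non-negative")
        if isinstance(self.mutation_locus, str):  # accept plain strings from configs
            object.__setattr__(self, "mutation_locus", MutationLocus(self.mutation_locus))

    @property
    def fill_threshold(self) -> int:
        """Occupancy at which a census is recorded and culling triggers."""
        return math.floor(self.max_fill_fraction * self.edge**2)

    @property
    def cull_target(self) -> int:
        """Occupancy immediately after a cull."""
        return math.floor(self.remaining_fraction * self.edge**2)

    @property
    def initial_population(self) -> int:
        return self.n_donors + self.n_recipients

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


class Lattice:
    """Toroidal grid of sites with O(1) occupancy bookkeeping.

    State is stored in flat numpy arrays indexed by ``site = x * edge + y``:
    ``types`` (int8 cell-type codes), ``cost`` (float64 current plasmid
    cost) and ``countdown`` (int64 divisions to amelioration). A packed
    array of occupied site indices plus a reverse position map supports
    uniform sampling and swap-with-last removal in constant time; per-type
    population counts are maintained incrementally.
    """

    def __init__(self, edge: int):
        if edge < 3:
            raise ValueError("edge must be >= 3")
        self.edge = int(edge)
        n = self.edge * self.edge
        self.types = np.zeros(n, dtype=np.int8)
        self.cost = np.zeros(n, dtype=np.float64)
        self.countdown = np.zeros(n, dtype=np.int64)
        # occupancy bookkeeping
        self.occupied_sites = np.zeros(n, dtype=np.int64)
        self.position_of = np.full(n, -1, dtype=np.int64)
        self.occupied_count = 0
        self.type_counts = np.zeros(7, dtype=np.int64)
        self.type_counts[0] = n

    # -- index helpers ----------------------------------------------------
    def site_index(self, x: int, y: int) -> int:
        e = self.edge
        return (x % e) * e + (y % e)

    def coords(self, site: int) -> tuple[int, int]:
        return divmod(int(site), self.edge)

    # -- state access -----------------------------------------------------
    def state(self, x: int, y: int) -> SiteState:
        s = self.site_index(x, y)
        return SiteState(
            CellType(int(self.types[s])), float(self.cost[s]), int(self.countdown[s])
        )

    def set_state(self, x: int, y: int, state: SiteState) -> None:
        """Write a site, keeping occupancy and type counters consistent."""
        s = self.site_index(x, y)
        old = int(self.types[s])
        new = int(state.cell_type)
        if old == 0 and new != 0:
            self._add_occupied(s)
        elif old != 0 and new == 0:
            self._remove_occupied(s)
        self.type_counts[old] -= 1
        self.type_counts[new] += 1
        self.types[s] = new
        self.cost[s] = state.plasmid_cost
        self.countdown[s] = state.countdown

    def _add_occupied(self, s: int) -> None:
        self.occupied_sites[self.occupied_count] = s
        self.position_of[s] = self.occupied_count
        self.occupied_count += 1

    def _remove_occupied(self, s: int) -> None:
        pos = int(self.position_of[s])
        last = self.occupied_sites[self.occupied_count - 1]
        self.occupied_sites[pos] = last
        self.position_of[last] = pos
        self.position_of[s] = -1
        self.occupied_count -= 1

    # -- integrity --------------------------------------------------------
    def recount(self) -> np.ndarray:
        """Full-grid recount of all seven type codes (integrity check)."""
        return np.bincount(self.types.astype(np.int64), minlength=7)

    def check_consistency(self) -> None:
        counts = self.recount()
        if not np.array_equal(counts, self.type_counts):
            raise AssertionError("incremental type counts diverged from recount")
        if self.occupied_count != int(counts[1:].sum()):
            raise AssertionError("occupied_count diverged from recount")

    def copy(self) -> "Lattice":
        out = Lattice.__new__(Lattice)
        out.edge = self.edge
        out.types = self.types.copy()
        out.cost = self.cost.copy()
        out.countdown = self.countdown.copy()
        out.occupied_sites = self.occupied_sites.copy()
        out.position_of = self.position_of.copy()
        out.occupied_count = self.occupied_count
        out.type_counts = self.type_counts.copy()
        return out


def init_lattice(params: SimulationParams, rng) -> Lattice:
    """Place donors and recipients uniformly at random without replacement.

    Exactly ``n_donors`` sites become DONOR (cost ``c``, countdown 0, already
    adapted) and ``n_recipients`` become RECIPIENT. Sampling site indices
    without replacement guarantees the initial counts exactly and respects
    single occupancy.

    ``rng`` is a legacy ``numpy.random.RandomState`` (or API-compatible
    object); the simulation engines share its draw conventions.
    """
    total = params.n_donors + params.n_recipients
    if total == 0:
        raise ValueError("initial population must not be empty")
    n_sites = params.edge**2
    if total > n_sites:
        raise ValueError("initial population exceeds grid capacity")
    lattice = Lattice(params.edge)
    chosen = rng.choice(n_sites, size=total, replace=False)
    donors, recipients = chosen[: params.n_donors], chosen[params.n_donors:]
    lattice.types[donors] = int(CellType.DONOR)
    lattice.cost[donors] = params.c
    lattice.types[recipients] = int(CellType.RECIPIENT)
    for s in chosen:
        lattice._add_occupied(int(s))
    lattice.type_counts[int(CellType.DONOR)] = params.n_donors
    lattice.type_counts[int(CellType.RECIPIENT)] = params.n_recipients
    lattice.type_counts[0] = n_sites - total
    return lattice


def local_neighbors(lattice: Lattice, x: int, y: int) -> list[tuple[int, int]]:
    """The 8 Moore neighbours of ``(x, y)`` with toroidal wraparound.

    Returned in the fixed scan order used by the event kernels; the focal
    site is never included. All coordinates are normalised into
    ``[0, edge)``.
    """
    e = lattice.edge
    return [((x + dx) % e, (y + dy) % e) for dx, dy in LOCAL_OFFSETS]


def empty_fraction_nutrient(lattice: Lattice, x: int, y: int) -> float:
    """Nutrient availability C: empty fraction of the 7×7 block around a cell.

    The denominator is all 49 sites including the (occupied) focal one, so
    C ≤ 48/49 for any occupied focal site.
    """
    s = lattice.site_index(x, y)
    if lattice.types[s] == 0:
        raise ValueError("focal site must be occupied")
    e = lattice.edge
    empties = 0
    for dx in range(-NUTRIENT_RADIUS, NUTRIENT_RADIUS + 1):
        xi = ((x + dx) % e) * e
        for dy in range(-NUTRIENT_RADIUS, NUTRIENT_RADIUS + 1):
            if lattice.types[xi + (y + dy) % e] == 0:
                empties += 1
    return empties / NUTRIENT_SITES
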