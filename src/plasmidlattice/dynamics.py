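"""Event kernels: growth (with segregation and amelioration), conjugation, culling.

These are the reference implementations of the three stochastic events the
scheduler dispatches. They are written for clarity and testability; the
production simulation loop (:mod:`plasmidlattice._kernel`) is a fused,
numba-compiled transcription that consumes random draws in exactly the same
order, so the two can be asserted trajectory-identical under a shared seed.

Random-draw order (one ``random_sample()`` per item, fixed contract):

* growth attempt, only if an empty local neighbour exists: (1) acceptance
  draw against the growth rate, then on acceptance (2) daughter-slot choice,
  then (3) segregation draw if the parent is plasmid-bearing;
* conjugation attempt, only if a plasmid-free local neighbour exists:
  (4) acceptance draw against the conjugation rate, then on acceptance
  (5) target choice;
* culling: one draw per removed cell (index into the packed occupied list).

Uniform integers in ``[0, n)`` are always taken as ``floor(u * n)`` from a
uniform ``u ∈ [0, 1)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .lattice import (
    CellType,
    Lattice,
    MutationLocus,
    SimulationParams,
    SiteState,
    LOCAL_OFFSETS,
    empty_fraction_nutrient,
)

__all__ = [
    "EventKind",
    "EventOutcome",
    "growth_rate",
    "conjugation_rate",
    "attempt_growth",
    "attempt_conjugation",
    "cull",
]


class EventKind(enum.Enum):
    NONE = "none"
    BIRTH = "birth"
    CONJUGATION = "conjugation"
    CULL = "cull"


@dataclass(frozen=True)
class EventOutcome:
    """What an event kernel did: kind plus affected coordinates/states."""

    kind: EventKind
    details: dict = field(default_factory=dict)


def growth_rate(C: float, psi_max: float, theta: float) -> float:
    """Division probability per attempt as a function of nutrient fraction C.

    Saturates at ``psi_max`` once C ≥ theta and falls off linearly to zero
    below; continuous at the threshold.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError("C must lie in [0, 1]")
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    if C >= theta:
        return psi_max
    return psi_max * C / theta


def conjugation_rate(C: float, gamma_max: float, theta1: float, theta2: float) -> float:
    """Plasmid-transfer probability per attempt as a function of C.

    Zero below ``theta1``, saturating at ``gamma_max`` above ``theta2``,
    linear in between; continuous at both thresholds. Transfer requires more
    nutrients than none but saturates well below the growth threshold.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError("C must lie in [0, 1]")
    if theta1 >= theta2:
        raise ValueError("theta1 must be < theta2")
    if C >= theta2:
        return gamma_max
    if C < theta1:
        return 0.0
    return gamma_max * (C - theta1) / (theta2 - theta1)


def _effective_psi_max(state: SiteState, params: SimulationParams) -> float:
    """ψmax reduced multiplicatively by the cell's current plasmid cost."""
    return params.psi_max * (1.0 - state.plasmid_cost)


def attempt_growth(lattice: Lattice, site: tuple[int, int], params: SimulationParams, rng) -> EventOutcome:
    """One division attempt by the focal cell.

    Requires an empty local (Moore) neighbour. The division fires with
    probability ``growth_rate(C, ψmax·(1−cost), θ)``; the daughter is placed
    on a uniformly chosen empty local site and copies the parent. If the
    parent is a non-adapted transconjugant the amelioration countdown is
    decremented first (the division consumes one unit; parent and daughter
    both carry the decremented value, and at zero the cost drops to ``c``).
    A plasmid-bearing parent's daughter segregates (loses the plasmid, no
    cost) with probability ``segregation_prob``, becoming the matching
    plasmid-free type.
    """
    x, y = site
    focal = lattice.state(x, y)
    if focal.cell_type == CellType.EMPTY:
        raise ValueError("attempt_growth requires an occupied focal site")
    e = lattice.edge
    empty_slots = [
        ((x + dx) % e, (y + dy) % e)
        for dx, dy in LOCAL_OFFSETS
        if lattice.types[((x + dx) % e) * e + (y + dy) % e] == 0
    ]
    if not empty_slots:
        return EventOutcome(EventKind.NONE)
    C = empty_fraction_nutrient(lattice, x, y)
    psi = growth_rate(C, _effective_psi_max(focal, params), params.theta)
    u = rng.random_sample()
    if u > psi:
        return EventOutcome(EventKind.NONE)
    k = int(rng.random_sample() * len(empty_slots))
    if k >= len(empty_slots):  # guard against u*n rounding up
        k = len(empty_slots) - 1
    slot = empty_slots[k]

    # amelioration: the division decrements the countdown before copying
    if focal.cell_type == CellType.TRANSCONJUGANT and focal.countdown > 0:
        new_cd = focal.countdown - 1
        new_cost = params.c if new_cd == 0 else focal.plasmid_cost
        focal = SiteState(CellType.TRANSCONJUGANT, new_cost, new_cd)
        lattice.set_state(x, y, focal)

    daughter = focal
    if focal.plasmid_bearing:
        if rng.random_sample() <= params.segregation_prob:
            if focal.cell_type == CellType.DONOR:
                seg_type = CellType.SEG_DONOR
            elif focal.countdown == 0:
                seg_type = CellType.SEG_ADAPTED
            else:
                seg_type = CellType.SEG_NONADAPTED
            daughter = SiteState(seg_type)
    lattice.set_state(*slot, daughter)
    return EventOutcome(
        EventKind.BIRTH,
        {"parent": (x, y), "daughter": slot, "daughter_state": daughter, "C": C},
    )


def _transfer_state(source: SiteState, target: SiteState, params: SimulationParams) -> SiteState:
    """State of a plasmid-free cell after receiving the plasmid.

    A segregant that originated from a donor becomes a donor again (cost
    ``c``): its chromosome is the donor chromosome, already co-adapted with
    the plasmid. Otherwise the outcome depends on where compensatory
    mutations reside:

    * plasmid locus — the incoming plasmid carries its own cost and
      countdown: from a donor that is the initial cost ``b`` with a full
      countdown, from a transconjugant it is that cell's current plasmid
      state (possibly already ameliorated to ``c``);
    * chromosome locus — the plasmid itself is unmodified, so the target
      pays ``b`` with a full countdown unless its own chromosome already
      carries the compensation (an adapted segregant re-acquiring the
      plasmid resumes at cost ``c``).
    """
    if target.cell_type == CellType.SEG_DONOR:
        return SiteState(CellType.DONOR, params.c, 0)
    if params.mutation_locus is MutationLocus.PLASMID:
        # the transferred plasmid copy carries its own adaptation state;
        # donor plasmids always transfer at the initial cost with a full
        # countdown (the donor's own adaptation is not encoded on it)
        if source.cell_type == CellType.DONOR:
            return SiteState(CellType.TRANSCONJUGANT, params.b, params.adaptation_time)
        return SiteState(CellType.TRANSCONJUGANT, source.plasmid_cost, source.countdown)
    # chromosome locus: adaptation belongs to the target's lineage
    if target.cell_type == CellType.SEG_ADAPTED:
        return SiteState(CellType.TRANSCONJUGANT, params.c, 0)
    return SiteState(CellType.TRANSCONJUGANT, params.b, params.adaptation_time)


def attempt_conjugation(lattice: Lattice, site: tuple[int, int], params: SimulationParams, rng) -> EventOutcome:
    """One plasmid-transfer attempt by the focal plasmid-bearing cell.

    Requires a plasmid-free local neighbour (recipient or any segregant).
    Transfer fires with probability ``conjugation_rate(C, γmax, θ1, θ2)``;
    the target is chosen uniformly among eligible neighbours and converted
    per :func:`_transfer_state`. Occupancy never changes.
    """
    x, y = site
    focal = lattice.state(x, y)
    if not focal.plasmid_bearing:
        raise ValueError("attempt_conjugation requires a plasmid-bearing focal cell")
    e = lattice.edge
    targets = [
        ((x + dx) % e, (y + dy) % e)
        for dx, dy in LOCAL_OFFSETS
        if int(lattice.types[((x + dx) % e) * e + (y + dy) % e]) in (1, 4, 5, 6)
    ]
    if not targets:
        return EventOutcome(EventKind.NONE)
    C = empty_fraction_nutrient(lattice, x, y)
    gamma = conjugation_rate(C, params.gamma_max, params.theta1, params.theta2)
    u = rng.random_sample()
    if u > gamma:
        return EventOutcome(EventKind.NONE)
    k = int(rng.random_sample() * len(targets))
    if k >= len(targets):
        k = len(targets) - 1
    tx, ty = targets[k]
    new_state = _transfer_state(focal, lattice.state(tx, ty), params)
    lattice.set_state(tx, ty, new_state)
    return EventOutcome(
        EventKind.CONJUGATION,
        {"source": (x, y), "target": (tx, ty), "target_state": new_state, "C": C},
    )


def cull(lattice: Lattice, params: SimulationParams, rng) -> EventOutcome:
    """Resource renewal: empty uniformly chosen occupied sites down to 50%.

    Cells are removed one at a time by uniform index into the packed
    occupied list (swap-with-last), which yields a uniformly random
    surviving subset — selection is blind to cell type. Only callable once
    occupancy has reached the fill threshold.
    """
    if lattice.occupied_count < params.fill_threshold:
        raise ValueError("cull requires occupancy at or above the fill threshold")
    target = params.cull_target
    removed = 0
    while lattice.occupied_count > target:
        j = int(rng.random_sample() * lattice.occupied_count)
        if j >= lattice.occupied_count:
            j = lattice.occupied_count - 1
        s = int(lattice.occupied_sites[j])
        lattice.set_state(*lattice.coords(s), SiteState(CellType.EMPTY))
        removed += 1
    return EventOutcome(EventKind.CULL, {"removed": removed})
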