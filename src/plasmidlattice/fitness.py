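"""Selection-rate fitness and replicate-level statistical comparisons.

The relative success of a subpopulation A against a subpopulation B over a
run is the *selection rate*

    S_AB = [ln(N_Af / N_Ai) − ln(N_Bf / N_Bi)] / t = m_A − m_B,

the difference of Malthusian parameters per generation: positive when the
A:B ratio grew over the run. Two standing aggregations are provided:

* donor fitness — A is the donor lineage (donors and donor-derived
  segregants), B is everything else (recipients, transconjugants, the
  other segregants, and descendants);
* plasmid fitness — A is the plasmid-bearing compartment (donors and
  transconjugants), B all plasmid-free cells.

Replicate-level comparisons follow the study design: runs are paired by
replicate index across the two mutation-locus modes (matched seeds), the
per-pair difference ΔS = S_chromosome − S_plasmid is tested against zero
with a one-sample Student t-test (α = 0.05 by default), and the
with-transfer versus no-transfer contrast uses a two-sample t-test against
matched γmax = 0 runs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .lattice import CellType
from .scheduler import CensusSeries, generations_elapsed

__all__ = [
    "FitnessResult",
    "Classification",
    "TransferEffect",
    "ComparisonResult",
    "selection_rate",
    "donor_fitness",
    "plasmid_fitness",
    "compare_modes",
    "classify_transfer_effect",
]

# census count-column order is type codes 1..6
_DONOR_LINEAGE = (CellType.DONOR, CellType.SEG_DONOR)
_PLASMID_BEARING = (CellType.DONOR, CellType.TRANSCONJUGANT)


@dataclass(frozen=True)
class FitnessResult:
    """Selection rate of A vs B with the counts and time that produced it.

    ``s_ab`` is NaN when any compartment count is zero (extinction);
    callers must handle that explicitly via :attr:`finite`.
    """

    s_ab: float
    n_a_init: float
    n_a_final: float
    n_b_init: float
    n_b_final: float
    time: float

    @property
    def finite(self) -> bool:
        return math.isfinite(self.s_ab)


class Classification(enum.Enum):
    """Donor success under plasmid-locus vs chromosome-locus mutations."""

    LOWER = "lower"  # significantly lower with mutations on the plasmid
    NO_DIFFERENCE = "no_difference"
    HIGHER = "higher"


class TransferEffect(enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NO_CHANGE = "no_change"


@dataclass(frozen=True)
class ComparisonResult:
    """Per-condition paired comparison of the two mutation-locus modes."""

    condition_id: int
    delta_s: tuple[float, ...]  # per replicate pair, S_chromosome − S_plasmid
    t_statistic: float
    p_value: float
    classification: Classification


def selection_rate(
    n_a_init: float,
    n_a_final: float,
    n_b_init: float,
    n_b_final: float,
    time: float,
) -> FitnessResult:
    """Selection rate S_AB = [ln(N_Af/N_Ai) − ln(N_Bf/N_Bi)] / time.

    Exactly antisymmetric under A↔B swap and invariant to rescaling all
    four counts by a common factor. Any zero count (an extinct compartment)
    yields a NaN rate, signalled rather than raised so that sweep-level
    callers can flag the condition instead of aborting.
    """
    if time <= 0:
        raise ValueError("time must be positive")
    counts = (n_a_init, n_a_final, n_b_init, n_b_final)
    if any(n < 0 for n in counts):
        raise ValueError("counts must be non-negative")
    if any(n == 0 for n in counts):
        s = math.nan
    else:
        s = (math.log(n_a_final / n_a_init) - math.log(n_b_final / n_b_init)) / time
    return FitnessResult(s, n_a_init, n_a_final, n_b_init, n_b_final, time)


def _compartment_fitness(series: CensusSeries, a_types: Sequence[CellType]) -> FitnessResult:
    if len(series) == 0:
        raise ValueError("series is empty")
    a_cols = [int(t) - 1 for t in a_types]
    b_cols = [i for i in range(6) if i not in a_cols]
    final = series.counts[-1]
    p = series.params
    # initial compartments: donors start the donor lineage and the
    # plasmid-bearing compartment; recipients start everything else
    init = np.zeros(6, dtype=np.int64)
    init[int(CellType.DONOR) - 1] = p.n_donors
    init[int(CellType.RECIPIENT) - 1] = p.n_recipients
    time = generations_elapsed(series)
    return selection_rate(
        float(init[a_cols].sum()),
        float(final[a_cols].sum()),
        float(init[b_cols].sum()),
        float(final[b_cols].sum()),
        time,
    )


def donor_fitness(series: CensusSeries) -> FitnessResult:
    """Selection rate of the donor lineage against everyone else.

    A = donors and donor-derived segregants (the initial donor cells and
    their descendants, whether or not they still carry the plasmid);
    B = recipients, transconjugants and transconjugant-derived segregants.
    Counts are taken from the initial condition and the last census record;
    time is the generation clock of the run.
    """
    return _compartment_fitness(series, _DONOR_LINEAGE)


def plasmid_fitness(series: CensusSeries) -> FitnessResult:
    """Selection rate of plasmid-bearing cells against plasmid-free cells.

    A = donors + transconjugants; B = recipients + all segregants.
    """
    return _compartment_fitness(series, _PLASMID_BEARING)


def _one_sample_t(deltas: np.ndarray) -> tuple[float, float]:
    """One-sample t-test of mean(deltas) vs 0, with degenerate handling.

    Zero variance is an exact tie when all values are 0 (p = 1) and an
    unambiguous displacement otherwise (p = 0); scipy returns NaN there.
    """
    sd = deltas.std(ddof=1)
    if sd == 0.0:
        if np.all(deltas == 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, deltas.mean()), 0.0
    t, p = stats.ttest_1samp(deltas, 0.0)
    return float(t), float(p)


def compare_modes(
    s_plasmid: Sequence[float],
    s_chromosome: Sequence[float],
    alpha: float = 0.05,
    condition_id: int = 0,
) -> ComparisonResult:
    """Paired comparison of donor (or plasmid) success between the modes.

    Replicates are paired by index (matched seeds across modes);
    Δ = S_chromosome − S_plasmid, so Δ > 0 means compensatory mutations on
    the plasmid are detrimental to the quantity compared. A one-sample
    t-test of mean Δ against zero at level ``alpha`` yields ``LOWER``
    (significant, Δ > 0: success lower with plasmid-locus mutations),
    ``HIGHER`` (significant, Δ < 0) or ``NO_DIFFERENCE``.
    """
    sp = np.asarray(s_plasmid, dtype=float)
    sc = np.asarray(s_chromosome, dtype=float)
    if sp.shape != sc.shape:
        raise ValueError("replicate lists must have equal length")
    if sp.size < 2:
        raise ValueError("need at least 2 replicates")
    if not (np.isfinite(sp).all() and np.isfinite(sc).all()):
        raise ValueError("non-finite fitness values; handle extinctions upstream")
    deltas = sc - sp
    t, p = _one_sample_t(deltas)
    if p > alpha:
        cls = Classification.NO_DIFFERENCE
    elif deltas.mean() > 0:
        cls = Classification.LOWER
    else:
        cls = Classification.HIGHER
    return ComparisonResult(condition_id, tuple(deltas), t, p, cls)


def classify_transfer_effect(
    s_with_transfer: Sequence[float],
    s_no_transfer: Sequence[float],
    alpha: float = 0.05,
) -> TransferEffect:
    """Does plasmid transfer change donor success, relative to γmax = 0 runs?

    Two-sample (Welch) t-test between replicate fitness values with transfer
    as configured and with transfer disabled; ``INCREASE``/``DECREASE`` per
    the sign of the mean difference when significant at ``alpha``.
    """
    a = np.asarray(s_with_transfer, dtype=float)
    b = np.asarray(s_no_transfer, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite fitness values; handle extinctions upstream")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return TransferEffect.NO_CHANGE
        return TransferEffect.INCREASE if diff > 0 else TransferEffect.DECREASE
    _, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(p):  # degenerate variance with displaced means
        p = 0.0
    if p > alpha:
        return TransferEffect.NO_CHANGE
    return TransferEffect.INCREASE if a.mean() > b.mean() else TransferEffect.DECREASE
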