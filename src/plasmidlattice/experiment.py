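"""Factorial parameter sweep: condition enumeration, seeding, orchestration.

The reference study design crosses 2 permanent costs × 3 initial costs ×
3 conjugation rates × 4 initial donor frequencies × 2 adaptation times =
144 conditions, each run in both mutation-locus modes with 3 replicates.
Replicate seeds are matched across the two modes so the per-condition mode
comparison is paired; seeds are distinct across (condition, replicate).

Outputs under ``out_dir``:

* ``conditions.csv`` — manifest of every condition's parameters;
* ``census_c####_<mode>_r#.csv`` — one census table per run
  (:data:`plasmidlattice.scheduler.CENSUS_COLUMNS` schema);
* ``summary.csv`` — one row per condition with mean donor/plasmid fitness
  per mode, the paired mode comparison (Δ, t, p, classification) and
  extinction flags; optionally the with/without-transfer contrast.

Re-running a sweep with the same ``base_seed`` is byte-identical; runs
whose census file already exists are skipped (resume support).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import fitness as fitness_mod
from .lattice import MutationLocus, SimulationParams
from .scheduler import (
    read_census_csv,
    run_simulation,
    series_from_dataframe,
    write_census_csv,
)

__all__ = ["SweepSpec", "enumerate_conditions", "condition_seed", "run_sweep", "analyze_sweep"]

logger = logging.getLogger(__name__)

#: donor frequencies of the reference design: 0.1%, 1%, 50%, 99%
DEFAULT_DONOR_FRACTIONS = (0.001, 0.01, 0.5, 0.99)


@dataclass(frozen=True)
class SweepSpec:
    """Value lists defining a factorial sweep plus run-level settings.

    ``total_population`` defaults to 1% of the grid's sites (10,000 cells
    on the reference 1000×1000 grid); donor counts are the rounded donor
    fractions of that total, clipped so both compartments start non-empty.
    """

    c_values: tuple[float, ...] = (0.0, 0.1)
    b_values: tuple[float, ...] = (0.2, 0.4, 0.6)
    gamma_max_values: tuple[float, ...] = (1.0, 0.1, 0.01)
    donor_fractions: tuple[float, ...] = DEFAULT_DONOR_FRACTIONS
    adaptation_times: tuple[int, ...] = (70, 400)
    modes: tuple[MutationLocus, ...] = (MutationLocus.PLASMID, MutationLocus.CHROMOSOME)
    replicates: int = 3
    base_seed: int = 0
    edge: int = 1000
    n_cull_events: int = 1073
    total_population: int | None = None
    alpha: float = 0.05
    transfer_baseline: bool = False  # also run matched gamma_max=0 baselines

    def __post_init__(self) -> None:
        for name in ("c_values", "b_values", "gamma_max_values", "donor_fractions", "adaptation_times", "modes"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must not be empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        mods = tuple(MutationLocus(m) if isinstance(m, str) else m for m in self.modes)
        object.__setattr__(self, "modes", mods)

    @property
    def population(self) -> int:
        if self.total_population is not None:
            return self.total_population
        return max(2, self.edge**2 // 100)

    def donor_counts(self, fraction: float) -> tuple[int, int]:
        total = self.population
        n_d = min(max(1, round(fraction * total)), total - 1)
        return n_d, total - n_d

    @property
    def n_conditions(self) -> int:
        return (
            len(self.c_values)
            * len(self.b_values)
            * len(self.gamma_max_values)
            * len(self.donor_fractions)
            * len(self.adaptation_times)
        )


def enumerate_conditions(spec: SweepSpec) -> list[tuple[int, SimulationParams]]:
    """All conditions of the sweep, in a fixed documented order.

    The Cartesian product iterates c (slowest), then b, γmax, donor
    fraction, adaptation time (fastest); ``condition_id`` is the 1-based
    index in that order. The returned parameter sets carry seed 0 and the
    chromosome locus; :func:`run_sweep` overrides both per run.
    """
    out = []
    combos = itertools.product(
        spec.c_values,
        spec.b_values,
        spec.gamma_max_values,
        spec.donor_fractions,
        spec.adaptation_times,
    )
    for cid, (c, b, gamma, frac, adapt) in enumerate(combos, start=1):
        n_d, n_r = spec.donor_counts(frac)
        out.append(
            (
                cid,
                SimulationParams(
                    edge=spec.edge,
                    gamma_max=gamma,
                    b=b,
                    c=c,
                    adaptation_time=adapt,
                    n_donors=n_d,
                    n_recipients=n_r,
                    n_cull_events=spec.n_cull_events,
                ),
            )
        )
    return out


def condition_seed(base_seed: int, condition_id: int, replicate: int) -> int:
    """Deterministic per-(condition, replicate) seed, shared across modes.

    Mode does not enter the mix: the two mutation-locus modes run from
    identical seeds so the per-condition comparison is paired. Seeds are
    drawn from a ``numpy.random.SeedSequence`` spawn mix and kept below
    2^31.
    """
    ss = np.random.SeedSequence([int(base_seed), int(condition_id), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def _census_name(condition_id: int, mode: MutationLocus, replicate: int, baseline: bool = False) -> str:
    tag = "baseline_" if baseline else ""
    return f"census_{tag}c{condition_id:04d}_{mode.value}_r{replicate}.csv"


def _run_or_load(
    params: SimulationParams,
    path: Path,
    condition_id: int,
    replicate: int,
    engine: str,
):
    if path.exists():
        logger.info("resume: %s exists, loading", path.name)
        return series_from_dataframe(read_census_csv(path), params)
    series = run_simulation(params, engine=engine)
    write_census_csv(series, path, replicate_id=replicate, condition_id=condition_id)
    return series


def _fitness_columns(series_list) -> tuple[list[float], list[float]]:
    s_donor = [fitness_mod.donor_fitness(s).s_ab for s in series_list]
    s_plasmid = [fitness_mod.plasmid_fitness(s).s_ab for s in series_list]
    return s_donor, s_plasmid


def _paired_summary(prefix: str, sp, sc, alpha: float, cid: int) -> dict:
    """Summary fields for one paired quantity (donor or plasmid fitness)."""
    row: dict = {
        f"{prefix}_s_plasmid_mode_mean": np.nanmean(sp),
        f"{prefix}_s_chromosome_mode_mean": np.nanmean(sc),
    }
    extinct = not (np.isfinite(sp).all() and np.isfinite(sc).all())
    row[f"{prefix}_extinct"] = extinct
    if extinct:
        row.update(
            {
                f"{prefix}_delta_mean": math.nan,
                f"{prefix}_t": math.nan,
                f"{prefix}_p": math.nan,
                f"{prefix}_classification": "extinct",
            }
        )
    else:
        cmp = fitness_mod.compare_modes(sp, sc, alpha=alpha, condition_id=cid)
        row.update(
            {
                f"{prefix}_delta_mean": float(np.mean(cmp.delta_s)),
                f"{prefix}_t": cmp.t_statistic,
                f"{prefix}_p": cmp.p_value,
                f"{prefix}_classification": cmp.classification.value,
            }
        )
    return row


def run_sweep(spec: SweepSpec, out_dir, engine: str = "numba") -> pd.DataFrame:
    """Run the full sweep and write census files plus ``summary.csv``.

    Returns the summary table (one row per condition). Conditions where a
    fitness compartment went extinct are flagged, never dropped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = enumerate_conditions(spec)

    manifest = pd.DataFrame(
        [
            {
                "condition_id": cid,
                "edge": p.edge,
                "c": p.c,
                "b": p.b,
                "gamma_max": p.gamma_max,
                "n_donors": p.n_donors,
                "n_recipients": p.n_recipients,
                "adaptation_time": p.adaptation_time,
                "n_cull_events": p.n_cull_events,
            }
            for cid, p in conditions
        ]
    )
    manifest.to_csv(out / "conditions.csv", index=False, encoding="utf-8")

    rows = []
    for cid, base_params in conditions:
        per_mode: dict[MutationLocus, list] = {}
        failed = False
        for mode in spec.modes:
            series_list = []
            for rep in range(spec.replicates):
                seed = condition_seed(spec.base_seed, cid, rep)
                params = base_params.with_(mutation_locus=mode, seed=seed)
                path = out / _census_name(cid, mode, rep)
                try:
                    series_list.append(_run_or_load(params, path, cid, rep, engine))
                except RuntimeError as exc:  # total extinction
                    logger.warning("condition %d %s rep %d failed: %s", cid, mode.value, rep, exc)
                    failed = True
            per_mode[mode] = series_list
        row = {
            "condition_id": cid,
            "c": base_params.c,
            "b": base_params.b,
            "gamma_max": base_params.gamma_max,
            "n_donors": base_params.n_donors,
            "n_recipients": base_params.n_recipients,
            "adaptation_time": base_params.adaptation_time,
            "run_failed": failed,
        }
        if not failed and len(spec.modes) == 2:
            mp, mc = spec.modes
            if mp is not MutationLocus.PLASMID:
                mp, mc = mc, mp
            d_p, p_p = _fitness_columns(per_mode[mp])
            d_c, p_c = _fitness_columns(per_mode[mc])
            row.update(_paired_summary("donor", d_p, d_c, spec.alpha, cid))
            row.update(_paired_summary("plasmid", p_p, p_c, spec.alpha, cid))
            if spec.transfer_baseline:
                row.update(
                    _transfer_effect_row(spec, cid, base_params, out, engine, d_p, d_c)
                )
        rows.append(row)

    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False, encoding="utf-8")
    return summary


def _transfer_effect_row(
    spec: SweepSpec,
    cid: int,
    base_params: SimulationParams,
    out: Path,
    engine: str,
    d_plasmid: list[float],
    d_chromosome: list[float],
) -> dict:
    """Matched γmax = 0 baseline runs and the with/without-transfer test."""
    base = base_params.with_(gamma_max=0.0)
    s_base = []
    for rep in range(spec.replicates):
        seed = condition_seed(spec.base_seed, cid, rep)
        params = base.with_(seed=seed)
        path = out / _census_name(cid, MutationLocus.CHROMOSOME, rep, baseline=True)
        series = _run_or_load(params, path, cid, rep, engine)
        s_base.append(fitness_mod.donor_fitness(series).s_ab)
    row: dict = {"baseline_s_mean": float(np.nanmean(s_base))}
    for prefix, vals in (("plasmid_mode", d_plasmid), ("chromosome_mode", d_chromosome)):
        if np.isfinite(vals).all() and np.isfinite(s_base).all():
            eff = fitness_mod.classify_transfer_effect(vals, s_base, alpha=spec.alpha)
            row[f"transfer_effect_{prefix}"] = eff.value
        else:
            row[f"transfer_effect_{prefix}"] = "extinct"
    return row


def analyze_sweep(in_dir, alpha: float = 0.05) -> pd.DataFrame:
    """Rebuild the summary table from census files already on disk.

    Reads ``conditions.csv`` and every present census file; conditions with
    missing replicates are flagged ``run_failed``.
    """
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "conditions.csv")
    rows = []
    for rec in manifest.to_dict("records"):
        cid = int(rec["condition_id"])
        params = SimulationParams(
            edge=int(rec["edge"]),
            c=float(rec["c"]),
            b=float(rec["b"]),
            gamma_max=float(rec["gamma_max"]),
            n_donors=int(rec["n_donors"]),
            n_recipients=int(rec["n_recipients"]),
            adaptation_time=int(rec["adaptation_time"]),
            n_cull_events=int(rec["n_cull_events"]),
        )
        per_mode = {}
        for mode in (MutationLocus.PLASMID, MutationLocus.CHROMOSOME):
            series_list = []
            rep = 0
            while True:
                path = in_dir / _census_name(cid, mode, rep)
                if not path.exists():
                    break
                series_list.append(series_from_dataframe(read_census_csv(path), params))
                rep += 1
            per_mode[mode] = series_list
        n_rep = {m: len(s) for m, s in per_mode.items()}
        row = {
            "condition_id": cid,
            "c": params.c,
            "b": params.b,
            "gamma_max": params.gamma_max,
            "n_donors": params.n_donors,
            "n_recipients": params.n_recipients,
            "adaptation_time": params.adaptation_time,
            "run_failed": min(n_rep.values()) == 0 or len(set(n_rep.values())) > 1,
        }
        if not row["run_failed"]:
            d_p, p_p = _fitness_columns(per_mode[MutationLocus.PLASMID])
            d_c, p_c = _fitness_columns(per_mode[MutationLocus.CHROMOSOME])
            row.update(_paired_summary("donor", d_p, d_c, alpha, cid))
            row.update(_paired_summary("plasmid", p_p, p_c, alpha, cid))
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(in_dir / "summary.csv", index=False, encoding="utf-8")
    return summary
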