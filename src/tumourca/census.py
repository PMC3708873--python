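"""Census time series, experiment drivers and protocol comparison.

The census is the hourly phase-resolved head count of the tumour —
total, G1, S-G2-M and quiescent cells, the hypoxic-area percentage and
the cumulative kill counters — written as a fixed-header CSV so that
identical (config, seed) pairs produce byte-identical files.

Experiment drivers run the standard in-silico protocols: grow one
seeded cell in a vascularised lattice, apply a treatment schedule, and
record the census.  ``ablation_run`` switches off single
ingredients of the radiation model (hypoxia OMF, the divisional delay,
phase-specific sensitivity, low-dose repair) against the fractionated
course; ``compare_protocols`` ranks schedules by final tumour burden
over replicate seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .automaton import World, init_world, step, write_snapshot
from .cellcycle import Phase
from .therapy import TreatmentSchedule, build_schedule

__all__ = ["CENSUS_COLUMNS", "RunResult", "census", "run_experiment",
           "ablation_run", "ABLATION_VARIANTS", "compare_protocols",
           "write_census", "read_census"]

logger = logging.getLogger("tumourca")

CENSUS_COLUMNS = [
    "time_h", "n_total", "n_g1", "n_sg2m", "n_resting",
    "hypoxic_area_pct", "killed_radiation_cum", "killed_chemo_cum",
]


def census(world: World) -> dict:
    """One census row: phase counts, hypoxic area, kill ledger."""
    ph = world.phase[np.flatnonzero(world.alive)]
    n_g1 = int(np.count_nonzero(ph == int(Phase.G1)))
    n_sg2m = int(np.count_nonzero(ph == int(Phase.SG2M)))
    n_rest = int(np.count_nonzero(ph == int(Phase.RESTING)))
    return {
        "time_h": float(world.clock),
        "n_total": n_g1 + n_sg2m + n_rest,
        "n_g1": n_g1,
        "n_sg2m": n_sg2m,
        "n_resting": n_rest,
        "hypoxic_area_pct": float(world.hypoxic_area_pct),
        "killed_radiation_cum": world.cumulative_kills["radiation"],
        "killed_chemo_cum": world.cumulative_kills["chemo"],
    }


@dataclass
class RunResult:
    """Census table plus the provenance needed to reproduce it."""

    census: pd.DataFrame
    config_digest: str
    seed: int
    schedule_name: str
    world: World | None = None  # final state (not serialised)

    @property
    def final_count(self) -> int:
        return int(self.census["n_total"].iloc[-1])


def write_census(df: pd.DataFrame, path) -> None:
    """Fixed header, UTF-8, LF endings — byte-stable across reruns."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def read_census(path) -> pd.DataFrame:
    return pd.read_csv(path)


def run_experiment(
    config,
    schedule: TreatmentSchedule | None,
    seed: int,
    horizon_h: float,
    out_dir=None,
    from_world: World | None = None,
    snapshot_times=(),
    keep_world: bool = True,
) -> RunResult:
    """Run one simulation to *horizon_h* and collect the hourly census.

    Starts from a fresh single-cell world, or — for branching one grown
    tumour into several treatment arms — from a copy of *from_world*.
    Therapy events are applied in the macro step covering their time
    stamp.  With *out_dir* set, writes ``census.csv``,
    ``run_meta.json`` and any requested phase-map snapshots.
    """
    config.validate()
    if schedule is not None:
        schedule.validate()
    if from_world is None:
        world = init_world(config, seed)
        world.census_rows.append(census(world))  # row at t = 0
    else:
        world = from_world.branch()
        # the branch adopts the (possibly modified) run configuration
        world.config = config
        world.o2_pct_to_mmhg = config.microenv.o2_pct_to_mmhg
    world.schedule = schedule
    snapshot_times = sorted(snapshot_times)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    n_steps = int(round((horizon_h - world.clock) / config.macro_dt))
    prev_kills = dict(world.cumulative_kills)
    for _ in range(n_steps):
        step(world, config.macro_dt)
        for cause, n in world.cumulative_kills.items():
            if n != prev_kills[cause]:
                logger.info("t=%.0f h %s therapy killed %d cells",
                            world.clock, cause, n - prev_kills[cause])
                prev_kills[cause] = n
        if out_dir is not None and snapshot_times \
                and world.clock >= snapshot_times[0]:
            write_snapshot(world, out_dir / f"snapshot_{world.clock:.0f}.tsv")
            snapshot_times.pop(0)

    df = pd.DataFrame(world.census_rows, columns=CENSUS_COLUMNS)
    name = schedule.name if schedule is not None else "no_treatment"
    result = RunResult(
        census=df,
        config_digest=config.digest(),
        seed=int(seed),
        schedule_name=name,
        world=world if keep_world else None,
    )
    if out_dir is not None:
        write_census(df, out_dir / "census.csv")
        meta = {"config_digest": result.config_digest, "seed": result.seed,
                "schedule": name, "horizon_h": horizon_h,
                "version": _version()}
        (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2))
    return result


ABLATION_VARIANTS = ("full", "no_hypoxia_OMF1", "no_delay", "uniform_gamma",
                     "no_repair")


def ablation_run(
    variant: str,
    config,
    seed: int,
    horizon_h: float = 520.0,
    from_world: World | None = None,
    out_dir=None,
) -> RunResult:
    """Fractionated-radiation experiment with one model switch applied.

    Variants: ``full`` (no switch), ``no_hypoxia_OMF1`` (every cell
    treated as fully oxygenated when computing kill), ``no_delay``
    (no post-irradiation divisional delay), ``uniform_gamma`` (maximal
    phase sensitivity for all cells), ``no_repair`` (repair correction
    ρ ≡ 1 at every dose).
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}; "
                         f"choose from {ABLATION_VARIANTS}")
    import copy

    cfg = copy.deepcopy(config)
    rad = cfg.therapy.radiation
    if variant == "no_hypoxia_OMF1":
        rad.omf_override = 1.0
    elif variant == "no_delay":
        rad.delay_enabled = False
    elif variant == "uniform_gamma":
        rad.gamma_g1 = rad.gamma_sg2m = rad.gamma_resting = 1.0
    elif variant == "no_repair":
        rad.repair_enabled = False
    schedule = build_schedule("fractionated")
    result = run_experiment(cfg, schedule, seed, horizon_h,
                            from_world=from_world, out_dir=out_dir)
    result.schedule_name = f"fractionated[{variant}]"
    return result


class ComparabilityError(ValueError):
    """Protocol comparison across mismatched configurations."""


def compare_protocols(results) -> pd.DataFrame:
    """Rank schedules by mean final tumour burden (ascending).

    *results* are RunResults from matching configs (any mix of
    schedules and replicate seeds).  Ties rank alphabetically by
    schedule name.  Returns one row per schedule with replicate mean,
    standard deviation and rank.
    """
    results = list(results)
    if len(results) < 2:
        raise ComparabilityError("need at least two runs to compare")
    digests = {r.config_digest for r in results}
    if len(digests) > 1:
        raise ComparabilityError(
            f"runs use {len(digests)} different configurations")
    rows = {}
    for r in results:
        rows.setdefault(r.schedule_name, []).append(r.final_count)
    table = pd.DataFrame(
        [
            {
                "schedule": name,
                "n_runs": len(counts),
                "final_n_total_mean": float(np.mean(counts)),
                "final_n_total_sd": float(np.std(counts, ddof=1))
                if len(counts) > 1 else 0.0,
            }
            for name, counts in rows.items()
        ]
    ).sort_values(["final_n_total_mean", "schedule"], kind="stable")
    table["rank"] = range(1, len(table) + 1)
    return table.reset_index(drop=True)


def _version() -> str:
    from . import __version__

    return __version__
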