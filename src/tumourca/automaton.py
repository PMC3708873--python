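"""The lattice world and the master time-stepping loop.

Each automaton site is empty, a blood-vessel cross-section, or holds
one tumour cell.  Cells carry their own cell-cycle network state
(:mod:`tumourca.cellcycle`); the shared microenvironment fields live on
the lattice (:mod:`tumourca.microenv`).  One macro step (default 1 h)
performs, in order:

1. refresh the quasi-steady oxygen field, the hypoxia mask and the
   per-cell hypoxia flags;
2. advance the cell-cycle network of every live, cycling cell whose
   post-irradiation delay timer is idle (delayed cells are frozen and
   their timer decremented instead);
3. resolve division events — cells whose CycB collapsed through the
   division threshold place a daughter in a free neighbour site, with
   the Moore and Von Neumann neighbourhoods used alternately per
   division event; a cell with no free neighbour enters quiescence;
4. return quiescent cells to G1 where space has opened up and the site
   is normoxic;
5. advance any active drug fields;
6. apply scheduled therapy events falling in this interval and the
   concentration-threshold chemotherapy kill;
7. append a census row.

Division events are resolved after all cell-cycle updates, in
row-major site order, which makes the within-step outcome independent
of cell bookkeeping order.
"""

from __future__ import annotations

import copy
from dataclasses import replace

import numpy as np

from . import therapy as _therapy
from ._kernels import advance_states
from .cellcycle import EARLY_G1_STATE, Phase
from .microenv import (Field, generate_vessels, hypoxic_mask, solve_oxygen,
                       step_drug)

__all__ = ["World", "EMPTY", "VESSEL", "init_world", "attempt_division",
           "update_resting", "step", "snapshot_codes", "write_snapshot"]

EMPTY = -1
VESSEL = -2

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (0, -1), (0, 1), (1, 0)]


class World:
    """Complete automaton state: lattice, cell registry, fields, clock.

    Cell attributes are stored as parallel arrays indexed by a cell id
    that is assigned once at birth and never reused; ``alive`` masks
    the live subset.  ``occupancy[r, c]`` is the id of the resident
    cell, or ``EMPTY`` / ``VESSEL``.
    """

    def __init__(self, config, seed: int, vessels=None):
        config.validate()
        self.config = config
        self.seed = int(seed)
        g = config.grid
        self.rows, self.cols = g.rows, g.cols
        self.site_um = g.site_um

        ss = np.random.SeedSequence(self.seed)
        ss_vessel, ss_dyn, ss_ther = ss.spawn(3)
        self.rng_dynamics = np.random.default_rng(ss_dyn)
        self.rng_therapy = np.random.default_rng(ss_ther)

        start = g.start_site if g.start_site is not None \
            else (g.rows // 2, g.cols // 2)
        self.start_site = tuple(start)
        if vessels is None:
            vessels = generate_vessels(
                g.rows, g.cols, g.vessel_density, g.vessel_min_separation,
                seed=ss_vessel, exclude={self.start_site})
        elif vessels.mask[self.start_site]:
            raise ValueError(f"start site {self.start_site} lies on a vessel")
        self.vessels = vessels

        self.occupancy = np.full((g.rows, g.cols), EMPTY, dtype=np.int64)
        self.occupancy[vessels.mask] = VESSEL

        # cell registry (parallel arrays, capacity-doubled)
        cap = 1024
        self._cap = cap
        self.n_created = 0
        self.alive = np.zeros(cap, dtype=bool)
        self.row = np.zeros(cap, dtype=np.int64)
        self.col = np.zeros(cap, dtype=np.int64)
        self.states = np.zeros((cap, 6), dtype=np.float64)
        self.phase = np.zeros(cap, dtype=np.int64)
        self.hypoxic = np.zeros(cap, dtype=bool)
        self.delay = np.zeros(cap, dtype=np.float64)
        self.born_at = np.zeros(cap, dtype=np.float64)
        # per-cell intrinsic mass-growth multiplier, drawn at birth
        self.growth_factor = np.ones(cap, dtype=np.float64)

        self.clock = 0.0
        self.division_parity = 0
        self.cumulative_kills = {"radiation": 0, "chemo": 0}
        self.schedule = None
        self.census_rows: list = []

        self.o2_pct_to_mmhg = config.microenv.o2_pct_to_mmhg
        self._oxygen_raw = None
        self._oxygen_occ = None
        self.oxygen = Field(np.zeros((g.rows, g.cols)), "oxygen")
        self.hypoxia_mask = np.zeros((g.rows, g.cols), dtype=bool)
        self.hypoxic_area_pct = 0.0
        self.drugs = {
            name: Field(np.zeros((g.rows, g.cols)), name)
            for name in config.therapy.chemo
        }
        self._drug_supply_until = {name: -np.inf for name in self.drugs}

        # seed cell and initial fields
        self.add_cell(*self.start_site, EARLY_G1_STATE.as_array(),
                      Phase.G1, born_at=0.0)
        self.refresh_oxygen()

    # -- registry ----------------------------------------------------------

    def _grow(self) -> None:
        new_cap = self._cap * 2
        for name in ("alive", "row", "col", "phase", "hypoxic", "delay",
                     "born_at", "growth_factor"):
            arr = getattr(self, name)
            out = np.zeros(new_cap, dtype=arr.dtype)
            out[: self._cap] = arr
            setattr(self, name, out)
        st = np.zeros((new_cap, 6))
        st[: self._cap] = self.states
        self.states = st
        self._cap = new_cap

    def _draw_growth_factor(self) -> float:
        """Lognormal (mean 1) intrinsic growth-rate multiplier."""
        cv = self.config.cellcycle.growth_rate_cv
        if cv <= 0:
            return 1.0
        s = float(np.sqrt(np.log1p(cv * cv)))
        return float(np.exp(self.rng_dynamics.normal(-0.5 * s * s, s)))

    def add_cell(self, r: int, c: int, state_array, phase: Phase,
                 born_at: float) -> int:
        if self.occupancy[r, c] != EMPTY:
            raise ValueError(f"site ({r}, {c}) is not empty")
        if self.n_created == self._cap:
            self._grow()
        cid = self.n_created
        self.n_created += 1
        self.alive[cid] = True
        self.row[cid], self.col[cid] = r, c
        self.states[cid] = state_array
        self.phase[cid] = int(phase)
        self.delay[cid] = 0.0
        self.born_at[cid] = born_at
        self.growth_factor[cid] = self._draw_growth_factor()
        self.occupancy[r, c] = cid
        return cid

    def kill_cell(self, cid: int) -> None:
        if not self.alive[cid]:
            raise ValueError(f"cell {cid} is not alive")
        self.alive[cid] = False
        self.occupancy[self.row[cid], self.col[cid]] = EMPTY

    @property
    def n_live(self) -> int:
        return int(self.alive.sum())

    @property
    def cells(self) -> dict:
        """Live-cell registry view (id -> record), for inspection."""
        from types import SimpleNamespace

        out = {}
        for cid in np.flatnonzero(self.alive):
            cid = int(cid)
            out[cid] = SimpleNamespace(
                position=(int(self.row[cid]), int(self.col[cid])),
                state=self.states[cid].copy(),
                phase=Phase(int(self.phase[cid])),
                hypoxic=bool(self.hypoxic[cid]),
                delay_timer=float(self.delay[cid]),
                born_at=float(self.born_at[cid]),
            )
        return out

    def check_consistency(self) -> None:
        """Registry <-> lattice bijection (cheap invariant check)."""
        ids = np.flatnonzero(self.alive)
        occ_ids = self.occupancy[self.occupancy >= 0]
        if sorted(occ_ids.tolist()) != sorted(ids.tolist()):
            raise AssertionError("occupancy/registry mismatch")
        if np.any(self.vessels.mask & (self.occupancy >= 0)):
            raise AssertionError("cell on a vessel site")

    # -- environment -------------------------------------------------------

    def cell_occupancy(self) -> np.ndarray:
        return self.occupancy >= 0

    def refresh_oxygen(self) -> None:
        params = self.config.microenv.oxygen
        occ = self.cell_occupancy()
        if self._oxygen_raw is None \
                or not np.array_equal(occ, self._oxygen_occ):
            # unchanged occupancy -> identical quasi-steady field; only
            # re-solve when the cell pattern actually moved
            raw = solve_oxygen(occ, self.vessels, params,
                               x0=self._oxygen_raw, normalise=False)
            self._oxygen_occ = occ
            self._oxygen_raw = raw.values
        raw = self._oxygen_raw
        peak = raw.max()
        pct = raw * (100.0 / peak) if peak > 0 else raw.copy()
        self.oxygen = Field(pct, "oxygen")
        self.hypoxia_mask, self.hypoxic_area_pct = hypoxic_mask(
            self.oxygen, self.config.microenv.hypoxia_threshold_pct)
        ids = np.flatnonzero(self.alive)
        self.hypoxic[ids] = self.hypoxia_mask[self.row[ids], self.col[ids]]

    # -- copying -----------------------------------------------------------

    def branch(self) -> "World":
        """Deep copy for branching one grown tumour into several arms."""
        return copy.deepcopy(self)


def init_world(config, seed: int, vessels=None) -> World:
    """Fresh world: vessels from seed, one early-G1 cell at the start
    site (default: lattice centre), fields solved once, clock at 0."""
    return World(config, seed, vessels=vessels)


def _free_neighbours(world: World, r: int, c: int, offsets):
    out = []
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < world.rows and 0 <= cc < world.cols \
                and world.occupancy[rr, cc] == EMPTY:
            out.append((rr, cc))
    return out


def attempt_division(world: World, cid: int, rng) -> tuple:
    """Place a daughter of cell *cid*, or park the mother in quiescence.

    The neighbourhood alternates per division event — Moore (8 sites)
    on even parity, Von Neumann (4 sites) on odd — and a free,
    non-vessel neighbour is drawn uniformly.  With no free neighbour
    the mother enters the resting phase and no daughter is created.
    Returns ``("placed", site)`` or ``("resting", None)``.
    """
    offsets = _MOORE if world.division_parity % 2 == 0 else _VON_NEUMANN
    world.division_parity += 1
    r, c = int(world.row[cid]), int(world.col[cid])
    free = _free_neighbours(world, r, c, offsets)
    if not free:
        world.phase[cid] = int(Phase.RESTING)
        return ("resting", None)
    site = free[int(rng.integers(len(free)))]
    split = world.config.cellcycle.division_mass_split
    mother_mass = world.states[cid, 5]
    world.states[cid, 5] = mother_mass * split
    daughter_state = world.states[cid].copy()
    daughter_state[5] = mother_mass * (1.0 - split)
    world.add_cell(site[0], site[1], daughter_state, Phase.G1,
                   born_at=world.clock)
    return ("placed", site)


def update_resting(world: World) -> list:
    """Return quiescent cells to G1 where conditions allow.

    A resting cell re-enters the cycle (state reset to the early-G1
    reference) when at least one Moore neighbour site is free and its
    own site is not hypoxic.  Returns the reactivated cell ids.
    """
    resting = np.flatnonzero(world.alive
                             & (world.phase == int(Phase.RESTING)))
    if resting.size == 0:
        return []
    free = world.occupancy == EMPTY
    has_free = np.zeros_like(free)
    for dr, dc in _MOORE:
        rs = slice(max(dr, 0), world.rows + min(dr, 0))
        rd = slice(max(-dr, 0), world.rows + min(-dr, 0))
        cs = slice(max(dc, 0), world.cols + min(dc, 0))
        cd = slice(max(-dc, 0), world.cols + min(-dc, 0))
        has_free[rd, cd] |= free[rs, cs]
    rr, cc = world.row[resting], world.col[resting]
    ok = has_free[rr, cc] & ~world.hypoxia_mask[rr, cc]
    reactivated = resting[ok]
    if reactivated.size:
        world.phase[reactivated] = int(Phase.G1)
        world.states[reactivated] = EARLY_G1_STATE.as_array()
        world.delay[reactivated] = 0.0
    return [int(i) for i in reactivated]


def _advance_cells(world: World, macro_dt: float) -> np.ndarray:
    """Stage 2: integrate cycling cells; freeze delayed ones.

    Returns the ids of cells whose CycB crossed the division threshold
    downward during this macro step.
    """
    cc = world.config.cellcycle
    ids = np.flatnonzero(world.alive & (world.phase != int(Phase.RESTING)))
    delayed = ids[world.delay[ids] > 0]
    world.delay[delayed] = np.maximum(world.delay[delayed] - macro_dt, 0.0)
    active = ids[world.delay[ids] <= 0]
    # note: cells whose timer just expired this step resume next step
    active = np.setdiff1d(active, delayed, assume_unique=True)
    if active.size == 0:
        return active
    states = world.states[active].copy()
    prev_cycb = states[:, 0].copy()
    hyp = world.growth_factor[active] \
        * np.where(world.hypoxic[active], cc.hypoxia_slowdown_factor, 1.0)
    n_full, rem = divmod(macro_dt, cc.dt_ode)
    advance_states(states, hyp, cc.as_array(), int(round(n_full)), cc.dt_ode)
    if rem > 1e-12:
        advance_states(states, hyp, cc.as_array(), 1, rem)
    world.states[active] = states
    thr = cc.cycb_threshold
    world.phase[active] = np.where(states[:, 0] < thr, int(Phase.G1),
                                   int(Phase.SG2M))
    dividing = active[(prev_cycb >= thr) & (states[:, 0] < thr)]
    return dividing


def _due_events(schedule, t0: float, t1: float):
    """Events with time in [t0, t1)."""
    rad = [(t, d) for t, d in (schedule.radiation if schedule else [])
           if t0 <= t < t1]
    chemo = [c for c in (schedule.chemo if schedule else [])
             if t0 <= c.time_h < t1]
    return rad, chemo


def step(world: World, macro_dt: float = 1.0) -> World:
    """Advance the world by one macro step (in place; returns world)."""
    if macro_dt <= 0:
        raise ValueError("macro_dt must be > 0")
    from .census import census  # late import: census sits a layer above

    t0, t1 = world.clock, world.clock + macro_dt

    # (1) microenvironment refresh
    world.refresh_oxygen()

    # (2) intracellular dynamics
    dividing = _advance_cells(world, macro_dt)

    # (3) division events, resolved in row-major site order
    if dividing.size:
        order = np.lexsort((world.col[dividing], world.row[dividing]))
        for cid in dividing[order]:
            attempt_division(world, int(cid), world.rng_dynamics)

    # (4) quiescence re-entry
    update_resting(world)

    # (5) therapy events due in [t0, t1); chemo doses open their supply
    # window before the field update so the infusion starts this step
    rad_events, chemo_events = _due_events(world.schedule, t0, t1)
    for c in chemo_events:
        drug = world.config.therapy.chemo[c.drug]
        dur = c.duration_h if c.duration_h is not None else drug.supply_duration
        world._drug_supply_until[c.drug] = max(
            world._drug_supply_until[c.drug], c.time_h + dur)

    # (6) drug fields, radiation fractions, then the chemo kill rule
    mp = world.config.microenv
    for name, fld in world.drugs.items():
        supplying = world._drug_supply_until[name] > t0
        if not supplying and 0 < fld.values.max() < 1e-9:
            # spent dose: far below any kill threshold, stop evolving it
            fld.values[:] = 0.0
        if supplying or fld.values.max() > 0:
            dp = replace(mp.drug,
                         supply_rate=world.config.therapy.chemo[name].supply_rate)
            world.drugs[name] = step_drug(
                fld, world.vessels, world.cell_occupancy(), supplying,
                macro_dt, dp)
    for _, dose in rad_events:
        _therapy.apply_fraction(world, dose, world.config.therapy.radiation,
                                world.rng_therapy)
    for name, fld in world.drugs.items():
        cp = world.config.therapy.chemo[name]
        if fld.values.max() >= cp.kill_threshold:
            _therapy.apply_chemo(world, fld, cp, name)

    # (7) bookkeeping
    world.clock = t1
    world.census_rows.append(census(world))
    return world


_PHASE_CODE = {int(Phase.G1): 2, int(Phase.SG2M): 3, int(Phase.RESTING): 4}


def snapshot_codes(world: World) -> np.ndarray:
    """Lattice of integer codes: 0 empty, 1 vessel, 2 G1, 3 S-G2-M,
    4 resting, +8 on any cell flagged hypoxic."""
    codes = np.zeros((world.rows, world.cols), dtype=np.int64)
    codes[world.vessels.mask] = 1
    for cid in np.flatnonzero(world.alive):
        code = _PHASE_CODE[int(world.phase[cid])]
        if world.hypoxic[cid]:
            code += 8
        codes[world.row[cid], world.col[cid]] = code
    return codes


def write_snapshot(world: World, path) -> None:
    np.savetxt(path, snapshot_codes(world), fmt="%d", delimiter="\t")
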