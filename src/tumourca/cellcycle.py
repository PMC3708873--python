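"""Intracellular cell-cycle dynamics.

Each tumour cell carries a six-variable regulatory network — the
Tyson–Novák antagonism between cyclin-B/Cdk and the APC activator Cdh1,
together with total and active Cdc20 (``p55cdc``), Plk1 and cell mass —
whose limit cycle drives growth and division.  The mitotic exit is read
off the cyclin-B trajectory: a downward crossing of ``cycb_threshold``
marks division, and the same threshold splits the cycle into a G1 phase
(CycB low) and a composite S-G2-M phase (CycB high).

Hypoxia couples into the network as a multiplicative slowdown of the
mass-growth term while the cell's HIF-1α switch is active, which
lengthens the intermitotic time.

The default rate constants are the published generic-model values
re-expressed per hour by the calibrated factors
:data:`PROTEIN_RATE_SCALE` and :data:`MASS_RATE_SCALE`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from ._kernels import advance_states, rhs_single

__all__ = [
    "Phase",
    "CellCycleState",
    "CellCycleParams",
    "EARLY_G1_STATE",
    "derivatives",
    "advance",
    "classify_phase",
    "detect_division",
]


class Phase(enum.IntEnum):
    """Cell-cycle phase label of one automaton cell."""

    G1 = 0
    SG2M = 1
    RESTING = 2


#: Factors applied to the rate constants of the base parameter set to
#: re-express them per hour.  The protein network (k1…k10) and the
#: mass-growth rate µ are scaled separately: protein rates set the
#: duration of the S-G2-M programme while mass growth limits G1 exit
#: (restriction-point behaviour), so their ratio fixes the G1 : S-G2-M
#: partition and µ fixes the intermitotic time (≈ mass-doubling time).
#: The defaults give a normoxic cycle of ≈18.9 h with G1 somewhat
#: longer than S-G2-M, calibrated so that one seeded cell grows to
#: ~10^3 cells by 400 h on the default lattice with a mildly
#: G1-dominant asynchronous phase distribution.
PROTEIN_RATE_SCALE = 7.0
MASS_RATE_SCALE = 3.9


@dataclass
class CellCycleState:
    """State of the six-variable network for a single cell.

    All concentrations are dimensionless.  ``p55cdcA`` (active Cdc20)
    can never exceed ``p55cdcT`` (total), and ``cdh1`` is a bounded
    activity fraction in [0, 1].
    """

    cycb: float
    cdh1: float
    p55cdcT: float
    p55cdcA: float
    plk1: float
    mass: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cycb, self.cdh1, self.p55cdcT, self.p55cdcA, self.plk1, self.mass],
            dtype=np.float64,
        )

    @classmethod
    def from_array(cls, a) -> "CellCycleState":
        return cls(*(float(v) for v in a))

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite cell-cycle state: {self}")
        if np.any(a < -1e-12):
            raise ValueError(f"negative cell-cycle state component: {self}")
        if self.cdh1 > 1 + 1e-9:
            raise ValueError(f"cdh1 exceeds 1: {self.cdh1}")
        if self.p55cdcA > self.p55cdcT + 1e-9:
            raise ValueError("active p55cdc exceeds total")
        if self.mass <= 0:
            raise ValueError("live cell must have positive mass")


#: Early-G1 reference state: snapshot of the settled limit cycle at the
#: default parameters, taken immediately after a division (mass already
#: halved).  Used for the initial seeded cell and for quiescent cells
#: re-entering G1.
EARLY_G1_STATE = CellCycleState(
    cycb=0.1751, cdh1=0.9332, p55cdcT=0.9344, p55cdcA=0.6796, plk1=0.5737, mass=0.3985
)


@dataclass
class CellCycleParams:
    """Rate constants (per hour) and automaton-side knobs.

    The k/J constants follow the published generic six-variable model;
    defaults are that set with the protein rates multiplied by
    :data:`PROTEIN_RATE_SCALE` and µ by :data:`MASS_RATE_SCALE`
    (J constants and the Hill exponent are dimensionless and are left
    untouched by the rescaling).
    """

    k1: float = 0.04 * PROTEIN_RATE_SCALE
    k2p: float = 0.04 * PROTEIN_RATE_SCALE
    k2pp: float = 1.0 * PROTEIN_RATE_SCALE
    k3p: float = 1.0 * PROTEIN_RATE_SCALE
    k3pp: float = 10.0 * PROTEIN_RATE_SCALE
    k4: float = 35.0 * PROTEIN_RATE_SCALE
    k5p: float = 0.005 * PROTEIN_RATE_SCALE
    k5pp: float = 0.2 * PROTEIN_RATE_SCALE
    k6: float = 0.1 * PROTEIN_RATE_SCALE
    k7: float = 1.0 * PROTEIN_RATE_SCALE
    k8: float = 0.5 * PROTEIN_RATE_SCALE
    k9: float = 0.1 * PROTEIN_RATE_SCALE
    k10: float = 0.02 * PROTEIN_RATE_SCALE
    J3: float = 0.04
    J4: float = 0.04
    J5: float = 0.3
    J7: float = 1e-3
    J8: float = 1e-3
    n: float = 4.0
    mad: float = 1.0
    mu: float = 0.01 * MASS_RATE_SCALE
    m_star: float = 10.0
    #: CycB level separating G1 (below) from S-G2-M (at/above); a
    #: downward crossing of this level is the division event.
    cycb_threshold: float = 0.2
    #: multiplicative factor on the mass-growth rate while hypoxic.
    hypoxia_slowdown_factor: float = 0.5
    #: fraction of the mother's mass kept by the mother at division.
    division_mass_split: float = 0.5
    #: fixed micro time step (h) of the RK4 integrator.
    dt_ode: float = 0.01
    #: coefficient of variation of the per-cell intrinsic mass-growth
    #: multiplier (lognormal, mean 1), drawn once at each cell's birth.
    #: Intrinsic growth-rate heterogeneity desynchronises the lineage:
    #: with zero variability every descendant of the seed cell would
    #: run the network in perfect phase lock, which no real tumour
    #: population does.
    growth_rate_cv: float = 0.20

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite parameter {f.name}")
        rate_names = [f.name for f in fields(self) if f.name.startswith(("k", "J", "m"))]
        for name in rate_names:
            if getattr(self, name) <= 0:
                raise ValueError(f"rate/threshold constant {name} must be > 0")
        if not (0 < self.hypoxia_slowdown_factor <= 1):
            raise ValueError("hypoxia_slowdown_factor must be in (0, 1]")
        if self.cycb_threshold <= 0:
            raise ValueError("cycb_threshold must be > 0")
        if not (0 < self.division_mass_split < 1):
            raise ValueError("division_mass_split must be in (0, 1)")
        if self.dt_ode <= 0:
            raise ValueError("dt_ode must be > 0")
        if self.growth_rate_cv < 0:
            raise ValueError("growth_rate_cv must be >= 0")

    def as_array(self) -> np.ndarray:
        """Constants in the fixed layout expected by the numba kernels."""
        return np.array(
            [
                self.k1, self.k2p, self.k2pp, self.k3p, self.k3pp, self.k4,
                self.k5p, self.k5pp, self.k6, self.k7, self.k8, self.k9,
                self.k10, self.J3, self.J4, self.J5, self.J7, self.J8,
                self.n, self.mad, self.mu, self.m_star,
            ],
            dtype=np.float64,
        )

    def scaled(self, factor: float) -> "CellCycleParams":
        """Return a copy with every rate constant multiplied by *factor*."""
        rate = ("k1 k2p k2pp k3p k3pp k4 k5p k5pp k6 k7 k8 k9 k10 mu").split()
        return replace(self, **{r: getattr(self, r) * factor for r in rate})


def derivatives(
    state: CellCycleState, params: CellCycleParams, hypoxic: bool = False
) -> np.ndarray:
    """Instantaneous time derivatives (per hour) of the six variables.

    When *hypoxic* is set, the mass-growth term is multiplied by
    ``params.hypoxia_slowdown_factor``; nothing else changes.
    """
    state.validate()
    hyp = params.hypoxia_slowdown_factor if hypoxic else 1.0
    return rhs_single(state.as_array(), params.as_array(), hyp)


def advance(
    state: CellCycleState,
    dt: float,
    params: CellCycleParams,
    hypoxic: bool = False,
) -> CellCycleState:
    """Integrate the network forward by *dt* hours (fixed-step RK4).

    Uses micro steps of ``params.dt_ode``; any remainder shorter than a
    micro step is taken as one final shorter step.  State invariants are
    enforced by projection after each step (undershoots clipped at 0,
    ``cdh1`` capped at 1, active p55cdc capped at total).
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    state.validate()
    if dt == 0:
        return replace(state)
    arr = state.as_array()[None, :].copy()
    hyp = np.array([params.hypoxia_slowdown_factor if hypoxic else 1.0])
    n_full, rem = divmod(dt, params.dt_ode)
    advance_states(arr, hyp, params.as_array(), int(round(n_full)), params.dt_ode)
    if rem > 1e-12:
        advance_states(arr, hyp, params.as_array(), 1, rem)
    return CellCycleState.from_array(arr[0])


def classify_phase(state: CellCycleState, params: CellCycleParams) -> Phase:
    """G1 when CycB is below the threshold, S-G2-M at or above it.

    The tie at exactly the threshold is resolved to S-G2-M so that the
    rule is a single strict inequality (deterministic and documented).
    """
    return Phase.G1 if state.cycb < params.cycb_threshold else Phase.SG2M


def detect_division(
    prev: CellCycleState, curr: CellCycleState, params: CellCycleParams
) -> bool:
    """True iff CycB crossed the division threshold from above.

    The crossing is the mitotic collapse of cyclin-B between two
    consecutive states of the same cell.
    """
    thr = params.cycb_threshold
    return prev.cycb >= thr and curr.cycb < thr
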