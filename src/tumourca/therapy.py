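"""Radiation and chemotherapy response models and treatment schedules.

Radiation survival follows the linear-quadratic (LQ) model with three
modifications applied per cell at the moment a fraction is delivered:

* **Oxygen.**  The oxygen enhancement ratio ``OER(p) = (OER_max·p + K)
  / (p + K)`` saturates from 1 (anoxic) to ``OER_max``; the oxygen
  modification factor ``OMF = OER(p)/OER_max`` scales the effective
  dose, so hypoxic cells are radioresistant.
* **Cell-cycle phase.**  A sensitivity γ multiplies the whole exponent;
  S-G2-M cells carry the maximal γ = 1, G1 and quiescent cells less.
* **Low-dose repair.**  A correction factor ρ(d) attenuates the LQ
  exponent at small doses, reflecting that almost all radiation damage
  is repaired after low-dose exposure; ρ rises linearly from
  ``repair_min_factor`` at zero dose to 1 at ``repair_dose_threshold``.

Survival of each irradiated cell is then

    ln S = − ρ(d) · γ(phase) · [ OMF·α·d + β·(OMF·d)² ] ,

and a uniform random draw per cell decides death.  Surviving cycling
cells acquire a 1–9 h divisional delay (cell-cycle arrest for damage
repair); quiescent survivors do not.

Phase-specific chemotherapy kills a cell when the local drug
concentration is at or above the drug's kill threshold *and* the cell
sits in the drug's target phase; quiescent cells are never killed by
either drug type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cellcycle import Phase

__all__ = [
    "RadiationParams",
    "ChemoParams",
    "ChemoDose",
    "TreatmentSchedule",
    "PRESET_NAMES",
    "oer",
    "omf",
    "repair_factor",
    "survival_probability",
    "apply_fraction",
    "apply_chemo",
    "build_schedule",
]

G1_DRUG = "G1_specific"
SG2M_DRUG = "SG2M_specific"
_DRUG_ALIASES = {"G1": G1_DRUG, "G2": SG2M_DRUG, G1_DRUG: G1_DRUG,
                 SG2M_DRUG: SG2M_DRUG}


@dataclass
class RadiationParams:
    """LQ sensitivity, oxygen and repair constants.

    ``alpha``/``beta`` are the usual LQ coefficients (Gy⁻¹, Gy⁻²);
    ``K_mmHg`` is the pO2 at half the OER rise from 1 to ``oer_max``.
    ``omf_override`` pins the oxygen modification factor (1.0 = treat
    every cell as fully oxygenated; used by the no-hypoxia ablation),
    ``fixed_survival`` bypasses the survival model entirely (test hook).
    """

    alpha: float = 0.3
    beta: float = 0.03
    oer_max: float = 3.0
    K_mmHg: float = 3.0
    gamma_g1: float = 0.5
    gamma_sg2m: float = 1.0
    gamma_resting: float = 0.12
    repair_enabled: bool = True
    repair_dose_threshold: float = 6.0  # Gy at which repair attenuation vanishes
    repair_min_factor: float = 0.02     # zero-dose limit: 98% of damage repaired
    delay_enabled: bool = True
    delay_min: float = 1.0
    delay_max: float = 9.0
    omf_override: float | None = None
    fixed_survival: float | None = None

    @property
    def gamma(self) -> dict:
        return {Phase.G1: self.gamma_g1, Phase.SG2M: self.gamma_sg2m,
                Phase.RESTING: self.gamma_resting}

    def gamma_array(self) -> np.ndarray:
        """Sensitivities indexed by Phase integer value."""
        return np.array([self.gamma_g1, self.gamma_sg2m, self.gamma_resting])

    def validate(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.oer_max <= 1:
            raise ValueError("oer_max must be > 1")
        if self.K_mmHg <= 0:
            raise ValueError("K_mmHg must be > 0")
        if not (self.gamma_sg2m >= self.gamma_g1 >= self.gamma_resting > 0):
            raise ValueError("need gamma_sg2m >= gamma_g1 >= gamma_resting > 0")
        if not (0 < self.repair_min_factor <= 1):
            raise ValueError("repair_min_factor must be in (0, 1]")
        if self.repair_dose_threshold <= 0:
            raise ValueError("repair_dose_threshold must be > 0")
        if not (1 <= self.delay_min <= self.delay_max):
            raise ValueError("need 1 <= delay_min <= delay_max")


@dataclass
class ChemoParams:
    """One phase-specific drug type."""

    target_phase: Phase
    kill_threshold: float = 5e-4  # concentration units of the drug field
    supply_duration: float = 2.0  # hours of vascular supply per dose
    supply_rate: float = 1.0      # conc/h at vessel sites while supplying

    def validate(self) -> None:
        if self.kill_threshold <= 0:
            raise ValueError("kill_threshold must be > 0")
        if self.target_phase not in (Phase.G1, Phase.SG2M):
            raise ValueError("target_phase must be G1 or SG2M")
        if self.supply_duration <= 0 or self.supply_rate <= 0:
            raise ValueError("supply_duration and supply_rate must be > 0")


@dataclass
class ChemoDose:
    """A single chemotherapy administration."""

    time_h: float
    drug: str  # G1_specific | SG2M_specific
    duration_h: float | None = None  # None -> the drug's default duration


@dataclass
class TreatmentSchedule:
    """Time-ordered radiation fractions and chemotherapy doses."""

    radiation: list = field(default_factory=list)  # [(time_h, dose_Gy)]
    chemo: list = field(default_factory=list)      # [ChemoDose]
    preset_name: str | None = None

    def validate(self) -> None:
        times = [t for t, _ in self.radiation]
        if any(t < 0 for t in times) or times != sorted(times):
            raise ValueError("radiation times must be non-negative and sorted")
        if any(d <= 0 for _, d in self.radiation):
            raise ValueError("radiation doses must be > 0")
        ctimes = [c.time_h for c in self.chemo]
        if any(t < 0 for t in ctimes) or ctimes != sorted(ctimes):
            raise ValueError("chemo times must be non-negative and sorted")
        for c in self.chemo:
            if c.drug not in (G1_DRUG, SG2M_DRUG):
                raise ValueError(f"unknown drug type {c.drug!r}")

    @property
    def name(self) -> str:
        return self.preset_name or "custom"

    def end_time(self) -> float:
        t = 0.0
        if self.radiation:
            t = max(t, self.radiation[-1][0])
        if self.chemo:
            t = max(t, self.chemo[-1].time_h)
        return t


def oer(pO2, params: RadiationParams):
    """Oxygen enhancement ratio at partial pressure *pO2* (mmHg).

    Saturating form with OER(0) = 1, OER(K) = (OER_max + 1)/2 and
    OER(∞) = OER_max; strictly increasing in pO2.
    """
    p = np.asarray(pO2, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("pO2 must be >= 0")
    out = (params.oer_max * p + params.K_mmHg) / (p + params.K_mmHg)
    return float(out) if np.isscalar(pO2) else out


def omf(pO2, params: RadiationParams):
    """Oxygen modification factor OER(pO2)/OER_max ∈ [1/OER_max, 1]."""
    return oer(pO2, params) / params.oer_max


def repair_factor(dose: float, params: RadiationParams) -> float:
    """Low-dose repair attenuation ρ(d); identically 1 when disabled."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if not params.repair_enabled:
        return 1.0
    frac = min(dose / params.repair_dose_threshold, 1.0)
    return params.repair_min_factor + (1.0 - params.repair_min_factor) * frac


def survival_probability(
    dose: float, pO2: float, phase: Phase, params: RadiationParams
) -> float:
    """Probability that one cell survives a fraction of *dose* Gy."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    f = params.omf_override if params.omf_override is not None \
        else omf(pO2, params)
    g = params.gamma[Phase(phase)]
    rho = repair_factor(dose, params)
    eff = f * params.alpha * dose + params.beta * (f * dose) ** 2
    return float(np.exp(-rho * g * eff))


def _survival_vector(dose, pO2, phases, params: RadiationParams) -> np.ndarray:
    """Vectorised survival for arrays of per-cell pO2 and phase codes."""
    if params.fixed_survival is not None:
        return np.full(len(pO2), params.fixed_survival)
    f = np.full(len(pO2), params.omf_override) \
        if params.omf_override is not None else omf(pO2, params)
    g = params.gamma_array()[phases]
    rho = repair_factor(dose, params)
    eff = f * params.alpha * dose + params.beta * (f * dose) ** 2
    return np.exp(-rho * g * eff)


def apply_fraction(world, dose: float, params: RadiationParams, rng):
    """Deliver one uniform radiation fraction to every live cell.

    For each cell a uniform random number is drawn and compared with its
    survival probability (the cell survives when the draw is below it);
    killed cells vacate their lattice sites.  Surviving G1/S-G2-M cells
    receive an integer divisional delay drawn uniformly from
    [delay_min, delay_max] hours, added to any delay still pending.

    Returns ``(killed_ids, delayed_ids)``.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    params.validate()
    ids = np.flatnonzero(world.alive)
    if dose == 0 or ids.size == 0:
        return [], []
    p_pct = world.oxygen.values[world.row[ids], world.col[ids]]
    pO2 = p_pct * world.o2_pct_to_mmhg
    surv = _survival_vector(dose, pO2, world.phase[ids], params)
    u = rng.random(ids.size)
    dead = u >= surv
    killed = ids[dead]
    for cid in killed:
        world.kill_cell(cid)
    world.cumulative_kills["radiation"] += int(dead.sum())
    delayed = np.array([], dtype=ids.dtype)
    if params.delay_enabled:
        alive_ids = ids[~dead]
        cycling = alive_ids[world.phase[alive_ids] != int(Phase.RESTING)]
        if cycling.size:
            d = rng.integers(int(params.delay_min), int(params.delay_max) + 1,
                             size=cycling.size)
            world.delay[cycling] += d
            delayed = cycling
    return list(killed), list(delayed)


def apply_chemo(world, drug_field, params: ChemoParams, drug_type: str):
    """Kill target-phase cells sitting in lethal drug concentrations.

    A live cell dies iff its phase equals the drug's target phase and
    the concentration at its site is at or above ``kill_threshold``;
    quiescent cells are never killed by either drug type.  Returns the
    killed cell ids.
    """
    params.validate()
    if drug_field.values.shape != world.occupancy.shape:
        raise ValueError("drug field and world shapes differ")
    ids = np.flatnonzero(world.alive)
    if ids.size == 0:
        return []
    in_phase = world.phase[ids] == int(params.target_phase)
    conc = drug_field.values[world.row[ids], world.col[ids]]
    doomed = ids[in_phase & (conc >= params.kill_threshold)]
    for cid in doomed:
        world.kill_cell(cid)
    world.cumulative_kills["chemo"] += int(doomed.size)
    return list(doomed)


# ---------------------------------------------------------------------------
# schedules


def _week_hour(week: int, day: int = 1, start_h: float = 0.0) -> float:
    """Hour of week *week*, weekday *day* (both 1-based) after *start_h*."""
    return start_h + ((week - 1) * 7 + (day - 1)) * 24.0


def _daily_fractions(start_h: float, n: int, dose: float):
    return [(start_h + 24.0 * i, dose) for i in range(n)]


def _weekday_fractions(first_week: int, n: int, dose: float, start_h: float):
    """n weekday-only fractions (5/week), so 25 span exactly 5 weeks."""
    out = []
    w, d = first_week, 1
    for _ in range(n):
        out.append((_week_hour(w, d, start_h), dose))
        d += 1
        if d > 5:
            d, w = 1, w + 1
    return out


def _infusion_weeks(weeks, start_h: float):
    """One chemo cycle per listed week: a bolus of the G1-specific drug
    on day 1 and a 96 h continuous infusion of the S-G2-M-specific drug
    over days 1–4 (the cisplatin + 5-FU pattern mapped onto the two
    generic phase-specific drug types).  The poor penetration of drug
    into the packed tumour keeps the prolonged exposure rim-limited."""
    doses = []
    for w in weeks:
        t = _week_hour(w, 1, start_h)
        doses.append(ChemoDose(t, G1_DRUG))
        doses.append(ChemoDose(t, SG2M_DRUG, duration_h=96.0))
    return doses


def build_schedule(
    preset: str | None = None,
    radiation=None,
    chemo=None,
    chemo_drugs=(G1_DRUG, G1_DRUG),
    start_h: float = 400.0,
) -> TreatmentSchedule:
    """Build a validated treatment schedule.

    Either give a *preset* name, or explicit ``radiation``
    ``[(time_h, dose_Gy), ...]`` and ``chemo`` ``[(time_h, drug), ...]``
    sequences (an empty explicit spec is the no-treatment control).
    ``chemo_drugs`` selects the drug type of each dose for the generic
    two-dose sequencing presets.  ``start_h`` anchors the week-based
    regimens: week 1, day 1 falls at ``start_h`` (the tumour is grown
    from a single cell until then).
    """
    if preset is not None:
        drugs = [_DRUG_ALIASES[d] for d in chemo_drugs]
        if preset == "single_3Gy":
            sched = TreatmentSchedule([(400.0, 3.0)], [])
        elif preset == "fractionated":
            sched = TreatmentSchedule(_daily_fractions(400.0, 5, 2.5), [])
        elif preset == "single_12_5Gy":
            sched = TreatmentSchedule([(400.0, 12.5)], [])
        elif preset == "neoadjuvant_chemo":
            sched = TreatmentSchedule(
                _daily_fractions(400.0, 5, 2.5),
                [ChemoDose(340.0, drugs[0]), ChemoDose(370.0, drugs[1])])
        elif preset == "adjuvant_chemo":
            sched = TreatmentSchedule(
                _daily_fractions(340.0, 5, 2.5),
                [ChemoDose(466.0, drugs[0]), ChemoDose(496.0, drugs[1])])
        elif preset == "sandwich":
            sched = TreatmentSchedule(
                _daily_fractions(370.0, 5, 2.5),
                [ChemoDose(340.0, drugs[0]), ChemoDose(496.0, drugs[1])])
        elif preset == "concurrent":
            sched = TreatmentSchedule(
                _daily_fractions(340.0, 5, 2.5),
                [ChemoDose(370.0, drugs[0]), ChemoDose(400.0, drugs[1])])
        elif preset == "herskovic":
            sched = TreatmentSchedule(
                _weekday_fractions(1, 25, 2.0, start_h),
                _infusion_weeks([1, 5, 8, 11], start_h))
        elif preset == "modified_herskovic":
            sched = TreatmentSchedule(
                _weekday_fractions(6, 25, 2.0, start_h),
                _infusion_weeks([1, 3, 6, 10], start_h))
        elif preset == "experimental":
            sched = TreatmentSchedule(
                _weekday_fractions(12, 20, 2.5, start_h),
                _infusion_weeks([1, 3, 6, 9], start_h))
        else:
            raise ValueError(f"unknown preset {preset!r}")
        sched.preset_name = preset
    else:
        rad = sorted([(float(t), float(d)) for t, d in (radiation or [])])
        cdoses = []
        for entry in (chemo or []):
            if isinstance(entry, ChemoDose):
                cdoses.append(entry)
            else:
                t, drug = entry[0], _DRUG_ALIASES[entry[1]]
                dur = entry[2] if len(entry) > 2 else None
                cdoses.append(ChemoDose(float(t), drug, dur))
        cdoses.sort(key=lambda c: c.time_h)
        sched = TreatmentSchedule(rad, cdoses)
    sched.chemo.sort(key=lambda c: c.time_h)
    sched.validate()
    return sched


def load_schedule(path) -> TreatmentSchedule:
    """Read a schedule file: YAML with ``radiation: [{t_h, dose_Gy}]``
    and ``chemo: [{t_h, drug, duration_h?}]`` lists."""
    import yaml
    from pathlib import Path

    data = yaml.safe_load(Path(path).read_text()) or {}
    rad = [(e["t_h"], e["dose_Gy"]) for e in data.get("radiation", [])]
    chemo = [ChemoDose(float(e["t_h"]), _DRUG_ALIASES[e["drug"]],
                       e.get("duration_h"))
             for e in data.get("chemo", [])]
    sched = TreatmentSchedule(sorted(rad), sorted(chemo, key=lambda c: c.time_h))
    sched.validate()
    return sched


PRESET_NAMES = (
    "single_3Gy", "fractionated", "single_12_5Gy",
    "neoadjuvant_chemo", "adjuvant_chemo", "sandwich", "concurrent",
    "herskovic", "modified_herskovic", "experimental",
)
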