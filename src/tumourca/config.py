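"""Run configuration: one dataclass tree, YAML round-trip, stable digest.

Every tunable of the simulator lives here with its default; a YAML file
needs to mention only the entries it overrides.  The digest is a SHA-256
of the canonical JSON form and identifies a parameterisation in run
metadata and in protocol comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cellcycle import CellCycleParams, Phase
from .microenv import DiffusionParams
from .therapy import ChemoParams, RadiationParams, G1_DRUG, SG2M_DRUG

__all__ = ["GridConfig", "MicroenvConfig", "TherapyConfig", "SimConfig",
           "default_config"]


@dataclass
class GridConfig:
    """Lattice geometry and vasculature layout."""

    rows: int = 100
    cols: int = 100
    site_um: float = 20.0           # one automaton element = one cell diameter
    vessel_density: float = 0.01    # vessel cross-sections per site
    vessel_min_separation: float = 2.0
    start_site: tuple | None = None  # None -> lattice centre

    def validate(self) -> None:
        if self.rows < 3 or self.cols < 3:
            raise ValueError("grid must be at least 3x3")
        if not (0 <= self.vessel_density <= 0.2):
            raise ValueError("vessel_density must be in [0, 0.2]")
        if self.site_um <= 0:
            raise ValueError("site_um must be > 0")


def _default_drug_diffusion() -> DiffusionParams:
    # Effective (binding-retarded) drug diffusivity with systemic
    # clearance: penetration depth sqrt(D/eta) ~ 5 sites (~100 µm) in
    # open tissue, the textbook range for tissue penetration of
    # anticancer agents, and much poorer inside the packed tumour
    # (D_tumour_factor 0.1 -> ~1.6 sites), so a dose erodes the exposed
    # rim and perivascular cells while the avascular core is shielded.
    # Cellular uptake of drug is neglected (zero consumption).
    return DiffusionParams(D_base=50.0, D_tumour_factor=0.1,
                           supply_rate=1.0, consumption_rate=0.0,
                           background_decay=0.0, drug_decay=2.0,
                           steady_state_tol=1e-6, sor_omega=1.8)


@dataclass
class MicroenvConfig:
    """Oxygen and drug field coefficients plus the hypoxia rule."""

    oxygen: DiffusionParams = field(default_factory=DiffusionParams)
    drug: DiffusionParams = field(default_factory=_default_drug_diffusion)
    #: sites below this % of the current field maximum are hypoxic
    hypoxia_threshold_pct: float = 10.0
    #: converts oxygen % of maximum to pO2 in mmHg for the OER
    o2_pct_to_mmhg: float = 1.0

    def validate(self) -> None:
        self.oxygen.validate()
        self.drug.validate()
        if not (0 <= self.hypoxia_threshold_pct <= 100):
            raise ValueError("hypoxia_threshold_pct must be in [0, 100]")
        if self.o2_pct_to_mmhg <= 0:
            raise ValueError("o2_pct_to_mmhg must be > 0")


def _default_chemo() -> dict:
    return {
        G1_DRUG: ChemoParams(target_phase=Phase.G1),
        SG2M_DRUG: ChemoParams(target_phase=Phase.SG2M),
    }


@dataclass
class TherapyConfig:
    radiation: RadiationParams = field(default_factory=RadiationParams)
    chemo: dict = field(default_factory=_default_chemo)

    def validate(self) -> None:
        self.radiation.validate()
        for params in self.chemo.values():
            params.validate()


@dataclass
class SimConfig:
    """Everything a run needs except the seed and the schedule."""

    grid: GridConfig = field(default_factory=GridConfig)
    cellcycle: CellCycleParams = field(default_factory=CellCycleParams)
    microenv: MicroenvConfig = field(default_factory=MicroenvConfig)
    therapy: TherapyConfig = field(default_factory=TherapyConfig)
    macro_dt: float = 1.0  # hours per automaton macro step

    def validate(self) -> None:
        self.grid.validate()
        self.cellcycle.validate()
        self.microenv.validate()
        self.therapy.validate()
        if self.macro_dt <= 0:
            raise ValueError("macro_dt must be > 0")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, Phase):
                return obj.name
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return enc(self)

    def digest(self) -> str:
        js = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(js.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        cfg = cls()
        _apply_overrides(cfg, data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _apply_overrides(obj, data: dict) -> None:
    for key, value in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config entry {key!r} on "
                           f"{type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply_overrides(current, value)
        elif isinstance(current, dict) and isinstance(value, dict):
            for name, sub in value.items():
                if name in current and dataclasses.is_dataclass(current[name]):
                    _apply_overrides(current[name], sub)
                else:
                    current[name] = sub
        elif key == "target_phase" and isinstance(value, str):
            setattr(obj, key, Phase[value])
        elif key == "start_site" and value is not None:
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)


def default_config() -> SimConfig:
    """The calibrated default parameterisation."""
    return SimConfig()
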