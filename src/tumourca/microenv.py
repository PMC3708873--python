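"""Tissue microenvironment: vasculature, oxygen and drug fields.

Oxygen and chemotherapeutic drugs are modelled as continuum
concentration fields on the automaton lattice, sourced at blood-vessel
cross-sections and evolving by reaction–diffusion with zero-flux
boundaries.  Oxygen relaxes much faster than the cell cycle, so the
oxygen field is taken to its quasi-steady state once per macro step

    0 = ∇·(D(x) ∇O) + r·v(x) − φ·c(x)·O − φ_B·O ,

where v marks vessel sites, c marks cell-occupied sites (first-order
consumption preserves positivity), φ_B is a background clearance that
gives cell-free tissue a finite steady state, and the diffusivity is
reduced by ``D_tumour_factor`` inside the tumour mass.  The solved
field is reported as a percentage of its current maximum, which is what
the hypoxia threshold and the radiosensitivity model consume.

Drug fields are genuinely time dependent

    ∂C/∂t = ∇·(D_c(x) ∇C) + r_c·v(x)·[supplying] − η·C ,

with zero cellular uptake, and are advanced by operator splitting:
conservative backward-Euler diffusion (exact discrete mass
conservation) followed by the exact pointwise solution of the linear
supply/decay reaction.

Discretisation: conservative 5-point finite differences with harmonic
averaging of D at cell interfaces; the zero-flux boundary is the
mirrored ghost-cell closure (boundary links simply absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import relax_field

__all__ = [
    "Field",
    "VesselMap",
    "DiffusionParams",
    "PlacementError",
    "ConvergenceError",
    "StabilityError",
    "generate_vessels",
    "solve_oxygen",
    "step_drug",
    "hypoxic_mask",
]


class PlacementError(RuntimeError):
    """Vessel placement infeasible at the requested density/separation."""


class ConvergenceError(RuntimeError):
    """The quasi-steady solver failed to reach the residual target."""


class StabilityError(RuntimeError):
    """A field update produced non-finite values."""


@dataclass
class Field:
    """A non-negative scalar concentration lattice."""

    values: np.ndarray
    kind: str = "oxygen"

    @property
    def shape(self):
        return self.values.shape

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise StabilityError(f"non-finite values in {self.kind} field")
        if np.any(self.values < 0):
            raise ValueError(f"negative values in {self.kind} field")


@dataclass
class VesselMap:
    """Fixed lattice of blood-vessel cross-sections (source sites)."""

    mask: np.ndarray  # bool, rows x cols
    density: float
    seed: int
    min_separation: float = 2.0

    @property
    def n_vessels(self) -> int:
        return int(self.mask.sum())

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) indices, row-major order."""
        return np.argwhere(self.mask)

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.coords, fmt="%d", delimiter="\t")

    @classmethod
    def from_tsv(cls, path, rows: int, cols: int) -> "VesselMap":
        coords = np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2)
        mask = np.zeros((rows, cols), dtype=bool)
        if coords.size:
            mask[coords[:, 0], coords[:, 1]] = True
        return cls(mask=mask, density=mask.mean(), seed=-1)


@dataclass
class DiffusionParams:
    """Coefficients of one reaction–diffusion field.

    Units: lengths in lattice sites (one site = 20 µm by default), time
    in hours.  The oxygen defaults put the intratumoural diffusion
    length  sqrt(D·D_tumour_factor / consumption_rate)  at ~3.5 sites
    (~70 µm), the scale over which tissue becomes radiobiologically
    hypoxic away from a vessel.
    """

    D_base: float = 22500.0       # site^2/h  (2.5e-5 cm^2/s at 20 µm sites)
    D_tumour_factor: float = 0.5  # diffusivity multiplier inside occupied sites
    supply_rate: float = 100.0    # conc/h at vessel sites
    consumption_rate: float = 900.0  # per h, at cell sites (oxygen only)
    background_decay: float = 22.5   # per h, everywhere
    drug_decay: float = 0.35      # per h (drug fields only)
    steady_state_tol: float = 1e-6
    max_sweeps: int = 20000
    sor_omega: float = 1.9  # near-optimal for the 100x100 5-point stencil

    def validate(self) -> None:
        if self.D_base < 0:
            raise ValueError("D_base must be >= 0")
        if not (0 < self.D_tumour_factor <= 1):
            raise ValueError("D_tumour_factor must be in (0, 1]")
        for name in ("supply_rate", "consumption_rate", "background_decay",
                     "drug_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.steady_state_tol < 1):
            raise ValueError("steady_state_tol must be in (0, 1)")


def generate_vessels(
    rows: int,
    cols: int,
    density: float,
    min_separation: float = 2.0,
    seed: int = 0,
    exclude=None,
    max_attempts_per_vessel: int = 2000,
) -> VesselMap:
    """Place ``round(density·rows·cols)`` vessel cross-sections at random.

    Rejection sampling enforces a minimum pairwise (Euclidean) distance
    and keeps vessels off any *exclude* sites (e.g. the initial tumour
    cell).  Fully reproducible from *seed*.
    """
    if not (0 <= density <= 0.2):
        raise ValueError("vessel density must be in [0, 0.2]")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    n_target = int(round(density * rows * cols))
    rng = np.random.default_rng(seed)
    mask = np.zeros((rows, cols), dtype=bool)
    placed = np.empty((n_target, 2), dtype=np.int64)
    n = 0
    attempts = 0
    budget = max_attempts_per_vessel * max(n_target, 1)
    sep2 = min_separation ** 2
    while n < n_target:
        if attempts >= budget:
            raise PlacementError(
                f"could only place {n}/{n_target} vessels at density "
                f"{density} with min_separation {min_separation}"
            )
        r = rng.integers(0, rows)
        c = rng.integers(0, cols)
        attempts += 1
        if mask[r, c]:
            continue
        if exclude is not None and (r, c) in exclude:
            continue
        if n and sep2 > 0:
            d2 = (placed[:n, 0] - r) ** 2 + (placed[:n, 1] - c) ** 2
            if d2.min() < sep2:
                continue
        mask[r, c] = True
        placed[n] = (r, c)
        n += 1
    return VesselMap(mask=mask, density=density, seed=seed,
                     min_separation=min_separation)


def _diffusivity(occupancy: np.ndarray, params: DiffusionParams) -> np.ndarray:
    D = np.full(occupancy.shape, params.D_base, dtype=np.float64)
    D[occupancy] *= params.D_tumour_factor
    return D


def _link_coefficients(D: np.ndarray):
    """Harmonic-mean interface conductances for the 5-point stencil.

    Returns (a_e, a_w, a_n, a_s); entries that would reach across the
    boundary are zero, which realises the zero-flux condition.
    """
    rows, cols = D.shape
    a_e = np.zeros_like(D)
    a_w = np.zeros_like(D)
    a_n = np.zeros_like(D)
    a_s = np.zeros_like(D)
    De, Dw = D[:, 1:], D[:, :-1]
    a_e[:, :-1] = np.divide(2.0 * De * Dw, De + Dw,
                            out=np.zeros_like(De), where=(De + Dw) > 0)
    a_w[:, 1:] = a_e[:, :-1]
    Ds, Dn = D[1:, :], D[:-1, :]
    a_s[:-1, :] = np.divide(2.0 * Ds * Dn, Ds + Dn,
                            out=np.zeros_like(Ds), where=(Ds + Dn) > 0)
    a_n[1:, :] = a_s[:-1, :]
    return a_e, a_w, a_n, a_s


def solve_oxygen(
    occupancy: np.ndarray,
    vessels: VesselMap,
    params: DiffusionParams,
    x0: np.ndarray | None = None,
    normalise: bool = True,
) -> Field:
    """Quasi-steady oxygen field on the current occupancy pattern.

    Solved by warm-started red-black SOR until the relative residual of
    the discrete operator falls below ``params.steady_state_tol``.  When
    *normalise* is true (the default) the field is rescaled so its
    maximum is 100 (%); pass ``normalise=False`` for the raw
    concentration (bounded above by supply_rate/background_decay).
    """
    params.validate()
    occupancy = np.asarray(occupancy, dtype=bool)
    if occupancy.shape != vessels.mask.shape:
        raise ValueError("occupancy and vessel map shapes differ")
    a_e, a_w, a_n, a_s = _link_coefficients(_diffusivity(occupancy, params))
    react = (params.consumption_rate * occupancy
             + params.background_decay * np.ones_like(a_e))
    a_p = a_e + a_w + a_n + a_s + react
    if np.any(a_p <= 0):
        raise ValueError("singular operator: need background_decay > 0 "
                         "or consumption everywhere")
    b = params.supply_rate * vessels.mask.astype(np.float64)
    x = np.zeros_like(b) if x0 is None else np.array(x0, dtype=np.float64)
    sweeps, res = relax_field(a_e, a_w, a_n, a_s, a_p, react, b, x,
                              params.sor_omega, params.steady_state_tol,
                              params.max_sweeps)
    if res >= params.steady_state_tol:
        raise ConvergenceError(
            f"oxygen solver stalled: relative residual {res:.3e} after "
            f"{sweeps} sweeps (target {params.steady_state_tol:.1e})"
        )
    np.maximum(x, 0.0, out=x)
    if normalise:
        peak = x.max()
        if peak > 0:
            x = x * (100.0 / peak)
    f = Field(values=x, kind="oxygen")
    f.validate()
    return f


def step_drug(
    drug: Field,
    vessels: VesselMap,
    occupancy: np.ndarray,
    supplying: bool,
    dt: float,
    params: DiffusionParams,
) -> Field:
    """Advance one drug field by *dt* hours.

    Splitting: (i) backward-Euler diffusion in conservative form — the
    implicit 5-point flux update conserves total lattice mass exactly in
    the absence of reaction terms; (ii) exact pointwise integration of
    dC/dt = r_c·v·[supplying] − η·C over the step.  Cellular uptake of
    the drug is neglected (set to zero).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    params.validate()
    drug.validate()
    c = drug.values.astype(np.float64, copy=True)
    if params.D_base > 0 and not np.all(c == c.flat[0]):
        D = _diffusivity(np.asarray(occupancy, dtype=bool), params)
        a_e, a_w, a_n, a_s = _link_coefficients(D)
        react = np.full(c.shape, 1.0 / dt)
        a_p = a_e + a_w + a_n + a_s + react
        b = c / dt
        x = c.copy()
        sweeps, res = relax_field(a_e, a_w, a_n, a_s, a_p, react, b, x,
                                  params.sor_omega, params.steady_state_tol,
                                  params.max_sweeps)
        if res >= params.steady_state_tol:
            raise ConvergenceError(
                f"drug diffusion solve stalled: relative residual {res:.3e} "
                f"after {sweeps} sweeps")
        c = x
    eta = params.drug_decay
    decay = np.exp(-eta * dt) if eta > 0 else 1.0
    c *= decay
    if supplying:
        gain = params.supply_rate * dt if eta == 0 else \
            params.supply_rate / eta * (1.0 - np.exp(-eta * dt))
        c[vessels.mask] += gain
    if not np.all(np.isfinite(c)):
        raise StabilityError(
            f"drug field update produced non-finite values (dt={dt}); "
            "use a smaller step"
        )
    np.maximum(c, 0.0, out=c)
    return Field(values=c, kind=drug.kind)


def hypoxic_mask(field: Field, threshold_pct: float):
    """Sites whose oxygen (in % of the field maximum) is below threshold.

    Returns ``(mask, hypoxic_area_pct)`` where the area is the flagged
    fraction of the whole lattice in percent.
    """
    mask = field.values < threshold_pct
    pct = 100.0 * mask.mean()
    return mask, pct
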