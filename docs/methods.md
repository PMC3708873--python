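# Model and methods

`tumourca` simulates a patch of vascularised tissue as a 2-D cellular
automaton (default 100 × 100 sites at 20 µm/site, i.e. 2 × 2 mm) in
which each lattice site is empty, a blood-vessel cross-section, or one
tumour cell.  Three coupled layers drive the dynamics: an intracellular
cell-cycle network per cell, reaction–diffusion oxygen and drug fields
on the lattice, and automaton rules for division placement, quiescence
and therapy response.  One macro step is 1 h; intracellular dynamics
run at a 0.01 h micro step inside it.

## Intracellular cell-cycle network

Every cell integrates the six-variable Tyson–Novák regulatory system —
cyclin-B/Cdk1 (CycB), the APC activator Cdh1, total and active Cdc20
(p55cdc), Plk1, and cell mass m with logistic growth
dm/dt = µ m (1 − m/m*).  Mass is the slow driver: its growth destroys
the G1 equilibrium (Cdh1 on, CycB low) and launches the S-G2-M
programme; the mitotic collapse of CycB through `cycb_threshold`
(default 0.2) is the division event, at which the mass splits 50/50
between mother and daughter.  CycB below/above the same threshold
labels the cell G1 / S-G2-M.

The published dimensionless constants are kept, re-expressed per hour
by two calibrated factors: protein rates × 7.0 and µ × 3.9·0.01/h.
Because the protein network times the S-G2-M programme while mass
growth limits G1 exit (restriction-point behaviour), the *ratio* of the
two factors sets the G1 : S-G2-M partition, and µ sets the intermitotic
time.  The defaults give a normoxic cycle of ≈18.9 h (G1 ≈ 11 h,
S-G2-M ≈ 8 h), chosen so that (i) one seeded cell grows to ~10³
cells by 400 h on the default lattice and (ii) the asynchronous
untreated population is mildly G1-dominant.  A uniform single-factor
rescaling cannot satisfy both at once: it fixes G1 at ~40% of the
cycle, giving an S-G2-M-dominant population.

Two automaton-level choices around the network:

* **Intrinsic growth-rate heterogeneity.**  Each cell draws a lognormal
  multiplier (mean 1, CV 0.20) on its mass-growth rate at birth.
  Without it, every descendant of the single seeded cell runs the
  network in perfect phase lock and the whole "tumour" divides in
  synchrony, which no real cell population does; a ~20% per-generation
  spread in cycle time is in the range reported for clonal mammalian
  cells and decoheres the lineage within a few generations.
* **Early-G1 reference state.**  The post-division point of the settled
  limit cycle is frozen as the canonical early-G1 state, used for the
  seeded cell and for quiescent cells re-entering the cycle.

**Hypoxia** acts through a HIF-1α switch: while a cell sits on a site
below the hypoxia threshold (10% of the current oxygen maximum), its
mass-growth term is multiplied by 0.5, roughly doubling the cycle time.
Whether hypoxia should instead slow a specific protein rate is an open
modelling question; the factor is a single config knob
(`hypoxia_slowdown_factor`).

**Integration** is fixed-step RK4 with projection of each step back
onto the state's invariant set (components ≥ 0, Cdh1 ≤ 1, active ≤
total p55cdc).  The Goldbeter–Koshland terms (J = 10⁻³) make the system
stiff in thin boundary layers; the projection keeps the explicit
integrator stable there at dt = 0.01 h, at the cost of an O(dt) chatter
confined to the layers.  Against a 10×-finer reference the intermitotic
time is accurate to ~0.5%; dt = 0.02 h would already shift it by ~3%,
which is why 0.01 h is the default.

## Microenvironment

**Vessels** are point cross-sections placed uniformly at random
(density 1%, minimum separation 2 sites, rejection sampling, never on
the initial cell site).

**Oxygen** obeys ∂O/∂t = ∇·(D∇O) + r·v(x) − φ·c(x)·O − φ_B·O with
zero-flux boundaries and is taken to quasi-steady state once per macro
step (oxygen equilibrates in seconds–minutes, far faster than the cell
cycle).  Defaults: D = 2.5·10⁻⁵ cm²/s halved inside occupied sites,
first-order consumption φ = 900/h at cell sites and background
clearance φ_B = 22.5/h.  These blanked-in-the-source coefficients were
chosen to give an intratumoural oxygen penetration depth of
√(D_t/φ) ≈ 3.5 sites (~70 µm, the classic diffusion-limited hypoxia
scale) and a hypoxic area of a few percent of the lattice at 400 h.
The solved field is reported as % of its current maximum; the hypoxia
mask (<10%) and the radiosensitivity model consume this normalised
field, with 1% ≡ 1 mmHg pO₂ for the oxygen enhancement ratio.

**Drugs** follow the same equation with zero cellular uptake, a decay
η = 2/h, and an effective diffusivity D = 50 site²/h reduced to 10%
inside occupied sites: penetration ~5 sites (~100 µm) in open tissue
and ~1.6 sites into the packed tumour, so a dose exposes the rim and
perivascular cells while the avascular core is shielded — the textbook
drug-penetration limitation.  Dosing switches the vascular supply on
for the dose's duration (default 2 h bolus).

**Discretisation.**  Conservative 5-point finite differences with
harmonic interface averaging of D; zero-flux via mirrored ghost cells.
Both the quasi-steady oxygen solve and the backward-Euler drug step are
solved by warm-started red-black SOR (ω = 1.9 / 1.8) with a
constant-mode deflation correction after each sweep; the correction
removes the near-Neumann global mode on which plain SOR stalls, and for
the backward-Euler system it enforces exact discrete mass conservation.
Iteration stops at a relative residual of 10⁻⁷ (oxygen) / 10⁻⁶ (drug).
A drug field whose maximum has decayed below 10⁻⁹ is zeroed.  When the
occupancy pattern has not changed since the previous macro step the
oxygen field is reused unchanged (the quasi-steady problem is
identical).

## Automaton rules

Per macro step: (1) oxygen refresh and hypoxia flags; (2) cell-cycle
integration of every live, non-quiescent cell whose post-irradiation
delay timer is idle — delayed cells are frozen whole (strictest reading
of "stays in the same phase") and the timer decremented; (3) division
events in row-major site order: the daughter goes to a uniformly drawn
free neighbour site, with Moore (8-site) and Von Neumann (4-site)
neighbourhoods alternating per division event; a mother with no free
neighbour enters quiescence; (4) quiescent cells with a free Moore
neighbour on a normoxic site re-enter G1 at the early-G1 reference
state; (5-6) drug fields, scheduled therapy events and the
concentration-threshold chemotherapy kill; (7) census row.

## Therapy

**Radiation** survival per cell:
ln S = −ρ(d)·γ(phase)·[OMF·α·d + β·(OMF·d)²], with α = 0.3 Gy⁻¹,
β = 0.03 Gy⁻².  OER(p) = (3p + 3)/(p + 3) (OER_max = 3, half-effect at
K = 3 mmHg) and OMF = OER/OER_max.  Phase sensitivities γ: S-G2-M 1.0,
G1 0.5, quiescent 0.12.  The quiescent value is the main calibration
lever for the absolute kill level because ~80% of the 400 h population
is quiescent; 0.12 reproduces the four reference ablation kill counts
within ±15%.  The repair correction rises linearly from
ρ(0) = 0.02 (98% of low-dose damage repaired) to 1 at 6 Gy; with a
1 Gy saturation the correction would be inert at clinical 2–2.5 Gy
fractions and the no-repair ablation could not differ from baseline,
so the saturation dose is calibrated against the reference ablation
kill counts.  Kill is decided per cell by a uniform draw against S; surviving
G1/S-G2-M cells receive a uniform integer 1–9 h arrest (quiescent
survivors none).

**Chemotherapy** is all-or-nothing: a cycling cell dies when it is in
the drug's target phase and the local concentration is at or above the
kill threshold (5·10⁻⁴ supply units, ≈ the 60th percentile of cell-site
exposure during a bolus); quiescent cells are never killed.  The two
generic drug types are G1-specific and S-G2-M-specific.  In the
oesophageal presets a chemo week maps cisplatin to a day-1 G1-specific
bolus and the 4-day 5-FU infusion to daily S-G2-M-specific boluses on
days 1–4: with a binary threshold rule, an uninterrupted multi-day
supra-threshold exposure would kill *every* cell transiting the target
phase and can exterminate a small tumour outright, which overstates the
intended partial effect.

**Schedules.**  Week-based regimens anchor week 1, day 1 at t = 400 h
(the tumour is grown from one cell until then) and expand to
weekday-only fractions, so 25 fractions span exactly weeks 1–5.  RNG
streams are split per concern (vessels / cell dynamics / therapy
draws), so paired-seed comparisons of treatment arms share identical
pre-treatment worlds and placement randomness.

## Calibration, problem sizes and known limitations

All simulations run on the default 100 × 100 lattice.  The reported
experiments use: untreated growth to 400 h (~1000 cells, 5 replicate
seeds), the single-3 Gy redistribution to 452 h (5 seeds), the
five-fraction ablations to 505 h (5 seeds in the reproduction script,
3 in the test suite), single-vs-fractionated comparisons to 650 h
(3 seeds), and the three oesophageal regimens to 17 treatment weeks
(3256 h, 3 replicate seeds).

What the synthetic setting does and does not capture: the vasculature
is static (no angiogenesis or flow), the domain is 2-D, cells do not
migrate, and there is no normal-tissue compartment, so "toxicity" is
out of scope and regrowth between courses is limited only by space and
oxygen.  Two consequences matter when reading results:

* **The redistribution window closes early.**  After 3 Gy the S-G2-M
  dominance window opens at ≈414 h, matching the reference onset
  (412 h), but closes at ≈420 h rather than ≈436 h: with the
  intermitotic time pinned at ~19 h by the growth calibration, the
  synchronised cohort transits S-G2-M in ~8 h.  Sustaining 24 h of
  contiguous dominance would require an S-G2-M phase longer than G1
  (making the untreated control S-G2-M-dominant) or a ~40 h cycle
  (breaking the growth target).  The three constraints cannot be met
  simultaneously in this automaton, and the window end is the one we
  let miss.
* **Final counts saturate in long runs.**  The 2 × 2 mm patch regrows
  to confluence between and after treatment courses, so 17-week
  regimens are compared by cumulative cell kill — the quantity that
  still separates them — rather than by final count, which is
  compressed against the lattice capacity.

Degenerate inputs: zero vessel density gives a zero oxygen field
(everything hypoxic); zero drug diffusivity reduces the drug step to
exact pointwise decay; a tie of CycB exactly at the threshold
classifies as S-G2-M (fixed, documented tie-break).
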