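"""Radiation survival model, chemotherapy kill rule, schedules."""

import itertools

import numpy as np
import pytest

import tumourca as tca
from tumourca.automaton import EMPTY, init_world, step
from tumourca.cellcycle import EARLY_G1_STATE, Phase
from tumourca.microenv import Field
from tumourca.therapy import (ChemoDose, ChemoParams, RadiationParams,
                              apply_chemo, apply_fraction, build_schedule,
                              load_schedule, oer, omf, repair_factor,
                              survival_probability, G1_DRUG, SG2M_DRUG)


class TestOxygenEnhancement:
    def test_anoxic_limit(self):
        assert oer(0.0, RadiationParams()) == pytest.approx(1.0)

    def test_saturation_limit(self):
        p = RadiationParams()
        assert oer(1e9, p) == pytest.approx(p.oer_max, rel=1e-6)

    def test_half_effect_at_K(self):
        p = RadiationParams()
        assert oer(p.K_mmHg, p) == pytest.approx((p.oer_max + 1) / 2)

    def test_negative_pO2_rejected(self):
        with pytest.raises(ValueError):
            oer(-1.0, RadiationParams())

    def test_omf_limits_and_monotone(self):
        p = RadiationParams()
        assert omf(1e9, p) == pytest.approx(1.0, rel=1e-6)
        assert omf(0.0, p) == pytest.approx(1.0 / p.oer_max)
        grid = omf(np.linspace(0, 60, 100), p)
        assert np.all(np.diff(grid) >= 0)


class TestSurvival:
    def test_zero_dose_is_certain_survival(self):
        assert survival_probability(0.0, 10.0, Phase.G1,
                                    RadiationParams()) == 1.0

    def test_monotone_in_dose(self):
        p = RadiationParams()
        assert survival_probability(4.0, 20.0, Phase.G1, p) \
            < survival_probability(2.0, 20.0, Phase.G1, p)

    @pytest.mark.parametrize("dose", [1.0, 2.0, 5.0])
    def test_lq_closed_form(self, dose):
        """With OMF = gamma = rho = 1 the survival is the plain
        linear-quadratic law exp(-alpha d - beta d^2)."""
        p = RadiationParams(omf_override=1.0, gamma_g1=1.0, gamma_sg2m=1.0,
                            gamma_resting=1.0, repair_enabled=False)
        expected = np.exp(-p.alpha * dose - p.beta * dose ** 2)
        assert survival_probability(dose, 0.0, Phase.G1, p) \
            == pytest.approx(expected, rel=1e-12)

    def test_bounded_and_monotone_in_oxygen_and_gamma(self):
        p = RadiationParams()
        svals = [survival_probability(2.5, pO2, Phase.SG2M, p)
                 for pO2 in np.linspace(0, 80, 50)]
        assert all(0 <= s <= 1 for s in svals)
        assert all(b <= a + 1e-12 for a, b in zip(svals, svals[1:]))
        for ph_hi, ph_lo in ((Phase.SG2M, Phase.G1), (Phase.G1, Phase.RESTING)):
            assert survival_probability(2.5, 20.0, ph_hi, p) \
                <= survival_probability(2.5, 20.0, ph_lo, p)

    def test_disabling_repair_never_increases_survival(self):
        p = RadiationParams()
        p_off = RadiationParams(repair_enabled=False)
        for dose in (0.5, 1.0, 2.5, 8.0):
            assert survival_probability(dose, 20.0, Phase.G1, p_off) \
                <= survival_probability(dose, 20.0, Phase.G1, p)

    def test_repair_factor_shape(self):
        p = RadiationParams()
        assert repair_factor(0.0, p) == pytest.approx(p.repair_min_factor)
        assert repair_factor(p.repair_dose_threshold, p) == 1.0
        assert repair_factor(2 * p.repair_dose_threshold, p) == 1.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(-1.0, 10.0, Phase.G1, RadiationParams())


def packed_world(config, n_cells, phase=Phase.G1):
    """World pre-filled with n_cells live cells (row-major placement)."""
    w = init_world(config, seed=123)
    w.refresh_oxygen()
    placed = 1
    for r, c in itertools.product(range(w.rows), range(w.cols)):
        if placed >= n_cells:
            break
        if w.occupancy[r, c] == EMPTY:
            cid = w.add_cell(r, c, EARLY_G1_STATE.as_array(), phase, 0.0)
            placed += 1
    return w


class TestApplyFraction:
    def test_zero_dose_no_effect(self, config):
        w = packed_world(config, 200)
        killed, delayed = apply_fraction(w, 0.0, config.therapy.radiation,
                                         w.rng_therapy)
        assert killed == [] and delayed == []

    def test_binomial_kill_at_fixed_survival(self, config):
        """With survival pinned at 0.5 the killed fraction of 10,000
        cells lies within 3 binomial standard deviations."""
        w = packed_world(config, 10_000)
        params = RadiationParams(fixed_survival=0.5)
        killed, _ = apply_fraction(w, 2.0, params, w.rng_therapy)
        frac = len(killed) / 10_000
        assert abs(frac - 0.5) < 3 * 0.005

    def test_delays_integer_hours_in_1_to_9(self, config):
        w = packed_world(config, 2_000)
        params = RadiationParams(fixed_survival=1.0)
        _, delayed = apply_fraction(w, 2.0, params, w.rng_therapy)
        d = w.delay[delayed]
        assert len(delayed) == 2_000
        assert np.all((d >= 1) & (d <= 9))
        assert np.all(d == np.round(d))

    def test_resting_survivors_not_delayed(self, config):
        w = packed_world(config, 500, phase=Phase.RESTING)
        params = RadiationParams(fixed_survival=1.0)
        _, delayed = apply_fraction(w, 2.0, params, w.rng_therapy)
        delayed = [cid for cid in delayed
                   if w.phase[cid] == int(Phase.RESTING)]
        assert delayed == []

    def test_killed_cells_vacate_lattice(self, config):
        w = packed_world(config, 1_000)
        params = RadiationParams(fixed_survival=0.3)
        killed, _ = apply_fraction(w, 2.0, params, w.rng_therapy)
        assert w.cumulative_kills["radiation"] == len(killed)
        for cid in killed:
            assert w.occupancy[w.row[cid], w.col[cid]] == EMPTY
        w.check_consistency()


class TestApplyChemo:
    def test_zero_field_no_kill(self, config):
        w = packed_world(config, 300)
        field = Field(np.zeros((w.rows, w.cols)), G1_DRUG)
        assert apply_chemo(w, field, config.therapy.chemo[G1_DRUG],
                           G1_DRUG) == []

    def test_phase_specificity(self, config):
        w = packed_world(config, 300, phase=Phase.SG2M)
        params = config.therapy.chemo[G1_DRUG]
        field = Field(np.full((w.rows, w.cols), 100 * params.kill_threshold),
                      G1_DRUG)
        killed = apply_chemo(w, field, params, G1_DRUG)
        survivors = [int(Phase(p)) for p in w.phase[np.flatnonzero(w.alive)]]
        assert all(w.phase[cid] == int(Phase.G1) for cid in killed)
        assert int(Phase.SG2M) in survivors  # no S-G2-M cell was touched

    def test_resting_never_killed(self, config):
        w = packed_world(config, 300, phase=Phase.RESTING)
        w.phase[0] = int(Phase.RESTING)  # the seeded cell too
        for name in (G1_DRUG, SG2M_DRUG):
            params = config.therapy.chemo[name]
            field = Field(np.full((w.rows, w.cols),
                                  100 * params.kill_threshold), name)
            before = w.n_live
            assert apply_chemo(w, field, params, name) == []
            assert w.n_live == before

    def test_matches_brute_force_enumeration(self):
        """On a hand-built 5x5 world the killed set equals exhaustive
        enumeration over (phase, concentration) conditions."""
        cfg = tca.default_config()
        cfg.grid.rows = cfg.grid.cols = 5
        cfg.grid.vessel_density = 0.0
        cfg.grid.start_site = (0, 0)
        w = init_world(cfg, seed=1)
        rng = np.random.default_rng(8)
        for r in range(5):
            for c in range(5):
                if w.occupancy[r, c] == EMPTY:
                    w.add_cell(r, c, EARLY_G1_STATE.as_array(),
                               Phase(int(rng.integers(3))), 0.0)
        w.phase[0] = int(Phase(int(rng.integers(3))))
        params = ChemoParams(target_phase=Phase.SG2M, kill_threshold=0.5)
        conc = rng.random((5, 5))
        expected = {
            int(w.occupancy[r, c])
            for r in range(5) for c in range(5)
            if w.occupancy[r, c] >= 0
            and w.phase[w.occupancy[r, c]] == int(Phase.SG2M)
            and conc[r, c] >= 0.5
        }
        killed = apply_chemo(w, Field(conc, SG2M_DRUG), params, SG2M_DRUG)
        assert set(killed) == expected


class TestSchedules:
    def test_fractionated_preset_times(self):
        s = build_schedule("fractionated")
        assert s.radiation == [(400.0 + 24 * k, 2.5) for k in range(5)]

    def test_herskovic_preset(self):
        s = build_schedule("herskovic")
        assert len(s.radiation) == 25
        assert all(d == 2.0 for _, d in s.radiation)
        # weekday-only fractions: 25 fractions span exactly weeks 1-5
        assert s.radiation[0][0] == 400.0
        assert s.radiation[-1][0] == 400.0 + (4 * 7 + 4) * 24
        assert len(s.chemo) == 8  # 4 cycles x (bolus + 96 h infusion)

    def test_experimental_preset(self):
        s = build_schedule("experimental")
        assert len(s.radiation) == 20
        assert all(d == 2.5 for _, d in s.radiation)
        assert s.radiation[0][0] == 400.0 + 11 * 7 * 24

    def test_empty_schedule_is_control(self):
        s = build_schedule(radiation=[], chemo=[])
        assert s.radiation == [] and s.chemo == []

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            build_schedule("banana")

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(radiation=[(-5.0, 2.0)])

    def test_schedule_file_round_trip(self, tmp_path):
        path = tmp_path / "sched.yaml"
        path.write_text(
            "radiation:\n- {t_h: 400, dose_Gy: 3.0}\n"
            "chemo:\n- {t_h: 340, drug: G1_specific}\n"
            "- {t_h: 370, drug: SG2M_specific, duration_h: 96}\n")
        s = load_schedule(path)
        assert s.radiation == [(400, 3.0)]
        assert s.chemo[1].duration_h == 96


class TestConservationLedger:
    def test_created_equals_live_plus_killed(self, small_config):
        """Every cell ever created is either alive or accounted to one
        kill counter (exact ledger identity)."""
        cfg = small_config
        schedule = build_schedule(
            radiation=[(30.0, 2.0), (60.0, 2.0)],
            chemo=[(40.0, G1_DRUG), (50.0, SG2M_DRUG)])
        res = tca.run_experiment(cfg, schedule, seed=5, horizon_h=80.0)
        w = res.world
        assert w.n_created == (w.n_live
                               + w.cumulative_kills["radiation"]
                               + w.cumulative_kills["chemo"])
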