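"""Microenvironment: vessel placement, oxygen and drug fields."""

import numpy as np
import pytest

from tumourca.microenv import (ConvergenceError, DiffusionParams, Field,
                               PlacementError, VesselMap, generate_vessels,
                               hypoxic_mask, solve_oxygen, step_drug,
                               _link_coefficients, _diffusivity)


def dense_solve(occupancy, vessels, params):
    """Independent dense-matrix solve of the discrete steady state.

    Builds the 5-point operator row by row with explicit loops (no code
    shared with the production assembly beyond the harmonic-mean rule).
    """
    rows, cols = occupancy.shape
    n = rows * cols
    D = np.where(occupancy, params.D_base * params.D_tumour_factor,
                 params.D_base)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(rows):
        for j in range(cols):
            k = i * cols + j
            diag = params.background_decay
            if occupancy[i, j]:
                diag += params.consumption_rate
            for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                ii, jj = i + di, j + dj
                if 0 <= ii < rows and 0 <= jj < cols:
                    h = 2 * D[i, j] * D[ii, jj] / (D[i, j] + D[ii, jj])
                    diag += h
                    A[k, ii * cols + jj] = -h
            A[k, k] = diag
            if vessels.mask[i, j]:
                b[k] = params.supply_rate
    return np.linalg.solve(A, b).reshape(rows, cols)


class TestGenerateVessels:
    def test_zero_density_empty(self):
        assert generate_vessels(50, 50, 0.0, seed=1).n_vessels == 0

    def test_count_formula(self):
        vm = generate_vessels(100, 100, 0.01, seed=3)
        assert vm.n_vessels == 100

    def test_reproducible_and_seed_sensitive(self):
        for seed in range(10):
            a = generate_vessels(40, 40, 0.02, seed=seed)
            b = generate_vessels(40, 40, 0.02, seed=seed)
            c = generate_vessels(40, 40, 0.02, seed=seed + 1000)
            assert np.array_equal(a.mask, b.mask)
            assert not np.array_equal(a.mask, c.mask)

    def test_min_separation_respected(self):
        vm = generate_vessels(60, 60, 0.01, min_separation=3.0, seed=7)
        xy = vm.coords
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1).astype(float)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 9.0

    def test_excluded_sites_avoided(self):
        vm = generate_vessels(20, 20, 0.05, seed=5, exclude={(10, 10)})
        assert not vm.mask[10, 10]

    def test_infeasible_density_raises(self):
        with pytest.raises(PlacementError):
            generate_vessels(10, 10, 0.2, min_separation=10.0, seed=1)

    def test_tsv_round_trip(self, tmp_path):
        vm = generate_vessels(30, 30, 0.02, seed=2)
        path = tmp_path / "vessels.tsv"
        vm.to_tsv(path)
        back = VesselMap.from_tsv(path, 30, 30)
        assert np.array_equal(vm.mask, back.mask)


class TestSolveOxygen:
    def test_no_vessels_zero_field(self):
        occ = np.zeros((20, 20), dtype=bool)
        vm = generate_vessels(20, 20, 0.0, seed=1)
        f = solve_oxygen(occ, vm, DiffusionParams())
        assert np.all(f.values == 0)

    def test_uniform_source_analytic_steady_state(self):
        """Vessels everywhere, no cells: raw field is r/phi_B at every
        site (the spatially uniform analytic solution)."""
        p = DiffusionParams()
        vm = VesselMap(mask=np.ones((15, 15), dtype=bool), density=1.0, seed=0)
        occ = np.zeros((15, 15), dtype=bool)
        f = solve_oxygen(occ, vm, p, normalise=False)
        assert np.allclose(f.values, p.supply_rate / p.background_decay,
                           rtol=1e-6)

    def test_matches_dense_oracle_on_small_grid(self):
        p = DiffusionParams(steady_state_tol=1e-12)
        vm = VesselMap(mask=np.zeros((10, 10), dtype=bool), density=0.01,
                       seed=0)
        vm.mask[4, 6] = True
        occ = np.zeros((10, 10), dtype=bool)
        mine = solve_oxygen(occ, vm, p, normalise=False).values
        ref = dense_solve(occ, vm, p)
        assert np.allclose(mine, ref, atol=1e-8 * ref.max())

    def test_maximum_principle(self):
        """Raw steady state never exceeds r/phi_B (random instances)."""
        rng = np.random.default_rng(0)
        p = DiffusionParams()
        bound = p.supply_rate / p.background_decay
        for _ in range(10):
            vm = generate_vessels(20, 20, 0.02, seed=int(rng.integers(1e6)))
            occ = rng.random((20, 20)) < 0.3
            f = solve_oxygen(occ, vm, p, normalise=False)
            assert f.values.max() <= bound * (1 + 1e-6)

    def test_extra_consumer_never_raises_oxygen(self):
        p = DiffusionParams(steady_state_tol=1e-12)
        vm = generate_vessels(12, 12, 0.03, seed=9)
        occ = np.zeros((12, 12), dtype=bool)
        occ[5, 5] = True
        base = dense_solve(occ, vm, p)
        occ2 = occ.copy()
        occ2[6, 5] = True
        more = dense_solve(occ2, vm, p)
        assert np.all(more <= base + 1e-12)
        # and the production solver agrees with the oracle on both
        assert np.allclose(solve_oxygen(occ2, vm, p, normalise=False).values,
                           more, atol=1e-8 * base.max())

    def test_normalised_max_is_100(self):
        vm = generate_vessels(20, 20, 0.02, seed=3)
        f = solve_oxygen(np.zeros((20, 20), dtype=bool), vm, DiffusionParams())
        assert f.values.max() == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        vm = generate_vessels(20, 20, 0.02, seed=3)
        with pytest.raises(ValueError):
            solve_oxygen(np.zeros((10, 10), dtype=bool), vm, DiffusionParams())


def drug_params(**kw):
    base = dict(D_base=50.0, D_tumour_factor=0.5, supply_rate=1.0,
                consumption_rate=0.0, background_decay=0.0, drug_decay=2.0)
    base.update(kw)
    return DiffusionParams(**base)


class TestStepDrug:
    def test_pointwise_exponential_decay_without_diffusion(self):
        p = drug_params(D_base=0.0, drug_decay=0.7)
        c0 = 3.0
        f = Field(np.full((10, 10), c0), "drug")
        vm = generate_vessels(10, 10, 0.0, seed=1)
        out = step_drug(f, vm, np.zeros((10, 10), dtype=bool), False, 1.5, p)
        assert np.allclose(out.values, c0 * np.exp(-0.7 * 1.5), rtol=1e-12)

    def test_zero_field_stays_zero(self):
        p = drug_params()
        f = Field(np.zeros((10, 10)), "drug")
        vm = generate_vessels(10, 10, 0.02, seed=1)
        out = step_drug(f, vm, np.zeros((10, 10), dtype=bool), False, 1.0, p)
        assert np.all(out.values == 0)

    def test_mass_conserved_diffusion_only(self):
        """Pure diffusion (no decay, no supply) conserves total mass."""
        p = drug_params(drug_decay=0.0)
        rng = np.random.default_rng(5)
        occ = rng.random((20, 20)) < 0.3
        f = Field(rng.random((20, 20)), "drug")
        vm = generate_vessels(20, 20, 0.0, seed=1)
        total0 = f.values.sum()
        for _ in range(5):
            f = step_drug(f, vm, occ, False, 1.0, p)
        assert f.values.sum() == pytest.approx(total0, rel=1e-10)

    def test_total_mass_matches_fine_step_reference(self):
        """Supply on for 3 h then off: the lattice-mass trajectory at
        dt = 1 h matches a 10x finer integration within 1%."""
        p = drug_params()
        vm = generate_vessels(20, 20, 0.02, seed=4)
        occ = np.zeros((20, 20), dtype=bool)

        def run(dt):
            f = Field(np.zeros((20, 20)), "drug")
            masses = []
            for k in range(int(round(6 / dt))):
                supplying = k * dt < 3.0
                f = step_drug(f, vm, occ, supplying, dt, p)
                if abs((k + 1) * dt - round((k + 1) * dt)) < 1e-9:
                    masses.append(f.values.sum())
            return np.array(masses)

        coarse, fine = run(1.0), run(0.1)
        assert np.allclose(coarse, fine, rtol=0.01)

    def test_invalid_dt_rejected(self):
        f = Field(np.zeros((5, 5)), "drug")
        vm = generate_vessels(5, 5, 0.0, seed=1)
        with pytest.raises(ValueError):
            step_drug(f, vm, np.zeros((5, 5), dtype=bool), False, 0.0,
                      drug_params())


class TestHypoxicMask:
    def test_uniform_oxic_field(self):
        mask, pct = hypoxic_mask(Field(np.full((10, 10), 100.0)), 10.0)
        assert not mask.any() and pct == 0.0

    def test_single_oxic_site(self):
        values = np.zeros((10, 10))
        values[3, 3] = 100.0
        mask, pct = hypoxic_mask(Field(values), 10.0)
        assert pct == pytest.approx(99.0)
        assert not mask[3, 3]

    def test_zero_threshold(self):
        mask, pct = hypoxic_mask(Field(np.zeros((10, 10))), 0.0)
        assert pct == 0.0
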