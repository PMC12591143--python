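import numpy as np
import pytest

from nsphase import fh
from nsphase.errors import DomainError


def small_params(**kw):
    defaults = dict(grid_n=64, seed=11)
    defaults.update(kw)
    return fh.FHParams(**defaults)


class TestFreeEnergyDensity:
    def test_pure_solvent_is_zero(self):
        assert fh.free_energy_density(0.0, 0.0, small_params()) == 0.0

    def test_reference_value(self):
        # frozen from an independent term-by-term evaluation:
        # 2*0.23*ln(0.23) + 0.54*ln(0.54) + 2*0.23^2 + 2*4*0.23*0.54
        p = small_params(chi_AA=4, chi_BB=4, chi_AB=2)
        assert fh.free_energy_density(0.23, 0.23, p) == pytest.approx(0.090608538, abs=1e-8)

    def test_species_exchange_symmetry(self):
        p = small_params(chi_AA=4, chi_BB=4, chi_AB=2.7)
        assert fh.free_energy_density(0.1, 0.35, p) == pytest.approx(
            fh.free_energy_density(0.35, 0.1, p)
        )

    def test_outside_simplex_raises(self):
        with pytest.raises(DomainError):
            fh.free_energy_density(0.7, 0.5, small_params())
        with pytest.raises(DomainError):
            fh.free_energy_density(-0.1, 0.2, small_params())


class TestTotalFreeEnergy:
    def test_homogeneous_state(self):
        p = small_params(noise_amp=0.0)
        s = fh.initial_state(p)
        expected = p.grid_n**2 * p.dx**2 * fh.free_energy_density(p.phi_A0, p.phi_B0, p)
        assert fh.total_free_energy(s, p) == pytest.approx(expected, rel=1e-10)

    def test_area_scaling(self):
        p1 = small_params(noise_amp=0.0, dx=1.0)
        p2 = small_params(noise_amp=0.0, dx=2.0)
        f1 = fh.total_free_energy(fh.initial_state(p1), p1)
        f2 = fh.total_free_energy(fh.initial_state(p2), p2)
        assert f2 == pytest.approx(4 * f1, rel=1e-10)


class TestChemicalPotentials:
    def test_homogeneous_symmetric_state(self):
        p = small_params(chi_AA=4, chi_BB=4, noise_amp=0.0)
        mu_a, mu_b = fh.chemical_potentials(fh.initial_state(p), p)
        assert np.allclose(mu_a, mu_b)
        assert np.ptp(mu_a) < 1e-10

    def test_matches_functional_derivative(self):
        # brute-force oracle: dF/dphi_A at one pixel ~ mu_A * dx^2
        p = small_params(chi_AB=2.5, noise_amp=0.02, seed=4)
        s = fh.initial_state(p)
        mu_a, mu_b = fh.chemical_potentials(s, p)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for _ in range(5):
            i, j = rng.integers(0, p.grid_n, 2)
            for mu, field in ((mu_a, "phi_A"), (mu_b, "phi_B")):
                plus = fh.FieldState(s.phi_A.copy(), s.phi_B.copy())
                getattr(plus, field)[i, j] += eps
                minus = fh.FieldState(s.phi_A.copy(), s.phi_B.copy())
                getattr(minus, field)[i, j] -= eps
                num = (fh.total_free_energy(plus, p) - fh.total_free_energy(minus, p)) / (
                    2 * eps * p.dx**2
                )
                assert num == pytest.approx(mu[i, j], rel=1e-4, abs=1e-8)

    def test_entropy_only_dilute_limit(self):
        p = small_params(chi_AA=0, chi_BB=0, chi_AB=0, phi_A0=0.01, phi_B0=0.01,
                         noise_amp=0.0)
        s = fh.initial_state(p)
        mu_a, _ = fh.chemical_potentials(s, p)
        expected = np.log(0.01) - np.log(0.98)
        assert np.allclose(mu_a, expected, atol=1e-9)


class TestDynamics:
    def test_homogeneous_fixed_point(self):
        p = small_params(noise_amp=0.0)
        s0 = fh.initial_state(p)
        s1 = fh.step(s0, p, 50)
        assert np.allclose(s1.phi_A, s0.phi_A, atol=1e-12)
        assert np.allclose(s1.phi_B, s0.phi_B, atol=1e-12)

    def test_mass_conservation_long_run(self):
        # conserved dynamics keep spatial means to 1e-8 over >= 1e4 steps
        p = small_params(chi_AB=3.5)
        final = fh.run(p, [10000])[-1]
        ea, eb = fh.mass_error(final, p)
        assert ea <= 1e-8 and eb <= 1e-8

    def test_energy_descent_along_trajectory(self):
        p = small_params(chi_AB=4.0, seed=2)
        states = fh.run(p, [500, 1000, 2000, 4000, 8000])
        energies = [fh.total_free_energy(s, p) for s in states]
        for f_prev, f_next in zip(energies, energies[1:]):
            assert f_next <= f_prev + 1e-6 * abs(f_prev)

    def test_determinism_same_seed(self):
        p = small_params(chi_AB=3.0, seed=21)
        run1 = fh.run(p, [200, 400])
        run2 = fh.run(p, [200, 400])
        assert np.array_equal(run1[-1].phi_A, run2[-1].phi_A)
        assert np.array_equal(run1[-1].phi_B, run2[-1].phi_B)

    def test_species_exchange_symmetry_of_trajectories(self):
        # swapping (phi_A0, chi_AA) with (phi_B0, chi_BB) and the noise fields
        # mirrors the trajectory exactly
        p = small_params(chi_AA=4.0, chi_BB=3.5, phi_A0=0.2, phi_B0=0.26,
                         chi_AB=2.5, noise_amp=0.0)
        rng = np.random.default_rng(33)
        na = rng.normal(0, 0.01, (64, 64))
        nb = rng.normal(0, 0.01, (64, 64))
        s = fh.FieldState(p.phi_A0 + na - na.mean(), p.phi_B0 + nb - nb.mean())
        p_sw = small_params(chi_AA=3.5, chi_BB=4.0, phi_A0=0.26, phi_B0=0.2,
                            chi_AB=2.5, noise_amp=0.0)
        s_sw = fh.FieldState(p_sw.phi_A0 + nb - nb.mean(), p_sw.phi_B0 + na - na.mean())
        out = fh.step(s, p, 300)
        out_sw = fh.step(s_sw, p_sw, 300)
        assert np.allclose(out.phi_A, out_sw.phi_B, atol=1e-12)
        assert np.allclose(out.phi_B, out_sw.phi_A, atol=1e-12)

    def test_snapshot_schedule_validation(self):
        p = small_params()
        with pytest.raises(ValueError):
            fh.run(p, [100, 100])

    def test_default_schedule_is_geometric_with_five_points(self):
        sched = fh.default_snapshot_steps(16000)
        assert len(sched) == 5
        assert sched[-1] == 16000
        ratios = [b / a for a, b in zip(sched, sched[1:])]
        assert all(r == pytest.approx(2.0, rel=0.01) for r in ratios)


class TestRenderSnapshot:
    def test_rescale_contract(self):
        p = small_params(noise_amp=0.0)
        s = fh.initial_state(p)
        s.phi_A = np.linspace(0.05, 0.55, 64 * 64).reshape(64, 64)
        img = fh.render_snapshot(s)
        assert img.channel_A.min() == 0.0
        assert img.channel_A.max() == 1.0
        assert img.pixel_size == p.dx

    def test_swap_fields_swaps_channels(self):
        p = small_params(noise_amp=0.02, seed=9)
        s = fh.initial_state(p)
        img = fh.render_snapshot(s)
        swapped = fh.render_snapshot(fh.FieldState(s.phi_B, s.phi_A, params=p))
        assert np.array_equal(img.channel_A, swapped.channel_B)

    def test_constant_field_flagged(self):
        p = small_params(noise_amp=0.0)
        img = fh.render_snapshot(fh.initial_state(p))
        assert img.metadata.get("degenerate_rescale")
        assert np.all(img.channel_A == 0)


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(phi_A0=0.0), dict(phi_A0=0.6, phi_B0=0.5), dict(dt=0.0), dict(grid_n=16)],
    )
    def test_bad_params(self, kw):
        with pytest.raises(DomainError):
            small_params(**kw)


class TestInstability:
    def test_non_finite_state_raises_with_step_index(self):
        from nsphase.errors import SimulationUnstableError

        p = small_params(noise_amp=0.0)
        s = fh.initial_state(p)
        s.phi_A[3, 3] = np.nan
        with pytest.raises(SimulationUnstableError) as exc:
            fh.step(s, p, 10)
        assert exc.value.step_index == 0
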