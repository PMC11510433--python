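import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dessol.sigma_profiles import (
    GRID_SIZE,
    SigmaProfile,
    SolventComposition,
    make_grid,
    mixture_potential,
    read_profile,
    region_decomposition,
    relative_sigma_potential,
    step_average,
    write_profile,
)
from tests.conftest import make_profile

finite_potentials = arrays(
    np.float64,
    GRID_SIZE,
    elements=st.floats(-100, 100, allow_nan=False, allow_infinity=False),
)


class TestGrid:
    def test_endpoints_and_count(self):
        grid = make_grid()
        assert len(grid) == 61
        assert grid[0] == pytest.approx(-0.030, abs=1e-12)
        assert grid[-1] == pytest.approx(+0.030, abs=1e-12)

    def test_middle_point_is_zero(self):
        assert make_grid()[30] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_step(self):
        diffs = np.diff(make_grid())
        assert np.allclose(diffs, 0.001, atol=1e-12)
        assert np.all(diffs > 0)


class TestProfileValidation:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="61"):
            SigmaProfile("X", 298.15, np.zeros(60))

    def test_non_finite_rejected(self):
        vals = np.zeros(GRID_SIZE)
        vals[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            SigmaProfile("X", 298.15, vals)


class TestComposition:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SolventComposition([("A", 0.5), ("B", 0.4)])

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SolventComposition([("A", 1.5), ("B", -0.5)])

    def test_too_many_components(self):
        comps = [(f"C{i}", 0.2) for i in range(5)]
        with pytest.raises(ValueError, match="1-4"):
            SolventComposition(comps)


class TestMixturePotential:
    def test_single_component_identity(self, random_profile):
        p = random_profile("A")
        mixed = mixture_potential([p], SolventComposition([("A", 1.0)]))
        assert np.allclose(mixed.potential, p.potential)
        assert mixed.temperature == p.temperature

    def test_equal_profiles_convexity(self, random_profile, binary_composition):
        p = random_profile("A")
        q = make_profile(p.potential, "B", p.temperature)
        mixed = mixture_potential([p, q], binary_composition)
        assert np.allclose(mixed.potential, p.potential)

    def test_weighted_mean_of_constants(self, constant_profile, binary_composition):
        mixed = mixture_potential(
            [constant_profile(1.0, "A"), constant_profile(3.0, "B")], binary_composition
        )
        assert np.allclose(mixed.potential, 2.5)

    def test_missing_profile_names_id(self, random_profile, binary_composition):
        with pytest.raises(KeyError, match="B"):
            mixture_potential([random_profile("A")], binary_composition)

    def test_temperature_mismatch(self, binary_composition):
        a = make_profile(np.zeros(GRID_SIZE), "A", 298.15)
        b = make_profile(np.zeros(GRID_SIZE), "B", 308.15)
        with pytest.raises(ValueError, match="[Tt]emperature"):
            mixture_potential([a, b], binary_composition)

    def test_component_order_invariance(self, random_profile):
        a, b = random_profile("A"), random_profile("B")
        c1 = SolventComposition([("A", 0.3), ("B", 0.7)])
        c2 = SolventComposition([("B", 0.7), ("A", 0.3)])
        m1 = mixture_potential([a, b], c1)
        m2 = mixture_potential([b, a], c2)
        assert np.allclose(m1.potential, m2.potential)


class TestRelativePotential:
    def test_self_difference_is_zero(self, random_profile):
        p = random_profile("A")
        assert np.allclose(relative_sigma_potential(p, p).potential, 0.0)

    def test_constant_difference(self, constant_profile):
        d = relative_sigma_potential(constant_profile(2.0, "A"), constant_profile(2.5, "B"))
        assert np.allclose(d.potential, -0.5)

    def test_antisymmetry(self, random_profile):
        a, b = random_profile("A"), random_profile("B")
        fwd = relative_sigma_potential(a, b).potential
        bwd = relative_sigma_potential(b, a).potential
        assert np.allclose(fwd + bwd, 0.0, atol=1e-12)

    def test_temperature_mismatch(self):
        a = make_profile(np.zeros(GRID_SIZE), "A", 298.15)
        b = make_profile(np.zeros(GRID_SIZE), "B", 308.15)
        with pytest.raises(ValueError, match="[Tt]emperature"):
            relative_sigma_potential(a, b)

    @settings(max_examples=25, deadline=None)
    @given(mu=finite_potentials, nu=finite_potentials, x=st.floats(0.0, 1.0))
    def test_linearity_in_components(self, mu, nu, x):
        api = make_profile(np.zeros(GRID_SIZE), "api")
        comp = SolventComposition([("A", x), ("B", 1.0 - x)])
        a, b = make_profile(mu, "A"), make_profile(nu, "B")
        mixed = mixture_potential([a, b], comp)
        rel = relative_sigma_potential(api, mixed)
        expected = -(x * mu + (1.0 - x) * nu)
        assert np.allclose(rel.potential, expected, atol=1e-10)


class TestStepAverage:
    def test_constant_profile_any_bins(self, constant_profile):
        for n_bins in (6, 12):
            assert np.allclose(step_average(constant_profile(4.2), n_bins), 4.2)

    def test_output_length_12(self, random_profile):
        assert step_average(random_profile(), 12).shape == (12,)

    def test_grid_valued_profile_6_bins_brute_force(self):
        # oracle: arithmetic mean of each contiguous 10-point block of sigma
        # values, summing the raw sequence directly
        grid = make_grid()
        profile = make_profile(grid)
        expected = []
        for b in range(6):
            block = [grid[b * 10 + j] for j in range(10)]
            expected.append(sum(block) / 10.0)
        assert np.allclose(step_average(profile, 6), expected, atol=1e-15)

    def test_invalid_bins_rejected(self, random_profile):
        for bad in (0, -3, 7, 61):
            with pytest.raises(ValueError, match="divisor"):
                step_average(random_profile(), bad)

    @settings(max_examples=25, deadline=None)
    @given(mu=finite_potentials, nu=finite_potentials, k=st.floats(-10, 10))
    def test_commutes_with_addition_and_scaling(self, mu, nu, k):
        s_sum = step_average(make_profile(mu + nu), 12)
        s_parts = step_average(make_profile(mu), 12) + step_average(make_profile(nu), 12)
        assert np.allclose(s_sum, s_parts, atol=1e-9)
        assert np.allclose(
            step_average(make_profile(k * mu), 6), k * step_average(make_profile(mu), 6), atol=1e-9
        )

    def test_constant_carried_at_all_resolutions(self, constant_profile):
        p = constant_profile(7.5)
        assert np.allclose(p.potential, 7.5)
        assert np.allclose(step_average(p, 12), 7.5)
        assert np.allclose(step_average(p, 6), 7.5)


class TestRegionDecomposition:
    def test_constant(self, constant_profile):
        assert region_decomposition(constant_profile(3.0)) == pytest.approx((3.0, 3.0, 3.0))

    def test_support_confinement(self):
        grid = make_grid()
        vals = np.where(grid > 0.01, 5.0, 0.0)  # support inside (+0.01, +0.03]
        hba, hyd, hbd = region_decomposition(make_profile(vals))
        assert hba == 0.0
        assert hyd == 0.0
        assert hbd > 0.0

    def test_even_profile_symmetry(self, rng):
        half = rng.normal(size=30)
        vals = np.concatenate([half[::-1], [rng.normal()], half])
        hba, _, hbd = region_decomposition(make_profile(vals))
        assert hba == pytest.approx(hbd, abs=1e-12)


class TestProfileIO:
    def test_round_trip(self, tmp_path, random_profile):
        p = random_profile("caffeine", temperature=303.15)
        path = tmp_path / "p.txt"
        write_profile(p, path)
        q = read_profile(path)
        assert q.compound_id == p.compound_id
        assert q.temperature == pytest.approx(p.temperature, abs=1e-12)
        assert np.allclose(q.potential, p.potential, atol=1e-12)

    def test_wrong_row_count(self, tmp_path, random_profile):
        path = tmp_path / "p.txt"
        write_profile(random_profile(), path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one data row
        with pytest.raises(ValueError, match="61"):
            read_profile(path)

    def test_shuffled_sigma_column(self, tmp_path, random_profile):
        path = tmp_path / "p.txt"
        write_profile(random_profile(), path)
        lines = path.read_text().splitlines()
        lines[1], lines[10] = lines[10], lines[1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="increasing"):
            read_profile(path)

    def test_missing_header(self, tmp_path, random_profile):
        path = tmp_path / "p.txt"
        write_profile(random_profile(), path)
        body = "\n".join(path.read_text().splitlines()[1:])
        path.write_text(body + "\n")
        with pytest.raises(ValueError, match="header"):
            read_profile(path)
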