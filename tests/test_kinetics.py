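"""Photocycle scheme construction, analytic propagation, surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import linregress

import photokin as pk
from photokin.kinetics import DEFAULT_TIME_CONSTANTS, log_time_grid

from conftest import ode_propagate


def two_state(k=1.0):
    return pk.PhotocycleScheme(states=["A", "B"], edges=[("A", "B", k)])


class TestBuildRateMatrix:
    def test_single_irreversible_decay(self):
        K = pk.build_rate_matrix(two_state())
        np.testing.assert_allclose(K.matrix, [[-1.0, 0.0], [1.0, 0.0]])

    def test_default_chain_is_lower_triangular_with_edge_rates(self):
        K = pk.build_rate_matrix(pk.default_scheme())
        assert K.matrix.shape == (6, 6)
        assert np.all(np.triu(K.matrix, 1) == 0)
        np.testing.assert_allclose(
            -np.diag(K.matrix)[:5], [1.0 / tau for tau in DEFAULT_TIME_CONSTANTS]
        )
        assert K.matrix[5, 5] == 0  # recovered ground state is absorbing

    def test_reversible_edge_columns_sum_to_zero(self):
        scheme = pk.PhotocycleScheme(
            states=["L", "M", "N"],
            edges=[("L", "M", 3.0), ("M", "L", 1.5), ("M", "N", 0.7)],
        )
        K = pk.build_rate_matrix(scheme)
        assert K.matrix[0, 1] == 1.5 and K.matrix[1, 0] == 3.0
        np.testing.assert_allclose(K.matrix.sum(axis=0), 0.0, atol=1e-15)

    @pytest.mark.parametrize(
        "edges, err",
        [
            ([("A", "B", 1.0), ("A", "B", 2.0)], "duplicate edge"),
            ([("A", "C", 1.0)], "unknown state"),
            ([("A", "A", 1.0)], "self-edge"),
            ([("A", "B", -1.0)], "non-positive rate"),
        ],
    )
    def test_invalid_schemes_rejected(self, edges, err):
        with pytest.raises(ValueError, match=err):
            pk.PhotocycleScheme(states=["A", "B"], edges=edges)

    def test_unreachable_state_rejected(self):
        with pytest.raises(ValueError, match="not reachable"):
            pk.PhotocycleScheme(states=["A", "B", "C"], edges=[("A", "B", 1.0)])


class TestPropagatePopulations:
    def test_two_state_closed_form(self):
        K = pk.build_rate_matrix(two_state())
        pops = pk.propagate_populations(K, [1.0, 0.0], np.array([1.0]))
        np.testing.assert_allclose(pops[0], [np.exp(-1), 1 - np.exp(-1)], rtol=1e-12)

    def test_terminal_state_filled_after_fast_phases(self):
        """By 2 s every phase but the 91 s recovery is complete, so nearly
        all cycling molecules sit in the 13-cis ground state."""
        K = pk.build_rate_matrix(pk.default_scheme())
        p0 = np.zeros(6)
        p0[0] = 1.0
        pops = pk.propagate_populations(K, p0, np.array([2.0]))
        assert pops[0, K.states.index("P13C")] > 0.95

    def test_population_conservation_and_nonnegativity(self):
        K = pk.build_rate_matrix(pk.default_scheme())
        p0 = np.zeros(6)
        p0[0] = 1.0
        pops = pk.propagate_populations(K, p0, log_time_grid())
        np.testing.assert_allclose(pops.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(pops > -1e-12)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(
        n=st.integers(3, 6),
        log_rates=st.lists(st.floats(-2.0, 6.0), min_size=5, max_size=5),
    )
    def test_matches_dense_ode_oracle_on_random_chains(self, n, log_rates):
        """Analytic eigendecomposition agrees with stiff ODE integration to
        1e-8 for random irreversible chains spanning 8 rate decades."""
        states = [f"S{i}" for i in range(n)]
        edges = [
            (states[i], states[i + 1], 10.0 ** log_rates[i]) for i in range(n - 1)
        ]
        K = pk.build_rate_matrix(pk.PhotocycleScheme(states=states, edges=edges))
        p0 = np.zeros(n)
        p0[0] = 1.0
        times = np.logspace(-7, 1, 100)
        pops = pk.propagate_populations(K, p0, times)
        oracle = ode_propagate(K.matrix, p0, times)
        assert np.max(np.abs(pops - oracle)) < 1e-8

    def test_degenerate_eigensystem_falls_back_to_ode(self):
        """Equal consecutive rates make the chain matrix defective; the
        propagator must switch to numerical integration and still match the
        closed-form Poisson solution p_B = k t e^(-kt)."""
        scheme = pk.PhotocycleScheme(
            states=["A", "B", "C"], edges=[("A", "B", 1.0), ("B", "C", 1.0)]
        )
        K = pk.build_rate_matrix(scheme)
        times = np.array([0.5, 1.0, 2.0])
        pops, info = pk.propagate_populations(K, [1.0, 0.0, 0.0], times, return_info=True)
        assert info["method"] == "ode_fallback"
        np.testing.assert_allclose(pops[:, 1], times * np.exp(-times), atol=1e-6)

    def test_invalid_p0_rejected(self):
        K = pk.build_rate_matrix(two_state())
        with pytest.raises(ValueError):
            pk.propagate_populations(K, [0.5, 0.2], np.array([1.0]))


class TestApparentTimeConstants:
    def test_default_chain_reproduces_phase_lifetimes_exactly(self):
        K = pk.build_rate_matrix(pk.default_scheme())
        np.testing.assert_allclose(
            pk.apparent_time_constants(K), sorted(DEFAULT_TIME_CONSTANTS), rtol=0
        )

    def test_single_decay(self):
        K = pk.build_rate_matrix(two_state(5.0))
        np.testing.assert_allclose(pk.apparent_time_constants(K), [0.2])

    def test_reversible_block_matches_characteristic_polynomial_roots(self):
        """With a reversible L<->M step the apparent lifetimes differ from
        the edge lifetimes; check them against roots of the symbolically
        computed characteristic polynomial."""
        import sympy

        scheme = pk.PhotocycleScheme(
            states=["L", "M", "N"],
            edges=[("L", "M", 4.0), ("M", "L", 1.0), ("M", "N", 2.0)],
        )
        K = pk.build_rate_matrix(scheme)
        taus = pk.apparent_time_constants(K)
        poly = sympy.Matrix(K.matrix).charpoly()
        roots = [complex(r) for r in sympy.nroots(poly.as_expr())]
        expected = sorted(-1.0 / r.real for r in roots if abs(r.real) > 1e-12)
        np.testing.assert_allclose(taus, expected, rtol=1e-9)
        assert not np.allclose(np.sort(taus), [0.25, 1 / 3.0])  # not the edge lifetimes

    def test_oscillatory_kinetics_rejected(self):
        cyc = pk.PhotocycleScheme(
            states=["A", "B", "C"],
            edges=[("A", "B", 1.0), ("B", "C", 1.0), ("C", "A", 1.0)],
        )
        with pytest.raises(ValueError, match="complex eigenvalues"):
            pk.apparent_time_constants(pk.build_rate_matrix(cyc))


class TestSimulateSurface:
    def test_identical_spectra_give_zero_surface(self, cfg):
        cfg0 = cfg.with_(k_shift_nm=0.0, l_shift_nm=0.0, m_band_nm=568.0, p13c_band_nm=568.0)
        spectra = pk.synth.make_species_spectra(cfg0)
        K = pk.build_rate_matrix(pk.default_scheme())
        surf = pk.simulate_surface(K, spectra, log_time_grid(), excited_fraction=0.05)
        np.testing.assert_allclose(surf.delta_a, 0.0, atol=1e-15)

    def test_late_slice_equals_terminal_difference_spectrum(self, cfg):
        """At 2 s the surface equals the (13-cis minus ground) difference
        spectrum scaled by the photoexcited fraction — the standing
        light-minus-dark signature."""
        spectra = pk.synth.make_species_spectra(cfg)
        K = pk.build_rate_matrix(pk.default_scheme())
        surf = pk.simulate_surface(K, spectra, log_time_grid(), excited_fraction=0.05)
        # by 2 s a fraction ~exp(-2/91) of the cycling molecules still sits
        # in the 13-cis state (the 200 ms M decay delays its filling slightly)
        still_13c = np.exp(-2.0 / 91.0)
        expected = 0.05 * still_13c * (spectra.profiles["P13C"] - spectra.ground)
        np.testing.assert_allclose(surf.delta_a[-1], expected, atol=1e-3 * 0.05)

    def test_single_decay_traces_are_one_exponential(self):
        """Every wavelength of a one-intermediate surface decays with the
        same lifetime; log-linear regression recovers it to 1e-6."""
        wl = np.arange(400.0, 601.0, 10.0)
        band = pk.gaussian_band(wl, 500.0).absorbance
        ground = np.zeros_like(band)
        spectra = pk.SpeciesSpectra(wl, {"A": band, "B": ground}, ground)
        K = pk.build_rate_matrix(two_state(1000.0))
        times = np.linspace(1e-5, 3e-3, 200)
        surf = pk.simulate_surface(K, spectra, times, excited_fraction=1.0)
        for j in np.where(band > 0.05)[0]:
            res = linregress(times, np.log(surf.delta_a[:, j]))
            assert abs(-1.0 / res.slope - 1e-3) < 1e-6 * 1e-3 * 10

    def test_linear_in_excited_fraction_and_spectra(self, cfg):
        spectra = pk.synth.make_species_spectra(cfg)
        K = pk.build_rate_matrix(pk.default_scheme())
        times = log_time_grid(points_per_decade=5)
        a = pk.simulate_surface(K, spectra, times, excited_fraction=0.02).delta_a
        b = pk.simulate_surface(K, spectra, times, excited_fraction=0.04).delta_a
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)
        doubled = pk.SpeciesSpectra(
            spectra.wavelengths,
            {k: 2.0 * v for k, v in spectra.profiles.items()},
            2.0 * spectra.ground,
        )
        c = pk.simulate_surface(K, doubled, times, excited_fraction=0.02).delta_a
        np.testing.assert_allclose(c, 2.0 * a, rtol=1e-12)

    def test_missing_profile_rejected(self):
        wl = np.arange(400.0, 500.0, 10.0)
        spectra = pk.SpeciesSpectra(wl, {"A": np.ones_like(wl)}, np.ones_like(wl))
        K = pk.build_rate_matrix(two_state())
        with pytest.raises(ValueError, match="missing"):
            pk.simulate_surface(K, spectra, np.array([1.0]))
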