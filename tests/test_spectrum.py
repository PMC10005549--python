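import math

import numpy as np
import pytest

from ringexciton.couplings import coupling_pair
from ringexciton.geometry import (
    RingSpec,
    StackSpec,
    build_ring,
    build_stack,
    lh2_geometry,
    rotate_z,
)
from ringexciton.spectrum import (
    bloch_blocks,
    bloch_eigenmodes,
    canonical_m_values,
    cosine_band,
    effective_dipole_dicke,
    effective_hamiltonian,
    full_eigenmodes,
    light_line_m,
    mode_overlap,
    propagate_amplitudes,
    relative_phase_eta,
    symmetric_split,
)
from conftest import random_symmetric_array


def bloch_spectrum(array, **kw):
    return bloch_eigenmodes(bloch_blocks(array), **kw)


class TestCanonicalMSet:
    @pytest.mark.parametrize("N,expected", [
        (2, [0, 1]),
        (3, [-1, 0, 1]),
        (9, list(range(-4, 5))),
        (20, list(range(-9, 11))),
    ])
    def test_m_values(self, N, expected):
        assert canonical_m_values(N).tolist() == expected


class TestFullEigenmodes:
    def test_single_emitter(self):
        arr = build_ring(RingSpec(N=2, R=0.1))
        H = effective_hamiltonian(arr)[:1, :1]
        spec = full_eigenmodes(H)
        assert spec.shifts == pytest.approx([0.0])
        assert spec.rates == pytest.approx([1.0])

    def test_two_emitter_pair_matches_analytic_2x2(self):
        arr = build_ring(RingSpec(N=2, R=0.07))
        omega12, gamma12 = coupling_pair(
            arr.positions[0], arr.dipoles[0], arr.positions[1], arr.dipoles[1]
        )
        spec = full_eigenmodes(effective_hamiltonian(arr))
        assert sorted(spec.rates) == pytest.approx(
            sorted([1 + gamma12, 1 - gamma12]), abs=1e-12
        )
        assert sorted(spec.shifts) == pytest.approx(
            sorted([omega12, -omega12]), abs=1e-12
        )

    def test_zero_dissipation_gives_zero_rates(self):
        arr = build_ring(RingSpec(N=5, R=0.2))
        H = effective_hamiltonian(arr)
        H = H.real.astype(complex)  # strip -i*Gamma/2
        spec = full_eigenmodes(H)
        assert np.allclose(spec.rates, 0.0, atol=1e-12)

    def test_nonfinite_hamiltonian_rejected(self):
        with pytest.raises(ValueError):
            full_eigenmodes(np.array([[np.nan + 0j]]))


class TestBlochReduction:
    def test_two_point_dft(self):
        # N=2 single ring: block eigenvalues are G0 +- G1 exactly
        arr = build_ring(RingSpec(N=2, R=0.1, theta=0.3, phi=0.4))
        H = effective_hamiltonian(arr)
        blocks = {b.m: complex(b.gtilde[0, 0]) for b in bloch_blocks(arr)}
        g0, g1 = H[0, 0], H[0, 1]
        assert blocks[0] == pytest.approx(g0 + g1, rel=1e-14)
        assert blocks[1] == pytest.approx(g0 - g1, rel=1e-14)

    @pytest.mark.parametrize("geometry", [
        RingSpec(N=3, R=0.2, theta=1.0, phi=0.5),
        RingSpec(N=9, R=0.05),
        RingSpec(N=20, R=0.3, theta=math.pi / 2),
    ])
    def test_single_ring_bloch_equals_dense(self, geometry):
        arr = build_ring(geometry)
        dense = np.sort_complex(full_eigenmodes(effective_hamiltonian(arr)).eigenvalues)
        bloch = np.sort_complex(bloch_spectrum(arr).eigenvalues)
        assert np.allclose(dense, bloch, atol=1e-10)

    def test_double_ring_bloch_equals_dense(self, double_ring_transverse):
        arr = double_ring_transverse
        dense = np.sort_complex(full_eigenmodes(effective_hamiltonian(arr)).eigenvalues)
        bloch = np.sort_complex(bloch_spectrum(arr).eigenvalues)
        assert np.max(np.abs(dense - bloch)) < 1e-10

    def test_asymmetric_array_rejected(self, double_ring_transverse):
        arr = double_ring_transverse
        arr.positions[3, 0] += 1e-4  # break the 9-fold symmetry
        with pytest.raises(ValueError, match="symmetry"):
            bloch_blocks(arr)

    def test_dicke_ring_bright_mode_structure(self):
        # small N=20 ring: transverse -> single bright m=0 mode near N*Gamma0
        spec = bloch_spectrum(build_ring(RingSpec(N=20, R=0.05)))
        bright = spec.rates > 1.0
        assert bright.sum() == 1
        assert spec.m[bright].tolist() == [0]
        assert spec.rates[bright][0] == pytest.approx(20.0, rel=0.05)

    def test_rotation_invariance_of_spectrum(self, rng):
        arr = random_symmetric_array(rng)
        ref = np.sort_complex(bloch_spectrum(arr).eigenvalues)
        rot = np.sort_complex(bloch_spectrum(rotate_z(arr, 1.234)).eigenvalues)
        scale = max(1.0, float(np.abs(ref).max()))
        assert np.max(np.abs(ref - rot)) < 1e-9 * scale

    def test_trace_conservation_and_positivity(self, rng):
        for _ in range(20):
            arr = random_symmetric_array(rng)
            spec = bloch_spectrum(arr)
            scale = max(1.0, float(np.abs(spec.eigenvalues).max()))
            assert spec.rates.sum() == pytest.approx(arr.n_total, abs=1e-9 * scale)
            assert spec.rates.min() >= -1e-9 * scale

    def test_populations_normalized(self):
        spec = bloch_spectrum(lh2_geometry())
        assert np.allclose(spec.populations.sum(axis=1), 1.0, atol=1e-12)
        assert len(set(map(int, spec.m))) == 9
        assert spec.populations.shape[1] == 3


class TestSymmetricSplit:
    @pytest.fixture
    def splits(self, double_ring_transverse):
        return [symmetric_split(b) for b in bloch_blocks(double_ring_transverse)]

    def test_branch_rates_sum_to_twice_single_ring(self, splits):
        for s in splits:
            assert s["Gamma_sym"] + s["Gamma_asym"] == pytest.approx(
                2 * s["Gamma_m"], rel=1e-12
            )

    def test_antisymmetric_branch_always_darker(self, splits):
        for s in splits:
            assert s["Gamma_asym"] <= s["Gamma_sym"] + 1e-12

    def test_rejects_unequal_rings(self):
        r1 = RingSpec(N=9, R=0.05)
        r2 = RingSpec(N=9, R=0.045, z=0.02)
        arr = build_stack(StackSpec(rings=(r1, r2)))
        with pytest.raises(ValueError, match="identical"):
            symmetric_split(bloch_blocks(arr)[0])


class TestRelativePhase:
    def test_unrotated_identical_rings_phase_is_zero_or_pi(self, double_ring_transverse):
        # the inter-ring coupling keeps a small dissipative imaginary part,
        # so eta sits within ~Gamma12/(2*Omega12) of exactly 0 or pi; in the
        # Dicke regime the dispersive part dominates by >= 2 orders
        for b in bloch_blocks(double_ring_transverse):
            g12 = b.gtilde[0, 1]
            ratio = abs(g12.imag) / abs(g12.real)
            assert ratio < 0.02
            eta = relative_phase_eta(g12)
            assert min(abs(eta), abs(abs(eta) - math.pi)) <= ratio + 1e-12

    def test_half_cell_rotation_phase_near_half_pi(self):
        r1 = RingSpec(N=9, R=0.05)
        r2 = RingSpec(N=9, R=0.05, z=0.005, delta=math.pi / 9)
        arr = build_stack(StackSpec(rings=(r1, r2)))
        blk = {b.m: b for b in bloch_blocks(arr)}[4]
        assert abs(relative_phase_eta(blk.gtilde[0, 1])) == pytest.approx(
            math.pi / 2, abs=0.3
        )

    def test_zero_coupling_rejected(self):
        with pytest.raises(ValueError):
            relative_phase_eta(0.0)


class TestDickeClosedForms:
    def test_transverse_effective_dipole(self):
        ring = RingSpec(N=20, R=0.05)
        p0, g0 = effective_dipole_dicke(ring, 0)
        assert g0 == pytest.approx(20.0, rel=1e-12)
        assert np.allclose(p0, [0, 0, math.sqrt(20)], atol=1e-12)
        for m in (1, 5, 10):
            _, gm = effective_dipole_dicke(ring, m)
            assert gm == pytest.approx(0.0, abs=1e-12)

    def test_tangential_bright_pair(self):
        ring = RingSpec(N=20, R=0.05, theta=math.pi / 2)
        for m in (1, -1):
            _, gm = effective_dipole_dicke(ring, m)
            assert gm == pytest.approx(10.0, rel=1e-12)
        _, g0 = effective_dipole_dicke(ring, 0)
        assert g0 == pytest.approx(0.0, abs=1e-12)

    def test_effective_rate_approximates_exact_bloch_rate(self):
        ring = RingSpec(N=20, R=0.05)
        spec = bloch_spectrum(build_ring(ring))
        exact = float(spec.rates[spec.m == 0][0])
        _, approx = effective_dipole_dicke(ring, 0)
        assert approx == pytest.approx(exact, rel=0.05)

    def test_exact_rates_converge_to_dicke_forms_as_ring_shrinks(self):
        theta = 0.7
        prev_err = None
        for R in (0.05, 0.02, 0.01):
            ring = RingSpec(N=12, R=R, theta=theta)
            spec = bloch_spectrum(build_ring(ring))
            g0 = float(spec.rates[spec.m == 0][0])
            g1 = float(spec.rates[spec.m == 1][0])
            err = abs(g0 - 12 * math.cos(theta) ** 2) + abs(
                g1 - 6 * math.sin(theta) ** 2
            )
            if prev_err is not None:
                assert err < prev_err
            prev_err = err
        assert prev_err < 0.05


class TestCosineBand:
    def test_even_in_m_and_zero_sum(self):
        ring = RingSpec(N=20, R=0.05, theta=math.pi / 2)
        assert cosine_band(ring, 3) == pytest.approx(cosine_band(ring, -3), rel=1e-14)
        total = sum(cosine_band(ring, int(m)) for m in canonical_m_values(20))
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_band_edges_within_empirical_tolerance(self):
        # nearest-neighbour approximation captures the band edges of a
        # small tangential ring to ~20% (longer-range terms shift the
        # m=0 edge hardest)
        ring = RingSpec(N=20, R=0.05, theta=math.pi / 2)
        spec = bloch_spectrum(build_ring(ring))
        for m in (0, 10):
            exact = float(spec.shifts[(spec.m == m)][0])
            assert cosine_band(ring, m) == pytest.approx(exact, rel=0.20)


class TestLightLine:
    def test_value_is_N_times_lattice_constant(self):
        ring = RingSpec.from_lattice_constant(100, 1 / 3)
        assert light_line_m(ring) == pytest.approx(100 / 3, rel=1e-12)
        small = RingSpec.from_lattice_constant(20, 0.05)
        assert light_line_m(small) == pytest.approx(1.0, rel=1e-12)

    def test_large_ring_brightest_mode_near_light_line(self):
        # radial polarization: the brightest mode sits just below the
        # light line m0 = N d / lambda (the last radiant wavenumber)
        ring = RingSpec.from_lattice_constant(100, 1 / 3, theta=math.pi / 2, phi=math.pi / 2)
        spec = bloch_spectrum(build_ring(ring))
        m_brightest = abs(int(spec.m[np.argmax(spec.rates)]))
        m0 = light_line_m(ring)
        assert m0 - 4.0 <= m_brightest <= m0

    def test_guided_modes_require_subhalf_wavelength_spacing(self):
        # d < lambda/2: the darkest guided mode is exponentially suppressed
        # with N; d > lambda/2: no suppression with N at all
        def min_rate(N, d):
            s = bloch_spectrum(build_ring(RingSpec.from_lattice_constant(N, d)))
            return float(s.rates.min())

        assert min_rate(40, 1 / 3) / min_rate(20, 1 / 3) < 0.1
        assert min_rate(40, 0.6) / min_rate(20, 0.6) > 0.5


class TestModeOverlap:
    def test_overlaps_sum_to_one(self, double_ring_transverse, rng):
        v = rng.normal(size=18) + 1j * rng.normal(size=18)
        table = mode_overlap(v, double_ring_transverse)
        assert table[["symmetric", "antisymmetric"]].to_numpy().sum() == pytest.approx(1.0)

    def test_most_subradiant_mode_is_band_edge_antisymmetric(self, double_ring_transverse):
        spec = full_eigenmodes(effective_hamiltonian(double_ring_transverse))
        table = mode_overlap(spec.eigvecs[spec.most_subradiant()], double_ring_transverse)
        row = table.loc[table["antisymmetric"].idxmax()]
        assert row["abs_m"] == 4
        assert row["antisymmetric"] == pytest.approx(1.0, abs=1e-6)

    def test_dimension_mismatch_rejected(self, double_ring_transverse):
        with pytest.raises(ValueError):
            mode_overlap(np.ones(7), double_ring_transverse)


class TestPropagation:
    def test_single_emitter_exponential_decay(self):
        H = np.array([[-0.5j]])
        t = np.linspace(0, 5, 40)
        _, survival = propagate_amplitudes(H, np.array([1.0]), t)
        assert np.allclose(survival, np.exp(-t), rtol=1e-9)

    def test_hermitian_hamiltonian_conserves_norm(self, small_ring):
        H = effective_hamiltonian(small_ring).real.astype(complex)
        c0 = np.zeros(9, complex)
        c0[0] = 1.0
        _, survival = propagate_amplitudes(H, c0, np.linspace(0, 3, 30))
        assert np.allclose(survival, 1.0, atol=1e-9)

    def test_survival_probability_non_increasing(self, small_ring):
        H = effective_hamiltonian(small_ring)
        c0 = np.ones(9, complex) / 3.0
        _, survival = propagate_amplitudes(H, c0, np.linspace(0, 10, 100))
        assert np.all(np.diff(survival) <= 1e-12)
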