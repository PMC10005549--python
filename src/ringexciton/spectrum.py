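"""Collective mode spectra: dense diagonalization and Bloch-mode reduction.

In the single-excitation manifold the dynamics is governed by the
non-Hermitian effective Hamiltonian

    H_eff = diag(detunings) + Omega - i * Gamma / 2,

a complex symmetric matrix over all emitters.  Each right eigenvalue
``lam`` yields a collective mode with frequency shift ``Re(lam)`` and decay
rate ``-2 Im(lam)`` (both in Gamma0).

For an N-fold symmetric structure H_eff is block circulant over the N unit
cells, so the angular momentum ``m`` is a good quantum number: the full
spectrum is the union over the canonical m-set of the eigenvalues of the
n_cell x n_cell Bloch blocks

    Gtilde_m[alpha, beta] = sum_ell exp(i 2 pi m ell / N) * G_ell[alpha, beta],

where ``G_ell`` couples component alpha of cell 0 to component beta of cell
ell (with the on-site term ``detuning - i/2`` at ell = 0, alpha = beta).
This reduces an N*n_cell diagonalization to N small ones and attaches the
m label the dense path cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from ringexciton.couplings import coupling_matrices, coupling_pair
from ringexciton.geometry import EmitterArray, RingSpec, build_ring

__all__ = [
    "canonical_m_values",
    "effective_hamiltonian",
    "BlochBlock",
    "ModeSpectrum",
    "full_eigenmodes",
    "bloch_blocks",
    "bloch_eigenmodes",
    "symmetric_split",
    "relative_phase_eta",
    "effective_dipole_dicke",
    "cosine_band",
    "light_line_m",
    "mode_overlap",
    "propagate_amplitudes",
]


def canonical_m_values(N: int) -> np.ndarray:
    """Canonical angular momentum set: the N integers in (-N/2, N/2].

    For odd N this is 0, +-1, ..., +-(N-1)/2; for even N the unpaired
    boundary value N/2 is included once.
    """
    return np.arange(-((N - 1) // 2), N // 2 + 1)


def effective_hamiltonian(array: EmitterArray) -> np.ndarray:
    """Assemble H_eff = diag(detunings) + Omega - i*Gamma/2 for the array."""
    cm = coupling_matrices(array)
    H = cm.omega - 0.5j * cm.gamma
    H += np.diag(array.detunings.astype(complex))
    return H


@dataclass
class BlochBlock:
    """The n_cell x n_cell coupling block at angular momentum m."""

    m: int
    gtilde: np.ndarray  # complex (n_cell, n_cell) [Gamma0]


@dataclass
class ModeSpectrum:
    """Per-mode shifts, decay rates and unit-cell eigenvectors.

    ``m`` holds the angular momentum label where available (Bloch path) and
    is all-zero with ``has_m=False`` for dense diagonalization.  ``branch``
    indexes the n_cell branches at fixed m, sorted by increasing shift.
    Eigenvectors are unit-norm right eigenvectors; ``populations`` are the
    squared magnitudes of their components (summing to one), i.e. the
    excited-state occupation probability of each unit-cell component.
    """

    m: np.ndarray  # (n_modes,) int
    branch: np.ndarray  # (n_modes,) int
    shifts: np.ndarray  # (n_modes,) Re(eigenvalue) - reference [Gamma0]
    rates: np.ndarray  # (n_modes,) -2 Im(eigenvalue) [Gamma0]
    eigvecs: np.ndarray  # (n_modes, dim) complex, unit norm
    has_m: bool = True
    reference_detuning: float = 0.0

    @property
    def n_modes(self) -> int:
        return self.shifts.shape[0]

    @property
    def populations(self) -> np.ndarray:
        return np.abs(self.eigvecs) ** 2

    @property
    def eigenvalues(self) -> np.ndarray:
        """Complex eigenvalues (shift relative to reference) - i*rate/2."""
        return self.shifts - 0.5j * self.rates

    def most_subradiant(self) -> int:
        """Index of the global minimum decay rate.

        Ties (degenerate +-m pairs) are broken by smaller |m|, then by
        lower branch index, for deterministic reporting.
        """
        order = np.lexsort((self.branch, np.abs(self.m), np.round(self.rates, 12)))
        return int(order[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "m": self.m,
                "branch": self.branch,
                "Omega_over_Gamma0": self.shifts,
                "Gamma_over_Gamma0": self.rates,
            }
        )
        pops = self.populations
        for a in range(pops.shape[1]):
            df[f"pop_component_{a + 1}"] = pops[:, a]
        return df


def full_eigenmodes(H: np.ndarray, reference_detuning: float = 0.0) -> ModeSpectrum:
    """Dense right-eigendecomposition of the effective Hamiltonian.

    Modes are sorted by (decay rate ascending, then shift).  The m label is
    unavailable on this path (``has_m=False``); use the Bloch path for it.
    """
    H = np.asarray(H, dtype=complex)
    if not np.all(np.isfinite(H)):
        raise ValueError("Hamiltonian contains non-finite entries")
    lam, V = scipy.linalg.eig(H)
    shifts = lam.real - reference_detuning
    rates = -2.0 * lam.imag
    order = np.lexsort((shifts, rates))
    V = V[:, order]
    V = V / np.linalg.norm(V, axis=0)
    return ModeSpectrum(
        m=np.zeros(H.shape[0], dtype=int),
        branch=np.arange(H.shape[0]),
        shifts=shifts[order],
        rates=rates[order],
        eigvecs=V.T.copy(),
        has_m=False,
        reference_detuning=reference_detuning,
    )


def bloch_blocks(array: EmitterArray, tol: float = 1e-9) -> list[BlochBlock]:
    """Fourier-reduce H_eff of an N-fold symmetric array to its m-blocks.

    Verifies that the cell-resolved coupling depends only on the cell
    separation ell = j - i (block circulant structure) to within ``tol``
    relative to the largest coupling magnitude (deep-subwavelength
    geometries carry couplings of 1e6 Gamma0 and more, so an absolute
    tolerance would flag pure floating-point roundoff), raising with the
    worst offending pair otherwise.
    """
    N, nc = array.N, array.n_cell
    H = effective_hamiltonian(array)
    # reorder flat index (alpha*N + ell) -> tensor [alpha, ell, beta, ell']
    Ht = H.reshape(nc, N, nc, N)
    # C_ell[alpha, beta] = coupling of (cell 0, alpha) to (cell ell, beta)
    C = Ht[:, 0, :, :].transpose(2, 0, 1)  # (N, nc, nc)
    # circulant check: Ht[a, i, b, j] == C[(j - i) % N, a, b]
    i_idx = np.arange(N)
    shift = (i_idx[None, :] - i_idx[:, None]) % N  # shift[i, j] = (j-i)%N
    expected = C[shift].transpose(2, 0, 3, 1)  # (nc, N, nc, N)
    dev = np.abs(Ht - expected)
    worst = float(dev.max())
    scale = max(1.0, float(np.max(np.abs(C))))
    if worst > tol * scale:
        a, i, b, j = np.unravel_index(int(dev.argmax()), dev.shape)
        raise ValueError(
            "array violates the N-fold symmetry of the couplings: "
            f"|H[{a},{i};{b},{j}] - C_(j-i)| = {worst:.3e} > "
            f"{tol:.1e} x scale {scale:.3e}"
        )
    ms = canonical_m_values(N)
    ell = np.arange(N)
    phases = np.exp(2j * np.pi * np.outer(ms, ell) / N)  # (N_m, N)
    gt = np.tensordot(phases, C, axes=(1, 0))  # (N_m, nc, nc)
    return [BlochBlock(m=int(m), gtilde=gt[k]) for k, m in enumerate(ms)]


def bloch_eigenmodes(
    blocks: list[BlochBlock], reference_detuning: float = 0.0
) -> ModeSpectrum:
    """Diagonalize every Bloch block and collect the labelled spectrum.

    Within each m the n_cell branches are sorted by increasing frequency
    shift.  Component populations are the squared magnitudes of the
    normalized unit-cell eigenvector (the per-ring occupation probability
    of the mode).
    """
    m_out, branch_out, shifts, rates, vecs = [], [], [], [], []
    for blk in blocks:
        lam, V = np.linalg.eig(blk.gtilde)
        order = np.argsort(lam.real)
        lam = lam[order]
        V = V[:, order]
        V = V / np.linalg.norm(V, axis=0)
        for b in range(lam.size):
            m_out.append(blk.m)
            branch_out.append(b)
            shifts.append(lam[b].real - reference_detuning)
            rates.append(-2.0 * lam[b].imag)
            vecs.append(V[:, b])
    return ModeSpectrum(
        m=np.array(m_out),
        branch=np.array(branch_out),
        shifts=np.array(shifts),
        rates=np.array(rates),
        eigvecs=np.array(vecs),
        has_m=True,
        reference_detuning=reference_detuning,
    )


def symmetric_split(block: BlochBlock, tol: float = 1e-9) -> dict:
    """Symmetric/antisymmetric branches of two identical unrotated rings.

    For equal rings at delta = 0 the 2x2 Bloch block is complex symmetric
    with equal diagonals g_m, so the eigenmodes are the fixed superpositions
    (|m,1> +- |m,2>)/sqrt(2) with eigenvalues g_m +- Gtilde_m12.  Returns
    the single-ring shift/rate (Omega_m, Gamma_m), the inter-ring couplings
    Omega_m_inter = Re Gtilde_m12 and Gamma_m_inter = -2 Im Gtilde_m12, and
    both branches.
    """
    g = block.gtilde
    if g.shape != (2, 2):
        raise ValueError("symmetric split requires a two-ring (2x2) block")
    if abs(g[0, 0] - g[1, 1]) > tol or abs(g[0, 1] - g[1, 0]) > tol:
        raise ValueError(
            "block is not complex symmetric with equal diagonals; the rings "
            "are not identical unrotated copies"
        )
    gm = g[0, 0]
    c = g[0, 1]
    omega_m, gamma_m = gm.real, -2.0 * gm.imag
    omega_inter, gamma_inter = c.real, -2.0 * c.imag
    lam_sym = gm + c
    lam_asym = gm - c
    isq = 1.0 / np.sqrt(2.0)
    return {
        "m": block.m,
        "Omega_m": omega_m,
        "Gamma_m": gamma_m,
        "Omega_inter": omega_inter,
        "Gamma_inter": gamma_inter,
        "Omega_sym": lam_sym.real,
        "Gamma_sym": -2.0 * lam_sym.imag,
        "Omega_asym": lam_asym.real,
        "Gamma_asym": -2.0 * lam_asym.imag,
        "state_sym": np.array([isq, isq]),
        "state_asym": np.array([isq, -isq]),
    }


def relative_phase_eta(g12: complex) -> float:
    """Relative phase eta of the two-ring superposition (|m,1> + e^{i eta}|m,2>).

    Defined from the off-diagonal Bloch coupling as
    eta = atan2(Im Gtilde_m12, Re Gtilde_m12), in (-pi, pi].  Undefined
    (raises) when the inter-ring coupling vanishes.
    """
    g12 = complex(g12)
    if g12 == 0:
        raise ValueError("relative phase undefined: inter-ring coupling is zero")
    return float(np.arctan2(g12.imag, g12.real))


def effective_dipole_dicke(ring: RingSpec, m: int) -> tuple[np.ndarray, float]:
    """Dicke-limit effective dipole moment and bright-mode decay rate.

    For a ring much smaller than lambda the emitters radiate as one point
    dipole per Bloch mode,

        p_eff = N^{-1/2} sum_ell exp(i 2 pi m ell / N) p_hat_ell,
        Gamma_m = |p_eff|^2 * Gamma0.

    Transverse polarization concentrates all oscillator strength in m=0
    (|p_eff|^2 = N); tangential/radial in m = +-1 (|p_eff|^2 = N/2); all
    other modes are dark in this limit.
    """
    arr = build_ring(ring)
    ell = np.arange(ring.N)
    phases = np.exp(2j * np.pi * m * ell / ring.N)
    p_eff = (phases[:, None] * arr.dipoles).sum(axis=0) / np.sqrt(ring.N)
    gamma_m = float(np.sum(np.abs(p_eff) ** 2))
    return p_eff, gamma_m


def cosine_band(ring: RingSpec, m: int) -> float:
    """Nearest-neighbour cosine approximation of the single-ring band.

    In the small-ring regime the coherent coupling is dominated by first
    neighbours, giving Omega_m ~ 2 * Omega_d * cos(2 pi m / N) where
    Omega_d is the nearest-neighbour coherent coupling (computed exactly
    from the Green's tensor, not from a closed-form fit).
    """
    arr = build_ring(ring)
    omega_d, _ = coupling_pair(
        arr.positions[0], arr.dipoles[0], arr.positions[1], arr.dipoles[1]
    )
    return 2.0 * omega_d * float(np.cos(2.0 * np.pi * m / ring.N))


def light_line_m(ring: RingSpec) -> float:
    """Angular momentum of the light line, m0 = N d / lambda.

    Modes with m >~ m0 are guided (evanescent transverse field, strongly
    subradiant); m <~ m0 are radiant.  Guided modes require d < lambda/2.
    """
    return ring.N * ring.d


def mode_overlap(eigvec: np.ndarray, array: EmitterArray) -> pd.DataFrame:
    """Decompose a dense two-ring eigenvector over (|m|, parity) Bloch waves.

    Projects onto the orthonormal states (|m,1> +- |m,2>)/sqrt(2) built from
    the ring Bloch waves, combining +m and -m into |m|.  Returns a frame
    with columns ``abs_m``, ``symmetric``, ``antisymmetric``; all entries
    sum to one for a normalized input vector.
    """
    if array.n_cell != 2:
        raise ValueError("mode_overlap requires a two-ring array")
    N = array.N
    v = np.asarray(eigvec, dtype=complex)
    if v.shape != (2 * N,):
        raise ValueError(f"eigenvector length {v.shape} does not match 2N={2 * N}")
    v = v / np.linalg.norm(v)
    ms = canonical_m_values(N)
    ell = np.arange(N)
    rows: dict[int, dict[str, float]] = {}
    for m in ms:
        bloch = np.exp(2j * np.pi * m * ell / N) / np.sqrt(N)
        for parity, sign in (("symmetric", 1.0), ("antisymmetric", -1.0)):
            basis = np.concatenate([bloch, sign * bloch]) / np.sqrt(2.0)
            w = float(np.abs(basis.conj() @ v) ** 2)
            rec = rows.setdefault(int(abs(m)), {"symmetric": 0.0, "antisymmetric": 0.0})
            rec[parity] += w
    df = pd.DataFrame(
        [
            {"abs_m": k, "symmetric": r["symmetric"], "antisymmetric": r["antisymmetric"]}
            for k, r in sorted(rows.items())
        ]
    )
    return df


def propagate_amplitudes(
    H: np.ndarray, c0: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Single-excitation amplitude dynamics under dc/dt = -i H c.

    Solved exactly through the eigendecomposition of H (small dense
    systems).  Returns the amplitude trajectories, shape (n_times, n), and
    the survival probability ||c(t)||^2, which is non-increasing whenever
    the dissipative matrix is positive semidefinite.
    """
    H = np.asarray(H, dtype=complex)
    if not np.all(np.isfinite(H)):
        raise ValueError("Hamiltonian contains non-finite entries")
    c0 = np.asarray(c0, dtype=complex)
    times = np.asarray(times, dtype=float)
    lam, V = scipy.linalg.eig(H)
    coef = np.linalg.solve(V, c0)
    phases = np.exp(-1j * np.outer(times, lam))
    traj = phases * coef[None, :] @ V.T
    survival = np.sum(np.abs(traj) ** 2, axis=1)
    return traj, survival
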