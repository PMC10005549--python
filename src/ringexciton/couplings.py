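"""Free-space dyadic Green's tensor and dipole-dipole coupling matrices.

Two emitters at separation r with unit dipole orientations p_i, p_j couple
through the vacuum field with a coherent (dispersive) part Omega_ij and a
dissipative part Gamma_ij,

    Omega_ij = -(3*pi*Gamma0/k0) Re[ p_i . G(r, w0) . p_j ],
    Gamma_ij =  (6*pi*Gamma0/k0) Im[ p_i . G(r, w0) . p_j ],

with the free-space dyadic Green's tensor at the transition frequency

    G(r) = e^{i k0 r} / (4 pi k0^2 r^3) * [ (k0^2 r^2 + i k0 r - 1) I
           - (k0^2 r^2 + 3 i k0 r - 3) (r x r^T) / r^2 ].

Everything is expressed in natural units: lengths in lambda (k0 = 2*pi) and
rates in the single-emitter decay rate Gamma0 = 1.

Numerical note: the imaginary part of the projected tensor is an O(x^3)
difference of O(x) oscillatory terms at small x = k0 r, which loses digits
to cancellation exactly in the deep-subwavelength (Dicke / light-harvesting)
regime.  Below a configurable threshold the scalar combinations are
therefore evaluated from their Taylor series instead of from sin/cos.
"""

from __future__ import annotations

import numpy as np

from ringexciton.geometry import EmitterArray

__all__ = [
    "K0",
    "green_tensor",
    "coupling_pair",
    "coupling_matrices",
    "CouplingMatrices",
    "gamma_scalars_series",
    "SMALL_X_THRESHOLD",
]

#: Wavenumber of the transition in lambda units.
K0 = 2.0 * np.pi

#: Below this value of x = k0*r the dissipative scalars switch to series.
SMALL_X_THRESHOLD = 1e-2

# sinc-like combinations entering Im[p.G.p]:
#   h(x) = sin(x)/x
#   g(x) = (sin(x) - x cos(x)) / x^3
# Both are O(1) with no cancellation when summed from their Taylor series.
_SERIES_TERMS = 12


def _h_series(x: np.ndarray) -> np.ndarray:
    # sin(x)/x = sum_k (-1)^k x^(2k) / (2k+1)!
    out = np.zeros_like(x)
    term = np.ones_like(x)
    out += term
    x2 = x * x
    for k in range(1, _SERIES_TERMS):
        term = term * (-x2) / ((2 * k) * (2 * k + 1))
        out += term
    return out


def _g_series(x: np.ndarray) -> np.ndarray:
    # (sin x - x cos x)/x^3 = sum_k (-1)^k (2k+2) x^(2k) / (2k+3)!
    out = np.zeros_like(x)
    x2 = x * x
    term = np.full_like(x, 1.0 / 3.0)  # k = 0
    out += term
    for k in range(1, _SERIES_TERMS):
        term = term * (-x2) * (2 * k + 2) / ((2 * k) * (2 * k + 2) * (2 * k + 3))
        out += term
    return out


def gamma_scalars_series(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Series evaluation of the two dissipative scalars.

    Returns ``(ImF1, ImF2)`` where ``ImF1 = sin x/x + cos x/x^2 - sin x/x^3``
    multiplies the identity part of the tensor and ``ImF2 = sin x/x
    + 3 cos x/x^2 - 3 sin x/x^3`` the longitudinal part.  Valid for
    ``|x| <~ 1``; used below :data:`SMALL_X_THRESHOLD` and as an independent
    cross-check of the direct evaluation in tests.
    """
    x = np.asarray(x, dtype=float)
    h = _h_series(x)
    g = _g_series(x)
    return h - g, h - 3.0 * g


def _gamma_scalars_direct(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s, c = np.sin(x), np.cos(x)
    g = (s - x * c) / x**3
    h = s / x
    return h - g, h - 3.0 * g


def _omega_scalars(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Re F1 = cos x/x - sin x/x^2 - cos x/x^3 ; Re F2 with factors 3.
    # Dominated by the 1/x^3 term at small x: no cancellation issue.
    s, c = np.sin(x), np.cos(x)
    re1 = c / x - s / x**2 - c / x**3
    re2 = c / x - 3.0 * s / x**2 - 3.0 * c / x**3
    return re1, re2


def green_tensor(r: np.ndarray, k0: float = K0) -> np.ndarray:
    """Free-space dyadic Green's tensor G(r, w0) at separation ``r``.

    Symmetric (G = G^T) and even in r (G(-r) = G(r)).  Raises for zero
    separation; self-interaction is handled by the Gamma0 diagonal
    convention of :func:`coupling_matrices`.
    """
    r = np.asarray(r, dtype=float)
    rn = np.linalg.norm(r)
    if rn == 0.0:
        raise ValueError("Green's tensor diverges at zero separation")
    x = k0 * rn
    rr = np.outer(r, r) / rn**2
    pref = np.exp(1j * x) / (4.0 * np.pi * k0**2 * rn**3)
    return pref * ((x**2 + 1j * x - 1.0) * np.eye(3) - (x**2 + 3j * x - 3.0) * rr)


def coupling_pair(
    ri: np.ndarray,
    pi: np.ndarray,
    rj: np.ndarray,
    pj: np.ndarray,
    small_x_threshold: float = SMALL_X_THRESHOLD,
) -> tuple[float, float]:
    """Coherent and dissipative couplings (Omega_ij, Gamma_ij) of one pair.

    ``pi``/``pj`` must be real unit vectors; complex polarization is not
    supported.  Symmetric under exchange of the two emitters.
    """
    pi = np.asarray(pi)
    pj = np.asarray(pj)
    if np.iscomplexobj(pi) or np.iscomplexobj(pj):
        raise ValueError("complex dipole polarizations are not supported")
    r = np.asarray(ri, dtype=float) - np.asarray(rj, dtype=float)
    rn = np.linalg.norm(r)
    if rn == 0.0:
        raise ValueError("coupling undefined for coincident emitters")
    x = np.array(K0 * rn)
    a = float(pi @ pj)
    b = float((pi @ r) * (pj @ r)) / rn**2
    re1, re2 = _omega_scalars(x)
    if x < small_x_threshold:
        im1, im2 = gamma_scalars_series(x)
    else:
        im1, im2 = _gamma_scalars_direct(x)
    omega = -0.75 * (a * re1 - b * re2)
    gamma = 1.5 * (a * im1 - b * im2)
    return float(omega), float(gamma)


class CouplingMatrices:
    """Dense coherent/dissipative coupling matrices of an emitter array.

    ``omega`` is real symmetric with zero diagonal; ``gamma`` is real
    symmetric with Gamma0 on the diagonal and is positive semidefinite up
    to numerical noise (its eigenvalues are the emission rates into the
    orthogonal radiation channels).
    """

    def __init__(self, omega: np.ndarray, gamma: np.ndarray):
        self.omega = omega
        self.gamma = gamma

    @property
    def n_total(self) -> int:
        return self.omega.shape[0]


def coupling_matrices(
    array: EmitterArray, small_x_threshold: float = SMALL_X_THRESHOLD
) -> CouplingMatrices:
    """Assemble Omega and Gamma over all emitter pairs (vectorised).

    Diagonal convention: Omega_ii = 0 (the Lamb shift is absorbed into the
    transition frequency), Gamma_ii = Gamma0.
    """
    pos = array.positions
    dip = array.dipoles
    n = array.n_total
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.min(dist[off]) <= 0.0:
        i, j = divmod(int(np.argmin(np.where(off, dist, np.inf))), n)
        raise ValueError(f"emitters {i} and {j} coincide; couplings diverge")

    x = K0 * np.where(off, dist, 1.0)
    a = dip @ dip.T
    rhat = diff / np.where(off, dist, 1.0)[:, :, None]
    proj = np.einsum("ik,ijk->ij", dip, rhat)  # p_i . rhat_ij
    projT = np.einsum("jk,ijk->ij", dip, rhat)  # p_j . rhat_ij
    b = proj * projT

    re1, re2 = _omega_scalars(x)
    im1d, im2d = _gamma_scalars_direct(x)
    im1s, im2s = gamma_scalars_series(x)
    small = x < small_x_threshold
    im1 = np.where(small, im1s, im1d)
    im2 = np.where(small, im2s, im2d)

    omega = -0.75 * (a * re1 - b * re2)
    gamma = 1.5 * (a * im1 - b * im2)
    omega[~off] = 0.0
    gamma[~off] = 1.0
    # enforce exact symmetry (guards against last-bit asymmetry in einsum)
    omega = 0.5 * (omega + omega.T)
    gamma = 0.5 * (gamma + gamma.T)
    return CouplingMatrices(omega=omega, gamma=gamma)
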