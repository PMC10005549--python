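"""Construction of N-fold symmetric ring and multi-ring emitter arrays.

A single ring of ``N`` emitters of radius ``R`` (in units of the transition
wavelength lambda) places emitter ``i`` at azimuth ``gamma_i = 2*pi*i/N +
delta``.  The transition dipole of each emitter is specified by a polar
angle ``theta`` (measured from the vertical axis) and an azimuth ``phi`` in
the local frame spanned by the tangential unit vector ``e_phi``, the radial
unit vector ``e_r`` and the vertical ``e_z``:

    p_hat = sin(theta) cos(phi) e_phi + sin(theta) sin(phi) e_r
            + cos(theta) e_z

so ``theta = 0`` is transverse (out-of-plane) polarization, ``theta = pi/2,
phi = 0`` is tangential and ``theta = pi/2, phi = pi/2`` is radial.

Several rings sharing one ``N`` may be stacked concentrically; the combined
structure retains the N-fold rotational symmetry and is organised into
``N`` unit cells of ``n_cell`` components (one site of each ring per cell),
the labelling used by the Bloch-mode reduction in :mod:`ringexciton.spectrum`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RingSpec",
    "StackSpec",
    "EmitterArray",
    "build_ring",
    "build_stack",
    "lh2_geometry",
    "lh2_default_params",
    "scale_geometry",
    "rotate_z",
    "check_n_fold_symmetry",
    "polarization_angles",
]

#: Named dipole orientations used throughout: (theta, phi).
POLARIZATIONS = {
    "transverse": (0.0, 0.0),
    "tangential": (math.pi / 2, 0.0),
    "radial": (math.pi / 2, math.pi / 2),
}


def polarization_angles(name: str) -> tuple[float, float]:
    """Return (theta, phi) for a named polarization direction."""
    try:
        return POLARIZATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown polarization {name!r}; choose from {sorted(POLARIZATIONS)}"
        ) from None


@dataclass(frozen=True)
class RingSpec:
    """Parameters of a single N-emitter ring.

    Attributes
    ----------
    N : int
        Number of emitters (>= 2).
    R : float
        Ring radius in units of lambda.
    z : float
        Vertical offset of the ring plane [lambda].
    delta : float
        Rigid rotation of the ring about the z-axis [rad], in [0, 2*pi/N).
    theta, phi : float
        Dipole polar/azimuth angles [rad] in the local (e_phi, e_r, e_z)
        frame.
    detuning : float
        On-site transition-frequency offset [Gamma0].
    """

    N: int
    R: float
    z: float = 0.0
    delta: float = 0.0
    theta: float = 0.0
    phi: float = 0.0
    detuning: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.R, self.z, self.delta, self.theta, self.phi, self.detuning)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("ring parameters must be finite")
        if self.N < 2:
            raise ValueError(f"need at least 2 emitters per ring, got N={self.N}")
        if self.R <= 0:
            raise ValueError(f"ring radius must be positive, got R={self.R}")
        if not (0.0 <= self.delta < 2 * math.pi / self.N):
            raise ValueError(
                f"delta={self.delta} outside [0, 2*pi/N={2 * math.pi / self.N:.6f})"
            )

    @property
    def d(self) -> float:
        """Lattice constant: chord distance between neighbouring emitters."""
        return 2.0 * self.R * math.sin(math.pi / self.N)

    @classmethod
    def from_lattice_constant(cls, N: int, d: float, **kwargs) -> "RingSpec":
        """Build a spec from the lattice constant d instead of the radius."""
        if d <= 0:
            raise ValueError(f"lattice constant must be positive, got d={d}")
        return cls(N=N, R=d / (2.0 * math.sin(math.pi / N)), **kwargs)


@dataclass(frozen=True)
class StackSpec:
    """Ordered collection of concentric rings sharing one N."""

    rings: tuple[RingSpec, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rings = tuple(self.rings)
        object.__setattr__(self, "rings", rings)
        if not rings:
            raise ValueError("a stack needs at least one ring")
        N = rings[0].N
        if any(r.N != N for r in rings):
            raise ValueError(
                "all rings in a stack must share the same N "
                f"(got {[r.N for r in rings]}); the N-fold symmetry reduction "
                "is otherwise invalid"
            )
        labels = tuple(self.labels) or tuple(f"ring{i + 1}" for i in range(len(rings)))
        if len(labels) != len(rings):
            raise ValueError("one label per ring required")
        object.__setattr__(self, "labels", labels)

    @property
    def N(self) -> int:
        return self.rings[0].N


@dataclass
class EmitterArray:
    """Positions, dipole orientations and detunings of all emitters.

    Emitters are stored component-major: index ``alpha * N + ell`` holds the
    site of ring/component ``alpha`` in unit cell ``ell``.  ``cell_index``
    and ``component_index`` make the labelling explicit.
    """

    positions: np.ndarray  # (n, 3) [lambda]
    dipoles: np.ndarray  # (n, 3) real unit vectors
    detunings: np.ndarray  # (n,) [Gamma0]
    N: int  # fold of the rotational symmetry
    n_cell: int  # components per unit cell
    cell_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    component_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        self.detunings = np.asarray(self.detunings, dtype=float)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.dipoles.shape != (n, 3):
            raise ValueError("positions and dipoles must be (n, 3) arrays")
        if self.detunings.shape != (n,):
            raise ValueError("detunings must be a length-n vector")
        if n != self.N * self.n_cell:
            raise ValueError(
                f"{n} emitters inconsistent with N={self.N} x n_cell={self.n_cell}"
            )
        norms = np.linalg.norm(self.dipoles, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("dipole orientations must be unit vectors (1e-12)")
        if self.cell_index is None:
            self.cell_index = np.tile(np.arange(self.N), self.n_cell)
        if self.component_index is None:
            self.component_index = np.repeat(np.arange(1, self.n_cell + 1), self.N)
        self.cell_index = np.asarray(self.cell_index, dtype=int)
        self.component_index = np.asarray(self.component_index, dtype=int)
        if not self.labels:
            self.labels = tuple(f"ring{a + 1}" for a in range(self.n_cell))
        # reject coincident emitters early: couplings diverge there
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if np.min(dist) <= 0.0:
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            raise ValueError(f"emitters {i} and {j} coincide")

    @property
    def n_total(self) -> int:
        return self.positions.shape[0]

    def index_of(self, cell: int, component: int) -> int:
        """Flat emitter index of component ``component`` (1-based) in ``cell``."""
        return (component - 1) * self.N + (cell % self.N)

    def pairwise_distances(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_ring(spec: RingSpec) -> EmitterArray:
    """Construct a single ring per its spec.

    Emitter ``i`` sits at azimuth ``gamma_i = 2*pi*i/N + delta`` with dipole
    expressed in its local tangential/radial/vertical frame.
    """
    i = np.arange(spec.N)
    gamma = 2.0 * math.pi * i / spec.N + spec.delta
    cg, sg = np.cos(gamma), np.sin(gamma)
    positions = np.column_stack([spec.R * cg, spec.R * sg, np.full(spec.N, spec.z)])
    e_r = np.column_stack([cg, sg, np.zeros(spec.N)])
    e_phi = np.column_stack([-sg, cg, np.zeros(spec.N)])
    e_z = np.array([0.0, 0.0, 1.0])
    st, ct = math.sin(spec.theta), math.cos(spec.theta)
    cp, sp = math.cos(spec.phi), math.sin(spec.phi)
    dipoles = st * cp * e_phi + st * sp * e_r + ct * e_z
    dipoles /= np.linalg.norm(dipoles, axis=1)[:, None]
    return EmitterArray(
        positions=positions,
        dipoles=dipoles,
        detunings=np.full(spec.N, spec.detuning),
        N=spec.N,
        n_cell=1,
    )


def build_stack(spec: StackSpec) -> EmitterArray:
    """Concatenate concentric rings into one array with shared unit cells.

    Component ``alpha`` enumerates the rings; cell ``ell`` collects emitter
    ``ell`` of every ring, so the 2*pi/N rotation maps cell ``ell`` to
    ``ell+1`` for the whole structure.
    """
    arrays = [build_ring(r) for r in spec.rings]
    out = EmitterArray(
        positions=np.concatenate([a.positions for a in arrays]),
        dipoles=np.concatenate([a.dipoles for a in arrays]),
        detunings=np.concatenate([a.detunings for a in arrays]),
        N=spec.N,
        n_cell=len(spec.rings),
        labels=spec.labels,
    )
    check_n_fold_symmetry(out)
    return out


def scale_geometry(array: EmitterArray, alpha: float) -> EmitterArray:
    """Uniformly rescale the structure: positions -> alpha * positions.

    Radii, lattice constants and vertical offsets all scale by ``alpha``;
    dipole orientations and detunings are unchanged.
    """
    if not (alpha > 0 and math.isfinite(alpha)):
        raise ValueError(f"scale factor must be positive and finite, got {alpha}")
    return EmitterArray(
        positions=alpha * array.positions,
        dipoles=array.dipoles.copy(),
        detunings=array.detunings.copy(),
        N=array.N,
        n_cell=array.n_cell,
        cell_index=array.cell_index.copy(),
        component_index=array.component_index.copy(),
        labels=array.labels,
    )


def rotate_z(array: EmitterArray, angle: float) -> EmitterArray:
    """Rigidly rotate the whole array about the z-axis (spectra invariant)."""
    U = _rotation_z(angle)
    return EmitterArray(
        positions=array.positions @ U.T,
        dipoles=array.dipoles @ U.T,
        detunings=array.detunings.copy(),
        N=array.N,
        n_cell=array.n_cell,
        cell_index=array.cell_index.copy(),
        component_index=array.component_index.copy(),
        labels=array.labels,
    )


def check_n_fold_symmetry(array: EmitterArray, tol: float = 1e-10) -> None:
    """Verify the defining invariant of an N-fold symmetric array.

    Rotating all positions and dipoles by 2*pi/N about z must reproduce the
    array with cell index ell -> ell+1 (mod N), identical detunings.
    Raises ``ValueError`` reporting the worst offender otherwise.
    """
    U = _rotation_z(2.0 * math.pi / array.N)
    rot_pos = array.positions @ U.T
    rot_dip = array.dipoles @ U.T
    # target index of (cell ell, comp alpha) after rotation is (ell+1, alpha)
    perm = np.empty(array.n_total, dtype=int)
    for k in range(array.n_total):
        alpha = array.component_index[k]
        ell = array.cell_index[k]
        perm[k] = array.index_of(ell + 1, alpha)
    err_pos = np.max(np.abs(rot_pos - array.positions[perm]))
    err_dip = np.max(np.abs(rot_dip - array.dipoles[perm]))
    err_det = np.max(np.abs(array.detunings - array.detunings[perm]))
    err = max(err_pos, err_dip, err_det)
    if err > tol:
        raise ValueError(
            f"array is not N-fold symmetric: worst deviation {err:.3e} > {tol:.1e} "
            "under the 2*pi/N rotation"
        )


# --------------------------------------------------------------------------
# LH2-like three-ring motif
# --------------------------------------------------------------------------

def lh2_default_params() -> dict:
    """Approximate (synthetic) structural parameters of the LH2 motif.

    The LH2 antenna of purple bacteria hosts 18 B850 bacteriochlorophylls
    arranged as a two-component ring of 9-fold symmetry, plus a concentric
    9-emitter B800 ring that is blue-shifted (it absorbs at a shorter
    wavelength) and vertically displaced.  The numbers below are an
    explicitly approximate stand-in patterned on the published crystal
    structure scale (B850 radius ~2.6 nm, B800 radius ~3.1 nm, plane
    separation ~1.7 nm, transition wavelength ~850 nm, single-emitter decay
    rate Gamma ~ tens of MHz): they reproduce the qualitative three-band
    structure but are not the crystallographic values.

    Lengths are in lambda; detunings in Gamma0.  The B800 detuning of 1e7
    matches the order of magnitude of the 800 nm vs 850 nm transition
    difference expressed in units of the emitter linewidth.
    """
    return {
        "N": 9,
        "b850a": {
            "R": 0.00306,
            "z": 0.0,
            "delta": 0.0,
            "theta": 1.70,  # mostly in-plane, small downward vertical tilt
            "phi": 0.10,
            "detuning": 0.0,
        },
        "b850b": {
            "R": 0.00306,
            "z": 0.0004,
            "delta": 0.349,  # ~pi/9: sites near the midpoints of the partner ring
            "theta": 1.45,  # small upward tilt
            "phi": -0.10,
            "detuning": 0.0,
        },
        "b800": {
            "R": 0.00365,
            "z": 0.0020,
            "delta": 0.175,
            "theta": 1.40,
            "phi": 0.30,
            "detuning": 1.0e7,
        },
    }


def lh2_geometry(params: dict | None = None) -> EmitterArray:
    """Build the 27-emitter, 9-fold symmetric LH2-like array.

    ``params`` follows :func:`lh2_default_params`: a shared ``N`` and one
    sub-dict per component (two B850 components and the B800 ring), each
    with keys ``R, z, delta, theta, phi, detuning``.
    """
    p = lh2_default_params() if params is None else params
    N = p["N"]
    names = ("b850a", "b850b", "b800")
    missing = [k for k in names if k not in p]
    if missing:
        raise ValueError(f"LH2 parameter set missing components: {missing}")
    rings = tuple(RingSpec(N=N, **p[name]) for name in names)
    spec = StackSpec(rings=rings, labels=("B850a", "B850b", "B800"))
    array = build_stack(spec)  # build_stack validates the 9-fold symmetry
    return array
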