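"""Scattered electromagnetic field of collective modes.

Once the per-emitter coherences c_i of a mode are known, the positive
frequency component of the scattered field follows from the input-output
relation

    E+(r) = sum_i G(r - r_i, w0) . p_hat_i c_i,

with the field prefactor |p| k0^2 / eps0 set to one: the figures of merit
are intensity patterns, not absolute radiometric scales.  Grid points
closer than an exclusion radius to any emitter are masked (the Green's
tensor diverges there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ringexciton.couplings import K0
from ringexciton.geometry import EmitterArray

__all__ = [
    "FieldGrid",
    "scattered_field",
    "intensity_cut",
    "bloch_mode_amplitudes",
    "DEFAULT_EXCLUSION_RADIUS",
]

#: Default radius [lambda] around each emitter inside which grid points are masked.
DEFAULT_EXCLUSION_RADIUS = 0.02


@dataclass
class FieldGrid:
    """Complex field samples E+(r) on a set of points.

    ``values`` holds the complex 3-vector field at each point (arbitrary
    units); ``mask`` is True where the point was excluded for sitting
    within the exclusion radius of an emitter (values there are zero).
    """

    points: np.ndarray  # (n_pts, 3) [lambda]
    values: np.ndarray  # (n_pts, 3) complex
    mask: np.ndarray  # (n_pts,) bool, True = excluded
    shape: tuple | None = None  # original 2-D grid shape for plane cuts
    axes: tuple | None = None  # (axis1 coords, axis2 coords) for plane cuts

    @property
    def intensity(self) -> np.ndarray:
        """|E|^2 summed over Cartesian components; NaN on masked points."""
        inten = np.sum(np.abs(self.values) ** 2, axis=-1)
        out = np.where(self.mask, np.nan, inten)
        return out.reshape(self.shape) if self.shape is not None else out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["x", "y", "z"])
        for k, ax in enumerate("xyz"):
            df[f"E{ax}_re"] = self.values[:, k].real
            df[f"E{ax}_im"] = self.values[:, k].imag
        inten = np.sum(np.abs(self.values) ** 2, axis=-1)
        df["intensity"] = np.where(self.mask, np.nan, inten)
        return df


def scattered_field(
    array: EmitterArray,
    amplitudes: np.ndarray,
    grid: np.ndarray,
    r_excl: float = DEFAULT_EXCLUSION_RADIUS,
) -> FieldGrid:
    """Superpose the Green's-tensor field of every emitter on the grid.

    ``amplitudes`` are the per-emitter coherences (mode components);
    ``grid`` is an (n_pts, 3) array of observation points in lambda units.
    The field is linear in the amplitudes.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty field grid")
    if grid.shape[1] != 3:
        raise ValueError("grid must be (n_pts, 3)")
    amplitudes = np.asarray(amplitudes, dtype=complex)
    if amplitudes.shape != (array.n_total,):
        raise ValueError(
            f"need one amplitude per emitter ({array.n_total}), got {amplitudes.shape}"
        )
    # displacement of every grid point from every emitter: (n_pts, n_em, 3)
    diff = grid[:, None, :] - array.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    mask = np.any(dist < r_excl, axis=1)

    safe = np.where(dist > 0, dist, 1.0)
    x = K0 * safe
    rhat = diff / safe[..., None]
    pref = np.exp(1j * x) / (4.0 * np.pi * K0**2 * safe**3)
    c1 = pref * (x**2 + 1j * x - 1.0)  # multiplies p_i
    c2 = pref * (x**2 + 3j * x - 3.0)  # multiplies rhat (rhat . p_i)
    pdot = np.einsum("pek,ek->pe", rhat, array.dipoles)
    field = np.einsum(
        "pe,ek->pk", c1 * amplitudes[None, :], array.dipoles.astype(complex)
    ) - np.einsum("pe,pek->pk", c2 * amplitudes[None, :] * pdot, rhat.astype(complex))
    field[mask] = 0.0
    return FieldGrid(points=grid, values=field, mask=mask)


def bloch_mode_amplitudes(array: EmitterArray, m: int, eigvec: np.ndarray) -> np.ndarray:
    """Per-emitter coherences of a Bloch mode (m, unit-cell eigenvector).

    The emitter of component alpha in cell ell carries the coherence
    exp(i 2 pi m ell / N) * v_alpha / sqrt(N), matching the Bloch-operator
    convention of the spectrum module; the result is unit-norm for a
    unit-norm eigenvector.
    """
    eigvec = np.asarray(eigvec, dtype=complex)
    if eigvec.shape != (array.n_cell,):
        raise ValueError(
            f"eigenvector must have one component per unit-cell site "
            f"({array.n_cell}), got {eigvec.shape}"
        )
    phases = np.exp(2j * np.pi * m * array.cell_index / array.N)
    amps = phases * eigvec[array.component_index - 1] / np.sqrt(array.N)
    return amps


def intensity_cut(
    array: EmitterArray,
    amplitudes: np.ndarray,
    plane: str,
    extent: float,
    resolution: int = 101,
    r_excl: float = DEFAULT_EXCLUSION_RADIUS,
) -> FieldGrid:
    """2-D intensity map on an axis-aligned plane cut.

    ``plane`` is a string like ``"z=0.3"`` or ``"y=0"`` selecting the fixed
    coordinate; the remaining two coordinates span ``[-extent, extent]``
    with ``resolution`` points each.
    """
    try:
        axis, value = plane.split("=")
        axis = axis.strip().lower()
        value = float(value)
    except ValueError:
        raise ValueError(f"invalid plane spec {plane!r}; expected e.g. 'z=0.3'") from None
    if axis not in ("x", "y", "z"):
        raise ValueError(f"plane axis must be x, y or z, got {axis!r}")
    if resolution < 2 or extent <= 0:
        raise ValueError("need extent > 0 and resolution >= 2")
    coords = np.linspace(-extent, extent, resolution)
    A, B = np.meshgrid(coords, coords, indexing="ij")
    flat = np.empty((resolution * resolution, 3))
    free = [k for k, ax in enumerate("xyz") if ax != axis]
    fixed = "xyz".index(axis)
    flat[:, free[0]] = A.ravel()
    flat[:, free[1]] = B.ravel()
    flat[:, fixed] = value
    fg = scattered_field(array, amplitudes, flat, r_excl=r_excl)
    fg.shape = (resolution, resolution)
    fg.axes = (coords, coords)
    return fg
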