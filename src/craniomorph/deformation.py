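"""Dense deformation fields: evaluation, composition, inversion, I/O.

A :class:`DeformationField` stores world-mm displacement vectors on a regular
node lattice.  The field represents the map ``phi(x) = x + u(x)`` with ``u``
trilinearly interpolated between nodes; like every transform in craniomorph it
is used in the pull-back sense (target world point -> source world point).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import DomainError, FormatError, ParameterError
from .volume import AffineTransform, Volume

__all__ = [
    "DeformationField",
    "compose",
    "invert_field",
    "read_field",
    "write_field",
]


@dataclass
class DeformationField:
    """Displacement vectors (mm, world frame) on a regular lattice.

    Parameters
    ----------
    displacements : ndarray, shape (nx, ny, nz, 3)
        World-mm displacement at each lattice node.
    affine : ndarray, shape (4, 4)
        Node-index -> world-mm map of the lattice.
    """

    displacements: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ParameterError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ParameterError("displacements must be finite")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    @property
    def node_spacing(self) -> np.ndarray:
        """Per-axis node spacing in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def _world_to_node(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine[:3, :3])
        return (np.asarray(xyz, dtype=float) - self.affine[:3, 3]) @ inv.T

    def grid_world(self) -> np.ndarray:
        idx = np.indices(self.shape, dtype=float)
        ijk = np.moveaxis(idx, 0, -1)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def displacement_at(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated displacement (mm) at world points (..., 3).

        Outside the lattice the nearest-node displacement is used; use
        :meth:`contains` to flag such points.
        """
        node = self._world_to_node(xyz)
        coords = np.moveaxis(node, -1, 0)
        out = np.empty(node.shape, dtype=float)
        for c in range(3):
            out[..., c] = ndimage.map_coordinates(
                self.displacements[..., c], coords, order=1, mode="nearest",
                prefilter=False,
            )
        return out

    def map_points(self, xyz: np.ndarray) -> np.ndarray:
        """Apply ``phi(x) = x + u(x)`` to world points (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz + self.displacement_at(xyz)

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """True where points fall inside the node lattice."""
        node = self._world_to_node(xyz)
        hi = np.asarray(self.shape, dtype=float) - 1.0
        return np.all((node >= -1e-9) & (node <= hi + 1e-9), axis=-1)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def copy(self) -> "DeformationField":
        return DeformationField(self.displacements.copy(), self.affine.copy())

    @classmethod
    def zeros_like_volume(cls, volume: Volume, spacing_mm: float | None = None
                          ) -> "DeformationField":
        """Zero field on the volume's grid, optionally at coarser node spacing."""
        if spacing_mm is None:
            return cls(np.zeros(volume.shape + (3,)), volume.affine.copy())
        step = np.maximum(1, np.round(spacing_mm / volume.spacing)).astype(int)
        shape = tuple((np.asarray(volume.shape) - 1) // step + 1)
        aff = volume.affine.copy()
        aff[:3, :3] = aff[:3, :3] * step[None, :]
        return cls(np.zeros(shape + (3,)), aff)

    def resampled_to(self, affine: np.ndarray, shape: tuple[int, int, int]
                     ) -> "DeformationField":
        """The same map re-sampled onto a new node lattice."""
        affine = np.asarray(affine, dtype=float)
        idx = np.indices(shape, dtype=float)
        ijk = np.moveaxis(idx, 0, -1)
        xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
        disp = self.displacement_at(xyz)
        return DeformationField(disp, affine)


def compose(outer, inner) -> DeformationField:
    """Composition ``(outer o inner)(x) = outer(inner(x))``.

    Either argument may be an :class:`AffineTransform` or a
    :class:`DeformationField`.  The result is sampled on ``inner``'s lattice
    (or ``outer``'s when ``inner`` is affine).
    """
    if isinstance(inner, DeformationField):
        ref = inner
    elif isinstance(outer, DeformationField):
        ref = outer
    else:
        raise ParameterError("compose of two affines: use the @ operator")
    xyz = ref.grid_world()
    mid = inner.apply(xyz) if isinstance(inner, AffineTransform) else xyz + inner.displacement_at(xyz)
    out = outer.apply(mid) if isinstance(outer, AffineTransform) else mid + outer.displacement_at(mid)
    return DeformationField(out - xyz, ref.affine.copy())


def invert_field(field: DeformationField, tol_mm: float = 0.05,
                 max_iter: int = 20) -> DeformationField:
    """Invert a diffeomorphic deformation field by fixed-point iteration.

    Solves ``v(y) = -u(y + v(y))`` at every node, so that
    ``phi(phi_inv(y)) = y``.  Convergence requires the input to be
    diffeomorphic on its domain (Jacobian determinant of ``I + grad u``
    positive everywhere); a negative-Jacobian input raises
    :class:`~craniomorph.exceptions.DomainError`.

    A composition residual above ``tol_mm`` at more than 1% of nodes issues a
    warning (and never an exception).
    """
    from .dbm import jacobian_of_field  # local import to avoid a cycle

    jac = jacobian_of_field(field)
    if np.any(jac <= 0):
        raise DomainError(
            f"field is not invertible: {int(np.sum(jac <= 0))} nodes with "
            "non-positive Jacobian determinant"
        )
    xyz = field.grid_world()
    v = np.zeros_like(field.displacements)
    for _ in range(max_iter):
        v_new = -field.displacement_at(xyz + v)
        delta = np.linalg.norm(v_new - v, axis=-1).max()
        v = v_new
        if delta < 0.25 * tol_mm:
            break
    inverse = DeformationField(v, field.affine.copy())
    residual = np.linalg.norm(field.map_points(inverse.map_points(xyz)) - xyz,
                              axis=-1)
    bad = int(np.sum(residual > tol_mm))
    if bad > 0.01 * residual.size:
        warnings.warn(
            f"field inversion did not converge to {tol_mm} mm at {bad} of "
            f"{residual.size} nodes (max residual {residual.max():.3g} mm)",
            RuntimeWarning,
            stacklevel=2,
        )
    return inverse


def write_field(field: DeformationField, path) -> None:
    """Serialize as a 4D NIfTI (x/y/z displacement components, mm).

    A sidecar ``<path>.json`` records the node spacing and the direction
    convention so the file is self-describing.
    """
    img = nib.Nifti1Image(field.displacements.astype(np.float32), field.affine)
    nib.save(img, str(path))
    meta = {
        "node_spacing_mm": [float(s) for s in field.node_spacing],
        "convention": "pull-back: phi(x) = x + u(x), target world -> source world",
        "units": "mm",
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_field(path) -> DeformationField:
    """Read a deformation field written by :func:`write_field`."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"could not read deformation field {path!s}: {exc}") from exc
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"{path!s}: expected 4D field with 3 components, got {data.shape}"
        )
    return DeformationField(np.asarray(data, dtype=float), np.asarray(img.affine))
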