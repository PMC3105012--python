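"""Volume container, NIfTI I/O, affine transforms, resampling and smoothing.

Conventions used throughout craniomorph
---------------------------------------
* World coordinates are millimetres, right-handed, defined by the NIfTI
  voxel-to-world affine.  All transforms and landmarks live in world space,
  so voxel grids of differing extents interoperate.
* Every transform passed to :func:`resample` is a *pull-back* map: it sends
  points of the **target** geometry into the **source** volume, and the output
  value at a target voxel is the source intensity interpolated at the mapped
  point.  This convention is used everywhere; no function takes a forward
  (source-to-target) map.
* Interpolation is trilinear; samples outside the source field of view are
  zero (volumes are brain-stripped heads on an empty background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import (
    DimensionalityError,
    FormatError,
    ParameterError,
    SingularTransformError,
)

__all__ = [
    "Volume",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "read_affine",
    "write_affine",
    "resample",
    "gaussian_blur",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class Volume:
    """A 3D scalar lattice with a voxel-to-world affine (mm).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, finite.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> world-mm map.  The upper-left 3x3 block
        must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ParameterError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise SingularTransformError("voxel-to-world affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm (..., 3) to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (xyz - self.affine[:3, 3]) @ inv.T

    def grid_world(self) -> np.ndarray:
        """World coordinates of every voxel, shape (nx, ny, nz, 3)."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.moveaxis(idx, 0, -1)
        return self.voxel_to_world(ijk)

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with this geometry and the given data."""
        return Volume(np.asarray(data), self.affine.copy())

    def sample_world(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the volume at world points (..., 3)."""
        vox = self.world_to_voxel(xyz)
        coords = np.moveaxis(vox, -1, 0)
        return ndimage.map_coordinates(
            self.data.astype(float, copy=False), coords, order=1, mode="constant",
            cval=0.0, prefilter=False,
        )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix Rz @ Ry @ Rx (intrinsic x-y-z order)."""
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


class AffineTransform:
    """Parameterized linear world-to-world map (mm).

    The homogeneous matrix is the composition, in this fixed order::

        M = Translate @ Rotate(Rz Ry Rx) @ Shear @ Scale

    where ``Shear`` is unit upper-triangular (xy, xz, yz components) and
    ``Scale`` is diagonal and positive.  With this order the parameters are
    uniquely recoverable from any matrix whose 3x3 block has positive
    determinant (RQ-style decomposition).

    Parameters follow the 6/9/12 degree-of-freedom families used in linear
    head registration: 3 rotations (rad), 3 translations (mm), 3 scales,
    3 shears.
    """

    def __init__(
        self,
        rotations=(0.0, 0.0, 0.0),
        translations=(0.0, 0.0, 0.0),
        scales=(1.0, 1.0, 1.0),
        shears=(0.0, 0.0, 0.0),
    ) -> None:
        self.rotations = np.asarray(rotations, dtype=float)
        self.translations = np.asarray(translations, dtype=float)
        self.scales = np.asarray(scales, dtype=float)
        self.shears = np.asarray(shears, dtype=float)
        if np.any(self.scales <= 0):
            raise ParameterError("scales must be positive")

    @property
    def matrix(self) -> np.ndarray:
        R = _euler_matrix(*self.rotations)
        SH = np.eye(3)
        SH[0, 1], SH[0, 2], SH[1, 2] = self.shears
        SC = np.diag(self.scales)
        M = np.eye(4)
        M[:3, :3] = R @ SH @ SC
        M[:3, 3] = self.translations
        return M

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AffineTransform":
        """Recover parameters from a homogeneous matrix.

        Raises
        ------
        SingularTransformError
            If the 3x3 block has non-positive determinant.
        """
        matrix = np.asarray(matrix, dtype=float)
        A = matrix[:3, :3]
        if np.linalg.det(A) <= 0:
            raise SingularTransformError(
                "3x3 block must have positive determinant"
            )
        # A = R @ U with R rotation, U upper-triangular positive-diagonal:
        # QR of A with sign fix.
        Q, U = np.linalg.qr(A)
        sgn = np.sign(np.diag(U))
        sgn[sgn == 0] = 1.0
        Q = Q * sgn
        U = sgn[:, None] * U
        scales = np.diag(U).copy()
        # U = SH @ SC with SC = diag(scales): SH[i, j] = U[i, j] / scales[j]
        SH = U / scales[None, :]
        shears = (SH[0, 1], SH[0, 2], SH[1, 2])
        ry = math.asin(max(-1.0, min(1.0, -Q[2, 0])))
        rx = math.atan2(Q[2, 1], Q[2, 2])
        rz = math.atan2(Q[1, 0], Q[0, 0])
        return cls(
            rotations=(rx, ry, rz),
            translations=matrix[:3, 3],
            scales=scales,
            shears=shears,
        )

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to world points (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        M = self.matrix
        return xyz @ M[:3, :3].T + M[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform.from_matrix(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform.from_matrix(self.matrix @ other.matrix)

    def __repr__(self) -> str:
        with np.printoptions(precision=4, suppress=True):
            return (
                f"AffineTransform(rot={self.rotations}, t={self.translations}, "
                f"scale={self.scales}, shear={self.shears})"
            )


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 volume.

    Raises
    ------
    FormatError
        If the file is unreadable or not NIfTI.
    DimensionalityError
        If the image is not 3-dimensional.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except DimensionalityError:
        raise
    except Exception as exc:  # nibabel raises many concrete types
        raise FormatError(f"could not read NIfTI volume from {path!s}: {exc}") from exc
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path!s}: expected a 3D volume, got shape {data.shape}"
        )
    return Volume(data, np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    nib.save(img, str(path))


def write_affine(transform: AffineTransform, path) -> None:
    """Write an affine as 4 whitespace-delimited matrix rows.

    A comment header records the 12 parameters (rotations rad, translations
    mm, scales, shears) for human inspection; only the matrix is read back.
    """
    with open(path, "w") as fh:
        fh.write(
            "# affine transform: rows of the 4x4 world-to-world matrix (mm)\n"
            f"# rotations_rad: {' '.join(f'{v:.10g}' for v in transform.rotations)}\n"
            f"# translations_mm: {' '.join(f'{v:.10g}' for v in transform.translations)}\n"
            f"# scales: {' '.join(f'{v:.10g}' for v in transform.scales)}\n"
            f"# shears: {' '.join(f'{v:.10g}' for v in transform.shears)}\n"
        )
        for row in transform.matrix:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_affine(path) -> AffineTransform:
    """Read an affine written by :func:`write_affine`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(tok) for tok in line.split()])
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise FormatError(f"{path!s}: expected 4 rows of 4 numbers")
    return AffineTransform.from_matrix(np.asarray(rows))


def resample(volume: Volume, transform, target: Volume) -> Volume:
    """Resample ``volume`` onto the geometry of ``target``.

    ``transform`` maps target world coordinates into source world coordinates
    (pull-back convention).  It may be an :class:`AffineTransform`, a
    :class:`~craniomorph.deformation.DeformationField`, or ``None`` for the
    identity.  Interpolation is trilinear; points outside the source field of
    view are zero.
    """
    src_inv = np.linalg.inv(volume.affine)
    data = volume.data.astype(float, copy=False)
    if transform is None or isinstance(transform, AffineTransform):
        M = np.eye(4) if transform is None else transform.matrix
        if abs(np.linalg.det(M[:3, :3])) < 1e-12:
            raise SingularTransformError("resampling transform is singular")
        # voxel(target) -> world(target) -> world(source) -> voxel(source)
        total = src_inv @ M @ target.affine
        out = ndimage.affine_transform(
            data, total[:3, :3], offset=total[:3, 3], output_shape=target.shape,
            order=1, mode="constant", cval=0.0, prefilter=False,
        )
        return target.like(out)
    # deformation field: world displacement added to target grid coordinates
    xyz = target.grid_world()
    src_world = transform.map_points(xyz)
    vox = src_world @ src_inv[:3, :3].T + src_inv[:3, 3]
    out = ndimage.map_coordinates(
        data, np.moveaxis(vox, -1, 0), order=1, mode="constant", cval=0.0,
        prefilter=False,
    )
    return target.like(out)


def gaussian_blur(volume: Volume, fwhm_mm: float) -> Volume:
    """Convolve with an isotropic Gaussian of the given FWHM in mm.

    Per-axis sigma in voxel units honours anisotropic voxel sizes.
    """
    if fwhm_mm <= 0:
        raise ParameterError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = sigma_mm / volume.spacing
    # nearest-edge padding: exact for constant volumes, and equivalent to
    # zero padding for head data (the background is already zero)
    out = ndimage.gaussian_filter(
        volume.data.astype(float, copy=False), sigma=sigma_vox, mode="nearest",
    )
    return volume.like(out)
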