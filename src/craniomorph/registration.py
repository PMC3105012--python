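"""Intensity-driven linear and nonlinear registration, transform algebra.

Linear registration (6/9/12 degrees of freedom) maximizes the normalized
cross-correlation (NCC) of Gaussian-blurred intensities over a coarse-to-fine
pyramid with a Nelder-Mead simplex.  Nonlinear registration follows the
classic multi-resolution node-grid scheme: at each schedule step both images
are blurred, control nodes are placed on a lattice at the step spacing, each
node's local translation is optimized by a derivative-free simplex inside a
spherical search region, and the data-driven update is blended with a
smoothed neighborhood field (stiffness/weight/similarity regularization).

All returned transforms are pull-back maps: they send points of the *target*
geometry into the *source* volume, so that ``resample(source, transform,
target)`` aligns the source onto the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.linalg import expm, logm

from ._animal import update_nodes
from .deformation import DeformationField, compose, invert_field
from .exceptions import DomainError, ParameterError
from .volume import AffineTransform, Volume, gaussian_blur

__all__ = [
    "NonlinearSchedule",
    "OptimizerConfig",
    "register_linear",
    "register_nonlinear",
    "average_affines",
    "ncc",
    "DeformationField",
    "compose",
    "invert_field",
]

# full-resolution schedule used for 1-mm human head data:
# (step size mm, iterations, Gaussian blur FWHM mm)
FULL_SCHEDULE = ((8, 30, 16), (8, 30, 8), (4, 30, 8), (4, 30, 4),
                 (2, 10, 4), (2, 10, 2))
# reduced schedule for 64^3 phantoms (same step pyramid, fewer iterations)
PHANTOM_SCHEDULE = ((8, 10, 8), (4, 10, 4), (2, 5, 2))


@dataclass(frozen=True)
class NonlinearSchedule:
    """Ordered multi-resolution steps ``(step_size_mm, iterations, blur_fwhm_mm)``.

    Step sizes and blur FWHMs must be positive and non-increasing.
    """

    steps: tuple = FULL_SCHEDULE

    def __post_init__(self) -> None:
        steps = tuple(tuple(s) for s in self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ParameterError("schedule must contain at least one step")
        for step, iters, blur in steps:
            if step <= 0 or iters <= 0 or blur <= 0:
                raise ParameterError("schedule entries must be positive")
        sizes = [s[0] for s in steps]
        blurs = [s[2] for s in steps]
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ParameterError("step sizes must be non-increasing")
        if any(b > a for a, b in zip(blurs, blurs[1:])):
            raise ParameterError("blur FWHMs must be non-increasing")

    @classmethod
    def default(cls) -> "NonlinearSchedule":
        """The full-resolution schedule for 1-mm head MRI."""
        return cls(FULL_SCHEDULE)

    @classmethod
    def phantom(cls) -> "NonlinearSchedule":
        """Reduced schedule suitable for 64^3 synthetic phantoms."""
        return cls(PHANTOM_SCHEDULE)


@dataclass(frozen=True)
class OptimizerConfig:
    """Node-optimizer knobs: simplex regularization and search geometry.

    ``stiffness``, ``weight`` and ``similarity`` (defaults 1, 1, 0.3) set the
    blending factor ``alpha = similarity / (similarity + stiffness * weight)``
    between each node's data-driven update and the Gaussian-smoothed
    neighborhood field.  The spherical search region around each node has
    radius ``search_radius_factor * step_size``.
    """

    stiffness: float = 1.0
    weight: float = 1.0
    similarity: float = 0.3
    search_radius_factor: float = 3.0
    max_evaluations: int = 50
    #: minimum local-NCC gain for a node to move off zero / its current
    #: displacement (minimal-deformation bias; counters the aperture problem)
    tie_epsilon: float = 3e-3
    #: quadratic minimal-deformation prior: the node objective is
    #: NCC - penalty * (|d| / search_radius)^2, so moves near the search
    #: boundary must buy a real similarity gain
    deformation_penalty: float = 0.02
    #: similarity window = sphere of radius window_factor * step_size,
    #: sampled at spacing step_size / window_samples_per_step
    window_factor: float = 2.0
    window_samples_per_step: float = 1.0

    @property
    def alpha(self) -> float:
        return self.similarity / (self.similarity + self.stiffness * self.weight)


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized cross-correlation of two arrays (optionally masked)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask).astype(bool).ravel()
        a, b = a[m], b[m]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom < 1e-12:
        return 0.0
    return float((a @ b) / denom)


def _n_params(dof: int) -> int:
    return {6: 6, 9: 9, 12: 12}[dof]


def _params_to_transform(p: np.ndarray, dof: int) -> AffineTransform:
    """Internal scaled parameters -> AffineTransform (about the origin).

    One internal unit is 1 mm of translation, 0.02 rad of rotation, 2% of
    scale (log-space, keeping scales positive) and 0.02 of shear, so the
    simplex sees comparably scaled axes.
    """
    rot = p[0:3] * 0.02
    trans = p[3:6] * 1.0
    scales = np.ones(3)
    shears = np.zeros(3)
    if dof >= 9:
        scales = np.exp(p[6:9] * 0.02)
    if dof == 12:
        shears = p[9:12] * 0.02
    return AffineTransform(rot, trans, scales, shears)


def register_linear(
    source: Volume,
    target: Volume,
    dof: int = 12,
    init: AffineTransform | None = None,
    levels: tuple = ((8.0, 4), (4.0, 2), (2.0, 2)),
    maxfev_per_param: int = 100,
) -> AffineTransform:
    """Linear registration of ``source`` onto ``target``.

    Parameters
    ----------
    dof : {6, 9, 12}
        6 = rigid (rotations + translations), 9 = + scales, 12 = + shears.
    init : AffineTransform, optional
        Initial pull-back map; defaults to the intensity-centroid shift.
    levels : sequence of (blur_fwhm_mm, grid_stride)
        Coarse-to-fine pyramid; NCC is evaluated on a strided target grid.

    Returns
    -------
    AffineTransform
        Pull-back map (target world -> source world) maximizing NCC.  If the
        optimization failed to improve on the initialization, the result
        carries ``converged = False`` and a warning is issued.
    """
    if dof not in (6, 9, 12):
        raise ParameterError(f"dof must be 6, 9 or 12, got {dof}")
    n = _n_params(dof)

    tdata = target.data.astype(float, copy=False)
    w = np.clip(tdata, 0, None)
    if w.sum() <= 0:
        raise ParameterError("target volume has no positive intensities")
    idx = np.indices(target.shape, dtype=float)
    com_t_vox = np.array([(idx[i] * w).sum() / w.sum() for i in range(3)])
    center = target.voxel_to_world(com_t_vox)

    if init is None:
        sdata = np.clip(source.data.astype(float, copy=False), 0, None)
        idx_s = np.indices(source.shape, dtype=float)
        com_s_vox = np.array([(idx_s[i] * sdata).sum() / max(sdata.sum(), 1e-9)
                              for i in range(3)])
        shift = source.voxel_to_world(com_s_vox) - center
        init = AffineTransform(translations=shift)
    m_init = init.matrix

    t_plus = np.eye(4)
    t_plus[:3, 3] = center
    t_minus = np.eye(4)
    t_minus[:3, 3] = -center

    src_inv = np.linalg.inv(source.affine)

    def full_matrix(p: np.ndarray) -> np.ndarray:
        return m_init @ t_plus @ _params_to_transform(p, dof).matrix @ t_minus

    x = np.zeros(n)
    objective = None
    for fwhm, stride in levels:
        tb = gaussian_blur(target, fwhm).data
        sb = gaussian_blur(source, fwhm).data
        sl = (slice(None, None, stride),) * 3
        tb_s = tb[sl]
        mask = tb_s > 0.05 * tb_s.max()
        ijk = np.indices(target.shape, dtype=float)[(slice(None),) + sl]
        ijk = np.moveaxis(ijk, 0, -1)[mask]
        pts_t = target.voxel_to_world(ijk)
        tvals = tb_s[mask]
        tvals = tvals - tvals.mean()
        tnorm = np.sqrt(tvals @ tvals)

        def objective(p: np.ndarray) -> float:
            M = full_matrix(p)
            mapped = pts_t @ M[:3, :3].T + M[:3, 3]
            vox = mapped @ src_inv[:3, :3].T + src_inv[:3, 3]
            svals = ndimage.map_coordinates(sb, vox.T, order=1,
                                            mode="constant", cval=0.0,
                                            prefilter=False)
            svals = svals - svals.mean()
            denom = tnorm * np.sqrt(svals @ svals)
            if denom < 1e-12:
                return 0.0
            return -float((tvals @ svals) / denom)

        edge = 2.0 if fwhm >= 4 else 0.5
        simplex = np.vstack([x] + [x + edge * e for e in np.eye(n)])
        res = optimize.minimize(
            objective, x, method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": maxfev_per_param * n,
                "xatol": 0.02,
                "fatol": 1e-7,
            },
        )
        x = res.x
        f_final = res.fun

    # compare against the initialization under the final level's objective
    f_init = objective(np.zeros(n))
    converged = bool(f_final <= f_init + 1e-9)
    if not converged:
        warnings.warn(
            "linear registration did not improve similarity over the "
            f"initialization (init NCC {-f_init:.4f}, final {-f_final:.4f}); "
            "keeping the initialization",
            RuntimeWarning,
            stacklevel=2,
        )
        x = np.zeros(n)
    result = AffineTransform.from_matrix(full_matrix(x))
    result.converged = converged
    return result


def average_affines(transforms) -> AffineTransform:
    """Log-space (geometric) mean of affine transforms.

    Computed as ``expm(mean(logm(M_i)))``, which is symmetric under inversion:
    averaging a transform with its inverse yields the identity.

    Raises
    ------
    DomainError
        If the list is empty or any matrix has non-positive determinant.
    """
    transforms = list(transforms)
    if not transforms:
        raise DomainError("cannot average an empty list of transforms")
    logs = []
    for t in transforms:
        M = t.matrix
        if np.linalg.det(M[:3, :3]) <= 0:
            raise DomainError("all transforms must have positive determinant")
        L = logm(M)
        if np.iscomplexobj(L):
            L = L.real
        logs.append(L)
    mean_log = np.mean(logs, axis=0)
    M = expm(mean_log)
    M[3, :] = (0.0, 0.0, 0.0, 1.0)
    return AffineTransform.from_matrix(M)


def _sphere_offsets(radius_mm: float, spacing_mm: float) -> np.ndarray:
    """World-mm sample offsets on a grid inside a sphere (center included)."""
    n = int(np.floor(radius_mm / spacing_mm))
    ax = np.arange(-n, n + 1) * spacing_mm
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(pts, axis=1) <= radius_mm + 1e-9
    return np.ascontiguousarray(pts[keep])


def register_nonlinear(
    source: Volume,
    target: Volume,
    schedule: NonlinearSchedule | None = None,
    config: OptimizerConfig | None = None,
    init: DeformationField | None = None,
) -> DeformationField:
    """Multi-resolution node-grid nonlinear registration.

    ``source`` must already be linearly aligned to ``target``.  For each
    schedule step both volumes are blurred at the stated FWHM, control nodes
    are placed on the target lattice at the step spacing, each node's local
    translation is found by Nelder-Mead on local NCC within a sphere of radius
    ``search_radius_factor * step_size``, and the update is regularized by
    blending with the Gaussian-smoothed neighborhood field.  The field is
    upsampled to initialize the next step.

    Returns
    -------
    DeformationField
        Pull-back map sending target points to source points.
    """
    if schedule is None:
        schedule = NonlinearSchedule.default()
    if config is None:
        config = OptimizerConfig()
    alpha = config.alpha

    field: DeformationField | None = init
    min_spacing = float(target.spacing.min())
    for step_size, iterations, blur_fwhm in schedule.steps:
        tb = gaussian_blur(target, blur_fwhm)
        sb = gaussian_blur(source, blur_fwhm)

        lattice = DeformationField.zeros_like_volume(target, step_size)
        if field is not None:
            field = field.resampled_to(lattice.affine, lattice.shape)
        else:
            field = lattice
        grid_shape = field.shape
        node_world = np.ascontiguousarray(field.grid_world().reshape(-1, 3))

        sample_spacing = max(min_spacing,
                             step_size / config.window_samples_per_step)
        offsets = _sphere_offsets(config.window_factor * float(step_size),
                                  sample_spacing)
        patches = tb.sample_world(node_world[:, None, :] + offsets[None, :, :])
        pmean = patches.mean(axis=1, keepdims=True)
        pc = patches - pmean
        pnorm = np.sqrt((pc * pc).sum(axis=1))
        global_max = float(tb.data.max())
        active = (patches.max(axis=1) > 0.05 * global_max) & (pnorm > 1e-9)
        t_norm = np.zeros_like(pc)
        t_norm[active] = pc[active] / pnorm[active, None]

        s_ainv = np.ascontiguousarray(np.linalg.inv(sb.affine[:3, :3]))
        s_orig = np.ascontiguousarray(sb.affine[:3, 3])
        sdata = np.ascontiguousarray(sb.data.astype(np.float64, copy=False))
        search_r = config.search_radius_factor * float(step_size)
        edge = float(step_size) / 2.0

        u = np.ascontiguousarray(field.displacements.reshape(-1, 3))
        sigma_nodes = 1.0  # Gaussian over neighboring nodes, sigma = step size
        for _ in range(iterations):
            data_u = update_nodes(
                node_world, u, active, np.ascontiguousarray(t_norm),
                offsets, sdata, s_ainv, s_orig, search_r, edge,
                config.max_evaluations, config.tie_epsilon,
                config.deformation_penalty,
            )
            grid_u = data_u.reshape(grid_shape + (3,))
            smooth_u = np.empty_like(grid_u)
            for c in range(3):
                smooth_u[..., c] = ndimage.gaussian_filter(
                    grid_u[..., c], sigma=sigma_nodes, mode="nearest")
            blended = alpha * grid_u + (1.0 - alpha) * smooth_u
            flat = blended.reshape(-1, 3)
            flat[~active] = smooth_u.reshape(-1, 3)[~active]
            u = np.ascontiguousarray(flat)
        field = DeformationField(u.reshape(grid_shape + (3,)), field.affine)
    return field
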