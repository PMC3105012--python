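"""Deformation-based morphometry: Jacobian maps, voxel-wise GLM, RFT.

The Jacobian determinant ``det(I + grad u)`` of a displacement field indexes
local volume expansion (>1) or contraction (<1) relative to the template.
Per-subject Jacobian maps are smoothed, restricted to a face mask, and
modeled voxel-by-voxel with ordinary least squares; family-wise error over
the search region is controlled with the expected Euler characteristic of a
t random field (Gaussian random field theory), with a Bonferroni bound as a
safety net.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .deformation import DeformationField
from .exceptions import (
    ConfigurationError,
    DesignError,
    DomainError,
    ParameterError,
)
from .volume import Volume

__all__ = [
    "StatMap",
    "ClusterTable",
    "jacobian_map",
    "jacobian_of_field",
    "make_face_mask",
    "fit_glm",
    "estimate_smoothness",
    "rft_correct",
    "resel_counts",
    "ec_density_t",
]

logger = logging.getLogger(__name__)


def _displacement_jacobian(disp: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """det(I + du/dx) for a displacement lattice, world-coordinate derivatives.

    Central finite differences in the interior, one-sided at the borders
    (np.gradient).  Voxel-axis derivatives are mapped to world derivatives
    through the inverse of the 3x3 affine block, so oblique lattices are
    handled correctly.
    """
    ainv = np.linalg.inv(np.asarray(affine, dtype=float)[:3, :3])
    shape = disp.shape[:3]
    J = np.zeros(shape + (3, 3))
    for i in range(3):
        grads = np.gradient(disp[..., i], axis=(0, 1, 2))
        for k in range(3):
            # du_i/dx_k = sum_j du_i/dvox_j * ainv[j, k]
            J[..., i, k] = sum(grads[j] * ainv[j, k] for j in range(3))
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    return np.linalg.det(J)


def jacobian_of_field(field: DeformationField) -> np.ndarray:
    """Jacobian determinants on the field's own node lattice."""
    return _displacement_jacobian(field.displacements, field.affine)


def jacobian_map(field: DeformationField, geometry: Volume) -> Volume:
    """Jacobian-determinant volume of a deformation field on a target grid.

    The displacement is interpolated onto the geometry's lattice and
    ``det(I + grad u)`` is evaluated with central differences (one-sided at
    borders) in world mm.  Non-positive determinants are allowed in the
    output but are counted and logged (they flag folding).
    """
    disp = field.displacement_at(geometry.grid_world())
    det = _displacement_jacobian(disp, geometry.affine)
    n_bad = int(np.sum(det <= 0))
    if n_bad:
        logger.warning("jacobian_map: %d voxels with non-positive determinant",
                       n_bad)
    return geometry.like(det)


def make_face_mask(model: Volume, forehead_plane_y: float,
                   head_threshold_frac: float = 0.1) -> Volume:
    """Binary face mask: head voxels anterior to the forehead plane.

    The analysis region excludes everything posterior to the top of the
    forehead, limiting statistics to facial structures.  "Anterior" is world
    y greater than ``forehead_plane_y`` (RAS-style axes).

    Raises
    ------
    ConfigurationError
        If the plane lies outside the model FOV or the mask comes out empty.
    """
    y = model.grid_world()[..., 1]
    if forehead_plane_y < y.min() - 1e-9 or forehead_plane_y > y.max() + 1e-9:
        raise ConfigurationError(
            f"forehead plane y={forehead_plane_y} mm outside model FOV "
            f"[{y.min():.1f}, {y.max():.1f}]"
        )
    head = model.data > head_threshold_frac * model.data.max()
    mask = head & (y > forehead_plane_y)
    if not mask.any():
        raise ConfigurationError(
            "face mask is empty: forehead plane excludes the whole head"
        )
    return model.like(mask.astype(np.uint8))


@dataclass
class StatMap:
    """Voxel-wise t statistics with their search region and smoothness.

    Attributes
    ----------
    t_values : Volume
        t statistic per voxel (zero outside the mask).
    effect : Volume
        Contrast of parameter estimates (same units as the response).
    df : int
        Residual degrees of freedom (n - rank of design).
    mask : Volume
        Binary search region.
    fwhm_est_mm : float
        Estimated residual smoothness (FWHM, mm).
    design_labels : list of str
    contrast : ndarray
    """

    t_values: Volume
    effect: Volume
    df: int
    mask: Volume
    fwhm_est_mm: float
    design_labels: list
    contrast: np.ndarray


@dataclass
class ClusterTable:
    """Suprathreshold clusters of a StatMap after RFT correction.

    ``table`` columns: cluster_id, n_voxels, volume_mm3, peak_t, peak_x_mm,
    peak_y_mm, peak_z_mm, p_peak_corrected, p_cluster_corrected.
    """

    table: pd.DataFrame
    threshold: float
    alpha: float
    resels: np.ndarray
    labels: Volume


def _design_matrix(design, labels=None) -> tuple[np.ndarray, list]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    if labels is None:
        labels = [f"x{i}" for i in range(X.shape[1])]
    return X, list(labels)


def _check_rank(X: np.ndarray, labels) -> int:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via vanishing R diagonal in pivoted QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [labels[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )
    return rank


def fit_glm(jacobians, design, contrast, mask: Volume,
            smoothness_fallback_fwhm_mm: float = 8.0) -> StatMap:
    """Voxel-wise ordinary least squares over a masked search region.

    Parameters
    ----------
    jacobians : sequence of Volume
        Per-subject (already smoothed) Jacobian maps on a common grid.
    design : DataFrame or 2D array
        One row per subject; must include an intercept column.
    contrast : 1D array or column name
        Contrast vector ``c`` for ``t = c'beta / sqrt(c'(X'X)^-1 c sigma^2)``.
    mask : Volume
        Binary search region.

    Residual smoothness is estimated from the normalized residual gradients
    when at least 10 subjects are available; otherwise the applied blur FWHM
    (``smoothness_fallback_fwhm_mm``) is used.
    """
    X, labels = _design_matrix(design)
    if isinstance(contrast, str):
        if contrast not in labels:
            raise DesignError(f"contrast column {contrast!r} not in design")
        c = np.zeros(X.shape[1])
        c[labels.index(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=float)
    if c.shape != (X.shape[1],):
        raise DesignError(
            f"contrast length {c.size} does not match {X.shape[1]} regressors"
        )
    n = X.shape[0]
    if len(jacobians) != n:
        raise DesignError(
            f"{len(jacobians)} maps but {n} design rows"
        )
    rank = _check_rank(X, labels)
    df = n - rank
    if df <= 0:
        raise DesignError("no residual degrees of freedom")

    m = mask.data.astype(bool)
    Y = np.stack([np.asarray(v.data, dtype=float)[m] for v in jacobians])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid * resid).sum(axis=0) / df
    cov_c = float(c @ xtx_inv @ c)
    eff = c @ beta
    denom = np.sqrt(np.maximum(cov_c * sigma2, 1e-300))
    tvals = eff / denom

    t_vol = np.zeros(mask.shape)
    t_vol[m] = tvals
    e_vol = np.zeros(mask.shape)
    e_vol[m] = eff

    if n >= 10:
        res_vols = np.zeros((n,) + mask.shape)
        res_vols[:, m] = resid
        fwhm = estimate_smoothness(
            [mask.like(r) for r in res_vols], mask)
    else:
        fwhm = float(smoothness_fallback_fwhm_mm)

    return StatMap(
        t_values=mask.like(t_vol),
        effect=mask.like(e_vol),
        df=int(df),
        mask=mask,
        fwhm_est_mm=float(fwhm),
        design_labels=labels,
        contrast=c,
    )


def estimate_smoothness(residuals, mask: Volume) -> float:
    """Residual smoothness (FWHM, mm) from normalized residual gradients.

    Standard resel estimation: residual vectors are normalized to unit length
    across subjects at each voxel; the variance of their spatial derivatives
    gives a per-axis roughness ``lambda_j`` and
    ``FWHM_j = sqrt(4 ln 2 / lambda_j)``.  Returns the geometric mean of the
    per-axis FWHMs.

    Raises
    ------
    DomainError
        For an empty mask, fewer than 2 residual maps, or residuals with zero
        gradient variance (e.g. constant maps).
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise DomainError("smoothness estimation: empty mask")
    residuals = list(residuals)
    if len(residuals) < 2:
        raise DomainError("smoothness estimation needs >= 2 residual maps")
    R = np.stack([np.asarray(r.data, dtype=float) for r in residuals])
    norm = np.sqrt((R * R).sum(axis=0))
    ok = norm > 1e-12
    U = np.where(ok[None], R / np.where(ok, norm, 1.0)[None], 0.0)
    spacing = mask.spacing
    # forward differences between voxel pairs fully inside the mask
    # (central differences would halve the apparent roughness of rough maps)
    valid = m & ok
    lam = np.zeros(3)
    sl = [slice(None)] * 3
    sr = [slice(None)] * 3
    for j in range(3):
        sl[j], sr[j] = slice(None, -1), slice(1, None)
        both = valid[tuple(sl)] & valid[tuple(sr)]
        if not both.any():
            raise DomainError("smoothness estimation: mask too thin")
        g = (U[(slice(None),) + tuple(sr)] - U[(slice(None),) + tuple(sl)]) \
            / spacing[j]
        lam[j] = float((g * g).sum(axis=0)[both].mean())
        sl[j] = sr[j] = slice(None)
    if np.any(lam <= 1e-12):
        raise DomainError(
            "smoothness estimation failed: zero residual gradient variance"
        )
    fwhm = np.sqrt(4.0 * math.log(2.0) / lam)
    return float(np.exp(np.mean(np.log(fwhm))))


def resel_counts(mask: Volume, fwhm_mm: float) -> np.ndarray:
    """Resel counts R_0..R_3 of a binary search region.

    Counts points, edges, faces and cubes of the mask lattice and converts
    them to resolution elements using the voxel sizes in FWHM units
    (the standard lattice approximation of the Lipschitz-Killing curvatures).
    """
    m = mask.data.astype(bool)
    dx, dy, dz = mask.spacing / fwhm_mm
    P = float(m.sum())
    Ex = float((m[:-1] & m[1:]).sum())
    Ey = float((m[:, :-1] & m[:, 1:]).sum())
    Ez = float((m[..., :-1] & m[..., 1:]).sum())
    Fxy = float((m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]).sum())
    Fxz = float((m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]).sum())
    Fyz = float((m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]).sum())
    C = float((m[:-1, :-1, :-1] & m[1:, :-1, :-1] & m[:-1, 1:, :-1]
               & m[:-1, :-1, 1:] & m[1:, 1:, :-1] & m[1:, :-1, 1:]
               & m[:-1, 1:, 1:] & m[1:, 1:, 1:]).sum())
    r0 = P - (Ex + Ey + Ez) + (Fxy + Fxz + Fyz) - C
    r1 = (Ex - Fxy - Fxz + C) * dx + (Ey - Fxy - Fyz + C) * dy \
        + (Ez - Fxz - Fyz + C) * dz
    r2 = (Fxy - C) * dx * dy + (Fxz - C) * dx * dz + (Fyz - C) * dy * dz
    r3 = C * dx * dy * dz
    return np.array([r0, r1, r2, r3])


def ec_density_t(t: float, df: int) -> np.ndarray:
    """Euler-characteristic densities rho_0..rho_3 of a t field."""
    v = float(df)
    f = (1.0 + t * t / v) ** (-(v - 1.0) / 2.0)
    c = math.sqrt(4.0 * math.log(2.0))
    gam = math.exp(gammaln((v + 1.0) / 2.0) - gammaln(v / 2.0)) / math.sqrt(v / 2.0)
    rho0 = float(t_dist.sf(t, v))
    rho1 = c / (2.0 * math.pi) * f
    rho2 = c ** 2 / (2.0 * math.pi) ** 1.5 * gam * t * f
    rho3 = c ** 3 / (2.0 * math.pi) ** 2 * ((v - 1.0) * t * t / v - 1.0) * f
    return np.array([rho0, rho1, rho2, rho3])


def expected_ec(t: float, df: int, resels: np.ndarray) -> float:
    """Expected Euler characteristic of the excursion set above ``t``."""
    return float(resels @ ec_density_t(t, df))


def rft_threshold(df: int, resels: np.ndarray, alpha: float,
                  n_voxels: int) -> float:
    """Peak-level threshold at family-wise alpha.

    Solves ``E[EC](t) = alpha``; the result is clipped between the
    uncorrected alpha quantile and the Bonferroni threshold over the in-mask
    voxels (the expected-EC approximation is only valid for smooth fields,
    and Bonferroni is exact-conservative).
    """
    t_unc = float(t_dist.isf(alpha, df))
    t_bonf = float(t_dist.isf(alpha / max(n_voxels, 1), df))

    def fn(t):
        return expected_ec(t, df, resels) - alpha

    hi = t_bonf + 10.0
    if fn(t_unc) <= 0:
        t_rft = t_unc
    elif fn(hi) >= 0:
        t_rft = hi
    else:
        t_rft = float(optimize.brentq(fn, t_unc, hi))
    return float(min(max(t_rft, t_unc), t_bonf))


def rft_correct(stat: StatMap, alpha: float = 0.05) -> ClusterTable:
    """Random-field-theory corrected clusters of a t map (positive tail).

    The peak threshold comes from the expected Euler characteristic of a
    t field with ``stat.df`` degrees of freedom over the mask's resel counts.
    Clusters are formed at that threshold with 18-connectivity; each cluster
    gets a peak-level corrected p (expected EC at its peak) and an
    approximate cluster-extent p (Friston-style expected-cluster-size
    approximation, flagged approximate).

    To analyze the negative tail, flip the contrast sign.
    """
    if stat.df <= 2:
        raise DomainError(f"RFT correction requires df > 2, got {stat.df}")
    if alpha <= 0 or alpha >= 1:
        raise ParameterError("alpha must be in (0, 1)")
    m = stat.mask.data.astype(bool)
    n_vox = int(m.sum())
    resels = resel_counts(stat.mask, stat.fwhm_est_mm)
    thr = rft_threshold(stat.df, resels, alpha, n_vox)

    tmap = np.where(m, stat.t_values.data, -np.inf)
    supra = tmap > thr
    structure = ndimage.generate_binary_structure(3, 2)  # 18-connectivity
    labels, n_clusters = ndimage.label(supra, structure=structure)

    vox_vol = float(np.abs(np.linalg.det(stat.mask.affine[:3, :3])))
    # cluster-extent approximation ingredients
    Em = max(expected_ec(thr, stat.df, resels), 1e-12)
    p_above = float(t_dist.sf(thr, stat.df))
    EN = n_vox * p_above  # expected suprathreshold voxels

    rows = []
    for cid in range(1, n_clusters + 1):
        where = labels == cid
        nvox = int(where.sum())
        tv = np.where(where, tmap, -np.inf)
        peak_idx = np.unravel_index(int(np.argmax(tv)), tv.shape)
        peak_t = float(tv[peak_idx])
        peak_world = stat.mask.voxel_to_world(np.asarray(peak_idx, dtype=float))
        p_peak = min(1.0, expected_ec(peak_t, stat.df, resels))
        if EN > 0:
            beta = (math.gamma(2.5) * Em / EN) ** (2.0 / 3.0)
            p_ext = math.exp(-beta * nvox ** (2.0 / 3.0))
        else:
            p_ext = 1.0
        p_cluster = 1.0 - math.exp(-Em * p_ext)
        rows.append({
            "cluster_id": cid,
            "n_voxels": nvox,
            "volume_mm3": nvox * vox_vol,
            "peak_t": peak_t,
            "peak_x_mm": peak_world[0],
            "peak_y_mm": peak_world[1],
            "peak_z_mm": peak_world[2],
            "p_peak_corrected": p_peak,
            "p_cluster_corrected": p_cluster,
        })
    table = pd.DataFrame(
        rows, columns=["cluster_id", "n_voxels", "volume_mm3", "peak_t",
                       "peak_x_mm", "peak_y_mm", "peak_z_mm",
                       "p_peak_corrected", "p_cluster_corrected"],
    )
    if len(table):
        table = table.sort_values("peak_t", ascending=False,
                                  ignore_index=True)
    return ClusterTable(
        table=table,
        threshold=float(thr),
        alpha=float(alpha),
        resels=resels,
        labels=stat.mask.like(labels),
    )
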