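"""Point-distribution model: landmark PCA, score models, TPS simulation.

The PDM concatenates the (x, y, z) coordinates of all 56 propagated
landmarks into a 168-vector per subject, subtracts the model's landmark
coordinates (the reference), and eigendecomposes the resulting second-moment
matrix across subjects.  Because centering is on the model rather than the
sample mean (the sample-mean offset then appears in the scores), "variance"
below means mean-square deviation from the reference; a flag switches to
conventional sample-mean centering.

Facial-feature simulation displaces the reference landmarks along one
eigenvector and carries the whole face along with an interpolating 3D
thin-plate spline (kernel U(r) = r), whose affine part and nonlinear weights
are exposed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DomainError,
    PairingError,
    SingularTransformError,
)
from .landmarks import LandmarkSet, fit_sex_age_models
from .volume import Volume

__all__ = [
    "PDMModel",
    "TPSWarp",
    "fit_pdm",
    "analyze_scores",
    "tps_fit",
    "tps_apply",
    "tps_bending_energy",
    "tps_warp_volume",
    "simulate_pc",
    "save_pdm",
    "load_pdm",
]


@dataclass
class PDMModel:
    """Shape model: reference, orthonormal modes, variances, subject scores.

    Attributes
    ----------
    mean_reference : ndarray, shape (3K,)
        The reference landmark coordinates (mm) subtracted before PCA.
    eigenvectors : ndarray, shape (3K, R)
        Orthonormal modes, by descending eigenvalue.
    eigenvalues : ndarray, shape (R,)
        Mode variances (mm^2): mean-square score along each mode.
    scores : DataFrame, subjects x R
        Per-subject mode scores (mm), indexed by subject id.
    landmark_names : list of str
    """

    mean_reference: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    landmark_names: list

    @property
    def rank(self) -> int:
        return self.eigenvalues.size

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def cumulative_weights(self) -> pd.DataFrame:
        """Per-PC and cumulative variance fractions (percent)."""
        ratio = 100.0 * self.explained_variance_ratio()
        return pd.DataFrame({
            "pc": np.arange(1, self.rank + 1),
            "individual_weight_pct": ratio,
            "cumulative_weight_pct": np.cumsum(ratio),
        })

    def mode_landmarks(self, pc_index: int, amplitude_mm: float
                       ) -> LandmarkSet:
        """Reference landmarks displaced along one mode (0-based index)."""
        vec = self.mean_reference + amplitude_mm * self.eigenvectors[:, pc_index]
        return LandmarkSet(self.landmark_names, vec.reshape(-1, 3),
                           "model")


def fit_pdm(landmark_sets, reference: LandmarkSet,
            center: str = "reference") -> PDMModel:
    """PCA of concatenated landmark coordinates across subjects.

    Parameters
    ----------
    landmark_sets : sequence of LandmarkSet or mapping id -> LandmarkSet
        Propagated landmarks, all in head-size-free (subject_linear) space
        with the same names in the same order.
    reference : LandmarkSet
        The model landmarks whose coordinates are subtracted.
    center : {"reference", "sample_mean"}
        What to subtract before the eigendecomposition.

    Raises
    ------
    PairingError
        If any subject's names differ from the reference.
    """
    if isinstance(landmark_sets, dict):
        ids = list(landmark_sets)
        sets = [landmark_sets[k] for k in ids]
    else:
        sets = list(landmark_sets)
        ids = [f"S{i:03d}" for i in range(len(sets))]
    if len(sets) < 3:
        raise PairingError("PDM needs at least 3 subjects")
    for s in sets:
        if s.names != reference.names:
            raise PairingError(
                "landmark names differ from the reference template")
    data = np.stack([s.points.ravel() for s in sets])
    ref_vec = reference.points.ravel()
    if center == "reference":
        X = data - ref_vec
    elif center == "sample_mean":
        X = data - data.mean(axis=0)
    else:
        raise ConfigurationError(f"unknown centering {center!r}")
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    V = Vt.T
    # fix PCA sign indeterminacy: largest-magnitude loading positive
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = X @ V
    return PDMModel(
        mean_reference=ref_vec.copy(),
        eigenvectors=V,
        eigenvalues=eigenvalues,
        scores=pd.DataFrame(scores, index=pd.Index(ids, name="subject_id"),
                            columns=[f"PC{k + 1}" for k in range(V.shape[1])]),
        landmark_names=list(reference.names),
    )


def analyze_scores(model: PDMModel, covariates: pd.DataFrame,
                   residualize_bodyfat: bool = False,
                   n_components: int = 5) -> pd.DataFrame:
    """Sex/age/age-by-sex models of the first PC scores.

    When ``residualize_bodyfat`` is set, each PC score is first replaced by
    its residual from a simple regression on percent body fat
    (``bodyfat_pct`` column required), then modeled — the robustness check
    against soft-tissue (fat) rather than skeletal effects.
    """
    k = min(n_components, model.rank)
    scores = model.scores.iloc[:, :k].copy()
    if residualize_bodyfat:
        if "bodyfat_pct" not in covariates.columns:
            raise ConfigurationError(
                "residualize_bodyfat requires a bodyfat_pct covariate column")
        cov = covariates.set_index("subject_id").loc[scores.index]
        bf = cov["bodyfat_pct"].to_numpy(dtype=float)
        Xbf = np.column_stack([np.ones_like(bf), bf])
        hat = Xbf @ np.linalg.lstsq(Xbf, scores.to_numpy(), rcond=None)[0]
        scores = pd.DataFrame(scores.to_numpy() - hat, index=scores.index,
                              columns=scores.columns)
    return fit_sex_age_models(scores, covariates)


@dataclass
class TPSWarp:
    """An interpolating 3D thin-plate spline.

    ``f(x) = affine_part @ [x, 1] + sum_i weights[i] * U(|x - source[i]|)``
    with kernel ``U(r) = r``; maps every source point exactly onto its
    target.
    """

    source_points: np.ndarray
    target_points: np.ndarray
    affine_part: np.ndarray  # (3, 4): linear map columns + offset
    weights: np.ndarray      # (N, 3)


def _tps_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def tps_fit(source: LandmarkSet | np.ndarray,
            target: LandmarkSet | np.ndarray) -> TPSWarp:
    """Fit the interpolating TPS carrying source landmarks onto target.

    Raises
    ------
    PairingError
        If the point sets differ in names or length.
    SingularTransformError
        For duplicate source points (singular system).
    """
    if isinstance(source, LandmarkSet) and isinstance(target, LandmarkSet):
        if source.names != target.names:
            raise PairingError("source and target landmark names differ")
    src = source.points if isinstance(source, LandmarkSet) else np.asarray(source, float)
    tgt = target.points if isinstance(target, LandmarkSet) else np.asarray(target, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise PairingError("matched (N, 3) point sets required")
    n = src.shape[0]
    K = _tps_kernel(src, src)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and K[off].min() < 1e-9:
        raise SingularTransformError("duplicate source points make the TPS "
                                     "system singular")
    P = np.column_stack([np.ones(n), src])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = tgt
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularTransformError(f"TPS system is singular: {exc}") from exc
    w = sol[:n]
    poly = sol[n:]  # rows: 1, x, y, z
    affine_part = np.column_stack([poly[1:].T, poly[0]])
    return TPSWarp(source_points=src.copy(), target_points=tgt.copy(),
                   affine_part=affine_part, weights=w)


def tps_apply(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Apply the spline to arbitrary points (..., 3)."""
    pts = np.asarray(points, dtype=float)
    flat = pts.reshape(-1, 3)
    U = _tps_kernel(flat, warp.source_points)
    out = (flat @ warp.affine_part[:, :3].T + warp.affine_part[:, 3]
           + U @ warp.weights)
    return out.reshape(pts.shape)


def tps_bending_energy(warp: TPSWarp) -> float:
    """Bending energy; zero exactly when the displacement is globally affine.

    For the conditionally negative-definite kernel U(r) = r under the
    polynomial constraints, ``-w' K w`` is non-negative and vanishes iff the
    nonlinear weights are all zero.
    """
    K = _tps_kernel(warp.source_points, warp.source_points)
    e = -float(np.einsum("id,ij,jd->", warp.weights, K, warp.weights))
    return max(e, 0.0)


def tps_warp_volume(volume: Volume, warp_target_to_source: TPSWarp,
                    target: Volume | None = None) -> Volume:
    """Resample a volume through a TPS pull-back map.

    ``warp_target_to_source`` must send target-space points into the source
    volume (fit it from the *displaced* landmarks onto the originals to
    render a simulated face).
    """
    target = target or volume
    xyz = target.grid_world()
    src_world = tps_apply(warp_target_to_source, xyz)
    inv = np.linalg.inv(volume.affine)
    vox = src_world @ inv[:3, :3].T + inv[:3, 3]
    from scipy import ndimage

    out = ndimage.map_coordinates(volume.data.astype(float, copy=False),
                                  np.moveaxis(vox, -1, 0), order=1,
                                  mode="constant", cval=0.0, prefilter=False)
    return target.like(out)


def simulate_pc(model: PDMModel, pc_index: int,
                proportions=(0.2, 0.4, 0.6, 0.8, 1.0),
                amplitude_sd: float = 3.0) -> list:
    """Displace the reference along one PC and fit the TPS for each step.

    For each proportion ``p`` the landmarks are displaced by
    ``p * amplitude_sd * sqrt(eigenvalue) * eigenvector`` (``amplitude_sd``
    standard deviations of the mode at full proportion, exaggerating the
    feature relationships the mode encodes).  Returns ``[(landmarks, warp),
    ...]`` where each warp carries the reference onto the displaced set,
    ready for warping the atlas volume or a mesh.

    Raises
    ------
    DomainError
        For a zero-variance (degenerate) mode.
    """
    if not 0 <= pc_index < model.rank:
        raise DomainError(f"pc_index {pc_index} outside model rank {model.rank}")
    lam = model.eigenvalues[pc_index]
    if lam <= 0:
        raise DomainError(f"PC{pc_index + 1} has zero eigenvalue (degenerate)")
    ref = LandmarkSet(model.landmark_names,
                      model.mean_reference.reshape(-1, 3), "model")
    out = []
    for p in proportions:
        amp = float(p) * amplitude_sd * np.sqrt(lam)
        displaced = model.mode_landmarks(pc_index, amp)
        warp = tps_fit(ref, displaced)
        out.append((displaced, warp))
    return out


def save_pdm(model: PDMModel, directory) -> None:
    """Write mean.tsv / eigenvectors.tsv / eigenvalues.tsv / scores.tsv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    np.savetxt(d / "mean.tsv", model.mean_reference[None], delimiter="\t",
               fmt=fmt)
    np.savetxt(d / "eigenvectors.tsv", model.eigenvectors, delimiter="\t",
               fmt=fmt)
    np.savetxt(d / "eigenvalues.tsv", model.eigenvalues[None], delimiter="\t",
               fmt=fmt)
    model.scores.to_csv(d / "scores.tsv", sep="\t", float_format="%.10g")
    with open(d / "landmark_names.tsv", "w") as fh:
        fh.write("\n".join(model.landmark_names) + "\n")


def load_pdm(directory) -> PDMModel:
    d = Path(directory)
    mean = np.loadtxt(d / "mean.tsv", delimiter="\t").ravel()
    vecs = np.loadtxt(d / "eigenvectors.tsv", delimiter="\t")
    vals = np.atleast_1d(np.loadtxt(d / "eigenvalues.tsv", delimiter="\t")).ravel()
    if vecs.ndim == 1:
        vecs = vecs[:, None]
    scores = pd.read_csv(d / "scores.tsv", sep="\t", index_col="subject_id")
    with open(d / "landmark_names.tsv") as fh:
        names = [line.strip() for line in fh if line.strip()]
    return PDMModel(mean, vecs, vals, scores, names)
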