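"""Synthetic brain-stripped head phantoms with full ground truth.

The canonical template is an analytic "head": an ellipsoidal soft-tissue
shell with a bright skull ring and an empty (brain-extracted) interior,
decorated with face-like intensity features — protruding nose, lips, chin,
eye sockets, brow ridges, ears, cheekbones.  Subjects are produced by
*warping this template* with an analytic forward map

    psi = Scale o RandomWarp o FeatureBumps,

so every subject comes with exact ground truth: the deformation that made
it, the true positions of all 56 template landmarks, and the planted
feature/covariate effects.  Feature bumps are Gaussian displacement bumps of
unit weight at their anchor landmark, so a planted feature delta moves its
anchor by exactly that amount (before scaling/warping).

Cohorts plant sex, age and body-fat effects on the feature parameters; the
generator's defaults emulate adolescent craniofacial dimorphism (broader
male jaw and mouth, more prominent female lips, male-specific age slopes)
at desk scale: 64 voxel cubes at 1 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .deformation import DeformationField, invert_field
from .dbm import jacobian_of_field
from .exceptions import ParameterError
from .landmarks import LandmarkSet
from .volume import FWHM_TO_SIGMA, Volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "BodyfatModel",
    "CohortResult",
    "CohortTruth",
    "FEATURES",
    "canonical_template",
    "face_template",
    "feature_bumps",
    "generate_phantom",
    "generate_cohort",
]

# canonical head geometry (world mm; grid is 1-mm isotropic, origin 0)
_CENTER = np.array([32.0, 30.0, 32.0])
_AXES = np.array([18.0, 20.0, 24.0])

#: displaceable feature parameters (deltas in mm from the canonical face)
FEATURES = (
    "nose_length",
    "nose_width",
    "chin_protrusion",
    "jaw_width",
    "lip_thickness",
    "forehead_slope",
    "mouth_width",
)

_FEATURE_BOUND_MM = 8.0
_BUMP_WIDTH_MM = 6.0

# intensity blobs: (center, per-axis sigma, amplitude)
_BLOBS = (
    ((32.0, 50.5, 33.0), (2.5, 3.0, 6.0), 120.0),   # nose ridge
    ((29.5, 50.0, 27.5), (1.2, 1.5, 1.2), -50.0),   # right nostril
    ((34.5, 50.0, 27.5), (1.2, 1.5, 1.2), -50.0),   # left nostril
    ((24.5, 45.5, 42.0), (2.5, 2.0, 1.8), -70.0),   # right eye socket
    ((39.5, 45.5, 42.0), (2.5, 2.0, 1.8), -70.0),   # left eye socket
    ((32.0, 49.0, 26.0), (5.5, 2.0, 2.2), 60.0),    # lips
    ((32.0, 45.5, 15.0), (4.0, 2.5, 3.0), 50.0),    # chin
    ((19.0, 36.0, 17.0), (3.0, 3.0, 3.0), 40.0),    # right jaw angle
    ((45.0, 36.0, 17.0), (3.0, 3.0, 3.0), 40.0),    # left jaw angle
    ((14.5, 30.0, 33.0), (1.5, 2.5, 3.0), 70.0),    # right ear
    ((49.5, 30.0, 33.0), (1.5, 2.5, 3.0), 70.0),    # left ear
    ((25.0, 45.5, 45.5), (3.0, 1.5, 1.5), 40.0),    # right brow ridge
    ((39.0, 45.5, 45.5), (3.0, 1.5, 1.5), 40.0),    # left brow ridge
    ((22.0, 44.0, 34.0), (2.5, 2.5, 2.5), 30.0),    # right cheekbone
    ((42.0, 44.0, 34.0), (2.5, 2.5, 2.5), 30.0),    # left cheekbone
)

# 56 face landmarks: anatomical anchors on the canonical template (world mm).
# Names follow the printed labels of the published accuracy table where
# available; the full original landmark list is not public, so this is a
# documented reconstruction.  Two jaw semi-landmarks are appended
# programmatically below.
_ANCHORS: dict[str, tuple[float, float, float]] = {
    # eyes (10)
    "lateral_right_eye": (20.5, 43.5, 42.0),
    "medial_right_eye": (28.5, 44.5, 42.0),
    "superior_right_eye": (24.5, 44.8, 44.5),
    "inferior_right_eye": (24.5, 44.8, 39.5),
    "center_right_eye": (24.5, 45.5, 42.0),
    "lateral_left_eye": (43.5, 43.5, 42.0),
    "medial_left_eye": (35.5, 44.5, 42.0),
    "superior_left_eye": (39.5, 44.8, 44.5),
    "inferior_left_eye": (39.5, 44.8, 39.5),
    "center_left_eye": (39.5, 45.5, 42.0),
    # nose (9)
    "nose_tip": (32.0, 53.0, 33.0),
    "nose_bridge": (32.0, 50.0, 41.0),
    "nose_dorsum_mid": (32.0, 51.5, 37.0),
    "nose_base_mid": (32.0, 49.5, 27.0),
    "subnasale": (32.0, 49.0, 25.5),
    "right_nostril": (29.5, 50.0, 27.5),
    "left_nostril": (34.5, 50.0, 27.5),
    "right_ala": (28.0, 49.5, 29.0),
    "left_ala": (36.0, 49.5, 29.0),
    # lips (12)
    "mid_mouth_seam": (32.0, 50.5, 26.0),
    "right_mid_mouth_seam": (28.0, 50.0, 26.0),
    "left_mid_mouth_seam": (36.0, 50.0, 26.0),
    "right_mouth_corner": (25.0, 48.5, 26.0),
    "left_mouth_corner": (39.0, 48.5, 26.0),
    "upper_lip_peak_mid": (32.0, 50.5, 28.2),
    "upper_lip_right_peak": (29.5, 50.2, 28.0),
    "upper_lip_left_peak": (34.5, 50.2, 28.0),
    "upper_lip_superior_mid": (32.0, 50.0, 29.5),
    "lower_lip_inferior_mid": (32.0, 50.0, 23.0),
    "right_mid_lower_lip": (28.5, 49.5, 24.0),
    "left_mid_lower_lip": (35.5, 49.5, 24.0),
    # jaw / chin (8 + 2 semi-landmarks appended below)
    "chin_tip": (32.0, 47.0, 15.0),
    "bottom_of_chin": (32.0, 42.0, 10.5),
    "chin_right": (28.0, 45.5, 14.0),
    "chin_left": (36.0, 45.5, 14.0),
    "right_gonion": (19.0, 36.0, 17.0),
    "left_gonion": (45.0, 36.0, 17.0),
    "right_maxillary_process": (22.5, 43.0, 22.0),
    "left_maxillary_process": (41.5, 43.0, 22.0),
    # ears (4)
    "right_ear": (14.5, 30.0, 33.0),
    "left_ear": (49.5, 30.0, 33.0),
    "right_tragus": (15.5, 33.0, 33.0),
    "left_tragus": (48.5, 33.0, 33.0),
    # forehead / brow (6)
    "forehead_mid": (32.0, 44.0, 49.0),
    "glabella": (32.0, 48.0, 44.0),
    "right_brow": (25.0, 45.5, 45.5),
    "left_brow": (39.0, 45.5, 45.5),
    "right_temple": (18.0, 38.0, 42.0),
    "left_temple": (46.0, 38.0, 42.0),
    # zygomatic (5)
    "right_zygomatic_arch": (17.0, 38.0, 36.0),
    "left_zygomatic_arch": (47.0, 38.0, 36.0),
    "right_cheekbone": (22.0, 44.0, 34.0),
    "left_cheekbone": (42.0, 44.0, 34.0),
    "infraorbital_mid": (32.0, 47.5, 38.0),
}


def _semilandmark(a, b):
    return tuple((np.asarray(a) + np.asarray(b)) / 2.0)


def _all_anchors() -> dict:
    anchors = dict(_ANCHORS)
    # semi-landmarks: halfway between the chin tip and the maxillary process
    anchors["right_mid_jaw"] = _semilandmark(
        anchors["bottom_of_chin"], anchors["right_maxillary_process"])
    anchors["left_mid_jaw"] = _semilandmark(
        anchors["bottom_of_chin"], anchors["left_maxillary_process"])
    return anchors


# feature -> list of (anchor landmark, unit direction, weight of the delta)
_FEATURE_MAP = {
    "nose_length": [("nose_tip", (0.0, 1.0, 0.0), 1.0)],
    "nose_width": [("right_ala", (-1.0, 0.0, 0.0), 0.5),
                   ("left_ala", (1.0, 0.0, 0.0), 0.5)],
    "chin_protrusion": [("chin_tip", (0.0, 1.0, 0.0), 1.0)],
    "jaw_width": [("right_gonion", (-1.0, 0.0, 0.0), 0.5),
                  ("left_gonion", (1.0, 0.0, 0.0), 0.5)],
    "lip_thickness": [("mid_mouth_seam", (0.0, 1.0, 0.0), 1.0)],
    "forehead_slope": [("forehead_mid", (0.0, 1.0, 0.0), 1.0)],
    "mouth_width": [("right_mouth_corner", (-1.0, 0.0, 0.0), 0.5),
                    ("left_mouth_corner", (1.0, 0.0, 0.0), 0.5)],
}


def face_template() -> LandmarkSet:
    """The 56-landmark face template on the canonical model (world mm)."""
    anchors = _all_anchors()
    names = list(anchors)
    pts = np.array([anchors[n] for n in names], dtype=float)
    return LandmarkSet(names, pts, "model")


def _analytic_intensity(pts: np.ndarray) -> np.ndarray:
    """Template intensity at arbitrary world points (..., 3)."""
    d = (pts - _CENTER) / _AXES
    rho = np.sqrt((d * d).sum(axis=-1))
    # feature widths are kept at or above ~2 mm so the phantom is properly
    # sampled on a 1-mm grid (real T1 tissue interfaces are no sharper)
    tissue = 100.0 / (1.0 + np.exp(-8.0 * (1.0 - rho)))        # soft tissue
    # smooth fixed intensity texture (muscle/fat heterogeneity): anchors
    # registration tangentially along otherwise uniform surfaces
    x, y, zc = pts[..., 0], pts[..., 1], pts[..., 2]
    texture = (np.cos(0.55 * x + 0.21 * y)
               + np.cos(0.48 * y - 0.33 * zc + 1.3)
               + np.cos(0.42 * zc + 0.27 * x + 2.1)) / 3.0
    val = tissue * (1.0 + 0.18 * texture)
    val -= 100.0 / (1.0 + np.exp(-10.0 * (0.62 - rho)))        # brain removed
    val += 80.0 * np.exp(-(((rho - 0.82) / 0.10) ** 2))        # skull ring
    for center, sig, amp in _BLOBS:
        q = (pts - np.asarray(center)) / np.asarray(sig)
        val = val + amp * np.exp(-0.5 * (q * q).sum(axis=-1))
    return np.clip(val, 0.0, None)


def canonical_template(grid_size: int = 64) -> Volume:
    """The canonical head phantom on a 1-mm isotropic grid."""
    shape = (grid_size,) * 3
    idx = np.indices(shape, dtype=float)
    pts = np.moveaxis(idx, 0, -1)
    return Volume(_analytic_intensity(pts), np.eye(4))


def feature_bumps(feature_deltas: dict) -> list:
    """Displacement bumps (anchor point, direction*amplitude) for deltas.

    Each bump is a Gaussian of width 6 mm with weight exactly 1 at its
    anchor landmark, so a lone feature delta moves that landmark by exactly
    the planted amount.
    """
    anchors = _all_anchors()
    bumps = []
    for name, delta in feature_deltas.items():
        if name not in _FEATURE_MAP:
            raise ParameterError(
                f"unknown feature {name!r}; valid: {FEATURES}")
        if abs(delta) > _FEATURE_BOUND_MM:
            raise ParameterError(
                f"feature {name!r} delta {delta} mm outside plausible bound "
                f"±{_FEATURE_BOUND_MM} mm")
        for anchor_name, direction, weight in _FEATURE_MAP[name]:
            vec = np.asarray(direction) * (weight * delta)
            bumps.append((np.asarray(anchors[anchor_name], dtype=float), vec))
    return bumps


def _bump_displacement(pts: np.ndarray, bumps: list) -> np.ndarray:
    disp = np.zeros_like(pts, dtype=float)
    for anchor, vec in bumps:
        d2 = ((pts - anchor) ** 2).sum(axis=-1)
        w = np.exp(-d2 / (2.0 * _BUMP_WIDTH_MM ** 2))
        disp = disp + w[..., None] * vec
    return disp


def _forward_points(pts: np.ndarray, bumps: list,
                    warp: DeformationField | None,
                    scale: float) -> np.ndarray:
    """The forward map psi = Scale o Warp o Features at world points."""
    out = pts + _bump_displacement(pts, bumps)
    if warp is not None:
        out = out + warp.displacement_at(out)
    if scale != 1.0:
        out = _CENTER + scale * (out - _CENTER)
    return out


def _smooth_random_warp(rng: np.random.Generator, grid_size: int,
                        amplitude_mm: float,
                        blur_fwhm_mm: float = 12.0) -> DeformationField:
    """Gaussian-blurred white-noise vector field with head-RMS amplitude."""
    shape = (grid_size,) * 3
    noise = rng.normal(size=shape + (3,))
    sigma = blur_fwhm_mm * FWHM_TO_SIGMA
    for c in range(3):
        noise[..., c] = ndimage.gaussian_filter(noise[..., c], sigma=sigma,
                                                mode="constant")
    idx = np.indices(shape, dtype=float)
    pts = np.moveaxis(idx, 0, -1)
    d = (pts - _CENTER) / _AXES
    head = (d * d).sum(axis=-1) < 1.2 ** 2
    rms = np.sqrt((noise[head] ** 2).sum(axis=-1).mean())
    if rms > 1e-12:
        noise *= amplitude_mm / rms
    return DeformationField(noise, np.eye(4))


def _forward_field(grid_size: int, bumps: list,
                   warp: DeformationField | None,
                   scale: float) -> DeformationField:
    shape = (grid_size,) * 3
    idx = np.indices(shape, dtype=float)
    pts = np.moveaxis(idx, 0, -1)
    disp = _forward_points(pts, bumps, warp, scale) - pts
    return DeformationField(disp, np.eye(4))


def _clamped_forward(grid_size, bumps, warp, scale, min_jac=0.15,
                     max_tries=6):
    """Forward field with the random warp scaled down until diffeomorphic."""
    for _ in range(max_tries):
        fwd = _forward_field(grid_size, bumps, warp, scale)
        if jacobian_of_field(fwd).min() > min_jac:
            return fwd, warp
        if warp is None:
            break
        warp = DeformationField(warp.displacements * 0.7, warp.affine.copy())
    return _forward_field(grid_size, bumps, warp, scale), warp


@dataclass(frozen=True)
class PhantomSpec:
    """A single synthetic head: feature deltas, noise, bias field, seed.

    Feature deltas are mm offsets from the canonical face; same seed gives a
    bit-identical phantom.
    """

    grid_size: int = 64
    features: dict = dc_field(default_factory=dict)
    noise_sd: float = 2.0
    bias_field: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ParameterError("grid_size must be at least 16")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        feature_bumps(self.features)  # validates names and bounds


def _render_subject(template: Volume, fwd: DeformationField | None,
                    noise_sd: float, bias_field: bool,
                    rng: np.random.Generator
                    ) -> tuple[Volume, DeformationField | None]:
    """Warp the template by the forward map and add noise/bias.

    Returns the subject volume and the pull-back field (subject grid ->
    template) actually used for rendering (None for the identity).
    """
    if fwd is None or np.abs(fwd.displacements).max() < 1e-12:
        vol = template.copy()
        pullback = None
    else:
        pullback = invert_field(fwd, tol_mm=0.02, max_iter=40)
        # render analytically at the pulled-back points: no interpolation,
        # so the stored pull-back field reproduces the volume exactly
        pts = template.grid_world() + pullback.displacements
        vol = template.like(_analytic_intensity(pts))
    data = vol.data
    if bias_field:
        idx = np.indices(vol.shape, dtype=float)
        ramp = (idx[0] / max(vol.shape[0] - 1, 1)
                + 0.5 * idx[2] / max(vol.shape[2] - 1, 1))
        ramp = (ramp - ramp.mean()) / max(np.abs(ramp - ramp.mean()).max(), 1e-9)
        data = data * (1.0 + 0.1 * ramp)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=vol.shape)
    return Volume(data, vol.affine), pullback


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[Volume, LandmarkSet, DeformationField]:
    """Generate one phantom with its true landmarks and true deformation.

    Returns
    -------
    volume : Volume
        The phantom (template warped by the feature bumps, plus noise).
    landmarks : LandmarkSet
        True positions of the 56 template landmarks on this phantom
        (analytic forward map of the template anchors).
    pullback : DeformationField
        The map from the phantom grid back into the canonical template:
        ``resample(canonical_template(), pullback, ...)`` reproduces the
        noise-free phantom.  Zero field when no features are planted.
    """
    rng = np.random.default_rng(spec.seed)
    template = canonical_template(spec.grid_size)
    bumps = feature_bumps(spec.features)
    lm = face_template()
    true_pts = _forward_points(lm.points, bumps, None, 1.0)
    if bumps:
        fwd, _ = _clamped_forward(spec.grid_size, bumps, None, 1.0)
    else:
        fwd = None
    vol, pullback = _render_subject(template, fwd, spec.noise_sd,
                                    spec.bias_field, rng)
    if pullback is None:
        pullback = DeformationField(
            np.zeros((spec.grid_size,) * 3 + (3,)), np.eye(4))
    return vol, LandmarkSet(lm.names, true_pts, "model"), pullback


@dataclass(frozen=True)
class BodyfatModel:
    """Percent body fat: mean/sd, sex offset, optional link to a feature.

    ``feature``/``mm_per_pct`` couple body fat to a face feature (each
    percent above the mean adds that many mm to the feature), which plants
    exactly the confound that PC-score body-fat residualization is meant to
    remove.
    """

    mean: float = 22.0
    sd: float = 7.0
    sex_delta: float = 8.0  # females higher on average
    feature: str | None = None
    mm_per_pct: float = 0.0


def _normalize_age_slopes(age_slope: dict) -> dict:
    out = {}
    for feat, v in (age_slope or {}).items():
        if isinstance(v, dict):
            out[feat] = (float(v.get("male", 0.0)), float(v.get("female", 0.0)))
        else:
            out[feat] = (float(v), float(v))
    return out


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: sample size, planted effects, nuisance levels.

    Defaults emulate the adolescent setting this pipeline is aimed at:
    ages 12-18 years (144-216 months), balanced sexes, a few percent head
    size variation, broader male jaw/mouth, more prominent female lips, and
    male-specific age slopes.  ``sex_effect`` values are mm added for
    females (the female-positive sign convention used by all downstream
    models); ``age_slope`` values are mm/month, optionally per-sex.
    """

    n_subjects: int = 8
    sex_effect: dict = dc_field(default_factory=lambda: {
        "jaw_width": -3.0, "mouth_width": -2.0, "lip_thickness": 1.5})
    age_slope: dict = dc_field(default_factory=lambda: {
        "jaw_width": {"male": 0.06, "female": 0.0},
        "nose_length": {"male": 0.03, "female": 0.015}})
    age_range_months: tuple = (144.0, 216.0)
    headsize_sd: float = 0.03
    deformation_sd: float = 1.5
    noise_sd: float = 2.0
    bodyfat: BodyfatModel = dc_field(default_factory=BodyfatModel)
    zero_mean_warps: bool = False
    grid_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ParameterError("a cohort needs at least 3 subjects")
        if self.headsize_sd < 0 or self.deformation_sd < 0 or self.noise_sd < 0:
            raise ParameterError("spread parameters must be non-negative")
        for feat in list(self.sex_effect) + list(self.age_slope):
            if feat not in _FEATURE_MAP:
                raise ParameterError(f"unknown feature {feat!r}")


@dataclass
class CohortTruth:
    """Everything the generator knows: per-subject ground truth."""

    template: Volume
    template_landmarks: LandmarkSet
    feature_deltas: list
    scales: np.ndarray
    pullback_fields: list
    forward_nonlinear_fields: list
    true_landmarks_linear: list
    true_landmarks_native: list


@dataclass
class CohortResult:
    volumes: list
    covariates: pd.DataFrame
    truth: CohortTruth


def generate_cohort(spec: CohortSpec, render_volumes: bool = True
                    ) -> CohortResult:
    """Generate a cohort with planted sex/age/body-fat effects.

    Per subject: sex ~ Bernoulli(0.5), age uniform in the stated range,
    isotropic head-size scale ~ lognormal(0, headsize_sd), feature deltas =
    sex effect (females) + age slope x centered age (+ body-fat coupling),
    plus a smooth random warp of RMS ``deformation_sd`` mm.  Body fat is
    Gaussian with a sex offset and optionally feeds back into a feature.

    With ``render_volumes=False`` only covariates and landmark-level truth
    are produced (volumes and dense fields are skipped) — used for cheap
    statistical calibration studies.

    The returned truth bundle holds, per subject: the exact pull-back
    deformation used to render the volume, the nonlinear-only forward field
    (features + warp, head size removed — the space in which landmarks are
    compared), and true landmark positions in both spaces.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    template = canonical_template(spec.grid_size) if render_volumes else None
    lm = face_template()
    age_lo, age_hi = spec.age_range_months
    age_mid = 0.5 * (age_lo + age_hi)

    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    ages = rng.uniform(age_lo, age_hi, size=n)
    scales = np.exp(rng.normal(0.0, spec.headsize_sd, size=n))
    slopes = _normalize_age_slopes(spec.age_slope)

    bf = spec.bodyfat
    bodyfat = (bf.mean + np.where(sexes == "F", 0.5, -0.5) * bf.sex_delta
               + rng.normal(0.0, bf.sd, size=n))

    warps: list = []
    for i in range(n):
        if spec.deformation_sd > 0:
            warps.append(_smooth_random_warp(rng, spec.grid_size,
                                             spec.deformation_sd))
        else:
            warps.append(None)
    if spec.zero_mean_warps and spec.deformation_sd > 0:
        mean_disp = np.mean([w.displacements for w in warps], axis=0)
        warps = [DeformationField(w.displacements - mean_disp,
                                  w.affine.copy()) for w in warps]

    volumes, deltas_list, pullbacks, fwd_nl_fields = [], [], [], []
    lms_linear, lms_native = [], []
    for i in range(n):
        female = sexes[i] == "F"
        deltas: dict = {}
        for feat, eff in spec.sex_effect.items():
            if female:
                deltas[feat] = deltas.get(feat, 0.0) + eff
        for feat, (slope_m, slope_f) in slopes.items():
            slope = slope_f if female else slope_m
            deltas[feat] = deltas.get(feat, 0.0) + slope * (ages[i] - age_mid)
        if bf.feature is not None and bf.mm_per_pct:
            deltas[bf.feature] = (deltas.get(bf.feature, 0.0)
                                  + bf.mm_per_pct * (bodyfat[i] - bf.mean))
        deltas = {k: float(np.clip(v, -_FEATURE_BOUND_MM, _FEATURE_BOUND_MM))
                  for k, v in deltas.items()}
        deltas_list.append(deltas)
        bumps = feature_bumps(deltas)

        pts_linear = _forward_points(lm.points, bumps, warps[i], 1.0)
        pts_native = _CENTER + scales[i] * (pts_linear - _CENTER)
        lms_linear.append(LandmarkSet(lm.names, pts_linear, "subject_linear"))
        lms_native.append(LandmarkSet(lm.names, pts_native, "subject_linear"))

        if render_volumes:
            fwd_nl, warp_used = _clamped_forward(spec.grid_size, bumps,
                                                 warps[i], 1.0)
            fwd_total = _forward_field(spec.grid_size, bumps, warp_used,
                                       float(scales[i]))
            vol, pullback = _render_subject(template, fwd_total,
                                            spec.noise_sd, False, rng)
            if pullback is None:
                pullback = DeformationField(
                    np.zeros((spec.grid_size,) * 3 + (3,)), np.eye(4))
            volumes.append(vol)
            pullbacks.append(pullback)
            fwd_nl_fields.append(fwd_nl)

    covariates = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "sex": sexes,
        "age_months": ages,
        "bodyfat_pct": bodyfat,
        "headsize_true": scales ** 3,
    })
    truth = CohortTruth(
        template=template,
        template_landmarks=lm,
        feature_deltas=deltas_list,
        scales=scales,
        pullback_fields=pullbacks,
        forward_nonlinear_fields=fwd_nl_fields,
        true_landmarks_linear=lms_linear,
        true_landmarks_native=lms_native,
    )
    return CohortResult(volumes=volumes, covariates=covariates, truth=truth)
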