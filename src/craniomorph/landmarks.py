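"""Landmark sets, propagation via deformation fields, anthropometrics.

Landmarks are named, ordered 3D points in world mm.  A template defined on
the population average is propagated to each subject by evaluating the
subject's model-to-subject deformation (the inverse of the transform that
carried the subject onto the model).  Because that field lives in the space
of the linear (12-parameter) registration, propagated landmarks are free of
global head-size differences — the registration-based analogue of Procrustes
superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

from .deformation import DeformationField
from .exceptions import DesignError, PairingError
from .volume import AffineTransform

__all__ = [
    "LandmarkSet",
    "AnthropometricSpec",
    "DEFAULT_ANTHROPOMETRICS",
    "propagate_landmarks",
    "landmark_error",
    "anthropometrics",
    "fit_anthro_models",
    "fit_sex_age_models",
    "read_landmarks",
    "write_landmarks",
    "sex_to_numeric",
]


@dataclass
class LandmarkSet:
    """Ordered, named 3D points in world mm.

    ``space_tag`` records which space the coordinates live in: ``"model"``
    for the population average, ``"subject_linear"`` for an individual after
    the linear (head-size-removing) stage.
    """

    names: list
    points: np.ndarray
    space_tag: str = "model"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (len(self.names), 3):
            raise PairingError(
                f"{len(self.names)} names but points of shape {self.points.shape}"
            )
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise PairingError(f"duplicate landmark names: {dupes}")
        if not np.all(np.isfinite(self.points)):
            raise PairingError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def get(self, name: str) -> np.ndarray:
        try:
            return self.points[self.names.index(name)]
        except ValueError:
            raise PairingError(f"no landmark named {name!r}") from None

    def transformed(self, transform: AffineTransform,
                    space_tag: str | None = None) -> "LandmarkSet":
        return LandmarkSet(self.names, transform.apply(self.points),
                           space_tag or self.space_tag)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.names,
            "x_mm": self.points[:, 0],
            "y_mm": self.points[:, 1],
            "z_mm": self.points[:, 2],
            "space_tag": self.space_tag,
        })


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    """Write the TSV interchange format (name, x_mm, y_mm, z_mm, space_tag)."""
    landmarks.to_dataframe().to_csv(path, sep="\t", index=False,
                                    float_format="%.6f")


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path, sep="\t")
    tags = df["space_tag"].unique()
    return LandmarkSet(
        list(df["name"]),
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        str(tags[0]) if len(tags) else "model",
    )


@dataclass(frozen=True)
class AnthropometricSpec:
    """A named inter-landmark distance (two template landmark labels)."""

    measure_name: str
    landmark_a: str
    landmark_b: str


#: classical facial distances, matched to the template landmark names
DEFAULT_ANTHROPOMETRICS = (
    AnthropometricSpec("left_eye_length", "medial_left_eye", "lateral_left_eye"),
    AnthropometricSpec("right_eye_length", "medial_right_eye", "lateral_right_eye"),
    AnthropometricSpec("left_eye_height", "superior_left_eye", "inferior_left_eye"),
    AnthropometricSpec("right_eye_height", "superior_right_eye", "inferior_right_eye"),
    AnthropometricSpec("mouth_width", "right_mouth_corner", "left_mouth_corner"),
    AnthropometricSpec("craniofacial_width_ears", "right_ear", "left_ear"),
    AnthropometricSpec("craniofacial_width_zygoma", "right_zygomatic_arch",
                       "left_zygomatic_arch"),
    AnthropometricSpec("nose_width", "right_ala", "left_ala"),
    AnthropometricSpec("filtrum_length", "nose_base_mid", "upper_lip_peak_mid"),
    AnthropometricSpec("nose_to_chin", "nose_base_mid", "bottom_of_chin"),
    AnthropometricSpec("lip_to_chin", "lower_lip_inferior_mid", "bottom_of_chin"),
)


def propagate_landmarks(model_landmarks: LandmarkSet,
                        subject_inverse: DeformationField) -> LandmarkSet:
    """Map model-space landmarks to a subject with its inverse nonlinear map.

    ``subject_inverse`` is the deformation sending model points to the
    subject (the inverse of the subject's subject-to-model transform, i.e.
    the same pull-back field used to resample the subject onto the model).
    The output is tagged ``subject_linear``: global head-size differences
    were removed by the linear stage, so these coordinates are directly
    comparable across subjects.

    Points falling outside the field's lattice are still mapped (using the
    nearest-node displacement) but flagged ``False`` in ``result.valid``.
    """
    if model_landmarks.space_tag != "model":
        raise PairingError(
            f"expected model-space landmarks, got {model_landmarks.space_tag!r}"
        )
    pts = subject_inverse.map_points(model_landmarks.points)
    inside = subject_inverse.contains(model_landmarks.points)
    return LandmarkSet(model_landmarks.names, pts, "subject_linear",
                       valid=np.asarray(inside, dtype=bool))


def _check_paired(a: LandmarkSet, b: LandmarkSet) -> None:
    if a.names != b.names:
        offenders = sorted(set(a.names) ^ set(b.names)) or ["(ordering differs)"]
        raise PairingError(f"landmark sets do not pair up: {offenders}")


def landmark_error(auto: LandmarkSet, manual: LandmarkSet) -> pd.DataFrame:
    """Per-landmark Euclidean distance (mm) between paired sets."""
    _check_paired(auto, manual)
    d = np.linalg.norm(auto.points - manual.points, axis=1)
    return pd.DataFrame({"name": auto.names, "distance_mm": d})


def anthropometrics(landmarks: LandmarkSet, specs=DEFAULT_ANTHROPOMETRICS
                    ) -> pd.DataFrame:
    """Euclidean inter-landmark distances (mm) for each measure spec."""
    rows = []
    for spec in specs:
        a = landmarks.get(spec.landmark_a)
        b = landmarks.get(spec.landmark_b)
        rows.append({
            "measure": spec.measure_name,
            "distance_mm": float(np.linalg.norm(a - b)),
        })
    return pd.DataFrame(rows)


def sex_to_numeric(sex) -> np.ndarray:
    """Code sex as female = +0.5, male = -0.5.

    With this coding a positive sex coefficient means a greater value in
    females, and the age main effect is the between-sex average slope.
    Accepts "F"/"M" (case-insensitive), "female"/"male", or 1/0 with
    1 = female.
    """
    out = []
    for v in np.asarray(sex).ravel():
        s = str(v).strip().lower()
        if s in ("f", "female", "1", "1.0"):
            out.append(0.5)
        elif s in ("m", "male", "0", "0.0"):
            out.append(-0.5)
        else:
            raise DesignError(f"unrecognized sex code {v!r}")
    return np.asarray(out)


def fit_sex_age_models(values: pd.DataFrame, covariates: pd.DataFrame
                       ) -> pd.DataFrame:
    """Linear models ``value ~ sex + age + age x sex`` per column of values.

    ``values`` is indexed by subject id (one column per measure);
    ``covariates`` must contain ``subject_id``, ``sex`` and ``age_months``.
    Age is centered before forming the interaction.  Sex is coded
    female = +0.5 / male = -0.5, so positive sex coefficients indicate
    greater values in females.  Follow-up per-sex age slopes are reported as
    ``age_slope_male`` / ``age_slope_female`` terms.
    """
    cov = covariates.set_index("subject_id").loc[values.index]
    sex = sex_to_numeric(cov["sex"])
    age = cov["age_months"].to_numpy(dtype=float)
    if np.ptp(age) < 1e-12:
        raise DesignError("age_months is constant")
    if np.ptp(sex) < 1e-12:
        raise DesignError("sex is constant")
    age_c = age - age.mean()
    X = np.column_stack([np.ones_like(age_c), sex, age_c, age_c * sex])
    terms = ["intercept", "sex", "age", "age_x_sex"]

    rows = []
    for measure in values.columns:
        y = values[measure].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        for name, b, se, tv, p in zip(terms, fit.params, fit.bse,
                                      fit.tvalues, fit.pvalues):
            rows.append({"measure": measure, "term": name, "coef": b,
                         "se": se, "t": tv, "p": p})
        # per-sex age slopes: slope_sex = b_age + sex_code * b_interaction
        cov_b = fit.cov_params()
        for label, code in (("age_slope_male", -0.5), ("age_slope_female", 0.5)):
            slope = fit.params[2] + code * fit.params[3]
            var = (cov_b[2, 2] + code ** 2 * cov_b[3, 3]
                   + 2 * code * cov_b[2, 3])
            se = float(np.sqrt(var))
            tv = slope / se
            p = 2 * float(t_dist.sf(abs(tv), fit.df_resid))
            rows.append({"measure": measure, "term": label, "coef": slope,
                         "se": se, "t": tv, "p": p})
    return pd.DataFrame(rows)


def fit_anthro_models(measures: pd.DataFrame, covariates: pd.DataFrame
                      ) -> pd.DataFrame:
    """Sex/age/age-by-sex models of anthropometric distances.

    ``measures`` is a wide table indexed by subject id with one column per
    distance (as produced by stacking :func:`anthropometrics` over
    subjects).  See :func:`fit_sex_age_models` for the model and coding.
    """
    return fit_sex_age_models(measures, covariates)
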