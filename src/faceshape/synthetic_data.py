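"""Synthetic landmark and rating data with fully known ground truth.

The generator emulates a facial-attractiveness study design: a face-like 2-D
landmark template (outline semilandmarks plus fixed interior landmarks) is
displaced along three fixed orthonormal direction fields — a sex-dimorphism
axis and per-unit age and BMI effects — plus independent per-coordinate
individual variation and optional digitization noise; raw configurations can
additionally be rotated, translated and scaled at random (the nuisance
transforms that Procrustes superimposition must remove).  Attractiveness
ratings are drawn from group-specific linear preference functions of the
faces' standardized age, BMI, averageness and sexual-shape-dimorphism
scores, with rater and face random intercepts, and discretized to a 7-point
scale through fixed cutpoints.  Every true parameter is recorded, so each
downstream stage is testable by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from faceshape.landmark_io import (
    LandmarkConfiguration,
    SliderTable,
    ValidationError,
    RATER_GROUPS,
)

__all__ = ["SyntheticConfig", "generate_template", "simulate_faces", "simulate_ratings"]

#: Default group preference weights (intercept, b_age, b_bmi, b_avrg, b_sshd)
#: on the latent rating scale per SD of each predictor.  Magnitudes are in
#: the range typical of facial-attractiveness studies: averageness dominates
#: (more distinct faces rated lower), age and BMI mildly negative, dimorphism
#: weak, with small between-group differences.
DEFAULT_GROUP_WEIGHTS: dict[str, tuple[float, float, float, float, float]] = {
    "CZ": (0.0, -0.20, -0.20, -0.40, -0.10),
    "CZVN": (-0.15, -0.22, -0.17, -0.30, -0.11),
    "AVN": (0.40, -0.17, -0.12, -0.25, -0.12),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Shape parameters are in Procrustes units (the template has centroid size
    1): ``dimorphism_magnitude`` is the full distance between the male and
    female mean shapes; ``age_effect`` and ``bmi_effect`` are displacement
    magnitudes per year and per BMI unit along fixed unit direction fields;
    the two noise SDs are per coordinate.  Rating parameters define a latent
    cumulative-threshold model cut into the 1..7 scale.
    """

    n_per_sex: int = 50
    n_landmarks: int = 72
    n_semilandmarks: int = 36
    dimorphism_magnitude: float = 0.05
    age_effect: float = 0.001
    bmi_effect: float = 0.001
    shape_noise_sd: float = 0.002
    digitization_noise_sd: float = 0.0005
    nuisance: bool = True
    age_range: tuple[float, float] = (19.0, 36.0)
    bmi_mean: float = 23.0
    bmi_sd: float = 2.5
    group_weights: Mapping[str, tuple[float, float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    n_raters_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CZ": 30, "CZVN": 30, "AVN": 30}
    )
    rater_intercept_sd: float = 0.7
    face_intercept_sd: float = 0.6
    residual_sd: float = 0.9
    cutpoints: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_sex < 1:
            raise ValidationError("n_per_sex must be >= 1")
        if self.n_landmarks < 4:
            raise ValidationError("n_landmarks must be >= 4")
        if not (0 <= self.n_semilandmarks < self.n_landmarks):
            raise ValidationError("need 0 <= n_semilandmarks < n_landmarks")
        for name in (
            "dimorphism_magnitude",
            "age_effect",
            "bmi_effect",
            "shape_noise_sd",
            "digitization_noise_sd",
            "rater_intercept_sd",
            "face_intercept_sd",
            "residual_sd",
            "bmi_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        cp = np.asarray(self.cutpoints, dtype=float)
        if len(cp) != 6 or not np.all(np.diff(cp) > 0):
            raise ValidationError("cutpoints must be 6 strictly increasing thresholds")
        for g, w in self.group_weights.items():
            if len(w) != 5:
                raise ValidationError(f"group {g!r}: weights must be length 5")
        for g, n in self.n_raters_per_group.items():
            if n < 1:
                raise ValidationError(f"group {g!r}: n_raters must be >= 1")


def generate_template(
    n_landmarks: int, n_semilandmarks: int
) -> tuple[LandmarkConfiguration, SliderTable]:
    """Deterministic face-like template with slider definitions.

    The outline is an ellipse arc carrying the semilandmarks between two
    fixed anchor landmarks (so every semilandmark has a before/after neighbor
    on the curve); remaining fixed landmarks fill the interior on a sunflower
    (Fermat spiral) layout, which avoids collinearity for any count.  The
    template is centered at the origin with centroid size 1.
    """
    if n_landmarks < 4:
        raise ValidationError(f"n_landmarks must be >= 4, got {n_landmarks}")
    if not (0 <= n_semilandmarks < n_landmarks):
        raise ValidationError(
            f"need 0 <= n_semilandmarks < n_landmarks, got "
            f"({n_landmarks}, {n_semilandmarks})"
        )
    if n_landmarks - n_semilandmarks < 2:
        raise ValidationError(
            "template needs at least 2 fixed landmarks to anchor the outline"
        )
    n_outline = n_semilandmarks + 2 if n_semilandmarks else 0
    n_interior = n_landmarks - n_outline
    pts = []
    # face outline: ellipse, slightly taller than wide
    a_ax, b_ax = 1.0, 1.3
    if n_outline:
        angles = np.linspace(0.0, 2.0 * np.pi, n_outline, endpoint=False)
        pts.append(np.column_stack([a_ax * np.cos(angles), b_ax * np.sin(angles)]))
    if n_interior:
        i = np.arange(n_interior)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        r = 0.65 * np.sqrt((i + 0.5) / n_interior)
        th = i * golden + 0.39
        pts.append(np.column_stack([a_ax * r * np.cos(th), b_ax * r * np.sin(th)]))
    coords = np.vstack(pts)
    coords -= coords.mean(axis=0)
    coords /= np.sqrt(np.sum(coords**2))

    if n_semilandmarks:
        # outline order is 0..n_outline-1; anchors at positions 0 and 1..:
        # semilandmarks are outline positions 1..n_outline-2 (first and last
        # outline points stay fixed), with curve neighbors as before/after.
        rows = [
            (j - 1, j, j + 1) for j in range(1, n_outline - 1)
        ]
        sliders = SliderTable(np.asarray(rows, dtype=int), n_landmarks=n_landmarks)
    else:
        sliders = SliderTable(np.empty((0, 3), dtype=int), n_landmarks=n_landmarks)
    return LandmarkConfiguration("template", coords), sliders


def _tangent_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 2k-4 dim tangent space at a unit preshape.

    The excluded directions are the two translations, the scaling direction
    (the template vector itself) and the in-plane rotation direction.
    """
    k = template.shape[0]
    t = template.ravel()
    rot = np.column_stack([-template[:, 1], template[:, 0]]).ravel()
    tx = np.tile([1.0, 0.0], k) / np.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / np.sqrt(k)
    excluded = np.column_stack([tx, ty, t / np.linalg.norm(t), rot / np.linalg.norm(rot)])
    # complete to a full basis, then drop the excluded block
    q, _ = np.linalg.qr(np.column_stack([excluded, np.eye(2 * k)]))
    return q[:, 4 : 2 * k]


def _direction_fields(template: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Three orthonormal displacement fields in the template's tangent space."""
    basis = _tangent_basis(template)
    raw = rng.standard_normal((basis.shape[1], 3))
    fields = basis @ raw
    # Gram-Schmidt
    for j in range(3):
        for i in range(j):
            fields[:, j] -= (fields[:, j] @ fields[:, i]) * fields[:, i]
        fields[:, j] /= np.linalg.norm(fields[:, j])
    return fields  # columns: u_dim, u_age, u_bmi


def simulate_faces(
    config: SyntheticConfig,
) -> tuple[list[LandmarkConfiguration], pd.DataFrame, pd.DataFrame]:
    """Simulate landmark configurations with known shape ground truth.

    Returns ``(configurations, covariates, truth)``.  The covariate table has
    specimen_id, sex, age, weight_kg, height_m (weight is back-computed from
    the drawn BMI and a sex-typical height so that weight/height^2 equals the
    drawn BMI exactly).  The truth table records each face's drawn BMI, its
    signed coordinate along the dimorphism field (including individual shape
    variation, excluding digitization noise and nuisance transforms) and its
    pre-digitization distance from its own sex's mean shape.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_fields, rng_faces, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    template_cfg, sliders = generate_template(config.n_landmarks, config.n_semilandmarks)
    template = template_cfg.coords
    k = config.n_landmarks
    fields = _direction_fields(template, rng_fields)
    u_dim, u_age, u_bmi = fields[:, 0], fields[:, 1], fields[:, 2]

    n = 2 * config.n_per_sex
    sex = np.array(["F"] * config.n_per_sex + ["M"] * config.n_per_sex)
    s_num = (sex == "F").astype(float)  # F = 1 so positive dimorphism is feminine
    age = rng_faces.uniform(*config.age_range, size=n)
    bmi = rng_faces.normal(config.bmi_mean, config.bmi_sd, size=n)
    bmi = np.clip(bmi, 15.0, 40.0)
    height = np.where(
        sex == "F",
        rng_faces.normal(1.67, 0.06, size=n),
        rng_faces.normal(1.80, 0.07, size=n),
    )
    weight = bmi * height**2

    ids = np.array(
        [f"{s}{i + 1:03d}" for s, i in zip(sex, list(range(config.n_per_sex)) * 2)]
    )

    mean_part = (
        (s_num - 0.5)[:, None] * config.dimorphism_magnitude * u_dim[None, :]
        + age[:, None] * config.age_effect * u_age[None, :]
        + bmi[:, None] * config.bmi_effect * u_bmi[None, :]
    )
    indiv_noise = rng_faces.normal(0.0, config.shape_noise_sd, size=(n, 2 * k))
    clean = template.ravel()[None, :] + mean_part + indiv_noise

    dim_coord = (clean - template.ravel()[None, :]) @ u_dim
    dist_sex_mean = np.empty(n)
    for label in ("F", "M"):
        mask = sex == label
        mu = clean[mask].mean(axis=0)
        dist_sex_mean[mask] = np.linalg.norm(clean[mask] - mu, axis=1)

    configs: list[LandmarkConfiguration] = []
    for i in range(n):
        coords = clean[i].reshape(k, 2)
        if config.nuisance:
            theta = rng_faces.uniform(0.0, 2.0 * np.pi)
            scale = rng_faces.lognormal(0.0, 0.1)
            shift = rng_faces.normal(0.0, 1.0, size=2)
            c, s = np.cos(theta), np.sin(theta)
            coords = scale * coords @ np.array([[c, -s], [s, c]]).T + shift
        if config.digitization_noise_sd > 0:
            coords = coords + rng_faces.normal(
                0.0, config.digitization_noise_sd, size=(k, 2)
            )
        configs.append(LandmarkConfiguration(ids[i], coords))

    covariates = pd.DataFrame(
        {
            "specimen_id": ids,
            "sex": sex,
            "age": age,
            "weight_kg": weight,
            "height_m": height,
        }
    )
    truth = pd.DataFrame(
        {
            "specimen_id": ids,
            "sex": sex,
            "bmi_true": bmi,
            "dim_coord": dim_coord,
            "dist_sex_mean": dist_sex_mean,
        }
    )
    return configs, covariates, truth


def simulate_ratings(
    face_scores: pd.DataFrame,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Simulate long-format attractiveness ratings from group preference weights.

    ``face_scores`` must carry specimen_id, sex, age, bmi, sshd, avrg (the
    output of :func:`faceshape.shape_scores.score_table`).  For each rater
    group g the latent rating of rater i for face j is

        intercept_g + b_age,g z(age_j) + b_bmi,g z(bmi_j)
        + b_avrg,g z(avrg_j) + b_sshd,g z(sshd_j) + u_i + v_j + eps_ij

    with u, v, eps Gaussian; predictors are standardized within each face
    sex.  The latent value is cut at the configured thresholds into 1..7.
    Raters only rate opposite-sex faces.
    """
    config.validate()
    required = {"specimen_id", "sex", "age", "bmi", "sshd", "avrg"}
    missing = required - set(face_scores.columns)
    if missing:
        raise ValidationError(f"face_scores missing columns {sorted(missing)}")
    for g in config.n_raters_per_group:
        if g not in config.group_weights:
            raise ValidationError(f"no preference weights for rater group {g!r}")
        if g not in RATER_GROUPS:
            raise ValidationError(f"unknown rater group {g!r}")

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    cut = np.asarray(config.cutpoints, dtype=float)

    records: list[tuple] = []
    for face_sex, rater_sex in (("F", "M"), ("M", "F")):
        faces = face_scores[face_scores["sex"] == face_sex].reset_index(drop=True)
        if faces.empty:
            continue
        z = {}
        for col in ("age", "bmi", "avrg", "sshd"):
            v = faces[col].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            z[col] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        v_face = rng.normal(0.0, config.face_intercept_sd, size=len(faces))
        for group in RATER_GROUPS:
            if group not in config.n_raters_per_group:
                continue
            w0, w_age, w_bmi, w_avrg, w_sshd = config.group_weights[group]
            fixed = (
                w0
                + w_age * z["age"]
                + w_bmi * z["bmi"]
                + w_avrg * z["avrg"]
                + w_sshd * z["sshd"]
            )
            n_raters = config.n_raters_per_group[group]
            u = rng.normal(0.0, config.rater_intercept_sd, size=n_raters)
            for i in range(n_raters):
                eps = rng.normal(0.0, config.residual_sd, size=len(faces))
                latent = fixed + u[i] + v_face + eps
                ratings = 1 + np.searchsorted(cut, latent, side="left")
                rater_id = f"{group}_{rater_sex}{i + 1:03d}"
                for j, face_id in enumerate(faces["specimen_id"]):
                    records.append(
                        (rater_id, group, rater_sex, face_id, int(ratings[j]))
                    )
    return pd.DataFrame(
        records, columns=["rater_id", "rater_group", "rater_sex", "face_id", "rating"]
    )
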