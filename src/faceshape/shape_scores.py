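"""Per-face shape statistics: sexual shape dimorphism (SShD), averageness, BMI.

SShD is a face's signed position along the axis connecting the male and
female mean shapes in the tangent space of a joint (both-sex) Procrustes
superimposition; higher values are more female-typical.  Averageness
("avrg", distance from the average) is the partial Procrustes distance of a
face to its own-sex consensus from a per-sex superimposition; higher values
mean a more distinct face.  The two fits are deliberately separate: the
dimorphism axis only exists in the pooled sample, while averageness must be
measured against the norm of the face's own sex.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from faceshape.gpa import gpa, procrustes_distance
from faceshape.landmark_io import (
    LandmarkConfiguration,
    SliderTable,
    ValidationError,
)

__all__ = ["bmi", "sshd_scores", "averageness_scores", "score_table"]


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight [kg] divided by squared height [m]."""
    if not (weight_kg > 0):
        raise ValidationError(f"weight must be positive, got {weight_kg}")
    if not (height_m > 0):
        raise ValidationError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


def _check_sexes(sex_labels: Sequence[str], n: int) -> np.ndarray:
    sex = np.asarray(sex_labels)
    if len(sex) != n:
        raise ValidationError("sex_labels length must match dataset size")
    bad = set(sex) - {"F", "M"}
    if bad:
        raise ValidationError(f"unknown sex labels: {sorted(bad)}")
    return sex


def sshd_scores(
    dataset: Sequence[LandmarkConfiguration],
    sex_labels: Sequence[str],
    sliders: SliderTable | None = None,
    normalize: str = "norm",
    max_iter: int = 20,
    tol: float = 1e-8,
) -> np.ndarray:
    """Signed sexual-shape-dimorphism score per specimen.

    A single Procrustes superimposition is run over both sexes together; in
    tangent coordinates the dimorphism axis is v = mean(F) - mean(M) and each
    specimen's score is ((x - g) . v) / ||v|| with g the grand mean, so the
    positive direction is female-typical and scores are in Procrustes units.
    ``normalize="norm_sq"`` divides by ||v||^2 instead (score of the female
    mean minus score of the male mean is then 1).
    """
    sex = _check_sexes(sex_labels, len(dataset))
    for label in ("F", "M"):
        if np.sum(sex == label) < 2:
            raise ValidationError(f"need at least 2 specimens of sex {label!r}")
    aligned = gpa(dataset, sliders=sliders, max_iter=max_iter, tol=tol)
    x = aligned.tangent_coords
    f_mean = x[sex == "F"].mean(axis=0)
    m_mean = x[sex == "M"].mean(axis=0)
    v = f_mean - m_mean
    v_norm = np.linalg.norm(v)
    if v_norm < 1e-12:
        raise ValidationError(
            "male and female mean shapes coincide; dimorphism axis undefined"
        )
    g = x.mean(axis=0)
    denom = v_norm if normalize == "norm" else v_norm**2
    if normalize not in ("norm", "norm_sq"):
        raise ValueError(f"unknown normalize option {normalize!r}")
    return (x - g) @ v / denom


def averageness_scores(
    dataset: Sequence[LandmarkConfiguration],
    sex_labels: Sequence[str],
    sliders: SliderTable | None = None,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> np.ndarray:
    """Averageness per specimen: Procrustes distance to the own-sex consensus.

    A separate superimposition is run within each sex; sexes are never mixed.
    Scores are nonnegative; 0 means the face coincides with its sex's mean
    shape, larger values mean a more distinct face.
    """
    sex = _check_sexes(sex_labels, len(dataset))
    scores = np.full(len(dataset), np.nan)
    for label in np.unique(sex):
        idx = np.flatnonzero(sex == label)
        if len(idx) < 2:
            raise ValidationError(
                f"sex group {label!r} has {len(idx)} specimen(s); need >= 2"
            )
        sub = [dataset[i] for i in idx]
        aligned = gpa(sub, sliders=sliders, max_iter=max_iter, tol=tol)
        for j, i in enumerate(idx):
            scores[i] = procrustes_distance(aligned.aligned[j], aligned.consensus)
    return scores


def score_table(
    dataset: Sequence[LandmarkConfiguration],
    covariates: pd.DataFrame,
    sliders: SliderTable | None = None,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Assemble the per-face score table (specimen_id, sex, age, bmi, sshd, avrg).

    ``covariates`` must contain specimen_id, sex, age, weight_kg, height_m
    for every specimen in the dataset, in any order.
    """
    ids = [c.specimen_id for c in dataset]
    cov = covariates.set_index("specimen_id")
    missing = [i for i in ids if i not in cov.index]
    if missing:
        raise ValidationError(f"covariates missing for specimens {missing[:5]}")
    cov = cov.loc[ids]
    sex = cov["sex"].to_numpy()
    sshd = sshd_scores(dataset, sex, sliders=sliders, max_iter=max_iter, tol=tol)
    avrg = averageness_scores(dataset, sex, sliders=sliders, max_iter=max_iter, tol=tol)
    bmis = [bmi(w, h) for w, h in zip(cov["weight_kg"], cov["height_m"])]
    return pd.DataFrame(
        {
            "specimen_id": ids,
            "sex": sex,
            "age": cov["age"].to_numpy(),
            "bmi": bmis,
            "sshd": sshd,
            "avrg": avrg,
        }
    )
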