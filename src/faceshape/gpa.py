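"""Generalized Procrustes analysis for 2-D landmark configurations.

Implements partial (unit-centroid-size) Procrustes superimposition with a
closed-form 2-D rotation, iterative consensus estimation, orthogonal
tangent-space projection, thin-plate-spline bending energy, and
bending-energy-minimizing sliding of semilandmarks.

Reflections are never permitted: faces (and bilateral structures generally)
have a handedness that an optimal-rotation-with-flip would destroy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from faceshape.landmark_io import LandmarkConfiguration, SliderTable, ValidationError

__all__ = [
    "AlignedShapes",
    "centroid_size",
    "center",
    "preshape",
    "optimal_superimposition",
    "procrustes_distance",
    "gpa",
    "tangent_project",
    "bending_energy_matrix",
    "bending_energy",
    "slide_semilandmarks",
    "DegenerateShapeError",
]


class DegenerateShapeError(ValueError):
    """A configuration has zero centroid size or a singular TPS system."""


@dataclass
class AlignedShapes:
    """Result of a generalized Procrustes superimposition.

    Attributes
    ----------
    aligned : (n, k, 2) ndarray
        Superimposed configurations at unit centroid size, centered at the
        origin, each optimally rotated to the consensus.
    consensus : (k, 2) ndarray
        Mean configuration, centered, centroid size 1.
    centroid_sizes : (n,) ndarray
        Pre-scaling centroid size of each raw specimen.
    tangent_coords : (n, 2k) ndarray
        Vectorized configurations after orthogonal projection onto the
        tangent space at the consensus.
    specimen_ids : list of str
    iterations_used : int
    converged : bool
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    tangent_coords: np.ndarray
    specimen_ids: list[str]
    iterations_used: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of summed squared deviations of landmarks from their centroid."""
    coords = _as_coords(config)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def center(config) -> np.ndarray:
    coords = _as_coords(config)
    return coords - coords.mean(axis=0)


def preshape(config) -> np.ndarray:
    """Center and scale to unit centroid size."""
    centered = center(config)
    size = np.sqrt(np.sum(centered**2))
    if size < 1e-300:
        raise DegenerateShapeError("configuration has zero centroid size")
    return centered / size


def _optimal_rotation_angle(moving: np.ndarray, target: np.ndarray) -> float:
    """Rotation angle (radians, in (-pi, pi]) minimizing ||R(theta) m - t||^2.

    Closed form for 2-D: theta = atan2(sum cross, sum dot).  No reflection is
    considered.  For degenerate (rotation-invariant) cases atan2(0, 0) = 0,
    the smallest-magnitude angle.
    """
    dot = float(np.sum(moving * target))
    cross = float(np.sum(moving[:, 0] * target[:, 1] - moving[:, 1] * target[:, 0]))
    return float(np.arctan2(cross, dot))


def _rotate(coords: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return coords @ rot.T


def optimal_superimposition(moving, target):
    """Optimally rotate a preshape onto a target preshape (no reflection).

    Both inputs must be centered and of unit centroid size.  Returns
    ``(rotation_matrix, aligned_moving, residual_ss)``.
    """
    m = _as_coords(moving)
    t = _as_coords(target)
    if m.shape != t.shape:
        raise ValidationError(f"landmark count mismatch: {m.shape} vs {t.shape}")
    for name, arr in (("moving", m), ("target", t)):
        if np.sqrt(np.sum(center(arr) ** 2)) < 1e-300:
            raise DegenerateShapeError(f"{name} configuration has zero centroid size")
    theta = _optimal_rotation_angle(m, t)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    aligned = m @ rot.T
    residual_ss = float(np.sum((aligned - t) ** 2))
    return rot, aligned, residual_ss


def procrustes_distance(a, b, variant: str = "partial") -> float:
    """Shape distance between two configurations.

    Both are reduced to preshapes (centered, unit centroid size) and
    optimally rotated.  Variants:

    - ``"partial"`` (default): chord distance between unit preshapes,
      sqrt(2 - 2 cos(rho)) where rho is the Procrustes geodesic angle;
    - ``"full"``: sin(rho), the full Procrustes distance with optimal scaling;
    - ``"geodesic"``: rho itself.
    """
    ka = preshape(a)
    kb = preshape(b)
    theta = _optimal_rotation_angle(ka, kb)
    # chord computed from the rotated difference: numerically stable near 0
    chord = float(np.sqrt(np.sum((_rotate(ka, theta) - kb) ** 2)))
    chord = min(chord, 2.0)
    if variant == "partial":
        return chord
    if variant == "full":
        return chord * float(np.sqrt(1.0 - (chord / 2.0) ** 2))
    if variant == "geodesic":
        return 2.0 * float(np.arcsin(chord / 2.0))
    raise ValueError(f"unknown distance variant {variant!r}")


def gpa(
    dataset: Sequence[LandmarkConfiguration] | np.ndarray,
    sliders: SliderTable | None = None,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> AlignedShapes:
    """Generalized Procrustes superimposition of a sample of configurations.

    All configurations are centered and scaled to unit centroid size, then
    iteratively rotated to the current consensus; the consensus is the mean
    of the aligned configurations, re-centered and rescaled to unit size each
    round.  If ``sliders`` is given, one bending-energy sliding pass against
    the current consensus is performed per outer iteration, after which
    configurations are re-centered, re-scaled and re-aligned.  Iteration
    stops when the root summed squared change of the consensus falls below
    ``tol``.
    """
    if isinstance(dataset, np.ndarray):
        coords_list = [np.asarray(c, dtype=float) for c in dataset]
        ids = [f"spec_{i}" for i in range(len(coords_list))]
    else:
        coords_list = [c.coords for c in dataset]
        ids = [c.specimen_id for c in dataset]
    n = len(coords_list)
    if n < 2:
        raise ValidationError("GPA needs at least 2 configurations")
    k = coords_list[0].shape[0]
    for i, c in enumerate(coords_list):
        if c.shape != (k, 2):
            raise ValidationError(
                f"specimen {ids[i]!r}: landmark count {c.shape[0]} != {k}"
            )
    if sliders is not None and len(sliders) and sliders.rows.max() >= k:
        raise ValidationError("slider index out of range for this dataset")

    sizes = np.array([centroid_size(c) for c in coords_list])
    shapes = np.stack([preshape(c) for c in coords_list])

    consensus = shapes[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            theta = _optimal_rotation_angle(shapes[i], consensus)
            shapes[i] = _rotate(shapes[i], theta)
        if sliders is not None and len(sliders):
            be = bending_energy_matrix(consensus)
            for i in range(n):
                slid = slide_semilandmarks(shapes[i], consensus, sliders, be)
                shapes[i] = preshape(slid)
                theta = _optimal_rotation_angle(shapes[i], consensus)
                shapes[i] = _rotate(shapes[i], theta)
        new_consensus = preshape(shapes.mean(axis=0))
        # keep consensus orientation anchored to the previous one
        theta = _optimal_rotation_angle(new_consensus, consensus)
        new_consensus = _rotate(new_consensus, theta)
        change = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # canonical orientation: anchor the consensus to the first specimen's
    # preshape (rotation-optimality is mutual, so re-running gpa on its own
    # aligned output reproduces the same orientation)
    anchor = _optimal_rotation_angle(consensus, preshape(coords_list[0]))
    consensus = _rotate(consensus, anchor)
    for i in range(n):
        theta = _optimal_rotation_angle(shapes[i], consensus)
        shapes[i] = _rotate(shapes[i], theta)

    tangent = tangent_project(shapes, consensus)
    return AlignedShapes(
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        tangent_coords=tangent,
        specimen_ids=ids,
        iterations_used=iterations,
        converged=converged,
    )


def tangent_project(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space.

    The consensus, vectorized and unit-normalized, defines the pole c; each
    vectorized shape x is mapped to c + (x - (x.c) c), i.e. the component of
    x orthogonal to c, offset back to the pole so tangent coordinates remain
    on the scale of the aligned coordinates.  The projection is idempotent
    and for small shape variation preserves Procrustes distances.
    """
    arr = np.asarray(aligned, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    c = np.asarray(consensus, dtype=float).ravel()
    c = c / np.linalg.norm(c)
    x = arr.reshape(arr.shape[0], -1)
    proj = c[None, :] + (x - np.outer(x @ c, c))
    return proj[0] if single else proj


def bending_energy_matrix(reference) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a 2-D reference.

    Builds the TPS system with kernel U(r) = r^2 log(r^2) (U(0) = 0) and the
    affine border Q = [1 | x | y]; returns the upper-left k x k block of the
    inverse bordered matrix [[K, Q], [Q', 0]].  The result is symmetric PSD
    with the affine functions of the reference in its null space.
    """
    ref = _as_coords(reference)
    k = ref.shape[0]
    if k < 4:
        raise ValidationError("bending energy needs at least 4 landmarks")
    r2 = cdist(ref, ref, "sqeuclidean")
    kernel = np.zeros_like(r2)
    nz = r2 > 0
    kernel[nz] = r2[nz] * np.log(r2[nz])
    q = np.column_stack([np.ones(k), ref])
    bordered = np.zeros((k + 3, k + 3))
    bordered[:k, :k] = kernel
    bordered[:k, k:] = q
    bordered[k:, :k] = q.T
    if np.linalg.matrix_rank(q) < 3:
        raise DegenerateShapeError("reference landmarks are collinear; TPS undefined")
    try:
        inv = np.linalg.inv(bordered)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError(
            "singular TPS system (duplicated or collinear reference points)"
        ) from exc
    be = inv[:k, :k]
    return (be + be.T) / 2.0


def bending_energy(config, reference, be: np.ndarray | None = None) -> float:
    """TPS bending energy of the displacement field reference -> config."""
    if be is None:
        be = bending_energy_matrix(reference)
    d = _as_coords(config) - _as_coords(reference)
    return float(d[:, 0] @ be @ d[:, 0] + d[:, 1] @ be @ d[:, 1])


def slide_semilandmarks(
    config,
    reference,
    sliders: SliderTable,
    be: np.ndarray | None = None,
) -> np.ndarray:
    """Slide semilandmarks along their tangents to minimize bending energy.

    Each semilandmark j moves along the unit vector t_j from its
    before-neighbor to its after-neighbor in the current configuration; the
    sliding amounts w solve the generalized least-squares system
    ``min_w (d - T w)' E (d - T w)`` where d is the vectorized displacement
    config - reference and E is the bending energy quadratic form (one block
    per coordinate axis).  Fixed landmarks are unchanged and the post-sliding
    bending energy never exceeds the pre-sliding value.
    """
    coords = _as_coords(config).copy()
    ref = _as_coords(reference)
    if be is None:
        be = bending_energy_matrix(ref)
    m = len(sliders)
    if m == 0:
        return coords
    k = coords.shape[0]
    tangents = np.zeros((m, 2))
    for row_no, (b, s, a) in enumerate(sliders.rows):
        t = coords[a] - coords[b]
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            raise DegenerateShapeError(
                f"slider row {row_no} (landmark {s}): coincident neighbors, "
                "tangent direction undefined"
            )
        tangents[row_no] = t / norm

    dx = coords[:, 0] - ref[:, 0]
    dy = coords[:, 1] - ref[:, 1]
    # T has one column per slider; E-weighted normal equations assembled
    # blockwise (x and y share the same bending-energy block).
    sl = sliders.slider_indices
    tx = np.zeros((k, m))
    ty = np.zeros((k, m))
    tx[sl, np.arange(m)] = tangents[:, 0]
    ty[sl, np.arange(m)] = tangents[:, 1]
    be_tx = be @ tx
    be_ty = be @ ty
    a_mat = tx.T @ be_tx + ty.T @ be_ty
    rhs = be_tx.T @ dx + be_ty.T @ dy
    try:
        cond = np.linalg.cond(a_mat)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateShapeError(
            "singular sliding system: slider tangent directions are linearly "
            "dependent under the bending-energy metric"
        )
    w = np.linalg.solve(a_mat, rhs)
    slid = coords.copy()
    slid[sl, 0] -= tangents[:, 0] * w
    slid[sl, 1] -= tangents[:, 1] * w
    return slid
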