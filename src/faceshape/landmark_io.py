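"""Reading and writing landmark configurations, sliders, covariates and ratings.

Internal conventions: landmark indices are 0-based everywhere; TPS files are
order-based (index-free) so no conversion is needed on that side, while CSV
slider files store 0-based indices.  Coordinates are x rightward, y upward;
``IMAGE=`` lines in TPS files are ignored and axes are never flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RATER_GROUPS = ("CZ", "CZVN", "AVN")

__all__ = [
    "LandmarkConfiguration",
    "SliderTable",
    "TPSParseError",
    "ValidationError",
    "read_tps",
    "write_tps",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_sliders_csv",
    "write_sliders_csv",
    "read_covariates_csv",
    "read_ratings_csv",
    "RATER_GROUPS",
]


class ValidationError(ValueError):
    """An input table or configuration violates a declared invariant."""


def repr_float(x) -> str:
    """Shortest round-trip decimal representation of a float64 (for CSV output)."""
    return repr(float(x))


class TPSParseError(ValueError):
    """A TPS file could not be parsed; the message names the failing record."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark coordinates.

    Parameters
    ----------
    specimen_id : str
        Unique specimen label.
    coords : (k, 2) ndarray
        Ordered landmark coordinates, x rightward, y upward, arbitrary but
        dataset-consistent units.
    """

    specimen_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: coords must be (k, 2), "
                f"got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks, "
                f"got {self.coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class SliderTable:
    """Semilandmark slider definitions: rows of (before, slider, after).

    Indices are 0-based positions in the landmark order.  Each row's three
    indices must be distinct and each slider index may appear only once.
    """

    rows: np.ndarray
    n_landmarks: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        if self.rows.size == 0:
            self.rows = self.rows.reshape(0, 3)
        if self.rows.ndim != 2 or self.rows.shape[1] != 3:
            raise ValidationError("slider table must have rows of (before, slider, after)")
        for i, (b, s, a) in enumerate(self.rows):
            if len({int(b), int(s), int(a)}) != 3:
                raise ValidationError(
                    f"slider row {i}: indices ({b}, {s}, {a}) are not distinct"
                )
            if min(b, s, a) < 0:
                raise ValidationError(f"slider row {i}: negative index")
            if self.n_landmarks is not None and max(b, s, a) >= self.n_landmarks:
                raise ValidationError(
                    f"slider row {i}: index out of range for k={self.n_landmarks}"
                )
        sliders = self.rows[:, 1]
        if len(np.unique(sliders)) != len(sliders):
            raise ValidationError("a slider index appears in more than one row")

    @property
    def slider_indices(self) -> np.ndarray:
        return self.rows[:, 1]

    def __len__(self) -> int:
        return len(self.rows)


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a 2-D TPS file into a list of configurations.

    Records are ``LM=k`` followed by k coordinate lines; ``ID=`` names the
    specimen, ``SCALE=`` multiplies the coordinates, ``IMAGE=`` is ignored.
    All records must share the same k.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record = 0
    k_expected: int | None = None
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        record += 1
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{path.name}, record {record}: expected 'LM=', got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(
                f"{path.name}, record {record}: malformed landmark count {line!r}"
            ) from exc
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines):
                raise TPSParseError(
                    f"{path.name}, record {record}: truncated coordinate block"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path.name}, record {record}, landmark {j + 1}: "
                    f"expected 2 coordinates, got {lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TPSParseError(
                    f"{path.name}, record {record}, landmark {j + 1}: "
                    f"non-numeric coordinate in {lines[i]!r}"
                ) from exc
            i += 1
        specimen_id = f"record_{record}"
        scale = None
        while i < len(lines):
            meta = lines[i].strip()
            if not meta or meta.upper().startswith("LM="):
                break
            key, _, value = meta.partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(
                        f"{path.name}, record {record}: malformed SCALE {meta!r}"
                    ) from exc
            # IMAGE= and other keys are ignored
            i += 1
        if scale is not None:
            coords = coords * scale
        if k_expected is None:
            k_expected = k
        elif k != k_expected:
            raise TPSParseError(
                f"{path.name}, record {record} ({specimen_id}): has {k} landmarks, "
                f"previous records have {k_expected}"
            )
        configs.append(LandmarkConfiguration(specimen_id, coords))
    return configs


def write_tps(dataset: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as TPS; round-trips exactly through :func:`read_tps`."""
    if len(dataset) == 0:
        raise ValidationError("cannot write an empty TPS dataset")
    path = Path(path)
    out: list[str] = []
    for cfg in dataset:
        out.append(f"LM={cfg.k}")
        for x, y in cfg.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={cfg.specimen_id}")
    path.write_text("\n".join(out) + "\n")


def _dataset_frame(dataset: Sequence[LandmarkConfiguration]) -> pd.DataFrame:
    k = dataset[0].k
    cols = ["specimen_id"] + [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    rows = []
    for cfg in dataset:
        if cfg.k != k:
            raise ValidationError(
                f"specimen {cfg.specimen_id!r} has {cfg.k} landmarks, expected {k}"
            )
        rows.append([cfg.specimen_id, *cfg.coords.ravel()])
    return pd.DataFrame(rows, columns=cols)


def write_landmarks_csv(dataset: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    if len(dataset) == 0:
        raise ValidationError("cannot write an empty landmark dataset")
    # shortest round-trip representation: read_landmarks_csv recovers the
    # exact float64 values
    _dataset_frame(dataset).to_csv(path, index=False, float_format=repr_float)


def read_landmarks_csv(path: str | Path) -> list[LandmarkConfiguration]:
    """Read wide-format landmark CSV (specimen_id, x1, y1, x2, y2, ...)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "specimen_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'specimen_id' column")
    coord_cols = [c for c in df.columns if c != "specimen_id"]
    k2 = len(coord_cols)
    if k2 < 6 or k2 % 2:
        raise ValidationError(f"{path}: expected an even number (>=6) of coordinate columns")
    expected = [f"{ax}{i + 1}" for i in range(k2 // 2) for ax in ("x", "y")]
    if coord_cols != expected:
        raise ValidationError(f"{path}: coordinate columns must be x1,y1,x2,y2,...")
    configs = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = np.asarray(row[1:], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"{path}, line {row_no}: non-finite coordinate")
        configs.append(LandmarkConfiguration(str(row[0]), vals.reshape(-1, 2)))
    return configs


def write_sliders_csv(sliders: SliderTable, path: str | Path) -> None:
    pd.DataFrame(sliders.rows, columns=["before", "slider", "after"]).to_csv(
        path, index=False
    )


def read_sliders_csv(path: str | Path, n_landmarks: int | None = None) -> SliderTable:
    """Read a 0-based slider CSV with header ``before,slider,after``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["before", "slider", "after"]:
        raise ValidationError(f"{path}: header must be before,slider,after")
    try:
        rows = df.to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-integer slider index") from exc
    return SliderTable(rows, n_landmarks=n_landmarks)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    """Read specimen covariates (specimen_id, sex, age, weight_kg, height_m)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["specimen_id", "sex", "age", "weight_kg", "height_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["specimen_id"] = df["specimen_id"].astype(str)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.sex not in ("F", "M"):
            raise ValidationError(f"{path}, line {row_no}: sex must be 'F' or 'M'")
        for col in ("age", "weight_kg", "height_m"):
            v = getattr(row, col)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{path}, line {row_no}: {col}={v} must be > 0")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate specimen_id {dup!r}")
    return df


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Read long-format ratings (rater_id, rater_group, rater_sex, face_id, rating).

    Ratings must be integers in 1..7; (rater_id, face_id) must be unique;
    rater_group must be one of CZ, CZVN, AVN.  Missing ratings are simply
    absent rows — no imputation is attempted here.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["rater_id", "rater_group", "rater_sex", "face_id", "rating"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["rater_id"] = df["rater_id"].astype(str)
    df["face_id"] = df["face_id"].astype(str)
    return validate_ratings(df, source=str(path))


def validate_ratings(df: pd.DataFrame, source: str = "ratings") -> pd.DataFrame:
    """Validate a ratings table against its type invariants (never coerces)."""
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        r = row.rating
        if not (float(r).is_integer() and 1 <= r <= 7):
            raise ValidationError(
                f"{source}, line {row_no}: rating {r} outside integer range 1..7"
            )
        if row.rater_group not in RATER_GROUPS:
            raise ValidationError(
                f"{source}, line {row_no}: unknown rater_group {row.rater_group!r}"
            )
        if row.rater_sex not in ("F", "M"):
            raise ValidationError(
                f"{source}, line {row_no}: rater_sex must be 'F' or 'M'"
            )
    dup = df.duplicated(subset=["rater_id", "face_id"])
    if dup.any():
        idx = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValidationError(f"{source}, line {idx}: duplicate (rater_id, face_id)")
    out = df.copy()
    out["rating"] = out["rating"].astype(int)
    return out
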