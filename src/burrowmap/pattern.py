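"""Multitype marked point patterns in a rectangular observation window.

The data model mirrors how territorial-structure surveys are recorded in the
field: each row is one mapped structure (a kangaroo-rat mound or a harvester-ant
colony disc) with planar coordinates in meters, a species/type label, and
optional marks such as disc diameter, occupancy, cohort, or survival status.
Coordinates are continuous planar meters; no projection handling is done.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Window",
    "TypedPointPattern",
    "DistanceCovariate",
    "read_pattern",
    "write_pattern",
    "pairwise_distance_matrix",
    "nn_distance",
    "boundary_distance",
    "build_distance_covariate",
]

#: columns that are coordinates / type, everything else is a mark
_CORE_COLUMNS = ("x", "y", "type")

#: two same-type points closer than this (meters) are considered duplicates
DUPLICATE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, coordinates in meters."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: x [{self.x_min}, {self.x_max}], "
                f"y [{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    def boundary_distance(self, x, y) -> np.ndarray:
        """Distance from interior location(s) to the nearest window edge."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise ValueError("point(s) outside window")
        return np.minimum(
            np.minimum(x - self.x_min, self.x_max - x),
            np.minimum(y - self.y_min, self.y_max - y),
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "Window":
        """Build from ``{"x": [x0, x1], "y": [y0, y1]}`` (YAML/JSON config)."""
        (x0, x1), (y0, y1) = cfg["x"], cfg["y"]
        return cls(float(x0), float(x1), float(y0), float(y1))

    def to_config(self) -> dict:
        return {"x": [self.x_min, self.x_max], "y": [self.y_min, self.y_max]}


class TypedPointPattern:
    """An ordered set of typed, optionally marked points inside a window.

    Parameters
    ----------
    window :
        The rectangular observation window.
    x, y :
        Coordinates in meters, one entry per point.
    types :
        Type label per point (e.g. ``"K"`` for mounds, ``"A"`` for colonies).
    marks :
        Optional DataFrame of mark columns aligned with the points.
    check_duplicates :
        Reject same-type point pairs closer than `duplicate_tol`; coincident
        structures cannot physically exist (hard-core assumption).
    """

    def __init__(
        self,
        window: Window,
        x: Sequence[float],
        y: Sequence[float],
        types: Sequence[str],
        marks: pd.DataFrame | None = None,
        check_duplicates: bool = True,
        duplicate_tol: float = DUPLICATE_TOLERANCE,
    ) -> None:
        x = np.ascontiguousarray(x, dtype=float)
        y = np.ascontiguousarray(y, dtype=float)
        types_arr = np.asarray(types, dtype=object)
        if not (len(x) == len(y) == len(types_arr)):
            raise ValueError("x, y and types must have equal length")
        inside = window.contains(x, y)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)[:5]
            raise ValueError(f"points outside window at rows {bad.tolist()}")
        if marks is not None:
            marks = pd.DataFrame(marks).reset_index(drop=True)
            if len(marks) != len(x):
                raise ValueError("marks must have one row per point")
        self.window = window
        self.x = x
        self.y = y
        self.types = types_arr
        self.marks = marks
        if check_duplicates and len(x) > 1:
            self._check_duplicates(duplicate_tol)

    def _check_duplicates(self, tol: float) -> None:
        tree = cKDTree(self.coords())
        for i, j in tree.query_pairs(tol):
            if self.types[i] == self.types[j]:
                raise ValueError(
                    f"points {i} and {j} of type {self.types[i]!r} are closer "
                    f"than the duplicate tolerance {tol} m"
                )

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.x)

    @property
    def n(self) -> int:
        return len(self.x)

    def type_labels(self) -> list[str]:
        """Distinct type labels, in order of first appearance."""
        return list(dict.fromkeys(self.types))

    def n_by_type(self) -> dict[str, int]:
        labels, counts = np.unique(self.types.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def coords(self, type_label: str | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally restricted to one type."""
        if type_label is None:
            return np.column_stack([self.x, self.y])
        sel = self.types == type_label
        return np.column_stack([self.x[sel], self.y[sel]])

    def subset(self, mask) -> "TypedPointPattern":
        mask = np.asarray(mask)
        marks = self.marks.loc[mask].reset_index(drop=True) if self.marks is not None else None
        return TypedPointPattern(
            self.window, self.x[mask], self.y[mask], self.types[mask],
            marks=marks, check_duplicates=False,
        )

    def of_type(self, type_label: str) -> "TypedPointPattern":
        return self.subset(self.types == type_label)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y, "type": self.types})
        if self.marks is not None:
            df = pd.concat([df, self.marks.reset_index(drop=True)], axis=1)
        return df

    def intensity(self, type_label: str | None = None) -> float:
        """Empirical intensity n / |W| (points per square meter)."""
        n = self.n if type_label is None else int(np.sum(self.types == type_label))
        return n / self.window.area

    def __repr__(self) -> str:
        counts = ", ".join(f"{k}: {v}" for k, v in self.n_by_type().items())
        return (
            f"TypedPointPattern({counts}; window "
            f"{self.window.width:g} x {self.window.height:g} m)"
        )


def read_pattern(
    path: str | Path | io.IOBase,
    window: Window,
    strict: bool = True,
) -> TypedPointPattern:
    """Read a delimited point table (header ``x,y,type[,marks...]``).

    Comma- and tab-delimited files are accepted. Extra columns become marks.
    With ``strict=True`` a point outside the window is a validation error;
    otherwise such rows are dropped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point table is missing required columns: {missing}")
    inside = window.contains(df["x"].to_numpy(float), df["y"].to_numpy(float))
    if not inside.all():
        if strict:
            raise ValueError(
                f"{int((~inside).sum())} point(s) fall outside the window"
            )
        warnings.warn(
            f"dropping {int((~inside).sum())} point(s) outside the window",
            stacklevel=2,
        )
        df = df.loc[inside].reset_index(drop=True)
    mark_cols = [c for c in df.columns if c not in _CORE_COLUMNS]
    marks = df[mark_cols] if mark_cols else None
    return TypedPointPattern(
        window,
        df["x"].to_numpy(float),
        df["y"].to_numpy(float),
        df["type"].astype(str).to_numpy(object),
        marks=marks,
    )


def write_pattern(pattern: TypedPointPattern, path: str | Path) -> None:
    """Write the pattern as CSV in the same dialect `read_pattern` accepts."""
    pattern.to_frame().to_csv(path, index=False)


def pairwise_distance_matrix(
    pattern: TypedPointPattern, type_i: str, type_j: str
) -> np.ndarray:
    """Euclidean distance matrix between points of ``type_i`` and ``type_j``.

    Symmetric with zero diagonal when the two types coincide. Empty types
    yield an empty matrix.
    """
    a = pattern.coords(type_i)
    b = pattern.coords(type_j)
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def nn_distance(
    pattern: TypedPointPattern, from_type: str, to_type: str
) -> np.ndarray:
    """Per from-type point, distance to the nearest to-type point.

    Self is excluded when the two types coincide. Returns an empty array when
    there are not enough opposing points (none; or fewer than two for the
    same-type case).
    """
    src = pattern.coords(from_type)
    dst = pattern.coords(to_type)
    if len(src) == 0:
        return np.zeros(0)
    same = from_type == to_type
    if len(dst) == 0 or (same and len(dst) < 2):
        return np.zeros(0)
    tree = cKDTree(dst)
    if same:
        d, _ = tree.query(src, k=2)
        return d[:, 1]
    d, _ = tree.query(src, k=1)
    return np.atleast_1d(d)


def boundary_distance(point, window: Window) -> float | np.ndarray:
    """Distance from a point (or (n,2) array) inside the window to its edge."""
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    d = window.boundary_distance(pts[:, 0], pts[:, 1])
    return float(d[0]) if np.ndim(point) == 1 else d


class DistanceCovariate:
    """Spatial covariate: exact distance to the nearest reference point.

    Used for e.g. "distance to nearest unoccupied mound" or "distance to
    nearest established colony". Evaluates to zero at the reference points
    and is 1-Lipschitz everywhere.
    """

    def __init__(self, reference_points) -> None:
        pts = np.atleast_2d(np.asarray(reference_points, dtype=float))
        if pts.size == 0:
            raise ValueError("reference point set must be nonempty")
        if pts.shape[1] != 2:
            raise ValueError("reference points must be (n, 2)")
        self.reference_points = pts
        self._tree = cKDTree(pts)

    def __call__(self, location) -> float | np.ndarray:
        loc = np.atleast_2d(np.asarray(location, dtype=float))
        d, _ = self._tree.query(loc, k=1)
        d = np.atleast_1d(d)
        return float(d[0]) if np.ndim(location) == 1 else d


def build_distance_covariate(reference: Iterable) -> DistanceCovariate:
    """Build a nearest-reference-distance covariate from reference locations."""
    return DistanceCovariate(np.asarray(list(reference), dtype=float))
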