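"""Branch-structured vessel centerlines.

A centerline is a set of branches; each branch is an ordered polyline of 3D
points in world mm with a per-point unit tangent.  Branches carry an integer
``branch_id`` and an optional ``parent_id`` linking a side branch to the
branch it bifurcates from.  Centerlines drive patch placement: one patch (or
patch triple) is extracted per centerline point.

File schema
-----------
CSV with header ``branch_id,parent_id,point_index,x_mm,y_mm,z_mm`` (UTF-8,
comma separated, points sorted by (branch_id, point_index); empty or negative
parent_id means a root branch), or an equivalent JSON file
``{"branches": [{"branch_id": .., "parent_id": .., "points": [[x,y,z], ..]}]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContentError, FormatError, ParameterError

__all__ = [
    "Branch",
    "Centerline",
    "read_centerline",
    "write_centerline",
    "resample_centerline",
    "compute_tangents",
]


def compute_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central finite differences (one-sided at endpoints)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ContentError("a branch needs at least 2 points")
    tangents = np.empty_like(points)
    tangents[0] = points[1] - points[0]
    tangents[-1] = points[-1] - points[-2]
    if len(points) > 2:
        tangents[1:-1] = points[2:] - points[:-2]
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ContentError("zero-length tangent (duplicate consecutive points)")
    return tangents / norms


@dataclass
class Branch:
    branch_id: int
    parent_id: int | None
    points: np.ndarray  # (n, 3) world mm
    tangents: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ContentError(
                f"branch {self.branch_id} has {len(self.points)} point(s); need >= 2")
        if self.tangents is None:
            self.tangents = compute_tangents(self.points)
        else:
            self.tangents = np.asarray(self.tangents, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    def arclengths(self) -> np.ndarray:
        """Cumulative arclength from the branch start, per point (mm)."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class Centerline:
    branches: list[Branch]

    def __iter__(self):
        return iter(self.branches)

    def __len__(self) -> int:
        return len(self.branches)

    def n_points(self) -> int:
        return sum(len(b) for b in self.branches)

    def branch(self, branch_id: int) -> Branch:
        for b in self.branches:
            if b.branch_id == branch_id:
                return b
        raise KeyError(f"no branch with id {branch_id}")

    def max_step(self) -> float:
        return max(
            float(np.max(np.linalg.norm(np.diff(b.points, axis=0), axis=1)))
            for b in self.branches)


_CSV_COLUMNS = ["branch_id", "parent_id", "point_index", "x_mm", "y_mm", "z_mm"]


def read_centerline(path: str | Path) -> Centerline:
    """Read a centerline from the CSV or JSON schema described above."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        branches = []
        for rec in data.get("branches", []):
            parent = rec.get("parent_id")
            parent = None if parent in (None, -1, "") else int(parent)
            branches.append(Branch(int(rec["branch_id"]), parent,
                                   np.asarray(rec["points"], dtype=float)))
        if not branches:
            raise ContentError(f"{path}: no branches")
        return Centerline(branches)

    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    branches = []
    for bid, grp in df.groupby("branch_id", sort=True):
        grp = grp.sort_values("point_index")
        parent_raw = grp["parent_id"].iloc[0]
        parent = None if pd.isna(parent_raw) or int(parent_raw) < 0 else int(parent_raw)
        pts = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        branches.append(Branch(int(bid), parent, pts))
    return Centerline(branches)


def write_centerline(cl: Centerline, path: str | Path) -> None:
    rows = []
    for b in cl.branches:
        parent = -1 if b.parent_id is None else b.parent_id
        for i, p in enumerate(b.points):
            rows.append((b.branch_id, parent, i, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _resample_polyline(points: np.ndarray, max_step_mm: float) -> np.ndarray:
    # Subdivide each segment separately so original vertices are retained and
    # total arclength is preserved exactly.
    out = [points[0]]
    for p, q in zip(points[:-1], points[1:]):
        length = float(np.linalg.norm(q - p))
        if length == 0:
            continue
        n = max(1, int(np.ceil(length / max_step_mm - 1e-12)))
        ts = np.arange(1, n + 1) / n
        out.extend(p + t * (q - p) for t in ts)
    if len(out) < 2:
        out.append(points[-1])
    return np.asarray(out)


def resample_centerline(cl: Centerline, max_step_mm: float = 0.25) -> Centerline:
    """Arclength-resample every branch so consecutive node distance never
    exceeds ``max_step_mm`` (piecewise linear; endpoints preserved exactly)."""
    if max_step_mm <= 0:
        raise ParameterError(f"max_step_mm must be positive, got {max_step_mm}")
    return Centerline([
        Branch(b.branch_id, b.parent_id, _resample_polyline(b.points, max_step_mm))
        for b in cl.branches
    ])
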