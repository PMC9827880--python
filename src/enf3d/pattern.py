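"""Marked 3D point patterns of nerve-tree points.

A pattern holds the base points (where a nerve trunk enters the epidermis),
the first branching points, and the end points (terminations) of the nerve
trees in one sample, together with the tree membership linking them and the
observation window.  The pattern is the central object every other module
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .window import BoxWindow

__all__ = ["PointPattern3D", "POINT_TYPES", "min_interpoint_distance"]

POINT_TYPES = ("base", "branching", "end")


@dataclass
class PointPattern3D:
    """A simple marked point pattern in a 3D box window.

    Parameters
    ----------
    coords : (n, 3) float array
        Point coordinates in μm.
    types : (n,) array of str
        Mark per point, one of ``{"base", "branching", "end"}``.
    tree_ids : (n,) int array
        Tree membership; base points carry their own id and branching/end
        points reference it.  ``-1`` marks an unassigned point.
    window : BoxWindow
        3D observation box; every point must lie inside it (closed box).
    labels : dict
        Optional study-hierarchy labels (``group``, ``subject``, ``sample``).
    metadata : dict
        Free-form provenance (e.g. generating parameters for synthetic data).
    """

    coords: np.ndarray
    types: np.ndarray
    tree_ids: np.ndarray
    window: BoxWindow
    labels: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    #: single-mark sub-patterns keep tree ids but cannot resolve them
    check_tree_refs: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.types = np.asarray(self.types, dtype=object).reshape(-1)
        self.tree_ids = np.asarray(self.tree_ids, dtype=int).reshape(-1)
        n = len(self.coords)
        if len(self.types) != n or len(self.tree_ids) != n:
            raise ValueError("coords, types and tree_ids must have equal length")
        if self.window.ndim != 3:
            raise ValueError("PointPattern3D requires a 3D window")
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        bad_type = [t for t in np.unique(self.types) if t not in POINT_TYPES]
        if bad_type:
            raise ValueError(f"unknown point types: {bad_type}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        inside = self.window.contains(self.coords) if self.n else np.ones(0, bool)
        if not np.all(inside):
            rows = np.flatnonzero(~inside)
            raise ValueError(f"points outside the window at rows {rows.tolist()}")
        # simplicity: no two points may share identical coordinates
        if self.n > 1:
            _, first, counts = np.unique(
                self.coords, axis=0, return_index=True, return_counts=True
            )
            if np.any(counts > 1):
                dup = first[counts > 1]
                raise ValueError(f"duplicate coordinates (pattern not simple), e.g. rows {dup.tolist()}")
        # tree references: every assigned branching/end id must match a base point
        if self.check_tree_refs:
            base_ids = set(self.tree_ids[self.types == "base"].tolist())
            child = (self.types != "base") & (self.tree_ids >= 0)
            dangling = sorted(set(self.tree_ids[child].tolist()) - base_ids)
            if dangling:
                raise ValueError(f"tree ids without a base point: {dangling}")

    # -- accessors ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.coords)

    def mask_of(self, kind: str) -> np.ndarray:
        if kind not in POINT_TYPES:
            raise ValueError(f"unknown point type {kind!r}")
        return self.types == kind

    def points_of(self, kind: str) -> np.ndarray:
        """Coordinates of all points of one mark, shape ``(m, 3)``."""
        return self.coords[self.mask_of(kind)]

    def count_of(self, kind: str) -> int:
        return int(np.count_nonzero(self.mask_of(kind)))

    def subset(self, kind: str) -> "PointPattern3D":
        """Sub-pattern containing a single mark (keeps window and labels)."""
        m = self.mask_of(kind)
        return PointPattern3D(
            self.coords[m], self.types[m], self.tree_ids[m], self.window,
            dict(self.labels), dict(self.metadata),
            check_tree_refs=(kind == "base"),
        )


def min_interpoint_distance(pattern: PointPattern3D | np.ndarray, kind: str = "end") -> float:
    """Minimum 3D Euclidean distance over all distinct pairs of one mark.

    This is the observed ``d_min`` entering the hardcore estimator; by
    default it is taken over the end points, the mark the interaction model
    applies to.  Raises if fewer than two points of the mark are present.
    """
    if isinstance(pattern, PointPattern3D):
        pts = pattern.points_of(kind)
    else:
        pts = np.asarray(pattern, dtype=float)
    if len(pts) < 2:
        raise ValueError(
            f"d_min undefined: need at least 2 points of type {kind!r}, got {len(pts)}"
        )
    return float(pdist(pts).min())
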