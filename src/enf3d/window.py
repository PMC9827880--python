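"""Axis-aligned observation windows (2D rectangles and 3D boxes).

Skin-biopsy samples are observed in rectangular boxes whose planar extent is
fixed by the imaging protocol (320 x 432 μm by default) and whose depth
``zmax`` follows the local thickness of the epidermis.  The window owns all
geometry used by the estimators: Lebesgue measure, translation-overlap
volumes for edge correction, and erosion for minus sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoxWindow", "translation_overlap", "erode_window"]


@dataclass(frozen=True)
class BoxWindow:
    """Axis-aligned box ``[xmin,xmax] x [ymin,ymax] (x [0,zmax])``.

    ``zmax=None`` denotes a planar (2D) window.  The z extent always starts
    at 0: depth is measured from the bottom of the imaged box.

    All lengths are in μm.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    zmax: float | None = None

    #: the z origin is fixed by convention
    zmin: float = 0.0

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"degenerate window extents: {self}")
        if self.zmax is not None and not (self.zmax > self.zmin):
            raise ValueError(f"non-positive window depth: zmax={self.zmax}")

    # -- basic geometry -------------------------------------------------
    @classmethod
    def from_extents(cls, xmax: float, ymax: float, zmax: float | None = None) -> "BoxWindow":
        """Window anchored at the origin with the given side lengths."""
        return cls(0.0, float(xmax), 0.0, float(ymax), None if zmax is None else float(zmax))

    @property
    def ndim(self) -> int:
        return 2 if self.zmax is None else 3

    @property
    def sides(self) -> np.ndarray:
        """Side lengths, shape ``(ndim,)``."""
        s = [self.xmax - self.xmin, self.ymax - self.ymin]
        if self.zmax is not None:
            s.append(self.zmax - self.zmin)
        return np.asarray(s, dtype=float)

    @property
    def lower(self) -> np.ndarray:
        lo = [self.xmin, self.ymin]
        if self.zmax is not None:
            lo.append(self.zmin)
        return np.asarray(lo, dtype=float)

    @property
    def upper(self) -> np.ndarray:
        hi = [self.xmax, self.ymax]
        if self.zmax is not None:
            hi.append(self.zmax)
        return np.asarray(hi, dtype=float)

    @property
    def measure(self) -> float:
        """Lebesgue measure: area (μm²) in 2D, volume (μm³) in 3D."""
        return float(np.prod(self.sides))

    @property
    def area(self) -> float:
        """Area of the planar projection (μm²)."""
        return float((self.xmax - self.xmin) * (self.ymax - self.ymin))

    def projection(self) -> "BoxWindow":
        """The 2D (xy) projection of the window."""
        return BoxWindow(self.xmin, self.xmax, self.ymin, self.ymax, None)

    # -- membership -----------------------------------------------------
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Closed-box membership test for an ``(n, ndim)`` array of points.

        Boundary points count as inside, so traced points lying exactly on
        a slide boundary are never dropped.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.ndim:
            raise ValueError(f"points are {pts.shape[1]}D but window is {self.ndim}D")
        return np.all((pts >= self.lower) & (pts <= self.upper), axis=1)

    def erode(self, margin_xy: float, margin_z: float = 0.0) -> "BoxWindow":
        """Inner window shrunk by ``margin_xy`` on all four planar sides and
        by ``margin_z`` on both z sides (minus sampling).

        Raises ``ValueError`` if the erosion collapses any side.
        """
        if margin_xy < 0 or margin_z < 0:
            raise ValueError("erosion margins must be non-negative")
        if self.zmax is None and margin_z > 0:
            raise ValueError("margin_z > 0 on a planar window")
        new_zmax = None
        if self.zmax is not None:
            new_zmax = self.zmax - margin_z
            if new_zmax - (self.zmin + margin_z) <= 0:
                raise ValueError("erosion collapses the window in z")
        xmin, xmax = self.xmin + margin_xy, self.xmax - margin_xy
        ymin, ymax = self.ymin + margin_xy, self.ymax - margin_xy
        if xmax - xmin <= 0 or ymax - ymin <= 0:
            raise ValueError("erosion collapses the window in xy")
        if new_zmax is None:
            return BoxWindow(xmin, xmax, ymin, ymax, None)
        return BoxWindow(xmin, xmax, ymin, ymax, new_zmax, self.zmin + margin_z)

    def translation_overlap(self, shift) -> float:
        """Measure of ``W ∩ W_shift``, the window intersected with itself
        translated by ``shift`` (the translation edge-correction weight).

        Equals ``∏_k max(0, L_k − |shift_k|)``; symmetric in the sign of
        the shift and non-increasing in each ``|shift_k|``.
        """
        s = np.asarray(shift, dtype=float)
        if s.shape != (self.ndim,):
            raise ValueError(
                f"shift has {s.shape} components but window is {self.ndim}D"
            )
        return float(np.prod(np.maximum(0.0, self.sides - np.abs(s))))


def translation_overlap(window: BoxWindow, shift) -> float:
    """Functional form of :meth:`BoxWindow.translation_overlap`."""
    return window.translation_overlap(shift)


def erode_window(window: BoxWindow, margin_xy: float, margin_z: float = 0.0) -> BoxWindow:
    """Functional form of :meth:`BoxWindow.erode`."""
    return window.erode(margin_xy, margin_z)
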