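"""Second-order summary statistics for (an)isotropic point patterns.

Implements translation-corrected estimators of Ripley's K function and of
the cylindrical K function, their variance-stabilised centred L variants,
and the weighted pooling used for replicated, hierarchically structured
patterns (samples within subjects within groups).

Estimators
----------
Isotropic K, translation edge correction::

    K(r) = 1/(λ n) Σ'  1{‖x1−x2‖ ≤ r} / |W ∩ W_{x2−x1}|,   λ = n/|W|

Cylindrical K in axis direction u with half-width w::

    K_cyl^u(r) = 1/λ2 Σ'  1{x1−x2 ∈ B_u(r, w)} / |W ∩ W_{x2−x1}|,
    λ2 = n(n−1)/|W|²

where the sums run over distinct ordered pairs and ``B_u(r, w)`` is the
cylinder of radius ``w`` and half-height ``r`` oriented along ``u``.  With
this structuring set ``K_cyl^u(r) = 2π w² r`` under complete spatial
randomness, so the centred variant ``L_cyl^u(r) − r = K_cyl^u(r)/(2πw²) − r``
is exactly zero in the CSR case, mirroring ``L(r) − r`` for the isotropic
statistic.  Positive values indicate clustering along ``u``; negative
values regularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as _gamma_fn

from .pattern import PointPattern3D
from .window import BoxWindow

__all__ = [
    "SummaryFunction",
    "default_r_grid",
    "k_translation",
    "k_cylindrical",
    "l_transform",
    "pool",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class SummaryFunction:
    """A summary function estimated on an r grid, with pooling metadata.

    ``direction`` is ``None`` for the isotropic statistic or one of
    ``"x"/"y"/"z"`` for the cylindrical one; ``half_width`` (μm) is the
    cylinder radius and is ``None`` for isotropic functions.  ``weight``
    carries the pattern's pooling weight (by default the number of points
    that produced the estimate).
    """

    r: np.ndarray
    values: np.ndarray
    direction: str | None = None
    half_width: float | None = None
    weight: float = 1.0
    kind: str = "K"
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).reshape(-1)
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.r.shape != self.values.shape:
            raise ValueError("r grid and values must have the same length")
        if len(self.r) > 1 and not np.all(np.diff(self.r) > 0):
            raise ValueError("r grid must be strictly increasing")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.direction is not None and self.direction not in _AXES:
            raise ValueError(f"direction must be one of {sorted(_AXES)} or None")

    def compatible_with(self, other: "SummaryFunction") -> bool:
        return (
            self.r.shape == other.r.shape
            and np.array_equal(self.r, other.r)
            and self.direction == other.direction
            and self.kind == other.kind
            and (
                (self.half_width is None and other.half_width is None)
                or (
                    self.half_width is not None
                    and other.half_width is not None
                    and np.isclose(self.half_width, other.half_width)
                )
            )
        )


def default_r_grid(r_max: float = 30.0, dr: float = 0.5) -> np.ndarray:
    """Default grid 0..30 μm in 0.5 μm steps — the scale of the end-point
    clusters."""
    return np.arange(0.0, r_max + dr / 2, dr)


def _as_coords(pattern) -> np.ndarray:
    if isinstance(pattern, PointPattern3D):
        return pattern.coords
    return np.atleast_2d(np.asarray(pattern, dtype=float))


def _pair_arrays(coords: np.ndarray, window: BoxWindow):
    """Upper-triangle pair differences and translation weights.

    Returns ``(diffs, overlap)`` for all unordered pairs; each unordered
    pair stands for two ordered pairs with equal overlap volume.
    """
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    diffs = coords[iu] - coords[ju]
    overlap = np.prod(np.maximum(0.0, window.sides - np.abs(diffs)), axis=1)
    return diffs, overlap


def _cumulative(thresholds, contrib, r_grid, bad_thresholds):
    """Sum ``contrib`` over pairs with ``threshold ≤ r`` for each grid r;
    r values reached by a zero-overlap pair are flagged undefined (NaN)."""
    order = np.argsort(thresholds)
    thr = thresholds[order]
    csum = np.concatenate([[0.0], np.cumsum(contrib[order])])
    values = csum[np.searchsorted(thr, r_grid, side="right")]
    if bad_thresholds.size:
        values[r_grid >= bad_thresholds.min()] = np.nan
    return values


def k_translation(pattern, window: BoxWindow, r_grid=None) -> SummaryFunction:
    """Translation-corrected estimate of Ripley's K function.

    Works on 2D or 3D point sets; the window dimensionality must match.
    Raises for patterns with fewer than two points.
    """
    coords = _as_coords(pattern)
    if coords.shape[1] != window.ndim:
        raise ValueError("point and window dimensionality differ")
    n = len(coords)
    if n < 2:
        raise ValueError("K estimation requires at least 2 points")
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)

    diffs, overlap = _pair_arrays(coords, window)
    dist = np.linalg.norm(diffs, axis=1)
    ok = overlap > 0
    contrib = np.zeros_like(overlap)
    contrib[ok] = 2.0 / overlap[ok]  # ordered pairs
    # normalisation 1/(λ̂ n) with λ̂ = n/|W|
    values = (window.measure / n**2) * _cumulative(dist, contrib, r_grid, dist[~ok])

    labels = dict(pattern.labels) if isinstance(pattern, PointPattern3D) else {}
    return SummaryFunction(r_grid, values, None, None, weight=float(n), kind="K", labels=labels)


def k_cylindrical(
    pattern,
    window: BoxWindow,
    direction: str,
    half_width: float,
    r_grid=None,
) -> SummaryFunction:
    """Translation-corrected cylindrical K function along a coordinate axis.

    A pair contributes at distance r when its displacement lies in the
    cylinder ``B_u(r, w)``: component along ``direction`` at most r in
    absolute value, perpendicular planar distance at most ``half_width``.
    """
    coords = _as_coords(pattern)
    if coords.shape[1] != 3 or window.ndim != 3:
        raise ValueError("the cylindrical K function is defined for 3D patterns")
    if direction not in _AXES:
        raise ValueError(f"direction must be one of {sorted(_AXES)}")
    if not half_width > 0:
        raise ValueError("half_width must be positive")
    n = len(coords)
    if n < 2:
        raise ValueError("K estimation requires at least 2 points")
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)

    axis = _AXES[direction]
    perp_axes = [a for a in range(3) if a != axis]
    diffs, overlap = _pair_arrays(coords, window)
    axial = np.abs(diffs[:, axis])
    perp = np.linalg.norm(diffs[:, perp_axes], axis=1)

    in_cyl = perp <= half_width
    ok = overlap > 0
    sel = in_cyl & ok
    contrib = 2.0 / overlap[sel]
    # λ2̂ = n(n−1)/|W|²
    lam2 = n * (n - 1) / window.measure**2
    values = _cumulative(axial[sel], contrib, r_grid, axial[in_cyl & ~ok]) / lam2

    labels = dict(pattern.labels) if isinstance(pattern, PointPattern3D) else {}
    return SummaryFunction(
        r_grid, values, direction, float(half_width), weight=float(n), kind="K", labels=labels
    )


def unit_ball_volume(d: int) -> float:
    """Volume ``b_d`` of the unit ball in ``R^d``."""
    return float(np.pi ** (d / 2) / _gamma_fn(d / 2 + 1))


def l_transform(summary: SummaryFunction, dimension: int | None = None) -> SummaryFunction:
    """Centred L transform of a K-type summary function.

    Isotropic: ``L(r) − r = (K(r)/b_d)^{1/d} − r`` with ``b_d`` the unit-ball
    volume in dimension ``d``.  Cylindrical (3D): ``K_cyl(r)/(2πw²) − r``.
    Either way the result vanishes identically under CSR.
    """
    finite = np.isfinite(summary.values)
    if np.any(summary.values[finite] < 0):
        raise ValueError("K values must be non-negative")
    if summary.direction is None:
        if dimension is None:
            raise ValueError("dimension required for the isotropic L transform")
        vals = (summary.values / unit_ball_volume(dimension)) ** (1.0 / dimension) - summary.r
    else:
        if summary.half_width is None:
            raise ValueError("cylindrical L transform requires a known half-width")
        vals = summary.values / (2 * np.pi * summary.half_width**2) - summary.r
    out = replace(summary, values=vals)
    out.kind = "L-r"
    return out


def pool(functions, weights=None) -> SummaryFunction:
    """Pointwise weighted mean of summary functions on a common r grid.

    Used in two stages for replicated data: the samples of a subject are
    pooled into a subjectwise function, and subjectwise functions into a
    groupwise one.  The returned weight is the sum of the input weights, so
    two-stage pooling with carried-forward weights reproduces the one-stage
    pooled estimate exactly.
    """
    functions = list(functions)
    if not functions:
        raise ValueError("nothing to pool")
    ref = functions[0]
    for f in functions[1:]:
        if not ref.compatible_with(f):
            raise ValueError("summary functions with mismatched grids or metadata")
    w = np.asarray(
        [f.weight for f in functions] if weights is None else weights, dtype=float
    )
    if len(w) != len(functions):
        raise ValueError("one weight per function required")
    if np.any(w < 0) or not w.sum() > 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    stacked = np.stack([f.values for f in functions])
    pooled = w @ stacked
    return SummaryFunction(
        ref.r.copy(), pooled, ref.direction, ref.half_width,
        weight=float(sum(f.weight for f in functions) if weights is None else np.sum(weights)),
        kind=ref.kind,
    )
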