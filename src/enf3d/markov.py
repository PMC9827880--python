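"""Pairwise-interaction Markov random field for end-point depths.

Given the planar locations of the end points, the vector of z-coordinates
follows a Gibbs density proportional to ``γ^{s_B} · 1{hardcore}``, where
``s_B`` counts the unordered pairs of points that are neighbours — the
displacement lies in a cylinder of radius ``w`` and half-height ``t``
oriented along z — and the hardcore indicator requires every pair of
points to be strictly further than ``h`` apart in 3D.  ``γ = 1`` means no
interaction, ``γ > 1`` attraction and ``γ < 1`` repulsion between
neighbouring end points.

The full conditional of a single depth ``z_i`` is
``f(z_i | rest) = γ^{s_i(z_i)} 1{hardcore} / c_i`` with ``s_i`` the number
of neighbours of point i and ``c_i`` a 1D normalising integral over the
depth window ``Wz = [0, zmax]``.  Because the planar locations are fixed,
the integrand is piecewise constant in z — neighbour relations toggle at
``z_j ± t`` and the hardcore constraint toggles at
``z_j ± sqrt(h² − d_xy²)`` — so ``c_i`` is computed exactly.

Parameters are estimated by maximising the log pseudo-likelihood
``Σ_i log f(z_i | rest)`` in γ for every cell of a (w, t) grid, after
plugging in the hardcore estimate ``ĥ = (n−1) d_min / n``; the grid cell
with the highest pseudo-likelihood supplies ``(ŵ, t̂, γ̂)``.  Minus
sampling restricts the sum to points of an eroded window while neighbour
counts still use every observed point, which removes most of the edge
bias.  Simulation is by a fixed-n single-site Metropolis–Hastings sampler
with uniform proposals, whose acceptance ratio needs only the interaction
term because ``c_i`` cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .pattern import PointPattern3D, min_interpoint_distance
from .window import BoxWindow

__all__ = [
    "MarkovZParams",
    "FitResult",
    "neighbor_counts",
    "neighbor_count_si",
    "pair_neighbor_count",
    "hardcore_ok",
    "normalizing_constant_ci",
    "conditional_density",
    "estimate_hardcore",
    "log_pseudolikelihood",
    "fit_markov",
    "simulate_z",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class MarkovZParams:
    """Parameters (γ, h, w, t) of the conditional Markov field plus the
    depth ``zmax`` of the window ``Wz = [0, zmax]``.

    ``w`` and ``t`` (μm) are the radius and half-height of the cylindrical
    interaction region (cylinder height ``2t``); ``h`` (μm) is the hardcore
    distance below which configurations have density zero; ``gamma`` is the
    dimensionless pairwise interaction weight.
    """

    gamma: float
    h: float
    w: float
    t: float
    zmax: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.h < 0:
            raise ValueError("hardcore distance must be non-negative")
        if not (self.w > 0 and self.t > 0):
            raise ValueError("cylinder parameters w and t must be positive")
        if not self.zmax > 0:
            raise ValueError("zmax must be positive")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in ("gamma", "h", "w", "t", "zmax")}

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovZParams":
        return cls(**{k: float(d[k]) for k in ("gamma", "h", "w", "t", "zmax")})


@dataclass
class FitResult:
    """Result of the grid-search / pseudo-likelihood fit."""

    params: MarkovZParams
    log_pl: float
    grid: np.ndarray  # structured array: w, t, gamma, log_pl per grid cell
    n_interior: int
    h: float

    def __post_init__(self) -> None:
        if len(self.grid) and self.log_pl < np.max(self.grid["log_pl"]) - 1e-9:
            raise AssertionError("reported optimum is not the grid maximum")


# ---------------------------------------------------------------------------
# neighbour and hardcore primitives
# ---------------------------------------------------------------------------

def _coords_of(pattern) -> np.ndarray:
    if isinstance(pattern, PointPattern3D):
        return pattern.points_of("end")
    return np.atleast_2d(np.asarray(pattern, dtype=float))


def neighbor_counts(coords: np.ndarray, w: float, t: float) -> np.ndarray:
    """Per-point neighbour counts ``s_i`` under the cylindrical relation.

    Points i and j are neighbours when their planar distance is at most
    ``w`` and their depth difference at most ``t``.  The relation is
    symmetric, so ``Σ_i s_i`` is twice the pair count ``s_B``.
    """
    c = np.asarray(coords, dtype=float)
    dxy = np.linalg.norm(c[:, None, :2] - c[None, :, :2], axis=-1)
    dz = np.abs(c[:, None, 2] - c[None, :, 2])
    adj = (dxy <= w) & (dz <= t)
    np.fill_diagonal(adj, False)
    return adj.sum(axis=1)


def neighbor_count_si(i: int, coords: np.ndarray, w: float, t: float) -> int:
    """Neighbour count of a single point."""
    c = np.asarray(coords, dtype=float)
    dxy = np.linalg.norm(c[:, :2] - c[i, :2], axis=1)
    dz = np.abs(c[:, 2] - c[i, 2])
    ok = (dxy <= w) & (dz <= t)
    ok[i] = False
    return int(ok.sum())


def pair_neighbor_count(coords: np.ndarray, w: float, t: float) -> int:
    """Total unordered neighbour-pair count ``s_B`` (the Gibbs exponent)."""
    return int(neighbor_counts(coords, w, t).sum() // 2)


def hardcore_ok(coords: np.ndarray, h: float) -> bool:
    """True iff every distinct pair is strictly further apart than ``h``."""
    if h < 0:
        raise ValueError("hardcore distance must be non-negative")
    c = np.asarray(coords, dtype=float)
    if len(c) < 2:
        return True
    from scipy.spatial.distance import pdist

    return bool(pdist(c).min() > h)


def estimate_hardcore(pattern) -> float:
    """Hardcore estimate ``ĥ = (n−1) d_min / n`` from the end points."""
    coords = _coords_of(pattern)
    n = len(coords)
    d_min = min_interpoint_distance(coords)
    return (n - 1) * d_min / n


# ---------------------------------------------------------------------------
# exact 1D integration of the conditional density
# ---------------------------------------------------------------------------

def _profile(z_others, dxy_others, w, t, h, zmin, zmax):
    """Piecewise-constant profile of the conditional integrand for one point.

    Returns ``(lengths, counts, feasible)`` describing segments of
    ``[zmin, zmax]`` on which the neighbour count ``s_i(z)`` and the
    hardcore feasibility are constant.  Breakpoints sit at ``z_j ± t`` for
    planar neighbours and at ``z_j ± sqrt(h² − d_xy²)`` for points closer
    than ``h`` in the plane; between breakpoints both are constant, so
    midpoint evaluation is exact.
    """
    z_others = np.asarray(z_others, dtype=float)
    dxy = np.asarray(dxy_others, dtype=float)

    nb = dxy <= w
    z_nb = z_others[nb]
    hc = dxy < h
    z_hc = z_others[hc]
    delta = np.sqrt(np.maximum(h**2 - dxy[hc] ** 2, 0.0))

    cuts = [np.array([zmin, zmax])]
    if z_nb.size:
        cuts.append(z_nb - t)
        cuts.append(z_nb + t)
    if z_hc.size:
        cuts.append(z_hc - delta)
        cuts.append(z_hc + delta)
    edges = np.unique(np.clip(np.concatenate(cuts), zmin, zmax))
    lengths = np.diff(edges)
    keep = lengths > 0
    lengths = lengths[keep]
    mids = (edges[:-1] + edges[1:])[keep] / 2

    if z_nb.size:
        counts = (np.abs(mids[:, None] - z_nb[None, :]) <= t).sum(axis=1)
    else:
        counts = np.zeros(len(mids), dtype=int)
    if z_hc.size:
        feasible = np.all(np.abs(mids[:, None] - z_hc[None, :]) > delta[None, :], axis=1)
    else:
        feasible = np.ones(len(mids), dtype=bool)
    return lengths, counts, feasible


def _measure_by_count(lengths, counts, feasible):
    """Aggregate feasible segment lengths by neighbour count.

    Returns ``(ks, measures)`` with ``c_i(γ) = Σ measures · γ^ks``.
    """
    lf = lengths[feasible]
    cf = counts[feasible]
    if lf.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    ks = np.unique(cf)
    measures = np.array([lf[cf == k].sum() for k in ks], dtype=float)
    return ks, measures


def _point_geometry(i, coords):
    c = np.asarray(coords, dtype=float)
    others = np.delete(np.arange(len(c)), i)
    dxy = np.linalg.norm(c[others, :2] - c[i, :2], axis=1)
    return c[others, 2], dxy


def normalizing_constant_ci(i: int, coords: np.ndarray, params: MarkovZParams,
                            zmin: float = 0.0) -> float:
    """Exact normalising constant ``c_i = ∫_{Wz} γ^{s_i(z)} 1{hardcore} dz``.

    A value of 0 means the hardcore excludes every depth for point i and
    the conditional density is undefined.
    """
    z_others, dxy = _point_geometry(i, coords)
    lengths, counts, feasible = _profile(
        z_others, dxy, params.w, params.t, params.h, zmin, params.zmax
    )
    return float(np.sum(lengths[feasible] * params.gamma ** counts[feasible]))


def conditional_density(z: float, i: int, coords: np.ndarray,
                        params: MarkovZParams, zmin: float = 0.0) -> float:
    """Full conditional density of ``z_i = z`` given all other points.

    ``f = γ^{s_i} 1{hardcore} / c_i``; integrates to one over ``Wz`` by
    construction.  Raises when ``c_i = 0``.
    """
    if not zmin <= z <= params.zmax:
        return 0.0
    ci = normalizing_constant_ci(i, coords, params, zmin)
    if ci <= 0:
        raise ValueError(f"conditional density undefined: c_{i} = 0")
    z_others, dxy = _point_geometry(i, coords)
    dz = np.abs(z_others - z)
    # hardcore: any other point within 3D distance h kills the density
    if np.any(dxy**2 + dz**2 <= params.h**2):
        return 0.0
    s = int(np.sum((dxy <= params.w) & (dz <= params.t)))
    return float(params.gamma**s / ci)


# ---------------------------------------------------------------------------
# pseudo-likelihood
# ---------------------------------------------------------------------------

def _interior_profiles(coords, window: BoxWindow, h, w, t, eroded: BoxWindow):
    """Per-interior-point sufficient statistics for the profile
    pseudo-likelihood: neighbour count ``s_i`` of the data and the
    ``(ks, measures)`` decomposition of ``c_i(γ)``."""
    coords = np.asarray(coords, dtype=float)
    interior = np.flatnonzero(eroded.contains(coords))
    s_all = neighbor_counts(coords, w, t)
    stats = []
    for i in interior:
        z_others, dxy = _point_geometry(i, coords)
        lengths, counts, feasible = _profile(z_others, dxy, w, t, h,
                                             0.0, window.zmax)
        ks, measures = _measure_by_count(lengths, counts, feasible)
        stats.append((int(s_all[i]), ks, measures))
    return stats


def _pl_from_profiles(stats, gamma: float) -> float:
    pl = 0.0
    for s_i, ks, measures in stats:
        ci = np.sum(measures * gamma**ks)
        if ci <= 0:
            return NEG_INF
        pl += s_i * np.log(gamma) - np.log(ci)
    return float(pl)


def log_pseudolikelihood(pattern, params: MarkovZParams,
                         eroded_window: BoxWindow | None = None,
                         window: BoxWindow | None = None) -> float:
    """Log pseudo-likelihood ``Σ_i log f(z_i | rest)`` with minus sampling.

    The sum runs over points inside ``eroded_window`` (all points if it is
    None) while neighbour counts and normalising constants use every point.
    Returns ``−inf`` when the data violate the hardcore.
    """
    if isinstance(pattern, PointPattern3D):
        coords = pattern.points_of("end")
        window = window or pattern.window
    else:
        coords = np.atleast_2d(np.asarray(pattern, dtype=float))
        if window is None:
            window = BoxWindow(
                coords[:, 0].min(), coords[:, 0].max() + 1e-9,
                coords[:, 1].min(), coords[:, 1].max() + 1e-9, params.zmax,
            )
    if not hardcore_ok(coords, params.h):
        return NEG_INF
    eroded = eroded_window or window
    stats = _interior_profiles(coords, window, params.h, params.w, params.t, eroded)
    return _pl_from_profiles(stats, params.gamma)


def _optimize_gamma(stats, log_gamma_bounds=(-5.0, 5.0)):
    """Maximise the profile pseudo-likelihood over log γ."""
    def neg(lg):
        return -_pl_from_profiles(stats, float(np.exp(lg)))

    lo, hi = log_gamma_bounds
    # an identifiability guard: a flat surface (no interaction information)
    if abs(neg(lo) - neg(hi)) < 1e-12 and abs(neg(lo) - neg(0.0)) < 1e-12:
        return 1.0, -neg(0.0)
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-7})
    return float(np.exp(res.x)), float(-res.fun)


def fit_markov(
    pattern,
    w_grid,
    t_grid,
    window: BoxWindow | None = None,
    h: float | None = None,
    log_gamma_bounds=(-5.0, 5.0),
) -> FitResult:
    """Fit (γ, w, t) by pseudo-likelihood with a grid search over (w, t).

    For every grid cell the interaction parameter is profiled out by
    bounded 1D optimisation of the log pseudo-likelihood in log γ; the
    cell with the highest optimum supplies the estimates.  The hardcore
    defaults to ``ĥ = (n−1) d_min / n``.  Erosion margins for minus
    sampling are ``max(max(w_grid), ĥ)`` in xy and ``max(max(t_grid), ĥ)``
    in z, so every candidate cell scores the same interior points and the
    grid values are comparable.
    """
    if isinstance(pattern, PointPattern3D):
        coords = pattern.points_of("end")
        window = window or pattern.window
    else:
        coords = np.atleast_2d(np.asarray(pattern, dtype=float))
        if window is None:
            raise ValueError("window required when fitting bare coordinates")
    w_grid = np.atleast_1d(np.asarray(w_grid, dtype=float))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if w_grid.size == 0 or t_grid.size == 0:
        raise ValueError("empty (w, t) grid")
    if h is None:
        h = estimate_hardcore(coords)
    if not hardcore_ok(coords, h):
        raise AssertionError("data violate the hardcore estimate; ĥ < d_min must hold")

    eroded = window.erode(max(w_grid.max(), h), max(t_grid.max(), h))
    interior = int(np.count_nonzero(eroded.contains(coords)))
    if interior < 2:
        raise ValueError(
            f"only {interior} points remain after minus sampling; "
            "reduce the grid extents or use a larger pattern"
        )

    rows = []
    best = None
    for w in w_grid:
        for t in t_grid:
            stats = _interior_profiles(coords, window, h, w, t, eroded)
            gamma, pl = _optimize_gamma(stats, log_gamma_bounds)
            rows.append((w, t, gamma, pl))
            if best is None or pl > best[3]:
                best = (w, t, gamma, pl)
    grid = np.array(rows, dtype=[("w", float), ("t", float),
                                 ("gamma", float), ("log_pl", float)])
    w, t, gamma, pl = best
    params = MarkovZParams(gamma=gamma, h=float(h), w=float(w), t=float(t),
                           zmax=float(window.zmax))
    return FitResult(params=params, log_pl=float(pl), grid=grid,
                     n_interior=interior, h=float(h))


# ---------------------------------------------------------------------------
# fixed-n Metropolis–Hastings simulation
# ---------------------------------------------------------------------------

def _feasible_init(planar, params, rng, max_tries=1000):
    """Sequential feasible initialisation: each depth is drawn uniformly
    and redrawn until compatible with the already-placed points."""
    n = len(planar)
    z = np.empty(n)
    h2 = params.h**2
    for k in range(n):
        dxy2 = np.sum((planar[:k] - planar[k]) ** 2, axis=1)
        close = np.flatnonzero(dxy2 < h2)
        delta = np.sqrt(h2 - dxy2[close])
        for _ in range(max_tries):
            cand = rng.uniform(0.0, params.zmax)
            if close.size == 0 or np.all(np.abs(z[close] - cand) > delta):
                z[k] = cand
                break
        else:
            raise RuntimeError(
                f"no hardcore-feasible depth found for point {k}: the window "
                f"is too shallow for {n} points at hardcore h={params.h}"
            )
    return z


def simulate_z(
    planar_pattern,
    params: MarkovZParams,
    n_sweeps: int = 5000,
    burn_in: int = 5000,
    seed=None,
    init=None,
    record_pair_counts: bool = False,
):
    """Sample end-point depths by fixed-n single-site Metropolis–Hastings.

    Every sweep visits each point once in a fresh random order, proposes a
    uniform new depth, and accepts with probability
    ``min(1, γ^{Δs} · 1{hardcore})`` — the ratio of full conditionals, in
    which the normalising constant cancels.  Returns the depth vector after
    ``burn_in + n_sweeps`` sweeps; with ``record_pair_counts=True`` also
    returns the trajectory of the neighbour-pair count ``s_B`` over the
    post-burn-in sweeps (one value per sweep).
    """
    rng = np.random.default_rng(seed)
    planar = np.atleast_2d(np.asarray(planar_pattern, dtype=float))[:, :2]
    n = len(planar)
    gamma, h, w, t, zmax = params.gamma, params.h, params.w, params.t, params.zmax

    # static planar geometry: neighbour candidates and hardcore candidates
    dxy = np.linalg.norm(planar[:, None, :] - planar[None, :, :], axis=-1)
    np.fill_diagonal(dxy, np.inf)
    nb_idx = [np.flatnonzero(dxy[i] <= w) for i in range(n)]
    hc_idx = [np.flatnonzero(dxy[i] < h) for i in range(n)]
    hc_delta = [np.sqrt(np.maximum(h**2 - dxy[i, hc_idx[i]] ** 2, 0.0)) for i in range(n)]

    z = _feasible_init(planar, params, rng) if init is None else np.array(init, dtype=float)
    if init is not None and not hardcore_ok(np.column_stack([planar, z]), h):
        raise ValueError("provided initial state violates the hardcore")

    iu, ju = np.triu_indices(n, k=1)
    nb_pairs = dxy[iu, ju] <= w
    pi, pj = iu[nb_pairs], ju[nb_pairs]

    history = [] if record_pair_counts else None
    total = burn_in + n_sweeps
    for sweep in range(total):
        order = rng.permutation(n)
        proposals = rng.uniform(0.0, zmax, size=n)
        us = rng.random(n)
        for k in range(n):
            i = order[k]
            z_new = proposals[k]
            hci = hc_idx[i]
            if hci.size and np.any(np.abs(z[hci] - z_new) <= hc_delta[i]):
                continue
            nbi = nb_idx[i]
            if nbi.size:
                z_nb = z[nbi]
                ds = int(np.count_nonzero(np.abs(z_nb - z_new) <= t)
                         - np.count_nonzero(np.abs(z_nb - z[i]) <= t))
            else:
                ds = 0
            if ds == 0 or (gamma >= 1.0) == (ds > 0) or us[k] < gamma**ds:
                z[i] = z_new
        if history is not None and sweep >= burn_in:
            history.append(int(np.count_nonzero(np.abs(z[pi] - z[pj]) <= t)))
    if record_pair_counts:
        return z, np.asarray(history)
    return z
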