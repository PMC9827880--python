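"""Two-step planar cluster model for nerve-tree points.

Conditioned on the observed base points, each nerve tree is built in two
steps.  First a single first-branching point is placed at distance
``L1 ~ Gamma(α1, β1)`` from its base point, in direction
``Φ1 ~ vonMises(m, κ)`` where the known mean direction ``m`` points towards
open space — away from the nearest other base point.  Second, a cluster of
``S`` end points is placed around the branching point with radial distances
``L2 ~ Gamma(α2, β2)`` and isotropic angles ``Φ2 ~ Uniform(0, 2π)``; the
tree size satisfies ``S − 1 ~ NB(s, p)`` so every tree has at least one
end point, with mean cluster size ``1 + p·s/(1−p)``.

All components are assumed independent, so each is estimated from its own
empirical sample: Gamma and negative-binomial parameters by maximum
likelihood, and the von Mises concentration by the standard approximate
MLE based on the mean resultant length of the centred angles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .pattern import PointPattern3D
from .window import BoxWindow

__all__ = [
    "PlanarModelParams",
    "ComponentSamples",
    "open_space_direction",
    "simulate_planar",
    "extract_components",
    "fit_gamma",
    "fit_vonmises_kappa",
    "fit_vonmises_kappa_mle",
    "fit_negbin",
    "fit_planar",
]

logger = logging.getLogger(__name__)

TWO_PI = 2 * np.pi


@dataclass(frozen=True)
class PlanarModelParams:
    """The seven parameters of the two-step planar model.

    ``alpha1/beta1`` and ``alpha2/beta2`` are Gamma shape/scale pairs (μm)
    for the base→branching and branching→end segment lengths, ``kappa`` the
    von Mises concentration of the branching direction around the
    open-space direction, and ``(s, p)`` the negative-binomial success
    count and success probability of the tree size minus one.
    """

    alpha1: float
    beta1: float
    kappa: float
    alpha2: float
    beta2: float
    s: float
    p: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2", "s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0 < self.p < 1:
            raise ValueError("p must lie strictly in (0, 1)")

    @property
    def mean_l1(self) -> float:
        return self.alpha1 * self.beta1

    @property
    def mean_l2(self) -> float:
        return self.alpha2 * self.beta2

    @property
    def nb_mean(self) -> float:
        """Mean μ = p·s/(1−p) of the tree size minus one."""
        return self.p * self.s / (1 - self.p)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("alpha1", "beta1", "kappa", "alpha2", "beta2", "s", "p")}

    @classmethod
    def from_dict(cls, d: dict) -> "PlanarModelParams":
        return cls(**{k: float(d[k]) for k in
                      ("alpha1", "beta1", "kappa", "alpha2", "beta2", "s", "p")})


@dataclass
class ComponentSamples:
    """Empirical samples of the model components extracted from a pattern."""

    l1: np.ndarray        # base→branching planar distances
    phi1: np.ndarray      # branching azimuths
    m: np.ndarray         # known open-space mean directions, aligned with phi1
    l2: np.ndarray        # branching→end planar distances
    s: np.ndarray         # tree sizes (end points per tree)

    def concatenate(self, other: "ComponentSamples") -> "ComponentSamples":
        return ComponentSamples(
            np.concatenate([self.l1, other.l1]),
            np.concatenate([self.phi1, other.phi1]),
            np.concatenate([self.m, other.m]),
            np.concatenate([self.l2, other.l2]),
            np.concatenate([self.s, other.s]),
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def open_space_direction(base_points: np.ndarray, index: int | None = None):
    """Open-space direction(s): azimuth away from the nearest other base point.

    For base point ``i`` the direction ``m_i`` is the azimuth of the vector
    from its nearest other base point through the point itself, in
    ``[0, 2π)``.  Distance ties are broken by the lowest competing index.
    """
    pts = np.atleast_2d(np.asarray(base_points, dtype=float))[:, :2]
    n = len(pts)
    if n < 2:
        raise ValueError("open-space direction undefined for fewer than 2 base points")
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    nearest = np.argmin(d2, axis=1)  # argmin returns the lowest index on ties
    vec = pts - pts[nearest]
    m = np.mod(np.arctan2(vec[:, 1], vec[:, 0]), TWO_PI)
    return m if index is None else float(m[index])


def _draw_in_window(rng, origin, draw_length, draw_angle, window: BoxWindow,
                    max_tries: int = 100) -> np.ndarray:
    """Rejection sampling of one offspring point constrained to the window.

    Resampling both the length and the angle preserves their distributions
    conditionally on window containment.
    """
    for _ in range(max_tries):
        length = draw_length()
        angle = draw_angle()
        pt = origin + length * np.array([np.cos(angle), np.sin(angle)])
        if window.contains(pt[None, :])[0]:
            return pt
    raise RuntimeError(
        f"no in-window offspring of {origin} found in {max_tries} draws; "
        "check the segment-length scale against the window size"
    )


@dataclass
class PlanarSimulation:
    """Output of :func:`simulate_planar`: branching and end points with
    the base-point tree ids they belong to."""

    branching: np.ndarray       # (n_trees, 2)
    branching_tree: np.ndarray  # (n_trees,) int
    ends: np.ndarray            # (n_end, 2)
    ends_tree: np.ndarray       # (n_end,) int

    @property
    def tree_sizes(self) -> np.ndarray:
        return np.array([(self.ends_tree == t).sum() for t in self.branching_tree])


def simulate_planar(
    base_points: np.ndarray,
    params: PlanarModelParams,
    window: BoxWindow,
    seed=None,
    tree_ids: np.ndarray | None = None,
    max_tries: int = 100,
) -> PlanarSimulation:
    """Simulate branching and end points conditioned on base points.

    One branching point is generated per base point, then ``S`` end points
    per branching point.  Points falling outside the (planar) window are
    redrawn up to ``max_tries`` times.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed)
    base = np.atleast_2d(np.asarray(base_points, dtype=float))[:, :2]
    win2d = window.projection()
    n_trees = len(base)
    if n_trees < 2:
        raise ValueError("need at least 2 base points (open-space direction)")
    if tree_ids is None:
        tree_ids = np.arange(n_trees)
    m = open_space_direction(base)

    branching = np.empty((n_trees, 2))
    for i in range(n_trees):
        branching[i] = _draw_in_window(
            rng, base[i],
            lambda: rng.gamma(params.alpha1, params.beta1),
            lambda: rng.vonmises(m[i], params.kappa) % TWO_PI if params.kappa > 0
            else rng.uniform(0, TWO_PI),
            win2d, max_tries,
        )

    sizes = 1 + rng.negative_binomial(params.s, 1 - params.p, size=n_trees)
    ends = np.empty((int(sizes.sum()), 2))
    ends_tree = np.repeat(tree_ids, sizes)
    k = 0
    for i in range(n_trees):
        for _ in range(sizes[i]):
            ends[k] = _draw_in_window(
                rng, branching[i],
                lambda: rng.gamma(params.alpha2, params.beta2),
                lambda: rng.uniform(0, TWO_PI),
                win2d, max_tries,
            )
            k += 1
    return PlanarSimulation(branching, np.asarray(tree_ids), ends, ends_tree)


def extract_components(pattern: PointPattern3D) -> ComponentSamples:
    """Extract the planar component samples (L1, Φ1 with m, L2, S) per tree.

    Distances and azimuths are planar (xy).  Trees without a branching
    point are skipped with a logged warning; end points of skipped trees do
    not contribute to L2 or S.
    """
    base_mask = pattern.mask_of("base")
    base_xy = pattern.coords[base_mask, :2]
    base_ids = pattern.tree_ids[base_mask]
    if len(base_xy) < 2:
        raise ValueError("component extraction needs at least 2 base points")
    m_all = open_space_direction(base_xy)
    m_by_id = dict(zip(base_ids.tolist(), m_all))
    base_by_id = {t: base_xy[i] for i, t in enumerate(base_ids.tolist())}

    br_mask = pattern.mask_of("branching")
    br_xy = pattern.coords[br_mask, :2]
    br_ids = pattern.tree_ids[br_mask]
    br_by_id = {t: br_xy[i] for i, t in enumerate(br_ids.tolist())}

    end_mask = pattern.mask_of("end")
    end_xy = pattern.coords[end_mask, :2]
    end_ids = pattern.tree_ids[end_mask]

    l1, phi1, m_used, l2, s = [], [], [], [], []
    for t in base_ids.tolist():
        if t not in br_by_id:
            if np.any(end_ids == t):
                logger.warning("tree %s has end points but no branching point; skipped", t)
            continue
        seg = br_by_id[t] - base_by_id[t]
        l1.append(np.hypot(*seg))
        phi1.append(np.arctan2(seg[1], seg[0]) % TWO_PI)
        m_used.append(m_by_id[t])
        sel = end_ids == t
        size = int(sel.sum())
        if size == 0:
            logger.warning("tree %s has a branching point but no end points; skipped from S", t)
            continue
        s.append(size)
        segs = end_xy[sel] - br_by_id[t]
        l2.extend(np.hypot(segs[:, 0], segs[:, 1]).tolist())
    return ComponentSamples(
        np.asarray(l1), np.asarray(phi1), np.asarray(m_used),
        np.asarray(l2), np.asarray(s, dtype=int),
    )


# ---------------------------------------------------------------------------
# component estimators
# ---------------------------------------------------------------------------

def fit_gamma(samples) -> tuple[float, float]:
    """Maximum-likelihood Gamma shape and scale for positive samples."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("Gamma fit needs at least 2 samples")
    if np.any(x <= 0):
        raise ValueError("Gamma fit requires strictly positive samples")
    if np.ptp(x) == 0:
        raise ValueError("Gamma fit degenerate: all samples equal")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return float(shape), float(scale)


def fit_vonmises_kappa(angles, known_means) -> float:
    """Approximate MLE of the von Mises concentration with known means.

    Centres each angle by its known mean direction, computes the mean
    resultant length ``R̄`` and returns ``κ̂ = R̄(2 − R̄²)/(1 − R̄²)``,
    clipped to be non-negative.  ``κ̂ ≈ 0`` signals the uniform circular
    distribution.
    """
    theta = np.asarray(angles, dtype=float)
    mu = np.broadcast_to(np.asarray(known_means, dtype=float), theta.shape)
    if theta.size == 0:
        raise ValueError("no angles provided")
    centred = theta - mu
    rbar = float(np.hypot(np.mean(np.cos(centred)), np.mean(np.sin(centred))))
    rbar = min(rbar, 1.0 - 1e-12)
    kappa = rbar * (2 - rbar**2) / (1 - rbar**2)
    return float(max(kappa, 0.0))


def fit_vonmises_kappa_mle(angles, known_means) -> float:
    """Full numerical MLE of κ: solves ``A(κ) = I1(κ)/I0(κ) = R̄``.

    Provided as a cross-check for the closed-form approximation.
    """
    theta = np.asarray(angles, dtype=float)
    mu = np.broadcast_to(np.asarray(known_means, dtype=float), theta.shape)
    centred = theta - mu
    rbar = float(np.hypot(np.mean(np.cos(centred)), np.mean(np.sin(centred))))
    if rbar <= 0:
        return 0.0

    def eqn(k):
        return special.i1e(k) / special.i0e(k) - rbar

    if eqn(1e-8) > 0:
        return 0.0
    hi = 10.0
    while eqn(hi) < 0 and hi < 1e8:
        hi *= 10
    return float(optimize.brentq(eqn, 1e-8, hi, xtol=1e-10))


def fit_negbin(cluster_sizes) -> tuple[float, float]:
    """Maximum-likelihood NB(s, p) fit for tree sizes ``S`` (on ``S − 1``).

    Exploits the MLE stationarity condition: at the optimum the implied
    mean ``p·s/(1−p)`` equals the sample mean of ``S − 1``, so ``p`` is
    profiled out and only ``s`` is optimised numerically.  Underdispersed
    samples (variance below mean) admit no NB maximum; a large-``s``
    quasi-Poisson fit is returned with a warning.
    """
    S = np.asarray(cluster_sizes)
    if len(S) < 2:
        raise ValueError("NB fit needs at least 2 tree sizes")
    if np.any(S < 1) or not np.allclose(S, np.round(S)):
        raise ValueError("tree sizes must be integers >= 1")
    y = S.astype(int) - 1
    mean = float(np.mean(y))
    var = float(np.var(y))
    if mean == 0:
        raise ValueError("all trees have a single end point; NB fit degenerate")
    s_cap = 1e6
    if var <= mean:
        warnings.warn(
            "tree sizes are under/equi-dispersed; returning a large-s "
            "quasi-Poisson negative-binomial fit", stacklevel=2,
        )
        s = s_cap
        return float(s), float(mean / (s + mean))

    def negll(log_s):
        s = np.exp(log_s)
        # scipy's nbinom(n, q) has mean n(1-q)/q; mean-matching gives q = s/(s+mean)
        return -np.sum(stats.nbinom.logpmf(y, s, s / (s + mean)))

    res = optimize.minimize_scalar(negll, bounds=(-10, np.log(s_cap)), method="bounded")
    s = float(np.exp(res.x))
    p = float(mean / (s + mean))  # success probability in the ps/(1−p) parameterisation
    return s, p


def fit_planar(components: ComponentSamples) -> PlanarModelParams:
    """Fit all seven planar-model parameters from extracted components."""
    a1, b1 = fit_gamma(components.l1)
    a2, b2 = fit_gamma(components.l2)
    kappa = fit_vonmises_kappa(components.phi1, components.m)
    s, p = fit_negbin(components.s)
    return PlanarModelParams(a1, b1, kappa, a2, b2, s, p)
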