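"""Synthetic study generator for nerve-fibre-like 3D point patterns.

Produces group/subject/sample-structured patterns with known parameters by
chaining the model stages: base points from a hardcore-thinned planar
Poisson process, branching and end points from the two-step planar cluster
model, and end-point depths from the cylindrical-neighbourhood Markov
field sampler.  The generator mirrors the geometry of the real biopsy
data: 320 × 432 μm planar windows with a per-sample depth drawn uniformly
between 50 and 200 μm, and a healthy-like versus a mild-neuropathy-like
parameter set whose contrasts follow the directions reported for real
patterns (mild: shorter branches, more concentrated branching directions,
smaller clusters, weaker and shorter-ranged depth attraction).

Every sample's random stream is derived deterministically from the master
seed and the (group, subject, sample) indices, so studies are reproducible
and individual samples can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import MarkovZParams, simulate_z
from .pattern import PointPattern3D
from .planar import PlanarModelParams, simulate_planar
from .window import BoxWindow

__all__ = [
    "GroupParams",
    "StudyDesign",
    "healthy_like_group",
    "mild_like_group",
    "generate_base_points",
    "generate_sample",
    "generate_study",
    "sample_seed",
]


@dataclass(frozen=True)
class GroupParams:
    """Generating parameters of one disease group."""

    label: str
    planar: PlanarModelParams
    gamma: float
    h: float
    w: float
    t: float


def healthy_like_group(label: str = "healthy") -> GroupParams:
    """Healthy-like defaults: long branches, weakly concentrated branching
    directions, large clusters, and clear depth attraction in wide
    cylinders."""
    return GroupParams(
        label=label,
        planar=PlanarModelParams(alpha1=2.0, beta1=10.0, kappa=0.5,
                                 alpha2=2.0, beta2=6.0, s=3.0, p=0.6),
        gamma=3.0, h=1.5, w=10.0, t=4.0,
    )


def mild_like_group(label: str = "mild") -> GroupParams:
    """Mild-neuropathy-like defaults: shorter branches, more concentrated
    directions, smaller clusters, weaker and narrower depth attraction."""
    return GroupParams(
        label=label,
        planar=PlanarModelParams(alpha1=2.0, beta1=7.0, kappa=2.0,
                                 alpha2=2.0, beta2=4.0, s=2.0, p=0.5),
        gamma=2.0, h=1.0, w=6.0, t=3.0,
    )


@dataclass(frozen=True)
class StudyDesign:
    """Layout and generating conditions of a synthetic study.

    The window template is the 320 × 432 μm biopsy box; the depth of each
    sample is drawn uniformly from ``zmax_range``.  ``base_intensity`` is
    the planar base-point intensity (points/μm²) before hardcore thinning;
    the default yields roughly 20 nerve trees per sample.
    """

    groups: tuple[GroupParams, ...] = field(
        default_factory=lambda: (healthy_like_group(), mild_like_group())
    )
    subjects_per_group: int = 3
    samples_per_subject: int = 4
    base_intensity: float = 1.5e-4
    base_hardcore: float = 10.0
    xmax: float = 320.0
    ymax: float = 432.0
    zmax_range: tuple[float, float] = (50.0, 200.0)
    master_seed: int = 0
    mcmc_burn_in: int = 5000
    mcmc_sweeps: int = 5000

    def __post_init__(self) -> None:
        if self.subjects_per_group < 1 or self.samples_per_subject < 1:
            raise ValueError("counts must be at least 1")
        if not self.base_intensity > 0:
            raise ValueError("base intensity must be positive")
        if not 0 < self.zmax_range[0] <= self.zmax_range[1]:
            raise ValueError("invalid zmax range")


def sample_seed(master_seed: int, group: int, subject: int, sample: int) -> int:
    """Deterministic per-sample child seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), group, subject, sample])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_base_points(window: BoxWindow, intensity: float, hardcore: float = 0.0,
                         seed=None) -> np.ndarray:
    """Hardcore-thinned planar Poisson base points (Matérn-II-style).

    A Poisson number of candidate points is placed uniformly in the planar
    window and scanned in random arrival order; a candidate is kept only if
    no already-kept point lies within ``hardcore``.  With ``hardcore=0``
    this is a homogeneous Poisson process with the given intensity.
    """
    if not intensity > 0:
        raise ValueError("intensity must be positive")
    if hardcore < 0:
        raise ValueError("hardcore must be non-negative")
    rng = np.random.default_rng(seed)
    win = window.projection() if window.ndim == 3 else window
    n = rng.poisson(intensity * win.area)
    pts = np.column_stack([
        rng.uniform(win.xmin, win.xmax, n),
        rng.uniform(win.ymin, win.ymax, n),
    ])
    if hardcore == 0 or n < 2:
        return pts
    keep: list[int] = []
    for i in range(n):
        if keep:
            d = np.linalg.norm(pts[keep] - pts[i], axis=1)
            if d.min() < hardcore:
                continue
        keep.append(i)
    return pts[keep]


def generate_sample(
    group: GroupParams,
    window: BoxWindow,
    seed=None,
    labels: dict | None = None,
    mcmc_burn_in: int = 5000,
    mcmc_sweeps: int = 5000,
    base_intensity: float = 1.5e-4,
    base_hardcore: float = 10.0,
    base_points: np.ndarray | None = None,
) -> PointPattern3D:
    """Generate one fully marked 3D sample from the chained model.

    Base points (given or generated) sit at depth 0 together with the
    branching points — only the end points carry modelled depths, drawn
    from the Markov field conditional on the simulated planar locations.
    The generating parameters are recorded in the pattern metadata.
    """
    rng = np.random.default_rng(seed)
    if base_points is None:
        base_points = generate_base_points(window, base_intensity, base_hardcore, rng)
    base_points = np.atleast_2d(np.asarray(base_points, dtype=float))[:, :2]
    if len(base_points) < 2:
        raise RuntimeError("fewer than 2 base points generated; raise the intensity")

    sim = simulate_planar(base_points, group.planar, window, rng)
    zparams = MarkovZParams(gamma=group.gamma, h=group.h, w=group.w, t=group.t,
                            zmax=window.zmax)
    z_end = simulate_z(sim.ends, zparams, n_sweeps=mcmc_sweeps,
                       burn_in=mcmc_burn_in, seed=rng)

    n_base, n_branch, n_end = len(base_points), len(sim.branching), len(sim.ends)
    coords = np.vstack([
        np.column_stack([base_points, np.zeros(n_base)]),
        np.column_stack([sim.branching, np.zeros(n_branch)]),
        np.column_stack([sim.ends, z_end]),
    ])
    types = np.array(["base"] * n_base + ["branching"] * n_branch + ["end"] * n_end,
                     dtype=object)
    tree_ids = np.concatenate([
        np.arange(n_base), sim.branching_tree, sim.ends_tree
    ]).astype(int)
    meta = {
        "planar_params": group.planar.to_dict(),
        "markov_params": zparams.to_dict(),
        "group_label": group.label,
    }
    return PointPattern3D(coords, types, tree_ids, window,
                          labels=dict(labels or {}), metadata=meta)


def generate_study(design: StudyDesign):
    """Generate a full group/subject/sample hierarchy.

    Returns ``(patterns, manifest)`` where the manifest is a DataFrame with
    one row per sample: group, subject, sample, n_base, n_end, zmax, seed.
    """
    patterns: list[PointPattern3D] = []
    rows = []
    for gi, group in enumerate(design.groups):
        for si in range(design.subjects_per_group):
            subject = f"{group.label}-s{si + 1}"
            for ki in range(design.samples_per_subject):
                seed = sample_seed(design.master_seed, gi, si, ki)
                rng = np.random.default_rng(seed)
                zmax = float(rng.uniform(*design.zmax_range))
                window = BoxWindow.from_extents(design.xmax, design.ymax, zmax)
                labels = {"group": group.label, "subject": subject,
                          "sample": f"{subject}-k{ki + 1}"}
                pat = generate_sample(
                    group, window, seed=rng, labels=labels,
                    mcmc_burn_in=design.mcmc_burn_in,
                    mcmc_sweeps=design.mcmc_sweeps,
                    base_intensity=design.base_intensity,
                    base_hardcore=design.base_hardcore,
                )
                patterns.append(pat)
                rows.append({
                    "group": group.label, "subject": subject,
                    "sample": labels["sample"],
                    "n_base": pat.count_of("base"),
                    "n_end": pat.count_of("end"),
                    "zmax": zmax, "seed": seed,
                })
    return patterns, pd.DataFrame(rows)
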