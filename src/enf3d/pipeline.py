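"""Subjectwise and groupwise fitting workflows for replicated samples.

A subject contributes several samples; subjectwise planar fits concatenate
the component samples (segment lengths, angles, tree sizes) across the
subject's samples, while subjectwise Markov fits sum the log
pseudo-likelihood contributions of all samples at shared ``(γ, w, t)``,
with the hardcore replaced by the subject-level estimate
``ĥ = (N−1)/N · min_samples d_min`` (``N`` = total end points).  Groupwise
summary curves pool the subjectwise pooled curves.
"""

from __future__ import annotations

import hashlib
import json


import numpy as np
import pandas as pd

from . import __version__
from .markov import (FitResult, MarkovZParams, _interior_profiles,
                     _optimize_gamma, hardcore_ok)
from .pattern import min_interpoint_distance
from .planar import ComponentSamples, PlanarModelParams, extract_components, fit_planar
from .summaries import SummaryFunction, k_cylindrical, l_transform, pool

__all__ = [
    "fit_subject_planar", "fit_subject_markov", "fit_study",
    "pooled_group_curves", "provenance",
]


def provenance(config: dict, seed=None) -> dict:
    """Stable provenance stamp: config hash, seed and package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "version": __version__,
    }


def _group_by_subject(patterns):
    subjects: dict[tuple, list] = {}
    for p in patterns:
        key = (p.labels.get("group", ""), p.labels.get("subject", ""))
        subjects.setdefault(key, []).append(p)
    return subjects


def fit_subject_planar(patterns) -> PlanarModelParams:
    """Planar fit pooling the component samples of all of a subject's samples."""
    patterns = list(patterns)
    comps: ComponentSamples | None = None
    for p in patterns:
        c = extract_components(p)
        comps = c if comps is None else comps.concatenate(c)
    return fit_planar(comps)


def subject_hardcore(patterns) -> float:
    """Subject-level hardcore estimate ``(N−1)/N · min over samples d_min``."""
    n_total = sum(p.count_of("end") for p in patterns)
    d_min = min(min_interpoint_distance(p, "end") for p in patterns)
    return (n_total - 1) * d_min / n_total


def fit_subject_markov(patterns, w_grid, t_grid, h: float | None = None,
                       log_gamma_bounds=(-5.0, 5.0)) -> FitResult:
    """Markov fit pooling all of a subject's samples.

    For each (w, t) grid cell the per-sample pseudo-likelihood profiles are
    summed and a single shared γ is optimised.  For a single sample this
    reduces exactly to the samplewise fit.
    """
    patterns = list(patterns)
    w_grid = np.atleast_1d(np.asarray(w_grid, dtype=float))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if h is None:
        h = subject_hardcore(patterns)
    per_sample = []
    n_interior = 0
    for p in patterns:
        coords = p.points_of("end")
        if not hardcore_ok(coords, h):
            raise ValueError(
                f"sample {p.labels.get('sample')} violates the subject hardcore {h}"
            )
        eroded = p.window.erode(max(w_grid.max(), h), max(t_grid.max(), h))
        per_sample.append((coords, p.window, eroded))
        n_interior += int(np.count_nonzero(eroded.contains(coords)))

    rows, best = [], None
    for w in w_grid:
        for t in t_grid:
            stats = []
            for coords, window, eroded in per_sample:
                stats.extend(_interior_profiles(coords, window, h, w, t, eroded))
            gamma, pl = _optimize_gamma(stats, log_gamma_bounds)
            rows.append((w, t, gamma, pl))
            if best is None or pl > best[3]:
                best = (w, t, gamma, pl)
    grid = np.array(rows, dtype=[("w", float), ("t", float),
                                 ("gamma", float), ("log_pl", float)])
    w, t, gamma, pl = best
    zmax = max(p.window.zmax for p in patterns)
    params = MarkovZParams(gamma=gamma, h=float(h), w=float(w), t=float(t), zmax=zmax)
    return FitResult(params=params, log_pl=float(pl), grid=grid,
                     n_interior=n_interior, h=float(h))


def fit_study(patterns, w_grid, t_grid) -> pd.DataFrame:
    """Subjectwise planar + Markov fits for a whole study.

    Returns one row per subject with the seven planar parameters and the
    four Markov parameters.
    """
    rows = []
    for (group, subject), pats in _group_by_subject(patterns).items():
        planar = fit_subject_planar(pats)
        markov = fit_subject_markov(pats, w_grid, t_grid)
        rows.append({
            "group": group, "subject": subject,
            "n_samples": len(pats),
            "n_end": sum(p.count_of("end") for p in pats),
            **planar.to_dict(),
            "mean_l1": planar.mean_l1, "mean_l2": planar.mean_l2,
            "nb_mean": planar.nb_mean,
            **{f"markov_{k}": v for k, v in markov.params.to_dict().items()},
        })
    return pd.DataFrame(rows)


def pooled_group_curves(patterns, direction: str, half_width: float,
                        r_grid=None) -> dict[str, SummaryFunction]:
    """Two-stage pooled centred cylindrical L curves per group.

    Samples are pooled into subjectwise curves weighted by point count,
    subjects into groupwise curves by their accumulated weights.
    """
    by_subject = _group_by_subject(patterns)
    group_funcs: dict[str, list[SummaryFunction]] = {}
    for (group, _subject), pats in by_subject.items():
        curves = []
        for p in pats:
            k = k_cylindrical(p.subset("end"), p.window, direction, half_width, r_grid)
            curves.append(l_transform(k))
        group_funcs.setdefault(group, []).append(pool(curves))
    return {g: pool(funcs) for g, funcs in group_funcs.items()}
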