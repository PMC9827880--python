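# enf3d

Anisotropic 3D point-process modelling of epidermal nerve fibre (ENF)
endings.

ENFs are thin sensory fibres that enter the epidermis at *base points*,
split at *first branching points* and terminate at *end points*; peripheral
neuropathy thins and rearranges them, and the spatial pattern of the end
points carries diagnostic signal.  `enf3d` treats the traced points of a
skin-biopsy sample as a marked 3D point pattern in a box window and
provides the full modelling stack for such data:

- **Two-step planar cluster model.**  Conditioned on the base points, each
  tree gets one branching point at distance `L1 ~ Gamma(α1, β1)` in
  direction `Φ1 ~ vonMises(m, κ)` (with `m` the open-space direction, away
  from the nearest other base point), then a cluster of
  `S = 1 + NB(s, p)` end points at distances `L2 ~ Gamma(α2, β2)` and
  uniform angles.  Componentwise maximum-likelihood estimation.
- **Pairwise-interaction Markov field for the depths.**  Given the planar
  locations, the end-point depths follow a Gibbs density
  `∝ γ^{s_B} · 1{hardcore}`, where `s_B` counts pairs within a cylinder of
  radius `w` and half-height `t` along z and no pair may be closer than
  `h` in 3D.  Fitting maximises the log pseudo-likelihood
  `Σ_i log f(z_i | rest)` in γ over a `(w, t)` grid, with
  `ĥ = (n−1)d_min/n`, exact piecewise evaluation of the 1D normalising
  constants, and minus sampling; simulation is a fixed-n single-site
  Metropolis–Hastings sweep whose acceptance ratio the normalising
  constant cancels out of.
- **Anisotropic second-order diagnostics.**  Translation-corrected Ripley
  K and cylindrical K functions, the centred transforms `L(r) − r` and
  `L_cyl^u(r) − r = K_cyl^u(r)/(2πw²) − r` (zero under complete spatial
  randomness), two-stage pooling for sample/subject/group hierarchies,
  global rank envelopes (extreme-rank-length ordering) and pointwise
  bootstrap envelopes.
- **Synthetic study generator** producing group/subject/sample-structured
  data with known parameters (320 × 432 μm windows, depths 50–200 μm),
  including healthy-like and mild-neuropathy-like parameter sets.

See `docs/methods.md` for the model, estimators, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from enf3d import (BoxWindow, healthy_like_group, generate_sample, fit_markov,
                   extract_components, fit_planar, k_cylindrical, l_transform)

window = BoxWindow.from_extents(320, 432, 100)          # μm
sample = generate_sample(healthy_like_group(), window, seed=7)
print("points:", sample.count_of("base"), "bases,",
      sample.count_of("end"), "ends")

planar = fit_planar(extract_components(sample))
print(f"planar fit: kappa={planar.kappa:.2f}, "
      f"mean L1={planar.mean_l1:.1f} um, mean L2={planar.mean_l2:.1f} um, "
      f"mean tree size={1 + planar.nb_mean:.1f}")

fit = fit_markov(sample, w_grid=[6, 8, 10, 12], t_grid=[2, 3, 4, 5])
p = fit.params
print(f"depth-model fit: gamma={p.gamma:.2f}, h={p.h:.2f} um, "
      f"w={p.w:.0f} um, t={p.t:.0f} um")

L = l_transform(k_cylindrical(sample.subset("end"), window, "z", 7.0))
print(f"centred cylindrical L at r=10 um (z direction): {L.values[20]:.2f} um")
```

prints

```
points: 21 bases, 132 ends
planar fit: kappa=0.67, mean L1=17.9 um, mean L2=11.3 um, mean tree size=6.3
depth-model fit: gamma=3.50, h=2.28 um, w=10 um, t=4 um
centred cylindrical L at r=10 um (z direction): 137.32 um
```

The sample was generated with κ = 0.5, mean L1 = 20 μm, mean L2 = 12 μm,
mean tree size 5.5 and depth interaction (γ, h, w, t) = (3, 1.5, 10, 4):
the componentwise fits land close to the truth, the grid search returns
the generating cylinder exactly, and γ̂ = 3.5 correctly signals attraction
(γ > 1) between neighbouring end points.  The strongly positive centred
cylindrical L value reflects the tight clustering of end points around
their branching points — a CSR pattern would give ≈ 0.

The same workflows are scriptable through the `enf3d` command line
(`synth`, `fit-planar`, `fit-markov`, `simulate-planar`, `simulate-z`,
`k`, `kcyl`, `pool`, `envelope`, `bootstrap-envelope`, `pipeline`); every
command reads/writes plain CSV/YAML/JSON and takes `--seed` where
randomness is involved.

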