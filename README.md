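# fragdep

Forest-dependency analysis of small-mammal assemblages in fragmented
tropical landscapes.

When an agricultural frontier fragments continuous forest, the rodent
and marsupial communities left in forest patches do not simply lose
species: open-habitat species from the surrounding pasture matrix move
in as forest specialists drop out. `fragdep` implements the full
analysis chain used to quantify that turnover from live-/pitfall-trap
survey data, and to project it across a whole landscape over decades of
deforestation.

## What it computes

**Effort standardization.** Capture counts are converted to rates per
1000 trap-nights from per-site, per-stratum effort tables (or from the
survey's trap-allocation design rules). Sampling adequacy is checked
with the abundance-based sample-coverage estimator
`C = 1 − (f₁/n)·(n−1)f₁/((n−1)f₁ + 2f₂)`.

**Forest-dependency index.** For each species, with live-trap capture
rates `r_F` (forest) and `r_M` (matrix),

```
FD = log10((r_F + c) / (r_M + c)),   c = 0.01
```

Species are classified from FD and the threshold τ = max FD among
matrix-recorded species: `FD < 0` → open-habitat, `0 ≤ FD ≤ τ` →
matrix-tolerant, `FD > τ` → forest-dependent. Pitfall-only species
borrow the FD of a declared donor species. The per-site
community-averaged FD is the abundance-weighted mean of species FD — a
community-weighted mean trait.

**Community structure.** Richness, log-abundance, Bray–Curtis
dissimilarity and principal coordinates analysis (PCoA) with a
deterministic sign convention; axis 1 serves as the composition
response.

**Multimodel inference.** Gaussian GLMs with AICc bookkeeping
(`k` counts the residual variance), all-subsets enumeration with the
quadratic area term tied to its linear term, ΔAICc ≤ 2 confidence sets,
conditional model averaging with unconditional standard errors
(Burnham–Anderson), relative importance as summed Akaike weights,
Pearson/VIF collinearity screening, hierarchical partitioning of R²
(exact Chevan–Sutherland enumeration), buffer-radius selection, and
declared-outlier refits.

**Landscape projection.** Forest patches are delineated from binary
grids (8-connectivity by default), each patch receives
`cfd = b₀ + 0.35·log10(area) − 0.04·log10(area)²`, and a deforestation
chronosequence is summarized (patch counts, forest area, area fraction
with negative projected community FD, between-year transition
fractions). A FRAGSTATS-style proximity index with edge-to-edge pixel
distances is included.

**Synthetic surveys.** A seeded generator emulates the underlying study
design — 19 patches spanning 1.4–14,480.5 ha plus 3 continuous-forest
reference sites, a 20-species pool in three habitat-preference
archetypes, Poisson captures proportional to effort, and monotone
region-growing deforestation grids — so the whole pipeline is testable
end to end.

## Worked example

```python
import numpy as np, pandas as pd
import fragdep as fd

cfg = fd.SimulationConfig(seed=1)
sites = fd.generate_landscape(cfg)
pool = fd.generate_species_pool(cfg)
effort = fd.design_effort_table(sites, cfg.design)
captures = fd.simulate_captures(sites, pool, effort, seed=1)

profiles, tau = fd.build_species_profiles(captures, effort)
cm = fd.standardize_abundance(captures, effort)
cfd = fd.community_fd(cm, profiles)["cfd"]
x = np.log10(sites.set_index("site_id").loc[cfd.index, "area_ha"]).to_numpy()
fit = fd.fit_gaussian(cfd.to_numpy(), pd.DataFrame({"logA": x, "logA2": x**2}))
print(f"threshold tau = {tau:.3f}")
print(f"community FD range: {cfd.min():.2f} - {cfd.max():.2f}")
print(f"quadratic fit: b1={fit.params['logA']:.3f}, R2={fit.r2:.2f}")
```

prints

```
threshold tau = 0.453
community FD range: 0.81 - 2.44
quadratic fit: b1=0.218, R2=0.79
```

i.e. on this synthetic survey the largest FD among matrix-recorded
species is 0.453 (every species above it never appeared in the matrix),
site-level community FD spans 0.81–2.44, and log patch area explains
79% of its variance — small patches carry low-FD (matrix-leaning)
communities.

The same steps are available from a shell via the `fragdep` console
script (`simulate`, `standardize`, `fd`, `ordinate`, `infer`,
`project`).

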