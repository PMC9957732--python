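# potspread

Statistical machinery for studying how pottery technology spread among
prehistoric hunter-gatherer communities, combining biomolecular evidence of
what the pots were used for with typological evidence of how they were made.

The package is aimed at archaeological scientists working with organic
residue data (GC–MS / GC–C–IRMS molecular and isotopic features) and binary
trait inventories of ceramic assemblages. It provides, as one composable
pipeline:

* **Residue classification** — the 17 interpretative criteria that map lipid
  features onto food-commodity classes: aquatic resources
  `(c1 ∧ c2) ∨ c3`, ruminant fats `c4 ∨ c5` (Δ¹³C = δ¹³C₁₈:₀ − δ¹³C₁₆:₀ below
  −1.72 ‰, i.e. two s.d. below the non-ruminant reference mean
  0.36 ± 1.04 ‰), non-specific animal fats `c6 ∧ ¬(c2…c5)`, plants
  `∨(c7…c14)` and heating `∨(c15…c17)`, with three-valued logic so missing
  measurements can only withhold a class, never assert one.
* **Trait distances** — presence/absence aggregation to vessel or site level
  and Jaccard dissimilarity `d = 1 − |A∩B|/|A∪B|` per trait block
  (decoration, morphology, technology, use).
* **Spatial statistics** — Mantel and partial Mantel tests (permutation
  p-values, bootstrap CIs), Mantel correlograms with 213-km distance
  classes, and correspondence analysis of site × trait tables
  (SVD of `D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}`, total inertia = χ²/n).
* **Landscape distances** — haversine great-circle, least-cost paths over a
  cost raster (Dijkstra, 8/16-neighbourhood) and circuit-theory effective
  resistance (graph-Laplacian solve).
* **Diffusion chronology** — reduced-major-axis regression of arrival date
  (cal BC) on distance from an origin, `slope = sign(r)·s_y/s_x`, front
  speed `= 1/|slope|`, with Monte-Carlo propagation of radiocarbon posterior
  uncertainty; thin-plate-spline arrival surfaces and GeoJSON isochrones.
* **Splits networks** — NeighborNet circular orderings with nonnegative
  least-squares split weights, written as NEXUS SPLITS blocks.
* **A synthetic-data generator** with known ground truth (constant-speed
  diffusion front, latent-Gaussian trait fields with `exp(−d/ρ)` spatial
  correlation, class-conditional lipid features), so every estimator can be
  validated by recovery.

## Worked example

```python
from potspread import (SimConfig, simulate_sites, simulate_traits, simulate_lipids,
                       classify_table, summarize_by_region, jaccard_matrix,
                       JaccardOptions, haversine_matrix, partial_mantel, diffusion_mc)

cfg = SimConfig(n_sites=40, seed=42)           # default study conditions
sites, truth = simulate_sites(cfg)             # 8 km/yr front from the eastern origin
traits = simulate_traits(sites, cfg, truth)
lipids, truth = simulate_lipids(sites, cfg, truth)

freq = summarize_by_region(classify_table(lipids), sites)
print(freq[freq["class"] == "aquatic"][["region", "count", "n_interpretable", "fraction"]])

geo = haversine_matrix(sites)
fit = diffusion_mc(sites, geo, "ORIGIN", n_draws=500, seed=1)
print(f"diffusion speed: {fit.speed:.2f} km/yr "
      f"(95% CI {fit.speed_ci_low:.2f}-{fit.speed_ci_high:.2f})")

prod = jaccard_matrix(traits, JaccardOptions(blocks=("decoration", "morphology", "technology")))
use = jaccard_matrix(traits, JaccardOptions(blocks=("use",)))
res = partial_mantel(prod, use, geo, n_perm=999, n_boot=500, seed=2)
print(f"partial Mantel r = {res.r:.3f}, p = {res.p_value:.3f}")
```

prints

```
   region  count  n_interpretable  fraction
northeast     19               54  0.351852
northwest     18               55  0.327273
southeast     47               57  0.824561
southwest     29               45  0.644444
diffusion speed: 8.05 km/yr (95% CI 6.19-12.37)
partial Mantel r = 0.226, p = 0.002
```

Reading the numbers: aquatic residues dominate the south-eastern cuisine
profile (82% of interpretable samples) and fall off to the north-west, as
configured in the generator; the reduced-major-axis Monte-Carlo estimate
recovers the simulated 8 km/yr front speed; and the partial Mantel test
detects the coupling between pottery production traits and use traits after
geographic distance is held constant (the generator's shared latent factor).

A command-line interface mirrors the stages
(`potspread simulate | classify | traits | distances | ca | mantel |
correlogram | diffusion | nnet | pipeline`); `potspread pipeline config.yaml`
chains them from a YAML config into a run directory with per-stage CSV/NEXUS
outputs and a `summary.json`.

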