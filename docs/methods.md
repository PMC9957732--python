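# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Residue classification

Each analysed residue (an absorbed sherd extract or a charred surface
deposit) carries optional molecular and isotopic features. Seventeen
criteria map these onto commodity classes; all thresholds sit in
`CriteriaThresholds` so sensitivity analyses are one-line changes:

| criterion | feature | default cut | class |
|---|---|---|---|
| c1 | APAA C18 ∧ (C20 ∨ C22) ∧ isoprenoid acid | — | aquatic (with c2) |
| c2 | APAA C20:C18 ratio | > 0.06 | aquatic |
| c3 | SRR phytanic diastereomer | > 75.5 % | aquatic |
| c4 | Δ¹³C | < −1.72 ‰ | ruminant |
| c5 | Δ¹³C < −1.26 ‰ ∧ SRR% < 64 | | ruminant |
| c6 | cholesterol alteration products | flag | animal (non-specific) |
| c7–c14 | waxes, LCSFA > 15 %, P:S > 4, C12:C14 > 1, amyrins, phytosterols, APAA-C18 E:H > 4, 2-OH acids | | plant |
| c15–c17 | APAAs, long-chain ketones, BPCAs | flags | heating |

The −1.72 ‰ cut is derived, not free: it is the non-ruminant reference mean
minus two of its standard deviations (0.36 − 2×1.04), rounded to the
2-decimal precision at which the reference statistics are expressed. The
relaxed −1.26 ‰ cut is kept verbatim as conventionally quoted (numerically
it is one s.d. above the ruminant reference mean −2.28 ± 1.02 ‰, not two;
the package follows the quoted value rather than re-deriving it).

Criteria are three-valued: a missing measurement yields *unknown*, and
unknowns are coerced to *false* only at class assignment. Counts are
therefore a conservative floor — absence of a criterion is not evidence of
absence of a commodity — and `classify_table` logs how many samples had
unknowns that could only have added classes. "APAAs with C18 and at least
C20 carbon atoms" is read as C18 present AND (C20 or C22) present. The
non-specific-animal exclusion is exactly `NOT (c2..c5)`; criterion 1 does
not veto it. The interpretability gate passes samples above 5 µg g⁻¹
(sherds) or 100 µg g⁻¹ (foodcrusts) of lipid, or with any source-specific
biomarker present.

## Trait distances

Aggregation upward is presence-OR. Jaccard dissimilarity is computed on the
selected blocks; a pair of rows that are both empty in those blocks gets
distance 0 (they are indistinguishable) — a convention, logged when it
fires, with `drop_empty_rows` available instead. Vessel-level analyses are
expected to drop empty rows (fragmented assemblages carry no signal).

## Mantel machinery

The Mantel statistic is the Pearson correlation of the vectorized upper
triangles. p-values come from joint row/column permutations of one matrix,
`p = (count ≥ observed + 1)/(n_perm + 1)`, two-sided on |r| by default
(`n_perm` 999; an exact enumeration mode exists for n ≤ 8). Confidence
intervals are a percentile bootstrap over **site labels** (500 resamples by
default); pairs formed by two copies of one site are excluded since their
distance is a structural zero. Bootstrapping sites rather than pairs keeps
the exchangeable unit the site, which is also the unit the permutation test
relabels.

Partial Mantel residualizes both matrices on the control by OLS on the
vectorized off-diagonals and permutes the raw first matrix, re-residualizing
each time (Legendre's raw-matrix permutation method).

Correlograms use fixed-width great-circle classes (default 213 km). For
class k the statistic is −1 × the Mantel r between the trait matrix and the
class-membership indicator, so **positive r means within-class similarity**.
Classes are truncated once fewer than 2 pairs remain; a constant indicator
(every pair in one class) reports r = 0, p = 1. No multiple-testing
correction is applied across classes by default; a Holm step-down is easy to
add downstream and deliberately not imposed.

## Correspondence analysis

Standard symmetric CA by SVD of the standardized residual matrix. All-zero
rows/columns are dropped with a log message. Axis orientation is fixed by
making the largest-magnitude row loading on each axis positive — orientation
carries no information, and a deterministic sign makes runs and tests
reproducible. The label "two-factor principal canonical correlation"
sometimes attached to this analysis is nonstandard; what is implemented is
ordinary CA of a two-way table, whose total inertia equals χ²/n (asserted to
1e-10 in the tests).

## Landscape distances

Great-circle distances use the haversine formula with a configurable Earth
radius (default 6371 km). Least-cost distances run Dijkstra on the raster
lattice with edge weight = mean of the two cell costs × metric step length;
the default 16-neighbourhood (knight's moves) keeps the angular
discretization error ≈ 2.8 % versus ≈ 8 % for the 8-neighbourhood, which
matters because these distances feed the diffusion regression. The cost
function applied to a DEM is `cost = base × (1 + slope_penalty · tan slope)`
with slope from finite differences — the upstream GIS cost surface is
unspecified in the literature this emulates, so the function is explicit and
configurable rather than implicit. Effective resistance treats each lattice
edge as a conductor `g = 1/(mean cost × step length)` and solves the graph
Laplacian with one node per component grounded (sparse LU, factorized once
per component). Raster analyses take projected coordinates (or a projector
such as `equirectangular_projector`); nothing is reprojected implicitly.

## Diffusion chronology

The front model: arrival date (cal BC, larger = earlier) declines linearly
with distance from the origin; speed is the reciprocal slope magnitude of a
reduced-major-axis fit (`slope = sign(r)·s_date/s_dist`, the geometric mean
of the two OLS slopes, symmetric under axis exchange — so it does not matter
which variable is "the response"). The origin site is configurable and
required; the regression may use great-circle or least-cost distances.

Chronological uncertainty is handled by Monte Carlo over the per-site
posterior draws. Plain RMA on noisy dates is attenuated: sampling one date
per site inflates the between-site date variance by, on average, the mean
within-site posterior variance, multiplying the RMA slope by
`sqrt(1 + σ²_post/σ²_true)` and shrinking the speed accordingly (≈ 12 %
under the default conditions). `diffusion_mc` therefore subtracts the mean
posterior variance (computed from the observed posteriors — no ground truth
involved) from each draw's date variance before forming the slope, an
errors-in-variables correction that vanishes for zero-width posteriors. The
corrected variance is floored at 25 % of the raw variance to keep the slope
defined in extreme draws; this floor produces the heavy upper tail visible
in the speed CI. The point estimate is the fit to posterior means, where
the measurement noise is already averaged down by `1/√n_draws`.

Arrival (or Δ¹³C) surfaces use thin-plate splines — kernel `r² log r` plus
an affine part, smoothing parameter λ; λ = 0 interpolates exactly, λ → ∞
tends to the least-squares plane. Isochrones are marching-squares contours
of the surface exported as GeoJSON line features.

## NeighborNet

The agglomerative ordering follows the canonical two-level selection (the
neighbour-joining adjusted distance Q first over clusters, then over member
nodes) with the 2/3–1/3 reduction replacing three consecutive path nodes by
two, until three or fewer nodes remain; reversing the reductions yields the
circular ordering. Ties break toward the lowest-index pair so output is
deterministic; the tie-break only matters on degenerate inputs. Split
weights solve a nonnegative least squares problem over all n(n−1)/2
circular-interval splits (active-set NNLS); splits under 1e-9 are dropped
as numerical dust — low enough not to hide genuine reticulation. On
additive inputs the recovered splits equal the tree's splits with branch
lengths as weights (verified exhaustively for all 4- and 5-taxon
topologies). NEXUS output carries TAXA and SPLITS blocks (cycle plus
weighted splits) readable by standard splits-graph viewers.

## Synthetic data: what it emulates, and what it does not

`simulate_sites` places sites uniformly over a bounding box spanning the
west-of-Urals to Baltic extent (lon 10–70° E, lat 48–66° N, origin on the
eastern edge at 6500 cal BC) and dates them by a constant-speed front
(default 8 km yr⁻¹). Per-site chronology is a vector of posterior draws,
`Normal(true + site_noise, posterior_sd)`; the defaults are
`posterior_sd = 100 yr` and `site_noise = 0`, i.e. all dating uncertainty is
chronological measurement carried by the posteriors — a Student-t or
Gaussian site-level scatter off the front is available as a robustness knob
but is not part of the default conditions.

`simulate_traits` draws each trait as a thresholded latent Gaussian field
with inter-site correlation `exp(−d/ρ)` (ρ defaults: 300 km for
decoration/morphology/technology, 150 km for use; prevalence 0.35). A
single shared spatial factor couples the blocks: production traits load on
it with α = 0.6, use traits with β (default 0.2), so the latent
production–use correlation is αβ. β = 0.2 was calibrated once so the
partial Mantel correlation between production and use Jaccard matrices,
holding geography constant, sits near 0.2 under the default conditions —
the coupling strength itself is a free parameter of the generator, not an
empirical quantity. The latent-field model was chosen over an explicit
copying/transmission simulation because it produces isolation-by-distance
with two interpretable knobs (range ρ, prevalence) and exact limiting
behaviour (ρ → ∞ gives identical sites; ρ → 0 gives spatial independence).

`simulate_lipids` draws per-vessel commodity sets from regional cuisine
profiles (aquatic-dominated in the south-east, ruminant-heavier in the west
and north-east). Per-class *sensitivity* is the probability that a present
commodity expresses its full diagnostic signature — for ruminant fats this
means a Δ¹³C draw from the reference ruminant distribution truncated below
the −1.72 ‰ cut, because an untruncated `Normal(−2.28, 1.02)` draw falls
below the cut only ~71 % of the time and "perfect markers" would otherwise
top out well short of full recall. Conversely an unexpressed or absent
class draws from the non-diagnostic side. *Specificity* is the probability
that an absent class does not express. Mixtures average Δ¹³C contributions
with random Dirichlet-like weights. APAA presence ties aquatic
identification to heating, as the chemistry dictates.

What passing the synthetic suite shows: the estimators recover the
quantities their models define, at the configured noise levels, with
calibrated error rates. What it does not show: real assemblages violate the
generator in known ways — traits are not exchangeable thresholded Gaussians,
vessel sampling is highly uneven, cuisine profiles drift over time within a
region, isotope mixing is not linear in mass fractions, and chronological
posteriors from calibration curves are multimodal rather than normal. Site
recovery is also not spatially uniform. Conclusions about real data rest on
the estimators' robustness to these departures, which the Student-t noise
and configurable profiles only partially probe.

## Problem sizes and determinism

The packaged validation runs at the study scale (40 sites, 162 ceramic +
17 use traits, 500 Monte-Carlo draws, 999 permutations, 500 bootstrap
resamples, 500 null simulations for the type-I error check); exhaustive
oracles run at the sizes where exhaustion is feasible (all 64 six-trait
rows, all 4- and 5-taxon tree topologies, full truth tables of interacting
criteria, 120-permutation exact Mantel at n = 5). Every stochastic
component takes an explicit seed, and rerunning any stage with the same
seed and inputs reproduces its outputs exactly.
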