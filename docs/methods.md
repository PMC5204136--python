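# Methods

## Functional entities

Species are partitioned by exact identity of all six trait categories.
Five traits are ordered (size class 6 levels, home range 3, position 3,
activity 3, schooling 5); diet is nominal with 7 levels. Entity
identifiers are built from 1-based category codes
(`S2.D5.H1.P1.A1.G3`), so they are stable across platforms, label
spellings and input row order. Validation rejects missing or unknown
categories rather than imputing: a trait database used for this
analysis is expected to be complete for adult life stages, and silent
imputation would move species between entities.

## Trait space

Gower distance with equal trait weights 1/6: ordered traits are encoded
as equally spaced ranks rescaled to [0, 1] and contribute absolute
differences; diet contributes simple matching. The distance is a metric
on these encoded vectors, bounded by [0, 1].

PCoA retains the first four axes (`n_axes` configurable). Gower
matrices are generally non-Euclidean, so negative eigenvalues appear.
Policy (`negative_policy`):

- `drop` ignores negative axes;
- `correct` always applies the Lingoes additive correction
  (d′² = d² + 2|λ_min| off-diagonal), which shifts every non-trivial
  eigenvalue up by |λ_min| and makes the embedding exact;
- `auto` (default) corrects only when |λ_min| ≥ λ₍n_axes₎, i.e. when the
  negative structure is large enough to distort a retained axis.

Axis signs are fixed so each axis' largest-magnitude coordinate is
positive. Since species in one entity share all categories, their Gower
distance is 0 and their ordination coordinates coincide; the entity's
point in trait space is that shared point.

Functional richness is the exact convex-hull volume (Qhull facet
decomposition) of a region's species points, divided by the global
pool's hull volume. A Monte-Carlo rejection estimator exists in the
test suite purely as an independent oracle. Degenerate point sets
(not full-dimensional in 4-D) raise an explicit error instead of
returning a zero volume.

## β-diversity

The Jaccard dissimilarity is partitioned additively into turnover
β_jtu = 2·min(b,c)/(a + 2·min(b,c)) and nestedness-resultant
β_jne = β_jac − β_jtu. For taxonomic β the triple (a, b, c) counts
shared and unique species. For functional β the same formulas are
applied to hull volumes: shared volume of the two regional hulls as a,
unique volumes as b and c. Intersection volumes in 4-D are estimated by
seeded rejection sampling inside the union's bounding box (default 10⁵
points; the binomial standard error of the shared-fraction is
reported). Exact 4-D polytope intersection is deliberately avoided: the
two-decimal precision at which these indices are interpreted does not
warrant it. Identical member sets short-circuit to exact zeros, and a
region nested strictly inside another yields β_jtu = 0 exactly, because
no sample can fall in the inner hull without the outer.

## Redundancy

Mean abundance of species i is its arithmetic mean count over all N
transects of the region (zeros included), at the common transect area.
Surveys recorded at a smaller area are first pooled by seeded random
disjoint grouping (e.g. two 250 m² transects → one 500 m² unit); an odd
leftover transect is dropped with a warning. FR_ab sums member means;
FR_Shannon = exp(−Σ p_i ln p_i) uses natural logarithms — the
exponential back-transform makes the index an equivalent number of
species, so the logarithm base cancels. Zero-abundance members
contribute p_i = 0 and are excluded from the entropy sum (0·ln 0 := 0;
proportions that underflow to zero in floating point are treated the
same way). Entities none of whose members were observed in a region
keep FR_S = 0 with undefined (NaN) FR_Shannon and are excluded from
that region's vulnerability ranking: an absent function has no
redundancy to rank.

## Vulnerability (TOPSIS)

Default criteria: sensitivity (cost) and FR_Shannon (benefit), equal
weights. FR_Shannon subsumes both the species-count and
abundance-structure aspects of redundancy, which keeps the criteria
space two-dimensional and interpretable; any subset of
{FR_S, FR_ab, FR_Shannon} and custom weights can be configured.
Criteria are min–max normalised over the FE set of the region being
analysed (not the global pool), because vulnerability is a relative
ranking within an assemblage. A constant criterion is pinned to 0.5 so
it contributes symmetrically to both distances and cannot tip the
ranking. V = d⁺/(d⁺ + d⁻) with Euclidean distances in the normalised
space; the orientation (V = 0 at the positive ideal, 1 at the negative)
is fixed by the boundary definition of the index, not by the common
TOPSIS "closeness" convention, which is its complement. Each region is
ranked independently; ties are broken lexicographically by entity id.

## Kernel-density maps

Index values (redundancy, sensitivity, vulnerability) are used as KDE
weights, normalised to sum to 1 — the map shows where in trait space
the index mass sits, not merely where entities sit. The kernel is
isotropic Gaussian with the bivariate normal-reference bandwidth
h = σ·n^(−1/6), σ² the mean of the two per-axis sample variances
(ddof = 1). Default grid: 100×100 over the point extents padded by 3h
per side, axis pairs (PC1, PC2) and (PC3, PC4). The discretised surface
is renormalised so its Riemann sum is exactly 1 (the Gaussian tail mass
beyond the padded grid is below ~10⁻³ and discretisation error smaller
still). Surface agreement is reported both as FE-level Pearson
correlation of the raw index values (the default, and the mode in which
the headline correlations are interpreted) and as grid-cell correlation
of the two surfaces; grid-cell correlations are systematically higher
because both surfaces share the point geometry.

## Synthetic communities

The generator emulates an unfished Indo-Pacific reef survey:

- **Entity structure.** Species-per-FE multiplicities are drawn from a
  power law over 1..17 (17 = the most packed entity size such surveys
  show; `packing` rescales the cap). The exponent is solved at run time
  so the expected singleton fraction equals `singleton_target`
  (default 0.62, matching the >60 % observed). Each entity receives a
  distinct uniform-random trait combination, so entity size is
  independent of trait identity by construction.
- **Abundances.** Latent species means are log-normal (median 8
  individuals per 500 m², log-sd `abundance_dispersion` = 1.2); counts
  are Poisson per transect. No abundance distribution is reported for
  such surveys; the log-normal is an assumption, and the zero-variance
  limit (all species equal) is available for testing. Default survey
  effort: 3 regions × 20 transects × 500 m².
- **Regional occupancy.** Bernoulli per species and region with
  p = 0.45, chosen so that the expected fraction of species shared by
  all three regions is ≈ 0.11–0.13 and the expected pairwise taxonomic
  β_jac = 2(1−p)/(2−p) ≈ 0.71, the sharing structure reported for
  these faunas. Every species is forced into at least one region.
- **Sensitivity.** Expected score rises linearly with size class
  (from 15 % to 75 % of the configured range), Gaussian noise of sd
  15 % of the range, clipped. Because trait combinations are assigned
  independently of entity size, sensitivity is independent of
  redundancy by construction.

One seed drives three independent substreams (traits, abundances,
sensitivity), so each stage is reproducible in isolation.

What the generator does *not* emulate: real trait covariances (big fish
are not preferentially piscivores here), spatial autocorrelation among
transects, detection biases of visual censuses, and region-specific
richness gradients. Passing tests therefore demonstrate that the
pipeline recovers the structural pattern it is designed to measure —
vulnerability driven by sensitivity where redundancy is scarce and
independent of it — not that any particular real fauna behaves this way.

## Problem sizes and numerics

Tests and the acceptance script run the generator at its default 400
species (the survey scale the method targets) and estimate hull
intersections with 10⁵ rejection samples, hull-volume cross-checks with
2×10⁵ samples against a 3-standard-error band, and structural-recovery
correlations as means over 20 seeds × 3 regions, mirroring the
"mean across regions" form in which such coefficients are reported.
Pipeline determinism is asserted on SHA-256 checksums of every artifact,
with CSV floats written at 10 significant digits.

## Known limitations

- Functional β components inherit Monte-Carlo noise (~0.003 SE at
  default settings); they are not suited to discriminating differences
  below ~1 %.
- The Lingoes `auto` trigger compares |λ_min| to the smallest retained
  eigenvalue; datasets hovering near that boundary may switch policy
  between otherwise similar inputs (pin `correct` or `drop` for strict
  comparability across datasets).
- FRic requires at least 5 affinely independent points per region in
  4-D; very depauperate regions raise a degenerate-hull error rather
  than a value.
- Sensitivity scoring itself (the 0–100 scale) is an input produced by
  an external expert system; the package neither validates nor
  reproduces it beyond range checks.
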