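# fvuln — baseline functional vulnerability of reef-fish communities

`fvuln` asks how well a fish assemblage is buffered against species loss
*before* fishing starts. Even on unfished reefs, most combinations of
ecological traits are carried by a single species: losing that one
species erases the function. The package quantifies this "baseline
functional vulnerability" for community ecologists working from
transect surveys, a categorical trait database and per-species
fishing-sensitivity scores.

## The analysis

1. **Functional entities (FEs).** Species are grouped by identical
   categories on six traits (size class, diet, home range, water-column
   position, activity period, schooling). An FE is a proxy for one
   functional role.
2. **Trait space.** Gower distances (equal weight 1/6 per trait;
   range-normalised ranks for ordered traits, simple matching for diet)
   are ordinated by PCoA; the first four axes are retained. Functional
   richness of a region, FRic, is its convex-hull volume as a fraction
   of the global pool's hull.
3. **β-diversity.** Pairwise Jaccard dissimilarity between regions is
   partitioned into turnover and nestedness-resultant components,

       β_jac = (b + c) / (a + b + c),
       β_jtu = 2·min(b, c) / (a + 2·min(b, c)),
       β_jne = β_jac − β_jtu,

   for species incidence (a = shared, b/c = unique) and, analogously,
   for hull volumes in trait space (shared volume as a).
4. **Redundancy.** Per FE and region: species count FR_S, summed mean
   abundance FR_ab (individuals per 500 m² transect), and the
   equivalent number of species FR_Shannon = exp(−Σ p_i ln p_i) with
   p_i the members' abundance proportions (a Hill number of order 1:
   1 for singletons, FR_S when members are equally abundant).
5. **Vulnerability.** TOPSIS over a criteria matrix — sensitivity
   (0–100, cost) and redundancy (benefit) — min–max normalised. With A+
   the positive ideal (min sensitivity, max redundancy) and A− the
   negative ideal, V = d⁺ / (d⁺ + d⁻) ∈ [0, 1]; V = 0 at A+, 1 at A−.
6. **Maps.** Each index is drawn as a weighted Gaussian kernel density
   over pairs of functional axes, bandwidth h = σ·n^(−1/6) (normal
   reference), and surfaces/indices are compared by Pearson correlation.

A seeded synthetic-community generator reproduces the statistical
structure such surveys show — a few hundred species collapsing onto far
fewer FEs, >60 % single-species FEs, log-normal abundances, sensitivity
rising with body size but independent of redundancy — so the whole
pipeline is testable without survey data.

## Worked example

```sh
cat > run.yml <<EOF
outdir: out
seed: 1
synth:
  n_species: 400
EOF
fvuln all --config run.yml
# wrote 51 artifacts to out
```

`out/fric.csv` — each region's hull volume against the 400-species pool:

```
region_id  hull_volume  global_volume  fric_ratio
  region1     0.043985       0.064638    0.680479
  region2     0.052081       0.064638    0.805735
  region3     0.054290       0.064638    0.839922
```

Regions keep 68–84 % of the pool's functional volume despite holding
only about half of its species each — functional breadth is far more
stable than species identity (the taxonomic β_jac in `out/beta.csv` is
≈ 0.75–0.78 while functional turnover is ≈ 0.15–0.21).

`out/vulnerability.csv`, most vulnerable entities of region1:

```
            fe_id  FR_S  FR_Shannon  sensitivity        V  rank
S4.D6.H2.P1.A2.G5     1         1.0   100.000000 1.000000     1
S6.D2.H3.P3.A2.G2     1         1.0    92.692076 0.948426     2
S5.D2.H2.P1.A3.G5     1         1.0    92.678091 0.948329     3
```

The top entities are large piscivores and macroalgal feeders
(`S4`–`S6` size codes, `D6`/`D2` diet codes) with no redundancy
(FR_S = 1) and near-maximal sensitivity. `out/correlations.csv` shows
the structural signature: vulnerability tracks sensitivity at the FE
level (r ≈ 0.79–0.84 per region) while sensitivity and redundancy are
uncorrelated (r ≈ −0.05 to −0.08).

The same pipeline runs on real data by replacing `synth:` with

```yaml
inputs:
  traits: traits.csv            # species_id + six trait columns
  abundances: [abundance_A.csv, abundance_B.csv]
  sensitivity: sensitivity.csv  # species_id, sensitivity in [0, 100]
```

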