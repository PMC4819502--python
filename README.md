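# rhizotransfer

Natural-abundance δ¹⁵N estimation of nitrogen transfer from an
N₂-fixing shrub to its neighbouring grasses, with the blocked-transect
statistics and community analyses that go with it.

## The problem

Leguminous shrubs encroaching into semi-arid grasslands fix atmospheric
N₂ and release part of that nitrogen into the soil through their living
roots (*rhizodeposition*: exudates, root-hair turnover, fine-root
litter). Neighbouring grasses can take this nitrogen up, and because
biologically fixed N carries a δ¹⁵N signature close to the atmospheric
value (0 ‰) while soil-derived plant N is typically more enriched, the
shoot δ¹⁵N of a grass records how much of its nitrogen came from the
shrub. This package implements the natural-abundance two-source mixing
approach that turns those signatures into quantitative transfer
fractions, for ecologists analysing blocked shrub-transect designs
(or stress-testing the method on simulated ones).

## The method

Rhizosphere soil (RS, adhering to shrub roots) is enriched in N over
non-rhizosphere soil (NRS). Attributing that enrichment to
rhizodeposition gives the deposition fraction of rhizosphere-soil N

    P_depo = (N_RS − N_NRS) / N_RS

Writing the same fraction as a two-source isotope mixing model and
solving for the unmeasurable δ¹⁵N of rhizodeposition:

    δ¹⁵N_depo = (δ¹⁵N_RS − δ¹⁵N_NRS) · N_RS / (N_RS − N_NRS) + δ¹⁵N_NRS

A second mixing model then partitions each grass's shoot N between
rhizodeposition and reference soil-derived N:

    P_transfer = (δ¹⁵N_mix − δ¹⁵N_ref) / (δ¹⁵N_depo − δ¹⁵N_ref)

where δ¹⁵N_mix is the species' mean shoot signature at a transect
distance and δ¹⁵N_ref its mean signature in reference plants growing
far from any shrub. Uncertainty is propagated by a nonparametric block
bootstrap that resamples shrub clusters — the design's replicate unit —
jointly through the soil and plant stages.

Around the mixing core the package provides the design's inferential
layer (linear mixed models with a random block intercept compared by ML
likelihood-ratio tests, Tukey–Kramer all-pairs comparisons with compact
letter display for unbalanced cells, species-pair δ¹⁵N regressions),
community responses (Pielou evenness on biomass proportions, paired
Within/Open contrasts), and a synthetic field generator that simulates
the entire study from known truth so every estimator can be validated
end to end.

## Worked example

Simulate one realisation of the default design (6 shrub-cluster blocks,
distances 0–500 cm plus a reference position, three grasses with
contrasting true transfer profiles) and estimate everything:

```sh
rhizotransfer simulate --seed 1 --out-dir out
rhizotransfer estimate --seed 1 --out-dir out
rhizotransfer community --seed 1 --out-dir out
rhizotransfer report   --seed 1 --out-dir out
```

The `estimate` step prints the derived deposition end-member:

```
d15N_depo = -3.255 per mil, P_depo(soil) = 0.220 (0 degenerate bootstrap draws dropped)
```

i.e. rhizodeposition is strongly ¹⁵N-depleted relative to bulk soil
(−3.26 ‰) and accounts for 22 % of rhizosphere-soil N in this
realisation (truth: −3.0 ‰ and 25 %). The report then gives per-species
transfer profiles, e.g. for the rhizomatous grass (true fraction 0.47
at every distance):

```
LC: transfer fraction by distance (cm)
     0 :  45.5 % (95% CI  41.5 to  50.2, n = 5)
    20 :  46.4 % (95% CI  43.1 to  50.6, n = 6)
    ...
   500 :  42.8 % (95% CI  38.6 to  47.7, n = 4)
  mean across distances:  44.3 %
```

The bunchgrass profile shows transfer only at the canopy edge
(21.4 % at 0 cm) and the endophyte-infected bunchgrass stays near zero,
while the community stage reports reduced Pielou evenness within the
canopy (paired t across 6 blocks, P = 0.012 in this run). Each
percentage is the two-source mixing fraction applied to that cell's
mean shoot δ¹⁵N; the intervals are percentile block-bootstrap bounds.

The same machinery is available as a library of sklearn-style
estimators:

```python
from rhizotransfer import EndMemberEstimator, TransferProfileEstimator

em = EndMemberEstimator(n_boot=1000, random_state=1).fit(soil_table)
profile = TransferProfileEstimator(end_members=em).fit(plant_table)
profile.estimates_          # species × distance transfer fractions + CIs
```

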