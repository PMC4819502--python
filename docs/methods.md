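# Methods

## The mixing model and its assumptions

The package estimates the fraction of a grass's shoot nitrogen derived
from the rhizodeposition of a neighbouring N₂-fixing shrub using only
natural-abundance measurements. The chain rests on three assumptions:

1. **The RS−NRS nitrogen contrast is rhizodeposition.** The entire
   excess of rhizosphere-soil N over non-rhizosphere-soil N is
   attributed to root-derived inputs, so
   `P_depo = (N_RS − N_NRS)/N_RS`. Nothing in the data can validate
   this attribution; it is adopted as the method's defining premise,
   and its sensitivity can be probed through the generator by violating
   it deliberately.
2. **Two-source mixing.** Rhizosphere-soil N, and likewise grass shoot
   N, is a linear mixture of exactly two isotopically distinct pools.
   Equating the concentration-based and the isotope-based expressions
   for `P_depo` yields the deposition signature
   `δ¹⁵N_depo = (δ¹⁵N_RS − δ¹⁵N_NRS)·N_RS/(N_RS − N_NRS) + δ¹⁵N_NRS`
   (algebraically exact; the package tests this identity to 1e−12
   relative error).
3. **Species-specific reference.** The non-deposition end-member of a
   grass is that species' shoot δ¹⁵N measured on reference plants far
   from any shrub; no fractionation during uptake or within-plant
   allocation is modelled.

Raw mixing fractions can leave [0, 1] under noise. The raw value is
always retained (`p_transfer_raw`) next to the clipped value
(`p_transfer`), with `CLIPPED_LOW`/`CLIPPED_HIGH` flags — transparency
over silent truncation.

## Uncertainty: block bootstrap

The replicate unit is the shrub cluster (block). Uncertainty is
propagated with a nonparametric block bootstrap, default 1000 draws:
blocks are resampled with replacement, keeping the RS/NRS pairing
within each block, and the full chain (compartment means → `δ¹⁵N_depo`
→ per-cell transfer fraction) is recomputed per draw. The plant stage
reuses the soil stage's resampled block indices, so a draw represents
one coherent resampled field campaign and shared block effects
propagate consistently. Draws with `N_RS ≤ N_NRS` leave the deposition
signature undefined; they are dropped and counted rather than clipped —
the count is a diagnostic of end-member separability. Intervals are
percentile intervals; with 6 blocks these under-cover somewhat (the
package's own calibration experiment at the default noise level finds
pooled coverage of nominal-95 % intervals a little above 0.86), which
is the familiar small-n behaviour of the percentile bootstrap.

Point estimates apply the mixing model to per-cell means (mean shoot
δ¹⁵N at a species × distance cell against the species' mean reference
signature). Averaging per-block mixing ratios instead is exposed as an
option (`per_block=True`); the two coincide when within-cell variation
vanishes.

## Mixed models and likelihood-ratio tests

Responses (shoot N %, shoot δ¹⁵N) are modelled with a Gaussian linear
mixed model: species, distance class (reference position included as a
level) and optionally their interaction as fixed effects, a random
intercept per block. Fits use maximum likelihood, not REML, because the
compared models differ in fixed effects; each effect is tested by a
likelihood-ratio test against the model without it (main effects
against the additive model, the interaction against the additive
model), referred to a χ² distribution with df equal to the
fixed-effect parameter difference. Boundary fits with (near-)zero block
variance are reported with a `singular` flag, and a response with zero
variance short-circuits to statistic 0, p = 1.

The χ² reference is asymptotic. At the default design size
(6 blocks, ~139 plant rows) the package's own null-simulation
experiment shows the low-df tests (species, df = 2; distance, df = 7)
running slightly hot (rejection near 0.06–0.07 at nominal 0.05) and the
high-df interaction test (df = 14) distinctly anticonservative
(~0.13). Interaction p-values near the threshold should therefore be
read with caution at this design size; no small-sample correction
(Kenward–Roger, parametric bootstrap) is applied, keeping the standard
ML/χ² pairing.

## Tukey–Kramer comparisons and letters

All-pairs distance comparisons use the studentized-range distribution
with the Kramer unequal-n standard error
`sqrt(s²/2·(1/nᵢ + 1/nⱼ))`, pooled one-way residual variance on
N − k df — the standard treatment for the design's missing cells
(4–5 replicates in some species × distance cells, 6 elsewhere).
Residual df come from the one-way layout per species; the block random
effect is deliberately ignored at this stage (a model-based pairwise
procedure is out of scope). With equal n the procedure reduces exactly
to Tukey's HSD, which the tests cross-check against an independent
numerical quadrature of the studentized-range distribution and against
statsmodels. Compact letter displays use the insert-and-absorb
algorithm; an independent checker in the test suite re-derives the
significance pattern from the letters.

Shapiro–Wilk and Levene screens are computed and reported but never
gate any analysis.

## Community analyses

Evenness is Pielou's J = H′/ln S on biomass proportions per quadrat
(abundance proportions available as an option); J is undefined and
flagged for single-species quadrats, and zero-biomass species are
dropped. Within-canopy vs open contrasts — per-species biomass, height
and abundance, functional-group biomass totals, and per-block evenness
— use paired t tests on per-block Within − Open differences, dropping
and counting incomplete blocks. A zero-variance nonzero difference is
reported with p at the smallest positive float rather than erroring.

## The synthetic field generator

The generator forward-simulates the emulated study design: 6 blocks,
transect distances 0, 20, 50, 100, 150, 300, 500 cm plus a reference
position, three grasses with contrasting transfer profiles, and the
design's stated missing cells (5 replicates for the rhizomatous grass
at 0 cm and 4 at 500 cm; 5 for the endophyte-infected bunchgrass at
0 cm and 4 at 20 cm). Soil truth is parameterised by the deposition
pool (`δ¹⁵N_depo = −3 ‰`, deposition fraction 0.25, background soil
3 ‰ / 0.15 % N) so the implied rhizosphere means invert exactly through
the estimation chain; transect and reference soils are flat at the
background means. Default species truths: constant 0.47 transfer for
the rhizomatous grass (reference shoot δ¹⁵N 4 ‰), a 0.19 step at the
canopy edge for the bunchgrass (reference 2 ‰), zero transfer for the
endophyte-infected bunchgrass (reference 1 ‰, highest shoot N). These
reproduce the qualitative field patterns — near-shrub shoot δ¹⁵N
between 0 and 1 ‰, enriched references, rhizosphere soil N-richer and
¹⁵N-depleted — and are config values, not data assertions.

Noise is additive Gaussian on δ¹⁵N (default residual sd 0.3 ‰, block
intercept sd 0.1 ‰) and on N % (sd 0.08, block sd 0.03, floored at a
small positive value); variance components are not derivable from the
emulated design's summary statistics, so these defaults are choices,
exposed in the config. Shoot N couples to the transfer fraction
linearly, `N = N_ref·(1 + n_gain·P)` — the simplest coupling producing
a monotone N-vs-distance pattern.

The community generator draws paired Within/Open quadrats from a
nine-species pool (three dominant grasses plus a forb tail) with
additive Within-shifts per species: the rhizomatous grass gains biomass
and height inside the canopy, both bunchgrasses lose biomass, forbs are
lightly suppressed — concentrating biomass and reducing evenness within
the canopy. The pool is smaller and more balanced than a real steppe
community, so absolute evenness values run higher than field values;
it is the Within − Open contrast, not the level, that the generator
emulates.

What passing tests on generator data do **not** show: correctness of
the rhizodeposition attribution on real soils, absence of isotopic
fractionation during uptake, robustness to non-Gaussian or
spatially structured noise, or behaviour under end-member contrasts
near instrument precision (0.1 ‰) — the validation experiments
deliberately use separable end-members.

## Numerical and design choices

- Distance classes are integers (cm) with the literal string `REF`
  sorting last; no float keys.
- Validation severity: impossible values (N % ≤ 0 or ≥ 10) are errors,
  implausible ones (|δ¹⁵N| > 20 ‰) warnings.
- Bootstrap draws that resample only blocks missing at a cell are
  excluded from that cell's percentile interval.
- Degenerate end-members raise distinct errors at the mean level and
  are dropped-with-count at the draw level.
- All stochastic stages consume a single integer seed; CLI outputs are
  written atomically and are byte-identical across runs of the same
  (config, seed).
- Validation problem sizes: 200 replicates × 400 bootstrap draws for
  recovery/coverage, 500 null and 200 effect simulations for LRT
  calibration and power, 10,000 tuples for the mixing identity.
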