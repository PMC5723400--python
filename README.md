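# clonalscape

Clonal richness of tropical seagrasses and its environmental drivers.

Seagrass meadows are collections of ramets (shoots/rhizome units) belonging
to a much smaller number of genets (genetic individuals recruited from
seed). How many genets stand behind a meadow — its *clonal richness* —
reflects the balance of genet mortality and seedling recruitment, and hence
the disturbance regime the meadow experiences: tropical-cyclone seas,
dugong grazing, temperature and turbidity stress, and isolation from seed
sources. `clonalscape` implements the full quantitative chain used to study
this in north-west Australian meadows of *Halodule uninervis*, *Halophila
ovalis*, and *Thalassia hemprichii*:

1. **Genotypes → clones.** Multilocus genotypes (MLGs) are read from
   GenAlEx-style wide tables or genepop files; samples sharing all allele
   calls are one clone. Clonal richness is

   ```
   R = (G − 1) / (N − 1)
   ```

   for `G` distinct MLGs among `N` sampled ramets (0 = monoclonal,
   1 = all distinct).

2. **Marker power.** The probability of identity,
   `P_ID = Σ p_i⁴ + Σ_{i<j} (2 p_i p_j)²` per locus, multiplied across
   independent loci, is the chance two random individuals share an MLG
   under Hardy–Weinberg equilibrium; `C(N,2)·P_ID` is the expected number
   of duplicate-genotype pairs among the N samples.

3. **Cyclone exposure.** Hourly cyclone-vortex winds are blended with
   synoptic winds (full cyclone weight inside three eye radii, linear ramp
   to zero at six), mapped to significant wave height, and thresholded at
   4 m to count yearly exposure events. The annual exposure probability is
   the Poisson tail

   ```
   Pr(X ≥ 1) = 1 − e^(−λ)
   ```

   with λ the mean yearly event count.

4. **Driver selection.** Site-level R is modelled against cyclone-exposure
   probability (√), dugong-hotspot presence (factor), mean SST (log),
   KD490 turbidity (√), and distance from shore (√) with Gaussian additive
   models (regression splines, basis dimension 4). A full-subset sweep —
   at most two predictors per model, no pair with |r| > 0.28, predictors
   with |r| > 0.8 against a retained predictor pre-dropped — is ranked by
   AICc. Akaike weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)` give
   per-predictor variable importance (the weight sum over models
   containing the predictor); the selected model is the most parsimonious
   within two AICc units of the best.

5. **Comparisons.** Kruskal–Wallis plus Mood's median test across species;
   Pearson correlations of R with latitude and between co-occurring
   species.

A seeded synthetic-data module generates every input the pipeline needs —
clonal populations sampled 50 ramets at ≥ 2 m spacing in a 50-m-diameter
site, parametric-vortex storm histories, and covariate–response scenarios
with known truth — so the whole chain is testable end-to-end without any
field data.

## Worked example

```
$ clonalscape simulate population --genets 8 --seed 7 --out demo_pop
wrote demo_pop/genotypes.csv (50 samples, 8 sampled genets)

$ clonalscape clonality --in demo_pop/genotypes.csv --policy strict
site=site1 N=50 G=8 R=0.1429 policy=strict
cumulative P_ID=3.085e-06 expected duplicate pairs=0.0038
```

Fifty ramets resolved into 8 clones: R = (8−1)/(50−1) = 0.143, a strongly
clonal meadow. The marker panel's cumulative P_ID of 3.1·10⁻⁶ means only
0.0038 duplicate pairs are expected among the 1225 sample pairs by chance —
the clones are real, not marker artefacts.

```
$ clonalscape simulate drivers --sites 16 --seed 7 --out demo_drv
$ clonalscape drivers --covariates demo_drv/covariates.csv
== synthetic ==
       model       AICc  delta.AICc   wi.AICc       r2  n  k
cyclone.sqrt -36.429249    0.000000  0.934247 0.870148 16  5
...
importance:
cyclone_pr    0.999970
dugong        0.064935
parsimonious: cyclone.sqrt
```

The scenario generated R as a hump-shaped function of cyclone probability;
the sweep correctly top-ranks the cyclone-only model (Akaike weight 0.93,
r² = 0.87) and assigns cyclone essentially all the variable importance.

The same operations are available as library functions
(`clonalscape.identify_mlgs`, `probability_of_identity`,
`annual_exposure_probability`, `run_driver_analysis`, ...).

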