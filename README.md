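# translocmove

Movement analysis of translocated animals: how individuals released
into a novel environment transition from **exploration** (wide-ranging
information gathering) to **exploitation** (settled use of known
resources), and how habitat quality shapes that transition.

The package implements, as a reusable and tested pipeline, the analysis
chain used in GPS-collar translocation studies of wild pigs
(*Sus scrofa*) released into upland pine vs. bottomland hardwood
habitat:

1. **Trajectory preprocessing** — PDOP quality filtering (fixes with
   PDOP > 9 discarded), thinning of mixed collar schedules to a common
   2-h cadence, detection of homing returns (an animal re-entering
   1.6 km of its capture site within 10 days is reclassified as a
   resident, with the pre-return track censored), and truncation to 90
   days post release.
2. **Dynamic Brownian bridge movement model (dBBMM)** — between
   consecutive fixes the position at fraction α of a bridge of
   duration *T* is bivariate normal with mean a + α(b − a) and
   per-coordinate variance

   ```
   σ²(α) = T α(1−α) σ²ₘ + (1−α)² δ² + α² δ²
   ```

   where σ²ₘ is the Brownian motion variance (m²/s) and δ = 15 m the
   telemetry error SD. σ²ₘ is estimated by leave-one-out maximum
   likelihood in a sliding window of 11 fixes with a margin of 5, with
   a BIC test for a structural break in each window. Integrating the
   bridge densities gives a utilization distribution (UD); the 50% and
   95% isopleths are the core and range areas.
3. **7-day moving-window metrics** — per day (the day ± 3 days):
   dBBMM core/range areas, mean distance to the release site, daily
   distance travelled, net squared displacement; aggregated to group
   (status × release habitat) mean ± SE series.
4. **Phase detection** — a translocated group switches from
   exploration to exploitation on the first day its mean 95% range
   area reaches the resident group's average; that crossing day is the
   last exploration day.
5. **Phase-stratified step-selection functions (SSF)** — each observed
   step is compared with 20 random steps drawn from empirical
   step-length/turning-angle distributions (stratified by phase and
   release habitat, excluding the focal animal), habitat recorded at
   step endpoints from a 3-class, 30-m landcover raster, and selection
   estimated by conditional logistic regression with animal-clustered
   sandwich standard errors. Four candidate models (habitat; ×status;
   ×release habitat; ×(status + release habitat)) are ranked by AIC,
   a post-hoc model adds habitat × diel (day/night) interactions, and
   weekly nocturnal fits trace selection for bottomland habitat
   through 13 weeks.
6. **Synthetic cohorts** — an agent-based simulator produces GPS
   tables, metadata and patchy landscapes with known ground truth
   (true selection coefficients β, programmed switch day T*, movement
   kernels, homing returners), so every stage is testable without any
   field data.

It is aimed at movement ecologists and spatial biostatisticians who
want the full analysis (or any stage of it) on their own telemetry
tables, and at methodologists who want a ground-truthed testbed for
space-use and step-selection estimators.

## Worked example

Run the one-command demo (a seeded synthetic cohort through the whole
pipeline):

```bash
translocmove run --demo --out demo_run --seed 7 --n-animals 6 \
    --horizon-days 30 --cell-size 60
```

which prints

```
artifacts in demo_run
numeric hash: d7de5a5b93abdb68c6089698f77841f8276289afdbf60b58cd102650358f286e
phase transition translocated_upland_pine: crossing day 27 (reached=True)
                             model  k       loglik          aic  n_strata  delta_aic  equivalent
     habitat_x_status_plus_release  7 -5614.148145 11242.296291      1898   0.000000        True
                 habitat_x_release  5 -5616.368893 11242.737787      1898   0.441496        True
habitat_x_status_plus_release+diel 13 -5609.655857 11245.311714      1898   3.015424       False
                  habitat_x_status  5 -5622.970322 11255.940644      1898  13.644353       False
                           habitat  3 -5627.352313 11260.704626      1898  18.408336       False
```

Reading the output: the translocated-to-upland group's mean 95% range
area fell to the resident reference level on day 27 (its cohort was
simulated with a programmed switch at day 25; the 7-day window lags
the true switch by a few days because windows spanning the switch
still contain exploratory track). The AIC table ranks the candidate
selection models on identical choice sets — here the status + release
habitat model wins, with the release-only model statistically
equivalent (ΔAIC ≤ 2). `demo_run/` also contains the per-animal daily
metrics, group mean ± SE series, SSF strata and fitted coefficients,
the weekly nocturnal bottomland-selection series, four summary
figures, and a manifest whose `numeric_hash` is identical across
reruns with the same seed.

The same pipeline runs on file inputs:

```bash
translocmove run --gps gps.csv --metadata animals.csv \
    --landcover landcover.asc --out run1 --seed 1
```

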