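# strikerisk

Daily bird-strike collision likelihood on an airfield, estimated three
complementary ways from routinely collected wildlife-management data.

Airport wildlife teams record daily species counts by management zone,
harassment (dispersal) operations, weather, aircraft movements and the
occasional strike. Strikes are rare — single digits per species over two
years — which makes day-level risk estimation a rare-event problem. This
package implements three parallel techniques on the same per-species
day table and combines their signals, flagging a day as *elevated* if any
one technique does:

1. **Algebraic.** Calendar days are mapped to a cyclic *solar day*
   coordinate relative to a species marker date, so January and December
   are seasonally close: `s = cos(2π · daydiff(d, m)/365)`. Daily
   abundance up-weights birds near the runways:

   ```
   count_hz   = observed_hz + harassed_hz          (per zone z)
   count_hp   = Σ_{z ∈ Z_p} count_hz               (per proximity band p)
   abundance  = Σ_p count_hp / p
   ```

   The seasonal mean abundance (*expected abundance*) is a kernel mix of
   m Gaussians `a·exp(−(x−b)²/2c²)` and n sigmoid-difference "bumps"
   `a·(σ((x−b+c)/k) − σ((x−b−c)/k))`, fitted by bounded multi-start least
   squares. Collision likelihood is a single-attribute threshold rule
   (`elevated iff attribute > t_a`, boundary low) extracted from a logistic
   regression fitted after minority oversampling, with accuracy/F-score
   from stratified cross-validation.

2. **Bayesian network.** A discrete network (≤ 3 states per node) over
   season, weather, counts, zone population and traffic, with a likelihood
   label derived per day as `Σ_z location_risk(z) · observed(z) / proximity(z)`
   and discretised. CPTs are learned by smoothed counting (EM when entries
   are missing); inference is exact; model quality comes from stratified
   K-fold cross-validation (K = 2 by default) and ROC/AUC on P(High).

3. **Day typing.** K-means on standardised daily feature vectors (strike
   data excluded), screened with the Hopkins statistic and validated with
   silhouette widths and the Dunn index. Each cluster's daily collision
   probability p = strikes/days gets a percentile-bootstrap 95% CI
   (B = 10,000); a cluster whose CI does not overlap the overall CI is a
   strike-associated day type.

A synthetic-campaign generator (`strikerisk.synthetic`) emulates a 761-day
study with eleven zones and three hazard species of contrasting ecology —
a summer migrant, a resident raptor with a seasonal hunting-mode switch,
and a volatile flocking species — with strike rates calibrated to the
single-digit counts such campaigns record, so every stage is testable with
known ground truth.

## Worked example

```sh
strikerisk simulate --seed 2 --n-days 761 --out demo/data
strikerisk run --seed 2 --data-dir demo/data --out demo/report
```

The simulated campaign writes 9,238 observation rows and 33 strike records
across the three species. The run reports every stage `ok` and flags 1,005
of the 2,283 species-days elevated. `demo/report/cluster_association.csv`
mirrors the day-type association table:

```
species,cluster,days,strikes,p,ci_low,ci_high,overlap
Cattle Egret,All,761,8,0.011,0.004,0.018,
Cattle Egret,1,168,4,0.024,0.006,0.048,Y
Cattle Egret,2,593,4,0.007,0.002,0.013,Y
Nankeen Kestrel,All,761,22,0.029,0.017,0.042,
...
```

Reading the first rows: the migrant was struck on 8 of 761 days
(p = 0.011); its minority day type (cluster 1, 168 days) concentrates half
the strikes (p = 0.024), but the bootstrap intervals still overlap (`Y`),
so this campaign does not support calling cluster 1 a significantly
strike-associated day type. `cluster_validation.json` reports Hopkins
0.08–0.20 (clusterable), average silhouettes 0.29–0.53 and Dunn 0.04–0.06
for K = 2; `bn_crossvalidation.json` reports mean 2-fold accuracies of
0.968, 0.819 and 0.966 on the likelihood node; `threshold_rules.json`
holds the extracted rule per species, e.g. for the migrant *elevated iff
expected abundance > 10.0*.

Per-stage subcommands (`features`, `algebraic`, `bayes`, `cluster`) run
any one technique on an existing data directory.

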