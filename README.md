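# socialunits

Inference of social units from sparse field observations, over multiple
timescales.

Many group-living animals — the motivating system is a wild population of
vulturine guineafowl, a terrestrial bird living in a multi-level society —
organise into stable *social units* of a few tens of individuals that persist
for months, yet their day-to-day grouping is fluid: units temporarily fission
into subunits, and several units can merge into supergroups lasting days to
months.  Field data are correspondingly messy: a twice-daily census records
aggregations of identified (colour-banded) individuals, but any individual
may go unobserved for days or weeks, and the aggregation you see may be one
cohesive unit or several units passing through the same place.  Which set of
individuals counts as "the group" therefore depends on the time window over
which you aggregate the observations — and that choice propagates into every
downstream estimate of group size, stability and cohesion.

This package implements the full inference pipeline and the machinery to
compare timescale choices, for behavioural ecologists working with
census-style resighting data and (optionally) GPS telemetry:

1. **Census handling** — the standard filters (keep only cohesive 'single'
   and complete observations; drop individuals seen ≤ 2 times in a window)
   and sliding focal windows (1-month and 2-month bases sampled with a
   one-month margin on each side, or a single full-study window).
2. **Association networks** — group-by-individual matrices and the simple
   ratio index, SRI(i,j) = x / (x + y_i + y_j), the fraction of observations
   of either individual in which the two were together; edges with
   SRI < 0.5 are removed before community detection.
3. **Unit detection** — walktrap community detection (Pons–Latapy random-walk
   agglomeration, maximum-modularity cut), either directly on the observed
   network or on a bootstrapped *meta-network*: the observation rows are
   resampled with replacement 100 times, communities re-detected each time,
   and the dyadic co-membership frequencies clustered.  Communities larger
   than any single field observation of the window are recursively
   re-processed on their own members' records (oversize splitting).
4. **Dynamic membership** — per-window communities are linked across windows
   into persistent global unit identities by mutual-majority overlap, with
   merge/split/birth/death lineage events; individuals missing from a single
   window are re-added by interpolation; per-unit stability is the Jaccard
   similarity J = |members_t ∩ members_t+1| / |members_t ∪ members_t+1|.
5. **Spatial cohesion** — GPS fixes subsampled to a 5-minute grid; per unit
   and day, the mean distance over all tagged dyads at shared time bins,
   summarised per window as the mean and maximum daily distance.
6. **Approach comparison** — the full grid of window basis × bootstrap ×
   carryover (ten combinations), exported as tidy tables ready for model
   fitting in any statistics environment.

A ground-truthed **synthetic-society generator** (stable units, re-drawn
fission subsets, supergroup windows, imperfect census detection, tagged-male
GPS tracks) makes every stage testable without field data.

The clustering core is exposed as scikit-learn-style estimators
(`WalktrapCommunities`, `BootstrapCommunities` with `fit` / `labels_` /
`get_params`), so it composes with sklearn tooling; the rest of the pipeline
is plain functions over small domain dataclasses.

## Worked example

```python
import datetime as dt
import socialunits as su

params = su.SocietyParams(
    n_units=4, unit_size_mean=15,
    study_start=dt.date(2020, 9, 1), study_end=dt.date(2021, 1, 1),
    fission_rate=0.02, seed=11,
)
truth, census, gps = su.simulate_society(params)
print(f"{len(truth.individuals)} individuals, {len(census)} census records, "
      f"{len(gps)} GPS fixes")

config = su.ApproachConfig(basis="1-month", bootstrap=True, carryover=True,
                           n_boot=100, seed=11)
result = su.run_approach(census, gps, config, gps_ids=set(truth.tagged))
print(f"global units: {result.unit_count}, individuals included: "
      f"{result.individuals_included}")
for rec in result.stability:
    print(f"  {rec.global_unit} {rec.window_t} -> {rec.window_t1}: "
          f"J = {rec.jaccard:.3f}")
for c in result.cohesion:
    print(f"  {c.unit} {c.window_id}: mean daily distance "
          f"{c.mean_daily_distance:.1f} m over {c.n_days} days")
```

Output:

```
67 individuals, 597 census records, 140544 GPS fixes
global units: 4, individuals included: 61
  G000 1m-2020-10 -> 1m-2020-11: J = 1.000
  G001 1m-2020-10 -> 1m-2020-11: J = 1.000
  G002 1m-2020-10 -> 1m-2020-11: J = 1.000
  G003 1m-2020-10 -> 1m-2020-11: J = 1.000
  G000 1m-2020-10: mean daily distance 213.2 m over 31 days
  G001 1m-2020-10: mean daily distance 88.2 m over 31 days
  ...
```

The four simulated units are recovered as four global identities with
perfect month-to-month Jaccard stability.  Units whose tagged males moved as
one cluster show mean daily dyadic distances near 88 m — two birds scattered
independently around the cluster centroid with σ = 50 m sit at an expected
distance of σ√π ≈ 88.6 m — while G000's larger values reflect a fission
event that temporarily placed its tagged males in different subunits.

The same pipeline runs from the shell:

```sh
socialunits simulate --seed 11 --out-dir data/
socialunits detect --census data/census.csv --seed 11 --out-dir out/
socialunits link --membership out/membership.csv --out-dir out/
socialunits cohesion --gps data/gps.csv --membership out/membership.csv \
    --gps-ids data/tagged_ids.txt --out-dir out/
socialunits compare --census data/census.csv --gps data/gps.csv \
    --seed 11 --out-dir out/
```

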