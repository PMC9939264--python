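# Methods

This note documents the models, conventions and numerical choices behind the
package, the points where the design was genuinely open, and what the test
suite does and does not establish.

## Data model and filtering

A census record is one observed aggregation: date, AM/PM session, a cohesion
label ('single' = one cohesive set of individuals, 'multiple' = several
distinct sets that happened to be co-located), the set of identified
individuals, a count of unmarked individuals, and a completeness flag.  Only
'single' and complete records enter network construction: 'multiple' records
mix distinct units in one row, and incomplete records add noise.  Individuals
observed fewer than three times in a window are dropped (`min_obs = 3`),
because network positions estimated from one or two sightings are
unreliable.

The observation-count filter is applied over the window's **sampling
interval** — the data actually used to build that window's network — rather
than the narrower focal interval.  This was an open choice; the sampling
interval was picked because it is the unit of network estimation.

## Focal windows

Windows are defined on calendar months (matching how field campaigns report
effort), with half-open `[start, end)` intervals throughout; a record on the
end boundary belongs to the next window.  The 1-month basis yields one
window per interior month, sampled with a one-month margin on either side,
so consecutive sampling intervals overlap by exactly two months.  The
2-month basis tiles the interior months with consecutive non-overlapping
two-month blocks, again sampled with a one-month margin.  The full-study
("8-month") basis is a single window over the whole study.  Carryover
linking is undefined for a single window and is rejected for that basis.

## Association index and thresholding

The simple ratio index uses the single census observation row as the
sampling unit: SRI(i,j) = (rows containing both) / (rows containing i or j
or both).  Joint absences do not enter the denominator; dyads with a zero
denominator get weight 0 rather than missing.  Weights below 0.5 are zeroed
before community detection because the detection is far more sensitive to
edge presence than to edge weight.

The 0.5 boundary decision is exact.  Both counts are small integers, IEEE
division is correctly rounded, and one half is exactly representable, so a
ratio whose true value is 1/2 compares equal to 0.5 and is kept ("strictly
less than" is zeroed).  No rational arithmetic is needed; a dedicated test
sweeps ratios such as 2/4, 3/6 and 11/22 across the boundary.

## Community detection

Walktrap (random-walk agglomeration with the merge sequence cut at maximal
modularity) is delegated to python-igraph with the conventional walk length
of 4 steps.  Isolated individuals become singleton communities; detected
singletons are retained in partitions rather than discarded, since the
decision of what to do with them belongs to the analyst.

The test suite cross-checks the wrapper against an independent pure-numpy
implementation of the published algorithm (`tests/reference_walktrap.py`),
which recomputes the exact Ward-style community distance at every merge.
The igraph C implementation adds a self-loop of each vertex's mean incident
edge weight before the walk (reproduced in the oracle) but also uses
heap-based distance updates that are not kept exact for neighbours adjacent
to only one merge partner.  On 50 frozen random weighted graphs the two
implementations produce identical partitions on 48 and adjusted Rand
indices of 0.57 and 0.66 on the remaining two, where near-tied merge orders
diverge; all planted structures (disconnected cliques, bridged cliques)
match exactly.  The acceptance test therefore asserts exact recovery of
planted partitions, at least 45/50 identical random-graph partitions and a
mean ARI of at least 0.95.

### Bootstrap meta-network

Each of `n_boot = 100` replicates resamples the observation rows with
replacement (same count as observed), rebuilds the SRI network over the
individuals present in the resample, applies the 0.5 threshold, and runs
walktrap.  The meta-network entry for a dyad is the fraction of replicates
containing both individuals in which they shared a community; the
denominator is replicate presence, since an individual can vanish from a
resample.  Dyads never co-present get 0.  The final walktrap runs on the
meta-network's positive entries as weighted edges, **without** thresholding:
the 0.5 rule belongs to the SRI networks, and co-membership probabilities
are already a cleaned signal.

### Oversize splitting

Sparse networks tempt community detection into returning whole connected
components.  A detected community cannot plausibly exceed the largest number
of identified individuals seen together in one cohesive field observation of
the same period (M).  Any community larger than M is re-processed: the
window's records are restricted to that community's members, and the full
bootstrap + walktrap procedure re-run on them, recursively, until no
community exceeds M, a re-run fails to split (fixed point), or a depth limit
of 10 is reached (accepted with a warning).  M counts identified individuals
only, as unmarked birds cannot be assigned.  Each re-run derives a fresh
seed from (seed, window id, community label) so recursion is reproducible.
The check applies to the meta-network path only, where the extra step is
needed; the direct path is left as detected.

## Dynamic membership

The cross-window linker is a mutual-majority overlap tracker.  A community
at window t+1 continues the global identity of the community at t with
which it shares the most members, provided the overlap exceeds half of both
communities' sizes (strictly).  Ties in the largest-overlap choice break
toward the larger source community, then the lexicographically smaller
label.  An even 50/50 split is deliberately *not* a continuation: both
halves receive fresh identities and a `split` event.  Several sources each
sending a strict majority of their members into one unmatched target record
a `merge`; one source forming the strict majority of several unmatched
targets records a `split`; remaining unmatched communities open (`birth`)
or close (`death`) identities.  These conventions substitute for the
unpublished parameters of dynamic-community trackers; analyses comparing
against other linkers should expect small discrepancies from this step, and
the tracker is regression-tested against latent unit identity on simulated
societies (NMI ≥ 0.95 under 5% per-window membership churn).

Interpolation fills single-window gaps only: an individual absent from
window t but assigned to the same global unit at t−1 and t+1 is re-added at
t and flagged.  Longer gaps are treated as genuine absence.  Interpolation
never changes an existing assignment and is idempotent.  Jaccard stability
is computed after interpolation (interpolated members count as present), as
stability is a property of the carryover output.

Unit counting follows the reporting convention of the approach grid: with
carryover, units are distinct global identities over all windows; without,
each window's communities count separately.

## Spatial cohesion

GPS fixes are subsampled to one per individual per 5-minute bin, bins
aligned to the UTC epoch, keeping the earliest fix per bin and relabelling
it with the bin start.  Dyadic distances pair fixes sharing the same bin —
no interpolation between fixes — in projected planar metres.  Aggregation
order is fixed: mean over all dyad-bin distances within a day, then mean
and maximum over the daily values per window.  Communities with fewer than
two tagged members are skipped silently; communities whose dyads share no
bins are skipped with a warning.  Sex filtering (e.g. philopatric males
only, to keep dispersers from inflating distances) is the caller's
responsibility via `gps_ids`.

## Synthetic societies

The generator emulates the grouping dynamics the pipeline is built for:

- **Units**: sizes 2 + Poisson(mean − 2) around a mean of 20; latent unit
  identity is fixed for the study (no demography).
- **Fission**: per unit per day with probability `fission_rate`
  (default 0.01), a fresh random 20–50% subset of the unit departs for a
  geometric number of days (mean 7) — membership is non-repeatable across
  events.  Concurrent fissions are allowed while the main cluster keeps at
  least four members.
- **Supergroups**: within designated date windows each unit joins with
  probability 0.8 (re-drawn per window); joined units move as one cohesive
  cluster and disband back into their original units.
- **Census**: two sessions per day; each spatial cluster is detected with
  probability 0.5; ~90% of individuals are marked (identifiable), and a
  marked member present is missed with probability 0.2; unmarked members
  are counted but not identified; 2% of records are flagged incomplete.  On
  the day a fission starts, the departing subunit and the main cluster are
  co-located while moving apart — if both are detected in one session they
  are recorded as a single 'multiple' observation.
- **GPS**: the first two males of each unit are tagged; clusters follow a
  reflected random walk (15 m steps per fix) inside a square home range of
  side 2 km, with unit centres 4 km apart on a grid; each tagged bird's fix
  is the cluster centroid plus isotropic Gaussian scatter of σ = 50 m; one
  fix per 5 min during 06:00–18:00 UTC.

All randomness flows from one seed through a splittable generator
(independent streams for membership, census and GPS), so simulations are
exactly reproducible and census output is regression-tested byte for byte.

What the generator does **not** emulate: births, deaths and dispersal;
sex-differences in movement; habitat structure and home-range drift;
battery-dependent GPS duty cycles; observer effort varying in space or
time; misidentification.  Tests passing on synthetic data therefore show
the pipeline's correctness and its robustness to detection noise, missed
identifications and fission–fusion dynamics — not robustness to demographic
turnover or identification error.

Where rates had no published value (fission and supergroup frequencies,
detection probabilities), defaults were chosen once as field-plausible
values that exercise every code path, and are not tuned thereafter.

## Problem sizes

The simulated acceptance study uses 8 units × ~20 individuals over 6–8
months with 100 bootstrap replicates per window — large enough that a unit's
retained members are estimated from dozens of sightings, and sizes the full
suite and the acceptance script run in a few minutes on one CPU.  Under
those conditions the pipeline recovers latent units with per-window ARI
≥ 0.9 (typically 1.0) and restores ≥ 90% of planted single-window absences.

## Known limitations

- The linker's mutual-majority rule is one of several defensible
  conventions; counts of carryover units on real data are sensitive to it.
- The oversize check bounds community size by the largest single
  observation, which is itself an estimate; with very low detection the
  bound can be too tight and trigger unnecessary splits.
- Meta-network probabilities are treated as edge weights without
  uncertainty; no significance testing of modularity is attempted.
- Cohesion summaries require simultaneous (same-bin) fixes; tags whose duty
  cycles never align contribute nothing.
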