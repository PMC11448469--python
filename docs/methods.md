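# Methods

This note records the modeling choices behind `ctgrisk`: what each stage
assumes, the parameters that matter, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Coordinates and epochs

All times are seconds *before delivery*; delivery is 0 and larger values
are earlier. Every interval — events, uninterpretable segments, epochs —
is half-open `[start, end)` with `start > end`, so adjacent intervals
share a boundary without overlapping. Epoch *k* spans
`[(k+1)·1200, k·1200)`: epoch 0 ends at delivery and indices grow
backwards in time. Analyses are anchored at delivery because the clinical
question is how far ahead of birth risk becomes visible; records are
capped at 12 h (43,200 s).

A complete epoch is *valid* when at least 80% of its span is
interpretable. Validity is computed on continuous time (the fraction of
the window not covered by uninterpretable segments); for densely sampled
signals this is equivalent to counting samples. Invalid epochs are kept on
the grid as placeholders rather than dropped, because the decision rule
needs to know which grid slots are missing. A trailing partial epoch at
the record start is discarded.

## Event features

Eleven features per valid epoch:

- **Six ordered FHR transition counts** — BAS→ACC, ACC→BAS, BAS→DEC,
  DEC→BAS, ACC→DEC, DEC→ACC. A transition is a chronologically
  consecutive pair of FHR events with *different* labels whose inter-event
  gap is at most `gap_tolerance` (default 60 s, configurable). Event
  detectors leave unlabeled spans and noise removal cuts events apart, so
  some adjacency rule is unavoidable; 60 s admits detector-scale gaps
  while refusing to bridge long uninterpretable stretches. Pairs with
  equal labels (possible across a gap) are never counted — the semi-Markov
  state must change. A transition is assigned to the epoch containing the
  *later* event's start instant; boundary instants belong to the
  closer-to-delivery epoch, consistent with the half-open convention.
- **Five dwell totals** — the summed intersection, in seconds, of each
  label's intervals (BAS, ACC, DEC on FHR; CON, RIN on UP) with the epoch
  window. Totals, not means: an epoch half-spent in deceleration reads 600
  regardless of how many deceleration events produced it.

Conservation holds by construction: a label's dwell summed over epochs
equals its total event mass within the epoched span, and shifting a record
by a whole epoch shifts features by one index with unchanged values (both
property-tested).

## Classifier

A random forest over the 11-dimensional epoch vectors, healthy vs
pathological (acidosis ∪ HIE), with **per-tree balanced bootstraps**: each
tree draws *m* epochs with replacement from each class, *m* = minority
class size. With pathological prevalence near 8% of epochs, an ordinary
bootstrap would let trees ignore the minority class entirely; balancing
per tree preserves the ensemble's variance-reduction while equalizing
class influence. Tree induction is standard CART
(`sklearn.tree.DecisionTreeClassifier`); defaults are 2,500 trees at full
scale, unlimited depth, `max_features = 3` (⌊√11⌋). Depth and
features-per-split are exposed in `ForestConfig` but untuned — out-of-bag
performance at the defaults drives all downstream selection.

pHIE for a new epoch is the fraction of all trees voting pathological. On
the training set, the **out-of-bag** variant uses only trees whose
bootstrap excluded the epoch; epochs present in every bag (possible only
for tiny forests) have undefined OOB probability and propagate downstream
as missing rather than being imputed. The bootstrap is at epoch level;
the train/test split is strictly at subject level, so no held-out subject
leaks into training.

## Decision rule

Policy = (n, p<sub>t</sub>). An epoch alerts iff pHIE > p<sub>t</sub>
(strict: pHIE equal to the threshold does not alert). Processing
chronologically, at each epoch the window of the last *n* grid slots is
examined:

- more than ⌊n/2⌋ slots missing, or all slots missing → **deferred** (the
  system does not decide until there are more observations);
- otherwise, if every observed slot alerts → **recommend**;
- otherwise → no recommendation.

Windows that would extend before monitoring onset are deferred: a
recommendation requires *n* monitored epochs, so the earliest possible
decision comes after n·20 min (100 min for n = 5). ⌊n/2⌋ is the
conservative reading of "half the window" for odd *n* (n = 5 tolerates 2
missing). Deferral never resets the run — the window test is simply
re-applied one epoch later. Recommendations latch by default, making
subject-level detection curves cumulative; an unlatched mode exists for
exploration.

**Selection.** For each n in 1–10 a subject-level ROC is built from
training OOB streams: a subject counts as recommended at threshold
p<sub>t</sub> iff the rule fires by end of record. Internally this uses an
exact reduction — the subject's score is the maximum over admissible
windows of the minimum observed pHIE in the window, and the rule fires iff
that score exceeds p<sub>t</sub> — which makes the ROC a standard score
ROC; equivalence with the literal state machine is oracle-tested. The
threshold grid is every distinct OOB pHIE value plus {0, 1} (exact ROC, no
binning); AUC is the trapezoidal area with (0,0) and (1,1) appended. n̂
maximizes AUC with ties broken toward smaller n (earlier decisions);
p̂<sub>t</sub> is the *smallest* grid threshold whose training FPR is at
or below the target — the most sensitive operating point inside the
false-alarm budget. The default target is the healthy group's observed
Caesarean rate on the full cohort. If no threshold satisfies the bound,
p̂<sub>t</sub> = 1.0 with a warning (pHIE can never strictly exceed 1).

The ROC is built at subject level (post-aggregation) because the object
being selected is the recommendation system, not the epoch classifier; an
epoch-level ROC can be had by running `roc_for_n` with n = 1 on epoch
streams directly.

## Evaluation protocol

Stratified 90/10 subject splits (per-group test counts round-half-up,
minimum one), repeated from a root seed; 100 iterations at full scale,
fewer for desk work. Each iteration freezes (n̂, p̂<sub>t</sub>) from
training OOB data only, then applies the policy to held-out subjects.
Reported surfaces: cumulative recommendation-rate curves per group
(denominator: all test subjects of the group; deferred-at-end subjects
count as not recommended), AUC vs n, and median OOB pHIE trajectories per
group and epoch (pooled across subjects).

Medians come with distribution-free order-statistic 95% CIs (binomial
ranks at p = 1/2; needs ≥ 8 values). Recommendation rates are compared to
the group's observed Caesarean rate by a two-sided one-sample Wilcoxon
signed-rank test across iterations — a paired nonparametric choice
consistent with the median-based reporting; it is this package's choice,
not a claim about how the emulated study computed its p-values. Reporting
epochs are labeled by both start and end time (the epoch with index 9
starts 3 h 20 min and ends 3 h before delivery) to avoid ambiguity.

## Synthetic cohorts

Each channel is an independent semi-Markov process generated
chronologically from record start toward delivery: alternate log-normal
dwell draws and zero-diagonal transition draws. The drift applied to an
interval uses the time-to-delivery of its *start*, keeping the dynamics
causal. Log-normal dwells: positive support and the heavy right tail
typical of event durations.

Defaults (all configurable): dwell medians BAS 240 s, ACC 40 s, DEC 50 s,
CON 70 s, RIN 120 s with log-sds 0.6/0.4/0.4/0.3/0.5 — active-labor
scales, contractions every ~3 min lasting ~70 s; UP alternates CON↔RIN
deterministically; FHR returns to baseline with probability 0.9 after an
acceleration or deceleration. Record durations are uniform on 4–12 h.
Uninterpretable segments arrive as a Poisson process (1/h, exponential
mean 120 s); FHR events overlapping them are split at segment boundaries
and fragments under 5 s are dropped; UP events are untouched (the noise
model represents FHR signal loss).

Pathology enters through two linear-in-time drifts inside a 4-h horizon:
the BAS→DEC entry probability rises (healthy 0.30→0.45, acidosis
0.40→0.65, HIE 0.45→0.80 at delivery) and the DEC dwell mean is multiplied
by up to 1.2/1.5/1.8. Decelerations are the expected signature of
progressive intrapartum hypoxia, so risk separability grows toward
delivery, strongest for HIE — which is what the classifier is supposed to
exploit. The healthy group also drifts mildly: labor is stressful for
every fetus, and all groups' epoch probabilities should rise near
delivery. Group prevalences (91.6/7.5/0.9%) and Caesarean rates
(38.9/37.6/54.9%) match the emulated study population. Cohorts use
largest-remainder rounding for group counts and one spawned RNG substream
per record, so generation is reproducible and order-independent.

**What the simulator does not emulate:** coupling between contractions
and decelerations (channels are independent given the group; coupled
generation is an extension point), clinical covariates, detector-specific
artifact structure, and the real cohort's feature distributions. Passing
tests therefore demonstrate that the pipeline recovers planted
semi-Markov risk structure under realistic prevalence, noise and
missingness — not clinical performance. In particular the synthetic
signal is cleaner than real CTG: single epochs are individually
informative, so the selected n̂ is often 1–3 rather than the longer runs
a noisier clinical signal favors, and recommendation rates for the
pathological groups run higher than any clinical system would.

## Problem sizes and numerical conventions

Desk-scale defaults used by the test suite and the acceptance script:
2,000-subject cohorts, 10 iterations, 300 trees (the trajectory check uses
one 5,000-subject training pass, since per-epoch medians of a 0.9%-
prevalence group need the mass). Full-scale settings (2,500 trees, 100
iterations) are plain configuration.

Numerical conventions: transition rows must sum to 1 within 1e-9 with zero
diagonal; dwell conservation is asserted to 1e-6 s; event files store
floats at 17 significant digits and are re-parsed with round-trip
precision, so write∘read is field-exact; CIs require n ≥ 8; all
randomness flows from explicit `numpy` generators or spawned seed
sequences — same seed, same output, across all stages.

## Known limitations

- Balanced bootstrap accepts subject leakage *within* the training set
  across trees (epoch-level bagging); the subject-level train/test split
  contains it.
- OOB probabilities of different epochs use different numbers of trees;
  at 300 trees the vote-fraction granularity is visible in the threshold
  grid. This is inherent to OOB estimation, not a defect.
- The Wilcoxon comparison treats iterations as exchangeable paired
  replicates; iterations share 80% of training subjects, so its p-values
  are optimistic at small cohort sizes.
- The simulator's drift is linear and deterministic per group; real
  hypoxic trajectories are heterogeneous in onset and slope.
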