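# Methods

## Measurement model

Three accelerometer monitors record simultaneously on a common clock and
are exported as 15 s epochs. The thigh-worn monitor is treated as the gold
standard for activity: per epoch it yields a step count, walking time and
upright time, with standing time defined as upright minus walking time. A
thigh placement supports posture classification; the monitors strapped to
the removable cast walker (RCW) and to the contralateral shoe-lift do not,
so their processed posture output cannot be trusted directly. What *is*
informative from a device-mounted monitor is motion energy: the per-axis
sample-to-sample variation within the epoch, summarized as the mean across
axes, `V_avg = (X + Y + Z)/3`. The variation values are treated as opaque
non-negative per-epoch inputs from the vendor processing; their exact
internal definition is not relied on.

The classification model assumes three regimes for a device in an epoch
where the thigh indicates standing or walking:

* stationary (not in use): `V_avg = 0`, up to rare handling artifacts;
* worn during standing: `V_avg` in a low band;
* worn during walking: `V_avg` in a high band, because a device on a
  moving limb shakes much harder.

A threshold pair `0 ≤ th_min < th_max` separates the regimes: standing use
when `th_min < V_avg < th_max`, walking use when `V_avg > th_max`, with
strict inequalities (a value equal to a threshold is classified into
neither band). An epoch that mixes walking and standing evaluates both
criteria independently; since the two bands are disjoint, at most one can
hold. Attribution is all-or-nothing per epoch: a walking-use epoch
contributes all of its thigh steps (step counts, not walking seconds, are
the quantity of interest because cumulative plantar stress scales with
steps), and a standing-use epoch contributes all of its thigh standing
seconds.

## Threshold calibration

Calibration uses the in-lab sessions of `n_training = 5` randomly selected
subjects (seeded, reproducible). For each training subject the minimum and
maximum `V_avg` observed in the device monitors during thigh-defined
standing and thigh-defined walking (device-on epochs only) bracket the two
bands. Across subjects these extremes seed initial thresholds: `th_min⁰` is
the smallest standing-band value; `th_max⁰` is the midpoint between the
largest standing-band and the smallest walking-band value, falling back to
the largest standing-band value when the observed bands overlap.

Both thresholds are then varied over an exhaustive grid (default 101 × 101;
`th_min` over `[0, min standing V_avg]`, `th_max` over the observed
standing/walking gap, widened ±10% when degenerate). The objective is

```
J = (accuracy_steps,on + accuracy_standing,on)/2
  − (false_attribution_steps,off + false_attribution_standing,off)/2
```

in percent, i.e. balanced device-on accuracy minus balanced device-off
false attribution. On cleanly separable data the optimum is a plateau; ties
are broken first by lowest combined false attribution, then by the grid
point nearest the centroid of the tying set, which returns the plateau
midpoint — the widest-margin choice. By default one threshold pair is fit
on pooled RCW + lift training epochs and applied to both devices (the two
devices' variance signatures are indistinguishable in practice and a shared
pair is what the validated method used); a per-device mode is available
behind a flag.

## Validation metrics

**Accuracy** (per subject × device, device-on condition): the percentage of
thigh-derived steps, and of thigh-derived standing seconds, that the
algorithm attributes to the device. Undefined components (zero denominator)
are reported as not-applicable rather than 0 or 100.

**Error**: the amount of activity attributed to the device during (i)
device-off epochs, plus (ii) device-on epochs in which the thigh shows none
of that activity yet the device-use criterion holds — in that case the
device monitor's own vendor-reported amount (VANE steps, VANE upright −
walking time) is the only available quantity — expressed relative to total
thigh-derived activity over all condition-labeled epochs.

**Condition labels** come from the investigator log: each condition's span
runs from its first logged activity's start to its last logged activity's
end, so unlogged standing pauses between activities inherit the
surrounding condition; epochs in neither span (device donning) are
unlabeled and excluded from condition-restricted metrics.

**Agreement**: ICC from a two-way random-effects ANOVA, single measures,
absolute agreement — ICC(2,1) = `(MS_R − MS_E) / (MS_R + (k−1)MS_E +
(k/n)(MS_C − MS_E))` with k = 2 methods — with significance from
F = MS_R/MS_E on (n−1, (n−1)(k−1)) df. ICC > 0.9 is read as excellent,
0.75–0.9 good, 0.5–0.75 moderate, below poor. The single-measures
absolute-agreement form is the right one for comparing two measurement
methods' absolute values; average-measures is available behind a flag.
Bland-Altman statistics use differences oriented diary − algorithm
(DA − AA) and limits of agreement `bias ± 1.96 × SD` (sample SD, ddof = 1).

**Outlier QC**: subjects whose error exceeds the across-subject
mean + 2 SD (population SD, one-sided, single pass) are excluded. In the
laboratory analysis the QC statistic is the subject's mean error over the
four metric × device combinations. In the 24-h analysis the statistic is
the absolute algorithm-vs-diary discrepancy |DA − AA| per metric × device
series (union of exclusions): a diary that disagrees with the monitors by
more than 2 SD is not a trustworthy self-report. Note a boundary artifact
of the rule: with four equal values and a single outlier, mean + 2 SD
equals the outlier exactly, so the strict inequality keeps it.

**Diary-derived adherence**: diary don/doff intervals are merged, clipped
to the monitoring horizon and intersected with the thigh epoch grid. Steps
are indivisible counts, so an epoch's steps count toward SC_DA iff at least
half the epoch overlaps a donned interval; standing seconds are divisible
and prorate by the exact overlap fraction. This avoids systematic over- or
under-counting at don/doff boundaries.

## Synthetic studies

The generator produces complete studies — monitor CSVs, investigator logs,
diaries and exact ground truth — as pure functions of (config, seed).

*In-lab session*: a scripted block (three walking speeds ~90 s each,
1 min sitting, two bend repetitions, 1 min lying, with 15–45 s unlogged
standing pauses whose lengths vary by subject) performed once with devices
doffed and once worn, separated by a 1-min donning gap. Walking cadence is
~27 steps/epoch habitual (33 fast, 20 slow) with per-subject and per-epoch
variation.

*Community day*: 5760 epochs (24 h); 16 h awake with bout-structured
activity (walk/stand/sit/lie; per-subject activity level lognormal,
σ = 0.5, clipped to a plausible healthy-adult range of roughly 2–18 k
steps/day) followed by 8 h lying. Subjects alternate wear configurations
(RCW only, lift only, both) in 15–40 min segments covering the awake
period; the diary is the true wear intervals with Gaussian timing jitter
(default SD 300 s) and per-interval omission (default probability 0.05).

*Device variance*: truncated lognormal bands per (wear state, activity) —
standing-worn support (0.05, 0.9), walking-worn (1.5, 6.0), worn-sedentary
(0.001, 0.3), doffed exactly 0. Truncation makes the standing and walking
bands strictly separable, which is what the laboratory validation of the
threshold method implies about real devices; an overlap mode exists for
stress-testing calibration. Doffed devices spike with small probability
(default 0.01 per epoch; 0.8 for designated high-noise subjects emulating
repeated investigator handling, and 0.5 in the donning gap). A handled
device moves like a worn one, so spike magnitudes are drawn from the
standing-band law with probability 0.7 and the walking-band law otherwise —
spikes therefore produce both standing and step false attributions but
never fall inside the separating gap itself. Synthetic vendor (VANE)
output on the device monitors is a noisy transform of truth (median ~75%
step recovery with heavy spread, ~90% upright-time recovery, occasional
phantom upright time while sedentary), used by the error metric's
component (ii) and the baseline comparison.

What the generator does **not** emulate: raw waveforms, gait pathology
(neuropathic steadiness differences), posture misclassification by the
thigh monitor itself, multi-day wear, device repositioning drift, or
diaries biased by social desirability. Passing tests therefore demonstrate
the algorithm's correctness and the pipeline's statistical behavior under
the stated measurement model, not robustness to thigh-reference failure or
to variance bands that overlap in reality.

## Numerical and design choices

* Problem sizes: validation runs use 30 subjects (3 high-noise), ~86 lab
  epochs/subject, 5760 community epochs/subject; property tests use
  smaller cohorts (4–6 subjects) and coarser grids (21–41 points), which
  exercise the same code paths.
* Strict threshold inequalities throughout; `V_avg = 0` is always non-use.
* Missing device epochs are excluded from classification and reported as
  coverage, never imputed.
* Grid search is separable in the two thresholds and fully vectorized;
  the tie-break (lowest false attribution, then plateau centroid) makes
  the returned pair deterministic and order-invariant.
* ICC is computed from explicit ANOVA mean squares; identical inputs give
  ICC = 1 (0/0 resolved by the limit), zero total variance returns
  not-applicable with a flag rather than a number.
* All randomness flows through `numpy.random.Generator` seeded per
  (config seed, subject index, stream), so any subject can be regenerated
  independently and identically.

## Known limitations

* The error metric's component (ii) depends on vendor-reported amounts,
  which are themselves inaccurate on device-mounted monitors; it is a
  conservative stand-in for a quantity the measurement design cannot
  observe directly (activity the thigh did not register).
* Calibration optimizes on training subjects only; device-off artifacts in
  a training subject's data can shift a threshold toward the edge of the
  plateau. With band-shaped spikes this shift is bounded by training-set
  order statistics and was not observed to affect held-out accuracy.
* The mean + 2 SD exclusion rule is self-limiting: when many subjects are
  noisy the cutoff inflates and mild outliers survive. This mirrors the
  rule as specified, not a defect of the implementation.
* Agreement between algorithm and diary depends on the assumed diary noise
  and wear-pattern granularity; with fewer, longer wear intervals a single
  forgotten interval removes a large share of a subject's diary-derived
  adherence and agreement degrades accordingly.
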