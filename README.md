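# offload-adherence

Objective monitoring of adherence to offloading interventions — a removable
cast walker (RCW) and a contralateral shoe-lift — from synchronized
accelerometer monitors, for researchers and clinicians studying diabetic
foot ulcer (DFU) offloading behavior.

Healing a plantar ulcer requires keeping mechanical load off the foot, but
patients can doff a removable walker at will, and self-reported wear time
is unreliable. This package implements an epoch-level classification
algorithm that combines a thigh-worn monitor (the reference for *what* the
wearer did) with monitors mounted on the RCW and on the shoe-lift (evidence
of *whether each device moved*), producing objective adherent step counts
and adherent standing time, together with the full validation stack used to
establish the method: threshold calibration, accuracy and misclassification
error against investigator logs, intraclass correlation against thigh
truth, and agreement with wear diaries over a free-living day.

## The algorithm

All monitor outputs are binned into 15 s epochs on a shared clock. The
thigh monitor provides steps, walking time and upright time per epoch;
standing time is `upright − walking`. Each device monitor provides per-axis
sample-to-sample variation, summarized as

```
V_avg = (X + Y + Z) / 3
```

`V_avg = 0` means the device sat still (non-use); worn devices show a low
variance band during standing and a high band during walking. Given a
calibrated threshold pair `th_min < th_max`, for every epoch of
thigh-defined standing or walking:

* **standing use** if `th_min < V_avg < th_max` → the epoch's standing
  seconds count toward adherent standing time (ST_AA);
* **walking use** if `V_avg > th_max` → *all* thigh steps of the epoch
  count toward the adherent step count (SC_AA).

Thresholds are calibrated on a few randomly chosen training subjects: the
extremes of `V_avg` during thigh-defined standing/walking seed initial
estimates, then an exhaustive grid search maximizes device-on accuracy
while penalizing device-off false attribution. Validation metrics include
accuracy (% of device-on thigh activity attributed), a two-component
misclassification error, ICC(2,1) (two-way random effects, absolute
agreement) and Bland-Altman bias/limits of agreement between
algorithm-derived (AA) and diary-derived (DA) adherence. Outlying subjects
are excluded by a one-pass mean + 2 SD rule.

Because no raw study data are deposited, the package ships a first-class
synthetic-data generator (`offload_adherence.synth`) that emulates both
study phases — the scripted in-lab protocol with investigator logs, and a
24-h community day with noisy don/doff diaries — with exact ground truth,
so the whole pipeline is testable end to end.

## Worked example

`examples/03_classify_and_score.py` runs the laboratory validation on a
simulated 30-subject cohort (three of them with noisy device-off data from
investigator handling of the doffed devices):

```
thresholds: th_min=0.0704, th_max=1.2667
excluded by mean+2SD error QC: ['S28', 'S29', 'S30'] -> n=27

device acc steps% acc stand% err steps% err stand% VANE steps%
rcw        100.00     100.00       0.18       0.23        90.5
lift       100.00     100.00       0.19       0.38        85.0

ICC between thigh-measured and algorithm-attributed device-on totals:
  rcw   steps     ICC = 1.0000 (excellent), p = 0
  ...
```

The calibrated thresholds sit inside the gap between the standing and
walking variance bands, so during device-on every thigh step and standing
second is attributed to the device (accuracy 100%), while the handful of
handling spikes in doffed periods produce well under 1% error for the
retained subjects; the three planted high-noise subjects are exactly the
ones the mean + 2 SD rule removes. `examples/04_community_agreement.py`
continues into the 24-h phase, where with realistic diary noise (5-min
timing jitter, 5% forgotten intervals) algorithm- and diary-derived
adherence still agree at ICC ≥ 0.98 with a small negative diary bias (the
diary misses wear the algorithm sees).

A command-line interface wraps the same pipelines:

```
adhere simulate --n 30 --seed 7 --mode community --out study/
adhere calibrate --n 30 --seed 7 --out calibration.json
adhere run-study --n 30 --seed 7 --out report/
```

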