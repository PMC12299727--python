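# gaitwin

Temporal gait parameters from a single, loosely carried IMU — and an
honest account of how well they agree with an optical-marker reference.

Clinically useful gait monitoring outside the lab means extracting
stride time, stance time, swing time and double-support time from a
smartphone-sized inertial sensor that is *not* strapped to the body: it
sits in a hand, a trouser pocket or a jacket pocket, at three walking
speeds. `gaitwin` implements that pipeline end to end and validates it on
synthetic cohorts with exact ground truth, for researchers in wearable
sensing and gait biomechanics who want a fully reproducible, testable
reference implementation of each stage:

1. **Synthetic cohort simulation** — a subject × speed × placement
   factorial of trials, each with a six-channel IMU record (±16 g
   accelerometer, ±2000 °/s gyroscope, 1259 Hz), bilateral vertical
   calcaneus/metatarsal marker trajectories (100 Hz) and the exact event
   schedule that generated both.
2. **Marker-based reference events (M1)** — heel strike as the minimum of
   the calcaneus track in the first 30% of each foot-motion-peak
   interval; toe-off as the minimum of the metatarsal track between 40%
   and 80% of the same interval.
3. **IMU event detection (M2)** — resample to 100 Hz, zero-phase
   4th-order Butterworth low-pass at 10 Hz, per-channel robust scaling,
   200 ms windows every 100 ms, positives only when an event lies in the
   central 45–55% of the window; one conv+LSTM classifier per event
   stream (HS/TO × left/right, NumPy implementation, subject-wise 80/20
   split), then reconstruction of continuous event times from window
   probabilities.
4. **Cycle parameters and quality filter** — per cycle,
   stance = HS→ipsilateral TO, swing = TO→next HS (so
   stance + swing = stride identically), double support = interval
   intersection of the two sides' stance phases; cycles with negative
   durations, condition transitions or implausible strides are excluded
   and tallied.
5. **Agreement battery** —
   rRMSE = 100·√(mean((M2−M1)²))/mean(M1) per subject-condition,
   summarized by median/IQR and a bootstrap 95% CI of the mean; Pearson r
   on condition means with weak (r<0.3) / moderate (0.3≤r<0.6) / strong
   (r≥0.6) tiers; Bland–Altman bias and 95% limits of agreement
   (bias ± 1.96·SD of M1−M2).

See `docs/methods.md` for the model details, parameter defaults and
design rationale.

## Worked example

```python
from gaitwin.experiment import ExperimentConfig, run_experiment
from gaitwin.simulate import SimulationConfig

cfg = ExperimentConfig(
    simulation=SimulationConfig(n_subjects=5, speeds=(1.0, 1.5),
                                placements=("hand", "jacket"),
                                trial_duration=60.0),
    n_boot=500,
    seed=11,
)
run = run_experiment(cfg)
print(run.results.summary())
```

```
Agreement analysis (experimental M1 vs predicted M2)
========================================================

Relative RMSE (%) by parameter (pooled):
  stride          median   1.09
  stance          median   2.13
  swing           median   2.81
  double_support  median 125.23

Pearson association (condition-level means, pooled):
  stride          r=+1.000 (strong)**  n=4
  stance          r=+1.000 (strong)**  n=4
  swing           r=+1.000 (strong)**  n=4
  double_support  r=-0.226 (weak)  n=4

Bland-Altman (s):
  stride          hand     bias=-0.0000 LoA=[-0.0000, +0.0000] 100.0% within
  stride          jacket   bias=+0.0001 LoA=[-0.0003, +0.0005] 100.0% within
  stance          hand     bias=+0.0048 LoA=[-0.0030, +0.0126] 100.0% within
  stance          jacket   bias=+0.0045 LoA=[-0.0001, +0.0090] 100.0% within
  swing           hand     bias=-0.0048 LoA=[-0.0126, +0.0030] 100.0% within
  swing           jacket   bias=-0.0044 LoA=[-0.0093, +0.0006] 100.0% within
  double_support  hand     bias=+0.0088 LoA=[-0.0068, +0.0245] 100.0% within
  double_support  jacket   bias=-0.2366 LoA=[-0.3771, -0.0962] 100.0% within
```

Reading this: stride time — a long interval bounded by a single event
type — is recovered almost perfectly (rRMSE ≈ 1%, r = 1.0, negligible
bias). Double support, a 0.1–0.2 s interval assembled from four event
streams, is hypersensitive to individual event errors: its relative error
explodes (here driven by the jacket condition of the single held-out
subject, bias −0.24 s), and its inter-subject association collapses to
weak. That ordering — long single-event parameters accurate, short
multi-event parameters fragile, jacket placement worst — is the central
error mechanism this package quantifies.

The `ExperimentRun` also exposes every intermediate (manifest, both cycle
sets, paired cycles, per-condition rRMSE values) and
`run.results.plot_bland_altman("stride")` draws the per-placement
agreement panels.

## Command line

```bash
gaitwin simulate --out cohort/ --seed 7          # write per-trial CSVs
gaitwin run-all  --out results/ --seed 7         # full pipeline + tables
gaitwin truth    --cohort cohort/ --trial S00_v1.25_hand --out events/
```

Configs are JSON files with the `gaitwin.validate_config` schema; every
tabular artifact is plain CSV (`table1_rrmse.csv`, `table2_pearson.csv`,
`bland_altman.csv`, `cycles_m*.csv`, `paired_cycles.csv`).

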