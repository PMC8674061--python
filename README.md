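# eoghci

Electrooculogram (EOG) eye-movement classification for multi-state
human-computer interfaces.

People with severe motor impairment but intact eye-muscle control can
drive an interface with deliberate eye movements: the corneo-retinal
standing potential makes each gaze shift appear as a step deflection on
periocular electrodes. This package implements a complete classification
pipeline for an eleven-task protocol — six directional gaze shifts,
rapid and lateral compound movements (the eight "event" commands), and
the non-events open, close, stare — recorded as two-channel (horizontal
+ vertical) 100-sample trials at 100 Hz, with ten trials per task, i.e.
110 labeled trials per subject.

The stages:

1. **Synthetic trial generation** (`eoghci.synthetic`) — seeded,
   template-based two-channel EOG trials with Gaussian noise and
   optional 50 Hz mains contamination.
2. **Preprocessing** (`eoghci.preprocess`) — 50 Hz notch filter and a
   zero-phase Butterworth filter bank splitting 0.1–16 Hz into eight
   2-Hz bands.
3. **Feature extraction** (`eoghci.features`) — per band *b* and
   channel *j* the convolution-theorem statistic

   ```
   f(X_b^j) = Re Σ_k  F(X_b^j)[k] · F(R_b^j)[k],   R_b^j = time reversal of X_b^j
            = N · Σ_n  x[n] x[(n+1) mod N]
   ```

   (the summed pointwise spectral product of a band signal with its
   reversal, equal to N times the circular lag-1 autocorrelation),
   giving 2 channels × 8 bands = 16 features per trial, min-max
   normalized to [0, 1] on the training split.
4. **Classification** (`eoghci.networks`) — from-scratch 16-8-4 Elman
   recurrent network (gradient-descent backpropagation, initial rate
   .001) and distributed time-delay network (Levenberg–Marquardt, tap
   delays 0–2 on input and hidden layers); iteration cap 1000, error
   goal 0.001, 75%/25% stratified split, 4-bit binary class codes.
5. **Evaluation** (`eoghci.evaluation`) — per-task single-trial
   accuracies, event/nonevent sensitivity–specificity–accuracy

   ```
   Sens = TP/(TP+FN),  Spec = TN/(TN+FP),  Acc = (TP+TN)/(TP+TN+FP+FN)
   ```

   and the Wolpaw-style bit transfer rate for n selectable commands,
   action period T_act and mean accuracy p_a:

   ```
   BTR = (60/T_act) [ log2 n + p_a log2 p_a + (1−p_a) log2((1−p_a)/(n−1)) ]  bits/min
   ```

## Worked example

```sh
eoghci simulate --seed 42 --out runs          # writes runs/trials.csv (110 trials)
eoghci extract runs/trials.csv --seed 42 --out runs
eoghci train-eval runs/features.csv --seed 42 --out runs
```

or equivalently in Python:

```python
from eoghci.pipeline import RunConfig, cmd_simulate, cmd_extract, cmd_train_eval

cfg = RunConfig(n_subjects=1, n_repeats=5, seed=42)
trials = cmd_simulate(cfg, "runs")
features = cmd_extract(trials, cfg, "runs")
reports = cmd_train_eval(features, cfg, "runs")
```

This trains both networks five times on fresh 75/25 splits of one
synthetic subject and prints/writes per-subject reports. With seed 42:

```
ernn  max=95.45 min=93.64 mean=94.36 std=0.76 btr=88.78 sens=0.951 spec=0.929
dtdnn max=87.27 min=75.45 mean=80.73 std=4.70 btr=63.36 sens=0.970 spec=0.636
```

Accuracies are percentages over all 110 trials per run (the table
convention also used for max/min/mean/std); `btr` is the bit transfer
rate in bits/min computed from the mean accuracy with n = 11 and
T_act = 2 s; sensitivity/specificity come from the event/nonevent
confusion counts. `runs/table_btr_ernn.csv`:

```
subject,max,min,mean,btr
S1,95.4545,93.6364,94.3636,88.7807
```

The held-out-only accuracy is reported alongside in
`runs/reports.json` (`extra.mean_test_accuracy`, here 92.73 for the
Elman network).

`eoghci reproduce-btr-tables` recomputes the BTR column of the packaged
per-subject reference accuracy tables (20 subjects × 2 architectures)
from their printed mean accuracies.

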