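# emgrasp

Decoding **upcoming grasp gestures from dynamic surface EMG** during
reach-to-grasp movements.

Most myoelectric gesture decoders are trained and evaluated on static,
steady-state contractions. In real use, the hand pre-shapes while the arm is
still moving: the EMG is transient, phase durations vary trial to trial, and
the interesting question is *how early* the upcoming grasp can be read out.
`emgrasp` implements a complete framework for studying that question:

1. **Synthetic sessions** faithful to a reach-to-grasp collection protocol —
   13 grasp gestures (plus open-palm rest, 14 classes `l ∈ {0,…,13}`),
   4 objects per gesture, 6 four-second trials per object, C = 12 muscles at
   f = 1562.5 Hz, plus per-muscle 3-s maximum-voluntary-contraction (MVC)
   bursts — with full ground truth (phase breakpoints, labels, seeds).
2. **Preprocessing** — 4th-order 40–500 Hz Butterworth band-pass, linear
   envelopes (rectify + 6 Hz low-pass), per-muscle MVC normalization.
3. **Unsupervised phase segmentation** by greedy Gaussian segmentation
   (GGS): each trial is split into reaching / grasping / returning / resting
   by K = 3 breakpoints maximizing a regularized Gaussian log-likelihood

       score(i, j) = −(n/2)·log det(Σ̂ + λ·(tr Σ̂ / d)·I),

   fitted by greedy insertion with re-adjustment sweeps; an exact
   dynamic-programming oracle verifies the greedy fit on small instances.
4. **Windowed features** — T = 320 ms windows, 40 ms step; per-channel RMS,
   MAV and VAR concatenated into Z ∈ R^{3C}.
5. **Gesture decoding** — a 50-tree extra-trees classifier under three
   training strategies: S1 (reaching + resting), S2 (grasping + resting),
   S3 (reaching + grasping + resting); returning never trains. Per-object
   4/2 trial split, 3 folds, every trial validated once.
6. **Real-time-style evaluation** — validation trials aligned at grasp onset
   (0 ms), 700 ms of preceding rest prepended, probability and accuracy
   curves averaged across trials, and two scalar summaries: **t_i**, the
   time where the grasp-gesture probability overtakes the rest probability
   (negative = before the grasp), and **d_p**, the margin between the
   grasp-probability peak and the strongest competing gesture. A 14×14
   confusion matrix summarizes the pre-shaping window [t_i, 0].

Intended users: researchers in myoelectric control / neural engineering who
want a reproducible, fully synthetic testbed for dynamic-EMG intent decoding
and for change-point segmentation of multichannel envelopes.

## Worked example

```python
from pathlib import Path
import emgrasp as eg

cfg = eg.RunConfig(
    synth=eg.SyntheticProtocolConfig(
        n_gestures=13, objects_per_gesture=2, trials_per_object=6, seed=31
    ),
    folds=(0,),
)
summary = eg.run_pipeline(cfg, Path("run31"))
for name, m in summary["strategies"].items():
    print(f"{name}: t_i = {m['t_i_ms']:.0f} ms, d_p = {m['d_p']:.3f}, "
          f"pre-shaping accuracy = {m['preshape_accuracy']:.3f}")
```

Output (a 156-trial session, one fold, ~1 minute on one CPU):

```
S1: t_i = -973 ms, d_p = 0.995, pre-shaping accuracy = 0.852
S2: t_i = -690 ms, d_p = 0.980, pre-shaping accuracy = 0.860
S3: t_i = -966 ms, d_p = 0.997, pre-shaping accuracy = 0.857
```

Reading: training only on grasping-phase data (S2) detects the upcoming
gesture 283 ms *later* than training on reaching data (S1) — the reaching
phase carries pre-shaping information — while combining phases (S3) keeps
the earliest detection *and* the largest probability margin over competing
gestures. On clean synthetic data the absolute numbers are optimistic; the
ordering is the behavior under study (see `docs/methods.md`).

The run directory contains `session.h5` (signals + ground truth),
`segmentation.json`, `features.csv`, per-strategy `curves_*.csv` /
`confusion_*.csv`, and `metrics.json` / `summary.json`.

The same pipeline is scriptable from the shell:

```bash
emgrasp run-all --config cfg.yaml --out run/ --seed 31
emgrasp report --curves run/curves_S3.csv --metrics run/metrics.json --out fig.png
```

(`simulate`, `preprocess`, `segment`, `featurize`, `evaluate` run the chain
up to that stage; reruns reuse artifacts whose configuration hash matches.)

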