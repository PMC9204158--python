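# Methods

`emgrasp` implements a complete offline replica of a real-time grasp-intent
decoding framework for dynamic surface EMG: continuous reach-to-grasp trials
are segmented without supervision into movement phases, phase-labeled windows
feed a randomized-tree gesture decoder, and performance is summarized on a
grasp-onset-aligned timeline.  This note documents the models, the defaults
and why they were chosen, and what the synthetic data can and cannot show.

## Signal model and synthetic sessions

A session follows the collection protocol of the experiment the package
models: 13 grasp gestures (labels `l = 1..13`; `l = 0` is open-palm rest),
4 objects per gesture (52 objects), 6 trials per object (312 trials), each
trial 4 s at f = 1562.5 Hz over C = 12 muscles (FDI, APB, FDM, EI, EDC, FDS,
BRD, ECR, ECU, FCU, BIC, TRI).  Every trial contains four phases in fixed
order — reaching, grasping, returning, resting — separated by three
breakpoints drawn uniformly over all placements leaving each phase at least
300 ms (order-statistics construction on the slack), emulating subjects who
pace phases freely inside the 4-s trial.

Each channel is a zero-mean Gaussian carrier band-limited to 20–450 Hz and
amplitude-modulated by a per-phase envelope:

* resting: a uniform muscle tone of 0.05 (unitless activation scale);
* grasping: a gesture-specific pattern, one amplitude per channel drawn once
  from U(0.1, 0.9) with one dominant channel per gesture set to 1.0 (fixed
  pattern seed, so sessions share gesture identities);
* reaching / returning: convex blends `rest + b·(grasp − rest)` with
  b = 0.6 and 0.5 respectively.  The reaching blend is the *pre-shaping*
  knob: it is what makes gesture information available before the grasp, and
  the evaluation's strategy ordering depends on it being strictly between 0
  and 1.

Phase boundaries are smoothed with 50 ms raised-cosine crossfades
(instantaneous envelope switches are physiologically implausible and would
make segmentation artificially easy).  An independent band-limited noise
floor (amplitude 0.02) is added throughout.  Channels are uncorrelated by
construction (diagonal covariance per phase).

MVC recordings are 3-s bursts, one per muscle, whose target channel carries
1.5x that muscle's largest task activation.  The headroom factor matters:
the envelope of a random carrier fluctuates around its mean level, and the
per-channel maximum over 312 trials of task envelope would otherwise
occasionally exceed the maximum over a single 3-s MVC envelope.  With 1.5x
headroom, normalized task envelopes stay below 1 in practice.

All randomness flows from one seed through `numpy` `SeedSequence` spawning
(one child stream per trial), so identical configurations produce
bit-identical sessions.

What the generator does **not** emulate: motor-unit physiology, fatigue,
electrode shift, cross-talk between channels, force-dependent spectral
changes, or inter-subject variability.  Passing tests on this data shows the
pipeline's machinery is correct and that its metrics respond to signal
structure in the expected direction; it does not certify performance numbers
on real recordings.

## Preprocessing

Fourth-order Butterworth band-pass, 40–500 Hz, applied forward-backward
(zero phase) per channel.  At f = 1562.5 Hz the 500 Hz edge is below Nyquist;
for other rates the high edge is clipped to 0.99x Nyquist with a warning.
Envelopes are full-wave rectification followed by a second-order zero-phase
low-pass at 6 Hz (standard linear-envelope practice; a Hilbert-magnitude
variant is available — which envelope the original framework used is not
recorded).  Each task channel is divided by the maximum of that muscle's MVC
envelope, computed with identical settings.  The first and last 100 ms are
flagged in metadata as forward-backward filter transients.  Zero-phase
filtering is acausal; it is the right choice for this offline windowed
evaluation, and a causal mode (`zero_phase=False`) exists for
honest-latency studies.

## Greedy Gaussian segmentation

Each trial's MVC-normalized envelope, decimated to 100 Hz with a polyphase
anti-aliasing resampler, is split into K+1 = 4 contiguous segments, each
modeled as an i.i.d. multivariate Gaussian with its own mean and covariance.
Segment [i, j) scores

    score(i, j) = -(n/2) · log det(S + (λ·tr(S)/d + 1e-12) · I),

the profiled Gaussian log-likelihood up to partition-independent constants,
with trace-scaled diagonal loading so λ is unitless and the score is
scale-equivariant (multiplying all channels by c shifts every partition's
total by the same amount).  Segment means are estimated, not fixed at zero:
the zero-mean EMG assumption applies to raw EMG, whereas envelopes are
non-negative slow signals whose level differences between phases carry most
of the information.  Raw-signal segmentation is available behind
`GgsConfig(on="raw")`.

The fit is greedy: K breakpoint insertions, each at the position maximizing
the total score, interleaved with cyclic adjustment sweeps that re-optimize
each breakpoint between its neighbors.  Two additional escape moves run
after the insertions, both strictly improvement-accepting, so the recorded
objective history is non-decreasing:

* *global re-insertion* — remove one breakpoint and re-place it at the best
  position in any segment (local sweeps cannot carry a breakpoint past its
  neighbor);
* *paired re-insertion* — remove an adjacent pair and jointly re-place it
  inside the enclosing super-segment (exhaustively for small spans; coarse
  grid plus exact local refinement for large ones).

Ties always resolve to the earliest index, making the fit deterministic.

Numerical defaults.  λ = 0.3.  This is deliberately heavy shrinkage: at
100 Hz a 100-ms minimum segment holds ~10 samples of a 12-channel,
6-Hz-smoothed (hence heavily autocorrelated) envelope, so unregularized
segment covariances are rank-deficient and near-singular segments would earn
unbounded log-det rewards; with weak loading (λ ~ 1e-3) the fit degenerates
into clusters of minimum-length segments (median breakpoint error ~408 ms on
default trials), while λ in 0.3–3 recovers breakpoints to ~11 ms median and
the result is insensitive inside that range.  The minimum segment length is
100 ms (physiological floor); the exact-oracle comparison suites use λ = 0.5
and a 15-sample minimum for the same reason at their smaller dimensions.

`exhaustive_fit` solves the identical objective by dynamic programming and
serves as the test oracle; it refuses instances with more than 1e6 candidate
partitions.

With K = 3 the four segments are labeled reaching → grasping → returning →
resting in temporal order; the ordering prior mentioned for the original
method is not formalized there and is realized here purely through this
fixed assignment.  Per-sample gesture annotation gives the trial's gesture
to the three motional segments and 0 to resting.

## Windows, features, decoder

Envelopes are cut into T = 320 ms windows stepped every 40 ms.  The step is
62.5 samples at the native rate, so start indices are computed in
milliseconds and floored per window — the mean step stays exactly 62.5
samples with no cumulative drift.  A window takes the phase of its center
sample (the least-biased single assignment for boundary-straddling windows).
Features are per-channel RMS, MAV and population variance in the fixed order
[RMS_1..C, MAV_1..C, VAR_1..C] (3C = 36 columns); they are computed on the
normalized envelope, which is the pipeline's working representation.

The decoder is an extra-trees ensemble of 50 trees (scikit-learn
`ExtraTreesClassifier`, remaining hyperparameters at library defaults,
`n_jobs=1` for determinism).  Training follows a per-object 4/2 trial split:
each object's 6 trials are randomly paired into 3 disjoint validation pairs;
fold f validates pair f and trains on the other 4 trials, so 3 folds
validate every trial exactly once (the alternative — three independent 4/2
draws — is available by re-seeding single folds).  Three phase-selection
strategies are compared: S1 trains on reaching + resting windows, S2 on
grasping + resting, S3 on reaching + grasping + resting.  Returning windows
never train (the grasp is already released) but validation always covers
whole trials.  Probability outputs are expanded to all 14 classes with zeros
for classes absent from training; argmax ties break toward the lowest class
index.

## Time-aligned evaluation

Validation trials are aligned at grasp onset (first breakpoint, 0 ms);
window times snap to the 40-ms grid.  700 ms of resting-phase signal from
the end of the preceding trial (none for an object's first trial, flagged)
is prepended at negative times so the rest-to-reach transition is visible —
17 extra grid points at the default step.  Averaged curves take, per grid
point, the mean over trials with a window there: the trial's own gesture
probability (p_grasp), the rest probability (p_rest), and the *top
competitor* — the strongest class that is neither rest nor the trial's
gesture, taken per trial per time point before averaging (the competitor
may change identity over time).  Accuracy curves condition on the trial's
phase at that point, with the prepended context counted toward rest.

Scalar summaries:

* **t_i** — earliest grid time where p_grasp ≥ p_rest for 3 consecutive
  supported points (persistence suppresses single-window noise), refined by
  linear interpolation between the bracketing points; negative values mean
  detection before grasp onset.  Grid points supported by fewer than 20% of
  trials are masked — trial-length variability makes curve tails
  unreliable.
* **d_p** — p_grasp at its peak (earliest peak on ties) minus the
  simultaneous top-competitor probability.
* **pre-shaping confusion** — row-normalized 14x14 confusion over windows
  in [t_i, 0]; the mean diagonal over populated rows is the pre-shaping
  accuracy.

Averaging pools all validation trials (and, in the full protocol, folds)
with equal per-trial weight.

## Expected behavior on synthetic data

Because the synthetic gestures are cleanly separable, absolute numbers are
far better than any real-EMG deployment: S3 grasping-phase window accuracy
is ~0.999 and d_p ~0.99 on the default session.  What carries over from the
real framework is the *ordering*: a grasp-trained decoder (S2) crosses
later (t_i(S2) > t_i(S1)), combining phases (S3) keeps the largest d_p, and
making reaching more grasp-like (raising the pre-shaping blend) never delays
t_i for a grasp-trained decoder.  On clean data t_i lands earlier relative
to grasp onset than on real recordings, because trials with long reaching
phases are detected essentially at movement onset.

## Problem sizes

The default session (52 objects x 6 trials, 3 strategies x 3 folds) runs end
to end in a few minutes on one CPU; the test suite uses reduced sessions
chosen as the smallest sizes at which each property is stable: 100 default
trials for breakpoint recovery, 13 gestures x 2 objects for the strategy
ordering, 13 objects x 6 trials for end-to-end determinism, and 5-gesture
sessions over 5 seeds for the pre-shaping monotonicity of t_i.

## Known limitations

* The evaluation is offline; zero-phase filtering and whole-trial
  segmentation both look ahead of the window being classified.
* t_i is undefined (reported as null) when the averaged curves never cross.
* The confusion window [t_i, 0] can include resting context when t_i is
  very early, deflating pre-shaping accuracy relative to a window clipped at
  movement onset.
* Session-level pooling treats every trial equally; per-subject weighting is
  not implemented because sessions here are single-subject.
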