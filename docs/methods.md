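# Methods

## The study design being emulated

Twenty-eight simulated subjects each fly one nine-turn exercise: two
climbing turns, four leveling turns, three descending turns, with printed
pre/post headings (e.g. 127°→40°, a delta of 87°) and altitudes (e.g.
1800→3000 ft). The three turn types are treated as cognitive-load classes:
climbing = high (class 1), leveling = low (class 2), descending =
intermediate (class 3). The pipeline recovers the turns from telemetry,
attaches windowed HRV features to them, and asks whether the load class can
be decoded from physiology alone.

## Synthetic data

**Telemetry.** Flight plans are lists of legs (target heading, altitude,
speed, straight-leg duration). Heading ramps between legs along the shorter
circular arc at a configurable turn rate; altitude ramps linearly during
turns; Gaussian jitter (0.1° heading, 5 ft altitude, 0.5 kt speed) is added
per 1-s sample. A leg may carry a separate `entry_altitude`: the aircraft
reaches it during the inbound turn and then climbs/descends to the leg's
target in the middle of the straight segment. This reconciles the one place
in the printed plan where consecutive turns' altitudes do not chain (the
en-route descent 3000→2500 ft before the fifth turn) without contaminating
any turn's altitude profile.

The default turn rate is 0.5 °/s rather than the 3 °/s standard-rate turn.
The windowed analysis needs each turn to span several 30-s windows (a
length-3 window sequence covers 66 s); at 3 °/s the printed 30–180° turns
would last 10–60 s and produce no usable sequences. 0.5 °/s yields turns of
1–6 minutes, the regime the windowing implies.

**Heartbeats.** Beats are emitted by cumulative-interval construction: each
next interval (ms) is

    RR(t) = 60000 / base_hr + lf_amp·sin(2π·0.1·t + φ_LF)
                            + hf_amp·sin(2π·0.25·t + φ_HF) + ε,
    ε ~ N(0, noise_sd²),

with the parameter set of the turn segment active at t (a baseline set
outside turns), a 300-ms refractory floor, and a 2% chance per interval of
an artifact (the interval halved or doubled — a spurious or missed optical
detection). Class presets encode the direction of the load effect only:

| class       | base_hr | lf_amp | hf_amp | noise_sd |
|-------------|--------:|-------:|-------:|---------:|
| climbing    |      95 |     15 |     12 |       12 |
| descending  |      88 |     20 |     26 |       16 |
| leveling    |      82 |     25 |     32 |       18 |
| baseline    |      78 |     20 |     22 |       14 |

These are free parameters chosen once for physiological plausibility
(resting HR in the 80s–90s under task load; rmssd in the 20–40 ms range)
and for the ordering high load → low variability; no subject-level effect
size is claimed. Subjects get independent RNG streams spawned from the
master seed, a N(0, 3 bpm) heart-rate offset, a log-normal (σ = 0.08)
common scaling of all amplitudes, and random modulation phases.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: respiratory sinus arrhythmia coupled to actual
breathing, non-stationarity within a maneuver (load ramping up as the turn
progresses), circadian/arousal drift, ectopic-beat morphology, and
subject-specific autonomic response shapes. Class-conditioned statistics
here are stationary within a segment; consequences below.

## Preprocessing

An interval is anomalous when it deviates more than 20% from the median of
the 5-interval window centered on it (self-inclusive; clipped at the
edges). The self-inclusive median stays robust in very short series, where
a neighbors-only reference would be dragged toward the artifact and flag
its clean neighbors instead. Flagged runs strictly inside the series are
replaced by linear interpolation between the bracketing valid intervals
(y_{i+k} = y_i + k·(y_{i+n} − y_i)/n); runs touching either end are
dropped, because extrapolating an artifact fabricates data. Beat times are
rebuilt cumulatively. One notational caveat: the interpolation formula is
sometimes printed with an (n−1) denominator, which read literally fails to
reach the right bracket at k = n−1; the denominator n is the evident
intent and is what is implemented.

## Turn segmentation

At 1 Hz telemetry no single sample-to-sample heading step reaches 20°, so
the 20° threshold is applied to the *accumulated* change of a sustained
ramp: per-step signed circular changes are smoothed with a 5-sample moving
average, samples whose smoothed rate exceeds 0.25 °/s are marked turning,
contiguous runs closer than 10 s merge, and runs whose total circular
change falls short of 20° are discarded. Pre/post headings come from the
stable samples bordering the run. Altitude change over the run types the
turn with a ±50 ft level band: the band must be below 100 ft (the smallest
printed real altitude change, 2500→2400 ft, must classify as descending)
and above the ~5 ft sample jitter; 50 ft splits the difference.

Windows are labeled by majority overlap: a window takes the class of the
segment covering the largest fraction of it, if that fraction is ≥ 0.5;
otherwise it is excluded.

## HRV features

Thirty features per 30-s window, 18-s stride (40% overlap), windows with
fewer than 4 intervals skipped. Conventions:

* all SDs are sample SDs (ddof = 1), making sd1 = sdsd/√2 exact;
* nni_20/nni_50 count strict exceedances; pnni percentages are per
  successive difference;
* spectra: NN series linearly interpolated to 4 Hz, mean removed, Welch
  with a single Hann segment (30 s is too short to average segments);
  VLF [0.003, 0.04), LF [0.04, 0.15), HF [0.15, 0.4) Hz. A 30-s window
  holds ~1 VLF cycle, so vlf and total_power are method-sensitive at this
  window length and should not be compared across toolkits;
* Poincaré: sd1/sd2 as SDs of the rotated lag-1 coordinates; csi = sd2/sd1,
  Modified_csi = (2·sd2)²/(2·sd1), cvi = log10(16·sd1·sd2);
* triangular index at the standard 1/128-s histogram bin width.

## Statistical screening

Each feature is routed by a one-sample KS test against a normal with
estimated mean/SD (α = 0.05). Estimating the parameters makes this variant
anti-conservative toward declaring normality — kept because it mirrors
common statistical-package usage. Normal features are compared across the
three classes by one-way ANOVA, others by Kruskal–Wallis, no
multiple-testing correction by default (a Benjamini–Hochberg option
exists), windows pooled across subjects (a per-subject aggregation option
exists for sensitivity). Features with p < 0.05 are selected, most
significant first. On generator defaults the class effect is strong enough
and pooled n large enough that all 30 features pass; the selected set —
not a fixed subset — feeds the classifiers.

## Classifiers and training

Samples are sequences of 3 consecutive overlapping windows within one turn
(66 s of signal), so recurrent models see genuine short-term structure.
Split 70/30 stratified by class; min-max scaling to [0, 1] fitted on the
training set only; minority classes up-sampled with replacement — after
the split by default, since balancing first duplicates windows across the
split and inflates test scores (a `paper_order` flag restores
balance-then-split for comparability).

The LSTM-Attention network and the plain LSTM (same stack without
attention/concatenation) run on the package's own reverse-mode autodiff
(float64). Numerical choices: Glorot input-block and orthogonal
recurrent-block initialization, forget-gate bias 1, global gradient-norm
clipping at 1, Adam (initial lr 0.005, halved when the validation loss
stalls, floor 1e-4), batch 150, ≤ 50 epochs, early stopping with patience
5 on a 15% stratified validation split with best-weights restore, L2 0.01
on kernel matrices only (penalizing recurrent matrices as well makes
weight decay dominate the small cross-entropy gradients and training
collapses). A fit that never beats chance-level validation loss — an
occasional small-RNN initialization pathology — is restarted from a
reseeded initialization, up to 3 times. Baselines: KNN (k = 5) and random
forest (100 trees) on flattened sequences. Correctness of the autodiff is
established by finite-difference gradient checks over the full
LSTM-Attention graph.

## Evaluation

Macro-averaged precision/recall/F1 (each class weighted equally; macro-F1
is the headline number under class imbalance), one-vs-rest ROC per class
with trapezoid AUC — verified against Mann–Whitney pair counting — and a
3×3 confusion matrix. Models are ranked by macro-F1, ties broken by macro
AUC.

## Known limitations

* Under this generator the class-conditioned process is stationary within
  a turn, so a single window's features are statistically sufficient and
  the sequence adds no information. Flattened-feature ensembles therefore
  match or slightly exceed the recurrent models here (random forests also
  profit from memorizing the overlap structure shared by train and test
  windows of the same turn — train accuracy 1.0). A recurrent advantage
  of the kind reported on real cockpit physiology requires temporal
  non-stationarity and noise characteristics this generator deliberately
  does not fabricate; the synthetic study validates the pipeline and the
  direction of the load effect, not that ranking.
* Under label permutation the ensembles sit at chance macro-F1 (~1/3)
  while the recurrent nets converge to near-constant class probabilities
  whose argmax picks one class, giving macro-F1 *below* chance — evidence
  of no leakage, but not the ~1/3 a prediction-randomizing model would
  give.
* Trained at desk scale: 28 subjects × 1 flight ≈ 2500 windows ≈ 2000
  sequences; all quantities reported by the analysis scripts and
  acceptance run are computed at exactly this scale.
* The feature screen pools windows, so its p-values treat overlapping
  windows as independent — fine for ranking features on synthetic data,
  anticonservative as inference.
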