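# Methods

`replaykit` implements the complete analysis chain used to study awake
hippocampal replay on a figure-eight maze task, together with a synthetic
session generator that gives every stage a ground truth to be tested
against. This note records the models, the parameters that matter, and the
design choices made where the procedure was genuinely open.

## Task and coordinate system

The maze is a 100 × 140 cm figure-eight with a 20-cm-wide path: two start
zones at the bottom corners, a central stem, a decision point (junction) at
the top of the stem, and two goals at the top corners. A lap is one of four
*journeys* — LL, LR, RL, RR, named (start side, goal side) — and runs under
one of three subtask rules: visually guided discrimination (VD), non-delayed
spatial alternation (NA), and delayed alternation (DA, with a 5-s barrier
wait 20 cm into the stem). Since the alternation rules only produce crossing
journeys on correct trials, the eight *trial types* are VD×{LL, LR, RL, RR}
and {NA, DA}×{LR, RL}. Each journey is an idealized polyline sampled at 1-cm
intervals; 2D positions are linearized by nearest-sample projection (ties
toward the smaller arc length), giving an arc coordinate of 0–200 cm from
the journey start. Zones on that coordinate: start [0, 20), stem [40, 140),
junction [140, 160), goal vicinity [180, 200] (the goal vicinity extent is
configurable; the analysis default is the final 20 cm).

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
biophysics:

- **Protocol.** Subtask blocks VD(20) NA(20) VD(10) DA(20), repeated twice:
  140 laps, a 60:40:40 VD:NA:DA experience ratio. Behavior is sampled at
  50 Hz; running speed fluctuates (AR(1)) around 50 cm/s and never drops
  below the 5-cm/s place-map criterion during runs. After each reward the
  animal descends the outer return rail and pauses 1–5 s in the start zone
  at < 2 cm/s.
- **Place code.** Each of 100 cells has a Gaussian tuning bump (SD 10 cm,
  peak 8 Hz over a 0.1-Hz baseline) on the linearized coordinate of every
  journey, with independent centers per journey (global remapping). Each
  cell multiplies its rate by a subtask gain; by default the gain set
  {1.0, 1.5, 2.25} is randomly permuted across the three subtasks per cell
  (rate remapping with a population-balanced budget — a scalar-per-subtask
  assignment is also supported and is measurably *less* discriminable after
  binarization). Spikes are inhomogeneous-Poisson draws at the simulated
  position; outside tuned runs cells fire at gain-averaged baseline.
- **Replays.** Each pause receives a forward "virtual traversal" of the
  upcoming trial type: position advances at `run_speed × compression`
  (default 10×) from the animal's arc position to the goal, and rates are
  `compression × gain × tuning`, i.e. the running spike process time-scaled
  by the compression factor (a 200-cm traversal at 50 cm/s lasts 0.4 s at
  10×). Matched *null bursts* reuse a traversal's spike count profile with
  cell identities permuted against spike times (the identity permutation is
  rejected), destroying sequential structure while preserving the
  population rate envelope.
- **LFP.** Pink (1/f) background noise at 1250 Hz, an 8-Hz theta sinusoid
  (2 SD amplitude) while running, and a 180-Hz ripple burst (5 SD, Gaussian
  envelope matched to the event duration) at each injected replay.
  Amplitudes are free choices; they are set so that a mean + 3 SD
  envelope detector operates in a realistic regime rather than at a
  ceiling.

A fixed seed makes the whole bundle reproducible bit-for-bit. What the
generator does *not* emulate: theta phase precession, multi-field and
directional cells, reverse or remote replay, noise correlations, behavioral
variability in path shape. Passing tests therefore demonstrate the
correctness and calibration of the analysis code under the assumed
statistical structure, not performance on real recordings.

## Place maps and screening

Per (cell, trial type), spike counts and occupancy from running samples
(> 5 cm/s, within trials — this also removes the DA barrier wait) are
accumulated on 2-cm linear bins, both smoothed with a 3-cm-SD Gaussian
kernel (reflective edges keep the kernel mass-conserving), and divided.
Unvisited bins carry rate 0 and are masked from decoding. Trials of the
same type are pooled across blocks.

Screening keeps putative principal cells (session mean rate in
[0.1, 5) Hz) with spatial information above 0.3 bits/spike
(Skaggs–McNaughton per-spike information, evaluated on the cell's best
trial-type map) and a trial-type effect on windowed firing rate after
adjusting for running speed, head direction (sine/cosine pair) and x/y
position — an ANCOVA-style F-test at p < 0.05 on 250-ms running windows.
The spike-width criterion used for principal-cell classification on real
tetrode data has no synthetic counterpart and is not simulated.

## Bayesian decoding

For a window of duration τ with counts *n<sub>i</sub>* and maps
*f<sub>i</sub>*:

    Prob(Pos|spikes) = (Π_i f_i(Pos)^{n_i}) · exp(−τ Σ_i f_i(Pos)),

normalized over all bins of the concatenated candidate journeys (each
journey is a disjoint bin block, so a decoded location is a (journey, arc)
pair). τ is 250 ms during task running and 20 ms during replays; replay
decoding scales the rates by the 10× compression factor, implemented as
τ-scaling inside the exponential because the product term changes only by a
bin-independent constant. A rate floor of 0.01 Hz inside the likelihood
prevents zero-probability annihilation; rows with no likelihood fall back
to uniform and are flagged.

A point (MAP) estimate is issued only when the posterior row passes a
unimodality gate: Hartigan's dip test at p < 0.05 (multimodal rows yield no
estimate), with ties broken to the smallest bin. The dip statistic is
computed exactly from its definition — for each candidate mode, the minimal
sup-norm band half-width around the ECDF that admits a monotone CDF convex
left of the mode and concave right of it; the two within-region chord
systems have closed forms and the coupled condition through the shared
modal value is solved by bisection. The implementation agrees to ≤ 1e-7
with an independent linear-programming formulation of the same definition
(kept as a test oracle) and with the closed forms dip = 1/(2n) for an even
grid and dip → 1/4 for two equal point masses. The posterior row is turned
into a sample by deterministic inverse-CDF quantiles (m = 32, piecewise-
linear within bins), and the p-value is calibrated against a cached
1000-draw uniform null (fixed internal seed), so the gate is deterministic.

The simple spatial reconstruction alternative is
Rp = Σ<sub>i</sub> n<sub>i</sub> f<sub>i</sub> with the location estimate at
argmax Rp.

## Event detection

- **SWRs:** 150–250 Hz zero-phase Butterworth band-pass (order 3), Hilbert
  envelope; local peaks > mean + 3 SD extended to the surrounding mean
  crossings; kept only when speed at the peak is < 2 cm/s.
- **Theta:** 4–12 Hz band power (squared envelope) z-scored against the
  whole trace, averaged per interval.
- **Candidates:** the summed spike train of all cells on a 1-ms grid,
  smoothed with a 10-ms-SD Gaussian. The mean and SD are computed over
  immobility only (< 2 cm/s), so running-rate elevation cannot inflate the
  threshold; the baseline epoch is otherwise a free choice.
  Supra-mean immobile periods containing a > mean + 3 SD peak are reduced
  to the span of their participating cells' spikes; an event needs ≥ 10% of
  all cells with ≥ 2 spikes each and ≥ 30 ms. Reducing instead to the
  literally smallest sub-window still meeting those floors would cut a
  dense 100-cell burst to ~15% of its extent and starve the downstream
  path-distance criterion, so the boundary-reduction reading is used.

## Path replays

Candidates are decoded in 20-ms windows advanced in 5-ms steps. Valid
(gated) MAP locations are concatenated into periods wherever neighboring
locations are < 25 cm apart within one journey block; an event whose best
period covers more than the distance criterion — read as 4 × 25 cm =
100 cm, configurable because the four-window rule admits more than
one reading — is a
candidate path.

Certification statistic: S = |weighted Pearson correlation between window
index and decoded location| × (fraction of steps < 25 cm), windows weighted
by their posterior peak. The certification procedure fixes the shuffle
modes but not the statistic; this one is chosen to honor both path
criteria (continuity and covered distance) and is pluggable. Nulls: (A) permute the cell →
place-map assignment; (B) circularly shift each cell's map by an
independent uniform offset within each journey block. 5000 shuffles per
mode by default with add-one p-values, p < 0.05 in both modes certifies a
path replay. Inside the shuffle machinery, per-window locations are plain
argmax for the observed and shuffled statistics alike: the dip gate costs a
Monte-Carlo calibration per window and would multiply the cost a
thousandfold, and since observed and null are computed identically the
comparison remains exchangeable.

## Compression rate

Per candidate, per-cell ISIs with both spikes inside the event are pooled;
the reference pool holds per-cell ISIs with both spikes outside every
candidate *and* above 5 cm/s. The event's compression rate is (reference
median)/(event median); the session summary is the median over events.
Medians are used because the mean of the rest-of-session pool is dominated
by between-pass gaps (a literal mean quotient misestimates a 10×
construction by an order of magnitude), and the reference is restricted to
running because a replay is a compressed running pattern — with the
unrestricted pool the estimator reads ~24% high against ground truth.
`statistic="mean"` and `reference_speed_min=None` restore the literal
reading.

## Trial-type prediction

A cell is *high* in a window when its firing rate there strictly exceeds
its whole-session mean rate. Reference vectors R store, per (trial type,
location bin, cell), the probability of the high state, estimated from
200-ms running windows with a symmetric pseudocount α = 1 (no data → 0.5).
A window at decoded location p is assigned the trial type maximizing
Prob(C|t) = Π<sub>i</sub> Prob<sub>i</sub>(c<sub>i</sub>|t, p), computed in
log space; ties break in canonical type order.

Defaults the procedure leaves open, fixed here after pilot runs on the
generator:

- **Reference location bins: 20 cm** (not the 2-cm map bins). At 140 laps a
  2-cm bin holds only a handful of 200-ms windows per type, and estimation
  noise across ~100 cells swamps the rate-remapping signal; 20 cm is about
  the spatial footprint of a 200-ms window at running speed.
- **Reference windows are stepped by 100 ms** (50% overlap) to cover every
  location bin densely. Leave-one-*trial*-out removes whole trials, so no
  window is predicted by a reference containing itself.
- **Running prediction windows are 200 ms** — the same basis on which the
  binary vector is defined — while the location entering the lookup is
  still decoded from the 250-ms task window centered on the prediction
  window, over journey-pooled maps (pooling prevents the posterior from
  splitting into duplicate same-journey blocks across subtasks, which
  would trip the unimodality gate).

Shrinking R hierarchically toward journey-pooled estimates was evaluated
and *rejected*: it lowers leave-one-out accuracy, because the subtask
signal is diffuse across the population rather than confined to a few
cells.

Running performance is summarized as a confusion matrix of per-window
predictions with leave-one-trial-out references; chance for eight
equiprobable types is 12.5%. On generator defaults the accuracy is
0.70–0.73 across seeds; richer rate remapping (e.g., fields appearing or
disappearing between subtasks) would push it higher.

For each certified path replay, trial type is predicted in its 20-ms
windows (the same high/low rule against the session mean; compressed
participants read as high, which is the intended signal) at the decoded
per-window locations. The event statistic is the summed normalized
probability of the modal predicted type; nulls are cell-identity
permutation within C and permutation of decoded locations across windows
(5000 each by default). Both p < 0.05 makes the replay *episodic*.

## Session statistics

Path-representation strength is the summed posterior probability over a
named arc region across an event's windows (over the whole maze it equals
the number of windows, by normalization). Event profiles can be aligned to
a common frame: translated to the start position (start-zone events) or
the animal's location (stem events), reflected toward the memory-guided
goal, and optionally scaled by the distance to that goal; mass is
accumulated by nearest-grid-bin assignment, which conserves probability.
Subtask preference of episodic replay counts is a chi-square goodness of
fit against the 60:40:40 experience ratio with BH-corrected pairwise
binomial post hocs. Actual-vs-predicted trial-type agreement uses Cohen's
κ with the large-sample z-test (null variance by the
Fleiss–Cohen–Everitt formula). Wilcoxon/rank-sum comparisons are standard
scipy routines — reporting glue, not method.

## Numerical and scale choices

Windows are half-open [t, t + τ). The acceptance script and test suite run
at desk scale: one 140-lap, 100-cell session per scenario; 200 null events
with 500 shuffles per mode for the false-positive control; 200 shuffles per
mode where only sensitivity, not the p-value resolution, is measured.
Shuffle p-values use the add-one estimator, so p = 0 is impossible.
Seeds: every stochastic routine takes an explicit seed or generator;
internal calibration tables (the dip null) use fixed private seeds and are
cached per process.

## Known limitations

- The generator's rate remapping is purely multiplicative; real rate
  remapping includes field appearance/disappearance, which carries more
  binary-vector signal, so leave-one-out accuracies on real ensembles can
  exceed the synthetic figures here.
- The shuffle statistic is one reasonable choice among several (weighted
  correlation with a continuity factor); radon/line-fitting statistics
  would slot into the same interface.
- Reverse and remote replays are out of scope: injected events are forward
  traversals toward the upcoming goal, and the certification statistic
  takes absolute correlation, so reverse events would certify but are
  never generated.
- Head direction enters screening as a sine/cosine pair; circular-circular
  statistics on behavior are not implemented.
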