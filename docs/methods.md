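# Methods

## The model

`headrace` implements a generative account of heading discrimination with
simultaneous visual (optic flow) and vestibular (inertial) cues, in which a
single bounded-accumulation process jointly produces the choice, the
reaction time, and the confidence rating of every trial.

**Momentary evidence.** The stimulus is a brief forward translation with a
Gaussian-bell velocity profile `v(t)` (duration 2 s, SD = duration/6,
normalized to peak 1) and acceleration `a(t) = dv/dt` (normalized to peak
1). Visual evidence about heading is carried by velocity and scaled by
motion coherence `c`; vestibular evidence is carried by acceleration. The
instantaneous sensitivity envelopes are

    s_vis(t) = k_vis * c * |v(t)|        s_ves(t) = k_ves * |a(t)|

and the momentary-evidence mean (drift) for a cue at heading `h_m` is
`mu_m(t) = s_m(t) * sin(h_m)`. In the combined condition the two cues are
weighted by their instantaneous squared sensitivities,

    mu_comb(t) = sqrt(s_vis^2 + s_ves^2)
                 * [w_vis(t) sin(h_vis) + w_ves(t) sin(h_ves)],
    w_m(t)     = s_m(t)^2 / (s_vis(t)^2 + s_ves(t)^2),

so that instantaneous signal-to-noise adds across cues
(`mu_comb^2 = mu_vis^2 + mu_ves^2` when the cues agree). Cue conflict
displaces the visual heading to `h - Delta/2` and the vestibular heading to
`h + Delta/2`. Evidence units are normalized to unit diffusion variance per
second; all stimulus sensitivity lives in the gains `k_vis`, `k_ves`.

The vestibular envelope uses `|a(t)|` rather than signed biphasic
acceleration: reliability cannot be negative, and we read the weighting
scheme as sign-corrected accumulation so that the deceleration phase does
not cancel earlier evidence. The signed convention is available via
`drift_schedule(..., signed_acceleration=True)` but is not the default and
is not endorsed.

**The race.** Two accumulators (rightward/leftward) receive bivariate
normal increments with means `[mu dt, -mu dt]` and covariance
`dt [[1, rho], [rho, 1]]`, `rho < -0.5` (default -0.7). Both start at 0;
the first to reach the bound `B` fixes the choice and the decision time,
and RT adds a non-decision latency `t_nd` (fixed by default; uniform jitter
available). After the stimulus ends the drift is zero but diffusion
continues until the deadline `t_max` (default twice the stimulus duration);
trials that reach the deadline are censored, with the choice read from the
sign of the accumulator difference. Simulation is Euler–Maruyama on the
schedule's grid (default 1 ms), jitted with numba. Same-step double
crossings are resolved by the larger overshoot, exact ties by a fair coin.

**Confidence.** Because the winner is pinned at the bound, the informative
state at decision time is the pair (elapsed time, losing-accumulator
value). The observer is assumed to know the mapping from that pair to the
log odds of having chosen correctly. We estimate the map by Monte Carlo:
simulate the design's nonzero headings (uniformly), bin decisions on a
(time x losing-state) grid (default 40 x 40, 2e5 trials), and convert
per-bin fraction correct to log odds with add-one smoothing. Empty bins
are invalid and are never interpolated; lookups falling in them resolve to
the nearest valid bin. Ratings on the experiment's guess(0) -> certain(1)
scale are `clip(2 sigmoid(scale (L - offset)) - 1, 0, 1)`: log odds 0 (a
dead heat) maps to "complete guess" and large log odds saturate at "100%
certain". One map is built per modality x coherence, mirroring the idea
that the observer learns one mapping per stimulus context.

## Synthetic experiment

The generator emulates the pilot design: 5 participants, modalities
{vestibular, visual, combined}, coherences {0.4, 0.7}, headings
+-{1.5, 3, 6, 12} and 0 degrees, cue conflicts {-3, 0, +3} degrees applied
to combined cells, 10 trials per cell (~810 per subject, ~4050 in total,
matching the pilot's ~4092), trial order randomized within subject and cut
into 30-trial blocks; feedback exists only as percent correct per block
(computable via `block_feedback`, not part of the generative model — no
learning dynamics). Zero-heading trials are rewarded by a fair coin.

Default parameters (`SubjectParams`): `k_vis = 120`, `k_ves = 42`,
`B = 2.0`, `rho = -0.7`, `t_nd = 0.3 s`, identity-scale link. These were
calibrated once so the synthetic experiment reproduces the pilot's visible
features: psychometric thresholds of 1.3–2.4 degrees with the visual cue
less reliable than the vestibular at coherence 0.4 and more reliable at
0.7 (the ordering that drives the conflict-bias reversal), mean RTs of
0.8–2.4 s peaked at the hardest heading, a confidence trough at 0 degrees,
and essentially no decisions before the stimulus envelope delivers
evidence. `default_subject_params` adds +-15% jitter to the gains, +-10%
to the bound and +-50 ms to `t_nd` across subjects.

What the generator does **not** emulate: sequential/learning effects,
lapses, post-decision processing, response-modality details (saccade
kinematics), or any deviation of real observers from the model itself.
Passing tests therefore demonstrate internal consistency of the method and
the analyses, not that human data follow the model.

## Analyses

Psychometric curves are binomial maximum-likelihood cumulative Gaussians
with optional lapse in [0, 0.1] (fixed at 0 by default), multi-start and
deterministic; complete separation drives sigma to the optimizer bound and
flags the fit. RT and confidence profiles against heading are least-squares
Gaussians on condition means (peak for RT, trough for confidence; censored
trials excluded). Cue weights follow from the conflict-induced bias:
`w_ves = 0.5 - PSE / Delta`. The static optimal-combination benchmark is
`sigma_c^2 = sigma_a^2 sigma_b^2 / (sigma_a^2 + sigma_b^2)`. Confidence by
RT quantile uses 5 empirical quantile bins within |heading| x modality
groups, left/right pooled, censored excluded.

## Fitting

The joint likelihood of (choice, RT, confidence) is intractable, so the
objective is a quantile-binned multinomial negative log-likelihood: per
design cell, simulated trials (fixed per-cell seeds — common random
numbers, hence a deterministic objective) are sorted into
{choice x 5 RT quantile bins x 3 confidence terciles} with edges taken
from the data, Laplace-smoothed, and scored against the observed counts.
Cells with fewer than 30 trials collapse to choice x RT. The fitting
simulations use a 2 ms step (the choice/RT likelihood is insensitive to
the step at this scale); maps for predicted confidence are rebuilt from
the pooled cell simulations. Optimization is derivative-free: 10 fixed
log-spaced starts screened at 800 simulations/cell, Nelder-Mead at 1500
(maxfev 100), then a restarted simplex at 3000 (maxfev 50), and a final
re-score at 10^4 simulations/cell. `rho` is held fixed (it trades off with
the bound and is weakly identified); the link offset/scale are fitted only
when confidence bins are in use.

The parameter-recovery experiment (5 seeded ~4050-trial datasets at the
default parameters; single subject, no conflicts) fits with choice x RT
binning only. The reason is a property of synthetic confidence, not of the
model: generated ratings pass through a finite-simulation log-odds map, and
in near-ceiling cells the data-defined terciles are so narrow (~0.01 in
rating units) that the irreproducible Monte-Carlo noise of a refitted map
dominates the confidence likelihood and biases it away from the generating
parameters. Choice and RT identify all four free parameters; recovery
errors are typically under 6% per parameter, well inside the 20% margin.

## Numerical choices and degenerate inputs

- Euler step 1 ms (simulation/generation), 2 ms (fitting); the bound-
  crossing discretization bias at these steps is ~1% of `B`, far below
  sampling noise at the study's trial counts.
- Time steps where both sensitivity envelopes vanish produce zero drift
  rather than an error; zero-heading, zero-conflict schedules are exactly
  zero everywhere.
- Randomness: one seeded generator drives each simulation batch
  sequentially inside the jitted kernel; every higher-level routine
  derives child seeds via `SeedSequence` spawn keys, so all outputs are
  bit-reproducible from a single master seed.
- Map bins with zero trials are NaN and excluded from analysis; lookups in
  them use the nearest valid bin (KD-tree on scale-normalized bin centers).
- Add-one smoothing bounds per-bin log odds by ~log(n+1).

## Known limitations

- **Confidence vs RT at easy headings.** Within hard and intermediate
  heading magnitudes the model reproduces the signature negative
  confidence–RT relation, but at the easiest magnitude tested (6 degrees)
  it predicts a flat-to-positive relation. Two structural causes: (i) the
  stimulus delivers most of its evidence mid-trial, so the probability of
  being correct given a very early decision — and hence the learned map at
  early times — rises before it falls; (ii) with `rho = -0.7` the losing
  accumulator drifts away from its bound as time elapses, so the late
  deciders in easy conditions carry very negative losing states and map to
  high confidence. Both effects shrink as `rho -> -1` or as the bound
  rises relative to the gains, but under pilot-realistic parameters they
  do not vanish. The acceptance suite asserts the negative relation in
  every group and is accordingly red for the 6-degree groups.
- Flat bounds only (no collapse/urgency); Monte Carlo only (no
  Fokker–Planck solver); no post-decision evidence or metacognitive noise;
  no hierarchical pooling across subjects; 1-D heading (azimuth) only.
- Censored trials (~5–15% in the hardest cells) are flagged and excluded
  from RT/confidence means; a real reaction-time task has no such deadline
  artifact.

## Problem sizes

Defaults used by the test suite and the acceptance script: 10^5 trials for
the first-passage oracle; 10^4 trials/cell for the conflict-shift
experiment; 5 x 10^3 trials per signed heading (10^4 per |heading| group)
for the confidence-quantile experiment; 2 x 10^5 simulations per log-odds
map in dedicated map experiments and 5 x 10^4 inside dataset generation;
5 datasets x 4050 trials for recovery. These sizes put Monte-Carlo error
well below every asserted effect.
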