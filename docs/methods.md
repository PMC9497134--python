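# Methods

`ppsbound` estimates the boundary of peripersonal space (PPS) — the region
around the body where an approaching visual stimulus speeds up tactile
processing — from trial-level reaction times (RTs) in a looming visuo-tactile
task, and tests whether a motor training shifts that boundary. This note
documents the model behind each stage, the parameters that matter, and the
choices made where the design was genuinely open.

## Task geometry

A ball travels at constant velocity `v` (default 75 cm/s) toward (looming) or
away from (receding) the trunk. A vibrotactile tap is delivered at one of five
delays from motion onset, `t ∈ {433, 866, 1299, 1732, 2165}` ms, so each delay
maps to a tap distance. For looming stimuli

    d(t) = d0 − v·t,    d0 = 199.5 cm,

giving taps from 167.03 cm (D1, earliest tap) down to 37.12 cm (D5) in steps
of `v·Δt = 32.475 ≈ 32.5` cm. `d0` is reconstructed from the printed distance
range at the printed velocity and delays; distances are compared to printed
values at ±0.01 cm because the original rounding convention is unknown. The
receding trajectory origin is not documented anywhere we know of; we use the
mirror construction `d(t) = 4.65 + v·t` cm so both directions tap at the same
five distances. D-labels order distances body-outward: D1 is always the
farthest tap, so for receding stimuli D1 is the *latest* tap.

A session holds 220 trials in two balanced blocks of 110. The composition —
16 repetitions × 5 distances × {looming, receding} = 160 multisensory trials,
30 unisensory tactile trials, 30 visual-only catch trials — is a package
default chosen to satisfy the 220-trial total with equal per-cell repetitions
and enough unisensory trials for the facilitation contrast; the original
composition is not public, so every count is configurable
(`TrialBreakdown`). Catch trials exist so that "respond only to touch" is a
testable property; they carry no RT. Order is pseudo-randomized per block by
a seeded generator; counts are seed-invariant.

## Synthetic cohort

The generator emulates the data structure the analysis assumes: `n = 22`
subjects, a fully within-subject 2 (experiment: real/virtual training) × 2
(session: pre/post) design, four full sessions per subject (19,360 trials
with defaults). For subject *i* with baseline offset `b_i ~ N(0, 40 ms)` and
boundary `pse_i ~ N(1277.5, 120 ms)`, expected multisensory RT at delay `t`
is a descending logistic on the delay axis,

    looming:  560 + b_i − 62·L((t − pse)/150)
    receding: 560 + b_i + 15 − 10·L((t − pse)/150)

with `L` the standard logistic CDF. The asymptote (560 ms), facilitation
amplitude (62 ms), pre-training PSE (1277.5 ms), post-training real-arm shift
(−109.9 ms) and unisensory baseline (604 ms) are anchored to the reference
group statistics for this task; the logistic scale (150 ms), the
between-subject SDs (40 / 120 ms), the trial noise (90 ms), the receding
penalty/amplitude (15 / 10 ms) and the miss rate (0.01) are not reported
anywhere and are package choices of plausible magnitude — they set the
difficulty of the estimation problem and are the first thing to revisit when
matching a new data set. `GeneratorParams.calibrated()` refits (asymptote,
amplitude, PSE, scale) by least squares to the five per-distance group means,
for work that needs the per-distance profile rather than the individual
curve parameters.

Trial noise is Gaussian truncated at a 150 ms floor (redrawn, not clipped); a
shifted-lognormal option (`noise="lognormal"`, matched mean and SD, support
above the floor) is available for heavier right tails. Missed taps
(probability `miss_rate`) are redrawn until a response lands, mirroring the
task's repeat-on-miss rule, so every planned tactile trial yields one valid
RT. Training is not simulated as a process: it acts only through the
per-experiment PSE shift applied to post sessions. The generator does not
model learning or fatigue across blocks, RT autocorrelation, or embodiment
covariates — passing tests show that the *analysis chain* behaves correctly
on data with this structure, not that real cohorts look like this.

## Boundary estimation (Spearman–Kärber)

Per subject × experiment × session, using multisensory looming trials only
(receding trials are simulated and summarized but never enter boundary
estimates):

1. **Filter**: drop missed trials and RTs outside [150, 1500] ms
   (configurable); an exclusion log counts removals per rule, and wiping out
   an entire cell is an error rather than a silent gap.
2. **Aggregate**: mean RT per delay level (16 trials per level by default).
3. **Normalize**: facilitation proportion `p_k = (RT_max − RT_k)/(RT_max −
   RT_min)` over the five level means, so the slowest level maps to 0 and the
   fastest to 1. The original transform is not public; within-curve min/max
   anchoring is the package default.
4. **Monotonize**: pool-adjacent-violators (isotonic least squares), since
   the Spearman–Kärber reading requires a nondecreasing response function.
5. **Augment**: if the monotone curve does not reach 0 (respectively 1) at
   its ends, add a virtual level one delay-spacing below (above) the tested
   range carrying p = 0 (p = 1). This makes the estimator well defined for
   curves that never saturate and bounds every estimate by the augmented
   range.
6. **Estimate**: treating the curve as the CDF of a latent threshold
   distribution, `PSE = Σ (x_k + x_{k+1})/2 · (p_{k+1} − p_k)` (the SK mean)
   and `DL = (Q75 − Q25)/2`, quartiles taken by linear interpolation of the
   piecewise-linear CDF, skipping flat segments at the rising edge. DL as
   half the interquartile spread is the standard SK difference limen; for an
   exact logistic with scale `k` it equals `k·ln 3`.

PSE lives on the delay axis (ms), matching how boundary values are reported
for this task; the body-centred distance `d0 − v·PSE` (cm) is attached as a
derived convenience, with larger distances meaning an expanded PPS.

### Known limitation: mean reversion under high trial noise

With 16 trials per level, 90 ms trial noise and a 62 ms facilitation
amplitude (the generator defaults), the per-level proportion noise is large
(level-mean SE ≈ 22.5 ms against a 62 ms dynamic range). In that regime the
min/max normalization and the endpoint augmentation make the SK estimate
strongly mean-reverting toward the centre of the augmented delay grid, with
an upward asymmetry (the slowest level is well separated, so the p = 0 anchor
is stable, while the p = 1 anchor is contested among the three nearest
levels, pushing augmentation mass to the right tail). Consequences, computed
by the acceptance checks: cohort-mean PSE recovery is biased toward the grid
centre for anchor values away from it, generator-level pre/post shifts are
strongly attenuated in estimate space, and the detection power of the
Condition × Experiment interaction at n = 22 is far below nominal, while the
type-I rate under the null stays at α (5% ± 2% band, verified over 1000
cohorts). With noiseless data the chain recovers each subject's PSE to a
fraction of a millisecond, so this is a property of the noise regime, not of
the estimator implementation; halving the trial noise (or increasing
repetitions per level) restores near-unbiased recovery. Users fitting real
data should check their per-level SEs against the facilitation amplitude
before trusting individual SK estimates.

## Inference

`rm_anova` is a from-scratch fully-within-subject decomposition (one or two
factors): each effect is tested against its own subject-interaction error
term, `F = MS_effect / MS_effect×subject`, with partial eta-squared
`SS_effect/(SS_effect + SS_error)` as effect size. Sums of squares conserve
total SS to 1e-9 relative; F and p agree with an independent reference
implementation to better than 1e-8 on random balanced designs. No sphericity
correction is applied by default (two-level factors are always spherical; the
2 × 2 design of the main analysis has all dfs = 1); `correction="gg"` reports
Greenhouse–Geisser corrected p-values using the Box epsilon computed on each
effect's orthonormal contrast subspace (for the interaction, the Kronecker
product of the main-effect contrasts — note that other packages use different
interaction-epsilon conventions).

Newman–Keuls post-hoc comparisons order the cell means ascending (ties broken
by label), test the widest span first with studentized-range critical values
`q(1 − α, r, df_error)`, and step down; a pair nested inside a
non-significant span is declared non-significant without testing
(containment). On the 2 × 2 interaction the four cell means are one family
with n = subjects and the interaction MS error as the error term — the
conventional choice. The studentized-range CDF/quantiles come from
`scipy.stats.studentized_range`.

The facilitation contrast (multisensory looming vs unisensory tactile,
per-subject means) is the one-factor two-level case, identical to the squared
paired t statistic.

## Pipeline and reproducibility

`run_analysis` composes filter → per-cell SK estimates → Condition ×
Experiment ANOVA on PSE and on DL → Newman–Keuls on significant interactions
→ facilitation test, and returns a report whose every number is recomputable
from the trial CSV plus the run configuration. Group SEs are SD/√n over
subjects. Reports carry a provenance block: SHA-256 of the canonical JSON
config (seed excluded, so the hash identifies the analysis, not the draw),
the seed, and the package version. Identical config + seed yields
byte-identical trial CSVs and reports. The CLI (`ppsbound simulate /
estimate / analyze / report`) is a thin wrapper; all logic lives in the
library.

## Problem sizes and tolerances used in the checks

Recovery studies use 200 simulated subjects (averaging pre-session estimates
from both experiment arms); detection behaviour uses 100 cohorts of 22
subjects for power and 1000 for type-I calibration; estimator oracles use
dense grids (4000 points) against analytic logistic results (location ±1 ms,
spread ±2%). Degenerate inputs fail loudly: flat curves, wiped cells,
incomplete designs, and unparsable trial rows all raise typed errors naming
the offending cell or row.
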