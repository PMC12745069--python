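# Methods

## Environment model

The world is a 720-px-wide strip of length 9,000 / 13,500 / 18,000 px with
36×36-px obstacles whose corners are i.i.d. uniform over the admissible
rectangle; obstacle counts follow the difficulty table (12/34/68 short,
32/84/168 long, 58–62 / 116–124 for mid-length layouts). The 36×36-px ship
descends 6 px per logical frame on an exact 60-FPS clock; real-time frame
jitter is not modeled. A keyed frame moves the ship ±6 px, or a signed draw
from Normal(6, σ) under input noise — negative tail draws are applied
as-is, so the ship can momentarily move against the keyed direction, the
simplest reading of a sampled step. Drift sections are 270-px,
non-overlapping vertical spans (rejection-sampled in y) that push the ship
3 px/frame toward a fixed side; only *normal* and *invisible* sections
exert force, *fake* and *off* do not.

Drift membership uses the ship's top edge (`y_start ≤ y < y_start+270`), so
an uncontrolled traverse lasts exactly 270/6 = 45 frames and accumulates
exactly 135 px — the closed form the test suite checks. A box-overlap
membership rule would instead give a phase-dependent 51 frames; the
point-membership rule was chosen for this exact invariant.

Collision uses half-open pixel boxes `[x, x+36)`, so abutting sprites do
not collide; wall contact (x < 0 or x+36 > 720) is a crash. Generated
layouts are rejected (and resampled with an incremented seed) if any
horizontal band has no ship-wide free column, so every shipped layout is in
principle completable.

The screen shows a 1920×1080 window with the ship sprite pinned at
(954, 270) and a 270-px occluder along the bottom; objects count as "on
screen" while their box strictly intersects the top 810 px. A 36-px object
therefore dwells (810+36)/6 − 1 = 140 frames ≈ 2.3 s, matching the roughly
2.45 s the task description reports for the crossing time. Trials begin
with a 45-frame uncontrolled entry from the screen top to the control
point; the control phase ends at the finish line (length/6 frames) or at a
crash. Sessions draw configurations in random order, requeue crashed
configurations up to three attempts, play the normal block first in the
block design, and insert an easy 18,000-px training layout (manipulations
from halfway) that never enters analysis tables.

## Scripted agents

The greedy-gap policy plans against the nearest obstacle band within a
400-px lookahead: it computes the free horizontal gaps, heads for the
widest one (or the nearest when the band is almost upon the ship, since
crossing a blocked column late is fatal), and aims at the nearest point a
12-px margin inside the gap rather than the gap center. That corner-cutting
is deliberate: each keyed frame draws a noisy step, so the achieved
clearance degrades with the noise σ and completion probability declines
monotonically in noise — the property the completion models need. While
idle inside an active drift section the agent leans against the push on
half of the frames, cancelling drift in expectation, which mirrors the
finding that predictable drift does not reduce completion. A skill
parameter (default 0.9) injects per-frame lapses; policies are otherwise
deterministic given the seed. They are task plumbing, not models of human
cognition.

## Synthetic gaze

Gaze is generated per trial at 2000 Hz as alternating fixations and
saccades. A fixation onset point lies at distance *d* from the on-screen
ship center, with *d* drawn from the Close or Distant mixture component
(P(Distant) = 0.35 by default). On the component's transform scale the mean
is shifted linearly by the onset frame's covariates and the participant
intercept, so the corresponding fitted model is linear in the planted
coefficients by construction. Defaults: Close 3.0° (sd 1.0°), Distant 8.0°
(sd 1.2°), participant intercept sd 0.5°; Close shifts +0.07°/on-screen
obstacle and noise-level shifts 0 / −0.02 / −0.11 / −0.15 / −0.20° for
σ = 0/3/6/9/12 (successive differences −0.02 and −0.09 for the first three
levels, the reported Close-fixation pattern); Distant shifts
+0.05°/obstacle and +0.15°/on-screen drift section. Distances are truncated
to [0.2°, 12°] — well inside what the visible screen allows — and the
direction is drawn with a downward bias (toward where objects appear),
redrawing the angle, never the distance, if the point would leave the
visible region.

Within a fixation the fixated point scrolls with the world (0.18 px per
sample, an order of magnitude below the 1.25-px annotation bound), which
stands in for smooth pursuit; positional jitter is a random walk with
0.3-px steps clipped so no per-sample displacement reaches the bound. The
two eyes are the cyclopean trace ± half a 4-px vergence offset; each
fixation loses one eye's signal with probability 0.05. Saccades are linear
interpolations of at least 0.5° whose per-sample steps exceed 1.26 px.
Consequently, with zero jitter and no dropout the displacement-based
detector recovers the generated fixation onsets sample-exactly — the
round-trip test. Fixation durations are Normal(350, 100) ms truncated at
60 ms; durations and mixture weights are free parameters of the generator,
chosen as typical for fast visuomotor tasks, since no empirical
distribution is available to copy.

Judgments of control (1–7) come from a latent Gaussian — intercept 3.2 plus
effects of completion (+1.5), difficulty, noise level, drift/block
(invisible −0.69), fixation count (+1.2·10⁻³) and consecutive
crash→completions (+0.03), a participant intercept (sd 0.4) and residual
noise (sd 0.8) — rounded and clipped; they are generated and analyzed as
Gaussian, mirroring the untransformed treatment of this scale.

What the generator does *not* emulate: main-sequence saccade kinematics,
microsaccades, blinks beyond validity flags, oculomotor delays, or any
dependence of gaze on the agent's plan. Passing recovery tests therefore
shows the pipeline's statistical machinery is faithful and calibrated on
data that satisfy its assumptions — not that the assumptions hold for human
gaze.

## Event detection

The cyclopean position is the midpoint of both eyes, the single valid eye
when one signal is lost, and absent when both are lost. Fixations are
maximal runs in which every available eye travels ≤ 1.25 px (0.026°)
between consecutive samples for ≥ 25 samples; runs are never merged across
interruptions. Saccade verification computes per-eye, per-axis velocities
with a 5-sample centered window (the standard choice for this family of
algorithms), centers them on their median so steady pursuit scroll does not
masquerade as saccadic motion, and thresholds the elliptic criterion at
λ = 6 median-based standard deviations; candidates need ≥ 4 samples (2 ms)
and ≥ 0.5° total displacement, both gates applied conjunctively. Verified
saccade samples are excluded before the 25-sample fixation rule, so events
never overlap. All detection runs in screen pixels; conversion uses the
fixed equivalence 1.25 px = 0.026° (0.0208°/px), taken as authoritative.
The fixation onset frame is `floor(onset_t · 60)` relative to the first
control frame.

## Close/Distant split

Distances to the ship are divided by their standard deviation and clustered
with k = 2 using the quantile-based loss
`−log(θ_k(1−θ_k)) + ρ_θk(x − q_k)` per point, with θ_k estimated per
cluster by profile optimization and q_k the θ_k-quantile. The fit keeps the
best of b = 50 random initializations of the assign/update iteration, then
polishes with a contiguous-split search (exhaustive over all admissible
splits for n ≤ 2000, local hill-climb above). For 1-D two-cluster data the
optimum is a single split of the sorted values; the exhaustive search over
that family, shipped as `exhaustive_split`, is the normative definition of
correctness here, and the fit is required by test to agree with it. The
reported threshold is the midpoint of the boundary gap (strictly between
the cluster centers); a distance exactly at the threshold is Distant. The
5.70°/5.65°/5.00° boundaries reported for the human datasets are
data-dependent reference values, not targets.

## Measures

Distance to the ship is the Euclidean distance from the fixation onset
point to the fixed ship center (972, 288), in degrees. Distance to the
closest obstacle minimizes over centers of on-screen obstacles at the onset
frame and is missing when none is visible (such rows leave that model).
On-screen drift-section counts include invisible-type sections — the
covariate is defined by the environment, not the display — but exclude
sections that carry no force at all ("off"). Fixations beginning during the
entry phase or after the crash frame are excluded; training trials never
enter the tables. Consecutive crash→completions counts (crash at i,
completion at i+1) pairs over the strictly prior attempt history.

## Inference

Box–Cox profile likelihood selects λ̂, mapped to the nearest of identity
(λ≈1), square root (≈0.5), log (≈0), reciprocal (≈−1);
reciprocal-of-the-log is available as an explicit override. Nonpositive
values are nudged to half the smallest positive observation before
log-family transforms, with a logged note. Gaussian models are linear mixed
models fitted by maximum likelihood (statsmodels MixedLM); the Bernoulli
completion model is a variational-Bayes logistic mixed model with a
participant intercept, with z = posterior mean / posterior sd. Fixed
structures are never pruned; only the candidate random structures compete
by BIC, on a default ladder from an intercept to a slope on the main
manipulation (the full "maximal structure" candidate set is not enumerable
from the description and is left configurable). Ordered factors use
backward-difference ("successive difference") coding, each level against
the previous one. Significance is |z| ≥ 2; the suite checks that this rule
has ≈5% Type-I error on null cohorts. Parametric-bootstrap CIs simulate
responses from the fitted model (fixed effects + random-effect draws from
the estimated covariance + residual), refit, and report the 95%
highest-density interval of the coefficient draws; refit failures are
counted and >1% triggers a warning. Non-convergence is flagged on the
result, never silently replaced.

## Problem sizes

The shipped checks run at desk scale: oracle equivalence uses 10⁴
90-sample traces and clustering inputs up to n = 500; Type-I calibration
uses 200 null cohorts of 12 participants × 16 trials; bootstrap coverage
uses 25 outer null datasets × 1000-replicate bootstraps; sign recovery
uses 10 replicates of two 25-participant cohorts — the three short layouts
× 3 noise levels × drift on/off (18 configurations), and two short
8-drift-section layouts × 3 blocks × 2 complementary assignments (12
configurations). These sizes are the package's reference configuration for
a complete run on a single CPU; all of them are parameters, and the
recovery scenarios use the same generator defaults as a full-size cohort.

## Known limitations

* The Bernoulli mixed model is variational, so its z-scores and bootstrap
  are approximate in a different sense than the Gaussian ML fits.
* The k-quantiles hill-climb used above n = 2000 is exact in every tested
  case but carries no global-optimality proof for multimodal split-loss
  profiles.
* JoC values are ordinal but modeled as Gaussian throughout, by design.
* The generator's effect magnitudes are set on the identity scale of each
  mixture component; when a response transform is requested the shifts are
  rescaled by the local derivative at the component mean, which is exact
  only to first order.
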