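# Methods

This note records the models the package implements, the conventions and
defaults it adopts where the field leaves choices open, and what the
simulation-based tests do and do not demonstrate.

## Time, position and binning conventions

Timestamps are decimal seconds since an arbitrary epoch; positions are
local planar easting/northing in kilometres with y increasing north. Bins
are half-open `[start, start + 600 s)`, indexed from the follow start,
which is taken one bin length after tag deployment so immediate post-
tagging behavior is excluded. An event exactly on a boundary belongs to
the later bin. Bin boundary positions are linearly interpolated between
bracketing fixes (straight-line, constant-speed assumption); a boundary
outside the fix record marks the bin missing, and any bin with a missing
metric — always including each tag's first bin, which has no previous
course — is excluded from clustering.

Course is the bearing of net displacement, clockwise from north; with zero
net displacement the course is undefined, so the previous course is
carried and the deviation set to 0 (logged). Speed south is −Δy/Δt, so it
is negative during net northward movement and can never exceed speed in
magnitude.

## Dive segmentation

A deep dive is a maximal excursion with depth strictly > 10 m and duration
strictly > 75 s; everything else is surface time, so dives and surface
intervals partition the record exactly (testable tiling). Boundaries sit
at the linearly interpolated threshold crossings, making durations nearly
independent of sampling rate. "Surface" for the surface-proportion metric
means *not inside a deep dive* — the field definition ("successive shallow
dives with repeated surfacings") is descriptive, and the complement
definition is the one that makes the metric well defined. A dive is
counted in the bin containing its start; its duration is allocated pro
rata across the bins it spans when computing surface proportion.

## Behavioral states

The six metrics are centered and scaled to unit sample variance (centering
is adopted explicitly; it does not change k-means geometry). The cluster
count is a majority vote of four internal validity indices — silhouette,
Calinski–Harabasz, Davies–Bouldin, and the gap statistic with a uniform
bounding-box reference (B = 10) and the 1-SE rule — over k = 2…8, ties to
the smallest k, with every vote reported so disagreement stays visible.
This replaces the 30-index consensus tool used in the original field
analysis with a reproducible, dependency-free vote. All k-means runs use
Lloyd's algorithm with ≥ 25 seeded restarts and tolerance 1e-6; the same
restart policy is applied inside the index scan, because validity indices
computed on a poorly converged partition can vote for spurious k.

For k = 2 the cluster with the lower mean raw speed is resting/milling and
the other travelling, so labels are invariant to k-means' arbitrary
cluster indexing. For k ≠ 2 raw clusters are returned unlabelled.

Dive-parameter models are binomial (logit) random-intercept models, state
(travelling = 1) on the female's dive duration, mean depth and maximum
depth, fitted over all seven non-empty predictor subsets and ranked by
AIC.

## Mixed models

statsmodels provides no maximum-likelihood GLMM for binomial, negative-
binomial or gamma families, so `pairspace.glmm` implements the scalar
random-intercept case directly: the marginal likelihood integrates the
per-group normal intercept out with 32-node Gauss–Hermite quadrature
(accurate far beyond the Wald precision used for inference, and yielding
AICs comparable across fixed-effect sets). Optimization is L-BFGS-B from
moment-based starts at two initial variance values, followed by a
bounded Nelder–Mead polish — finite-difference gradients otherwise stall
~1e-3 from the optimum when the likelihood is flat in the variance
parameter. Standard errors come from the inverse observed information
(central finite differences); a dispersion or variance parameter pinned at
its bound spans a flat direction, so it is held fixed in the inversion
(its own Wald SE is reported as undefined) rather than allowed to corrupt
the fixed-effect covariance. Degenerate situations — all-zero counts,
complete separation, a variance at zero — are flagged on the results, not
raised.

The call-rate model uses the quadratic negative binomial,
Var = μ + μ²/θ (θ → ∞ recovers Poisson; θ is log-parameterized and capped
at e¹⁵, effectively Poisson), a log link, a log offset of exposure in
decimal hours — so estimates are rates and are exactly invariant to the
time unit — and a random intercept per tag. Counts are modelled per
10-min bin, not aggregated per follow, keeping the random effect
meaningful. Calf rates carry an `is_minimum` flag: the tag sits on the
female, and distant calf calls can be missed.

The received-level model is a Gaussian mixed model fitted by REML
(statsmodels `MixedLM`), adult-female calls only — calf received levels
confound source level with the unknown mother–calf range. Inference uses
Wald z for the GLMM contrasts and a t reference with `n_groups − 1`
degrees of freedom for the Gaussian and gamma models, a deliberately
simple small-sample convention adopted in place of unavailable
Satterthwaite machinery. Least-squares means are the model means per state
with other terms at reference values; pairwise contrasts are adjusted by
the multivariate-t equicoordinate probability of the joint contrast
distribution (a tiny ridge keeps the rank-deficient >2-level case well
posed); with a single contrast the adjustment is exactly the identity.

## Active space

Broadband noise is the power sum of third-octave band levels within
40 Hz–2.5 kHz. A call is matched to the most recent noise sample at or
before it within 600 s (the sampling cadence); otherwise it is excluded
from the active-space analysis with a logged reason. The transmission-loss
model is `TL = a + b·log10(x)` per octave band with slopes `b_near`/`b_far`
around a crossover distance; log is base-10 (the dB-per-decade convention
in underwater acoustics) and the two pieces are constrained continuous at
the crossover — without continuity the detection distance would not be
unique. A band without a slope change is expressed as crossover = ∞.
Detection distance inverts TL in closed form on whichever piece contains
the solution; when the SNR budget cannot exceed TL even at the 1 m
reference distance, the estimate is floored at 1 m and flagged rather than
dropped (floored estimates are excluded from the state model by default).
Depth-dependent propagation is not modelled; calls produced above 10 m are
flagged `near_surface` because surface interference (Lloyd mirror) makes
their distances overestimates. The (received level × noise) surface is a
descriptive grid of cell medians for plotting — no spatial smoothing is
fitted.

## Synthetic data

The generator reproduces the structure the analysis assumes, at the
study's design scale: 15 follows of 2–23 bins; a two-state Markov chain
with transition probabilities 0.30 (rest→travel) and 0.16 (travel→rest),
stationary ≈ 35% resting; per-state speeds 1.7 ± 0.7 vs 4.6 ± 0.7 km/h;
heading increments of SD 120° (resting) vs 26° with mean-reversion toward
due south (travelling), chosen so simulated course deviations average near
91° vs 21°; ESB counts Poisson 0.30/0.21 per bin; dive durations 414 ± 90 s
vs 262 ± 50 s with surface gaps tuned to ≈ 0.83 vs ≈ 1.79 dives per bin;
call rates 4.6 vs 1.6 (female) / 1.9 (calf) calls/h; received levels
148 ± 9 dB (female, truncated to 124–172) and 140 ± 9 dB (calf, 124–173)
re 1 µPa; peak-frequency octave modes 125 Hz resting vs 500 Hz travelling;
and wind noise as a reflected random walk within 94–104 dB re 1 µPa
emitted as a wind-shaped third-octave spectrum. Within-state SDs are not
published as such, so they are generator defaults chosen once for
realistic overlap between states. The planted dive duration is defined as
time below the 10 m threshold — the quantity the segmenter measures — with
short entry/exit ramps charged to the surface interval. Dives keep their
full duration across bin and state boundaries; only a dive that would
overrun the record end is replaced by surface time.

The depth series is 1 Hz, positions come from integrating per-bin
speed/heading with fixes every ~5 min plus 20 m jitter, and everything
derives from one seeded generator, so a seed fixes the dataset
byte-for-byte.

The generator does **not** emulate: measurement error structure of
theodolite fixes, tidal currents, within-dive kinematics beyond a
trapezoidal profile, call-type structure or waveforms, vessel noise, or
any female–calf separation process (the calf's own depth record is not
generated). Passing recovery tests therefore shows the pipeline's
estimators are consistent and calibrated under the assumed data-generating
process, not that the field data satisfy those assumptions.

Because the site's measured per-band TL regression table is not
redistributable, the package ships a synthetic stand-in
(`synthetic_tl_bands`): intercepts of 1–4 dB, near slopes 17–18 dB/decade,
far slopes 22–30 dB/decade growing with frequency, crossovers at 1 km —
values picked once to yield detection distances from roughly ten metres to
a few kilometres with a median near 0.5 km at the simulated signal and
noise levels. Real analyses should supply measured coefficients via
`tl_bands.csv`.

## Numerical choices and test scales

Zero-displacement bins carry the previous course (logged). Standardization
uses the sample SD (ddof = 1) and refuses constant columns by name.
Detection-distance inversion is verified by forward evaluation to 1e-6 dB;
TL continuity to 1e-9 dB; dive/surface tiling to 1e-6 s. Simulation-based
checks run at the study's design scale where that is cheap (15 follows for
state recovery, 20 seeds; 15 groups × ~10 bins × 200 replicates for
rate-contrast recovery; 200 replicates for the null calibration of the
level and distance models) and at reduced replicate counts for the
heavier dive-model examples (20–40 replicates), sizes chosen to keep the
default suite in the low minutes on one CPU.

## Known limitations

- One scalar random intercept per model; no crossed or nested effects.
- Wald/t inference, no parametric bootstrap or Kenward–Roger corrections;
  with 15 groups the null tests run slightly conservative (~2–3% empirical
  size at nominal 5%).
- The SNR = 0 audibility criterion ignores hearing thresholds, critical
  ratios and directivity; detection distances are upper-bound style
  estimates, further biased upward for near-surface calls.
- k labelling is defined only for k = 2; other k values return unlabelled
  clusters by design.
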