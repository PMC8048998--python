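# Methods

`nestcam` estimates seabird breeding success from time-lapse camera imagery
that has already been annotated: nest locations on a reference frame, and
chick locations per image. This note documents the statistical model, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## From annotations to count series

Nest seeds induce a Voronoi partition of the camera frame (pixel
coordinates, origin top-left, y down): every pixel belongs to the nearest
seed. Zones are computed once per site/year — camera positions are fixed —
by bounding the tessellation with a distant ghost-point ring and clipping
cells to the frame, so zone areas always sum to the frame area. Chick
detections are assigned by nearest seed (equivalent to zone membership);
a point equidistant between seeds goes to the lower nest id, which makes
assignment deterministic. Because clutches hold at most two eggs, a zone
count above two is capped at two and logged; such counts arise from
annotation noise or crèching neighbors wandering through a zone.

Hourly counts collapse to a daily maximum (the highest count seen in any
image that day), which is robust to chicks being temporarily brooded out of
view. The 60-day model timeline is anchored at the extrapolated lay date,
crèche date minus 60 days; model day *t* is the calendar date `lay + t`
days, so the crèche date is exactly *t* = 60. Days before the first chick
sighting are missing by construction: egg contents are not scored from
images.

## State-space survival model

Each nest *i* in site/year *(j,k)* starts with two eggs. The latent count
of survivors and the observed count are

    z[1]   = 2
    z[t]   | z[t-1] ~ Binomial(z[t-1], phi_jk)        t = 2..60
    y[t]   | z[t]   ~ Binomial(z[t], p_{t,i})          observed days only

    logit(phi_jk)  = mu_phi_jk,  mu_phi_jk ~ N(theta_phi, sigma_mu_phi)
    logit(p_{t,i}) = mu_p + nu_i + beta_jk * x_t

with `x_t = (t-1)/59` in [0, 1]. A single daily survival probability per
site/year spans egg and chick stages; detection varies over time (chicks
become more visible as they grow — a logistic curve in probability space),
across nests (camera angle, occlusion by the nest's own geometry), and
across site/years. The two chicks of a clutch are exchangeable in an
image, hence the binomial rather than per-chick Bernoulli formulation.
Nests that never show a chick stay in the likelihood; their observed zeros
pull survival downward, which avoids the upward bias of conditioning on
success.

Missing days simply contribute no observation factor. Failure and
detection are confounded day-by-day but separate over the series: repeated
zeros after a sighting are far more likely under death than under repeated
non-detection once `p` is informed by the rest of the data.

### Priors

Hyperparameters take weakly-informative defaults:
Normal(0, 1.5²) on `theta_phi`, `mu_p`, `mu_beta_p`; half-Normal(0, 1) on
`sigma_mu_phi`, `sigma_beta_p`, `sigma_nu_p`. All are configurable and
echoed in every fit report. Note that a Normal(0, 1.5²) prior on logit
daily survival is informative in an awkward place for long-lived eggs
(logit 0.995 ≈ 5.3 sits three prior sd from the mode); with very few
site/years it shrinks the grand mean visibly. This is retained as the
default for comparability; widen `theta_phi_sd` for small studies if
shrinkage matters.

### Inference

The discrete latent states are marginalized exactly: per nest, a scaled
forward recursion over the three states {0, 1, 2} computes the marginal
likelihood in O(T) (numba kernel, ~50 µs for 60 nests × 60 days). Sampling
is adaptive Metropolis-within-Gibbs over the continuous parameters:

- site/year survival means and detection slopes: per-group random-walk
  proposals, accepted independently per group (nests are conditionally
  independent), step sizes adapted toward 44% acceptance during warmup;
- hierarchy means `theta_phi`, `mu_beta_p`: conjugate normal draws;
- hierarchy scales: log-scale random walks, plus
  ancillarity–sufficiency interweaving (ASIS) updates that re-propose each
  (mean, scale) pair in the non-centered parameterization — this removes
  the funnel that otherwise cripples mixing with 3–6 groups;
- nest offsets `nu`: one vectorized proposal per sweep, accepted per nest;
- the flat ridge between the detection intercept and the offsets/slopes is
  crossed with dedicated shift moves (`mu_p + d, nu - d` is likelihood-
  invariant and judged on priors alone; `mu_p + d, beta - d` pins the
  season-end detection level). The detection-mean block runs twice per
  sweep because it remains the slowest direction.

Desk-scale default: 4 chains × (2,000 warmup + 3,500 samples), thin 1 —
about 40 s for 3 site/years × 20 nests on one core, reaching split-Rhat
< 1.1 and ESS/chain > 100 on all monitored parameters. A `paper` preset
(6 chains, 400,000 warmup, 400,000 samples, thin 100) is provided for
full-scale replication runs. Convergence failure warns (with diagnostics
attached) and never silently passes or errors.

### Derived quantities

Latent trajectories are recovered by forward-filtering backward-sampling
(FFBS) conditional on each stored parameter draw; the colony total
`Z_t = sum_i z[t,i]` and breeding success `BS = Z_60 / n_nests` are
computed per draw, so their posterior spread propagates both parameter and
state uncertainty. `Z_1` is exactly twice the nest count with zero
variance, by the two-egg assumption. Posterior predictive checks simulate
fresh datasets from parameter draws on the observed-day mask; the default
discrepancy is the total observed count (per-day totals and the count of
nonzero nest-days are also available), with the Bayesian p-value
P(T_rep ≥ T_obs).

## Season phases

The 60-day timeline splits into egg (days 1–30), young-chick (31–45) and
old-chick (46–60) phases, with shared boundary days so that
`30·egg + 15·young + 15·old = Z_1 − Z_60` exactly. Rates use the
posterior-mean trajectory by default; a per-draw variant exists because
the choice is genuinely open. Differences across phases over matched
site/years are tested with a self-contained Friedman test using the
general midrank form `Q = (k−1)·Σ(R_j − n(k+1)/2)² / Σ(r_ij − (k+1)/2)²`,
which equals the classical statistic without ties, applies the tie
correction automatically, and returns Q = 0, p = 1 for all-constant
blocks. P-values use the chi-square reference with k−1 df; simulation at
n = 28 blocks puts the realized type-I error at 0.050.

## Drivers

- **Precipitation**: events scored R1–R3 / S1–S3; the covariate is the
  count of events at magnitude ≥ 2, rain and snow pooled, one score per
  causative event.
- **Krill catch**: monthly catches per management-unit polygon are
  area-weighted by the fraction of a 150-km geodesic buffer each unit
  covers, and summed March (year t−1) through January (year t) — 11
  calendar months covering winter carry-over and the breeding season.
  Buffers use a spherical Lambert azimuthal equal-area projection centered
  on the site (a circle about the projection center is the exact geodesic
  disc and areas are preserved; mean Earth radius 6371.0088 km), with all
  polygon algebra in shapely. Weights are fractions of total buffer area,
  so they sum to ≤ 1 and to 1 when units tile the buffer; uncovered area
  contributes zero catch (a site with no overlap gets 0 with a warning).
  The covariate enters as log(catch); zero catches receive an offset of
  half the smallest positive catch, recorded in the output metadata (only
  an all-zero table is an error).
- **Tourism**: visitors summed from lay date to crèche date, both ends
  inclusive.

Each driver is fit in its own univariate errors-in-variables regression

    bs_obs_i  ~ N(bs_true_i, sigma_bs_i)     sigma_bs_i known
    bs_true_i ~ N(alpha + beta x_i, sigma)

where `bs_obs_i`/`sigma_bs_i` are the posterior mean/sd of breeding
success. Covariates are not standardized by default (slopes stay on raw
scales); an option exists. Priors: Normal(0, 10²) on alpha, beta;
half-Normal(0, 1) on sigma. The Gibbs sampler uses conjugate normal draws
for `bs_true` and (alpha, beta) and a stepping-out slice sampler on
log sigma; `sigma_bs = 0` pins the latent value to the observation, and a
`sigma_fixed` option turns the model into exact conjugate Bayesian linear
regression (used as a cross-check). Summaries report the posterior median
slope with a central 95% interval.

## Synthetic data

The generator mirrors the model exactly — two-egg clutches, binomial
survival with site/year rates drawn from the logit-normal hierarchy,
logistic-in-time detection with nest offsets, observation window opening
at a fixed hatch day — plus a few study-shaped conveniences: defaults of
14 sites × 2 seasons × 20 nests, hatch at day 31 (consistent with a
30-day egg period), grand-mean survival logit(0.995) (≈1.5 chicks per pair
at crèche) with between-site/year sd 0.6 (spanning roughly 0.6–1.9), an
optional per-day camera-outage probability, and an extreme-event injector
that crashes one day's survival and logs a magnitude-3 snow event. The
injector replays the generator's RNG stream, so a zero-size event
reproduces the original dataset draw for draw.

What it does not emulate: annotation error in nest seeds or chick points,
within-day detection structure (images are collapsed to daily maxima
before the model ever sees them), re-laying after early failure, chicks
crossing zone boundaries near crèche, drift in camera pointing, or any
dependence of survival on covariates (driver tables with known effects are
generated separately, at the breeding-success level). Passing
parameter-recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
the ways real imagery violates them.

## Numerical notes and limitations

- Forward recursions rescale per step; an impossible observation path
  returns log-likelihood −inf rather than underflowing.
- Boundary ties in zone assignment and the phase-boundary convention are
  fixed, documented choices; results do not depend on run order.
- All randomness fans out from one seed through named `SeedSequence`
  spawns; pipeline re-runs are byte-identical apart from wall-clock fields
  in the fit report.
- Single survival probability per site/year: intra-seasonal hazard changes
  show up only through the derived Z trajectory, not through stage-specific
  parameters. Egg losses and chick losses are not mechanistically
  distinguished.
- The detection curve is monotone in time by construction; a mid-season
  visibility dip (e.g., persistent snow on the lens) is absorbed into
  missingness, not modeled.
- The chi-square Friedman reference is approximate for very few blocks;
  with n < 10 site/years prefer the permutation comparison used in the
  test suite.
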