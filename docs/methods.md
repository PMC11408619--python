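# Methods

`riboforce` analyses single-molecule magnetic force spectroscopy (MFS)
recordings of a bead-tethered riboswitch aptamer and fits the bulk
dose-response curves that accompany such experiments.  This note documents
the models, the tunable parameters, the synthetic-data generator used for
validation, and the numerical choices made where the design was open.

## Physical model

The aptamer is treated as a two-state system — folded and unfolded —
whose transition rates depend exponentially on the applied force
(Bell/Kramers):

    k_unfold(F) = k_u0 · exp(+F·x_u / kBT) · s(c)
    k_refold(F) = k_f0 · exp(−F·x_f / kBT) · g(c)

with `x_u`, `x_f` the distances to the transition state (nm), `kBT = 4.07
pN·nm` (22 °C), and `s(c)`, `g(c)` concentration-dependent ligand factors.
Unfolding adds `ΔL` nm of extension (drawn per molecule from U[12, 22] nm in
cohort simulations; the analyzable window is 10–25 nm).  Measured extension
is `baseline + 0.2 nm/pN · F + ΔL·[unfolded] + N(0, σ²)`; the linear
compliance term is the simplest tether model that preserves jump sizes,
which is all the analysis consumes.

Two ligand mechanisms are modelled:

- **Kinetic stabilizer** (synthetic-ligand-like).  One folded state; the
  ligand slows unfolding, `s(c) = 1/(1 + (S−1)·θ)` with occupancy
  `θ = c/(c+K_D)` and maximal slow-down factor `S` (default 2), and
  optionally speeds refolding, `g(c) = 1 + (G−1)·θ`.  Signature: the single
  rupture-force peak shifts up with concentration; constant-force unfolding
  slows only once `θ` is appreciable (c ≳ K_D/4).
- **Pseudoknot inducer** (cognate-ligand-like).  Each refolding event
  commits the molecule to a much more stable pseudoknot state with
  probability `θ`; that state unfolds with its own Bell parameters.
  Signature: a second rupture-force peak at high force whose weight grows
  with concentration while the first peak stays put, and a second (long)
  lifetime component in the folded dwell distribution whose weight is the
  pseudoknot occupancy.

The default control parameter set (`k_u0 = 1.3e-3 /s`, `x_u = 3 nm`,
`k_f0 = 8 /s`, `x_f = 2 nm`) was derived in closed form from the ramp
survival integral so that the median control rupture force sits near 9 pN
— inside the 5–15 pN selection window — for the default 1→25 pN, 2 pN/s
ramp, and so that the two-state equilibrium force is ~7 pN for
constant-force work.  Pseudoknot parameters (`6.7e-4 /s`, `1.5 nm`) place
the second peak near 18 pN, within the ramp range.

### Planting a half-effect concentration

In stabilizer mode the measurable effect is the log-rate (equivalently
rupture-force) shift `∝ ln(1 + (S−1)θ)`, which reaches half its saturating
value at `c = K_D/√S`.  `kd_for_half_effect(c_half, S)` inverts this
(`K_D = √S·c_half`) so that recovery studies can plant an EC50 exactly,
before any fitting is run.

## Simulation scheme

Force ramps are discretized at the sampling rate (30 Hz) with per-sample
transition probability `1 − exp(−k(F)·Δt)`.  A resolution guard raises an
error when `k·Δt > 0.5` at any force the departing state still occupies
with probability > 1e-3 under the ramp hazard; rates at forces the state
never survives to are irrelevant to every statistic computed downstream
(the deepest tail used anywhere is the control 95th percentile) and are not
held against the time step.  Near the median rupture force `k·Δt ≈ 0.03`,
so discretization error is far below the sampling resolution.

Constant-force recordings sample dwells exactly (exponential waiting
times, Gillespie) and then emit the state path at 30 Hz with Gaussian
noise.  Cohort helpers add per-molecule heterogeneity: unfolding size
U[12, 22] nm and a 5%-scale force-calibration factor shared across a
molecule's conditions, which is what per-bead control normalization is
meant to cancel.

### What the generator does not emulate

No worm-like-chain elasticity, bead rotation, camera blur, drift, or
correlated (non-white) tracking noise.  Passing tests therefore demonstrate
the correctness and statistical calibration of the analysis under the
stated two-state Bell model with white Gaussian noise — not robustness to
every instrumental artifact of real recordings (the Brownian-noise QC and
window-range screens address the grossest of those).

## Ramp analysis

- **QC**: in 1-s windows at the top 20% of the force range, detrended
  extension variance is compared with the tethered-bead expectation
  `kBT·L/F`; a trace passes if a majority of windows fall within a factor
  2.
- **Cycle segmentation**: minima/maxima of the median-filtered (1 s) force,
  refined to the raw-force extremum to sample accuracy.
- **Event detection** (production path): per ramp phase, HDBSCAN
  (min cluster size 10) on the (force, extension) points; clusters ordered
  by force; for each adjacent pair the event sample is the best time-axis
  split of the two memberships, the event size the offset between the two
  clusters' linear force-extension trends at that force (minimum 5 nm).
  One unfold and one refold per cycle by default (largest jump); a
  multi-event mode reports all jumps.
- **Changepoint oracle** (validation path): exhaustive least-squares
  segmentation with per-segment linear trends, greedy up to a BIC stop; in
  single-event mode the best single split is reported, which expresses the
  same "dominant transition" a two-cluster boundary does.  The two methods
  are algorithmically independent; their ≥95% agreement (0.5 pN / 2 nm) on
  simulated noisy cycles is a standing acceptance check.
- **Selection filter** (control condition): median unfolding force in
  5–15 pN, median size in 10–25 nm, > 20 analyzable cycles, unfolding in
  > 80% of cycles (strict), present in > half the conditions.
- **Normalization**: forces divided by the bead's control medians
  (division, not subtraction — normalized control distributions center at
  1), cancelling bead-to-bead force-calibration error.
- **High-force fraction**: threshold at the 95th percentile
  (linear-interpolation convention) of control normalized unfolding
  forces; cycles above threshold *or with no unfolding at all* count as
  high-force.  No-unfold cycles also stay in the denominator of the
  unfold-proportion filter.
- **Dose response**: per concentration, the pooled *median* of normalized
  rupture forces across selected molecules, with a bead-level bootstrap SE
  (200 resamples) weighting the saturation fit
  `y = (u + b·x/K_D)/(1 + x/K_D)` (multistart over a decade grid of K_D).
  The median was chosen over the KDE-peak-median because the two estimate
  the same location for a unimodal distribution and the median has roughly
  half the sampling variance (verified against planted EC50s);
  `peak_median` (Gaussian KDE, Silverman bandwidth, median within ±1
  bandwidth of the dominant mode) remains available and is the right tool
  when a second high-force mode could contaminate a pooled median.  The
  weighted fit matters because the c = 0 response is pinned near 1 by
  construction and should anchor `u`.

## Constant-force analysis

- **Noise screen**: 1-s sliding-window peak-to-peak range (on a 5-sample
  median-filtered copy, so the screen responds to real excursions rather
  than Gaussian tails) must not exceed 2× the expected structure length;
  traces that never transition, or never fold under pseudoknot-inducer
  conditions, are excluded.  Rare-level detection uses extreme (0.1/99.9)
  percentiles so a molecule that folds 0.3% of the time is recognized as
  "never folds" rather than "no transitions".
- **State assignment**: the "simple heuristic HMM" is concretized as a
  fixed-level two-state Viterbi decoder: emission levels from the two
  dominant modes of the smoothed extension histogram (≥5 nm apart), shared
  Gaussian width from a robust MAD estimate, symmetric switching prior
  0.01/sample.  Runs shorter than 2 samples (unresolvable at 30 Hz) are
  merged.  Deterministic by construction.
- **Dwells**: run-length encoding; first and last segments censored.
  Censored dwells are dropped from likelihoods (the bias is negligible when
  traces contain ≫10 dwells; a censoring-aware likelihood was judged not
  worth its complexity here and is a known limitation).
- **Lifetime mixtures**: EM for 1–3 exponential components, 20 seeded
  restarts run in parallel, convergence at 1e-8 relative log-likelihood
  (BIC differences are O(1), so this tolerance is conservative);
  `BIC = −2·loglik + (2k−1)·ln n` (k lifetimes + k−1 weights); k = 1 is the
  closed form (lifetime = sample mean).
- **Aggregation**: per molecule and condition, `log(1/mean lifetime)` for
  each state; for pseudoknot-inducer conditions the BIC-selected mixture
  replaces the pooled mean, reporting the short component as the
  pre-pseudoknot rate, the long component separately, and its weight as
  pseudoknot occupancy.  A component counts as "long" when its lifetime
  exceeds 3× the control lifetime — this keeps the occupancy correct at
  saturating ligand, where BIC rightly selects a single (purely long)
  exponential.  Rates are normalized per molecule against its control
  (log-rate differences), then averaged across molecules (mean ± SD):
  molecules, not dwells, are the exchangeable unit.

## Bulk dose-response fits

Three hyperbolic models (see `dose_response`): the MFS saturation curve,
one-site total binding `B_max·x/(K_D+x) + ns·x + bg` (nonspecific slope
free by default, constrainable to zero), and termination efficiency
`e_min + (e_max−e_min)·x/(T_50+x)` (either sign of `e_max − e_min`).
All fits are multistart least squares with Jacobian-based standard errors;
`fit_t50` adds a seeded residual-bootstrap SE.  Flags: `non_identifiable`
(flat saturation curve, |b−u| < 2·SE), `not_saturated` (half-saturation
beyond the tested range).  Termination efficiency per gel lane is
`T/(T+RT)`.

## Recovery-study conditions

The acceptance script and tests plant literature-scale parameters and
recover them from scratch: force-shift EC50s of 394 µM (unfolding) and
456 µM (refolding) through cohorts of 20 molecules × 50 cycles × 12
concentrations (0 and 25–6400 µM, log-spaced); termination T_50s of 11.1
and 6.8 µM from 8-concentration × 3-replicate gel tables with 5%
multiplicative noise; binding K_Ds of 21.9 and 29.0 µM from 0–250 µM
titrations with 2% replicate noise (typical for cuvette fluorescence, and
matching the ~10% K_D precision such fits report).  With these cohort
sizes the EC50 recovery has an intrinsic sampling CV of roughly 25%
(rupture-force distributions are ~1.7 pN wide for ~1000 events per
concentration), so recovered EC50s scatter accordingly; the T_50 and K_D
recoveries are precise to ~10%.

## Known limitations

- Dwell lifetimes estimated from decoded state paths carry a small upward
  bias (~10–15% at lifetime ≈ 4 s, 30 Hz) from unresolved fast excursions
  merged by the 2-sample minimum dwell; the bias is common to numerator
  and denominator of the control-normalized log-rates and largely cancels
  there.
- The changepoint oracle's jump-size estimate degrades in phases with
  multiple flickers (its segments mix states); the cluster method's sizes
  are the more accurate ones in that regime.
- The equilibrium-force procedure for stepped protocols is reported only
  as the force of nearest 50/50 occupancy; no interpolation model is fit.
- Three-state hidden-path inference is out of scope: pseudoknot and
  pre-pseudoknot folded states are distinguished only through the dwell
  mixture, not per sample.
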