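# Methods

`blinkcount` counts fluorophores in diffraction-limited regions of
interest (ROIs) and reconstructs each fluorophore's photophysical
trajectory from a single brightness-versus-time trace. This note records
the model, the sampler, the synthetic benchmark, and the numerical and
design choices a maintainer would want to know.

## Forward model

Each of the `K_r` fluorophores in ROI `r` occupies one photo-state per
frame: dark (`σ_D`, recoverable, non-emitting), one or two active states
(`σ_A1`, `σ_A2`, emitting `μ_A1`, `μ_A2` expected photons per frame), and
an absorbing photobleached state (`σ_B`). Trajectories are Markov:

    s_1 ~ Categorical(π0),   s_n | s_{n-1} ~ Categorical(π_{s_{n-1}})

with transitions restricted to dark↔dark, dark↔bright, bright↔bright,
bright→bleached and bleached→bleached; a dark fluorophore can never
bleach directly. The ROI's expected photon count for frame `n` is the
background plus the bright-state brightnesses of the currently active
fluorophores,

    μ_n^r = μ_B^r + Σ_k μ(s_n^{k,r}),

and an EMCCD camera with gain `G` (ADU per photon-equivalent) reports

    w_n^r | μ_n^r ~ Gamma(shape = μ_n^r / 2, scale = 2G),

so the readout has mean `μ_n^r·G` and variance `2·μ_n^r·G²` — the
electron-multiplication excess noise factor of 2. Because this gamma is
closed under addition at a common `2G`, summing ROI traces yields a
valid trace for the pooled ROI, which is how high-count control data are
constructed.

## Inverse model

The number of fluorophores per ROI is unknown, so the model carries
`K ≫ K_r` *model* fluorophores per ROI, each with a binary load

    b^{k,r} ~ Bernoulli( γ / (K + γ − 1) ),

the weak-limit truncation of a Beta-Bernoulli process: for large `K`
inference is insensitive to `K`, and the count is `B_r = Σ_k b^{k,r}`.
Only loaded fluorophores contribute brightness. Because illumination is
long enough that every real fluorophore photobleaches, the final frame of
every trajectory is fixed at `σ_B` — treated as an observation, applied
to loaded and virtual fluorophores alike (virtual trajectories never
touch the likelihood, so this only simplifies the kernel).

Priors: Dirichlet(1) on each transition-matrix row restricted to its
allowed support (forbidden transitions are structural zeros, not small
numbers); Dirichlet(1) on π0 over non-bleached states; Gamma(shape 2,
scale init/2) on each brightness, centring the prior on the data-driven
initialisation with ~70% coefficient of variation.

## Gibbs sampler

Each sweep updates three blocks.

**States and loads.** Loads are visited in groups of `J = 2`, paired
uniformly at random each sweep (a random-scan partition — fixed pairs
leave split/merged configurations metastable for ~K/2 sweeps because two
specific chains only interact when grouped together). Within a group the
load configuration and both trajectories are drawn *exactly* from their
full conditional: the load is constant over the trace, so the sampler
filters over photo-states for each of the `2^J` load configurations
(`S`-state filter for one-on, `S²`-state factorised filter for both-on,
a flat-emission prior filter for off chains), samples the configuration
from the resulting marginal likelihoods times the Bernoulli prior, and
backward-samples trajectories from the matching filter. Cost is
`O(S^J N)` per group, `O(S^J N R K / J)` per sweep. ROIs are independent
and may run in worker threads; every ROI consumes only its own pre-drawn
uniforms, so threaded and sequential runs are bit-identical.

**Kinetics.** Conjugate Dirichlet draws of π rows and π0 from transition
and initial-state counts pooled over loaded fluorophores in all ROIs.
The absorbing row stays `(0, …, 0, 1)` exactly.

**Brightnesses.** The gamma emission is not conjugate in `μ`, so `μ_A`
(each bright state) and `μ_B^r` (each ROI) take log-normal random-walk
Metropolis steps with the log-normal Jacobian in the acceptance ratio.
Proposal scales adapt toward ~30% acceptance during burn-in
(Robbins-Monro on the log step) and freeze at retention, so retained
draws come from a fixed kernel. Without adaptation the `μ_A` chain has
near-zero acceptance at realistic data sizes and its random-walk bias
leaks into the counts.

**Numerics.** Filtering uses per-frame max-subtraction on the
log-emission levels followed by scaled linear-domain recursion with
per-frame normalisation and accumulated log-normalisers — the same
underflow guard as log-space filtering at a fraction of the cost. The
emission log-density drops per-frame constants (they cancel in the
shift); `lgamma(μ/2)` values are cached on the lattice of bright-state
occupancy counts, which is what makes a sweep affordable. Readouts of
zero ADU (possible in integer-quantised data) are clamped to 0.5 ADU
before likelihood evaluation, since the gamma support is `(0, ∞)`.
Backward sampling inverts cumulative sums over a fixed state order.
A frame at which every load configuration has zero filter mass raises a
diagnostic error naming the frame; a non-finite log-posterior aborts the
run with the last-good state attached.

**Initialisation.** Backgrounds come from the trailing 5% of frames. The
single-fluorophore brightness unit is the median magnitude of
significant downward steps (4× the local shot-noise level) in a smoothed
trace, pooled across ROIs, using the shortest smoothing lag (5, 12, then
25 frames) that finds at least two steps — longer lags merge consecutive
bleaches into double-height steps, and per-ROI medians are too noisy on
small data. All loads start on; a ruler-style count guess determines how
many chains start bright-until-apparent-bleach, the rest idle in the
dark with a minimal valid path to bleaching. Misinitialising the unit by
~2× is the one reliable way to trap the chain in a wrong mode (many dim
fluorophores), which is why the step detector earns its complexity.

## Synthetic benchmark

`make_benchmark` replicates the validation conditions: each ROI draws a
true count from Binomial(20 sites, 0.7 labelling efficiency), two bright
states at 450 and 350 photons/frame, background 1000 photons/frame, gain
50, 50 ms frames. Defaults are the published full-scale trace length
(N = 20000, R = 50); the reduced configuration used by the acceptance
checks is R = 10, N = 2000 — chosen as the package's single-CPU test
scale.

Kinetic rates are not published, so the defaults are declared: per-frame
bleach rate `20/N` (expected photo-lifetime ≈ N/10 frames counting dark
excursions, so bleaching always completes in-trace), bright→dark twice
the bleach rate, dark→bright twice the bleach rate (dark dwell ≈ N/40
frames, stationary dark fraction 1/2 among unbleached dyes), and
bright↔bright interconversion twice the bleach rate. The dark dwell is
deliberately long relative to the 10-frame ruler window: dyes of this
class spend a large share of their pre-bleach life dark, and it is what
makes a calibration ruler miss initially-dark fluorophores by more than
their 40% starting fraction in the dark-start regime. Two scenario knobs
mirror the comparison regimes: `dark_start_fraction` (fraction of
fluorophores whose trajectory begins dark) and `noise_scale` ν, which
maps μ → μ/ν and G → G·ν, holding the mean ADU level fixed while
inflating relative shot noise.

What the generator does *not* emulate: drifting baselines, diffusing
unbound fluorophores, detector models other than the EMCCD gamma (sCMOS,
PMT), pixel-level imaging, and ROI detection. Passing tests therefore
demonstrate correctness of the inference given the stated forward model,
not robustness to those real-data artifacts.

## Baselines

The **two-state model** is the identical Gibbs engine on a
bright/bleached space with forced bright start — classical step counting
with population bookkeeping. It matches the full model when the data are
blink-free, undercounts strongly when dyes blink or start dark, and
becomes competitive again in the high-noise regime where blink dips hide
inside the readout variance. The **ruler** divides the
background-subtracted mean of the first 10 frames by a one-fluorophore
unit (`μ_A·G`; with two bright states, the π0-weighted initial-state
expectation). On simulated data it is given the true calibration, so its
failures are structural (initially-dark dyes, early blinking), not
calibration error.

## Posterior summaries

Per-ROI point estimates are the posterior mean of the integer count
draws (the MAP mode is also reported); intervals are central 95%
quantile intervals. Two pooled histograms are emitted, since either
reading of "histogram the counts over ROIs" may be wanted: pooling every
posterior draw (the inference-widened marginal) and histogramming the
per-ROI point estimates. Trace overlays reconstruct `μ_n^r` from the
highest-log-posterior retained draw by default.

## Known limitations

- At the reduced scale the posterior carries a small (~0.1–1% of draws)
  overcount tail: a transient load bright for a few crowded early frames
  then bleaching costs only a few nats when the per-frame bleach
  probability is ~0.01. At the published scale (N = 20000, bleach
  probability ~0.001) the same configuration costs ~2.3 nats more, which
  is why "no draw more than 2 off" holds there but occasionally reads 3
  here.
- Counts of fluorophores that bleach within the first handful of frames
  are genuinely unidentifiable and are absorbed into the posterior's
  ±1 uncertainty.
- γ (the Beta-Bernoulli concentration, default 10) acts as a prior
  expected count; values far below the true count bias counts downward
  in regimes where loads are weakly identified (e.g. many dark starts).
- `G` and γ are fixed inputs, never inferred; multi-chain convergence
  diagnostics are left to standard post-processing of the stored draws.
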