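# blinkcount

Bayesian nonparametric counting of fluorophores in diffraction-limited
spots, from a single brightness-versus-time trace per region of interest
(ROI).

Step counting by photobleaching is the standard way to ask "how many
labelled molecules sit inside this spot?", but classical step counters
assume every fluorophore starts bright and switches off exactly once.
Real dyes blink — they visit reversible dark states — and in
photoactivation-style experiments many start dark, so step counters and
brightness "rulers" systematically undercount. `blinkcount` instead
treats the trace as the output of a factorial hidden Markov model: each
fluorophore runs its own Markov photo-state trajectory over
{dark, bright (one or two states), photobleached}, the ROI brightness is
the summed emission of the currently active fluorophores plus
background, and an EMCCD camera reads it out through a gamma noise model

    w_n ~ Gamma(mu_n / 2, 2G),    mu_n = mu_B + sum_k b_k mu(s_n_k),

with mean `mu_n G` ADU and variance `2 mu_n G^2` (excess noise factor 2).
Because the number of fluorophores is unknown, each ROI carries K model
fluorophores gated by binary loads with the weak-limit Beta-Bernoulli
prior `b ~ Bernoulli(gamma / (K + gamma - 1))`; the count is the number
of active loads, and inference is insensitive to K once it is large.
Posteriors over loads, trajectories, transition probabilities `pi`,
initial-state probabilities `pi0`, and brightnesses `mu_A`, `mu_B` are
sampled by a Gibbs sampler whose state block draws two loads at a time
exactly, by forward filtering / backward sampling over the joint
photo-state space.

The package also ships the generative simulator used for benchmarking
(binomial fluorophore counts from binding sites x labelling efficiency,
Markov photo-trajectories, gamma readout, ROI summing) and the two
baseline counters the method is compared against: a fluorescence ruler
and a bright/bleached-only restriction of the same engine.

## Worked example

```python
from blinkcount import BenchmarkConfig, FluorophoreCountModel, make_benchmark

traces = make_benchmark(BenchmarkConfig(n_rois=3, n_frames=2000, seed=7))
print("true counts:", traces.ground_truth.counts)

model = FluorophoreCountModel(traces, k_loads=40, gamma=10.0)
result = model.fit(n_sweeps=600, n_burn=300, seed=1)
print(result.summary())
metrics = result.error_metrics()
print(f"mean error {metrics['mean_error']:+.2f} fluorophores, "
      f"max draw deviation {metrics['max_draw_deviation']:.0f}")
```

prints (about a minute on one core):

```
true counts: [12 14 13]
Fluorophore count posterior (300 draws, 3 ROIs, K=40, gamma=10.0)
----------------------------------------------------------------
 ROI     mean   MAP       95% CI
   0    11.85    12     [11, 14]
   1    14.31    14     [13, 16]
   2    12.22    12     [12, 13]
----------------------------------------------------------------
mu_A[bright1]: 450.8 (sd 2.0) photons/frame
mu_A[bright2]: 346.9 (sd 1.6) photons/frame
mu_B per ROI: 1002, 1000, 1000 photons/frame
mean transition matrix (rows: dark, bright1, bright2, bleached):
    0.9802  0.0095  0.0103  0.0000
    0.0179  0.9585  0.0149  0.0087
    0.0160  0.0175  0.9523  0.0142
    0.0000  0.0000  0.0000  1.0000
mean pi0: 0.053  0.801  0.147  0.000
MH acceptance: mu_A1=0.24, mu_A2=0.24, mu_B=0.28

mean error -0.21 fluorophores, max draw deviation 3
```

The per-ROI posterior means sit within a fluorophore of the simulated
truth, and the bright-state brightnesses (true 450 and 350 photons per
frame) and background (true 1000) are recovered along the way.
`result.plot_trace_overlay(roi)` superimposes the sampled mean
brightness on the measured trace; `result.plot_count_histogram()` shows
the pooled count posterior against the ground-truth distribution.

A command-line interface wraps the same pipeline:

```
blinkcount simulate --preset paper-3.2 --seed 7 --out-dir sim/
blinkcount infer sim/traces.csv --sweeps 1000 --loads 50 --out draws.h5
blinkcount baseline sim/traces.csv --method ruler --truth sim/ground_truth.json
blinkcount report draws.h5 --traces sim/traces.csv --truth sim/ground_truth.json
```

Real traces are read from plain CSV (one ADU column per ROI) with gain
and frame-period metadata in a JSON sidecar or `# key = value` header
comments.

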