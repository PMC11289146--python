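# Methods

## The model

In a response-signal experiment a participant may answer only while a brief
response signal (0.2 s) is on, so the response time `x` is pinned to the
window `(T, T + 0.2]` above the stimulus-onset asynchrony (SOA) `T`.  The
probability of a correct two-alternative forced-choice response is modelled
by the speed-accuracy tradeoff function

    psi(x) = 0.5 + lam * (1 - exp(-gamma * (x - delta)))   for x > delta,
    psi(x) = 0.5                                           otherwise,

with `lam` the asymptote above chance (theoretical limit 0.5), `gamma` the
rate in 1/s, and `delta` the intercept time in seconds.  Each task
condition (e.g. congruent and incongruent flanker trials) has its own
parameter triple, estimated concurrently.

## Grid posterior

Inference is a discrete Bayesian update on a Cartesian lattice of
hypotheses.  Defaults: 21 linearly spaced `lam` values, 30 `gamma` values
on [1, 30], 25 `delta` values on [0.02, 0.5] (15,750 cells), with a uniform
prior.  After each trial the per-cell likelihood `psi(theta, x)` (or its
complement for an incorrect response) multiplies the mass, which is then
renormalized; updates commute, so trial order within a session does not
affect the posterior.

Two `lam` axes are supported: the *unpadded* range (0.4, 0.5) respecting
the theoretical limit, and the *padded* range (0.4, 0.55), the
package-wide default.  Padding removes the downward bias of the posterior
mean when the true asymptote sits at the edge of the hypothesis space; in
exchange `psi` can exceed 1 for padded cells, so every probability used as
a Bernoulli/binomial parameter is clamped to `[1e-6, 1 - 1e-6]`, and
*reported* asymptote estimates are truncated at 0.5.  The posterior itself
is never truncated.

Point estimates are marginal posterior means.  The predictive accuracy
curve is the exact posterior expectation of the clamped `psi` at each
evaluation time — the infinite-sample limit of averaging resampled curves;
a seeded 1000-resample mode (`resampled_pc_curve`) exists as a fidelity
cross-check but the exact expectation is deterministic and faster.

## Stimulus selection

A block of `n = 16` trials per condition at SOA `T` is summarized, for
planning purposes, by the number of correct responses per condition,
modelled as Binomial(n, psi(theta, x_hat)) at the expected response time
`x_hat = T + 0.1` (the window midpoint).  The expected information gain of
testing `T` is the mutual information between that outcome count and the
parameters under the current posterior.  Because conditions are independent
given their parameters, the joint gain decomposes exactly into the sum of
per-condition gains (verified in the tests against brute-force joint
enumeration); the "sum" strategy maximizes this sum over the 49 candidate
SOAs (0 to 1.2 s in 0.025-s steps), while the single-condition strategies
maximize one condition's gain alone.  Entropies use natural logarithms —
the argmax is base-invariant — and ties (e.g. the all-zero profile of a
degenerate posterior) resolve to the smallest SOA, with a 1e-12-nat
tolerance absorbing floating-point noise.  The first block is selected from
the uniform prior; selection happens once per block using the posteriors
updated through all completed trials.

## Virtual participants

Simulated response times follow an ex-Gaussian law (mu = 0.3 s,
sigma = 0.06 s, tau = 0.08 s — a typical fast perceptual-decision RT
distribution, mean 0.38 s), truncated and renormalized to each trial's
response window.  Sampling inverts the renormalized CDF; since the
ex-Gaussian CDF has no closed-form inverse, each window's CDF is tabulated
on a 2049-point grid (survival-function evaluations, accurate deep in the
right tail at long SOAs) and inverted by linear interpolation, with a
rejection sampler serving as the test oracle (two-sample KS < 0.02 at
10,000 draws).  Windows with numerically zero density mass fall back to a
uniform draw and are logged.  Correctness is Bernoulli with probability
`psi_true(x)`.

A session is 16 blocks of 16 trials per condition (256 trials per
condition, 512 total for two conditions), conditions randomly interleaved
within each block.  Interleaving order cannot affect the per-condition
posterior (updates commute and selection happens only between blocks), but
it is seeded and recorded so logs replay exactly.

Randomness is structured for reproducibility: a session seed expands into
one substream per condition — consumed as a (trial x [RT draw, correctness
draw]) uniform table — plus one stream for ordering.  In a batch, run `r`
of master seed `m` uses `SeedSequence(m, spawn_key=(r,))`, so any run of
any batch can be reproduced in isolation and results do not depend on how
runs are grouped.  The lockstep batch engine (`run_adaptive_batch`) keeps
all runs' posteriors in one matrix and reproduces the per-session path
bit-for-bit (asserted in the tests).

## Evaluation metrics

All curve metrics are evaluated at the 49 SOA values treated as response
times (evaluating at `SOA + 0.1` instead is supported but fits the
published results worse).

**Accuracy (MAE).**  The headline statistic aggregates the *signed*
deviation across runs before taking the absolute value:

    MAE_i = sum_k | sum_j (pc_ijk - pc_true_k) | / (J * K),

so independent run-level errors cancel and the statistic converges to the
absolute bias of the mean estimated curve.  The per-run mean absolute
deviation is computed alongside (`mae_alt`, always >= the signed form by
the triangle inequality) but is roughly twice as large as the published
accuracy values, so the signed form is the primary metric.

**Precision (HWCI).**  At each evaluation time the grid induces a
mass-weighted discrete distribution of predicted accuracies; the HWCI is
half the length of the *shortest* (highest-density) interval containing at
least 68.2% of that mass, averaged over the 49 points and over runs.  The
shortest-interval convention was an open design choice — the central
interval defined by the 15.9%/84.1% step quantiles is also implementable —
and was settled empirically: the central convention runs ~15% wide of the
published precision values across all strategies and participants, while
the highest-density convention matches them to well within the Monte-Carlo
tolerance, so it is the package convention.  Numerically the interval is
found by scanning 512 equally spaced lower-tail mass levels and minimizing
the corresponding quantile spread, on an equal-count coarsening of the
sorted cells into at most 1024 support points; both discretizations are
exact for small grids and introduce < 2e-4 error on the default grid.

**Efficiency.**  Trials-to-criterion is the first trial index whose metric
trajectory reaches the threshold (MAE 0.010, HWCI 0.020); no monotonicity
is assumed, and when snapshots are strided the first recorded snapshot at
or after the crossing is reported (never interpolated).

**Agreement.**  Method-of-constant-stimuli (MCS) baselines are summarized
by equal-count RT bins (default 8, remainder spread to the earliest bins);
RMSE compares per-run adaptive predictions at the bins' mean RTs with the
binned accuracies.

## Replication studies and problem sizes

`replicate_simulation1` compares the three selection strategies for three
participants whose incongruent-condition parameters grow increasingly
extreme (Table-style output: MAE/HWCI at 256 trials and trials-to-
criterion).  It uses the unpadded `lam` grid: the source tables for the
strategy study are mutually consistent with the no-adjustment variant of
the padding study, which identifies the unpadded grid as the one used
there.  `replicate_simulation2` compares the unpadded and padded grids for
a mid-range (`lam` = 0.45) and a near-ceiling (`lam` = 0.495) participant
under sum-rule selection.

The studies were originally run at 1000 sessions per cell;
`scripts/acceptance.py` uses 200 per cell, chosen as the smallest depth at
which the signed-MAE noise floor (which shrinks as `1/sqrt(J)`) stays well
inside the comparison tolerance; `--runs` restores any depth, with
Monte-Carlo error scaling accordingly.  Per-run credible-width
trajectories, the one genuinely expensive statistic, are recorded at every
trial by default and at a stride (2-4 trials) in the batch studies, which
bounds the trials-to-criterion resolution by the stride.

## What the simulator does and does not show

The virtual participants implement exactly the generative model the
estimator assumes (an exponential-approach SAT function with ex-Gaussian
RTs and stationary parameters).  Passing recovery tests therefore
demonstrates the correctness and efficiency of the inference and selection
machinery, not robustness to model misspecification: real data can show
below-chance accuracy dips at short SOAs (seen in incongruent flanker
trials), lapses, or drift, none of which are modelled.  Trial logs from
real sessions can still be refit offline (`estimate_from_log`, `satf
estimate`), with out-of-window response times flagged but retained.

## Known limitations

- Concurrent estimation degrades when the conditions' informative SOA
  ranges barely overlap (the extreme participant's incongruent condition
  stays imprecise at 256 trials even under the sum rule), mirroring the
  published behaviour.
- The grid bounds are hard model assumptions; parameters at or beyond the
  axis edges bias posterior means toward the interior (the padded `lam`
  axis addresses exactly this for the asymptote).
- Mutual information is computed one block ahead (greedy); there is no
  multi-block lookahead.
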