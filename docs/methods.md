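# Methods

## Neuron model and integration

The simulator implements the adaptive exponential integrate-and-fire (AdEx)
point neuron: two coupled ODEs for membrane potential `V` and adaptation
current `w`, an exponential spike-initiation term, and a discrete reset
(`V ← V_r`, `w ← w + b`) whenever `V` exceeds `V_peak`. The right-hand side
of the voltage equation includes both the adaptation current `−w` and the
injected current `+I(t)`; these are part of the standard AdEx formulation
and are required for the model to adapt and to respond to stimulation at
all. The membrane starts at the leak reversal potential (`V_init = E_L`)
and the adaptation current at `w_init = 0` pA, the common simulator default.

Internally the model runs in a dimensionally closed unit system —
pA / pF / nS / mV / ms (nS·mV = pA, pF·mV/ms = pA) — while every time
crossing the public interface is in seconds.

Integration is fixed-step forward Euler, default `dt = 0.1 ms`
(configurable). The choice favors simplicity and bit-exact reproducibility:
identical inputs always produce identical spike trains. Spike detection is a
threshold crossing `V > V_peak` after a step; the reset is applied within
the same step, so recorded trace samples never exceed `V_peak` and the
sample following a spike sits exactly at `V_r`. Numerical guards:

* the exponential argument `(V − V_T)/Δ_T` is capped at `exp_clip = 30`
  before exponentiation — the upstroke diverges in finite time anyway, so
  the cap prevents float overflow without changing spike timing at step
  resolution;
* any non-finite state terminates the run and flags the result `diverged`
  instead of raising; the fitness module maps such candidates to a finite
  penalty score (1e9) so the optimizer retains a total ordering.

Accuracy caveat: forward Euler has O(dt) phase error, and with a hard reset
that error accumulates across spikes (roughly dt/2 per inter-spike
interval). Halving `dt` therefore moves *early* spike times by less than
2·dt, but spike times deep into a long train drift proportionally to the
number of preceding spikes. All fitting runs use the same `dt` for candidate
and reference, so this bias cancels in the objective. In the
integrate-and-fire limit (`Δ_T = 1 mV`, `a = b = 0`, reset at threshold,
`dt = 0.01 ms`), 1-s spike counts match the closed-form period
`T = τ_m ln[(I − g_L(V_r−E_L))/(I − g_L(V_T−E_L))]` within one spike across
a grid of suprathreshold currents; with `V_peak` well above `V_T` the
exponential upstroke adds a systematic per-period delay of order
`(C Δ_T/μ)·ln(1 + μ/(g_L Δ_T))` (μ the suprathreshold current), so the
closed form is a limit statement, not a general-purpose oracle.

## Stimulation protocols and features

The default protocol suite is the granule-cell characterization set: step
currents of 10/16/22 pA for 1 s, and sinusoids of 6 and 8 pA amplitude over
a 12 pA offset for 22.5 s. The sinusoidal frequency grid is configurable and
defaults to {1, 2, 4, 6, 8, 10, 12} Hz, spanning the theta band where
granule cells resonate in vitro (~5–12 Hz). The sine starts at phase 0 at
stimulus onset (`I(onset) = offset`); a configurable phase offset is
provided for users who prefer aligning analysis windows to another phase.

Three features are extracted per candidate:

* **mean frequency** — spike count over the stimulation window divided by
  its length (Hz), per step stimulus;
* **first-spike latency** — time from onset to the first spike (s).
  Candidates that never spike return the stimulus duration as a sentinel:
  this keeps the score finite and penalizes silence in proportion to the
  window, and it is the documented, configurable policy for an otherwise
  undefined quantity;
* **burst frequency** — per sinusoidal cycle, the inverse of the mean
  inter-spike interval of the spikes inside that cycle (algebraically
  `(k−1)/(t_last − t_first)` for `k ≥ 2` spikes); zero for cycles holding
  one spike or none, matching how silent cycles are treated in vitro. The
  per-condition value is the mean over the first 10 complete cycles after
  onset (count and analysis onset configurable), with the population
  standard deviation over the same cycles feeding the stability penalty.
  Cycle windows are full stimulation periods, abutting and disjoint;
  inter-spike intervals never straddle a window edge, keeping cycles
  independent. Windowing by the positive half-wave instead is possible via
  the phase-offset option but is not the default: bursts fall into the
  positive phase naturally.

## Objective

The total score is the weighted sum of absolute feature errors (see the
README for the formula). Weights default to 1 (mean frequency, Hz), 1000
(latency, s) and 1 (burst frequency, Hz), equalizing 1 Hz errors and 1 ms
lags. Two readings of the burst-stability factor were possible; the factor
implemented is `(std over the analyzed cycles of that condition) + 1`,
multiplying that condition's absolute error — stability across cycles is
the only reading under which a "burst stability" penalty is meaningful.
As printed, the factor multiplies the error, so a candidate with the right
mean burst frequency pays nothing regardless of its variability. Latencies
are stored in seconds only; the reference-file schema rejects targets
declared in milliseconds, as a unit mix-up would silently scale the latency
component a thousandfold.

## Multimodal optimizer

The optimizer maintains species — (center, cached fitness, radius) triples
— in the normalized unit box `[0,1]^10`. Normalization is essential: raw
units would let the slope factor (range 999 mV) dominate every Euclidean
distance. The diameter of the normalized space is `√10 ≈ 3.162`, and the
default minimum radius is `r = 0.7` in that space. Defaults `M = 100`
species, `N = 10,000,000` evaluations, `l = 50` levels reproduce the
full-scale study configuration; scaled-down settings are used everywhere
runtime matters (tests, examples).

Per level `i`, new species receive radius
`diameter·(r_min/diameter)^((i−1)/(l−1))` — geometric cooling from the full
diameter to `r_min`. Species creation (from level 2 on) gets `3·M`
evaluations per level, split evenly across species; within each species'
ball, `n` uniform points are drawn with `n` the largest integer such that
`n + C(n,2) ≤ allotment`, so that evaluating all pair midpoints also fits
the budget (with a full population this is exactly one pair plus its
midpoint per species, which is what makes the `3·M` budget natural). A pair
whose midpoint scores strictly worse than both endpoints indicates the
endpoints sit in different basins; both become new species at the level
radius. Strictness matters: ties create nothing, avoiding species explosion
on plateaus. Any evaluated point that strictly beats the parent's center
replaces it.

Fusion merges any two species whose centers are closer than the level
radius, keeping the better center (earlier-created on ties — a fixed,
deterministic scan order) and the *larger* radius, so the covered region
never shrinks and a full-diameter species survives to the end. Shortening
removes shortest-radius species first (worse fitness first on ties) until
at most `M` remain.

The local search is SASS (Solis–Wets): propose
`clip(center + radius·σ·g, box)` with `g` standard normal, displacement norm
capped at the species radius; accept strict improvements; `σ` starts at 1,
doubles after 5 consecutive successes, halves after 3 consecutive failures,
clamped to `[1e-5, 1]`; a search self-terminates after 32 consecutive
failed or discarded moves (a move is discarded, without consuming an
evaluation, when clipping cancels it entirely). The classical Solis–Wets
bias vector is omitted: the perturbation is a plain Gaussian draw in a
random direction. Per-level local-search budgets ramp linearly with the
level index — `floor(B·i / Σ_{k=1..l} k)` with `B` the evaluation budget
remaining after creation and initialization — spending more effort on later,
finer levels while keeping the total within `N`; the first level's ramp
share funds the mandatory local optimization of the initial species. The
exact budget formula is a design choice of this package: the requirement it
realizes is only that later levels receive more evaluations.

Runs typically consume far less than `N`: every local search gives up after
32 consecutive failures and unspent budget is dropped, which is the
method's intended economy (full-scale configurations spend a few times
`10^4` evaluations of the `10^7` allowed). Equal seeds give bit-identical
populations; all randomness flows from one seeded generator.

## Synthetic references

Published in-vitro target values for the granule-cell fit are not
available, so references are synthesized: a chosen ground-truth parameter
set is run through the protocol suite and its features become the targets.
A noise-free reference scores its own generator at exactly zero, which
anchors the self-consistency tests. Optional Gaussian noise is applied at
the *feature* level (frequencies clipped at zero) — the objective consumes
features, so feature-level scatter is where measurement noise enters the
scoring; spike-train-level noise is deliberately not modeled. Two example
granule-cell-like parameter sets ship with the package as plausible ground
truths. What passing tests show is therefore internal consistency and
recoverability under the model's own dynamics; they cannot certify fits to
real recordings, whose noise structure, cell-to-cell variability and
non-AdEx dynamics the generator does not emulate.

## Candidate analysis

The final population is ranked by recomputed total score (asserted to equal
the optimizer's cached fitness exactly — a cross-module consistency check),
with the burst component decomposed per stimulation amplitude. Populations
are embedded in two dimensions with *classical* (Torgerson) MDS —
double-centering of the squared Euclidean distance matrix between
raw-unit parameter vectors, eigendecomposition, top-2 coordinates scaled by
root eigenvalues, negative eigenvalues truncated at zero. Classical MDS is
implemented directly (not stress-majorization, which common library
defaults use) because distance-matrix inputs realizable in 2-D must be
reproduced exactly. Distances default to physical units with a
normalized-space option. Parameter distributions are summarized by median,
quartiles and 5/95 percentiles using linear interpolation between closest
ranks (the numpy default); single-candidate subsets degenerate to the
candidate's own values.

## Scaled-down test conditions

The test suite exercises the full pipeline at reduced problem sizes chosen
to preserve the method's character: steps of 0.5 s, sinusoids of 2.5 s at
{4, 6, 8} Hz for both amplitudes, `dt = 0.1 ms`, and optimizer settings
`M = 20`, `l = 10`, `N = 20,000`. Because the optimizer is stochastic and a
single run may settle in a different niche than the generating truth, the
recovery check mirrors the full-scale workflow — several independent seeded
executions with the best-scoring run selected for analysis. Toy objectives
(2-d sphere, 1-d two-well) validate the optimizer's population invariants
and multimodality independently of the neuron model.

## Known limitations

* Forward Euler phase error accumulates over long spike trains (see above);
  a higher-order or adaptive integrator would trade reproducibility and
  simplicity for accuracy.
* The latency sentinel makes the objective discontinuous at the silence
  boundary.
* Burst windows are anchored to stimulus onset, not to burst phase; for
  candidates whose bursts straddle window edges the per-cycle std (and thus
  the stability penalty) can be inflated.
* The per-level budget ramp is a documented stand-in for the original
  method's unpublished schedule; only its qualitative property (later
  levels get more) is specified.
* With 10 normalized dimensions and `r_min = 0.7`, early-level radii exceed
  typical pairwise distances, so populations stay small until late levels;
  this is inherent to the radius-cooling design, not a defect.
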