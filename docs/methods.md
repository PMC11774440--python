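# Methods

## The model

The package studies how task-selective gating can emerge from plain gradient
descent in the simplest setting that exhibits it: a linear student network
with `P` weight pathways `W_p ∈ R^{dout×din}` whose outputs are mixed by
gating variables `c_p`,

```
y = Σ_p c_p W_p x            (scalar gates)
y_i = Σ_p c_{p,i} (W_p x)_i  (one gate per output row, "per_row" mode)
```

Data come from a multi-task teacher–student setup: each task `m` is a linear
map `W*_m`, inputs are i.i.d. standard normal, labels are `y* = W*_m x`, and
tasks are presented in contiguous blocks of duration `τ_B`, cycling
sequentially. The model never receives the task identity.

Weights and gates are both trained by gradient descent on the regularized
squared loss

```
L = ½‖y* − y‖²  +  λ_norm · ½(‖c‖_k − 1)²  +  λ_nonneg · Σ_p max(0, −c_p)
```

with `k = 1` by default (`k = 2` available). The two penalties push the
gates towards a bounded, nonnegative, roughly convex mixture — they do not
by themselves favor any assignment of pathways to tasks. Training is
treated as a gradient flow with separate time constants,

```
τ_w dW_p/dt = −∇_{W_p} L,     τ_c dc_p/dt = −∇_{c_p} L,
```

and the interesting phenomena occur when the gates are faster than the
weights (`τ_c < τ_w`). In expectation mode the input distribution is
integrated out exactly (`E[L_task] = ½‖W* − Σ_q c_q W_q‖_F²` for whitened
Gaussian inputs), making runs fully deterministic; minibatch mode draws
fresh Gaussian batches each step.

Two qualitative end states are distinguished. In the **flexible** regime
each pathway specializes to one teacher and the gates switch pathways after
a block change — increasingly quickly as training proceeds, because the
gate drive `dc_p/dt ∝ ⟨W_p, error⟩` grows with the students' alignment and
magnitude. In the **forgetful** regime all pathways chase the currently
active teacher and previous knowledge is overwritten every block. The
matched forgetful control of any model sets `τ_c = τ_w` and
`λ_norm = λ_nonneg = 0` and changes nothing else.

## Reduction to specialization coordinates

For two orthogonal teachers the expectation-mode dynamics close on the
projections `w^p_m = u*_m^T W_p v*_m` (per singular mode of the teachers):

```
τ_w dw^p/dt = c_p ε,     τ_c dc_p/dt = w^p·ε − λ ∇_{c_p} L_reg,
ε = y* − Σ_p c_p w^p,
```

with `y*` the active teacher's unit vector in the teacher basis. The
reduction is exact whenever the students lie in the span of the teacher
modes; out-of-span components of the weights only decay and contribute
`O(σ²)` to the gate drive, so the theory tests initialize inside the span
and the simulator can record the projected coordinates alongside the full
state (`integrate(..., record_reduced=True)`).

Specialization is summarized by two scalars: `w̄ = ½(w̄_1 + w̄_2)` with
`w̄_1 = w^1_1 − w^2_1`, `w̄_2 = w^2_2 − w^1_2` (how differently the two
pathways represent the two teachers), and the gate separation
`c̄ = c_1 − c_2`. Their drift is

```
τ_c dc̄/dt = w̄_1 ε_1 − w̄_2 ε_2,     τ_w dw̄/dt = ½ c̄ (ε_1 − ε_2);
```

the L1 normalization pull is identical on both (positive) gates and cancels
in `c̄`. These two equations exhibit the feedback loop at the heart of the
flexible regime: specialization accelerates gate separation, and separated
gates protect and deepen specialization.

## Closed-form adaptation under symmetry

During one block of adaptation from full specialization
(`w^p_m = δ_pm`, `c_p = δ_p1`, new target = teacher 2), under the symmetry
`w̄_1 = w̄_2 = w̄` and strong L1 normalization (`Σ_p c_p` pinned to 1), the
ratio of the two drifts gives the separable ODE

```
(τ_c/τ_w) dc̄/dw̄ = 2 w̄ / c̄.
```

Separating variables, `τ_c c̄ dc̄ = 2 τ_w w̄ dw̄`, so
`w̄² − (τ_c / 2τ_w) c̄²` is a first integral; fixing the constant at the
specialized start `(c̄, w̄) = (1, 1)` yields

```
w̄ = sqrt( 1 − (τ_c / 2τ_w) (1 − c̄²) ).
```

The square root is required for the stated initial condition (the
expression under it equals `w̄²`); the implementation certifies this form
against direct numerical integration of the separable ODE and against
simulated adaptation paths. At full separation (`c̄ = ±1`) specialization
is exactly 1 for any timescale ratio; the minimum over the path,
`sqrt(1 − τ_c/2τ_w)` at `c̄ = 0`, quantifies *protection*: for
`τ_c ≪ τ_w` the gates complete the switch before the weights can move.

On the symmetric manifold the dynamics close on `(w̄, c̄)` alone
(`τ_w dw̄/dt = −½ c̄ (1 + w̄c̄)`, `τ_c dc̄/dt = −w̄ (1 + w̄c̄)`, task loss
`(1 + w̄c̄)²/4`), which `symmetric_adaptation` integrates with a stiff
implicit solver; the first integral is conserved to solver precision.
`block_adaptation` instead integrates the full per-path reduced system with
explicit strong regularization (`λ_norm = λ_nonneg = 1000`, which keeps
`Σ_p c_p` within about 1e-4 of 1); Radau handles the stiffness.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `τ_w` | weight time constant (time units) | 1.3 | studied two-task condition |
| `τ_c` | gate time constant | 0.03 | studied two-task condition (≈ 43× faster) |
| `τ_B` | block length | 1.0 | studied two-task condition |
| `λ_norm`, `λ_nonneg` | gate regularization weights | 1.0 | comparable to the task-gradient scale; a single multiplier is swept in the phase diagram |
| `k` | gate norm order | 1 | the analytically transparent case; `k = 2` by config |
| `σ` | weight init scale (`W ~ N(0, σ²/din)`) | 0.01 | small-initialization regime |
| `din`, `dout` | input/output dimensions | 32, 8 | fits `M·dout ≤ din` orthogonal teacher rows for `M ≤ 4` |
| `row_norm` | teacher row norm | 1.0 | unit-scale tasks |
| `dt` | Euler step | `τ_c/50` | guard `dt ≤ τ_c/10`; halving changes final losses by < 1% |
| gates init | | 1/2 | half-open start |

## What the generator emulates — and what it does not

Teachers are random orthonormal row sets scaled to `row_norm` (a QR
orthonormalization of a Gaussian matrix, split into `M` teachers), so
distinct tasks produce exactly orthogonal responses; a `correlation`
parameter can instead give paired teacher rows a fixed cosine, as a hook
for non-orthogonal task studies. Inputs are whitened Gaussians with no
label noise, no input correlations, and no nonstationarity within a block.
Passing tests therefore demonstrate the mechanism under idealized
conditions — linear tasks, exact orthogonality, noiseless labels — and say
nothing quantitative about nonlinear networks or naturalistic data.

## Experiment design choices

- **Regime comparison** (two tasks): 24 blocks of length 1.0. The regime
  classifier is an operationalization, since "flexible" has no universal
  quantitative definition: a run is flexible iff final matched total
  alignment exceeds 0.9 *and* the mean time-to-criterion (expected loss
  below 0.1) over the last quarter of blocks is below that of the first
  quarter. Matched total alignment maximizes the cosine between the
  concatenated students and teachers over injective path-to-teacher
  assignments (exhaustive up to 4 paths, greedy beyond), so a collapse of
  two pathways onto one teacher scores strictly below 1.
- **Criterion timing** always uses the closed-form expected loss, never a
  minibatch estimate, so timing statistics carry no sampling jitter.
- **Composition**: three teachers A, B, C (30 blocks), then six blocks
  cycling the pairwise sums A+B, A+C, B+C (scalar gates) or the
  row-interleaved combinations (per-row gates). Per-row regularization
  treats each output row's gate vector as an independent mixture.
- **Phase diagram**: final matched alignment over an 8×8 grid of block
  length × regularization multiplier (or gate rate `1/τ_c`) at fixed total
  training time 16 — short blocks mean more switches but equal data. The
  informative block lengths sit near the gate timescale; the packaged grid
  spans `τ_B ∈ [0.02, 1]`, which brackets the forgetful-to-flexible
  transition, with 3 seeds per cell as the desk-scale default.
- **Switch-speed trend**: mean expected loss over the first 10% of each
  block, regressed on block index over 24 blocks of length 2.0. The longer
  blocks matter: the comparison presumes each task is mastered within its
  block (as in practiced task switching), and with unit blocks the
  forgetful control never masters a task, leaving its trend dominated by a
  slow drift instead of the deceleration caused by growing weight norms.
- **Block adaptation horizon**: 4.0 time units, long enough that the
  slowest studied gate timescale (`τ_c = τ_w = 1`) completes the switch
  (the gate-only decay bound is `e^{−2t/τ_c}`).
- **Deep linear network**: hidden width `M·dout`, gate-style constraints
  moved onto the second layer (per-output-row L1 normalization plus
  elementwise hinge, `τ_2 < τ_1`), since the second-layer entries play the
  role of gates. The sorting analysis assigns each hidden unit to the
  teacher maximizing the absolute cosine with its input row (ties to the
  lowest index; absolute value because linear pathways are sign-symmetric),
  permutes `W1` rows and `W2` columns identically — leaving the
  input–output map untouched — and reports the mean of each sorted block of
  `W2` as that student's emergent gate.

## Numerical choices

Explicit Euler with `dt = τ_c/50` for all full-model runs (deterministic
and exactly mirrored by the reduced Euler integrator, which is what makes
the exactness comparison meaningful at 1e-6); Radau with tight tolerances
for the stiff strongly regularized reduced systems. Subgradients at the
kinks are 0 (`sign(0) = 0` for the L1 norm, hinge slope 0 at `c = 0`);
gradient-descent monotonicity holds away from the hinge, where finite Euler
steps can chatter with amplitude `~ dt·λ/τ_c`. Divergence (expected loss
above 1e6) raises an error naming the step size. Zero-norm rows contribute
0 to row-averaged alignment, with a warning. Trajectories are
bit-reproducible from (seeds, dt, config); initialization and data sampling
use separate seeds so seed-averaged comparisons can share initializations.

## Known limitations

The two-teacher reduction requires `M = 2`, orthogonal teachers, and scalar
gates; multi-mode teachers are projected per mode, with the gate drive
summing over modes. The regime classifier and the flexible-region
definition in the phase diagram are package operationalizations. The
forgetful model's switch-speed deceleration only appears once blocks are
long enough for per-block mastery. Nonlinear architectures, label noise,
and non-Gaussian or correlated inputs are out of scope.
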