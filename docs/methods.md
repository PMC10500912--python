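# Methods

## Statevector engine

States are dense complex128 vectors of length 2^n. **Qubit 0 is the
leftmost tensor factor**: its bit occupies the most significant position of
the basis index, so for two qubits the basis order is |00⟩, |01⟩, |10⟩,
|11⟩. Single-qubit gates are applied by reshaping the amplitude vector to a
rank-n tensor and contracting the 2 × 2 matrix into the target axis;
CNOT swaps the two target-axis slices of the control = 1 block. This is
algebraically identical to multiplying by the full Kronecker-product
matrix, which the test suite builds independently and compares against
elementwise (tolerance 1e-10, 100 seeded random circuits on ≤ 3 qubits).

Gate set: R_x, R_y, R_z (half-angle convention,
R_y(t) = [[cos t/2, −sin t/2], [sin t/2, cos t/2]]), the Paulis, CNOT, and
the Euler-angle gate

U(θ, φ, λ) = [[cos θ/2, −e^{iλ} sin θ/2], [e^{iφ} sin θ/2, e^{i(φ+λ)} cos θ/2]].

A circulating claim that X = U(π, π, π/2) does not hold under this
definition — substituting gives a different matrix; the standard identity
is X = U(π, 0, π) (exact, no phase needed here since U(π,0,π) = X
elementwise). The implementation follows the matrix definition above
literally.

Expectations are exact (no shot noise). ⟨Z_k⟩ is computed from basis
probabilities and clipped to [−1, 1] to remove O(1e-16) roundoff
excursions. Norm and unitarity tolerances are 1e-10 throughout. States are
compared elementwise except in gate-equivalence checks, where a global
phase is irrelevant.

## Quanvolution

Preprocessing: area-average (local-mean) resize to m × m, then min–max
scaling; a constant image maps to all zeros by convention. Encoding maps
pixel x ∈ [0, 1] to an R_y(πx) rotation from |0⟩, so a lone pixel has the
closed form ⟨Z⟩ = cos(πx); with a zero kernel and no entangler the whole
feature map reduces to cos(π·pixel), which the tests use as an analytic
limit.

The kernel u(θ) has exactly four trainable angles (one R_y per window
qubit) followed by an entangler chosen from {"none", "ring"}; "ring" is
CNOT(0→1), CNOT(1→2), CNOT(2→3), CNOT(3→0). One kernel is shared across
all window positions (weight sharing, as in a classical convolution).
Windows are processed as independent 4-qubit circuits; a whole-image
register (m² qubits) would be exponentially expensive and adds nothing at
the 2 × 2 window granularity used here.

Quantum pooling appends a parameter-free unitary V — by default the CNOT
ladder CNOT(1→0), CNOT(2→0), CNOT(3→0) funneling the window state onto
qubit 0 — and measures only the pooled qubit, giving one value per window:
a length-(m−1)² vector for stride 1. Stride defaults to 1 (overlapping
windows, (m−1)² positions); larger strides are supported.

Random-kernel mode draws θ uniformly from [0, 2π) from an explicit
generator and freezes it; trainable kernels receive exact parameter-shift
gradients, d⟨Z⟩/dθ_i = [⟨Z⟩(θ_i + π/2) − ⟨Z⟩(θ_i − π/2)]/2, valid because
every parameter generates an R_y rotation.

## Classical head and training

Dense layers with relu/tanh/sigmoid/softmax activations, Glorot-style
uniform initialization (seeded), and a small im2col Conv2D / 2×2 MaxPool
stack for the classical reference CNN. The training loss defaults to
categorical cross-entropy (fused softmax gradient); the ½Σ(t−o)² squared
error is provided as an alternative, including the full softmax Jacobian
path. Analytic gradients are verified against central finite differences
(relative error < 1e-5) on random dense models, a conv model, and the
parameter-shift path. Max-pool gradient ties are split equally; random
initialization makes exact ties measure-zero in practice.

Parameter counting is standard: dense in·out + out, conv
(k²·c_in + 1)·filters, 4 for a trainable quanvolution kernel, 0 for
pooling/flatten. The selected hybrid architecture
(quanv 4 + dense 4→128 + 128→64 + 64→4) totals 9160. The reference CNN
uses this same standard counting; no attempt is made to emulate
nonstandard per-layer totals that standard counting cannot reproduce.

The per-epoch training loss reported in histories is the mean of batch
losses over the epoch (the convention of mainstream deep-learning
frameworks' `history['loss']`); the evaluation loss is computed on the
held-out set after the epoch and is what drives the adaptive schedule.

## Adaptive optimizer

lr(epoch) = 0.01 · 0.1^epoch depends only on the epoch index. Momentum is
0.9 for epochs 0–1 and β / (1 − e^{−(loss_t + loss_{t−1})}) clamped to
0.999 afterwards, with β = 1 by default. For β = 1 the raw value exceeds 1
for every finite positive loss sum, so the clamp binds and the momentum
sits at 0.999 until losses diverge; for β < 1 it tends to β as losses
grow. A zero loss sum returns the clamp value (continuity from below). The
velocity buffer is **carried across epochs** — the heavy-ball recursion
Δw(n+1) = −η∇L + αΔw(n) runs over all iterations — rather than being
reset at epoch boundaries; resetting measurably degrades the adaptive
run (the decayed learning rate leaves nothing to rebuild velocity from).
A stability bound for the numerator constant in terms of an input
autocorrelation matrix exists in the literature but is not operational
here and is not implemented; β is exposed directly.

Two behavioral caveats, both visible in the tests:

* Because the learning rate decays by 10× per epoch, parameter motion
  driven by fresh gradients is negligible after roughly epoch 4; later
  progress comes almost entirely from the 0.999-momentum coasting of early
  velocity.
* On the convex quadratic toy the schedule converges (loss < 1e-4 in 200
  steps) when epochs contain ~50 mini-batch steps; with very short epochs
  the combination of collapsed learning rate and 0.999 momentum produces
  slow oscillation instead. The scaled-down convergence-ordering check
  against plain SGD inherits the same sensitivity: the adaptive run wins
  only when its momentum-amplified first epochs already undercut the plain
  run's final loss, which at the default synthetic conditions happens in a
  majority — but not ≥ 8/10 — of seeds.

The plain momentum SGD and Adam baselines are intentionally thin
comparison implementations.

## Genetic search

Defaults: population 12, 10 generations, tournament size 3, crossover 0.8,
per-gene mutation 0.1, elitism 1 — small budgets chosen for desk-scale
runtime; elitism makes best-so-far fitness monotone, which is asserted.
Two-objective hybrid fitness (accuracy, −parameter count) is compared
lexicographically. Failed candidate evaluations are flagged with fitness 0
rather than aborting the run. The search is validated by recovering the
brute-force optimum of a stub landscape (maximize −(g−3)² over integers
0..10) in ≥ 9/10 seeded runs.

## Evaluation statistics

Multiclass confusion counts use micro one-vs-rest aggregation: each class
in turn is positive and per-class TP/TN/FP/FN are summed, so an n-sample
k-class problem has count total n·k. Published aggregate counts are
accepted directly as inputs, so the formulas — not any aggregation
guess — are what the worked-example tests verify. A metric with a zero
denominator is reported as undefined and flagged, never silently zero.
Percentages are rounded half-away-from-zero to 2 decimals and compared at
±0.01 pp, because printed last digits are occasionally inconsistent.

The paired t-test uses the sample standard deviation of differences
(n − 1), df = n − 1, and the exact t-distribution CDF for the two-sided
p-value; the tests cross-check it against both an explicit-sum textbook
formula and scipy's implementation. Cohen's d uses the pooled sample SD.
Confidence intervals are mean ± t_{(1+level)/2, n−1} · sd/√n.

Per-epoch significance trajectories (p-values, effect sizes at individual
epochs) require replicate runs that are not part of this package's inputs
and are out of scope.

## Synthetic data

The generator emulates a balanced 4-class grayscale task: centered disc,
off-center disc, ring, and uniform background prototypes on an m × m grid,
plus zero-mean Gaussian noise (σ = 0.05 by default) clipped to [0, 1].
Defaults m = 8 and 100 images per class keep per-window 4-qubit simulation
fast while remaining non-trivial. The patterns are geometric stand-ins:
they share with real MRI data only the coarse statistical structure
(4 balanced classes, bounded intensities, additive noise), so passing
tests demonstrate pipeline correctness and optimizer behavior, not
clinical performance. At σ = 0.05 a nearest-centroid classifier already
exceeds 90% held-out accuracy, which is asserted as the separability
contract.

DICOM reading applies the modality rescale slope/intercept when present
and ignores windowing metadata; PNG/JPEG input is collapsed to grayscale
by channel averaging. Splits are stratified 80/20 shuffles, seeded.

## Problem sizes

Default test and acceptance runs use: 100 random oracle circuits on ≤ 3
qubits; 20 random models for gradient checks; 10 GA seeds × 20
generations; 10 optimizer-comparison seeds × 2 runs × 20 epochs on
400-image synthetic sets (320 train / 80 test). These sizes were chosen so
the whole suite runs comfortably on a single CPU core.
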