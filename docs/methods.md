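# Methods

`predrep` studies a single question in three model systems: when a network
is trained only to predict its next sensory observation, how much of the
low-dimensional latent structure generating those observations ends up
explicitly represented in its activity? The package therefore has three
layers — simulators that define latent spaces and observation streams,
network models trained on prediction (or autoencoding, as a control), and
a battery of representation metrics.

## Environments

**Card-game lattice.** States live on a 5×5 lattice (any d-dimensional
shape is supported). Each state is assigned a random hand of 5 cards from
a 40-card deck, drawn without repetition within the hand and independently
across states; the hand is the state's observation and is statistically
independent of the lattice geometry. Actions are the four unit moves plus
a null action (N_a = 5; seven actions in 3-D). The walk samples uniformly
from the actions valid at the current state, so edge states never emit an
off-grid move. Observations default to a one-hot code over the distinct
card sets (turning prediction into classification); a multi-hot code over
the 40 cards is available as an alternative. With the default deck the 25
hands are distinct with overwhelming probability, so the one-hot length is
the number of states.

**Colored-wall arena.** A 64×64 (reduced: 16×16) tile grid whose boundary
tiles are walls. Wall colors are i.i.d. uniform RGB smoothed along the
unrolled perimeter by a wrap-around Gaussian kernel of variance 2 tiles²
(σ = √2; we read "variance two tiles" literally as a variance). The agent
carries a heading θ that diffuses with per-step Gaussian increments of
variance 0.5 rad² (the implementation-level value; the narrative's "30°"
is superseded), moves to whichever of its 8 neighbors best aligns with the
new heading, and stays put — doubling the next increment's variance to
1.0 rad² — when that neighbor is a wall. Increments are sign-flipped when
they would turn against the direction of the last executed move (the
coherence rule dθ·wrap(θ − d_a) ≥ 0); flipping preserves the increment's
magnitude distribution. Actions are allocentric 9-way codes (8 compass
moves + stay) reporting the executed move. Five sensors at offsets
{−45°, −22.5°, 0°, +22.5°, +45°} from the heading each report the distance
to the wall along their ray and the hit tile's RGB (observation length
5 × 4 = 20). Because walls exist only on the boundary, hits are computed
in closed form as the ray's first crossing of the interior box — exact,
with no marching tolerance. Raw distance is the entry distance plus half a
tile (center-to-center for a squarely faced wall, so a wall one tile ahead
reads 1.0); observations carry distances normalized by the arena diagonal
so every channel lies in [0, 1], matching the bounded readout
nonlinearity. Raw distances are recoverable exactly from the stored
normalization constant.

**Six-muscle arm.** A deliberately simplified two-joint kinematic arm:
six binary pulse channels (independent symmetric two-state Markov chains,
flip probability 0.05 → mean run 20 steps) are low-pass filtered
(first-order, τ = 10 steps) into activations, mapped by a signed 2×6
moment-arm matrix (antagonist pair per joint plus two biarticular
columns) to torques on the shoulder angle α and interior elbow angle β,
and integrated by damped explicit Euler with joint-limit clipping. The
published arm model this emulates delegates its muscle equations to an
external codebase; the properties exercised here require only that six
temporally correlated binary actions drive smooth nonlinear dynamics on a
two-dimensional latent space, which this model preserves. Torque and
damping scales were chosen so that the arm sweeps a nondegenerate region
of joint space on a 10⁴–10⁵-step run with per-step observation changes of
a few percent of the range — fast enough that genuine prediction is
distinguishable from copying the current input. Observations are the
elbow and wrist (x, y) relative to the shoulder (β = π is a straight arm),
normalized by the total arm length.

What the simulators do *not* emulate: sensory noise, interior obstacles,
continuous positions, reward or goal structure, and Hill-type muscle
dynamics. Passing tests therefore show that the metrics behave as claimed
on clean model systems with known ground truth, not that they would on
noisy biological recordings.

## Network models

The card network is a two-layer perceptron: first layer sigmoid (width
100) receiving the one-hot observation and action blocks, second layer
tanh, sigmoid readout under binary cross-entropy. The first layer is the
analyzed representation; its observation-block columns w_s and
action-block columns w_a are the objects of the translation-invariance
analysis. Without actions the next observation is stochastic, so the
readout becomes linear with a mean-squared-error loss and the optimum is
the transition-kernel average.

The recurrent model is a vanilla RNN, r_t = tanh(W r_{t−1} + W_o o_t +
W_a a_t), y_t = tanh(W_out r_t), with W initialized to the identity and
the other matrices to Normal(0, 0.02²). Predictive training targets
o_{t+1}; non-predictive (autoencoding) training targets o_t. Training is
truncated backpropagation through time (window 20), with the trajectory
split into contiguous parallel subsequences and the hidden state carried,
gradient-truncated, across windows. Observations are affinely mapped into
[−0.8, 0.8] (one global offset/gain per trajectory) so the tanh readout
can represent them without saturation; predictions are mapped back to
observation units before any metric sees them. Both models are
implemented directly in NumPy with hand-derived gradients, which the test
suite validates against central finite differences to 10⁻⁴ relative
error.

**Optimization.** RMSprop (lr 10⁻⁴, α 0.95, ε 10⁻⁷) with
reduce-on-plateau (×0.5, patience 8) and early stopping (patience 25,
min-delta 5·10⁻⁵) on a contiguous 20% validation tail — contiguous rather
than shuffled to avoid temporal leakage. The card network instead trains
with plain SGD (lr 20, batch 256, init 0.005): at equal final loss, SGD's
implicit bias yields a first layer whose action geometry is far more
translation-invariant than RMSprop's per-parameter rescaling allows
(score ≈ 3× below the random-weight baseline versus ≈ 1.4×), and the
additive-structure analysis is precisely the point of that model.
Checkpoints (all weights) are stored every epoch, including the
initialization, so every metric can be replayed over learning.

**Scales.** Three presets per task. "full": 64×64 arena, 500 units,
10⁶-step epochs — hours of compute, for manual launches. "reduced" (the
test battery's conditions): 16×16 arena / 10⁵-step trajectories / 100
units, trained 300 epochs at batch 16 for the arena (≈ the full-scale
update count; 30 epochs at the published batch size would leave the net
far from convergence), 60 epochs for the arm, 25 SGD epochs for the
cards; probes are separate 2×10⁴-step trajectories. "fixture": a
minutes-scale smoke configuration.

## Metrics

*Predictive error*: C(L) = mean_t ‖o_{t+L} − y_t‖² over lags −5..+5, with
the observation self-similarity mean_t ‖o_{t+L} − o_t‖² as baseline; edge
steps without a lag partner are dropped, never padded. Its *symmetry
axis* is found by scanning candidate axes at 0.05-lag resolution and
minimizing the mean squared difference between the curve and its
reflection, linearly interpolating at non-integer reflected lags; only
reflections landing inside the lag range count, candidates with fewer
than 3 overlapping lags are excluded (otherwise boundary candidates win
vacuously), ties break toward 0, and a flat curve returns 0 with a
degenerate flag. An axis near +1 distinguishes genuine prediction from
autoencoding (axis near 0).

*Lag decoding*: ridge readout (α = 10⁻²) from the representation at t to
each latent at t+L, fit on the first half and scored as held-out RMS;
circular variables decode through (cos, sin) with errors on the circle.

*Signal transfer*: the representation is projected onto its top principal
components (mean-centered, never variance-scaled — raw PCs are what the
analyses plot); canonical correlations against a covariate block are
computed from the whitened cross-covariance with a relative ridge of
10⁻⁶ on both blocks, and their mean is reported. The latent block is
(x, y) (or α, β); θ enters as its (cos, sin) pair. The observation-space
variant uses the top 3 PCs of the observation stream as the block.

*Participation ratio*: PR = (Σλ)²/Σλ² over eigenvalues of the centered
activation covariance — the standard form from the dimensionality
literature (N for isotropic N-dim data, 1 for rank one).

*Intrinsic dimensionality*: two estimators of the small-radius scaling
#B_r ~ r^d. The correlation dimension fits the slope of log pair-fraction
versus log radius over the window where the pair fraction lies in
[10⁻³, 10⁻¹] (widened if too sparse) on ≤ 2000 points; the k-NN
maximum-likelihood estimator averages the Levina–Bickel inverse mean
log-distance-ratio over points and over k = 10..20. Points are subsampled
to ≤ 10⁴ with a fixed seed and exact duplicates pruned with a warning.
The estimator registry accepts additional methods; only these two are
implemented. *Dimensionality gain* DG = PR / (mean of the implemented ID
estimates).

*Tuning maps*: per-unit mean activity binned on a regular grid over
either physical (x, y) (place maps) or the population's own top-2 PC
scores (manifold-cell maps); bins with fewer than `min_occupancy` visits
are reported missing (NaN), never zero-filled.

*Translation-invariance score*: for each lattice move action a, the
difference vectors Δ_{s,a} = w_{s′} − w_s over all linked state pairs;
the score is the mean over actions of (mean pairwise dispersion of
Δ_{s,a}) / (mean norm of Δ_{s,a}). Exactly additive action structure
gives 0; i.i.d. random columns give ≈ √2, estimated empirically by a
seed-matched Monte-Carlo baseline.

The metric timeline evaluates the full battery per stored checkpoint on
one shared probe trajectory with fixed seeds, so recomputation from saved
checkpoints is bit-identical; a failed metric is recorded as NaN and the
timeline continues.

## Observed behavior at reduced scale, and limitations

On the reduced arena the predictive run reproduces the qualitative
signature suite: the error-curve symmetry axis settles near +0.85, latent
signal transfer rises from ≈ 0.3 to ≈ 0.98 while observation transfer
falls, intrinsic dimensionality drops from ≈ 9 toward ≈ 3 (the number of
latent variables), DG exceeds 1.5, and the paired autoencoding control
shows a symmetry axis at 0 with latent transfer staying below 0.5.

Two caveats are worth stating plainly. First, the participation ratio
*rises monotonically across trained checkpoints* (≈ 4.9 → 6.4), but the
untrained network — whose identity recurrence makes it a leaky integrator
of the 20-dim observation stream — already scores PR ≈ 7–9 on a probe
rollout, so the final trained PR does not exceed the raw-initialization
PR under reduced conditions; at full scale, where training runs orders of
magnitude longer, the trained representation keeps curving and PR keeps
growing. Second, the translation-invariance score of the trained card
network drops about 3× below the random baseline (under SGD; only 1.4×
under RMSprop), not more: the learned lattice geometry is concentrated in
the leading principal components of the first layer, while the remaining
dimensions retain state-idiosyncratic ("combinatorial") structure that
the loss never penalizes. The linked-pair representation distances show
the same picture: ≈ 0.4× the unlinked distance in the full space, ≈ 0.2×
in the top PCs — partial, subspace-concentrated collapse rather than the
exact additive solution.

The arm task's error curve is dominated by observation smoothness: the
trained net's axis sits at ≈ +0.9, but its absolute error at lag +1 does
not beat the (very small) lag-1 observation self-similarity — prediction
reveals itself in the asymmetry of the curve, not in beating the
copy-last-input baseline, on this task.
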