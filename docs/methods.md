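# Methods

## The model

A transcription factor (TF) at chemical potential μ binds an M-bp DNA
window with energy E; the expected occupancy of a sequence S of length
L is the sum of Fermi-like terms over all windows,

    P(S) = Σ_{i=0}^{L−M}  1 / (1 + exp(E(S_{i:i+M}) − μ)),

so lower window energy means higher occupancy, and μ (set by the
nuclear TF concentration) acts as the binding threshold.  Window energy
comes in three nested forms:

- **independent**: E = Σ_j w[j, base_j], with w an M×4 position-specific
  energy matrix (a PWM on the energy scale);
- **full dinucleotide**: the independent term plus Σ_j d[j, 4a+b] for
  the dinucleotide (a, b) at step j, with d ∈ ℝ^(M−1)×16;
- **shape-restricted dinucleotide**: the correction is expressed through
  K structural features of each dinucleotide step (helix twist, minor
  groove width, propeller twist, roll), E_shape = Σ_j Σ_k df[j,k]·F[j,k],
  where F is the per-step shape profile of the window and df ∈ ℝ^(M−1)×K
  is the TF's position-specific shape preference.

Because the shape profile of a window is a lookup into the K×16
dinucleotide table D, the shape model is exactly the dinucleotide model
restricted to the row space of D: `d = df @ D`.  This identity is used
for all heavy computation (no per-sequence shape profiles needed) and is
enforced by tests at 1e−12.

Predicted ChIP-seq signal is the affine calibration `a·P + b`.  By
default both strands are scanned (binding is strand-agnostic); a flag
restores the single-strand scan for equation-level checks.  Windows
containing N contribute zero occupancy, and training windows containing
N are dropped outright so they cannot distort the calibration.

**Sign conventions.** The occupancy exponent is exp(E − μ): positive
`df[j,k]` means high feature values *raise* the energy and *lower*
affinity.  Heatmap panels are labeled with this convention, and the
renderer has a `flip_sign` toggle for the opposite interpretive reading;
the math itself never flips.

## Fitting

Parameters W = (w, df or d, μ, a, b) minimize the regularized cost

    L  = β·L_D + Σ_i α_i·W_i²,
    L_D = ½ Σ_i (a·P(S_i) + b − t_i)²,

with grouped L2 hyperparameters: one α_w for all of w, one α_d[p] per
motif position p shared by all dependency weights at that position, and
one α_aux for (μ, a, b).  After each descent phase the hyperparameters
are re-estimated from the Bayesian evidence equations at fixed W:

    γ_i = 1 − α_i·(H⁻¹)_ii,   α_group = γ_group / Σ W_i²,
    β = (n_data − Σγ) / (2·L_D),

iterated to a fixed point (tolerance 1e−4, ≤100 inner iterations).
γ_i is the effective number of parameters; per-position grouping lets
the update clamp dependency weights at positions where they do not help
(α → large) while leaving informative positions free — this is what the
position-recovery tests exercise.  The curvature H is the Gauss–Newton
surrogate β·GᵀG + 2·diag(α) (G = per-sequence prediction gradients),
which is positive semidefinite by construction; the exact-Hessian terms
it drops involve second derivatives of the sigmoid and are not needed
for a stable evidence update.  With H ⪰ 2·diag(α), each γ_i lies in
[½, 1]; degenerate all-zero groups get α capped at 1e6, and a perfect
fit caps β at 1e12.

Fitting is two-stage: stage 1 fits (w, μ, a, b) with the correction
absent; stage 2 freezes (w, μ), re-fits (a, b) and the correction from
zero — so the stage-2 starting point reproduces the stage-1 model
exactly, and df = 0 recovers the independent model.

**Descent.** Each phase minimizes L with limited-memory BFGS (scipy
L-BFGS-B, unconstrained; memory 20, ftol 1e−9, ≤1500 iterations).  The
problem is badly conditioned: the calibration slope multiplies an
occupancy of order 10², so its curvature is ~10⁶ while informative
motif directions are nearly flat, and fixed-metric gradient steps stall
measurably (misfit pinned at the target variance).  A curvature-adaptive
method traverses this without trouble.  The per-phase cost history is
recorded and is non-increasing by the line-search contract.

**Initialization.** The default seeds w from the most enriched k-mer
(core of min(M, 8) bp, counted on both strands, above-median-signal
sequences versus the rest): consensus bases get energy 0, all others
+2, flanks 0, plus a ±1e−3 jitter to break exact ties.  This matters:
around uninformative energies the cost surface is a plateau — the
occupancy of every sequence is dominated by background windows — and
descent from a random w of any scale does not find the motif basin,
while any start inside the basin converges to the noise floor.  Random
and PWM-based initializations remain available (`init="random"`,
`init="pwm"`; JASPAR counts are converted with pseudocount 1 via
w = −log(freq/0.25)).  (a, b) start scale-matched: a = sd(t)/sd(P) with
the sign of their correlation, b matching the means.  A least-squares
start for (a, b) is deliberately avoided: at a random w it sets a ≈ 0,
and since every model-parameter gradient scales with a, that is a saddle
the fit never leaves.

The outer alternation runs up to 10 rounds and stops when L_D changes
by less than 1e−4 (relative to max(1, L_D)) between rounds; the final
state is returned, carrying the converged hyperparameters.  On the
first round α = 1e−6 and β = 1 (weak regularization).

**Identifiability.** Energies are defined up to a per-position additive
constant (absorbed by μ), and under both-strand scanning a motif and its
reverse complement are indistinguishable.  Recovery comparisons
therefore correlate per-position-centered energies and take the better
of the two orientations (`recovery_correlation`).

**Retention filter.** A fitted model is kept only if r² of predicted vs
observed signal exceeds 0.4 and the ROC AUC of occupancy for
positive vs background sequences exceeds 0.75 — both strictly.

## Variant scoring (δdbA)

For background threshold θ (a quantile, default 0.95, of log-occupancy
over a background sequence set — recorded with every report), the
above-background binding strength is dbA(x) = max(0, ln P(x) − θ) and a
variant scores δdbA = dbA(alt) − dbA(ref): negative when a site is
weakened or destroyed, positive when one is created or strengthened,
exactly zero when both alleles are below background.  Scores from
several models (e.g., alternative PWMs of the same TF) are averaged,
and variants are ranked by |mean δdbA|; no further post-processing (in
particular no PCA of score vectors) is applied.  Callers should score
windows of length ≥ 2M−1 centered on the variant so every overlapping
motif placement is scanned.  When neither allele clips, the score is
antisymmetric under swapping ref and alt; clipping breaks antisymmetry
by design.

## The dinucleotide shape table

The packaged table (`data/dinucleotide_shape_synthetic.tsv`) holds
representative B-DNA values for helix twist (°), minor groove width
(Å), propeller twist (°) and roll (°), one per dinucleotide,
reverse-complement symmetric; it is a synthetic stand-in compiled from
published crystallographic averages, not a database export, and the
test suite depends only on its 4×16 shape and the subspace identity,
never on specific values.  For fitting, each feature is z-scored across
the 16 dinucleotides (default on) so that per-position shared
regularization treats features of different physical units on one
scale; raw values remain available for reporting.  Any K×16 table in
the same TSV layout can be substituted.

## Synthetic data: what it emulates and what it does not

The generator draws exactly the data-generating process the model
assumes: i.i.d. background at a chosen GC content; one motif instance
per positive sequence at a uniform offset, with bases sampled from the
Boltzmann distribution p(a) ∝ exp(−w[j,a]) (refined by 50 single-site
Metropolis sweeps under the full window energy when a dinucleotide or
shape term is present); targets a·P + b plus Gaussian noise; and
labeled ref/alt variant pairs — positives place the full consensus
(a bound site) and destroy its most informative base, negatives mutate
plain background.  Every sampling operation derives its generator from
the study seed plus a fixed stream offset, so operations are
order-independent and reproducible.

Default study conditions used by the recovery checks: M = 8, 500 + 500
sequences of 100 bp for stage 1 with target noise at 10% of the clean
signal spread; 300 + 300 sequences of 60 bp and 10 seeded replicates
for stage-2 shape recovery.  These sizes keep a full run of the test
suite and the reproduction script in the minutes range on one core.

Real ChIP-seq differs in ways the generator deliberately omits: peaks
carry fragment-level read noise, GC and mappability biases, multiple or
partial motif instances, cofactor motifs, and nucleosome-induced shape
distortion.  Passing the recovery tests therefore shows the estimator
is correct under its own assumptions — not that those assumptions hold
in vivo.

## Numerical choices

- Sigmoids are computed in a branch-stable form; extreme energies
  neither overflow nor produce NaN.
- H is inverted with an escalating-ridge fallback (then pseudo-inverse)
  if singular.
- The evidence β update requires n_data > Σγ and rejects otherwise.
- Dinucleotide indexing is 0-based 4a+b with A,C,G,T = 0..3 throughout.
- Interval coordinates are 0-based half-open; peak windows are centered
  at floor((start+end)/2) with the window [c − w/2, c − w/2 + w).
- Negative-set sampling is without replacement of start positions and
  requires a seed.
- PR curves use rectangular (step) integration over recall; ROC ties
  count half.
- Preference matrices are compared by Pearson correlation of the
  flattened (M−1)×K matrices; a per-feature breakdown is available; a
  zero-variance matrix yields an undefined correlation, recorded as
  missing and excluded from the median.

## Known limitations

- Motif discovery from a cold start depends on the enrichment seed; a
  motif too diffuse to enrich any single k-mer (or data where the
  signal is uncorrelated with motif presence) will not be found by
  descent alone.
- The evidence update treats the Gauss–Newton matrix as the Hessian;
  for strongly non-quadratic regions the γ values are approximate.
- Occupancy is additive over windows: no cooperativity, no cofactors,
  no nucleosome competition, no methylation-aware alphabet.
- The shape table is dinucleotide-resolution; pentamer/hexamer shape
  contexts are out of scope, so inferred preferences can be offset by a
  base pair or two relative to wider-context methods.
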