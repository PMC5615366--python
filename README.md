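# shapebind

Biophysical models of transcription-factor–DNA binding with DNA shape
readout: occupancy prediction from sequence, Bayesian
evidence-regularized fitting, and δdbA variant-effect scoring, plus a
synthetic-data generator so the whole pipeline is testable without any
genomic downloads.

## Who this is for

Regulatory genomicists who want *interpretable* TF binding models
fitted to ChIP-seq-style signal: per-position binding energies (a PWM
on the energy scale), optional dinucleotide-dependency corrections, and
— the distinctive part — corrections restricted to the subspace spanned
by dinucleotide DNA shape features (helix twist, minor groove width,
propeller twist, roll), so every fitted coefficient reads directly as
"this TF prefers high/low values of this shape feature at this motif
position".

## The model

Occupancy of a sequence S is a sum of Fermi-like terms over all M-bp
windows,

    P(S) = Σᵢ 1 / (1 + exp(E(Sᵢ:ᵢ₊ₘ) − μ)),

with μ the chemical potential and window energy

    E = Σⱼ w[j, baseⱼ]                       (independent)
      + Σⱼ d[j, 4a+b]                        (full dinucleotide), or
      + Σⱼ Σₖ df[j,k] · F[j,k]               (shape-restricted),

where F is the window's per-step shape profile from a K×16 dinucleotide
table D.  Since F is a lookup into D, the shape model is exactly a
dinucleotide model with coefficients restricted to a linear subspace:
`d = df @ D`.  ChIP signal is predicted as `a·P + b`; parameters are
fitted in two stages by L-BFGS descent on the cost
`β·L_D + Σ αᵢWᵢ²`, alternating with Bayesian evidence updates of the
grouped regularization strengths (`γᵢ = 1 − αᵢ(H⁻¹)ᵢᵢ`,
`α = γ/ΣW²`, `β = (n − Σγ)/2L_D`).  Per-position grouping of the
dependency αs automatically shuts down motif positions where
dependencies do not help.  Variants are scored by the change in
above-background log-occupancy, δdbA = dbA(alt) − dbA(ref) with
dbA(x) = max(0, ln P(x) − θ); |mean δdbA| over a panel of models ranks
variants for allele-specific binding.  See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
import shapebind as sb

# ground truth: an 8-bp motif with a shape preference at step 4
table = sb.load_shape_table()
rng = np.random.default_rng(0)
true_w = rng.normal(0, 1, (8, 4)); true_w -= true_w.min(axis=1, keepdims=True); true_w *= 2
true_df = np.zeros((7, table.K)); true_df[4] = [0.9, -0.6, 0.4, 0.0]

spec = sb.SimulationSpec(M=8, true_w=true_w, true_df=true_df, table=table,
                         seq_length=60, n_pos=300, n_neg=300, noise_sd=0.02, seed=1)
data = sb.simulate_training_set(spec)

# stage 1: independent model from scratch
fit1 = sb.fit_independent(data, M=8, seed=0)
print(f"stage 1: misfit {fit1.trace[-1]['LD']:.4f}, "
      f"recovery r = {sb.recovery_correlation(fit1.model.independent.w, true_w):.3f}, "
      f"retained = {sb.retain_model(fit1, data)}")

# stage 2: shape preferences on top of the known PWM
base = sb.AffinityModel(independent=sb.IndependentModel(w=true_w, mu=0.0))
fit2 = sb.fit_correction(base, data, kind="shape", table=table, seed=0)
norms = np.linalg.norm(fit2.model.correction.df, axis=1)
print("stage 2 |df| by position:", np.array2string(norms, precision=3))
print(f"strongest shape preference at step {norms.argmax()} (planted: 4)")

# variant effect under the shape model
thr = sb.background_threshold(fit2.model, sb.sample_background(spec, n=200), 0.95)
e = sb.make_variant_benchmark(spec, 2)[0]   # a site-destroying SNV
print(f"site-destroying variant: ddbA = {sb.delta_dbA(e.ref_seq, e.alt_seq, fit2.model, thr):.3f}")
```

prints

```
stage 1: misfit 0.1176, recovery r = 0.965, retained = True
stage 2 |df| by position: [1.604e-04 5.531e-05 8.165e-05 9.042e-05 1.076e+00 1.129e-04 1.370e-04]
strongest shape preference at step 4 (planted: 4)
site-destroying variant: ddbA = -1.072
```

Reading the numbers: the independent fit reaches the noise floor of the
simulated signal and recovers the planted energies at r = 0.965 (after
per-position centering, best strand orientation), passing the retention
filter (r² > 0.4, AUC > 0.75).  In stage 2 the evidence update clamps
the shape weights at the six uninformative steps to ~1e−4 while the
planted step keeps |df| ≈ 1.1 — position-resolved shape readout.  The
site-destroying SNV gets a negative δdbA, i.e., a predicted loss of
binding.

## Command line

A thin CLI wraps the same functions:

```bash
shapebind simulate --motif-length 8 --n-pos 500 --n-neg 500 --n-variants 200 --seed 1 --out-dir study/
shapebind dataset  --genome genome.fa --peaks peaks.bed --tss tss.tsv --window 100 --max-peaks 1000 --seed 1 --out-dir data/
shapebind fit      --positives data/positives.fasta --negatives data/negatives.fasta --kind shape --motif-size 10,15,20 --seed 1 --out-dir models/
shapebind delta-dba --models models/model_shape_M10.json --variants variants.tsv --background bg.fasta --quantile 0.95 --out scores.tsv
shapebind compare-shapes --models a.json,b.json,c.json
shapebind plot     --model models/model_shape_M10.json --sign positive --out-dir plots/
```

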