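# tripletabf

Free-energy landscapes of codon–anticodon triplet binding by
adaptive-biasing-force (ABF) sampling.

## The problem

During initiation of eukaryotic translation, the scanning pre-initiation
complex must recognize the start codon by pairing it against the
initiator-tRNA anticodon in the ribosomal P-site. The cognate codon AUG
binds strongly; near-cognate codons such as GUG and CUG, which differ at
the first position, initiate much less efficiently. A quantitative handle
on this discrimination is the free-energy landscape **G(d₁, d₂, d₃)** over
the three base-pair distances dᵢ — each measured between the centers of
the Watson–Crick hydrogen-bond donor/acceptor atoms of the i-th codon base
and its paired anticodon base.

`tripletabf` is a reusable implementation of that analysis for
computational structural biologists: the ABF estimator on a 3-D
reaction-coordinate grid, the probability/free-energy conversions, binding
scores, 2-D projections, a convergence diagnostic, and bin-conditioned
structure averaging — exercised end to end on a bundled toy simulator
(analytic codon-model potentials under overdamped Langevin dynamics) that
stands in for all-atom molecular dynamics, with an exact quadrature oracle
for validation. The analysis stages read plain-text formats, so they can
equally be applied to reaction-coordinate time series exported by a real
MD engine.

## The model

Sampling runs on the grid 4.0 ≤ dᵢ ≤ 9.0 Å with bin width Δd = 0.5 Å;
half-harmonic walls (spring 10 pN/Å) restrain each dᵢ inside 3.0–10.0 Å.
Per bin, ABF accumulates the count and the instantaneous force along each
coordinate; once a bin holds 200 samples, the negated running mean force
is applied as a bias, flattening the landscape. The mean-force gradient
field is integrated to a potential of mean force by a global least-squares
(discrete Poisson) solve, and converted to a state probability by

&nbsp;&nbsp;P(d₁,d₂,d₃) = exp(−G/k_BT) / Σ exp(−G/k_BT),
&nbsp;&nbsp;G = −k_BT ln P + const,  min G = 0.

P is averaged over five independent trials per codon model, and binding is
scored by probability-weighted mean free energies over the bound
(all dᵢ ∈ [4, 6] Å) and unbound (all dᵢ ∈ [7, 9] Å) states:

&nbsp;&nbsp;ΔG_binding = G_bound − G_unbound.

Negative ΔG_binding means the triplet prefers the bound state. 2-D
projections marginalize G over one axis (P-weighted mean) and recompute
the 2-D P by Boltzmann normalization; run convergence is tracked by
L(τ, τ−Δτ) = Σ (P(·;τ) − P(·;τ−Δτ))², and representative structures are
per-atom averages over all snapshots whose reaction coordinates fall in a
chosen bin. See `docs/methods.md` for details and assumptions.

## Worked example

Run the cognate and first-position-wobble codon models (five seeded ABF
trials each, trial-averaged fields, scores, projections, convergence,
bound-bin structure), then compare:

```sh
tripletabf run --model AUG_like --seed 1 --outdir runs/aug
tripletabf run --model GUG_like --seed 1 --outdir runs/gug
tripletabf compare runs/aug runs/gug
```

prints

```
AUG_like: dg_binding (averaged field) = -3.5582 kT
GUG_like: dg_binding (averaged field) = 2.3141 kT
   model  n_trials  dg_mean_of_trials  dg_sem_of_trials  dg_averaged_field  welch_t_vs_GUG_like  welch_p_vs_GUG_like
AUG_like         5          -3.558202          0.005346          -3.558188          -531.384474         9.356790e-16
GUG_like         5           2.313904          0.009672           2.314050                  NaN                  NaN
```

The cognate model binds (ΔG_binding ≈ −3.6 k_BT: the bound state is
favoured), the wobble model is penalized (≈ +2.3 k_BT), and the Welch
t-test on the per-trial scores confirms the separation. Both score routes
are shown: the physically relevant score from the trial-averaged
probability field, and the mean ± SEM of per-trial scores used for the
significance test. The exact quadrature oracle for the same toy potential
gives −3.98 and +2.23 k_BT, so the ABF estimate recovers the landscape to
a few tenths of k_BT at this desk scale.

`tripletabf analyze runs/aug/averaged/probability_3d.tsv --outdir proj`
then writes the three 2-D projected fields and prints

```
g_bound=1.3095 kT  g_unbound=4.8677 kT  dg_binding=-3.5582 kT
```

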