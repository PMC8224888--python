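# Methods

## Reaction coordinates, grid, and fields

The three codon–anticodon base-pair distances (d₁, d₂, d₃), in Å, are the
reaction coordinates. All landscape quantities live on a regular grid,
4.0 ≤ dᵢ ≤ 9.0 with bin width 0.5 Å (10 bins per axis, 1000 bins). Bins
are half-open `[l + kΔ, l + (k+1)Δ)` with the last bin closed at the
upper bound, so the closed sampling window is tiled exactly; samples
outside the window on any axis are not accumulated.

Fields carry an explicit boolean mask of visited/defined bins. Unvisited
bins are excluded from every sum and never represented as infinite free
energies — this keeps the Boltzmann normalization over sampled states
well defined and avoids NaN propagation. Free-energy fields are stored
min-shifted (min over masked bins = 0, the published convention);
probability fields are normalized to 1 over masked bins.

Energies are internally dimensionless (k_BT units). The `Thermo` helper
(default 310 K) supplies conversions to joules and kcal/mol for
reporting, and converts the wall spring constant quoted in pN/Å:
10 pN/Å = 1 × 10⁻²¹ J/Å² ≙ 0.23364 k_BT/Å² at 310 K.

## ABF estimator

Per bin, the engine accumulates the sample count and the sum of the
instantaneous systematic force components (potential plus walls,
excluding the bias itself). The running mean force estimates −∂G/∂dᵢ.
The bias is the negated mean force, applied as a hard on/off rule once
the bin has collected `full_samples = 200` samples — the literal reading
of the activation protocol. A linear ramp variant exists
(`ABFParams(ramp=True)`) but is off by default; MD engines differ on
this point, and the hard threshold is the conservative choice.

Because the toy coordinates are themselves the dynamical variables, the
instantaneous generalized force is simply the negative gradient of
potential plus walls; there are no Jacobian/metric correction terms.
This is a stated simplification relative to all-atom ABF on derived
collective variables.

### Gradient → PMF integration

The per-bin gradient field is integrated by a global least-squares
solve: every pair of adjacent masked bins along axis a contributes the
midpoint-rule equation (G[j] − G[i])/Δ = (ĝₐ[i] + ĝₐ[j])/2. The normal
equations are solved sparsely with one gauge anchor per connected
component of the mask, and the result is min-shifted. The global solve
is robust to the estimator noise that makes a sampled gradient field
slightly non-conservative, where line integration would accumulate
path-dependent error. The midpoint rule is exact for quadratic
landscapes; components disconnected in the mask are integrated
independently (their relative offsets are not determined by the data; a
warning is logged). Checkpoints integrate a snapshot of the
accumulators into a probability field via the Boltzmann relation; per
run, checkpoints are emitted at 10 equal step intervals, and the
convergence metric L is computed between consecutive checkpoints of the
3-D field and of each 2-D projection.

### Score routes

Two distinct score routes are computed and not asserted equal: ΔG_binding
from the trial-averaged probability field (the physically relevant
number), and the mean ± SEM of per-trial ΔG_binding (the sample used for
the Welch unequal-variance t-test between codon models). Averaging P
across trials and then taking −ln differs from averaging per-trial G by a
Jensen-type inequality; both are reported in `scores.tsv`.

## Toy system (synthetic-data generator)

The generator emulates the qualitative structure of codon-dependent
triplet-binding landscapes, not all-atom energetics. Per axis, the
potential is a soft quadratic background (k = 0.6 k_BT/Å² about 6.5 Å)
carrying a Gaussian "bound" well near 4.8 Å and a Gaussian "unbound"
well near 8.0 Å (widths 0.5/0.6 Å); axes couple through products of
logistic "boundness" switches (midpoint 6.5 Å, width 0.4 Å), so joint
binding can be rewarded or penalized. Presets:

- **AUG_like** — deep bound wells (3.5 k_BT) on all axes, mild
  cooperative couplings (−0.3): strongly negative binding score.
- **GUG_like** — shallow first-position bound well (0.8), deeper
  first-position unbound well, and a strong positive d₁–d₃ coupling
  (+2.6) encoding anti-cooperativity of the first and third pairs:
  positive binding score.
- **CUG_like** — intermediate first-position well plus shallow
  mid-range minima (6.3 Å) on axes 1 and 3, giving extra metastable
  states: small positive binding score.
- **flat**, **harmonic**, **double_well_1d** — diagnostics (uniformity,
  equipartition, 1-D PMF recovery; the double well has a ~4 k_BT
  barrier with axes 2 and 3 stiffly confined).

Preset well depths and couplings were calibrated once against the
quadrature oracle to fix the sign ordering ΔG(AUG) < 0 < ΔG(CUG) ≤
ΔG(GUG) with magnitudes of a few k_BT (−3.98, +0.89, +2.23), and then
frozen. They are design targets for the generator, not fits to any
all-atom data; the toy system makes no claim about absolute energetics,
solvent, or initiation-factor contacts, so quantitative agreement of the
toy scores with experimental initiation frequencies is out of scope.

Dynamics are overdamped Langevin in reduced time units, d ← d + DFΔt +
√(2DΔt)ξ with D = 1 Å²/time and Δt = 0.01 (thermal displacement
~0.14 Å per step, well under the bin width). The nominal mapping "one
checkpoint interval ≙ 100 ns of MD" is metadata only. A random-walk
Metropolis sampler provides an independent bias-free route to the same
Boltzmann distribution, validating sampler and oracle against each
other.

The quadrature oracle computes exact bin free energies,
G = −ln ⟨e^(−U)⟩_bin, with a tensor-product midpoint rule at 10 sub-points
per axis per bin (1000 points/bin), evaluated in slabs to bound memory.
Convergence is second order (errors shrink ~4× per sub-grid doubling);
at the default resolution the max-norm error is ~10⁻² k_BT for the
sharp-welled presets and the binding score is stable to ~10⁻³ k_BT —
far below the ±0.5 k_BT band used for recovery tests.

### Toy structure frames

Frames reduce each base to its Watson–Crick donor/acceptor atoms
(A: N1,N6; U: N3,O4; G: N1,N2,O6; C: N3,N4,O2) on two strands; the codon
side is fixed and the anticodon bases are placed so the three
centroid-to-centroid distances equal the recorded reaction coordinates
exactly, then jittered (Gaussian, default σ = 0.05 Å, anticodon atoms
only). Bin-conditioned averaging selects frames with
d̃ᵢ − Δd/2 ≤ dᵢ < d̃ᵢ + Δd/2 on all axes and takes per-atom arithmetic
means with **no** prior superposition: the emulated system is
positionally restrained, so the lab frame is fixed (an optional
superposition step would be meaningful for unrestrained inputs and is
deliberately not applied). The averaged structure's coordinates are
written as single-model PDB with the contributing frame count in the
B-factor column; its reaction coordinates are recomputed from the
averaged geometry.

## Problem sizes and numerical choices

Desk-scale defaults, chosen so a full multi-model analysis completes in
minutes on one CPU: 5 trials × 4 × 10⁵ Langevin steps per codon model,
10 checkpoints per trial, 2 × 10⁶ Metropolis samples for validation,
10⁶ steps for the 1-D PMF benchmark. At these sizes the ABF landscapes
recover the oracle binding scores to ≲0.43 k_BT (the residual is
dominated by the bin-discretization difference between the mean-force
estimate at bin centers and the Boltzmann-weighted bin free energy,
largest for the deep narrow AUG-like wells — it does not shrink with
more sampling, and sits well inside the ±0.5 k_BT recovery band used in
tests). Sampling loops are numba-compiled; each run is bit-reproducible
from its integer seed, and per-trial seeds derive from one master seed
via `SeedSequence` spawning, so adding consumers never perturbs
existing streams.

Degenerate inputs are defined errors, not silent results: empty masks,
unsampled score regions, single-checkpoint convergence series,
sub-two-point t-test samples, and unpopulated structure bins all raise
with specific messages. Ties at the grid's upper edge fall in the last
bin (closed upper bound); bin-selector membership uses a strict upper
bound, as written in the selection rule.

## Known limitations

- The toy instantaneous force omits Jacobian terms present in all-atom
  ABF on derived collective variables.
- Trial runs are fully independent (no shared bias, no multiple
  walkers); combination happens only through probability averaging.
- No reweighting (WHAM/MBAR) and no per-bin error bars beyond
  across-trial dispersion.
- Plots are not produced; all outputs are numeric text formats.
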