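# Methods

## Model

A classically computed similarity T ∈ [0, 1] is amplitude-encoded into
one qubit via θ = 2·arccos(√T), so that cos²(θ/2) = T, and then spread
over three qubits by CNOT fan-out, producing the GHZ-like state
√T|000⟩ + √(1−T)|111⟩. The computational-basis distribution is
P(000) = T, P(111) = 1 − T, all others zero; the parity observable
satisfies ⟨ZZZ⟩ = 2T − 1, which is the readout channel for T. Every
single- or two-qubit X-type observable (IIX, IXI, XIX) has expectation
exactly zero on this state for every T — a useful diagnostic, since any
nonzero measured value is pure noise.

The map θ(T) is strictly decreasing, from π at T = 0 to 0 at T = 1,
steepest near the extremes; θ(0.5) = π/2 gives the balanced
superposition.

## Noise model

Gate noise is modeled as a depolarizing channel applied immediately
after each entangling gate. On a qubit subset Q of size k,

    ρ → (1 − p)·ρ + p·(I/2^k) ⊗ Tr_Q(ρ).

The default (`two_qubit_on_cnot`) applies it to the two qubits of each
CNOT; `three_qubit_global` depolarizes the whole register after each
CNOT instead. The phrase "depolarizing errors on (CX) gates" is
ambiguous about arity — CX is a two-qubit gate — so both readings are
config options rather than hard-coded. The single-qubit RY and the
measurement are noiseless by default: entangling gates dominate error
budgets on current superconducting hardware by roughly an order of
magnitude.

Under either default-arity channel the GHZ parity decays by (1 − p)
per noisy gate:

    ⟨ZZZ⟩_noisy = (1 − p)²·(2T − 1),

equivalently s_noisy = (1 + (1−p)²(2T−1))/2. Two consequences anchor
the qualitative behaviour: for T > 0.5 noise deflates the recovered
similarity, for T < 0.5 it inflates it (a dissimilar pair looks more
similar under noise), and the distortion is monotone in p. Both
directions are asserted on a p-grid in the tests. Simulated summary
tables produced by other noise parameterizations are not bit-targets:
the decay constant depends on exactly where and how the channel is
inserted, so only the closed form above (verified against an
independent matrix oracle) and the distortion directions are treated
as checkable.

## Simulation

States are dense 8×8 complex density matrices; gates act by unitary
conjugation, built from explicit 2×2 blocks and Kronecker products.
Index convention: |b0 b1 b2⟩ ↦ 4·b0 + 2·b1 + b2, i.e. the leftmost
character of a label is qubit 0; the convention is recorded in every
serialized artifact. Global phase is irrelevant (RY on |0⟩ keeps
amplitudes real and non-negative).

After the full gate sequence the state is validated: Hermiticity and
unit trace to 1e-10, eigenvalues ≥ −1e-10. Eigenvalue dust in
[−1e-10, 0) is clipped to zero and the state renormalized; anything
more negative raises an error rather than being silently repaired.

Shot sampling draws a single multinomial over the 8 diagonal
probabilities of the final (basis-rotated) density matrix using
`numpy.random.default_rng(seed)`; the seed is recorded in the counts
object. X-basis measurement is realized by a Hadamard on the flagged
qubits before sampling. Default 1000 shots per run. In sweeps, each
(rate, pair) grid cell derives an independent child seed from the
master seed via `numpy.random.SeedSequence`, so runs are reproducible
cell-by-cell and reports are byte-identical for identical configs.

## Estimation

From counts, a Pauli expectation is the signed average
⟨O⟩ = (1/S)·Σ_i s_i·C_i with s_i = (−1)^(number of 1-bits of outcome i
restricted to the observable's support). This parity convention is the
unique one making ⟨ZZZ⟩ = P(even) − P(odd) and reproducing
⟨ZZZ⟩ = 2T−1 on the encoded state. The standard error uses the
binomial form for a ±1-valued estimator, √((1−⟨O⟩²)/S). Estimating an
observable from counts taken in an incompatible basis is an error, not
a silent zero.

The product approximation reconstructs ⟨ZZZ⟩ from single-circuit
Z-basis observables as clip(⟨ZIZ⟩·⟨IZI⟩, −1, 1) — the default, chosen
because the two supports are disjoint and tile all three qubits, so
the product equals ⟨ZZZ⟩ under an independence assumption. A
three-factor composition ⟨IIZ⟩·⟨IZI⟩·⟨ZIZ⟩ is available behind a flag;
neither composition is canonical, so results carry a
`product_approx` source tag.

## Mitigation

⟨ZZZ⟩_mitigated = ⟨ZZZ⟩_noisy·e^ε, clipped to [−1, 1] (clip events are
flagged), then T_mitigated = (1 + ⟨ZZZ⟩_mitigated)/2. Three exponent
policies:

- `from_noise_p` (default): ε = p. First-order only — it recovers
  roughly half of the error at small p and undercorrects as p grows,
  which matches the qualitative finding that rescaling loses
  effectiveness above ~5% error rates.
- `calibrated`: ε = −n·ln(1−p) with n = 2 noisy gates. Since the
  default channel multiplies ⟨ZZZ⟩ by exactly (1−p)², this inverts it
  identically in exact-expectation mode; tests verify recovery of T to
  1e-10 across T ∈ {0, 0.035, 0.5, 1} and p ≤ 0.2.
- `fixed`: user-supplied ε.

Error bookkeeping: ε_abs = |s_base − s_estimated| (absolute deviation
of a recovered similarity from its classical baseline) and
ε_r = 100·(ε_unmitigated − ε_mitigated)/ε_unmitigated percent.
ε_r is undefined when the unmitigated error is zero; the pipeline
reports 0.0 only when the mitigated error is also identical, and
not-applicable otherwise. Percent values are rounded to two decimals
in tabular output; raw doubles are kept in JSON.

## Fingerprints

Morgan (ECFP-style) fingerprints come from RDKit's
`MorganGenerator`, radius 2, 2048 bits by default — the common toolkit
convention; both are exposed as parameters and recorded in a
provenance string together with the RDKit version. The Tanimoto of two
all-zero vectors is 0/0 and raises rather than returning a number,
because a silent 0 would be encoded downstream as a real similarity.

Fingerprint bit patterns, and hence third-decimal Tanimoto values for
specific molecules, can shift between toolkit releases. With the
RDKit version pinned in this environment, aspirin–butane at radius 2 /
2048 bits gives 1/28 ≈ 0.0357 (reference value from an adjacent
release: 0.035); self-similarity is exactly 1.0 regardless of version.
Tests therefore pin the invariant structure (bounds, symmetry,
self-similarity) exactly and the cross-molecule value to 1e-3.

## Synthetic fingerprint pairs

The generator builds two n-bit vectors whose Tanimoto best
approximates a target t: it scans union sizes u = 1…n, sets
i = round(u·t), and keeps the (u, i) minimizing |i/u − t| with ties
going to the smallest u; i shared on-bits and u − i exclusive bits
(alternately assigned so both vectors stay nonzero) are placed at
seeded random positions. The achieved similarity is exactly i/u and is
returned alongside the vectors. This emulates only the combinatorial
structure that the Tanimoto coefficient sees — intersection and union
cardinalities — not the correlated, hash-collision-prone bit patterns
of real circular fingerprints; passing tests demonstrate correctness
of the similarity → state → recovery chain, not chemical realism of
the vectors.

## Statistical design of the stochastic checks

Shot-level tests are fully seeded. The 1000-shot consistency check
compares the counts-based ⟨ZZZ⟩ against the exact trace value for 100
consecutive seeds with a 3-standard-error band; since a single
independent draw exceeds 3σ with probability ≈ 0.27%, up to two
exceedances in 100 are within statistical expectation and more than
two fail the test. The noiseless goodness-of-fit check runs a
chi-square test of 10⁴-shot counts against P(000) = t, P(111) = 1 − t
over 10 seeds at the 1% level, requiring at least 80% non-rejections.
Problem sizes (8-dimensional states, ≤10⁵ shots, grids of ≤ a few
hundred points) keep the whole suite in a few seconds.

## Known limitations

- Noise is restricted to depolarizing channels after entangling gates;
  amplitude damping, crosstalk, readout error and dynamical decoupling
  are out of scope.
- The calibrated exponent inverts only the package's own default
  channel; on hardware, ε would need empirical calibration.
- The product approximation assumes independence of the factor
  observables, which entanglement violates in general; it is flagged
  approximate and never fed into the mitigation chain.
- No transpilation or hardware backend: the simulator is the backend.
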