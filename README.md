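# qtanimoto

Quantum-encoded molecular similarity under depolarizing noise, with
exponential error mitigation.

## The problem

Tanimoto (Jaccard) similarity over binary molecular fingerprints,

    T(A, B) = |A ∩ B| / |A ∪ B|,

is the workhorse comparison metric of chemoinformatics. `qtanimoto`
studies how faithfully such a classically computed similarity survives
being written into — and read back out of — a small entangled quantum
register on noisy (NISQ-era) hardware. It is aimed at researchers
benchmarking noise resilience and error-mitigation protocols with a
chemically meaningful, minimal test circuit.

The encoding maps T to a rotation angle θ = 2·arccos(√T) and prepares
the 3-qubit GHZ-like state

    |ψ⟩ = √T |000⟩ + √(1−T) |111⟩

with one RY(θ) on qubit 0 followed by CNOTs 0→1 and 0→2. Measuring all
qubits gives |000⟩ with probability T, and the parity observable obeys
⟨ZZZ⟩ = 2T − 1, so T = (1 + ⟨ZZZ⟩)/2.

Depolarizing noise of strength p after each CNOT (on that CNOT's qubit
pair, by default) shrinks the parity to

    ⟨ZZZ⟩_noisy = (1 − p)² (2T − 1),

which inflates the recovered similarity of dissimilar pairs and
deflates it for similar pairs. Exponential mitigation rescales the
noisy expectation, ⟨ZZZ⟩_mitigated = ⟨ZZZ⟩_noisy · e^ε (clipped to
[−1, 1]); with the calibrated exponent ε = −2·ln(1−p) this inverts the
default channel exactly. Recovery quality is tracked by the absolute
error ε_abs = |s_base − s_estimated| and the percent error reduction
ε_r = 100·(ε_unmitigated − ε_mitigated)/ε_unmitigated.

The package contains:

- `fingerprints` — RDKit Morgan/ECFP fingerprints and the Tanimoto
  coefficient (plus a direct-similarity entry path),
- `encoding` — the T ↔ θ maps, circuit builder and ideal state,
- `simulator` — exact 8×8 density-matrix evolution with configurable
  depolarizing noise and seeded multinomial shot sampling,
- `observables` — Pauli expectations from counts or traces,
  ideal-vs-noisy probability deltas, and a product approximation of
  ⟨ZZZ⟩ from single-circuit Z observables,
- `mitigation` — exponential rescaling, similarity recovery, error
  metrics,
- `pipeline` — end-to-end runs, noise sweeps, synthetic fingerprint
  pairs, CSV/JSON reports, and the `qtanimoto` CLI.

## Worked example

The similarity front end, on the two reference molecules:

```
$ qtanimoto similarity "CC(=O)OC1=CC=CC=C1C(=O)O" "CCCC"
{
  "t_value": 0.03571428571428571,
  "label": "CC(=O)OC1=CC=CC=C1C(=O)O|CCCC",
  "method": "morgan_tanimoto",
  "radius": 2,
  "n_bits": 2048,
  "provenance": "rdkit=2024.09.2 morgan radius=2 n_bits=2048"
}
```

Aspirin and butane share 1 of 28 set fingerprint bits, so T = 1/28 ≈
0.036 (the exact third decimal shifts slightly between RDKit
releases). Aspirin against itself gives T = 1.0.

A noise sweep in exact-expectation mode, with the default ε = p
mitigation policy:

```
$ qtanimoto sweep --t 1.0 --t 0.035 --mode exact
error_level_pct,pair,baseline,unmitigated,mitigated,eps_unmitigated,eps_mitigated,eps_reduction_pct
0.1,direct_t=0.035,0.035,0.03592953500000001,0.03546523242240307,0.0009295350000000091,0.00046523242240306684,49.95
0.1,direct_t=1.0,1.0,0.9990005,0.9994997500834375,0.000999500000000042,0.0005002499165625007,49.95
1.0,direct_t=0.035,0.035,0.04425350000000006,0.039673171526975304,0.009253500000000053,0.0046731715269753005,49.5
1.0,direct_t=1.0,1.0,0.99005,0.9949750843795965,0.009950000000000014,0.005024915620403525,49.5
...
10.0,direct_t=0.035,0.035,0.12335000000000002,0.08373737370680728,0.08835000000000001,0.04873737370680728,44.84
10.0,direct_t=1.0,1.0,0.905,0.9475942218206372,0.09499999999999997,0.05240577817936276,44.84
```

Reading the rows: at a 1% depolarizing rate the similar pair's
unmitigated similarity has decayed to 0.990 and the dissimilar pair's
has inflated to 0.044; mitigation pulls both roughly halfway back
(ε = p corrects the channel only to first order — pass
`--eps-policy calibrated` for exact inversion, which recovers the
baseline to 10 significant figures in exact mode). At 10% noise the
dissimilar pair has drifted to 0.123, and mitigation is proportionally
less effective — the characteristic failure mode of NISQ-era rescaling.

Other subcommands: `encode` (θ and circuit JSON for a given T),
`simulate` (single noisy run), `synth` (random fingerprint pair with a
target Tanimoto value).

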