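"""End-to-end experiment orchestration and noise sweeps.

One experiment: similarity T (from a molecule pair or given directly)
→ rotation angle → circuit → noisy density-matrix simulation → ⟨ZZZ⟩
estimate (exact trace or seeded shot counts) → exponential mitigation →
recovered similarities and error metrics.  A sweep repeats this over a
grid of depolarizing rates and pairs, producing a table with one row
per (rate, pair).

Also hosts the synthetic fingerprint-pair generator used throughout the
test fixtures: given a target similarity it finds the intersection/union
pair (i, u) whose ratio best approximates the target and lays the bits
out at seeded random positions.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import angle_from_similarity, build_circuit
from .fingerprints import (
    FingerprintVector,
    MoleculePair,
    SimilarityRecord,
    similarity_from_pair,
)
from .mitigation import (
    MitigationConfig,
    MitigationResult,
    error_metric,
    error_reduction,
    mitigate_expectation,
    resolve_epsilon,
    similarity_from_zzz,
)
from .observables import PauliObservable, exact_expectation, expectation_from_counts
from .errors import UndefinedErrorReductionError
from .simulator import NoiseSpec, run_circuit

# noise levels of the reference sweep (percent/100); a log-dense
# 1e-3..1e-1 grid is available via log_spaced_rates()
DEFAULT_ERROR_RATES = (0.001, 0.01, 0.015, 0.05, 0.10)

TABLE_COLUMNS = (
    "error_level_pct",
    "pair",
    "baseline",
    "unmitigated",
    "mitigated",
    "eps_unmitigated",
    "eps_mitigated",
    "eps_reduction_pct",
)

_ZZZ = PauliObservable("ZZZ")


def log_spaced_rates(n: int = 20, low: float = 1e-3, high: float = 1e-1) -> tuple[float, ...]:
    """Logarithmically spaced depolarizing rates, default 10⁻³…10⁻¹."""
    return tuple(float(x) for x in np.logspace(np.log10(low), np.log10(high), n))


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of a sweep: pairs, noise grid, sampling, policies."""

    pairs: tuple[SimilarityRecord, ...]
    error_rates: tuple[float, ...] = DEFAULT_ERROR_RATES
    shots: int = 1000
    seed: int = 0
    noise_arity: str = "two_qubit_on_cnot"
    mitigation: MitigationConfig = field(default_factory=MitigationConfig)
    mode: str = "exact"  # "exact" | "shots"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("need at least one pair")
        if not self.error_rates:
            raise ValueError("need at least one error rate")
        if any(not 0.0 <= r < 1.0 for r in self.error_rates):
            raise ValueError("error rates must lie in [0, 1)")
        if self.shots < 1:
            raise ValueError("shots must be >= 1")


@dataclass(frozen=True)
class SweepTable:
    """Ordered mitigation results, one row per (error level, pair label)."""

    rows: tuple[MitigationResult, ...]
    config: ExperimentConfig

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "error_level_pct": 100.0 * r.error_rate,
                    "pair": r.label,
                    "baseline": r.t_base,
                    "unmitigated": r.t_noisy,
                    "mitigated": r.t_mitigated,
                    "eps_unmitigated": r.eps_unmitigated,
                    "eps_mitigated": r.eps_mitigated,
                    "eps_reduction_pct": (
                        round(r.eps_reduction_pct, 2)
                        if r.eps_reduction_pct is not None
                        else None
                    ),
                }
            )
        return pd.DataFrame.from_records(records, columns=list(TABLE_COLUMNS))

    def provenance(self) -> dict:
        cfg = self.config
        return {
            "seed": cfg.seed,
            "shots": cfg.shots,
            "mode": cfg.mode,
            "noise_arity": cfg.noise_arity,
            "epsilon_policy": cfg.mitigation.epsilon_policy,
            "error_rates": list(cfg.error_rates),
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        }


def _run_seed(base_seed: int, rate_index: int, pair_index: int) -> int:
    # independent, reproducible stream per grid cell; kept below 2^31
    ss = np.random.SeedSequence([base_seed, rate_index, pair_index])
    return int(ss.generate_state(1)[0] % 2**31)


def run_experiment(
    record: SimilarityRecord,
    rate: float,
    config: ExperimentConfig,
    run_seed: int | None = None,
) -> MitigationResult:
    """Encode one similarity, simulate it at one noise level, mitigate."""
    t_base = record.t_value
    angle = angle_from_similarity(t_base)
    circuit = build_circuit(angle)
    noise = NoiseSpec(p=rate, arity=config.noise_arity) if rate > 0.0 else None
    if run_seed is None:
        run_seed = config.seed
    rho, counts = run_circuit(
        circuit, noise=noise, mode=config.mode, shots=config.shots, seed=run_seed
    )
    if config.mode == "exact":
        zzz_noisy = exact_expectation(rho, _ZZZ).value
    else:
        zzz_noisy = expectation_from_counts(counts, _ZZZ).value
    epsilon = resolve_epsilon(config.mitigation, noise)
    mit_config = replace(config.mitigation, epsilon=epsilon, epsilon_policy="fixed")
    zzz_mit = mitigate_expectation(zzz_noisy, mit_config)
    clipped = zzz_mit != zzz_noisy * np.exp(epsilon)
    t_noisy = similarity_from_zzz(zzz_noisy, clip=True)
    t_mit = similarity_from_zzz(zzz_mit, clip=True)
    eps_u = error_metric(t_base, t_noisy)
    eps_m = error_metric(t_base, t_mit)
    try:
        reduction = error_reduction(eps_u, eps_m)
    except UndefinedErrorReductionError:
        reduction = 0.0 if eps_m == eps_u else None
    return MitigationResult(
        error_rate=rate,
        label=record.label,
        t_base=t_base,
        t_noisy=t_noisy,
        t_mitigated=t_mit,
        zzz_noisy=zzz_noisy,
        zzz_mitigated=zzz_mit,
        epsilon=epsilon,
        eps_unmitigated=eps_u,
        eps_mitigated=eps_m,
        eps_reduction_pct=reduction,
        clipped=clipped,
    )


def run_sweep(config: ExperimentConfig) -> SweepTable:
    """Complete (rate × pair) grid, rows sorted by rate then pair label."""
    rows = []
    rates = sorted(config.error_rates)
    pairs = sorted(config.pairs, key=lambda r: r.label)
    for i, rate in enumerate(rates):
        for j, record in enumerate(pairs):
            seed = _run_seed(config.seed, i, j)
            rows.append(run_experiment(record, rate, config, run_seed=seed))
    return SweepTable(rows=tuple(rows), config=config)


def pairs_from_smiles(
    smiles_pairs, radius: int = 2, n_bits: int = 2048
) -> tuple[SimilarityRecord, ...]:
    """Convenience: SimilarityRecords for (smiles_a, smiles_b, label) triples."""
    records = []
    for sa, sb, label in smiles_pairs:
        pair = MoleculePair(smiles_a=sa, smiles_b=sb, label=label)
        records.append(similarity_from_pair(pair, radius=radius, n_bits=n_bits))
    return tuple(records)


def generate_synthetic_pair(
    n_bits: int, target_t: float, seed: int
) -> tuple[FingerprintVector, FingerprintVector, float]:
    """Random fingerprint pair whose Tanimoto best approximates a target.

    Searches union sizes u ≤ n_bits and intersections i = round(u·t) for
    the ratio i/u closest to the target (ties go to the smallest u),
    then places i shared on-bits and u−i exclusive bits — split between
    the two vectors so each stays nonzero — at seeded random positions.
    The achieved similarity is exactly i/u.
    """
    if not 0.0 <= target_t <= 1.0:
        raise ValueError(f"target similarity must lie in [0, 1], got {target_t}")
    if n_bits < 2:
        raise ValueError("n_bits must be >= 2 to host two nonzero fingerprints")
    best: tuple[float, int, int] | None = None  # (|i/u - t|, u, i)
    for u in range(1, n_bits + 1):
        i = int(round(target_t * u))
        i = max(0, min(u, i))
        if i == 0 and u < 2:
            continue  # both vectors must keep at least one on-bit
        err = abs(i / u - target_t)
        if best is None or err < best[0] - 1e-15:
            best = (err, u, i)
    if best is None:
        raise ValueError(f"no feasible construction for n_bits={n_bits}")
    _, u, i = best
    rng = np.random.default_rng(seed)
    positions = rng.choice(n_bits, size=u, replace=False)
    shared = positions[:i]
    exclusive = positions[i:]
    bits_a = np.zeros(n_bits, dtype=np.uint8)
    bits_b = np.zeros(n_bits, dtype=np.uint8)
    bits_a[shared] = 1
    bits_b[shared] = 1
    bits_a[exclusive[0::2]] = 1
    bits_b[exclusive[1::2]] = 1
    prov = f"synthetic u={u} i={i} seed={seed}"
    fa = FingerprintVector.from_bits(bits_a, provenance=prov)
    fb = FingerprintVector.from_bits(bits_b, provenance=prov)
    return fa, fb, i / u


def write_report(table: SweepTable, path: str, format: str = "csv") -> None:
    """Serialize a sweep table (CSV with a provenance header, or JSON)."""
    if not table.rows:
        raise ValueError("cannot write an empty table")
    df = table.to_dataframe()
    if format == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            for key, val in table.provenance().items():
                fh.write(f"# {key}: {val}\n")
            df.to_csv(fh, index=False)
    elif format == "json":
        payload = {
            "provenance": table.provenance(),
            "rows": df.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_report(path: str, format: str = "csv") -> pd.DataFrame:
    """Read back a sweep report written by :func:`write_report`."""
    if format == "csv":
        return pd.read_csv(path, comment="#")
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return pd.DataFrame.from_records(payload["rows"], columns=list(TABLE_COLUMNS))
    raise ValueError(f"unknown format: {format!r}")
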