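"""Exponential error mitigation of noisy GHZ-parity expectations.

The noisy expectation is rescaled as ⟨ZZZ⟩_mitigated = ⟨ZZZ⟩_noisy·e^ε
and clipped to the physical range [−1, 1]; the similarity is then
recovered via T = (1 + ⟨ZZZ⟩)/2.  Three policies set the exponent ε:

``from_noise_p`` (default)
    ε equals the depolarizing probability p — the "ε is the chance of
    error" reading; approximate, exact only to first order in p.
``calibrated``
    ε = −n·ln(1−p) with n the number of noisy entangling gates (2
    here).  Because the default channel shrinks ⟨ZZZ⟩ by exactly
    (1−p)ⁿ, this exponent inverts it identically in exact-expectation
    mode.
``fixed``
    A user-supplied ε.

Error bookkeeping: ε_abs = |s_base − s_estimated| (absolute deviation
of a recovered similarity from the classical baseline) and the error
reduction ε_r = 100·(ε_unmitigated − ε_mitigated)/ε_unmitigated in
percent, which is negative when mitigation overshoots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, UndefinedErrorReductionError
from .simulator import NoiseSpec


@dataclass(frozen=True)
class MitigationConfig:
    """Exponent policy and clipping behaviour for exponential rescaling."""

    epsilon: float = 0.0
    clip: bool = True
    epsilon_policy: str = "from_noise_p"  # "fixed" | "from_noise_p" | "calibrated"

    def __post_init__(self) -> None:
        if self.epsilon < 0.0:
            raise DomainError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.epsilon_policy not in ("fixed", "from_noise_p", "calibrated"):
            raise ValueError(f"unknown epsilon policy: {self.epsilon_policy!r}")


@dataclass(frozen=True)
class MitigationResult:
    """One pipeline run: noisy and mitigated parities, recovered similarities
    and error metrics, keyed by the noise level and pair label."""

    error_rate: float
    label: str
    t_base: float
    t_noisy: float
    t_mitigated: float
    zzz_noisy: float
    zzz_mitigated: float
    epsilon: float
    eps_unmitigated: float
    eps_mitigated: float
    eps_reduction_pct: float | None
    clipped: bool = False


def mitigate_expectation(zzz_noisy: float, config: MitigationConfig) -> float:
    """Rescale a noisy expectation by e^ε, clipping to [−1, 1] if configured."""
    if abs(zzz_noisy) > 1.0 + 1e-12:
        raise DomainError(f"|zzz_noisy| must be <= 1, got {zzz_noisy}")
    value = zzz_noisy * math.exp(config.epsilon)
    if config.clip:
        value = max(-1.0, min(1.0, value))
    return value


def similarity_from_zzz(zzz: float, clip: bool = False) -> float:
    """Recover the similarity T = (1 + ⟨ZZZ⟩)/2 from a parity expectation."""
    if clip:
        zzz = max(-1.0, min(1.0, zzz))
    elif not -1.0 <= zzz <= 1.0:
        raise DomainError(f"zzz must lie in [-1, 1], got {zzz}")
    return (1.0 + zzz) / 2.0


def error_metric(s_base: float, s_estimated: float) -> float:
    """Absolute deviation |s_base − s_estimated| of a recovered similarity."""
    for name, s in (("s_base", s_base), ("s_estimated", s_estimated)):
        if not 0.0 <= s <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {s}")
    return abs(s_base - s_estimated)


def error_reduction(eps_unmitigated: float, eps_mitigated: float) -> float:
    """Percent error reduction 100·(ε_u − ε_m)/ε_u; negative if worsened.

    Raises :class:`UndefinedErrorReductionError` when the unmitigated
    error is zero (the relative reduction has no value).
    """
    if eps_unmitigated < 0.0 or eps_mitigated < 0.0:
        raise DomainError("error magnitudes must be >= 0")
    if eps_unmitigated == 0.0:
        raise UndefinedErrorReductionError(
            "error reduction is undefined when the unmitigated error is 0"
        )
    return 100.0 * (eps_unmitigated - eps_mitigated) / eps_unmitigated


def calibrated_epsilon(noise: NoiseSpec, n_noisy_gates: int = 2) -> float:
    """Exponent ε = −n·ln(1−p) that exactly inverts the depolarizing decay.

    The default channel multiplies ⟨ZZZ⟩ by (1−p) per noisy gate, so
    rescaling by e^ε = (1−p)^−n recovers the noiseless expectation
    identically (in exact-expectation mode).
    """
    if noise.p >= 1.0:
        raise DomainError("calibrated epsilon diverges at p = 1")
    if n_noisy_gates < 0:
        raise ValueError("n_noisy_gates must be >= 0")
    return -n_noisy_gates * math.log(1.0 - noise.p)


def resolve_epsilon(
    config: MitigationConfig, noise: NoiseSpec | None, n_noisy_gates: int = 2
) -> float:
    """Concrete exponent for a run, according to the configured policy."""
    if config.epsilon_policy == "fixed":
        return config.epsilon
    p = 0.0 if noise is None else noise.p
    if config.epsilon_policy == "from_noise_p":
        return p
    return calibrated_epsilon(NoiseSpec(p=p), n_noisy_gates)
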