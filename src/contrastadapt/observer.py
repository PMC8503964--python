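"""Generative simulated observer.

The observer produces contrast matches according to a log-log matching law
with an adaptation-dependent intercept and slope:

    ln(match) = (b0 + u) + b1*ln(c) + [b2 + b3*ln(c)] * 1{adaptation} + eps

where ``c`` is the reference (upper) contrast, ``u`` is a per-observer
intercept deviation, and ``eps ~ N(0, sigma_eps^2)`` is trial noise on the
natural-log scale (so matches are lognormal around the matching law).  The
default coefficients are the fitted population values from the two-observer
replication dataset, making analysis-side parameter recovery target those
same numbers.

The real generative process of a human observer is of course unknown; this
lognormal formulation simply mirrors the error structure of the model the
analysis fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ObserverParams",
    "PopulationParams",
    "expected_log_match",
    "simulate_match",
    "sample_observer",
]

CONTROL = "control"
ADAPTATION = "adaptation"


def _check_condition(condition: str) -> bool:
    if condition not in (CONTROL, ADAPTATION):
        raise ValueError(f"condition must be '{CONTROL}' or '{ADAPTATION}'")
    return condition == ADAPTATION


@dataclass(frozen=True)
class ObserverParams:
    """Coefficients of one observer's matching law (natural-log scale).

    beta0: control intercept; beta1: slope vs ln(upper contrast);
    beta2: adaptation intercept shift; beta3: adaptation slope increment;
    sigma_eps: trial-noise SD; id_offset: this observer's intercept deviation.
    """

    beta0: float = -0.084
    beta1: float = 0.982
    beta2: float = 0.052
    beta3: float = 0.443
    sigma_eps: float = 0.2875
    id_offset: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.beta0, self.beta1, self.beta2, self.beta3, self.sigma_eps, self.id_offset)
        if not all(np.isfinite(vals)):
            raise ValueError("all observer parameters must be finite")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")


@dataclass(frozen=True)
class PopulationParams:
    """Population-level matching law: fixed effects plus the SD of the
    per-observer intercept deviation (``sigma_id``)."""

    beta0: float = -0.084
    beta1: float = 0.982
    beta2: float = 0.052
    beta3: float = 0.443
    sigma_eps: float = 0.2875
    sigma_id: float = 0.0424

    def __post_init__(self) -> None:
        if self.sigma_id < 0:
            raise ValueError("sigma_id must be >= 0")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")


def expected_log_match(p: ObserverParams, condition: str, c: float) -> float:
    """Deterministic part of the matching law: E[ln(match)] at contrast ``c``."""
    if not c > 0:
        raise ValueError("upper contrast must be > 0")
    is_adapt = _check_condition(condition)
    lc = np.log(c)
    mu = p.beta0 + p.id_offset + p.beta1 * lc
    if is_adapt:
        mu += p.beta2 + p.beta3 * lc
    return float(mu)


def simulate_match(
    p: ObserverParams, condition: str, c: float, rng: np.random.Generator
) -> float:
    """One noisy match: exp(E[ln match] + eps), eps ~ N(0, sigma_eps^2).

    The returned value is the observer's *intended* match; the session
    engine clamps it into the active slider's range and quantizes it onto
    the nearest slider position.
    """
    mu = expected_log_match(p, condition, c)
    eps = rng.normal(0.0, p.sigma_eps) if p.sigma_eps > 0 else 0.0
    with np.errstate(over="ignore"):  # inf is caught by the session engine
        return float(np.exp(mu + eps))


def sample_observer(
    pop: PopulationParams, rng: np.random.Generator
) -> ObserverParams:
    """Draw one observer: fixed effects copied, id_offset ~ N(0, sigma_id^2)."""
    offset = rng.normal(0.0, pop.sigma_id) if pop.sigma_id > 0 else 0.0
    return ObserverParams(
        beta0=pop.beta0,
        beta1=pop.beta1,
        beta2=pop.beta2,
        beta3=pop.beta3,
        sigma_eps=pop.sigma_eps,
        id_offset=float(offset),
    )
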