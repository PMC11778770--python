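"""Sample-size mathematics for estimating a clinic's viral-suppression
proportion to a chosen precision.

The unadjusted size for a 95% confidence interval of half-width ``e`` around
an anticipated proportion ``p`` is

    n0 = z^2 * p * (1 - p) / e^2        (z^2 = 3.84 by default)

and, because clinic populations are finite, it is shrunk by the finite
population correction

    n = n0 / (1 + (n0 - 1) / N)

then rounded up and capped at N. The same n is used to estimate both the
on-ART and the virally-suppressed proportions; sizing on the suppression
proportion is conservative for the (usually higher) ART proportion only when
p_ART is further from 0.5, which holds in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import DomainError, PrecisionCategory, PrecisionLevel

#: z^2 for a 95% confidence interval, at the printed two-figure precision.
DEFAULT_Z_SQUARED = 3.84

#: Data-entry workload assumption: minutes per patient record.
DEFAULT_MINUTES_PER_PATIENT = 15.0

#: Named accuracy levels -> confidence-interval half-width (0-1 scale).
PRECISION_PRESETS = {
    PrecisionCategory.VERY_HIGH: 0.025,
    PrecisionCategory.HIGH: 0.05,
    PrecisionCategory.MODERATE: 0.10,
}


@dataclass(frozen=True)
class SampleSizeResult:
    """A sample-size calculation with its inputs and workload estimate."""

    population_size: int
    p: float
    e: float
    n0: float
    n_adjusted: float
    n_required: int
    workload_hours: float

    def __post_init__(self):
        if not 0 <= self.n_required <= self.population_size:
            raise DomainError("n_required must lie in [0, N]")


def _check_domain(p: float, e: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"anticipated proportion p must be in [0, 1], got {p}")
    if not 0.0 < e < 0.5:
        raise DomainError(f"half-width e must be in (0, 0.5), got {e}")


def unadjusted_sample_size(p: float, e: float,
                           z_squared: float = DEFAULT_Z_SQUARED) -> float:
    """Infinite-population sample size n0 = z^2 * p * (1-p) / e^2."""
    _check_domain(p, e)
    if z_squared <= 0:
        raise DomainError(f"z_squared must be positive, got {z_squared}")
    return z_squared * p * (1.0 - p) / (e * e)


def fpc_adjust(n0: float, N: int) -> float:
    """Finite population correction: n = n0 / (1 + (n0 - 1)/N)."""
    if N < 1:
        raise DomainError(f"population size N must be >= 1, got {N}")
    if n0 < 0:
        raise DomainError(f"n0 must be nonnegative, got {n0}")
    return n0 / (1.0 + (n0 - 1.0) / N)


def required_sample_size(
    N: int,
    p: float,
    e: float,
    z_squared: float = DEFAULT_Z_SQUARED,
    minutes_per_patient: float = DEFAULT_MINUTES_PER_PATIENT,
) -> SampleSizeResult:
    """Required random-sample size for a clinic of N people.

    Composes the unadjusted formula with the finite population correction,
    rounds up to the next whole person (never under-powering), caps at N, and
    attaches the data-entry workload estimate (15 minutes per patient by
    default).
    """
    if N < 1:
        raise DomainError(f"population size N must be >= 1, got {N}")
    n0 = unadjusted_sample_size(p, e, z_squared)
    n_adj = fpc_adjust(n0, N)
    n_req = min(math.ceil(n_adj), N)
    return SampleSizeResult(
        population_size=N,
        p=p,
        e=e,
        n0=n0,
        n_adjusted=n_adj,
        n_required=n_req,
        workload_hours=n_req * minutes_per_patient / 60.0,
    )


def precision_for_level(level: PrecisionCategory | str) -> float:
    """Half-width e for a named accuracy level.

    very_high -> 0.025, high -> 0.05, moderate -> 0.10. The 'high' level is
    the +/-5 percentage-point setting used when validating the tool; the
    other two bracket it symmetrically on the log scale.
    """
    try:
        level = PrecisionCategory(level)
    except ValueError:
        raise DomainError(f"unknown precision level: {level!r}") from None
    return PRECISION_PRESETS[level]


def precision_level(level: PrecisionCategory | str) -> PrecisionLevel:
    """The :class:`PrecisionLevel` object for a named accuracy level."""
    cat = PrecisionCategory(level)
    return PrecisionLevel(level=cat, e=PRECISION_PRESETS[cat])
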