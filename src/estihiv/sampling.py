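"""Random-sample selection: systematic every-k-th selection for ordered paper
files, and seeded uniform random sampling without replacement.

Systematic sampling suits clinics working from a physically ordered file
(alphabetical, by date of birth, by region ...): take every k-th record,
k = floor(N/n), starting from a chosen (or randomized) offset, continuing —
wrapping past the end of the file — until the target count is reached.
Uniform random sampling is the reference method used to validate the tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .core_model import DomainError


@dataclass(frozen=True)
class SamplePlan:
    """An auditable record of one sample selection."""

    method: Literal["systematic", "uniform_random"]
    N: int
    n: int
    selected_ids: tuple[str, ...]
    interval_k: Optional[int] = None
    start_offset: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.selected_ids) != self.n:
            raise DomainError("plan must contain exactly n ids")
        if len(set(self.selected_ids)) != self.n:
            raise DomainError("selected ids must be distinct")


def systematic_interval(N: int, n: int) -> int:
    """Selection interval k = floor(N/n) for an ordered file of N records.

    E.g. a clinic of 200 needing a sample of 25 picks every 8th patient.
    """
    if n < 1:
        raise DomainError(f"sample size n must be >= 1, got {n}")
    if n > N:
        raise DomainError(f"sample size n={n} exceeds population N={N}")
    return N // n


def systematic_sample(
    ordered_ids: Sequence[str],
    n: int,
    start_offset: Optional[int] = None,
    seed: Optional[int] = None,
) -> SamplePlan:
    """Every-k-th selection from an ordered file, wrapping until n distinct
    ids are selected.

    ``start_offset`` is 1-based in [1, k]; when omitted it is drawn uniformly
    from [1, k] with ``seed`` (a random start keeps the design unbiased).
    When the wrap-around revisits already-selected positions (possible when k
    shares a factor with N), the walk shifts one position forward and
    continues, guaranteeing n distinct selections for any n <= N.
    """
    ids = list(ordered_ids)
    N = len(ids)
    if len(set(ids)) != N:
        raise DomainError("ordered_ids must be distinct")
    k = systematic_interval(N, n)
    if start_offset is None:
        if seed is None:
            raise DomainError("provide start_offset or a seed to randomize the start")
        start_offset = int(np.random.default_rng(seed).integers(1, k + 1))
    if not 1 <= start_offset <= k:
        raise DomainError(f"start_offset must be in [1, {k}], got {start_offset}")

    selected: list[int] = []
    taken = np.zeros(N, dtype=bool)
    pos = start_offset - 1
    while len(selected) < n:
        if taken[pos]:
            pos = (pos + 1) % N  # cycle exhausted; shift and keep walking
            continue
        taken[pos] = True
        selected.append(pos)
        pos = (pos + k) % N
    return SamplePlan(
        method="systematic",
        N=N,
        n=n,
        selected_ids=tuple(ids[i] for i in selected),
        interval_k=k,
        start_offset=start_offset,
        seed=seed,
    )


def uniform_random_sample(ids: Sequence[str], n: int, seed: int) -> SamplePlan:
    """Simple random sample without replacement via a seeded uniform RNG.

    Ids are canonically sorted before drawing, so the same (ids, n, seed)
    triple yields the same sample regardless of input row order.
    """
    pool = sorted(set(ids))
    if len(pool) != len(ids):
        raise DomainError("ids must be distinct")
    N = len(pool)
    if n < 1:
        raise DomainError(f"sample size n must be >= 1, got {n}")
    if n > N:
        raise DomainError(f"sample size n={n} exceeds population N={N}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(N, size=n, replace=False)
    return SamplePlan(
        method="uniform_random",
        N=N,
        n=n,
        selected_ids=tuple(pool[i] for i in chosen),
        seed=seed,
    )
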