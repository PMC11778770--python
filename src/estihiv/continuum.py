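"""The last two stages of the HIV continuum of care: the percentage of people
in care who are on antiretroviral therapy (ART) and the percentage virally
suppressed (VS), each with a 95% Wald confidence interval.

Classification rules:

* VS: most recent viral load strictly below the threshold (<200 copies/ml by
  default; some settings use <500), or below a declared assay limit of
  detection when that limit is at or above the threshold. A person with no
  viral-load measurement counts as NOT suppressed (missing-as-failure).
* ART: on treatment iff the recorded status is "yes"; unknown status counts
  as not on ART, mirroring the missing-as-failure convention (a logged,
  configurable choice — complete-case mode drops unknowns instead).

Both percentages use the full number in care as the denominator (not the
cascading denominators of the UNAIDS 95-95-95 framework).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional

from scipy import stats

from .core_model import (
    ArtStatus,
    ClinicPopulation,
    DomainError,
    EmptyPopulationError,
    PatientRecord,
)

logger = logging.getLogger("estihiv")

#: Groups smaller than this are masked in stratified output (privacy).
DEFAULT_MASKING_MINIMUM = 5


@dataclass(frozen=True)
class ContinuumEstimate:
    """Point estimates and 95% CIs for the in-care -> ART -> VS stages."""

    n_in_care: int
    n_art: int
    pct_art: float
    art_ci: tuple[float, float]
    n_vs: int
    pct_vs: float
    vs_ci: tuple[float, float]
    n_missing_vl: int
    pct_missing_vl: float
    vs_threshold: int
    group_label: str = ""
    masked: bool = False

    def __post_init__(self):
        if self.n_in_care <= 0:
            raise DomainError("denominator must be positive")
        for count in (self.n_art, self.n_vs, self.n_missing_vl):
            if not 0 <= count <= self.n_in_care:
                raise DomainError("stage counts must lie in [0, n_in_care]")


def classify_vs(record: PatientRecord, threshold: int = 200,
                lod: Optional[int] = None) -> bool:
    """True iff the record counts as virally suppressed.

    Suppressed requires a measured viral load below ``threshold`` — or below
    a dataset-level assay limit of detection ``lod`` when lod >= threshold
    (a value reported "below LOD" cannot be distinguished from suppressed).
    Missing viral load is never suppressed.
    """
    if threshold <= 0:
        raise DomainError(f"vs threshold must be positive, got {threshold}")
    if record.last_vl is None:
        return False
    if record.last_vl < 0:
        raise DomainError(f"negative viral load: {record.last_vl}")
    effective = threshold
    if lod is not None and lod >= threshold:
        effective = lod
    return record.last_vl < effective


def classify_art(record: PatientRecord, unknown_as_failure: bool = True) -> bool:
    """True iff the record counts as on ART (recorded status "yes").

    With the default missing-as-failure rule an unknown status counts as not
    on ART (logged). ``unknown_as_failure=False`` is only meaningful to
    callers running a complete-case analysis, which drop unknowns upstream.
    """
    if record.on_art == ArtStatus.UNKNOWN and unknown_as_failure:
        logger.debug("record %s: unknown ART status counted as not on ART",
                     record.patient_id)
    return record.on_art == ArtStatus.YES


def wald_ci(count: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Normal-approximation (Wald) CI for a proportion, in percent.

    p_hat +/- z * sqrt(p_hat (1 - p_hat) / n), clipped to [0, 100]. At 95%
    confidence z is the conventional 1.96.
    """
    if n <= 0:
        raise DomainError(f"sample size must be positive, got {n}")
    if not 0 <= count <= n:
        raise DomainError(f"count {count} outside [0, {n}]")
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    z = 1.96 if confidence == 0.95 else float(stats.norm.ppf(0.5 + confidence / 2.0))
    p_hat = count / n
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    lower = max(0.0, (p_hat - half) * 100.0)
    upper = min(100.0, (p_hat + half) * 100.0)
    return lower, upper


def estimate_continuum(
    pop: ClinicPopulation,
    vs_threshold: Optional[int] = None,
    lod: Optional[int] = None,
    confidence: float = 0.95,
    complete_case: bool = False,
    group_label: str = "",
) -> ContinuumEstimate:
    """ART% and VS% with 95% CIs for a population (or sample).

    The denominator is everyone in care. ``complete_case=True`` switches to
    the non-default analysis that restricts the VS denominator to people with
    a measured viral load and the ART denominator to people with a known ART
    status — useful for quantifying the impact of missing-as-failure, and
    clearly not the primary rule.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot estimate a continuum on an empty population")
    threshold = pop.vs_threshold if vs_threshold is None else vs_threshold
    lod = pop.lod if lod is None else lod

    n = len(pop)
    n_missing_vl = sum(1 for r in pop if r.last_vl is None)
    n_vs = sum(1 for r in pop if classify_vs(r, threshold, lod))
    n_art = sum(1 for r in pop if classify_art(r))

    if complete_case:
        n_vs_denom = n - n_missing_vl
        n_art_denom = sum(1 for r in pop if r.on_art != ArtStatus.UNKNOWN)
        if n_vs_denom == 0 or n_art_denom == 0:
            raise EmptyPopulationError("complete-case analysis has an empty denominator")
    else:
        n_vs_denom = n_art_denom = n

    return ContinuumEstimate(
        n_in_care=n,
        n_art=n_art,
        pct_art=100.0 * n_art / n_art_denom,
        art_ci=wald_ci(n_art, n_art_denom, confidence),
        n_vs=n_vs,
        pct_vs=100.0 * n_vs / n_vs_denom,
        vs_ci=wald_ci(n_vs, n_vs_denom, confidence),
        n_missing_vl=n_missing_vl,
        pct_missing_vl=100.0 * n_missing_vl / n,
        vs_threshold=threshold,
        group_label=group_label or pop.label,
    )


StratifyBy = Literal["gender", "transmission_group", "gender_transmission"]


def _group_key(record: PatientRecord, by: StratifyBy) -> str:
    if by == "gender":
        return record.gender.value
    if by == "transmission_group":
        return record.transmission_group.value
    if by == "gender_transmission":
        return f"{record.gender.value}/{record.transmission_group.value}"
    raise DomainError(f"unknown stratification: {by!r}")


def stratify_continuum(
    pop: ClinicPopulation,
    by: StratifyBy,
    masking_minimum: int = DEFAULT_MASKING_MINIMUM,
    **kwargs,
) -> list[ContinuumEstimate]:
    """One continuum estimate per risk-group stratum, each with its own
    denominator.

    Groups with fewer than ``masking_minimum`` people are returned with
    ``masked=True`` and percentages/CIs suppressed (set to nan) — counts only
    — so small-cell disclosure is avoided in exported reports.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot stratify an empty population")
    groups: dict[str, list[PatientRecord]] = {}
    for r in pop:
        groups.setdefault(_group_key(r, by), []).append(r)

    out: list[ContinuumEstimate] = []
    for key in sorted(groups):
        members = groups[key]
        sub = pop.subset([r.patient_id for r in members], label=key)
        est = estimate_continuum(sub, group_label=key, **kwargs)
        if len(members) < masking_minimum:
            nan = float("nan")
            est = ContinuumEstimate(
                n_in_care=est.n_in_care,
                n_art=est.n_art,
                pct_art=nan,
                art_ci=(nan, nan),
                n_vs=est.n_vs,
                pct_vs=nan,
                vs_ci=(nan, nan),
                n_missing_vl=est.n_missing_vl,
                pct_missing_vl=nan,
                vs_threshold=est.vs_threshold,
                group_label=key,
                masked=True,
            )
        out.append(est)
    return out
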