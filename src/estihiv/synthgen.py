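"""Synthetic clinic populations with the marginal structure the estimator
assumes: configurable true rates of ART use, viral suppression and missing
viral load, plus demographic margins (age bands, CD4 bands, gender/risk
categories, years since diagnosis).

The generator exists so that every other module is testable without patient
data, which cannot be public. It reproduces marginal distributions only —
real joint structure (CD4 vs suppression, age vs risk group) is not modelled,
and viral-load magnitudes are nuisance values drawn uniformly on either side
of the threshold; the estimator only ever thresholds them.

By default suppression is nested within ART (a suppressed person is on ART),
since suppression without treatment is epidemiologically rare; ``nested=False``
draws the two states independently. ``p_vs`` is always the MARGINAL fraction
classified suppressed under the missing-as-failure rule, so the conditional
draw probability is rescaled for missingness (and, when nested, for ART
coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    ArtStatus,
    ClinicPopulation,
    DomainError,
    Gender,
    PatientRecord,
    TransmissionGroup,
)

AGE_BANDS = ("<=30", "30-40", ">40")
CD4_BANDS = ("<=500", ">500", "missing")
YEARS_SINCE_DX_BANDS = ("<=1", "1-3", ">3", "unknown")

#: The eight gender/risk-of-acquisition categories and their record fields.
GENDER_RISK_CATEGORIES: tuple[tuple[str, Gender, TransmissionGroup], ...] = (
    ("MSM", Gender.MALE, TransmissionGroup.MSM),
    ("male heterosexual", Gender.MALE, TransmissionGroup.HETEROSEXUAL),
    ("female heterosexual", Gender.FEMALE, TransmissionGroup.HETEROSEXUAL),
    ("male IDU", Gender.MALE, TransmissionGroup.IDU),
    ("female IDU", Gender.FEMALE, TransmissionGroup.IDU),
    ("male other", Gender.MALE, TransmissionGroup.OTHER),
    ("female other", Gender.FEMALE, TransmissionGroup.OTHER),
    ("non-male/-female", Gender.NON_MALE_FEMALE, TransmissionGroup.OTHER),
)

_DEFAULT_WINDOW = (date(2019, 1, 1), date(2019, 12, 31))


def _normalized(weights: Sequence[float], k: int, what: str) -> tuple[float, ...]:
    w = np.asarray(weights, dtype=float)
    if w.shape != (k,):
        raise DomainError(f"{what} must have {k} entries, got {w.shape}")
    if (w < 0).any():
        raise DomainError(f"{what} must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise DomainError(f"{what} must have positive mass")
    return tuple(w / total)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic clinic population."""

    N: int
    p_art: float = 0.95
    p_vs: float = 0.90
    p_missing_vl: float = 0.0
    vs_threshold: int = 200
    age_band_weights: tuple[float, ...] = (0.10, 0.30, 0.60)
    cd4_band_weights: tuple[float, ...] = (0.30, 0.65, 0.05)
    gender_risk_weights: tuple[float, ...] = (
        0.40, 0.16, 0.19, 0.10, 0.03, 0.07, 0.03, 0.02)
    years_since_dx_weights: tuple[float, ...] = (0.10, 0.20, 0.68, 0.02)
    window: tuple[date, date] = _DEFAULT_WINDOW
    seed: int = 0
    nested: bool = True
    exact_counts: bool = False
    label: str = "synthetic"

    def __post_init__(self):
        if self.N < 1:
            raise DomainError(f"N must be >= 1, got {self.N}")
        for name in ("p_art", "p_vs", "p_missing_vl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        if self.vs_threshold <= 0:
            raise DomainError("vs_threshold must be positive")
        object.__setattr__(self, "age_band_weights",
                           _normalized(self.age_band_weights, 3, "age_band_weights"))
        object.__setattr__(self, "cd4_band_weights",
                           _normalized(self.cd4_band_weights, 3, "cd4_band_weights"))
        object.__setattr__(self, "gender_risk_weights",
                           _normalized(self.gender_risk_weights, 8, "gender_risk_weights"))
        object.__setattr__(
            self, "years_since_dx_weights",
            _normalized(self.years_since_dx_weights, 4, "years_since_dx_weights"))
        if self.window[0] > self.window[1]:
            raise DomainError("window_start must be <= window_end")


def _years_back(d: date, years: int) -> date:
    """Same calendar day `years` earlier; Feb 29 maps to Feb 28."""
    try:
        return d.replace(year=d.year - years)
    except ValueError:
        return d.replace(year=d.year - years, day=28)


def _exact_count_mask(rng: np.random.Generator, N: int, p: float) -> np.ndarray:
    """Boolean mask with exactly floor(N*p) True entries, randomly placed."""
    k = int(np.floor(N * p))
    mask = np.zeros(N, dtype=bool)
    mask[rng.permutation(N)[:k]] = True
    return mask


def _exact_subset_mask(rng: np.random.Generator, candidates: np.ndarray,
                       k: int) -> np.ndarray:
    idx = np.flatnonzero(candidates)
    mask = np.zeros(candidates.size, dtype=bool)
    mask[rng.permutation(idx)[:k]] = True
    return mask


def generate_population(config: SyntheticConfig) -> ClinicPopulation:
    """Draw one clinic population, fully reproducible from ``config.seed``.

    Outcome states: ART ~ Bernoulli(p_art); a fraction ``p_missing_vl`` have
    no viral load recorded; among the rest, suppression is assigned so the
    EXPECTED fraction classified suppressed (missing-as-failure) equals
    ``p_vs``. With ``exact_counts=True`` each state instead hits
    floor(N * p) exactly (hypergeometric-style assignment), for deterministic
    fixtures. All ages are >= 18 at the visit by construction.
    """
    rng = np.random.default_rng(config.seed)
    N = config.N

    avail = 1.0 - config.p_missing_vl
    if config.nested:
        avail *= config.p_art
    if config.p_vs > avail + 1e-12:
        raise DomainError(
            f"target p_vs={config.p_vs} infeasible: at most {avail:.4f} can be "
            "classified suppressed given p_missing_vl"
            + (" and nesting within p_art" if config.nested else ""))
    q = 0.0 if avail == 0 else min(config.p_vs / avail, 1.0)

    if config.exact_counts:
        missing = _exact_count_mask(rng, N, config.p_missing_vl)
        art = _exact_count_mask(rng, N, config.p_art)
        candidates = ~missing & (art if config.nested else np.ones(N, dtype=bool))
        k_vs = int(np.floor(N * config.p_vs))
        if k_vs > candidates.sum():
            raise DomainError("exact-count p_vs infeasible for this draw")
        suppressed = _exact_subset_mask(rng, candidates, k_vs)
    else:
        missing = rng.random(N) < config.p_missing_vl
        art = rng.random(N) < config.p_art
        candidates = ~missing & (art if config.nested else np.ones(N, dtype=bool))
        suppressed = candidates & (rng.random(N) < q)

    # Demographics: categorical draws from the configured margins.
    age_band = rng.choice(3, size=N, p=config.age_band_weights)
    cd4_band = rng.choice(3, size=N, p=config.cd4_band_weights)
    gr = rng.choice(8, size=N, p=config.gender_risk_weights)
    dx_band = rng.choice(4, size=N, p=config.years_since_dx_weights)

    w0, w1 = config.window
    span = (w1 - w0).days
    visit_offset = rng.integers(0, span + 1, size=N)
    # Completed age at visit, uniform within each band (18-30 / 31-40 / 41-85).
    age_lo = np.array([18, 31, 41])[age_band]
    age_hi = np.array([30, 40, 85])[age_band]
    ages = rng.integers(age_lo, age_hi + 1)
    dob_extra = rng.integers(0, 365, size=N)  # keeps completed age exact

    cd4_vals = np.where(cd4_band == 0,
                        rng.integers(50, 501, size=N),
                        rng.integers(501, 1501, size=N))
    vl_vals = np.where(suppressed,
                       rng.integers(0, config.vs_threshold, size=N),
                       rng.integers(config.vs_threshold, 100001, size=N))
    dx_lo = np.array([0, 366, 3 * 365 + 1, 0])[dx_band]
    dx_hi = np.array([365, 3 * 365, 20 * 365, 1])[dx_band]
    dx_days = rng.integers(dx_lo, dx_hi + 1)

    width = len(str(N))
    records = []
    for i in range(N):
        visit = w0 + timedelta(days=int(visit_offset[i]))
        dob = _years_back(visit, int(ages[i])) - timedelta(days=int(dob_extra[i]))
        _, gender, risk = GENDER_RISK_CATEGORIES[gr[i]]
        has_vl = not missing[i]
        has_dx = dx_band[i] != 3
        dx_date = visit - timedelta(days=int(dx_days[i])) if has_dx else None
        if dx_date is not None and dx_date < dob:
            dx_date = dob  # degenerate but valid: diagnosed at birth
        records.append(PatientRecord(
            patient_id=f"{config.label}-{i:0{width}d}",
            last_visit_date=visit,
            date_of_birth=dob,
            gender=gender,
            country_of_origin=None,
            transmission_group=risk,
            last_cd4=None if cd4_band[i] == 2 else int(cd4_vals[i]),
            last_cd4_date=None if cd4_band[i] == 2 else visit,
            last_vl=int(vl_vals[i]) if has_vl else None,
            last_vl_date=visit if has_vl else None,
            on_art=ArtStatus.YES if art[i] else ArtStatus.NO,
            art_status_date=visit,
            hiv_diagnosis_date=dx_date,
            first_visit_date=dx_date or visit,
            death_date=None,
        ))
    return ClinicPopulation(
        records=tuple(records),
        window_start=w0,
        window_end=w1,
        vs_threshold=config.vs_threshold,
        label=config.label,
    )


def table1_profile(name: str, N: Optional[int] = None,
                   seed: int = 0) -> SyntheticConfig:
    """Preset configurations emulating the two study populations.

    ``proof_of_concept``: 8852 people from seven clinics in seven countries
    seen in 2017 — younger, shorter time since diagnosis, lower CD4, 93.8%
    on ART and 76.7% suppressed. ``respond``: 26426 people from 27 country
    cohorts seen in 2019 — older, long-diagnosed, 97.8% on ART, 91.5%
    suppressed, 3.5% missing viral load.
    """
    if name == "proof_of_concept":
        return SyntheticConfig(
            N=N or 8852,
            p_art=0.938,
            p_vs=0.767,
            p_missing_vl=0.05,
            age_band_weights=(0.142, 0.344, 0.514),
            cd4_band_weights=(0.433, 0.554, 0.013),
            gender_risk_weights=(0.357, 0.166, 0.174, 0.186, 0.022, 0.076,
                                 0.019, 0.0),
            years_since_dx_weights=(0.133, 0.217, 0.646, 0.004),
            window=(date(2017, 1, 1), date(2017, 12, 31)),
            seed=seed,
            label="poc",
        )
    if name == "respond":
        return SyntheticConfig(
            N=N or 26426,
            p_art=0.978,
            p_vs=0.915,
            p_missing_vl=0.035,
            age_band_weights=(0.036, 0.152, 0.812),
            cd4_band_weights=(0.25, 0.67, 0.08),
            gender_risk_weights=(0.459, 0.158, 0.194, 0.085, 0.036, 0.043,
                                 0.024, 0.002),
            years_since_dx_weights=(0.0, 0.0, 0.918, 0.02),
            window=(date(2019, 1, 1), date(2019, 12, 31)),
            seed=seed,
            label="respond",
        )
    raise DomainError(f"unknown profile: {name!r}")


def generate_multi_country(configs: Sequence[SyntheticConfig],
                           master_seed: int) -> list[ClinicPopulation]:
    """Independent populations (e.g. one per country), with per-population
    seeds derived deterministically from one master seed."""
    if not configs:
        raise DomainError("need at least one config")
    seeds = np.random.SeedSequence(master_seed).generate_state(len(configs))
    pops = []
    for i, cfg in enumerate(configs):
        derived = replace(cfg, seed=int(seeds[i] & 0x7FFFFFFF),
                          label=cfg.label if cfg.label != "synthetic"
                          else f"pop{i:03d}")
        pops.append(generate_population(derived))
    return pops
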