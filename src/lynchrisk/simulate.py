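"""Synthetic carrier cohorts with known ground truth.

The generator embodies the statistical model the estimators assume: within
each (gene, sex, organ) stratum the cancer hazard is piecewise constant over
the 5-year age bands 25-75, carriers enter at a truncated-normal inclusion
age of at least 25, end of follow-up is exponential (administratively capped),
and death after a first cancer follows an organ-specific exponential hazard,
so true 10-year survival is exp(-10 mu).  Organs are simulated as independent
latent failure times and the death clock starts at the earliest cancer only,
matching the crude (cause-ignoring) survival and mortality the estimators
report.  Hazards outside the 25-75 grid are zero.

Event ages are drawn by analytic inverse-CDF over the piecewise-constant
cumulative hazard, conditioned on being event-free at inclusion (left
truncation), so no rejection sampling is involved.  All draws come from a
single seeded generator in a fixed vectorised order; cohorts are
byte-identical across runs for the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .cohort import (
    FEMALE_ONLY,
    GENES,
    MALE_ONLY,
    SEXES,
    CancerEvent,
    CarrierRecord,
)
from .incidence import BAND_WIDTH, GRID_END, GRID_START

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "ground_truth",
    "default_config",
    "config_from_yaml",
    "config_to_yaml",
]

N_BANDS = int((GRID_END - GRID_START) / BAND_WIDTH)
_EDGES = GRID_START + BAND_WIDTH * np.arange(N_BANDS + 1)

#: Gene mix observed in large surveillance series (MLH1, MSH2, MSH6, PMS2).
DEFAULT_GENE_MIX = {"MLH1": 0.368, "MSH2": 0.373, "MSH6": 0.194, "PMS2": 0.065}


def _normalise_hazards(hazards: dict) -> dict[tuple[str, str, str], np.ndarray]:
    """Expand a nested hazard spec to a flat {(organ, gene, sex): bands} map.

    Accepted per-organ values: a scalar (constant over all bands, genes and
    sexes), a length-10 list, or a dict keyed by gene whose values are again
    scalars, lists, or dicts keyed by sex.  Sex-incompatible strata are
    forced to zero hazard.
    """

    def as_bands(v) -> np.ndarray:
        arr = np.full(N_BANDS, float(v)) if np.isscalar(v) else np.asarray(v, float)
        if arr.shape != (N_BANDS,):
            raise ValueError(f"hazard spec must be scalar or length {N_BANDS}: {v!r}")
        if (arr < 0).any():
            raise ValueError(f"hazards must be non-negative: {v!r}")
        return arr

    from .cohort import ORGANS

    flat: dict[tuple[str, str, str], np.ndarray] = {}
    for organ, spec in hazards.items():
        if organ not in ORGANS:
            raise ValueError(f"unknown organ {organ!r} in hazard table")
        by_gene = spec if isinstance(spec, dict) else {g: spec for g in GENES}
        for gene, gspec in by_gene.items():
            if gene not in GENES:
                raise ValueError(f"unknown gene {gene!r} in hazard table")
            by_sex = gspec if isinstance(gspec, dict) else {s: gspec for s in SEXES}
            for sex, bands in by_sex.items():
                if sex not in SEXES:
                    raise ValueError(f"unknown sex {sex!r} in hazard table")
                incompatible = (sex == "M" and organ in FEMALE_ONLY) or (
                    sex == "F" and organ in MALE_ONLY
                )
                flat[(organ, gene, sex)] = (
                    np.zeros(N_BANDS) if incompatible else as_bands(bands)
                )
    return flat


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    ``hazards`` maps organs to annual cancer hazards (events per
    person-year) over the ten 5-year bands; ``death_hazards`` maps organs to
    the annual all-cause death hazard mu after a diagnosis in that organ, so
    10-year survival is exp(-10 mu).  ``censor_hazard`` is the annual rate of
    (non-cancer) end of follow-up; with the default 0.12 mean follow-up is
    roughly the 8 years seen in large surveillance series.
    """

    n_carriers: int
    hazards: dict
    death_hazards: dict[str, float]
    gene_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENE_MIX))
    female_fraction: float = 0.54
    inclusion_age_mean: float = 44.0
    inclusion_age_sd: float = 12.0
    censor_hazard: float = 0.12
    admin_cutoff_age: float = 80.0
    prevalent_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self._flat_hazards = _normalise_hazards(self.hazards)
        if self.n_carriers < 0:
            raise ValueError("n_carriers must be non-negative")
        if abs(sum(self.gene_mix.values()) - 1.0) > 1e-9:
            raise ValueError("gene_mix probabilities must sum to 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be a probability")
        if not 0.0 <= self.prevalent_fraction <= 1.0:
            raise ValueError("prevalent_fraction must be a probability")
        for organ, mu in self.death_hazards.items():
            if mu < 0:
                raise ValueError(f"death hazard for {organ} must be non-negative")
        if self.censor_hazard < 0:
            raise ValueError("censor_hazard must be non-negative")

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(sorted({o for (o, _, _) in self._flat_hazards}))

    def band_hazards(self, organ: str, gene: str, sex: str) -> np.ndarray:
        return self._flat_hazards.get((organ, gene, sex), np.zeros(N_BANDS))


@dataclass
class GroundTruth:
    """Closed-form counterparts of the pipeline estimates.

    ``q_grid[(organ, gene, sex)]`` holds the true cumulative incidence
    1 - exp(-sum of band hazards x width) at ages 25, 30, ..., 75;
    ``s10[organ]`` the true 10-year post-diagnosis survival; and
    ``m75[(organ, gene, sex)]`` the true crude mortality Q*(65) x (1 - S10*).
    """

    ages: np.ndarray
    q_grid: dict[tuple[str, str, str], np.ndarray]
    s10: dict[str, float]
    m75: dict[tuple[str, str, str], float]

    def q(self, organ: str, gene: str, sex: str, age: float) -> float:
        return float(np.interp(age, self.ages, self.q_grid[(organ, gene, sex)]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (organ, gene, sex), qs in sorted(self.q_grid.items()):
            rows.append(
                {
                    "organ": organ,
                    "gene": gene,
                    "sex": sex,
                    "q65": float(np.interp(65.0, self.ages, qs)),
                    "q75": float(qs[-1]),
                    "s10": self.s10.get(organ, 1.0),
                    "m75": self.m75[(organ, gene, sex)],
                }
            )
        return pd.DataFrame(rows, columns=["organ", "gene", "sex", "q65", "q75", "s10", "m75"])


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Closed-form Q*, S10* and M75* implied by the configuration."""
    ages = _EDGES.copy()
    q_grid = {}
    m75 = {}
    s10 = {
        organ: float(np.exp(-10.0 * mu)) for organ, mu in config.death_hazards.items()
    }
    for key, lam in config._flat_hazards.items():
        cum = np.concatenate([[0.0], np.cumsum(lam * BAND_WIDTH)])
        q = 1.0 - np.exp(-cum)
        q_grid[key] = q
        organ = key[0]
        q65 = float(np.interp(65.0, ages, q))
        m75[key] = q65 * (1.0 - s10.get(organ, 1.0))
    return GroundTruth(ages=ages, q_grid=q_grid, s10=s10, m75=m75)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _sample_event_ages(
    lam: np.ndarray, incl: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draw of first-event age given event-free at inclusion.

    ``lam`` is (n, N_BANDS); returns event ages (inf where no event before
    the grid end).  Conditioning uses the memoryless decomposition
    H(t) - H(incl) ~ Exp(1) on the cumulative-hazard scale.
    """
    n = lam.shape[0]
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(lam * BAND_WIDTH, axis=1)], axis=1)
    idx = np.clip(np.searchsorted(_EDGES, incl, side="right") - 1, 0, N_BANDS - 1)
    rows = np.arange(n)
    h_incl = cum[rows, idx] + lam[rows, idx] * np.clip(incl - _EDGES[idx], 0.0, None)
    h_incl = np.where(incl >= GRID_END, cum[:, -1], h_incl)
    target = h_incl + rng.exponential(size=n)
    band = (cum[:, 1:] <= target[:, None]).sum(axis=1)
    ages = np.full(n, np.inf)
    hit = band < N_BANDS
    if hit.any():
        b = band[hit]
        lam_b = lam[rows[hit], b]
        ages[hit] = _EDGES[b] + (target[hit] - cum[rows[hit], b]) / lam_b
    return ages


def simulate_cohort(config: SimulationConfig) -> list[CarrierRecord]:
    """Draw a cohort of carrier records from the configured model.

    Reproducible: the same configuration (including seed) yields an
    identical cohort.  Guarantees that death never precedes the first
    cancer and that no prospective event falls after last observation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_carriers
    genes = rng.choice(list(config.gene_mix), size=n, p=list(config.gene_mix.values()))
    sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
    a = (GRID_START - config.inclusion_age_mean) / config.inclusion_age_sd
    incl = truncnorm.rvs(
        a,
        np.inf,
        loc=config.inclusion_age_mean,
        scale=config.inclusion_age_sd,
        size=n,
        random_state=rng,
    )
    if config.censor_hazard > 0:
        censor = incl + rng.exponential(1.0 / config.censor_hazard, size=n)
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, config.admin_cutoff_age)
    censor = np.maximum(censor, incl)

    organs = config.organs
    event_ages = np.full((n, len(organs)), np.inf)
    for j, organ in enumerate(organs):
        lam = np.zeros((n, N_BANDS))
        for gene in GENES:
            for sex in SEXES:
                mask = (genes == gene) & (sexes == sex)
                if mask.any():
                    lam[mask] = config.band_hazards(organ, gene, sex)
        ages = _sample_event_ages(lam, incl, rng)
        ages[ages > censor] = np.inf  # unobserved: follow-up ended first
        event_ages[:, j] = ages

    death_draw = rng.exponential(size=n)
    first = event_ages.min(axis=1)
    first_organ = event_ages.argmin(axis=1)
    death_age = np.full(n, np.inf)
    has_cancer = np.isfinite(first)
    for j, organ in enumerate(organs):
        mu = config.death_hazards.get(organ, 0.0)
        mask = has_cancer & (first_organ == j)
        if mu > 0 and mask.any():
            death_age[mask] = first[mask] + death_draw[mask] / mu

    last_obs = np.minimum(censor, death_age)
    dead = death_age <= censor

    prevalent_mask = np.zeros(n, dtype=bool)
    prev_organ_idx = np.zeros(n, dtype=int)
    prev_age = np.zeros(n)
    if config.prevalent_fraction > 0 and organs:
        prevalent_mask = rng.random(n) < config.prevalent_fraction
        prev_organ_idx = rng.integers(0, len(organs), size=n)
        prev_age = incl - rng.uniform(1.0, 15.0, size=n)

    records: list[CarrierRecord] = []
    width = len(str(max(n, 1)))
    for i in range(n):
        events: list[CancerEvent] = []
        if prevalent_mask[i]:
            organ = organs[prev_organ_idx[i]]
            compatible = not (
                (sexes[i] == "M" and organ in FEMALE_ONLY)
                or (sexes[i] == "F" and organ in MALE_ONLY)
            )
            if compatible:
                events.append(
                    CancerEvent(organ=organ, age_dx=float(prev_age[i]), timing="prevalent")
                )
        for j, organ in enumerate(organs):
            age = event_ages[i, j]
            if np.isfinite(age) and age <= last_obs[i]:
                events.append(
                    CancerEvent(organ=organ, age_dx=float(age), timing="prospective")
                )
        events.sort(key=lambda e: (e.age_dx, e.organ))
        records.append(
            CarrierRecord(
                carrier_id=f"S{i + 1:0{width}d}",
                gene=str(genes[i]),
                sex=str(sexes[i]),
                age_inclusion=float(incl[i]),
                age_last_obs=float(last_obs[i]),
                vital_status="dead" if dead[i] else "alive",
                events=events,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Defaults and YAML round-trip
# ---------------------------------------------------------------------------

#: Plausible as-surveilled annual hazards for the three most frequent Lynch
#: syndrome cancers, rising with age; gene scalings reflect the ordering
#: MLH1 ~ MSH2 >> MSH6 > PMS2 seen in published penetrance estimates.
_COLON_BASE = np.array(
    [0.002, 0.004, 0.006, 0.009, 0.012, 0.014, 0.015, 0.015, 0.014, 0.012]
)
_ENDO_BASE = np.array(
    [0.0, 0.001, 0.004, 0.008, 0.012, 0.012, 0.010, 0.008, 0.006, 0.004]
)
_GENE_SCALE = {"MLH1": 1.0, "MSH2": 0.9, "MSH6": 0.3, "PMS2": 0.1}


def default_config(n_carriers: int = 2000, seed: int = 0) -> SimulationConfig:
    """A realistic three-organ default configuration."""
    hazards = {
        "colon": {g: (s * _COLON_BASE).tolist() for g, s in _GENE_SCALE.items()},
        "rectum": {g: (s * 0.25 * _COLON_BASE).tolist() for g, s in _GENE_SCALE.items()},
        "endometrium": {g: (s * _ENDO_BASE).tolist() for g, s in _GENE_SCALE.items()},
    }
    death_hazards = {"colon": 0.014, "rectum": 0.033, "endometrium": 0.008}
    return SimulationConfig(
        n_carriers=n_carriers,
        hazards=hazards,
        death_hazards=death_hazards,
        seed=seed,
    )


def config_to_yaml(config: SimulationConfig, path) -> None:
    doc = {
        "n_carriers": config.n_carriers,
        "hazards": config.hazards,
        "death_hazards": dict(config.death_hazards),
        "gene_mix": dict(config.gene_mix),
        "female_fraction": config.female_fraction,
        "inclusion_age_mean": config.inclusion_age_mean,
        "inclusion_age_sd": config.inclusion_age_sd,
        "censor_hazard": config.censor_hazard,
        "admin_cutoff_age": config.admin_cutoff_age,
        "prevalent_fraction": config.prevalent_fraction,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SimulationConfig(**doc)
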