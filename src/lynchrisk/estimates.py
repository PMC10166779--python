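"""Derived statistics: crude mortality at 75, median age of onset, deaths.

Crude mortality up to age 75 for cancer in an organ is the product of the
cumulative incidence of that cancer at 65 and the probability of dying
within 10 years of the diagnosis:

    M75 = Q(65) x (1 - S10)

It is an empirical, assumption-free decomposition: everyone who both
develops the cancer by 65 and dies within a decade of it has died by 75.

The median age of onset conditions the risk curve on developing the cancer
at all: c(a) = Q(a) / Q(75), with Q(75) standing in for lifetime risk.  The
median is the first age at which the piecewise-linear interpolant of c on
the 5-year grid crosses 50%; the same crossing applied to the conditional
CI curves gives an age interval (upper risk curve -> lower age bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GENES, CarrierRecord, OrganGroup, score_prospective_events, single_organ
from .incidence import CumulativeIncidenceCurve

__all__ = [
    "MortalityEstimate",
    "mortality_at_75",
    "round_half_away",
    "OnsetEstimate",
    "median_onset",
    "death_table",
    "death_shares",
    "overlap_excess",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class MortalityEstimate:
    """Crude mortality to 75 following cancer in one organ, one stratum."""

    organ: str
    gene: str
    sex: str
    q65: float
    s10: float
    m75: float

    @property
    def m75_percent(self) -> int:
        """Display form: integer percent, half away from zero."""
        return round_half_away(100.0 * self.m75)


def mortality_at_75(
    q65: float, s10: float, organ: str = "", gene: str = "all", sex: str = "all"
) -> MortalityEstimate:
    """M75 = Q65 x (1 - S10); inputs are proportions in [0, 1]."""
    for name, v in (("q65", q65), ("s10", s10)):
        if not (0.0 <= v <= 1.0) or not math.isfinite(v):
            raise ValueError(f"{name}={v} is not a proportion in [0, 1]")
    return MortalityEstimate(
        organ=organ, gene=gene, sex=sex, q65=q65, s10=s10, m75=q65 * (1.0 - s10)
    )


# ---------------------------------------------------------------------------
# Median age of onset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OnsetEstimate:
    """Median age of onset from the conditional risk curve c(a) = Q(a)/Q(75).

    Any value is NaN when the corresponding interpolated curve never crosses
    50% (e.g. a lifetime risk of zero, or a CI curve entirely below 50%).
    ``ci_low_age`` comes from the conditional *upper* CI curve (higher risk
    crosses earlier) and ``ci_high_age`` from the conditional lower curve.
    """

    organ_set: str
    gene: str
    sex: str
    ages: np.ndarray
    conditional: np.ndarray
    median_age: float
    ci_low_age: float
    ci_high_age: float


def first_crossing(ages: np.ndarray, values: np.ndarray, level: float = 0.5) -> float:
    """First age at which the piecewise-linear interpolant reaches ``level``.

    Over a flat segment sitting exactly at the level, the segment's left
    endpoint is reported.  NaN if the curve never reaches the level.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if values[0] >= level:
        return float(ages[0])
    for i in range(1, len(ages)):
        v0, v1 = values[i - 1], values[i]
        if v1 >= level:
            if v1 == v0:  # flat segment at the level
                return float(ages[i - 1])
            return float(ages[i - 1] + (ages[i] - ages[i - 1]) * (level - v0) / (v1 - v0))
    return float("nan")


def median_onset(curve: CumulativeIncidenceCurve) -> OnsetEstimate:
    """Median age of cancer onset by conditional-risk interpolation."""
    q_life = curve.q75
    ages = curve.ages
    if q_life <= 0:
        nan = float("nan")
        return OnsetEstimate(
            organ_set=curve.organ_set,
            gene=curve.gene,
            sex=curve.sex,
            ages=ages,
            conditional=np.full_like(curve.q, np.nan),
            median_age=nan,
            ci_low_age=nan,
            ci_high_age=nan,
        )
    cond = np.clip(curve.q / q_life, 0.0, 1.0)
    cond_low = np.clip(curve.ci_low / q_life, 0.0, 1.0)
    cond_high = np.clip(curve.ci_high / q_life, 0.0, 1.0)
    return OnsetEstimate(
        organ_set=curve.organ_set,
        gene=curve.gene,
        sex=curve.sex,
        ages=ages,
        conditional=cond,
        median_age=first_crossing(ages, cond),
        ci_low_age=first_crossing(ages, cond_high),
        ci_high_age=first_crossing(ages, cond_low),
    )


# ---------------------------------------------------------------------------
# Death tabulation
# ---------------------------------------------------------------------------


def death_table(
    records: list[CarrierRecord], organ_set: OrganGroup
) -> pd.DataFrame:
    """Cancers and subsequent deaths per (organ, gene) over an organ set.

    ``n`` counts carriers with a scored prospective cancer in the organ and
    ``n_deaths`` those among them dead at last observation.  A carrier with
    scored cancers in two organs appears in both organ rows (semantics are
    per cancer type, not per carrier), so the total-death denominator is the
    column sum.
    """
    rows = []
    for organ in organ_set.members:
        group = single_organ(organ)
        for gene in GENES:
            n = n_deaths = 0
            for rec in records:
                if rec.gene != gene:
                    continue
                scored = score_prospective_events(rec, group)[organ]
                if scored.eligible and scored.age_event is not None:
                    n += 1
                    if rec.vital_status == "dead":
                        n_deaths += 1
            rows.append({"organ": organ, "gene": gene, "n": n, "n_deaths": n_deaths})
    return pd.DataFrame(rows, columns=["organ", "gene", "n", "n_deaths"])


def death_shares(table: pd.DataFrame) -> pd.DataFrame:
    """Per-organ death counts and their share of all deaths in the table.

    Shares are fractions of the column sum of deaths; NaN when no deaths.
    """
    per_organ = (
        table.groupby("organ", sort=False)[["n", "n_deaths"]].sum().reset_index()
    )
    total = per_organ["n_deaths"].sum()
    per_organ["share"] = (
        per_organ["n_deaths"] / total if total > 0 else np.nan
    )
    return per_organ


def overlap_excess(member_q: dict[str, float], group_q: float) -> float:
    """Sum of member-organ cumulative incidences minus the group value.

    The group curve counts a carrier once however many member organs were
    affected, so the excess measures how many carriers had cancers in more
    than one member organ.  Must be non-negative, and the group value must be
    at least the largest member value.
    """
    total = float(sum(member_q.values()))
    if group_q > total + 1e-12 or group_q < max(member_q.values()) - 1e-12:
        raise ValueError(
            f"group incidence {group_q} violates max <= group <= sum bounds "
            f"for members {member_q}"
        )
    return total - group_q
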