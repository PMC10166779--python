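"""Person-year incidence rates and Nelson-Aalen cumulative incidence.

The estimators work in person-time form on a fixed grid of 5-year age bands
covering ages 25-75.  Each eligible carrier contributes observation time from
max(inclusion age, 25) until the first scored cancer in the organ set, the
age of last observation, or 75 — whichever comes first.  The annual incidence
rate (AIR) in a band is events / person-years; the cumulative hazard is the
band-width-weighted sum of AIRs and the cumulative incidence is
Q(a) = 1 − exp(−H(a)), zero at age 25 by construction (left truncation:
time before inclusion contributes nothing).

Confidence intervals treat per-band event counts as Poisson given the
person-years, so var H(a) = Σ d_i / PY_i²; a log-normal interval on H is
mapped through 1 − exp(−·).  Strata with zero events up to an age get the
exact Poisson zero-event upper bound 1 − exp(−3/PY) ("rule of three").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import (
    CarrierRecord,
    OrganGroup,
    ScoredOrgan,
    organs_for_sex,
    score_prospective_events,
)

__all__ = [
    "AgeBand",
    "default_grid",
    "person_years",
    "incidence_table",
    "CumulativeIncidenceCurve",
    "cumulative_incidence",
]

GRID_START = 25.0
GRID_END = 75.0
BAND_WIDTH = 5.0

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class AgeBand(NamedTuple):
    """Half-open age interval [lower, upper)."""

    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


def default_grid(start: float = GRID_START, end: float = GRID_END,
                 width: float = BAND_WIDTH) -> list[AgeBand]:
    """The standard grid [25,30), [30,35), ..., [70,75)."""
    edges = np.arange(start, end + width / 2, width)
    return [AgeBand(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def _grid_edges(grid: list[AgeBand]) -> np.ndarray:
    edges = np.array([b.lower for b in grid] + [grid[-1].upper])
    if not np.allclose(np.diff(edges), [b.width for b in grid]):
        raise ValueError("age bands must tile the grid without gaps or overlap")
    return edges


# ---------------------------------------------------------------------------
# Person-year attribution (record level)
# ---------------------------------------------------------------------------


def person_years(
    carrier: CarrierRecord,
    organ_set: OrganGroup,
    grid: list[AgeBand] | None = None,
    scored: dict[str, ScoredOrgan] | None = None,
) -> tuple[np.ndarray, int | None]:
    """Observation time per band and the band index of the event, if any.

    Ineligible carriers (previous/prevalent cancer in a member organ) return
    all-zero person-years and no event.  The event band is the band
    containing the age of the first scored cancer in any member organ, and
    only when that age is below the grid end and is the cause of stopping.
    """
    if grid is None:
        grid = default_grid()
    edges = _grid_edges(grid)
    scored = scored if scored is not None else score_prospective_events(carrier, organ_set)
    members = organs_for_sex(organ_set, carrier.sex)
    py = np.zeros(len(grid))
    if not members or any(not scored[o].eligible for o in members):
        return py, None
    event_age = min(
        (scored[o].age_event for o in members if scored[o].age_event is not None),
        default=np.inf,
    )
    entry = max(carrier.age_inclusion, edges[0])
    stop = min(event_age, carrier.age_last_obs, edges[-1])
    if stop > entry:
        py = np.clip(
            np.minimum(stop, edges[1:]) - np.maximum(entry, edges[:-1]), 0.0, None
        )
    event_band: int | None = None
    if event_age < edges[-1] and event_age <= carrier.age_last_obs:
        event_band = int(np.searchsorted(edges, event_age, side="right") - 1)
        event_band = max(event_band, 0)
    return py, event_band


# ---------------------------------------------------------------------------
# Incidence table (vectorised over the cohort)
# ---------------------------------------------------------------------------


def _stratum_arrays(records, organ_set, grid):
    """Vectorised entry/stop/event arrays for all carriers, one organ set."""
    edges = _grid_edges(grid)
    n = len(records)
    entry = np.empty(n)
    stop = np.empty(n)
    event_age = np.full(n, np.inf)
    eligible = np.ones(n, dtype=bool)
    for i, rec in enumerate(records):
        scored = score_prospective_events(rec, organ_set)
        members = organs_for_sex(organ_set, rec.sex)
        if not members or any(not scored[o].eligible for o in members):
            eligible[i] = False
            entry[i] = stop[i] = edges[0]
            continue
        ea = min(
            (scored[o].age_event for o in members if scored[o].age_event is not None),
            default=np.inf,
        )
        event_age[i] = ea
        entry[i] = max(rec.age_inclusion, edges[0])
        stop[i] = min(ea, rec.age_last_obs, edges[-1])
    return entry, stop, event_age, eligible, edges


def incidence_table(
    records: list[CarrierRecord],
    organ_sets: list[OrganGroup],
    grid: list[AgeBand] | None = None,
    by: tuple[str, ...] = ("gene", "sex"),
) -> pd.DataFrame:
    """Person-years, event counts and annual incidence rates per stratum.

    Returns a long-format frame with one row per
    (organ set, gene, sex, age band); dimensions not listed in ``by`` are
    pooled and labelled ``"all"``.  AIR is NaN where person-years are zero.
    """
    if grid is None:
        grid = default_grid()
    genes = sorted({r.gene for r in records}) if "gene" in by else ["all"]
    sexes = sorted({r.sex for r in records}) if "sex" in by else ["all"]
    rows = []
    for organ_set in organ_sets:
        entry, stop, event_age, eligible, edges = _stratum_arrays(
            records, organ_set, grid
        )
        rec_gene = np.array([r.gene for r in records]) if records else np.array([])
        rec_sex = np.array([r.sex for r in records]) if records else np.array([])
        has_event = eligible & (event_age < edges[-1]) & (event_age <= stop)
        for gene in genes:
            for sex in sexes:
                mask = eligible.copy()
                if gene != "all":
                    mask &= rec_gene == gene
                if sex != "all":
                    mask &= rec_sex == sex
                e, s = entry[mask], stop[mask]
                py = np.clip(
                    np.minimum(s[:, None], edges[1:][None, :])
                    - np.maximum(e[:, None], edges[:-1][None, :]),
                    0.0,
                    None,
                ).sum(axis=0) if mask.any() else np.zeros(len(grid))
                ev = event_age[mask & has_event]
                d = np.histogram(ev, bins=edges)[0] if ev.size else np.zeros(len(grid), int)
                for band, py_b, d_b in zip(grid, py, d):
                    rows.append(
                        {
                            "organ_set": organ_set.name,
                            "gene": gene,
                            "sex": sex,
                            "age_lower": band.lower,
                            "age_upper": band.upper,
                            "person_years": float(py_b),
                            "n_events": int(d_b),
                            "air": float(d_b / py_b) if py_b > 0 else np.nan,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "organ_set",
            "gene",
            "sex",
            "age_lower",
            "age_upper",
            "person_years",
            "n_events",
            "air",
        ],
    )


# ---------------------------------------------------------------------------
# Cumulative incidence
# ---------------------------------------------------------------------------


@dataclass
class CumulativeIncidenceCurve:
    """Nelson-Aalen cumulative incidence Q(a) on the age grid with 95% CI.

    ``ages`` are the grid edges 25, 30, ..., 75; ``hazard`` is the cumulative
    hazard H(a), ``q`` = 1 − exp(−H(a)).  Per-band event counts and
    person-years are retained so that variances can be recomputed.
    """

    organ_set: str
    gene: str
    sex: str
    ages: np.ndarray
    hazard: np.ndarray
    var_hazard: np.ndarray
    q: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_events: np.ndarray
    person_years: np.ndarray

    def value_at(self, age: float) -> float:
        """Q at an age, linearly interpolated between grid points."""
        return float(np.interp(age, self.ages, self.q))

    def se_at(self, age: float) -> float:
        """Standard error of Q(a): exp(−H)·√var(H), interpolated."""
        se = np.exp(-self.hazard) * np.sqrt(self.var_hazard)
        return float(np.interp(age, self.ages, se))

    @property
    def q75(self) -> float:
        return float(self.q[-1])

    @property
    def q65(self) -> float:
        return self.value_at(65.0)


def cumulative_incidence(
    table: pd.DataFrame,
    organ_set: str,
    gene: str = "all",
    sex: str = "all",
    alpha: float = 0.05,
) -> CumulativeIncidenceCurve:
    """Build the cumulative incidence curve for one stratum of the table.

    Bands with zero events contribute zero hazard and zero variance; a band
    with events but no person-years is an error.
    """
    sub = table[
        (table["organ_set"] == organ_set)
        & (table["gene"] == gene)
        & (table["sex"] == sex)
    ].sort_values("age_lower")
    if sub.empty:
        raise KeyError(f"stratum ({organ_set!r}, {gene!r}, {sex!r}) not in table")
    if (sub["age_lower"].values[0] != GRID_START) or (
        sub["age_upper"].values[-1] != GRID_END
    ):
        raise ValueError("cumulative incidence needs the full 25-75 grid")
    py = sub["person_years"].to_numpy(float)
    d = sub["n_events"].to_numpy(float)
    width = (sub["age_upper"] - sub["age_lower"]).to_numpy(float)
    bad = (py <= 0) & (d > 0)
    if bad.any():
        raise ValueError(
            f"stratum ({organ_set}, {gene}, {sex}): events with zero person-years "
            f"in band(s) {sub['age_lower'].to_numpy()[bad]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        air = np.where(py > 0, d / py, 0.0)
        # var of the band's hazard increment AIR x width is width^2 d / PY^2
        var_inc = np.where(py > 0, width**2 * d / py**2, 0.0)
    # H and var(H) at the right edge of each band, prepended with 0 at 25.
    hazard = np.concatenate([[0.0], np.cumsum(air * width)])
    var_h = np.concatenate([[0.0], np.cumsum(var_inc)])
    ages = np.concatenate([[sub["age_lower"].values[0]], sub["age_upper"].to_numpy(float)])
    q = 1.0 - np.exp(-hazard)

    z = float(-_norm_ppf(alpha / 2.0))
    ci_low = np.zeros_like(hazard)
    ci_high = np.zeros_like(hazard)
    cum_py = np.concatenate([[0.0], np.cumsum(py)])
    pos = hazard > 0
    if pos.any():
        se_log = np.sqrt(var_h[pos]) / hazard[pos]
        ci_low[pos] = 1.0 - np.exp(-hazard[pos] * np.exp(-z * se_log))
        ci_high[pos] = 1.0 - np.exp(-hazard[pos] * np.exp(z * se_log))
    # Zero cumulative events: exact Poisson zero-event bound ("rule of three").
    zero = (~pos) & (cum_py > 0)
    ci_high[zero] = 1.0 - np.exp(-3.0 / cum_py[zero])
    return CumulativeIncidenceCurve(
        organ_set=organ_set,
        gene=gene,
        sex=sex,
        ages=ages,
        hazard=hazard,
        var_hazard=var_h,
        q=q,
        ci_low=ci_low,
        ci_high=ci_high,
        n_events=d.astype(int),
        person_years=py,
    )


def _norm_ppf(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def curves_to_frame(curves: list[CumulativeIncidenceCurve]) -> pd.DataFrame:
    """Long-format export of cumulative incidence curves."""
    rows = []
    for c in curves:
        for a, q, lo, hi in zip(c.ages, c.q, c.ci_low, c.ci_high):
            rows.append(
                {
                    "organ_set": c.organ_set,
                    "gene": c.gene,
                    "sex": c.sex,
                    "age": float(a),
                    "q": float(q),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(
        rows, columns=["organ_set", "gene", "sex", "age", "q", "ci_low", "ci_high"]
    )
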