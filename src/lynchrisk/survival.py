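"""Crude (all-cause) survival after a first prospective cancer.

Time origin is the age at diagnosis of the first scored cancer in the organ;
the event is death from any cause at the age of last observation, and
carriers alive at last observation are censored there.  Survival is the
Nelson-Aalen transform S(t) = exp(−H(t)) with H(t) = Σ d_i / n_i over death
times up to t; this is the risk-set analogue of the person-time estimator
used for incidence and shares its log-normal CI construction
(var H = Σ d_i / n_i²).  Deaths are processed before censorings at tied
times, the standard conservative convention.

A hook is provided for adjusting the risk set for possible surveillance
overdiagnosis of colon cancer; no adjustment is applied by default because
no concrete correction is defined — the default is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import CarrierRecord, score_prospective_events, single_organ
from .incidence import Z_95

__all__ = [
    "SurvivalCurve",
    "survival_after_cancer",
    "nelson_aalen",
    "kaplan_meier",
    "diagnosis_table",
]


@dataclass
class SurvivalCurve:
    """Step-function survival curve with 95% CI and risk-set sizes.

    ``times`` are the distinct death times (prepended with 0); values are
    carried forward between death times.  ``is_na`` flags an empty risk set.
    """

    organ: str
    stratum: str
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    cum_hazard: np.ndarray
    var_cum_hazard: np.ndarray
    n_at_risk: np.ndarray
    n_entered: int

    @property
    def is_na(self) -> bool:
        return self.n_entered == 0

    def value_at(self, t: float) -> float:
        """S(t), last value carried forward; NaN for an empty risk set."""
        if self.is_na:
            return float("nan")
        i = int(np.searchsorted(self.times, t, side="right") - 1)
        return float(self.survival[max(i, 0)])

    def se_at(self, t: float) -> float:
        """Standard error of S(t): S·√var(H), carried forward."""
        if self.is_na:
            return float("nan")
        i = max(int(np.searchsorted(self.times, t, side="right") - 1), 0)
        return float(self.survival[i] * np.sqrt(self.var_cum_hazard[i]))

    @property
    def s5(self) -> float:
        return self.value_at(5.0)

    @property
    def s10(self) -> float:
        return self.value_at(10.0)


def nelson_aalen(
    durations: np.ndarray, observed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Nelson-Aalen cumulative hazard over right-censored durations.

    Returns (death times, H, var H, n at risk just before each death time).
    Risk sets count every subject with duration ≥ t, so subjects censored at
    a death time are still at risk there.
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    death_times = np.unique(durations[observed])
    n_at_risk = np.array([(durations >= t).sum() for t in death_times], dtype=float)
    d = np.array([(observed & (durations == t)).sum() for t in death_times], dtype=float)
    hazard = np.cumsum(d / n_at_risk) if death_times.size else np.array([])
    var = np.cumsum(d / n_at_risk**2) if death_times.size else np.array([])
    return death_times, hazard, var, n_at_risk


def _curve_from_na(organ, stratum, times, hazard, var, n_at_risk, n_entered):
    if n_entered:
        t = np.concatenate([[0.0], times])
        h = np.concatenate([[0.0], hazard])
        v = np.concatenate([[0.0], var])
        nar = np.concatenate([[float(n_entered)], n_at_risk])
        s = np.exp(-h)
        lo = np.ones_like(s)
        hi = np.ones_like(s)
        pos = h > 0
        if pos.any():
            se_log = np.sqrt(v[pos]) / h[pos]
            # wider hazard -> lower survival bound
            lo[pos] = np.exp(-h[pos] * np.exp(Z_95 * se_log))
            hi[pos] = np.exp(-h[pos] * np.exp(-Z_95 * se_log))
    else:
        t = h = v = nar = np.array([0.0])
        s = lo = hi = np.array([1.0])
    return SurvivalCurve(
        organ=organ,
        stratum=stratum,
        times=t,
        survival=s,
        ci_low=lo,
        ci_high=hi,
        cum_hazard=h,
        var_cum_hazard=v,
        n_at_risk=nar,
        n_entered=n_entered,
    )


def diagnosis_table(
    records: list[CarrierRecord], organ: str, age_cap: float = 65.0
) -> pd.DataFrame:
    """Risk-set table: one row per carrier with a first scored cancer in
    ``organ`` diagnosed before ``age_cap``.

    ``duration`` is years from diagnosis to last observation and ``died``
    whether the carrier was dead at last observation (death from any cause;
    metachronous cancers in other organs do not remove anyone).
    """
    rows = []
    group = single_organ(organ)
    for rec in records:
        scored = score_prospective_events(rec, group)[organ]
        if not scored.eligible or scored.age_event is None:
            continue
        if scored.age_event >= age_cap:
            continue
        rows.append(
            {
                "carrier_id": rec.carrier_id,
                "gene": rec.gene,
                "sex": rec.sex,
                "age_dx": scored.age_event,
                "duration": rec.age_last_obs - scored.age_event,
                "died": rec.vital_status == "dead",
            }
        )
    return pd.DataFrame(
        rows, columns=["carrier_id", "gene", "sex", "age_dx", "duration", "died"]
    )


def survival_after_cancer(
    records: list[CarrierRecord],
    organ: str,
    age_cap: float = 65.0,
    by_gene: bool = False,
    risk_set_adjustment: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> SurvivalCurve | dict[str, SurvivalCurve]:
    """Crude survival after a first prospective cancer in ``organ``.

    Only cancers diagnosed before ``age_cap`` (default 65) enter the risk
    set.  With ``by_gene=True`` a dict of per-gene curves is returned;
    otherwise carriers of all four genes are pooled.
    ``risk_set_adjustment`` is an extension hook that may filter or reweight
    the diagnosis table (e.g. for colonoscopy overdiagnosis); default is the
    identity.
    """
    table = diagnosis_table(records, organ, age_cap=age_cap)
    if risk_set_adjustment is not None:
        table = risk_set_adjustment(table)
    if not by_gene:
        return _fit_one(table, organ, "all")
    return {
        gene: _fit_one(table[table["gene"] == gene], organ, gene)
        for gene in sorted(table["gene"].unique())
    }


def _fit_one(table: pd.DataFrame, organ: str, stratum: str) -> SurvivalCurve:
    n = len(table)
    if n == 0:
        return _curve_from_na(organ, stratum, None, None, None, None, 0)
    times, hazard, var, n_at_risk = nelson_aalen(
        table["duration"].to_numpy(), table["died"].to_numpy()
    )
    return _curve_from_na(organ, stratum, times, hazard, var, n_at_risk, n)


def kaplan_meier(durations, observed) -> Callable[[float], float]:
    """Kaplan-Meier product-limit estimator (via lifelines), as a function.

    Used as an independent cross-check of the Nelson-Aalen transform, which
    dominates it pointwise: exp(−H(t)) ≥ S_KM(t).
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(durations, float), np.asarray(observed, bool))
    return lambda t: float(kmf.predict(t))


def curves_to_frame(curves: list[SurvivalCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        if c.is_na:
            continue
        for t, s, lo, hi, nar in zip(
            c.times, c.survival, c.ci_low, c.ci_high, c.n_at_risk
        ):
            rows.append(
                {
                    "organ": c.organ,
                    "stratum": c.stratum,
                    "t": float(t),
                    "s": float(s),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_at_risk": float(nar),
                }
            )
    return pd.DataFrame(
        rows, columns=["organ", "stratum", "t", "s", "ci_low", "ci_high", "n_at_risk"]
    )


def readouts_frame(curves: list[SurvivalCurve]) -> pd.DataFrame:
    rows = [
        {
            "organ": c.organ,
            "stratum": c.stratum,
            "n": c.n_entered,
            "s5": c.s5,
            "s10": c.s10,
        }
        for c in curves
    ]
    return pd.DataFrame(rows, columns=["organ", "stratum", "n", "s5", "s10"])
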