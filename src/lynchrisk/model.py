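"""Model/Results interface tying the whole estimation pipeline together.

:class:`ProspectiveCohortModel` holds a validated cohort and the analysis
settings (organ groups, age grid, survival age cap and horizon); ``fit()``
runs validate -> score -> incidence -> survival -> mortality/onset/deaths
and returns a :class:`CohortResults` with every table, plus ``summary()``
and ``save()`` for reporting.  The fit is deterministic given the input
records and settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CRC,
    GYNAE,
    LS_CANCERS,
    LS_ORGANS,
    CarrierRecord,
    OrganGroup,
    cohort_summary,
    load_cohort,
    single_organ,
    validate_cohort,
)
from .estimates import MortalityEstimate, OnsetEstimate, median_onset, mortality_at_75
from .incidence import (
    AgeBand,
    CumulativeIncidenceCurve,
    cumulative_incidence,
    curves_to_frame,
    default_grid,
    incidence_table,
)
from .estimates import death_shares, death_table
from .survival import (
    SurvivalCurve,
    readouts_frame,
    survival_after_cancer,
)
from .survival import curves_to_frame as survival_curves_to_frame

__all__ = ["ProspectiveCohortModel", "CohortResults", "default_organ_sets"]


def default_organ_sets() -> list[OrganGroup]:
    """Singleton groups for the 12 LS organs plus the standard combinations."""
    return [single_organ(o) for o in LS_ORGANS] + [CRC, GYNAE, LS_CANCERS]


class ProspectiveCohortModel:
    """Prospective cancer risk, survival and mortality for a carrier cohort.

    Parameters
    ----------
    records:
        Carrier records; validated on construction.
    organ_sets:
        Organ groups to analyse (default: each LS organ singly, colorectum,
        endometrium/ovary, and all LS cancers combined).
    grid:
        Age bands for incidence (default [25,30) ... [70,75)).
    strict:
        Whether invalid records abort (True) or are skipped and logged.
    """

    def __init__(
        self,
        records: list[CarrierRecord],
        organ_sets: list[OrganGroup] | None = None,
        grid: list[AgeBand] | None = None,
        strict: bool = True,
    ) -> None:
        self.records, self.issues = validate_cohort(records, strict=strict)
        self.organ_sets = organ_sets if organ_sets is not None else default_organ_sets()
        self.grid = grid if grid is not None else default_grid()
        self.cohort_summary = cohort_summary(self.records)

    @classmethod
    def from_csv(
        cls,
        carriers_path,
        events_path=None,
        organ_sets: list[OrganGroup] | None = None,
        grid: list[AgeBand] | None = None,
        strict: bool = True,
    ) -> "ProspectiveCohortModel":
        records, issues = load_cohort(carriers_path, events_path, strict=strict)
        model = cls(records, organ_sets=organ_sets, grid=grid, strict=False)
        model.issues.update(issues)
        return model

    def fit(
        self,
        age_cap: float = 65.0,
        horizon: float = 10.0,
        by: tuple[str, ...] = ("gene", "sex"),
        survival_by_gene: bool = False,
    ) -> "CohortResults":
        """Run the full pipeline and return the results object."""
        table = incidence_table(self.records, self.organ_sets, self.grid, by=by)
        curves: dict[tuple[str, str, str], CumulativeIncidenceCurve] = {}
        for key, _ in table.groupby(["organ_set", "gene", "sex"], sort=False):
            organ_set, gene, sex = key
            curves[key] = cumulative_incidence(table, organ_set, gene, sex)

        organs = sorted({o for g in self.organ_sets for o in g.members})
        surv: dict[str, SurvivalCurve] = {
            o: survival_after_cancer(self.records, o, age_cap=age_cap) for o in organs
        }
        surv_by_gene: dict[str, dict[str, SurvivalCurve]] = {}
        if survival_by_gene:
            surv_by_gene = {
                o: survival_after_cancer(self.records, o, age_cap=age_cap, by_gene=True)
                for o in organs
            }

        mortality_rows = []
        for (organ_set, gene, sex), curve in curves.items():
            if organ_set not in organs:  # mortality is per single organ
                continue
            if curve.person_years.sum() == 0:  # e.g. wrong sex for the organ
                continue
            sc = surv[organ_set]
            if sc.is_na:
                continue
            est = mortality_at_75(
                curve.q65, sc.value_at(horizon), organ=organ_set, gene=gene, sex=sex
            )
            mortality_rows.append(est)

        onsets = {key: median_onset(curve) for key, curve in curves.items()}
        deaths = death_table(self.records, LS_CANCERS)

        return CohortResults(
            model=self,
            age_cap=age_cap,
            horizon=horizon,
            incidence=table,
            curves=curves,
            survival=surv,
            survival_by_gene=surv_by_gene,
            mortality=mortality_rows,
            onsets=onsets,
            deaths=deaths,
        )


@dataclass
class CohortResults:
    """Every table the pipeline produces, with export helpers."""

    model: ProspectiveCohortModel
    age_cap: float
    horizon: float
    incidence: pd.DataFrame
    curves: dict[tuple[str, str, str], CumulativeIncidenceCurve]
    survival: dict[str, SurvivalCurve]
    survival_by_gene: dict[str, dict[str, SurvivalCurve]]
    mortality: list[MortalityEstimate]
    onsets: dict[tuple[str, str, str], OnsetEstimate]
    deaths: pd.DataFrame

    # ---- tabular views -----------------------------------------------------

    @property
    def cumulative_incidence_frame(self) -> pd.DataFrame:
        return curves_to_frame(list(self.curves.values()))

    @property
    def survival_frame(self) -> pd.DataFrame:
        curves = list(self.survival.values()) + [
            c for d in self.survival_by_gene.values() for c in d.values()
        ]
        return survival_curves_to_frame(curves)

    @property
    def survival_readouts(self) -> pd.DataFrame:
        curves = list(self.survival.values()) + [
            c for d in self.survival_by_gene.values() for c in d.values()
        ]
        return readouts_frame(curves)

    @property
    def mortality_frame(self) -> pd.DataFrame:
        rows = [
            {
                "organ": e.organ,
                "gene": e.gene,
                "sex": e.sex,
                "q65": e.q65,
                "s10": e.s10,
                "m75": e.m75,
                "m75_percent": e.m75_percent,
            }
            for e in self.mortality
        ]
        return pd.DataFrame(
            rows, columns=["organ", "gene", "sex", "q65", "s10", "m75", "m75_percent"]
        )

    @property
    def onset_frame(self) -> pd.DataFrame:
        rows = [
            {
                "organ_set": o.organ_set,
                "gene": o.gene,
                "sex": o.sex,
                "median_age": o.median_age,
                "ci_low_age": o.ci_low_age,
                "ci_high_age": o.ci_high_age,
            }
            for o in self.onsets.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["organ_set", "gene", "sex", "median_age", "ci_low_age", "ci_high_age"],
        )

    @property
    def death_shares(self) -> pd.DataFrame:
        return death_shares(self.deaths)

    # ---- reporting ---------------------------------------------------------

    def summary(self) -> str:
        s = self.model.cohort_summary
        lines = [
            "Prospective carrier cohort analysis",
            "=" * 35,
            f"carriers: {s['n_carriers']}",
            f"by gene: "
            + ", ".join(f"{g}={n}" for g, n in s["by_gene"].items()),
            f"by sex: " + ", ".join(f"{x}={n}" for x, n in s["by_sex"].items()),
            f"observation years: {s['observation_years']:.1f}",
            f"mean follow-up: {s['mean_follow_up']:.1f} years",
            f"prospective cancer events: {s['n_prospective_events']}",
            "",
            f"survival age cap: {self.age_cap:g}; readout horizon: {self.horizon:g} years",
            "",
            "Crude mortality to age 75 (Q65 x (1 - S10)):",
        ]
        mf = self.mortality_frame
        if mf.empty:
            lines.append("  (no estimable organ strata)")
        else:
            for row in mf.itertuples(index=False):
                lines.append(
                    f"  {row.organ:<16} {row.gene:<5} {row.sex}  "
                    f"Q65={100 * row.q65:5.1f}%  S10={100 * row.s10:5.1f}%  "
                    f"M75={100 * row.m75:4.1f}% (~{row.m75_percent}%)"
                )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the full CSV bundle plus a deterministic run log."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.incidence.to_csv(out / "incidence_table.csv", index=False)
        self.cumulative_incidence_frame.to_csv(
            out / "cumulative_incidence.csv", index=False
        )
        self.survival_frame.to_csv(out / "survival.csv", index=False)
        self.survival_readouts.to_csv(out / "survival_readouts.csv", index=False)
        self.mortality_frame.to_csv(out / "mortality.csv", index=False)
        self.onset_frame.to_csv(out / "onset.csv", index=False)
        self.deaths.to_csv(out / "deaths.csv", index=False)
        self.death_shares.to_csv(out / "death_shares.csv", index=False)
        s = self.model.cohort_summary
        log = [
            f"lynchrisk {__version__}",
            f"carriers={s['n_carriers']}",
            f"observation_years={s['observation_years']:.3f}",
            f"mean_follow_up={s['mean_follow_up']:.3f}",
            f"age_cap={self.age_cap:g}",
            f"horizon={self.horizon:g}",
            f"validation_issues={len(self.model.issues)}",
        ]
        for cid, msgs in self.model.issues.items():
            log.append(f"issue {cid}: {'; '.join(msgs)}")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")

    # ---- plotting ----------------------------------------------------------

    def plot_cumulative_incidence(self, organ_set: str, gene: str = "all",
                                  sex: str = "all", ax=None):
        """Step-free plot of Q(a) with its 95% band."""
        import matplotlib.pyplot as plt

        curve = self.curves[(organ_set, gene, sex)]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.ages, 100 * curve.q, color="C0")
        ax.fill_between(curve.ages, 100 * curve.ci_low, 100 * curve.ci_high,
                        alpha=0.2, color="C0")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("cumulative incidence (%)")
        ax.set_title(f"{organ_set} ({gene}, {sex})")
        return ax

    def plot_survival(self, organ: str, ax=None):
        import matplotlib.pyplot as plt

        curve = self.survival[organ]
        if ax is None:
            _, ax = plt.subplots()
        ax.step(curve.times, 100 * curve.survival, where="post", color="C1")
        ax.fill_between(curve.times, 100 * curve.ci_low, 100 * curve.ci_high,
                        step="post", alpha=0.2, color="C1")
        ax.set_xlabel("years since diagnosis")
        ax.set_ylabel("crude survival (%)")
        ax.set_title(organ)
        return ax
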