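"""Domain types, validation and event-scoring for prospective carrier cohorts.

A cohort is a list of :class:`CarrierRecord` objects, one per surveilled
carrier of a pathogenic mismatch-repair (MMR) variant.  Each carrier enters
observation at their inclusion age (first prospectively planned surveillance
colonoscopy, at 25 years or older) and is followed to an age of last
observation, at which point they are classified alive or dead.  Cancer events
carry an organ code, an age at diagnosis and a timing flag: ``previous`` or
``prevalent`` cancers were diagnosed before or at inclusion and remove the
carrier from that organ's risk set entirely; ``prospective`` cancers were
diagnosed under surveillance and are the events the estimators count.

Scoring follows the first-tumour-per-organ rule: within each organ, only the
earliest prospective cancer counts, and only in carriers with no previous or
prevalent cancer in that organ.  Prospective cancers in *other* organs never
affect a carrier's eligibility for an organ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "GENES",
    "SEXES",
    "ORGANS",
    "LS_ORGANS",
    "CancerEvent",
    "CarrierRecord",
    "OrganGroup",
    "CRC",
    "GYNAE",
    "LS_CANCERS",
    "CohortValidationError",
    "ScoredOrgan",
    "score_prospective_events",
    "validate_cohort",
    "cohort_summary",
    "read_carriers_csv",
    "read_events_csv",
    "load_cohort",
    "write_cohort_csv",
    "records_to_frames",
    "organs_for_sex",
]

GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
SEXES = ("F", "M")
TIMINGS = ("previous", "prevalent", "prospective")
VITAL_STATUSES = ("alive", "dead")

#: Controlled organ vocabulary (grouping follows the first three positions of
#: ICD9; free-text mapping is out of scope — labels must already be canonical).
ORGANS = (
    "colon",
    "rectum",
    "endometrium",
    "ovary",
    "stomach",
    "small_intestine",
    "bile_duct",
    "pancreas",
    "ureter_kidney",
    "urinary_bladder",
    "prostate",
    "brain",
    "breast",
    "skin",
    "other",
)

FEMALE_ONLY = frozenset({"endometrium", "ovary"})
MALE_ONLY = frozenset({"prostate"})

#: Organs in which cancers are conventionally counted as Lynch-syndrome
#: cancers.  Breast and skin are carried through incidence computation but
#: flagged non-LS; osteosarcoma is too infrequent to appear in the vocabulary.
LS_ORGANS = (
    "colon",
    "rectum",
    "endometrium",
    "ovary",
    "stomach",
    "small_intestine",
    "bile_duct",
    "pancreas",
    "ureter_kidney",
    "urinary_bladder",
    "prostate",
    "brain",
)

NON_LS_ORGANS = frozenset({"breast", "skin", "other"})


class CohortValidationError(ValueError):
    """Raised when carrier records violate the cohort invariants."""


@dataclass(frozen=True)
class CancerEvent:
    """A single cancer diagnosis in one organ.

    ``timing`` is ``previous`` (diagnosed before inclusion), ``prevalent``
    (identified at inclusion) or ``prospective`` (diagnosed under follow-up).
    """

    organ: str
    age_dx: float
    timing: str


@dataclass
class CarrierRecord:
    """One surveilled carrier of a pathogenic MMR variant."""

    carrier_id: str
    gene: str
    sex: str
    age_inclusion: float
    age_last_obs: float
    vital_status: str
    events: list[CancerEvent] = field(default_factory=list)

    @property
    def follow_up(self) -> float:
        """Observation years contributed: age_last_obs − age_inclusion."""
        return self.age_last_obs - self.age_inclusion


@dataclass(frozen=True)
class OrganGroup:
    """A named, non-empty set of organ codes analysed jointly.

    A first cancer in *any* member organ is the event; a previous or
    prevalent cancer in any member organ makes the carrier ineligible for
    the whole group.
    """

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"organ group {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"organ group {self.name!r} has duplicate members")
        unknown = set(self.members) - set(ORGANS)
        if unknown:
            raise ValueError(
                f"organ group {self.name!r} has unknown organ codes: {sorted(unknown)}"
            )

    def __contains__(self, organ: str) -> bool:
        return organ in self.members


def single_organ(organ: str) -> OrganGroup:
    return OrganGroup(organ, (organ,))


CRC = OrganGroup("colorectum", ("colon", "rectum"))
GYNAE = OrganGroup("endometrium_ovary", ("endometrium", "ovary"))
LS_CANCERS = OrganGroup("ls_cancers", LS_ORGANS)


def organs_for_sex(group: OrganGroup, sex: str) -> tuple[str, ...]:
    """Member organs anatomically possible for ``sex``."""
    if sex == "F":
        return tuple(o for o in group.members if o not in MALE_ONLY)
    return tuple(o for o in group.members if o not in FEMALE_ONLY)


# ---------------------------------------------------------------------------
# Event scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoredOrgan:
    """Per-organ outcome of scoring one carrier.

    ``eligible`` is False iff the carrier had a previous or prevalent cancer
    in the organ (they then contribute no person-time for it).  ``age_event``
    is the age of the earliest prospective cancer in that organ, or ``None``.
    """

    eligible: bool
    age_event: float | None


def score_prospective_events(
    carrier: CarrierRecord, organ_set: OrganGroup
) -> dict[str, ScoredOrgan]:
    """Apply the first-tumour-per-organ scoring rule for each member organ.

    A carrier is ineligible for an organ iff they had a previous/prevalent
    cancer in that organ; otherwise the scored event is the earliest
    prospective cancer in the organ (later same-organ cancers, synchronous or
    metachronous, are discarded).  Prospective cancers in other organs never
    affect eligibility.
    """
    out: dict[str, ScoredOrgan] = {}
    for organ in organ_set.members:
        pre = [e for e in carrier.events if e.organ == organ and e.timing != "prospective"]
        if pre:
            out[organ] = ScoredOrgan(eligible=False, age_event=None)
            continue
        prosp = [e for e in carrier.events if e.organ == organ and e.timing == "prospective"]
        for e in prosp:
            if e.age_dx <= carrier.age_inclusion:
                raise CohortValidationError(
                    f"carrier {carrier.carrier_id}: prospective {organ} cancer at "
                    f"{e.age_dx} is not after inclusion at {carrier.age_inclusion}"
                )
        age = min((e.age_dx for e in prosp), default=None)
        out[organ] = ScoredOrgan(eligible=True, age_event=age)
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _record_issues(rec: CarrierRecord) -> list[str]:
    issues = []
    if rec.gene not in GENES:
        issues.append(f"unknown gene {rec.gene!r}")
    if rec.sex not in SEXES:
        issues.append(f"unknown sex {rec.sex!r}")
    if rec.vital_status not in VITAL_STATUSES:
        issues.append(f"unknown vital status {rec.vital_status!r}")
    if not math.isfinite(rec.age_inclusion) or rec.age_inclusion < 25:
        issues.append(f"inclusion age {rec.age_inclusion} is below 25")
    if not math.isfinite(rec.age_last_obs) or rec.age_last_obs < rec.age_inclusion:
        issues.append(
            f"last observation age {rec.age_last_obs} precedes inclusion at {rec.age_inclusion}"
        )
    for e in rec.events:
        if e.organ not in ORGANS:
            issues.append(f"unknown organ {e.organ!r}")
            continue
        if e.timing not in TIMINGS:
            issues.append(f"unknown event timing {e.timing!r}")
            continue
        if rec.sex == "M" and e.organ in FEMALE_ONLY:
            issues.append(f"{e.organ} cancer recorded for a male carrier")
        if rec.sex == "F" and e.organ in MALE_ONLY:
            issues.append(f"{e.organ} cancer recorded for a female carrier")
        if e.timing == "prospective" and not (
            rec.age_inclusion < e.age_dx <= rec.age_last_obs
        ):
            issues.append(
                f"prospective {e.organ} cancer at {e.age_dx} outside "
                f"({rec.age_inclusion}, {rec.age_last_obs}]"
            )
        if e.timing in ("previous", "prevalent") and e.age_dx > rec.age_inclusion:
            issues.append(
                f"{e.timing} {e.organ} cancer at {e.age_dx} after inclusion at "
                f"{rec.age_inclusion}"
            )
    return issues


def validate_cohort(
    records: list[CarrierRecord], strict: bool = True
) -> tuple[list[CarrierRecord], dict[str, list[str]]]:
    """Check every cohort invariant; return (valid records, issue log).

    With ``strict=True`` any violation raises :class:`CohortValidationError`
    naming the offending carriers; with ``strict=False`` invalid records are
    skipped and reported in the log keyed by carrier_id.
    """
    issues: dict[str, list[str]] = {}
    valid: list[CarrierRecord] = []
    for rec in records:
        rec_issues = _record_issues(rec)
        if rec_issues:
            issues[str(rec.carrier_id)] = rec_issues
        else:
            valid.append(rec)
    if issues and strict:
        lines = [f"{cid}: {'; '.join(msgs)}" for cid, msgs in issues.items()]
        raise CohortValidationError(
            f"{len(issues)} invalid carrier record(s):\n" + "\n".join(lines)
        )
    return valid, issues


def cohort_summary(records: list[CarrierRecord]) -> dict:
    """Descriptive counts used for sanity checks and the run log."""
    n = len(records)
    total_years = sum(r.follow_up for r in records)
    by_gene = {g: sum(1 for r in records if r.gene == g) for g in GENES}
    by_sex = {s: sum(1 for r in records if r.sex == s) for s in SEXES}
    n_prospective = sum(
        1 for r in records for e in r.events if e.timing == "prospective"
    )
    return {
        "n_carriers": n,
        "by_gene": by_gene,
        "by_sex": by_sex,
        "observation_years": total_years,
        "mean_follow_up": total_years / n if n else float("nan"),
        "n_prospective_events": n_prospective,
    }


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

CARRIER_COLUMNS = ["carrier_id", "gene", "sex", "age_inclusion", "age_last_obs", "vital_status"]
EVENT_COLUMNS = ["carrier_id", "organ", "age_dx", "timing"]


def _canon(value: str, upper: bool = False) -> str:
    s = str(value).strip()
    return s.upper() if upper else s.lower()


def read_carriers_csv(path) -> pd.DataFrame:
    """Read carriers.csv; vocabularies are case-insensitive on read."""
    df = pd.read_csv(path, dtype={"carrier_id": str})
    missing = set(CARRIER_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"carriers file missing columns {sorted(missing)}")
    df["gene"] = df["gene"].map(lambda v: _canon(v, upper=True))
    df["sex"] = df["sex"].map(lambda v: _canon(v, upper=True))
    df["vital_status"] = df["vital_status"].map(_canon)
    df["age_inclusion"] = df["age_inclusion"].astype(float)
    df["age_last_obs"] = df["age_last_obs"].astype(float)
    return df[CARRIER_COLUMNS]


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"carrier_id": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"events file missing columns {sorted(missing)}")
    df["organ"] = df["organ"].map(_canon)
    df["timing"] = df["timing"].map(_canon)
    df["age_dx"] = df["age_dx"].astype(float)
    return df[EVENT_COLUMNS]


def frames_to_records(
    carriers: pd.DataFrame, events: pd.DataFrame | None = None
) -> list[CarrierRecord]:
    """Assemble CarrierRecord objects from the two flat tables."""
    ev_by_id: dict[str, list[CancerEvent]] = {}
    if events is not None and len(events):
        for row in events.itertuples(index=False):
            ev_by_id.setdefault(str(row.carrier_id), []).append(
                CancerEvent(organ=row.organ, age_dx=float(row.age_dx), timing=row.timing)
            )
    records = []
    for row in carriers.itertuples(index=False):
        cid = str(row.carrier_id)
        records.append(
            CarrierRecord(
                carrier_id=cid,
                gene=row.gene,
                sex=row.sex,
                age_inclusion=float(row.age_inclusion),
                age_last_obs=float(row.age_last_obs),
                vital_status=row.vital_status,
                events=sorted(ev_by_id.get(cid, []), key=lambda e: (e.age_dx, e.organ)),
            )
        )
    return records


def load_cohort(
    carriers_path, events_path=None, strict: bool = True
) -> tuple[list[CarrierRecord], dict[str, list[str]]]:
    """Read, assemble and validate a cohort from CSV files."""
    carriers = read_carriers_csv(carriers_path)
    events = read_events_csv(events_path) if events_path is not None else None
    return validate_cohort(frames_to_records(carriers, events), strict=strict)


def records_to_frames(records: list[CarrierRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten records back into the carriers/events tables (canonical case)."""
    carriers = pd.DataFrame(
        [
            {
                "carrier_id": r.carrier_id,
                "gene": r.gene,
                "sex": r.sex,
                "age_inclusion": r.age_inclusion,
                "age_last_obs": r.age_last_obs,
                "vital_status": r.vital_status,
            }
            for r in records
        ],
        columns=CARRIER_COLUMNS,
    )
    events = pd.DataFrame(
        [
            {
                "carrier_id": r.carrier_id,
                "organ": e.organ,
                "age_dx": e.age_dx,
                "timing": e.timing,
            }
            for r in records
            for e in r.events
        ],
        columns=EVENT_COLUMNS,
    )
    return carriers, events


def write_cohort_csv(records: list[CarrierRecord], carriers_path, events_path) -> None:
    carriers, events = records_to_frames(records)
    carriers.to_csv(carriers_path, index=False)
    events.to_csv(events_path, index=False)
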