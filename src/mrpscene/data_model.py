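"""Data schema, CSV I/O, decision-x-confidence encoding and participant exclusions.

The atomic observation is one probe response in a massive-report-paradigm
session: a participant briefly sees a natural scene, is then shown a small
image patch, and reports presence/absence with two confidence levels.  The
four response options are encoded as a signed decision-x-confidence (D x C)
value: +3 "absolutely present", +1 "maybe present", -1 "maybe absent",
-3 "absolutely absent".

A cohort couples a long-format table of probe responses with a
participant-level metadata table (practice performance, session completeness,
catch-question accuracy) that drives the three-stage exclusion pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

AGE_GROUPS: tuple[str, ...] = ("5-6", "7-9", "10-12", "adult")
AGE_CODING: dict[str, int] = {g: i for i, g in enumerate(AGE_GROUPS)}

RESPONSES: tuple[str, ...] = (
    "absolutely_present",
    "maybe_present",
    "maybe_absent",
    "absolutely_absent",
)
DXC_VALUES: tuple[int, ...] = (3, 1, -1, -3)
DXC_MAP: dict[str, int] = dict(zip(RESPONSES, DXC_VALUES))

PROBE_TYPES: tuple[str, ...] = ("original", "modified", "present", "absent", "catch")
SIGNAL_PROBES: tuple[str, ...] = ("original", "present")
NOISE_PROBES: tuple[str, ...] = ("absent",)
CONGRUENCY_LEVELS: tuple[str, ...] = ("congruent", "incongruent")

RECORD_COLUMNS: list[str] = [
    "participant_id",
    "age_group",
    "trial_index",
    "probe_index",
    "probe_type",
    "location",
    "image_id",
    "initial_congruency",
    "response",
    "rt_ms",
]
META_COLUMNS: list[str] = [
    "participant_id",
    "age_group",
    "practice_correct",
    "completed_trials",
    "catch_n",
    "catch_correct",
]


class SchemaError(ValueError):
    """A table violates the cohort schema (bad column, category or key)."""


def encode_dxc(response: str) -> int:
    """Map a response label to its decision-x-confidence integer.

    The encoding is a bijection between the four labels and {+3, +1, -1, -3},
    ordered by confidence in presence.
    """
    try:
        return DXC_MAP[response]
    except KeyError:
        raise SchemaError(
            f"unknown response label {response!r}; expected one of {RESPONSES}"
        ) from None


@dataclasses.dataclass
class Cohort:
    """Probe-level records plus participant-level metadata.

    ``records`` has one row per probe response (columns ``RECORD_COLUMNS``
    plus a derived ``dxc`` column); ``meta`` has one row per participant
    (columns ``META_COLUMNS``).  Every participant appearing in ``records``
    must appear in ``meta`` with a consistent age group.
    """

    records: pd.DataFrame
    meta: pd.DataFrame

    @property
    def participants(self) -> list[str]:
        return list(self.meta["participant_id"])

    @property
    def n_participants(self) -> int:
        return len(self.meta)

    def scored_records(self) -> pd.DataFrame:
        """Records excluding catch probes (the scored probes only)."""
        return self.records[self.records["probe_type"] != "catch"]


def validate_cohort(cohort: Cohort, n_trials: int = 30) -> None:
    """Raise :class:`SchemaError` on any schema violation.

    Checks column presence, category membership, trial/probe ranges,
    duplicate (participant, trial, probe) keys, meta coverage and age-group
    consistency between the two tables, and the stored-vs-recomputed ``dxc``.
    """
    rec, meta = cohort.records, cohort.meta
    for col in RECORD_COLUMNS:
        if col not in rec.columns:
            raise SchemaError(f"records table missing column {col!r}")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"meta table missing column {col!r}")

    bad_resp = set(rec["response"]) - set(RESPONSES)
    if bad_resp:
        raise SchemaError(f"non-enumerated response value(s): {sorted(bad_resp)}")
    bad_probe = set(rec["probe_type"]) - set(PROBE_TYPES)
    if bad_probe:
        raise SchemaError(f"non-enumerated probe_type value(s): {sorted(bad_probe)}")
    bad_cong = set(rec["initial_congruency"]) - set(CONGRUENCY_LEVELS)
    if bad_cong:
        raise SchemaError(f"non-enumerated congruency value(s): {sorted(bad_cong)}")
    bad_age = (set(rec["age_group"]) | set(meta["age_group"])) - set(AGE_GROUPS)
    if bad_age:
        raise SchemaError(f"non-enumerated age_group value(s): {sorted(bad_age)}")

    trial = rec["trial_index"].to_numpy()
    if ((trial < 1) | (trial > n_trials)).any():
        raise SchemaError(f"trial_index outside 1..{n_trials}")
    probe = rec["probe_index"].to_numpy()
    if ((probe < 1) | (probe > 7)).any():
        raise SchemaError("probe_index outside 1..7")
    if (rec["rt_ms"].to_numpy() < 0).any():
        raise SchemaError("negative rt_ms")

    key = rec[["participant_id", "trial_index", "probe_index"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise SchemaError(
            "duplicate (participant, trial, probe) key: "
            f"{tuple(dup)}"
        )

    if "dxc" in rec.columns:
        expect = rec["response"].map(DXC_MAP)
        if not (rec["dxc"].to_numpy() == expect.to_numpy()).all():
            raise SchemaError("stored dxc disagrees with response encoding")

    missing = set(rec["participant_id"]) - set(meta["participant_id"])
    if missing:
        raise SchemaError(f"records reference unknown participant(s): {sorted(missing)[:5]}")
    age_of = dict(zip(meta["participant_id"], meta["age_group"]))
    rec_age = rec.drop_duplicates("participant_id")[["participant_id", "age_group"]]
    for pid, age in zip(rec_age["participant_id"], rec_age["age_group"]):
        if age_of[pid] != age:
            raise SchemaError(f"age_group mismatch for participant {pid!r}")

    if (meta["catch_correct"].to_numpy() > meta["catch_n"].to_numpy()).any():
        raise SchemaError("catch_correct exceeds catch_n")
    if (meta["completed_trials"].to_numpy() > n_trials).any():
        raise SchemaError(f"completed_trials exceeds {n_trials}")


def read_cohort(records_path: str | Path, meta_path: str | Path,
                n_trials: int = 30) -> Cohort:
    """Read a cohort from the records and meta CSV files and validate it.

    The ``dxc`` column is recomputed from ``response``; if the file carries a
    stored ``dxc`` it is checked against the recomputed value.
    """
    records = pd.read_csv(records_path)
    meta = pd.read_csv(meta_path)
    cohort = Cohort(records=records, meta=meta)
    validate_cohort(cohort, n_trials=n_trials)
    records["dxc"] = records["response"].map(DXC_MAP).astype(int)
    return cohort


def write_cohort(cohort: Cohort, records_path: str | Path,
                 meta_path: str | Path) -> None:
    """Write the cohort's two tables as UTF-8 comma-separated files."""
    cols = RECORD_COLUMNS + (["dxc"] if "dxc" in cohort.records.columns else [])
    cohort.records[cols].to_csv(records_path, index=False)
    cohort.meta[META_COLUMNS].to_csv(meta_path, index=False)


_CRITERIA = ("practice", "incomplete", "catch")


@dataclasses.dataclass
class ExclusionReport:
    """Counts of participants removed by each sequential exclusion filter.

    Each excluded participant is counted once, under the first criterion it
    fails, in the order practice -> completeness -> catch; the identity
    ``n_total - n_fail_practice - n_incomplete - n_fail_catch = n_final``
    therefore holds exactly.  ``by_group`` gives the same breakdown per age
    group; ``undefined_catch`` lists participants with ``catch_n == 0``
    (excluded under the catch criterion with an explicit flag).
    """

    n_total: int
    n_fail_practice: int
    n_incomplete: int
    n_fail_catch: int
    n_final: int
    by_group: dict[str, dict[str, int]]
    undefined_catch: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def apply_exclusions(
    cohort: Cohort,
    min_practice_correct: int = 5,
    catch_threshold: float = 0.70,
    required_trials: int = 30,
) -> tuple[Cohort, ExclusionReport]:
    """Apply the three participant filters and return the retained cohort.

    A participant is retained when all three hold:

    * ``practice_correct >= min_practice_correct``,
    * ``completed_trials == required_trials``,
    * ``catch_correct / catch_n >= catch_threshold`` (a rate of exactly the
      threshold is retained; only performance *below* it excludes).

    A participant with ``catch_n == 0`` has an undefined catch rate and is
    excluded under the catch criterion, listed in ``undefined_catch``.
    """
    meta = cohort.meta
    reasons: dict[str, str | None] = {}
    undefined: list[str] = []
    for row in meta.itertuples(index=False):
        if row.practice_correct < min_practice_correct:
            reasons[row.participant_id] = "practice"
        elif row.completed_trials != required_trials:
            reasons[row.participant_id] = "incomplete"
        elif row.catch_n == 0:
            reasons[row.participant_id] = "catch"
            undefined.append(row.participant_id)
        elif row.catch_correct / row.catch_n < catch_threshold:
            reasons[row.participant_id] = "catch"
        else:
            reasons[row.participant_id] = None

    by_group: dict[str, dict[str, int]] = {}
    for row in meta.itertuples(index=False):
        grp = by_group.setdefault(
            row.age_group,
            {"n_total": 0, "n_fail_practice": 0, "n_incomplete": 0,
             "n_fail_catch": 0, "n_final": 0},
        )
        grp["n_total"] += 1
        reason = reasons[row.participant_id]
        if reason == "practice":
            grp["n_fail_practice"] += 1
        elif reason == "incomplete":
            grp["n_incomplete"] += 1
        elif reason == "catch":
            grp["n_fail_catch"] += 1
        else:
            grp["n_final"] += 1

    keep = [pid for pid, r in reasons.items() if r is None]
    keep_set = set(keep)
    retained = Cohort(
        records=cohort.records[cohort.records["participant_id"].isin(keep_set)]
        .reset_index(drop=True),
        meta=meta[meta["participant_id"].isin(keep_set)].reset_index(drop=True),
    )
    report = ExclusionReport(
        n_total=len(meta),
        n_fail_practice=sum(r == "practice" for r in reasons.values()),
        n_incomplete=sum(r == "incomplete" for r in reasons.values()),
        n_fail_catch=sum(r == "catch" for r in reasons.values()),
        n_final=len(keep),
        by_group=by_group,
        undefined_catch=undefined,
    )
    return retained, report
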