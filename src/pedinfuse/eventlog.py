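"""Append-only timestamped action logs and extraction of time outcomes.

Every preparation action is recorded with a timestamp in seconds relative to
scenario start (monotonic, never wall clock — the trial outcomes are elapsed
times).  The two outcomes are read off the log per drug:

* TDP, time to drug preparation: prescription -> preparation_complete;
* TDD, time to drug delivery: prescription -> delivery_start (includes TDP).

Logs are value objects: ``record`` returns a new log, prior records are
immutable, and erasure is a separate operation guarded by ``force``.
"""

from __future__ import annotations

import csv
import enum
import json
from pathlib import Path
from typing import NamedTuple, Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Action",
    "ActionRecord",
    "EventLog",
    "EventLogError",
    "MissingMilestoneError",
    "Times",
    "record",
    "extract_times",
    "erase",
    "write_log",
    "read_log",
]


class EventLogError(ValueError):
    pass


class MissingMilestoneError(EventLogError):
    def __init__(self, drug: str, action: "Action"):
        self.drug = drug
        self.action = action
        super().__init__(f"log has no {action.value!r} record for drug {drug!r}")


class Action(str, enum.Enum):
    PRESCRIPTION = "prescription"
    SELECT_DRUG = "select_drug"
    PREPARE_STEP = "prepare_step"
    PREPARATION_COMPLETE = "preparation_complete"
    DELIVERY_START = "delivery_start"
    PAUSE = "pause"
    STOP = "stop"
    RATE_CHANGE = "rate_change"


class ActionRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    timestamp: float  # s since scenario start
    actor: str
    action: Action
    drug: str
    payload: dict = {}

    @field_validator("timestamp")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("timestamp must be >= 0")
        return v


class EventLog(BaseModel):
    model_config = ConfigDict(frozen=True)

    scenario_id: str
    records: tuple[ActionRecord, ...] = ()

    @model_validator(mode="after")
    def _ordered(self) -> "EventLog":
        times = [r.timestamp for r in self.records]
        if any(b < a for a, b in zip(times, times[1:])):
            raise EventLogError("record timestamps must be non-decreasing")
        seen: set[str] = set()
        for r in self.records:
            if r.action is Action.PRESCRIPTION:
                if r.drug in seen:
                    raise EventLogError(
                        f"more than one prescription for drug {r.drug!r}"
                    )
                seen.add(r.drug)
        return self

    def __len__(self) -> int:
        return len(self.records)


class Times(NamedTuple):
    tdp_s: float
    tdd_s: float


def record(log: EventLog, r: ActionRecord) -> EventLog:
    """Append one record; rejects out-of-order timestamps."""
    if log.records and r.timestamp < log.records[-1].timestamp:
        raise EventLogError(
            f"out-of-order timestamp {r.timestamp} < {log.records[-1].timestamp}"
        )
    if r.action is Action.PRESCRIPTION and any(
        x.action is Action.PRESCRIPTION and x.drug == r.drug for x in log.records
    ):
        raise EventLogError(f"more than one prescription for drug {r.drug!r}")
    return EventLog(scenario_id=log.scenario_id, records=log.records + (r,))


def erase(log: EventLog, *, force: bool = False) -> EventLog:
    """Clear the log. Destructive, so it must be forced explicitly."""
    if not force:
        raise EventLogError("refusing to erase log without force=True")
    return EventLog(scenario_id=log.scenario_id)


def _milestone(log: EventLog, drug: str, action: Action) -> float:
    for r in log.records:
        if r.drug == drug and r.action is action:
            return r.timestamp
    raise MissingMilestoneError(drug, action)


def extract_times(log: EventLog, drug: str) -> Times:
    """TDP and TDD (seconds) for one drug; other drugs' records are ignored."""
    t_rx = _milestone(log, drug, Action.PRESCRIPTION)
    t_prep = _milestone(log, drug, Action.PREPARATION_COMPLETE)
    t_del = _milestone(log, drug, Action.DELIVERY_START)
    if t_prep < t_rx:
        raise EventLogError(f"preparation of {drug!r} completed before prescription")
    if t_del < t_prep:
        raise EventLogError(f"delivery of {drug!r} started before preparation completed")
    return Times(tdp_s=t_prep - t_rx, tdd_s=t_del - t_rx)


_COLUMNS = ["scenario_id", "timestamp_s", "actor", "action", "drug", "payload"]


def write_log(log: EventLog, path: Union[str, Path]) -> None:
    """Delimited-text serialization; timestamps round-trip exactly."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for r in log.records:
            w.writerow(
                [
                    log.scenario_id,
                    repr(r.timestamp),
                    r.actor,
                    r.action.value,
                    r.drug,
                    json.dumps(r.payload, sort_keys=True),
                ]
            )


def read_log(path: Union[str, Path], scenario_id: Optional[str] = None) -> EventLog:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _COLUMNS:
            raise EventLogError(f"unexpected log header: {header}")
        records = []
        sid = scenario_id
        for row in reader:
            if sid is None:
                sid = row[0]
            elif row[0] != sid and scenario_id is None:
                raise EventLogError("log file mixes scenario ids")
            records.append(
                ActionRecord(
                    timestamp=float(row[1]),
                    actor=row[2],
                    action=Action(row[3]),
                    drug=row[4],
                    payload=json.loads(row[5]),
                )
            )
    return EventLog(scenario_id=sid or "", records=tuple(records))
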