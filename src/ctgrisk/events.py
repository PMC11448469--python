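"""Domain types and file I/O for event-annotated labor records.

A labor record is a set of labeled intervals on two channels — fetal heart
rate (FHR: baseline / acceleration / deceleration) and uterine pressure
(UP: contraction / resting interval) — together with uninterpretable
segments where signal quality prevented FHR analysis.

Time is measured in seconds *before delivery*: delivery is 0 and larger
values are earlier. Intervals are half-open ``[start, end)`` in that
coordinate, with ``start > end >= 0``, so adjacent events share a boundary
without overlapping.

File format
-----------
Events file (CSV, header required):
    ``subject_id,channel,label,start_s,end_s``
with channel in {FHR, UP}, label in {BAS, ACC, DEC} for FHR, {CON, RIN}
for UP. Uninterpretable segments are stored as ``FHR,INV`` rows so that a
written cohort reads back field-for-field.

Metadata file (CSV, header required):
    ``subject_id,group,duration_s,caesarean``
with group in {healthy, acidosis, HIE} and caesarean in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

FHR = "FHR"
UP = "UP"

FHR_LABELS = ("BAS", "ACC", "DEC")
UP_LABELS = ("CON", "RIN")
INVALID_LABEL = "INV"  # file-format marker for uninterpretable segments

GROUPS = ("healthy", "acidosis", "HIE")
PATHOLOGICAL_GROUPS = ("acidosis", "HIE")

#: Records are capped at 12 h of monitoring before delivery.
MAX_DURATION_S = 43_200.0

LABELS_BY_CHANNEL = {FHR: FHR_LABELS, UP: UP_LABELS}

EVENT_COLUMNS = ["subject_id", "channel", "label", "start_s", "end_s"]
METADATA_COLUMNS = ["subject_id", "group", "duration_s", "caesarean"]


@dataclass(frozen=True)
class EventInterval:
    """One labeled interval on one channel, in time-before-delivery seconds.

    ``start > end >= 0``: the interval begins earlier (``start``) and ends
    closer to delivery (``end``); its duration is ``start - end``.
    """

    channel: str
    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.start - self.end

    def __post_init__(self) -> None:
        if self.channel not in LABELS_BY_CHANNEL:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.label not in LABELS_BY_CHANNEL[self.channel]:
            raise ValueError(
                f"label {self.label!r} is not valid on channel {self.channel!r}"
            )
        if not self.start > self.end:
            raise ValueError(
                f"interval must have positive duration: start={self.start}, end={self.end}"
            )
        if self.end < 0:
            raise ValueError(f"interval end must be >= 0, got {self.end}")


@dataclass
class LaborRecord:
    """A subject's full annotation set.

    ``events`` maps channel -> list of :class:`EventInterval` sorted by
    decreasing ``start`` (chronological order). ``invalid_intervals`` are
    ``(start, end)`` pairs of uninterpretable time, also ``start > end``.
    """

    subject_id: str
    group: str
    duration: float
    caesarean: bool
    events: dict[str, list[EventInterval]] = field(default_factory=dict)
    invalid_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events.setdefault(FHR, [])
        self.events.setdefault(UP, [])

    def channel_events(self, channel: str) -> list[EventInterval]:
        return self.events.get(channel, [])


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_record`."""

    invariant: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.invariant}] {self.message}"


def _intervals_overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> bool:
    # half-open [start, end) intervals in before-delivery time
    return min(a_start, b_start) > max(a_end, b_end)


def validate_record(record: LaborRecord) -> list[Violation]:
    """Check every LaborRecord invariant; return violations, never raise.

    Checked: group and duration sanity, label/channel consistency, per-channel
    chronological ordering (decreasing start) without overlap, all intervals
    inside [0, duration], and no overlap between uninterpretable segments and
    FHR events.
    """
    out: list[Violation] = []
    if record.group not in GROUPS:
        out.append(Violation("group", f"unknown group {record.group!r}"))
    if not (0 < record.duration <= MAX_DURATION_S):
        out.append(
            Violation("duration", f"duration {record.duration} outside (0, {MAX_DURATION_S}]")
        )
    for channel, events in record.events.items():
        if channel not in LABELS_BY_CHANNEL:
            out.append(Violation("channel", f"unknown channel {channel!r}"))
            continue
        for ev in events:
            if ev.channel != channel:
                out.append(
                    Violation("channel-consistency", f"event {ev} filed under channel {channel}")
                )
            if ev.label not in LABELS_BY_CHANNEL[channel]:
                out.append(
                    Violation("label-channel", f"label {ev.label} invalid on {channel}: {ev}")
                )
            if not ev.start > ev.end:
                out.append(Violation("positive-duration", f"start <= end in {ev}"))
            if ev.start > record.duration or ev.end < 0:
                out.append(
                    Violation("bounds", f"event {ev} outside [0, duration={record.duration}]")
                )
        for earlier, later in zip(events, events[1:]):
            if later.start > earlier.start:
                out.append(
                    Violation(
                        "ordering",
                        f"{channel} events not sorted by decreasing start: "
                        f"{earlier} before {later}",
                    )
                )
            if _intervals_overlap(earlier.start, earlier.end, later.start, later.end):
                out.append(
                    Violation("overlap", f"{channel} events overlap: {earlier} and {later}")
                )
    for start, end in record.invalid_intervals:
        if not start > end:
            out.append(
                Violation("invalid-positive-duration", f"invalid interval ({start}, {end})")
            )
        if start > record.duration or end < 0:
            out.append(
                Violation(
                    "invalid-bounds",
                    f"invalid interval ({start}, {end}) outside [0, {record.duration}]",
                )
            )
        for ev in record.channel_events(FHR):
            if _intervals_overlap(start, end, ev.start, ev.end):
                out.append(
                    Violation(
                        "invalid-overlaps-event",
                        f"invalid interval ({start}, {end}) overlaps FHR event {ev}",
                    )
                )
    return out


def write_records(records: list[LaborRecord], events_path, metadata_path) -> None:
    """Write a cohort to the events/metadata CSV pair.

    Uninterpretable segments are emitted as ``FHR,INV`` rows.
    ``read_records(write_records(x)) == x`` field-for-field for valid cohorts.
    """
    ev_rows = []
    md_rows = []
    for rec in records:
        md_rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "duration_s": rec.duration,
                "caesarean": int(rec.caesarean),
            }
        )
        for channel in (FHR, UP):
            for ev in rec.channel_events(channel):
                ev_rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "channel": channel,
                        "label": ev.label,
                        "start_s": ev.start,
                        "end_s": ev.end,
                    }
                )
        for start, end in rec.invalid_intervals:
            ev_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "channel": FHR,
                    "label": INVALID_LABEL,
                    "start_s": start,
                    "end_s": end,
                }
            )
    # %.17g guarantees bit-exact float round-trips through the text format
    pd.DataFrame(ev_rows, columns=EVENT_COLUMNS).to_csv(
        events_path, index=False, float_format="%.17g"
    )
    pd.DataFrame(md_rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, index=False, float_format="%.17g"
    )


def read_records(events_path, metadata_path) -> list[LaborRecord]:
    """Read a cohort from the events/metadata CSV pair and validate it.

    Raises ``ValueError`` naming the line number for malformed rows, for
    events referencing unknown subjects, and for any record that fails
    :func:`validate_record`.
    """
    md = pd.read_csv(metadata_path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = set(METADATA_COLUMNS) - set(md.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    ev = pd.read_csv(events_path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")

    records: dict[str, LaborRecord] = {}
    for i, row in enumerate(md.itertuples(index=False), start=2):  # 1-based + header
        if row.group not in GROUPS:
            raise ValueError(f"{metadata_path}:{i}: unknown group {row.group!r}")
        if row.caesarean not in (0, 1):
            raise ValueError(f"{metadata_path}:{i}: caesarean must be 0/1, got {row.caesarean!r}")
        if row.subject_id in records:
            raise ValueError(f"{metadata_path}:{i}: duplicate subject {row.subject_id!r}")
        records[row.subject_id] = LaborRecord(
            subject_id=row.subject_id,
            group=row.group,
            duration=float(row.duration_s),
            caesarean=bool(row.caesarean),
        )

    for i, row in enumerate(ev.itertuples(index=False), start=2):
        rec = records.get(row.subject_id)
        if rec is None:
            raise ValueError(f"{events_path}:{i}: unknown subject {row.subject_id!r}")
        start, end = float(row.start_s), float(row.end_s)
        if row.label == INVALID_LABEL:
            rec.invalid_intervals.append((start, end))
            continue
        if row.channel not in LABELS_BY_CHANNEL:
            raise ValueError(f"{events_path}:{i}: unknown channel {row.channel!r}")
        if row.label not in LABELS_BY_CHANNEL[row.channel]:
            raise ValueError(
                f"{events_path}:{i}: label {row.label!r} not valid on channel {row.channel!r}"
            )
        try:
            rec.events[row.channel].append(
                EventInterval(channel=row.channel, label=row.label, start=start, end=end)
            )
        except ValueError as exc:
            raise ValueError(f"{events_path}:{i}: {exc}") from exc

    out = []
    for rec in records.values():
        for channel in (FHR, UP):
            rec.events[channel].sort(key=lambda e: -e.start)
        rec.invalid_intervals.sort(key=lambda iv: -iv[0])
        violations = validate_record(rec)
        if violations:
            msgs = "; ".join(str(v) for v in violations)
            raise ValueError(f"record {rec.subject_id!r} invalid: {msgs}")
        out.append(rec)
    return out
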