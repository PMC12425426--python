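"""Reading, merging, labelling and windowing of per-minute actigraphy cohorts.

The on-disk dialect mirrors the public Depresjon layout: one CSV per
participant with columns ``timestamp,date,activity`` (one row per minute of
wrist-worn accelerometer counts) plus a single ``scores.csv`` table of
demographics and MADRS ratings. Group membership (clinical *condition* vs
healthy *control*) is carried by the participant identifier prefix, as in the
original file names (``condition_12``, ``control_3``).
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "ActivityRecording",
    "ParticipantMetadata",
    "ActivityWindow",
    "Cohort",
    "CohortIOError",
    "FormatError",
    "ValidationError",
    "read_activity_file",
    "write_activity_file",
    "read_scores_table",
    "write_scores_table",
    "read_cohort_dir",
    "write_cohort_dir",
    "merge_cohort",
    "assign_binary_label",
    "assign_severity_label",
    "window_recording",
    "age_band_midpoint",
]

ACTIVITY_COLUMNS = ("timestamp", "date", "activity")
SCORES_COLUMNS = (
    "number", "days", "gender", "age", "afftype", "melanch", "inpatient",
    "edu", "marriage", "work", "madrs1", "madrs2",
)
#: required subset of the scores header; clinical covariates are optional
SCORES_REQUIRED = ("number", "days", "gender", "age", "madrs1", "madrs2")

MADRS_MAX = 60
#: MADRS ceiling supported by the three-class severity map (no severe cases)
SEVERITY_MADRS_MAX = 34


class CohortIOError(Exception):
    """Base error for cohort ingestion problems."""


class FormatError(CohortIOError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(CohortIOError):
    """Parsed content violates a domain invariant."""


class Group(enum.Enum):
    CONDITION = "condition"
    CONTROL = "control"
    UNKNOWN = "unknown"

    @classmethod
    def from_participant_id(cls, participant_id: str) -> "Group":
        low = participant_id.lower()
        if low.startswith("condition"):
            return cls.CONDITION
        if low.startswith("control"):
            return cls.CONTROL
        return cls.UNKNOWN


@dataclass
class ActivityRecording:
    """One participant's per-minute activity count series."""

    participant_id: str
    group: Group
    timestamps: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValidationError("participant_id must be non-empty")
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.timestamps):
            raise ValidationError("timestamps and counts lengths differ")
        if len(self.counts) and np.any(self.counts < 0):
            raise ValidationError(
                f"{self.participant_id}: negative activity count"
            )

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class ParticipantMetadata:
    """Demographics and MADRS ratings for one participant.

    Gender uses the dataset's coding (1 female, 2 male); ``age_band`` is a
    string range such as ``"45-49"``; MADRS scores, when present, lie in
    [0, 60] (madrs1 before, madrs2 after the inspection period).
    """

    number: str
    days: int
    gender: int
    age_band: str
    afftype: Optional[int] = None
    melanch: Optional[int] = None
    inpatient: Optional[int] = None
    edu: Optional[str] = None
    marriage: Optional[int] = None
    work: Optional[int] = None
    madrs1: Optional[int] = None
    madrs2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gender not in (1, 2):
            raise ValidationError(
                f"participant {self.number}: gender must be 1 or 2, "
                f"got {self.gender}"
            )
        if self.days < 1:
            raise ValidationError(f"participant {self.number}: days < 1")
        for name in ("madrs1", "madrs2"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= MADRS_MAX):
                raise ValidationError(
                    f"participant {self.number}: {name}={v} outside [0, 60]"
                )


@dataclass
class ActivityWindow:
    """A fixed-length slice of a recording (default one day = 1440 minutes)."""

    participant_id: str
    start: pd.Timestamp
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValidationError("window contains negative counts")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class CohortMember:
    recording: ActivityRecording
    metadata: ParticipantMetadata

    @property
    def participant_id(self) -> str:
        return self.recording.participant_id

    @property
    def group(self) -> Group:
        return self.recording.group


@dataclass
class Cohort:
    members: list[CohortMember]
    join_log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def read_activity_file(path: str | Path) -> ActivityRecording:
    """Parse one participant's ``timestamp,date,activity`` CSV.

    Rows are returned sorted by timestamp; the participant id is the file
    stem and the group is inferred from its prefix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    ts = pd.to_datetime(df["timestamp"], format="mixed", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based indexing
        raise FormatError(
            f"{path.name}: unparseable timestamp at line {bad[0] + 2}"
        )
    counts = pd.to_numeric(df["activity"], errors="coerce")
    badc = np.flatnonzero(counts.isna().to_numpy())
    if badc.size:
        raise FormatError(
            f"{path.name}: unparseable activity at line {badc[0] + 2}"
        )
    counts = counts.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValidationError(f"{path.name}: negative activity count")
    order = np.argsort(ts.to_numpy(), kind="stable")
    pid = path.stem
    return ActivityRecording(
        participant_id=pid,
        group=Group.from_participant_id(pid),
        timestamps=pd.DatetimeIndex(ts.to_numpy()[order]),
        counts=np.round(counts[order]).astype(np.int64),
    )


def write_activity_file(recording: ActivityRecording, path: str | Path) -> None:
    """Write a recording in the ``timestamp,date,activity`` dialect."""
    ts = recording.timestamps
    pd.DataFrame(
        {
            "timestamp": ts.strftime("%Y-%m-%d %H:%M:%S"),
            "date": ts.strftime("%Y-%m-%d"),
            "activity": recording.counts.astype(int),
        }
    ).to_csv(path, index=False)


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    return int(float(s))


def read_scores_table(path: str | Path) -> list[ParticipantMetadata]:
    """Parse the demographics/MADRS ``scores.csv`` table.

    Blank clinical cells map to absent values (None), never to zero.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SCORES_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    records: list[ParticipantMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        number = str(row["number"]).strip()
        if number in seen:
            raise ValidationError(f"duplicate participant number {number!r}")
        seen.add(number)
        edu = row.get("edu")
        records.append(
            ParticipantMetadata(
                number=number,
                days=int(float(row["days"])),
                gender=int(float(row["gender"])),
                age_band=str(row["age"]).strip(),
                afftype=_opt_int(row.get("afftype")),
                melanch=_opt_int(row.get("melanch")),
                inpatient=_opt_int(row.get("inpatient")),
                edu=None if edu is None or str(edu).strip() in ("", "nan")
                else str(edu).strip(),
                marriage=_opt_int(row.get("marriage")),
                work=_opt_int(row.get("work")),
                madrs1=_opt_int(row.get("madrs1")),
                madrs2=_opt_int(row.get("madrs2")),
            )
        )
    return records


def write_scores_table(
    metadata: Sequence[ParticipantMetadata], path: str | Path
) -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "number": m.number,
                "days": m.days,
                "gender": m.gender,
                "age": m.age_band,
                "afftype": m.afftype,
                "melanch": m.melanch,
                "inpatient": m.inpatient,
                "edu": m.edu,
                "marriage": m.marriage,
                "work": m.work,
                "madrs1": m.madrs1,
                "madrs2": m.madrs2,
            }
        )
    pd.DataFrame(rows, columns=list(SCORES_COLUMNS)).to_csv(path, index=False)


def merge_cohort(
    recordings: Sequence[ActivityRecording],
    metadata: Sequence[ParticipantMetadata],
) -> Cohort:
    """Join recordings with their scores rows on the participant number.

    Unmatched entries on either side are reported in the cohort's join log
    (one JSON-serialisable dict per orphan); zero matches is an error.
    """
    ids = [r.participant_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate participant ids among recordings")
    meta_by_id = {m.number: m for m in metadata}
    members: list[CohortMember] = []
    log: list[dict] = []
    for rec in recordings:
        meta = meta_by_id.pop(rec.participant_id, None)
        if meta is None:
            log.append(
                {"side": "recording", "id": rec.participant_id,
                 "reason": "no scores row"}
            )
        else:
            members.append(CohortMember(recording=rec, metadata=meta))
    for number in meta_by_id:
        log.append(
            {"side": "scores", "id": number, "reason": "no activity file"}
        )
    if not members:
        raise ValidationError("no participant matched between recordings and scores")
    return Cohort(members=members, join_log=log)


def read_cohort_dir(directory: str | Path) -> Cohort:
    """Read every activity CSV plus ``scores.csv`` from a directory tree."""
    directory = Path(directory)
    scores = directory / "scores.csv"
    if not scores.exists():
        raise FileNotFoundError(scores)
    metadata = read_scores_table(scores)
    recordings = [
        read_activity_file(p)
        for p in sorted(directory.rglob("*.csv"))
        if p.name != "scores.csv"
    ]
    return merge_cohort(recordings, metadata)


def write_cohort_dir(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for member in cohort:
        sub = directory / member.group.value
        sub.mkdir(exist_ok=True)
        write_activity_file(member.recording, sub / f"{member.participant_id}.csv")
    write_scores_table([m.metadata for m in cohort], directory / "scores.csv")
    if cohort.join_log:
        with open(directory / "join_log.jsonl", "w") as fh:
            for entry in cohort.join_log:
                fh.write(json.dumps(entry) + "\n")


def assign_binary_label(group: Group) -> int:
    """Depressed-vs-not target: clinical condition -> 1, control -> 0."""
    if group is Group.CONDITION:
        return 1
    if group is Group.CONTROL:
        return 0
    raise ValidationError(f"cannot label group {group!r}")


def assign_severity_label(madrs: int, allow_severe: bool = False) -> int:
    """Map a MADRS score to the three-class severity target.

    0-6 -> 0 (normal), 7-19 -> 1 (mild), 20-34 -> 2 (moderate). Scores >= 35
    fall in the severe band that the study population does not contain and
    are rejected unless ``allow_severe`` maps them to a fourth class (3).
    """
    madrs = int(madrs)
    if madrs < 0:
        raise ValidationError(f"MADRS score {madrs} is negative")
    if madrs <= 6:
        return 0
    if madrs <= 19:
        return 1
    if madrs <= SEVERITY_MADRS_MAX:
        return 2
    if madrs <= MADRS_MAX and allow_severe:
        return 3
    raise ValidationError(
        f"MADRS score {madrs} outside the supported range [0, 34] "
        "(no severe class; pass allow_severe=True to map to class 3)"
    )


def window_recording(
    recording: ActivityRecording,
    length: int = 1440,
    gap_tolerance: int = 2,
) -> tuple[list[ActivityWindow], list[dict]]:
    """Cut a recording into consecutive non-overlapping fixed-length windows.

    The minute grid is rebuilt from the first to the last timestamp; gaps of
    at most ``gap_tolerance`` missing minutes are forward-filled with zeros,
    while any window spanning a longer gap is dropped and logged. A trailing
    partial window is dropped silently; a recording shorter than ``length``
    yields an empty list with a warning.

    Returns ``(windows, drop_log)``.
    """
    if length < 2:
        raise ValueError("window length must be >= 2")
    if len(recording) < length:
        warnings.warn(
            f"{recording.participant_id}: recording shorter than one window "
            f"({len(recording)} < {length})",
            stacklevel=2,
        )
        return [], []
    ts = recording.timestamps.round("min")
    full = pd.date_range(ts[0], ts[-1], freq="min")
    series = pd.Series(recording.counts.astype(float), index=ts)
    series = series[~series.index.duplicated(keep="first")].reindex(full)
    missing = series.isna().to_numpy()
    counts = series.fillna(0.0).to_numpy()

    # run-length of each missing stretch, broadcast onto its positions
    gap_run = np.zeros(len(counts), dtype=int)
    run = 0
    for i in range(len(counts)):
        run = run + 1 if missing[i] else 0
        gap_run[i] = run
    for i in range(len(counts) - 2, -1, -1):
        if missing[i] and missing[i + 1]:
            gap_run[i] = gap_run[i + 1]

    windows: list[ActivityWindow] = []
    drop_log: list[dict] = []
    for start in range(0, len(counts) - length + 1, length):
        sl = slice(start, start + length)
        if gap_run[sl].max(initial=0) > gap_tolerance:
            drop_log.append(
                {
                    "participant_id": recording.participant_id,
                    "start": str(full[start]),
                    "reason": "timestamp gap exceeds tolerance",
                }
            )
            continue
        windows.append(
            ActivityWindow(
                participant_id=recording.participant_id,
                start=full[start],
                counts=counts[sl],
            )
        )
    return windows, drop_log


def age_band_midpoint(age_band: str) -> float:
    """Ordinal encoding of an age band string, e.g. ``"45-49" -> 47.0``."""
    parts = age_band.replace("–", "-").split("-")
    try:
        lo, hi = (float(p) for p in parts)
    except (ValueError, TypeError):
        raise ValidationError(f"unparseable age band {age_band!r}") from None
    return (lo + hi) / 2.0
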