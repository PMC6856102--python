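"""Core data model for detector-array capture-recapture datasets.

The observation unit is a *detector-occasion*: each detector (a natural
bear rub fitted with barbed wire, or any passive hair-snag station) is
visited on a schedule of dates within a season ("session", one calendar
year here).  The first visit of a season clears old hair; every
subsequent visit closes a collection interval ("occasion").  An
encounter record says that a known individual left hair at a given
detector during a given occasion.  Multiple samples within one
detector-occasion collapse to a single binary detection.

Coordinates are planar kilometres in an arbitrary projected system;
longitude/latitude handling is deliberately out of scope (projection
happens upstream in GIS).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Land-ownership security scores: stronger protection of the land around
#: a detector gets a higher ordinal score.
SECURITY_CODING: dict[str, int] = {
    "NPS": 10,      # national park
    "USFS": 7,      # national forest
    "STATE": 3,     # state or other public land
    "PRIVATE": 1,   # private land
}

SEXES = ("F", "M")


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class DetectorArray:
    """Detector locations, site covariates and visit schedules.

    ``table`` has one row per (detector_id, session) with columns
    ``detector_id, session, x_km, y_km, cover_pct, curv_sd, security``
    (numeric ordinal score) and ``visit_dates`` (list of strictly
    increasing day-of-year integers; the first entry is the clearing
    visit, so a detector with ``v`` visits contributes ``v - 1``
    collection occasions).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def sessions(self) -> list[int]:
        return sorted(self.table["session"].unique().tolist())

    def for_session(self, session: int) -> pd.DataFrame:
        sub = self.table[self.table["session"] == session]
        if sub.empty:
            raise KeyError(f"no detectors in session {session}")
        return sub.reset_index(drop=True)

    def n_detectors(self, session: int) -> int:
        return int((self.table["session"] == session).sum())

    def coords(self, session: int | None = None) -> np.ndarray:
        sub = self.table if session is None else self.for_session(session)
        return sub[["x_km", "y_km"]].to_numpy(dtype=float)

    def occasion_count(self, detector_id: str, session: int) -> int:
        row = self.table[
            (self.table["detector_id"] == detector_id)
            & (self.table["session"] == session)
        ]
        if row.empty:
            raise KeyError(f"unknown detector {detector_id!r} in session {session}")
        return len(row.iloc[0]["visit_dates"]) - 1

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        required = {"detector_id", "session", "x_km", "y_km",
                    "cover_pct", "curv_sd", "security", "visit_dates"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"detector table missing columns {sorted(missing)}")
        if t.duplicated(["detector_id", "session"]).any():
            dup = t[t.duplicated(["detector_id", "session"])].iloc[0]
            raise ValidationError(
                f"duplicate detector row {dup['detector_id']!r} session {dup['session']}")
        xy = t[["x_km", "y_km"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite detector coordinates")
        cover = t["cover_pct"].to_numpy(dtype=float)
        if ((cover < 0) | (cover > 100)).any():
            raise ValidationError("cover_pct outside [0, 100]")
        if (t["curv_sd"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative curv_sd")
        for _, row in t.iterrows():
            dates = list(row["visit_dates"])
            if len(dates) < 1:
                raise ValidationError(
                    f"detector {row['detector_id']!r} session {row['session']}: "
                    "empty visit schedule")
            if any(b <= a for a, b in itertools.pairwise(dates)):
                raise ValidationError(
                    f"detector {row['detector_id']!r} session {row['session']}: "
                    f"visit dates not strictly increasing: {dates}")


@dataclass
class EncounterData:
    """Binary detections of identified individuals at detector-occasions.

    ``table`` columns: ``individual_id, sex, session, detector_id,
    occasion`` (1-based index into that detector's collection
    intervals).  One row per detection; duplicates collapse on read.
    """

    table: pd.DataFrame

    @property
    def sessions(self) -> list[int]:
        return sorted(self.table["session"].unique().tolist())

    @property
    def individuals(self) -> list[str]:
        return sorted(self.table["individual_id"].unique().tolist())

    def n_individuals(self, session: int | None = None, sex: str | None = None) -> int:
        t = self.table
        if session is not None:
            t = t[t["session"] == session]
        if sex is not None:
            t = t[t["sex"] == sex]
        return t["individual_id"].nunique()

    def for_sex(self, sex: str) -> "EncounterData":
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        return EncounterData(self.table[self.table["sex"] == sex].reset_index(drop=True))

    def validate(self, detectors: DetectorArray) -> None:
        t = self.table
        required = {"individual_id", "sex", "session", "detector_id", "occasion"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"encounter table missing columns {sorted(missing)}")
        bad_sex = set(t["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex codes {sorted(bad_sex)}")
        sex_per_ind = t.groupby("individual_id")["sex"].nunique()
        if (sex_per_ind > 1).any():
            bad = sex_per_ind[sex_per_ind > 1].index[0]
            raise ValidationError(f"individual {bad!r} has inconsistent sex")
        det_key = detectors.table.set_index(["detector_id", "session"])["visit_dates"]
        for _, row in t.iterrows():
            key = (row["detector_id"], row["session"])
            if key not in det_key.index:
                raise ValidationError(
                    f"encounter references unknown detector {key[0]!r} in session {key[1]}")
            n_occ = len(det_key.loc[key]) - 1
            if not (1 <= int(row["occasion"]) <= n_occ):
                raise ValidationError(
                    f"encounter at {key[0]!r} session {key[1]} has occasion "
                    f"{row['occasion']} but the schedule defines {n_occ} occasion(s)")
        if t.duplicated(["individual_id", "session", "detector_id", "occasion"]).any():
            raise ValidationError("duplicate detection rows present (collapse first)")


@dataclass
class EffortSummary:
    """Per-session sampling effort."""

    session: int
    n_detectors: int
    cumulative_rub_days: int


@dataclass
class OutlierReport:
    """An individual-session whose detections span an implausible distance."""

    individual_id: str
    session: int
    max_pairwise_distance: float
    #: (individual_id, sex, session, detector_id, occasion) of the record
    #: whose removal most reduces the maximum pairwise distance.
    flagged_detection: tuple = field(default=None)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_visit_dates(raw: str, line_no: int) -> list[int]:
    try:
        dates = [int(tok) for tok in str(raw).split(";") if tok != ""]
    except ValueError as exc:
        raise ValidationError(f"line {line_no}: malformed visit_dates {raw!r}") from exc
    return dates


def read_detectors(path: str | Path,
                   coding: Mapping[str, int] | None = None) -> DetectorArray:
    """Read a ``detectors.csv`` file.

    Columns: ``detector_id, session, x_km, y_km, cover_pct, curv_sd,
    security, visit_dates``; ``security`` may be a label from ``coding``
    (default :data:`SECURITY_CODING`) or already a numeric score, and
    ``visit_dates`` is a semicolon-separated day-of-year list.
    """
    coding = dict(SECURITY_CODING if coding is None else coding)
    valid_scores = set(coding.values())
    df = pd.read_csv(path, dtype={"detector_id": str, "security": str})
    rows = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        sec_raw = row["security"]
        if sec_raw in coding:
            sec = coding[sec_raw]
        else:
            try:
                sec = int(sec_raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"line {line_no}: unknown security label {sec_raw!r}; "
                    f"expected one of {sorted(coding)}")
            if sec not in valid_scores:
                raise ValidationError(
                    f"line {line_no}: security score {sec} not in coding table "
                    f"{sorted(valid_scores)}")
        try:
            rows.append({
                "detector_id": str(row["detector_id"]),
                "session": int(row["session"]),
                "x_km": float(row["x_km"]),
                "y_km": float(row["y_km"]),
                "cover_pct": float(row["cover_pct"]),
                "curv_sd": float(row["curv_sd"]),
                "security": sec,
                "visit_dates": _parse_visit_dates(row["visit_dates"], line_no),
            })
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"line {line_no}: malformed row ({exc})") from exc
    table = pd.DataFrame(
        rows, columns=["detector_id", "session", "x_km", "y_km",
                       "cover_pct", "curv_sd", "security", "visit_dates"])
    return DetectorArray(table)


def write_detectors(det: DetectorArray, path: str | Path) -> None:
    out = det.table.copy()
    out["visit_dates"] = out["visit_dates"].map(
        lambda d: ";".join(str(int(v)) for v in d))
    out.to_csv(path, index=False)


def read_encounters(path: str | Path, detectors: DetectorArray) -> EncounterData:
    """Read ``encounters.csv`` and validate it against the detector array.

    Duplicate (individual, session, detector, occasion) rows are
    collapsed to a single binary detection with a logged warning.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "detector_id": str,
                                  "sex": str})
    df["session"] = df["session"].astype(int)
    df["occasion"] = df["occasion"].astype(int)
    key = ["individual_id", "session", "detector_id", "occasion"]
    n_dup = int(df.duplicated(key).sum())
    if n_dup:
        logger.warning("collapsed %d duplicate detection row(s) in %s", n_dup, path)
        df = df.drop_duplicates(key)
    enc = EncounterData(df.reset_index(drop=True)[
        ["individual_id", "sex", "session", "detector_id", "occasion"]])
    enc.validate(detectors)
    return enc


def write_encounters(enc: EncounterData, path: str | Path) -> None:
    enc.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Effort
# ---------------------------------------------------------------------------

def compute_effort(detectors: DetectorArray) -> list[EffortSummary]:
    """Cumulative rub sampling days per session.

    Each detector contributes the total number of days spanned by its
    collection intervals (days accrue only after the clearing visit), so
    a detector visited on days ``[150, 210, 240]`` contributes
    ``60 + 30 = 90`` days.  A detector with a clearing visit only
    contributes 0.  Additive over detectors and sessions.
    """
    out = []
    for session in detectors.sessions:
        sub = detectors.for_session(session)
        days = 0
        for dates in sub["visit_dates"]:
            days += int(dates[-1] - dates[0])
        out.append(EffortSummary(session=session,
                                 n_detectors=len(sub),
                                 cumulative_rub_days=days))
    return out


def effort_table(detectors: DetectorArray) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in compute_effort(detectors)])


# ---------------------------------------------------------------------------
# Outlier movements
# ---------------------------------------------------------------------------

def _detection_locations(enc_rows: pd.DataFrame, det: DetectorArray) -> np.ndarray:
    coords = det.table.set_index(["detector_id", "session"])[["x_km", "y_km"]]
    pts = [coords.loc[(r["detector_id"], r["session"])].to_numpy(dtype=float)
           for _, r in enc_rows.iterrows()]
    return np.asarray(pts, dtype=float)


def max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def flag_outliers(enc: EncounterData, det: DetectorArray,
                  threshold_km: float = 100.0) -> list[OutlierReport]:
    """Flag individual-sessions whose detections span > ``threshold_km``.

    For each flagged individual-session the single detection whose
    removal most reduces the maximum pairwise distance is identified
    (ties broken by the first such record in the table).  Individuals
    with a single detection are never flagged.
    """
    if threshold_km <= 0:
        raise ValueError("threshold_km must be positive")
    reports: list[OutlierReport] = []
    for (ind, session), rows in enc.table.groupby(["individual_id", "session"],
                                                  sort=True):
        pts = _detection_locations(rows, det)
        dmax = max_pairwise_distance(pts)
        if dmax <= threshold_km or len(pts) < 2:
            continue
        best_idx, best_after = None, np.inf
        for drop in range(len(pts)):
            remaining = np.delete(pts, drop, axis=0)
            after = max_pairwise_distance(remaining)
            if after < best_after - 1e-12:
                best_after, best_idx = after, drop
        flagged = tuple(rows.iloc[best_idx][
            ["individual_id", "sex", "session", "detector_id", "occasion"]])
        reports.append(OutlierReport(individual_id=ind, session=session,
                                     max_pairwise_distance=dmax,
                                     flagged_detection=flagged))
    return reports


def remove_detections(enc: EncounterData,
                      flagged: Iterable[tuple]) -> EncounterData:
    """Return a copy of ``enc`` without the flagged detection records."""
    keys = {(f[0], f[2], f[3], f[4]) for f in flagged}
    t = enc.table
    mask = [
        (r["individual_id"], r["session"], r["detector_id"], r["occasion"]) not in keys
        for _, r in t.iterrows()
    ]
    return EncounterData(t[mask].reset_index(drop=True))
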