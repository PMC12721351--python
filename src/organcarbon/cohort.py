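"""Observation windows and cohort filters.

For each organ the observation period is centered on its acuity-circle
implementation date: the post period runs from the implementation month
through the end of study data, and the pre period extends the same number
of months back from the implementation month. Materialized as whole
calendar months, the implementation month sits at the exact center of the
window and is assigned to the post period (a transplant on or after the
implementation date is "post").

Cohort filters drop living-donor organs and records missing a transplant
center ID, then restrict to the window, tallying each exclusion reason.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import PolicyCalendar


@dataclass(frozen=True)
class TransplantRecord:
    """One organ movement from donor hospital to recipient center."""

    record_id: str
    organ: str
    transplant_date: dt.date
    donor_type: str = "deceased"  # "deceased" | "living"
    donor_zip: Optional[str] = None
    recipient_zip: Optional[str] = None
    recipient_city_state: Optional[str] = None
    center_id: Optional[str] = None
    region: Optional[str] = None


@dataclass(frozen=True)
class ObservationWindow:
    """Whole-calendar-month observation window for one organ.

    ``n_pre_months`` counts the months strictly before the implementation
    month; ``n_post_months`` counts the implementation month through the
    end month. The window is symmetric in the sense that the
    implementation month is the same number of months from both ends.
    """

    organ: str
    window_start: dt.date
    implementation_date: dt.date
    window_end: dt.date
    n_pre_months: int
    n_post_months: int

    @property
    def n_months(self) -> int:
        return self.n_pre_months + self.n_post_months

    @property
    def start_month(self) -> pd.Period:
        return pd.Period(self.window_start, freq="M")

    @property
    def implementation_month(self) -> pd.Period:
        return pd.Period(self.implementation_date, freq="M")

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.window_start, self.window_end, freq="M")

    def month_index(self, date) -> int:
        """1-based month index m within the window (m = 1 at window start)."""
        return (pd.Period(date, freq="M") - self.start_month).n + 1

    def is_post_month(self, month: pd.Period) -> bool:
        return month >= self.implementation_month

    def contains(self, date) -> bool:
        return self.window_start <= _as_date(date) <= self.window_end


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()


def build_window(organ: str, calendar: PolicyCalendar | None = None) -> ObservationWindow:
    """Construct the equidistant pre/post observation window for an organ.

    The post length is the number of whole calendar months elapsed from
    the implementation month to the end-of-data month; the window start
    is that many months before the implementation month. With the default
    policy calendar this yields windows starting Nov 2011 (lung),
    Sep 2013 (heart), May 2016 (liver) and Jul 2018 (kidney), all ending
    Nov 2023.
    """
    calendar = calendar or PolicyCalendar()
    impl = calendar.implementation_date(organ)
    end = calendar.study_end
    impl_month = pd.Period(impl, freq="M")
    end_month = pd.Period(end, freq="M")
    d = (end_month - impl_month).n
    if d < 1:
        raise ValueError(f"{organ}: no post months between {impl} and {end}")
    start_month = impl_month - d
    return ObservationWindow(
        organ=organ,
        window_start=start_month.start_time.date(),
        implementation_date=impl,
        window_end=end,
        n_pre_months=d,
        n_post_months=d + 1,
    )


@dataclass
class ExclusionTally:
    """Counts of records removed per exclusion reason (first match wins)."""

    living: int = 0
    missing_center_id: int = 0
    out_of_window: int = 0

    def total(self) -> int:
        return self.living + self.missing_center_id + self.out_of_window

    def as_dict(self) -> dict[str, int]:
        return {
            "living": self.living,
            "missing_center_id": self.missing_center_id,
            "out_of_window": self.out_of_window,
        }


def filter_cohort(
    records: Iterable[TransplantRecord], window: ObservationWindow
) -> tuple[list[TransplantRecord], ExclusionTally]:
    """Apply the cohort exclusions for one organ window.

    Keeps deceased-donor records with a non-missing center ID dated
    within [window_start, window_end]. Exclusion reasons are checked in
    the order living donor, missing center ID, out of window; the tally
    records the first matching reason so kept + tallied == input count.
    """
    kept: list[TransplantRecord] = []
    tally = ExclusionTally()
    for rec in records:
        if rec.donor_type == "living":
            tally.living += 1
        elif rec.center_id is None or (isinstance(rec.center_id, str) and not rec.center_id):
            tally.missing_center_id += 1
        elif not window.contains(rec.transplant_date):
            tally.out_of_window += 1
        else:
            kept.append(rec)
    return kept, tally


def records_to_frame(records: Iterable[TransplantRecord]) -> pd.DataFrame:
    cols = [
        "record_id",
        "organ",
        "transplant_date",
        "donor_type",
        "donor_zip",
        "recipient_zip",
        "recipient_city_state",
        "center_id",
        "region",
    ]
    return pd.DataFrame(
        [
            (
                r.record_id,
                r.organ,
                r.transplant_date.isoformat(),
                r.donor_type,
                r.donor_zip,
                r.recipient_zip,
                r.recipient_city_state,
                r.center_id,
                r.region,
            )
            for r in records
        ],
        columns=cols,
    )


def records_from_frame(frame: pd.DataFrame) -> list[TransplantRecord]:
    def _opt(v):
        return None if pd.isna(v) else str(v)

    return [
        TransplantRecord(
            record_id=str(row.record_id),
            organ=str(row.organ),
            transplant_date=dt.date.fromisoformat(str(row.transplant_date)),
            donor_type=str(row.donor_type),
            donor_zip=_opt(row.donor_zip),
            recipient_zip=_opt(row.recipient_zip),
            recipient_city_state=_opt(row.recipient_city_state),
            center_id=_opt(row.center_id),
            region=_opt(row.region),
        )
        for row in frame.itertuples(index=False)
    ]


def records_from_csv(path) -> list[TransplantRecord]:
    frame = pd.read_csv(
        path, dtype={"donor_zip": str, "recipient_zip": str, "center_id": str}
    )
    return records_from_frame(frame)
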