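"""Deterministic age arithmetic anchored on week of birth.

Birth dates arrive at week granularity (anonymisation); every age in the
pipeline is computed from the Monday of the recorded week so that ages are
reproducible.  "Completed months" uses calendar-month arithmetic with
day-of-month clamping (someone anchored on the 31st completes a month on the
last day of a short month), and completed years are completed months // 12.
"""

from __future__ import annotations

import calendar
import datetime as dt


def monday_anchor(week_of_birth: dt.date) -> dt.date:
    """Monday of the week containing the recorded week-of-birth date."""
    return week_of_birth - dt.timedelta(days=week_of_birth.weekday())


def add_months(anchor: dt.date, months: int) -> dt.date:
    """Calendar-month addition with day clamped to the target month's length."""
    y, m = divmod(anchor.month - 1 + months, 12)
    year, month = anchor.year + y, m + 1
    day = min(anchor.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def completed_months(anchor: dt.date, date: dt.date) -> int:
    """Whole calendar months elapsed from *anchor* to *date* (clamped).

    Raises ``ValueError`` if *date* precedes the anchor.
    """
    if date < anchor:
        raise ValueError(f"date {date} precedes birth anchor {anchor}")
    m = (date.year - anchor.year) * 12 + (date.month - anchor.month)
    anniversary_day = min(anchor.day, calendar.monthrange(date.year, date.month)[1])
    if date.day < anniversary_day:
        m -= 1
    return m


def completed_years(anchor: dt.date, date: dt.date) -> int:
    return completed_months(anchor, date) // 12
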