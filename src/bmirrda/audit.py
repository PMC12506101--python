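"""Record-level audit log.

Every record the pipeline drops or rewrites is accounted for here with the
stage and reason, so that the accounting identity (kept + removed = input)
can be checked on every run and exported alongside the RRDA.
"""

from __future__ import annotations

import pandas as pd

AUDIT_COLUMNS = ["stage", "reason", "person_id", "date", "source", "record_id", "count"]


class AuditLog:
    def __init__(self) -> None:
        self._rows: list[dict] = []

    def add(self, stage: str, reason: str, person_id="", date=None, source="", record_id="", count=1) -> None:
        self._rows.append(
            {
                "stage": stage,
                "reason": reason,
                "person_id": person_id,
                "date": date,
                "source": source,
                "record_id": record_id,
                "count": count,
            }
        )

    def add_frame(self, stage: str, reason: str, frame: pd.DataFrame, date_col: str = "date") -> None:
        """Log one row per record of *frame* (which carries person/source ids)."""
        for row in frame.itertuples():
            self.add(
                stage,
                reason,
                person_id=getattr(row, "person_id", ""),
                date=getattr(row, date_col, None),
                source=getattr(row, "source", ""),
                record_id=getattr(row, "record_id", ""),
            )

    def count(self, stage: str | None = None, reason: str | None = None) -> int:
        total = 0
        for r in self._rows:
            if stage is not None and r["stage"] != stage:
                continue
            if reason is not None and r["reason"] != reason:
                continue
            total += r["count"]
        return total

    def record_ids(self, stage: str | None = None, reason: str | None = None) -> list[str]:
        return [
            r["record_id"]
            for r in self._rows
            if r["record_id"]
            and (stage is None or r["stage"] == stage)
            and (reason is None or r["reason"] == reason)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=AUDIT_COLUMNS)

    def write(self, path) -> None:
        df = self.to_frame().copy()
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d").fillna("")
        df.to_csv(path, index=False)
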