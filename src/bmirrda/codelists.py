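"""Clinical code lists mapping Read v2 / ICD-10 codes to BMI components.

Code lists are user-supplied data, not a contract of this package: every
deployment curates its own.  :func:`default_codelists` ships a small
illustrative (synthetic, non-authoritative) list so that the pipeline and the
synthetic-data generator are runnable out of the box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pandas as pd

from .config import CATEGORIES

CODE_SYSTEMS = ("ReadV2", "ICD10")
COMPONENTS = ("bmi_value", "height", "weight", "bmi_category", "obesity_dx")


class CodeListError(ValueError):
    pass


@dataclass(frozen=True)
class CodeList:
    """A single coded concept and the BMI component it captures."""

    code: str
    code_system: str
    component: str
    category_map: Optional[str] = None

    def __post_init__(self):
        if self.code_system not in CODE_SYSTEMS:
            raise CodeListError(f"unknown code system {self.code_system!r} for {self.code!r}")
        if self.component not in COMPONENTS:
            raise CodeListError(f"unknown component {self.component!r} for {self.code!r}")
        if self.component == "obesity_dx" and self.code_system != "ICD10":
            raise CodeListError(f"obesity_dx requires ICD10, got {self.code_system} ({self.code!r})")
        needs_map = self.component in ("bmi_category", "obesity_dx")
        if needs_map and self.category_map not in CATEGORIES:
            raise CodeListError(
                f"{self.component} code {self.code!r} requires a category_map in {CATEGORIES}"
            )
        if not needs_map and self.category_map is not None:
            raise CodeListError(f"category_map not allowed for component {self.component!r}")


class CodeListCollection:
    """Indexed collection of :class:`CodeList` entries, unique on (code, system)."""

    def __init__(self, entries: Iterable[CodeList]):
        self._by_key: dict[tuple[str, str], CodeList] = {}
        for e in entries:
            key = (e.code, e.code_system)
            if key in self._by_key:
                raise CodeListError(f"duplicate code list entry {key}")
            self._by_key[key] = e

    def lookup(self, code: str, code_system: str) -> Optional[CodeList]:
        return self._by_key.get((code, code_system))

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[CodeList]:
        return iter(self._by_key.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "code": e.code,
                    "code_system": e.code_system,
                    "component": e.component,
                    "category_map": e.category_map if e.category_map is not None else "",
                }
                for e in self
            ],
            columns=["code", "code_system", "component", "category_map"],
        )


def load_codelists(path) -> CodeListCollection:
    """Read a delimited code-list file with columns
    ``code, code_system, component, category_map`` (empty map = none)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"code", "code_system", "component", "category_map"}
    missing = required - set(df.columns)
    if missing:
        raise CodeListError(f"code list file missing columns: {sorted(missing)}")
    entries = [
        CodeList(
            code=row.code,
            code_system=row.code_system,
            component=row.component,
            category_map=row.category_map or None,
        )
        for row in df.itertuples()
    ]
    return CodeListCollection(entries)


def write_codelists(codelists: CodeListCollection, path) -> None:
    codelists.to_frame().to_csv(path, index=False)


def default_codelists() -> CodeListCollection:
    """Illustrative code list (synthetic, NON-authoritative).

    The Read v2 stems follow the familiar shape of primary-care BMI coding
    (a BMI-value stem, height and weight stems, and category codes) and the
    ICD-10 obesity block E66, but the exact list used by any real extraction
    is governance-controlled data the user must supply.
    """
    return CodeListCollection(
        [
            CodeList("22K..", "ReadV2", "bmi_value"),
            CodeList("229..", "ReadV2", "height"),
            CodeList("22A..", "ReadV2", "weight"),
            CodeList("22K3.", "ReadV2", "bmi_category", "underweight"),
            CodeList("22K2.", "ReadV2", "bmi_category", "normal"),
            CodeList("22K5.", "ReadV2", "bmi_category", "overweight"),
            CodeList("22K7.", "ReadV2", "bmi_category", "obese"),
            CodeList("E66", "ICD10", "obesity_dx", "obese"),
            CodeList("E66.0", "ICD10", "obesity_dx", "obese"),
            CodeList("E66.9", "ICD10", "obesity_dx", "obese"),
        ]
    )
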