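"""Patient-by-variable cohort container and plain-text round-trip I/O.

A cohort is a rectangular table: one row per medical record, one column per
variable.  Variables carry two pieces of metadata, a *kind* (``dichotomous``,
``discrete`` or ``continuous``) and a *role* (``diagnosis``, ``medication``,
``demographic`` or ``outcome``).  Missing entries are represented as NaN in
memory and as empty cells on disk; the metadata travels in a JSON companion
file next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KINDS = ("dichotomous", "discrete", "continuous")
ROLES = ("diagnosis", "medication", "demographic", "outcome")


@dataclass(frozen=True)
class VariableMeta:
    """Kind/role metadata for one cohort variable."""

    kind: str
    role: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}; expected one of {KINDS}")
        if self.role not in ROLES:
            raise ValueError(f"unknown variable role {self.role!r}; expected one of {ROLES}")


@dataclass
class CohortTable:
    """A patient-by-variable matrix plus per-variable metadata.

    Parameters
    ----------
    data
        One row per record.  Dichotomous columns hold 0/1 (NaN when missing).
    meta
        Mapping of every column name to its :class:`VariableMeta`.
    """

    data: pd.DataFrame
    meta: dict[str, VariableMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.meta)
        extra = set(self.meta) - set(self.data.columns)
        if missing:
            raise ValueError(f"columns without metadata: {sorted(missing)}")
        if extra:
            raise ValueError(f"metadata for absent columns: {sorted(extra)}")
        for name, m in self.meta.items():
            if m.kind == "dichotomous":
                col = self.data[name]
                bad = col.dropna()[~col.dropna().isin((0, 1))]
                if len(bad):
                    raise ValueError(
                        f"dichotomous column {name!r} contains non-binary value {bad.iloc[0]!r}"
                    )

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def outcome_column(self) -> str:
        names = [n for n, m in self.meta.items() if m.role == "outcome"]
        if len(names) != 1:
            raise ValueError(f"expected exactly one outcome column, found {names}")
        return names[0]

    def columns_by_role(self, role: str) -> list[str]:
        return [n for n in self.data.columns if self.meta[n].role == role]

    def columns_by_kind(self, kind: str) -> list[str]:
        return [n for n in self.data.columns if self.meta[n].kind == kind]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing cells (True = missing)."""
        return self.data.isna()

    def equals(self, other: "CohortTable") -> bool:
        if self.meta != other.meta:
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        a = self.data.to_numpy(dtype=float)
        b = other.data.to_numpy(dtype=float)
        if a.shape != b.shape:
            return False
        return bool(np.array_equal(a, b, equal_nan=True))


class CohortParseError(ValueError):
    """Raised when a cohort file on disk violates the format contract."""


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort as CSV plus a ``<name>.meta.json`` companion.

    Floats are written with full round-trip precision so that
    ``read_cohort(write_cohort(t)) == t`` bit-exactly.
    """
    path = Path(path)
    table.data.to_csv(path, index=False, float_format="%.17g")
    meta = {name: {"kind": m.kind, "role": m.role} for name, m in table.meta.items()}
    _meta_path(path).write_text(json.dumps({"variables": meta}, indent=1) + "\n")


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort written by :func:`write_cohort`.

    Raises
    ------
    CohortParseError
        On an empty file, a missing companion metadata file, or a
        non-binary value in a dichotomous column (with its line number).
    """
    path = Path(path)
    if not path.exists():
        raise CohortParseError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise CohortParseError(f"{path}: empty file (line 1)")
    mpath = _meta_path(path)
    if not mpath.exists():
        raise CohortParseError(f"{mpath}: companion metadata file missing")
    raw_meta = json.loads(mpath.read_text())["variables"]
    meta = {name: VariableMeta(**mm) for name, mm in raw_meta.items()}

    try:
        data = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise CohortParseError(f"{path}: {exc}") from exc
    if data.shape[1] == 0 or len(data) == 0:
        raise CohortParseError(f"{path}: no data rows (line 2)")

    for name, m in meta.items():
        if name not in data.columns:
            raise CohortParseError(f"{path}: column {name!r} in metadata but not in header (line 1)")
        if m.kind == "dichotomous":
            col = data[name]
            bad = col.dropna()[~col.dropna().isin((0.0, 1.0))]
            if len(bad):
                # +2: header line plus 1-based data row
                line = int(bad.index[0]) + 2
                raise CohortParseError(
                    f"{path}: non-binary value {bad.iloc[0]!r} in dichotomous "
                    f"column {name!r} (line {line})"
                )
    return CohortTable(data=data, meta=meta)
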