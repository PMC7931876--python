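"""Cohort curation: exclusions, dichotomization, BMI categories, missingness.

Turns a raw cohort into the analysis-ready matrix used by the selection and
network stages.  The stage drops, in a fixed order: records carrying an
excluded outcome label (e.g. a type-1-diabetes flag), records at or below the
minimum age, explicitly excluded variables, variables exceeding the maximum
missing fraction, and finally any remaining record with a missing value in a
retained column (complete-case).  Every drop is written to a ledger with its
reason, so that record/variable counts are conserved by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableMeta

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
DEFAULT_BMI_BREAKS = (18.5, 25.0, 30.0)


@dataclass(frozen=True)
class CurationConfig:
    exclude_variables: tuple[str, ...] = ()
    max_missing_fraction: float = 0.5
    min_age: float = 18.0
    exclude_outcome_labels: tuple = ()
    bmi_breaks: tuple[float, float, float] = DEFAULT_BMI_BREAKS
    dichotomize_rules: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError(
                f"max_missing_fraction must be in [0,1], got {self.max_missing_fraction}"
            )
        if list(self.bmi_breaks) != sorted(self.bmi_breaks) or len(set(self.bmi_breaks)) != len(
            self.bmi_breaks
        ):
            raise ValueError(f"bmi_breaks must be strictly increasing, got {self.bmi_breaks}")


@dataclass
class CuratedMatrix:
    """Analysis matrix: binary features (plus discrete demographics), outcome,
    and the drop ledger."""

    features: pd.DataFrame
    outcome: pd.Series
    meta: dict[str, VariableMeta]
    ledger: pd.DataFrame  # columns: kind ('record'|'variable'), id, reason

    @property
    def n_records(self) -> int:
        return len(self.features)

    @property
    def n_variables(self) -> int:
        return self.features.shape[1]

    def dichotomous_columns(self) -> list[str]:
        return [c for c in self.features.columns if self.meta[c].kind == "dichotomous"]

    def to_cohort(self) -> CohortTable:
        """Re-wrap as a CohortTable (features + outcome), e.g. to re-curate."""
        outcome_name = next(n for n, m in self.meta.items() if m.role == "outcome")
        data = self.features.copy()
        data[outcome_name] = self.outcome
        return CohortTable(data=data, meta=dict(self.meta))


def categorize_bmi(bmi: float, breaks=DEFAULT_BMI_BREAKS) -> str | None:
    """Weight category for one BMI value.

    Half-open intervals [low, high): underweight [0, b0), normal [b0, b1),
    overweight [b1, b2), obese [b2, inf).  Non-positive or missing BMI
    returns None (record flagged upstream).
    """
    if bmi is None or not np.isfinite(bmi) or bmi <= 0:
        return None
    idx = int(np.searchsorted(np.asarray(breaks), bmi, side="right"))
    return BMI_CATEGORIES[idx]


def bmi_indicators(bmi: pd.Series, breaks=DEFAULT_BMI_BREAKS) -> pd.DataFrame:
    """Four 0/1 indicator columns (``bmi_<category>``) from a BMI column.

    Rows with non-positive or missing BMI get all-missing indicators.
    """
    vals = bmi.to_numpy(dtype=float)
    ok = np.isfinite(vals) & (vals > 0)
    idx = np.searchsorted(np.asarray(breaks), vals, side="right")
    out = {}
    for k, cat in enumerate(BMI_CATEGORIES):
        col = np.where(ok, (idx == k).astype(float), np.nan)
        out[f"bmi_{cat}"] = col
    return pd.DataFrame(out, index=bmi.index)


def dichotomize(column: pd.Series, positive_levels: frozenset | set) -> pd.Series:
    """Map a discrete column to 0/1: 1 iff the value is in ``positive_levels``.

    Missing values stay missing.  Raises if the positive set names a level
    never observed in the column.
    """
    observed = set(column.dropna().unique())
    unknown = set(positive_levels) - observed
    if unknown:
        raise ValueError(f"positive levels {sorted(map(repr, unknown))} not observed in column")
    out = column.map(lambda v: float(v in positive_levels), na_action="ignore")
    return out.astype(float)


def apply_curation(table: CohortTable, config: CurationConfig) -> CuratedMatrix:
    """Apply the full curation sequence; deterministic; ledger-conserving."""
    outcome_name = table.outcome_column  # raises if absent
    data = table.data.copy()
    meta = dict(table.meta)
    ledger_rows: list[tuple[str, str, str]] = []

    # 1. records with excluded outcome labels
    if config.exclude_outcome_labels:
        bad = data[outcome_name].isin(config.exclude_outcome_labels)
        for rid in data.index[bad]:
            ledger_rows.append(("record", str(rid), "excluded outcome label"))
        data = data.loc[~bad]

    # 2. age filter (records with age <= min_age dropped)
    if "age" in data.columns:
        too_young = data["age"].notna() & (data["age"] <= config.min_age)
        for rid in data.index[too_young]:
            ledger_rows.append(("record", str(rid), "age at or below minimum"))
        data = data.loc[~too_young]

    # 3. explicit variable exclusions
    for name in config.exclude_variables:
        if name in data.columns:
            ledger_rows.append(("variable", name, "explicit exclusion"))
            data = data.drop(columns=[name])
            meta.pop(name)

    # 4. dichotomization of discrete variables with a rule
    for name, levels in config.dichotomize_rules.items():
        if name in data.columns and name != outcome_name:
            data[name] = dichotomize(data[name], levels)
            meta[name] = VariableMeta("dichotomous", meta[name].role)

    # 5. BMI -> four weight-category indicators
    if "bmi" in data.columns and meta["bmi"].kind == "continuous":
        ind = bmi_indicators(data["bmi"], config.bmi_breaks)
        pos = data.columns.get_loc("bmi")
        data = data.drop(columns=["bmi"])
        for j, c in enumerate(ind.columns):
            data.insert(pos + j, c, ind[c])
            meta[c] = VariableMeta("dichotomous", "demographic")
        meta.pop("bmi")

    # 6. variables too missing
    if len(data):
        frac = data.drop(columns=[outcome_name]).isna().mean()
        for name, f in frac.items():
            if f > config.max_missing_fraction:
                ledger_rows.append(("variable", str(name), "missingness"))
                data = data.drop(columns=[name])
                meta.pop(str(name))

    # 7. complete-case: drop records with residual missing cells
    any_missing = data.isna().any(axis=1)
    for rid in data.index[any_missing]:
        ledger_rows.append(("record", str(rid), "missing value"))
    data = data.loc[~any_missing]

    # contract: retained dichotomous columns are strictly 0/1
    for name in data.columns:
        if name == outcome_name:
            continue
        if meta[name].kind == "dichotomous":
            vals = data[name].to_numpy()
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError(f"column {name!r} is declared dichotomous but is not 0/1")

    outcome = data[outcome_name].astype(float)
    if len(data) and not outcome.isin((0.0, 1.0)).all():
        raise ValueError(
            f"outcome column {outcome_name!r} is not binary after label exclusions; "
            "provide a dichotomize rule"
        )
    features = data.drop(columns=[outcome_name])
    feat_meta = {k: v for k, v in meta.items() if k != outcome_name}
    feat_meta[outcome_name] = meta[outcome_name]

    ledger = pd.DataFrame(ledger_rows, columns=["kind", "id", "reason"])
    if not len(data):
        warnings.warn("curation removed every record", stacklevel=2)
    return CuratedMatrix(features=features, outcome=outcome, meta=feat_meta, ledger=ledger)
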