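"""Synthetic EHR-like cohort generator with planted ground truth.

The generator emulates the statistical shape of an administrative diabetes
cohort: mostly dichotomous diagnosis/medication indicators, demographic
columns (integer age, binary sex, continuous BMI), a binary outcome drawn
from a logistic model, block-correlated comorbidity groups, deliberately
redundant duplicate columns, and completely-at-random missingness.

Within-block association is induced by a shared latent Bernoulli factor per
block: each feature copies the latent factor with probability ``rho`` and is
redrawn independently at the block's baseline prevalence otherwise.  ``rho``
is solved numerically so that each within-block feature pair attains (in
expectation) the requested pairwise odds ratio, while every feature keeps the
block's marginal prevalence.  ``rho=0`` gives independence (OR 1); ``rho→1``
gives perfectly coupled features (OR → ∞).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import CohortTable, VariableMeta

# Demographic defaults: adult cohort 18-76 years, 43% male, BMI lognormal
# with median 27 so that all four weight categories are populated.
AGE_RANGE = (18, 76)
MALE_FRACTION = 0.43
BMI_LOG_MEDIAN = np.log(27.0)
BMI_LOG_SIGMA = 0.20
REDUNDANT_FLIP_RATE = 0.02
NOISE_PREVALENCE_RANGE = (0.05, 0.40)


@dataclass(frozen=True)
class BlockSpec:
    """One correlated feature block (comorbidity / risk-factor group)."""

    name: str
    n_features: int
    within_block_association: float  # target pairwise odds ratio, >= 1
    baseline_prevalence: float

    def feature_names(self) -> list[str]:
        return [f"{self.name}_{i + 1}" for i in range(self.n_features)]


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_patients: int
    blocks: tuple[BlockSpec, ...] = ()
    n_noise_features: int = 0
    outcome_coefficients: dict[str, float] = field(default_factory=dict)
    outcome_intercept: float = 0.0
    n_redundant: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        names: list[str] = []
        for b in self.blocks:
            if not 0 < b.baseline_prevalence < 1:
                raise ValueError(
                    f"baseline_prevalence of block {b.name!r} must be in (0,1), "
                    f"got {b.baseline_prevalence}"
                )
            if b.within_block_association < 1:
                raise ValueError(
                    f"within_block_association of block {b.name!r} must be >= 1, "
                    f"got {b.within_block_association}"
                )
            if b.n_features < 1:
                raise ValueError(f"block {b.name!r} must have n_features >= 1")
            names.extend(b.feature_names())
        if len(names) != len(set(names)):
            raise ValueError("block feature names are not unique")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be >= 0")
        if self.n_redundant < 0:
            raise ValueError("n_redundant must be >= 0")
        all_names = set(names) | {f"noise_{i + 1}" for i in range(self.n_noise_features)}
        all_names |= {"age", "sex", "bmi"}
        for key in self.outcome_coefficients:
            if key not in all_names:
                raise ValueError(f"outcome_coefficients names unknown feature {key!r}")

    def feature_names(self) -> list[str]:
        """Block + noise feature names in generation order (no redundant/demo)."""
        names: list[str] = []
        for b in self.blocks:
            names.extend(b.feature_names())
        names.extend(f"noise_{i + 1}" for i in range(self.n_noise_features))
        return names


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated cohort, for recovery tests."""

    predictive_set: frozenset[str]
    block_membership: dict[str, str]
    redundant_sources: dict[str, str]
    generating_params: CohortSpec


def _solve_block_rho(odds_ratio: float, prevalence: float) -> float:
    """Mixing weight rho achieving the target within-block pairwise OR.

    With latent z ~ Bern(prev) and feature x = z w.p. rho else Bern(prev):
    P(x=1|z=1) = rho + (1-rho)*prev, P(x=1|z=0) = (1-rho)*prev, so the
    marginal prevalence is exactly ``prev`` for every rho.  The pairwise OR
    between two features of the block is monotone increasing in rho.
    """
    if odds_ratio == 1.0:
        return 0.0

    def log_or(rho: float) -> float:
        q = prevalence
        p1 = rho + (1 - rho) * q
        p0 = (1 - rho) * q
        p11 = q * p1 * p1 + (1 - q) * p0 * p0
        p10 = prevalence - p11
        p00 = 1 - 2 * prevalence + p11
        return np.log(p11) + np.log(p00) - 2 * np.log(p10)

    target = np.log(odds_ratio)
    hi = 1.0 - 1e-9
    if log_or(hi) < target:  # pragma: no cover - astronomically large ORs only
        return hi
    return float(brentq(lambda r: log_or(r) - target, 0.0, hi, xtol=1e-12))


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort from ``spec``; bit-exact for identical spec+seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, VariableMeta] = {}
    block_membership: dict[str, str] = {}

    for b in spec.blocks:
        rho = _solve_block_rho(b.within_block_association, b.baseline_prevalence)
        z = rng.random(n) < b.baseline_prevalence
        for name in b.feature_names():
            copy = rng.random(n) < rho
            fresh = rng.random(n) < b.baseline_prevalence
            x = np.where(copy, z, fresh)
            cols[name] = x.astype(float)
            meta[name] = VariableMeta("dichotomous", "diagnosis")
            block_membership[name] = b.name

    for i in range(spec.n_noise_features):
        prev = rng.uniform(*NOISE_PREVALENCE_RANGE)
        name = f"noise_{i + 1}"
        cols[name] = (rng.random(n) < prev).astype(float)
        meta[name] = VariableMeta("dichotomous", "medication")

    redundant_sources: dict[str, str] = {}
    base_names = list(cols)
    if spec.n_redundant and not base_names:
        raise ValueError("n_redundant > 0 requires at least one block or noise feature")
    for i in range(spec.n_redundant):
        src = base_names[int(rng.integers(len(base_names)))]
        name = f"dup{i + 1}_{src}"
        flips = rng.random(n) < REDUNDANT_FLIP_RATE
        cols[name] = np.where(flips, 1.0 - cols[src], cols[src])
        meta[name] = VariableMeta("dichotomous", meta[src].role)
        redundant_sources[name] = src

    cols["age"] = rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=n).astype(float)
    meta["age"] = VariableMeta("discrete", "demographic")
    cols["sex"] = (rng.random(n) < MALE_FRACTION).astype(float)  # 1 = male
    meta["sex"] = VariableMeta("dichotomous", "demographic")
    cols["bmi"] = np.exp(rng.normal(BMI_LOG_MEDIAN, BMI_LOG_SIGMA, size=n))
    meta["bmi"] = VariableMeta("continuous", "demographic")

    logit = np.full(n, spec.outcome_intercept, dtype=float)
    for name, beta in spec.outcome_coefficients.items():
        logit += beta * cols[name]
    p = 1.0 / (1.0 + np.exp(-logit))
    cols["outcome"] = (rng.random(n) < p).astype(float)
    meta["outcome"] = VariableMeta("dichotomous", "outcome")

    data = pd.DataFrame(cols)
    if spec.missing_rate > 0:
        feature_cols = [c for c in data.columns if c != "outcome"]
        mask = rng.random((n, len(feature_cols))) < spec.missing_rate
        vals = data[feature_cols].to_numpy()
        vals[mask] = np.nan
        data[feature_cols] = vals

    truth = GroundTruth(
        predictive_set=frozenset(k for k, v in spec.outcome_coefficients.items() if v != 0.0),
        block_membership=block_membership,
        redundant_sources=redundant_sources,
        generating_params=replace(spec),
    )
    return CohortTable(data=data, meta=meta), truth
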