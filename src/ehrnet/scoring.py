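"""Node scoring: Wald z-scores from a joint logistic regression.

The selected variables are fitted jointly against the outcome in one
multivariable logistic regression (Newton/IRLS).  Each variable's score is
z = beta / SE(beta) with a two-sided normal p-value; network node sizes
downstream are proportional to |z|.  Variables causing perfect separation
are flagged and reported without a score rather than silently regularized;
constant columns are dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

# A coefficient this large on a binary predictor (odds ratio > e^15) is a
# numerical-divergence signature, not a plausible effect.
SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class NodeScore:
    variable: str
    coefficient: float | None
    standard_error: float | None
    z: float | None
    p_value: float | None
    significant: bool
    note: str = ""

    @property
    def available(self) -> bool:
        return self.z is not None


def _separating_variables(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Binary columns that perfectly predict the outcome in a 2x2 sense."""
    out = []
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        levels = np.unique(x)
        if len(levels) != 2:
            continue
        sep = all(len(np.unique(y[x == v])) == 1 for v in levels)
        if sep and len(np.unique(y)) == 2:
            out.append(name)
    return out


def logistic_zscores(
    features: pd.DataFrame,
    outcome,
    selected,
    alpha: float = 0.05,
    max_iter: int = 100,
    gtol: float = 1e-8,
) -> list[NodeScore]:
    """Joint logistic fit over ``selected`` variables; one NodeScore each.

    Variables flagged for perfect separation (or a diverging coefficient)
    get ``z=None`` and are excluded from the fit of the remaining ones.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected set is empty")
    X = features[selected].astype(float).copy()
    y = np.asarray(outcome, dtype=float)

    dropped_constant = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped_constant:
        warnings.warn(f"dropping constant columns: {dropped_constant}", stacklevel=2)
        X = X.drop(columns=dropped_constant)

    flagged = _separating_variables(X, y)
    if flagged:
        warnings.warn(
            f"perfect separation detected for {flagged}; scores unavailable", stacklevel=2
        )
    fit_cols = [c for c in X.columns if c not in flagged]

    params: dict[str, tuple[float, float]] = {}
    diverged: list[str] = []
    if fit_cols:
        design = sm.add_constant(X[fit_cols], has_constant="add")
        model = sm.Logit(y, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(method="newton", maxiter=max_iter, tol=gtol, disp=0)
            except Exception:  # singular Hessian / separation mid-iteration
                res = None
        if res is not None:
            bse = np.asarray(res.bse, dtype=float)
            beta = np.asarray(res.params, dtype=float)
            for i, name in enumerate(design.columns):
                if name == "const":
                    continue
                if not np.isfinite(bse[i]) or abs(beta[i]) > SEPARATION_COEF:
                    diverged.append(name)
                else:
                    params[name] = (float(beta[i]), float(bse[i]))
        else:
            diverged = list(fit_cols)
    if diverged:
        warnings.warn(
            f"diverging coefficients for {diverged}; scores unavailable", stacklevel=2
        )

    scores: list[NodeScore] = []
    for name in selected:
        if name in params:
            beta, se = params[name]
            z = beta / se
            p = float(2.0 * norm.sf(abs(z)))
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            scores.append(NodeScore(name, beta, se, float(z), p, significant=p < alpha))
        elif name in dropped_constant:
            scores.append(NodeScore(name, None, None, None, None, False, note="constant"))
        else:
            scores.append(NodeScore(name, None, None, None, None, False, note="separation"))
    return scores


def filter_significant(scores: list[NodeScore], alpha: float = 0.05) -> list[NodeScore]:
    """Keep scored variables with two-sided p < alpha."""
    return [s for s in scores if s.available and s.p_value < alpha]


def scores_to_frame(scores: list[NodeScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [s.variable for s in scores],
            "beta": [s.coefficient for s in scores],
            "se": [s.standard_error for s in scores],
            "z": [s.z for s in scores],
            "p": [s.p_value for s in scores],
            "significant": [s.significant for s in scores],
            "note": [s.note for s in scores],
        }
    )
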