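"""Mutual-information networks over the case subpopulation.

Nodes are significant variables (sized by |z| from the logistic step); an
edge between two binary variables carries their plug-in mutual information,
a Monte-Carlo permutation p-value, a multiplicity-adjusted p-value, and the
number of patients positive for both variables.  Following the source
analysis, the network is built on the outcome-positive (case) records only,
and edges are retained when the adjusted p-value is below alpha AND the
shared-patient count reaches ``min_patients``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .scoring import NodeScore

LN2 = np.log(2.0)


def _counts_2x2(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    n = x.size
    n11 = int(np.sum((x == 1) & (y == 1)))
    nx1 = int(np.sum(x == 1))
    ny1 = int(np.sum(y == 1))
    return n11, nx1, ny1, n


def mi_from_counts(n11, nx1, ny1, n, base: str = "nats"):
    """Plug-in MI of a 2x2 table given the joint 1-1 count and margins.

    Vectorized over ``n11`` (and the margins).  Zero joint cells contribute
    zero; the result is clipped at 0 against -1e-12 rounding.
    """
    n11, nx1, ny1 = np.broadcast_arrays(
        np.asarray(n11, dtype=float),
        np.asarray(nx1, dtype=float),
        np.asarray(ny1, dtype=float),
    )
    n = float(n)
    cells = np.stack(
        [n11, nx1 - n11, ny1 - n11, n - nx1 - ny1 + n11]
    )  # (1,1), (1,0), (0,1), (0,0)
    px = np.stack([nx1, nx1, n - nx1, n - nx1]) / n
    py = np.stack([ny1, n - ny1, ny1, n - ny1]) / n
    pj = cells / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * (np.log(pj) - np.log(px) - np.log(py))
    terms = np.where(pj > 0, terms, 0.0)
    mi = terms.sum(axis=0)
    mi = np.where(mi < 0, np.where(mi > -1e-12, 0.0, mi), mi)
    if base == "bits":
        mi = mi / LN2
    return mi if mi.ndim else float(mi)


def mutual_information(x, y, base: str = "nats") -> float:
    """Plug-in mutual information of two equal-length binary vectors.

    Natural log by default (``base='bits'`` divides by ln 2).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 1:
        raise ValueError("vectors must have length >= 1")
    if np.isnan(xa).any() or np.isnan(ya).any():
        raise ValueError("missing values are not allowed")
    return float(mi_from_counts(*_counts_2x2(xa, ya), base=base))


def binary_entropy(x, base: str = "nats") -> float:
    """Plug-in marginal entropy of a binary vector."""
    xa = np.asarray(x, dtype=float)
    p = float(np.mean(xa == 1))
    h = 0.0
    for q in (p, 1 - p):
        if q > 0:
            h -= q * np.log(q)
    return h / LN2 if base == "bits" else h


def permutation_pvalue(x, y, B: int, seed: int = 0, base: str = "nats"):
    """Monte-Carlo permutation p-value for the MI of two binary vectors.

    ``y`` is permuted uniformly ``B`` times; the add-one estimator
    ``p = (1 + #{MI_perm >= MI_obs - 1e-12}) / (B + 1)`` keeps p in
    [1/(B+1), 1] and counts ties conservatively.  Returns ``(p, null)``
    with the B permuted MI values.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    obs = mutual_information(xa, ya, base=base)
    rng = np.random.default_rng(seed)
    n11, nx1, ny1, n = _counts_2x2(xa, ya)
    # permuting y only moves the joint 1-1 count; margins are fixed
    perm = np.tile(ya, (B, 1))
    perm = rng.permuted(perm, axis=1)
    n11_perm = perm @ (xa == 1)
    null = np.asarray(mi_from_counts(n11_perm, nx1, ny1, n, base=base))
    p = (1.0 + int(np.sum(null >= obs - 1e-12))) / (B + 1.0)
    return float(p), null


def shared_patient_count(x, y) -> int:
    """Number of records positive for both variables."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    return int(np.sum((xa == 1) & (ya == 1)))


def sex_prevalence(x, sex) -> float | None:
    """Male fraction among records positive for the variable.

    ``sex`` is binary with 1 = male.  Returns None (reported missing) when
    the variable has no positive records.
    """
    xa = np.asarray(x, dtype=float)
    sa = np.asarray(sex, dtype=float)
    if xa.shape != sa.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {sa.shape}")
    pos = xa == 1
    if not pos.any():
        return None
    return float(np.mean(sa[pos] == 1))


@dataclass(frozen=True)
class NetworkParams:
    B: int = 999
    alpha: float = 0.05
    correction: str = "fdr_bh"  # 'fdr_bh' | 'bonferroni' | 'none'
    min_patients: int = 15
    cases_only: bool = True
    base: str = "nats"


def build_network(
    curated,
    scores: list[NodeScore],
    params: NetworkParams = NetworkParams(),
    seed: int = 0,
) -> nx.Graph:
    """MI network over the case subpopulation for the significant nodes.

    Every pair of significant nodes is tested; retained edges satisfy
    ``p_adjusted < alpha`` and ``shared_patients >= min_patients``.  The
    returned ``networkx.Graph`` carries node attributes (z, size=|z|,
    sex_prevalence) and edge attributes (mi, p, p_adjusted,
    shared_patients); graph attributes record the parameters and the
    subpopulation size.  Deterministic given the seed.
    """
    nodes = [s for s in scores if s.available and s.significant]
    if len(nodes) < 2:
        raise ValueError(f"need >= 2 significant nodes, got {len(nodes)}")
    node_names = [s.variable for s in nodes]
    non_binary = [
        n for n in node_names if curated.meta[n].kind != "dichotomous"
    ]
    if non_binary:
        raise ValueError(f"MI network requires dichotomous variables; got {non_binary}")

    if params.cases_only:
        rows = curated.outcome.to_numpy(dtype=float) == 1
    else:
        rows = np.ones(len(curated.outcome), dtype=bool)
    if not rows.any():
        raise ValueError("case subpopulation is empty")
    sub = curated.features.loc[rows]
    n_sub = len(sub)

    G = nx.Graph(
        subpopulation="cases" if params.cases_only else "all",
        n_subpopulation=n_sub,
        B=params.B,
        alpha=params.alpha,
        correction=params.correction,
        min_patients=params.min_patients,
        mi_base=params.base,
    )
    sex = sub["sex"].to_numpy(dtype=float) if "sex" in sub.columns else None
    for s in nodes:
        x = sub[s.variable].to_numpy(dtype=float)
        sp = sex_prevalence(x, sex) if sex is not None else None
        G.add_node(
            s.variable,
            z=float(s.z),
            size=abs(float(s.z)),
            sex_prevalence=float(sp) if sp is not None else float("nan"),
        )

    rng = np.random.default_rng(seed)
    pairs = [
        (node_names[i], node_names[j])
        for i in range(len(node_names))
        for j in range(i + 1, len(node_names))
    ]
    records = []
    for u, v in pairs:
        pair_seed = int(rng.integers(2**31 - 1))
        x = sub[u].to_numpy(dtype=float)
        y = sub[v].to_numpy(dtype=float)
        mi = mutual_information(x, y, base=params.base)
        p, _ = permutation_pvalue(x, y, B=params.B, seed=pair_seed, base=params.base)
        records.append((u, v, mi, p, shared_patient_count(x, y)))

    pvals = np.array([r[3] for r in records])
    if params.correction == "none":
        padj = pvals
    else:
        padj = multipletests(pvals, method=params.correction)[1]

    kept = 0
    for (u, v, mi, p, shared), pa in zip(records, padj):
        if pa < params.alpha and shared >= params.min_patients:
            G.add_edge(
                u, v, mi=float(mi), p=float(p), p_adjusted=float(pa), shared_patients=int(shared)
            )
            kept += 1
    if kept == 0:
        warnings.warn("no edge passed the significance and patient-count filters", stacklevel=2)
    return G


def network_to_frames(G: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flat node and edge tables of a built network (for CSV export)."""
    nodes = pd.DataFrame(
        [
            {"variable": n, **{k: d[k] for k in ("z", "size", "sex_prevalence")}}
            for n, d in sorted(G.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "mi": d["mi"],
                "p": d["p"],
                "p_adjusted": d["p_adjusted"],
                "shared_patients": d["shared_patients"],
            }
            for u, v, d in sorted(G.edges(data=True))
        ]
    )
    return nodes, edges
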