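import numpy as np
import pandas as pd
import pytest

from ehrnet import (
    CuratedMatrix,
    NetworkParams,
    NodeScore,
    VariableMeta,
    binary_entropy,
    build_network,
    mutual_information,
    network_to_frames,
    permutation_pvalue,
    sex_prevalence,
    shared_patient_count,
)


def _mi_oracle(x, y):
    """Independent double-loop plug-in MI (nats) over the 2x2 cells."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    mi = 0.0
    for a in (0.0, 1.0):
        for b in (0.0, 1.0):
            pj = np.mean((x == a) & (y == b))
            px = np.mean(x == a)
            py = np.mean(y == b)
            if pj > 0:
                mi += pj * np.log(pj / (px * py))
    return mi


def _vectors_from_cells(n11, n10, n01, n00):
    x = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
    y = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
    return x, y


def test_mutual_information_hand_value():
    # joint (0.4, 0.1, 0.1, 0.4): MI = 0.8 ln 1.6 + 0.2 ln 0.4
    x, y = _vectors_from_cells(4, 1, 1, 4)
    expected = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)
    assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
    assert mutual_information(x, y) == pytest.approx(0.192745, abs=1e-6)
    assert mutual_information(x, y, base="bits") == pytest.approx(expected / np.log(2))


def test_identical_balanced_vectors_give_ln2():
    x = np.array([0.0, 1.0] * 50)
    assert mutual_information(x, x) == pytest.approx(np.log(2), abs=1e-12)
    assert binary_entropy(x) == pytest.approx(np.log(2), abs=1e-12)
    assert binary_entropy(x, base="bits") == pytest.approx(1.0, abs=1e-12)


def test_independence_and_constant_give_zero():
    x, y = _vectors_from_cells(9, 21, 21, 49)  # p(x)=0.3, p(y)=0.3, independent
    assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)
    assert mutual_information(np.ones(40), (np.arange(40) % 2).astype(float)) == 0.0


def test_mi_symmetry_nonnegativity_and_entropy_bound(rng):
    for _ in range(50):
        x = (rng.random(120) < rng.uniform(0.1, 0.9)).astype(float)
        y = np.where(rng.random(120) < 0.3, x, (rng.random(120) < 0.5).astype(float))
        mi = mutual_information(x, y)
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-14)
        assert mi >= 0.0
        assert mi <= min(binary_entropy(x), binary_entropy(y)) + 1e-12
        assert mi == pytest.approx(_mi_oracle(x, y), abs=1e-13)


def test_mi_decreases_under_flip_noise(rng):
    x = (rng.random(5000) < 0.5).astype(float)
    last = mutual_information(x, x)
    for flip_rate in (0.05, 0.15, 0.3, 0.45):
        noisy = np.where(rng.random(5000) < flip_rate, 1.0 - x, x)
        mi = mutual_information(x, noisy)
        assert mi < last
        last = mi


def test_mutual_information_input_validation():
    with pytest.raises(ValueError, match="length"):
        mutual_information([0.0, 1.0], [1.0])
    with pytest.raises(ValueError, match="missing"):
        mutual_information([0.0, np.nan], [1.0, 0.0])


def test_permutation_pvalue_extremes():
    rng = np.random.default_rng(7)
    x = (rng.random(400) < 0.5).astype(float)
    # constant second variable: MI identically 0, every permutation ties
    p_null, null = permutation_pvalue(np.ones(400), x, B=99, seed=1)
    assert p_null == 1.0
    assert np.allclose(null, 0.0)
    # identical vectors: no permutation can reach the observed MI
    p_dep, _ = permutation_pvalue(x, x, B=999, seed=2)
    assert p_dep == pytest.approx(1 / 1000)
    with pytest.raises(ValueError, match="B"):
        permutation_pvalue(x, x, B=0)


def test_permutation_pvalue_is_seed_deterministic():
    rng = np.random.default_rng(8)
    x = (rng.random(200) < 0.3).astype(float)
    y = (rng.random(200) < 0.4).astype(float)
    p1, null1 = permutation_pvalue(x, y, B=200, seed=42)
    p2, null2 = permutation_pvalue(x, y, B=200, seed=42)
    assert p1 == p2
    assert np.array_equal(null1, null2)


def test_shared_patient_count_and_sex_prevalence():
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
    y = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
    sex = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
    assert shared_patient_count(x, y) == 2
    assert sex_prevalence(x, sex) == pytest.approx(2 / 3)
    assert sex_prevalence(np.zeros(5), sex) is None


# ----------------------------------------------------------- network builder


def _curated_for_network(n=300, seed=0, coupled=True):
    rng = np.random.default_rng(seed)
    a = (rng.random(n) < 0.5).astype(float)
    b = np.where(rng.random(n) < 0.8, a, (rng.random(n) < 0.5).astype(float)) if coupled else (
        rng.random(n) < 0.5
    ).astype(float)
    c = (rng.random(n) < 0.4).astype(float)
    features = pd.DataFrame(
        {"a": a, "b": b, "c": c, "sex": (rng.random(n) < 0.43).astype(float)}
    )
    outcome = pd.Series(np.ones(n))  # everyone is a case
    meta = {k: VariableMeta("dichotomous", "diagnosis") for k in ("a", "b", "c")}
    meta["sex"] = VariableMeta("dichotomous", "demographic")
    meta["outcome"] = VariableMeta("dichotomous", "outcome")
    curated = CuratedMatrix(features=features, outcome=outcome, meta=meta, ledger=pd.DataFrame())
    scores = [
        NodeScore("a", 1.0, 0.25, 4.0, 1e-4, True),
        NodeScore("b", 0.8, 0.25, 3.2, 1.4e-3, True),
        NodeScore("c", -0.5, 0.2, -2.5, 1.2e-2, True),
    ]
    return curated, scores


def test_vacuous_filters_give_the_complete_graph():
    curated, scores = _curated_for_network()
    params = NetworkParams(B=19, alpha=1.1, correction="none", min_patients=0)
    G = build_network(curated, scores, params=params, seed=0)
    assert set(G.nodes) == {"a", "b", "c"}
    assert G.number_of_edges() == 3
    for _, _, d in G.edges(data=True):
        assert d["mi"] >= 0 and 0 < d["p"] <= 1 and d["shared_patients"] >= 0
    assert G.nodes["a"]["size"] == pytest.approx(4.0)
    assert G.graph["n_subpopulation"] == 300


def test_impossible_patient_filter_empties_the_network():
    curated, scores = _curated_for_network()
    params = NetworkParams(B=19, alpha=1.1, correction="none", min_patients=10**6)
    with pytest.warns(UserWarning, match="no edge"):
        G = build_network(curated, scores, params=params, seed=0)
    assert G.number_of_edges() == 0
    assert G.number_of_nodes() == 3


def test_significance_filter_keeps_only_the_coupled_pair():
    curated, scores = _curated_for_network(n=500, seed=3)
    params = NetworkParams(B=199, alpha=0.05, correction="fdr_bh", min_patients=15)
    G = build_network(curated, scores, params=params, seed=3)
    assert ("a", "b") in G.edges or ("b", "a") in G.edges
    assert ("a", "c") not in G.edges and ("b", "c") not in G.edges


def test_tighter_alpha_retains_a_subset_of_edges():
    curated, scores = _curated_for_network(n=500, seed=4)
    loose = build_network(
        curated, scores, params=NetworkParams(B=199, alpha=0.5, min_patients=0), seed=4
    )
    strict_params = NetworkParams(B=199, alpha=0.01, min_patients=0)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        strict = build_network(curated, scores, params=strict_params, seed=4)
    assert set(strict.edges) <= set(loose.edges)


def test_network_rejects_insufficient_or_nonbinary_nodes():
    curated, scores = _curated_for_network()
    with pytest.raises(ValueError, match="significant nodes"):
        build_network(curated, scores[:1])
    bad = scores + [NodeScore("sex", 0.2, 0.05, 4.0, 1e-4, True)]
    curated.meta["sex"] = VariableMeta("discrete", "demographic")
    with pytest.raises(ValueError, match="dichotomous"):
        build_network(curated, bad)


def test_cases_only_subpopulation_is_respected():
    curated, scores = _curated_for_network(n=400, seed=5)
    outcome = curated.outcome.copy()
    outcome.iloc[: 150] = 0.0
    curated = CuratedMatrix(
        features=curated.features, outcome=outcome, meta=curated.meta, ledger=curated.ledger
    )
    params = NetworkParams(B=19, alpha=1.1, correction="none", min_patients=0)
    G = build_network(curated, scores, params=params, seed=5)
    assert G.graph["n_subpopulation"] == 250
    G_all = build_network(
        curated,
        scores,
        params=NetworkParams(B=19, alpha=1.1, correction="none", min_patients=0, cases_only=False),
        seed=5,
    )
    assert G_all.graph["n_subpopulation"] == 400


def test_network_to_frames_round_trip():
    curated, scores = _curated_for_network()
    params = NetworkParams(B=19, alpha=1.1, correction="none", min_patients=0)
    G = build_network(curated, scores, params=params, seed=0)
    nodes, edges = network_to_frames(G)
    assert list(nodes.columns) == ["variable", "z", "size", "sex_prevalence"]
    assert list(edges.columns) == ["source", "target", "mi", "p", "p_adjusted", "shared_patients"]
    assert len(nodes) == 3 and len(edges) == 3
    assert (nodes["sex_prevalence"].between(0, 1)).all()
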