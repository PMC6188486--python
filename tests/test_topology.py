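"""Centralities, power-law fits, rank tests, hub selection and modules."""

import math
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernet.topology import (
    compute_centralities,
    extract_module,
    fit_loglog,
    fit_power_law,
    select_hubs,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# brute-force centrality oracle: enumerate every simple path per node pair
# ---------------------------------------------------------------------------


def _all_shortest_paths(g, s, t):
    nodes = [v for v in g.nodes if v not in (s, t)]
    best, found = None, []
    for k in range(len(nodes) + 1):
        for inner in permutations(nodes, k):
            path = (s, *inner, t)
            if all(g.has_edge(a, b) for a, b in zip(path, path[1:])):
                if best is None or len(path) < best:
                    best, found = len(path), [path]
                elif len(path) == best:
                    found.append(path)
        if best is not None:
            break  # any longer permutation cannot beat a found path
    return found


def brute_force_centralities(g):
    nodes = sorted(g.nodes)
    n = len(nodes)
    bet = {v: 0.0 for v in nodes}
    dist_sum = {v: 0.0 for v in nodes}
    reach = {v: 0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        d = len(paths[0]) - 1
        for v in (s, t):
            dist_sum[v] += d
            reach[v] += 1
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return {
        v: {
            "degree": g.degree(v),
            "betweenness": bet[v] / scale,
            "closeness": reach[v] / dist_sum[v] if dist_sum[v] > 0 else 0.0,
            "raw_betweenness": bet[v],
        }
        for v in nodes
    }


def test_centralities_closed_forms_star_path_cycle():
    star = nx.star_graph(3)
    topo = compute_centralities(star).set_index("node")
    assert topo.loc[0, ["degree", "betweenness", "closeness"]].tolist() == [3, 1.0, 1.0]
    for leaf in (1, 2, 3):
        assert topo.loc[leaf, "degree"] == 1
        assert topo.loc[leaf, "betweenness"] == 0.0
        assert topo.loc[leaf, "closeness"] == pytest.approx(3 / 5)

    path = nx.path_graph(3)
    topo = compute_centralities(path).set_index("node")
    assert topo.loc[1, "betweenness"] == pytest.approx(1.0)
    assert topo.loc[0, "closeness"] == pytest.approx(2 / 3)

    cycle = nx.cycle_graph(4)
    topo = compute_centralities(cycle)
    assert topo["betweenness"].tolist() == pytest.approx([1 / 6] * 4)
    assert topo["closeness"].tolist() == pytest.approx([3 / 4] * 4)


def test_centralities_match_brute_force_on_random_graphs():
    rng = np.random.default_rng(42)
    for trial in range(50):
        n = int(rng.integers(2, 9))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        topo = compute_centralities(g).set_index("node")
        oracle = brute_force_centralities(g)
        raw_from_nx = nx.betweenness_centrality(g, normalized=False)
        for v, expected in oracle.items():
            assert topo.loc[v, "degree"] == expected["degree"]
            assert topo.loc[v, "betweenness"] == pytest.approx(
                expected["betweenness"], abs=1e-9
            )
            assert topo.loc[v, "closeness"] == pytest.approx(
                expected["closeness"], abs=1e-9
            )
        # raw pair-dependency mass equals total interior incidences
        assert sum(raw_from_nx.values()) == pytest.approx(
            sum(e["raw_betweenness"] for e in oracle.values()), abs=1e-9
        )


def test_centralities_isolated_node_and_empty_graph():
    g = nx.Graph()
    g.add_node("lonely")
    g.add_edge("a", "b")
    topo = compute_centralities(g).set_index("node")
    assert topo.loc["lonely", "closeness"] == 0.0
    assert topo.loc["lonely", "betweenness"] == 0.0
    assert compute_centralities(nx.Graph()).empty


# ---------------------------------------------------------------------------
# power-law fit
# ---------------------------------------------------------------------------


def test_power_law_exact_on_quadratic_decay_counts():
    # counts 64,16,4,1 at k=1,2,4,8 give P(k) proportional to k^-2 exactly
    degrees = [1] * 64 + [2] * 16 + [4] * 4 + [8]
    fit = fit_power_law(degrees)
    assert fit.slope == pytest.approx(-2.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.n_points == 4


def test_power_law_undefined_for_regular_graph():
    with pytest.raises(ValueError, match="undefined fit"):
        fit_power_law([3, 3, 3, 3])


def test_power_law_on_preferential_attachment_graph():
    g = nx.barabasi_albert_graph(1000, 2, seed=11)
    fit = fit_power_law([d for _, d in g.degree()])
    assert -3.5 <= fit.slope <= -1.5
    assert fit.r_squared > 0.6
    assert fit.mle_exponent is not None and fit.mle_exponent > 1


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    s=st.floats(min_value=0.5, max_value=4.0),
    c=st.floats(min_value=-3.0, max_value=3.0),
)
def test_loglog_fit_recovers_any_exact_log_linear_law(s, c):
    k = np.array([1.0, 2.0, 3.0, 5.0, 9.0, 17.0])
    pk = 10.0**c * k**-s
    fit = fit_loglog(k, pk)
    assert fit.slope == pytest.approx(-s, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def test_rank_sum_most_extreme_split_doubles_to_one_third():
    res = wilcoxon_rank_sum([1, 2], [3, 4])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(1 / 3)


def test_rank_sum_identical_samples_report_no_difference():
    res = wilcoxon_rank_sum([5, 5, 7, 9], [5, 5, 7, 9])
    assert res.p_value >= 0.99


def test_rank_sum_exact_branch_matches_scipy_exact():
    rng = np.random.default_rng(3)
    for _ in range(25):
        na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        pooled = rng.permutation(np.arange(1.0, na + nb + 1))  # distinct -> no ties
        a, b = pooled[:na], pooled[na:]
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "exact"
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(float(expected.pvalue), abs=1e-12)


def test_rank_sum_large_samples_use_corrected_normal_approximation():
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=30), rng.normal(loc=1.0, size=30)
    res = wilcoxon_rank_sum(a, b)
    assert res.method == "normal-approx"
    assert 0 <= res.p_value <= 1
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# hubs and modules
# ---------------------------------------------------------------------------


def _toy_topology():
    return pd.DataFrame(
        {
            "node": ["a", "b", "c", "d", "e", "f"],
            "node_class": ["circRNA"] * 3 + ["mRNA"] * 3,
            "degree": [9, 5, 4, 4, 2, 1],
            "betweenness": [0.9, 0.1, 0.4, 0.2, 0.0, 0.0],
            "closeness": [0.95, 0.5, 0.7, 0.6, 0.4, 0.3],
        }
    )


def test_select_hubs_intersects_the_three_rankings():
    topo = _toy_topology()
    assert select_hubs(topo, k=1) == ["a"]
    # top-2 by degree is {a, b} but b trails on the other indices
    assert select_hubs(topo, k=2) == ["a"]
    # k=3: degree ties at 4 pull in d; intersection ordered by degree then betweenness
    assert select_hubs(topo, k=3) == ["a", "c", "d"]
    assert set(select_hubs(topo, k=10)) == set(topo["node"])  # k >= N keeps all
    with pytest.raises(ValueError):
        select_hubs(topo, k=0)


def test_select_hubs_ties_and_order_invariance():
    topo = _toy_topology()
    shuffled = topo.sample(frac=1.0, random_state=9).reset_index(drop=True)
    assert select_hubs(topo, k=3) == select_hubs(shuffled, k=3)
    # degree ties at the k-th value pull in every tied node
    ties = _toy_topology()
    assert {"c", "d"} <= set(select_hubs(ties, k=4))


def test_extract_module_is_the_hub_neighbor_closure():
    star = nx.star_graph(4)
    module = extract_module(star, [0])
    assert module.node_ids == set(star.nodes)

    two = nx.Graph()
    two.add_edges_from([("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")])
    module = extract_module(two, ["a"])
    assert module.node_ids == {"a", "b", "c"}
    assert module.n_edges == 3
    with pytest.raises(KeyError):
        extract_module(two, ["missing"])


def test_module_gene_list_reports_mrna_members():
    g = nx.Graph()
    g.add_node("C", kind="circRNA")
    g.add_node("G1", kind="mRNA")
    g.add_node("G2", kind="mRNA")
    g.add_edges_from([("C", "G1"), ("C", "G2")])
    assert extract_module(g, ["C"]).genes() == ["G1", "G2"]
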