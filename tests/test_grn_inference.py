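"""Information estimators, path-consistency skeletons, MCL, K-means/FOM."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import motifrecruit as mr
from motifrecruit.grn_inference import DegenerateSignalError, GRNConfig


def bivariate(rho, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return x, y


class TestMutualInformation:
    def test_independent_gaussians_near_zero(self):
        x, y = bivariate(0.0, 10_000, seed=1)
        assert mr.mutual_information_gaussian(x, y) < 0.01

    def test_correlated_gaussians_match_closed_form(self):
        # population MI = -1/2 ln(1 - rho^2)
        x, y = bivariate(0.8, 10_000, seed=2)
        assert abs(mr.mutual_information_gaussian(x, y) - 0.5108256) < 0.05

    def test_exact_dependence_is_degenerate(self):
        x = np.random.default_rng(3).standard_normal(100)
        with pytest.raises(DegenerateSignalError):
            mr.mutual_information_gaussian(x, x)
        with pytest.raises(DegenerateSignalError):
            mr.mutual_information_gaussian(x, 2 * x + 1)

    def test_constant_vector_is_degenerate(self):
        x = np.random.default_rng(4).standard_normal(50)
        with pytest.raises(DegenerateSignalError):
            mr.mutual_information_gaussian(x, np.ones(50))

    def test_non_negative_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x, y = rng.standard_normal((2, 30))
            assert mr.mutual_information_gaussian(x, y) >= 0.0


class TestConditionalMutualInformation:
    def test_empty_conditioning_set_reduces_to_mi_bitwise(self):
        x, y = bivariate(0.5, 500, seed=6)
        assert mr.conditional_mutual_information_gaussian(x, y, []) == \
            mr.mutual_information_gaussian(x, y)

    def test_chain_renders_endpoints_conditionally_independent(self):
        rng = np.random.default_rng(7)
        n = 10_000
        x = rng.standard_normal(n)
        z = x + rng.standard_normal(n)
        y = z + rng.standard_normal(n)
        assert mr.conditional_mutual_information_gaussian(x, y, [z]) < 0.01

    def test_direct_edge_cmi_matches_population_covariance_oracle(self):
        # X -> Y and X -> Z with unit weights and unit noise.  The oracle
        # plugs the model's exact covariance into the determinant formula.
        cov = np.array([  # order: X, Y, Z
            [1.0, 1.0, 1.0],
            [1.0, 2.0, 1.0],
            [1.0, 1.0, 2.0],
        ])
        def ld(ix):
            return np.linalg.slogdet(cov[np.ix_(ix, ix)])[1]
        oracle = 0.5 * (ld([0, 2]) + ld([1, 2]) - ld([2]) - ld([0, 1, 2]))
        rng = np.random.default_rng(8)
        n = 10_000
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        z = x + rng.standard_normal(n)
        est = mr.conditional_mutual_information_gaussian(x, y, [z])
        assert abs(est - oracle) < 0.05

    def test_non_negative_on_random_data(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            x, y, z = rng.standard_normal((3, 40))
            assert mr.conditional_mutual_information_gaussian(x, y, [z]) >= 0.0


def brute_force_pca_cmi(expr: pd.DataFrame, theta: float, max_order: int) -> set:
    """Direct transcription of the procedure with per-pair np.cov calls."""
    genes = list(expr.index)
    data = {g: expr.loc[g].to_numpy(dtype=float) for g in genes}
    edges = set()
    for a, b in itertools.combinations(genes, 2):
        if mr.mutual_information_gaussian(data[a], data[b]) >= theta:
            edges.add(frozenset((a, b)))
    for order in range(1, max_order + 1):
        while True:
            frozen = set(edges)
            def nbrs(g):
                return {next(iter(e - {g})) for e in frozen if g in e}
            removed = set()
            for e in frozen:
                a, b = sorted(e)
                common = sorted(nbrs(a) & nbrs(b))
                subsets = list(itertools.combinations(common, order))
                if not subsets:
                    continue
                best = max(
                    mr.conditional_mutual_information_gaussian(
                        data[a], data[b], [data[z] for z in Z]
                    )
                    for Z in subsets
                )
                if best < theta:
                    removed.add(e)
            edges -= removed
            if not removed:
                break
    return edges


class TestPcaCmi:
    def test_independent_genes_give_empty_graph(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.standard_normal((2, 5000)), index=["a", "b"])
        g = mr.pca_cmi(expr, GRNConfig(theta=0.05, max_order=1))
        assert g.number_of_edges() == 0

    def test_three_gene_chain_recovers_exact_skeleton(self):
        g = nx.Graph()
        g.add_edge("X", "Z", weight=1.0)
        g.add_edge("Z", "Y", weight=1.0)
        expr = mr.generate_expression(g, 5000, 1.0, seed=11)
        est = mr.pca_cmi(expr, GRNConfig(theta=0.05, max_order=1))
        assert set(map(frozenset, est.edges)) == {frozenset(("X", "Z")), frozenset(("Z", "Y"))}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(6, 0.4, seed=seed)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(6)})
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.choice((-1.0, 1.0)))
        expr = mr.generate_expression(g, 400, 1.0, seed=seed + 100)
        est = mr.pca_cmi(expr, GRNConfig(theta=0.03, max_order=2))
        brute = brute_force_pca_cmi(expr, theta=0.03, max_order=2)
        assert set(map(frozenset, est.edges)) == brute

    def test_order0_edges_monotone_in_theta(self):
        g = nx.gnp_random_graph(8, 0.3, seed=13)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        expr = mr.generate_expression(g, 300, 1.0, seed=14)
        e_low = set(map(frozenset, mr.pca_cmi(expr, GRNConfig(0.02, 0)).edges))
        e_high = set(map(frozenset, mr.pca_cmi(expr, GRNConfig(0.08, 0)).edges))
        assert e_high <= e_low

    def test_zero_variance_gene_excluded_with_warning(self):
        rng = np.random.default_rng(15)
        expr = pd.DataFrame(rng.standard_normal((3, 100)), index=["a", "b", "c"])
        expr.loc["c"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            g = mr.pca_cmi(expr, GRNConfig())
        assert "c" not in g.nodes


def reference_mcl(adj: np.ndarray, inflation: float = 2.0, iters: int = 200) -> list[set]:
    """Dense-matrix MCL transcribed directly from the algorithm definition."""
    M = adj.astype(float).copy()
    np.fill_diagonal(M, 1.0)
    M = M / M.sum(axis=0)
    for _ in range(iters):
        M = np.linalg.matrix_power(M, 2)
        M = M**inflation
        M = M / M.sum(axis=0)
    clusters = []
    seen = set()
    for i in range(M.shape[0]):
        members = set(np.nonzero(M[i] > 1e-6)[0]) | ({i} if M[i, i] > 1e-6 else set())
        if members and not members & seen:
            clusters.append(members)
            seen |= members
    for j in range(M.shape[0]):
        if j not in seen:
            clusters.append({j})
            seen.add(j)
    return clusters


class TestMcl:
    def test_disjoint_triangles_form_two_communities(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        comms = mr.mcl_communities(g)
        parts = sorted(sorted(c.genes) for c in comms)
        assert parts == [[0, 1, 2], [3, 4, 5]]

    def test_edgeless_graph_gives_singletons(self):
        g = nx.empty_graph(5)
        comms = mr.mcl_communities(g)
        assert sorted(c.genes for c in comms) == [[i] for i in range(5)]

    def test_barbell_splits_at_bridge_matching_reference(self):
        g = nx.Graph()
        for base in (0, 6):
            for i, j in itertools.combinations(range(6), 2):
                g.add_edge(base + i, base + j)
        g.add_edge(0, 6)
        ours = sorted(sorted(c.genes) for c in mr.mcl_communities(g, inflation=2.0))
        adj = nx.to_numpy_array(g, nodelist=range(12))
        ref = sorted(sorted(c) for c in reference_mcl(adj, inflation=2.0))
        assert ours == ref == [[0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11]]

    def test_partition_covers_all_nodes(self):
        g = nx.gnp_random_graph(15, 0.2, seed=16)
        comms = mr.mcl_communities(g)
        members = sorted(x for c in comms for x in c.genes)
        assert members == sorted(g.nodes)

    def test_invariant_to_node_relabeling(self):
        g = nx.gnp_random_graph(12, 0.25, seed=17)
        comms = mr.mcl_communities(g)
        mapping = {i: f"node_{(i * 7) % 12:02d}" for i in range(12)}
        comms_rel = mr.mcl_communities(nx.relabel_nodes(g, mapping))
        a = sorted(sorted(mapping[x] for x in c.genes) for c in comms)
        b = sorted(sorted(c.genes) for c in comms_rel)
        assert a == b

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mr.mcl_communities(nx.Graph())


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestKmeansFom:
    def test_two_separated_blobs_choose_k2(self):
        rng = np.random.default_rng(18)
        a = rng.standard_normal((20, 8)) * 0.5
        b = rng.standard_normal((20, 8)) * 0.5 + 10.0  # 10x the noise scale apart
        expr = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(40)])
        k, assignment, curve = mr.kmeans_fom(expr, (2, 6), seed=0)
        assert k == 2
        left = set(assignment.iloc[:20])
        right = set(assignment.iloc[20:])
        assert left.isdisjoint(right)

    def test_identical_rows_choose_smallest_k(self):
        expr = pd.DataFrame(np.ones((10, 5)), index=[f"g{i}" for i in range(10)])
        k, _, curve = mr.kmeans_fom(expr, (2, 5), seed=0)
        assert k == 2
        assert (curve["fom"] < 1e-9).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(19)
        expr = pd.DataFrame(rng.standard_normal((15, 6)))
        _, a, _ = mr.kmeans_fom(expr, (2, 4), seed=3)
        _, b, _ = mr.kmeans_fom(expr, (2, 4), seed=3)
        assert a.equals(b)

    def test_k_not_smaller_than_gene_count(self):
        expr = pd.DataFrame(np.random.default_rng(20).standard_normal((5, 4)))
        with pytest.raises(ValueError):
            mr.kmeans_fom(expr, (2, 5), seed=0)
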