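"""Spearman matrices and thresholded network construction."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from micronet import AbundanceTable, SpearmanNetworkBuilder, build_network, spearman_matrix
from micronet.netbuild import (CorrelationResult, NetworkError,
                               _benjamini_hochberg, write_edge_list, write_graph)

from _oracles import spearman_closed_form


def table_from(matrix) -> AbundanceTable:
    matrix = np.asarray(matrix, dtype=float)
    return AbundanceTable(
        pd.DataFrame(matrix, index=[f"asv{i}" for i in range(matrix.shape[0])],
                     columns=[f"s{j}" for j in range(matrix.shape[1])])
    )


def corr_from(pairs) -> CorrelationResult:
    """CorrelationResult for 2 ASVs with a prescribed (r, p)."""
    r, p = pairs
    ids = ["a", "b"]
    rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=ids, columns=ids)
    pm = pd.DataFrame([[0.0, p], [p, 0.0]], index=ids, columns=ids)
    return CorrelationResult(r=rm, p=pm, n_samples=20, constant_ids=[])


class TestSpearmanMatrix:
    def test_perfect_antitone(self):
        res = spearman_matrix(table_from([[1, 2, 3, 4], [4, 3, 2, 1]]))
        assert res.r.iloc[0, 1] == pytest.approx(-1.0)

    def test_rank_difference_closed_form(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        res = spearman_matrix(table_from([x, y]))
        assert spearman_closed_form(x, y) == pytest.approx(0.8)
        assert res.r.iloc[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_t_approximation_pvalue(self):
        """r=0.6 at n=20 -> t = 3.182, two-sided p = 0.0052 (18 df)."""
        r, n = 0.6, 20
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_oracle = 2 * stats.t.sf(t, df=n - 2)
        assert t == pytest.approx(3.182, abs=1e-3)
        assert p_oracle == pytest.approx(0.0052, abs=2e-4)
        rng = np.random.default_rng(0)
        for _ in range(40):  # find a pair landing near r=0.6 and check its p
            mat = rng.exponential(size=(2, n))
            res = spearman_matrix(table_from(mat))
            robs = res.r.iloc[0, 1]
            texp = robs * np.sqrt((n - 2) / (1 - robs**2))
            assert res.p.iloc[0, 1] == pytest.approx(2 * stats.t.sf(abs(texp), n - 2), rel=1e-9)

    def test_constant_asv_flagged_and_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_matrix(table_from([[1, 2, 3, 4], [5, 5, 5, 5], [4, 2, 1, 3]]))
        assert res.constant_ids == ["asv1"]
        assert np.isnan(res.r.iloc[0, 1])
        assert res.r.iloc[0, 0] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(NetworkError, match="4 samples"):
            spearman_matrix(table_from([[1, 2, 3], [3, 2, 1]]))

    def test_exact_permutation_pvalue_small_n(self):
        # n=4 distinct ranks: P(|rho| = 1) = 2/4! = 1/12
        res = spearman_matrix(table_from([[1, 2, 3, 4], [10, 20, 30, 40]]),
                              p_method="exact")
        assert res.p.iloc[0, 1] == pytest.approx(2 / 24)

    def test_exact_rejected_above_n9(self):
        with pytest.raises(NetworkError, match="n <= 9"):
            spearman_matrix(table_from(np.random.default_rng(0).random((2, 12))),
                            p_method="exact")


class TestBuildNetwork:
    @pytest.mark.parametrize(
        "r, p, present",
        [(0.61, 0.04, True), (0.61, 0.06, False), (0.59, 0.001, False),
         (-0.61, 0.04, True)],
    )
    def test_threshold_rule(self, r, p, present):
        G = build_network(corr_from((r, p)))
        assert G.has_edge("a", "b") == present
        if present:
            assert G["a"]["b"]["sign"] == ("+" if r > 0 else "-")

    def test_raising_threshold_never_adds_edges(self, planted_table):
        table, _ = planted_table
        corr = spearman_matrix(table)
        loose = {frozenset(e) for e in build_network(corr, r_threshold=0.6).edges()}
        strict = {frozenset(e) for e in build_network(corr, r_threshold=0.8).edges()}
        assert strict <= loose

    def test_extreme_thresholds_give_empty_network(self, rng):
        table = table_from(rng.random((20, 10)))
        corr = spearman_matrix(table)
        with pytest.warns(UserWarning, match="no correlation"):
            G = build_network(corr, r_threshold=0.999, p_threshold=1e-9)
        assert G.number_of_edges() == 0  # warning, not an exception

    def test_edge_set_invariant_to_monotone_rescaling(self, planted_table):
        table, _ = planted_table
        e1 = {frozenset(e) for e in build_network(spearman_matrix(table)).edges()}
        # per-sample monotone transform: cube root then scale by sample depth
        transformed = AbundanceTable(table.counts ** (1 / 3) * 7.7,
                                     domain=table.domain)
        e2 = {frozenset(e) for e in build_network(spearman_matrix(transformed)).edges()}
        assert e1 == e2

    def test_invariant_to_sample_permutation(self, planted_table):
        table, _ = planted_table
        shuffled = AbundanceTable(
            table.counts[list(table.counts.columns[::-1])], domain=table.domain)
        e1 = {frozenset(e) for e in build_network(spearman_matrix(table)).edges()}
        e2 = {frozenset(e) for e in build_network(spearman_matrix(shuffled)).edges()}
        assert e1 == e2

    def test_isolates_dropped_by_default(self):
        corr = corr_from((0.2, 0.9))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert build_network(corr).number_of_nodes() == 0
            assert build_network(corr, keep_isolates=True).number_of_nodes() == 2

    def test_node_metadata_attached(self, planted_table):
        table, _ = planted_table
        G = build_network(spearman_matrix(table), table=table)
        node = next(iter(G.nodes))
        assert G.nodes[node]["domain"] in ("bacteria", "fungi")
        assert 0 < G.nodes[node]["mean_rel_abundance"] < 1
        assert G.graph["r_threshold"] == 0.6

    def test_fdr_matches_statsmodels_and_is_stricter(self, planted_table):
        table, _ = planted_table
        corr = spearman_matrix(table)
        p = corr.p.to_numpy()[np.triu_indices(corr.p.shape[0], 1)]
        ours = _benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        plain = build_network(corr)
        adjusted = build_network(corr, fdr=True)
        assert {frozenset(e) for e in adjusted.edges()} <= {frozenset(e) for e in plain.edges()}


class TestEstimatorAndExport:
    def test_builder_fit_attributes(self, planted_table):
        table, truth = planted_table
        builder = SpearmanNetworkBuilder().fit(table)
        assert builder.n_edges_ == builder.network_.number_of_edges()
        assert builder.n_nodes_ > 0
        assert builder.correlation_.n_samples == table.n_samples

    def test_edge_list_and_graph_roundtrip(self, tmp_path, planted_table):
        table, _ = planted_table
        G = SpearmanNetworkBuilder().fit(table).network_
        write_edge_list(G, tmp_path / "edges.csv")
        edges = pd.read_csv(tmp_path / "edges.csv")
        assert len(edges) == G.number_of_edges()
        assert set(edges.columns) == {"source", "target", "r", "p", "sign"}
        for fmt, reader in [("gexf", nx.read_gexf), ("graphml", nx.read_graphml)]:
            path = tmp_path / f"net.{fmt}"
            write_graph(G, path)
            back = reader(path)
            assert back.number_of_edges() == G.number_of_edges()
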