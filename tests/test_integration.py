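"""Correlation, three-gate pair building, counts, novelty and network export."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from iugrnet.integration import (
    build_pairs,
    classify_novel,
    correlate,
    count_targets_per_mirna,
    export_network,
)


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        x = np.arange(6.0)
        mir = pd.DataFrame([x], index=["m1"], columns=[f"S{i}" for i in range(6)])
        mrna = pd.DataFrame([-x], index=["p1"], columns=[f"S{i}" for i in range(6)])
        out = correlate(mir, mrna)
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_constant_vector_excluded_with_warning(self):
        cols = [f"S{i}" for i in range(6)]
        mir = pd.DataFrame([[1.0] * 6, np.arange(6.0)], index=["m0", "m1"], columns=cols)
        mrna = pd.DataFrame([np.arange(6.0)], index=["p1"], columns=cols)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlate(mir, mrna)
        assert set(out["mirna_id"]) == {"m1"}

    def test_sample_mismatch_rejected(self):
        mir = pd.DataFrame([[1, 2, 3]], index=["m1"], columns=["a", "b", "c"])
        mrna = pd.DataFrame([[1, 2, 3]], index=["p1"], columns=["a", "b", "d"])
        with pytest.raises(ValueError, match="sample columns"):
            correlate(mir, mrna)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        cols = [f"S{i}" for i in range(10)]
        mir = pd.DataFrame(rng.normal(size=(3, 10)), index=list("abc"), columns=cols)
        mrna = pd.DataFrame(rng.normal(size=(4, 10)), index=list("wxyz"), columns=cols)
        base = correlate(mir, mrna)["r"].to_numpy()
        scaled = correlate(mir * 3.2 + 1.0, mrna * -0.5 + 7.0)["r"].to_numpy()
        assert np.allclose(np.abs(base), np.abs(scaled))
        assert np.allclose(scaled, -base)  # negative rescale flips sign


@pytest.fixture
def pair_inputs():
    de_mirna = pd.DataFrame(
        {
            "probe_id": ["m_up", "m_down"],
            "direction": ["up", "down"],
            "significant": [True, True],
        }
    )
    de_genes = pd.DataFrame(
        {
            "gene_id": ["g_dn", "g_up"],
            "probe_id": ["p_dn", "p_up"],
            "direction": ["down", "up"],
            "significant": [True, True],
        }
    )
    hits = pd.DataFrame(
        {
            "mirna_id": ["m_up", "m_up", "m_down"],
            "gene_id": ["g_dn", "g_up", "g_up"],
            "mfe": [-30.0, -28.0, -26.0],
        }
    )
    corr = pd.DataFrame(
        {
            "mirna_id": ["m_up", "m_up", "m_down", "m_down"],
            "probe_id": ["p_dn", "p_up", "p_dn", "p_up"],
            "r": [-0.9, -0.8, -0.7, -0.25],
        }
    )
    return de_mirna, de_genes, hits, corr


class TestBuildPairs:
    def test_three_gates_conjunction(self, pair_inputs):
        de_mirna, de_genes, hits, corr = pair_inputs
        pairs = build_pairs(de_mirna, de_genes, hits, corr)
        # (m_up, g_dn): all gates pass.  (m_down, g_up): hit but r=-0.25 fails.
        # (m_up, g_up): same direction, never considered despite hit and r.
        assert list(zip(pairs["mirna_id"], pairs["gene_id"])) == [("m_up", "g_dn")]
        row = pairs.iloc[0]
        assert row["r"] <= -0.3 and row["mfe"] == -30.0
        assert row["mirna_direction"] != row["gene_direction"]

    def test_correlation_without_hit_excluded(self, pair_inputs):
        de_mirna, de_genes, _, corr = pair_inputs
        no_hits = pd.DataFrame(columns=["mirna_id", "gene_id", "mfe"])
        pairs = build_pairs(de_mirna, de_genes, no_hits, corr)
        assert len(pairs) == 0

    def test_inclusive_threshold_boundary(self, pair_inputs):
        de_mirna, de_genes, hits, corr = pair_inputs
        corr.loc[corr["probe_id"] == "p_dn", "r"] = -0.3
        pairs = build_pairs(de_mirna, de_genes, hits, corr)
        assert len(pairs) == 1  # r == -0.3 kept (inclusive)

    def test_sorted_by_mirna_then_r(self, small_bundle_pairs):
        pairs = small_bundle_pairs
        key = list(zip(pairs["mirna_id"], pairs["r"]))
        assert key == sorted(key)

    def test_surviving_pairs_match_independence_product(self):
        # with random gates, E[survivors] = n * P(hit) * P(r <= t)
        rng = np.random.default_rng(4)
        n_mir, n_gene = 12, 40
        de_mirna = pd.DataFrame(
            {
                "probe_id": [f"m{i}" for i in range(n_mir)],
                "direction": ["up"] * (n_mir // 2) + ["down"] * (n_mir // 2),
                "significant": True,
            }
        )
        de_genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_gene)],
                "probe_id": [f"p{i}" for i in range(n_gene)],
                "direction": ["up"] * (n_gene // 2) + ["down"] * (n_gene // 2),
                "significant": True,
            }
        )
        p_hit = 0.3
        hit_rows = [
            {"mirna_id": m, "gene_id": g, "mfe": -26.0}
            for m in de_mirna["probe_id"]
            for g in de_genes["gene_id"]
            if rng.random() < p_hit
        ]
        r_vals = rng.uniform(-1, 1, n_mir * n_gene)
        corr = pd.DataFrame(
            {
                "mirna_id": np.repeat(de_mirna["probe_id"].to_numpy(), n_gene),
                "probe_id": np.tile(de_genes["probe_id"].to_numpy(), n_mir),
                "r": r_vals,
            }
        )
        pairs = build_pairs(de_mirna, de_genes, pd.DataFrame(hit_rows), corr)
        n_scanned = 2 * (n_mir // 2) * (n_gene // 2)
        expected = n_scanned * p_hit * 0.35  # P(U(-1,1) <= -0.3)
        assert abs(len(pairs) - expected) <= 3 * np.sqrt(expected)


@pytest.fixture(scope="session")
def small_bundle_pairs(small_bundle):
    """Pairs built from the small synthetic bundle using truth directions."""
    truth = small_bundle.truth
    de_mirna = pd.DataFrame(
        {
            "probe_id": list(truth.de_mirna),
            "direction": list(truth.de_mirna.values()),
            "significant": True,
        }
    )
    gene_probe = {g: p for p, g in truth.gene_map.items()}
    de_genes = pd.DataFrame(
        {
            "gene_id": [truth.gene_map[p] for p in truth.de_mrna],
            "probe_id": list(truth.de_mrna),
            "direction": list(truth.de_mrna.values()),
            "significant": True,
        }
    )
    hits = pd.DataFrame(
        [
            {"mirna_id": m, "gene_id": g, "mfe": -30.0}
            for m, g in truth.planted_pairs
        ]
    )
    corr = correlate(
        small_bundle.mirna.values.loc[de_mirna["probe_id"]],
        small_bundle.mrna.values.loc[de_genes["probe_id"]],
    )
    return build_pairs(de_mirna, de_genes, hits, corr)


class TestCountsAndNovelty:
    def test_counts_deduplicate_genes(self):
        pairs = pd.DataFrame(
            {
                "mirna_id": ["m1", "m1", "m1", "m2"],
                "gene_id": ["g1", "g1", "g2", "g1"],
            }
        )
        counts = count_targets_per_mirna(pairs)
        assert dict(zip(counts["mirna_id"], counts["n_targets"])) == {"m1": 2, "m2": 1}
        assert counts.iloc[0]["mirna_id"] == "m1"  # ranked descending

    def test_count_sum_equals_distinct_pairs(self, small_bundle_pairs):
        counts = count_targets_per_mirna(small_bundle_pairs)
        distinct = len(set(zip(small_bundle_pairs["mirna_id"], small_bundle_pairs["gene_id"])))
        assert counts["n_targets"].sum() == distinct

    def test_empty_pairs_empty_counts(self):
        assert len(count_targets_per_mirna(pd.DataFrame(columns=["mirna_id", "gene_id"]))) == 0

    def test_novel_partition(self):
        table = classify_novel(
            ["m1", "m2", "m3", "m4"], ["m1", "m2"], ["m2", "m3"]
        )
        cats = dict(zip(table["mirna_id"], table["category"]))
        assert cats == {
            "m1": "iugr_only",
            "m2": "both",
            "m3": "muscle_only",
            "m4": "novel",
        }
        assert len(table) == 4  # partition sizes sum to the input size

    def test_all_novel_when_lists_empty(self):
        table = classify_novel(["a", "b"], [], [])
        assert set(table["category"]) == {"novel"}

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            table = classify_novel(["a", "a"], [], [])
        assert len(table) == 1


class TestNetworkExport:
    def test_counts_and_roundtrip(self, tmp_path):
        pairs = pd.DataFrame(
            {
                "mirna_id": ["m1", "m1", "m2"],
                "gene_id": ["g1", "g2", "g3"],
                "r": [-0.5, -0.6, -0.7],
                "mfe": [-30.0, -28.0, -26.0],
                "mirna_direction": ["up", "up", "down"],
                "gene_direction": ["down", "down", "up"],
            }
        )
        g = export_network(pairs, tmp_path)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 3
        back = nx.read_graphml(tmp_path / "network.graphml")
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        edge = back.edges[("m1", "g1")]
        assert edge["r"] == pytest.approx(-0.5)
        assert edge["mfe"] == pytest.approx(-30.0)
        nodes = pd.read_csv(tmp_path / "network_nodes.tsv", sep="\t")
        assert len(nodes) == 5 and set(nodes["node_type"]) == {"miRNA", "gene"}

    def test_min_abs_r_one_empties_graph(self, tmp_path):
        pairs = pd.DataFrame(
            {
                "mirna_id": ["m1"],
                "gene_id": ["g1"],
                "r": [-0.9],
                "mfe": [-30.0],
                "mirna_direction": ["up"],
                "gene_direction": ["down"],
            }
        )
        g = export_network(pairs, tmp_path, min_abs_r=1.0)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0
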