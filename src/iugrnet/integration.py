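"""Integration of DE results, duplex hits and expression anti-correlation.

A miRNA-mRNA pair survives integration only when all three gates hold:

1. the miRNA and the gene are differentially expressed in *opposite*
   directions (up-miRNA x down-gene in pass 1, down-miRNA x up-gene in
   pass 2, mirroring repression logic);
2. the gene carries a predicted duplex hit for the miRNA (MFE below
   threshold);
3. their Pearson correlation across all selected samples (both groups
   pooled) is at or below the threshold (default -0.3).

Multiple array probes mapping to one gene are collapsed to the most
significant DE probe before pairing, so target counts are per gene.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "correlate",
    "collapse_probes_to_genes",
    "build_pairs",
    "count_targets_per_mirna",
    "classify_novel",
    "export_network",
]


def correlate(mirna_values: pd.DataFrame, mrna_values: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every (miRNA probe, mRNA probe) row pair.

    Both frames must share identical sample columns (>= 3 samples); rows
    with zero variance are excluded with a warning.  Returns a long table
    (mirna_id, probe_id, r).
    """
    if list(mirna_values.columns) != list(mrna_values.columns):
        raise ValueError("sample columns of the two matrices do not match")
    n = mirna_values.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")

    def standardize(df: pd.DataFrame):
        x = df.to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        keep = sd[:, 0] > 0
        if not keep.all():
            dropped = list(df.index[~keep])
            warnings.warn(
                f"excluding zero-variance rows from correlation: {dropped}",
                stacklevel=3,
            )
        z = (x[keep] - mu[keep]) / sd[keep]
        return z, df.index[keep]

    zm, mi = standardize(mirna_values)
    zg, gi = standardize(mrna_values)
    r = zm @ zg.T / (n - 1)
    return pd.DataFrame(
        {
            "mirna_id": np.repeat(np.asarray(mi, dtype=object), len(gi)),
            "probe_id": np.tile(np.asarray(gi, dtype=object), len(mi)),
            "r": r.ravel(),
        }
    )


def collapse_probes_to_genes(de_table: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse mRNA probes to genes, keeping the most significant probe.

    Ties on p are broken by probe_id so the choice is deterministic.
    Returns the DE table with a ``gene_id`` column, one row per gene.
    """
    ann = annotation.loc[annotation["probe_class"] == "mRNA", ["probe_id", "gene_symbol"]]
    merged = de_table.merge(ann, on="probe_id", how="inner").rename(
        columns={"gene_symbol": "gene_id"}
    )
    merged = merged.sort_values(["gene_id", "p", "probe_id"], kind="stable")
    return merged.groupby("gene_id", sort=True).head(1).reset_index(drop=True)


def build_pairs(
    de_mirna: pd.DataFrame,
    de_mrna_genes: pd.DataFrame,
    hits: pd.DataFrame,
    correlations: pd.DataFrame,
    r_threshold: float = -0.3,
) -> pd.DataFrame:
    """Integrated miRNA-mRNA pair table (two opposite-direction passes).

    ``de_mirna`` and ``de_mrna_genes`` are DE tables restricted to
    significant probes/genes (columns direction, significant, probe_id /
    gene_id); ``hits`` is the duplex hit table; ``correlations`` the long
    r table keyed by (mirna_id, probe_id).  A pair is kept iff it has a hit
    and r <= r_threshold; output sorted by (mirna_id, r).
    """
    sig_mir = de_mirna.loc[de_mirna["significant"]]
    sig_gene = de_mrna_genes.loc[de_mrna_genes["significant"]]
    mir_dir = dict(zip(sig_mir["probe_id"], sig_mir["direction"]))
    gene_dir = dict(zip(sig_gene["gene_id"], sig_gene["direction"]))
    gene_probe = dict(zip(sig_gene["gene_id"], sig_gene["probe_id"]))

    rmap = {
        (m, p): r
        for m, p, r in correlations[["mirna_id", "probe_id", "r"]].itertuples(index=False)
    }
    if len(hits):
        hit_mfe = {
            (m, g): e for m, g, e in hits[["mirna_id", "gene_id", "mfe"]].itertuples(index=False)
        }
    else:
        hit_mfe = {}

    rows = []
    for passes in (("up", "down"), ("down", "up")):
        mdir, gdir = passes
        for mirna in sorted(m for m, d in mir_dir.items() if d == mdir):
            for gene in sorted(g for g, d in gene_dir.items() if d == gdir):
                if (mirna, gene) not in hit_mfe:
                    continue
                r = rmap.get((mirna, gene_probe[gene]))
                if r is None or r > r_threshold:
                    continue
                rows.append(
                    {
                        "mirna_id": mirna,
                        "gene_id": gene,
                        "r": r,
                        "mfe": hit_mfe[(mirna, gene)],
                        "mirna_direction": mdir,
                        "gene_direction": gdir,
                    }
                )
    pairs = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "r", "mfe", "mirna_direction", "gene_direction"]
    )
    return pairs.sort_values(["mirna_id", "r"], kind="stable").reset_index(drop=True)


def count_targets_per_mirna(pairs: pd.DataFrame) -> pd.DataFrame:
    """Distinct target genes per miRNA, ranked descending."""
    if not len(pairs):
        return pd.DataFrame(columns=["mirna_id", "n_targets"])
    counts = (
        pairs.groupby("mirna_id")["gene_id"].nunique().reset_index(name="n_targets")
    )
    return counts.sort_values(["n_targets", "mirna_id"], ascending=[False, True], kind="stable").reset_index(drop=True)


def classify_novel(up_mirnas, known_iugr_list, known_muscle_list) -> pd.DataFrame:
    """Partition miRNAs by prior association: both / iugr_only / muscle_only / novel."""
    ups = list(up_mirnas)
    if len(set(ups)) != len(ups):
        warnings.warn("duplicate miRNA ids in input; deduplicated", stacklevel=2)
        ups = sorted(set(ups))
    iugr, muscle = set(known_iugr_list), set(known_muscle_list)
    rows = []
    for m in sorted(ups):
        in_i, in_m = m in iugr, m in muscle
        cat = (
            "both" if in_i and in_m
            else "iugr_only" if in_i
            else "muscle_only" if in_m
            else "novel"
        )
        rows.append({"mirna_id": m, "category": cat})
    return pd.DataFrame(rows, columns=["mirna_id", "category"])


def export_network(pairs: pd.DataFrame, outdir, min_abs_r: float = 0.0):
    """Write node/edge TSVs and GraphML for the integrated pair network.

    Nodes are typed (miRNA/gene) with direction attributes; edges carry r
    and MFE.  Pairs with |r| below ``min_abs_r`` are omitted; the graph has
    no isolated nodes.  Returns the networkx graph.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kept = pairs.loc[pairs["r"].abs() >= min_abs_r]
    g = nx.Graph()
    for row in kept.itertuples(index=False):
        g.add_node(row.mirna_id, node_type="miRNA", direction=row.mirna_direction)
        g.add_node(row.gene_id, node_type="gene", direction=row.gene_direction)
        g.add_edge(row.mirna_id, row.gene_id, r=float(row.r), mfe=float(row.mfe))
    nodes = pd.DataFrame(
        [
            {"node_id": n, "node_type": d["node_type"], "direction": d["direction"]}
            for n, d in sorted(g.nodes(data=True))
        ],
        columns=["node_id", "node_type", "direction"],
    )
    edges = kept.rename(columns={"mirna_id": "source", "gene_id": "target"})
    nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False, float_format="%.6g")
    nx.write_graphml(g, outdir / "network.graphml")
    return g
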