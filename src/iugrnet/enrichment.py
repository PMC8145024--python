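"""Hypergeometric over-representation analysis with BH FDR control.

For a gene list of size n drawn from a universe of size N, a set with K
members in the universe and k members in the list is scored by the
upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).  The
universe is the set of genes that passed expression filtering (standard
ORA practice), not the whole genome.  Sets are intersected with the
universe before testing; BH adjustment runs across all tested sets and a
set is significant at fdr <= threshold (inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["hypergeom_upper_tail", "run_ora", "read_gmt", "write_gmt"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(
    gene_list,
    gene_sets: dict,
    universe,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set for over-representation of ``gene_list``.

    ``gene_sets`` maps set_id to ``(name, members)`` (or to a plain member
    list).  Results are one row per set with K >= 1 after intersection with
    the universe, sorted by p then set_id.
    """
    universe = set(universe)
    genes = set(gene_list)
    if offenders := sorted(genes - universe):
        raise ValueError(f"genes missing from the universe: {offenders}")
    N, n = len(universe), len(genes)
    rows = []
    for set_id in sorted(gene_sets):
        entry = gene_sets[set_id]
        name, members = entry if isinstance(entry, tuple) else (set_id, entry)
        in_universe = set(members) & universe
        K = len(in_universe)
        if K == 0:
            continue
        overlap = sorted(in_universe & genes)
        k = len(overlap)
        rows.append(
            {
                "set_id": set_id,
                "name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(k, K, n, N),
                "member_overlap": ";".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set_id", "name", "k", "K", "n", "N", "p", "member_overlap"]
    )
    if len(table):
        from .diffexpr import bh_adjust

        table["fdr"] = bh_adjust(table["p"].to_numpy())
    else:
        table["fdr"] = pd.Series(dtype=float)
    table["significant"] = table["fdr"] <= fdr_threshold
    return table.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict:
    """GMT file to ``{set_id: (name, members)}`` (id, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(gene_sets):
            entry = gene_sets[set_id]
            name, members = entry if isinstance(entry, tuple) else (set_id, entry)
            fh.write("\t".join([set_id, name, *members]) + "\n")
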