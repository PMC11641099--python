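"""Over-representation analysis of circRNA host genes against gene sets.

The query (host genes of expressed circRNAs) is tested against each gene
set with an upper-tail hypergeometric test, restricted to a background
universe of expressed genes: with N background genes, K of them in the set,
and a query of n genes overlapping the set in k, p = P[X >= k] for
X ~ Hypergeom(N, K, n).  Sets whose within-background size falls outside
[min_size, max_size] are excluded before testing; the tested sets are
Benjamini-Hochberg adjusted.

Significant sets are then grouped into clusters: two sets are connected
when the Jaccard index of their within-background memberships reaches a
threshold, and connected components with fewer than three sets are dropped.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust


def ora(
    query_genes: set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
    min_size: int = 5,
    max_size: int = 400,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query."""
    if not background:
        raise ValueError("background universe is empty")
    query = set(query_genes) & background
    dropped = len(set(query_genes)) - len(query)
    if dropped:
        warnings.warn(
            f"{dropped} query genes outside the background were dropped",
            stacklevel=2,
        )
    N, n = len(background), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & background
        K = len(members)
        if K < min_size or K > max_size:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "pvalue": p})
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "pvalue"])
    if len(df):
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["padj"] = pd.Series(dtype=float)
    return df.sort_values(["padj", "set_name"], kind="mergesort").reset_index(drop=True)


def cluster_terms(
    results: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    background: set[str],
    jaccard_cut: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group significant sets into connected components by Jaccard overlap.

    Components with fewer than three sets are removed; each surviving
    cluster is labelled by its lexicographically smallest member.
    """
    sig = sorted(results.loc[results["padj"] < alpha, "set_name"])
    members = {s: gene_sets[s] & background for s in sig}
    parent = {s: s for s in sig}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(sig):
        for b in sig[i + 1 :]:
            u = members[a] | members[b]
            if not u:
                continue
            jac = len(members[a] & members[b]) / len(u)
            if jac >= jaccard_cut:
                parent[find(a)] = find(b)

    comps: dict[str, list[str]] = {}
    for s in sig:
        comps.setdefault(find(s), []).append(s)
    rows = []
    for comp in comps.values():
        if len(comp) < 3:
            continue
        label = min(comp)
        for s in sorted(comp):
            rows.append({"cluster": label, "set_name": s, "cluster_size": len(comp)})
    return (
        pd.DataFrame(rows, columns=["cluster", "set_name", "cluster_size"])
        .sort_values(["cluster", "set_name"], kind="mergesort")
        .reset_index(drop=True)
    )
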