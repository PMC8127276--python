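"""Co-expression networks and core-regulator discovery.

Differentially expressed transcription factors / epigenetic regulators act
as key nodes.  Two graphs are built from significant positive Pearson
correlations (BH FDR <= 0.01): a bipartite regulator→target network over
all genes, and a regulator–regulator graph whose maximal cliques are
enumerated (Bron-Kerbosch).  Each regulator's score is the number of
maximal cliques containing it; a clique's score is the sum of its member
scores; the clique with the highest score defines the core regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

MAX_CLIQUES = 1_000_000


def _positive_corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """One-sided p for H1: rho > 0 from the t-transform of Pearson r."""
    df = n - 2
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt(df / (1.0 - r**2))
    return stats.t.sf(t, df)


def _center_by_group(x: np.ndarray, groups: np.ndarray | None) -> np.ndarray:
    if groups is None:
        return x
    out = x.astype(float).copy()
    for g in np.unique(groups):
        m = groups == g
        out[:, m] -= out[:, m].mean(axis=1, keepdims=True)
    return out


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    za = (a - a.mean(axis=1, keepdims=True))
    zb = (b - b.mean(axis=1, keepdims=True))
    sa = np.sqrt((za**2).sum(axis=1, keepdims=True))
    sb = np.sqrt((zb**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (za @ zb.T) / (sa * sb.T)


def build_bipartite(
    expression: pd.DataFrame,
    regulators: list[str],
    fdr: float = 0.01,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Regulator→target edges at positive-correlation BH FDR <= ``fdr``.

    Correlations run across the supplied (tumor) samples; when subgroup
    labels are given each gene is centered within subgroup first so the
    co-expression is not driven by the subgroup mean shift itself.
    Returns an edge frame (regulator, target, pcc, p, p_adj).
    """
    regs = [r for r in regulators if r in expression.index]
    if not regs:
        warnings.warn("no regulator found in the expression matrix; "
                      "empty network", stacklevel=2)
        return pd.DataFrame(columns=["regulator", "target", "pcc", "p", "p_adj"])
    grp = groups.reindex(expression.columns).to_numpy() if groups is not None else None
    x = _center_by_group(expression.to_numpy(dtype=float), grp)
    xdf = pd.DataFrame(x, index=expression.index, columns=expression.columns)
    n = expression.shape[1]
    r = _corr_matrix(xdf.loc[regs].to_numpy(), xdf.to_numpy())
    p = _positive_corr_pvalues(r, n)
    reg_idx = {g: i for i, g in enumerate(expression.index)}
    mask = np.ones_like(p, dtype=bool)
    for i, rg in enumerate(regs):
        mask[i, reg_idx[rg]] = False  # no self edges
    flat_p = p[mask]
    p_adj = np.full(p.shape, np.nan)
    p_adj[mask] = bh_adjust(flat_p)
    rows = []
    genes = expression.index.to_numpy()
    for i, rg in enumerate(regs):
        keep = mask[i] & (p_adj[i] <= fdr) & (r[i] > 0)
        for j in np.flatnonzero(keep):
            rows.append((rg, genes[j], float(r[i, j]), float(p[i, j]),
                         float(p_adj[i, j])))
    return pd.DataFrame(rows, columns=["regulator", "target", "pcc", "p", "p_adj"])


def regulator_degrees(edges: pd.DataFrame) -> pd.Series:
    return edges.groupby("regulator").size().rename("degree")


@dataclass
class CliqueAnalysis:
    graph: nx.Graph
    cliques: list[tuple[str, ...]]
    regulator_score: dict[str, int]
    clique_score: list[int]
    core_clique: tuple[str, ...]
    core_regulators: list[str]


def regulator_graph(
    expression: pd.DataFrame,
    fdr: float = 0.01,
    groups: pd.Series | None = None,
) -> nx.Graph:
    """Regulator–regulator graph by the positive-correlation BH rule."""
    if expression.shape[0] < 2:
        raise ValueError("need >= 2 regulators")
    grp = groups.reindex(expression.columns).to_numpy() if groups is not None else None
    x = _center_by_group(expression.to_numpy(dtype=float), grp)
    n = expression.shape[1]
    r = _corr_matrix(x, x)
    p = _positive_corr_pvalues(r, n)
    iu = np.triu_indices(len(x), k=1)
    p_adj = bh_adjust(p[iu])
    g = nx.Graph()
    names = list(expression.index)
    g.add_nodes_from(names)
    for (i, j), q in zip(zip(*iu), p_adj):
        if q <= fdr and r[i, j] > 0:
            g.add_edge(names[i], names[j], pcc=float(r[i, j]), p_adj=float(q))
    return g


def clique_analysis(graph: nx.Graph, all_cliques: bool = False) -> CliqueAnalysis:
    """Score maximal cliques and pick the core-regulator clique.

    Ties on the clique score resolve to the larger clique, then to the
    lexicographically smallest member set, so the result is deterministic.
    ``all_cliques=True`` scores every clique of size >= 2 instead of the
    maximal ones (sensitivity analysis).
    """
    if all_cliques:
        cliques = [
            tuple(sorted(c))
            for c in nx.enumerate_all_cliques(graph)
            if len(c) >= 2
        ]
        if not cliques:  # edgeless graph: fall back to singletons
            cliques = [(v,) for v in sorted(graph.nodes)]
    else:
        cliques = []
        for c in nx.find_cliques(graph):
            cliques.append(tuple(sorted(c)))
            if len(cliques) > MAX_CLIQUES:
                raise RuntimeError(
                    f"more than {MAX_CLIQUES} maximal cliques; graph too dense"
                )
    cliques.sort()
    score = {v: 0 for v in graph.nodes}
    for c in cliques:
        for v in c:
            score[v] += 1
    clique_scores = [sum(score[v] for v in c) for c in cliques]
    order = sorted(
        range(len(cliques)),
        key=lambda i: (-clique_scores[i], -len(cliques[i]), cliques[i]),
    )
    best = order[0] if order else None
    core = cliques[best] if best is not None else tuple()
    return CliqueAnalysis(
        graph=graph,
        cliques=cliques,
        regulator_score=score,
        clique_score=clique_scores,
        core_clique=core,
        core_regulators=list(core),
    )


def core_regulators(
    expression: pd.DataFrame,
    fdr: float = 0.01,
    groups: pd.Series | None = None,
    all_cliques: bool = False,
) -> CliqueAnalysis:
    """Full pipeline on a regulator expression submatrix."""
    return clique_analysis(
        regulator_graph(expression, fdr=fdr, groups=groups),
        all_cliques=all_cliques,
    )
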