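"""Compositionally aware co-occurrence networks.

Correlations among genome abundances are estimated with the SparCC
procedure (log-ratio variation matrix plus a sparsity assumption), which
avoids the spurious negative correlations induced by compositional
closure. Strong positive associations form an undirected network whose
Louvain modularity classes are mapped to the disturbance regime each
module dominates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _sparcc_single(fractions: np.ndarray, exclusion_iterations: int,
                   exclusion_threshold: float) -> np.ndarray:
    """One SparCC basis-correlation estimate from a sample x genome
    fraction matrix.

    The variation matrix ``t_ij = var(log(x_i / x_j))`` relates to the
    basis variances ``w`` by ``t_ij = w_i + w_j - 2 cov_ij``; under the
    sparsity assumption the covariance terms are negligible in the row
    sums, giving a linear system for ``w``. The most strongly correlated
    pair is iteratively excluded from the approximation while its
    correlation exceeds the exclusion threshold.
    """
    logs = np.log(fractions)
    n_genomes = logs.shape[1]
    cov = np.cov(logs, rowvar=False)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov  # variation matrix

    included = np.ones((n_genomes, n_genomes), dtype=bool)
    np.fill_diagonal(included, False)

    def solve_basis() -> np.ndarray:
        m = included.astype(float)
        np.fill_diagonal(m, included.sum(axis=1))
        rhs = (t * included).sum(axis=1)
        w, *_ = np.linalg.lstsq(m, rhs, rcond=None)
        return np.maximum(w, 1e-12)

    def correlations(w: np.ndarray) -> np.ndarray:
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    w = solve_basis()
    rho = correlations(w)
    for _ in range(exclusion_iterations):
        masked = np.abs(rho) * included
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        if included.sum(axis=1).min() < 2:
            break  # keep the system overdetermined
        w = solve_basis()
        rho = correlations(w)
    return rho


def sparcc_correlations(counts: pd.DataFrame, n_resample: int = 20,
                        exclusion_iterations: int = 10,
                        exclusion_threshold: float = 0.1,
                        seed: int = 0,
                        pseudocount: float = 0.5) -> pd.DataFrame:
    """SparCC correlation estimate for a sample x genome count table.

    Per resample, fractions are drawn from per-sample Dirichlet
    posteriors with a flat pseudocount of 0.5 per cell (zero
    replacement), converted to log-ratios, and solved for basis
    correlations; the final estimate is the elementwise median across
    resamples, with an exact unit diagonal.
    """
    if counts.shape[1] < 4:
        raise ValueError("SparCC needs >= 4 genomes (basis system solvable)")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    absent = counts.columns[arr.sum(axis=0) == 0]
    if len(absent):
        raise ValueError("genomes absent from all samples: "
                         + ", ".join(map(str, absent)))
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_resample, counts.shape[1], counts.shape[1]))
    alpha = arr + pseudocount
    for b in range(n_resample):
        fractions = np.vstack([rng.dirichlet(a) for a in alpha])
        estimates[b] = _sparcc_single(fractions, exclusion_iterations,
                                      exclusion_threshold)
    rho = np.median(estimates, axis=0)
    rho = (rho + rho.T) / 2
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)


def build_network(correlations: pd.DataFrame, r_min: float = 0.20,
                  positive_only: bool = True) -> nx.Graph:
    """Thresholded association network.

    Edges connect pairs with correlation >= ``r_min`` (inclusive;
    positive associations only by default, absolute value otherwise).
    Isolated nodes are retained.
    """
    rho = correlations.to_numpy(dtype=float)
    if not np.allclose(rho, rho.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    g = nx.Graph()
    nodes = list(correlations.index)
    g.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            val = rho[i, j]
            keep = (val >= r_min) if positive_only else (abs(val) >= r_min)
            if keep:
                g.add_edge(nodes[i], nodes[j], weight=float(val))
    return g


@dataclass
class ModuleResult:
    modules: dict[str, int]   # node -> module id
    q: float                  # modularity of the returned partition
    partition: list[set]


def modularity_q(graph: nx.Graph, partition: list[set]) -> float:
    """Newman's weighted modularity Q of a partition (exact evaluation)."""
    return nx.community.modularity(graph, partition, weight="weight")


def louvain_modules(graph: nx.Graph, resolution: float = 1.0,
                    seed: int = 0) -> ModuleResult:
    """Louvain modularity maximisation (seeded, deterministic).

    An edgeless graph yields singleton modules with Q = 0 and a warning.
    """
    if graph.number_of_edges() == 0:
        warnings.warn("edgeless graph: every node is its own module, Q = 0")
        partition = [{n} for n in graph.nodes]
        modules = {n: i for i, n in enumerate(graph.nodes)}
        return ModuleResult(modules=modules, q=0.0, partition=partition)
    partition = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed)
    partition = [set(c) for c in partition]
    modules = {}
    for i, comm in enumerate(sorted(partition, key=lambda c: sorted(c)[0])):
        for node in comm:
            modules[node] = i
    q = modularity_q(graph, partition)
    return ModuleResult(modules=modules, q=float(q), partition=partition)


REGIME_ORDER = ("undisturbed", "intermediate", "press")


def module_regime_association(modules: dict[str, int],
                              rel_abundance: pd.DataFrame,
                              regimes: pd.Series) -> pd.DataFrame:
    """Label each module by the regime where its summed member abundance
    is on average highest. Ties are broken by regime order (undisturbed <
    intermediate < press) and flagged."""
    regimes = regimes.loc[rel_abundance.index]
    rows = []
    for module_id in sorted(set(modules.values())):
        members = [n for n, m in modules.items() if m == module_id]
        if not members:
            raise ValueError(f"module {module_id} is empty")
        missing = [m for m in members if m not in rel_abundance.columns]
        if missing:
            raise ValueError(
                f"module {module_id} genomes absent from abundance table: "
                + ", ".join(missing))
        summed = rel_abundance[members].sum(axis=1)
        means = {r: summed[regimes == r].mean() for r in REGIME_ORDER
                 if (regimes == r).any()}
        best = max(means.values())
        winners = [r for r in REGIME_ORDER if r in means
                   and means[r] >= best - 1e-15]
        label = winners[0]
        ordered = sorted(means.values(), reverse=True)
        margin = ordered[0] - ordered[1] if len(ordered) > 1 else np.nan
        rows.append({
            "module": module_id, "regime": label, "margin": margin,
            "tie": len(winners) > 1, "n_members": len(members),
            **{f"mean_{r}": means.get(r, np.nan) for r in REGIME_ORDER},
        })
    return pd.DataFrame(rows).set_index("module")


def export_network(graph: nx.Graph, modules: dict[str, int] | None,
                   outdir: Path | str, layout_seed: int = 0) -> dict[str, Path]:
    """Write the network as GraphML and a TSV edge list, plus optional
    module table and Fruchterman-Reingold layout coordinates (cosmetic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = graph.copy()
    if modules is not None:
        nx.set_node_attributes(g, modules, "module")
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    paths = {}
    graphml = outdir / "network.graphml"
    nx.write_graphml(g, graphml)
    paths["graphml"] = graphml
    edges = pd.DataFrame(
        [{"source": u, "target": v, "weight": d["weight"]}
         for u, v, d in g.edges(data=True)]
    )
    edge_path = outdir / "edges.tsv"
    edges.to_csv(edge_path, sep="\t", index=False)
    paths["edges"] = edge_path
    if modules is not None:
        mod_path = outdir / "modules.tsv"
        pd.Series(modules, name="module").rename_axis("node").to_csv(
            mod_path, sep="\t")
        paths["modules"] = mod_path
    pos = nx.spring_layout(g, seed=layout_seed)
    layout = pd.DataFrame(pos, index=["x", "y"]).T.rename_axis("node")
    layout_path = outdir / "layout.tsv"
    layout.to_csv(layout_path, sep="\t", float_format="%.6g")
    paths["layout"] = layout_path
    return paths
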