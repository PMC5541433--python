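"""Genus co-occurrence networks from Spearman correlation.

Adjacency is Spearman's rank correlation between taxa (average ranks for
ties). Significance comes from margin permutations: each of the >= 999
permutation rounds shuffles the sample order of one side of the rank
matrix, giving a null correlation for every pair simultaneously; p-values
are BH-adjusted per matrix. Edges pass ``|rho| >= min_abs_rho`` and
``q <= max_q`` (both CLI-exposed; the thresholds are conventional defaults,
not derived from any reference dataset). Compositionality correction is
not applied — correlations are computed on relative abundances as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .tablesio import AbundanceTable, SampleMetadata, to_relative

logger = logging.getLogger(__name__)

__all__ = [
    "SpearmanResult",
    "spearman_matrix",
    "filter_taxa",
    "build_network",
    "network_density",
    "network_centralization",
    "largest_component",
    "neighbors_of",
    "temporal_networks",
    "network_metrics",
    "write_edge_list",
]


@dataclass
class SpearmanResult:
    """Pairwise Spearman matrix with permutation p and BH q values."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    seed: int
    n_permutations: int
    excluded_taxa: list


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, AbundanceTable):
        return table.data
    return table


def spearman_matrix(
    table, n_permutations: int = 999, seed: int = 0
) -> SpearmanResult:
    """All-pairs Spearman rho with permutation p-values.

    Constant taxa have undefined rank correlation; their rows/columns are
    NaN and they are reported in ``excluded_taxa`` (and logged).
    """
    df = _as_frame(table)
    values = df.to_numpy(dtype=float)
    t, s = values.shape
    if s < 4:
        raise ValueError("need at least 4 samples for rank correlation")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    ranks = rankdata(values, axis=1)
    sd = ranks.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning(
            "excluding %d constant taxa from correlation: %s",
            const.sum(), df.index[const].tolist(),
        )
    Z = np.zeros_like(ranks)
    ok = ~const
    Z[ok] = (ranks[ok] - ranks[ok].mean(axis=1, keepdims=True)) / sd[ok, None]

    rho = Z @ Z.T / s
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))

    rng = np.random.default_rng(seed)
    exceed = np.zeros((t, t), dtype=np.int64)
    abs_obs = np.abs(rho) - 1e-12
    for _ in range(n_permutations):
        perm = rng.permutation(s)
        null = Z @ Z[:, perm].T / s
        exceed += np.abs(null) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.nan)

    iu = np.triu_indices(t, k=1)
    q = np.full((t, t), np.nan)
    flat_p = p[iu]
    fin = np.isfinite(flat_p)
    if fin.any():
        _, q_fin, _, _ = multipletests(flat_p[fin], method="fdr_bh")
        flat_q = np.full(flat_p.shape, np.nan)
        flat_q[fin] = q_fin
        q[iu] = flat_q
        q.T[iu] = flat_q

    idx = df.index
    return SpearmanResult(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        q=pd.DataFrame(q, index=idx, columns=idx),
        seed=seed,
        n_permutations=n_permutations,
        excluded_taxa=df.index[const].tolist(),
    )


def filter_taxa(
    table: AbundanceTable,
    min_prevalence: float = 0.5,
    min_mean_abundance: float = 0.001,
) -> AbundanceTable:
    """Node filter: keep taxa present in >= ``min_prevalence`` of samples
    with mean relative abundance >= ``min_mean_abundance``."""
    rel = to_relative(table)
    vals = rel.values
    prevalence = (vals > 0).mean(axis=1)
    mean_ab = vals.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_ab >= min_mean_abundance)
    return AbundanceTable(rel.data.loc[keep], kind="relative")


def build_network(
    result: SpearmanResult,
    min_abs_rho: float = 0.3,
    max_q: float = 0.05,
) -> nx.Graph:
    """Threshold a correlation matrix into a signed undirected graph.

    Nodes are all non-constant taxa; an edge (i < j) is kept iff
    ``|rho| >= min_abs_rho`` and ``q <= max_q``, with attributes ``rho``,
    ``q`` and ``sign`` ('+'/'-').
    """
    taxa = [t for t in result.rho.index if t not in set(result.excluded_taxa)]
    g = nx.Graph(min_abs_rho=min_abs_rho, max_q=max_q)
    g.add_nodes_from(taxa)
    rho = result.rho
    q = result.q
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            r = rho.at[a, b]
            qq = q.at[a, b]
            if np.isfinite(r) and np.isfinite(qq) and abs(r) >= min_abs_rho and qq <= max_q:
                g.add_edge(a, b, rho=float(r), q=float(qq), sign="+" if r > 0 else "-")
    return g


def network_density(net: nx.Graph) -> float:
    """Realized fraction of possible edges, 2E / (n(n-1))."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def network_centralization(net: nx.Graph) -> float:
    """Freeman degree centralization, sum(deg_max - deg_i)/((n-1)(n-2))."""
    n = net.number_of_nodes()
    if n < 3:
        raise ValueError("centralization undefined for fewer than 3 nodes")
    degrees = np.array([d for _, d in net.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def largest_component(net: nx.Graph) -> nx.Graph:
    """Node-induced subgraph of the largest connected component; size ties
    break toward the lexicographically smallest sorted node-id set."""
    if net.number_of_nodes() == 0:
        return nx.Graph()
    comps = [sorted(c, key=str) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), [str(x) for x in c]))
    return net.subgraph(comps[0]).copy()


def neighbors_of(net: nx.Graph, taxa: Sequence[str]) -> tuple[list, list]:
    """Neighbors of any queried taxon, split by edge sign.

    Queried ids absent from the network are warned about, not fatal.
    Returns sorted (positive, negative) neighbor lists excluding the
    queried taxa themselves.
    """
    taxa = set(taxa)
    missing = taxa - set(net.nodes)
    if missing:
        logger.warning("queried taxa not in network: %s", sorted(missing))
    pos, neg = set(), set()
    for t in taxa & set(net.nodes):
        for nb in net.neighbors(t):
            if nb in taxa:
                continue
            if net.edges[t, nb]["sign"] == "+":
                pos.add(nb)
            else:
                neg.add(nb)
    return sorted(pos), sorted(neg)


def network_metrics(net: nx.Graph) -> dict:
    """Density, centralization (NaN when undefined), mean |rho| of edges,
    node/edge counts and component sizes."""
    n = net.number_of_nodes()
    rhos = [abs(d["rho"]) for _, _, d in net.edges(data=True)]
    return {
        "n_nodes": n,
        "n_edges": net.number_of_edges(),
        "density": network_density(net) if n >= 2 else float("nan"),
        "centralization": network_centralization(net) if n >= 3 else float("nan"),
        "mean_abs_rho": float(np.mean(rhos)) if rhos else float("nan"),
        "component_sizes": sorted((len(c) for c in nx.connected_components(net)), reverse=True),
    }


def temporal_networks(
    table: AbundanceTable,
    metadata: SampleMetadata,
    periods: Sequence[int],
    group: str | None = None,
    min_samples: int = 4,
    min_abs_rho: float = 0.3,
    max_q: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
    min_prevalence: float = 0.5,
    min_mean_abundance: float = 0.001,
) -> dict:
    """Pooled-plus-per-period networks with summary metrics.

    Samples from all ``periods`` (optionally restricted to ``group``) are
    pooled into a global network; each period is then analyzed separately.
    Periods with fewer than ``min_samples`` samples are skipped with a
    warning. Returns ``{"pooled": {...}, "periods": {day: {...}}}`` where
    each entry carries the graph and its :func:`network_metrics`.
    """
    meta = metadata.data
    mask = meta["age_days"].isin(list(periods))
    if group is not None:
        mask &= meta["group"] == group
    ids = meta.loc[mask, "sample_id"].tolist()
    ids = [s for s in ids if s in table.data.columns]
    if len(ids) < min_samples:
        raise ValueError("too few samples across the requested periods")

    def _one(sample_ids, sub_seed):
        sub = filter_taxa(
            table.select_samples(sample_ids), min_prevalence, min_mean_abundance
        )
        res = spearman_matrix(sub, n_permutations=n_permutations, seed=sub_seed)
        net = build_network(res, min_abs_rho=min_abs_rho, max_q=max_q)
        info = network_metrics(net)
        info["network"] = net
        return info

    out = {"pooled": _one(ids, seed), "periods": {}}
    for day in periods:
        day_ids = [s for s in ids if int(meta.set_index("sample_id").loc[s, "age_days"]) == day]
        if len(day_ids) < min_samples:
            logger.warning("period %s has %d samples (< %d); skipped", day, len(day_ids), min_samples)
            continue
        out["periods"][int(day)] = _one(day_ids, seed + int(day))
    return out


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"taxon_a": str(a), "taxon_b": str(b), "rho": d["rho"], "q": d["q"], "sign": d["sign"]}
        for a, b, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "q", "sign"]).to_csv(
        path, sep="\t", index=False
    )
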