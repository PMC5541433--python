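"""Community statistics: alpha diversity, beta distances, permutation
tests (PERMANOVA / ANOSIM) and per-genus group comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tablesio import AbundanceTable, SampleMetadata, to_relative

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaDiversity",
    "GroupTestResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "beta_distance",
    "permanova",
    "anosim",
    "genus_kruskal",
]

_METRICS = ("braycurtis", "euclidean", "cityblock", "jaccard")


@dataclass
class AlphaDiversity:
    """Per-sample diversity: observed richness, Shannon (nats by default),
    Gini-Simpson, and bias-corrected Chao1."""

    sample_id: str
    observed: int
    shannon: float
    simpson: float
    chao1: float


@dataclass
class GroupTestResult:
    statistic: float
    p: float
    n_permutations: int
    method: str = ""


def alpha_diversity(counts: Sequence[float], sample_id: str = "", base2: bool = False) -> AlphaDiversity:
    """Diversity indices of one sample's count vector.

    shannon = -sum p*ln p (log2 optional); simpson = 1 - sum p^2;
    chao1 = S_obs + F1(F1-1)/(2(F2+1)) with F1/F2 the singleton/doubleton
    counts (bias-corrected form, defined even when F2 = 0).
    """
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError(f"empty sample {sample_id!r}")
    if (c < 0).any():
        raise ValueError("negative counts")
    nz = c[c > 0]
    p = nz / nz.sum()
    log = np.log2 if base2 else np.log
    shannon = float(-(p * log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    s_obs = int(nz.size)
    f1 = int((nz == 1).sum())
    f2 = int((nz == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return AlphaDiversity(sample_id, s_obs, shannon, simpson, float(chao1))


def alpha_diversity_table(table: AbundanceTable, base2: bool = False) -> pd.DataFrame:
    if table.kind != "counts":
        raise ValueError("alpha diversity requires counts (Chao1 needs singletons)")
    rows = []
    for sid in table.sample_ids:
        a = alpha_diversity(table.data[sid].to_numpy(), sample_id=sid, base2=base2)
        rows.append(vars(a))
    return pd.DataFrame(rows).set_index("sample_id")


def beta_distance(table: AbundanceTable, metric: str = "braycurtis") -> pd.DataFrame:
    """Pairwise sample distance matrix on relative abundances."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; supported: {list(_METRICS)}")
    rel = to_relative(table)
    X = rel.values.T  # samples x taxa
    d = squareform(pdist(X, metric=metric))
    return pd.DataFrame(d, index=rel.sample_ids, columns=rel.sample_ids)


def _dist_and_labels(dist, groups) -> tuple[np.ndarray, np.ndarray]:
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    labels = np.asarray(list(groups))
    if labels.size != d.shape[0]:
        raise ValueError("group labels do not match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"singleton groups: {bad}")
    return d, labels


def _perm_label_matrix(labels: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    n = labels.size
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    return labels[order]


def permanova(
    dist, groups, n_permutations: int = 999, seed: int = 0
) -> GroupTestResult:
    """One-way PERMANOVA pseudo-F on a distance matrix.

    SS_total = sum of squared distances / N; SS_within sums per-group
    squared distances / n_g; F = (SS_among/(a-1)) / (SS_within/(N-a)).
    The p-value is from label permutations,
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations). All permutation
    statistics are computed vectorized from group-indicator quadratic forms.
    """
    d, labels = _dist_and_labels(dist, groups)
    n = labels.size
    uniq = np.unique(labels)
    a = uniq.size
    D2 = d**2
    sst = D2.sum() / (2.0 * n)

    def ss_within(label_rows: np.ndarray) -> np.ndarray:
        # label_rows: (B, n); returns SS_within per row
        out = np.zeros(label_rows.shape[0])
        for g in uniq:
            E = (label_rows == g).astype(float)
            ng = E[0].sum()
            out += np.einsum("bi,ij,bj->b", E, D2, E) / (2.0 * ng)
        return out

    ssw_obs = ss_within(labels[None, :])[0]
    ssa = sst - ssw_obs
    if ssw_obs <= 0 or sst <= 0:
        logger.warning("degenerate distance matrix (no within-group variance)")
        return GroupTestResult(float("nan"), 1.0, n_permutations, "permanova")
    f_obs = (ssa / (a - 1)) / (ssw_obs / (n - a))

    rng = np.random.default_rng(seed)
    perms = _perm_label_matrix(labels, n_permutations, rng)
    ssw_perm = ss_within(perms)
    f_perm = ((sst - ssw_perm) / (a - 1)) / (ssw_perm / (n - a))
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_permutations)
    return GroupTestResult(float(f_obs), float(p), n_permutations, "permanova")


def anosim(
    dist, groups, n_permutations: int = 999, seed: int = 0
) -> GroupTestResult:
    """ANOSIM R on rank-transformed distances with a permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2), with M
    the number of sample pairs; R is 1 when every between-group distance
    exceeds every within-group distance. (Some studies label this
    statistic "F"; it is reported here as R, ANOSIM's own symbol.)
    """
    d, labels = _dist_and_labels(dist, groups)
    n = labels.size
    condensed = squareform(d, checks=False)
    ranks = squareform(stats.rankdata(condensed), checks=False)
    m = n * (n - 1) / 2
    total = ranks.sum() / 2.0

    def r_stat(label_rows: np.ndarray) -> np.ndarray:
        within_sum = np.zeros(label_rows.shape[0])
        within_pairs = 0.0
        for g in np.unique(labels):
            E = (label_rows == g).astype(float)
            ng = E[0].sum()
            within_sum += np.einsum("bi,ij,bj->b", E, ranks, E) / 2.0
            within_pairs += ng * (ng - 1) / 2
        between_pairs = m - within_pairs
        r_w = within_sum / within_pairs
        r_b = (total - within_sum) / between_pairs
        return (r_b - r_w) / (m / 2.0)

    r_obs = r_stat(labels[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = _perm_label_matrix(labels, n_permutations, rng)
    r_perm = r_stat(perms)
    p = (1.0 + np.sum(r_perm >= r_obs - 1e-12)) / (1.0 + n_permutations)
    return GroupTestResult(float(r_obs), float(p), n_permutations, "anosim")


def genus_kruskal(
    table: AbundanceTable, metadata: SampleMetadata, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-genus Kruskal-Wallis across groups within each time point.

    BH adjustment is applied within each time point. Constant genera get
    p = 1 (logged). Returns a tidy frame with columns ``age_days``,
    ``taxon_id``, ``H``, ``p``, ``p_adj``, ``significant``.
    """
    metadata.check_covers(table)
    meta = metadata.data.set_index("sample_id")
    rows = []
    for day, day_meta in metadata.data.groupby("age_days"):
        ids = [s for s in day_meta["sample_id"] if s in table.data.columns]
        grps = day_meta.set_index("sample_id").loc[ids, "group"]
        if grps.nunique() < 2:
            logger.warning("day %s has < 2 groups; skipped", day)
            continue
        sub = table.data[ids]
        ps, hs = [], []
        for taxon in sub.index:
            vals = sub.loc[taxon]
            if np.all(vals.to_numpy() == vals.iloc[0]):
                hs.append(float("nan"))
                ps.append(1.0)
                continue
            h, p = stats.kruskal(*(vals[grps == g].to_numpy() for g in grps.unique()))
            hs.append(float(h))
            ps.append(float(p))
        _, p_adj, _, _ = multipletests(ps, method="fdr_bh")
        for taxon, h, p, pa in zip(sub.index, hs, ps, p_adj):
            rows.append(
                {"age_days": int(day), "taxon_id": taxon, "H": h, "p": p,
                 "p_adj": float(pa), "significant": bool(pa < alpha)}
            )
    return pd.DataFrame(rows, columns=["age_days", "taxon_id", "H", "p", "p_adj", "significant"])
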