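"""KO differential testing and reporter-score pathway enrichment.

Per-KO Kruskal-Wallis tests across treatment groups are BH-adjusted; each
adjusted p-value is mapped to a Z-score through the inverse normal CDF,
``z = ppf(1 - p_adj)`` (p clipped to [eps, 1-eps] so the score stays
finite). Member-KO Z-scores aggregate per pathway as ``sum(z) / sqrt(k)``,
and the aggregate is standardized against the mean and SD of the same
statistic over random size-k KO sets drawn from all tested KOs (1000 sets
by default). The standardized score is the reporter score; pathways at or
above the detection threshold (default 1.6) are called enriched.

Note the construction is significance-only: direction of change is lost in
``1 - p``. A signed variant (multiplying z by the sign of the group
difference) is available via ``signed=True`` but is a non-standard
extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tablesio import KoTable, PathwayDefinition, SampleMetadata

logger = logging.getLogger(__name__)

P_CLIP_EPS = 1e-15
DEFAULT_THRESHOLD = 1.6
DEFAULT_N_SETS = 1000

__all__ = [
    "KoTestResult",
    "ReporterScore",
    "ko_differential_test",
    "ko_zscore",
    "pathway_zscore",
    "background_correct",
    "score_pathways",
    "call_enriched_pathways",
    "pc_group_separation",
]


@dataclass
class KoTestResult:
    ko_id: str
    p_value: float
    p_adj: float
    z: float = np.nan


@dataclass
class ReporterScore:
    pathway_id: str
    k: int
    z_pathway: float
    mu_k: float
    sigma_k: float
    z_adjusted: float
    significant: bool


def _groups_to_arrays(
    table: KoTable, groups: Mapping[str, str] | SampleMetadata
) -> dict[str, np.ndarray]:
    """Column indices of each group, in table order."""
    if isinstance(groups, SampleMetadata):
        lookup = dict(zip(groups.data["sample_id"], groups.data["group"]))
    else:
        lookup = dict(groups)
    missing = [s for s in table.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    out: dict[str, list[int]] = {}
    for j, s in enumerate(table.sample_ids):
        out.setdefault(lookup[s], []).append(j)
    return {g: np.array(ix) for g, ix in out.items()}


def ko_differential_test(
    table: KoTable, groups: Mapping[str, str] | SampleMetadata
) -> list[KoTestResult]:
    """Tie-corrected Kruskal-Wallis per KO across groups, BH-adjusted.

    KOs constant across all samples get p = 1 (logged) rather than an
    exception. Z-scores are filled in from the adjusted p-values.
    """
    gidx = _groups_to_arrays(table, groups)
    if len(gidx) < 2:
        raise ValueError("need at least 2 groups")
    for g, ix in gidx.items():
        if ix.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    values = table.values
    pvals = np.empty(table.n_taxa)
    n_const = 0
    for i in range(table.n_taxa):
        row = values[i]
        if np.all(row == row[0]):
            pvals[i] = 1.0
            n_const += 1
            continue
        _, p = stats.kruskal(*(row[ix] for ix in gidx.values()))
        pvals[i] = p
    if n_const:
        logger.info("%d KOs constant across samples; p set to 1", n_const)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        KoTestResult(ko, float(p), float(pa), ko_zscore(float(pa)))
        for ko, p, pa in zip(table.ko_ids, pvals, p_adj)
    ]


def ko_zscore(p_adj: float, eps: float = P_CLIP_EPS) -> float:
    """Inverse-normal score of an adjusted p-value, ``ppf(1 - p)``, with p
    clipped to [eps, 1-eps] to keep the score finite."""
    if not 0.0 <= p_adj <= 1.0:
        raise ValueError(f"p_adj must lie in [0, 1], got {p_adj}")
    # isf(p) == ppf(1 - p) without the catastrophic cancellation near p = 1
    return float(stats.norm.isf(np.clip(p_adj, eps, 1.0 - eps)))


def pathway_zscore(z_values: Sequence[float]) -> float:
    """Aggregate member-KO Z-scores: ``sum(z) / sqrt(k)``."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("pathway has no member KOs with test results")
    return float(z.sum() / np.sqrt(z.size))


def background_correct(
    z_pathway: float,
    k: int,
    all_ko_z: Sequence[float],
    n_sets: int = DEFAULT_N_SETS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Standardize a pathway score against random same-size KO sets.

    Draws ``n_sets`` size-``k`` subsets without replacement from
    ``all_ko_z`` (one ``Generator.choice`` call per set, in order), scores
    each with :func:`pathway_zscore`, and returns their mean ``mu_k``,
    sample SD ``sigma_k`` (ddof=1) and the standardized score.
    """
    z_all = np.asarray(all_ko_z, dtype=float)
    if k > z_all.size:
        raise ValueError("k exceeds the number of tested KOs")
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.empty(n_sets)
    for b in range(n_sets):
        subset = rng.choice(z_all.size, size=k, replace=False)
        scores[b] = z_all[subset].sum() / np.sqrt(k)
    mu = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("degenerate background (sigma_k = 0); score undefined")
    return mu, sd, (z_pathway - mu) / sd


def score_pathways(
    results: Sequence[KoTestResult],
    pathways: Sequence[PathwayDefinition],
    n_sets: int = DEFAULT_N_SETS,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> list[ReporterScore]:
    """Reporter scores for every pathway with tested member KOs.

    ``k`` counts only member KOs present in ``results``. Background
    mean/SD depend only on ``k``, so they are computed once per distinct
    member count; the background for size k is drawn from a generator
    seeded with ``SeedSequence([seed, k])``. Pathways with no tested
    members are skipped with a warning.
    """
    z_by_ko = {r.ko_id: r.z for r in results}
    all_z = np.array([r.z for r in results])
    ks_needed = sorted(
        {sum(1 for ko in p.member_kos if ko in z_by_ko) for p in pathways} - {0}
    )
    background: dict[int, tuple[float, float]] = {}
    for k in ks_needed:
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        mu, sd, _ = background_correct(0.0, k, all_z, n_sets=n_sets, seed=rng)
        background[k] = (mu, sd)
    out: list[ReporterScore] = []
    for p in sorted(pathways, key=lambda p: p.pathway_id):
        members = [ko for ko in sorted(p.member_kos) if ko in z_by_ko]
        if not members:
            logger.warning("pathway %s has no tested KOs; skipped", p.pathway_id)
            continue
        zp = pathway_zscore([z_by_ko[ko] for ko in members])
        mu, sd = background[len(members)]
        z_adj = (zp - mu) / sd
        out.append(
            ReporterScore(
                pathway_id=p.pathway_id,
                k=len(members),
                z_pathway=zp,
                mu_k=mu,
                sigma_k=sd,
                z_adjusted=z_adj,
                significant=z_adj >= threshold,
            )
        )
    return out


def call_enriched_pathways(
    scores: Sequence[ReporterScore], threshold: float = DEFAULT_THRESHOLD
) -> set[str]:
    """Pathways whose reporter score meets the threshold (inclusive)."""
    return {s.pathway_id for s in scores if s.z_adjusted >= threshold}


def pc_group_separation(
    table: KoTable,
    groups: Mapping[str, str] | SampleMetadata,
    n_components: int = 2,
) -> dict:
    """Centered PCA on the samples x KO matrix with per-PC group t-tests.

    Returns ``{"variance_fraction": [...], "tests": {(g1, g2): [p per PC]}}``
    where variance fractions cover the full rank and tests cover the first
    ``n_components`` PCs for every group pair (classic equal-variance
    two-sample t-test).
    """
    gidx = _groups_to_arrays(table, groups)
    if len(gidx) < 2:
        raise ValueError("need at least 2 groups")
    X = table.values.T  # samples x KOs
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    scores = U * S  # samples x PCs
    labels = sorted(gidx)
    tests: dict[tuple[str, str], list[float]] = {}
    npc = min(n_components, scores.shape[1])
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            g1, g2 = labels[a], labels[b]
            ps = []
            for pc in range(npc):
                _, p = stats.ttest_ind(scores[gidx[g1], pc], scores[gidx[g2], pc])
                ps.append(float(p))
            tests[(g1, g2)] = ps
    return {"variance_fraction": var_frac.tolist(), "tests": tests}


def results_to_frame(results: Sequence[KoTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"ko_id": r.ko_id, "p_value": r.p_value, "p_adj": r.p_adj, "z": r.z} for r in results]
    )


def scores_to_frame(scores: Sequence[ReporterScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": s.pathway_id,
                "k": s.k,
                "z_pathway": s.z_pathway,
                "mu_k": s.mu_k,
                "sigma_k": s.sigma_k,
                "z_adjusted": s.z_adjusted,
                "significant": s.significant,
            }
            for s in scores
        ]
    )
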