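"""Synthetic cohorts with known ground truth.

Three generators back the test and acceptance suites:

* :func:`generate_cohort` — longitudinal count tables in which a subset of
  taxa follow logistic age trajectories, time-warped per treatment group
  (warp > 1 matures faster, < 1 slower), with log-normal sample noise and
  multinomial count draws at fixed depth.
* :func:`generate_ko_study` — KO tables with designated pathways whose
  member KOs are shifted in one group by a known multiplicative effect.
* :func:`generate_correlated_block` — taxa blocks sharing a latent monotone
  factor with a target Spearman correlation, for network recovery tests.

Samples are generated independently; within-subject longitudinal
correlation is deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tablesio import AbundanceTable, KoTable, PathwayDefinition, SampleMetadata

__all__ = [
    "TaxonTrajectory",
    "CohortConfig",
    "KoStudyConfig",
    "taxon_expected_abundance",
    "make_default_trajectories",
    "generate_cohort",
    "generate_ko_study",
    "generate_correlated_block",
]


@dataclass(frozen=True)
class TaxonTrajectory:
    """Logistic expected-abundance trajectory of one taxon over host age.

    Expected abundance at age ``t`` under time-warp ``w`` is
    ``baseline + amplitude * sigmoid(rate * (w*t - midpoint_day))``, clipped
    at zero. ``direction`` is redundant with the sign of ``amplitude`` and
    validated against it.
    """

    taxon_id: str
    baseline: float
    amplitude: float
    midpoint_day: float
    rate: float
    direction: str = "increasing"

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError(f"{self.taxon_id}: baseline must be non-negative")
        if self.rate <= 0:
            raise ValueError(f"{self.taxon_id}: rate must be positive")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"{self.taxon_id}: bad direction {self.direction!r}")
        if self.amplitude > 0 and self.direction == "decreasing":
            raise ValueError(f"{self.taxon_id}: positive amplitude but decreasing")
        if self.amplitude < 0 and self.direction == "increasing":
            raise ValueError(f"{self.taxon_id}: negative amplitude but increasing")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic longitudinal cohort.

    ``groups`` maps each label to its time-warp factor gamma (> 0); gamma 2
    reaches any given maturation state in half the chronologic time.
    ``maturation_end_day`` is the day by which age trajectories are ~95%
    saturated under warp 1 — i.e. the engineered plateau of the unwarped
    group.
    """

    n_taxa: int = 40
    n_age_taxa: int = 12
    sampling_days: tuple = (1, 7, 28, 42)
    n_per_day: int = 6
    groups: tuple = (("control", 1.0),)
    noise_sd: float = 0.3
    depth: int = 2490
    seed: int = 0
    maturation_end_day: float = 30.0

    def __post_init__(self) -> None:
        if self.n_age_taxa > self.n_taxa:
            raise ValueError("n_age_taxa must be <= n_taxa")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        days = list(self.sampling_days)
        if any(d < 1 for d in days) or sorted(set(days)) != days:
            raise ValueError("sampling_days must be strictly increasing and >= 1")
        for label, warp in self.groups:
            if warp <= 0:
                raise ValueError(f"group {label!r}: warp must be positive")
        if self.maturation_end_day <= 0:
            raise ValueError("maturation_end_day must be positive")


@dataclass(frozen=True)
class KoStudyConfig:
    """Configuration of a synthetic two-group KO study."""

    n_kos: int = 400
    n_pathways: int = 40
    kos_per_pathway: int = 10
    enriched_pathways: tuple = ()
    effect_size: float = 2.0
    n_samples_per_group: int = 10
    seed: int = 0
    group_labels: tuple = ("control", "treatment")

    def __post_init__(self) -> None:
        if self.kos_per_pathway * self.n_pathways > self.n_kos:
            raise ValueError("pathways require more KOs than n_kos provides")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        known = {_pathway_id(i) for i in range(self.n_pathways)}
        unknown = set(self.enriched_pathways) - known
        if unknown:
            raise ValueError(f"enriched pathways not defined: {sorted(unknown)}")
        if len(self.group_labels) != 2:
            raise ValueError("exactly two group labels expected")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def taxon_expected_abundance(
    traj: TaxonTrajectory, age_days: float, warp: float = 1.0
) -> float:
    """Expected (noise-free) abundance of ``traj`` at ``age_days`` under ``warp``.

    Satisfies the warp identity exactly: value at age t under warp g equals
    the value at age g*t under warp 1.
    """
    if warp <= 0:
        raise ValueError("warp must be positive")
    if age_days < 0:
        raise ValueError("age_days must be non-negative")
    val = traj.baseline + traj.amplitude * _sigmoid(
        traj.rate * (warp * age_days - traj.midpoint_day)
    )
    return float(max(val, 0.0))


def _pathway_id(i: int) -> str:
    return f"pw{i:03d}"


def make_default_trajectories(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[TaxonTrajectory], list[str]]:
    """Build age-taxon trajectories plus constant baselines for the rest.

    Midpoints are spread over the first ~60% of ``maturation_end_day`` and
    rates chosen so each logistic is ~99% saturated at that day; half of the
    age taxa decrease with age. Background taxa get long-tailed constant
    baselines so importance ranking faces realistic competition.

    Returns (trajectories for every taxon, ids of the age-tracking taxa).
    """
    T = config.maturation_end_day
    trajs: list[TaxonTrajectory] = []
    age_ids: list[str] = []
    for i in range(config.n_age_taxa):
        tid = f"age{i:03d}"
        age_ids.append(tid)
        mid = float(rng.uniform(0.15 * T, 0.60 * T))
        rate = 4.6 / (T - mid)  # sigmoid(4.6) ~ 0.99 at day T
        amp = float(rng.lognormal(mean=1.0, sigma=0.5))
        if i % 2 == 0:
            trajs.append(
                TaxonTrajectory(tid, baseline=0.05 * amp, amplitude=amp,
                                midpoint_day=mid, rate=rate, direction="increasing")
            )
        else:
            trajs.append(
                TaxonTrajectory(tid, baseline=1.1 * amp, amplitude=-amp,
                                midpoint_day=mid, rate=rate, direction="decreasing")
            )
    for i in range(config.n_taxa - config.n_age_taxa):
        tid = f"bg{i:03d}"
        base = float(rng.lognormal(mean=0.0, sigma=1.2))
        trajs.append(
            TaxonTrajectory(tid, baseline=base, amplitude=0.0,
                            midpoint_day=1.0, rate=1.0, direction="increasing")
        )
    return trajs, age_ids


def generate_cohort(
    config: CohortConfig,
    trajectories: Sequence[TaxonTrajectory] | None = None,
) -> tuple[AbundanceTable, SampleMetadata, dict]:
    """Simulate a longitudinal count cohort.

    For each group/day, expected abundances are evaluated from the (warped)
    trajectories, perturbed by per-sample multiplicative log-normal noise,
    closed to a composition and drawn as multinomial counts at
    ``config.depth``. Returns the count table, metadata, and a truth dict
    with per-group warps and the age-taxon ids.
    """
    rng = np.random.default_rng(config.seed)
    if trajectories is None:
        trajectories, age_ids = make_default_trajectories(config, rng)
    else:
        trajectories = list(trajectories)
        age_ids = [t.taxon_id for t in trajectories if t.amplitude != 0]
    if config.n_per_day < 1 or not config.sampling_days or not config.groups:
        raise ValueError("cohort would contain zero samples")

    taxon_ids = [t.taxon_id for t in trajectories]
    columns: dict[str, np.ndarray] = {}
    rows = []
    for label, warp in config.groups:
        for day in config.sampling_days:
            expected = np.array(
                [taxon_expected_abundance(t, day, warp) for t in trajectories]
            )
            for r in range(config.n_per_day):
                noisy = expected * np.exp(
                    rng.normal(0.0, config.noise_sd, size=len(trajectories))
                )
                total = noisy.sum()
                if total <= 0:
                    raise ValueError("all-zero expected composition")
                counts = rng.multinomial(config.depth, noisy / total)
                sid = f"{label}-d{day:02d}-r{r:02d}"
                columns[sid] = counts
                rows.append(
                    {"sample_id": sid, "subject_id": f"{label}-s{r:02d}",
                     "group": label, "age_days": int(day)}
                )

    table = AbundanceTable(
        pd.DataFrame(columns, index=pd.Index(taxon_ids, name="#ID")), kind="counts"
    )
    meta = SampleMetadata(pd.DataFrame(rows))
    truth = {
        "warp": {label: warp for label, warp in config.groups},
        "age_taxa": list(age_ids),
        "maturation_end_day": config.maturation_end_day,
        "depth": config.depth,
    }
    return table, meta, truth


def generate_ko_study(
    config: KoStudyConfig,
) -> tuple[KoTable, SampleMetadata, list[PathwayDefinition], dict]:
    """Simulate a two-group KO abundance study with planted enrichment.

    Every KO draws i.i.d. log-normal abundances around a KO-specific mean;
    KOs belonging to an enriched pathway have that mean multiplied by
    ``effect_size`` in the second group only. ``effect_size == 1`` is the
    null. Pathways partition the first ``n_pathways * kos_per_pathway`` KOs.
    """
    rng = np.random.default_rng(config.seed)
    ko_ids = [f"K{i:05d}" for i in range(config.n_kos)]
    pathways = []
    member_of: dict[str, str] = {}
    for p in range(config.n_pathways):
        pid = _pathway_id(p)
        members = ko_ids[p * config.kos_per_pathway : (p + 1) * config.kos_per_pathway]
        pathways.append(PathwayDefinition(pid, frozenset(members)))
        for ko in members:
            member_of[ko] = pid
    enriched = set(config.enriched_pathways)

    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_kos)
    n = config.n_samples_per_group
    g0, g1 = config.group_labels
    cols: dict[str, np.ndarray] = {}
    rows = []
    for label in (g0, g1):
        for r in range(n):
            mean = base_mean.copy()
            if label == g1 and enriched:
                shift = np.array(
                    [member_of.get(k) in enriched for k in ko_ids], dtype=bool
                )
                mean[shift] *= config.effect_size
            vals = mean * np.exp(rng.normal(0.0, 0.5, size=config.n_kos))
            sid = f"{label}-r{r:02d}"
            cols[sid] = vals
            rows.append(
                {"sample_id": sid, "subject_id": sid, "group": label, "age_days": 0}
            )
    table = KoTable(
        pd.DataFrame(cols, index=pd.Index(ko_ids, name="#ID")), kind="counts"
    )
    meta = SampleMetadata(pd.DataFrame(rows))
    truth = {
        "enriched_pathways": sorted(enriched),
        "effect_size": config.effect_size,
        "shifted_group": g1,
    }
    return table, meta, pathways, truth


def generate_correlated_block(
    n_samples: int,
    block_spec: Sequence[tuple[int, str, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate taxa blocks with planted monotone dependence.

    Each ``(size, sign, strength)`` block shares a latent Gaussian factor.
    Loadings are chosen via the Gaussian-copula identity
    ``pearson = 2*sin(pi*spearman/6)`` so pairwise Spearman rho within a
    block converges to ``strength`` as n grows (exactly +-1 at strength 1).
    For ``sign == '-'`` the first taxon of the block loads positively and
    the rest negatively (a negative hub); blocks are mutually independent.

    Returns a taxa x samples DataFrame of positive abundances.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    rng = np.random.default_rng(seed)
    rows = {}
    for b, (size, sign, strength) in enumerate(block_spec):
        if size < 1:
            raise ValueError("block size must be >= 1")
        if not 0.0 <= strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if sign not in ("+", "-"):
            raise ValueError(f"bad sign {sign!r}")
        a = 2.0 * np.sin(np.pi * strength / 6.0)  # pearson needed for target spearman
        factor = rng.normal(size=n_samples)
        for t in range(size):
            load = np.sqrt(a) if (sign == "+" or t == 0) else -np.sqrt(a)
            eps = rng.normal(size=n_samples)
            latent = load * factor + np.sqrt(max(0.0, 1.0 - a)) * eps
            rows[f"b{b}t{t}"] = np.exp(latent)
    df = pd.DataFrame(rows, index=[f"s{i:03d}" for i in range(n_samples)]).T
    df.index.name = "#ID"
    return df


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
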