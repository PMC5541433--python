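"""Microbiota-age modelling and the intestinal microbiota maturation index.

The workflow mirrors the microbiota-for-age construction used for
longitudinal cohorts:

1. On the reference ("control") group, regression forests are trained
   repeatedly to rank taxa by feature importance
   (:func:`rank_taxa_by_importance`).
2. Cross-validation over nested top-k subsets picks the minimal number of
   age-discriminatory taxa (:func:`select_feature_count`).
3. A final forest on those taxa is the age model (:func:`fit_age_model`);
   its out-of-bag R^2 is the reported training fit.
4. Microbiota age is predicted for every sample
   (:func:`predict_microbiota_age`) — out-of-bag predictions are used for
   training samples to avoid optimistic curves.
5. Per group, a smoothing spline of microbiota age vs chronologic age is
   fitted and its plateau located (:func:`fit_maturity_curve`); the plateau
   value of the reference curve defines 100% maturity.
6. The maturation index of a group (:func:`compute_immi`) is the earliest
   day its curve reaches the reference full-maturity value.

Defaults follow the conventional regression-forest setup: 5000 trees,
mtry = floor(p/3), 100 importance iterations, 10-fold CV.
"""

from __future__ import annotations

import logging
import uuid
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

from .tablesio import AbundanceTable, SampleMetadata, to_relative

logger = logging.getLogger(__name__)

__all__ = [
    "AgeModelConfig",
    "AgeModel",
    "MaturityCurve",
    "ImmiResult",
    "rank_taxa_by_importance",
    "select_feature_count",
    "fit_age_model",
    "predict_microbiota_age",
    "fit_maturity_curve",
    "compute_immi",
    "run_maturity_analysis",
]


@dataclass(frozen=True)
class AgeModelConfig:
    """Hyper-parameters of the microbiota-age workflow.

    ``mtry_fraction`` is the fraction of features tried per split
    (mtry = floor(p * mtry_fraction), at least 1). ``cv_tolerance`` is the
    relative slack used to pick the minimal subset size whose CV error is
    within (1 + tolerance) of the minimum. ``cv_n_trees`` optionally uses a
    smaller forest during subset-size CV for speed (defaults to
    ``n_trees``). ``importance`` is ``"permutation"`` (default) or
    ``"impurity"``.
    """

    n_trees: int = 5000
    mtry_fraction: float = 1.0 / 3.0
    n_importance_iters: int = 100
    cv_folds: int = 10
    cv_tolerance: float = 0.05
    seed: int = 0
    importance: str = "permutation"
    cv_n_trees: int | None = None
    candidate_ks: tuple | None = None
    full_scan_max: int = 20

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.mtry_fraction <= 1:
            raise ValueError("mtry_fraction must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.importance not in ("permutation", "impurity"):
            raise ValueError("importance must be 'permutation' or 'impurity'")

    def mtry(self, p: int) -> int:
        return max(1, int(p * self.mtry_fraction))


@dataclass
class AgeModel:
    """A trained microbiota-age regressor and its selection artefacts."""

    selected_taxa: list  # [(taxon_id, mean importance)], descending
    cv_curve: dict  # subset size -> CV mean squared error
    forest: RandomForestRegressor
    train_r2: float
    training_sample_ids: list
    oob_predictions: pd.Series
    age_range: tuple
    model_id: str = field(default_factory=lambda: uuid.uuid4().hex)

    @property
    def selected_taxon_ids(self) -> list:
        return [t for t, _ in self.selected_taxa]


@dataclass
class MaturityCurve:
    """Fitted microbiota-age-vs-chronologic-age curve of one group."""

    group: str
    grid_ages: np.ndarray
    fitted_microbiota_age: np.ndarray
    plateau_age: float
    plateau_value: float
    delta: float
    model_id: str = ""

    def value_at(self, age: float) -> float:
        return float(np.interp(age, self.grid_ages, self.fitted_microbiota_age))


@dataclass
class ImmiResult:
    """Days needed to reach the reference group's full-maturity value."""

    group: str
    immi_days: float
    reference_value: float
    censored: bool = False


def _sorted_by_sample(df: pd.DataFrame, ages: Sequence) -> tuple[np.ndarray, np.ndarray, list]:
    """Canonicalize sample order so results are invariant to input order."""
    sample_ids = list(df.columns)
    order = np.argsort(np.asarray(sample_ids, dtype=object))
    ids = [sample_ids[i] for i in order]
    X = df.to_numpy(dtype=float).T[order]  # samples x taxa
    y = np.asarray(ages, dtype=float)[order]
    return X, y, ids


def _check_training_input(table: AbundanceTable, ages: Sequence, config: AgeModelConfig) -> None:
    ages = np.asarray(ages, dtype=float)
    if len(ages) != table.n_samples:
        raise ValueError("ages length does not match table samples")
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 distinct ages to train an age model")
    if table.n_samples < config.cv_folds:
        raise ValueError(
            f"fewer samples ({table.n_samples}) than cv_folds ({config.cv_folds})"
        )


def rank_taxa_by_importance(
    table: AbundanceTable, ages: Sequence, config: AgeModelConfig
) -> list[tuple[str, float]]:
    """Rank taxa by mean forest importance over repeated independently
    seeded fits.

    Each iteration trains a fresh forest of ``config.n_trees`` trees on the
    relative table and scores features by permutation importance (one
    permutation pass per iteration; impurity importance optional). Taxa are
    returned sorted by mean importance, descending; taxa whose mean
    importance is not positive are logged as non-discriminatory but kept at
    the tail of the ranking.
    """
    table = to_relative(table)
    _check_training_input(table, ages, config)
    X, y, _ = _sorted_by_sample(table.data, ages)
    p = X.shape[1]
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.n_importance_iters)
    imps = np.zeros((config.n_importance_iters, p))
    for i in range(config.n_importance_iters):
        rf = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features=config.mtry(p),
            random_state=int(seeds[2 * i]),
            n_jobs=1,
        )
        rf.fit(X, y)
        if config.importance == "impurity":
            imps[i] = rf.feature_importances_
        else:
            res = permutation_importance(
                rf, X, y, n_repeats=1,
                random_state=int(seeds[2 * i + 1]),
            )
            imps[i] = res.importances_mean
    mean_imp = imps.mean(axis=0)
    order = np.argsort(-mean_imp, kind="stable")
    ranked = [(table.taxon_ids[j], float(mean_imp[j])) for j in order]
    n_flat = sum(1 for _, v in ranked if v <= 0)
    if n_flat:
        logger.info("%d taxa have non-positive mean importance", n_flat)
    return ranked


def _candidate_subset_sizes(p: int, config: AgeModelConfig) -> list[int]:
    ks = set(range(1, min(config.full_scan_max, p) + 1))
    k = p
    while k >= 1:
        ks.add(k)
        k //= 2
    return sorted(ks)


def select_feature_count(
    table: AbundanceTable,
    ages: Sequence,
    ranked: Sequence[tuple[str, float]],
    config: AgeModelConfig,
) -> tuple[int, dict]:
    """Pick the minimal top-k subset whose CV error is near-optimal.

    Evaluates ``config.cv_folds``-fold CV mean squared error for nested
    top-k subsets (k halving from p down to 1, plus every k up to
    ``full_scan_max``) and returns the smallest k whose error is within
    ``(1 + cv_tolerance)`` of the minimum, together with the CV curve.
    """
    table = to_relative(table)
    _check_training_input(table, ages, config)
    X, y, _ = _sorted_by_sample(table.data, ages)
    ranked_ids = [t for t, _ in ranked]
    col = {t: j for j, t in enumerate(table.taxon_ids)}
    idx = [col[t] for t in ranked_ids]
    p = len(idx)
    ks = list(config.candidate_ks) if config.candidate_ks else _candidate_subset_sizes(p, config)
    n_trees = config.cv_n_trees or config.n_trees
    ss = np.random.SeedSequence([config.seed, 0xCF])
    kf_seed, forest_seed = (int(s) for s in ss.generate_state(2))
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=kf_seed)
    splits = list(kf.split(X))
    cv_curve: dict[int, float] = {}
    for k in ks:
        Xk = X[:, idx[:k]]
        sq_err = []
        for f, (tr, te) in enumerate(splits):
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=config.mtry(k),
                random_state=(forest_seed + 31 * k + f) % (2**32),
                n_jobs=1,
            )
            rf.fit(Xk[tr], y[tr])
            sq_err.append((rf.predict(Xk[te]) - y[te]) ** 2)
        cv_curve[k] = float(np.concatenate(sq_err).mean())
    best = min(cv_curve.values())
    k_star = min(k for k, e in cv_curve.items() if e <= (1 + config.cv_tolerance) * best)
    return k_star, cv_curve


def fit_age_model(
    table: AbundanceTable,
    ages: Sequence,
    k_star: int,
    config: AgeModelConfig,
    ranked: Sequence[tuple[str, float]] | None = None,
    cv_curve: dict | None = None,
) -> AgeModel:
    """Train the final forest on the top ``k_star`` ranked taxa.

    ``train_r2`` is the out-of-bag R^2 on the training group (clipped at 0
    for the degenerate worse-than-mean case). If ``ranked`` is omitted the
    ranking is computed here.
    """
    table = to_relative(table)
    if table.n_samples < 2:
        raise ValueError("need at least 2 training samples")
    if ranked is None:
        if np.unique(np.asarray(ages, dtype=float)).size >= 2:
            ranked = rank_taxa_by_importance(table, ages, config)
        else:
            # constant target: any subset is equivalent, keep table order
            ranked = [(t, 0.0) for t in table.taxon_ids]
    if k_star > len(ranked):
        raise ValueError("k_star exceeds the number of ranked taxa")
    selected = list(ranked[:k_star])
    sel_ids = [t for t, _ in selected]
    X, y, sample_ids = _sorted_by_sample(table.data.loc[sel_ids], ages)
    seed = int(np.random.SeedSequence([config.seed, 0xF1]).generate_state(1)[0])
    rf = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.mtry(k_star),
        random_state=seed,
        oob_score=True,
        bootstrap=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        rf.fit(X, y)
    oob = pd.Series(rf.oob_prediction_, index=sample_ids)
    r2 = float(max(0.0, rf.oob_score_))
    return AgeModel(
        selected_taxa=selected,
        cv_curve=dict(cv_curve or {}),
        forest=rf,
        train_r2=r2,
        training_sample_ids=sample_ids,
        oob_predictions=oob,
        age_range=(float(np.min(y)), float(np.max(y))),
    )


def predict_microbiota_age(
    model: AgeModel,
    table: AbundanceTable,
    metadata: SampleMetadata | None = None,
    use_oob_for_training: bool = True,
) -> pd.Series:
    """Predict microbiota age (days) for every sample in ``table``.

    Samples that were part of the training set are scored with their
    out-of-bag prediction when ``use_oob_for_training`` (the default);
    selected taxa missing from ``table`` are imputed as zero abundance with
    a warning.
    """
    table = to_relative(table)
    sel = model.selected_taxon_ids
    missing = [t for t in sel if t not in table.data.index]
    data = table.data
    if missing:
        warnings.warn(
            f"{len(missing)} selected taxa absent from table, imputed as 0: {missing}",
            stacklevel=2,
        )
        fill = pd.DataFrame(0.0, index=missing, columns=data.columns)
        data = pd.concat([data, fill])
    X = data.loc[sel].to_numpy(dtype=float).T
    pred = pd.Series(model.forest.predict(X), index=table.sample_ids, name="microbiota_age")
    if use_oob_for_training:
        train = pred.index.intersection(model.oob_predictions.index)
        good = model.oob_predictions.loc[train].dropna()
        pred.loc[good.index] = good
    return pred


def fit_maturity_curve(
    chrono_ages: Sequence,
    microbiota_ages: Sequence,
    group: str = "",
    delta: float = 0.05,
    model_id: str = "",
) -> MaturityCurve:
    """Fit a smoothing spline of microbiota age against chronologic age and
    locate its plateau.

    Replicated ages are collapsed to weighted means; with >= 5 distinct ages
    the smoothing parameter is chosen by generalized cross-validation, with
    exactly 4 a natural cubic interpolant through the means is used. The
    curve is evaluated on a daily grid covering the observed age range; the
    plateau is the earliest grid day whose fitted value reaches
    ``(1 - delta)`` of the grid maximum, and the fitted value there is the
    full-maturity microbiota age.
    """
    x = np.asarray(chrono_ages, dtype=float)
    y = np.asarray(microbiota_ages, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("chronologic and microbiota ages must be equal-length 1-d")
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < 4:
        raise ValueError("insufficient time points for plateau detection (< 4 distinct ages)")
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    w = np.bincount(inv).astype(float)
    if ux.size >= 5:
        spline = make_smoothing_spline(ux, uy, w=w, lam=None)  # GCV-chosen lambda
    else:
        spline = CubicSpline(ux, uy, bc_type="natural")
    grid = np.arange(np.ceil(ux[0]), np.floor(ux[-1]) + 1.0)
    fitted = np.asarray(spline(grid), dtype=float)
    if not np.isfinite(fitted).all():
        raise ValueError("non-finite fitted maturity curve")
    target = (1.0 - delta) * fitted.max()
    i = int(np.argmax(fitted >= target))
    return MaturityCurve(
        group=group,
        grid_ages=grid,
        fitted_microbiota_age=fitted,
        plateau_age=float(grid[i]),
        plateau_value=float(fitted[i]),
        delta=delta,
        model_id=model_id,
    )


def compute_immi(control_curve: MaturityCurve, group_curve: MaturityCurve) -> ImmiResult:
    """Earliest day a group's curve reaches the reference full-maturity
    value; censored at the last grid day if never reached."""
    if control_curve.model_id != group_curve.model_id:
        raise ValueError(
            "maturity curves come from different age models and cannot be compared"
        )
    ref = control_curve.plateau_value
    reached = group_curve.fitted_microbiota_age >= ref
    if reached.any():
        day = float(group_curve.grid_ages[int(np.argmax(reached))])
        return ImmiResult(group=group_curve.group, immi_days=day, reference_value=ref)
    return ImmiResult(
        group=group_curve.group,
        immi_days=float(group_curve.grid_ages[-1]),
        reference_value=ref,
        censored=True,
    )


def run_maturity_analysis(
    table: AbundanceTable,
    metadata: SampleMetadata,
    control_group: str,
    config: AgeModelConfig | None = None,
    delta: float = 0.05,
) -> dict:
    """End-to-end maturation analysis.

    Trains the age model on ``control_group``, predicts microbiota age for
    every sample, fits one maturity curve per group, and computes each
    group's maturation index against the control plateau. Returns a dict
    with keys ``model``, ``k_star``, ``predictions`` (Series),
    ``curves`` (group -> MaturityCurve) and ``immi`` (group -> ImmiResult).
    """
    config = config or AgeModelConfig()
    metadata.check_covers(table)
    rel = to_relative(table)
    control_ids = [s for s in metadata.samples_in_group(control_group) if s in rel.data.columns]
    if not control_ids:
        raise ValueError(f"no samples for control group {control_group!r}")
    ctrl = rel.select_samples(control_ids)
    ctrl_ages = metadata.ages_for(control_ids)
    ranked = rank_taxa_by_importance(ctrl, ctrl_ages, config)
    k_star, cv_curve = select_feature_count(ctrl, ctrl_ages, ranked, config)
    model = fit_age_model(ctrl, ctrl_ages, k_star, config, ranked=ranked, cv_curve=cv_curve)
    preds = predict_microbiota_age(model, rel)
    curves: dict[str, MaturityCurve] = {}
    for grp in pd.unique(metadata.data["group"]):
        ids = [s for s in metadata.samples_in_group(grp) if s in rel.data.columns]
        curves[grp] = fit_maturity_curve(
            metadata.ages_for(ids), preds.loc[ids].to_numpy(),
            group=grp, delta=delta, model_id=model.model_id,
        )
    immi = {g: compute_immi(curves[control_group], c) for g, c in curves.items()}
    return {
        "model": model,
        "k_star": k_star,
        "predictions": preds,
        "curves": curves,
        "immi": immi,
    }
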