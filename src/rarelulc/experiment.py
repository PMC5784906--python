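"""Scenario experiments under repeated stratified cross-validation.

Four scenarios are compared on the same repeated 6-fold stratified split:
S1 original training data, S2 with majority-class Tomek links removed,
S3 additionally LN-SMOTEs the three smallest classes up to the
second-largest class count, and S4 additionally undersamples the majority
class to that count.  Test folds are never resampled.  The classifier is
a random forest (1000 trees, unpruned) whose per-split feature count
(mtry) is tuned per outer fold by an inner stratified 5-fold grid search
on the macro F-score; ties go to the smallest mtry.

Runs are fully deterministic under a master seed: seeds are derived
hierarchically (master -> repetition -> fold -> scenario), so any single
fold can be reproduced in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import macro_f_score
from .resampling import SCENARIOS, SmoteConfig, TrainingSet, apply_scenario

__all__ = [
    "FoldPlan",
    "ExperimentConfig",
    "ScenarioResult",
    "stratified_folds",
    "tune_mtry",
    "run_scenario",
    "run_all",
    "results_to_frame",
]


@dataclass
class FoldPlan:
    """Stratified fold assignment for one repetition."""

    rep: int
    folds: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.folds)
        if np.unique(all_idx).size != all_idx.size:
            raise ValueError("folds overlap")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class ExperimentConfig:
    """Cross-validation and classifier settings.

    The ``full`` profile matches the study protocol (1000 trees, 10
    repetitions, a dense mtry grid); the default reduced profile keeps
    desk-scale runtime while preserving the protocol's structure.
    """

    n_folds: int = 6
    reps: int = 3
    inner_folds: int = 5
    n_tree: int = 200
    nodesize: int = 1
    mtry_grid: tuple[int, ...] = (2, 8, 32)
    scenarios: tuple[str, ...] = SCENARIOS
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    #: optional factory (mtry, seed, n_features) -> estimator with
    #: fit/predict; defaults to the random forest below
    classifier_factory: object = None

    @classmethod
    def full_profile(cls, **over) -> "ExperimentConfig":
        kw = dict(reps=10, n_tree=1000, mtry_grid=tuple(range(2, 73)))
        kw.update(over)
        return cls(**kw)


@dataclass
class ScenarioResult:
    """Predictions and bookkeeping for one scenario in one repetition."""

    scenario: str
    rep: int
    predicted: np.ndarray  # (n_pixels,), every pixel predicted once
    mtry_per_fold: list[int]
    audits: list[dict]
    plan: FoldPlan | None = None


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def stratified_folds(
    labels: np.ndarray, n_folds: int = 6, rng: np.random.Generator | int = 0, rep: int = 0
) -> FoldPlan:
    """Split each class separately into ``n_folds`` near-equal folds."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cid in np.unique(y):
        idx = rng.permutation(np.where(y == cid)[0])
        if idx.size < n_folds:
            warnings.warn(
                f"class {cid} has {idx.size} members; some folds will lack it"
            )
        start = int(rng.integers(n_folds))  # rotate so remainders spread over folds
        for j, i in enumerate(idx):
            folds[(start + j) % n_folds].append(int(i))
    return FoldPlan(rep=rep, folds=[np.sort(np.array(f, dtype=int)) for f in folds], seed=-1)


def _make_classifier(cfg: ExperimentConfig, mtry: int, seed: int, n_features: int):
    if cfg.classifier_factory is not None:
        return cfg.classifier_factory(mtry, seed, n_features)
    return RandomForestClassifier(
        n_estimators=cfg.n_tree,
        min_samples_leaf=cfg.nodesize,
        max_features=min(mtry, n_features),
        random_state=seed,
        n_jobs=1,
    )


def tune_mtry(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[int, ...],
    inner_folds: int,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
) -> int:
    """Inner stratified CV grid search on macro F-score; ties -> smallest mtry."""
    if len(grid) == 0:
        raise ValueError("empty mtry grid")
    if len(grid) == 1:
        return int(grid[0])
    plan = stratified_folds(y, inner_folds, rng)
    clf_seed = int(rng.integers(2**31))
    best_mtry, best_score = None, -np.inf
    for mtry in sorted(grid):
        scores = []
        for h in range(inner_folds):
            test_idx = plan.folds[h]
            if test_idx.size == 0:
                continue
            train_idx = np.concatenate([plan.folds[j] for j in range(inner_folds) if j != h])
            clf = _make_classifier(cfg, mtry, clf_seed, X.shape[1])
            clf.fit(X[train_idx], y[train_idx])
            scores.append(macro_f_score(y[test_idx], clf.predict(X[test_idx])))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_mtry = score, int(mtry)
    return best_mtry


def run_scenario(
    X: np.ndarray,
    y: np.ndarray,
    scenario: str,
    plan: FoldPlan,
    cfg: ExperimentConfig,
    seed_seq: np.random.SeedSequence | int = 0,
    pixel_ids: np.ndarray | None = None,
) -> ScenarioResult:
    """One repetition of one scenario: transform, tune, fit, predict."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if pixel_ids is None:
        pixel_ids = np.arange(len(y))
    predicted = np.full(len(y), -1, dtype=int)
    mtrys, audits = [], []
    fold_seqs = seed_seq.spawn(plan.n_folds)
    for h in range(plan.n_folds):
        test_idx = plan.folds[h]
        train_idx = np.concatenate([plan.folds[j] for j in range(plan.n_folds) if j != h])
        rng = np.random.default_rng(fold_seqs[h])
        train = TrainingSet.from_arrays(X[train_idx], y[train_idx], pixel_ids[train_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            transformed, audit = apply_scenario(train, scenario, cfg.smote, rng)
            mtry = tune_mtry(transformed.X, transformed.y, cfg.mtry_grid,
                             cfg.inner_folds, cfg, rng)
            clf = _make_classifier(cfg, mtry, int(rng.integers(2**31)), X.shape[1])
            clf.fit(transformed.X, transformed.y)
        predicted[test_idx] = clf.predict(X[test_idx])
        mtrys.append(mtry)
        audit["fold"] = h
        audit["class_counts_after"] = transformed.class_counts().tolist()
        audits.append(audit)
    if (predicted < 0).any():
        raise RuntimeError("some pixels were never predicted")
    return ScenarioResult(scenario=scenario, rep=plan.rep, predicted=predicted,
                          mtry_per_fold=mtrys, audits=audits, plan=plan)


def run_all(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ExperimentConfig | None = None,
    master_seed: int = 0,
    pixel_ids: np.ndarray | None = None,
) -> list[ScenarioResult]:
    """All repetitions of all scenarios, sharing fold plans per repetition."""
    cfg = cfg or ExperimentConfig()
    ss = np.random.SeedSequence(master_seed)
    rep_seqs = ss.spawn(cfg.reps)
    results = []
    for rep, rep_seq in enumerate(rep_seqs):
        children = rep_seq.spawn(1 + len(cfg.scenarios))
        plan_rng = np.random.default_rng(children[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = stratified_folds(y, cfg.n_folds, plan_rng, rep=rep)
        plan.seed = _seed_int(children[0])
        for si, scenario in enumerate(cfg.scenarios):
            results.append(
                run_scenario(X, y, scenario, plan, cfg, children[1 + si], pixel_ids)
            )
    return results


def results_to_frame(results: list[ScenarioResult], y: np.ndarray) -> pd.DataFrame:
    """Long per-class metric table (scenario, rep, class, tpr, fpr, ...)."""
    from .evaluation import confusion, per_class_rates

    y = np.asarray(y, dtype=int)
    recs = []
    for res in results:
        rates = per_class_rates(confusion(y, res.predicted))
        rates.insert(0, "scenario", res.scenario)
        rates.insert(1, "rep", res.rep)
        recs.append(rates)
    return pd.concat(recs, ignore_index=True)
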