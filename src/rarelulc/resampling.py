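"""Training-set resampling: Tomek-link cleaning, LN-SMOTE oversampling,
random undersampling and the four scenario transformations.

LN-SMOTE (local-neighborhood SMOTE) generates synthetic minority samples
on the segment between a seed point Q_i and one of its k nearest
neighbors Q_n, where the neighborhood spans *all* classes.  The safe
level sl(Q) counts how many of Q's k neighbors share Q's class; the safe
level ratio slr = sl(Q_i)/sl(Q_n) selects one of five cases that bound
the uniform interpolation weight delta:

1. sl_i = 0 and sl_n = 0  -> both points are noise, nothing is generated;
2. sl_i > 0 and sl_n = 0  -> Q_n is noise, Q_i is duplicated (a = b = 0);
3. slr = 1                -> plain SMOTE, a = 0, b = 1;
4. slr > 1                -> stay near Q_i, a = 0, b = 1/slr;
5. slr < 1                -> stay near Q_n, a = 1 - slr, b = 1.

When Q_i and Q_n belong to different classes the drawn delta is further
scaled by sl(Q_n)/k, biasing the synthetic point towards Q_i's class.
Every generated row carries a full provenance record (SmoteDraw).

Tomek links are mutual nearest-neighbor pairs with different labels;
removing the majority-class member of each link cleans the class
boundary before oversampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .classes import CLASS_NAMES

__all__ = [
    "TrainingSet",
    "SmoteConfig",
    "SmoteDraw",
    "TomekReport",
    "knn_indices",
    "tomek_links",
    "remove_majority_tomek",
    "safe_level",
    "slr_case",
    "ln_smote_sample",
    "oversample_class",
    "undersample_random",
    "apply_scenario",
    "SCENARIOS",
]

SCENARIOS = ("S1", "S2", "S3", "S4")

ORIGINAL, SYNTHETIC, DUPLICATED = "original", "synthetic", "duplicated"


@dataclass
class TrainingSet:
    """Feature rows with labels and per-row provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray
    pixel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        self.pixel_ids = np.asarray(self.pixel_ids, dtype=int)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        if not (len(self.X) == len(self.y) == len(self.provenance) == len(self.pixel_ids)):
            raise ValueError("misaligned training set")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= len(CLASS_NAMES)):
            raise ValueError("labels outside the class enum")

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: np.ndarray, pixel_ids=None) -> "TrainingSet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if pixel_ids is None:
            pixel_ids = np.arange(len(y))
        return cls(X=X, y=y, provenance=np.array([ORIGINAL] * len(y), dtype=object),
                   pixel_ids=np.asarray(pixel_ids))

    def __len__(self) -> int:
        return len(self.y)

    def copy(self) -> "TrainingSet":
        return TrainingSet(self.X.copy(), self.y.copy(), self.provenance.copy(),
                           self.pixel_ids.copy())

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        return TrainingSet(self.X[idx], self.y[idx], self.provenance[idx],
                           self.pixel_ids[idx])

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=len(CLASS_NAMES))


@dataclass(frozen=True)
class SmoteConfig:
    """LN-SMOTE and scenario settings."""

    k: int = 5
    target: int | None = None  # None -> second-largest class count in the fold
    oversample_classes: tuple[int, ...] = (3, 4, 5)  # fallow, perennial, mixed forest
    majority_class: int = 0  # deciduous forest
    draw_budget_factor: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class SmoteDraw:
    """Provenance of one oversampling draw."""

    seed_index: int
    neighbor_index: int
    seed_pixel: int
    neighbor_pixel: int
    sl_i: int
    sl_n: int
    slr: float
    a: float
    b: float
    delta_raw: float
    delta: float
    outcome: str  # noise_skip | duplicate | interpolate


@dataclass
class TomekReport:
    pairs: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)
    removed: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Neighborhoods


def knn_indices(X: np.ndarray, query_index: int, k: int) -> np.ndarray:
    """Indices of the k nearest Euclidean neighbors (self excluded).

    Ties are broken towards the lower index; results are sorted by
    distance.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    d = np.linalg.norm(X - X[query_index], axis=1)
    d[query_index] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def _nearest_neighbor_all(X: np.ndarray) -> np.ndarray:
    """1-NN index for every point (ties to the lower index)."""
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    return np.argmin(d, axis=1)


def tomek_links(X: np.ndarray, y: np.ndarray) -> TomekReport:
    """Mutual nearest-neighbor pairs with different labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < 2:
        raise ValueError("need at least two points")
    nn = _nearest_neighbor_all(X)
    report = TomekReport()
    for i in range(len(X)):
        j = int(nn[i])
        if j > i and int(nn[j]) == i and y[i] != y[j]:
            report.pairs.append((i, j, (int(y[i]), int(y[j]))))
    return report


def remove_majority_tomek(train: TrainingSet, majority_class: int) -> tuple[TrainingSet, TomekReport]:
    """Drop the majority-class member of every Tomek link."""
    report = tomek_links(train.X, train.y)
    drop = set()
    for i, j, (yi, yj) in report.pairs:
        if yi == majority_class:
            drop.add(i)
        if yj == majority_class:
            drop.add(j)
    report.removed = sorted(drop)
    keep = np.array([i for i in range(len(train)) if i not in drop], dtype=int)
    return train.subset(keep), report


def safe_level(index: int, y: np.ndarray, knn_set: np.ndarray) -> int:
    """Number of the point's k neighbors sharing its class."""
    return int(np.sum(np.asarray(y)[knn_set] == y[index]))


def slr_case(sl_i: int, sl_n: int, k: int) -> tuple[str, float, float]:
    """Map a safe-level pair to (outcome, a, b)."""
    if sl_i < 0 or sl_n < 0:
        raise ValueError("safe levels must be non-negative")
    if sl_i > k or sl_n > k:
        raise ValueError("safe levels cannot exceed k")
    if sl_i == 0 and sl_n == 0:
        return "noise_skip", 0.0, 0.0
    if sl_n == 0:
        return "duplicate", 0.0, 0.0
    slr = sl_i / sl_n
    if slr == 1.0:
        return "interpolate", 0.0, 1.0
    if slr > 1.0:
        return "interpolate", 0.0, 1.0 / slr
    return "interpolate", 1.0 - slr, 1.0


def ln_smote_sample(
    q_i: np.ndarray,
    q_n: np.ndarray,
    a: float,
    b: float,
    same_class: bool,
    sl_n: int,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """Draw delta ~ U(a, b), scale across classes, and interpolate.

    Returns (new_point, delta_raw, delta_effective).
    """
    delta_raw = float(rng.uniform(a, b)) if b > a else float(a)
    delta = delta_raw if same_class else delta_raw * sl_n / k
    return q_i + delta * (q_n - q_i), delta_raw, delta


def oversample_class(
    train: TrainingSet,
    class_id: int,
    target: int,
    cfg: SmoteConfig,
    rng: np.random.Generator,
) -> tuple[TrainingSet, dict, list[SmoteDraw]]:
    """LN-SMOTE one class up to (at most) ``target`` rows.

    Neighborhoods are frozen on the original rows of the training fold
    (after any Tomek removal); synthetic rows never serve as neighbors.
    Noise skips can leave the class short of the target; a draw budget of
    ``draw_budget_factor`` times the requested count bounds the loop.
    """
    orig = np.where(train.provenance == ORIGINAL)[0]
    members = orig[train.y[orig] == class_id]
    if members.size == 0:
        raise ValueError(f"class {class_id} absent from the training set")
    n_c = int(members.size)
    current = int(np.sum(train.y == class_id))
    needed = target - current
    report = {
        "class_id": class_id,
        "class_name": CLASS_NAMES[class_id],
        "n_original": n_c,
        "target": target,
        "nominal_rate": max(needed, 0) / n_c,
    }
    if needed <= 0:
        report.update(actual_rate=0.0, generated=0, skipped=0)
        return train.copy(), report, []

    Xo = train.X[orig]
    yo = train.y[orig]
    pos = {int(g): i for i, g in enumerate(orig)}  # global -> local index
    dmat = cdist(Xo, Xo)
    np.fill_diagonal(dmat, np.inf)
    knn_cache: dict[int, np.ndarray] = {}

    def knn_of(local: int) -> np.ndarray:
        if local not in knn_cache:
            knn_cache[local] = np.argsort(dmat[local], kind="stable")[: cfg.k]
        return knn_cache[local]

    new_rows, draws = [], []
    budget = cfg.draw_budget_factor * needed
    attempts = generated = skipped = 0
    schedule = rng.permutation(members)
    si = 0
    while generated < needed and attempts < budget:
        attempts += 1
        gi = int(schedule[si % schedule.size])
        si += 1
        li = pos[gi]
        knn_i = knn_of(li)
        ln = int(rng.choice(knn_i))
        knn_n = knn_of(ln)
        sl_i = safe_level(li, yo, knn_i)
        sl_n = safe_level(ln, yo, knn_n)
        outcome, a, b = slr_case(sl_i, sl_n, cfg.k)
        slr = sl_i / sl_n if sl_n > 0 else np.inf
        gn = int(orig[ln])
        pix_i, pix_n = int(train.pixel_ids[gi]), int(train.pixel_ids[gn])
        if outcome == "noise_skip":
            skipped += 1
            draws.append(SmoteDraw(gi, gn, pix_i, pix_n, sl_i, sl_n, float(slr),
                                   a, b, np.nan, np.nan, outcome))
            continue
        if outcome == "duplicate":
            new_rows.append((Xo[li].copy(), DUPLICATED))
            draws.append(SmoteDraw(gi, gn, pix_i, pix_n, sl_i, sl_n, float(slr),
                                   a, b, 0.0, 0.0, outcome))
        else:
            same = bool(yo[ln] == class_id)
            point, d_raw, d_eff = ln_smote_sample(Xo[li], Xo[ln], a, b, same, sl_n, cfg.k, rng)
            new_rows.append((point, SYNTHETIC))
            draws.append(SmoteDraw(gi, gn, pix_i, pix_n, sl_i, sl_n, float(slr),
                                   a, b, d_raw, d_eff, outcome))
        generated += 1

    report.update(actual_rate=generated / n_c, generated=generated, skipped=skipped)
    if not new_rows:
        return train.copy(), report, draws
    Xn = np.vstack([r for r, _ in new_rows])
    prov = np.array([p for _, p in new_rows], dtype=object)
    out = TrainingSet(
        X=np.vstack([train.X, Xn]),
        y=np.concatenate([train.y, np.full(len(new_rows), class_id, dtype=int)]),
        provenance=np.concatenate([train.provenance, prov]),
        pixel_ids=np.concatenate([train.pixel_ids, np.full(len(new_rows), -1, dtype=int)]),
    )
    return out, report, draws


def undersample_random(
    train: TrainingSet, class_id: int, target: int, rng: np.random.Generator
) -> TrainingSet:
    """Reduce one class to exactly ``target`` rows, uniformly without replacement."""
    members = np.where(train.y == class_id)[0]
    if target > members.size:
        raise ValueError(f"target {target} exceeds class size {members.size}")
    keep_members = rng.choice(members, size=target, replace=False)
    keep = np.sort(np.concatenate([np.where(train.y != class_id)[0], keep_members]))
    return train.subset(keep)


def _resolve_target(train: TrainingSet, cfg: SmoteConfig) -> int:
    if cfg.target is not None:
        return cfg.target
    counts = train.class_counts()
    return int(np.sort(counts)[-2])  # second-largest class count


def apply_scenario(
    train: TrainingSet,
    scenario: str,
    cfg: SmoteConfig,
    rng: np.random.Generator,
) -> tuple[TrainingSet, dict]:
    """Transform a training fold for one of the four scenarios.

    S1 original; S2 Tomek-link removal in the majority class; S3 = S2 plus
    LN-SMOTE of the three smallest classes up to the second-largest class
    count; S4 = S3 plus random undersampling of the majority class to the
    same target.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {SCENARIOS}")
    audit: dict = {"scenario": scenario}
    if scenario == "S1":
        return train.copy(), audit
    out, tomek = remove_majority_tomek(train, cfg.majority_class)
    audit["tomek_links"] = len(tomek.pairs)
    audit["tomek_removed"] = len(tomek.removed)
    if scenario == "S2":
        return out, audit
    target = _resolve_target(train, cfg)
    audit["target"] = target
    audit["smote"] = []
    for cid in cfg.oversample_classes:
        out, rep, draws = oversample_class(out, cid, target, cfg, rng)
        rep["draws"] = draws
        audit["smote"].append(rep)
    if scenario == "S3":
        return out, audit
    maj_count = int(np.sum(out.y == cfg.majority_class))
    audit["undersampled_majority_to"] = min(target, maj_count)
    out = undersample_random(out, cfg.majority_class, min(target, maj_count), rng)
    return out, audit
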