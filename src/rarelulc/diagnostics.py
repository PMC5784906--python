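"""Class-overlap and dependency diagnostics.

Three quantities explain why an imbalanced land-cover classification
succeeds or fails independently of the classifier:

* the Jeffries-Matusita distance JMD = 2(1 - exp(-B)) between
  class-conditional Gaussians, with B the Bhattacharyya distance; JMD is 0
  for identical distributions and approaches 2 for fully separable ones.
  Covariances are estimated per band (18 dimensions) because the full
  72-dimensional covariance is singular for the small classes; if even the
  per-band covariance is ill-conditioned the Moore-Penrose pseudo-inverse
  and pseudo-determinant are used and the pair is flagged;
* the mutual information between a single reflectance feature and the
  class label, estimated by the k-nearest-neighbor (KSG) estimator in its
  discrete-continuous variant, then normalized to [-1, 1] via
  MI* = sign(MI) * sqrt(1 - exp(-2|MI|));
* the entropy (bits) of the class distribution, the information-theoretic
  difficulty of the classification task (maximal, log2 M, when classes
  are balanced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .classes import BANDS, CLASS_NAMES

__all__ = [
    "GaussianSummary",
    "class_gaussian",
    "bhattacharyya",
    "jmd",
    "jmd_matrix",
    "ksg_mi",
    "normalize_mi",
    "mi_profile",
    "class_entropy",
]

#: Condition-number threshold above which the pseudo-inverse path is used.
COND_LIMIT = 1e10

#: Relative eigenvalue tolerance for the pseudo-determinant.
PDET_TOL = 1e-10


@dataclass
class GaussianSummary:
    """Per-class, per-band Gaussian summary of the features."""

    class_id: int
    band: str
    mean: np.ndarray
    cov: np.ndarray
    n: int
    singular: bool


def _band_slice(band: str, n_common: int = 18) -> slice:
    bi = BANDS.index(band)
    return slice(bi * n_common, (bi + 1) * n_common)


def class_gaussian(
    features: np.ndarray, labels: np.ndarray, class_id: int, band: str
) -> GaussianSummary:
    """Mean and sample covariance of one class's per-band features."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n_common = X.shape[1] // len(BANDS)
    rows = X[y == class_id][:, _band_slice(band, n_common)]
    if len(rows) < 2:
        raise ValueError(f"class {class_id} has fewer than 2 samples")
    mean = rows.mean(axis=0)
    cov = np.cov(rows, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    singular = np.linalg.matrix_rank(cov) < cov.shape[0]
    return GaussianSummary(class_id=int(class_id), band=band, mean=mean, cov=cov,
                           n=len(rows), singular=singular)


def _log_floored_det(a: np.ndarray, floor: float) -> float:
    """Log-determinant with eigenvalues floored at a common tolerance.

    Flooring (rather than dropping) near-null eigenvalues keeps the
    log-determinant term dimension-consistent when the two classes'
    covariances have different ranks; a rank-deficient class then reads
    as (nearly) perfectly separable from a full-rank one, instead of
    producing an out-of-range distance.
    """
    w = np.linalg.eigvalsh(a)
    return float(np.sum(np.log(np.maximum(w, floor))))


def bhattacharyya(g1: GaussianSummary, g2: GaussianSummary) -> tuple[float, str]:
    """Bhattacharyya distance between two Gaussian summaries.

    Returns ``(B, method)`` where method records whether the ordinary
    inverse or the Moore-Penrose pseudo-inverse (with pseudo-determinant)
    was used for the average covariance.
    """
    if g1.mean.shape != g2.mean.shape:
        raise ValueError("dimension mismatch")
    diff = g1.mean - g2.mean
    avg = 0.5 * (g1.cov + g2.cov)
    ordinary = (
        not g1.singular
        and not g2.singular
        and np.linalg.cond(avg) < COND_LIMIT
    )
    if ordinary:
        inv = np.linalg.inv(avg)
        _, ld_avg = np.linalg.slogdet(avg)
        _, ld1 = np.linalg.slogdet(g1.cov)
        _, ld2 = np.linalg.slogdet(g2.cov)
        method = "inverse"
    else:
        inv = np.linalg.pinv(avg)
        floor = PDET_TOL * float(np.linalg.eigvalsh(avg).max())
        ld_avg = _log_floored_det(avg, floor)
        ld1 = _log_floored_det(g1.cov, floor)
        ld2 = _log_floored_det(g2.cov, floor)
        method = "pseudo_inverse"
    term1 = 0.125 * float(diff @ inv @ diff)
    term2 = 0.5 * (ld_avg - 0.5 * ld1 - 0.5 * ld2)
    return max(term1 + term2, 0.0), method


def jmd(b: float) -> float:
    """Jeffries-Matusita distance from a Bhattacharyya distance."""
    return 2.0 * (1.0 - np.exp(-b))


def jmd_matrix(features: np.ndarray, labels: np.ndarray, band: str) -> pd.DataFrame:
    """Pairwise per-band JMD over all class pairs present in the labels."""
    y = np.asarray(labels)
    present = [cid for cid in range(len(CLASS_NAMES)) if np.sum(y == cid) >= 2]
    gas = {cid: class_gaussian(features, y, cid, band) for cid in present}
    recs = []
    for i, ci in enumerate(present):
        for cj in present[i + 1:]:
            b, method = bhattacharyya(gas[ci], gas[cj])
            recs.append((band, CLASS_NAMES[ci], CLASS_NAMES[cj], jmd(b), method))
    return pd.DataFrame(recs, columns=["band", "class_a", "class_b", "jmd", "inverse_method"])


# ---------------------------------------------------------------------------
# Mutual information (discrete label vs continuous scalar feature)


def ksg_mi(x: np.ndarray, labels: np.ndarray, k_mi: int = 3) -> float:
    """KSG mutual-information estimate (nats) between a continuous scalar
    and a discrete label.

    Discrete-continuous variant: for each point, the distance to its
    k-th nearest neighbor *within its own label* defines a radius; the
    number of points of any label strictly inside that radius enters the
    digamma average.  The estimate may be slightly negative, which
    indicates estimation error under (near-)independence.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    n = x.size
    if n != y.size:
        raise ValueError("length mismatch")
    if n <= k_mi + 1:
        raise ValueError("need more samples than k_mi + 1")
    if np.ptp(x) == 0:
        raise ValueError("constant feature has undefined neighbor distances")
    radius = np.empty(n)
    label_counts = np.empty(n)
    k_all = np.empty(n)
    for lab in np.unique(y):
        mask = y == lab
        count = int(mask.sum())
        label_counts[mask] = count
        if count > 1:
            k = min(k_mi, count - 1)
            k_all[mask] = k
            tree = cKDTree(x[mask, None])
            dist, _ = tree.query(x[mask, None], k=k + 1)
            radius[mask] = np.nextafter(dist[:, -1], 0)
    keep = label_counts > 1
    m = int(keep.sum())
    tree = cKDTree(x[keep, None])
    m_all = tree.query_ball_point(x[keep, None], radius[keep], return_length=True) - 1.0
    return float(
        digamma(m)
        + np.mean(digamma(k_all[keep]))
        - np.mean(digamma(label_counts[keep]))
        - np.mean(digamma(m_all + 1.0))
    )


def normalize_mi(mi_hat: float) -> float:
    """Map a raw MI estimate (nats) to [-1, 1], preserving the sign."""
    return float(np.sign(mi_hat) * np.sqrt(1.0 - np.exp(-2.0 * abs(mi_hat))))


def mi_profile(features: np.ndarray, labels: np.ndarray, k_mi: int = 3) -> pd.DataFrame:
    """Normalized MI between the label and every (band, date) feature."""
    X = np.asarray(features, dtype=float)
    n_common = X.shape[1] // len(BANDS)
    recs = []
    for bi, band in enumerate(BANDS):
        for j in range(n_common):
            raw = ksg_mi(X[:, bi * n_common + j], labels, k_mi)
            recs.append((band, j, raw, normalize_mi(raw)))
    return pd.DataFrame(recs, columns=["band", "date_index", "mi_raw_nats", "mi_star"])


def class_entropy(counts, base: float = 2.0) -> float:
    """Entropy of a class distribution (bits by default)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or c.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    p = c / c.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(base))
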