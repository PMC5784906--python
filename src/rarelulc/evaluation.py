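"""Performance and landscape metrics.

Imbalance-aware performance is summarized by the macro-averaged precision
P_M and recall R_M (equal class weights), their harmonic mean the F-score,
the G-mean (geometric mean of per-class recalls, zero as soon as one class
is never recovered), per-class one-vs-rest TPR/FPR and the overall
accuracy.  Landscape structure is summarized by the patch density
(connected same-class patches per 100 ha) and pixel purity (share of a
class's pixels whose main-class fraction exceeds 0.5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import CLASS_NAMES, PIXEL_AREA_HA

__all__ = [
    "confusion",
    "per_class_rates",
    "macro_metrics",
    "macro_f_score",
    "patch_density",
    "purity_summary",
    "summarize_runs",
]


def confusion(true_labels, predicted_labels, n_classes: int | None = None) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size != p.size:
        raise ValueError("length mismatch")
    m = n_classes or len(CLASS_NAMES)
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= m):
        raise ValueError("labels outside the class range")
    conf = np.zeros((m, m), dtype=int)
    np.add.at(conf, (t, p), 1)
    return conf


def per_class_rates(conf: np.ndarray) -> pd.DataFrame:
    """One-vs-rest TPR, FPR, precision and recall per class.

    Rates that are undefined (a class absent from the test set, or never
    predicted) are reported as NaN and excluded from macro averages.
    """
    conf = np.asarray(conf, dtype=float)
    m = conf.shape[0]
    total = conf.sum()
    recs = []
    for i in range(m):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        tpr = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        fpr = fp / (fp + tn) if (fp + tn) > 0 else np.nan
        prec = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        name = CLASS_NAMES[i] if i < len(CLASS_NAMES) else str(i)
        recs.append((name, tpr, fpr, prec, tpr))
    return pd.DataFrame(recs, columns=["class", "tpr", "fpr", "precision", "recall"])


def macro_metrics(conf: np.ndarray) -> dict[str, float]:
    """Macro precision/recall, F-score, G-mean and overall accuracy."""
    conf = np.asarray(conf, dtype=float)
    rates = per_class_rates(conf)
    prec, rec = rates["precision"].to_numpy(), rates["recall"].to_numpy()
    if np.isnan(prec).any() or np.isnan(rec).any():
        warnings.warn("undefined per-class rates excluded from macro averages")
    p_m = float(np.nanmean(prec))
    r_m = float(np.nanmean(rec))
    f = 2 * p_m * r_m / (p_m + r_m) if (p_m + r_m) > 0 else 0.0
    rec_valid = rec[~np.isnan(rec)]
    g = float(np.prod(rec_valid) ** (1.0 / rec_valid.size)) if rec_valid.size else 0.0
    acc = float(np.trace(conf) / conf.sum()) if conf.sum() else 0.0
    return {"precision_macro": p_m, "recall_macro": r_m, "f_score": f,
            "g_mean": g, "accuracy": acc}


def macro_f_score(true_labels, predicted_labels, n_classes: int | None = None) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return macro_metrics(confusion(true_labels, predicted_labels, n_classes))["f_score"]


def patch_density(
    label_raster: np.ndarray,
    class_id: int,
    connectivity: int = 8,
    area_ha: float | None = None,
) -> dict[str, float]:
    """Connected same-class patches per 100 ha of catchment area."""
    grid = np.asarray(label_raster)
    if grid.size == 0:
        raise ValueError("empty raster")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    mask = grid == class_id
    _, n_patches = ndimage.label(mask, structure=structure)
    if area_ha is None:
        area_ha = grid.size * PIXEL_AREA_HA
    pd_per_100ha = n_patches / area_ha * 100.0
    return {"class_id": int(class_id), "n_patches": int(n_patches),
            "area_ha": float(area_ha), "pd_per_100ha": float(pd_per_100ha),
            "connectivity": connectivity}


def purity_summary(scene) -> pd.DataFrame:
    """Per class, the share of its pixels with main-class fraction > 0.5."""
    labels = scene.labels.ravel()
    recs = []
    for cid, name in enumerate(CLASS_NAMES):
        members = np.where(labels == cid)[0]
        if members.size == 0:
            recs.append((name, np.nan, 0))
            continue
        main_frac = scene.fractions[members, cid]
        recs.append((name, float(np.mean(main_frac > 0.5)), int(members.size)))
    return pd.DataFrame(recs, columns=["class", "purity", "n_pixels"])


def summarize_runs(metrics: pd.DataFrame, value_cols=("tpr", "fpr")) -> pd.DataFrame:
    """Median and 5-95% quantiles across repetitions.

    ``metrics`` must have columns scenario, rep, class and the value
    columns; the summary is per (scenario, class).
    """
    recs = []
    for (scenario, cls), grp in metrics.groupby(["scenario", "class"]):
        row = {"scenario": scenario, "class": cls, "n_reps": grp["rep"].nunique()}
        for col in value_cols:
            v = grp[col].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size == 0:
                row[f"{col}_median"] = np.nan
                row[f"{col}_q05"] = np.nan
                row[f"{col}_q95"] = np.nan
            else:
                row[f"{col}_median"] = float(np.median(v))
                row[f"{col}_q05"] = float(np.quantile(v, 0.05))
                row[f"{col}_q95"] = float(np.quantile(v, 0.95))
        recs.append(row)
    return pd.DataFrame(recs)
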