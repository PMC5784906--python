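"""QA filtering of 16-day composite reflectance time series.

One year of a MODIS-like vegetation-index product gives, per 250 m pixel,
23 composites in four bands (B1 red, B2 near-infrared, B3 blue, B7
mid-infrared) plus two quality layers ("VI quality", "VI usefulness").
Monsoon-season cloud contamination shows up as large positive spikes in
B1, B3 and B7 and must be removed before the series can be used as
classifier features.

The filtering has four steps, applied after dropping the snow/ice-prone
first four and last composites and excluding pixels with persistent cloud
cover:

1. despiking — summer values above the 75% quantile of the summer
   subseries in B1, B3 and B7 are set to missing (B2 is exempt because its
   naturally high reflectance masks the contamination);
2. gap closing — missing values are filled by locally weighted quadratic
   regression (loess, span 0.5) with prior weights derived from the
   "VI usefulness" flags;
3. median filtering — low-quality composites are replaced by a running
   median of width 5;
4. smoothing and resampling — a final weighted loess is evaluated at 18
   evenly spaced common dates, yielding a gap-free feature vector of
   length 72 (4 bands x 18 dates) per pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import BANDS, SUMMER_DOY

__all__ = [
    "QaSeries",
    "FilterConfig",
    "CleanSeries",
    "UnusablePixelError",
    "drop_edge_composites",
    "low_quality_mask",
    "flag_contaminated_pixels",
    "despike",
    "usefulness_weights",
    "weighted_loess",
    "close_gaps",
    "median_replace",
    "smooth_and_resample",
    "preprocess_series",
    "preprocess_scene",
    "to_feature_vector",
    "from_feature_vector",
    "feature_names",
]

#: Default mapping from "VI usefulness" flag to a prior weight for the
#: loess fits.  Flags of 5 and above mark data the filtering should
#: essentially ignore.
DEFAULT_USEFULNESS_WEIGHTS: dict[int, float] = {0: 1.0, 1: 1.0, 2: 0.8, 3: 0.6, 4: 0.4, 5: 0.1}

#: Bands despiked in step 1.  B2 is exempt.
SPIKE_BANDS = ("B1", "B3", "B7")


class UnusablePixelError(ValueError):
    """Raised when a pixel has too few valid observations to process."""


@dataclass
class QaSeries:
    """One pixel's multi-band composite series with quality flags."""

    dates: np.ndarray
    bands: dict[str, np.ndarray]
    vi_quality: np.ndarray
    vi_usefulness: np.ndarray
    pixel_id: int = -1

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("composite dates must be strictly increasing")
        n = self.dates.size
        self.bands = {b: np.asarray(v, dtype=float) for b, v in self.bands.items()}
        for b, v in self.bands.items():
            if v.size != n:
                raise ValueError(f"band {b} not aligned with dates")
        self.vi_quality = np.asarray(self.vi_quality, dtype=int)
        self.vi_usefulness = np.asarray(self.vi_usefulness, dtype=int)
        if self.vi_quality.size != n or self.vi_usefulness.size != n:
            raise ValueError("QA flags not aligned with dates")

    def __len__(self) -> int:
        return int(self.dates.size)

    def copy(self) -> "QaSeries":
        return QaSeries(
            dates=self.dates.copy(),
            bands={b: v.copy() for b, v in self.bands.items()},
            vi_quality=self.vi_quality.copy(),
            vi_usefulness=self.vi_usefulness.copy(),
            pixel_id=self.pixel_id,
        )


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the four-step filter."""

    drop_first: int = 4
    drop_last: int = 1
    summer_doy: tuple[float, float] = SUMMER_DOY
    spike_quantile: float = 0.75
    loess_degree: int = 2
    loess_span: float = 0.5
    median_window: int = 5
    low_vi_quality: int = 3
    low_usefulness: int = 5
    n_common_dates: int = 18
    usefulness_weight_map: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_USEFULNESS_WEIGHTS)
    )
    max_consecutive_cloudy: int = 3
    max_summer_cloudy: int = 4
    min_valid_per_band: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.loess_span <= 1.0):
            raise ValueError("loess span must be in (0, 1]")
        if self.median_window % 2 != 1:
            raise ValueError("median window must be odd")


@dataclass
class CleanSeries:
    """Gap-free series at the shared common dates (bands x dates)."""

    dates: np.ndarray
    values: np.ndarray  # shape (4, n_common), rows ordered as BANDS
    pixel_id: int = -1

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(BANDS), self.dates.size):
            raise ValueError("values must have shape (4, n_common)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clean series may not contain missing values")


# ---------------------------------------------------------------------------
# Pixel exclusion and edge handling


def drop_edge_composites(series: QaSeries, cfg: FilterConfig | None = None) -> QaSeries:
    """Drop the snow/ice-contaminated leading and trailing composites."""
    cfg = cfg or FilterConfig()
    n = len(series)
    if n <= cfg.drop_first + cfg.drop_last:
        raise ValueError(f"series of length {n} too short to drop edges")
    sl = slice(cfg.drop_first, n - cfg.drop_last)
    return QaSeries(
        dates=series.dates[sl],
        bands={b: v[sl] for b, v in series.bands.items()},
        vi_quality=series.vi_quality[sl],
        vi_usefulness=series.vi_usefulness[sl],
        pixel_id=series.pixel_id,
    )


def low_quality_mask(series: QaSeries, cfg: FilterConfig | None = None) -> np.ndarray:
    """Composites considered low quality (cloudy): VI quality == 3 or VI usefulness >= 5."""
    cfg = cfg or FilterConfig()
    return (series.vi_quality == cfg.low_vi_quality) | (
        series.vi_usefulness >= cfg.low_usefulness
    )


def _max_run_length(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def summer_mask(dates: np.ndarray, summer_doy: tuple[float, float] = SUMMER_DOY) -> np.ndarray:
    lo, hi = summer_doy
    d = np.asarray(dates, dtype=float)
    return (d >= lo) & (d <= hi)


def flag_contaminated_pixels(
    series_list: list[QaSeries], cfg: FilterConfig | None = None
) -> np.ndarray:
    """Keep mask over pixels, applied on the edge-dropped composite frame.

    A pixel is dropped when it has ``max_consecutive_cloudy`` or more
    consecutive cloudy composites, or ``max_summer_cloudy`` or more cloudy
    composites inside the summer window.
    """
    cfg = cfg or FilterConfig()
    keep = np.ones(len(series_list), dtype=bool)
    for i, s in enumerate(series_list):
        trimmed = drop_edge_composites(s, cfg) if len(s) > 18 else s
        cloudy = low_quality_mask(trimmed, cfg)
        in_summer = summer_mask(trimmed.dates, cfg.summer_doy)
        if _max_run_length(cloudy) >= cfg.max_consecutive_cloudy:
            keep[i] = False
        elif int(np.sum(cloudy & in_summer)) >= cfg.max_summer_cloudy:
            keep[i] = False
    return keep


# ---------------------------------------------------------------------------
# Step 1: despiking


def despike(
    values: np.ndarray,
    summer_idx: np.ndarray,
    band: str,
    quantile: float = 0.75,
) -> np.ndarray:
    """Set summer values above the summer 75% quantile to missing.

    ``summer_idx`` is a boolean mask or an index array over the series.
    The quantile uses linear interpolation and the comparison is strict,
    so a constant summer series loses nothing.  B2 is returned unchanged.
    """
    values = np.asarray(values, dtype=float).copy()
    if band == "B2":
        return values
    mask = np.zeros(values.size, dtype=bool)
    mask[summer_idx] = True
    summer_vals = values[mask]
    finite = summer_vals[np.isfinite(summer_vals)]
    if finite.size == 0:
        raise ValueError("summer window contains no valid values")
    q = np.quantile(finite, quantile)
    values[mask & np.isfinite(values) & (values > q)] = np.nan
    return values


# ---------------------------------------------------------------------------
# Prior weights and loess


def usefulness_weights(
    flags: np.ndarray, mapping: dict[int, float] | None = None
) -> np.ndarray:
    """Map "VI usefulness" flags to loess prior weights in [0, 1]."""
    mapping = mapping or DEFAULT_USEFULNESS_WEIGHTS
    flags = np.asarray(flags, dtype=int)
    if np.any(flags < 0):
        raise ValueError("usefulness flags must be non-negative")
    top = max(mapping)
    return np.array([mapping[min(int(f), top)] for f in flags], dtype=float)


def weighted_loess(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    xout: np.ndarray,
    degree: int = 2,
    span: float = 0.5,
) -> np.ndarray:
    """Locally weighted polynomial regression with prior weights.

    At each query point the ``span`` fraction of valid observations
    nearest in ``x`` is fit with a degree-``degree`` polynomial under
    tricube distance weights multiplied by the supplied prior weights;
    the fitted value at the query point is returned.  Rank-deficient
    local systems widen their window until enough positively weighted
    points are available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    xout = np.atleast_1d(np.asarray(xout, dtype=float))
    valid = np.isfinite(y) & np.isfinite(x) & (w > 0)
    xv, yv, wv = x[valid], y[valid], w[valid]
    n = xv.size
    if n < degree + 1:
        raise UnusablePixelError(
            f"only {n} valid points; need at least {degree + 1} for degree {degree}"
        )
    q0 = max(int(math.ceil(span * n)), degree + 1)
    out = np.empty(xout.size, dtype=float)
    for j, x0 in enumerate(xout):
        d = np.abs(xv - x0)
        order = np.argsort(d, kind="stable")
        q = q0
        while True:
            idx = order[:q]
            dmax = d[idx].max()
            if dmax == 0:
                tri = np.ones(idx.size)
            else:
                u = np.clip(d[idx] / dmax, 0.0, 1.0)
                tri = (1.0 - u**3) ** 3
            wloc = tri * wv[idx]
            if np.count_nonzero(wloc > 0) >= degree + 1 or q >= n:
                break
            q = min(n, q + 1)
        if np.count_nonzero(wloc > 0) < degree + 1:
            # all prior weight concentrated on too few points: fall back to
            # kernel weights only so the local system stays solvable
            wloc = tri if np.count_nonzero(tri > 0) >= degree + 1 else np.ones(idx.size)
        t = xv[idx] - x0
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(wloc)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], yv[idx] * sw, rcond=None)
        out[j] = beta[0]
    return out


# ---------------------------------------------------------------------------
# Steps 2-4


def close_gaps(series: QaSeries, cfg: FilterConfig | None = None) -> QaSeries:
    """Fill missing values by weighted loess; observed values are kept."""
    cfg = cfg or FilterConfig()
    out = series.copy()
    prior = usefulness_weights(series.vi_usefulness, cfg.usefulness_weight_map)
    for b, v in out.bands.items():
        gaps = ~np.isfinite(v)
        if not gaps.any():
            continue
        if np.count_nonzero(np.isfinite(v)) < cfg.min_valid_per_band:
            raise UnusablePixelError(
                f"band {b} has fewer than {cfg.min_valid_per_band} valid points"
            )
        v[gaps] = weighted_loess(
            series.dates, v, prior, series.dates[gaps],
            degree=cfg.loess_degree, span=cfg.loess_span,
        )
    return out


def _running_median(v: np.ndarray, window: int) -> np.ndarray:
    """Running median with windows shrunk (not padded) at the series ends."""
    half = window // 2
    n = v.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(v[lo:hi])
    return out


def median_replace(series: QaSeries, cfg: FilterConfig | None = None) -> QaSeries:
    """Replace low-quality composites by the running median (step 3)."""
    cfg = cfg or FilterConfig()
    out = series.copy()
    low = low_quality_mask(series, cfg)
    if not low.any():
        return out
    for b, v in out.bands.items():
        med = _running_median(v, cfg.median_window)
        v[low] = med[low]
    return out


def smooth_and_resample(series: QaSeries, cfg: FilterConfig | None = None) -> CleanSeries:
    """Final loess smoothing evaluated at the evenly spaced common dates."""
    cfg = cfg or FilterConfig()
    xnew = np.linspace(series.dates.min(), series.dates.max(), cfg.n_common_dates)
    prior = usefulness_weights(series.vi_usefulness, cfg.usefulness_weight_map)
    values = np.empty((len(BANDS), cfg.n_common_dates))
    for bi, b in enumerate(BANDS):
        values[bi] = weighted_loess(
            series.dates, series.bands[b], prior, xnew,
            degree=cfg.loess_degree, span=cfg.loess_span,
        )
    return CleanSeries(dates=xnew, values=values, pixel_id=series.pixel_id)


def preprocess_series(series: QaSeries, cfg: FilterConfig | None = None) -> CleanSeries:
    """Run the full per-pixel filter (edge drop + steps 1-4)."""
    cfg = cfg or FilterConfig()
    s = drop_edge_composites(series, cfg)
    sm = summer_mask(s.dates, cfg.summer_doy)
    for b in SPIKE_BANDS:
        s.bands[b] = despike(s.bands[b], sm, b, cfg.spike_quantile)
    s = close_gaps(s, cfg)
    s = median_replace(s, cfg)
    return smooth_and_resample(s, cfg)


# ---------------------------------------------------------------------------
# Feature vectors


def feature_names(n_common: int = 18) -> list[str]:
    return [f"{b}_d{j + 1:02d}" for b in BANDS for j in range(n_common)]


def to_feature_vector(clean: CleanSeries) -> np.ndarray:
    """Flatten band-major: B1 at all common dates, then B2, B3, B7."""
    return clean.values.reshape(-1).copy()


def from_feature_vector(vec: np.ndarray, dates: np.ndarray, pixel_id: int = -1) -> CleanSeries:
    vec = np.asarray(vec, dtype=float)
    dates = np.asarray(dates, dtype=float)
    return CleanSeries(dates=dates, values=vec.reshape(len(BANDS), dates.size), pixel_id=pixel_id)


def preprocess_scene(scene, cfg: FilterConfig | None = None):
    """Filter every pixel of a scene into a feature table.

    Returns ``(features, report)``: a DataFrame with pixel_id, label and
    f1..f72 columns (band-major), and a per-pixel report of kept/dropped
    status with the drop reason.
    """
    cfg = cfg or FilterConfig()
    series_list = [scene.qa_series(i) for i in range(scene.n_pixels)]
    keep = flag_contaminated_pixels(series_list, cfg)
    rows, report = [], []
    names = feature_names(cfg.n_common_dates)
    for i, s in enumerate(series_list):
        if not keep[i]:
            report.append((i, False, "cloud_rule"))
            continue
        try:
            clean = preprocess_series(s, cfg)
        except UnusablePixelError as exc:
            report.append((i, False, f"unusable: {exc}"))
            continue
        rows.append((i, int(scene.labels.ravel()[i]), *to_feature_vector(clean)))
        report.append((i, True, ""))
    features = pd.DataFrame(rows, columns=["pixel_id", "label", *names])
    report = pd.DataFrame(report, columns=["pixel_id", "kept", "reason"])
    return features, report
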