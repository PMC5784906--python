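"""Synthetic MODIS-like scene generator.

Emulates the statistical structure of an agro-ecological catchment scene
at 250 m resolution: six land-cover classes with a strongly imbalanced
distribution, class-specific double-logistic phenology in four bands,
mixed pixels built by linear spectral mixing of class endmembers, summer
cloud contamination as positive spikes in B1/B3/B7 with degraded quality
flags, and a patchy spatial layout (a deciduous-forest ring surrounding an
agricultural mosaic of rectangular fields).

Everything is a pure function of the configuration and seed, so every
downstream stage of the pipeline can be tested without any data download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import (
    BANDS,
    CLASS_LIBRARY,
    CLASS_NAMES,
    NOMINAL_DOY,
    PIXEL_AREA_HA,
    SIX_CLASS_COUNTS,
    SUMMER_DOY,
    BandPhenology,
    ClassSpec,
)
from .modis_preprocess import QaSeries

__all__ = [
    "SceneConfig",
    "Scene",
    "double_logistic",
    "simulate_phenology",
    "mix_fractions",
    "contaminate",
    "majority_label",
    "generate_scene",
    "write_scene",
    "read_scene",
]

#: Default per-class purity: probability that a pixel of the class is a
#: pure (one-hot) pixel rather than a mixed one.  Forests and paddy rice
#: are largely pure; the annual/fallow/perennial cropland classes are
#: inherently mixed.
DEFAULT_PURITY = {
    "deciduous_forest": 0.95,
    "annual_dryland": 0.55,
    "paddy_rice": 0.85,
    "fallow": 0.45,
    "perennial": 0.45,
    "mixed_forest": 0.85,
}

#: Half-normal scale of additive cloud spikes per despiked band.
SPIKE_SCALES = {"B1": 0.12, "B3": 0.15, "B7": 0.08}
SPIKE_FLOOR = 0.02


def _default_proportions() -> dict[str, float]:
    total = sum(SIX_CLASS_COUNTS)
    return {name: c / total for name, c in zip(CLASS_NAMES, SIX_CLASS_COUNTS)}


@dataclass
class SceneConfig:
    """Scene geometry, class composition and contamination settings."""

    rows: int = 40
    cols: int = 30
    proportions: dict[str, float] = field(default_factory=_default_proportions)
    purity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PURITY))
    mix_concentration: float = 3.0
    cloud_prob: float = 0.165
    noise_sd: float = 0.008
    jitter_scale: float = 1.0  # scales intra-class parameter variability
    dates: tuple[int, ...] = NOMINAL_DOY
    summer_doy: tuple[float, float] = SUMMER_DOY
    max_patch: int = 24
    blend_endmembers: dict[str, tuple[str, str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = sum(self.proportions.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"class proportions must sum to 1, got {s}")
        if self.rows * self.cols < len(self.proportions):
            raise ValueError("grid too small for the number of classes")
        for name in self.proportions:
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown class {name!r}")


@dataclass
class Scene:
    """A generated raster scene with per-pixel truth and QA series."""

    rows: int
    cols: int
    dates: np.ndarray
    labels: np.ndarray  # (rows, cols) int class ids
    fractions: np.ndarray  # (n_pixels, n_classes), rows sum to 1
    band_stacks: dict[str, np.ndarray]  # band -> (n_pixels, n_dates)
    vi_quality: np.ndarray  # (n_pixels, n_dates) int
    vi_usefulness: np.ndarray  # (n_pixels, n_dates) int
    config: SceneConfig

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def pixel_area_ha(self) -> float:
        return PIXEL_AREA_HA

    def qa_series(self, pixel_id: int) -> QaSeries:
        return QaSeries(
            dates=self.dates,
            bands={b: self.band_stacks[b][pixel_id] for b in BANDS},
            vi_quality=self.vi_quality[pixel_id],
            vi_usefulness=self.vi_usefulness[pixel_id],
            pixel_id=pixel_id,
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=len(CLASS_NAMES))


# ---------------------------------------------------------------------------
# Phenology


def double_logistic(t: np.ndarray, p: BandPhenology) -> np.ndarray:
    """Seasonal reflectance curve: baseline plus a green-up/senescence pulse."""
    t = np.asarray(t, dtype=float)
    up = 1.0 / (1.0 + np.exp(-p.greenup_rate * (t - p.greenup)))
    down = 1.0 / (1.0 + np.exp(p.senescence_rate * (t - p.senescence)))
    return p.baseline + p.amplitude * (up + down - 1.0)


def _jitter_params(p: BandPhenology, jit: dict[str, float], rng: np.random.Generator) -> BandPhenology:
    base = p.baseline + rng.normal(0.0, jit["baseline"])
    amp = p.amplitude * (1.0 + rng.normal(0.0, jit["amplitude"]))
    gu = p.greenup + rng.normal(0.0, jit["midpoint"])
    sn = p.senescence + rng.normal(0.0, jit["midpoint"])
    gur = p.greenup_rate * (1.0 + rng.normal(0.0, jit["rate"]))
    snr = p.senescence_rate * (1.0 + rng.normal(0.0, jit["rate"]))
    # keep the jittered curve inside [0, 1] and the midpoints ordered
    lo, hi = min(base, base + amp), max(base, base + amp)
    if lo < 0.0:
        base -= lo
    if hi > 1.0:
        amp *= (1.0 - base) / hi if amp > 0 else 1.0
    sn = max(sn, gu + 20.0)
    return BandPhenology(base, amp, gu, max(gur, 1e-3), sn, max(snr, 1e-3))


def simulate_phenology(
    spec: ClassSpec,
    dates: np.ndarray,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> dict[str, np.ndarray]:
    """Per-band reflectance series for one realization of a class.

    Without an ``rng`` the class endmember (median) curve is returned;
    with one, the double-logistic parameters are jittered by the class's
    intra-class variability and optional observation noise is added.
    """
    dates = np.asarray(dates, dtype=float)
    if np.any(np.diff(dates) <= 0):
        raise ValueError("dates must be strictly increasing")
    out = {}
    for b in BANDS:
        p = spec.bands[b]
        if rng is not None:
            p = _jitter_params(p, spec.jitter, rng)
        v = double_logistic(dates, p)
        if rng is not None and noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.size)
        out[b] = np.clip(v, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Mixed pixels


def mix_fractions(
    n_pixels: int,
    purity_target: float,
    concentration: float,
    rng: np.random.Generator,
    n_components: int = 3,
) -> np.ndarray:
    """Fraction vectors over a main component (column 0) and companions.

    With probability ``purity_target`` a pixel is pure (one-hot on the
    main component); otherwise its fractions are drawn from a symmetric
    Dirichlet with the given concentration, rearranged so the main
    component carries the largest share, and conditioned on that share
    not exceeding 0.5 so that purity (share of pixels whose main fraction
    exceeds 0.5) tracks ``purity_target``.
    """
    if not (0.0 < purity_target <= 1.0):
        raise ValueError("purity_target must be in (0, 1]")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    out = np.zeros((n_pixels, n_components))
    pure = rng.random(n_pixels) < purity_target
    out[pure, 0] = 1.0
    alpha = np.full(n_components, concentration / n_components)
    for i in np.where(~pure)[0]:
        for _ in range(100):
            f = rng.dirichlet(alpha)
            f = np.sort(f)[::-1]  # main component gets the largest share
            if f[0] <= 0.5 and f[0] > f[1]:
                out[i] = f
                break
        else:
            fallback = np.zeros(n_components)
            fallback[0] = 0.5
            rest = np.array([0.3, 0.2] + [0.0] * (n_components - 3))[: n_components - 1]
            fallback[1:] = rest * (0.5 / rest.sum()) if rest.sum() else 0.0
            if n_components == 2:
                fallback[1] = 0.5
            out[i] = fallback
    return out


def majority_label(fractions: np.ndarray) -> int:
    """Class of the largest fraction; ties break to the lowest class id."""
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    s = f.sum()
    if s == 0:
        raise ValueError("all-zero fraction vector")
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {s}")
    return int(np.argmax(f))


# ---------------------------------------------------------------------------
# Cloud contamination


def contaminate(
    series: QaSeries,
    cloud_prob: float,
    summer_idx: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> QaSeries:
    """Add cloud spikes to B1/B3/B7 and degrade the QA flags.

    Each composite is contaminated independently with probability
    ``cloud_prob``.  Contaminated composites receive strictly positive
    additive spikes in bands 1, 3 and 7 (band 2 is left untouched), their
    "VI quality" flag is set to 3 and "VI usefulness" raised to at least 5.
    """
    if not (0.0 <= cloud_prob <= 1.0):
        raise ValueError("cloud_prob must be in [0, 1]")
    out = series.copy()
    if cloud_prob == 0.0:
        return out
    if rng is None:
        rng = np.random.default_rng()
    cloudy = rng.random(len(series)) < cloud_prob
    if not cloudy.any():
        return out
    idx = np.where(cloudy)[0]
    for b, scale in SPIKE_SCALES.items():
        spikes = SPIKE_FLOOR + np.abs(rng.normal(0.0, scale, size=idx.size))
        out.bands[b][idx] = np.minimum(out.bands[b][idx] + spikes, 1.0)
    out.vi_quality[idx] = 3
    out.vi_usefulness[idx] = np.maximum(out.vi_usefulness[idx], rng.integers(5, 9, size=idx.size))
    return out


# ---------------------------------------------------------------------------
# Spatial layout


def _target_counts(proportions: dict[str, float], n: int) -> np.ndarray:
    """Largest-remainder apportionment of n pixels to the classes."""
    p = np.array([proportions.get(name, 0.0) for name in CLASS_NAMES])
    raw = p * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _split_rectangles(rows: int, cols: int, max_patch: int, rng: np.random.Generator):
    """Recursively split a rectangle into a mosaic of field-sized pieces."""
    stack = [(0, 0, rows, cols)]
    done = []
    while stack:
        r0, c0, h, w = stack.pop()
        if h * w <= max_patch or (h < 2 and w < 2):
            done.append((r0, c0, h, w))
            continue
        if h >= w:
            cut = int(rng.integers(1, h))
            stack.append((r0, c0, cut, w))
            stack.append((r0 + cut, c0, h - cut, w))
        else:
            cut = int(rng.integers(1, w))
            stack.append((r0, c0, h, cut))
            stack.append((r0, c0 + cut, h, w - cut))
    return done


def _layout_labels(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols, n = cfg.rows, cfg.cols, cfg.rows * cfg.cols
    counts = _target_counts(cfg.proportions, n)
    labels = np.full((rows, cols), -1, dtype=int)
    forest_id = 0
    # forest ring: widest border that fits inside the forest quota
    width = 0
    while True:
        w = width + 1
        if 2 * w >= min(rows, cols):
            break
        ring = n - (rows - 2 * w) * (cols - 2 * w)
        if ring > counts[forest_id]:
            break
        width = w
    if width > 0:
        labels[:width, :] = forest_id
        labels[-width:, :] = forest_id
        labels[:, :width] = forest_id
        labels[:, -width:] = forest_id
    remaining = counts - np.bincount(labels[labels >= 0], minlength=len(CLASS_NAMES))
    # interior mosaic of rectangular fields
    interior = _split_rectangles(rows - 2 * width, cols - 2 * width, cfg.max_patch, rng)
    order = rng.permutation(len(interior))
    for pi in order:
        r0, c0, h, w = interior[pi]
        quota = np.clip(remaining, 0, None).astype(float)
        if quota.sum() == 0:
            cid = int(np.argmax(remaining))
        else:
            cid = int(rng.choice(len(CLASS_NAMES), p=quota / quota.sum()))
        labels[width + r0 : width + r0 + h, width + c0 : width + c0 + w] = cid
        remaining[cid] -= h * w
    # repair pass: reassign single cells until counts match exactly
    flat = labels.ravel()
    current = np.bincount(flat, minlength=len(CLASS_NAMES))
    over = current - counts
    donors = np.concatenate([rng.permutation(np.where(flat == cid)[0]) for cid in np.where(over > 0)[0]]) if (over > 0).any() else np.array([], dtype=int)
    di = 0
    for cid in np.where(over < 0)[0]:
        for _ in range(-over[cid]):
            while di < donors.size and over[flat[donors[di]]] <= 0:
                di += 1
            if di >= donors.size:
                break
            j = donors[di]
            over[flat[j]] -= 1
            flat[j] = cid
            di += 1
    return labels


def _neighbor_classes(labels: np.ndarray, r: int, c: int) -> list[int]:
    rows, cols = labels.shape
    own = labels[r, c]
    seen = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and labels[rr, cc] != own:
                if labels[rr, cc] not in seen:
                    seen.append(int(labels[rr, cc]))
    return seen


def generate_scene(cfg: SceneConfig, seed: int | np.random.Generator = 0) -> Scene:
    """Generate one scene: layout, fractions, spectra, clouds. Pure in (cfg, seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = cfg.rows, cfg.cols
    n = rows * cols
    dates = np.asarray(cfg.dates, dtype=float)
    labels = _layout_labels(cfg, rng)
    n_classes = len(CLASS_NAMES)
    fractions = np.zeros((n, n_classes))
    band_stacks = {b: np.zeros((n, dates.size)) for b in BANDS}
    vi_quality = np.zeros((n, dates.size), dtype=int)
    vi_usefulness = np.zeros((n, dates.size), dtype=int)
    summer = (dates >= cfg.summer_doy[0]) & (dates <= cfg.summer_doy[1])

    for pid in range(n):
        r, c = divmod(pid, cols)
        main = int(labels[r, c])
        main_name = CLASS_NAMES[main]
        purity = cfg.purity.get(main_name, 0.8)
        frac = mix_fractions(1, purity, cfg.mix_concentration, rng)[0]
        companions = [cid for cid in _neighbor_classes(labels, r, c)]
        others = [cid for cid in range(n_classes) if cid != main and cid not in companions]
        rng.shuffle(others)
        companions = (companions + others)[:2]
        component_ids = [main] + companions
        fvec = np.zeros(n_classes)
        for share, cid in zip(frac, component_ids):
            fvec[cid] += share
        fractions[pid] = fvec
        # linear spectral mixing of jittered endmember series
        mix = {b: np.zeros(dates.size) for b in BANDS}
        for share, cid in zip(frac, component_ids):
            if share == 0:
                continue
            series = _component_series(CLASS_NAMES[cid], cfg, dates, rng)
            for b in BANDS:
                mix[b] += share * series[b]
        for b in BANDS:
            v = mix[b] + rng.normal(0.0, cfg.noise_sd, size=dates.size)
            band_stacks[b][pid] = np.clip(v, 0.0, 1.0)
        vi_usefulness[pid] = rng.integers(0, 3, size=dates.size)

    scene = Scene(
        rows=rows, cols=cols, dates=dates, labels=labels, fractions=fractions,
        band_stacks=band_stacks, vi_quality=vi_quality,
        vi_usefulness=vi_usefulness, config=cfg,
    )
    if cfg.cloud_prob > 0:
        for pid in range(n):
            s = contaminate(scene.qa_series(pid), cfg.cloud_prob, summer, rng)
            for b in BANDS:
                band_stacks[b][pid] = s.bands[b]
            vi_quality[pid] = s.vi_quality
            vi_usefulness[pid] = s.vi_usefulness
    # assigned label is the largest-fraction class (mixing keeps the layout
    # class dominant, so this matches the layout grid)
    assigned = np.array([majority_label(fractions[pid]) for pid in range(n)])
    scene.labels = assigned.reshape(rows, cols)
    return scene


def _component_series(
    name: str, cfg: SceneConfig, dates: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One component realization, honoring endmember-blend overrides."""

    def realize(class_name: str) -> dict[str, np.ndarray]:
        spec = CLASS_LIBRARY[class_name]
        if cfg.jitter_scale != 1.0:
            scaled = {k: v * cfg.jitter_scale for k, v in spec.jitter.items()}
            spec = dataclasses.replace(spec, jitter=scaled)
        return simulate_phenology(spec, dates, rng)

    if name in cfg.blend_endmembers:
        a, b_, w = cfg.blend_endmembers[name]
        sa, sb = realize(a), realize(b_)
        return {band: w * sa[band] + (1 - w) * sb[band] for band in BANDS}
    return realize(name)


# ---------------------------------------------------------------------------
# Scene I/O (plain multi-page TIFF stacks + CSV/JSON sidecars)


def write_scene(scene: Scene, out_dir: str | Path) -> Path:
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shape = (scene.dates.size, scene.rows, scene.cols)
    for b in BANDS:
        tifffile.imwrite(out / f"band_{b}.tif", scene.band_stacks[b].T.reshape(shape).astype(np.float32))
    tifffile.imwrite(out / "qa_vi_quality.tif", scene.vi_quality.T.reshape(shape).astype(np.int16))
    tifffile.imwrite(out / "qa_vi_usefulness.tif", scene.vi_usefulness.T.reshape(shape).astype(np.int16))
    tifffile.imwrite(out / "labels.tif", scene.labels.astype(np.int16))
    recs = []
    for pid in range(scene.n_pixels):
        for cid, f in enumerate(scene.fractions[pid]):
            if f > 0:
                recs.append((pid, CLASS_NAMES[cid], f))
    pd.DataFrame(recs, columns=["pixel_id", "class", "fraction"]).to_csv(
        out / "fractions.csv", index=False
    )
    meta = {
        "rows": scene.rows,
        "cols": scene.cols,
        "dates": list(map(float, scene.dates)),
        "class_names": list(CLASS_NAMES),
        "config": _config_to_dict(scene.config),
    }
    (out / "scene_meta.json").write_text(json.dumps(meta, indent=2))
    return out


def _config_to_dict(cfg: SceneConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["dates"] = list(map(float, d["dates"]))
    d["summer_doy"] = list(d["summer_doy"])
    d["blend_endmembers"] = {k: list(v) for k, v in d["blend_endmembers"].items()}
    return d


def read_scene(in_dir: str | Path) -> Scene:
    import tifffile

    src = Path(in_dir)
    meta = json.loads((src / "scene_meta.json").read_text())
    rows, cols = meta["rows"], meta["cols"]
    n = rows * cols
    dates = np.asarray(meta["dates"])
    cfg_d = meta["config"]
    cfg_d["proportions"] = dict(cfg_d["proportions"])
    cfg_d["dates"] = tuple(cfg_d["dates"])
    cfg_d["summer_doy"] = tuple(cfg_d["summer_doy"])
    cfg_d["blend_endmembers"] = {k: tuple(v) for k, v in cfg_d["blend_endmembers"].items()}
    cfg = SceneConfig(**cfg_d)
    band_stacks = {
        b: tifffile.imread(src / f"band_{b}.tif").reshape(dates.size, n).T.astype(float)
        for b in BANDS
    }
    vi_quality = tifffile.imread(src / "qa_vi_quality.tif").reshape(dates.size, n).T.astype(int)
    vi_usefulness = tifffile.imread(src / "qa_vi_usefulness.tif").reshape(dates.size, n).T.astype(int)
    labels = tifffile.imread(src / "labels.tif").astype(int)
    fr = pd.read_csv(src / "fractions.csv")
    fractions = np.zeros((n, len(CLASS_NAMES)))
    name_to_id = {name: i for i, name in enumerate(CLASS_NAMES)}
    for pid, cname, f in fr.itertuples(index=False):
        fractions[pid, name_to_id[cname]] = f
    return Scene(
        rows=rows, cols=cols, dates=dates, labels=labels, fractions=fractions,
        band_stacks=band_stacks, vi_quality=vi_quality,
        vi_usefulness=vi_usefulness, config=cfg,
    )
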