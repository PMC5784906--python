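"""Land-use/land-cover class definitions and the reference census.

The study system is a small mountainous agricultural catchment: a dense
deciduous forest ring surrounds a mosaic of paddy rice, annual dryland
crops, fallow fields and perennial crops (mainly ginseng), with patches of
mixed forest.  Six classes hold at least 20 reference pixels and are the
classification targets; the remaining census classes are too rare to train
on and are treated as background.

The per-class phenology library encodes qualitative knowledge about the
seasonal reflectance trajectories of these classes in the four MODIS
surface-reflectance bands (B1 red, B2 near-infrared, B3 blue, B7
mid-infrared): forests leaf out earlier and faster than crops, the
near-infrared amplitude dominates for all vegetated classes, and the
agricultural classes (annual dryland crops, fallow, perennial crops)
overlap spectrally much more than they differ from the forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BANDS = ("B1", "B2", "B3", "B7")

#: The six modeled classes, in decreasing order of reference pixel count.
#: Integer class ids are the positions in this tuple; ties in majority
#: labeling break to the lowest id.
CLASS_NAMES = (
    "deciduous_forest",
    "annual_dryland",
    "paddy_rice",
    "fallow",
    "perennial",
    "mixed_forest",
)

CLASS_IDS = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Ground-census class distribution of the study catchment (pixel counts on
#: the 250 m raster and mapped area in km^2, all 14 census classes).  The
#: first six rows are the modeled classes.
REFERENCE_CENSUS = (
    ("deciduous_forest", 691, 35.67),
    ("annual_dryland", 179, 7.34),
    ("paddy_rice", 135, 5.18),
    ("fallow", 82, 4.55),
    ("perennial", 35, 1.95),
    ("mixed_forest", 22, 1.34),
    ("urban", 14, 1.65),
    ("shrub", 12, 0.92),
    ("semi_natural", 11, 3.85),
    ("orchard", 11, 0.95),
    ("inland_water", 3, 0.56),
    ("bare_soil", 3, 0.14),
    ("coniferous_forest", 2, 0.19),
    ("cover_crops", 0, 0.06),
)

#: Unclassified background area in the census (km^2).
CENSUS_NA_AREA = 0.02

#: Pixel counts of the six modeled classes (subset of the census).
SIX_CLASS_COUNTS = tuple(row[1] for row in REFERENCE_CENSUS[:6])

#: MODIS pixel edge length and area.
PIXEL_SIZE_M = 250.0
PIXEL_AREA_HA = 6.25

#: Nominal 16-day composite start dates for one year, as day-of-year.
NOMINAL_DOY = tuple(1 + 16 * k for k in range(23))

#: Monsoon-season day-of-year window (2010-05-09 .. 2010-08-29) used for
#: despiking and for the summer cloud-exclusion rule.
SUMMER_DOY = (129, 241)


@dataclass(frozen=True)
class BandPhenology:
    """Double-logistic parameters of one band's seasonal trajectory.

    ``baseline`` is the dormant-season reflectance, ``amplitude`` the
    growing-season excursion (negative for bands that darken under a
    canopy), ``greenup``/``senescence`` the half-amplitude days-of-year
    and the two rates the logistic slopes (1/day).
    """

    baseline: float
    amplitude: float
    greenup: float
    greenup_rate: float
    senescence: float
    senescence_rate: float

    def __post_init__(self) -> None:
        lo = min(self.baseline, self.baseline + self.amplitude)
        hi = max(self.baseline, self.baseline + self.amplitude)
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"phenology curve leaves [0, 1]: baseline={self.baseline}, "
                f"amplitude={self.amplitude}"
            )


@dataclass(frozen=True)
class ClassSpec:
    """Endmember phenology of one class plus intra-class variability.

    ``jitter`` holds standard deviations for per-pixel parameter
    perturbations: additive for ``baseline`` and the midpoints,
    multiplicative (relative) for ``amplitude`` and the rates.
    """

    name: str
    bands: dict[str, BandPhenology]
    jitter: dict[str, float] = field(
        default_factory=lambda: {
            "baseline": 0.008,
            "amplitude": 0.12,
            "midpoint": 7.0,
            "rate": 0.15,
        }
    )

    @property
    def class_id(self) -> int:
        return CLASS_IDS[self.name]


def _spec(name, b1, b2, b3, b7):
    return ClassSpec(name=name, bands={"B1": b1, "B2": b2, "B3": b3, "B7": b7})


#: Versioned endmember library.  Forests green up around DOY 120-125 with
#: fast leaf flushing; crops follow from DOY 150-175.  The three
#: agricultural minority classes are deliberately close to each other
#: (small mutual separability), mixed forest sits close to deciduous
#: forest, and paddy rice is set apart by its flooded low-infrared
#: baseline.
CLASS_LIBRARY: dict[str, ClassSpec] = {
    "deciduous_forest": _spec(
        "deciduous_forest",
        BandPhenology(0.100, -0.060, 120.0, 0.120, 290.0, 0.080),
        BandPhenology(0.180, +0.230, 120.0, 0.120, 290.0, 0.080),
        BandPhenology(0.070, -0.040, 120.0, 0.120, 290.0, 0.080),
        BandPhenology(0.220, -0.120, 120.0, 0.120, 290.0, 0.080),
    ),
    "annual_dryland": _spec(
        "annual_dryland",
        BandPhenology(0.110, -0.050, 165.0, 0.090, 270.0, 0.100),
        BandPhenology(0.200, +0.160, 165.0, 0.090, 270.0, 0.100),
        BandPhenology(0.075, -0.030, 165.0, 0.090, 270.0, 0.100),
        BandPhenology(0.260, -0.100, 165.0, 0.090, 270.0, 0.100),
    ),
    "paddy_rice": _spec(
        "paddy_rice",
        BandPhenology(0.090, -0.040, 175.0, 0.100, 280.0, 0.120),
        BandPhenology(0.150, +0.200, 175.0, 0.100, 280.0, 0.120),
        BandPhenology(0.080, -0.035, 175.0, 0.100, 280.0, 0.120),
        BandPhenology(0.180, -0.090, 175.0, 0.100, 280.0, 0.120),
    ),
    "fallow": _spec(
        "fallow",
        BandPhenology(0.110, -0.040, 155.0, 0.050, 285.0, 0.060),
        BandPhenology(0.200, +0.130, 155.0, 0.050, 285.0, 0.060),
        BandPhenology(0.074, -0.025, 155.0, 0.050, 285.0, 0.060),
        BandPhenology(0.250, -0.080, 155.0, 0.050, 285.0, 0.060),
    ),
    "perennial": _spec(
        "perennial",
        BandPhenology(0.105, -0.045, 150.0, 0.060, 280.0, 0.070),
        BandPhenology(0.190, +0.120, 150.0, 0.060, 280.0, 0.070),
        BandPhenology(0.072, -0.028, 150.0, 0.060, 280.0, 0.070),
        BandPhenology(0.240, -0.070, 150.0, 0.060, 280.0, 0.070),
    ),
    "mixed_forest": _spec(
        "mixed_forest",
        BandPhenology(0.095, -0.055, 125.0, 0.110, 288.0, 0.080),
        BandPhenology(0.185, +0.195, 125.0, 0.110, 288.0, 0.080),
        BandPhenology(0.068, -0.036, 125.0, 0.110, 288.0, 0.080),
        BandPhenology(0.210, -0.100, 125.0, 0.110, 288.0, 0.080),
    ),
}

FOREST_CLASSES = ("deciduous_forest", "mixed_forest")
CROP_CLASSES = ("annual_dryland", "paddy_rice", "fallow", "perennial")
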