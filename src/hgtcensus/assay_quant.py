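"""Siderophore activity from chrome-azurol-S plate photographs.

Iron chelation turns the teal Fe-CAS-surfactant complex yellow; activity is
the yellow halo area in cm^2.  The dish itself provides the scale: its
diameter in pixels is detected from the image and mapped to the known
physical diameter, which makes the measured area invariant to uniform image
rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import color, measure

from .composition_stats import StatResult, anova_oneway, tukey_hsd

DEFAULT_DISH_DIAMETER_CM = 5.5
DEFAULT_HUE_BAND = (40.0, 70.0)  # degrees, CAS yellow
DEFAULT_SATURATION_MIN = 0.25
_FOREGROUND_VALUE_MIN = 0.3  # dish pixels are bright against the bench


@dataclass(frozen=True)
class PlateMeasurement:
    """One plate: strain, replicate and measured yellow area."""

    strain: str
    replicate: int
    yellow_area_cm2: float
    dish_diameter_cm: float = DEFAULT_DISH_DIAMETER_CM

    def __post_init__(self) -> None:
        dish_area = np.pi * (self.dish_diameter_cm / 2) ** 2
        if not 0 <= self.yellow_area_cm2 <= dish_area * 1.01:
            raise ValueError(
                f"yellow area {self.yellow_area_cm2:.2f} cm^2 outside plausible"
                f" range for a {self.dish_diameter_cm} cm dish"
            )


def _load_rgb(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        from PIL import Image

        arr = np.asarray(Image.open(str(image)).convert("RGB"))
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an RGB image")
    return arr[..., :3]


def measure_halo_area(
    image,
    dish_diameter_cm: float = DEFAULT_DISH_DIAMETER_CM,
    hue_band: tuple[float, float] = DEFAULT_HUE_BAND,
    saturation_min: float = DEFAULT_SATURATION_MIN,
) -> float:
    """Yellow area (cm^2) inside the detected dish circle.

    The dish is the largest bright, near-circular connected region; its
    equivalent diameter in pixels calibrates cm/px.  Yellow pixels are those
    inside the dish with HSV hue in ``hue_band`` (degrees) and saturation at
    least ``saturation_min``.
    """
    rgb = _load_rgb(image)
    hsv = color.rgb2hsv(rgb)
    foreground = hsv[..., 2] > _FOREGROUND_VALUE_MIN
    labels = measure.label(foreground)
    if labels.max() == 0:
        raise ValueError("no dish circle detected (no bright region)")
    regions = measure.regionprops(labels)
    dish = max(regions, key=lambda r: r.area)
    # a dish must be plausibly circular and not a sliver
    circle_fill = dish.area / (np.pi * (dish.equivalent_diameter_area / 2) ** 2)
    if dish.area < 100 or not 0.8 < circle_fill < 1.2:
        raise ValueError("no dish circle detected (largest region is not circular)")
    px_per_cm = dish.equivalent_diameter_area / dish_diameter_cm
    cy, cx = dish.centroid
    yy, xx = np.mgrid[0 : rgb.shape[0], 0 : rgb.shape[1]]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= (dish.equivalent_diameter_area / 2) ** 2
    hue_deg = hsv[..., 0] * 360.0
    yellow = (
        inside
        & (hue_deg >= hue_band[0])
        & (hue_deg <= hue_band[1])
        & (hsv[..., 1] >= saturation_min)
    )
    return float(yellow.sum() / px_per_cm**2)


def compare_activity(measurements: list[PlateMeasurement]) -> StatResult:
    """One-way ANOVA plus Tukey pairwise table across strains.

    Blanks and control plates enter as strains of their own, each needing
    at least two replicates.
    """
    groups: dict[str, list[float]] = {}
    for m in measurements:
        groups.setdefault(m.strain, []).append(m.yellow_area_cm2)
    if len(groups) < 2:
        raise ValueError("need at least two strains/plate groups")
    names = sorted(groups)
    arrays = [groups[n] for n in names]
    result = anova_oneway(arrays)
    result.pairwise = tukey_hsd(arrays, names=names)
    return result
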