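"""Retinal vacuolar-degeneration quantification.

Vacuoles in tangential retinal sections appear as pale regions against
stained tissue. They are segmented by thresholding (Otsu or fixed) within a
tissue mask, hole-filling, and 8-connected component labelling. The
degeneration metric is the vacuole-area fraction: the summed area of
vacuoles whose equivalent circular diameter exceeds a 4 um cut-off, divided
by the total retinal area. Genotypes are compared against a control by
unpaired t-tests with a Dunnett many-to-one adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .stats import dunnett_adjust

__all__ = [
    "RetinaImage",
    "VacuoleRegion",
    "segment_vacuoles",
    "vacuole_fraction",
    "analyze_image",
    "compare_groups",
]


@dataclass
class RetinaImage:
    """Grayscale retinal section with physical pixel size.

    ``mask`` (optional boolean array, same shape) delimits the tissue; the
    full frame is used when absent.
    """

    pixels: np.ndarray
    pixel_size_um: float
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match the image")

    @property
    def tissue_area_um2(self) -> float:
        n = int(self.mask.sum()) if self.mask is not None else self.pixels.size
        return n * self.pixel_size_um**2


@dataclass(frozen=True)
class VacuoleRegion:
    """One segmented vacuole."""

    label: int
    area_um2: float
    equivalent_diameter_um: float
    feret_diameter_um: float
    centroid: tuple[float, float]


def segment_vacuoles(
    image: RetinaImage, threshold: str | float = "otsu"
) -> list[VacuoleRegion]:
    """Segment vacuoles as bright regions within the tissue mask.

    Foreground pixels exceed the threshold; holes are filled and components
    are labelled with 8-connectivity. With ``threshold='otsu'`` an
    all-foreground or all-background outcome raises, suggesting a fixed
    threshold.
    """
    px = image.pixels.astype(float)
    inside = image.mask if image.mask is not None else np.ones_like(px, dtype=bool)
    values = px[inside]
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError("threshold must be 'otsu' or a number")
        if np.all(values == values.flat[0]):
            raise ValueError(
                "uniform intensities: Otsu thresholding is undefined; pass a fixed threshold"
            )
        thr = float(threshold_otsu(values))
    else:
        thr = float(threshold)
    fg = (px > thr) & inside
    if isinstance(threshold, str) and (fg[inside].all() or not fg[inside].any()):
        raise ValueError(
            "Otsu produced an all-foreground or all-background segmentation; "
            "use a fixed threshold"
        )
    fg = ndimage.binary_fill_holes(fg)
    fg &= inside
    labels = label(fg, connectivity=2)
    s = image.pixel_size_um
    out = []
    for rp in regionprops(labels):
        area_um2 = rp.area * s**2
        out.append(
            VacuoleRegion(
                label=int(rp.label),
                area_um2=float(area_um2),
                equivalent_diameter_um=float(2.0 * np.sqrt(area_um2 / np.pi)),
                feret_diameter_um=float(rp.feret_diameter_max * s),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return out


def vacuole_fraction(
    regions: Sequence[VacuoleRegion],
    total_area_um2: float,
    min_diameter_um: float = 4.0,
    diameter: str = "equivalent",
) -> float:
    """Vacuole-area fraction of the retina.

    Regions with diameter <= ``min_diameter_um`` are excluded (the cut-off
    follows the >4 um rule); the remaining areas are summed and divided by
    the total retinal area. ``diameter`` selects the equivalent circular
    diameter (default) or the maximum Feret diameter.
    """
    if total_area_um2 <= 0:
        raise ValueError("total_area_um2 must be > 0")
    if diameter not in ("equivalent", "feret"):
        raise ValueError("diameter must be 'equivalent' or 'feret'")
    key = "equivalent_diameter_um" if diameter == "equivalent" else "feret_diameter_um"
    qualifying = [r.area_um2 for r in regions if getattr(r, key) > min_diameter_um]
    frac = float(sum(qualifying) / total_area_um2)
    return min(frac, 1.0)


def analyze_image(
    image: RetinaImage,
    threshold: str | float = "otsu",
    min_diameter_um: float = 4.0,
    diameter: str = "equivalent",
) -> dict:
    """Segment one section and report its vacuole metrics."""
    regions = segment_vacuoles(image, threshold)
    total = image.tissue_area_um2
    return {
        "n_vacuoles": len(regions),
        "regions": regions,
        "total_area_um2": total,
        "vacuole_fraction": vacuole_fraction(regions, total, min_diameter_um, diameter),
    }


def compare_groups(
    fractions_by_genotype: Mapping[str, Sequence[float]],
    control_label: str,
    min_images: int = 3,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare per-genotype vacuole fractions against a control.

    Per non-control genotype: unpaired t p-value and the Dunnett-adjusted
    p-value versus the control group. Each genotype needs at least
    ``min_images`` images.
    """
    if control_label not in fractions_by_genotype:
        raise ValueError(f"control label {control_label!r} missing from groups")
    for g, vals in fractions_by_genotype.items():
        if len(vals) < min_images:
            raise ValueError(f"genotype {g!r} has fewer than {min_images} images")
    others = [g for g in fractions_by_genotype if g != control_label]
    if not others:
        return pd.DataFrame(columns=["genotype", "mean", "control_mean", "t", "p", "p_dunnett"])
    control = np.asarray(fractions_by_genotype[control_label], dtype=float)
    groups = [np.asarray(fractions_by_genotype[g], dtype=float) for g in others]
    res = dunnett_adjust(control, groups, n_draws=n_draws, seed=seed)
    return pd.DataFrame(
        {
            "genotype": others,
            "mean": [g.mean() for g in groups],
            "control_mean": control.mean(),
            "t": res.statistic,
            "p": res.p_raw,
            "p_dunnett": res.p_adjusted,
        }
    )
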