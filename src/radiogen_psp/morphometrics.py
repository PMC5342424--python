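"""Morphological features from labeled tumor masks.

Input masks are 2-D integer-label images (0 background, 1 enhanced tumor,
2 necrotic core), one per axial slice. Per slice, two groups of features
are computed:

* class-level features on the union of each tissue class: area, margin
  thickness, length (major axis), equivalent radius, region count and the
  class's proportion of total tumor area;
* shape descriptors of the *primary region* (largest 8-connected component
  of the class): area, perimeter, bounding-box area, major/minor axis
  length, orientation, solidity, eccentricity, compactness and sphericity.

Per case, the feature vector concatenates the features of the slice with
the largest tumor area with the mean/max/min/sum of every feature over all
slices. The enumeration is self-documenting: `feature_manifest()` returns
name -> definition for every entry.

Conventions: 8-connectivity throughout; row-major 0-based coordinates with
pixel centers on the integer lattice; perimeter by the 4-direction Crofton
estimator (low bias on smooth outlines); compactness = perimeter^2 /
(4*pi*area), clipped below at the
disk value 1; sphericity = 2*sqrt(pi*area)/perimeter = 1/sqrt(compactness),
clipped above at 1. Margin thickness is 4 * mean(EDT - 1/2) over class
pixels (EDT = Euclidean distance to the nearest background-or-other-class
pixel), an estimator calibrated so a constant-width margin of width w
returns w exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .synthetic_data import MaskStack

__all__ = [
    "ENHANCED",
    "NECROTIC",
    "CLASS_NAMES",
    "SliceFeatures",
    "ClassFeatures",
    "PrimaryRegionProps",
    "EmptyRegionError",
    "slice_features",
    "primary_region_props",
    "slice_feature_table",
    "aggregate_case",
    "case_features",
    "feature_manifest",
]

ENHANCED = 1
NECROTIC = 2
CLASS_NAMES = {ENHANCED: "enhanced", NECROTIC: "necrotic"}

_CLASS_FEATURES = (
    "area",
    "thickness",
    "length",
    "equivalent_radius",
    "region_count",
    "area_proportion",
)
_PRIMARY_FEATURES = (
    "area",
    "perimeter",
    "bbox_area",
    "major_axis_length",
    "minor_axis_length",
    "orientation",
    "solidity",
    "eccentricity",
    "compactness",
    "sphericity",
)


class EmptyRegionError(ValueError):
    """Raised when region properties are requested for an empty tissue class."""


@dataclass
class ClassFeatures:
    """Class-union features of one tissue class on one slice (pixel units)."""

    area: float
    thickness: float
    length: float
    equivalent_radius: float
    region_count: int
    area_proportion: float
    area_mm2: float | None = None


@dataclass
class SliceFeatures:
    """Per-class features of a single mask slice."""

    enhanced: ClassFeatures
    necrotic: ClassFeatures
    pixel_size: float | None = None


@dataclass
class PrimaryRegionProps:
    """Shape descriptors of the largest connected component of a class."""

    area: float
    perimeter: float
    bbox_area: float
    major_axis_length: float
    minor_axis_length: float
    orientation: float
    solidity: float
    eccentricity: float
    compactness: float
    sphericity: float


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    return mask


def _margin_thickness(class_mask: np.ndarray) -> float:
    """4 * mean(EDT - 1/2): equals the width of a constant-width band."""
    if not class_mask.any():
        return 0.0
    padded = np.pad(class_mask, 1)  # image border counts as complement
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return float(4.0 * (edt[class_mask] - 0.5).mean())


def _union_major_axis(class_mask: np.ndarray) -> float:
    """Major axis length of the (possibly disconnected) class union.

    Ellipse-with-equal-second-moments convention: 4 * sqrt(largest
    eigenvalue of the pixel covariance matrix).
    """
    coords = np.argwhere(class_mask).astype(float)
    if len(coords) == 0:
        return 0.0
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eigvals = np.linalg.eigvalsh(cov)
    return float(4.0 * np.sqrt(max(eigvals[-1], 0.0)))


def slice_features(mask_slice: np.ndarray, pixel_size: float | None = None) -> SliceFeatures:
    """Class-union features (area, thickness, length, radius, count, proportion).

    An empty class yields all-zero features with region_count 0.
    """
    mask = _validate_mask(mask_slice)
    total_area = int((mask > 0).sum())
    per_class: dict[int, ClassFeatures] = {}
    for label in (ENHANCED, NECROTIC):
        m = mask == label
        area = int(m.sum())
        if area == 0:
            per_class[label] = ClassFeatures(0.0, 0.0, 0.0, 0.0, 0, 0.0,
                                             0.0 if pixel_size else None)
            continue
        n_regions = int(measure.label(m, connectivity=2).max())
        per_class[label] = ClassFeatures(
            area=float(area),
            thickness=_margin_thickness(m),
            length=_union_major_axis(m),
            equivalent_radius=float(np.sqrt(area / np.pi)),
            region_count=n_regions,
            area_proportion=float(area / total_area),
            area_mm2=float(area * pixel_size**2) if pixel_size else None,
        )
    return SliceFeatures(
        enhanced=per_class[ENHANCED], necrotic=per_class[NECROTIC], pixel_size=pixel_size
    )


def _orientation_from_moments(mu: np.ndarray) -> float:
    """Angle (radians) between the major axis and the column (horizontal) axis.

    Zero for a shape elongated along image columns; range (-pi/2, pi/2].
    ``mu`` is the central-moment table with mu[p, q] = sum (r - rbar)^p (c - cbar)^q.
    """
    mu_rr, mu_cc, mu_rc = mu[2, 0], mu[0, 2], mu[1, 1]
    return float(0.5 * np.arctan2(2.0 * mu_rc, mu_cc - mu_rr))


def primary_region_props(mask_slice: np.ndarray, class_label: int) -> PrimaryRegionProps:
    """Shape descriptors of the largest 8-connected component of a class.

    Ties in area are broken toward the component whose first pixel comes
    earliest in raster (top-left) order.
    """
    mask = _validate_mask(mask_slice)
    m = mask == class_label
    if not m.any():
        name = CLASS_NAMES.get(class_label, str(class_label))
        raise EmptyRegionError(f"no pixels with class {name!r} in this slice")
    labeled = measure.label(m, connectivity=2)
    areas = np.bincount(labeled.ravel())[1:]
    primary_label = int(np.argmax(areas)) + 1  # first max = raster-order tie-break
    primary = labeled == primary_label
    rp = measure.regionprops(primary.astype(np.uint8))[0]

    area = float(rp.area)
    perimeter = float(measure.perimeter_crofton(primary, directions=4))
    if perimeter > 0:
        compactness = max(1.0, perimeter**2 / (4.0 * np.pi * area))
        sphericity = min(1.0, 2.0 * np.sqrt(np.pi * area) / perimeter)
    else:  # degenerate single-pixel / line region
        compactness, sphericity = 1.0, 1.0
    return PrimaryRegionProps(
        area=area,
        perimeter=perimeter,
        bbox_area=float(rp.area_bbox),
        major_axis_length=float(rp.axis_major_length),
        minor_axis_length=float(rp.axis_minor_length),
        orientation=_orientation_from_moments(rp.moments_central),
        solidity=float(rp.solidity),
        eccentricity=float(rp.eccentricity),
        compactness=float(compactness),
        sphericity=float(sphericity),
    )


# ---------------------------------------------------------------------------
# Per-slice table and per-case aggregation
# ---------------------------------------------------------------------------

def slice_feature_table(mask_slice: np.ndarray, pixel_size: float | None = None) -> pd.Series:
    """All per-slice features as a flat named Series (32 entries).

    Primary-region descriptors of an empty class are filled with zeros so
    slices without necrosis aggregate cleanly.
    """
    sf = slice_features(mask_slice, pixel_size)
    values: dict[str, float] = {}
    for label, cls_name in CLASS_NAMES.items():
        cf: ClassFeatures = getattr(sf, cls_name)
        for feat in _CLASS_FEATURES:
            values[f"{cls_name}_{feat}"] = float(getattr(cf, feat))
        try:
            props = primary_region_props(mask_slice, label)
            for feat in _PRIMARY_FEATURES:
                values[f"{cls_name}_primary_{feat}"] = float(getattr(props, feat))
        except EmptyRegionError:
            for feat in _PRIMARY_FEATURES:
                values[f"{cls_name}_primary_{feat}"] = 0.0
    return pd.Series(values)


def aggregate_case(per_slice: list[pd.Series]) -> pd.Series:
    """Case-level vector: largest-slice features + mean/max/min/sum over slices.

    The reference slice is the one with the largest total tumor area
    (enhanced + necrotic); ties go to the lowest slice index.
    """
    if not per_slice:
        raise ValueError("aggregate_case requires at least one slice")
    table = pd.DataFrame(per_slice).reset_index(drop=True)
    tumor_area = table["enhanced_area"] + table["necrotic_area"]
    largest = int(np.argmax(tumor_area.values))  # first max = lowest index
    parts = {
        "largest": table.iloc[largest],
        "mean": table.mean(),
        "max": table.max(),
        "min": table.min(),
        "sum": table.sum(),
    }
    out = {}
    for agg, series in parts.items():
        for name, value in series.items():
            out[f"{agg}_{name}"] = float(value)
    return pd.Series(out)


def case_features(stack: MaskStack | list[np.ndarray], pixel_size: float | None = None) -> pd.Series:
    """Convenience: per-case feature vector straight from a mask stack."""
    if isinstance(stack, MaskStack):
        slices = stack.slices
        pixel_size = pixel_size if pixel_size is not None else stack.pixel_size
    else:
        slices = list(stack)
    tables = [slice_feature_table(s, pixel_size) for s in slices]
    return aggregate_case(tables)


_CLASS_DEFS = {
    "area": "total class pixels (px^2)",
    "thickness": "margin thickness: 4 * mean(EDT - 1/2) over class pixels (px)",
    "length": "major axis of the class union from second-order moments (px)",
    "equivalent_radius": "sqrt(area / pi) (px)",
    "region_count": "number of 8-connected components of the class",
    "area_proportion": "class area / (enhanced + necrotic) area",
}
_PRIMARY_DEFS = {
    "area": "primary-region pixels (px^2)",
    "perimeter": "Crofton (4-direction) perimeter of the primary region (px)",
    "bbox_area": "bounding-box area of the primary region (px^2)",
    "major_axis_length": "major axis of the moment-matched ellipse (px)",
    "minor_axis_length": "minor axis of the moment-matched ellipse (px)",
    "orientation": "major-axis angle vs. the horizontal image axis (rad)",
    "solidity": "area / convex hull area",
    "eccentricity": "eccentricity of the moment-matched ellipse",
    "compactness": "perimeter^2 / (4*pi*area), >= 1, disk = 1",
    "sphericity": "2*sqrt(pi*area) / perimeter, <= 1, disk = 1",
}


def feature_manifest() -> dict[str, str]:
    """Name -> definition for every entry of the case feature vector.

    Note: 'length' and the class-union features are computed on the union of
    all components of the class, not only the primary region.
    """
    slice_defs: dict[str, str] = {}
    for cls_name in CLASS_NAMES.values():
        for feat, definition in _CLASS_DEFS.items():
            slice_defs[f"{cls_name}_{feat}"] = f"{cls_name} class: {definition}"
        for feat, definition in _PRIMARY_DEFS.items():
            slice_defs[f"{cls_name}_primary_{feat}"] = (
                f"{cls_name} primary region: {definition} (0 if the class is empty)"
            )
    agg_defs = {
        "largest": "value on the slice with the largest total tumor area",
        "mean": "mean over all slices",
        "max": "maximum over all slices",
        "min": "minimum over all slices",
        "sum": "sum over all slices",
    }
    manifest = {}
    for agg, agg_def in agg_defs.items():
        for name, definition in slice_defs.items():
            manifest[f"{agg}_{name}"] = f"{agg_def}; {definition}"
    return manifest
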