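"""Per-nucleus 5mC immunofluorescence intensity quantification.

Works on 8-bit grayscale micrographs (0–255). Nuclei are segmented as
connected components above a threshold (Otsu by default), small components
are discarded, and each nucleus is summarized by the arithmetic mean of its
pixel intensities minus a median-of-background estimate (switchable off for
parity with raw ImageJ-style means).

Group comparisons are only meaningful when all images were captured under
the same exposure conditions; the batch helpers enforce matching exposure
tags and raise on mixed batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "FluorescenceImage",
    "segment_nuclei",
    "mean_nuclear_intensity",
    "intensity_surface",
    "measure_if_batch",
    "read_fluorescence_image",
    "write_if_tsv",
]

MIN_NUCLEUS_SIZE_PX = 50


@dataclass(frozen=True)
class FluorescenceImage:
    """8-bit intensity grid with optional nucleus masks and acquisition meta."""

    values: np.ndarray
    masks: list[np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("fluorescence image must be 2D")
        if v.dtype != np.uint8:
            if (v < 0).any() or (v > 255).any():
                raise ValueError("intensities must lie within [0, 255]")
            v = v.astype(np.uint8)
        object.__setattr__(self, "values", v)

    @property
    def group(self) -> str:
        return self.meta.get("group", "")

    @property
    def exposure(self) -> str:
        return self.meta.get("exposure", "")


def segment_nuclei(
    img: FluorescenceImage,
    threshold: float | str = "otsu",
    min_size: int = MIN_NUCLEUS_SIZE_PX,
) -> list[np.ndarray]:
    """Connected components above a threshold, ordered by centroid row-major.

    Touching nuclei merge into one component — a documented limitation of
    threshold-based segmentation. Zero nuclei is a valid outcome.
    """
    v = img.values
    if threshold == "otsu":
        if v.min() == v.max():
            return []
        thr = threshold_otsu(v)
    else:
        thr = float(threshold)
    binary = v > thr
    lab = label(binary)
    props = sorted(
        (p for p in regionprops(lab) if p.area >= min_size),
        key=lambda p: (p.centroid[0], p.centroid[1]),
    )
    return [lab == p.label for p in props]


def mean_nuclear_intensity(
    img: FluorescenceImage,
    masks: list[np.ndarray],
    background_correction: bool = True,
) -> list[float]:
    """Mean pixel intensity per nucleus, minus the background median.

    The background estimate is the median intensity over all pixels outside
    every mask; with ``background_correction=False`` the raw means are
    returned.
    """
    v = img.values.astype(float)
    bg = 0.0
    if background_correction:
        union = np.zeros(v.shape, dtype=bool)
        for m in masks:
            union |= m
        outside = ~union
        bg = float(np.median(v[outside])) if outside.any() else 0.0
    out = []
    for m in masks:
        if not m.any():
            raise ValueError("empty nucleus mask")
        if m.shape != v.shape:
            raise ValueError("mask shape does not match image")
        out.append(float(v[m].mean()) - bg)
    return out


def intensity_surface(img: FluorescenceImage, factor: int = 1) -> pd.DataFrame:
    """Downsampled (x, y, intensity) table for 3D surface rendering."""
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    v = img.values[::factor, ::factor]
    yy, xx = np.mgrid[0: v.shape[0], 0: v.shape[1]]
    return pd.DataFrame({
        "x": (xx.ravel() * factor).astype(int),
        "y": (yy.ravel() * factor).astype(int),
        "intensity": v.ravel().astype(int),
    })


def measure_if_batch(
    images: list[FluorescenceImage],
    threshold: float | str = "otsu",
    min_size: int = MIN_NUCLEUS_SIZE_PX,
    background_correction: bool = True,
    use_provided_masks: bool = False,
) -> pd.DataFrame:
    """Segment and measure a batch into a tidy table (id, group, area, mean).

    All images must carry the same exposure tag — intensity comparisons
    across different exposures are not valid and raise immediately.
    """
    if not images:
        raise ValueError("no images")
    exposures = {img.exposure for img in images}
    if len(exposures) > 1:
        raise ValueError(
            f"mixed exposure tags {sorted(exposures)}: group comparisons "
            "require identical exposure conditions"
        )
    rows = []
    for i, img in enumerate(images):
        if use_provided_masks and img.masks is not None:
            masks = img.masks
        else:
            masks = segment_nuclei(img, threshold, min_size)
        means = mean_nuclear_intensity(img, masks, background_correction)
        for j, (m, mu) in enumerate(zip(masks, means)):
            rows.append({
                "id": f"img{i:03d}_nuc{j:03d}",
                "group": img.group,
                "area_px": int(m.sum()),
                "mean_intensity": mu,
            })
    return pd.DataFrame(rows, columns=["id", "group", "area_px", "mean_intensity"])


def read_fluorescence_image(
    path: str | Path, group: str = "", exposure: str = "default"
) -> FluorescenceImage:
    """Load an 8-bit grayscale TIFF or PNG micrograph."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        v = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        v = iio.imread(path)
    v = np.asarray(v)
    if v.ndim == 3:  # collapse an RGB(A) read of a grayscale image
        v = v[..., 0]
    return FluorescenceImage(values=v, meta={"group": group, "exposure": exposure,
                                             "source": str(path)})


def write_fluorescence_image(img: FluorescenceImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, img.values)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img.values)


def write_if_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
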