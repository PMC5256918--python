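"""Feulgen image-cytometry statistics: S_C% and AAR per nucleus.

The digitized nucleus is a per-pixel absorbance map. Two thresholds define
the measurement:

* the **removal floor** (default 0.020 absorbance): pixels at or below it
  are background and are removed from the nuclear image;
* the **condensed cutoff** (default 0.100 absorbance): nuclear pixels at or
  above it count as condensed chromatin.

From the four primitives — total nuclear area S_T, condensed area S_C (both
in μm², pixel area = pixel_um²), total integrated absorbance A_T and
condensed integrated absorbance A_C — the chromatin-texture statistics are

    S_C% = 100 * S_C / S_T
    AAR  = (A_C / S_C) / (A_T / S_T)

AAR (average absorption ratio) is the mean absorbance of condensed
chromatin relative to the mean absorbance of the whole nucleus; by
construction it is >= 1 whenever S_C > 0, and it is undefined (NaN) when no
pixel reaches the cutoff. Chromatin decondensation shows up as lower S_C%
with higher AAR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REMOVAL_FLOOR = 0.020
CONDENSED_CUTOFF = 0.100
PIXEL_UM = 0.5

__all__ = [
    "AbsorbanceImage",
    "NucleusMeasurement",
    "nuclear_mask",
    "condensed_mask",
    "measure_nucleus",
    "batch_measure",
    "read_absorbance_map",
    "write_measurements_tsv",
    "plot_scatter",
    "REMOVAL_FLOOR",
    "CONDENSED_CUTOFF",
    "PIXEL_UM",
]


@dataclass(frozen=True)
class AbsorbanceImage:
    """2D per-pixel absorbance map with a physical pixel size (μm)."""

    values: np.ndarray
    pixel_um: float = PIXEL_UM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("absorbance map must be 2D")
        if not np.all(np.isfinite(v)):
            raise ValueError("absorbance values must be finite")
        if (v < 0).any():
            raise ValueError("absorbance values must be >= 0")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        object.__setattr__(self, "values", v)

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_um ** 2


@dataclass(frozen=True)
class NucleusMeasurement:
    """The cytometry quartet and its derived statistics for one nucleus.

    ``AAR`` is NaN when S_C = 0 (no condensed pixel): the ratio is undefined
    there, and downstream statistics must drop it explicitly rather than see
    a fabricated 0 or infinity.
    """

    S_T: float
    S_C: float
    A_T: float
    A_C: float
    Sc_percent: float
    AAR: float
    removal_floor: float = REMOVAL_FLOOR
    cutoff: float = CONDENSED_CUTOFF


def nuclear_mask(img: AbsorbanceImage, removal_floor: float = REMOVAL_FLOOR) -> np.ndarray:
    """Pixels retained as nuclear signal: absorbance strictly above the floor.

    Raises ``ValueError("no nuclear signal")`` when every pixel is at or
    below the floor.
    """
    mask = img.values > removal_floor
    if not mask.any():
        raise ValueError("no nuclear signal")
    return mask


def condensed_mask(
    img: AbsorbanceImage,
    cutoff: float = CONDENSED_CUTOFF,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Subset of the nuclear mask at or above the condensed cutoff.

    The comparison is inclusive (>= cutoff) so that the cutoff value itself
    is attainable; an empty condensed mask is a valid outcome.
    """
    if mask is None:
        mask = nuclear_mask(img)
    if not mask.any():
        raise ValueError("nuclear mask is empty")
    return mask & (img.values >= cutoff)


def measure_nucleus(
    img: AbsorbanceImage,
    removal_floor: float = REMOVAL_FLOOR,
    cutoff: float = CONDENSED_CUTOFF,
) -> NucleusMeasurement:
    """Compute S_T, S_C, A_T, A_C, S_C% and AAR for a single-nucleus image."""
    nmask = nuclear_mask(img, removal_floor)
    cmask = condensed_mask(img, cutoff, nmask)
    px = img.pixel_area_um2
    S_T = float(nmask.sum()) * px
    S_C = float(cmask.sum()) * px
    A_T = float(img.values[nmask].sum())
    A_C = float(img.values[cmask].sum())
    # ratio first: S_C/S_T reduces exactly to the pixel-count fraction,
    # so S_C% agrees bitwise with 100 x the ground-truth fraction
    Sc_percent = 100.0 * (S_C / S_T)
    if S_C > 0:
        AAR = (A_C / S_C) / (A_T / S_T)
    else:
        AAR = math.nan
    return NucleusMeasurement(
        S_T=S_T, S_C=S_C, A_T=A_T, A_C=A_C,
        Sc_percent=Sc_percent, AAR=AAR,
        removal_floor=removal_floor, cutoff=cutoff,
    )


def batch_measure(
    images: Sequence[AbsorbanceImage],
    group_label: str,
    ids: Sequence[str] | None = None,
    removal_floor: float = REMOVAL_FLOOR,
    cutoff: float = CONDENSED_CUTOFF,
) -> pd.DataFrame:
    """Measure a list of single-nucleus images into a tidy table.

    Per-image failures (e.g. no pixel above the floor) are logged and the
    offending image skipped; the batch itself only fails when the input list
    is empty. Columns: id, group, S_T_um2, S_C_um2, A_T, A_C, Sc_percent,
    AAR.
    """
    if len(images) == 0:
        raise ValueError("no images")
    if ids is None:
        ids = [f"{group_label}_{i:03d}" for i in range(len(images))]
    if len(ids) != len(images):
        raise ValueError("ids and images length mismatch")
    rows = []
    for img_id, img in zip(ids, images):
        try:
            m = measure_nucleus(img, removal_floor, cutoff)
        except ValueError as exc:
            logger.warning("skipping %s: %s", img_id, exc)
            continue
        rows.append({
            "id": img_id, "group": group_label,
            "S_T_um2": m.S_T, "S_C_um2": m.S_C,
            "A_T": m.A_T, "A_C": m.A_C,
            "Sc_percent": m.Sc_percent, "AAR": m.AAR,
        })
    return pd.DataFrame(
        rows,
        columns=["id", "group", "S_T_um2", "S_C_um2", "A_T", "A_C",
                 "Sc_percent", "AAR"],
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_absorbance_map(path: str | Path, pixel_um: float = PIXEL_UM) -> AbsorbanceImage:
    """Load an absorbance map from plain-matrix CSV or 32-bit float TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        values = tifffile.imread(path).astype(float)
    else:
        values = np.loadtxt(path, delimiter=",", dtype=float)
    return AbsorbanceImage(values=np.atleast_2d(values), pixel_um=pixel_um)


def write_absorbance_map(img: AbsorbanceImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, img.values.astype(np.float32))
    else:
        np.savetxt(path, img.values, delimiter=",", fmt="%.6g")


def write_measurements_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def plot_scatter(table: pd.DataFrame, path: str | Path) -> None:
    """S_C% (x) vs AAR (y) scatter, one color per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in table.groupby("group", sort=True):
        ax.scatter(sub["Sc_percent"], sub["AAR"], s=12, label=str(grp), alpha=0.7)
    ax.set_xlabel("S$_C$ %")
    ax.set_ylabel("AAR")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
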