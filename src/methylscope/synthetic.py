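"""Synthetic Feulgen nuclei, 5mC immunofluorescence fields and DNA IR spectra.

Every generator carries its ground truth alongside the rendered data, so the
downstream measurement stages (cytometry, FT-IR band fitting, IF intensity
quantification) can be tested as parameter-recovery problems: simulate with a
known condensed-chromatin fraction / methylation level, measure, and compare
against the emitted truth rather than the requested value.

Conventions
-----------
* Absorbance images are dimensionless optical-density grids on 0.5 μm pixels
  (the scanning-spot size of the cytometry instrument).
* IR spectra live on a descending wavenumber grid, 3600 → 800 cm⁻¹ at
  4 cm⁻¹ resolution by default, and bands are Gaussians parameterized by
  FWHM with closed-form area ``h * fwhm * sqrt(pi / (4 ln 2))``.
* Immunofluorescence images are 8-bit (0–255).
* All randomness is drawn from ``numpy.random.default_rng(seed)``; equal
  seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cytometry import AbsorbanceImage
from .ftir import GAUSS_AREA_FACTOR, Spectrum, SpectrumState, gaussian_profile
from .ifquant import FluorescenceImage

__all__ = [
    "BandSpec",
    "NucleusSimParams",
    "SpectrumSimParams",
    "SimulatedNucleus",
    "default_dna_band_library",
    "generate_ftir_spectrum",
    "generate_nuclear_absorbance_map",
    "generate_if_image",
    "DEMO_METHYLATION_LEVELS",
]

#: Illustrative three-group demo levels (control / 1 mM / 20 mM). These mimic
#: the *direction* of the dose effect only; they are not measured values.
DEMO_METHYLATION_LEVELS: dict[str, float] = {
    "control": 1.0,
    "vpa_1mM": 0.6,
    "vpa_20mM": 0.3,
}


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusSimParams:
    """Ground-truth description of one simulated Feulgen-stained nucleus.

    Parameters
    ----------
    radius_um:
        Nuclear radius in μm.
    condensed_fraction:
        Target fraction of nuclear area occupied by condensed-chromatin
        blobs, in [0, 1].
    diffuse_level, condensed_level:
        Absorbance plateaus of diffuse and condensed chromatin. For the
        nucleus to be recoverable by the standard thresholds the diffuse
        level must sit above the 0.020 removal floor and at or below the
        0.100 condensed cutoff, with the condensed level above the cutoff;
        this is enforced when ``recoverable`` is true.
    noise_sd:
        Additive Gaussian absorbance noise, truncated at zero.
    pixel_um:
        Pixel side length; defaults to the 0.5 μm scanning spot.
    """

    radius_um: float
    condensed_fraction: float
    diffuse_level: float = 0.06
    condensed_level: float = 0.20
    noise_sd: float = 0.0
    pixel_um: float = 0.5
    seed: int = 0
    recoverable: bool = True

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if not 0.0 <= self.condensed_fraction <= 1.0:
            raise ValueError("condensed_fraction must lie in [0, 1]")
        if self.diffuse_level <= 0.020:
            raise ValueError("diffuse_level must exceed the 0.020 removal floor")
        if self.condensed_level <= self.diffuse_level:
            raise ValueError("condensed_level must exceed diffuse_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.recoverable:
            if not (self.condensed_level > 0.100 and self.diffuse_level <= 0.100):
                raise ValueError(
                    "recoverable nucleus requires condensed_level > 0.100 "
                    "and diffuse_level <= 0.100"
                )


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian IR band: center (cm⁻¹), height (absorbance), FWHM (cm⁻¹).

    ``methylation_scaled`` bands have their height multiplied by the
    simulation's methylation level, emulating –CH₃-group vibrations whose
    intensity tracks 5-methylcytosine abundance.
    """

    center: float
    height: float
    fwhm: float
    assignment: str = ""
    methylation_scaled: bool = False

    def __post_init__(self) -> None:
        if not 800.0 <= self.center <= 3600.0:
            raise ValueError("band center must lie within 3600-800 cm^-1")
        if self.height <= 0:
            raise ValueError("band height must be positive")
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be positive")

    @property
    def area(self) -> float:
        """Closed-form Gaussian area h * fwhm * sqrt(pi / (4 ln 2))."""
        return self.height * self.fwhm * GAUSS_AREA_FACTOR


@dataclass(frozen=True)
class SpectrumSimParams:
    methylation_level: float = 1.0
    bands: tuple[BandSpec, ...] = ()
    baseline_coeffs: tuple[float, ...] = ()
    noise_sd: float = 0.0
    wavenumber_range: tuple[float, float] = (3600.0, 800.0)
    resolution: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.methylation_level <= 1.0:
            raise ValueError("methylation_level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))
        hi, lo = max(self.wavenumber_range), min(self.wavenumber_range)
        object.__setattr__(self, "wavenumber_range", (hi, lo))


# ---------------------------------------------------------------------------
# IR band library and spectrum generator
# ---------------------------------------------------------------------------

def default_dna_band_library() -> list[BandSpec]:
    """Gaussian band set emulating an extracted-DNA absorption spectrum.

    Centers follow standard DNA IR assignments: the NH/NH₂ stretching region
    near 3410 cm⁻¹ (the tallest band), the –CH₃ stretching band at
    2935 cm⁻¹ and –CH₃ bending band at 1375 cm⁻¹ (both scaled by the
    methylation level), the 1707 cm⁻¹ base-pairing shoulder, the
    thymine/adenine band at 1661 cm⁻¹, cytosine in-plane vibrations at
    1492 cm⁻¹, and the phosphate doublet ν_as PO₂⁻ at 1225 cm⁻¹ (B-form
    marker) above ν_s PO₂⁻ at 1080 cm⁻¹.

    Heights and FWHMs are generator defaults chosen to reproduce the
    qualitative shape of such spectra (global maximum in the NH/NH₂ region,
    ν_s below ν_as, a resolvable 1707 shoulder); they are not measured
    values.
    """
    return [
        BandSpec(3410.0, 1.00, 180.0, "NH/NH2 stretch"),
        BandSpec(2935.0, 0.30, 40.0, "C-H stretch (-CH3)", methylation_scaled=True),
        BandSpec(1707.0, 0.28, 14.0, "base-pairing shoulder"),
        BandSpec(1661.0, 0.65, 50.0, "thymine/adenine"),
        BandSpec(1492.0, 0.35, 25.0, "cytosine in-plane"),
        BandSpec(1375.0, 0.30, 25.0, "CH3 bend", methylation_scaled=True),
        BandSpec(1225.0, 0.55, 45.0, "nu_as PO2- (B-form)"),
        BandSpec(1080.0, 0.42, 40.0, "nu_s PO2-"),
    ]


def generate_ftir_spectrum(params: SpectrumSimParams) -> Spectrum:
    """Render a raw-state spectrum from a band library plus baseline and noise.

    Absorbance is the sum of Gaussian bands (heights of methylation-scaled
    bands multiplied by ``methylation_level``), a polynomial baseline
    evaluated in ascending-power coefficient order, and seeded Gaussian
    noise.
    """
    if not params.bands:
        raise ValueError("no bands")
    hi, lo = params.wavenumber_range
    n = int(round((hi - lo) / params.resolution)) + 1
    wavenumbers = hi - params.resolution * np.arange(n)
    absorbance = np.zeros(n, dtype=float)
    for band in params.bands:
        h = band.height * (params.methylation_level if band.methylation_scaled else 1.0)
        absorbance += gaussian_profile(wavenumbers, band.center, h, band.fwhm)
    if params.baseline_coeffs:
        absorbance += np.polynomial.polynomial.polyval(
            wavenumbers, np.asarray(params.baseline_coeffs, dtype=float)
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        absorbance += rng.normal(0.0, params.noise_sd, size=n)
    return Spectrum(
        wavenumbers=wavenumbers,
        absorbances=absorbance,
        state=SpectrumState.RAW,
        meta={"synthetic": True, "methylation_level": params.methylation_level},
    )


def noiseless_band_sum(params: SpectrumSimParams, wavenumbers: np.ndarray) -> np.ndarray:
    """Pure band component (no baseline, no noise) on an arbitrary grid.

    Serves as the template against which corrected/averaged spectra are
    compared in recovery tests.
    """
    y = np.zeros_like(np.asarray(wavenumbers, dtype=float))
    for band in params.bands:
        h = band.height * (params.methylation_level if band.methylation_scaled else 1.0)
        y += gaussian_profile(wavenumbers, band.center, h, band.fwhm)
    return y


# ---------------------------------------------------------------------------
# Feulgen nucleus generator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedNucleus:
    """A rendered nucleus plus its ground truth."""

    image: AbsorbanceImage
    nucleus_mask: np.ndarray
    condensed_mask: np.ndarray
    realized_fraction: float
    params: NucleusSimParams = field(repr=False)


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_nuclear_absorbance_map(params: NucleusSimParams) -> SimulatedNucleus:
    """Render a circular nucleus with condensed-chromatin blobs.

    Condensed chromatin is laid down as rejection-sampled non-overlapping
    disks at ``condensed_level``; the last disk is trimmed pixelwise so the
    realized blob area matches the requested fraction to within one pixel.
    The remaining nuclear interior sits at ``diffuse_level`` and the
    background at zero. The realized fraction (from the emitted ground-truth
    mask) is the reference value for recovery tests.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    r_px = p.radius_um / p.pixel_um
    margin = 2
    size = int(math.ceil(2 * r_px)) + 2 * margin
    c = (size - 1) / 2.0
    nucleus = _disk_mask((size, size), c, c, r_px)
    n_nuc = int(nucleus.sum())
    if n_nuc == 0:
        raise ValueError("nucleus smaller than one pixel")

    target = int(round(p.condensed_fraction * n_nuc))
    condensed = np.zeros_like(nucleus)
    if target >= n_nuc:
        condensed = nucleus.copy()
    elif target > 0:
        blob_r_px = max(1.0, 0.1 * r_px)
        centers: list[tuple[float, float, float]] = []
        attempts = 0
        while condensed.sum() < target and attempts < 20_000:
            attempts += 1
            br = blob_r_px * rng.uniform(0.6, 1.4)
            ang = rng.uniform(0, 2 * math.pi)
            rad = r_px * math.sqrt(rng.uniform(0, 1))
            by, bx = c + rad * math.sin(ang), c + rad * math.cos(ang)
            # non-overlapping while the packing allows it; past the packing
            # limit (high fractions) blobs may merge so the target is met
            if attempts < 2_000 and any(
                    (by - y0) ** 2 + (bx - x0) ** 2 < (br + r0) ** 2
                    for y0, x0, r0 in centers):
                continue
            blob = _disk_mask((size, size), by, bx, br) & nucleus & ~condensed
            if not blob.any():
                continue
            centers.append((by, bx, br))
            overshoot = int(condensed.sum() + blob.sum()) - target
            if overshoot > 0:
                # trim the outermost pixels of this blob to land exactly on target
                ys, xs = np.nonzero(blob)
                d2 = (ys - by) ** 2 + (xs - bx) ** 2
                keep = np.argsort(d2, kind="stable")[: blob.sum() - overshoot]
                blob = np.zeros_like(blob)
                blob[ys[keep], xs[keep]] = True
            condensed |= blob

    values = np.zeros((size, size), dtype=float)
    values[nucleus] = p.diffuse_level
    values[condensed] = p.condensed_level
    if p.noise_sd > 0:
        values = values + rng.normal(0.0, p.noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)

    return SimulatedNucleus(
        image=AbsorbanceImage(values=values, pixel_um=p.pixel_um),
        nucleus_mask=nucleus,
        condensed_mask=condensed,
        realized_fraction=float(condensed.sum()) / n_nuc,
        params=replace(p),
    )


# ---------------------------------------------------------------------------
# Immunofluorescence generator
# ---------------------------------------------------------------------------

def generate_if_image(
    n_nuclei: int,
    methylation_level: float,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    radius_px: float = 16.0,
    base_signal: float = 40.0,
    gain: float = 160.0,
    group: str = "",
    exposure: str = "default",
) -> FluorescenceImage:
    """Render an 8-bit 5mC immunofluorescence field.

    Each nucleus is a disk whose interior intensity is
    ``background + base_signal + gain * methylation_level`` plus Gaussian
    noise, clipped to [0, 255] — an affine increasing map from methylation
    level to signal, matching the direction in which anti-5mC staining
    responds to demethylation. Ground-truth masks ride along on the returned
    image.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if not 0.0 <= methylation_level <= 1.0:
        raise ValueError("methylation_level must lie in [0, 1]")
    if not 0 <= background <= 255:
        raise ValueError("background must be an 8-bit intensity")
    if background + base_signal + gain > 255:
        raise ValueError("background + signal exceeds the 8-bit range")
    rng = np.random.default_rng(seed)
    values = np.full(shape, float(background))
    masks: list[np.ndarray] = []
    level = background + base_signal + gain * methylation_level
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(masks) < n_nuclei and attempts < 10_000:
        attempts += 1
        cy = rng.uniform(radius_px, shape[0] - radius_px)
        cx = rng.uniform(radius_px, shape[1] - radius_px)
        if any((cy - y0) ** 2 + (cx - x0) ** 2 < (2.2 * radius_px) ** 2
               for y0, x0 in centers):
            continue
        centers.append((cy, cx))
        m = _disk_mask(shape, cy, cx, radius_px)
        values[m] = level
        masks.append(m)
    if len(masks) < n_nuclei:
        raise ValueError("could not place all nuclei without overlap")
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=shape)
    values = np.clip(np.rint(values), 0, 255).astype(np.uint8)
    return FluorescenceImage(
        values=values,
        masks=masks,
        meta={"group": group, "exposure": exposure,
              "methylation_level": methylation_level},
    )
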