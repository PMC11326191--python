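"""Quantitative-phase background correction and dry-mass quantification.

A QPI image measures the optical path-length shift phi (radians) accumulated
through the specimen.  Dry-mass surface density follows from the specific
refractive increment alpha (~1.8e-4 m^3/kg for biomolecules):

    rho = phi * lambda / (2 * pi * alpha)

and cell dry mass is the pixel-area-weighted sum of rho over the cell label.
Phase reconstruction itself (e.g. DPC deconvolution) is upstream of this
package; phase images are consumed, not produced (outside the simulator).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .qdf_core import fit_background_poly

logger = logging.getLogger(__name__)

__all__ = ["PhaseImage", "MassConfig", "correct_phase_background",
           "density_map", "cell_dry_mass", "mass_per_area"]


@dataclass
class PhaseImage:
    """2-D phase-shift map (radians) with the metadata needed for mass."""

    phase: np.ndarray
    wavelength_um: float
    pixel_area_um2: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase image contains non-finite values")
        if self.wavelength_um <= 0 or self.pixel_area_um2 <= 0:
            raise ValueError("wavelength and pixel area must be positive")


@dataclass(frozen=True)
class MassConfig:
    """Specific refractive increment alpha, in m^3/kg."""

    alpha_m3_per_kg: float = 1.8e-4

    def __post_init__(self) -> None:
        if self.alpha_m3_per_kg <= 0:
            raise ValueError("alpha must be positive")


def correct_phase_background(
    p: PhaseImage,
    cell_mask: np.ndarray,
    degree: int = 8,
) -> PhaseImage:
    """Remove a polynomial phase background fitted to non-cell pixels.

    ``cell_mask`` marks pixels to exclude from the fit (cells plus a safety
    dilation); the fitted surface is subtracted everywhere.  Negative
    corrected-phase pixels are retained — clipping them would bias dry mass
    upward.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != p.phase.shape:
        raise ValueError("cell_mask shape must match the phase image")
    background = ~cell_mask
    frac = background.mean()
    if frac == 0:
        raise ValueError("cell mask covers the whole field; no background to fit")
    if frac < 0.3:
        logger.warning("correct_phase_background: only %.0f%% of pixels are background", 100 * frac)
    _, corrected = fit_background_poly(p.phase, background, degree=degree)
    return PhaseImage(phase=corrected, wavelength_um=p.wavelength_um,
                      pixel_area_um2=p.pixel_area_um2)


def density_map(p: PhaseImage, cfg: MassConfig = MassConfig()) -> np.ndarray:
    """Dry-mass surface density (pg/um^2), exactly linear in phase.

    rho = phi * lambda / (2*pi*alpha); with lambda in m and alpha in m^3/kg
    the result is kg/m^2, and 1 kg/m^2 = 1e3 pg/um^2.
    """
    lam_m = p.wavelength_um * 1e-6
    rho_kg_m2 = p.phase * lam_m / (2.0 * math.pi * cfg.alpha_m3_per_kg)
    return rho_kg_m2 * 1e3


def cell_dry_mass(density: np.ndarray, labels: np.ndarray, pixel_area_um2: float) -> pd.Series:
    """Dry mass (pg) of each labelled cell: sum of density * pixel area.

    Additive over disjoint labels; label 0 is background and excluded.
    """
    density = np.asarray(density, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != density.shape:
        raise ValueError("labels shape must match density map")
    if np.any(labels < 0):
        raise ValueError("labels must be nonnegative integers")
    ids = np.arange(1, labels.max() + 1) if labels.max() > 0 else np.array([], dtype=int)
    sums = ndimage.sum_labels(density, labels, ids) if len(ids) else np.array([])
    masses = pd.Series(sums * pixel_area_um2, index=pd.Index(ids, name="label"), name="mass_pg")
    empty = [int(i) for i in ids if not np.any(labels == i)]
    if empty:
        logger.warning("cell_dry_mass: empty labels %s reported with mass 0", empty)
    return masses


def mass_per_area(mass_pg: float, area_um2: float) -> float:
    """Dry mass divided by footprint area (pg/um^2) — a proxy for cell rounding."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return mass_pg / area_um2
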