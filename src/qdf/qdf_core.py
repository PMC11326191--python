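"""Quadrant darkfield (QDF) reconstruction and darkfield preprocessing.

Four darkfield images are acquired with the illumination annulus restricted to
one quadrant at a time (top-left, top-right, bottom-left, bottom-right).  Large
features such as cell or bead edges refract light directionally and therefore
light up only under illumination from the opposing quadrant, while sub-wavelength
puncta scatter into a broad Mie cone and contribute equally to all four images.
The anti-symmetric combination

    E = |TL - BR| + |BL - TR|

isolates the directional (edge) component, and

    QDF = c * DF - E,        DF = TL + TR + BL + BR

removes it from the summed darkfield, leaving the isotropic puncta signal.
``c`` is a system-specific scaling factor (typically 0.8-1.0) that matches the
darkfield edge brightness to the edge image; it is estimated by least squares
on a set of edge pixels (:func:`calibrate_c`).

This module also provides camera bit-depth rescaling, empty-field reference
subtraction, and masked 2-D polynomial background removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "QuadrantSet",
    "AcquisitionMeta",
    "CalibrationResult",
    "CalibrationError",
    "scale_to_bit_depth",
    "subtract_reference",
    "sum_darkfield",
    "edge_image",
    "qdf_image",
    "calibrate_c",
    "fit_background_poly",
    "edge_calibration_mask",
]

QUADRANT_ORDER = ("tl", "tr", "bl", "br")


@dataclass
class AcquisitionMeta:
    """Camera/illumination metadata carried with a quadrant set."""

    exposure_ms: float = 220.0
    gain_db: float = 25.0
    bit_depth: int = 12
    wavelength_um: float = 0.5

    @property
    def container_divisor(self) -> int:
        """Divisor taking 16-bit container values back to native counts."""
        return 2 ** (16 - self.bit_depth)


@dataclass
class QuadrantSet:
    """Four co-registered darkfield images, one per illumination quadrant."""

    tl: np.ndarray
    tr: np.ndarray
    bl: np.ndarray
    br: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        shapes = {np.asarray(getattr(self, q)).shape for q in QUADRANT_ORDER}
        if len(shapes) != 1:
            raise ValueError(f"quadrant images differ in shape: {shapes}")
        for q in QUADRANT_ORDER:
            setattr(self, q, np.asarray(getattr(self, q), dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return self.tl.shape

    def quadrants(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.tl, self.tr, self.bl, self.br

    def map(self, fn) -> "QuadrantSet":
        """Return a new set with ``fn`` applied to each quadrant image."""
        return QuadrantSet(*(fn(getattr(self, q)) for q in QUADRANT_ORDER), meta=self.meta)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted darkfield-to-edge scaling factor with diagnostics."""

    c: float
    edge_pixel_count: int
    residual_rms: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"scaling factor must be positive, got {self.c}")


class CalibrationError(RuntimeError):
    """Raised when the edge mask is too small or degenerate to calibrate c."""


def scale_to_bit_depth(image: np.ndarray, divisor: int = 16) -> np.ndarray:
    """Rescale container values to native camera counts.

    12-bit cameras commonly deliver data left-shifted into 16-bit containers;
    dividing by 16 and rounding to the nearest integer restores 12-bit counts.
    """
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    return np.rint(np.asarray(image, dtype=float) / divisor)


def subtract_reference(image: np.ndarray, reference: np.ndarray, floor: bool = True) -> np.ndarray:
    """Subtract an empty-field reference frame (stray light + lamp background).

    Negative residuals are floored at zero by default: darkfield intensity is
    physically nonnegative, and the floor only acts on noise excursions.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reference.shape}")
    out = image - reference
    if floor:
        np.maximum(out, 0.0, out=out)
    return out


def sum_darkfield(q: QuadrantSet) -> np.ndarray:
    """Summed darkfield image DF = TL + TR + BL + BR."""
    tl, tr, bl, br = q.quadrants()
    return tl + tr + bl + br


def edge_image(q: QuadrantSet) -> np.ndarray:
    """Edge image E = |TL - BR| + |BL - TR| (pixel-wise).

    Isotropic scatterers contribute equally to opposing quadrants and cancel;
    directional edge refraction appears in only one quadrant of each opposing
    pair and survives the absolute difference.
    """
    tl, tr, bl, br = q.quadrants()
    return np.abs(tl - br) + np.abs(bl - tr)


def qdf_image(
    df: np.ndarray,
    e: np.ndarray,
    c: float,
    clip_negative: bool = True,
) -> np.ndarray:
    """Quadrant darkfield image QDF = c * DF - E.

    With ``clip_negative`` the physically meaningless negative residuals are
    set to zero; pass ``False`` for unbiased pixel sums (noise is zero-mean
    only before clipping).
    """
    df = np.asarray(df, dtype=float)
    e = np.asarray(e, dtype=float)
    if df.shape != e.shape:
        raise ValueError(f"shape mismatch: {df.shape} vs {e.shape}")
    if not c > 0:
        raise ValueError("scaling factor c must be positive")
    out = c * df - e
    if clip_negative:
        n_clipped = int(np.count_nonzero(out < 0))
        if n_clipped:
            logger.debug("qdf_image: clipped %d negative pixels", n_clipped)
        np.maximum(out, 0.0, out=out)
    return out


def calibrate_c(
    df: np.ndarray,
    e: np.ndarray,
    edge_mask: np.ndarray,
    min_pixels: int = 100,
) -> CalibrationResult:
    """Least-squares estimate of the scaling factor c on edge pixels.

    Minimises sum_mask (c*DF - E)^2, i.e. c = sum(DF*E)/sum(DF^2) over the
    mask.  The mask should select pixels dominated by edge signal (e.g. the
    brightest edge-image pixels along object boundaries).
    """
    df = np.asarray(df, dtype=float)
    e = np.asarray(e, dtype=float)
    edge_mask = np.asarray(edge_mask, dtype=bool)
    if df.shape != e.shape or df.shape != edge_mask.shape:
        raise ValueError("df, e and edge_mask must share a shape")
    valid = edge_mask & (df > 0)
    n = int(np.count_nonzero(valid))
    if n < min_pixels:
        raise CalibrationError(
            f"cannot calibrate: only {n} usable edge pixels (need >= {min_pixels})"
        )
    dfm = df[valid]
    em = e[valid]
    denom = float(np.sum(dfm * dfm))
    if denom <= 0:
        raise CalibrationError("cannot calibrate: degenerate darkfield on mask")
    c = float(np.sum(dfm * em) / denom)
    if c <= 0:
        raise CalibrationError(f"calibration produced non-positive c = {c}")
    resid = c * dfm - em
    return CalibrationResult(c=c, edge_pixel_count=n, residual_rms=float(np.sqrt(np.mean(resid**2))))


def _poly_terms(degree: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(degree + 1) for j in range(degree + 1 - i)]


def _design_matrix(xn: np.ndarray, yn: np.ndarray, degree: int) -> np.ndarray:
    terms = _poly_terms(degree)
    cols = [xn**i * yn**j for i, j in terms]
    return np.stack(cols, axis=-1)


def fit_background_poly(
    image: np.ndarray,
    background_mask: np.ndarray,
    degree: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a 2-D polynomial background on masked pixels and subtract it.

    The polynomial contains all terms x^i y^j with i+j <= degree, fit by
    ordinary least squares on coordinates normalised to [-1, 1] for
    conditioning.  Returns ``(surface, corrected)`` where ``surface`` is the
    background evaluated over the whole field and ``corrected = image -
    surface``.  A rank-deficient design triggers automatic degree reduction.
    """
    image = np.asarray(image, dtype=float)
    background_mask = np.asarray(background_mask, dtype=bool)
    if image.shape != background_mask.shape:
        raise ValueError("image and background_mask must share a shape")
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    xn = 2.0 * xx / max(w - 1, 1) - 1.0
    yn = 2.0 * yy / max(h - 1, 1) - 1.0

    n_bg = int(np.count_nonzero(background_mask))
    deg = int(degree)
    while deg >= 0:
        n_terms = len(_poly_terms(deg))
        if n_bg >= 5 * n_terms:
            break
        deg -= 1
    else:
        raise ValueError(f"background mask too small: {n_bg} pixels")
    if deg < degree:
        logger.warning(
            "fit_background_poly: reduced degree %d -> %d for %d background pixels",
            degree, deg, n_bg,
        )

    xb = xn[background_mask]
    yb = yn[background_mask]
    zb = image[background_mask]
    while True:
        a = _design_matrix(xb, yb, deg)
        coeffs, _, rank, _ = np.linalg.lstsq(a, zb, rcond=None)
        if rank == a.shape[1] or deg == 0:
            if rank < a.shape[1]:
                logger.warning("fit_background_poly: rank-deficient at degree 0")
            break
        logger.warning("fit_background_poly: rank-deficient design, degree %d -> %d", deg, deg - 1)
        deg -= 1

    surface = _design_matrix(xn.ravel(), yn.ravel(), deg) @ coeffs
    surface = surface.reshape(image.shape)
    return surface, image - surface


def edge_calibration_mask(
    e: np.ndarray,
    foreground: np.ndarray,
    band_px: int = 3,
    percentile: float = 99.0,
    min_pixels: int = 200,
) -> np.ndarray:
    """Default calibration mask: brightest edge-image pixels on object boundaries.

    The boundary band is the morphological gradient of the foreground mask
    (dilation minus erosion with a ``band_px``-radius disk); within the band,
    pixels above the given percentile of E are kept, relaxed so that at least
    ``min_pixels`` of the brightest band pixels survive on small fields.
    """
    from scipy import ndimage

    e = np.asarray(e, dtype=float)
    foreground = np.asarray(foreground, dtype=bool)
    structure = ndimage.generate_binary_structure(2, 2)
    dil = ndimage.binary_dilation(foreground, structure, iterations=band_px)
    ero = ndimage.binary_erosion(foreground, structure, iterations=band_px)
    band = dil & ~ero
    n_band = int(np.count_nonzero(band))
    if n_band == 0:
        return band
    n_keep = max(min_pixels, int(round(n_band * (1.0 - percentile / 100.0))))
    n_keep = min(n_keep, n_band)
    thr = np.sort(e[band])[n_band - n_keep]
    return band & (e >= thr)
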