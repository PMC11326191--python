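"""Optical forward model for quadrant darkfield and phase imaging.

The simulator produces the four quadrant-illuminated darkfield frames, a
co-registered quantitative-phase image, and an empty-field reference frame for
scenes made of large refracting bodies (cells, beads) and sub-wavelength
scattering puncta (organelles).  It encodes the physical dichotomy the method
exploits:

* **Bodies** refract light directionally (Snell regime).  Under illumination
  from azimuth ``u_q`` a surface element with height gradient ``∇h`` emits
  ``edge_gain * relu(∇h · u_q)`` — i.e. the slope *facing away* from the
  source lights up, so a bead illuminated from the top-left shows a bright
  bottom-right arc.
* **Puncta** scatter into a broad Mie cone, modelled as perfectly isotropic:
  each punctum deposits ``scatter_amplitude / 4`` into every quadrant image
  before noise, so puncta cancel exactly in the edge image.

Both components are blurred with a Gaussian PSF, composited with stray light
and a smooth polynomial lamp background, then passed through a camera model
(Poisson shot noise, Gaussian read noise, bit-depth quantisation, 16-bit
container scaling).  Geometry is circularly symmetric: a body is a flat disc,
a spherical cap, or any volume-conserving interpolation between the two, which
gives closed-form volumes and makes the flat-to-rounded morph exactly
conservative.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import ndimage, optimize

from .qdf_core import AcquisitionMeta, QuadrantSet

logger = logging.getLogger(__name__)

__all__ = [
    "OpticsSpec",
    "Punctum",
    "BodySpec",
    "SceneSpec",
    "render_quadrants",
    "render_phase",
    "render_reference",
    "render_reference_set",
    "morph_roundness",
    "sample_population",
    "scene_ground_truth",
    "population_ground_truth",
    "bead_phantom",
    "adherent_cell",
]

#: specific refractive increment used to convert height*dn to dry-mass density
ALPHA_M3_PER_KG = 1.8e-4

#: default punctum scattering amplitude (total camera counts over all quadrants);
#: chosen so that simulated per-cell puncta SNR falls in the mid-20s to low-30s
#: under default noise, matching bright intracellular puncta on a 12-bit camera
DEFAULT_PUNCTUM_AMPLITUDE = 3000.0

#: default edge emission gain (counts per unit height slope)
DEFAULT_EDGE_GAIN = 250.0

#: population dry-mass range (pg), typical of adherent cancer cell lines
MASS_RANGE_PG = (150.0, 350.0)

# deterministic per-frame seed-stream codes
_FRAME_CODES = {"tl": 0, "tr": 1, "bl": 2, "br": 3,
                "ref_tl": 10, "ref_tr": 11, "ref_bl": 12, "ref_br": 13,
                "phase": 20}


@dataclass(frozen=True)
class OpticsSpec:
    """Imaging-system parameters.

    Defaults follow a 10x/0.25 NA objective with an LED annulus spanning
    1.05-1.33x the objective NA (darkfield condition), 0.5 um illumination,
    a ~0.5 um camera pixel at the sample, and a Gaussian PSF with
    sigma = 0.21 * lambda / NA ≈ 0.4 um.
    """

    wavelength_um: float = 0.5
    objective_na: float = 0.25
    annulus_na_range: tuple[float, float] = (0.2625, 0.3325)
    pixel_size_um: float = 0.5
    psf_sigma_um: float = 0.4
    bit_depth: int = 12
    quadrant_azimuths_deg: tuple[float, float, float, float] = (135.0, 45.0, 225.0, 315.0)
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.annulus_na_range[0] <= self.objective_na:
            raise ValueError("darkfield condition violated: annulus inner NA must exceed objective NA")
        if self.annulus_na_range[1] <= self.annulus_na_range[0]:
            raise ValueError("annulus NA range must be (inner, outer) with outer > inner")
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um

    @property
    def container_scale(self) -> int:
        """Multiplier storing native counts in 16-bit containers (16 for 12-bit data)."""
        return 2 ** (16 - self.bit_depth)

    def illumination_vectors(self) -> dict[str, np.ndarray]:
        """Unit vectors pointing from field centre toward each LED quadrant.

        Azimuths are measured in display orientation (x right, y up on screen);
        image arrays have y increasing downward, hence the sign flip on sin.
        """
        out = {}
        for name, az in zip(("tl", "tr", "bl", "br"), self.quadrant_azimuths_deg):
            a = math.radians(az)
            out[name] = np.array([math.cos(a), -math.sin(a)])
        return out


@dataclass(frozen=True)
class Punctum:
    """Sub-wavelength isotropic scatterer (organelle-scale punctum)."""

    position_um: tuple[float, float]  # (x, y)
    radius_um: float = 0.3
    scatter_amplitude: float = DEFAULT_PUNCTUM_AMPLITUDE
    refractive_contrast: float = 0.2  # vs cytoplasm; sets its phase bump

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("punctum radius must be positive")
        if self.scatter_amplitude < 0:
            raise ValueError("scatter_amplitude must be nonnegative")


@dataclass(frozen=True)
class BodySpec:
    """Large refracting body: circularly symmetric cell or bead.

    The height profile over the footprint of radius ``radius_um`` is

        h(rho) = height_um * [(1 - roundness) + roundness * sqrt(1 - (rho/R)^2)]

    so ``roundness = 0`` is a flat disc (sharp rim of height ``height_um``) and
    ``roundness = 1`` a spherical-cap dome of apex height ``height_um``.  A full
    sphere (bead) is ``roundness = 1`` with ``height_um = 2 * radius_um`` (the
    chord length profile).
    """

    center_um: tuple[float, float]
    radius_um: float
    height_um: float
    roundness: float = 0.0
    refractive_contrast: float = 0.05
    edge_gain: float = DEFAULT_EDGE_GAIN

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.height_um <= 0:
            raise ValueError("body radius and height must be positive")
        if not 0.0 <= self.roundness <= 1.0:
            raise ValueError("roundness must lie in [0, 1]")
        if self.edge_gain < 0:
            raise ValueError("edge_gain must be nonnegative")

    def volume_um3(self) -> float:
        """Closed-form volume of the height profile."""
        r = self.roundness
        shape_factor = (1.0 - r) / 2.0 + r / 3.0
        return 2.0 * math.pi * self.radius_um**2 * self.height_um * shape_factor

    def boundary(self, n_vertices: int = 256) -> np.ndarray:
        """Closed footprint contour as an (n, 2) polygon in um."""
        t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        cx, cy = self.center_um
        return np.column_stack([cx + self.radius_um * np.cos(t),
                                cy + self.radius_um * np.sin(t)])

    def height_map(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Height field (um) sampled at pixel centres; zero outside the footprint."""
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        cx, cy = self.center_um
        rho = np.hypot(xx * pixel_size_um - cx, yy * pixel_size_um - cy)
        inside = rho <= self.radius_um
        x = np.clip(rho / self.radius_um, 0.0, 1.0)
        profile = (1.0 - self.roundness) + self.roundness * np.sqrt(np.clip(1.0 - x**2, 0.0, None))
        return np.where(inside, self.height_um * profile, 0.0)

    def contains(self, x_um: float, y_um: float) -> bool:
        cx, cy = self.center_um
        return math.hypot(x_um - cx, y_um - cy) <= self.radius_um


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth scene: bodies, puncta, background/noise model, and a seed."""

    field_size: tuple[int, int]  # (ny, nx) pixels
    bodies: tuple[BodySpec, ...] = ()
    puncta: tuple[Punctum, ...] = ()
    background_poly_coeffs: tuple[tuple[float, ...], ...] = ((25.0, 4.0, 1.5), (6.0, 2.0, 0.0), (1.0, 0.0, 0.0))
    stray_light_frame: np.ndarray | None = None
    read_noise_sigma: float = 2.0
    shot_noise: bool = True
    phase_noise_sigma: float = 0.02
    phase_background_coeffs: tuple[tuple[float, ...], ...] = ((0.05, 0.02), (0.03, 0.0))
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.field_size
        if ny < 8 or nx < 8:
            raise ValueError("field_size must be at least 8x8 pixels")
        coeffs = np.asarray(self.background_poly_coeffs, dtype=float)
        if coeffs.ndim != 2 or max(coeffs.shape) > 9:
            raise ValueError("background polynomial degree must be <= 8")
        if self.stray_light_frame is not None and np.asarray(self.stray_light_frame).shape != (ny, nx):
            raise ValueError("stray_light_frame shape must match field_size")

    def validate_geometry(self, optics: OpticsSpec) -> None:
        """Reject scenes whose bodies or puncta do not fit the field."""
        ny, nx = self.field_size
        w_um, h_um = nx * optics.pixel_size_um, ny * optics.pixel_size_um
        for b in self.bodies:
            cx, cy = b.center_um
            if (cx - b.radius_um < 0 or cx + b.radius_um > w_um
                    or cy - b.radius_um < 0 or cy + b.radius_um > h_um):
                raise ValueError(f"field too small for body at {b.center_um} with radius {b.radius_um}")
        for p in self.puncta:
            x, y = p.position_um
            if not (0 <= x < w_um and 0 <= y < h_um):
                raise ValueError(f"punctum at {p.position_um} lies outside the field")


# ---------------------------------------------------------------------------
# rendering internals


def _background_surface(coeffs, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate a 2-D polynomial background on coordinates normalised to [-1, 1]."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    xn = 2.0 * xx / max(nx - 1, 1) - 1.0
    yn = 2.0 * yy / max(ny - 1, 1) - 1.0
    return npoly.polyval2d(xn, yn, np.asarray(coeffs, dtype=float))


def _splat_points(shape: tuple[int, int], xy_px: np.ndarray, amplitudes: np.ndarray) -> np.ndarray:
    """Bilinear deposition of point sources onto the pixel grid (flux-conserving)."""
    img = np.zeros(shape)
    if len(xy_px) == 0:
        return img
    x = xy_px[:, 0]
    y = xy_px[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            xi = np.clip(x0 + dx, 0, shape[1] - 1)
            yi = np.clip(y0 + dy, 0, shape[0] - 1)
            np.add.at(img, (yi, xi), amplitudes * wx * wy)
    return img


def _fine_grid(scene: SceneSpec, optics: OpticsSpec) -> tuple[tuple[int, int], float]:
    """Supersampled rendering grid: shape and pixel pitch (um)."""
    ss = optics.supersample
    ny, nx = scene.field_size
    return (ny * ss, nx * ss), optics.pixel_size_um / ss


def _block_sum(fine: np.ndarray, ss: int) -> np.ndarray:
    """Flux-conserving binning: camera pixels integrate the fine-grid field."""
    if ss == 1:
        return fine
    ny, nx = fine.shape[0] // ss, fine.shape[1] // ss
    return fine.reshape(ny, ss, nx, ss).sum(axis=(1, 3))


def _block_mean(fine: np.ndarray, ss: int) -> np.ndarray:
    return _block_sum(fine, ss) / (ss * ss)


def _puncta_splat(scene: SceneSpec, optics: OpticsSpec) -> np.ndarray:
    """Total punctum flux deposited on the fine grid (counts)."""
    fine_shape, pitch = _fine_grid(scene, optics)
    if not scene.puncta:
        return np.zeros(fine_shape)
    xy = np.array([p.position_um for p in scene.puncta]) / pitch
    amps = np.array([p.scatter_amplitude for p in scene.puncta])
    return _splat_points(fine_shape, xy, amps)


def _edge_emission(scene: SceneSpec, optics: OpticsSpec, quadrant: str) -> np.ndarray:
    """Directional refraction field for one illumination quadrant (fine grid).

    Emission per fine pixel is ``edge_gain * relu(∇h · u_q) / ss^2`` so that
    the camera-pixel flux (block sum) for a given slope is resolution
    independent; the supersampled gradient resolves the steep rim of rounded
    bodies that a camera-pitch grid would truncate.
    """
    u = optics.illumination_vectors()[quadrant]
    fine_shape, pitch = _fine_grid(scene, optics)
    out = np.zeros(fine_shape)
    for body in scene.bodies:
        h = body.height_map(fine_shape, pitch)
        gy, gx = np.gradient(h, pitch)
        out += body.edge_gain * np.maximum(gx * u[0] + gy * u[1], 0.0)
    return out / optics.supersample**2


def _composite(scene: SceneSpec, signal: np.ndarray) -> np.ndarray:
    total = signal + _background_surface(scene.background_poly_coeffs, scene.field_size)
    if scene.stray_light_frame is not None:
        total = total + np.asarray(scene.stray_light_frame, dtype=float)
    return total


def _camera(scene: SceneSpec, optics: OpticsSpec, expected: np.ndarray, frame: str) -> np.ndarray:
    """Apply shot/read noise and bit-depth quantisation; returns container values."""
    neg = int(np.count_nonzero(expected < 0))
    if neg:
        logger.warning("render: clamped %d negative pre-noise pixels in %s", neg, frame)
    expected = np.clip(expected, 0.0, None)
    rng = np.random.default_rng([int(scene.seed), _FRAME_CODES[frame]])
    out = rng.poisson(expected).astype(float) if scene.shot_noise else expected.copy()
    if scene.read_noise_sigma > 0:
        out += rng.normal(0.0, scene.read_noise_sigma, size=out.shape)
    out = np.clip(np.rint(out), 0, 2**optics.bit_depth - 1)
    return out * optics.container_scale


def render_quadrants(scene: SceneSpec, optics: OpticsSpec = OpticsSpec()) -> QuadrantSet:
    """Render the four quadrant-illuminated darkfield frames of a scene.

    Each quadrant image contains the directional edge emission for that
    illumination azimuth plus one quarter of every punctum's scatter
    amplitude, PSF-blurred, composited with stray light and lamp background,
    and passed through the camera model.  With noise disabled, puncta
    contributions are bit-identical across the four quadrants.
    """
    scene.validate_geometry(optics)
    ss = optics.supersample
    puncta = _puncta_splat(scene, optics) / 4.0
    _, pitch = _fine_grid(scene, optics)
    sigma_fine = optics.psf_sigma_um / pitch
    frames = {}
    for q in ("tl", "tr", "bl", "br"):
        fine = ndimage.gaussian_filter(_edge_emission(scene, optics, q) + puncta, sigma_fine)
        signal = _block_sum(fine, ss)
        frames[q] = _camera(scene, optics, _composite(scene, signal), q)
    meta = AcquisitionMeta(bit_depth=optics.bit_depth, wavelength_um=optics.wavelength_um)
    return QuadrantSet(frames["tl"], frames["tr"], frames["bl"], frames["br"], meta=meta)


def render_reference(scene: SceneSpec, optics: OpticsSpec = OpticsSpec(), frame: str = "ref_tl") -> np.ndarray:
    """Render one empty-field reference frame (stray light + background only).

    The reference position contains no bodies or puncta; its noise stream is
    independent of the science frames.
    """
    expected = _composite(scene, np.zeros(scene.field_size))
    return _camera(scene, optics, expected, frame)


def render_reference_set(scene: SceneSpec, optics: OpticsSpec = OpticsSpec()) -> QuadrantSet:
    """Empty-field reference for all four quadrant patterns (independent noise each)."""
    frames = [render_reference(scene, optics, f"ref_{q}") for q in ("tl", "tr", "bl", "br")]
    meta = AcquisitionMeta(bit_depth=optics.bit_depth, wavelength_um=optics.wavelength_um)
    return QuadrantSet(*frames, meta=meta)


def _noiseless_phase(scene: SceneSpec, optics: OpticsSpec, include_puncta: bool = True) -> np.ndarray:
    """Phase field (rad) from bodies and puncta, without background or noise.

    Rendered on the supersampled grid and pixel-averaged, so partially covered
    rim pixels carry their area-weighted phase and the dry-mass integral is
    grid independent.
    """
    k = 2.0 * math.pi / optics.wavelength_um
    fine_shape, pitch = _fine_grid(scene, optics)
    fine = np.zeros(fine_shape)
    for body in scene.bodies:
        fine += k * body.refractive_contrast * body.height_map(fine_shape, pitch)
    if include_puncta and scene.puncta:
        # integrated optical path of each punctum, deposited as a PSF-blurred point
        xy = np.array([p.position_um for p in scene.puncta]) / pitch
        opd = np.array([
            k * p.refractive_contrast * (4.0 / 3.0) * math.pi * p.radius_um**3
            for p in scene.puncta
        ]) / pitch**2  # rad * um^2 -> rad per fine pixel
        bumps = _splat_points(fine_shape, xy, opd)
        fine += ndimage.gaussian_filter(bumps, optics.psf_sigma_um / pitch)
    return _block_mean(fine, optics.supersample)


def render_phase(scene: SceneSpec, optics: OpticsSpec = OpticsSpec()):
    """Render the co-registered quantitative phase image (radians).

    Phase is ``(2*pi/lambda) * dn * h`` over each body plus small puncta bumps,
    a smooth polynomial phase background, and Gaussian phase noise.  Returns a
    :class:`qdf.qpi_mass.PhaseImage`.
    """
    from .qpi_mass import PhaseImage

    scene.validate_geometry(optics)
    phase = _noiseless_phase(scene, optics)
    phase = phase + _background_surface(scene.phase_background_coeffs, scene.field_size)
    if scene.phase_noise_sigma > 0:
        rng = np.random.default_rng([int(scene.seed), _FRAME_CODES["phase"]])
        phase = phase + rng.normal(0.0, scene.phase_noise_sigma, size=phase.shape)
    return PhaseImage(phase=phase, wavelength_um=optics.wavelength_um,
                      pixel_area_um2=optics.pixel_size_um**2)


def scene_ground_truth(scene: SceneSpec, optics: OpticsSpec = OpticsSpec()) -> pd.DataFrame:
    """Per-body ground truth: footprint area, dry mass, puncta content.

    Mass is the brute-force pixel sum of the noiseless dry-mass density map
    over each body footprint (puncta bumps included for puncta inside the
    body), i.e. exactly what an ideal phase pipeline should recover.
    """
    from .qpi_mass import MassConfig, PhaseImage, density_map

    phase = _noiseless_phase(scene, optics)
    pimg = PhaseImage(phase=phase, wavelength_um=optics.wavelength_um,
                      pixel_area_um2=optics.pixel_size_um**2)
    rho = density_map(pimg, MassConfig())  # pg / um^2
    fine_shape, pitch = _fine_grid(scene, optics)
    rows = []
    for i, body in enumerate(scene.bodies):
        mask = _block_mean(body.height_map(fine_shape, pitch), optics.supersample) > 0
        inside = [p for p in scene.puncta if body.contains(*p.position_um)]
        rows.append({
            "body": i,
            "area_um2": float(mask.sum()) * optics.pixel_size_um**2,
            "mass_pg": float(rho[mask].sum()) * optics.pixel_size_um**2,
            "volume_um3": body.volume_um3(),
            "puncta_count": len(inside),
            "puncta_amplitude": float(sum(p.scatter_amplitude for p in inside)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# morphology and populations


def _solve_morph(body: BodySpec, t: float) -> BodySpec:
    """Volume-conserving interpolation of one body toward a spherical cap."""
    v0 = body.volume_um3()
    r_t = body.roundness + (1.0 - body.roundness) * t
    shape_factor = (1.0 - r_t) / 2.0 + r_t / 3.0

    def volume_of(radius: float) -> float:
        height = (1.0 - t) * body.height_um + t * radius
        return 2.0 * math.pi * radius**2 * height * shape_factor - v0

    hi = max(body.radius_um, body.height_um) * 4.0
    radius = optimize.brentq(volume_of, 1e-9, hi, xtol=1e-12, rtol=1e-14)
    height = (1.0 - t) * body.height_um + t * radius
    return dataclasses.replace(body, radius_um=radius, height_um=height, roundness=r_t)


def morph_roundness(scene: SceneSpec, roundness: float) -> SceneSpec:
    """Morph every body from its current shape toward a rounded cap.

    ``roundness = 0`` returns the scene unchanged; ``roundness = 1`` turns each
    body into a spherical cap whose apex height equals its footprint radius.
    Body volume is conserved exactly (closed-form solve) and puncta travel
    affinely with their host body's contraction, amplitudes untouched.
    """
    if not 0.0 <= roundness <= 1.0:
        raise ValueError("roundness must lie in [0, 1]")
    if roundness == 0.0 or not scene.bodies:
        return scene
    new_bodies = [_solve_morph(b, roundness) for b in scene.bodies]

    new_puncta = []
    for p in scene.puncta:
        host = next((i for i, b in enumerate(scene.bodies) if b.contains(*p.position_um)), None)
        if host is None:
            new_puncta.append(p)
            continue
        old, new = scene.bodies[host], new_bodies[host]
        scale = new.radius_um / old.radius_um
        cx, cy = old.center_um
        x = cx + (p.position_um[0] - cx) * scale
        y = cy + (p.position_um[1] - cy) * scale
        if not new.contains(x, y):  # numerical guard: snap to nearest interior point
            logger.warning("morph_roundness: repositioning punctum to body interior")
            ang = math.atan2(y - cy, x - cx)
            rmax = new.radius_um * 0.999
            x, y = cx + rmax * math.cos(ang), cy + rmax * math.sin(ang)
        new_puncta.append(dataclasses.replace(p, position_um=(x, y)))
    return dataclasses.replace(scene, bodies=tuple(new_bodies), puncta=tuple(new_puncta))


def _field_for_radius(radius_um: float, pixel_size_um: float, margin_um: float = 10.0,
                      minimum: int = 64) -> int:
    n = int(math.ceil(2.0 * (radius_um + margin_um) / pixel_size_um))
    n = max(n, minimum)
    return int(math.ceil(n / 16.0)) * 16  # round up for tidy grids


def sample_population(
    template: SceneSpec,
    n: int,
    mass_per_area_range: tuple[float, float],
    puncta_per_mass: float,
    seed: int,
    optics: OpticsSpec = OpticsSpec(),
    mass_range_pg: tuple[float, float] = MASS_RANGE_PG,
    punctum_amplitude: float = DEFAULT_PUNCTUM_AMPLITUDE,
) -> list[SceneSpec]:
    """Generate ``n`` single-cell scenes spanning a mass-per-area range.

    Each cell draws an independent dry mass (uniform over ``mass_range_pg``)
    and mass-per-area (uniform over ``mass_per_area_range``, pg/um^2); the two
    fix its footprint radius and flat-disc height through the specific
    refractive increment.  The organelle count is Poisson with mean
    ``puncta_per_mass * mass`` — proportional to mass and independent of shape
    — with fixed per-punctum amplitude.  Noise/background parameters are
    inherited from ``template``; everything is reproducible under a fixed seed.
    """
    if n < 2:
        raise ValueError("population size must be at least 2")
    lo, hi = mass_per_area_range
    if not hi > lo > 0:
        raise ValueError(f"degenerate mass_per_area_range: {mass_per_area_range}")
    if not template.bodies:
        raise ValueError("template scene must contain a body to copy optical parameters from")
    proto = template.bodies[0]

    scenes = []
    for i in range(n):
        rng = np.random.default_rng([int(seed), i])
        mass = rng.uniform(*mass_range_pg)
        mpa = rng.uniform(lo, hi)
        area = mass / mpa  # um^2
        radius = math.sqrt(area / math.pi)
        # mass_per_area [pg/um^2] = dn * h[um] * 1e-3 / alpha  =>  h = mpa * alpha * 1e3 / dn
        height = mpa * ALPHA_M3_PER_KG * 1e3 / proto.refractive_contrast
        npx = _field_for_radius(radius, optics.pixel_size_um)
        center = (npx * optics.pixel_size_um / 2.0,) * 2
        body = dataclasses.replace(proto, center_um=center, radius_um=radius,
                                   height_um=height, roundness=0.0)
        count = int(rng.poisson(puncta_per_mass * mass))
        rho = (radius - 1.0) * np.sqrt(rng.uniform(0, 1, count))
        ang = rng.uniform(0, 2 * math.pi, count)
        puncta = tuple(
            Punctum(position_um=(center[0] + r * math.cos(a), center[1] + r * math.sin(a)),
                    scatter_amplitude=punctum_amplitude)
            for r, a in zip(rho, ang)
        )
        scenes.append(dataclasses.replace(
            template, field_size=(npx, npx), bodies=(body,), puncta=puncta,
            seed=int(rng.integers(2**31)),
        ))
    return scenes


def population_ground_truth(scenes: list[SceneSpec], optics: OpticsSpec = OpticsSpec()) -> pd.DataFrame:
    """Stack per-scene ground truth (first body of each scene) into one table."""
    rows = []
    for i, scene in enumerate(scenes):
        gt = scene_ground_truth(scene, optics).iloc[0].to_dict()
        gt["scene"] = i
        rows.append(gt)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scene factories


def bead_phantom(
    field_size: int = 128,
    radius_um: float = 10.0,
    refractive_contrast: float = 0.03,
    edge_gain: float = DEFAULT_EDGE_GAIN,
    imperfection: bool = True,
    imperfection_amplitude: float = DEFAULT_PUNCTUM_AMPLITUDE,
    seed: int = 0,
    optics: OpticsSpec = OpticsSpec(),
    **scene_kwargs,
) -> SceneSpec:
    """Polystyrene-bead phantom: a full sphere (chord-length height profile).

    Optionally carries a central "imperfection" punctum, mimicking inclusions
    that scatter isotropically and therefore survive QDF.
    """
    center = (field_size * optics.pixel_size_um / 2.0,) * 2
    body = BodySpec(center_um=center, radius_um=radius_um, height_um=2.0 * radius_um,
                    roundness=1.0, refractive_contrast=refractive_contrast, edge_gain=edge_gain)
    puncta = (Punctum(position_um=center, scatter_amplitude=imperfection_amplitude),) if imperfection else ()
    return SceneSpec(field_size=(field_size, field_size), bodies=(body,), puncta=puncta,
                     seed=seed, **scene_kwargs)


def adherent_cell(
    field_size: int = 128,
    radius_um: float = 20.0,
    height_um: float = 3.0,
    n_puncta: int = 200,
    punctum_amplitude: float = DEFAULT_PUNCTUM_AMPLITUDE,
    edge_gain: float = DEFAULT_EDGE_GAIN,
    refractive_contrast: float = 0.05,
    seed: int = 0,
    optics: OpticsSpec = OpticsSpec(),
    **scene_kwargs,
) -> SceneSpec:
    """Flat adherent cell with uniformly scattered interior puncta."""
    center = (field_size * optics.pixel_size_um / 2.0,) * 2
    body = BodySpec(center_um=center, radius_um=radius_um, height_um=height_um,
                    roundness=0.0, refractive_contrast=refractive_contrast, edge_gain=edge_gain)
    rng = np.random.default_rng([int(seed), 97])
    rho = (radius_um - 1.0) * np.sqrt(rng.uniform(0, 1, n_puncta))
    ang = rng.uniform(0, 2 * math.pi, n_puncta)
    puncta = tuple(
        Punctum(position_um=(center[0] + r * math.cos(a), center[1] + r * math.sin(a)),
                scatter_amplitude=punctum_amplitude)
        for r, a in zip(rho, ang)
    )
    return SceneSpec(field_size=(field_size, field_size), bodies=(body,), puncta=puncta,
                     seed=seed, **scene_kwargs)
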