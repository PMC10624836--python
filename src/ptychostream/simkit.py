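"""Synthetic ptychography: geometry, probes, phantoms, scans and the forward model.

Everything downstream (iterative phase retrieval, surrogate training,
stitching, evaluation) consumes data produced here.  The forward model is a
thin-sample far-field one: the exit wave at each scan position is the probe
times the local object transmission, and the detector records the squared
modulus of its centred Fourier transform, optionally Poisson sampled at a
configurable photon budget.

Conventions
-----------
* Positions are in nanometres, x to the right, y down; object grids are
  0-based with the scan position at the centre of the probe window.
* FFTs are centred (fftshift before and after) with orthonormal scaling, so
  Parseval holds exactly between the exit wave and the detector intensity.
* Sub-pixel scan positions are rounded to the nearest object pixel in the
  forward model; interpolation is reserved for label extraction and
  stitching.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectorGeometry",
    "Probe",
    "Phantom",
    "ScanPlan",
    "DiffractionStack",
    "DoseImage",
    "overlap_ratio",
    "pixel_size_from_geometry",
    "make_spiral_scan",
    "make_probe",
    "make_phantom",
    "simulate_scan",
    "dose_map",
    "data_volume",
    "fft2c",
    "ifft2c",
]

#: keV * nm; lambda(nm) = HC_KEV_NM / E(keV)
HC_KEV_NM = 1.23984


def fft2c(a: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2-D Fourier transform."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a, axes=(-2, -1)),
                                       norm="ortho"), axes=(-2, -1))


def ifft2c(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a, axes=(-2, -1)),
                                        norm="ortho"), axes=(-2, -1))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorGeometry:
    """Far-field detection geometry.

    Parameters
    ----------
    energy_keV : photon energy.
    distance_m : sample-to-detector distance z.
    n_pixels : detector frame side N.
    pixel_pitch_um : detector pixel size p.
    """

    energy_keV: float
    distance_m: float
    n_pixels: int
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        for name in ("energy_keV", "distance_m", "n_pixels", "pixel_pitch_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def wavelength_nm(self) -> float:
        return HC_KEV_NM / self.energy_keV

    @property
    def object_pixel_nm(self) -> float:
        return pixel_size_from_geometry(self)


@dataclass
class Probe:
    """Complex illumination field on the object-plane grid, unit total power."""

    field: np.ndarray
    pixel_size_nm: float
    fwhm_nm: float
    modes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.complex128)
        if self.field.ndim != 2:
            raise ValueError("probe field must be 2-D")
        if not np.all(np.isfinite(self.field.view(np.float64))):
            raise ValueError("probe field contains non-finite values")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")
        power = float(np.sum(np.abs(self.field) ** 2))
        if power <= 0:
            raise ValueError("probe field has zero power")
        self.field = self.field / np.sqrt(power)

    @property
    def power(self) -> float:
        return float(np.sum(np.abs(self.field) ** 2))

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.field) ** 2


@dataclass
class Phantom:
    """Thin-sample transmission: ``amplitude * exp(i * phase)``."""

    phase: np.ndarray
    amplitude: np.ndarray
    pixel_size_nm: float
    phase_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude grids must be congruent")
        lo, hi = self.phase_range
        if not (lo <= hi):
            raise ValueError("phase_range must be ordered (lo, hi)")
        eps = 1e-9
        if self.phase.min() < lo - eps or self.phase.max() > hi + eps:
            raise ValueError("phase values exceed the declared phase_range")
        if self.amplitude.min() <= 0 or self.amplitude.max() > 1 + eps:
            raise ValueError("amplitude must lie in (0, 1]")

    @property
    def transmission(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class ScanPlan:
    """Ordered scan positions plus the nominal step S and beam size B."""

    positions_nm: np.ndarray
    step_nm: float
    beamsize_nm: float

    def __post_init__(self) -> None:
        self.positions_nm = np.atleast_2d(np.asarray(self.positions_nm, dtype=np.float64))
        if self.positions_nm.shape[1] != 2 or self.positions_nm.shape[0] < 1:
            raise ValueError("positions_nm must be an (n, 2) array with n >= 1")

    @property
    def n_points(self) -> int:
        return int(self.positions_nm.shape[0])

    @property
    def overlap(self) -> float:
        return overlap_ratio(self.step_nm, self.beamsize_nm)

    def subset(self, indices: np.ndarray, step_nm: float | None = None) -> "ScanPlan":
        return ScanPlan(self.positions_nm[indices],
                        self.step_nm if step_nm is None else step_nm,
                        self.beamsize_nm)


@dataclass
class DiffractionStack:
    """Recorded (or expected) far-field counts for every scan position.

    ``frames`` holds integer Poisson counts when sampled with noise and the
    float-valued expected counts for noiseless simulations.
    """

    frames: np.ndarray
    exposure_ms: float
    flux_scale: float
    plan: ScanPlan
    geometry: DetectorGeometry | None = None
    seed: int | None = None
    poisson: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, N, N)")
        if self.frames.shape[0] != self.plan.n_points:
            raise ValueError("frame count must equal plan n_points")
        if self.frames.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.poisson and not np.issubdtype(self.frames.dtype, np.integer):
            raise ValueError("Poisson-sampled frames must be integer counts")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def photons_per_exposure(self) -> float:
        """Expected photons through a unit-power probe in one exposure."""
        return self.flux_scale * self.exposure_ms

    def subset(self, indices: np.ndarray, step_nm: float | None = None) -> "DiffractionStack":
        return DiffractionStack(self.frames[indices], self.exposure_ms,
                                self.flux_scale, self.plan.subset(indices, step_nm),
                                self.geometry, self.seed, self.poisson)


@dataclass
class DoseImage:
    """Accumulated photon dose in photons/nm^2 on a regular grid."""

    grid: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.min() < 0:
            raise ValueError("dose values must be >= 0")

    @property
    def total_photons(self) -> float:
        return float(self.grid.sum() * self.pixel_size_nm ** 2)

    @property
    def mean_dose(self) -> float:
        """Average dose over the illuminated (nonzero) area."""
        lit = self.grid[self.grid > 0]
        return float(lit.mean()) if lit.size else 0.0


# ---------------------------------------------------------------------------
# scalar relations
# ---------------------------------------------------------------------------

def overlap_ratio(step_nm: float, beamsize_nm: float) -> float:
    """Spiral-scan overlap ratio ``1 - sqrt(3) * S / B``.

    Zero or negative values mean adjacent illuminated discs no longer share
    area; the value is returned unclamped so callers can flag "no overlap".
    """
    if beamsize_nm <= 0:
        raise ValueError("beamsize_nm must be > 0")
    if step_nm < 0:
        raise ValueError("step_nm must be >= 0")
    return 1.0 - np.sqrt(3.0) * step_nm / beamsize_nm


def step_for_overlap(ratio: float, beamsize_nm: float) -> float:
    """Inverse of :func:`overlap_ratio`: the step S realising a target ratio."""
    if beamsize_nm <= 0:
        raise ValueError("beamsize_nm must be > 0")
    return (1.0 - ratio) * beamsize_nm / np.sqrt(3.0)


def pixel_size_from_geometry(geometry: DetectorGeometry) -> float:
    """Object-plane pixel size lambda*z/(N*p) of the far-field sampling, in nm."""
    lam_m = geometry.wavelength_nm * 1e-9
    pitch_m = geometry.pixel_pitch_um * 1e-6
    return lam_m * geometry.distance_m / (geometry.n_pixels * pitch_m) * 1e9


def data_volume(area_mm2: float, step_nm: float, pixels_per_frame: float,
                bit_depth: int) -> float:
    """Raw data volume in bytes for a raster scan of `area_mm2` at `step_nm`.

    Decimal units: 1 TB = 1e12 bytes.
    """
    if min(area_mm2, step_nm, pixels_per_frame, bit_depth) <= 0:
        raise ValueError("all arguments must be positive")
    n_positions = area_mm2 * 1e12 / step_nm ** 2  # mm^2 -> nm^2
    return n_positions * pixels_per_frame * bit_depth / 8.0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_spiral_scan(n_points: int, step_nm: float, beamsize_nm: float = 800.0,
                     center_nm: tuple[float, float] = (0.0, 0.0)) -> ScanPlan:
    """Constant-arc-length Archimedean spiral ``r = a * theta``.

    The ring pitch ``2*pi*a`` is set equal to the step so that nearest
    neighbours along the winding and across adjacent windings are both about
    ``step_nm`` apart, giving near-uniform areal sampling.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    a = step_nm / (2.0 * np.pi)
    theta = 0.0
    pts = np.empty((n_points, 2))
    for k in range(n_points):
        r = a * theta
        pts[k] = (center_nm[0] + r * np.cos(theta), center_nm[1] + r * np.sin(theta))
        # advance so the chord to the next point is ~step_nm
        theta += step_nm / np.hypot(a, r)
    return ScanPlan(pts, step_nm=step_nm, beamsize_nm=beamsize_nm)


def _radial_profile(intensity: np.ndarray, pixel_size_nm: float,
                    n_bins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    n = intensity.shape[0]
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - c, yy - c)
    n_bins = n_bins or c
    bins = np.clip(r.astype(int), 0, n_bins - 1)
    prof = np.bincount(bins.ravel(), intensity.ravel(), minlength=n_bins)
    cnt = np.bincount(bins.ravel(), minlength=n_bins)
    prof = prof / np.maximum(cnt, 1)
    radii = (np.arange(n_bins) + 0.5) * pixel_size_nm
    return radii, prof


def probe_intensity_fwhm(probe_intensity: np.ndarray, pixel_size_nm: float) -> float:
    """Full width of the region where azimuthal mean intensity >= half its peak.

    For an annular (donut) probe this measures the outer spot diameter, the
    quantity quoted as beam "spot size".
    """
    radii, prof = _radial_profile(probe_intensity, pixel_size_nm)
    half = prof.max() / 2.0
    above = np.nonzero(prof >= half)[0]
    if above.size == 0:
        return 0.0
    k = above[-1]
    if k + 1 < prof.size and prof[k] != prof[k + 1]:
        # linear interpolation of the outer half crossing
        frac = (prof[k] - half) / (prof[k] - prof[k + 1])
        r_half = radii[k] + frac * (radii[k + 1] - radii[k])
    else:
        r_half = radii[k]
    return 2.0 * r_half


def _annulus_probe_field(n: int, pixel_nm: float, defocus: float,
                         ring_ratio: float = 0.4,
                         seed: int | None = 0) -> np.ndarray:
    """Defocused ring-aperture probe on an n x n grid.

    The aperture lives in the pupil (spatial-frequency) plane as a hard
    annulus with inner/outer radius ratio `ring_ratio`; `defocus` is the peak
    quadratic phase (radians) applied across the pupil.  Growing the defocus
    expands the geometric ring shadow at the sample plane — the donut.  A
    smooth seeded phase texture (aberrations of a real optic) breaks the
    perfect circular symmetry; without it the coherent on-axis sum produces
    an unphysically bright axial spot inside the donut.
    """
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    q = np.hypot(xx - c, yy - c) / c  # normalized pupil radius in [0, sqrt2]
    aperture = ((q <= 1.0) & (q >= ring_ratio)).astype(np.complex128)
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=n / 24)
    texture *= 1.5 / max(texture.std(), 1e-12)
    pupil = aperture * np.exp(1j * (defocus * q ** 2 + texture))
    field = ifft2c(pupil)
    return field / np.sqrt(np.sum(np.abs(field) ** 2))


def make_probe(geometry: DetectorGeometry | None = None,
               object_pixel_nm: float | None = None,
               style: str = "annulus", fwhm_nm: float = 800.0,
               seed: int | None = None, n_pixels: int = 128) -> Probe:
    """Build an illumination probe with a target intensity FWHM.

    ``annulus`` emulates a defocused zone-plate illumination: a ring aperture
    propagated out of focus until the spot FWHM matches ``fwhm_nm`` within
    5%, with the characteristic central intensity dip.  ``gaussian`` is a
    plain focused spot.  The probe window side is ``n_pixels`` (or the
    geometry's detector side when a geometry is given).
    """
    if style not in ("annulus", "gaussian"):
        raise ValueError(f"unknown probe style {style!r}")
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be > 0")
    if object_pixel_nm is None:
        if geometry is None:
            raise ValueError("need geometry or object_pixel_nm")
        object_pixel_nm = pixel_size_from_geometry(geometry)
    n = geometry.n_pixels if geometry is not None else n_pixels
    span = n * object_pixel_nm
    if fwhm_nm > 0.9 * span:
        raise ValueError(
            f"requested FWHM {fwhm_nm} nm does not fit the {span:.0f} nm probe window")

    if style == "gaussian":
        sigma_px = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / object_pixel_nm
        c = n // 2
        yy, xx = np.mgrid[0:n, 0:n]
        amp = np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (4.0 * sigma_px ** 2))
        return Probe(amp.astype(np.complex128), object_pixel_nm, fwhm_nm)

    # bisect the pupil defocus until the measured spot FWHM matches; the
    # geometric ring-shadow radius is ~2c/pi pixels, so cap the defocus c
    # where the shadow reaches the window edge (beyond that it aliases)
    lo, hi = 0.0, np.pi * n / 4.0
    target = fwhm_nm
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = _annulus_probe_field(n, object_pixel_nm, mid, seed=seed or 0)
        w = probe_intensity_fwhm(np.abs(f) ** 2, object_pixel_nm)
        best = f
        if abs(w - target) / target < 0.005:
            break
        if w < target:
            lo = mid
        else:
            hi = mid
    w = probe_intensity_fwhm(np.abs(best) ** 2, object_pixel_nm)
    if abs(w - target) / target > 0.05:
        raise ValueError(
            f"could not realize FWHM {target} nm on this grid (got {w:.0f} nm)")
    return Probe(best, object_pixel_nm, fwhm_nm)


_GLYPH_STROKES = {
    # minimal 5-segment glyphs on a unit box: list of ((x0,y0),(x1,y1)) strokes
    "A": [((0, 1), (0.5, 0)), ((0.5, 0), (1, 1)), ((0.25, 0.55), (0.75, 0.55))],
    "E": [((0, 0), (0, 1)), ((0, 0), (1, 0)), ((0, 0.5), (0.8, 0.5)), ((0, 1), (1, 1))],
    "F": [((0, 0), (0, 1)), ((0, 0), (1, 0)), ((0, 0.5), (0.8, 0.5))],
    "H": [((0, 0), (0, 1)), ((1, 0), (1, 1)), ((0, 0.5), (1, 0.5))],
    "I": [((0.5, 0), (0.5, 1)), ((0.2, 0), (0.8, 0)), ((0.2, 1), (0.8, 1))],
    "L": [((0, 0), (0, 1)), ((0, 1), (1, 1))],
    "N": [((0, 1), (0, 0)), ((0, 0), (1, 1)), ((1, 1), (1, 0))],
    "T": [((0.5, 0), (0.5, 1)), ((0, 0), (1, 0))],
    "X": [((0, 0), (1, 1)), ((1, 0), (0, 1))],
    "Z": [((0, 0), (1, 0)), ((1, 0), (0, 1)), ((0, 1), (1, 1))],
}


def _render_letters(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Binary mask of glyph-like letter shapes scattered over the grid."""
    mask = np.zeros(shape, dtype=np.float64)
    h, w = shape
    size = max(8, min(h, w) // 6)
    n_letters = max(3, (h * w) // (size * size * 4))
    letters = list(_GLYPH_STROKES)
    for _ in range(n_letters):
        glyph = _GLYPH_STROKES[letters[rng.integers(len(letters))]]
        oy = rng.integers(0, max(1, h - size))
        ox = rng.integers(0, max(1, w - size))
        for (x0, y0), (x1, y1) in glyph:
            n_steps = 2 * size
            xs = ox + (x0 + (x1 - x0) * np.linspace(0, 1, n_steps)) * (size - 1)
            ys = oy + (y0 + (y1 - y0) * np.linspace(0, 1, n_steps)) * (size - 1)
            mask[np.clip(ys.astype(int), 0, h - 1), np.clip(xs.astype(int), 0, w - 1)] = 1.0
    # thicken strokes to ~size/6 pixels
    mask = ndimage.grey_dilation(mask, size=max(2, size // 6))
    return mask


def make_phantom(shape: tuple[int, int] = (512, 512), pixel_size_nm: float = 6.82,
                 phase_range: tuple[float, float] = (-0.4, 0.0),
                 style: str = "random_etch", seed: int = 0,
                 feature_size_px: float = 12.0) -> Phantom:
    """Binary-etched phantom with two phase levels and smoothed edges.

    ``random_etch`` thresholds a smoothed random field into islands;
    ``letters`` scatters glyph-like capital letters (features of a kind a
    model trained on random patterns has never seen).  The etched regions
    take the upper phase level, the background the lower one; a slight edge
    blur keeps values inside ``phase_range``.
    """
    if style not in ("random_etch", "letters"):
        raise ValueError(f"unknown phantom style {style!r}")
    lo, hi = phase_range
    if lo < -np.pi or hi > np.pi:
        raise ValueError("phase_range must lie within (-pi, pi); wrapping is not modeled")
    rng = np.random.default_rng(seed)
    if style == "random_etch":
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=feature_size_px / 2.0)
        mask = (smooth > np.median(smooth)).astype(np.float64)
    else:
        mask = _render_letters(shape, rng)
    mask = ndimage.gaussian_filter(mask, sigma=1.0)
    mask = np.clip(mask, 0.0, 1.0)
    phase = lo + mask * (hi - lo)
    amplitude = np.ones(shape)
    return Phantom(phase, amplitude, pixel_size_nm, phase_range)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def positions_to_pixels(positions_nm: np.ndarray, object_shape: tuple[int, int],
                        pixel_size_nm: float,
                        origin_nm: tuple[float, float] | None = None) -> np.ndarray:
    """Map scan positions to fractional (row, col) object-grid coordinates.

    When ``origin_nm`` is None the scan bounding-box centre is mapped to the
    object-grid centre.
    """
    pos = np.atleast_2d(positions_nm)
    if origin_nm is None:
        c = 0.5 * (pos.min(axis=0) + pos.max(axis=0))
        origin_x = c[0] - (object_shape[1] / 2.0) * pixel_size_nm
        origin_y = c[1] - (object_shape[0] / 2.0) * pixel_size_nm
    else:
        origin_x, origin_y = origin_nm
    cols = (pos[:, 0] - origin_x) / pixel_size_nm
    rows = (pos[:, 1] - origin_y) / pixel_size_nm
    return np.column_stack([rows, cols])


def _window_corner(center_rc: np.ndarray, win: int) -> tuple[int, int]:
    r0 = int(round(center_rc[0])) - win // 2
    c0 = int(round(center_rc[1])) - win // 2
    return r0, c0


def exit_wave(obj: np.ndarray, probe_field: np.ndarray, center_rc: np.ndarray,
              index: int = -1) -> np.ndarray:
    """Probe times the object patch centred (to nearest pixel) at ``center_rc``."""
    win = probe_field.shape[0]
    r0, c0 = _window_corner(center_rc, win)
    if r0 < 0 or c0 < 0 or r0 + win > obj.shape[0] or c0 + win > obj.shape[1]:
        raise ValueError(
            f"scan position {index} window [{r0}:{r0+win}, {c0}:{c0+win}] "
            f"exits the {obj.shape} object grid")
    return probe_field * obj[r0:r0 + win, c0:c0 + win]


def simulate_scan(phantom: Phantom, probe: Probe, plan: ScanPlan,
                  geometry: DetectorGeometry | None = None,
                  exposure_ms: float = 1.0, flux_scale: float = 1e8,
                  poisson: bool = True, seed: int = 0) -> DiffractionStack:
    """Far-field diffraction frames for every position of a scan plan.

    The expected frame is ``photons * |F{probe * object_patch}|^2`` with
    ``photons = flux_scale * exposure_ms`` the photon budget through a
    unit-power probe; Poisson sampling (seeded) yields integer counts.
    """
    if abs(probe.pixel_size_nm - phantom.pixel_size_nm) > 1e-9:
        raise ValueError("probe and phantom pixel sizes differ")
    obj = phantom.transmission
    # absolute frame: phantom pixel (0, 0) sits at 0 nm
    centers = positions_to_pixels(plan.positions_nm, phantom.phase.shape,
                                  phantom.pixel_size_nm, origin_nm=(0.0, 0.0))
    win = probe.field.shape[0]
    photons = flux_scale * exposure_ms
    frames = np.empty((plan.n_points, win, win))
    for i in range(plan.n_points):
        psi = exit_wave(obj, probe.field, centers[i], index=i)
        frames[i] = photons * np.abs(fft2c(psi)) ** 2
    if poisson:
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(np.uint32)
    return DiffractionStack(frames, exposure_ms, flux_scale, plan, geometry,
                            seed, poisson)


def dose_map(plan: ScanPlan, probe: Probe, flux_scale: float = 1e8,
             exposure_ms: float = 1.0, pixel_size_nm: float | None = None,
             pad_nm: float | None = None) -> DoseImage:
    """Accumulated photon dose (photons/nm^2) over the scanned area.

    Each shot deposits ``flux_scale * exposure_ms`` photons distributed as
    the unit-power probe intensity; total integrated dose is exactly
    ``n_points`` times the per-shot photon count.
    """
    if plan.n_points < 1:
        raise ValueError("empty scan plan")
    px = pixel_size_nm or probe.pixel_size_nm
    if abs(px - probe.pixel_size_nm) > 1e-9:
        raise ValueError("dose grid pixel size must match the probe grid")
    win = probe.field.shape[0]
    pad = pad_nm if pad_nm is not None else (win / 2.0 + 1) * px
    lo = plan.positions_nm.min(axis=0) - pad
    hi = plan.positions_nm.max(axis=0) + pad
    shape = (int(np.ceil((hi[1] - lo[1]) / px)) + 1,
             int(np.ceil((hi[0] - lo[0]) / px)) + 1)
    grid = np.zeros(shape)
    photons = flux_scale * exposure_ms
    footprint = probe.intensity * photons / px ** 2  # photons/nm^2 per shot
    centers = positions_to_pixels(plan.positions_nm, shape, px, origin_nm=(lo[0], lo[1]))
    for i in range(plan.n_points):
        r0, c0 = _window_corner(centers[i], win)
        if r0 < 0 or c0 < 0 or r0 + win > shape[0] or c0 + win > shape[1]:
            raise ValueError(f"dose grid too small for position {i}")
        grid[r0:r0 + win, c0:c0 + win] += footprint
    return DoseImage(grid, px, (float(lo[0]), float(lo[1])))
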