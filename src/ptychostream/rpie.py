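"""Regularized Ptychographic Iterative Engine (rPIE) with probe modes.

Sequential projection phase retrieval: for each scan position the exit wave
is propagated to the detector, its modulus replaced by the measured one, and
the object (and optionally the probe) relaxed towards consistency.  The
object update uses the rPIE denominator, a convex mix of ``|P|^2`` and its
maximum controlled by the relaxation constant ``alpha``; ``alpha -> 1``
recovers plain ePIE behaviour while smaller values regularize weakly
illuminated pixels.  Multiple mutually incoherent probe modes share the
measured intensity in proportion to their modelled intensities.

The retrieved phase serves both as the scientific result and as the label
source for surrogate-network training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simkit import (DiffractionStack, Probe, ScanPlan, exit_wave, fft2c,
                     ifft2c, positions_to_pixels)

__all__ = ["RpieOptions", "ReconResult", "ConvergenceTrace", "rpie_reconstruct",
           "data_error"]

_EPS = 1e-12


@dataclass
class RpieOptions:
    """Tuning knobs of the iterative engine.

    alpha is the rPIE object relaxation constant in (0, 1]; beta the probe
    relaxation in [0, 1] (0 freezes the probe entirely).  Probe updates only
    start at ``probe_update_start`` to let the object settle first.
    """

    iterations: int = 500
    alpha: float = 0.25
    beta: float = 0.9
    n_modes: int = 3
    probe_update_start: int = 10
    update_probe: bool = True
    random_object_init: bool = True
    anchor_phase: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must be in [0, 1]")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")


@dataclass
class ConvergenceTrace:
    """Per-iteration normalized modulus mismatch."""

    errors: list[float] = field(default_factory=list)

    def append(self, e: float) -> None:
        if not np.isfinite(e) or e < 0:
            raise FloatingPointError(f"invalid data error {e}")
        self.errors.append(float(e))


@dataclass
class ReconResult:
    """Object retrieved on a regular grid, with grid metadata."""

    phase: np.ndarray
    amplitude: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float]
    final_error: float = np.nan
    object_complex: np.ndarray | None = None
    probe_modes: list[np.ndarray] | None = None


def _orthogonalize(modes: list[np.ndarray]) -> list[np.ndarray]:
    """Gram-Schmidt over the mode stack, preserving total power."""
    total = sum(float(np.sum(np.abs(m) ** 2)) for m in modes)
    out: list[np.ndarray] = []
    for m in modes:
        v = m.astype(np.complex128)
        for u in out:
            v = v - u * (np.vdot(u, v) / max(np.vdot(u, u).real, _EPS))
        out.append(v)
    new_total = sum(float(np.sum(np.abs(m) ** 2)) for m in out)
    scale = np.sqrt(total / max(new_total, _EPS))
    return [m * scale for m in out]


def _init_modes(probe: Probe, n_modes: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Main probe plus orthogonalized seeded noise modes at -20 dB power."""
    modes = [probe.field.copy()]
    p0 = float(np.sum(np.abs(probe.field) ** 2))
    for _ in range(n_modes - 1):
        noise = rng.standard_normal(probe.field.shape) + 1j * rng.standard_normal(probe.field.shape)
        noise *= np.sqrt(0.01 * p0 / np.sum(np.abs(noise) ** 2))
        modes.append(noise)
    return _orthogonalize(modes) if n_modes > 1 else modes


def _model_frames(obj: np.ndarray, modes: list[np.ndarray],
                  centers: np.ndarray) -> np.ndarray:
    n = centers.shape[0]
    win = modes[0].shape[0]
    out = np.zeros((n, win, win))
    for i in range(n):
        for m in modes:
            out[i] += np.abs(fft2c(exit_wave(obj, m, centers[i], index=i))) ** 2
    return out


def data_error(model_intensity: np.ndarray, measured_intensity: np.ndarray) -> float:
    """Normalized modulus mismatch ``sum((sqrt(I) - |Psi|)^2) / sum(I)``."""
    num = float(np.sum((np.sqrt(measured_intensity) - np.sqrt(model_intensity)) ** 2))
    den = float(np.sum(measured_intensity))
    return num / max(den, _EPS)


def state_data_error(result: ReconResult, stack: DiffractionStack,
                     probe: Probe | None = None) -> float:
    """Data error of a retrieved object against a measured stack."""
    modes = result.probe_modes if result.probe_modes is not None else [probe.field]
    obj = result.object_complex
    if obj is None:
        obj = result.amplitude * np.exp(1j * result.phase)
    centers = positions_to_pixels(stack.plan.positions_nm, obj.shape,
                                  result.pixel_size_nm,
                                  origin_nm=result.origin_nm)
    model = _model_frames(obj, modes, centers)
    meas = stack.frames / stack.photons_per_exposure
    return data_error(model, meas)


def rpie_reconstruct(stack: DiffractionStack, probe: Probe,
                     options: RpieOptions | None = None,
                     object_init: np.ndarray | None = None,
                     probe_init_modes: list[np.ndarray] | None = None,
                     ) -> tuple[ReconResult, ConvergenceTrace]:
    """Run rPIE on a diffraction stack with a known initial probe.

    The object grid is sized to cover every probe window with a one-pixel
    margin; positions are rounded to the nearest object pixel (matching the
    forward model).  Visit order is reshuffled every iteration from the
    options seed.  Returns the retrieved object plus the convergence trace.
    """
    opts = options or RpieOptions()
    plan: ScanPlan = stack.plan
    win = probe.field.shape[0]
    if stack.frames.shape[1:] != probe.field.shape:
        raise ValueError("frame side must match the probe window")
    rng = np.random.default_rng(opts.seed)

    px = probe.pixel_size_nm
    span = plan.positions_nm.max(axis=0) - plan.positions_nm.min(axis=0)
    shape = (int(np.ceil(span[1] / px)) + win + 4, int(np.ceil(span[0] / px)) + win + 4)
    # snap the grid origin to the absolute pixel lattice so nearest-pixel
    # rounding here agrees with any other grid sharing that lattice
    origin = _grid_origin(plan, shape, px)
    origin = (round(origin[0] / px) * px, round(origin[1] / px) * px)
    centers = positions_to_pixels(plan.positions_nm, shape, px, origin_nm=origin)

    if object_init is not None:
        obj = object_init.astype(np.complex128).copy()
        if obj.shape != shape:
            raise ValueError(f"object_init must have shape {shape}")
    else:
        obj = np.ones(shape, dtype=np.complex128)
        if opts.random_object_init:
            obj *= np.exp(1j * rng.uniform(-0.1, 0.1, size=shape))

    if probe_init_modes is not None:
        modes = [m.astype(np.complex128).copy() for m in probe_init_modes]
    else:
        modes = _init_modes(probe, opts.n_modes, rng)

    # measured intensities on the model scale (unit-power probe)
    meas = stack.frames.astype(np.float64) / stack.photons_per_exposure
    sqrt_meas = np.sqrt(meas)
    total_meas = float(meas.sum())

    trace = ConvergenceTrace()
    n = plan.n_points
    for it in range(opts.iterations):
        order = rng.permutation(n)
        err_accum = 0.0
        for i in order:
            r0 = int(round(centers[i, 0])) - win // 2
            c0 = int(round(centers[i, 1])) - win // 2
            if r0 < 0 or c0 < 0 or r0 + win > shape[0] or c0 + win > shape[1]:
                raise ValueError(f"scan position {i} exits the object grid")
            patch = obj[r0:r0 + win, c0:c0 + win]
            psis = [m * patch for m in modes]
            Psis = [fft2c(p) for p in psis]
            I_model = np.zeros((win, win))
            for P in Psis:
                I_model += np.abs(P) ** 2
            err_accum += float(np.sum((sqrt_meas[i] - np.sqrt(I_model)) ** 2))
            # distribute the measured modulus across modes
            ratio = sqrt_meas[i] / np.sqrt(I_model + _EPS)
            dpsis = [ifft2c(P * ratio) - p for P, p in zip(Psis, psis)]

            # rPIE object update over all modes
            P_int = np.zeros((win, win))
            for m in modes:
                P_int += np.abs(m) ** 2
            denom_o = (1 - opts.alpha) * P_int + opts.alpha * P_int.max()
            num_o = np.zeros((win, win), dtype=np.complex128)
            for m, d in zip(modes, dpsis):
                num_o += np.conj(m) * d
            new_patch = patch + num_o / (denom_o + _EPS)
            if not np.all(np.isfinite(new_patch.view(np.float64))):
                raise FloatingPointError(f"NaN in object update at iteration {it}")
            obj[r0:r0 + win, c0:c0 + win] = new_patch

            if opts.update_probe and opts.beta > 0 and it >= opts.probe_update_start:
                O_int = np.abs(patch) ** 2
                denom_p = (1 - opts.beta) * O_int + opts.beta * O_int.max()
                for k, (m, d) in enumerate(zip(modes, dpsis)):
                    modes[k] = m + np.conj(patch) * d / (denom_p + _EPS)
                    if not np.all(np.isfinite(modes[k].view(np.float64))):
                        raise FloatingPointError(f"NaN in probe update at iteration {it}")
        if opts.update_probe and opts.beta > 0 and len(modes) > 1 and it >= opts.probe_update_start:
            modes = _orthogonalize(modes)
        trace.append(err_accum / max(total_meas, _EPS))

    if opts.anchor_phase:
        # the retrieved phase is defined only up to a constant; fix the
        # convention that the coverage-weighted circular mean phase is zero,
        # making labels from different scans of one sample mutually consistent
        coverage = np.zeros(shape)
        P_int = np.zeros((win, win))
        for m in modes:
            P_int += np.abs(m) ** 2
        for i in range(n):
            r0 = int(round(centers[i, 0])) - win // 2
            c0 = int(round(centers[i, 1])) - win // 2
            coverage[r0:r0 + win, c0:c0 + win] += P_int
        mean_dir = np.sum(coverage * np.exp(1j * np.angle(obj)))
        obj = obj * np.exp(-1j * np.angle(mean_dir))

    result = ReconResult(phase=np.angle(obj), amplitude=np.abs(obj),
                         pixel_size_nm=px, origin_nm=origin,
                         final_error=trace.errors[-1],
                         object_complex=obj, probe_modes=modes)
    return result, trace


def _grid_origin(plan: ScanPlan, shape: tuple[int, int], px: float) -> tuple[float, float]:
    c = 0.5 * (plan.positions_nm.min(axis=0) + plan.positions_nm.max(axis=0))
    return (float(c[0] - (shape[1] / 2.0) * px), float(c[1] - (shape[0] / 2.0) * px))
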