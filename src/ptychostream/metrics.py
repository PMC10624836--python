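"""Accuracy, overlap-sweep, robustness and resolution metrics.

The workhorse score is the structural similarity index (SSIM) between a
phase image and a ground truth, reported as a percentage after removing the
global phase offset (an iterative reconstruction is only defined up to a
constant phase).  The overlap sweep reproduces the sparse-sampling analysis:
positions are removed from a densely-overlapped scan, iterative retrieval
and stitched single-shot inference are scored side by side at each effective
overlap ratio.  Spatial resolution is estimated by Fourier ring correlation
between two independent reconstructions of the same region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from . import rpie as rpie_mod
from .simkit import DiffractionStack, Probe, step_for_overlap
from .stitch import PatchSet, StitchedImage, stitch

__all__ = ["AccuracyReport", "SweepResult", "FrcCurve", "ssim_accuracy",
           "overlap_sweep", "frc_resolution"]


@dataclass
class AccuracyReport:
    ssim_pct: float
    phase_offset_rad: float
    mask_coverage: float

    def __post_init__(self) -> None:
        if not -100.0 <= self.ssim_pct <= 100.0:
            raise ValueError("ssim_pct out of [-100, 100]")


def ssim_accuracy(phase: np.ndarray, truth: np.ndarray,
                  align_global_phase: bool = True,
                  mask: np.ndarray | None = None,
                  data_range: float | None = None) -> AccuracyReport:
    """SSIM (x100, as %) of a phase image against a ground truth.

    Gaussian 11-pixel window with sigma 1.5 and the standard constants
    K1=0.01, K2=0.03; the data range defaults to the ground truth's
    max - min.  When aligning, the mean phase difference over the valid mask
    is subtracted from ``phase`` first.  Masked-out (e.g. zero-weight) pixels
    are filled with the truth values so they contribute neutrally, and the
    local SSIM map is averaged over the mask only.
    """
    phase = np.asarray(phase, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if phase.shape != truth.shape:
        raise ValueError("phase images must be congruent")
    if mask is None:
        mask = np.isfinite(phase)
    mask = mask & np.isfinite(phase) & np.isfinite(truth)
    if not mask.any():
        raise ValueError("empty valid-pixel mask")

    offset = 0.0
    if align_global_phase:
        offset = float(np.mean(phase[mask] - truth[mask]))
        phase = phase - offset
    a = np.where(mask, phase, truth)
    if data_range is None:
        data_range = float(truth.max() - truth.min())
        if data_range == 0:
            data_range = 1.0
    _, smap = structural_similarity(a, truth, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False,
                                    data_range=data_range, full=True)
    ssim = float(smap[mask].mean())
    return AccuracyReport(ssim_pct=100.0 * ssim, phase_offset_rad=offset,
                          mask_coverage=float(mask.mean()))


@dataclass
class SweepResult:
    """Per-ratio accuracy of stitched inference vs iterative retrieval."""

    rows: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        if self.rows and kw["overlap_ratio"] >= self.rows[-1]["overlap_ratio"]:
            raise ValueError("overlap ratios must be strictly decreasing")
        self.rows.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def subsample_for_overlap(stack: DiffractionStack, target_ratio: float
                          ) -> tuple[DiffractionStack, float, bool]:
    """Keep every k-th spiral point to realize a sparser effective overlap.

    k is chosen so the areal point density matches a step
    ``S = B(1-ratio)/sqrt(3)``; the achieved ratio is reported and flagged
    when no k lands within 5% of the requested step.
    """
    b = stack.plan.beamsize_nm
    s0 = stack.plan.step_nm
    s_target = step_for_overlap(target_ratio, b)
    if s_target < s0:
        raise ValueError("target overlap exceeds the acquired scan's overlap")
    k = max(1, int(round((s_target / s0) ** 2)))
    s_eff = s0 * np.sqrt(k)
    idx = np.arange(0, stack.n_frames, k)
    exact = abs(s_eff - s_target) / s_target <= 0.05
    return stack.subset(idx, step_nm=s_eff), float(s_eff), exact


def resample_on_grid(image: np.ndarray, image_origin_nm: tuple[float, float],
                     image_pixel_nm: float, origin_nm: tuple[float, float],
                     shape: tuple[int, int], pixel_size_nm: float) -> np.ndarray:
    """Bilinearly resample an image onto another regular grid (nm frames)."""
    from scipy.ndimage import map_coordinates

    rows = (origin_nm[1] + np.arange(shape[0]) * pixel_size_nm
            - image_origin_nm[1]) / image_pixel_nm
    cols = (origin_nm[0] + np.arange(shape[1]) * pixel_size_nm
            - image_origin_nm[0]) / image_pixel_nm
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(image, [rr.ravel(), cc.ravel()], order=1,
                           mode="nearest").reshape(shape)


def overlap_sweep(full_stack: DiffractionStack, truth_phase: np.ndarray,
                  truth_origin_nm: tuple[float, float],
                  model, probe: Probe, rpie_opts=None,
                  target_ratios=(0.9, 0.6, 0.3, 0.0)) -> SweepResult:
    """Score stitched inference and iterative retrieval while thinning a scan.

    ``truth_phase`` is the ground truth (full-overlap iterative result or
    the phantom) on a regular grid with the probe's pixel size, anchored at
    ``truth_origin_nm`` in the scan coordinate frame.  For every target
    ratio the scan is subsampled to the matching step, a fresh iterative
    reconstruction runs on the subset, the surrogate's single-shot
    inferences are stitched on the truth grid, and both are scored by
    aligned masked SSIM against the truth.
    """
    from .network import infer  # local import to keep module deps one-way

    px = probe.pixel_size_nm
    result = SweepResult()
    for ratio in sorted(target_ratios, reverse=True):
        sub, s_eff, exact = subsample_for_overlap(full_stack, ratio)
        opts = rpie_opts or rpie_mod.RpieOptions()
        recon, _ = rpie_mod.rpie_reconstruct(sub, probe, opts)
        patches = infer(model, sub.frames)
        pset = PatchSet(patches, sub.plan.positions_nm, px)
        stitched = stitch(pset, origin_nm=truth_origin_nm,
                          shape=truth_phase.shape)
        ai = ssim_accuracy(stitched.phase, truth_phase,
                           mask=stitched.valid).ssim_pct
        truth_sub = resample_on_grid(truth_phase, truth_origin_nm, px,
                                     recon.origin_nm, recon.phase.shape, px)
        # score the iterative result where it is actually constrained
        amp_mask = recon.amplitude > 0.5 * np.median(recon.amplitude)
        it = ssim_accuracy(recon.phase, truth_sub, mask=amp_mask).ssim_pct
        result.add(overlap_ratio=ratio, ssim_ai_pct=ai, ssim_iterative_pct=it,
                   step_nm=s_eff, n_points=sub.n_frames, step_exact=exact)
    return result


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------

@dataclass
class FrcCurve:
    """Ring-wise correlation of two reconstructions plus the threshold curve.

    ``frequency_per_nm`` holds the ring centre spatial frequencies;
    ``resolution_nm`` the inverse frequency of the first crossing below the
    threshold (bounded below by twice the pixel size, the Nyquist limit).
    """

    frequency_per_nm: np.ndarray
    correlation: np.ndarray
    threshold: np.ndarray
    resolution_nm: float
    pixel_size_nm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_per_nm": self.frequency_per_nm,
                             "frc": self.correlation,
                             "threshold": self.threshold})


def _half_bit_threshold(n_ring: np.ndarray) -> np.ndarray:
    """1/2-bit information threshold as a function of ring sample count."""
    sqn = np.sqrt(np.maximum(n_ring, 1))
    return (0.2071 + 1.9102 / sqn) / (1.2071 + 0.9102 / sqn)


def frc_resolution(recon_a: np.ndarray, recon_b: np.ndarray,
                   pixel_size_nm: float,
                   threshold_rule: str = "half_bit") -> FrcCurve:
    """Fourier ring correlation resolution of two independent reconstructions.

    The inputs are phase images of the same region from independent data
    (different scans or a split of one scan).  Correlation per ring is
    ``|sum F_a conj(F_b)| / sqrt(sum |F_a|^2 sum |F_b|^2)``; the resolution
    is the inverse of the first frequency where it falls below the chosen
    threshold curve (1/2-bit by default, fixed 0.5 optionally).
    """
    if threshold_rule not in ("half_bit", "fixed_0.5"):
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    a = np.asarray(recon_a, dtype=np.float64)
    b = np.asarray(recon_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("reconstructions must be congruent")
    n = min(a.shape)
    if n < 64:
        raise ValueError("region too small for FRC (need >= 64 px side)")
    a = a[:n, :n] - a[:n, :n].mean()
    b = b[:n, :n] - b[:n, :n].mean()
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    rings = np.hypot(yy - c, xx - c).astype(int)
    n_bins = c
    sel = rings < n_bins
    num = np.bincount(rings[sel], (fa * np.conj(fb))[sel].real, minlength=n_bins)
    num_i = np.bincount(rings[sel], (fa * np.conj(fb))[sel].imag, minlength=n_bins)
    da = np.bincount(rings[sel], (np.abs(fa) ** 2)[sel], minlength=n_bins)
    db = np.bincount(rings[sel], (np.abs(fb) ** 2)[sel], minlength=n_bins)
    n_ring = np.bincount(rings[sel], minlength=n_bins)
    frc = np.hypot(num, num_i) / np.sqrt(np.maximum(da * db, 1e-300))
    frc[0] = 1.0  # DC ring is degenerate after mean removal; fix by convention
    freq = np.arange(n_bins) / (n * pixel_size_nm)  # cycles/nm

    if threshold_rule == "half_bit":
        thr = _half_bit_threshold(n_ring)
    else:
        thr = np.full(n_bins, 0.5)

    below = np.nonzero(frc[1:] < thr[1:])[0]
    if below.size:
        k = below[0] + 1
        res = 1.0 / max(freq[k], 1e-300)
    else:
        res = 2.0 * pixel_size_nm  # never crosses: Nyquist-limited
    res = max(res, 2.0 * pixel_size_nm)
    return FrcCurve(freq, frc, thr, float(res), pixel_size_nm)
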