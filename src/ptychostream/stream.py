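"""In-process streaming demonstration of the measure -> train -> infer loop.

A campaign is a sequence of scans over one sample.  For each scan the demo
(1) simulates the diffraction frames, (2) runs live single-shot inference on
every frame with the latest published model, (3) performs iterative phase
retrieval, (4) prepares labeled pairs, (5) runs the mismatch policy and, if
triggered, (6) trains incrementally and publishes the new model version.
Every step emits an ordered event so the whole run is auditable and
replayable; the real system's detector streaming, remote execution and edge
deployment are replaced by this single-process event queue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import continual, simkit
from .network import ModelState, NetworkSpec, build_network, infer
from .rpie import RpieOptions, rpie_reconstruct
from .metrics import ssim_accuracy
from .stitch import PatchSet, stitch

__all__ = ["CampaignConfig", "StreamEvent", "EventLog", "run_stream_demo"]


@dataclass
class CampaignConfig:
    """Everything needed to replay a synthetic campaign deterministically."""

    n_scans: int = 3
    points_per_scan: int = 120
    step_nm: float = 60.0
    beamsize_nm: float = 770.0
    probe_side: int = 64
    pixel_size_nm: float = 16.0
    phantom_shape: tuple[int, int] = (224, 224)
    phantom_style: str = "random_etch"
    phase_range: tuple[float, float] = (-0.4, 0.0)
    exposure_ms: float = 1.0
    flux_scale: float = 1e8
    poisson: bool = True
    rpie: RpieOptions = field(default_factory=lambda: RpieOptions(
        iterations=120, n_modes=1, update_probe=False))
    train: continual.TrainConfig = field(default_factory=continual.TrainConfig)
    network: NetworkSpec | None = None
    policy_tolerance: float = 10.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rpie"] = asdict(self.rpie)
        d["train"] = asdict(self.train)
        d["network"] = asdict(self.network) if self.network else None
        return d


@dataclass
class StreamEvent:
    seq: int
    kind: str  # frame | scan_end | model_update | inference
    payload: dict


class EventLog:
    """Totally ordered event stream with strictly increasing sequence numbers."""

    def __init__(self) -> None:
        self.events: list[StreamEvent] = []

    def emit(self, kind: str, **payload) -> StreamEvent:
        ev = StreamEvent(len(self.events), kind, payload)
        self.events.append(ev)
        return ev

    def of_kind(self, kind: str) -> list[StreamEvent]:
        return [e for e in self.events if e.kind == kind]


@dataclass
class CampaignReport:
    events: EventLog
    stitched_per_scan: list
    ssim_per_scan: list[float]
    model: ModelState
    truth_phase: np.ndarray


def run_stream_demo(config: CampaignConfig | None = None) -> CampaignReport:
    """Run a full synthetic campaign and return the audited report.

    Each scan covers a different offset region of one phantom, so later
    scans expose the model to fresh features.  A new network is initialized
    at campaign start (fresh-campaign rule); the stitched live inference of
    every scan is scored against the phantom so the improvement across the
    campaign is visible in the report.
    """
    cfg = config or CampaignConfig()
    log = EventLog()
    rng = np.random.default_rng(cfg.seed)

    spec = cfg.network or NetworkSpec(
        input_side=cfg.probe_side, encoder_widths=(8, 16, 32), bottleneck_convs=2)
    model = build_network(spec, seed=cfg.seed)
    policy = continual.PolicyState(tolerance_ssim_pct=cfg.policy_tolerance)

    phantom = simkit.make_phantom(cfg.phantom_shape, cfg.pixel_size_nm,
                                  cfg.phase_range, cfg.phantom_style, seed=cfg.seed)
    probe = simkit.make_probe(object_pixel_nm=cfg.pixel_size_nm, style="annulus",
                              fwhm_nm=0.75 * cfg.probe_side * cfg.pixel_size_nm,
                              n_pixels=cfg.probe_side)

    # scan centres spread across the phantom, clear of the borders
    margin = (cfg.probe_side / 2 + cfg.step_nm / cfg.pixel_size_nm
              + np.sqrt(cfg.points_per_scan / np.pi) * cfg.step_nm / cfg.pixel_size_nm)
    lo = margin * cfg.pixel_size_nm
    hi_x = cfg.phantom_shape[1] * cfg.pixel_size_nm - lo
    hi_y = cfg.phantom_shape[0] * cfg.pixel_size_nm - lo

    corpus: list[continual.LabeledPair] = []
    stitched_all = []
    ssim_all = []
    for s in range(cfg.n_scans):
        center = (float(rng.uniform(lo, hi_x)), float(rng.uniform(lo, hi_y)))
        plan = simkit.make_spiral_scan(cfg.points_per_scan, cfg.step_nm,
                                       cfg.beamsize_nm, center_nm=center)
        stack = simkit.simulate_scan(phantom, probe, plan, exposure_ms=cfg.exposure_ms,
                                     flux_scale=cfg.flux_scale, poisson=cfg.poisson,
                                     seed=cfg.seed * 1000 + s)
        for i in range(stack.n_frames):
            log.emit("frame", scan=s, index=i)
        # live inference with the latest published model
        patches = infer(model, stack.frames.astype(np.float64))
        log.emit("inference", scan=s, n_frames=stack.n_frames,
                 model_version=model.version)
        pset = PatchSet(patches, plan.positions_nm, probe.pixel_size_nm)
        live = stitch(pset)
        stitched_all.append(live)
        truth = _phantom_window(phantom, live)
        ssim_all.append(ssim_accuracy(live.phase, truth, mask=live.valid).ssim_pct)

        opts = RpieOptions(**{**asdict(cfg.rpie), "seed": cfg.seed * 100 + s})
        recon, _ = rpie_reconstruct(stack, probe, opts)
        pairs = continual.prepare_training_pairs(recon, plan, stack,
                                                 fov_side=spec.input_side, scan_id=s)
        log.emit("scan_end", scan=s, n_pairs=len(pairs))

        if model.version == 0:
            decision = "retrain"  # nothing published yet: always train first
        else:
            decision = continual.retrain_policy_step(policy, model, pairs, recon)
        if decision == "retrain":
            tc = continual.TrainConfig(**{**asdict(cfg.train), "seed": cfg.seed + s})
            model, history = continual.train_incremental(model, corpus, pairs, tc)
            log.emit("model_update", scan=s, version=model.version,
                     best_val_mae=float(history["val_mae"].min()),
                     corpus_size=len(corpus))
        else:
            corpus.extend(pairs)  # data is kept even while services sleep

    return CampaignReport(log, stitched_all, ssim_all, model, phantom.phase)


def _phantom_window(phantom: simkit.Phantom, stitched) -> np.ndarray:
    """Phantom phase resampled on the stitched image's grid (nearest node)."""
    from scipy.ndimage import map_coordinates

    px = phantom.pixel_size_nm
    h, w = stitched.phase.shape
    rows = (stitched.origin_nm[1] + np.arange(h) * stitched.pixel_size_nm) / px
    cols = (stitched.origin_nm[0] + np.arange(w) * stitched.pixel_size_nm) / px
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(phantom.phase, [rr.ravel(), cc.ravel()],
                           order=1, mode="nearest").reshape(h, w)
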