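"""Online training: label preparation, incremental updates, retraining policy.

During a campaign each finished scan is phase-retrieved iteratively, the
result is interpolated into per-position patches and paired with the raw
diffraction frames, and the surrogate is trained for a further fixed number
of epochs on the growing corpus (fresh 10% validation split every epoch,
triangular cyclic learning rate, Adam on mean absolute error).  The epoch
snapshot with the lowest validation loss becomes the new published model.
A mismatch-triggered policy decides when retraining is worth scheduling and
when the expensive iterative/training services can be suspended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ModelState, infer, preprocess_frames
from .nnops import Adam, mae_loss_grad, triangular_lr
from .rpie import ReconResult
from .simkit import DiffractionStack, ScanPlan
from .stitch import PatchSet, stitch
from .metrics import ssim_accuracy

__all__ = ["LabeledPair", "TrainConfig", "PolicyState", "prepare_training_pairs",
           "train_incremental", "downscale_training_intensities",
           "retrain_policy_step"]

logger = logging.getLogger(__name__)


@dataclass
class LabeledPair:
    """One diffraction frame paired with its interpolated phase label."""

    diffraction: np.ndarray
    phase_label: np.ndarray
    position_nm: tuple[float, float]
    scan_id: int = 0

    def __post_init__(self) -> None:
        if self.diffraction.shape != self.phase_label.shape:
            raise ValueError("diffraction and label must share the network input side")


@dataclass
class TrainConfig:
    """Hyper-parameters of one incremental training round."""

    epochs_per_increment: int = 50
    batch_size: int = 64
    val_fraction: float = 0.10
    lr_min: float = 1e-4
    lr_max: float = 5e-4
    lr_cycles_per_increment: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if not (self.lr_min < self.lr_max):
            raise ValueError("lr_min must be < lr_max")
        if self.epochs_per_increment < 1:
            raise ValueError("epochs_per_increment must be >= 1")


@dataclass
class PolicyState:
    """Mismatch-triggered retraining policy.

    Mismatch is 100 minus the SSIM-% between the stitched inference of the
    latest model on a new scan and the iteratively retrieved phase of the
    same scan.  At or above the tolerance the retraining service runs (and
    resumes if suspended); below it the iterative/training services are
    suspended and only a periodic check remains.
    """

    tolerance_ssim_pct: float = 10.0
    mode: str = "active"
    check_period: int = 1
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.tolerance_ssim_pct < 100):
            raise ValueError("tolerance must be in (0, 100)")


# ---------------------------------------------------------------------------
# label preparation
# ---------------------------------------------------------------------------

def prepare_training_pairs(recon: ReconResult, plan: ScanPlan,
                           stack: DiffractionStack, fov_side: int = 128,
                           scan_id: int = 0) -> list[LabeledPair]:
    """One labeled pair per scan position.

    The label is the iteratively retrieved phase bilinearly interpolated on
    an ``fov_side`` x ``fov_side`` regular grid (spacing = reconstruction
    pixel size) centred at the beam position — an exact crop when the
    position falls on a grid node, and well-defined on the irregular spiral
    grid otherwise.  Positions whose window exits the reconstruction are
    skipped with a logged warning.
    """
    from scipy.ndimage import map_coordinates

    px = recon.pixel_size_nm
    ox, oy = recon.origin_nm
    offs = np.arange(fov_side) - (fov_side - 1) / 2.0
    pairs: list[LabeledPair] = []
    for i in range(plan.n_points):
        x_nm, y_nm = plan.positions_nm[i]
        col_c = (x_nm - ox) / px
        row_c = (y_nm - oy) / px
        rows = row_c + offs
        cols = col_c + offs
        if (rows[0] < 0 or cols[0] < 0 or rows[-1] > recon.phase.shape[0] - 1
                or cols[-1] > recon.phase.shape[1] - 1):
            logger.warning("scan position %d window exits the reconstruction; skipped", i)
            continue
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        label = map_coordinates(recon.phase, [rr.ravel(), cc.ravel()],
                                order=1).reshape(fov_side, fov_side)
        pairs.append(LabeledPair(np.asarray(stack.frames[i], dtype=np.float64),
                                 label, (float(x_nm), float(y_nm)), scan_id))
    return pairs


def downscale_training_intensities(pairs: list[LabeledPair], k: float,
                                   poisson_resample: bool = True,
                                   seed: int = 0) -> list[LabeledPair]:
    """Divide diffraction counts by k, optionally re-drawing Poisson counts.

    Emulates training data taken at a k-fold lower photon budget; labels are
    untouched (the phase does not depend on dose).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for p in pairs:
        d = p.diffraction / k
        if poisson_resample:
            d = rng.poisson(d).astype(np.float64)
        out.append(LabeledPair(d, p.phase_label, p.position_nm, p.scan_id))
    return out


# ---------------------------------------------------------------------------
# incremental training
# ---------------------------------------------------------------------------

def train_incremental(model: ModelState, corpus: list[LabeledPair],
                      new_pairs: list[LabeledPair],
                      config: TrainConfig | None = None,
                      ) -> tuple[ModelState, pd.DataFrame]:
    """Append new pairs to the corpus and train for a fixed epoch budget.

    The 10% validation split is re-drawn from the full corpus every epoch
    (seeded); the epoch snapshot with the lowest validation MAE is returned
    as the new model version, with the corpus 99.9th-percentile count
    recorded as its input-normalization constant.  ``corpus`` is mutated
    in place (append-only within a campaign).
    """
    cfg = config or TrainConfig()
    corpus.extend(new_pairs)
    if not corpus:
        raise ValueError("cannot train on an empty corpus")

    x_raw = np.stack([p.diffraction for p in corpus]).astype(np.float64)
    y = np.stack([p.phase_label for p in corpus]).astype(np.float32)[..., None]
    transform = model.spec.input_transform
    x_t = np.sqrt(x_raw) if transform == "sqrt" else x_raw
    norm = float(np.percentile(x_t, 99.9))
    if norm <= 0:
        norm = 1.0
    x = preprocess_frames(x_raw, 1.0, norm, transform)[..., None]

    rng = np.random.default_rng(cfg.seed)
    net = model.net
    opt = Adam(net)
    n = x.shape[0]
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    steps_per_epoch = max(1, int(np.ceil((n - n_val) / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs_per_increment

    best_val = np.inf
    best_state = net.get_state()
    rows = []
    step = 0
    for epoch in range(cfg.epochs_per_increment):
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        ep_losses = []
        lr = cfg.lr_min
        for i in range(0, train_idx.size, cfg.batch_size):
            bi = train_idx[i:i + cfg.batch_size]
            pred = net.forward(x[bi])
            loss, grad = mae_loss_grad(pred, y[bi])
            net.backward(grad)
            lr = triangular_lr(step, total_steps, cfg.lr_min, cfg.lr_max,
                               cfg.lr_cycles_per_increment)
            opt.step(lr)
            ep_losses.append(loss)
            step += 1
        if n_val:
            val_pred = _forward_batched(net, x[val_idx], cfg.batch_size)
            val_loss = float(np.abs(val_pred - y[val_idx]).mean())
        else:
            val_loss = float(np.mean(ep_losses))
        train_loss = float(np.mean(ep_losses)) if ep_losses else val_loss
        rows.append({"epoch": epoch, "train_mae": train_loss,
                     "val_mae": val_loss, "lr": lr})
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()

    net.set_state(best_state)
    history = pd.DataFrame(rows)
    meta = {"epochs_seen": model.training_meta.get("epochs_seen", 0) + cfg.epochs_per_increment,
            "corpus_size": n, "best_val_mae": best_val}
    return model.bumped(net, norm, meta), history


def _forward_batched(net, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [net.forward(x[i:i + batch_size]) for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# retraining policy
# ---------------------------------------------------------------------------

def retrain_policy_step(policy: PolicyState, model: ModelState,
                        new_pairs: list[LabeledPair],
                        recon: ReconResult) -> str:
    """Decide whether the new scan warrants retraining.

    Stitches the current model's inference on the new scan's frames onto the
    reconstruction grid, scores it against the iteratively retrieved phase,
    and compares the mismatch (100 - SSIM-%) with the policy tolerance.
    Returns ``"retrain"`` (resuming services if suspended) or ``"suspend"``.
    """
    if not new_pairs:
        raise ValueError("policy step needs at least one new pair")
    frames = np.stack([p.diffraction for p in new_pairs])
    positions = np.array([p.position_nm for p in new_pairs])
    patches = infer(model, frames)
    pset = PatchSet(patches, positions, recon.pixel_size_nm)
    stitched = stitch(pset, origin_nm=recon.origin_nm, shape=recon.phase.shape)
    if stitched.phase.shape != recon.phase.shape:
        raise ValueError("stitched grid does not match the reconstruction grid")
    rep = ssim_accuracy(stitched.phase, recon.phase, mask=stitched.valid)
    mismatch = 100.0 - rep.ssim_pct
    if mismatch >= policy.tolerance_ssim_pct:
        decision = "retrain"
        policy.mode = "active"
    else:
        decision = "suspend"
        policy.mode = "suspended"
    policy.history.append({"mismatch_pct": mismatch, "decision": decision,
                           "model_version": model.version})
    return decision
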