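"""Lightweight encoder-decoder surrogate for single-shot phase retrieval.

The network maps one raw far-field diffraction frame (counts) to the
real-space phase of the illuminated sample patch in a single forward pass —
a learned inverse of the diffraction operator that is only valid for the
probe and refractive-index range it was trained on, which is precisely what
makes it small and fast.

Architecture (default spec): four encoder stages of two 3x3 convolutions
each at widths 16/32/64/128 with 2x max-pool downsampling, a two-convolution
bottleneck at width 128, and a mirrored decoder of nearest-neighbour
upsampling + convolution stages, ending in a single phase channel bounded to
(-pi, pi) by a scaled tanh.  The halved widths and the removal of the
amplitude branch relative to the original two-headed design bring the
trainable parameter count down to ~0.7M.  The network is fully
convolutional, so the parameter count is independent of the input side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nnops import (Conv3x3, MaxPool2, ReLU, ScaledTanh, Sequential, Upsample2)

__all__ = ["NetworkSpec", "ModelState", "build_network", "count_parameters",
           "preprocess_frames", "infer"]


@dataclass(frozen=True)
class NetworkSpec:
    """Hyper-structure of the surrogate network."""

    input_side: int = 128
    encoder_widths: tuple[int, ...] = (16, 32, 64, 128)
    bottleneck_convs: int = 2
    kernel: int = 3
    output_scale: float = float(np.pi)
    #: 'sqrt' feeds the modulus (amplitude) of the diffraction pattern,
    #: compressing the detector's huge dynamic range; 'counts' feeds raw
    #: intensities
    input_transform: str = "sqrt"

    def __post_init__(self) -> None:
        if self.kernel != 3:
            raise ValueError("only 3x3 kernels are supported")
        if self.input_transform not in ("sqrt", "counts"):
            raise ValueError("input_transform must be 'sqrt' or 'counts'")
        if len(self.encoder_widths) < 1 or any(w < 1 for w in self.encoder_widths):
            raise ValueError("encoder_widths must be positive")
        if self.input_side % (2 ** len(self.encoder_widths)) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by the "
                f"{2 ** len(self.encoder_widths)}x total downsampling")

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        """Mirror of the encoder, padded so every downsample has an upsample."""
        mirror = tuple(reversed(self.encoder_widths[:-1]))
        return mirror + (mirror[-1] if mirror else self.encoder_widths[-1],)


def _build_layers(spec: NetworkSpec, rng: np.random.Generator) -> Sequential:
    layers: list = []
    c = 1
    for w in spec.encoder_widths:
        layers += [Conv3x3(c, w, rng), ReLU(), Conv3x3(w, w, rng), ReLU(), MaxPool2()]
        c = w
    for _ in range(spec.bottleneck_convs):
        layers += [Conv3x3(c, c, rng), ReLU()]
    for w in spec.decoder_widths:
        layers += [Upsample2(), Conv3x3(c, w, rng), ReLU()]
        c = w
    layers += [Conv3x3(c, 1, rng), ScaledTanh(spec.output_scale)]
    return Sequential(layers)


@dataclass
class ModelState:
    """A versioned surrogate model: weights + spec + normalization constant.

    ``norm_count`` is the 99.9th-percentile diffraction count of the training
    corpus, recorded at training time so inference applies the identical
    input scaling.  ``version`` strictly increases on each accepted
    retraining.
    """

    net: Sequential
    spec: NetworkSpec
    version: int = 0
    norm_count: float = 1.0
    training_meta: dict = field(default_factory=dict)

    def bumped(self, net: Sequential, norm_count: float, meta: dict) -> "ModelState":
        return ModelState(net, self.spec, self.version + 1, norm_count, meta)


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> ModelState:
    """Deterministically initialized surrogate model for a given spec."""
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(seed)
    return ModelState(_build_layers(spec, rng), spec)


def count_parameters(model: ModelState | Sequential) -> int:
    """Exact count of trainable scalars."""
    net = model.net if isinstance(model, ModelState) else model
    return net.n_params()


def preprocess_frames(frames: np.ndarray, scale_factor: float = 1.0,
                      norm_count: float = 1.0,
                      transform: str = "sqrt") -> np.ndarray:
    """Scale raw counts, apply the input transform, normalize.

    ``scale_factor`` multiplies the counts first (the "upscale the
    experimental intensity" knob for low-count data); the transform
    ('sqrt' modulus or raw 'counts') is then applied and the result divided
    by ``norm_count``, the same statistic recorded on the transformed
    training corpus, mapping it into ~[0, 1].  No clipping is applied, so
    out-of-distribution count levels remain visible to the network.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    if transform not in ("sqrt", "counts"):
        raise ValueError("transform must be 'sqrt' or 'counts'")
    frames = np.asarray(frames, dtype=np.float64)
    if frames.min() < 0:
        raise ValueError("negative counts are invalid")
    out = frames * scale_factor
    if transform == "sqrt":
        out = np.sqrt(out)
    return (out / norm_count).astype(np.float32)


def infer(model: ModelState, frames: np.ndarray, scale_factor: float = 1.0,
          preprocessed: bool = False, batch_size: int = 32) -> np.ndarray:
    """Single-pass phase inference on a batch of diffraction frames.

    Returns an (n, side, side) float array of phases bounded in
    (-pi, pi).  Pure function of (model, input): no state is mutated.
    """
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    side = model.spec.input_side
    if frames.shape[1:] != (side, side):
        raise ValueError(f"frames must be (n, {side}, {side}), got {frames.shape}")
    if not preprocessed:
        frames = preprocess_frames(frames, scale_factor, model.norm_count,
                                   model.spec.input_transform)
    out = np.empty(frames.shape, dtype=np.float32)
    for i in range(0, frames.shape[0], batch_size):
        x = frames[i:i + batch_size, :, :, None].astype(np.float32)
        out[i:i + batch_size] = model.net.forward(x)[..., 0]
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ModelState, path) -> None:
    """Single-file archive: weights + spec + normalization + version."""
    meta = {"spec": asdict(model.spec), "version": model.version,
            "norm_count": model.norm_count, "training_meta": model.training_meta}
    arrays = {f"p{i}": a for i, a in enumerate(model.net.get_state())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        n = len([k for k in z.files if k.startswith("p")])
        state = [z[f"p{i}"] for i in range(n)]
    spec_d = meta["spec"]
    spec_d["encoder_widths"] = tuple(spec_d["encoder_widths"])
    spec = NetworkSpec(**spec_d)
    model = build_network(spec, seed=0)
    model.net.set_state(state)
    return ModelState(model.net, spec, meta["version"], meta["norm_count"],
                      meta["training_meta"])
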