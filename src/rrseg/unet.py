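"""Two-class UNet and the ensemble inference rule.

One encoder–decoder network with skip connections emits both class channels
(rod, ring) as logits; per-pixel probabilities are the logistic of those
logits. Inference averages the outputs of the k cross-validation members and
thresholds the averaged map at 0.2 — a deliberately permissive cut chosen
because the ensemble tends to over-classify the (dominant) background class.

Averaging happens on the probability scale by default, where the 0.2
threshold is meaningful; averaging on the raw logit scale is available via
``Ensemble(average="logit")``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .io_formats import ClassMasks, InputError
from .nn import (BatchNorm2d, Conv2d, MaxPool2, ReLU, UpsampleNearest2,
                 sigmoid)
from .preprocess import ModelInput


class ConfigurationError(ValueError):
    """Raised for invalid network/ensemble configuration."""


@dataclass(frozen=True)
class UNetConfig:
    """Architecture sizing. ``depth`` counts down-sampling stages.

    ``base_channels`` is the channel width of the first encoder stage;
    each deeper stage doubles it. Input is 1 channel (a single fluorescence
    stain), output is always 2 channels (rod, ring).
    """

    depth: int = 3
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 2

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.base_channels < 4:
            raise ConfigurationError("base_channels must be >= 4")
        if self.in_channels != 1 or self.out_channels != 2:
            raise ConfigurationError("network is fixed at 1 input / 2 output channels")


@dataclass
class ProbabilityMaps:
    """Per-class per-pixel scores in [0, 1], pre-threshold."""

    id: str
    rod: np.ndarray
    ring: np.ndarray

    def __post_init__(self) -> None:
        self.rod = np.asarray(self.rod, dtype=np.float32)
        self.ring = np.asarray(self.ring, dtype=np.float32)
        if self.rod.shape != self.ring.shape or self.rod.ndim != 2:
            raise InputError("rod/ring maps must be 2D with identical shapes")
        for name, arr in (("rod", self.rod), ("ring", self.ring)):
            if arr.size and (arr.min() < -1e-6 or arr.max() > 1 + 1e-6):
                raise InputError(f"{name} map values must lie in [0,1]")

    def stack(self) -> np.ndarray:
        return np.stack([self.rod, self.ring])


class _DoubleConv:
    """conv → batchnorm → ReLU, twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 first: bool = False) -> None:
        # the very first convolution sees raw data; no input gradient needed
        self.layers = [Conv2d(c_in, c_out, rng, needs_input_grad=not first),
                       BatchNorm2d(c_out), ReLU(),
                       Conv2d(c_out, c_out, rng), BatchNorm2d(c_out), ReLU()]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Encoder–decoder with skip connections; maps (N,1,H,W) → (N,2,H,W) logits.

    H and W must be divisible by ``2**depth``. The decoder upsamples by
    nearest neighbour, concatenates the encoder skip, and applies a double
    convolution back to the skip's width.
    """

    def __init__(self, config: UNetConfig, seed: int) -> None:
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        d, b = config.depth, config.base_channels
        enc_ch = [b * 2**i for i in range(d)]          # e.g. 16, 32, 64
        bott_ch = b * 2**d                              # e.g. 128
        self.enc = [_DoubleConv(config.in_channels if i == 0 else enc_ch[i - 1],
                                enc_ch[i], rng, first=(i == 0))
                    for i in range(d)]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _DoubleConv(enc_ch[-1], bott_ch, rng)
        self.ups = [UpsampleNearest2() for _ in range(d)]
        self.dec = []
        up_in = bott_ch
        for i in reversed(range(d)):
            self.dec.append(_DoubleConv(up_in + enc_ch[i], enc_ch[i], rng))
            up_in = enc_ch[i]
        self.head = Conv2d(enc_ch[0], config.out_channels, rng, kernel=1)
        # start the head at a background-prior logit: RR pixels are a rare
        # class, and this skips the early epochs a zero-init head spends
        # learning the base rate (standard practice for imbalanced dense
        # prediction)
        self.head.b[:] = -3.0
        self._skip_shapes: list | None = None

    # -- parameter plumbing ------------------------------------------------
    def params(self):
        ps = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def _batchnorms(self) -> list[BatchNorm2d]:
        bns = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            bns += [l for l in blk.layers if isinstance(l, BatchNorm2d)]
        return bns

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"p{i}": p for i, (p, _) in enumerate(self.params())}
        for j, bn in enumerate(self._batchnorms()):
            out[f"bn{j}_mean"] = bn.running_mean
            out[f"bn{j}_var"] = bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.params()):
            src = arrays[f"p{i}"]
            if src.shape != p.shape:
                raise ConfigurationError(
                    f"checkpoint parameter p{i} has shape {src.shape}, "
                    f"expected {p.shape}")
            p[:] = src
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean[:] = arrays[f"bn{j}_mean"]
            bn.running_var[:] = arrays[f"bn{j}_var"]

    # -- passes ------------------------------------------------------------
    def _check_shape(self, h: int, w: int) -> None:
        f = 2**self.config.depth
        if h % f or w % f:
            raise InputError(
                f"input {h}x{w} not divisible by 2^depth = {f}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise InputError(f"expected (N,1,H,W) input, got {x.shape}")
        self._check_shape(*x.shape[2:])
        # internal layout is (C, N, H, W); see rrseg.nn
        x = np.ascontiguousarray(x.transpose(1, 0, 2, 3), dtype=np.float32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_channels.append((x.shape[0], skip.shape[0]))
            x = np.concatenate([x, skip], axis=0)
            x = blk.forward(x, train=train)
        y = self.head.forward(x, train=train)
        return np.ascontiguousarray(y.transpose(1, 0, 2, 3))

    def backward(self, dlogits: np.ndarray) -> None:
        dy = np.ascontiguousarray(dlogits.transpose(1, 0, 2, 3),
                                  dtype=np.float32)
        dy = self.head.backward(dy)
        # dec[i] consumed the skip from enc[d-1-i]; walking the decoder in
        # reverse build order therefore yields skip gradients for
        # enc[0], enc[1], ... in appending order.
        dskips = []
        for i in reversed(range(len(self.dec))):
            dy = self.dec[i].backward(dy)
            c_up, _ = self._skip_channels[i]
            dskips.append(dy[c_up:])
            dy = self.ups[i].backward(dy[:c_up])
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(len(self.enc))):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)


def build_unet(config: UNetConfig, seed: int) -> UNet:
    """Construct a UNet with seeded, reproducible weight initialisation."""
    return UNet(config, seed)


def predict_member(model: UNet, model_input: ModelInput | np.ndarray,
                   id: str = "") -> ProbabilityMaps:
    """Run one member on one image; logistic maps logits to [0, 1]."""
    pixels = model_input.pixels if isinstance(model_input, ModelInput) else model_input
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim != 2:
        raise InputError(f"expected a 2D image, got shape {pixels.shape}")
    logits = model.forward(pixels[None, None], train=False)[0]
    probs = sigmoid(logits).astype(np.float32)
    if not id and isinstance(model_input, ModelInput):
        id = str(model_input.provenance.get("source_id", ""))
    return ProbabilityMaps(id=id, rod=probs[0], ring=probs[1])


@dataclass
class Ensemble:
    """k trained members sharing one config, plus the inference rule."""

    members: list[UNet]
    threshold: float = 0.2
    average: Literal["probability", "logit"] = "probability"

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ConfigurationError("ensemble needs at least one member")
        cfg = self.members[0].config
        if any(m.config != cfg for m in self.members):
            raise ConfigurationError("all members must share one UNetConfig")
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must lie in (0,1)")


def ensemble_predict(ensemble: Ensemble,
                     model_input: ModelInput | np.ndarray,
                     id: str = "") -> ProbabilityMaps:
    """Average member outputs per pixel, per class.

    On the default probability scale this is the arithmetic mean of the
    members' logistic outputs; on the logit scale raw outputs are averaged
    and the logistic applied once afterwards.
    """
    pixels = model_input.pixels if isinstance(model_input, ModelInput) else model_input
    pixels = np.asarray(pixels, dtype=np.float32)
    if not id and isinstance(model_input, ModelInput):
        id = str(model_input.provenance.get("source_id", ""))
    if ensemble.average == "logit":
        acc = None
        for m in ensemble.members:
            logits = m.forward(pixels[None, None], train=False)[0]
            acc = logits if acc is None else acc + logits
        probs = sigmoid(acc / len(ensemble.members)).astype(np.float32)
        return ProbabilityMaps(id=id, rod=probs[0], ring=probs[1])
    acc = np.zeros((2,) + pixels.shape, dtype=np.float64)
    for m in ensemble.members:
        acc += predict_member(m, pixels).stack()
    acc /= len(ensemble.members)
    return ProbabilityMaps(id=id, rod=acc[0], ring=acc[1])


def threshold_probabilities(maps: ProbabilityMaps,
                            t: float = 0.2) -> ClassMasks:
    """Binarise per-class maps at ``t``; a pixel exactly at ``t`` is positive."""
    if not 0 < t < 1:
        raise ConfigurationError(f"threshold must lie in (0,1), got {t}")
    return ClassMasks(id=maps.id, rod=maps.rod >= t, ring=maps.ring >= t)


# -- checkpointing ----------------------------------------------------------

def save_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Serialize members + config to a single ``.npz`` checkpoint."""
    path = Path(path)
    meta = {
        "config": ensemble.members[0].config.__dict__,
        "threshold": ensemble.threshold,
        "average": ensemble.average,
        "k": len(ensemble.members),
        "seeds": [m.seed for m in ensemble.members],
    }
    arrays = {"__meta__": np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)}
    for i, m in enumerate(ensemble.members):
        for name, arr in m.state_arrays().items():
            arrays[f"m{i}/{name}"] = arr
    np.savez(path, **arrays)


def load_ensemble(path: str | Path) -> Ensemble:
    path = Path(path)
    if not path.exists():
        raise InputError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        config = UNetConfig(**meta["config"])
        members = []
        for i in range(meta["k"]):
            m = UNet(config, seed=meta["seeds"][i])
            m.load_state_arrays({
                name.split("/", 1)[1]: data[name]
                for name in data.files if name.startswith(f"m{i}/")})
            members.append(m)
    return Ensemble(members=members, threshold=meta["threshold"],
                    average=meta["average"])
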