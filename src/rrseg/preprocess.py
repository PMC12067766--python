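"""Conversion of images into the fixed model-input frame.

The network consumes a fixed square input (512×512 by default, matching the
training convention of downscaling 1024×1024 confocal frames by half). No
intensity normalisation is applied anywhere: empirically, normalising
fluorescence inputs harms segmentation of these structures, so pixel values
pass through changed only by interpolation.

Two pipelines handle images from a microscope whose pixel size differs from
the training reference:

* :func:`fixed_magnification_pipeline` — resize the full frame to the model
  input regardless of pixel size. An object's on-model pixel extent then
  depends on the acquisition field of view, which is exactly what breaks
  inference across microscopes.
* :func:`fixed_pixel_size_pipeline` — first place the image on a canvas
  whose pixel count reproduces the *reference* physical field at the
  image's own pixel size (zero-padding a smaller field, centre-cropping a
  larger one), then resize. After this, an object of physical size *d*
  occupies the same number of model-input pixels as it would have under
  the reference microscope, which is what lets a model trained on one
  microscope segment images from another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .io_formats import ImageSample, InputError

#: model input side used by the full-scale training convention
DEFAULT_MODEL_SIZE = 512


@dataclass(frozen=True)
class ReferenceFrame:
    """The acquisition geometry the model was trained on.

    Defaults describe a 1024×1024 px confocal frame at 0.192 µm/px,
    i.e. a 196.6 µm physical field.
    """

    ref_pixel_size_um: float = 0.192
    ref_extent_px: int = 1024

    def __post_init__(self) -> None:
        if not (self.ref_pixel_size_um > 0 and self.ref_extent_px > 0):
            raise InputError("reference frame parameters must be positive")

    @property
    def ref_extent_um(self) -> float:
        return self.ref_pixel_size_um * self.ref_extent_px


@dataclass
class ModelInput:
    """A square float image ready for the network, with provenance."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise InputError(
                f"ModelInput must be square 2D, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("ModelInput values must be finite")


def _bilinear_resize(pixels: np.ndarray, size: int) -> np.ndarray:
    if pixels.shape == (size, size):
        return np.asarray(pixels, dtype=np.float32)
    out = _sk_resize(pixels.astype(np.float64), (size, size), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def resize_to_model_input(image: ImageSample,
                          model_size: int = DEFAULT_MODEL_SIZE) -> ModelInput:
    """Bilinear rescale of the frame to the model input size; no normalisation."""
    out = _bilinear_resize(image.pixels, model_size)
    return ModelInput(pixels=out, provenance={
        "source_id": image.id,
        "pipeline": "native",
        "scale": model_size / image.pixels.shape[0],
    })


def fixed_magnification_pipeline(image: ImageSample,
                                 model_size: int = DEFAULT_MODEL_SIZE,
                                 ) -> ModelInput:
    """Resize the full frame to the model input, ignoring pixel size.

    Coincides with :func:`resize_to_model_input` by construction; kept as a
    named pipeline because it is one of the two documented cross-microscope
    strategies (the one *without* physical-size preservation).
    """
    out = resize_to_model_input(image, model_size)
    out.provenance["pipeline"] = "fixed-magnification"
    return out


def _center_pad_crop(pixels: np.ndarray, target: int) -> np.ndarray:
    """Centre the image on a target×target canvas, zero-padding or cropping."""
    h, w = pixels.shape
    out = np.zeros((target, target), dtype=np.float64)
    # source and destination windows along each axis
    def windows(n: int) -> tuple[slice, slice]:
        if n >= target:
            start = (n - target) // 2
            return slice(start, start + target), slice(0, target)
        start = (target - n) // 2
        return slice(0, n), slice(start, start + n)

    src_r, dst_r = windows(h)
    src_c, dst_c = windows(w)
    out[dst_r, dst_c] = pixels[src_r, src_c]
    return out


def fixed_pixel_size_pipeline(image: ImageSample,
                              frame: ReferenceFrame = ReferenceFrame(),
                              model_size: int = DEFAULT_MODEL_SIZE,
                              ) -> ModelInput:
    """Match the reference physical field before resizing.

    The canvas side is ``frame.ref_extent_um / image.pixel_size_um`` pixels —
    the number of this image's pixels that span the reference field of view.
    A smaller field is zero-padded (fluorescence background is dark), a
    larger one centre-cropped; the canvas is then resized to the model
    input. Objects keep the pixel extent they would have had on the
    reference microscope.
    """
    if image.pixel_size_um is None or not image.pixel_size_um > 0:
        raise InputError("fixed_pixel_size_pipeline requires a known pixel size")
    canvas_px = int(round(frame.ref_extent_um / image.pixel_size_um))
    canvas = _center_pad_crop(image.pixels.astype(np.float64), canvas_px)
    out = _bilinear_resize(canvas, model_size)
    return ModelInput(pixels=out, provenance={
        "source_id": image.id,
        "pipeline": "fixed-pixel-size",
        "canvas_px": canvas_px,
        "pixel_size_um": image.pixel_size_um,
        "ref_pixel_size_um": frame.ref_pixel_size_um,
        "ref_extent_px": frame.ref_extent_px,
        "scale": model_size / canvas_px,
        "anchor": "center",
    })


def _nearest_resize_bool(mask: np.ndarray, size: int) -> np.ndarray:
    if mask.shape == (size, size):
        return mask.astype(bool)
    out = _sk_resize(mask.astype(np.float32), (size, size), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return out > 0.5


def transform_masks(masks: "ClassMasks", pixel_size_um: float,
                    pipeline: str = "native",
                    frame: ReferenceFrame = ReferenceFrame(),
                    model_size: int = DEFAULT_MODEL_SIZE) -> "ClassMasks":
    """Carry annotation masks through the same geometry as the image pipeline.

    Uses nearest-neighbour resampling so masks stay binary. ``pipeline`` is
    one of ``native``/``fixed-mag`` (full-frame resize) or ``fixed-pixel``
    (reference-field canvas, then resize). Needed whenever predictions made
    in the model-input frame are to be scored against annotations.
    """
    from .io_formats import ClassMasks

    out = {}
    for cls, mask in masks.classes().items():
        if pipeline in ("native", "fixed-mag"):
            out[cls] = _nearest_resize_bool(mask, model_size)
        elif pipeline == "fixed-pixel":
            canvas_px = int(round(frame.ref_extent_um / pixel_size_um))
            canvas = _center_pad_crop(mask.astype(np.float64), canvas_px)
            out[cls] = _nearest_resize_bool(canvas > 0.5, model_size)
        else:
            raise InputError(f"unknown pipeline {pipeline!r}")
    return ClassMasks(id=masks.id, rod=out["rod"], ring=out["ring"])
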