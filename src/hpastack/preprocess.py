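"""Channel compositions and backbone-input resizing.

Six 3-plane compositions are built per sample: each single channel replicated
on three planes (``gray_blue``, ``gray_green``, ``gray_red``, ``gray_yellow``),
a color composite mapping the red/green/blue channels onto the R/G/B planes
(``bgr_composite``), and the pixelwise mean of all four channels replicated on
three planes (``mean_gray``).  Resizing to a backbone's input geometry uses
bicubic interpolation with output clamped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from PIL import Image

from .io import CHANNEL_NAMES, SampleRecord


class CompositionMode(str, Enum):
    GRAY_BLUE = "gray_blue"
    GRAY_GREEN = "gray_green"
    GRAY_RED = "gray_red"
    GRAY_YELLOW = "gray_yellow"
    BGR_COMPOSITE = "bgr_composite"
    MEAN_GRAY = "mean_gray"


COMPOSITION_MODES: tuple[CompositionMode, ...] = tuple(CompositionMode)


@dataclass(frozen=True)
class ExtractorInputSpec:
    """Input geometry a feature extractor expects: side_px x side_px x 3."""

    extractor_name: str
    side_px: int

    def __post_init__(self) -> None:
        if self.side_px not in (224, 227, 299):
            raise ValueError(f"unsupported input side: {self.side_px}")


# Input sides per architecture family: 227 for AlexNet/SqueezeNet, 299 for the
# Inception family, 224 for everything else.
INPUT_SIDES: dict[str, int] = {
    "alexnet": 227,
    "vgg16": 224,
    "vgg19": 224,
    "mobilenet_v2": 224,
    "squeezenet": 227,
    "resnet18": 224,
    "googlenet": 224,
    "resnet50": 224,
    "inception_v3": 299,
    "resnet101": 224,
    "densenet201": 224,
    "inception_resnet_v2": 299,
}


def input_spec_for(extractor_name: str) -> ExtractorInputSpec:
    base = extractor_name.split("/")[0]
    if base not in INPUT_SIDES:
        raise KeyError(f"unknown extractor: {extractor_name!r}")
    return ExtractorInputSpec(extractor_name=extractor_name, side_px=INPUT_SIDES[base])


def compose(sample: SampleRecord, mode: CompositionMode) -> np.ndarray:
    """Build the 3-plane uint8 image for one composition mode."""
    mode = CompositionMode(mode)
    ch = sample.channels
    missing = [c for c in CHANNEL_NAMES if c not in ch]
    if missing:
        raise ValueError(f"sample {sample.sample_id!r} missing channel(s) {missing}")
    if mode is CompositionMode.BGR_COMPOSITE:
        # natural color mapping: red channel -> R plane, green -> G, blue -> B
        out = np.stack([ch["red"], ch["green"], ch["blue"]], axis=-1)
        return out.astype(np.uint8)
    if mode is CompositionMode.MEAN_GRAY:
        acc = np.mean([ch[c].astype(np.float64) for c in CHANNEL_NAMES], axis=0)
        gray = np.floor(acc + 0.5).clip(0, 255).astype(np.uint8)  # round half up
    else:
        color = mode.value.removeprefix("gray_")
        gray = ch[color].astype(np.uint8)
    return np.repeat(gray[..., None], 3, axis=-1)


def resize_for(image3: np.ndarray, spec: ExtractorInputSpec) -> np.ndarray:
    """Bicubic resize of a 3-plane uint8 image to the extractor's geometry.

    Bicubic over/undershoot is clamped to [0, 255] (uint8 saturation).
    """
    if image3.ndim != 3 or image3.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {image3.shape}")
    if image3.shape[0] == 0 or image3.shape[1] == 0:
        raise ValueError("zero-sized input image")
    side = spec.side_px
    if image3.shape[0] == side and image3.shape[1] == side:
        return image3.astype(np.uint8)
    pil = Image.fromarray(image3.astype(np.uint8), mode="RGB")
    out = pil.resize((side, side), resample=Image.Resampling.BICUBIC)
    return np.asarray(out, dtype=np.uint8)
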