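"""Guided-GradCAM saliency and per-electrode, per-band activation tables.

GradCAM: the gradient of a class logit w.r.t. the decoder's last
convolutional feature map is spatially averaged into per-channel weights;
the rectified weighted channel sum gives a coarse class-discriminative
map, bilinearly upsampled to the input grid. Guided backpropagation: the
input gradient computed with the rectifier backward rule (pass only where
the forward activation and the incoming gradient are both positive),
giving a high-resolution signed pixel map with one plane per frequency
band. Their elementwise product (Guided-GradCAM) localizes
class-discriminative evidence at pixel resolution; its magnitude averaged
over a 3x3 neighborhood at each electrode's pixel yields the activation
scores analyzed by the statistics module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Decoder

__all__ = [
    "SaliencyMap",
    "gradcam",
    "guided_backprop",
    "guided_gradcam",
    "extract_activations",
    "activation_table",
]


@dataclass
class SaliencyMap:
    """GradCAM / guided / combined maps for one sample and target class."""

    gradcam: np.ndarray          # (H, W), non-negative, upsampled
    guided: np.ndarray           # (H, W, bands), signed
    guided_gradcam: np.ndarray   # (H, W, bands)
    target: int
    sample_id: int | None = None


def _upsample(coarse: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    zoom = (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1])
    return ndimage.zoom(coarse, zoom, order=1, mode="nearest", grid_mode=True)


def gradcam(decoder: Decoder, image: np.ndarray, target: int) -> np.ndarray:
    """Rectified, channel-weighted class activation map at input resolution.

    Weights are the spatial mean of d(logit_target)/d(feature map) over the
    last convolutional feature map; the map is the ReLU of the weighted
    channel sum, bilinearly upsampled to the image grid.
    """
    if decoder.last_feature_index < 0:
        raise ValueError("decoder has no convolutional feature map")
    image = np.asarray(image, dtype=float)
    _, captured = decoder.input_gradient(image, target,
                                         capture=decoder.last_feature_index)
    acts, grads = captured          # (1, h, w, c) each
    w = grads.mean(axis=(1, 2))     # (1, c)
    coarse = np.maximum((acts * w[:, None, None, :]).sum(axis=-1)[0], 0.0)
    return _upsample(coarse, image.shape[:2])


def guided_backprop(decoder: Decoder, image: np.ndarray, target: int) -> np.ndarray:
    """Signed input-gradient map under the guided rectifier backward rule."""
    image = np.asarray(image, dtype=float)
    dx, _ = decoder.input_gradient(image, target, guided=True)
    return dx[0]


def guided_gradcam(decoder: Decoder, image: np.ndarray,
                   target: int | None = None,
                   sample_id: int | None = None) -> SaliencyMap:
    """Full saliency for one image: coarse map, guided map and product.

    ``target`` defaults to the decoder's predicted class for the image.
    """
    image = np.asarray(image, dtype=float)
    if target is None:
        target = int(decoder.predict_proba(image[None])[0].argmax())
    cam = gradcam(decoder, image, target)
    gbp = guided_backprop(decoder, image, target)
    return SaliencyMap(gradcam=cam, guided=gbp,
                       guided_gradcam=cam[:, :, None] * gbp,
                       target=target, sample_id=sample_id)


def extract_activations(maps, electrode_pixels: np.ndarray,
                        channel_names, band_names,
                        categories=None, subjects=None) -> pd.DataFrame:
    """Per-electrode, per-band activation scores from a set of saliency maps.

    The activation for (electrode, band) is the mean of |guided_gradcam|
    over the 3x3 pixel neighborhood centered at the electrode's pixel
    (truncated at the image border). Emits one row per sample x electrode
    x band with the sample's target (predicted) category.
    """
    electrode_pixels = np.asarray(electrode_pixels, dtype=int)
    rows = []
    for si, smap in enumerate(maps):
        g = np.abs(smap.guided_gradcam)
        H, W, n_bands = g.shape
        if (electrode_pixels[:, 0].max() >= H or electrode_pixels[:, 1].max() >= W
                or electrode_pixels.min() < 0):
            raise ValueError("electrode pixel outside the image grid")
        cat = categories[si] if categories is not None else smap.target
        subj = subjects[si] if subjects is not None else ""
        sid = smap.sample_id if smap.sample_id is not None else si
        for ei, name in enumerate(channel_names):
            r, c = electrode_pixels[ei]
            patch = g[max(0, r - 1):r + 2, max(0, c - 1):c + 2, :]
            means = patch.mean(axis=(0, 1))
            for bi, band in enumerate(band_names):
                rows.append((sid, subj, cat, name, band, float(means[bi])))
    return pd.DataFrame(
        rows, columns=["sample", "subject", "category", "electrode", "band",
                       "activation"])


def activation_table(decoder: Decoder, topomaps: np.ndarray,
                     electrode_pixels: np.ndarray, channel_names, band_names,
                     subjects=None, target: str = "predicted",
                     true_labels=None) -> pd.DataFrame:
    """Convenience chain: saliency per sample, then activation extraction.

    ``target`` is "predicted" (default) or "true" (requires true_labels).
    Category labels in the table are the decoder's class names.
    """
    maps, cats = [], []
    label_of = {i: c for i, c in enumerate(decoder.label_order)}
    idx_of = {c: i for i, c in enumerate(decoder.label_order)}
    for i in range(topomaps.shape[0]):
        if target == "true":
            if true_labels is None:
                raise ValueError("target='true' requires true_labels")
            cls = idx_of[true_labels[i]]
        else:
            cls = None
        smap = guided_gradcam(decoder, topomaps[i], target=cls, sample_id=i)
        maps.append(smap)
        cats.append(label_of[smap.target])
    return extract_activations(maps, electrode_pixels, channel_names,
                               band_names, categories=cats, subjects=subjects)
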