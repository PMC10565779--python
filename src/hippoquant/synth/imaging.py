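"""Synthetic two-channel immunofluorescence images.

Emulates cultures stained for a dendritic marker (MAP2) and a presynaptic
puncta marker (VGLUT1): the MAP2 channel is a dilated random-walk dendrite
skeleton at fixed intensity, the VGLUT1 channel a sum of Gaussian puncta
centred on (or near) the dendrites.  Both channels receive additive
Gaussian background noise.  The noiseless channels are kept in the truth
record so above-threshold sums are exact for any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["ImageTruth", "ImagePair", "make_image_truth",
           "synthesize_image_pair", "save_image_pair"]


@dataclass
class ImageTruth:
    """Ground truth of one synthetic image pair."""

    map2_mask: np.ndarray                # boolean dendrite mask
    puncta_centers: np.ndarray           # (n, 2) pixel coordinates
    puncta_intensity: float              # peak intensity per punctum, AU
    background_sd: float                 # noise SD, AU
    map2_intensity: float = 100.0        # mask intensity, AU
    puncta_sigma_px: float = 1.5
    vglut_clean: np.ndarray | None = field(default=None, repr=False)
    map2_clean: np.ndarray | None = field(default=None, repr=False)

    def vglut_sum_above(self, threshold: float) -> float:
        """Exact above-threshold VGLUT1 intensity sum of the clean image."""
        img = self.vglut_clean
        return float(img[img > threshold].sum())

    def map2_area_above(self, threshold: float) -> int:
        """Exact above-threshold MAP2 pixel count of the clean image."""
        return int((self.map2_clean > threshold).sum())


@dataclass
class ImagePair:
    vglut: np.ndarray
    map2: np.ndarray
    truth: ImageTruth


def make_image_truth(shape=(128, 128), n_dendrites: int = 3,
                     n_puncta: int = 50, puncta_intensity: float = 150.0,
                     background_sd: float = 5.0, seed: int = 0,
                     dilate_px: int = 2) -> ImageTruth:
    """Draw a dendrite mask (random-walk skeletons, dilated) and puncta
    centres on the mask."""
    if min(shape) < 64:
        raise ValueError("image must be at least 64x64")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_dendrites):
        r = float(rng.integers(5, shape[0] - 5))
        c = float(rng.integers(0, 5))
        angle = rng.uniform(-0.4, 0.4)
        while 0 <= int(r) < shape[0] and 0 <= int(c) < shape[1]:
            mask[int(r), int(c)] = True
            angle += rng.normal(0.0, 0.08)
            r += np.sin(angle)
            c += np.cos(angle)
    mask = ndimage.binary_dilation(mask, iterations=dilate_px)
    on_mask = np.argwhere(mask)
    if n_puncta > 0 and on_mask.size == 0:
        raise ValueError("empty dendrite mask")
    centers = (on_mask[rng.integers(0, len(on_mask), size=n_puncta)]
               if n_puncta > 0 else np.empty((0, 2), dtype=int))
    return ImageTruth(map2_mask=mask, puncta_centers=centers,
                      puncta_intensity=puncta_intensity,
                      background_sd=background_sd)


def _render_clean(truth: ImageTruth, shape) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    vglut = np.zeros(shape)
    s2 = 2.0 * truth.puncta_sigma_px ** 2
    for (r, c) in truth.puncta_centers:
        vglut += truth.puncta_intensity * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / s2)
    map2 = truth.map2_mask.astype(float) * truth.map2_intensity
    return vglut, map2


def synthesize_image_pair(truth: ImageTruth, shape=None,
                          seed: int = 0) -> ImagePair:
    """Render the two channels, add noise, and attach exact clean images to
    the truth record.  Same seed and truth give identical images."""
    shape = shape or truth.map2_mask.shape
    if min(shape) < 64:
        raise ValueError("image must be at least 64x64")
    if truth.map2_mask.shape != tuple(shape):
        raise ValueError("mask shape must match requested image shape")
    vglut_clean, map2_clean = _render_clean(truth, shape)
    truth.vglut_clean = vglut_clean
    truth.map2_clean = map2_clean
    rng = np.random.default_rng(seed)
    if truth.background_sd > 0:
        vglut = vglut_clean + rng.normal(0, truth.background_sd, shape)
        map2 = map2_clean + rng.normal(0, truth.background_sd, shape)
    else:
        vglut, map2 = vglut_clean.copy(), map2_clean.copy()
    return ImagePair(vglut=vglut, map2=map2, truth=truth)


def save_image_pair(pair: ImagePair, path: str | Path) -> None:
    """Write the pair as a 2-page float32 TIFF (page 0 VGLUT1, page 1 MAP2)."""
    import tifffile

    stack = np.stack([pair.vglut, pair.map2]).astype(np.float32)
    tifffile.imwrite(path, stack)
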