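"""Stain separation and intensity-level operations on stained-tissue images.

Images are plain numpy arrays: a gray image is a 2-D ``uint8``/float array of
intensities in [0, 255]; a binary mask is a 2-D boolean array of the same
shape.  Stain separation follows the optical-density unmixing of Ruifrok &
Johnston as implemented in the FIJI colour-deconvolution plugin: each pixel's
RGB optical density is a non-negative combination of per-stain unit OD
vectors, so concentrations are recovered by inverting the stain matrix.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "STAIN_BASES",
    "stain_matrix",
    "rgb_to_od",
    "unmix_od",
    "deconvolve_stain",
    "binarize",
    "hdm",
    "read_gray",
    "write_gray",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _with_residual(v1, v2) -> np.ndarray:
    """Complete a 2-stain basis with the normalized cross-product residual."""
    v1, v2 = _unit(v1), _unit(v2)
    v3 = np.cross(v1, v2)
    return np.stack([v1, v2, _unit(v3)])


# Published FIJI/Ruifrok stain OD vectors (rows = stains, columns = R,G,B).
STAIN_BASES: dict[str, np.ndarray] = {
    # haematoxylin + DAB (brown chromogen); channel 1 isolates DAB
    "H-DAB": _with_residual([0.650, 0.704, 0.286], [0.268, 0.570, 0.776]),
    # haematoxylin + PAS; channel 1 isolates the PAS/aniline-blue component
    "H-PAS": _with_residual([0.644, 0.717, 0.267], [0.175, 0.972, 0.155]),
}


def stain_matrix(basis: str | np.ndarray) -> np.ndarray:
    """Resolve a named or custom 3x3 stain basis (rows are unit OD vectors)."""
    if isinstance(basis, str):
        try:
            m = STAIN_BASES[basis]
        except KeyError:
            raise ValueError(
                f"unknown stain basis {basis!r}; known: {sorted(STAIN_BASES)}"
            ) from None
    else:
        m = np.asarray(basis, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("custom stain basis must be 3x3")
        m = m / np.linalg.norm(m, axis=1, keepdims=True)
    if abs(np.linalg.det(m)) < 1e-8:
        raise ValueError("stain matrix is singular: vectors are not independent")
    return m


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density OD = -log10((I + 1) / 256)."""
    rgb = np.asarray(rgb, dtype=float)
    return -np.log10((rgb + 1.0) / 256.0)


def unmix_od(rgb: np.ndarray, basis: str | np.ndarray = "H-DAB") -> np.ndarray:
    """Unmix an RGB image into per-stain OD concentrations.

    Returns an (H, W, 3) float array whose last axis indexes the stains of
    the basis in order.  Concentrations can be slightly negative for pixels
    that do not lie in the stain cone; they are left unclipped here.
    """
    m = stain_matrix(basis)
    od = rgb_to_od(rgb)
    return od @ np.linalg.inv(m)


def deconvolve_stain(
    rgb: np.ndarray,
    basis: str | np.ndarray = "H-DAB",
    channel: int | str = 1,
) -> np.ndarray:
    """Extract one stain channel as a gray image rescaled to [0, 255].

    ``channel`` is the stain row index in the basis, or one of the
    conventional names ``"hematoxylin"`` (0), ``"dab"``/``"pas"`` (1),
    ``"residual"`` (2).  The DAB (or PAS) channel is the default since it
    carries the ECM stain signal.
    """
    names = {"hematoxylin": 0, "dab": 1, "pas": 1, "residual": 2}
    if isinstance(channel, str):
        try:
            channel = names[channel.lower()]
        except KeyError:
            raise ValueError(f"unknown channel name {channel!r}") from None
    if channel not in (0, 1, 2):
        raise ValueError("channel index must be 0, 1 or 2")
    conc = unmix_od(rgb, basis)[..., channel]
    conc = np.clip(conc, 0.0, None)
    top = conc.max()
    if top <= 0:
        return np.zeros(conc.shape, dtype=np.uint8)
    return np.round(conc / top * 255.0).astype(np.uint8)


def binarize(img: np.ndarray, threshold: float | str = "otsu") -> np.ndarray:
    """Threshold a gray image into an ECM foreground mask (img >= threshold)."""
    img = np.asarray(img)
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if img.min() == img.max():
            # constant image: Otsu undefined, call everything background
            return np.zeros(img.shape, dtype=bool)
        threshold = threshold_otsu(np.asarray(img, dtype=float))
    else:
        if not 0 <= threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
    return np.asarray(img, dtype=float) >= float(threshold)


def hdm(img: np.ndarray, saturation_threshold: float = 140.0) -> float:
    """High-density matrix: fraction of pixels at or above the threshold."""
    if not 0 <= saturation_threshold <= 255:
        raise ValueError("saturation_threshold must lie in [0, 255]")
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        return 0.0
    return float(np.mean(img >= saturation_threshold))


def read_gray(path) -> np.ndarray:
    """Read a TIFF/PNG as 8-bit gray (RGB inputs are deconvolved by caller)."""
    from imageio.v3 import imread

    arr = imread(path)
    if arr.ndim == 3:
        return arr  # caller decides how to unmix
    return np.asarray(arr, dtype=np.uint8)


def write_gray(path, img: np.ndarray) -> None:
    from imageio.v3 import imwrite

    imwrite(path, np.asarray(img, dtype=np.uint8))
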