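"""Adaptive Wiener denoising.

Each pixel is shrunk toward its local window mean by the ratio of the global
noise variance to the local variance:

    out = in - (sigma_noise^2 / sigma_local^2) * (in - local_mean)

Where the local variance does not exceed the noise variance the window is
considered pure noise and the output is clamped to the local mean; where the
local variance dominates (edges), the pixel is left essentially untouched.
A zero noise variance reproduces the input exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

__all__ = ["WienerConfig", "local_statistics", "wiener_denoise"]

_MODES = {"reflect": "reflect", "constant": "constant"}


@dataclasses.dataclass(frozen=True)
class WienerConfig:
    window: int = 3
    global_noise_variance: float | str = "auto"
    border_mode: str = "reflect"

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.border_mode not in _MODES:
            raise ValueError(f"border_mode must be one of {sorted(_MODES)}")
        v = self.global_noise_variance
        if v != "auto" and (not np.isscalar(v) or float(v) < 0):
            raise ValueError("global_noise_variance must be 'auto' or >= 0")


def local_statistics(image: np.ndarray, window: int = 3,
                     border_mode: str = "reflect"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and variance over a square window."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("local_statistics expects a 2-D intensity array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    mode = _MODES[border_mode]
    mean = ndimage.uniform_filter(image, size=window, mode=mode)
    mean_sq = ndimage.uniform_filter(image * image, size=window, mode=mode)
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return mean, var


def _denoise_channel(channel: np.ndarray, config: WienerConfig) -> np.ndarray:
    mean, var = local_statistics(channel, config.window, config.border_mode)
    noise = (float(np.mean(var)) if config.global_noise_variance == "auto"
             else float(config.global_noise_variance))
    if noise == 0.0:
        return channel.copy()
    # ratio clamped to 1 where local variance <= noise variance -> local mean
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(var > noise, noise / var, 1.0)
    return channel - ratio * (channel - mean)


def wiener_denoise(image: np.ndarray, config: WienerConfig | None = None
                   ) -> np.ndarray:
    """Denoise a 2-D intensity image or an RGB image (per channel)."""
    config = config or WienerConfig()
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    if image.ndim == 2:
        return _denoise_channel(image, config)
    if image.ndim == 3:
        return np.stack([_denoise_channel(image[..., c], config)
                         for c in range(image.shape[-1])], axis=-1)
    raise ValueError("image must be 2-D or 3-D (H, W[, C])")
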