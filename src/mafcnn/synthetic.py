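"""Synthetic dermoscopy-style lesion images.

Real dermoscopic classes differ in lesion asymmetry, border irregularity and
colour.  The generator encodes a class as a prototype of those three cues and
renders each sample as a super-ellipse "lesion" with a sinusoidal boundary
perturbation on a skin-toned background, plus additive Gaussian pixel noise
to exercise the denoising stage.  Every stage of the classification pipeline
is therefore testable without the public dermoscopy corpora; loaders for
those corpora accept the same ``filename,label`` manifest layout.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["LesionSpec", "SyntheticDatasetConfig", "ImageSample",
           "make_class_prototypes", "render_lesion", "generate_dataset",
           "save_dataset", "load_dataset"]

MAX_CLASSES = 7

# Well-separated lesion colours: pairwise L-infinity distance >= 0.35 before
# jitter, so any two prototypes differ by >= 0.2 in some channel.
_PALETTE = np.array([
    [0.10, 0.05, 0.05],   # near-black (melanoma-like)
    [0.55, 0.30, 0.15],   # brown
    [0.90, 0.60, 0.45],   # tan
    [0.20, 0.45, 0.75],   # blue-grey
    [0.85, 0.20, 0.60],   # pink-red
    [0.45, 0.75, 0.35],   # olive
    [0.65, 0.85, 0.90],   # pale
])
_SKIN = np.array([0.87, 0.72, 0.60])


@dataclasses.dataclass(frozen=True)
class LesionSpec:
    """Shape/colour prototype of one lesion class."""

    class_id: int
    asymmetry: float            # 0 = circular, 1 = strongly elongated
    border_irregularity: float  # amplitude of the boundary perturbation
    lesion_color: tuple[float, float, float]
    background_color: tuple[float, float, float] = tuple(_SKIN)
    scale: float = 0.5          # lesion diameter as a fraction of image width

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        for name in ("asymmetry", "border_irregularity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.scale < 1.0:
            raise ValueError("scale must be in (0, 1)")
        for c in (*self.lesion_color, *self.background_color):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colours must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SyntheticDatasetConfig:
    n_per_class: tuple[int, ...]
    image_size: int = 64
    noise_sigma: float = 0.05
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    def __post_init__(self):
        if not 2 <= self.n_classes <= MAX_CLASSES:
            raise ValueError(f"need 2..{MAX_CLASSES} classes")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("every class needs at least one sample")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclasses.dataclass
class ImageSample:
    """One RGB image in [0,1]^(H,W,3) with its class label."""

    image: np.ndarray
    label: int
    sample_id: str


def make_class_prototypes(n_classes: int, seed: int) -> list[LesionSpec]:
    """Deterministic, pairwise-distinct class prototypes.

    Colours come from a spaced palette with small seeded jitter; asymmetry
    and border irregularity are spread over [0.1, 0.9] with the border order
    shuffled so shape cues are not collinear with colour cues.
    """
    if not 2 <= n_classes <= MAX_CLASSES:
        raise ValueError(f"n_classes must be in [2, {MAX_CLASSES}]")
    rng = np.random.default_rng(seed)
    colors = _PALETTE[:n_classes] + rng.uniform(-0.05, 0.05, (n_classes, 3))
    colors = np.clip(colors, 0.0, 1.0)
    asym = np.linspace(0.1, 0.9, n_classes)
    border = rng.permutation(np.linspace(0.1, 0.9, n_classes))
    scales = rng.uniform(0.42, 0.58, n_classes)
    return [
        LesionSpec(class_id=k, asymmetry=float(asym[k]),
                   border_irregularity=float(border[k]),
                   lesion_color=tuple(colors[k]), scale=float(scales[k]))
        for k in range(n_classes)
    ]


def render_lesion(spec: LesionSpec, image_size: int, noise_sigma: float,
                  rng: np.random.Generator) -> ImageSample:
    """Render one sample.

    The lesion is a rotated super-ellipse whose boundary radius is modulated
    by ``1 + 0.18*border_irregularity*sin(5θ+φ)``; being star-shaped it is
    always a single connected region, and the scale/asymmetry ranges keep its
    area between 5% and 60% of the image.
    """
    if image_size < 16:
        raise ValueError("image_size must be >= 16")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    s = image_size
    a = spec.scale * s / 2.0
    b = a * (1.0 - 0.5 * spec.asymmetry)
    theta0 = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    cy = s / 2.0 + rng.uniform(-0.05, 0.05) * s
    cx = s / 2.0 + rng.uniform(-0.05, 0.05) * s

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    y, x = yy - cy, xx - cx
    xr = np.cos(theta0) * x + np.sin(theta0) * y
    yr = -np.sin(theta0) * x + np.cos(theta0) * y
    p = 2.5  # super-ellipse exponent: slightly boxier than an ellipse
    d = ((np.abs(xr) / a) ** p + (np.abs(yr) / b) ** p) ** (1.0 / p)
    ang = np.arctan2(yr, xr)
    boundary = 1.0 + 0.18 * spec.border_irregularity * np.sin(5 * ang + phase)
    mask = (d <= boundary)[..., None]

    img = np.where(mask, np.asarray(spec.lesion_color),
                   np.asarray(spec.background_color))
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(image=img, label=spec.class_id,
                       sample_id=f"c{spec.class_id}")


def generate_dataset(config: SyntheticDatasetConfig
                     ) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate the configured dataset plus its ``filename,label`` manifest.

    Per-sample child generators are spawned from a single seed sequence, so
    the dataset is reproducible as a whole and per sample.
    """
    protos = make_class_prototypes(config.n_classes, config.seed)
    streams = np.random.SeedSequence(config.seed).spawn(sum(config.n_per_class))
    samples: list[ImageSample] = []
    rows = []
    i = 0
    for spec, n in zip(protos, config.n_per_class):
        for j in range(n):
            rng = np.random.default_rng(streams[i])
            sample = render_lesion(spec, config.image_size, config.noise_sigma, rng)
            sample.sample_id = f"c{spec.class_id}_{j:04d}"
            samples.append(sample)
            rows.append({"filename": sample.sample_id + ".png",
                         "label": spec.class_id})
            i += 1
    return samples, pd.DataFrame(rows)


def _to_uint8(image: np.ndarray) -> np.ndarray:
    # round-half-even, matching numpy's default rounding
    return np.round(np.clip(image, 0, 1) * 255.0).astype(np.uint8)


def save_dataset(samples: list[ImageSample], manifest: pd.DataFrame,
                 out_dir: str | pathlib.Path) -> pathlib.Path:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, fname in zip(samples, manifest["filename"]):
        Image.fromarray(_to_uint8(sample.image)).save(out / fname)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(data_dir: str | pathlib.Path,
                 manifest_name: str = "manifest.csv") -> list[ImageSample]:
    """Read an image directory with a ``filename,label`` manifest.

    This is also the adapter layout for the public dermoscopy corpora: lay
    the images flat in one directory and list them in the manifest.
    """
    data_dir = pathlib.Path(data_dir)
    manifest_path = data_dir / manifest_name
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    if not {"filename", "label"} <= set(manifest.columns):
        raise ValueError("manifest must have columns filename,label")
    samples = []
    for _, row in manifest.iterrows():
        arr = np.asarray(Image.open(data_dir / row["filename"]).convert("RGB"),
                         dtype=np.float64) / 255.0
        samples.append(ImageSample(image=arr, label=int(row["label"]),
                                   sample_id=str(row["filename"])))
    return samples
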