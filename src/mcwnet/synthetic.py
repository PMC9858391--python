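"""Seeded generator of radiograph-like test images.

Three class profiles emulate the visual structure of frontal chest films at
toy scale: a dark body background, two bright elliptical "lung fields", and
class-dependent blob opacities — none/faint for healthy-looking images, many
small peripheral opacities for the covid-like class, one or two large central
consolidations for the pneumonia-like class.  Gaussian sensor noise is added
on top.  Every image draws from its own random substream keyed by
``(seed, class index, image index)`` so per-image reproducibility survives
reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ImageSample, LabeledDataset


@dataclass(frozen=True)
class ClassProfile:
    """Blob statistics for one synthetic class.

    ``placement`` controls where blob centres may fall inside the lung
    fields: ``"peripheral"`` keeps them near the lung boundary,
    ``"central"`` near the lung centres, ``"anywhere"`` is uniform.
    """

    name: str
    blob_count: tuple[int, int]          # inclusive range
    blob_radius: tuple[float, float]     # pixels
    blob_intensity: tuple[float, float]  # added on top of lung field
    placement: str = "anywhere"

    def __post_init__(self) -> None:
        if self.blob_count[0] < 0 or self.blob_count[1] < self.blob_count[0]:
            raise ValueError(f"profile {self.name!r}: bad blob_count range")
        if self.placement not in ("anywhere", "peripheral", "central"):
            raise ValueError(f"profile {self.name!r}: bad placement")


def default_profiles() -> list[ClassProfile]:
    return [
        ClassProfile("covid_like", (3, 6), (4.0, 7.0), (0.35, 0.6), "peripheral"),
        ClassProfile("normal", (0, 1), (3.0, 5.0), (0.08, 0.18), "anywhere"),
        ClassProfile("pneumonia_like", (1, 2), (14.0, 20.0), (0.35, 0.6), "central"),
    ]


@dataclass
class SynthConfig:
    n_per_class: int = 10
    height: int = 128
    width: int = 128
    profiles: list[ClassProfile] = field(default_factory=default_profiles)
    background: float = 0.08
    lung_intensity: float = 0.38
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.height < 32 or self.width < 32:
            raise ValueError("images must be at least 32x32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.profiles) != 3:
            raise ValueError("exactly 3 class profiles are required")
        counts = [p.blob_count for p in self.profiles]
        for i in range(3):
            for j in range(i + 1, 3):
                if counts[i] == counts[j]:
                    raise ValueError(
                        "class profiles must have pairwise distinct blob-count ranges"
                    )


def _lung_fields(height: int, width: int) -> tuple[np.ndarray, list[tuple]]:
    """Boolean mask of the two lung ellipses plus (cy, cx, ay, ax) params."""
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    params = []
    mask = np.zeros((height, width), dtype=bool)
    for cx_frac in (0.30, 0.70):
        cy, cx = 0.52 * height, cx_frac * width
        ay, ax = 0.34 * height, 0.155 * width
        params.append((cy, cx, ay, ax))
        mask |= ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    return mask, params


def _sample_center(profile: ClassProfile, params: list[tuple],
                   rng: np.random.Generator) -> tuple[float, float]:
    cy, cx, ay, ax = params[int(rng.integers(0, len(params)))]
    theta = rng.uniform(0, 2 * np.pi)
    if profile.placement == "peripheral":
        rho = rng.uniform(0.6, 0.92)
    elif profile.placement == "central":
        rho = rng.uniform(0.0, 0.45)
    else:
        rho = np.sqrt(rng.uniform(0.0, 0.85))
    return cy + rho * ay * np.sin(theta), cx + rho * ax * np.cos(theta)


def generate_image(profile: ClassProfile, rng: np.random.Generator,
                   config: SynthConfig | None = None,
                   sample_id: str = "synthetic") -> ImageSample:
    """Draw one image for ``profile`` from ``rng``.

    The sample's ``meta["blobs"]`` log records each blob's centre, radius and
    intensity; at ``noise_sd == 0`` the logged blob count equals the number of
    connected bright components above the lung-field level (blob centres are
    rejection-sampled for pairwise separation so opacities do not merge).
    """
    cfg = config or SynthConfig()
    h, w = cfg.height, cfg.width
    lungs, params = _lung_fields(h, w)
    img = np.full((h, w), cfg.background, dtype=np.float64)
    img[lungs] = cfg.lung_intensity

    k = int(rng.integers(profile.blob_count[0], profile.blob_count[1] + 1))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    blobs: list[dict] = []
    for _ in range(k):
        r = rng.uniform(*profile.blob_radius)
        amp = rng.uniform(*profile.blob_intensity)
        by = bx = None
        for _attempt in range(200):
            cy, cx = _sample_center(profile, params, rng)
            if all(np.hypot(cy - b["y"], cx - b["x"]) > r + b["r"] + 3.0
                   for b in blobs):
                by, bx = cy, cx
                break
        if by is None:  # crowded frame: place at the last candidate anyway
            by, bx = cy, cx
        d2 = (yy - by) ** 2 + (xx - bx) ** 2
        # compact smooth bump: amp inside, soft cosine shoulder of ~2 px
        bump = amp * np.clip((r + 2.0 - np.sqrt(d2)) / 2.0, 0.0, 1.0)
        img += bump
        blobs.append({"y": float(by), "x": float(bx), "r": float(r),
                      "intensity": float(amp)})

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(img[:, :, None].astype(np.float32), profile.name,
                       sample_id, meta={"blobs": blobs, "profile": profile.name})


def generate_dataset(config: SynthConfig) -> LabeledDataset:
    """Generate ``3 * n_per_class`` samples, exactly balanced, seed-reproducible."""
    samples: list[ImageSample] = []
    for ci, profile in enumerate(config.profiles):
        for i in range(config.n_per_class):
            rng = np.random.default_rng((config.seed, ci, i))
            samples.append(
                generate_image(profile, rng, config,
                               sample_id=f"{profile.name}/{i:04d}")
            )
    class_names = sorted(p.name for p in config.profiles)
    return LabeledDataset(samples, class_names)
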