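"""Synthetic labeled produce-like images for end-to-end testing.

Each image holds one colored, textured, shaped object roughly centered on
a gray background with a smooth lighting gradient, emulating the
non-uniform illumination that defeats global thresholding on real produce
photographs.  Every image is a pure function of its class specification
and a seed, so whole datasets are reproducible bit for bit.

Three six-class presets isolate one descriptor family each:

* ``color6``   — classes differ only in base color,
* ``texture6`` — equal colors, classes differ in texture pattern,
* ``shape6``   — equal colors and textures, classes differ in shape.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from fruitvision.segmentation import write_mask

FRAME_SIZE = 256  # matches the nominal input size of the pipeline

TEXTURES = ("flat", "stripes", "speckle")
SHAPES = ("ellipse", "rounded-rect", "blob")


@dataclass(frozen=True)
class ClassSpec:
    """Rendering recipe for one synthetic class."""

    name: str
    color: tuple[int, int, int]
    color2: tuple[int, int, int] | None = None
    # when color2 is set the object is rendered two-tone: a random split
    # of the surface shows `color`, the rest `color2` (a bicolor fruit);
    # the patch fraction varies per image in two_tone_range.  With
    # bimodal=True the whole fruit instead takes one of the two colors
    # per image (a variety whose surface changes color entirely as it
    # ripens), making the class's feature region two separate modes.
    two_tone_range: tuple[float, float] = (0.35, 0.65)
    bimodal: bool = False
    color_jitter: float = 8.0            # per-image, per-channel uniform jitter
    texture: str = "flat"
    texture_amplitude: float = 0.0       # gray-level modulation of the pattern
    texture_period: float = 12.0         # stripe wavelength in pixels
    shape: str = "ellipse"
    size_range: tuple[float, float] = (0.45, 0.62)   # fraction of half-frame
    eccentricity_range: tuple[float, float] = (0.0, 0.3)
    blob_amplitude: float = 0.10         # radial modulation of blob outlines
    background_base: float = 60.0        # gray level at frame center
    background_gradient: float = 40.0    # gray-level swing across the frame
    background_curvature: float = 10.0   # radial bowl term of the lighting
    object_shading: float = 1.0          # how strongly the light field shades
                                         # the object surface (1 = as background)
    mottle_amplitude: float = 8.0        # low-frequency surface color variation
    mottle_cells: int = 6                # coarseness of the mottle field
    blur_sigma: float = 0.5              # camera point-spread blur in pixels
    noise_sigma: float = 3.0             # additive Gaussian pixel noise

    def __post_init__(self):
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")


def render_image(
    spec: ClassSpec, seed, size: int = FRAME_SIZE, bimodal_mode: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render one image and its ground-truth object mask.

    Deterministic given (spec, seed).  The object keeps a margin of at
    least 10% of the frame to every border.  For a bimodal spec,
    ``bimodal_mode`` (0 or 1) fixes which surface color the fruit shows;
    left None, the mode is drawn from the seed.
    """
    rng = np.random.default_rng(seed)
    half = size / 2.0

    # background: oriented linear gradient plus a shallow radial bowl
    yy, xx = np.mgrid[0:size, 0:size]
    u = xx / size - 0.5
    v = yy / size - 0.5
    theta = rng.uniform(0, 2 * np.pi)
    bg = (
        spec.background_base
        + spec.background_gradient * (np.cos(theta) * u + np.sin(theta) * v)
        + spec.background_curvature * ((u**2 + v**2) * 4.0 - 1.0)
    )
    image = np.repeat(bg[:, :, None], 3, axis=2)

    # object geometry
    frac = rng.uniform(*spec.size_range)
    r0 = frac * half
    ecc = rng.uniform(*spec.eccentricity_range)
    phi = rng.uniform(0, np.pi)
    cx = half + rng.uniform(-0.04, 0.04) * size
    cy = half + rng.uniform(-0.04, 0.04) * size
    a = r0
    b = r0 * np.sqrt(1.0 - ecc**2)
    dx, dy = xx - cx, yy - cy
    uo = np.cos(phi) * dx + np.sin(phi) * dy
    vo = -np.sin(phi) * dx + np.cos(phi) * dy
    if spec.shape == "ellipse":
        mask = (uo / a) ** 2 + (vo / b) ** 2 <= 1.0
    elif spec.shape == "rounded-rect":
        mask = np.abs(uo / a) ** 4 + np.abs(vo / b) ** 4 <= 1.0
    else:  # blob: low-order radial harmonics on an ellipse-like base
        ang = np.arctan2(vo, uo)
        wobble = np.zeros_like(ang)
        for k in range(2, 6):
            wobble += rng.uniform(0, spec.blob_amplitude / 2) * np.cos(
                k * ang + rng.uniform(0, 2 * np.pi)
            )
        rr = np.sqrt((uo / a) ** 2 + (vo / b) ** 2)
        mask = rr <= 1.0 + wobble

    # object appearance: jittered base color (or a two-tone patch pair),
    # plus texture modulation
    jitter = rng.uniform(-spec.color_jitter, spec.color_jitter, size=3)
    color_a = np.array(spec.color, dtype=np.float64) + jitter
    if spec.color2 is not None and spec.bimodal:
        mode = int(rng.integers(2)) if bimodal_mode is None else int(bimodal_mode)
        if mode == 1:
            color_a = np.array(spec.color2, dtype=np.float64) + jitter
        color_b = color_a
        field = np.zeros((size, size))
    elif spec.color2 is not None:
        color_b = np.array(spec.color2, dtype=np.float64) + jitter
        w = rng.uniform(*spec.two_tone_range)
        split_phi = rng.uniform(0, np.pi)
        proj = np.cos(split_phi) * uo + np.sin(split_phi) * vo
        # threshold at the w-quantile of the object's projections
        cut = np.quantile(proj[mask], w) if mask.any() else 0.0
        field = np.where(proj <= cut, 0.0, 1.0)
    else:
        color_b = color_a
        field = np.zeros((size, size))
    modulation = np.zeros((size, size))
    if spec.texture == "stripes" and spec.texture_amplitude > 0:
        stripe_phi = rng.uniform(0, np.pi)
        coord = np.cos(stripe_phi) * dx + np.sin(stripe_phi) * dy
        modulation = spec.texture_amplitude * np.sin(
            2 * np.pi * coord / spec.texture_period + rng.uniform(0, 2 * np.pi)
        )
    elif spec.texture == "speckle" and spec.texture_amplitude > 0:
        modulation = rng.uniform(
            -spec.texture_amplitude, spec.texture_amplitude, size=(size, size)
        )
    # the light field shades the object surface exactly as it does the
    # background, so object colors drift smoothly across the frame
    shading = spec.object_shading * (bg - spec.background_base)
    # low-frequency per-channel surface mottle, as on real fruit skin
    if spec.mottle_amplitude > 0:
        coarse = rng.normal(0.0, spec.mottle_amplitude,
                            size=(3, spec.mottle_cells, spec.mottle_cells))
        mottle = np.stack(
            [ndimage.zoom(coarse[ch],
                          (size / spec.mottle_cells, size / spec.mottle_cells),
                          order=3, grid_mode=True, mode="nearest")
             for ch in range(3)], axis=2
        )
    else:
        mottle = np.zeros((size, size, 3))
    for ch in range(3):
        tone = color_a[ch] + field * (color_b[ch] - color_a[ch])
        image[..., ch][mask] = (
            tone[mask] + modulation[mask] + shading[mask] + mottle[..., ch][mask]
        )

    if spec.blur_sigma > 0:  # camera point-spread function
        for ch in range(3):
            image[..., ch] = ndimage.gaussian_filter(image[..., ch], spec.blur_sigma)
    image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), mask


@dataclass
class SyntheticDataset:
    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: np.ndarray                   # class indices 1..C
    class_names: list[str]
    manifest: list[dict] = field(default_factory=list)


def generate_dataset(
    specs: list[ClassSpec],
    n_per_class: int,
    seed: int,
    out_dir: str | Path | None = None,
    size: int = FRAME_SIZE,
) -> SyntheticDataset:
    """Render ``n_per_class`` images per spec; optionally write to disk.

    When ``out_dir`` is given, images and ground-truth masks are written
    as PNGs along with a ``manifest.csv`` of path, label, mask path.
    """
    images, masks, labels, manifest = [], [], [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for ci, spec in enumerate(specs, start=1):
        for i in range(n_per_class):
            child = np.random.SeedSequence([int(seed), ci, i])
            # bimodal classes alternate modes so both are equally sampled
            mode = i % 2 if spec.bimodal else None
            img, mask = render_image(spec, child, size=size, bimodal_mode=mode)
            images.append(img)
            masks.append(mask)
            labels.append(ci)
            row = {"path": "", "label": ci, "class_name": spec.name, "mask_path": ""}
            if out is not None:
                from PIL import Image

                stem = f"{spec.name}_{i:03d}"
                img_path = out / f"{stem}.png"
                mask_path = out / f"{stem}_mask.png"
                Image.fromarray(img).save(img_path)
                write_mask(mask_path, mask)
                row["path"] = str(img_path)
                row["mask_path"] = str(mask_path)
            manifest.append(row)
    if out is not None:
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["path", "label", "class_name", "mask_path"]
            )
            writer.writeheader()
            writer.writerows(manifest)
    return SyntheticDataset(
        images=images,
        masks=masks,
        labels=np.array(labels, dtype=np.int64),
        class_names=[s.name for s in specs],
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# presets

# base colors keep their luma well above the background's 40-80 range so
# the split-and-merge border rule has contrast to work with
_RED = (230, 70, 50)
_YELLOW = (225, 205, 60)
_GREEN = (75, 205, 80)
# the exotic pair shares its luma (~112) so a purple/orange boundary is
# invisible to grayscale texture: the classes differ purely in color
_PURPLE = (150, 75, 200)
_ORANGE = (190, 85, 40)
_TAN = (180, 140, 80)


def _color6() -> list[ClassSpec]:
    """Solid, bicolor, and color-shifting classes.

    Besides three solid-color classes, ``bicolor`` fruits show two skin
    colors at once on each fruit (like bicolor apples), and ``shifter``
    fruits change surface color entirely as they ripen (like passion
    fruit), so that class occupies two separate color modes whose mixture
    region belongs to the bicolor class — class structure that no single
    linear decision function can carve up.
    """
    solid = dict(texture="speckle", texture_amplitude=10.0)
    return [
        ClassSpec(name="red", color=_RED, **solid),
        ClassSpec(name="yellow", color=_YELLOW, **solid),
        ClassSpec(name="bicolor_warm", color=_RED, color2=_YELLOW, **solid),
        ClassSpec(name="green", color=_GREEN, **solid),
        ClassSpec(name="shifter_exotic", color=_PURPLE, color2=_ORANGE,
                  bimodal=True, **solid),
        ClassSpec(name="bicolor_exotic", color=_PURPLE, color2=_ORANGE, **solid),
    ]


def _texture6() -> list[ClassSpec]:
    return [
        ClassSpec(name="flat", color=_TAN, texture="flat"),
        ClassSpec(
            name="stripes_fine", color=_TAN, texture="stripes",
            texture_amplitude=28.0, texture_period=6.0,
        ),
        ClassSpec(
            name="stripes_coarse", color=_TAN, texture="stripes",
            texture_amplitude=28.0, texture_period=24.0,
        ),
        ClassSpec(
            name="stripes_strong", color=_TAN, texture="stripes",
            texture_amplitude=45.0, texture_period=12.0,
        ),
        ClassSpec(
            name="speckle_soft", color=_TAN, texture="speckle",
            texture_amplitude=18.0,
        ),
        ClassSpec(
            name="speckle_hard", color=_TAN, texture="speckle",
            texture_amplitude=40.0,
        ),
    ]


def _shape6() -> list[ClassSpec]:
    return [
        ClassSpec(name="disk", color=_TAN, shape="ellipse",
                  eccentricity_range=(0.0, 0.1)),
        ClassSpec(name="ellipse", color=_TAN, shape="ellipse",
                  eccentricity_range=(0.80, 0.88)),
        ClassSpec(name="squarish", color=_TAN, shape="rounded-rect",
                  eccentricity_range=(0.0, 0.1)),
        ClassSpec(name="bar", color=_TAN, shape="rounded-rect",
                  eccentricity_range=(0.80, 0.88)),
        ClassSpec(name="blob_mild", color=_TAN, shape="blob",
                  blob_amplitude=0.06),
        ClassSpec(name="blob_wavy", color=_TAN, shape="blob",
                  blob_amplitude=0.14),
    ]


def preset(name: str) -> list[ClassSpec]:
    """Return one of the shipped six-class spec sets."""
    presets = {"color6": _color6, "texture6": _texture6, "shape6": _shape6}
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]()


PRESET_NAMES = ("color6", "texture6", "shape6")
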