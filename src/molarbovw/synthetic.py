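"""Seeded synthetic panoramic-radiograph generator.

Real panoramic radiographs of third-molar (wisdom tooth, "R8")
complications are clinical data and cannot ship with the package, so the
pipeline is exercised on synthetic phantoms that reproduce the
statistical structure the method relies on:

* a smooth low-frequency anatomical background (band-limited noise over
  a base exposure level) plus bright mandibular/maxillary arch bands;
* four third-molar sites at the canonical positions inside the ROI band
  (two upper, two lower);
* class-dependent molar structure at those sites.  An *affected* molar
  is rendered as a tilted ellipse carrying a cross-hatch striation
  texture; an unaffected site shows only a smooth tooth-like bump.
  Classes follow the clinical grouping: ``R8_Null`` no affected molar,
  ``R8_Lower`` lower sites affected, ``R8_Upper_Lower`` upper and lower
  sites affected;
* quantum mottle: Poisson (variance proportional to intensity) noise
  followed by additive Gaussian read noise.

Because the bag-of-visual-words representation discards keypoint
positions, the class signal is deliberately *textural*: affected molars
carry a striation pattern whose spatial period differs between upper
(finer) and lower (coarser) jaw, so each class populates distinct
regions of descriptor space irrespective of where the sites sit.

Everything is driven by one ``numpy`` Generator seeded from the config,
so a fixed seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError, FormatError

__all__ = [
    "CLASSES",
    "SyntheticConfig",
    "MolarSite",
    "LabeledImage",
    "generate_dataset",
    "write_dataset",
    "write_manifest",
    "read_manifest",
]

#: The three complication classes, in canonical order.
CLASSES = ("R8_Lower", "R8_Null", "R8_Upper_Lower")

# Canonical third-molar site centres on the 1200x2400 reference frame,
# (row, col, is_upper).  Sites sit near the lateral ends of the ROI band.
_REFERENCE_SITES = (
    (420, 640, True),
    (420, 2050, True),
    (770, 640, False),
    (770, 2050, False),
)
_REFERENCE_H = 1200
_REFERENCE_W = 2400

# Striation spatial periods (pixels) per jaw; upper molars are rendered
# with a finer texture so the two affected classes occupy different
# descriptor-space regions even under histogram normalisation.  Periods
# sit above the ~10 px suppression scale of the 9-px bilateral window so
# the texture survives the smoothing chain, as root/crown structure does
# on real radiographs.
_PERIOD_LOWER = 26.0
_PERIOD_UPPER = 16.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``tilt_range`` is the (min, max) magnitude in degrees of the
    impacted molar's tilt from vertical; the side (mesial/distal) is
    drawn at random per site.
    """

    n_images: int = 150
    class_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    height: int = 1200
    width: int = 2400
    noise_sigma: float = 8.0
    mottle_poisson: bool = True
    molar_contrast: float = 60.0
    tilt_range: tuple[float, float] = (15.0, 45.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_images < 3:
            raise ConfigurationError(f"n_images must be >= 3, got {self.n_images}")
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_proportions must be 3 nonnegative fractions summing to 1, got {self.class_proportions}"
            )
        if self.height < 16 or self.width < 16:
            raise ConfigurationError(
                f"dimensions {self.height}x{self.width} too small; minimum 16x16"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        lo, hi = self.tilt_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"invalid tilt_range {self.tilt_range}")


@dataclass(frozen=True)
class MolarSite:
    row: float
    col: float
    tilt_degrees: float
    present: bool
    is_upper: bool


@dataclass
class LabeledImage:
    image: np.ndarray  # uint8 height x width
    label: str
    ground_truth_sites: list[MolarSite] = field(default_factory=list)


def _class_counts(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment: realized counts deviate from
    floor(n*p) by at most 1."""
    p = np.asarray(proportions, dtype=float)
    base = np.floor(n * p).astype(int)
    remainder = n - base.sum()
    order = np.argsort(-(n * p - base), kind="stable")
    counts = base.copy()
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def _background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, (max(h // 32, 4) + 2, max(w // 32, 4) + 2))
    field_ = resize(coarse, (h, w), order=3, mode="edge", anti_aliasing=False)
    img = 85.0 + 12.0 * field_

    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    x = (cols - w / 2) / (w / 2)
    # mandibular arch (bright band curving down toward the edges)
    arch_lo = 0.62 * h + 0.16 * h * x**2
    img += 28.0 * np.exp(-((rows - arch_lo) ** 2) / (2.0 * (0.035 * h) ** 2))
    # maxillary band
    arch_hi = 0.40 * h - 0.06 * h * x**2
    img += 18.0 * np.exp(-((rows - arch_hi) ** 2) / (2.0 * (0.045 * h) ** 2))
    return img


def _stamp_site(
    img: np.ndarray,
    site: MolarSite,
    contrast: float,
    scale_r: float,
    scale_c: float,
) -> None:
    """Add tooth structure at one site, in place.

    Affected sites get a tilted ellipse with cross-hatch striation;
    unaffected sites a smooth low-contrast bump.
    """
    h, w = img.shape
    a = 72.0 * scale_r  # semi-axis along the tooth axis
    b = 36.0 * scale_c
    half = int(np.ceil(max(a, b) * 1.4))
    r0, r1 = int(site.row) - half, int(site.row) + half + 1
    c0, c1 = int(site.col) - half, int(site.col) + half + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    rr = np.arange(r0c, r1c, dtype=np.float64)[:, None] - site.row
    cc = np.arange(c0c, c1c, dtype=np.float64)[None, :] - site.col

    theta = np.deg2rad(site.tilt_degrees)
    # u along the (tilted) tooth axis, v across it
    u = rr * np.cos(theta) - cc * np.sin(theta)
    v = rr * np.sin(theta) + cc * np.cos(theta)
    ellipse = (u / a) ** 2 + (v / b) ** 2
    soft = np.exp(-(ellipse**2))

    if site.present:
        scale = (scale_r + scale_c) / 2.0
        if site.is_upper:
            # upper molars: lattice of enamel-like nodules (dot grid)
            period = _PERIOD_UPPER * scale
            texture = 0.5 * (
                np.cos(2 * np.pi * u / period) + np.cos(2 * np.pi * v / period)
            )
        else:
            # lower molars: cross-hatch striation along the tilt axis
            period = _PERIOD_LOWER * scale
            texture = np.sin(2 * np.pi * u / period) * np.sin(2 * np.pi * v / period)
        patch = contrast * (0.55 * soft + 0.5 * soft * texture)
    else:
        patch = 0.35 * contrast * soft
    img[r0c:r1c, c0c:c1c] += patch


def _render(
    rng: np.random.Generator, config: SyntheticConfig, label: str
) -> LabeledImage:
    h, w = config.height, config.width
    scale_r, scale_c = h / _REFERENCE_H, w / _REFERENCE_W
    img = _background(rng, h, w)

    sites: list[MolarSite] = []
    for ref_row, ref_col, is_upper in _REFERENCE_SITES:
        row = ref_row * scale_r + rng.uniform(-12, 12) * scale_r
        col = ref_col * scale_c + rng.uniform(-20, 20) * scale_c
        lo, hi = config.tilt_range
        tilt = rng.uniform(lo, hi) * rng.choice((-1.0, 1.0))
        if label == "R8_Null":
            present = False
        elif label == "R8_Lower":
            present = not is_upper
        else:  # R8_Upper_Lower
            present = True
        site = MolarSite(
            row=row,
            col=col,
            tilt_degrees=float(tilt) if present else 0.0,
            present=present,
            is_upper=is_upper,
        )
        sites.append(site)
        _stamp_site(img, site, config.molar_contrast, scale_r, scale_c)

    if config.mottle_poisson:
        # photon-count (quantum mottle) noise: variance = intensity
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    out = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return LabeledImage(image=out, label=label, ground_truth_sites=sites)


def generate_dataset(config: SyntheticConfig) -> list[LabeledImage]:
    """Generate ``config.n_images`` labeled phantoms, seeded and reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config.n_images, config.class_proportions)
    labels = np.repeat(np.array(CLASSES, dtype=object), counts)
    labels = labels[rng.permutation(len(labels))]
    return [_render(rng, config, str(label)) for label in labels]


def write_manifest(pairs: list[tuple[str, str]], path: str | Path) -> Path:
    """Write a ``path,label`` CSV manifest; paths are relative to its folder."""
    if not pairs:
        raise ConfigurationError("cannot write a manifest for an empty dataset")
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(pairs)
    return path


def read_manifest(path: str | Path) -> list[tuple[Path, str]]:
    """Read a manifest; returns (absolute path, label) pairs.

    Labels outside the three complication classes are rejected.
    """
    path = Path(path)
    out: list[tuple[Path, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["path", "label"]:
            raise FormatError(f"manifest {path} must start with 'path,label' header")
        for row in reader:
            if not row:
                continue
            if len(row) != 2:
                raise FormatError(f"malformed manifest row {row!r} in {path}")
            rel, label = row
            if label not in CLASSES:
                raise FormatError(
                    f"unknown label {label!r} in {path}; expected one of {CLASSES}"
                )
            out.append(((path.parent / rel).resolve(), label))
    return out


def write_dataset(
    dataset: list[LabeledImage],
    out_dir: str | Path,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write images as 8-bit grayscale PNGs plus a CSV manifest; returns
    the manifest path."""
    if not dataset:
        raise ConfigurationError("cannot write an empty dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for i, item in enumerate(dataset):
        name = f"img_{i:04d}.png"
        iio.imwrite(out_dir / name, item.image)
        pairs.append((name, item.label))
    return write_manifest(pairs, out_dir / manifest_name)
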