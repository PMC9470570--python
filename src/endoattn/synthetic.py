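"""Seeded generator of endoscopy-like frames with exact ground truth.

Real gastroscope data for the benign/malignant ulcer problem is restricted,
so every stage of this package is exercised on frames that emulate the
structure of such images:

* near-black device-annotation strips along the frame edges, carrying
  sparse light "glyph" speckle (they give the border detector a genuine
  vertical/horizontal edge to find);
* a tissue region of interest whose texture statistics differ by class —
  class 0 ("benign-like") is a smooth low-frequency mottling, class 1
  ("malignant-like") is a high-frequency granular texture with an irregular
  bright rim, a crude ulcer analogue;
* dark low-illumination discs (HSV value below 80) and bright low-saturation
  specular discs (saturation < 90, value > 200), painted disjointly.

Because patches are painted with hard edges at known geometry, the ground
truth masks are exact, which makes recovery rates of the preprocessing
pipeline measurable.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .preprocess import ROIBox

__all__ = [
    "FrameSpec", "GroundTruth", "DatasetManifest", "ManifestRecord",
    "generate_frame", "generate_dataset", "load_manifest",
    "texture_statistics",
]

# reddish tissue base colour; multiplicative texture preserves its HSV
# saturation (~113/255), keeping clean tissue clear of both thresholds
_TISSUE_BASE = np.array([185.0, 120.0, 105.0])
_BORDER_VALUE = 18
_GLYPH_DENSITY = 0.02


@dataclass(frozen=True)
class FrameSpec:
    """Geometry and content of one synthetic frame.

    ``dark_patches`` entries are ``(cx, cy, radius, value_level)`` with the
    value level on the 0–255 scale (must stay below the dark threshold 80);
    ``specular_spots`` entries are ``(cx, cy, radius)``.
    """

    width: int = 256
    height: int = 256
    border_columns_left: int = 28
    border_columns_right: int = 28
    border_rows_top: int = 0
    border_rows_bottom: int = 0
    dark_patches: tuple = ()
    specular_spots: tuple = ()
    texture_class: int = 0
    seed: int = 0

    def __post_init__(self):
        roi = self.roi_box  # validates borders leave room
        if self.texture_class not in (0, 1):
            raise ValueError("texture_class must be 0 or 1")
        discs = [(cx, cy, r) for cx, cy, r, _ in self.dark_patches]
        for cx, cy, r, level in self.dark_patches:
            if not 0 < level < 80:
                raise ValueError(
                    f"dark patch value_level {level} must lie in (0, 80)")
        discs += list(self.specular_spots)
        for cx, cy, r in discs:
            if r < 1:
                raise ValueError("patch radius must be >= 1")
            if not (roi.left <= cx - r and cx + r < roi.right
                    and roi.top <= cy - r and cy + r < roi.bottom):
                raise ValueError(
                    f"patch at ({cx}, {cy}) r={r} extends outside the ROI")
        for i in range(len(discs)):
            for j in range(i + 1, len(discs)):
                xi, yi, ri = discs[i]
                xj, yj, rj = discs[j]
                if (xi - xj) ** 2 + (yi - yj) ** 2 <= (ri + rj) ** 2:
                    raise ValueError("dark/specular discs overlap")

    @property
    def roi_box(self) -> ROIBox:
        box = ROIBox(self.border_columns_left, self.border_rows_top,
                     self.width - self.border_columns_right,
                     self.height - self.border_rows_bottom)
        if box.width < 16 or box.height < 16:
            raise ValueError("borders leave too little room for the ROI")
        return box


@dataclass(frozen=True)
class GroundTruth:
    roi_box: ROIBox
    dark_mask: np.ndarray
    reflective_mask: np.ndarray
    class_label: int

    def __post_init__(self):
        if self.dark_mask.shape != self.reflective_mask.shape:
            raise ValueError("ground-truth masks differ in shape")
        if np.logical_and(self.dark_mask, self.reflective_mask).any():
            raise ValueError("ground-truth masks overlap")

    @property
    def interference_mask(self) -> np.ndarray:
        return np.logical_or(self.dark_mask, self.reflective_mask)


def _disc_mask(shape: tuple[int, int], cx: int, cy: int, r: int) -> np.ndarray:
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-ish amplitude smoothed noise field."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    scale = np.abs(f).max()
    return f / scale if scale > 0 else f


def _paint_tissue(rng: np.random.Generator, h: int, w: int,
                  texture_class: int) -> np.ndarray:
    """Multiplicative texture over the base colour, clipped so clean tissue
    stays above the dark threshold and below the reflective floor."""
    if texture_class == 0:
        mod = 1.0 + 0.22 * _smooth_field(rng, (h, w), sigma=max(h, w) / 12)
    else:
        mod = 1.0 + 0.30 * _smooth_field(rng, (h, w), sigma=1.2)
        # irregular bright rim: an annulus warped by angular noise
        cy, cx = h * rng.uniform(0.35, 0.65), w * rng.uniform(0.35, 0.65)
        yy, xx = np.mgrid[:h, :w]
        rr = np.hypot(yy - cy, xx - cx)
        base_r = 0.30 * min(h, w)
        wobble = 1.0 + 0.25 * _smooth_field(rng, (h, w), sigma=max(h, w) / 10)
        band = np.exp(-((rr - base_r * wobble) ** 2) / (2 * (0.05 * min(h, w)) ** 2))
        mod = mod + 0.30 * band
    mod = np.clip(mod, 0.52, 1.34)  # max channel stays within (96, 248)
    return _TISSUE_BASE[None, None, :] * mod[:, :, None]


def generate_frame(spec: FrameSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame; returns (HxWx3 uint8 image, exact ground truth)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    roi = spec.roi_box

    img = np.empty((h, w, 3))
    # annotation border: near-black with sparse light glyph speckle
    border = np.full((h, w), float(_BORDER_VALUE))
    glyphs = rng.random((h, w)) < _GLYPH_DENSITY
    border[glyphs] = 185.0
    img[...] = border[:, :, None]

    tissue = _paint_tissue(rng, roi.height, roi.width, spec.texture_class)
    img[roi.top:roi.bottom, roi.left:roi.right] = tissue

    dark_mask = np.zeros((h, w), dtype=bool)
    for cx, cy, r, level in spec.dark_patches:
        disc = _disc_mask((h, w), cx, cy, r)
        colour = _TISSUE_BASE / _TISSUE_BASE.max() * level  # V == level
        img[disc] = colour
        dark_mask |= disc

    refl_mask = np.zeros((h, w), dtype=bool)
    for cx, cy, r in spec.specular_spots:
        disc = _disc_mask((h, w), cx, cy, r)
        v = rng.uniform(218, 246)
        img[disc] = (v, v * 0.94, v * 0.94)  # S ≈ 15 << 90, V >= 218
        refl_mask |= disc

    frame = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(roi_box=roi, dark_mask=dark_mask,
                        reflective_mask=refl_mask,
                        class_label=spec.texture_class)
    return frame, truth


def random_frame_spec(template: FrameSpec, texture_class: int,
                      seed: int) -> FrameSpec:
    """Randomized patch/spot geometry inside the template's ROI."""
    rng = np.random.default_rng(seed)
    roi = template.roi_box
    placed: list[tuple[int, int, int]] = []

    def place(radius_range) -> tuple[int, int, int] | None:
        for _ in range(200):
            r = int(rng.integers(*radius_range))
            cx = int(rng.integers(roi.left + r, roi.right - r))
            cy = int(rng.integers(roi.top + r, roi.bottom - r))
            if all((cx - x) ** 2 + (cy - y) ** 2 > (r + pr + 2) ** 2
                   for x, y, pr in placed):
                placed.append((cx, cy, r))
                return cx, cy, r
        return None

    dark = []
    for _ in range(int(rng.integers(1, 4))):
        got = place((8, 15))
        if got:
            dark.append((*got, int(rng.integers(30, 65))))
    spots = []
    for _ in range(int(rng.integers(1, 4))):
        got = place((5, 10))
        if got:
            spots.append(got)
    return replace(template, dark_patches=tuple(dark),
                   specular_spots=tuple(spots),
                   texture_class=texture_class, seed=seed)


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    dark_mask_path: str
    reflective_mask_path: str
    class_label: int
    patient_id: str


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]
    class_counts: dict
    root: str = "."

    def __post_init__(self):
        total = sum(self.class_counts.values())
        if total != len(self.records):
            raise ValueError("class_counts do not sum to the record count")

    def resolve(self, rel: str) -> Path:
        return Path(self.root) / rel

    def labels(self) -> np.ndarray:
        return np.array([r.class_label for r in self.records])

    def patients(self) -> np.ndarray:
        return np.array([r.patient_id for r in self.records])

    def save(self, path: Path) -> None:
        payload = {
            "records": [vars(r) for r in self.records],
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def load_manifest(path) -> DatasetManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    records = tuple(ManifestRecord(**r) for r in payload["records"])
    counts = {int(k): v for k, v in payload["class_counts"].items()}
    return DatasetManifest(records=records, class_counts=counts,
                           root=str(path.parent))


def _patient_runs(n_images: int, prefix: str, rng: np.random.Generator
                  ) -> list[str]:
    """Assign images to synthetic patients in runs of 2–6 per patient."""
    ids, i, p = [], 0, 0
    while i < n_images:
        run = int(rng.integers(2, 7))
        run = min(run, n_images - i)
        ids += [f"{prefix}{p:04d}"] * run
        i += run
        p += 1
    return ids


def generate_dataset(n_per_class: tuple[int, int],
                     frame_template: FrameSpec | None = None,
                     seed: int = 0, out_dir=None) -> DatasetManifest:
    """Write a labelled two-class dataset of frames, masks and a manifest.

    ``n_per_class`` is (benign-like count, malignant-like count); the study
    cohort analogue is ``(109, 69)``.  Output: PNG images, 0/255 PNG masks
    and ``manifest.json`` in ``out_dir``.
    """
    if out_dir is None:
        raise ValueError("out_dir is required")
    n0, n1 = n_per_class
    if n0 < 1 or n1 < 1:
        raise ValueError("need at least one frame per class")
    template = frame_template or FrameSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    frame_seeds = ss.spawn(n0 + n1)
    patient_rng = np.random.default_rng(ss.spawn(1)[0])

    records = []
    idx = 0
    for label, count in ((0, n0), (1, n1)):
        patients = _patient_runs(count, f"c{label}p", patient_rng)
        for k in range(count):
            child_seed = int(frame_seeds[idx].generate_state(1)[0] % (2 ** 31))
            spec = random_frame_spec(template, label, child_seed)
            frame, truth = generate_frame(spec)
            stem = f"frame_{label}_{k:04d}"
            iio.imwrite(out / f"{stem}.png", frame)
            iio.imwrite(out / f"{stem}_dark.png",
                        truth.dark_mask.astype(np.uint8) * 255)
            iio.imwrite(out / f"{stem}_refl.png",
                        truth.reflective_mask.astype(np.uint8) * 255)
            records.append(ManifestRecord(
                image_path=f"{stem}.png",
                dark_mask_path=f"{stem}_dark.png",
                reflective_mask_path=f"{stem}_refl.png",
                class_label=label, patient_id=patients[k]))
            idx += 1

    manifest = DatasetManifest(records=tuple(records),
                               class_counts={0: n0, 1: n1}, root=str(out))
    manifest.save(out / "manifest.json")
    return manifest


def texture_statistics(image: np.ndarray, roi: ROIBox | None = None
                       ) -> np.ndarray:
    """Simple per-frame texture features: mean intensity, intensity spread,
    and mean absolute Laplacian (local roughness).  The two generated
    classes are separable on these alone, which guarantees the training
    smoke tests are winnable."""
    a = np.asarray(image, dtype=np.float64)
    if roi is not None:
        a = roi.crop(a)
    gray = a.mean(axis=2)
    rough = np.abs(ndimage.laplace(gray)).mean()
    return np.array([gray.mean(), gray.std(), rough])
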