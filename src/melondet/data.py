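"""Dataset I/O, splitting, augmentation and synthetic melon scenes.

The target task is three-class ripeness detection of colour-changing
melon fruit: class 0 *immature* (green rind, close to the foliage
colour), class 1 *semi-mature* (green-to-orange transition) and class 2
*mature* (dark red rind).  Labels travel in YOLO text form (one
``class cx cy w h`` line per object, coordinates normalised to [0, 1])
or PASCAL VOC XML (pixel corner boxes).

Because the original field imagery is not deposited, the synthetic scene
generator emulates its stated properties: 640 x 640 crops of leafy-green
backgrounds with shaded ellipse-like fruits in the three class colours,
leaf occluders, fruit overlap and global brightness variation.  The
default augmentation plan mirrors the study's recipe: 1150 derived
images per 992-image training set (rotation 150, brightness 150, mirror
100, contrast 150, random erasure 150, deformation 150, Gaussian noise
150, Gaussian blur 150).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

CLASS_NAMES = ("immature", "semi-mature", "mature")


@dataclass
class Annotation:
    """One labelled fruit: class id and normalised centre-form box."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.class_id not in range(len(CLASS_NAMES)):
            raise ValueError(f"class id {self.class_id} outside the "
                             f"{len(CLASS_NAMES)}-class registry")
        if not (self.w > 0 and self.h > 0):
            raise ValueError("box width/height must be positive")
        for v in (self.cx - self.w / 2, self.cy - self.h / 2,
                  self.cx + self.w / 2, self.cy + self.h / 2):
            if v < -1e-6 or v > 1 + 1e-6:
                raise ValueError("box must lie within the unit square")

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_id]

    def corners(self, img_w: int, img_h: int) -> np.ndarray:
        """Denormalised corner-form box (x1, y1, x2, y2) in pixels."""
        return np.array([(self.cx - self.w / 2) * img_w,
                         (self.cy - self.h / 2) * img_h,
                         (self.cx + self.w / 2) * img_w,
                         (self.cy + self.h / 2) * img_h])


@dataclass
class ImageRecord:
    """One image (HWC uint8 RGB) with its annotations."""

    image: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)
    name: str = "image"

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


# ---------------------------------------------------------------------------
# YOLO label text
# ---------------------------------------------------------------------------

def read_yolo_labels(path: str | Path) -> list[Annotation]:
    annotations = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, "
                             f"got {len(parts)}")
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
        try:
            annotations.append(Annotation(cid, cx, cy, w, h))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return annotations


def write_yolo_labels(annotations: list[Annotation], path: str | Path) -> None:
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in annotations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# PASCAL VOC XML
# ---------------------------------------------------------------------------

def write_voc_xml(record: ImageRecord, path: str | Path,
                  folder: str = "images") -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = folder
    ET.SubElement(root, "filename").text = f"{record.name}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(record.width)
    ET.SubElement(size, "height").text = str(record.height)
    ET.SubElement(size, "depth").text = "3"
    for a in record.annotations:
        x1, y1, x2, y2 = a.corners(record.width, record.height)
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = a.class_name
        ET.SubElement(obj, "difficult").text = "0"
        box = ET.SubElement(obj, "bndbox")
        ET.SubElement(box, "xmin").text = str(int(round(x1)))
        ET.SubElement(box, "ymin").text = str(int(round(y1)))
        ET.SubElement(box, "xmax").text = str(int(round(x2)))
        ET.SubElement(box, "ymax").text = str(int(round(y2)))
    ET.ElementTree(root).write(path, encoding="unicode")


def read_voc_xml(path: str | Path) -> tuple[list[Annotation], int, int]:
    """Returns (annotations, image width, image height)."""
    root = ET.parse(path).getroot()
    w = int(root.findtext("size/width"))
    h = int(root.findtext("size/height"))
    annotations = []
    for obj in root.iter("object"):
        cid = CLASS_NAMES.index(obj.findtext("name"))
        x1 = float(obj.findtext("bndbox/xmin"))
        y1 = float(obj.findtext("bndbox/ymin"))
        x2 = float(obj.findtext("bndbox/xmax"))
        y2 = float(obj.findtext("bndbox/ymax"))
        annotations.append(Annotation(cid, (x1 + x2) / 2 / w,
                                      (y1 + y2) / 2 / h,
                                      (x2 - x1) / w, (y2 - y1) / h))
    return annotations, w, h


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(n_items: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random train/val/test partition of ``range(n_items)``.

    The train share is floored and the remainder split between val and
    test (val rounded up first), so 1240 items give 992/124/124.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to split three ways")
    if min(ratios) <= 0:
        raise ValueError("ratios must be positive")
    total = sum(ratios)
    ratios = tuple(r / total for r in ratios)
    perm = np.random.default_rng(seed).permutation(n_items)
    n_train = int(n_items * ratios[0])
    remainder = n_items - n_train
    n_val = int(round(remainder * ratios[1] / (ratios[1] + ratios[2])))
    train = np.sort(perm[:n_train])
    val = np.sort(perm[n_train:n_train + n_val])
    test = np.sort(perm[n_train + n_val:])
    return train, val, test


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentPlan:
    """Per-operation derived-image counts (defaults follow the study plan)."""

    rotation: int = 150      # 90 and 270 degrees, split evenly
    brightness: int = 150    # enhance and reduce, split evenly
    mirror: int = 100        # horizontal and vertical, split evenly
    contrast: int = 150      # enhance and reduce, split evenly
    erasure: int = 150
    deformation: int = 150
    noise: int = 150         # Gaussian
    blur: int = 150          # Gaussian

    @property
    def total(self) -> int:
        return (self.rotation + self.brightness + self.mirror + self.contrast
                + self.erasure + self.deformation + self.noise + self.blur)


def _rotate90(record: ImageRecord, clockwise: bool) -> ImageRecord:
    k = -1 if clockwise else 1
    img = np.ascontiguousarray(np.rot90(record.image, k))
    anns = []
    for a in record.annotations:
        if clockwise:
            anns.append(replace(a, cx=1 - a.cy, cy=a.cx, w=a.h, h=a.w))
        else:
            anns.append(replace(a, cx=a.cy, cy=1 - a.cx, w=a.h, h=a.w))
    return ImageRecord(img, anns, record.name)


def _mirror(record: ImageRecord, horizontal: bool) -> ImageRecord:
    if horizontal:
        img = record.image[:, ::-1]
        anns = [replace(a, cx=1 - a.cx) for a in record.annotations]
    else:
        img = record.image[::-1]
        anns = [replace(a, cy=1 - a.cy) for a in record.annotations]
    return ImageRecord(np.ascontiguousarray(img), anns, record.name)


def _photometric(record: ImageRecord, img: np.ndarray) -> ImageRecord:
    return ImageRecord(np.clip(img, 0, 255).astype(np.uint8),
                       list(record.annotations), record.name)


def _brightness(record: ImageRecord, factor: float) -> ImageRecord:
    return _photometric(record, record.image.astype(np.float32) * factor)


def _contrast(record: ImageRecord, factor: float) -> ImageRecord:
    img = record.image.astype(np.float32)
    mean = img.mean(axis=(0, 1), keepdims=True)
    return _photometric(record, (img - mean) * factor + mean)


def _erasure(record: ImageRecord, rng: np.random.Generator) -> ImageRecord:
    img = record.image.copy()
    h, w = img.shape[:2]
    area = rng.uniform(0.05, 0.15) * h * w
    aspect = rng.uniform(0.5, 2.0)
    eh = int(np.sqrt(area * aspect))
    ew = int(np.sqrt(area / aspect))
    eh, ew = min(eh, h - 1), min(ew, w - 1)
    y = rng.integers(0, h - eh)
    x = rng.integers(0, w - ew)
    img[y:y + eh, x:x + ew] = rng.integers(0, 256, (eh, ew, 3), dtype=np.uint8)
    return ImageRecord(img, list(record.annotations), record.name)


def _noise(record: ImageRecord, rng: np.random.Generator,
           sigma_frac: float = 0.01) -> ImageRecord:
    img = record.image.astype(np.float32)
    img += rng.normal(0, sigma_frac * 255.0, img.shape)
    return _photometric(record, img)


def _blur(record: ImageRecord, sigma: float) -> ImageRecord:
    img = ndimage.gaussian_filter(record.image.astype(np.float32),
                                  sigma=(sigma, sigma, 0))
    return _photometric(record, img)


def _deformation(record: ImageRecord, rng: np.random.Generator) -> ImageRecord:
    """Mild random affine warp; boxes follow their warped corner hull."""
    h, w = record.image.shape[:2]
    scale = rng.uniform(0.9, 1.1, 2)
    shear = rng.uniform(-0.08, 0.08)
    shift = rng.uniform(-0.05, 0.05, 2) * (w, h)
    # forward map: output <- input coordinates (x, y)
    A = np.array([[scale[0], shear], [shear, scale[1]]])
    centre = np.array([w / 2, h / 2])
    offset = centre - A @ centre + shift
    Ainv = np.linalg.inv(A)
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([xs.ravel(), ys.ravel()], axis=0).astype(np.float64)
    src = Ainv @ (pts - offset[:, None])
    coords = np.stack([src[1].reshape(h, w), src[0].reshape(h, w)])
    img = np.stack([
        ndimage.map_coordinates(record.image[..., c].astype(np.float32),
                                coords, order=1, mode="nearest")
        for c in range(3)], axis=-1)
    anns = []
    for a in record.annotations:
        x1, y1, x2, y2 = a.corners(w, h)
        corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]]).T
        warped = A @ corners + offset[:, None]
        nx1, ny1 = warped.min(axis=1)
        nx2, ny2 = warped.max(axis=1)
        nx1, ny1 = max(nx1, 0.0), max(ny1, 0.0)
        nx2, ny2 = min(nx2, float(w)), min(ny2, float(h))
        if (nx2 - nx1) * (ny2 - ny1) < 1.0:
            logger.warning("deformation emptied a box in %s; dropping it",
                           record.name)
            continue
        anns.append(Annotation(a.class_id, (nx1 + nx2) / 2 / w,
                               (ny1 + ny2) / 2 / h,
                               (nx2 - nx1) / w, (ny2 - ny1) / h))
    return ImageRecord(np.clip(img, 0, 255).astype(np.uint8), anns,
                       record.name)


def augment_training_set(records: list[ImageRecord],
                         plan: AugmentPlan | None = None,
                         seed: int = 0) -> list[ImageRecord]:
    """Expand a training set by exactly ``plan.total`` derived images.

    Source images are drawn uniformly without replacement per operation
    (with replacement only if an operation requests more images than the
    base set holds).  Validation/test sets are never augmented.
    """
    if not records:
        raise ValueError("cannot augment an empty training set")
    plan = plan or AugmentPlan()
    rng = np.random.default_rng(seed)
    out = list(records)

    def pick(count):
        replace_ = count > len(records)
        idx = rng.choice(len(records), size=count, replace=replace_)
        return [records[i] for i in idx]

    for i, rec in enumerate(pick(plan.rotation)):
        out.append(_rotate90(rec, clockwise=i % 2 == 0))
    for i, rec in enumerate(pick(plan.brightness)):
        out.append(_brightness(rec, rng.uniform(1.05, 1.3)
                               if i % 2 == 0 else rng.uniform(0.7, 0.95)))
    for i, rec in enumerate(pick(plan.mirror)):
        out.append(_mirror(rec, horizontal=i % 2 == 0))
    for i, rec in enumerate(pick(plan.contrast)):
        out.append(_contrast(rec, rng.uniform(1.05, 1.3)
                             if i % 2 == 0 else rng.uniform(0.7, 0.95)))
    for rec in pick(plan.erasure):
        out.append(_erasure(rec, rng))
    for rec in pick(plan.deformation):
        out.append(_deformation(rec, rng))
    for rec in pick(plan.noise):
        out.append(_noise(rec, rng))
    for rec in pick(plan.blur):
        out.append(_blur(rec, rng.uniform(1.0, 2.0)))
    return out


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

_FRUIT_COLORS = {
    0: np.array([70.0, 135.0, 60.0]),    # immature: green, near background
    1: np.array([215.0, 140.0, 45.0]),   # semi-mature: orange transition
    2: np.array([130.0, 30.0, 30.0]),    # mature: dark red
}


def _leafy_background(rng: np.random.Generator, size: int) -> np.ndarray:
    base = np.array([48.0, 86.0, 40.0])
    coarse = rng.normal(0, 1, (size // 16 + 1, size // 16 + 1, 3))
    low = ndimage.zoom(coarse, (16, 16, 1), order=1)[:size, :size]
    img = base + 18.0 * ndimage.gaussian_filter(low, (4, 4, 0))
    img += rng.normal(0, 6.0, (size, size, 3))  # leaf speckle
    return img


def _draw_leaf(img: np.ndarray, rng: np.random.Generator, cx: float,
               cy: float, r: float) -> None:
    size = img.shape[0]
    ys, xs = np.mgrid[0:size, 0:size]
    ang = rng.uniform(0, np.pi)
    la, lb = r * rng.uniform(0.8, 1.3), r * rng.uniform(0.35, 0.6)
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(ang) + dy * np.sin(ang)
    v = -dx * np.sin(ang) + dy * np.cos(ang)
    mask = (u / la) ** 2 + (v / lb) ** 2 <= 1.0
    shade = rng.uniform(0.75, 0.95)
    leaf = np.array([35.0, 95.0, 38.0]) * shade
    img[mask] = 0.85 * leaf + 0.15 * img[mask]


def generate_synthetic_scene(seed: int | None = None,
                             n_fruits: int | None = None,
                             class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                             occlusion_rate: float = 0.3,
                             size: int = 640,
                             fruit_scale: tuple[float, float] = (0.07, 0.16),
                             rng: np.random.Generator | None = None,
                             name: str = "synthetic") -> ImageRecord:
    """Render one leafy scene with shaded ellipse fruits and tight boxes.

    Deterministic for a fixed seed.  ``fruit_scale`` bounds the fruit
    semi-axes as a fraction of the image side; ``occlusion_rate`` is the
    per-fruit probability of a partially covering leaf.
    """
    rng = rng or np.random.default_rng(seed)
    if n_fruits is None:
        n_fruits = int(rng.integers(1, 6))
    if n_fruits < 0:
        raise ValueError("n_fruits must be >= 0")
    img = _leafy_background(rng, size)
    ys, xs = np.mgrid[0:size, 0:size]
    annotations: list[Annotation] = []
    mix = np.asarray(class_mix, dtype=np.float64)
    mix = mix / mix.sum()
    for _ in range(n_fruits):
        cid = int(rng.choice(3, p=mix))
        a = size * rng.uniform(*fruit_scale)
        b = a * rng.uniform(0.7, 1.3)
        ang = rng.uniform(0, np.pi)
        margin = max(a, b) * 1.05
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
        dx, dy = xs - cx, ys - cy
        u = dx * np.cos(ang) + dy * np.sin(ang)
        v = -dx * np.sin(ang) + dy * np.cos(ang)
        d2 = (u / a) ** 2 + (v / b) ** 2
        mask = d2 <= 1.0
        base = _FRUIT_COLORS[cid] * rng.uniform(0.85, 1.15)
        # radial shading, lit from the upper left
        light = 1.0 - 0.35 * np.sqrt(np.clip(d2, 0, 1)) \
            + 0.12 * (-(dx + dy) / (2.5 * max(a, b)))
        fruit = base[None, None, :] * light[..., None]
        if cid == 1:  # orange-to-green gradient toward the stem end
            t = np.clip((v / (b + 1e-9) + 1) / 2, 0, 1)[..., None]
            fruit = fruit * t + (_FRUIT_COLORS[0][None, None, :]
                                 * light[..., None]) * (1 - t)
        img[mask] = fruit[mask]
        if rng.uniform() < occlusion_rate:
            edge = rng.uniform(0, 2 * np.pi)
            _draw_leaf(img, rng, cx + 0.9 * a * np.cos(edge),
                       cy + 0.9 * b * np.sin(edge),
                       max(a, b) * rng.uniform(0.5, 0.8))
        # tight analytic extent of the rotated ellipse
        ex = np.sqrt((a * np.cos(ang)) ** 2 + (b * np.sin(ang)) ** 2)
        ey = np.sqrt((a * np.sin(ang)) ** 2 + (b * np.cos(ang)) ** 2)
        x1, x2 = max(cx - ex, 0), min(cx + ex, size)
        y1, y2 = max(cy - ey, 0), min(cy + ey, size)
        annotations.append(Annotation(cid, (x1 + x2) / 2 / size,
                                      (y1 + y2) / 2 / size,
                                      (x2 - x1) / size, (y2 - y1) / size))
    img *= rng.uniform(0.8, 1.2)  # global brightness jitter
    return ImageRecord(np.clip(img, 0, 255).astype(np.uint8), annotations,
                       name)


def generate_synthetic_dataset(n_images: int, seed: int = 0, size: int = 640,
                               **scene_kwargs) -> list[ImageRecord]:
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=n_images)
    return [generate_synthetic_scene(int(s), size=size, name=f"scene_{i:05d}",
                                     **scene_kwargs)
            for i, s in enumerate(seeds)]


# ---------------------------------------------------------------------------
# on-disk dataset layout
# ---------------------------------------------------------------------------

def write_dataset(records: list[ImageRecord], out_dir: str | Path,
                  split: str = "train", voc: bool = False) -> None:
    """Write records in the YOLO directory layout (plus optional VOC XML)."""
    out = Path(out_dir)
    img_dir = out / "images" / split
    lbl_dir = out / "labels" / split
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        Image.fromarray(rec.image).save(img_dir / f"{rec.name}.png")
        write_yolo_labels(rec.annotations, lbl_dir / f"{rec.name}.txt")
        if voc:
            voc_dir = out / "voc" / split
            voc_dir.mkdir(parents=True, exist_ok=True)
            write_voc_xml(rec, voc_dir / f"{rec.name}.xml")
    yaml_path = out / "dataset.yaml"
    yaml_path.write_text(
        "path: {}\ntrain: images/train\nval: images/val\ntest: images/test\n"
        "names:\n  0: immature\n  1: semi-mature\n  2: mature\n"
        .format(out.resolve()))


def load_dataset(root: str | Path, split: str) -> list[ImageRecord]:
    root = Path(root)
    records = []
    for img_path in sorted((root / "images" / split).glob("*")):
        lbl_path = root / "labels" / split / f"{img_path.stem}.txt"
        anns = read_yolo_labels(lbl_path) if lbl_path.exists() else []
        records.append(ImageRecord(np.asarray(Image.open(img_path).convert("RGB")),
                                   anns, img_path.stem))
    return records
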