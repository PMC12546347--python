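"""Readers/writers for the annotation formats used by leaf survey datasets.

Detection ground truth travels as LabelImg-dialect Pascal-VOC XML (1-based,
inclusive pixel coordinates — converted to the package's 0-based half-open
convention on read and back on write), leaf-region polygons as
Labelme-dialect JSON, masks as single-channel 0/255 PNG, and detections as
a small JSON list.  Writes are canonical and byte-stable so artifacts can
be diffed and round-tripped exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image, ImageDraw

from .geometry import BBox, Detection

PRIMARY_LEAF_LABEL = "leaf"


@dataclass
class ImageAnnotation:
    """VOC-style annotation of one image."""

    filename: str
    width: int
    height: int
    objects: list[Detection] = field(default_factory=list)


# ----------------------------------------------------------------- VOC XML


def read_voc(xml_path: str | Path) -> ImageAnnotation:
    """Parse a LabelImg VOC XML file.

    VOC boxes are 1-based and inclusive: (xmin=1, ymin=1, xmax=10, ymax=10)
    becomes the half-open (0, 0, 10, 10).  Unknown class names are kept
    verbatim.
    """
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML {xml_path}: {exc}") from exc
    root = tree.getroot()

    def _req(parent, name):
        el = parent.find(name)
        if el is None or (el.text is None and len(el) == 0):
            raise ValueError(f"VOC XML {xml_path} missing element <{name}>")
        return el

    size = _req(root, "size")
    width = int(_req(size, "width").text)
    height = int(_req(size, "height").text)
    filename_el = root.find("filename")
    filename = filename_el.text if filename_el is not None and filename_el.text else ""
    objects = []
    for obj in root.findall("object"):
        name = _req(obj, "name").text
        bnd = _req(obj, "bndbox")
        xmin = float(_req(bnd, "xmin").text)
        ymin = float(_req(bnd, "ymin").text)
        xmax = float(_req(bnd, "xmax").text)
        ymax = float(_req(bnd, "ymax").text)
        box = BBox(xmin - 1.0, ymin - 1.0, xmax, ymax)
        objects.append(Detection(box=box, label=name, confidence=1.0))
    return ImageAnnotation(filename=filename, width=width, height=height, objects=objects)


def _num(x: float) -> str:
    """Integer-valued floats serialize as ints (VOC writes whole pixels)."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_voc(ann: ImageAnnotation, xml_path: str | Path) -> None:
    """Write a canonical LabelImg-style VOC XML file (inverse of read_voc)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = ann.filename
    src = etree.SubElement(root, "source")
    etree.SubElement(src, "database").text = "Unknown"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for det in ann.objects:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = det.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = _num(det.box.x_min + 1.0)
        etree.SubElement(bnd, "ymin").text = _num(det.box.y_min + 1.0)
        etree.SubElement(bnd, "xmax").text = _num(det.box.x_max)
        etree.SubElement(bnd, "ymax").text = _num(det.box.y_max)
    Path(xml_path).write_bytes(etree.tostring(root, pretty_print=True))


# ------------------------------------------------------------ Labelme JSON


def write_labelme(
    path: str | Path,
    shapes: list[dict],
    image_size: tuple[int, int],
    image_path: str = "",
) -> None:
    """Write Labelme-dialect JSON; ``image_size`` is (W, H)."""
    data = {
        "version": "5.2.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": image_size[1],
        "imageWidth": image_size[0],
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_labelme_json(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    if "shapes" not in data:
        raise ValueError(f"Labelme JSON {path} has no 'shapes' field")
    return data


def polygon_shape(label: str, points: list[list[float]]) -> dict:
    return {
        "label": label,
        "points": points,
        "group_id": None,
        "shape_type": "polygon",
        "flags": {},
    }


def labelme_to_mask(
    data: dict,
    primary_label: str = PRIMARY_LEAF_LABEL,
    image_dims: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rasterize the primary-label polygons of a Labelme record to a mask.

    ``image_dims`` is (W, H); when omitted it is taken from the record's
    imageWidth/imageHeight (a missing value is a parse error).  Polygons are
    filled with the scanline even-odd rule; non-primary labels are ignored,
    and vertex orientation does not matter.
    """
    if image_dims is None:
        try:
            image_dims = (int(data["imageWidth"]), int(data["imageHeight"]))
        except KeyError as exc:
            raise ValueError("Labelme record lacks imageWidth/imageHeight") from exc
    w, h = image_dims
    img = Image.new("1", (w, h), 0)
    draw = ImageDraw.Draw(img)
    for shape in data.get("shapes", []):
        if shape.get("label") != primary_label:
            continue
        pts = [(float(x), float(y)) for x, y in shape["points"]]
        if len(pts) >= 3:
            draw.polygon(pts, fill=1)
    return np.array(img, dtype=bool)


def read_labelme(
    path: str | Path,
    primary_label: str = PRIMARY_LEAF_LABEL,
    image_dims: tuple[int, int] | None = None,
) -> np.ndarray:
    return labelme_to_mask(read_labelme_json(path), primary_label, image_dims)


def mask_to_polygon(mask: np.ndarray, step: int = 4) -> list[list[float]]:
    """Longest outer contour of a mask, subsampled to every ``step``-th vertex."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return []
    contour = max(contours, key=len)
    pts = contour[::step]
    return [[float(c), float(r)] for r, c in pts]  # (x, y) order


# ----------------------------------------------------------------- mask PNG


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255))).save(str(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.array(Image.open(str(path)).convert("L")) > 127


# ------------------------------------------------------------ detections JSON


def write_detections_json(dets: list[Detection] | dict[int, list[Detection]], path: str | Path) -> None:
    """Serialize detections; accepts a flat list or a per-tile mapping."""

    def enc(d: Detection) -> dict:
        return {
            "box": [d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max],
            "label": d.label,
            "confidence": d.confidence,
        }

    if isinstance(dets, dict):
        payload = {"per_tile": {str(k): [enc(d) for d in v] for k, v in dets.items()}}
    else:
        payload = {"detections": [enc(d) for d in dets]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_detections_json(path: str | Path) -> list[Detection] | dict[int, list[Detection]]:
    data = json.loads(Path(path).read_text())

    def dec(rec: dict) -> Detection:
        x0, y0, x1, y1 = rec["box"]
        return Detection(BBox(x0, y0, x1, y1), rec["label"], rec["confidence"])

    if "per_tile" in data:
        return {int(k): [dec(r) for r in v] for k, v in data["per_tile"].items()}
    return [dec(r) for r in data["detections"]]
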