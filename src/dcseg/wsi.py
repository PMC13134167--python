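"""Whole-slide tooling: tiling, patch filtering/labeling, prediction
stitching, contour extraction and ASAP-compatible XML annotation export.

The slide workflow mirrors common histopathology practice: a slide
scanned at high magnification is processed at a working magnification, cut
into 512x512 patches at stride 256, near-white patches are discarded, the
per-patch predictions are stitched back (overlaps resolved by averaging
probabilities), the tumor-region boundaries are traced and subsampled at a
fixed arc interval, and the resulting polygons — rescaled to slide
coordinates by the magnification factor — are written as an XML annotation
file the ASAP slide viewer can open for review and correction.

Coordinates are 0-based pixel indices at working magnification; X is the
column and Y the row, matching the ASAP convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from scipy import ndimage

__all__ = ["TileGrid", "Polygon", "AnnotationDocument", "tile",
           "filter_patch", "label_patch", "stitch", "trace_boundary",
           "extract_contours", "write_asap_xml", "read_asap_xml",
           "rasterize_document"]


@dataclass
class TileGrid:
    """Fully-inside tiling: half-open windows [y, y+patch) x [x, x+patch)."""
    patch_size: int = 512
    stride: int = 256

    def __post_init__(self):
        if self.stride > self.patch_size:
            raise ValueError("stride must not exceed patch_size")
        if self.patch_size < 1 or self.stride < 1:
            raise ValueError("patch_size and stride must be positive")


@dataclass
class Polygon:
    name: str
    group: str
    vertices: list          # [(order, x, y), ...] in slide coordinates

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")


@dataclass
class AnnotationDocument:
    polygons: list = field(default_factory=list)
    magnification_factor: float = 1.0


def tile(wsi, grid: TileGrid, pad_edges: bool = False,
         pad_value: float = 1.0) -> list:
    """Raster-order list of (tile_image, tile_mask, y, x).

    By default only positions fully inside the image are emitted
    (the non-overlapping extraction convention).  With ``pad_edges`` the
    trailing edge positions are included, padded with ``pad_value``
    (white, i.e. slide background) in the image and background 0 in the
    mask.  ``tile_mask`` is None when the source has no mask.
    """
    image = wsi.image if hasattr(wsi, "image") else np.asarray(wsi)
    mask = getattr(wsi, "mask", None)
    h, w = image.shape[:2]
    p, s = grid.patch_size, grid.stride
    if h < p or w < p:
        raise ValueError(f"image {h}x{w} smaller than patch size {p}")

    def positions(n):
        pos = list(range(0, n - p + 1, s))
        # one overhanging position covers the remainder (it is < stride)
        if pad_edges and pos[-1] + p < n:
            pos.append(pos[-1] + s)
        return pos

    out = []
    for y in positions(h):
        for x in positions(w):
            yy, xx = min(y + p, h), min(x + p, w)
            timg = image[y:yy, x:xx]
            tm = mask[y:yy, x:xx] if mask is not None else None
            if timg.shape[0] < p or timg.shape[1] < p:
                padded = np.full((p, p) + image.shape[2:], pad_value,
                                 dtype=image.dtype)
                padded[:timg.shape[0], :timg.shape[1]] = timg
                timg = padded
                if tm is not None:
                    pm = np.zeros((p, p), dtype=tm.dtype)
                    pm[:tm.shape[0], :tm.shape[1]] = tm
                    tm = pm
            out.append((timg, tm, y, x))
    return out


def filter_patch(tile_image, background_fraction_threshold: float = 0.5,
                 whiteness_threshold: float = 0.85) -> bool:
    """Keep a patch iff its near-white background fraction is <= threshold.

    A pixel counts as background when its dimmest RGB channel still exceeds
    the whiteness threshold (near-white, the empty-glass appearance).
    """
    img = np.asarray(tile_image)
    background = img.min(axis=-1) > whiteness_threshold
    return float(background.mean()) <= background_fraction_threshold


def label_patch(tile_mask, tumor_fraction_threshold: float = 0.25,
                tumor_class: int = 1) -> str:
    """'tumor' iff the tumor-pixel fraction strictly exceeds the threshold."""
    mask = np.asarray(tile_mask)
    frac = float((mask == tumor_class).mean())
    return "tumor" if frac > tumor_fraction_threshold else "non-tumor"


def stitch(tiles: list, canvas_size: tuple[int, int], n_classes: int = 2,
           mode: str = "average") -> np.ndarray:
    """Recompose per-tile predictions into a full-size label map.

    Each entry is (pred, y, x) where ``pred`` is either a (K, p, p)
    probability array or a (p, p) integer label tile (converted to one-hot).
    Overlaps are resolved by averaging probabilities before the argmax
    (``mode="average"``) or by last-write-wins (``mode="last"``).  Canvas
    area no tile covers is filled as background with a warning.
    """
    h, w = canvas_size
    acc = np.zeros((n_classes, h, w), dtype=np.float64)
    cover = np.zeros((h, w), dtype=np.int32)
    for pred, y, x in tiles:
        pred = np.asarray(pred)
        if pred.ndim == 2:
            onehot = np.zeros((n_classes, *pred.shape), dtype=np.float64)
            for c in range(n_classes):
                onehot[c] = pred == c
            pred = onehot
        ph, pw = pred.shape[1:]
        if y < 0 or x < 0 or y + ph > h or x + pw > w:
            raise ValueError(f"tile at ({y},{x}) exceeds canvas {h}x{w}")
        if mode == "last":
            acc[:, y:y + ph, x:x + pw] = pred
            cover[y:y + ph, x:x + pw] = 1
        else:
            acc[:, y:y + ph, x:x + pw] += pred
            cover[y:y + ph, x:x + pw] += 1
    uncovered = cover == 0
    if uncovered.any():
        warnings.warn(f"{int(uncovered.sum())} uncovered pixels filled as "
                      "background", stacklevel=2)
        acc[0, uncovered] = 1.0
        cover[uncovered] = 1
    return (acc / cover).argmax(axis=0)


# ---------------------------------------------------------------------------
# contour tracing
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order starting east (dy, dx)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_boundary(component: np.ndarray) -> list[tuple[int, int]]:
    """8-connected Moore boundary trace of a binary component.

    Returns the closed chain of boundary pixels as (y, x) tuples, each
    visited once per pass around the component; a single isolated pixel
    yields a chain of length 1.
    """
    ys, xs = np.nonzero(component)
    if len(ys) == 0:
        return []
    # start at the first foreground pixel in raster order; its west
    # neighbor is guaranteed background and serves as the initial backtrack
    order = np.lexsort((xs, ys))
    start = (int(ys[order[0]]), int(xs[order[0]]))
    h, w = component.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and component[p]

    chain = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)
    visited_edges: set = set()
    while True:
        b = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for i in range(1, 9):
            d = (b + i) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if fg(cand):
                nxt = cand
                prev_d = (d - 1) % 8
                new_backtrack = (cur[0] + _MOORE[prev_d][0],
                                 cur[1] + _MOORE[prev_d][1])
                break
        if nxt is None:              # isolated pixel
            return chain
        edge = (cur, nxt)
        if edge in visited_edges:    # full pass around the component done
            return chain
        visited_edges.add(edge)
        if nxt != start:             # closing move back into start not re-added
            chain.append(nxt)
        cur, backtrack = nxt, new_backtrack


def extract_contours(label_map, sample_interval: int = 15,
                     magnification_factor: float = 1.0,
                     foreground_class: int | None = None,
                     group: str = "tumor") -> AnnotationDocument:
    """Trace every connected foreground component and subsample its boundary.

    Vertices are taken every ``sample_interval`` pixels of arc position
    along the traced chain (the first vertex is always kept); components
    whose subsampled boundary has fewer than 3 vertices are dropped.
    Coordinates are multiplied by ``magnification_factor`` to map the
    working-resolution pixel grid back to slide space.
    """
    lm = np.asarray(label_map)
    binary = (lm == foreground_class) if foreground_class is not None else lm > 0
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    doc = AnnotationDocument(magnification_factor=magnification_factor)
    for comp in range(1, n + 1):
        chain = trace_boundary(labels == comp)
        sampled = chain[::sample_interval]
        if len(sampled) < 3:
            continue
        verts = [(k, float(x) * magnification_factor,
                  float(y) * magnification_factor)
                 for k, (y, x) in enumerate(sampled)]
        doc.polygons.append(Polygon(name=f"Annotation {len(doc.polygons)}",
                                    group=group, vertices=verts))
    return doc


# ---------------------------------------------------------------------------
# ASAP XML
# ---------------------------------------------------------------------------

_ASAP_COLOR = "#F4FA58"


def write_asap_xml(doc: AnnotationDocument, path) -> None:
    """Serialize to the ASAP annotation dialect.

    Layout: ASAP_Annotations / Annotations / Annotation(Name, Type=Polygon,
    PartOfGroup, Color) / Coordinates / Coordinate(Order, X, Y).
    """
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    groups = {p.group for p in doc.polygons}
    for poly in doc.polygons:
        ann = etree.SubElement(anns, "Annotation", Name=poly.name,
                               Type="Polygon", PartOfGroup=poly.group,
                               Color=_ASAP_COLOR)
        coords = etree.SubElement(ann, "Coordinates")
        for order, x, y in poly.vertices:
            etree.SubElement(coords, "Coordinate", Order=str(int(order)),
                             X=repr(float(x)), Y=repr(float(y)))
    ann_groups = etree.SubElement(root, "AnnotationGroups")
    for g in sorted(groups):
        etree.SubElement(ann_groups, "Group", Name=g, PartOfGroup="None",
                         Color=_ASAP_COLOR)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


def read_asap_xml(path) -> AnnotationDocument:
    """Parse an ASAP annotation file back into an AnnotationDocument."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed ASAP XML {path}: {exc}") from exc
    doc = AnnotationDocument()
    for ann in tree.findall(".//Annotations/Annotation"):
        verts = []
        for co in ann.findall("./Coordinates/Coordinate"):
            verts.append((int(co.get("Order")), float(co.get("X")),
                          float(co.get("Y"))))
        verts.sort(key=lambda v: v[0])
        doc.polygons.append(Polygon(name=ann.get("Name", ""),
                                    group=ann.get("PartOfGroup", "None"),
                                    vertices=verts))
    return doc


def rasterize_document(doc: AnnotationDocument, shape: tuple[int, int],
                       scale: float = 1.0) -> np.ndarray:
    """Fill the document's polygons into a binary mask of ``shape``.

    ``scale`` divides the stored (slide-space) coordinates, e.g. pass the
    magnification factor to rasterize back at working resolution.
    """
    from skimage.draw import polygon as sk_polygon

    out = np.zeros(shape, dtype=bool)
    for poly in doc.polygons:
        ys = np.array([v[2] / scale for v in poly.vertices])
        xs = np.array([v[1] / scale for v in poly.vertices])
        rr, cc = sk_polygon(ys, xs, shape=shape)
        out[rr, cc] = True
    return out
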