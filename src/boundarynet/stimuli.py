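"""Shape stimuli and presentation sequences.

Training and testing images are generated internally: closed polygon-like
objects whose sides are circular arcs of configurable curvature (concave /
straight / convex, plus sharper and broader variants), smooth random "blob"
silhouettes standing in for natural objects, and temporally ordered
presentation sequences in which each object is swept over a grid of retinal
locations before the next object appears (the ordering the trace learning
rule depends on).

Geometry conventions
--------------------
Object contours live in a mathematical frame (x right, y up, angles
counter-clockwise from "right", so "top" is 90 deg).  Rendering converts to
image coordinates (row-major, origin top-left, y down).  Vertices sit on a
circle of configurable circumradius; each side is a circular arc whose
signed sagitta is ``s * chord_length`` with ``s > 0`` bulging outward
(convex).  Rounding to the pixel grid is symmetric (half away from zero) so
that mirrored renderings are exact pixel flips and integer translations of
the center translate every foreground pixel exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "ShapeFamilySpec",
    "ShapeSpec",
    "BlobSpec",
    "RenderedStimulus",
    "PresentationSequence",
    "SequenceItem",
    "DEFAULT_CONFORMATION_SETS",
    "SAGITTA_RATIOS",
    "PASUPATHY_CONFORMATIONS",
    "enumerate_shapes",
    "render_shape",
    "render_blob",
    "make_pasupathy_set",
    "make_blob_objects",
    "make_sequence",
    "contour_points",
    "blob_contour",
    "write_pgm",
    "read_pgm",
]

# Signed sagitta as a fraction of the chord length, one entry per boundary
# conformation label.  Positive bulges outward (convex).
SAGITTA_RATIOS: dict[str, float] = {
    "concave": -0.25,
    "straight": 0.0,
    "convex": 0.25,
    "sharp_concave": -0.45,
    "sharp_convex": 0.45,
    # five-way set used for the V4-style closed shapes
    "broad_concave": -0.15,
    "medium_concave": -0.30,
    "broad_convex": 0.15,
    "medium_convex": 0.30,
}

DEFAULT_CONFORMATION_SETS: dict[int, tuple[str, ...]] = {
    1: ("straight",),
    2: ("concave", "convex"),
    3: ("concave", "straight", "convex"),
    4: ("sharp_concave", "concave", "convex", "sharp_convex"),
}

PASUPATHY_CONFORMATIONS: tuple[str, ...] = (
    "sharp_convex",
    "medium_convex",
    "broad_convex",
    "medium_concave",
    "broad_concave",
)


@dataclass(frozen=True)
class ShapeFamilySpec:
    """A family of closed shapes with ``n`` sides and ``p`` conformations per side."""

    n: int
    p: int
    conformation_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")
        if not self.conformation_set:
            try:
                object.__setattr__(
                    self, "conformation_set", DEFAULT_CONFORMATION_SETS[self.p]
                )
            except KeyError:
                raise ValueError(
                    f"no default conformation set for p={self.p}; pass one explicitly"
                ) from None
        if len(self.conformation_set) != self.p:
            raise ValueError(
                f"conformation_set has {len(self.conformation_set)} labels, expected p={self.p}"
            )
        for label in self.conformation_set:
            if label not in SAGITTA_RATIOS:
                raise ValueError(f"unknown conformation label {label!r}")

    @property
    def n_shapes(self) -> int:
        return self.p**self.n

    @property
    def n_elements(self) -> int:
        return self.n * self.p

    @property
    def side_names(self) -> tuple[str, ...]:
        """Side labels by midpoint angle (counter-clockwise, 'top' first)."""
        named = {90.0: "top", 180.0: "left", 270.0: "bottom", 0.0: "right",
                 210.0: "left", 330.0: "right"}
        out = []
        for i in range(self.n):
            ang = (90.0 + i * 360.0 / self.n) % 360.0
            out.append(named.get(round(ang, 6), f"side{ang:g}"))
        return tuple(out)


@dataclass(frozen=True)
class ShapeSpec:
    """One closed shape: an ordered conformation label per side.

    ``vertex_angles`` optionally gives the angular separations (degrees)
    between consecutive vertices; when omitted the vertices are equally
    spaced on the circumcircle.
    """

    family: ShapeFamilySpec
    elements: tuple[str, ...]
    vertex_angles: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.elements) != self.family.n:
            raise ValueError(
                f"expected {self.family.n} elements, got {len(self.elements)}"
            )
        for label in self.elements:
            if label not in self.family.conformation_set:
                raise ValueError(
                    f"label {label!r} not in family conformation set "
                    f"{self.family.conformation_set}"
                )
        if self.vertex_angles is not None:
            if len(self.vertex_angles) != self.family.n:
                raise ValueError("need one vertex angle per side")
            if abs(sum(self.vertex_angles) - 360.0) > 1e-6:
                raise ValueError(
                    f"vertex angles must sum to 360 deg, got {sum(self.vertex_angles)}"
                )

    @property
    def object_id(self) -> str:
        base = "+".join(self.elements)
        if self.vertex_angles is not None:
            base += "@" + "/".join(f"{a:g}" for a in self.vertex_angles)
        return base

    def element_labels(self) -> tuple[tuple[str, str], ...]:
        """(side_name, conformation) pairs, the boundary elements of this shape."""
        return tuple(zip(self.family.side_names, self.elements))


@dataclass(frozen=True)
class BlobSpec:
    """A smooth closed blob: radius function as a truncated Fourier series.

    r(phi) = base_radius * (1 + sum_k a_k cos(k phi) + b_k sin(k phi)).
    """

    base_radius: float
    cos_coeffs: tuple[float, ...]
    sin_coeffs: tuple[float, ...]
    blob_id: str = "blob"

    @property
    def object_id(self) -> str:
        return self.blob_id


@dataclass
class RenderedStimulus:
    """A grayscale image on the simulated retina, values in [0, 1]."""

    image: np.ndarray
    object_id: str
    center: tuple[float, float]
    orientation: float = 0.0
    mirror: bool = False
    source_spec: object | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("stimulus image must be 2-D")
        if img.size and (img.min() < 0 or img.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")
        self.image = img


@dataclass(frozen=True)
class SequenceItem:
    stimulus: RenderedStimulus
    object_id: str
    is_object_boundary: bool


@dataclass
class PresentationSequence:
    """Temporally ordered stimuli; boundary flags mark transitions between objects."""

    items: list[SequenceItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]


# ---------------------------------------------------------------------------
# enumeration

def enumerate_shapes(family: ShapeFamilySpec, cap: int = 1000) -> list[ShapeSpec]:
    """All p^n shapes of a family, in lexicographic order of conformation labels.

    Families with more than ``cap`` whole shapes are refused: full enumerations
    that large are impractical to train on.
    """
    if family.n_shapes > cap:
        raise ValueError(
            f"family has p^n = {family.n_shapes} shapes, above cap {cap}"
        )
    return [
        ShapeSpec(family, combo)
        for combo in itertools.product(family.conformation_set, repeat=family.n)
    ]


# ---------------------------------------------------------------------------
# contour geometry

def _round_sym(v: np.ndarray) -> np.ndarray:
    """Round half away from zero (symmetric under negation)."""
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def _vertex_positions(spec: ShapeSpec, radius: float) -> np.ndarray:
    """Vertices on the circumcircle, CCW; side i runs from vertex i to i+1."""
    n = spec.family.n
    if spec.vertex_angles is None:
        # equal spacing; side i's midpoint sits at 90 + i*360/n degrees
        mid = 90.0 + np.arange(n) * 360.0 / n
        start = np.deg2rad(mid - 180.0 / n)
    else:
        seps = np.asarray(spec.vertex_angles, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(seps)[:-1]])
        start = np.deg2rad(90.0 + cum)
    return radius * np.stack([np.cos(start), np.sin(start)], axis=1)


def _arc_points(a: np.ndarray, b: np.ndarray, sagitta_ratio: float,
                outward: np.ndarray, n_points: int) -> np.ndarray:
    """Circular arc from a to b with signed sagitta (fraction of chord).

    ``outward`` is the unit outward normal of the straight edge; positive
    sagitta bulges along it.
    """
    chord = np.linalg.norm(b - a)
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    if abs(sagitta_ratio) < 1e-9 or chord < 1e-12:
        return a[None, :] + t[:, None] * (b - a)[None, :]
    h = sagitta_ratio * chord
    mid = 0.5 * (a + b)
    apex = mid + h * outward
    # circle through a, b, apex: center on the perpendicular bisector of ab
    t_c = (h * h - chord * chord / 4.0) / (2.0 * h)
    center = mid + t_c * outward
    r_arc = abs(h - t_c)
    ang_a = np.arctan2(a[1] - center[1], a[0] - center[0])
    ang_b = np.arctan2(b[1] - center[1], b[0] - center[0])
    ang_p = np.arctan2(apex[1] - center[1], apex[0] - center[0])
    # sweep from a to b through the apex
    def _sweep(frm: float, to: float, direction: int) -> float:
        d = (to - frm) * direction
        return d % (2 * np.pi)
    for direction in (1, -1):
        total = _sweep(ang_a, ang_b, direction)
        to_apex = _sweep(ang_a, ang_p, direction)
        if to_apex <= total + 1e-9:
            angles = ang_a + direction * total * t
            return center[None, :] + r_arc * np.stack(
                [np.cos(angles), np.sin(angles)], axis=1
            )
    raise RuntimeError("arc sweep direction not found")  # pragma: no cover


def contour_points(spec: ShapeSpec, radius: float,
                   points_per_side: int = 128) -> np.ndarray:
    """Dense closed contour (CCW, math coords, centered on the origin).

    The returned array does not repeat the first point; the contour closes
    implicitly.
    """
    verts = _vertex_positions(spec, radius)
    n = spec.family.n
    pts = []
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        edge = b - a
        # CCW polygon: interior on the left of a->b, outward normal on the right
        outward = np.array([edge[1], -edge[0]])
        outward /= np.linalg.norm(outward)
        s = SAGITTA_RATIOS[spec.elements[i]]
        pts.append(_arc_points(a, b, s, outward, points_per_side))
    return np.concatenate(pts, axis=0)


def blob_contour(spec: BlobSpec, orientation: float = 0.0,
                 n_points: int = 512) -> np.ndarray:
    """Closed blob contour (CCW, math coords); rotation is a phase shift."""
    phi = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    shifted = phi - np.deg2rad(orientation)
    r = np.ones_like(phi)
    for k, (a, b) in enumerate(zip(spec.cos_coeffs, spec.sin_coeffs), start=1):
        r += a * np.cos(k * shifted) + b * np.sin(k * shifted)
    r = spec.base_radius * np.clip(r, 0.05, None)
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


# ---------------------------------------------------------------------------
# rasterization

def _rotate(points: np.ndarray, degrees: float) -> np.ndarray:
    th = np.deg2rad(degrees)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return points @ rot.T


def _rasterize(points: np.ndarray, retina_size: int, center: tuple[float, float],
               stroke_width: int, filled: bool, what: str) -> np.ndarray:
    """Rasterize a closed contour given in math coords around the origin."""
    cx, cy = center
    cols = _round_sym(points[:, 0]) + _round_sym(np.array(cx))
    rows = _round_sym(-points[:, 1]) + _round_sym(np.array(cy))
    cols = cols.astype(int)
    rows = rows.astype(int)
    pad = stroke_width // 2
    if (rows.min() - pad < 0 or cols.min() - pad < 0
            or rows.max() + pad >= retina_size or cols.max() + pad >= retina_size):
        raise ValueError(
            f"shape exceeds retina bounds ({retina_size}x{retina_size}) for {what}"
        )
    img = np.zeros((retina_size, retina_size), dtype=bool)
    if filled:
        rr, cc = _sk_polygon(rows, cols, shape=img.shape)
        img[rr, cc] = True
        img[rows, cols] = True
    else:
        img[rows, cols] = True
    if pad > 0:
        yy, xx = np.mgrid[-pad:pad + 1, -pad:pad + 1]
        struct = (yy * yy + xx * xx) <= pad * pad
        img = binary_dilation(img, structure=struct)
    return img.astype(float)


def render_shape(spec: ShapeSpec, retina_size: int = 256,
                 center: tuple[float, float] | None = None,
                 orientation: float = 0.0, mirror: bool = False,
                 mirror_axis_x: float = 0.0, radius: float | None = None,
                 stroke_width: int = 2, filled: bool = False,
                 points_per_side: int = 128) -> RenderedStimulus:
    """Render a shape as a white outline (or silhouette) on a black retina.

    ``orientation`` rotates counter-clockwise; ``mirror`` reflects the
    (already rotated) contour about the vertical line x = ``mirror_axis_x``
    in object coordinates before placement at ``center``.
    """
    if center is None:
        c = (retina_size - 1) / 2.0
        center = (c, c)
    if radius is None:
        radius = retina_size / 4.0
    pts = contour_points(spec, radius, points_per_side)
    if orientation:
        pts = _rotate(pts, orientation)
    if mirror:
        pts = pts.copy()
        pts[:, 0] = 2.0 * mirror_axis_x - pts[:, 0]
    what = (f"object {spec.object_id} at center={center}, "
            f"orientation={orientation}, mirror={mirror}")
    img = _rasterize(pts, retina_size, center, stroke_width, filled, what)
    return RenderedStimulus(img, spec.object_id, tuple(center), orientation,
                            mirror, source_spec=spec)


def render_blob(spec: BlobSpec, retina_size: int = 256,
                center: tuple[float, float] | None = None,
                orientation: float = 0.0, n_points: int = 512) -> RenderedStimulus:
    """Render a blob as a filled silhouette."""
    if center is None:
        c = (retina_size - 1) / 2.0
        center = (c, c)
    pts = blob_contour(spec, orientation, n_points)
    img = _rasterize(pts, retina_size, center, stroke_width=1, filled=True,
                     what=f"blob {spec.blob_id} at center={center}")
    return RenderedStimulus(img, spec.blob_id, tuple(center), orientation,
                            source_spec=spec)


# ---------------------------------------------------------------------------
# stimulus sets

def make_pasupathy_set(
    vertex_angle_sets: Sequence[Sequence[float]] = ((135.0, 135.0, 90.0),
                                                    (180.0, 90.0, 90.0)),
    conformation_labels: Sequence[str] = PASUPATHY_CONFORMATIONS,
) -> list[ShapeSpec]:
    """Closed shapes built from convex/concave elements at given vertex separations.

    Every combination of the conformation labels over the sides of each angle
    set is enumerated.  Each angle set must sum to 360 degrees.
    """
    labels = tuple(conformation_labels)
    shapes: list[ShapeSpec] = []
    for angles in vertex_angle_sets:
        angles = tuple(float(a) for a in angles)
        if abs(sum(angles) - 360.0) > 1e-6:
            raise ValueError(f"vertex angle set {angles} does not sum to 360 deg")
        fam = ShapeFamilySpec(n=len(angles), p=len(labels), conformation_set=labels)
        for combo in itertools.product(labels, repeat=len(angles)):
            shapes.append(ShapeSpec(fam, combo, vertex_angles=angles))
    return shapes


def make_blob_objects(count: int, seed: int, smoothness: float = 0.12,
                      retina_size: int = 256, base_radius: float | None = None,
                      n_harmonics: int = 4) -> list[RenderedStimulus]:
    """Distinct smooth filled blobs from random low-order Fourier radius functions.

    ``smoothness`` scales the harmonic amplitudes (sd of harmonic k is
    smoothness / k, so boundary curvature stays continuous and bounded).
    Deterministic under ``seed``.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if base_radius is None:
        base_radius = retina_size / 4.5
    rng = np.random.default_rng(seed)
    out = []
    for i in range(count):
        k = np.arange(1, n_harmonics + 1)
        a = rng.normal(0.0, smoothness / k)
        b = rng.normal(0.0, smoothness / k)
        spec = BlobSpec(base_radius, tuple(a), tuple(b), blob_id=f"blob{i:03d}")
        out.append(render_blob(spec, retina_size))
    return out


# ---------------------------------------------------------------------------
# presentation sequences

def _grid_centers(retina_size: int, grid: tuple[int, int],
                  spacing_px: int) -> list[tuple[int, int]]:
    gy, gx = grid
    c = (retina_size - 1) // 2
    oy = [int(i * spacing_px - ((gy - 1) * spacing_px) // 2) for i in range(gy)]
    ox = [int(j * spacing_px - ((gx - 1) * spacing_px) // 2) for j in range(gx)]
    return [(c + x, c + y) for y in oy for x in ox]  # raster order, (cx, cy)


def make_sequence(objects: Sequence[ShapeSpec | BlobSpec | RenderedStimulus],
                  grid: tuple[int, int] = (1, 1), spacing_px: int = 10,
                  orientations_deg: Sequence[float] = (0.0,),
                  retina_size: int = 256,
                  render_kwargs: Mapping | None = None) -> PresentationSequence:
    """Build the training sequence: per object, per orientation, all grid locations.

    Within one object every retinal location is visited (fixed raster order)
    before the orientation changes, and all of one object's transforms appear
    before the next object: the temporal structure that lets the trace rule
    bind transforms of the same object.  Total length is
    ``len(objects) * len(orientations) * n_locations``.
    """
    render_kwargs = dict(render_kwargs or {})
    centers = _grid_centers(retina_size, grid, spacing_px)
    seq = PresentationSequence()
    for obj in objects:
        spec = obj.source_spec if isinstance(obj, RenderedStimulus) else obj
        first = True
        for ori in orientations_deg:
            for cx, cy in centers:
                if isinstance(spec, BlobSpec):
                    stim = render_blob(spec, retina_size, center=(cx, cy),
                                       orientation=ori)
                elif isinstance(spec, ShapeSpec):
                    stim = render_shape(spec, retina_size, center=(cx, cy),
                                        orientation=ori, **render_kwargs)
                else:
                    raise TypeError(f"cannot sequence object of type {type(obj)}")
                seq.items.append(SequenceItem(stim, stim.object_id, first))
                first = False
    return seq


# ---------------------------------------------------------------------------
# image + manifest I/O

def write_pgm(path: str | Path, image: np.ndarray) -> None:
    """Write a [0,1] grayscale image as plain-text PGM (P2)."""
    img = np.asarray(image)
    data = np.clip(np.round(img * 255), 0, 255).astype(int)
    lines = [f"P2", f"{img.shape[1]} {img.shape[0]}", "255"]
    lines += [" ".join(map(str, row)) for row in data]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pgm(path: str | Path) -> np.ndarray:
    """Read a plain-text (P2) PGM back to a [0,1] float image."""
    tokens = Path(path).read_text().split()
    if tokens[0] != "P2":
        raise ValueError(f"{path}: not a plain (P2) PGM file")
    w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4:4 + w * h], dtype=float).reshape(h, w)
    return data / maxval


def save_sequence(seq: PresentationSequence, out_dir: str | Path) -> Path:
    """Write stimuli as PGM plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, item in enumerate(seq):
        fname = f"stim{i:05d}.pgm"
        write_pgm(out / fname, item.stimulus.image)
        entries.append({
            "file": fname,
            "object_id": item.object_id,
            "center": list(item.stimulus.center),
            "orientation": item.stimulus.orientation,
            "mirror": item.stimulus.mirror,
            "is_object_boundary": item.is_object_boundary,
        })
    manifest = out / "sequence.json"
    manifest.write_text(json.dumps({"items": entries}, indent=1))
    return manifest
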