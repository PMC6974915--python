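"""Quantification of the four corolla morphological traits.

The four traits summarize the leading axes of corolla shape variation:

tube curvature   second-order coefficient of a quadratic fitted to the tube
                 axis after projection into the sagittal plane (mm^-1, signed;
                 positive bends toward the dorsal side)
lobe area ratio  lobe surface area / total corolla surface area (0..1)
tube dilation    centroid size of the mid-tube transection (the order-14 tube
                 landmarks) divided by tube axis length (dimensionless)
lobe recurvation mean angle between the tube-opening plane normal and the five
                 lobe bending lines (degrees)

The tube axis is the polyline of centroids of the 10 tube landmarks (5 midrib
+ 5 rim) sharing each series order, proximal to distal.  Surface areas come
from a fixed, documented triangulation of the landmark configuration
(quad strips on the tube, boundary-to-midrib strips on each lobe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LandmarkSet, SpecimenCollection
from .errors import DegenerateGeometryError
from .procrustes import centroid_size
from .template import LandmarkTemplate, default_template

#: identifier of the triangulation scheme, reported alongside areas
TRIANGULATION_SCHEME = "quadstrip-fan/1"

_COLLINEAR_TOL = 1e-9


def _coords(landmarks) -> np.ndarray:
    if isinstance(landmarks, LandmarkSet):
        return landmarks.coords
    arr = np.asarray(landmarks, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected a LandmarkSet or (K, 3) array")
    return arr


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


@dataclass
class TubeAxis:
    """Tube centerline polyline, proximal to distal."""

    points: np.ndarray  # (n_orders, 3)
    length: float

    def __post_init__(self):
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise DegenerateGeometryError("tube axis has coincident consecutive points")


@dataclass
class SagittalFrame:
    """Orthonormal in-plane frame of the corolla's sagittal plane.

    ``abscissa`` points proximal to distal along the tube; ``ordinate`` points
    toward the dorsal side; ``normal`` completes the right-handed triple.
    """

    origin: np.ndarray
    abscissa: np.ndarray
    ordinate: np.ndarray
    normal: np.ndarray


def tube_axis(landmarks, template: LandmarkTemplate | None = None) -> TubeAxis:
    """Centroid polyline of same-order tube landmarks and its length."""
    template = template or default_template()
    coords = _coords(landmarks)
    points = np.stack([coords[grp].mean(axis=0) for grp in template.axis_order_groups()])
    length = float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())
    return TubeAxis(points=points, length=length)


def _dorsal_reference(coords: np.ndarray, template: LandmarkTemplate,
                      axis_centroid: np.ndarray) -> np.ndarray:
    ids = np.concatenate(
        [template.series_indices("tube_midrib", p) for p in template.dorsal_petals]
    )
    return coords[ids].mean(axis=0) - axis_centroid


def sagittal_frame(axis: TubeAxis, landmarks,
                   template: LandmarkTemplate | None = None) -> SagittalFrame:
    """Total-least-squares plane through the tube axis points, with the
    dorsal side of the corolla defining the positive ordinate.

    A perfectly straight axis has no unique plane; the frame then uses the
    axis direction plus the dorsal reference (mean dorsal-petal tube-midrib
    landmark relative to the axis centroid) to span the plane.
    """
    template = template or default_template()
    coords = _coords(landmarks)
    pts = axis.points
    origin = pts.mean(axis=0)
    centred = pts - origin
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    dorsal = _dorsal_reference(coords, template, origin)
    chord = pts[-1] - pts[0]

    if sv[1] <= _COLLINEAR_TOL * sv[0]:
        # straight axis: build the plane from the axis line and the dorsal side
        abscissa = _unit(chord)
        perp = dorsal - np.dot(dorsal, abscissa) * abscissa
        if np.linalg.norm(perp) <= _COLLINEAR_TOL * max(np.linalg.norm(dorsal), 1.0):
            raise DegenerateGeometryError(
                "straight tube axis with in-line dorsal reference: sagittal plane undefined"
            )
        ordinate = _unit(perp)
        normal = np.cross(abscissa, ordinate)
        return SagittalFrame(origin=origin, abscissa=abscissa, ordinate=ordinate, normal=normal)

    normal = vt[2]
    in_plane = chord - np.dot(chord, normal) * normal
    abscissa = _unit(in_plane)
    ordinate = np.cross(normal, abscissa)
    if np.dot(ordinate, dorsal) < 0:
        ordinate = -ordinate
    normal = np.cross(abscissa, ordinate)
    return SagittalFrame(origin=origin, abscissa=abscissa, ordinate=ordinate, normal=normal)


def tube_curvature(landmarks, template: LandmarkTemplate | None = None) -> float:
    """Quadratic coefficient (mm^-1) of the in-plane tube axis, positive when
    the tube bends toward the dorsal side.  Rigid-motion invariant; scales as
    1/length under uniform scaling."""
    template = template or default_template()
    axis = tube_axis(landmarks, template)
    frame = sagittal_frame(axis, landmarks, template)
    rel = axis.points - frame.origin
    u = rel @ frame.abscissa
    v = rel @ frame.ordinate
    if len(np.unique(np.round(u, 12))) < 3:
        raise DegenerateGeometryError("fewer than 3 distinct abscissa values for the fit")
    return float(np.polynomial.polynomial.polyfit(u, v, 2)[2])


# ---------------------------------------------------------------------------
# surface triangulation and areas
# ---------------------------------------------------------------------------

@dataclass
class CorollaSurface:
    """Deterministic landmark triangulation with per-triangle region tags."""

    triangles: np.ndarray  # (F, 3) landmark ids
    tags: np.ndarray       # (F,) "lobe" | "tube"
    n_dropped: int         # degenerate (zero-area) triangles removed
    scheme: str = TRIANGULATION_SCHEME

    def areas(self, coords: np.ndarray) -> np.ndarray:
        a = coords[self.triangles[:, 1]] - coords[self.triangles[:, 0]]
        b = coords[self.triangles[:, 2]] - coords[self.triangles[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def _split_quad(q00, q01, q10, q11, coords):
    """Split the quad (q00 q01 q11 q10) along its shorter diagonal."""
    d1 = np.linalg.norm(coords[q00] - coords[q11])
    d2 = np.linalg.norm(coords[q01] - coords[q10])
    if d1 <= d2:
        return [(q00, q01, q11), (q00, q11, q10)]
    return [(q00, q01, q10), (q01, q11, q10)]


def _zip_polylines(p, q):
    """Triangles bridging two polylines sharing their first vertex, marching
    greedily by fractional arc position.  Duplicate-id triangles are skipped."""
    tris = []
    i = j = 0
    while i < len(p) - 1 or j < len(q) - 1:
        adv_p = (i + 1) / (len(p) - 1) if i < len(p) - 1 else np.inf
        adv_q = (j + 1) / (len(q) - 1) if j < len(q) - 1 else np.inf
        if adv_p <= adv_q:
            tri = (p[i], q[j], p[i + 1])
            i += 1
        else:
            tri = (p[i], q[j], q[j + 1])
            j += 1
        if len(set(tri)) == 3:
            tris.append(tri)
    return tris


def corolla_triangulation(landmarks, template: LandmarkTemplate | None = None) -> CorollaSurface:
    """Fixed triangulation of the corolla surface.

    Tube: quad strips between azimuthally adjacent tube columns (each quad
    split along its shorter diagonal) plus distal cap triangles joining each
    primary-IV to the neighbouring rim tops.  Lobe: each half-lobe is a strip
    zipped between its boundary (rim + half contour) and the midrib spine, so
    every lobe landmark participates in the mesh.
    """
    template = template or default_template()
    coords = _coords(landmarks)
    tris: list[tuple] = []
    tags: list[str] = []

    cols = template.tube_columns()
    n_cols = len(cols)
    for c in range(n_cols):
        _, col_a = cols[c]
        _, col_b = cols[(c + 1) % n_cols]
        for row in range(25):
            for tri in _split_quad(col_a[row], col_b[row], col_a[row + 1], col_b[row + 1], coords):
                tris.append(tri)
                tags.append("tube")
    # distal cap: IV sits beyond the last rim row on each midrib column
    for c in range(0, n_cols, 2):  # midrib columns alternate with rim columns
        _, mid = cols[c]
        iv, m_top = mid[26], mid[25]
        _, rim_right = cols[(c + 1) % n_cols]
        _, rim_left = cols[(c - 1) % n_cols]
        for tri in [(m_top, rim_right[25], iv), (rim_left[25], m_top, iv)]:
            tris.append(tri)
            tags.append("tube")

    for petal in template.petal_cycle:
        comp = template.lobe_components(petal)
        iv = template.primary_index("primary-IV", petal)
        spine = list(comp["spine"])
        contour = list(comp["contour"])
        mid_c = len(contour) // 2  # contour order 8 sits at the lobe tip
        right = [iv] + list(comp["right_rim"]) + contour[: mid_c + 1]
        left = [iv] + list(comp["left_rim"]) + contour[::-1][: mid_c + 1]
        for half in (right, left):
            for tri in _zip_polylines(half, spine + [half[-1]]):
                tris.append(tri)
                tags.append("lobe")

    triangles = np.asarray(tris, dtype=int)
    tag_arr = np.asarray(tags)
    surface = CorollaSurface(triangles=triangles, tags=tag_arr, n_dropped=0)
    areas = surface.areas(coords)
    keep = areas > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-area triangles")
    return CorollaSurface(
        triangles=triangles[keep], tags=tag_arr[keep], n_dropped=n_dropped
    )


def lobe_area_ratio(landmarks, template: LandmarkTemplate | None = None) -> float:
    """Lobe surface area divided by total corolla surface area."""
    template = template or default_template()
    coords = _coords(landmarks)
    surface = corolla_triangulation(coords, template)
    areas = surface.areas(coords)
    total = areas.sum()
    if total <= 0:
        raise DegenerateGeometryError("zero total surface area")
    return float(areas[surface.tags == "lobe"].sum() / total)


def tube_dilation(landmarks, template: LandmarkTemplate | None = None,
                  transection_order: int = 14) -> float:
    """Centroid size of the mid-tube transection landmarks divided by tube
    axis length (dimensionless, scale invariant)."""
    template = template or default_template()
    coords = _coords(landmarks)
    axis = tube_axis(coords, template)
    if axis.length <= 0:
        raise DegenerateGeometryError("zero tube axis length")
    group = template.axis_order_groups()[transection_order - 1]
    return float(centroid_size(coords[group]) / axis.length)


def lobe_recurvation(landmarks, template: LandmarkTemplate | None = None) -> float:
    """Mean lobe bending angle over the five petals, in degrees.

    The tube-opening plane is the total-least-squares plane through the 10
    primary landmarks of types I and IV, its normal oriented distally; each
    petal's bending line runs from the proximal (IV) to the distal (III)
    landmark of its lobe midrib.
    """
    template = template or default_template()
    coords = _coords(landmarks)
    t = template.table
    opening_ids = t[t["role"].isin(["primary-I", "primary-IV"])]["landmark_id"].to_numpy()
    pts = coords[opening_ids]
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
    normal = vt[2]
    axis = tube_axis(coords, template)
    if np.dot(normal, axis.points[-1] - axis.points[0]) < 0:
        normal = -normal

    angles = []
    for petal in template.petal_cycle:
        bend = coords[template.primary_index("primary-III", petal)] - coords[
            template.primary_index("primary-IV", petal)
        ]
        norm = np.linalg.norm(bend)
        if norm == 0:
            warnings.warn(f"petal {petal!r} has a zero-length bending line; excluded")
            continue
        cosang = np.clip(np.dot(bend / norm, normal), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    if not angles:
        raise DegenerateGeometryError("all petals have degenerate bending lines")
    return float(np.mean(angles))


def trait_table(collection: SpecimenCollection) -> pd.DataFrame:
    """All four traits plus centroid size for every specimen.

    Geometric failures are recorded in the ``error`` column and the run
    continues; trait cells of failed specimens are NaN.
    """
    template = collection.template
    rows = []
    for s in collection:
        row = {
            "specimen_id": s.specimen_id,
            "species": s.species,
            "pollination": s.pollination,
            "centroid_size": centroid_size(s.coords),
            "tube_curvature": np.nan,
            "lobe_area_ratio": np.nan,
            "tube_dilation": np.nan,
            "lobe_recurvation": np.nan,
            "error": None,
        }
        try:
            row["tube_curvature"] = tube_curvature(s.coords, template)
            row["lobe_area_ratio"] = lobe_area_ratio(s.coords, template)
            row["tube_dilation"] = tube_dilation(s.coords, template)
            row["lobe_recurvation"] = lobe_recurvation(s.coords, template)
        except DegenerateGeometryError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


TRAIT_COLUMNS = ["tube_curvature", "lobe_area_ratio", "tube_dilation", "lobe_recurvation"]
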