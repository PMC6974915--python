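"""Landmark template for five-petal corollas.

A corolla is digitized as a fixed set of homologous 3D landmarks.  The default
template describes 415 landmarks: 25 *primary* landmarks at discrete anatomical
intersections (5 each of roles I-V) and 390 *secondary* landmarks equally
distributed along anatomical curves (lobe contours, lobe-lobe rims, lobe and
tube midribs, tube-tube rims).

Roles
-----
primary-I    intersections of adjacent lobes (shared between petals; stored as
             the distal entry of each lobe-lobe rim series)
primary-II   proximal points of the petal midribs
primary-III  distal points of the petal midribs (lobe tips)
primary-IV   intersections of the lobe-tube rims and the petal midribs
primary-V    proximal points of the tube-tube rims (shared between petals)

The template is expanded from a packaged JSON schema, so a user whose landmark
files follow a different convention can load their own schema file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import SchemaError

PRIMARY_ROLES = ("primary-I", "primary-II", "primary-III", "primary-IV", "primary-V")
SERIES_TYPES = (
    "lobe_contour",
    "lobe_lobe_rim",
    "lobe_midrib",
    "tube_midrib",
    "tube_tube_rim",
    "point",
)


def _rim_name(a: str, b: str) -> str:
    return f"{a}|{b}"


@dataclass(frozen=True)
class LandmarkTemplate:
    """Structural schema of a corolla landmark configuration.

    ``table`` has one row per landmark with columns ``landmark_id`` (0-based,
    contiguous), ``role`` (a primary role or ``secondary``), ``petal`` (petal
    name, or ``a|b`` for a rim shared between petals *a* and *b*), ``region``
    (``lobe``/``tube``), ``series`` (one of :data:`SERIES_TYPES`) and ``order``
    (1-based position within the series, proximal to distal).
    """

    name: str
    table: pd.DataFrame
    petal_cycle: tuple[str, ...]
    dorsal_petals: tuple[str, ...]
    series_counts: dict = field(default_factory=dict)

    # -- basic accessors ---------------------------------------------------
    @property
    def size(self) -> int:
        return len(self.table)

    def role_count(self, role: str) -> int:
        return int((self.table["role"] == role).sum())

    @property
    def rims(self) -> list[str]:
        cyc = self.petal_cycle
        return [_rim_name(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]

    def series_indices(self, series: str, owner: str) -> np.ndarray:
        """Landmark ids of one series (e.g. the tube midrib of one petal),
        sorted by ``order`` (proximal to distal)."""
        t = self.table
        sel = t[(t["series"] == series) & (t["petal"] == owner)]
        if sel.empty:
            raise SchemaError(f"template has no series {series!r} for {owner!r}")
        return sel.sort_values("order")["landmark_id"].to_numpy()

    def primary_index(self, role: str, owner: str) -> int:
        t = self.table
        sel = t[(t["role"] == role) & (t["petal"] == owner)]
        if len(sel) != 1:
            raise SchemaError(f"expected one {role!r} landmark for {owner!r}, found {len(sel)}")
        return int(sel["landmark_id"].iloc[0])

    # -- derived structure used by traits / synthetic geometry ------------
    def tube_columns(self) -> list[tuple[str, np.ndarray]]:
        """Tube landmark columns in cyclic azimuthal order.

        Alternates petal midrib columns ``[II, tube_midrib 1..n, IV]`` with
        tube-tube rim columns ``[V, tube_tube_rim 1..n]``, starting at the
        first petal of the cycle.  Used for tube-surface triangulation and for
        pairing same-order landmarks into the tube axis.
        """
        cols: list[tuple[str, np.ndarray]] = []
        cyc = self.petal_cycle
        for i, petal in enumerate(cyc):
            mid = np.concatenate(
                (
                    [self.primary_index("primary-II", petal)],
                    self.series_indices("tube_midrib", petal),
                    [self.primary_index("primary-IV", petal)],
                )
            )
            cols.append((petal, mid))
            rim = _rim_name(petal, cyc[(i + 1) % len(cyc)])
            rim_ids = np.concatenate(
                (
                    [self.primary_index("primary-V", rim)],
                    self.series_indices("tube_tube_rim", rim),
                )
            )
            cols.append((rim, rim_ids))
        return cols

    def axis_order_groups(self) -> list[np.ndarray]:
        """For each series order k, the ids of the 10 tube landmarks (5 midrib
        + 5 rim) at that order; their centroids form the tube axis."""
        n = self.series_counts["tube_midrib"]
        mids = [self.series_indices("tube_midrib", p) for p in self.petal_cycle]
        rims = [self.series_indices("tube_tube_rim", r) for r in self.rims]
        return [np.array([s[k] for s in mids + rims]) for k in range(n)]

    def lobe_components(self, petal: str) -> dict:
        """Landmark ids making up one lobe: left/right rims (orders 1..7, the
        7th being primary-I), contour, and the midrib spine [IV, 1..7, III]."""
        cyc = self.petal_cycle
        i = cyc.index(petal)
        left_rim = _rim_name(cyc[(i - 1) % len(cyc)], petal)
        right_rim = _rim_name(petal, cyc[(i + 1) % len(cyc)])
        spine = np.concatenate(
            (
                [self.primary_index("primary-IV", petal)],
                self.series_indices("lobe_midrib", petal),
                [self.primary_index("primary-III", petal)],
            )
        )
        return {
            "left_rim": self.series_indices("lobe_lobe_rim", left_rim),
            "right_rim": self.series_indices("lobe_lobe_rim", right_rim),
            "contour": self.series_indices("lobe_contour", petal),
            "spine": spine,
        }

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        if not np.array_equal(t["landmark_id"].to_numpy(), np.arange(len(t))):
            raise SchemaError("landmark_id must be 0-based and contiguous")
        for series in set(t["series"]) - {"point"}:
            for owner, grp in t[t["series"] == series].groupby("petal"):
                orders = np.sort(grp["order"].to_numpy())
                if not np.array_equal(orders, np.arange(1, len(orders) + 1)):
                    raise SchemaError(
                        f"orders of series {series!r} ({owner!r}) must be contiguous 1-based"
                    )


def _expand_layout(schema: dict) -> pd.DataFrame:
    rows = []

    def emit(owner, region, series, role, order):
        rows.append(
            {
                "landmark_id": len(rows),
                "role": role,
                "petal": owner,
                "region": region,
                "series": series,
                "order": order,
            }
        )

    def expand(owner, layout):
        for item in layout:
            series = item["series"]
            if series == "point":
                emit(owner, item["region"], "point", item["role"], 1)
                continue
            count = item["count"]
            distal_role = item.get("distal_role")
            for k in range(1, count + 1):
                role = distal_role if (distal_role and k == count) else "secondary"
                emit(owner, item["region"], series, role, k)

    cyc = schema["petal_cycle"]
    for petal in cyc:
        expand(petal, schema["petal_layout"])
    for i, petal in enumerate(cyc):
        expand(_rim_name(petal, cyc[(i + 1) % len(cyc)]), schema["rim_layout"])
    return pd.DataFrame(rows)


def load_template(schema: dict) -> LandmarkTemplate:
    """Expand a template schema dictionary into a :class:`LandmarkTemplate`."""
    counts = {item["series"]: item["count"]
              for layout in (schema["petal_layout"], schema["rim_layout"])
              for item in layout if item["series"] != "point"}
    tpl = LandmarkTemplate(
        name=schema.get("name", "custom"),
        table=_expand_layout(schema),
        petal_cycle=tuple(schema["petal_cycle"]),
        dorsal_petals=tuple(schema["dorsal_petals"]),
        series_counts=counts,
    )
    tpl.validate()
    return tpl


def load_template_file(path) -> LandmarkTemplate:
    with open(path, encoding="utf-8") as fh:
        return load_template(json.load(fh))


_DEFAULT: LandmarkTemplate | None = None


def default_template() -> LandmarkTemplate:
    """The packaged 415-landmark corolla template (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("corollamorph.schemas").joinpath("corolla415.json").read_text()
        _DEFAULT = load_template(json.loads(text))
    return _DEFAULT
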