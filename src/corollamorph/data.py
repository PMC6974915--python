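"""Specimen landmark data: containers, CSV I/O, and PLY surface reading.

The canonical landmark file is a UTF-8 CSV with header
``specimen_id,species,pollination,landmark_id,x,y,z`` and one row per landmark
per specimen.  Coordinates are stored in millimetres; files digitized in voxel
units of the source µCT scans can be converted on read with ``units="voxel"``
(36.547 µm per voxel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LandmarkParseError, SchemaError
from .template import LandmarkTemplate, default_template

#: µCT scanner resolution used to convert voxel-unit coordinates to mm.
VOXEL_SIZE_MM = 0.036547

POLLINATION_TYPES = ("hummingbird", "bee", "moth", "unknown")

_CSV_COLUMNS = ["specimen_id", "species", "pollination", "landmark_id", "x", "y", "z"]


@dataclass
class LandmarkSet:
    """One specimen's landmark configuration (K x 3, millimetres)."""

    specimen_id: str
    species: str
    pollination: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise SchemaError(f"coords of {self.specimen_id!r} must be K x 3")
        if not np.all(np.isfinite(self.coords)):
            raise SchemaError(f"non-finite coordinates in specimen {self.specimen_id!r}")
        if self.pollination not in POLLINATION_TYPES:
            raise SchemaError(
                f"unknown pollination type {self.pollination!r} for {self.specimen_id!r}"
            )


@dataclass
class SpecimenCollection:
    """A set of specimens conforming to one landmark template."""

    template: LandmarkTemplate
    specimens: list[LandmarkSet]
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self):
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise SchemaError("specimen_id values must be unique within a collection")
        for s in self.specimens:
            if s.coords.shape[0] != self.template.size:
                raise SchemaError(
                    f"specimen {s.specimen_id!r} has {s.coords.shape[0]} landmarks, "
                    f"template requires {self.template.size}"
                )
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {
                    "specimen_id": ids,
                    "species": [s.species for s in self.specimens],
                    "pollination": [s.pollination for s in self.specimens],
                }
            ).set_index("specimen_id")

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)

    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen_id for s in self.specimens]

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.specimens]

    @property
    def pollination(self) -> list[str]:
        return [s.pollination for s in self.specimens]

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an (S, K, 3) array."""
        return np.stack([s.coords for s in self.specimens])

    def subset(self, specimen_ids) -> "SpecimenCollection":
        keep = set(specimen_ids)
        return SpecimenCollection(
            template=self.template,
            specimens=[s for s in self.specimens if s.specimen_id in keep],
        )

    def species_subset(self, species) -> "SpecimenCollection":
        keep = set(species)
        return SpecimenCollection(
            template=self.template,
            specimens=[s for s in self.specimens if s.species in keep],
        )


def read_landmarks(path, template: LandmarkTemplate | None = None,
                   units: str = "mm") -> SpecimenCollection:
    """Read a landmark CSV into a :class:`SpecimenCollection`.

    Parameters
    ----------
    path : path-like
        CSV file in the canonical dialect (see module docstring).
    template : LandmarkTemplate, optional
        Defaults to the packaged 415-landmark template.
    units : {"mm", "voxel"}
        Coordinate units of the file; voxel units are converted to mm.
    """
    template = template or default_template()
    raw = pd.read_csv(
        path,
        dtype={"specimen_id": str, "species": str, "pollination": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in _CSV_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"landmark file is missing columns {missing_cols}")

    coords = raw[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1) & raw[["x", "y", "z"]].notna().any(axis=1)
    bad |= raw[["x", "y", "z"]].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise LandmarkParseError(f"non-numeric coordinate at line {line} of {path}")
    if units == "voxel":
        coords = coords * VOXEL_SIZE_MM
    elif units != "mm":
        raise ValueError(f"units must be 'mm' or 'voxel', got {units!r}")

    raw = raw.assign(x=coords["x"], y=coords["y"], z=coords["z"])
    specimens = []
    expected = np.arange(template.size)
    for sid, grp in raw.groupby("specimen_id", sort=False):
        grp = grp.sort_values("landmark_id")
        ids = grp["landmark_id"].to_numpy()
        if not np.array_equal(ids, expected):
            absent = sorted(set(expected) - set(ids))
            raise SchemaError(
                f"specimen {sid!r}: landmark ids do not match the template"
                + (f" (missing landmark {absent[0]})" if absent else "")
            )
        specimens.append(
            LandmarkSet(
                specimen_id=str(sid),
                species=str(grp["species"].iloc[0]),
                pollination=str(grp["pollination"].iloc[0]),
                coords=grp[["x", "y", "z"]].to_numpy(),
            )
        )
    return SpecimenCollection(template=template, specimens=specimens)


def write_landmarks(collection: SpecimenCollection, path) -> None:
    """Write a collection in the canonical CSV dialect (lossless round trip)."""
    frames = []
    for s in collection:
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": s.specimen_id,
                    "species": s.species,
                    "pollination": s.pollination,
                    "landmark_id": np.arange(s.coords.shape[0]),
                    "x": s.coords[:, 0],
                    "y": s.coords[:, 1],
                    "z": s.coords[:, 2],
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_CSV_COLUMNS)
    )
    # repr-precision floats keep the round trip bit-exact
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# PLY surfaces (optional convenience for the deposited surface scans)
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangular surface mesh (vertices V x 3, faces F x 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def area(self) -> float:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def read_ply(path) -> SurfaceMesh:
    """Load a PLY surface (ASCII or binary little-endian) as triangles.

    Non-triangular faces are fan-triangulated; zero-area faces are dropped
    with a warning.
    """
    import trimesh

    try:
        mesh = trimesh.load(str(path), file_type="ply", force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - trimesh error text varies
        raise SchemaError(f"could not read PLY file {path}: {exc}") from exc
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    if faces.size == 0:
        raise SchemaError(f"PLY file {path} contains no faces")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise SchemaError(f"PLY file {path} has out-of-range face indices")
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    if (areas == 0).any():
        warnings.warn(f"dropping {(areas == 0).sum()} degenerate faces from {path}")
        faces = faces[areas > 0]
    return SurfaceMesh(vertices=vertices, faces=faces)
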