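"""Scene data model and on-disk formats.

A *scene* is one segmented tomogram region: traced filament centerlines
(3D polylines, nm), particle point sets (e.g. ribosome centers), binary
compartment masks on a shared voxel grid, and metadata (genotype, lamella
bounds, provenance).  All coordinates are carried in nanometers in a single
right-handed frame; voxel <-> nm conversion happens only here, at the I/O
boundary.  Voxel index (i, j, k) maps to the *center* of that voxel at
``origin + voxel_size * (i, j, k)``.

Formats: CSV (UTF-8, header row) for filaments and points, MRC2014 for
masks (via gemmi), RELION-style STAR particle tables read-only, and a YAML
manifest tying a scene directory together.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Genotype",
    "Compartment",
    "MaskLabel",
    "Filament",
    "PointSet",
    "VoxelMask",
    "SceneMeta",
    "Scene",
    "FormatError",
    "read_filaments",
    "write_filaments",
    "read_points",
    "write_points",
    "read_mask",
    "write_mask",
    "load_scene",
    "save_scene",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class Genotype(str, enum.Enum):
    WT = "WT"
    dPomY = "dPomY"
    dPomZ = "dPomZ"
    dPomX = "dPomX"


class Compartment(str, enum.Enum):
    assembly = "assembly"
    nucleoid = "nucleoid"


class MaskLabel(str, enum.Enum):
    condensate = "condensate"
    nucleoid = "nucleoid"
    membrane = "membrane"
    cytoplasm = "cytoplasm"


def _as_points(a) -> np.ndarray:
    pts = np.asarray(a, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) coordinate array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite (no NaN/Inf)")
    return pts


@dataclass
class Filament:
    """One traced centerline: an ordered 3D polyline in nm."""

    id: str
    points: np.ndarray
    compartment: Compartment = Compartment.assembly

    def __post_init__(self):
        self.points = _as_points(self.points)
        self.compartment = Compartment(self.compartment)
        if len(self.points) < 2:
            raise ValueError(f"filament {self.id!r}: needs >= 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError(f"filament {self.id!r}: consecutive points must be distinct")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PointSet:
    """Labeled particle centers (N x 3, nm). Duplicate rows are invalid."""

    label: str
    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.size == 0:
            c = c.reshape(0, 3)
        self.coords = _as_points(c)
        if len(self.coords) > 1:
            uniq = np.unique(self.coords, axis=0)
            if len(uniq) != len(self.coords):
                raise ValueError(f"point set {self.label!r}: duplicate coordinates")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class VoxelMask:
    """Binary compartment mask on an isotropic voxel grid.

    ``grid[i, j, k]`` covers the point ``origin + voxel_size * (i, j, k)``
    (voxel centers carry coordinates).
    """

    label: MaskLabel
    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.label = MaskLabel(self.label)
        self.grid = np.ascontiguousarray(np.asarray(self.grid).astype(bool))
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        self.voxel_size = float(self.voxel_size)
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("mask origin must be finite")

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (nm) of all foreground voxel centers."""
        idx = np.argwhere(self.grid)
        return self.origin + self.voxel_size * idx

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each point (may fall outside the grid)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.rint((pts - self.origin) / self.voxel_size).astype(int)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Point-in-foreground-voxel test (False outside the grid)."""
        idx = self.world_to_index(points)
        inside = np.all((idx >= 0) & (idx < np.array(self.grid.shape)), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.grid[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def same_grid(self, other: "VoxelMask", tol: float = 1e-6) -> bool:
        return (
            self.grid.shape == other.grid.shape
            and abs(self.voxel_size - other.voxel_size) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )


# Plausible FIB-milled lamella thickness; configurable at validation time.
LAMELLA_RANGE_NM = (50.0, 200.0)


@dataclass
class SceneMeta:
    genotype: Genotype = Genotype.WT
    lamella_z: tuple | None = None  # (zmin, zmax) nm, set after slab cropping
    replicate: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.genotype = Genotype(self.genotype)
        if self.lamella_z is not None:
            z0, z1 = map(float, self.lamella_z)
            self.lamella_z = (z0, z1)

    def validate(self, lamella_range=LAMELLA_RANGE_NM):
        if self.lamella_z is not None:
            th = self.lamella_z[1] - self.lamella_z[0]
            lo, hi = lamella_range
            if not (lo <= th <= hi):
                raise ValueError(
                    f"lamella thickness {th:.1f} nm outside plausible range [{lo}, {hi}] nm"
                )


@dataclass
class Scene:
    """All components of one segmented tomogram region, in one frame."""

    filaments: list = field(default_factory=list)
    points: list = field(default_factory=list)
    masks: list = field(default_factory=list)
    meta: SceneMeta = field(default_factory=SceneMeta)

    def __post_init__(self):
        grids = self.masks
        for a in grids[1:]:
            if not grids[0].same_grid(a):
                raise ValueError("all masks in a scene must share one voxel grid")
        self.meta.validate()

    def get_mask(self, label) -> VoxelMask | None:
        label = MaskLabel(label)
        for m in self.masks:
            if m.label == label:
                return m
        return None

    def get_points(self, label: str) -> PointSet | None:
        for p in self.points:
            if p.label == label:
                return p
        return None

    def filaments_in(self, compartment) -> list:
        compartment = Compartment(compartment)
        return [f for f in self.filaments if f.compartment == compartment]


# ---------------------------------------------------------------------------
# filament tables

_FILAMENT_COLS = ["filament_id", "x", "y", "z"]


def read_filaments(path, compartment=Compartment.assembly) -> list:
    """Read filaments from a CSV with columns filament_id, x, y, z (nm).

    Rows are grouped by ``filament_id`` in file order; ids with fewer than
    two points are skipped with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in _FILAMENT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise FormatError(f"{path}: non-finite coordinates")
    out = []
    for fid, sub in df.groupby("filament_id", sort=False):
        pts = sub[["x", "y", "z"]].to_numpy(dtype=float)
        if len(pts) < 2:
            warnings.warn(f"{path}: filament {fid!r} has < 2 points, skipped")
            continue
        out.append(Filament(str(fid), pts, compartment))
    return out


def write_filaments(filaments, path) -> None:
    frames = [
        pd.DataFrame(
            {"filament_id": f.id, "x": f.points[:, 0], "y": f.points[:, 1], "z": f.points[:, 2]}
        )
        for f in filaments
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_FILAMENT_COLS)
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# particle tables

_STAR_COORD_TAGS = ["_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ"]


def read_points(path, dialect: str = "csv", label: str = "particle", pixel_size: float | None = None) -> PointSet:
    """Read particle centers; CSV gives nm directly, STAR gives voxels.

    STAR coordinates are multiplied by the pixel size (nm/voxel), taken
    from the table's pixel-size column unless ``pixel_size`` is given.
    """
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in ("x", "y", "z") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    elif dialect == "star":
        coords = _read_star_coords(path, pixel_size)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if coords.size and not np.all(np.isfinite(coords)):
        raise FormatError(f"{path}: non-finite coordinates")
    if len(coords) > 1:
        uniq = np.unique(coords, axis=0)
        if len(uniq) != len(coords):
            warnings.warn(f"{path}: {len(coords) - len(uniq)} duplicate points removed")
            coords = uniq
    return PointSet(label, coords)


def _read_star_coords(path, pixel_size: float | None) -> np.ndarray:
    doc = gemmi.cif.read_file(str(path))
    for block in doc:
        table = block.find(_STAR_COORD_TAGS)
        if len(table) == 0:
            continue
        vox = np.array(
            [[float(row[i]) for i in range(3)] for row in table], dtype=float
        )
        if pixel_size is None:
            for tag in ("_rlnImagePixelSize", "_rlnDetectorPixelSize"):
                vals = list(block.find_values(tag))
                if vals:
                    pixel_size = float(vals[0])
                    break
        if pixel_size is None:
            raise FormatError(f"{path}: STAR table has no pixel-size field and none was given")
        return vox * float(pixel_size)
    return np.empty((0, 3))


def write_points(points: PointSet, path) -> None:
    pd.DataFrame(points.coords, columns=["x", "y", "z"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MRC masks

_ORIGIN_WORDS = (50, 51, 52)  # MRC2014 ORIGIN x/y/z header words


def read_mask(path, label) -> VoxelMask:
    m = gemmi.read_ccp4_map(str(path))
    sp = m.grid.spacing
    if not all(np.isfinite(sp)) or min(sp) <= 0:
        raise FormatError(f"{path}: voxel size missing or non-positive ({sp})")
    if max(sp) - min(sp) > 1e-4 * max(sp):
        raise FormatError(f"{path}: anisotropic voxel size {sp} not supported")
    arr = np.array(m.grid, copy=True)
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS], dtype=float)
    return VoxelMask(label, arr != 0, float(sp[0]), origin)


def write_mask(mask: VoxelMask, path) -> None:
    nx, ny, nz = mask.grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    s = mask.voxel_size
    g.set_unit_cell(gemmi.UnitCell(nx * s, ny * s, nz * s, 90, 90, 90))
    np.array(g, copy=False)[:] = mask.grid.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip(_ORIGIN_WORDS, mask.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# scene directories

MANIFEST_NAME = "manifest.yaml"


def save_scene(scene: Scene, directory) -> Path:
    """Write a scene directory: manifest.yaml plus one file per component."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "genotype": scene.meta.genotype.value,
        "lamella_z": list(scene.meta.lamella_z) if scene.meta.lamella_z else None,
        "replicate": scene.meta.replicate,
        "seed": scene.meta.seed,
        "filaments": {},
        "points": {},
        "masks": {},
    }
    by_comp = {}
    for f in scene.filaments:
        by_comp.setdefault(f.compartment, []).append(f)
    for comp, fils in by_comp.items():
        name = f"filaments_{comp.value}.csv"
        write_filaments(fils, d / name)
        manifest["filaments"][comp.value] = name
    for ps in scene.points:
        name = f"points_{ps.label}.csv"
        write_points(ps, d / name)
        manifest["points"][ps.label] = name
    for mk in scene.masks:
        name = f"mask_{mk.label.value}.mrc"
        write_mask(mk, d / name)
        manifest["masks"][mk.label.value] = name
    with open(d / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return d


def load_scene(directory) -> Scene:
    d = Path(directory)
    mpath = d / MANIFEST_NAME
    if not mpath.exists():
        raise FormatError(f"{d}: no {MANIFEST_NAME}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    listed = (
        list(manifest.get("filaments", {}).values())
        + list(manifest.get("points", {}).values())
        + list(manifest.get("masks", {}).values())
    )
    missing = [name for name in listed if not (d / name).exists()]
    if missing:
        raise FormatError(f"{d}: manifest references missing files: {missing}")
    filaments = []
    for comp, name in manifest.get("filaments", {}).items():
        filaments.extend(read_filaments(d / name, Compartment(comp)))
    points = [
        read_points(d / name, "csv", label=lab)
        for lab, name in manifest.get("points", {}).items()
    ]
    masks = [
        read_mask(d / name, MaskLabel(lab))
        for lab, name in manifest.get("masks", {}).items()
    ]
    meta = SceneMeta(
        genotype=manifest.get("genotype", "WT"),
        lamella_z=tuple(manifest["lamella_z"]) if manifest.get("lamella_z") else None,
        replicate=manifest.get("replicate", "") or "",
        seed=manifest.get("seed"),
    )
    return Scene(filaments=filaments, points=points, masks=masks, meta=meta)
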