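"""Volumes and particle annotations: MRC, XML and STAR input/output.

Volumes (tomograms, templates, masks, score maps) are MRC2014 maps with an
isotropic voxel size recorded in the cell header; reading and writing goes
through gemmi.  Particle annotations use a minimal self-describing XML schema
natively and convert losslessly to RELION 3.1-style STAR files, including the
Euler-convention change (anticlockwise ZXZ to clockwise ZYZ).

Internally all coordinates are 0-based voxel indices with x as the first
array axis; unit or base conversions happen only at serialization
boundaries.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .geometry import (
    EulerConvention,
    EulerTriplet,
    euler_to_matrix,
    matrix_to_euler,
    to_relion_euler,
)

__all__ = [
    "DensityVolume",
    "ParticleAnnotation",
    "ParticleList",
    "read_volume",
    "write_volume",
    "particles_to_xml",
    "particles_from_xml",
    "particles_to_star",
    "particles_from_star",
    "convert_particles",
]

_SCORE_SLACK = 1e-6


@dataclass
class DensityVolume:
    """A 3D scalar grid with an isotropic voxel size in Angstrom.

    ``data`` is indexed ``[x, y, z]``; voxel (0, 0, 0) sits at the grid
    corner.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a non-empty 3D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.data.copy(), self.voxel_size)


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC2014 map; the voxel size comes from the cell parameters.

    Raises ``ValueError`` for anisotropic voxels and ``RuntimeError``/
    ``OSError`` for missing or corrupt files.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such map: {path}")
    ccp4 = gemmi.read_ccp4_map(str(path))
    grid = ccp4.grid
    spac = (grid.spacing[0], grid.spacing[1], grid.spacing[2])
    if max(spac) - min(spac) > 1e-4 * max(spac):
        raise ValueError(f"anisotropic voxel size in cell header: {spac}")
    data = np.array(grid, copy=True).astype(np.float64, copy=False)
    return DensityVolume(data=data, voxel_size=float(spac[0]))


def write_volume(volume: DensityVolume, path: str | Path) -> None:
    """Write an MRC2014 map (mode 2) with cell = dims * voxel_size and
    populated min/max/mean statistics."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    nx, ny, nz = volume.shape
    vs = volume.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(mode=2, update_stats=True)
    ccp4.write_ccp4_map(str(path))


# --------------------------------------------------------------------------
# Particle annotations


@dataclass
class ParticleAnnotation:
    """One detected (or planted) particle.

    Position is a 0-based voxel coordinate in the tomogram grid; the
    orientation rotates the template onto the particle (anticlockwise ZXZ);
    the score is the LCCmax at the position.
    """

    tomogram_id: str
    position: tuple[float, float, float]
    orientation: EulerTriplet
    score: float

    def __post_init__(self) -> None:
        if self.orientation.convention is not EulerConvention.ZXZ_ANTICLOCKWISE:
            raise ValueError("particle orientations are stored in ZXZ_ANTICLOCKWISE")
        if not -1.0 - _SCORE_SLACK <= self.score <= 1.0 + _SCORE_SLACK:
            raise ValueError(f"score {self.score} outside [-1, 1]")


@dataclass
class ParticleList:
    particles: list[ParticleAnnotation]
    tomogram_dims: tuple[int, int, int] | None = None
    voxel_size: float | None = None

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def __getitem__(self, i):
        return self.particles[i]

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.particles], dtype=float).reshape(-1, 3)

    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.particles], dtype=float)


# ---- XML -----------------------------------------------------------------

import xml.etree.ElementTree as _ET


def particles_to_xml(plist: ParticleList) -> str:
    """Serialize to the native XML schema: one <Particle> element per
    annotation with voxel coordinates and ZXZ-anticlockwise angles."""
    root = _ET.Element("ParticleList")
    if plist.voxel_size is not None:
        root.set("VoxelSize", repr(float(plist.voxel_size)))
    if plist.tomogram_dims is not None:
        root.set("TomogramDims", " ".join(str(int(d)) for d in plist.tomogram_dims))
    for p in plist.particles:
        el = _ET.SubElement(root, "Particle")
        el.set("Tomogram", p.tomogram_id)
        el.set("X", repr(float(p.position[0])))
        el.set("Y", repr(float(p.position[1])))
        el.set("Z", repr(float(p.position[2])))
        el.set("Phi", repr(float(p.orientation.phi)))
        el.set("Theta", repr(float(p.orientation.theta)))
        el.set("Psi", repr(float(p.orientation.psi)))
        el.set("Score", repr(float(p.score)))
    _ET.indent(root)
    return _ET.tostring(root, encoding="unicode", xml_declaration=True)


def particles_from_xml(text: str) -> ParticleList:
    root = _ET.fromstring(text)
    if root.tag != "ParticleList":
        raise ValueError(f"unexpected XML root element: {root.tag!r}")
    voxel_size = float(root.get("VoxelSize")) if root.get("VoxelSize") else None
    dims = None
    if root.get("TomogramDims"):
        dims = tuple(int(v) for v in root.get("TomogramDims").split())
    particles = []
    for el in root.findall("Particle"):
        particles.append(
            ParticleAnnotation(
                tomogram_id=el.get("Tomogram", ""),
                position=(float(el.get("X")), float(el.get("Y")), float(el.get("Z"))),
                orientation=EulerTriplet(
                    float(el.get("Phi")), float(el.get("Theta")), float(el.get("Psi"))
                ),
                score=float(el.get("Score", "0")),
            )
        )
    return ParticleList(particles, tomogram_dims=dims, voxel_size=voxel_size)


# ---- STAR ----------------------------------------------------------------

_STAR_COLUMNS = [
    "rlnMicrographName",
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnAutopickFigureOfMerit",
]


def particles_to_star(plist: ParticleList, coordinate_unit: str = "voxel") -> str:
    """Serialize to a RELION 3.1-style STAR document (single data_ block).

    Orientations are converted to clockwise ZYZ (rlnAngleRot/Tilt/Psi);
    coordinates are written in voxels or, with ``coordinate_unit='angstrom'``,
    multiplied by the voxel size.
    """
    if coordinate_unit not in ("voxel", "angstrom"):
        raise ValueError(f"unknown coordinate unit: {coordinate_unit!r}")
    if coordinate_unit == "angstrom" and plist.voxel_size is None:
        raise ValueError("angstrom output requires the particle list voxel size")
    scale = plist.voxel_size if coordinate_unit == "angstrom" else 1.0
    rows = []
    for p in plist.particles:
        rel = to_relion_euler(p.orientation)
        rows.append(
            (
                p.tomogram_id,
                p.position[0] * scale,
                p.position[1] * scale,
                p.position[2] * scale,
                rel.phi,
                rel.theta,
                rel.psi,
                p.score,
            )
        )
    out = _io.StringIO()
    out.write("\ndata_\n\nloop_\n")
    for i, col in enumerate(_STAR_COLUMNS, start=1):
        out.write(f"_{col} #{i}\n")
    for row in rows:
        # full-precision floats keep the conversion lossless
        out.write(f"{row[0]}\t" + "\t".join(repr(float(v)) for v in row[1:]) + "\n")
    return out.getvalue()


def _parse_star_block(text: str) -> pd.DataFrame:
    """Minimal parser for a single loop_ STAR block."""
    lines = [ln.strip() for ln in text.splitlines()]
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("data_"):
            continue
        if ln == "loop_":
            in_loop = True
            columns, rows = [], []
            continue
        if in_loop and ln.startswith("_"):
            columns.append(ln.split()[0].lstrip("_"))
            continue
        if in_loop:
            fields = ln.split()
            if len(fields) != len(columns):
                raise ValueError(f"STAR row has {len(fields)} fields, expected {len(columns)}")
            rows.append(fields)
    if not columns:
        raise ValueError("no loop_ block found in STAR document")
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        if col != "rlnMicrographName":
            df[col] = pd.to_numeric(df[col])
    return df


def particles_from_star(
    text: str,
    coordinate_unit: str = "voxel",
    voxel_size: float | None = None,
) -> ParticleList:
    """Parse a RELION 3.1-style STAR document back into a particle list.

    ``coordinate_unit`` states the unit the coordinates were written in;
    angstrom coordinates are divided by ``voxel_size`` to recover voxels.
    """
    if coordinate_unit not in ("voxel", "angstrom"):
        raise ValueError(f"unknown coordinate unit: {coordinate_unit!r}")
    if coordinate_unit == "angstrom" and voxel_size is None:
        raise ValueError("angstrom input requires a voxel size")
    df = _parse_star_block(text)
    required = {"rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"STAR document lacks columns: {sorted(missing)}")
    scale = 1.0 / voxel_size if coordinate_unit == "angstrom" else 1.0
    particles = []
    for _, row in df.iterrows():
        rel = EulerTriplet(
            float(row.get("rlnAngleRot", 0.0)),
            float(row.get("rlnAngleTilt", 0.0)),
            float(row.get("rlnAnglePsi", 0.0)),
            EulerConvention.ZYZ_CLOCKWISE,
        )
        native = matrix_to_euler(euler_to_matrix(rel), EulerConvention.ZXZ_ANTICLOCKWISE)
        particles.append(
            ParticleAnnotation(
                tomogram_id=str(row.get("rlnMicrographName", "")),
                position=(
                    float(row["rlnCoordinateX"]) * scale,
                    float(row["rlnCoordinateY"]) * scale,
                    float(row["rlnCoordinateZ"]) * scale,
                ),
                orientation=native,
                score=float(row.get("rlnAutopickFigureOfMerit", 0.0)),
            )
        )
    return ParticleList(particles, voxel_size=voxel_size)


def convert_particles(
    document: str,
    direction: str,
    coordinate_unit: str = "voxel",
    voxel_size: float | None = None,
) -> str:
    """Convert a serialized particle list between the XML and STAR formats.

    ``direction`` is ``'xml_to_star'`` or ``'star_to_xml'``.  The conversion
    is lossless up to the Euler-convention round trip.
    """
    if direction == "xml_to_star":
        plist = particles_from_xml(document)
        if voxel_size is not None:
            plist = replace(plist, voxel_size=voxel_size)
        return particles_to_star(plist, coordinate_unit=coordinate_unit)
    if direction == "star_to_xml":
        plist = particles_from_star(document, coordinate_unit=coordinate_unit, voxel_size=voxel_size)
        return particles_to_xml(plist)
    raise ValueError(f"unknown conversion direction: {direction!r}")
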