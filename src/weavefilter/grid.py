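"""Binary voxel geometry: the container every pipeline stage consumes.

A :class:`VoxelGrid` is a cubic-lattice occupancy array (1 = solid fiber,
0 = air) with a physical voxel pitch in micrometers and a record of which
z-slices contain the fabric.  The flow solver treats ``z`` as the through-
fabric (breathing) direction and ``x``/``y`` as the in-plane, periodic
directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class VoxelGrid:
    """Binary solid/air occupancy on a cubic lattice.

    Parameters
    ----------
    occupancy
        ``(n_x, n_y, n_z)`` array, strictly binary; 1 marks fiber voxels.
    voxel_pitch
        Physical side length of one cubic voxel, in micrometers.
    fabric_z_range
        Half-open slice-index interval ``(z_lo, z_hi)`` bounding the solid
        region along ``z``.  Computed from the occupancy when omitted.
    meta
        Free-form provenance (generator parameters, scale factors, ...).
    """

    occupancy: np.ndarray
    voxel_pitch: float
    fabric_z_range: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3 or min(occ.shape) < 1:
            raise ValueError("occupancy must be a non-empty 3D array")
        vals = np.unique(occ)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("occupancy must be strictly binary (0/1)")
        self.occupancy = occ.astype(np.uint8)
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        if self.fabric_z_range is None:
            self.fabric_z_range = self._solid_z_range()
        z_lo, z_hi = self.fabric_z_range
        if not (0 <= z_lo <= z_hi <= self.occupancy.shape[2]):
            raise ValueError("fabric_z_range outside the grid")
        self.fabric_z_range = (int(z_lo), int(z_hi))

    def _solid_z_range(self) -> tuple[int, int]:
        solid_per_slice = self.occupancy.sum(axis=(0, 1))
        nz = np.nonzero(solid_per_slice)[0]
        if nz.size == 0:
            return (0, 0)
        return (int(nz[0]), int(nz[-1]) + 1)

    # -- derived geometry ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def fabric_thickness_um(self) -> float:
        """Extent of ``fabric_z_range`` in micrometers (L_F)."""
        z_lo, z_hi = self.fabric_z_range
        return (z_hi - z_lo) * self.voxel_pitch

    @property
    def fabric_thickness_lattice(self) -> int:
        z_lo, z_hi = self.fabric_z_range
        return z_hi - z_lo

    def solid_fraction(self, z_range: tuple[int, int] | None = None) -> float:
        """Fraction of solid voxels, optionally restricted to a z interval."""
        if z_range is None:
            z_range = self.fabric_z_range
        z_lo, z_hi = z_range
        if z_hi <= z_lo:
            return 0.0
        sub = self.occupancy[:, :, z_lo:z_hi]
        return float(sub.mean())


def porosity_profile(grid: VoxelGrid) -> tuple[np.ndarray, float]:
    """Per-slice solid fraction alpha(z) and its mean inside the fabric.

    alpha(z) is the fraction of voxels in slice ``z`` that are fiber voxels
    (averaged over x and y).  The mean is taken over ``fabric_z_range``.
    """
    alpha = grid.occupancy.mean(axis=(0, 1)).astype(float)
    z_lo, z_hi = grid.fabric_z_range
    mean_alpha = float(alpha[z_lo:z_hi].mean()) if z_hi > z_lo else 0.0
    return alpha, mean_alpha


# -- I/O ---------------------------------------------------------------------

def save_grid(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as a multi-page TIFF stack plus a JSON sidecar.

    Slices are stored along the first TIFF page axis (one page per z-slice,
    slice 0 first) so the stack round-trips through ordinary image viewers.
    The sidecar ``<stem>.json`` carries the pitch and fabric z-range.
    """
    import tifffile

    path = Path(path)
    # pages: (nz, ny, nx) — image convention is (row=y, col=x)
    pages = np.transpose(grid.occupancy, (2, 1, 0)) * np.uint8(255)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "voxel_pitch_um": grid.voxel_pitch,
        "fabric_z_range": list(grid.fabric_z_range),
        "shape_xyz": list(grid.shape),
    }))


def load_grid(path: str | Path) -> VoxelGrid:
    """Read a grid written by :func:`save_grid`."""
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    occ = (np.transpose(pages, (2, 1, 0)) > 0).astype(np.uint8)
    sidecar = path.with_suffix(".json")
    pitch, z_range = 1.0, None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pitch = float(meta.get("voxel_pitch_um", 1.0))
        if "fabric_z_range" in meta:
            z_range = tuple(meta["fabric_z_range"])
    return VoxelGrid(occ, pitch, z_range)


def write_vtk_imagedata(path: str | Path, pitch_um: float,
                        scalars: dict[str, np.ndarray] | None = None,
                        vectors: dict[str, np.ndarray] | None = None) -> None:
    """Write point data on a cubic lattice as legacy-ASCII VTK STRUCTURED_POINTS.

    Plain-text writer for visualization in ParaView; arrays are indexed
    ``(nx, ny, nz)`` and serialized in VTK's x-fastest point order.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    arrays = list(scalars.values()) + list(vectors.values())
    if not arrays:
        raise ValueError("nothing to write")
    nx, ny, nz = arrays[0].shape[:3]
    lines = [
        "# vtk DataFile Version 3.0",
        "weavefilter field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {pitch_um} {pitch_um} {pitch_um}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in scalars.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    for name, arr in vectors.items():
        lines.append(f"VECTORS {name} float")
        flat = np.asarray(arr, dtype=float).transpose(2, 1, 0, 3).reshape(-1, 3)
        lines.extend(" ".join(f"{v:.6g}" for v in row) for row in flat)
    Path(path).write_text("\n".join(lines) + "\n")


def save_grid_vtk(grid: VoxelGrid, path: str | Path) -> None:
    """Export occupancy as legacy-ASCII VTK for 3D rendering."""
    write_vtk_imagedata(path, grid.voxel_pitch,
                        scalars={"occupancy": grid.occupancy.astype(float)})
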