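"""Segmentation of a 3D grayscale confocal stack into a binary fiber grid.

The pipeline converts a fluorescence confocal stack of dyed fabric into the
solid/air voxel geometry the flow solver needs, in four steps applied in
order:

1. zero the fiber intensity in the lowest-quality bottom slices (signal
   attenuates with depth);
2. pad the stack with all-zero slices above and below, so the simulation
   box includes the approach and exit flow regions;
3. blur with a separable 3D Gaussian (sigma in voxels) to suppress
   single-voxel noise before thresholding;
4. binarize at a fixed intensity threshold, label 26-connected components,
   and delete clusters at or below a minimum size (isolated specks cannot
   be fabric: real fabric is one connected structure, and after this filter
   nearly all solid voxels belong to the largest cluster).

The pipeline is linear before binarization, so rescaling intensities by a
factor gamma together with the threshold leaves the result unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid


@dataclass
class IntensityStack:
    """Raw grayscale stack: (n_x, n_y, n_z) non-negative intensities,
    isotropic voxel pitch in micrometers (slice 0 = top)."""

    intensities: np.ndarray
    voxel_pitch: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError("intensities must be 3D (x, y, z)")
        if np.issubdtype(arr.dtype, np.floating) and (arr < 0).any():
            raise ValueError("intensities must be non-negative")
        self.intensities = arr
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ImagePipelineParams:
    """Segmentation parameters; defaults reproduce the reference pipeline."""

    n_bottom_slices_dropped: int = 10
    n_pad_slices: int = 200
    blur_sigma: float = 1.0
    threshold: float = 10.0
    min_cluster: int = 25

    def __post_init__(self) -> None:
        if self.n_bottom_slices_dropped < 0 or self.n_pad_slices < 0 \
                or self.blur_sigma < 0 or self.min_cluster < 0:
            raise ValueError("pipeline parameters must be non-negative")


_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=np.uint8)


def load_stack(path: str | Path, voxel_pitch: float | None = None) -> IntensityStack:
    """Read a multi-page TIFF or a directory of ordered 2D slice images.

    Page/file order is slice order (slice 0 = top).  The pitch is read from
    a JSON sidecar (``<stem>.json`` or ``meta.json`` with key
    ``voxel_pitch_um``) unless given explicitly.
    """
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise FileNotFoundError(f"no slice images in {path}")
        slices = []
        for f in files:
            if f.suffix.lower() in (".tif", ".tiff"):
                img = tifffile.imread(f)
            else:
                import imageio.v3 as iio
                img = iio.imread(f)
                if img.ndim == 3:   # collapse RGB(A) to one channel
                    img = img[..., 0]
            slices.append(np.asarray(img))
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes: {shapes}")
        pages = np.stack(slices)
        sidecar = path / "meta.json"
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        sidecar = path.with_suffix(".json")

    if voxel_pitch is None:
        if sidecar.exists():
            voxel_pitch = float(json.loads(sidecar.read_text())
                                ["voxel_pitch_um"])
        else:
            raise ValueError("voxel pitch not given and no sidecar found")
    # pages are (z, y, x) image convention -> (x, y, z)
    intensities = np.transpose(pages, (2, 1, 0))
    return IntensityStack(intensities, voxel_pitch)


def save_stack(stack: IntensityStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF with a pitch sidecar (round-trips
    through :func:`load_stack`)."""
    import tifffile

    path = Path(path)
    pages = np.transpose(stack.intensities, (2, 1, 0))
    tifffile.imwrite(path, pages)
    path.with_suffix(".json").write_text(
        json.dumps({"voxel_pitch_um": stack.voxel_pitch}))


def preprocess(stack: IntensityStack,
               params: ImagePipelineParams | None = None) -> VoxelGrid:
    """Run the four segmentation steps and return the binary grid.

    The bottom slices (largest z indices) are zeroed in place, not removed,
    so the output depth is n_z + 2 * n_pad_slices.  Blurring uses zero
    padding outside the array, consistent with the stack being embedded in
    empty air.  Components are 26-connected; clusters of size
    <= ``min_cluster`` are deleted.
    """
    params = params or ImagePipelineParams()
    arr = np.asarray(stack.intensities, dtype=np.float64).copy()
    nb = params.n_bottom_slices_dropped
    if nb > 0:
        arr[:, :, arr.shape[2] - nb:] = 0.0
    npad = params.n_pad_slices
    if npad > 0:
        arr = np.pad(arr, ((0, 0), (0, 0), (npad, npad)))
    if params.blur_sigma > 0:
        arr = ndimage.gaussian_filter(arr, sigma=params.blur_sigma,
                                      mode="constant", cval=0.0)
    binary = (arr >= params.threshold).astype(np.uint8)
    binary = remove_small_clusters(binary, params.min_cluster)
    return VoxelGrid(binary, stack.voxel_pitch)


def remove_small_clusters(binary: np.ndarray, min_cluster: int,
                          return_stats: bool = False):
    """Delete 26-connected components of size <= ``min_cluster`` voxels."""
    labels, n = ndimage.label(binary, structure=_CONNECTIVITY_26)
    if n == 0:
        return (binary, {}) if return_stats else binary
    sizes = np.bincount(labels.ravel())
    keep = sizes > min_cluster
    keep[0] = False
    out = keep[labels].astype(np.uint8)
    if return_stats:
        kept = int(sizes[1:][keep[1:]].sum())
        deleted = int(sizes[1:][~keep[1:]].sum())
        largest = int(sizes[1:].max()) if n else 0
        stats = {"n_clusters": int(n), "kept_voxels": kept,
                 "deleted_voxels": deleted, "largest_cluster": largest}
        return out, stats
    return out


def crop_region(grid: VoxelGrid, x0: int, y0: int, nx: int, ny: int,
                z0: int = 0, nz: int | None = None) -> VoxelGrid:
    """Extract the sub-grid [x0:x0+nx, y0:y0+ny, z0:z0+nz]; the fabric
    z-range is recomputed from the cropped occupancy."""
    gx, gy, gz = grid.shape
    if nz is None:
        nz = gz - z0
    if not (0 <= x0 and x0 + nx <= gx and 0 <= y0 and y0 + ny <= gy
            and 0 <= z0 and z0 + nz <= gz and nx > 0 and ny > 0 and nz > 0):
        raise ValueError("crop box outside the grid")
    sub = grid.occupancy[x0:x0 + nx, y0:y0 + ny, z0:z0 + nz].copy()
    return VoxelGrid(sub, grid.voxel_pitch)


def threshold_sensitivity(stack: IntensityStack, params: ImagePipelineParams,
                          thresholds) -> dict[float, int]:
    """Fiber-voxel count as a function of the binarization threshold.

    Diagnostic report for the ~10% volume uncertainty that the choice of
    threshold induces; not an assertion.
    """
    out = {}
    for t in thresholds:
        p = ImagePipelineParams(
            n_bottom_slices_dropped=params.n_bottom_slices_dropped,
            n_pad_slices=params.n_pad_slices, blur_sigma=params.blur_sigma,
            threshold=float(t), min_cluster=params.min_cluster)
        out[float(t)] = int(preprocess(stack, p).occupancy.sum())
    return out
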