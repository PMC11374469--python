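"""Imaging-graph construction from tessellated slide images.

A slide (or synthetic grid) becomes an undirected graph IG = (H, A): nodes
are foreground tissue patches carrying a C-dimensional feature vector, and
edges connect patches that are adjacent on the patch grid (4- or
8-connectivity). Every node must have degree >= 1 and can have at most 8
neighbours; isolated patches are dropped with a warning rather than
force-connected.

Foreground/background separation runs on a downsampled thumbnail: Otsu
thresholding of the HSV saturation channel (tissue is stained, background
glass is unsaturated). Graphs are serialized one-per-slide to an HDF5
container with datasets ``H`` (float32), ``A_indices`` (COO int64 pairs) and
``coords``, plus ``patch_size`` / ``slide_id`` attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, EmptyGraphError, GraphFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ImagingGraph", "PatchGrid", "foreground_mask", "tessellate",
    "build_adjacency", "build_graph", "save_graph", "load_graph", "read_image",
]

MAX_DEGREE = 8  # a grid patch has at most 8 touching neighbours


@dataclass
class ImagingGraph:
    """Node feature matrix H (N x C) plus binary adjacency A (N x N)."""

    node_features: np.ndarray
    adjacency: sp.spmatrix
    coords: np.ndarray
    patch_size: int = 256
    slide_id: str = ""

    def __post_init__(self):
        self.node_features = np.ascontiguousarray(self.node_features,
                                                  dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.adjacency = sp.csr_matrix(self.adjacency, dtype=np.int8)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.node_features.shape[1]

    def validate(self) -> None:
        a = self.adjacency
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ConfigurationError("adjacency shape does not match node count")
        if (a != a.T).nnz != 0:
            raise ConfigurationError("adjacency is not symmetric")
        if a.diagonal().any():
            raise ConfigurationError("adjacency has nonzero diagonal")
        deg = np.asarray(a.sum(axis=1)).ravel()
        if self.n_nodes and (deg.min() < 1 or deg.max() > MAX_DEGREE):
            raise ConfigurationError(
                f"node degrees must lie in [1, {MAX_DEGREE}], "
                f"got [{deg.min()}, {deg.max()}]")
        if len(np.unique(self.coords, axis=0)) != self.n_nodes:
            raise ConfigurationError("node coords are not unique")


@dataclass
class PatchGrid:
    """Tessellation result: image tiles, grid coords, foreground flags."""

    patches: list = field(default_factory=list)
    coords: list = field(default_factory=list)
    foreground_flags: list = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.patches) == len(self.coords) == len(self.foreground_flags)):
            raise ConfigurationError("patch/coord/flag lists differ in length")

    @property
    def n_foreground(self) -> int:
        return int(np.sum(self.foreground_flags))


def read_image(path) -> np.ndarray:
    """Load a plain PNG/TIFF image as an RGB uint8 array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3]


def foreground_mask(image: np.ndarray, threshold_method: str = "otsu",
                    downsample: int = 32, fixed_threshold: float = 0.05
                    ) -> np.ndarray:
    """Tissue mask on a ``downsample``-x thumbnail of the slide.

    Tissue on an H&E slide is saturated (pink/purple) while the glass
    background is near-white, so thresholding the HSV saturation channel
    separates the two. ``threshold_method`` is ``otsu`` or ``fixed``.
    """
    from skimage.color import rgb2hsv
    from skimage.filters import threshold_otsu

    if image.size == 0:
        raise ConfigurationError("empty image")
    thumb = image[::downsample, ::downsample]
    sat = rgb2hsv(thumb.astype(np.float64) / 255.0
                  if thumb.dtype != np.float64 else thumb)[..., 1]
    if threshold_method == "fixed":
        return sat > fixed_threshold
    if threshold_method != "otsu":
        raise ConfigurationError(f"unknown threshold method {threshold_method!r}")
    if sat.max() - sat.min() < 1e-6:
        # uniform thumbnail: Otsu undefined; classify by absolute saturation
        return np.full(sat.shape, sat.mean() > fixed_threshold)
    return sat > threshold_otsu(sat)


def tessellate(image: np.ndarray, patch_size: int, mask: np.ndarray,
               coverage: float = 0.5) -> PatchGrid:
    """Cut the image into a row-major grid of ``patch_size`` tiles.

    A tile is flagged foreground when the fraction of tissue-mask pixels
    under it is >= ``coverage``. Remainder rows/columns are truncated.
    """
    h, w = image.shape[:2]
    n_rows, n_cols = h // patch_size, w // patch_size
    if n_rows == 0 or n_cols == 0:
        raise EmptyGraphError(
            f"patch_size {patch_size} larger than image {h}x{w}")
    # mask lives on a thumbnail; map tile extents into mask coordinates
    sy = mask.shape[0] / h
    sx = mask.shape[1] / w
    patches, coords, flags = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            tile = image[r * patch_size:(r + 1) * patch_size,
                         c * patch_size:(c + 1) * patch_size]
            m0, m1 = int(np.floor(r * patch_size * sy)), int(np.ceil((r + 1) * patch_size * sy))
            n0, n1 = int(np.floor(c * patch_size * sx)), int(np.ceil((c + 1) * patch_size * sx))
            sub = mask[m0:max(m1, m0 + 1), n0:max(n1, n0 + 1)]
            patches.append(tile)
            coords.append((r, c))
            flags.append(bool(sub.mean() >= coverage))
    return PatchGrid(patches, coords, flags)


def build_adjacency(coords, connectivity: int = 8) -> sp.csr_matrix:
    """Binary adjacency over grid coordinates.

    8-connectivity links coords at Chebyshev distance 1, 4-connectivity at
    Manhattan distance 1. Symmetric with zero diagonal.
    """
    if connectivity not in (4, 8):
        raise ConfigurationError(f"connectivity must be 4 or 8, got {connectivity}")
    coords = np.asarray(coords, dtype=np.int64)
    n = len(coords)
    if len(np.unique(coords, axis=0)) != n:
        raise ConfigurationError("coords must be unique")
    index = {tuple(rc): i for i, rc in enumerate(coords)}
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    rows, cols = [], []
    for i, (r, c) in enumerate(coords):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    a = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                      shape=(n, n))
    return a


def build_graph(grid: PatchGrid, features: np.ndarray, connectivity: int = 8,
                patch_size: int = 256, slide_id: str = "") -> ImagingGraph:
    """Assemble the imaging-graph over foreground patches.

    ``features`` must have one row per foreground patch, in row-major patch
    order. Nodes left with degree zero are dropped (warned), enforcing the
    degree >= 1 invariant.
    """
    fg = np.asarray(grid.foreground_flags, dtype=bool)
    if fg.sum() == 0:
        raise EmptyGraphError(f"slide {slide_id!r}: no foreground patches")
    features = np.asarray(features)
    if features.shape[0] != fg.sum():
        raise ConfigurationError(
            f"feature rows ({features.shape[0]}) != foreground patches ({fg.sum()})")
    coords = np.asarray(grid.coords, dtype=np.int64)[fg]
    adjacency = build_adjacency(coords, connectivity)
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    keep = degrees >= 1
    if not keep.all():
        logger.warning("slide %r: dropping %d isolated node(s)",
                       slide_id, int((~keep).sum()))
        coords = coords[keep]
        features = features[keep]
        adjacency = adjacency[keep][:, keep]
    if coords.shape[0] < 2:
        raise EmptyGraphError(
            f"slide {slide_id!r}: fewer than 2 connected nodes")
    graph = ImagingGraph(features, adjacency, coords, patch_size, slide_id)
    graph.validate()
    return graph


def save_graph(graph: ImagingGraph, path) -> None:
    """Write the HDF5 graph container (H float32, COO adjacency, coords)."""
    coo = graph.adjacency.tocoo()
    indices = np.stack([coo.row, coo.col], axis=1).astype(np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("H", data=graph.node_features.astype(np.float32))
        f.create_dataset("A_indices", data=indices)
        f.create_dataset("coords", data=graph.coords)
        f.attrs["patch_size"] = graph.patch_size
        f.attrs["slide_id"] = graph.slide_id


def load_graph(path) -> ImagingGraph:
    """Read the HDF5 graph container written by :func:`save_graph`."""
    with h5py.File(path, "r") as f:
        for name in ("H", "A_indices", "coords"):
            if name not in f:
                raise GraphFormatError(f"{path}: missing dataset {name!r}")
        h = f["H"][...]
        indices = f["A_indices"][...]
        coords = f["coords"][...]
        patch_size = int(f.attrs.get("patch_size", 256))
        slide_id = str(f.attrs.get("slide_id", ""))
    n = h.shape[0]
    a = sp.csr_matrix((np.ones(len(indices), dtype=np.int8),
                       (indices[:, 0], indices[:, 1])), shape=(n, n))
    return ImagingGraph(h, a, coords, patch_size, slide_id)
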