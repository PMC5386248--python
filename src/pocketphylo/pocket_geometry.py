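"""Grid-based two-probe pocket detection on a structure model.

The method belongs to the LIGSITE/POCASA family: space is voxelised, a
voxel is *blocked* for a probe of radius ``p`` when its centre lies within
``vdW(element) + p`` of any atom centre, and pockets are the regions a small
probe (1.4 Å, water-sized) can occupy but a large "closure" probe cannot
reach by rolling in from the outside. Concretely:

* ``exterior(probe_large)`` — the large-probe centre positions connected to
  the grid boundary (6-connected flood fill);
* the large-probe *accessible* region in small-probe-centre space is that
  exterior dilated by ``probe_large - probe_small`` (the rolling closure);
* the *envelope* is its complement, and pocket candidates are envelope
  voxels that are unblocked for the small probe;
* pockets are the 6-connected components of the candidate set, their volume
  is ``count * h^3``, mouths are voxels touching the accessible exterior,
  and a pocket with no mouth is *enclosed* (an interior cavity).

Depth is a geodesic (within-pocket) distance in Å: for an open pocket the
maximum over voxels of the 26-connected Euclidean-cost distance to the
nearest mouth voxel; for an enclosed pocket half the maximum geodesic
diameter (estimated by iterated farthest-point sweeps).

The closure scale ``probe_large`` bounds the mouth aperture a pocket may
have: concavities wider than the large probe are rolled over and therefore
not reported. Absolute volumes are not comparable to alpha-shape methods
(CASTp); only relative comparisons across structures are meaningful here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError, NoPocketError
from .io_formats import StructureModel

#: van der Waals radii (Å) by element; unknown elements fall back to carbon.
DEFAULT_VDW = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}
VDW_FALLBACK = 1.70

_FACES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class GridParams:
    """Grid and probe parameters for pocket detection (distances in Å)."""

    spacing: float = 0.6
    probe_small: float = 1.4
    probe_large: float = 4.0
    vdw_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW))
    min_volume: float = 25.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise GeometryError("grid spacing must be positive")
        if not self.probe_small < self.probe_large:
            raise GeometryError("probe_small must be smaller than probe_large")

    def vdw(self, element: str) -> float:
        return self.vdw_table.get(element.capitalize(),
                                  self.vdw_table.get(element.upper(), VDW_FALLBACK))

    @property
    def padding(self) -> float:
        max_vdw = max(self.vdw_table.values()) if self.vdw_table else VDW_FALLBACK
        return self.probe_large + max_vdw + 2 * self.spacing


@dataclass
class Grid:
    """A voxel grid anchored at ``origin`` with cubic spacing ``h``."""

    origin: np.ndarray
    shape: tuple[int, int, int]
    h: float

    def centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.h * np.arange(self.shape[axis])

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin[None, :] + self.h * np.asarray(indices, dtype=float)


@dataclass
class Pocket:
    """A detected pocket: voxel indices, volume, mouth, depth and lining."""

    pocket_id: int
    voxels: np.ndarray           # (n, 3) int indices into the grid
    grid: Grid
    volume: float                # |voxels| * h^3, Å^3
    mouth_voxels: np.ndarray     # (m, 3) subset of voxels on the mouth
    enclosed: bool
    depth: float | None = None
    lining_residues: set[tuple[str, int]] | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def _coords_and_radii(structure: StructureModel, params: GridParams):
    coords = np.array([[a.x, a.y, a.z] for a in structure.atoms])
    radii = np.array([params.vdw(a.element) for a in structure.atoms])
    return coords, radii


def make_grid(structure: StructureModel, params: GridParams) -> Grid:
    coords, _ = _coords_and_radii(structure, params)
    lo = coords.min(axis=0) - params.padding
    hi = coords.max(axis=0) + params.padding
    span = hi - lo
    if np.any(span <= 0):
        raise GeometryError("degenerate grid: structure bounding box collapsed")
    shape = tuple(int(np.ceil(s / params.spacing)) + 1 for s in span)
    return Grid(origin=lo, shape=shape, h=params.spacing)


def blocked_mask(
    structure: StructureModel, params: GridParams, probe: float,
    grid: Grid | None = None,
) -> np.ndarray:
    """Boolean mask of voxels whose centre is within vdW+probe of an atom."""
    if not structure.atoms:
        raise GeometryError("structure has no atoms")
    if grid is None:
        grid = make_grid(structure, params)
    coords, radii = _coords_and_radii(structure, params)
    mask = np.zeros(grid.shape, dtype=bool)
    ax = [grid.centers_axis(i) for i in range(3)]
    # per-atom local boxes: cheap and exact
    for (cx, cy, cz), r in zip(coords, radii):
        rr = r + probe
        i0 = np.searchsorted(ax[0], cx - rr, side="left")
        i1 = np.searchsorted(ax[0], cx + rr, side="right")
        j0 = np.searchsorted(ax[1], cy - rr, side="left")
        j1 = np.searchsorted(ax[1], cy + rr, side="right")
        k0 = np.searchsorted(ax[2], cz - rr, side="left")
        k1 = np.searchsorted(ax[2], cz + rr, side="right")
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx2 = (ax[0][i0:i1] - cx) ** 2
        dy2 = (ax[1][j0:j1] - cy) ** 2
        dz2 = (ax[2][k0:k1] - cz) ** 2
        local = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) < rr * rr
        mask[i0:i1, j0:j1, k0:k1] |= local
    return mask


_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def exterior_region(mask: np.ndarray, connectivity: int = 1) -> np.ndarray:
    """Unblocked voxels flood-connected to any boundary face of the grid.

    ``connectivity`` 1 = 6-connected (default), 3 = 26-connected; the
    large-probe exterior uses 26-connectivity because its narrow dips over
    pocket mouths are often only diagonally voxel-connected.
    """
    free = ~mask
    struct = _STRUCT26 if connectivity == 3 else _STRUCT6
    labels, _ = ndimage.label(free, structure=struct)
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border_labels.update(np.unique(face[face > 0]).tolist())
    if not border_labels:
        return np.zeros_like(mask)
    return np.isin(labels, sorted(border_labels))


def detect_pockets(
    structure: StructureModel, params: GridParams | None = None,
) -> list[Pocket]:
    """Detect pockets; returns them sorted by volume, largest first."""
    params = params or GridParams()
    if not structure.atoms:
        raise GeometryError("structure has no atoms")
    grid = make_grid(structure, params)
    blocked_small = blocked_mask(structure, params, params.probe_small, grid)
    blocked_large = blocked_mask(structure, params, params.probe_large, grid)
    ext_large = exterior_region(blocked_large, connectivity=3)
    # rolling closure: dilate the large-probe exterior into small-probe
    # space; the half-voxel term compensates the centre-sampling of the
    # exterior (its true boundary lies up to h*sqrt(3)/2 beyond the
    # represented voxel centres)
    dilate_r = (params.probe_large - params.probe_small
                + 0.5 * math.sqrt(3.0) * params.spacing)
    dist_to_ext = ndimage.distance_transform_edt(
        ~ext_large, sampling=params.spacing
    )
    accessible = dist_to_ext <= dilate_r + 1e-9
    candidate = ~accessible & ~blocked_small
    labels, n_labels = ndimage.label(candidate, structure=_STRUCT6)
    if n_labels == 0:
        return []
    ext_small = exterior_region(blocked_small)
    contact = accessible & ext_small
    # voxels 6-adjacent to the accessible exterior
    near_contact = ndimage.binary_dilation(contact, structure=_STRUCT6)
    pockets: list[Pocket] = []
    h3 = params.spacing ** 3
    for lab in range(1, n_labels + 1):
        comp = labels == lab
        volume = float(comp.sum()) * h3
        if volume < params.min_volume:
            continue
        mouth = comp & near_contact
        voxels = np.argwhere(comp)
        mouth_voxels = np.argwhere(mouth)
        enclosed = mouth_voxels.shape[0] == 0
        pockets.append(
            Pocket(
                pocket_id=0,
                voxels=voxels,
                grid=grid,
                volume=volume,
                mouth_voxels=mouth_voxels,
                enclosed=enclosed,
            )
        )
    pockets.sort(key=lambda p: -p.volume)
    for idx, p in enumerate(pockets):
        p.pocket_id = idx
        p.depth = pocket_depth(p, params)
        p.lining_residues = lining_residues(p, structure, params)
    return pockets


def _geodesic_from(seeds_mask: np.ndarray, region: np.ndarray, h: float):
    """26-connected geodesic distances (Å) from seed voxels within region."""
    from skimage.graph import MCP_Geometric

    costs = np.where(region, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    seeds = np.argwhere(seeds_mask)
    dist, _ = mcp.find_costs(seeds)
    return dist * h


def pocket_depth(pocket: Pocket, params: GridParams) -> float:
    """Pocket depth in Å (geodesic; see module docstring)."""
    if pocket.n_voxels <= 1:
        return 0.0
    region = np.zeros(pocket.grid.shape, dtype=bool)
    region[tuple(pocket.voxels.T)] = True
    if not pocket.enclosed:
        seeds = np.zeros_like(region)
        seeds[tuple(pocket.mouth_voxels.T)] = True
        dist = _geodesic_from(seeds, region, params.spacing)
        dist = dist[region]
        return float(dist[np.isfinite(dist)].max(initial=0.0))
    # enclosed: half the geodesic diameter, by iterated farthest-point sweeps
    start = np.zeros_like(region)
    start[tuple(pocket.voxels[0])] = True
    far = pocket.voxels[0]
    best = 0.0
    for _ in range(3):
        seeds = np.zeros_like(region)
        seeds[tuple(far)] = True
        dist = _geodesic_from(seeds, region, params.spacing)
        dist[~region | ~np.isfinite(dist)] = -1.0
        idx = np.unravel_index(np.argmax(dist), dist.shape)
        if dist[idx] <= best:
            break
        best = float(dist[idx])
        far = np.array(idx)
    return best / 2.0


def lining_residues(
    pocket: Pocket, structure: StructureModel, params: GridParams,
) -> set[tuple[str, int]]:
    """Residues with >=1 atom within vdW+probe_small+h of a pocket voxel."""
    if pocket.n_voxels == 0:
        return set()
    centers = pocket.grid.voxel_centers(pocket.voxels)
    tree = cKDTree(centers)
    out: set[tuple[str, int]] = set()
    for a in structure.atoms:
        key = (a.chain_id, a.residue_index)
        if key in out:
            continue
        cutoff = params.vdw(a.element) + params.probe_small + params.spacing
        if tree.query_ball_point([a.x, a.y, a.z], cutoff,
                                 return_length=True) > 0:
            out.add(key)
    return out


def select_catalytic_pocket(
    pockets: list[Pocket],
    anchor_residues: set[tuple[str, int]] | None = None,
) -> Pocket:
    """Pick the catalytic pocket: largest containing all anchors, else largest."""
    if not pockets:
        raise NoPocketError("no pockets detected")
    if not anchor_residues:
        return max(pockets, key=lambda p: p.volume)
    anchored = [
        p for p in pockets
        if p.lining_residues is not None
        and anchor_residues <= p.lining_residues
    ]
    if not anchored:
        raise NoPocketError(
            f"no pocket's lining contains all anchors {sorted(anchor_residues)}"
        )
    return max(anchored, key=lambda p: p.volume)
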