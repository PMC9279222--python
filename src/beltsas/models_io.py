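"""Atomic models in the membrane frame, excluded volumes and midplane curves.

The membrane frame convention used throughout the package: the
transmembrane (TM) axis is the z axis and the hydrophobic midplane is the
plane z = 0.  A protein is read from PDB, oriented so that the principal
axis of its TM selection lies along z with the TM centroid at z = 0, and
its excluded volume is rasterised on a cubic grid.  The surface grid
points of that volume at the z = 0 layer form a closed curve around the
protein circumference — the anchor on which the detergent corona is
built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .constants import DEFAULT_VDW_RADIUS, VDW_RADIUS


@dataclass
class AtomicModel:
    """Atomic coordinates with per-atom metadata.

    Attributes
    ----------
    positions : (N, 3) float array, Å
    elements : (N,) array of element symbols (upper case)
    electrons : (N,) float array, electron counts (atomic numbers, with
        hydrogen electrons folded into bonded heavy atoms when a file
        contained hydrogens)
    residue_index : (N,) int array
    chain_id : (N,) array of chain identifiers
    is_ca : (N,) bool array, True for Calpha atoms
    frame : "raw" or "membrane" — whether the model has been placed in
        the membrane frame
    """

    positions: np.ndarray
    elements: np.ndarray
    electrons: np.ndarray
    residue_index: np.ndarray
    chain_id: np.ndarray
    is_ca: np.ndarray
    frame: str = "raw"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.positions.shape[0] == 0:
            raise ValueError("empty model")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        self.elements = np.asarray(self.elements)
        self.electrons = np.asarray(self.electrons, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_id = np.asarray(self.chain_id)
        self.is_ca = np.asarray(self.is_ca, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def select_residues(self, ranges: list[tuple[int, int]]) -> np.ndarray:
        """Boolean mask of atoms whose residue index falls in any of the
        inclusive ``(start, stop)`` ranges."""
        mask = np.zeros(self.n_atoms, dtype=bool)
        for start, stop in ranges:
            mask |= (self.residue_index >= start) & (self.residue_index <= stop)
        return mask

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Return a copy with positions mapped through ``R x + t``."""
        pos = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, positions=pos)


@dataclass
class VolumeGrid:
    """Excluded volume of a model as occupied points on a cubic grid."""

    spacing: float
    points: np.ndarray  # (M, 3) occupied grid point positions, Å
    occupancy: np.ndarray = field(default=None)  # (nx, ny, nz) bool raster
    origin: np.ndarray = field(default=None)     # grid origin, Å

    @property
    def volume(self) -> float:
        """Volume estimate: occupied count × spacing³ (Å³)."""
        return self.points.shape[0] * self.spacing**3


@dataclass
class MidplaneCurve:
    """Ordered closed loop of surface points at the hydrophobic midplane."""

    points: np.ndarray  # (K, 3), all with |z| <= grid spacing
    closed: bool = True


def read_model(path, chain: str | None = None, model_index: int = 0) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel`.

    Hydrogens, when present, are removed and their electrons folded into
    the nearest heavy atom so that the total electron count is preserved.

    Parameters
    ----------
    path : str or Path
        PDB file with standard ATOM/HETATM records, coordinates in Å.
    chain : str, optional
        Restrict to one chain; default keeps all chains.
    model_index : int
        Which MODEL block to use for multi-model files.
    """
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise ValueError(f"empty model: no coordinates in {path}")
    model = structure[model_index]

    pos, elements, electrons, resi, chains, is_ca = [], [], [], [], [], []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            for atom in res:
                el = atom.element
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(el.name.upper())
                electrons.append(float(el.atomic_number))
                resi.append(res.seqid.num)
                chains.append(ch.name)
                is_ca.append(atom.name.strip() == "CA" and el.name.upper() == "C")
    if not pos:
        raise ValueError(f"empty model: no atoms selected from {path}")

    m = AtomicModel(
        positions=np.array(pos),
        elements=np.array(elements),
        electrons=np.array(electrons),
        residue_index=np.array(resi),
        chain_id=np.array(chains),
        is_ca=np.array(is_ca),
        frame="raw",
    )
    return _fold_hydrogens(m)


def _fold_hydrogens(model: AtomicModel) -> AtomicModel:
    """Drop H atoms, adding their electrons to the nearest heavy atom."""
    h_mask = model.elements == "H"
    if not h_mask.any():
        return model
    heavy = ~h_mask
    heavy_pos = model.positions[heavy]
    electrons = model.electrons[heavy].copy()
    for hp in model.positions[h_mask]:
        j = np.argmin(np.sum((heavy_pos - hp) ** 2, axis=1))
        electrons[j] += 1.0
    return AtomicModel(
        positions=heavy_pos,
        elements=model.elements[heavy],
        electrons=electrons,
        residue_index=model.residue_index[heavy],
        chain_id=model.chain_id[heavy],
        is_ca=model.is_ca[heavy],
        frame=model.frame,
    )


def orient_membrane_frame(
    model: AtomicModel, tm_selection: list[tuple[int, int]]
) -> AtomicModel:
    """Rigidly place a model in the membrane frame.

    The principal axis (largest-variance eigenvector of the coordinate
    covariance) of the transmembrane selection is rotated onto z, and the
    selection centroid is moved to z = 0 (x, y centred at the origin).
    The transform is rigid: all interatomic distances are preserved.

    Parameters
    ----------
    tm_selection : list of (start, stop) inclusive residue-index ranges
        defining the transmembrane span.
    """
    if not tm_selection:
        raise ValueError("tm_selection must be non-empty")
    mask = model.select_residues(tm_selection)
    if not mask.any():
        raise ValueError("tm_selection matches no atoms")
    sel = model.positions[mask]
    centroid = sel.mean(axis=0)
    cov = np.cov((sel - centroid).T)
    eigval, eigvec = np.linalg.eigh(cov)
    axis = eigvec[:, np.argmax(eigval)]
    if axis[2] < 0:
        axis = -axis

    rotation = _rotation_onto_z(axis)
    positions = (model.positions - centroid) @ rotation.T
    out = replace(model, positions=positions)
    out.frame = "membrane"
    return out


def _rotation_onto_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation taking a unit vector onto +z (Rodrigues)."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def excluded_volume(
    model: AtomicModel,
    spacing: float = 2.0,
    radii: dict[str, float] | None = None,
) -> VolumeGrid:
    """Rasterise the excluded volume of a model on a cubic grid.

    Each atom occupies every grid point within its van der Waals radius;
    the volume estimate is (occupied count) × spacing³.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    radii = radii or VDW_RADIUS
    rmax = max(
        radii.get(el, DEFAULT_VDW_RADIUS) for el in np.unique(model.elements)
    )
    lo = model.positions.min(axis=0) - rmax - spacing
    hi = model.positions.max(axis=0) + rmax + spacing
    if np.any(hi - lo < spacing):
        raise ValueError("spacing larger than model extent")
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    # keep the z = 0 plane on-grid so the midplane layer is well defined
    origin = lo - (lo[2] % spacing) * np.array([0.0, 0.0, 1.0])

    occ = np.zeros(n, dtype=bool)
    axes = [origin[d] + spacing * np.arange(n[d]) for d in range(3)]
    for el in np.unique(model.elements):
        r = radii.get(el, DEFAULT_VDW_RADIUS)
        k = int(np.ceil(r / spacing))
        for p in model.positions[model.elements == el]:
            idx = np.floor((p - origin) / spacing).astype(int)
            sl = []
            ranges = []
            for d in range(3):
                a = max(idx[d] - k, 0)
                b = min(idx[d] + k + 2, n[d])
                sl.append(slice(a, b))
                ranges.append(axes[d][a:b] - p[d])
            dx, dy, dz = np.meshgrid(*ranges, indexing="ij")
            occ[tuple(sl)] |= dx**2 + dy**2 + dz**2 <= r**2

    pts_idx = np.argwhere(occ)
    if pts_idx.shape[0] == 0:
        raise ValueError("no occupied grid points")
    points = origin + pts_idx * spacing
    return VolumeGrid(spacing=spacing, points=points, occupancy=occ, origin=origin)


def midplane_curve(grid: VolumeGrid) -> MidplaneCurve:
    """Extract the ordered closed curve of surface points at z = 0.

    The occupied grid layer nearest z = 0 is taken; its boundary points
    (occupied points with at least one unoccupied 4-neighbour within the
    layer) are ordered by polar angle about the layer centroid, ties
    broken by radius.  Requires occupied points on both sides of z = 0.
    """
    z = grid.points[:, 2]
    if z.min() > grid.spacing / 2 or z.max() < -grid.spacing / 2:
        raise ValueError("no midplane: model does not cross z = 0")
    if grid.occupancy is None or grid.origin is None:
        raise ValueError("grid lacks raster data")

    kz = int(round((0.0 - grid.origin[2]) / grid.spacing))
    kz = min(max(kz, 0), grid.occupancy.shape[2] - 1)
    layer = grid.occupancy[:, :, kz]
    if not layer.any():
        raise ValueError("no midplane: empty z = 0 layer")

    # boundary of the layer: occupied cell with an unoccupied 4-neighbour
    padded = np.pad(layer, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = layer & ~interior
    ij = np.argwhere(boundary)
    pts = grid.origin + np.column_stack(
        [ij[:, 0], ij[:, 1], np.full(len(ij), kz)]
    ) * grid.spacing

    center = pts[:, :2].mean(axis=0)
    d = pts[:, :2] - center
    angle = np.arctan2(d[:, 1], d[:, 0])
    radius = np.hypot(d[:, 0], d[:, 1])
    order = np.lexsort((radius, angle))
    return MidplaneCurve(points=pts[order], closed=True)
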