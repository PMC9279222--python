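"""Monte-Carlo detergent corona: geometry selection and contrast bookkeeping.

The detergent belt around a membrane protein is modelled as a
hydrocarbon core plus headgroup shell built from points randomly and
homogeneously distributed in a box.  Points within an (anisotropic)
distance R of the midplane curve become tail points; points between R
and R + D become headgroup points, provided they stay connected to the
core.  The tail core contains no water, so its volume — and from it the
number of detergent molecules N_DM — follows directly from the point
density; the headgroup shell is implicitly hydrated (only the fixed
total excess scattering of N_DM headgroups is distributed on its
points, however large its geometric volume).

Electron-density ordering for a maltoside detergent in aqueous buffer:
tail (81/294 ≈ 0.276 e/Å³) < buffer (0.340) < dry head (181/350 ≈ 0.517).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import constants as C
from .models_io import AtomicModel, MidplaneCurve


@dataclass
class DetergentSpec:
    """Per-molecule volumes, electron counts and molar mass of a detergent.

    Defaults describe n-decyl-beta-D-maltopyranoside (DM).
    """

    tail_volume: float = C.DM_TAIL_VOLUME
    head_dry_volume: float = C.DM_HEAD_DRY_VOLUME
    tail_electrons: float = C.DM_TAIL_ELECTRONS
    head_electrons: float = C.DM_HEAD_ELECTRONS
    molar_mass: float = C.DM_MOLAR_MASS

    def __post_init__(self) -> None:
        for name in ("tail_volume", "head_dry_volume", "tail_electrons",
                     "head_electrons", "molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def tail_excess(self, buffer_density: float) -> float:
        """Excess scattering length (e) of one tail vs buffer."""
        return self.tail_electrons - buffer_density * self.tail_volume

    def head_excess(self, buffer_density: float) -> float:
        """Excess scattering length (e) of one dry headgroup vs buffer."""
        return self.head_electrons - buffer_density * self.head_dry_volume


@dataclass
class SolventSpec:
    """Buffer electron density and hydration-layer defaults."""

    buffer_density: float = C.BUFFER_ELECTRON_DENSITY  # e/Å³
    hydration_thickness: float = 3.0                   # Å
    hydration_contrast: float = 0.03                   # e/Å³


@dataclass
class RimParams:
    """Core radii and shell thicknesses of the corona, x-y vs z resolved.

    R_xy, R_z (Å): core half-axes of the elliptical tube around the
    midplane curve. D_xy, D_z (Å): headgroup shell thicknesses; a shell
    thicker than 10 Å is not physically reasonable for a maltoside
    headgroup and is rejected.
    """

    R_xy: float
    R_z: float
    D_xy: float
    D_z: float

    def __post_init__(self) -> None:
        if self.R_xy <= 0 or self.R_z <= 0:
            raise ValueError("core radii must be positive")
        if not (0 < self.D_xy < 10 and 0 < self.D_z < 10):
            raise ValueError("shell thickness must be in (0, 10) Å")


@dataclass
class RimModel:
    """Selected corona point cloud with per-point excess scattering lengths."""

    tail_points: np.ndarray          # (Nt, 3) Å
    head_points: np.ndarray          # (Nh, 3) Å
    density: float                   # box point density, pts/Å³
    v_tail: float                    # Å³
    n_dm: int
    tail_b: np.ndarray = field(default=None)  # (Nt,) e
    head_b: np.ndarray = field(default=None)  # (Nh,) e

    def save_points(self, path) -> None:
        """Write the corona as a plain-text point cloud (x y z b)."""
        rows = []
        for pts, b in ((self.tail_points, self.tail_b),
                       (self.head_points, self.head_b)):
            if len(pts):
                rows.append(np.column_stack([pts, b]))
        data = np.vstack(rows) if rows else np.empty((0, 4))
        np.savetxt(path, data, fmt="%.4f", header="x y z b")


def sample_box(bounds: np.ndarray, n_points: int, seed: int) -> tuple[np.ndarray, float]:
    """Sample points uniformly in an axis-aligned box.

    Parameters
    ----------
    bounds : (2, 3) array, [[xlo, ylo, zlo], [xhi, yhi, zhi]] in Å.
    n_points : number of points (≥ 0).
    seed : RNG seed; the point set is a pure function of (bounds, n, seed).

    Returns
    -------
    points : (n_points, 3) array
    density : points per Å³
    """
    bounds = np.asarray(bounds, dtype=float).reshape(2, 3)
    extent = bounds[1] - bounds[0]
    if np.any(extent <= 0):
        raise ValueError("degenerate box")
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    volume = float(np.prod(extent))
    if n_points == 0:
        return np.empty((0, 3)), 0.0
    rng = np.random.default_rng(seed)
    points = bounds[0] + rng.random((n_points, 3)) * extent
    return points, n_points / volume


def curve_distance_sq(
    points: np.ndarray, curve_xy_sq: np.ndarray, curve_z_sq: np.ndarray,
    r_xy: float, r_z: float,
) -> np.ndarray:
    """Minimum scaled squared distance of each point to the curve.

    The anisotropic metric divides in-plane offsets by r_xy and axial
    offsets by r_z, i.e. the unit ball of the metric is an ellipsoidal
    tube of half-axes (r_xy, r_xy, r_z) around the curve.  Inputs are
    precomputed squared offsets (N, K) to each curve point.
    """
    scaled = curve_xy_sq / r_xy**2 + curve_z_sq / r_z**2
    return scaled.min(axis=1)


def _offsets(points: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared in-plane and axial offsets of points (N) to curve points (K)."""
    d = points[:, None, :] - curve[None, :, :]
    return d[..., 0] ** 2 + d[..., 1] ** 2, d[..., 2] ** 2


# large-instance threshold above which the fused numba scan is used;
# the two paths are bit-identical (same operation order, no fastmath)
_KERNEL_MIN_WORK = 2_000_000


def _curve_scan(points: np.ndarray, curve: np.ndarray, params: RimParams,
                _cache: dict | None = None):
    """Min scaled squared distances (core and shell metric) and the
    core-metric argmin curve index, per point."""
    rx2, rz2 = params.R_xy**2, params.R_z**2
    ox2 = (params.R_xy + params.D_xy) ** 2
    oz2 = (params.R_z + params.D_z) ** 2
    if len(points) * len(curve) >= _KERNEL_MIN_WORK:
        from ._kernels import curve_scan

        return curve_scan(np.ascontiguousarray(points),
                          np.ascontiguousarray(curve), rx2, rz2, ox2, oz2)
    if _cache is not None and "xy_sq" in _cache:
        xy_sq, z_sq = _cache["xy_sq"], _cache["z_sq"]
    else:
        xy_sq, z_sq = _offsets(points, curve)
        if _cache is not None:
            _cache["xy_sq"], _cache["z_sq"] = xy_sq, z_sq
    scaled_core = xy_sq / rx2 + z_sq / rz2
    scaled_outer = xy_sq / ox2 + z_sq / oz2
    return (scaled_core.min(axis=1), scaled_core.argmin(axis=1),
            scaled_outer.min(axis=1))


def select_rim(
    points: np.ndarray,
    curve: MidplaneCurve,
    protein: AtomicModel | None,
    params: RimParams,
    clearance: float = C.PROTEIN_CLEARANCE,
    _cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition box points into tail-core and headgroup-shell sets.

    Selection rules:

    * tails: scaled curve distance < 1 under the (R_xy, R_z) metric, and
      not within ``clearance`` of any protein atom;
    * heads: scaled curve distance in (1, 1 + relative shell] under the
      shell metric (R_xy + D_xy, R_z + D_z), not already a tail, not
      within ``clearance`` of the protein, and within the anisotropic
      shell thickness (D_xy, D_z) of the hydrocarbon core (head-tail
      connectivity: nearest sampled tail point, or the continuum core
      surface along the ray to the nearest curve point — the latter
      removes a finite-density bias at the outer shell edge).

    Returns boolean masks (tails, heads) over ``points``.
    """
    n = len(points)
    if n == 0:
        return np.zeros(0, bool), np.zeros(0, bool)
    if len(curve.points) == 0:
        raise ValueError("empty midplane curve")

    min_core, arg_core, min_outer = _curve_scan(
        points, curve.points, params, _cache=_cache
    )
    core = min_core < 1.0
    outer = min_outer <= 1.0

    if protein is not None:
        if _cache is not None and "prot_dmin" in _cache:
            dmin = _cache["prot_dmin"]
        else:
            tree = cKDTree(protein.positions)
            dmin, _ = tree.query(points, k=1)
            if _cache is not None:
                _cache["prot_dmin"] = dmin
        clear = dmin >= clearance
        core &= clear
        outer &= clear

    tails = core
    heads = outer & ~core

    if heads.any() and tails.any():
        # head-tail connectivity: a head must lie within the anisotropic
        # shell thickness (D_xy, D_z) of the hydrocarbon core.  Checked
        # against the sampled tail points (KD-tree on coordinates scaled
        # by 1/D) and, to avoid a sampling artifact that thins the outer
        # shell edge, also against the continuum core region along the
        # ray to the nearest curve point.
        scale = np.array([1.0 / params.D_xy, 1.0 / params.D_xy, 1.0 / params.D_z])
        tree = cKDTree(points[tails] * scale)
        dmin, _ = tree.query(points[heads] * scale, k=1)
        near = dmin <= 1.0

        hidx = np.flatnonzero(heads)
        jstar = arg_core[hidx]
        u = np.sqrt(min_core[hidx])
        off = points[hidx] - curve.points[jstar]
        d_scaled = np.sqrt(
            (off[:, 0] ** 2 + off[:, 1] ** 2) / params.D_xy**2
            + off[:, 2] ** 2 / params.D_z**2
        )
        with np.errstate(divide="ignore"):
            ray_ok = (1.0 - 1.0 / np.maximum(u, 1.0)) * d_scaled <= 1.0
        near |= ray_ok

        heads = np.zeros(n, bool)
        heads[hidx[near]] = True
    elif heads.any():
        heads = np.zeros(n, bool)

    return tails, heads


def rim_composition(
    n_tail_points: int, density: float, spec: DetergentSpec
) -> tuple[float, int]:
    """Tail volume and detergent molecule count from the point bookkeeping.

    The tail core contains no water, so V_tail = (tail point count) /
    (box density); N_DM = floor(V_tail / per-molecule tail volume).
    """
    if n_tail_points == 0:
        return 0.0, 0
    if density <= 0:
        raise ValueError("zero density")
    v_tail = n_tail_points / density
    return v_tail, int(math.floor(v_tail / spec.tail_volume))


def assign_contrasts(
    tail_points: np.ndarray,
    head_points: np.ndarray,
    n_dm: int,
    density: float,
    spec: DetergentSpec,
    solvent: SolventSpec,
) -> RimModel:
    """Distribute the total excess scattering of N_DM molecules on the points.

    The total core excess is N_DM × (tail electrons − ρ_buf × tail
    volume), the total shell excess N_DM × (head electrons − ρ_buf ×
    dry head volume); each is spread uniformly over its point class.
    Water in the shell is implicit: extra shell volume carries no net
    scattering because only the fixed total is distributed.
    """
    nt, nh = len(tail_points), len(head_points)
    if n_dm < 0:
        raise ValueError("n_dm must be >= 0")
    if n_dm > 0 and (nt == 0 or nh == 0):
        raise ValueError("point class empty with n_dm > 0")
    v_tail = nt / density if density > 0 else 0.0
    tail_total = n_dm * spec.tail_excess(solvent.buffer_density)
    head_total = n_dm * spec.head_excess(solvent.buffer_density)
    return RimModel(
        tail_points=tail_points,
        head_points=head_points,
        density=density,
        v_tail=v_tail,
        n_dm=n_dm,
        tail_b=np.full(nt, tail_total / nt) if nt else np.empty(0),
        head_b=np.full(nh, head_total / nh) if nh else np.empty(0),
    )


def build_rim(
    points: np.ndarray,
    density: float,
    curve: MidplaneCurve,
    protein: AtomicModel | None,
    params: RimParams,
    spec: DetergentSpec,
    solvent: SolventSpec,
    _cache: dict | None = None,
) -> RimModel:
    """Select, count and contrast-assign the corona in one call."""
    tails, heads = select_rim(points, curve, protein, params, _cache=_cache)
    v_tail, n_dm = rim_composition(int(tails.sum()), density, spec)
    if n_dm == 0:
        return RimModel(points[tails], points[heads], density, v_tail, 0,
                        np.zeros(int(tails.sum())), np.zeros(int(heads.sum())))
    return assign_contrasts(points[tails], points[heads], n_dm, density, spec, solvent)


def hydration_layer(
    protein: AtomicModel,
    points: np.ndarray,
    rim_mask: np.ndarray | None,
    solvent: SolventSpec,
    density: float,
    clearance: float = C.PROTEIN_CLEARANCE,
    _dmin: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Select hydration dummy points on the protein surface outside the rim.

    Box points whose distance to the nearest protein atom lies in
    (clearance, clearance + thickness] and which are not part of the
    corona become hydration points; each carries b = contrast / density
    so the layer's total scattering equals contrast × layer volume.
    ``_dmin`` may supply precomputed nearest-atom distances.

    Returns (positions, per-point b).
    """
    if solvent.hydration_thickness <= 0:
        raise ValueError("thickness must be positive")
    if len(points) == 0:
        return np.empty((0, 3)), np.empty(0)
    if _dmin is not None:
        dmin = _dmin
    else:
        tree = cKDTree(protein.positions)
        dmin, _ = tree.query(points, k=1)
    sel = (dmin > clearance) & (dmin <= clearance + solvent.hydration_thickness)
    if rim_mask is not None:
        sel &= ~rim_mask
    pos = points[sel]
    b = np.full(len(pos), solvent.hydration_contrast / density if density > 0 else 0.0)
    return pos, b
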