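"""Rim + rigid-body refinement against an experimental SAS curve.

The complex is modelled as a P2-symmetric parallel dimer (mate protomer
generated by a 180° rotation about the membrane normal, never
independently parameterised) decorated with the Monte-Carlo detergent
corona.  The objective is the reduced chi-squared of the forward curve
against the data plus two physics penalties: a steric-overlap term
between protomers (and between rigid bodies) and harmonic Calpha
connectivity restraints at rigid-body junctions around the ideal 3.8 Å
bond distance.  Optimisation is a keep-best random search whose step
sizes shrink geometrically over stages.

The corona is rebuilt at every evaluation from one fixed box point set
(fixed seed), so the objective is a deterministic function of the
parameters and Monte-Carlo noise cannot alias the search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import constants as C
from .models_io import AtomicModel, MidplaneCurve, excluded_volume, midplane_curve
from .rim import (
    DetergentSpec,
    RimModel,
    RimParams,
    SolventSpec,
    assign_contrasts,
    hydration_layer,
    rim_composition,
    sample_box,
    select_rim,
)
from .scattering import (
    SASCurve,
    ScatteringBody,
    coarsen_body,
    debye_intensity,
    protein_body,
    reduced_chi2,
)

P2_ROTATION = np.diag([-1.0, -1.0, 1.0])


@dataclass
class RigidBodyPartition:
    """Disjoint, ordered residue ranges defining rigid bodies of one chain.

    Junctions are the Calpha pairs bridging consecutive bodies: the last
    residue of body i and the first residue of body i+1.
    """

    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.ranges, self.ranges[1:]):
            if a1 >= b0:
                raise ValueError("body ranges must be disjoint and ordered")

    @property
    def n_bodies(self) -> int:
        return len(self.ranges)

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """(residue i, residue j) pairs bridging consecutive bodies."""
        return [(a[1], b[0]) for a, b in zip(self.ranges, self.ranges[1:])]


@dataclass
class SearchSchedule:
    """Shrinking-step random-search schedule."""

    n_stages: int = 4
    decay: float = 0.5
    evals_per_stage: int = 250
    max_evaluations: int = 10_000
    seed: int = 0
    step_radius: float = 4.0      # Å: rim radii, protomer offsets
    step_thickness: float = 2.0   # Å: shell thicknesses
    step_rotation: float = 5.0    # degrees: body rotations
    step_translation: float = 2.0 # Å: body translations

    def __post_init__(self) -> None:
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        if self.n_stages <= 0 or self.evals_per_stage <= 0:
            raise ValueError("stages and evaluations must be positive")

    def step_for(self, cls: str) -> float:
        return {
            "radius": self.step_radius,
            "thickness": self.step_thickness,
            "rotation": self.step_rotation,
            "translation": self.step_translation,
        }[cls]


@dataclass
class FitState:
    """The parameter vector of a complex fit.

    Rim geometry (R_xy, R_z, D_xy, D_z), protomer placement (x offset
    from the symmetry axis and z offset from the midplane) and one
    rigid transform per body beyond the first (rotation vector in
    degrees about the body centroid plus translation).  Under P2
    symmetry the mate protomer carries no parameters of its own.
    """

    rim: RimParams
    protomer_dx: float = 0.0
    z_offset: float = 0.0
    body_poses: np.ndarray = field(default_factory=lambda: np.zeros((0, 6)))
    p2: bool = True

    def copy(self) -> "FitState":
        return FitState(
            rim=replace(self.rim),
            protomer_dx=self.protomer_dx,
            z_offset=self.z_offset,
            body_poses=self.body_poses.copy(),
            p2=self.p2,
        )


# parameter metadata: (name, step class)
_RIM_PARAMS = [("R_xy", "radius"), ("R_z", "radius"),
               ("D_xy", "thickness"), ("D_z", "thickness")]
_PLACE_PARAMS = [("protomer_dx", "radius"), ("z_offset", "radius")]


def state_to_vector(state: FitState, fit_poses: bool, fit_placement: bool):
    """Flatten a FitState into (vector, step-class labels)."""
    vec = [getattr(state.rim, n) for n, _ in _RIM_PARAMS]
    cls = [c for _, c in _RIM_PARAMS]
    if fit_placement:
        vec += [state.protomer_dx, state.z_offset]
        cls += [c for _, c in _PLACE_PARAMS]
    if fit_poses:
        for pose in state.body_poses:
            vec += list(pose)
            cls += ["rotation"] * 3 + ["translation"] * 3
    return np.array(vec, dtype=float), cls


def vector_to_state(vec: np.ndarray, template: FitState,
                    fit_poses: bool, fit_placement: bool) -> FitState:
    state = template.copy()
    state.rim = RimParams(*vec[:4])
    i = 4
    if fit_placement:
        state.protomer_dx, state.z_offset = vec[i], vec[i + 1]
        i += 2
    if fit_poses:
        n_posed = len(template.body_poses)
        state.body_poses = vec[i:i + 6 * n_posed].reshape(n_posed, 6)
    return state


def _vector_valid(vec: np.ndarray) -> bool:
    r_xy, r_z, d_xy, d_z = vec[:4]
    return r_xy > 0 and r_z > 0 and 0 < d_xy < 10 and 0 < d_z < 10


def apply_p2(protomer: AtomicModel) -> AtomicModel:
    """Generate the parallel P2 dimer: mate = 180° rotation about z."""
    mate_pos = protomer.positions @ P2_ROTATION.T
    return AtomicModel(
        positions=np.vstack([protomer.positions, mate_pos]),
        elements=np.concatenate([protomer.elements] * 2),
        electrons=np.concatenate([protomer.electrons] * 2),
        residue_index=np.concatenate([protomer.residue_index] * 2),
        chain_id=np.concatenate(
            [protomer.chain_id, np.char.add(protomer.chain_id.astype(str), "'")]
        ),
        is_ca=np.concatenate([protomer.is_ca] * 2),
        frame=protomer.frame,
    )


def apply_poses(protomer: AtomicModel, partition: RigidBodyPartition,
                poses: np.ndarray) -> AtomicModel:
    """Rigidly move bodies 2..B of a partition; body 1 stays fixed.

    Each pose row is (rx, ry, rz, tx, ty, tz): a rotation vector in
    degrees applied about the body centroid, then a translation in Å.
    """
    if len(poses) != partition.n_bodies - 1:
        raise ValueError("need one pose per body beyond the first")
    out = protomer.positions.copy()
    for (start, stop), pose in zip(partition.ranges[1:], poses):
        mask = (protomer.residue_index >= start) & (protomer.residue_index <= stop)
        if not mask.any():
            continue
        rot = _rotvec_matrix(np.asarray(pose[:3], dtype=float))
        centroid = out[mask].mean(axis=0)
        out[mask] = (out[mask] - centroid) @ rot.T + centroid + pose[3:]
    return replace(protomer, positions=out)


def _rotvec_matrix(rotvec_deg: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(rotvec_deg)
    if theta < 1e-12:
        return np.eye(3)
    k = rotvec_deg / theta
    t = np.deg2rad(theta)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * kx @ kx


def overlap_penalty(groups: list[np.ndarray], cutoff: float = 3.0,
                    weight: float = 1.0) -> float:
    """Steric clash penalty between atom groups.

    weight × Σ over inter-group atom pairs with d < cutoff of
    (cutoff − d)²; zero when clash-free.  Groups are position arrays —
    typically the two protomers, or the rigid bodies of each.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    total = 0.0
    trees = [cKDTree(g) for g in groups if len(g)]
    kept = [g for g in groups if len(g)]
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            pairs = trees[i].query_ball_tree(trees[j], r=cutoff)
            for a, hits in enumerate(pairs):
                if hits:
                    d = np.linalg.norm(kept[j][hits] - kept[i][a], axis=1)
                    total += np.sum((cutoff - d[d < cutoff]) ** 2)
    return weight * total


def connectivity_penalty(protomer: AtomicModel, partition: RigidBodyPartition,
                         k: float = 1.0,
                         ideal: float = C.CA_CA_IDEAL) -> float:
    """Harmonic junction restraint: k × Σ (d_CαCα − 3.8 Å)².

    One term per junction between consecutive rigid bodies; the Calpha
    pair is the last residue of the earlier body and the first residue
    of the later one.
    """
    total = 0.0
    for res_i, res_j in partition.junctions:
        pi = _ca_position(protomer, res_i)
        pj = _ca_position(protomer, res_j)
        d = float(np.linalg.norm(pj - pi))
        total += (d - ideal) ** 2
    return k * total


def _ca_position(model: AtomicModel, residue: int) -> np.ndarray:
    mask = model.is_ca & (model.residue_index == residue)
    if not mask.any():
        raise ValueError(f"missing Calpha at residue {residue}")
    return model.positions[mask][0]


@dataclass
class FitResult:
    """Outcome of a refinement run."""

    state: FitState
    chi2: float
    penalties: dict
    objective: float
    n_dm: int
    trace: np.ndarray          # kept-best objective after each evaluation
    n_evaluations: int
    scale: float = 1.0
    converged: bool = True


def random_search(objective, x0: np.ndarray, classes: list[str],
                  schedule: SearchSchedule,
                  validate=_vector_valid) -> tuple[np.ndarray, float, np.ndarray]:
    """Keep-best random search with geometrically shrinking steps.

    At every evaluation all parameters are perturbed by Gaussian steps
    whose scale depends on the parameter class; a proposal is accepted
    only if it improves the objective, so the kept-best trace is
    non-increasing.  Degenerate proposals (invalid rim geometry) are
    re-drawn without being evaluated.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(schedule.seed)
    steps0 = np.array([schedule.step_for(c) for c in classes])
    best_x = x0.copy()
    best_f = objective(best_x)
    trace = [best_f]
    n_eval = 1
    exhausted = False
    for stage in range(schedule.n_stages):
        steps = steps0 * schedule.decay**stage
        for _ in range(schedule.evals_per_stage):
            if n_eval >= schedule.max_evaluations:
                exhausted = True
                break
            proposal = None
            for _attempt in range(100):
                cand = best_x + steps * rng.standard_normal(len(best_x))
                if validate is None or validate(cand):
                    proposal = cand
                    break
            if proposal is None:
                continue
            f = objective(proposal)
            n_eval += 1
            if f < best_f:
                best_f, best_x = f, proposal.copy()
            trace.append(best_f)
        if exhausted:
            warnings.warn("max evaluations exhausted; returning best so far")
            break
    return best_x, best_f, np.array(trace)


class ComplexForwardModel:
    """Forward model + objective for a protomer-in-corona fit.

    Holds the fixed Monte-Carlo box, detergent/solvent specs, the data
    curve and penalty weights; evaluates chi² + penalties for a
    FitState.  Geometry-dependent intermediates (excluded volume,
    midplane curve, point-to-curve offsets) are cached and reused while
    protein geometry is unchanged, which makes rim-only refinement
    cheap.
    """

    def __init__(
        self,
        protomer: AtomicModel | None,
        data: SASCurve,
        partition: RigidBodyPartition | None = None,
        detergent: DetergentSpec | None = None,
        solvent: SolventSpec | None = None,
        box_points: int = 30_000,
        box_margin: float = 40.0,
        box_margin_z: float = 28.0,
        box_seed: int = 1234,
        max_curve_points: int = 120,
        q_min: float = 0.02,
        w_overlap: float = 10.0,
        k_conn: float = 10.0,
        grid_spacing: float = 2.0,
        coarsen_cell: float = 3.0,
        include_hydration: bool = True,
        p2: bool = True,
        fit_background: bool = False,
    ) -> None:
        self.protomer = protomer
        self.data = data
        self.partition = partition
        self.detergent = detergent or DetergentSpec()
        self.solvent = solvent or SolventSpec()
        self.q_min = q_min
        self.w_overlap = w_overlap
        self.k_conn = k_conn
        self.grid_spacing = grid_spacing
        self.coarsen_cell = coarsen_cell
        self.include_hydration = include_hydration
        self.p2 = p2
        self.fit_background = fit_background
        self.max_curve_points = max_curve_points
        self.box_margin = box_margin
        self.box_margin_z = box_margin_z

        if protomer is not None:
            # snug anisotropic box: the corona reaches at most ~box_margin
            # beyond the protein in x-y and box_margin_z along z
            ext_xy = np.abs(protomer.positions[:, :2]).max()
            ext_z = np.abs(protomer.positions[:, 2]).max()
            half_xy = ext_xy + box_margin
            half_z = max(ext_z + 6.0, box_margin_z)
        else:
            half_xy = half_z = box_margin
        bounds = np.array([[-half_xy, -half_xy, -half_z],
                           [half_xy, half_xy, half_z]])
        self.box_points, self.box_density = sample_box(bounds, box_points, box_seed)
        self._geom_key = None
        self._geom = None

    # -- geometry (cached while protein placement unchanged) ------------

    def _geometry(self, state: FitState):
        key = (state.protomer_dx, state.z_offset, state.body_poses.tobytes())
        if key == self._geom_key:
            return self._geom
        if self.protomer is None:
            # micelle mode: degenerate curve at the origin
            curve = MidplaneCurve(points=np.zeros((1, 3)), closed=True)
            geom = {"model": None, "curve": curve, "cache": {}}
        else:
            protomer = self.protomer
            if self.partition is not None and len(state.body_poses):
                protomer = apply_poses(protomer, self.partition, state.body_poses)
            posed = protomer.transformed(
                np.eye(3), np.array([state.protomer_dx, 0.0, state.z_offset])
            )
            model = apply_p2(posed) if self.p2 else posed
            grid = excluded_volume(model, spacing=self.grid_spacing)
            curve = midplane_curve(grid)
            if len(curve.points) > self.max_curve_points:
                # thin the angle-ordered loop; spacing stays ≪ rim radii
                step = int(np.ceil(len(curve.points) / self.max_curve_points))
                curve = MidplaneCurve(points=curve.points[::step], closed=True)
            pen_overlap = 0.0
            if self.p2:
                mate = posed.positions @ P2_ROTATION.T
                pen_overlap = overlap_penalty(
                    [posed.positions, mate], weight=self.w_overlap
                )
            pen_conn = 0.0
            if self.partition is not None and self.partition.n_bodies > 1:
                pen_conn = connectivity_penalty(posed, self.partition,
                                                k=self.k_conn)
            geom = {"model": model, "curve": curve, "cache": {},
                    "protomer_posed": posed,
                    "protein_sb": protein_body(model, self.solvent.buffer_density),
                    "pen_overlap": pen_overlap, "pen_conn": pen_conn}
        self._geom_key = key
        self._geom = geom
        return geom

    # -- forward & objective --------------------------------------------

    def forward(self, state: FitState):
        """Model SAS curve, rim model and posed structure for a state."""
        geom = self._geometry(state)
        tails, heads = select_rim(
            self.box_points, geom["curve"], geom["model"], state.rim,
            _cache=geom["cache"],
        )
        v_tail, n_dm = rim_composition(
            int(tails.sum()), self.box_density, self.detergent
        )
        if n_dm > 0:
            rim = assign_contrasts(
                self.box_points[tails], self.box_points[heads], n_dm,
                self.box_density, self.detergent, self.solvent,
            )
        else:
            rim = RimModel(self.box_points[tails], self.box_points[heads],
                           self.box_density, v_tail, 0,
                           np.zeros(int(tails.sum())), np.zeros(int(heads.sum())))
        bodies = []
        if geom["model"] is not None:
            bodies.append(geom["protein_sb"])
        if len(rim.tail_points):
            bodies.append(ScatteringBody(rim.tail_points, rim.tail_b))
        if len(rim.head_points):
            bodies.append(ScatteringBody(rim.head_points, rim.head_b))
        if self.include_hydration and geom["model"] is not None:
            hpos, hb = hydration_layer(
                geom["model"], self.box_points, tails | heads, self.solvent,
                self.box_density, _dmin=geom["cache"].get("prot_dmin"),
            )
            if len(hpos):
                bodies.append(ScatteringBody(hpos, hb))
        # joint coarsening acts as local density smoothing: cells mixing
        # tail and head scatterers keep the correct net contrast
        body = coarsen_body(ScatteringBody.concatenate(bodies), self.coarsen_cell)
        curve = debye_intensity(body, self.data.q, method="histogram")
        return curve, rim, geom

    def evaluate(self, state: FitState):
        """(objective, components) for a state."""
        model_curve, rim, geom = self.forward(state)
        chi2, scale, bg = reduced_chi2(
            model_curve, self.data, fit_scale=True,
            fit_background=self.fit_background, q_min=self.q_min,
        )
        pen_overlap = geom.get("pen_overlap", 0.0)
        pen_conn = geom.get("pen_conn", 0.0)
        total = chi2 + pen_overlap + pen_conn
        return total, {
            "chi2": chi2, "scale": scale, "background": bg,
            "overlap": pen_overlap, "connectivity": pen_conn,
            "n_dm": rim.n_dm,
        }

    def objective(self, state: FitState) -> float:
        return self.evaluate(state)[0]


def fit(
    model: ComplexForwardModel,
    state0: FitState,
    schedule: SearchSchedule,
    fit_poses: bool = False,
    fit_placement: bool = False,
) -> FitResult:
    """Refine a FitState against the model's data by random search."""
    template = state0.copy()

    def obj(vec: np.ndarray) -> float:
        state = vector_to_state(vec, template, fit_poses, fit_placement)
        return model.objective(state)

    x0, classes = state_to_vector(state0, fit_poses, fit_placement)
    reach_xy = getattr(model, "box_margin", np.inf) - 2.0
    reach_z = getattr(model, "box_margin_z", np.inf) - 4.0

    def valid(vec: np.ndarray) -> bool:
        # rim must stay inside the Monte-Carlo box
        return (_vector_valid(vec) and vec[0] + vec[2] <= reach_xy
                and vec[1] + vec[3] <= reach_z)

    best_x, best_f, trace = random_search(obj, x0, classes, schedule, validate=valid)
    best_state = vector_to_state(best_x, template, fit_poses, fit_placement)
    total, comp = model.evaluate(best_state)
    return FitResult(
        state=best_state,
        chi2=comp["chi2"],
        penalties={"overlap": comp["overlap"], "connectivity": comp["connectivity"]},
        objective=best_f,
        n_dm=comp["n_dm"],
        trace=trace,
        n_evaluations=len(trace),
        scale=comp["scale"],
    )


def fit_micelle(
    data: SASCurve,
    state0: FitState | None = None,
    schedule: SearchSchedule | None = None,
    detergent: DetergentSpec | None = None,
    solvent: SolventSpec | None = None,
    box_points: int = 30_000,
    box_margin: float = 40.0,
    box_seed: int = 1234,
    q_min: float = 0.0,
) -> FitResult:
    """Fit a pure detergent micelle (core–shell sphere) to a SAS curve.

    The protein-free limit of the corona model: the midplane curve
    degenerates to a single point, so the core is a ball of radius R
    and the shell a spherical layer of thickness D.
    """
    model = ComplexForwardModel(
        protomer=None, data=data, detergent=detergent, solvent=solvent,
        box_points=box_points, box_margin=box_margin, box_seed=box_seed,
        q_min=q_min, include_hydration=False, p2=False,
    )
    if state0 is None:
        state0 = FitState(rim=RimParams(15.0, 15.0, 5.0, 5.0), p2=False)
    if schedule is None:
        schedule = SearchSchedule(n_stages=4, evals_per_stage=60)

    template = state0.copy()

    def obj(vec: np.ndarray) -> float:
        # isotropic micelle: one radius, one thickness
        full = np.array([vec[0], vec[0], vec[1], vec[1]])
        return model.objective(vector_to_state(full, template, False, False))

    x0 = np.array([state0.rim.R_xy, state0.rim.D_xy])
    classes = ["radius", "thickness"]

    def valid(vec):
        return vec[0] > 0 and 0 < vec[1] < 10

    best_x, best_f, trace = random_search(obj, x0, classes, schedule, validate=valid)
    best_state = vector_to_state(
        np.array([best_x[0], best_x[0], best_x[1], best_x[1]]),
        template, False, False,
    )
    total, comp = model.evaluate(best_state)
    return FitResult(
        state=best_state, chi2=comp["chi2"],
        penalties={"overlap": 0.0, "connectivity": 0.0},
        objective=best_f, n_dm=comp["n_dm"], trace=trace,
        n_evaluations=len(trace), scale=comp["scale"],
    )
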