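"""Synthetic data with known ground truth for every pipeline input.

Generators for toy transmembrane proteins (ideal poly-Ala helix
bundles), planted protein+corona and pure-micelle SAS curves, lamellar
diffraction patterns, and three-detector MALS observations.  Every
generator is a pure function of its parameters and seed, and each
dataset can carry a :class:`PlantedTruth` sidecar holding the
generating parameters, sufficient to regenerate it bit-identically.

Noise model: multiplicative Gaussian (σ = noise_fraction × I), the
conventional error model for one-dimensional SAS data; a Poisson mode
is available for diffraction patterns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .lamellar import DiffractionPattern
from .models_io import AtomicModel
from .refinement import ComplexForwardModel, FitState
from .rim import DetergentSpec, RimParams, SolventSpec
from .scattering import SASCurve

#: default SAXS momentum-transfer grid (Å⁻¹), log-spaced
DEFAULT_Q_GRID = np.geomspace(0.005, 0.5, 200)
#: default diffraction grid (nm⁻¹), linear
DEFAULT_S_GRID = np.linspace(0.1, 2.5, 1000)


@dataclass
class PlantedTruth:
    """Generating parameters of a synthetic dataset."""

    kind: str
    params: dict
    noise: float
    seed: int
    derived: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)

    @staticmethod
    def load(path) -> "PlantedTruth":
        with open(path) as fh:
            return PlantedTruth(**json.load(fh))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# toy protein models

# ideal alpha-helix parameters: rise per residue and Calpha helix radius
# chosen so consecutive Calpha atoms sit 3.8 Å apart
_HELIX_RISE = 1.5        # Å per residue
_HELIX_RADIUS = 2.3      # Å, Calpha track
_HELIX_TWIST = 100.0     # degrees per residue


def make_toy_protein(
    n_helices: int = 4,
    length: int = 26,
    bundle_radius: float = 8.0,
    path=None,
) -> AtomicModel:
    """Ideal poly-Ala transmembrane helix bundle along z.

    ``n_helices`` parallel ideal α-helices of ``length`` residues each,
    axes on a circle of radius ``bundle_radius``, centred so the bundle
    midpoint is at z = 0.  Backbone atoms N, CA, C, O are generated
    with approximate ideal geometry; consecutive intra-helix Calpha
    distances are 3.8 ± 0.05 Å.  Deterministic: same parameters give
    byte-identical PDB files.
    """
    if n_helices < 1 or length < 2:
        raise ValueError("need >= 1 helix of >= 2 residues")
    pos, names = [], []
    z0 = -(length - 1) * _HELIX_RISE / 2.0
    for h in range(n_helices):
        phi = 2.0 * np.pi * h / n_helices
        cx = bundle_radius * np.cos(phi) if n_helices > 1 else 0.0
        cy = bundle_radius * np.sin(phi) if n_helices > 1 else 0.0
        for i in range(length):
            t = np.deg2rad(i * _HELIX_TWIST + h * 60.0)
            z = z0 + i * _HELIX_RISE
            for name, rad, dt, dz in (
                ("N", 1.6, -0.52, -0.6),
                ("CA", _HELIX_RADIUS, 0.0, 0.0),
                ("C", 1.7, 0.52, 0.55),
                ("O", 2.0, 0.80, 1.40),
            ):
                pos.append([cx + rad * np.cos(t + dt), cy + rad * np.sin(t + dt), z + dz])
                names.append(name)

    n_res = n_helices * length
    elements = np.array([n[0] for n in names])
    electrons = np.array([{"N": 7.0, "C": 6.0, "O": 8.0}[e] for e in elements])
    model = AtomicModel(
        positions=np.array(pos),
        elements=elements,
        electrons=electrons,
        residue_index=np.repeat(np.arange(1, n_res + 1), 4),
        chain_id=np.array(["A"] * (4 * n_res)),
        is_ca=np.array([n == "CA" for n in names]),
        frame="membrane",
    )
    if path is not None:
        _write_pdb(model, np.array(names), path)
    return model


def _write_pdb(model: AtomicModel, atom_names: np.ndarray, path) -> None:
    st = gemmi.Structure()
    st.name = "toy"
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    last_res = None
    res = None
    for k in range(model.n_atoms):
        ri = int(model.residue_index[k])
        if ri != last_res:
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(ri, " ")
            chain.add_residue(res)
            res = chain[-1]
            last_res = ri
        atom = gemmi.Atom()
        atom.name = str(atom_names[k])
        atom.element = gemmi.Element(str(model.elements[k]))
        atom.pos = gemmi.Position(*model.positions[k])
        atom.occ = 1.0
        res.add_atom(atom)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# SAS curves


def simulate_complex_curve(
    protomer: AtomicModel,
    rim: RimParams,
    protomer_dx: float = 0.0,
    z_offset: float = 0.0,
    q: np.ndarray | None = None,
    noise: float = 0.01,
    seed: int = 0,
    detergent: DetergentSpec | None = None,
    solvent: SolventSpec | None = None,
    box_points: int = 40_000,
    p2: bool = True,
    coarsen_cell: float = 3.0,
    box_seed: int | None = None,
) -> tuple[SASCurve, PlantedTruth]:
    """Noisy SAS curve of a planted protein + corona complex.

    The forward Debye intensity of the P2 dimer with its detergent belt
    and hydration layer, with multiplicative Gaussian noise and a
    matching σ column.  The Monte-Carlo box seed defaults to a value
    derived from ``seed``; pass ``box_seed`` explicitly to share the
    box discretisation with a fit (planted-recovery benchmarks hold the
    box fixed so recovery error reflects only noise and the search).
    """
    q = DEFAULT_Q_GRID if q is None else np.asarray(q, dtype=float)
    placeholder = SASCurve(q, np.ones_like(q), np.ones_like(q))
    forward = ComplexForwardModel(
        protomer=protomer, data=placeholder, detergent=detergent,
        solvent=solvent, box_points=box_points,
        box_seed=(seed * 9176 + 11) % 2**31 if box_seed is None else box_seed,
        p2=p2, coarsen_cell=coarsen_cell,
    )
    state = FitState(rim=rim, protomer_dx=protomer_dx, z_offset=z_offset, p2=p2)
    model_curve, rim_model, _ = forward.forward(state)
    rng = np.random.default_rng(seed)
    sigma = np.maximum(noise, 1e-12) * model_curve.intensity
    intensity = model_curve.intensity + (
        rng.standard_normal(len(q)) * sigma if noise > 0 else 0.0
    )
    truth = PlantedTruth(
        kind="complex",
        params={
            "R_xy": rim.R_xy, "R_z": rim.R_z, "D_xy": rim.D_xy, "D_z": rim.D_z,
            "protomer_dx": protomer_dx, "z_offset": z_offset,
            "box_points": box_points, "p2": p2,
        },
        noise=noise,
        seed=seed,
        derived={"n_dm": rim_model.n_dm, "v_tail": rim_model.v_tail},
    )
    return SASCurve(q, intensity, sigma), truth


def simulate_micelle_curve(
    rim: RimParams | None = None,
    q: np.ndarray | None = None,
    noise: float = 0.01,
    seed: int = 0,
    detergent: DetergentSpec | None = None,
    solvent: SolventSpec | None = None,
    box_points: int = 40_000,
    box_seed: int | None = None,
    box_margin: float | None = None,
) -> tuple[SASCurve, PlantedTruth]:
    """Noisy SAS curve of a pure detergent micelle (core–shell sphere).

    Default geometry approximates a DM micelle of ~85 molecules:
    hydrocarbon core radius 18 Å (core volume ≈ 85 × 294 Å³) with a
    6 Å headgroup shell.  ``box_seed``/``box_margin`` may be set to
    share the Monte-Carlo discretisation with a fit.
    """
    rim = rim or RimParams(18.0, 18.0, 6.0, 6.0)
    q = DEFAULT_Q_GRID if q is None else np.asarray(q, dtype=float)
    placeholder = SASCurve(q, np.ones_like(q), np.ones_like(q))
    forward = ComplexForwardModel(
        protomer=None, data=placeholder, detergent=detergent, solvent=solvent,
        box_points=box_points,
        box_margin=(rim.R_xy + rim.D_xy + 12.0 if box_margin is None
                    else box_margin),
        box_seed=(seed * 9176 + 11) % 2**31 if box_seed is None else box_seed,
        p2=False, include_hydration=False,
    )
    state = FitState(rim=rim, p2=False)
    model_curve, rim_model, _ = forward.forward(state)
    rng = np.random.default_rng(seed)
    sigma = np.maximum(noise, 1e-12) * model_curve.intensity
    intensity = model_curve.intensity + (
        rng.standard_normal(len(q)) * sigma if noise > 0 else 0.0
    )
    truth = PlantedTruth(
        kind="micelle",
        params={"R": rim.R_xy, "D": rim.D_xy, "box_points": box_points},
        noise=noise, seed=seed,
        derived={"n_dm": rim_model.n_dm, "v_tail": rim_model.v_tail},
    )
    return SASCurve(q, intensity, sigma), truth


# ---------------------------------------------------------------------------
# lamellar diffraction


def simulate_lamellar_pattern(
    d: float,
    orders: dict[int, float] | None = None,
    width: float = 0.02,
    background: tuple[float, float, float] = (0.05, 2.0, 0.01),
    noise: float = 0.02,
    seed: int = 0,
    s: np.ndarray | None = None,
    noise_model: str = "gaussian",
) -> tuple[DiffractionPattern, PlantedTruth]:
    """Lamellar diffraction pattern with Gaussian Bragg peaks.

    Peaks sit at s = n·2π/d for each diffraction order n with the given
    amplitude; the background is A·s^(-p) + B with ``background =
    (A, p, B)``.  ``noise_model`` is 'gaussian' (multiplicative) or
    'poisson' (counts scaled by 1/noise²).

    Parameters
    ----------
    d : repeat distance in nm (with the default s grid in nm⁻¹).
    orders : {order: amplitude}; default {1: 1.0, 2: 0.3}.
    width : Gaussian σ of each peak, nm⁻¹.
    """
    if d <= 0:
        raise ValueError("repeat distance must be positive")
    orders = {1: 1.0, 2: 0.3} if orders is None else orders
    s = DEFAULT_S_GRID if s is None else np.asarray(s, dtype=float)
    A, p, B = background
    intensity = A * s**-p + B
    for n, amp in orders.items():
        center = n * 2.0 * np.pi / d
        intensity = intensity + amp * np.exp(-((s - center) ** 2) / (2 * width**2))
    rng = np.random.default_rng(seed)
    if noise > 0:
        if noise_model == "poisson":
            counts = np.maximum(intensity, 0) / noise**2
            intensity = rng.poisson(counts) * noise**2
        else:
            intensity = intensity * (1.0 + noise * rng.standard_normal(len(s)))
    truth = PlantedTruth(
        kind="lamellar",
        params={"d": d, "orders": {str(k): v for k, v in orders.items()},
                "width": width, "background": list(background),
                "noise_model": noise_model},
        noise=noise, seed=seed,
        derived={"peak_positions": [n * 2 * np.pi / d for n in sorted(orders)]},
    )
    return DiffractionPattern(s=s, intensity=intensity), truth


# ---------------------------------------------------------------------------
# MALS


def simulate_mals(
    mw_total: float,
    mw_protein: float,
    spec=None,
    concentration: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[dict, PlantedTruth]:
    """Forward three-detector MALS signals for a planted conjugate.

    With unit instrument constants: LS = c·MW·(dn/dc)², RI = c·(dn/dc),
    UV = c·w_p·ε, where w_p is the protein weight fraction and dn/dc the
    weight-fraction mixture of the component increments.  Invertible by
    :func:`beltsas.conjugate.conjugate_roundtrip`; exact when noiseless.
    """
    from .conjugate import ConjugateSpec, mixture_dndc

    if mw_total <= 0 or mw_protein <= 0 or mw_total < mw_protein:
        raise ValueError("need mw_total >= mw_protein > 0")
    spec = spec or ConjugateSpec()
    wp = mw_protein / mw_total
    dndc = mixture_dndc(wp, spec)
    signals = {
        "ls": concentration * mw_total * dndc**2,
        "ri": concentration * dndc,
        "uv": concentration * wp * spec.extinction,
    }
    if noise > 0:
        rng = np.random.default_rng(seed)
        for key in ("ls", "ri", "uv"):
            signals[key] *= 1.0 + noise * rng.standard_normal()
    truth = PlantedTruth(
        kind="mals",
        params={"mw_total": mw_total, "mw_protein": mw_protein,
                "concentration": concentration},
        noise=noise, seed=seed,
        derived={"fraction_protein": wp},
    )
    return signals, truth
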