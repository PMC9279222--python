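import numpy as np
import pytest

from beltsas import AtomicModel, make_toy_protein


@pytest.fixture(scope="session")
def toy_protein():
    """104-residue 4-helix transmembrane bundle in the membrane frame."""
    return make_toy_protein(4, 26, 8.0)


def solid_model(positions: np.ndarray, element: str = "C") -> AtomicModel:
    """Atomic model from bare positions (all one element, one chain)."""
    n = len(positions)
    electrons = {"C": 6.0, "N": 7.0, "O": 8.0}[element]
    return AtomicModel(
        positions=np.asarray(positions, dtype=float),
        elements=np.array([element] * n),
        electrons=np.full(n, electrons),
        residue_index=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        is_ca=np.zeros(n, bool),
        frame="membrane",
    )


@pytest.fixture(scope="session")
def cylinder_model():
    """Atoms whose vdW union is a cylinder of outer radius ~10 Å along z:
    carbon centres densely packed to radius 8.3 (+1.7 Å vdW)."""
    pts = []
    for z in np.arange(-12, 12.01, 0.8):
        for r in np.linspace(0, 8.3, 11):
            nang = max(int(2 * np.pi * r / 0.8), 1)
            for t in np.linspace(0, 2 * np.pi, nang, endpoint=False):
                pts.append([r * np.cos(t), r * np.sin(t), z])
    return solid_model(np.array(pts))


@pytest.fixture(scope="session")
def sphere_model():
    """Atoms whose vdW union is a sphere of outer radius ~10 Å: carbon
    centres densely packed to radius 8.3 (+1.7 Å vdW), z = 0 on-lattice."""
    g = np.arange(-8.4, 8.41, 0.8)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.sum(pts**2, axis=1) <= 8.3**2]
    # snap a lattice plane onto z = 0
    return solid_model(pts - [0.0, 0.0, pts[np.argmin(np.abs(pts[:, 2])), 2]])


def uniform_ball(n: int, radius: float, seed: int = 0) -> np.ndarray:
    """n uniform random points inside a ball."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return radius * (rng.random(n) ** (1 / 3))[:, None] * v


def sobol_ball(n: int, radius: float, seed: int = 5,
               shell: tuple | None = None) -> np.ndarray:
    """Low-discrepancy quasi-uniform points in a ball or spherical shell."""
    from scipy.stats import qmc

    s = qmc.Sobol(3, scramble=True, seed=seed).random(n)
    if shell is None:
        r = radius * s[:, 0] ** (1 / 3)
    else:
        r0, r1 = shell
        r = (r0**3 + (r1**3 - r0**3) * s[:, 0]) ** (1 / 3)
    z = 1 - 2 * s[:, 1]
    phi = 2 * np.pi * s[:, 2]
    st = np.sqrt(1 - z**2)
    return np.column_stack([r * st * np.cos(phi), r * st * np.sin(phi), r * z])


def sphere_form_factor(qa: np.ndarray) -> np.ndarray:
    """Normalised form factor of a homogeneous sphere, P(0) = 1."""
    qa = np.asarray(qa, dtype=float)
    return (3 * (np.sin(qa) - qa * np.cos(qa)) / qa**3) ** 2
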