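"""Shared fixtures and independent oracles for the lungsim test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lungsim as ls
from lungsim.morphometry import COLUMNS, MorphometryTable
from lungsim.tree import AirwayTree


# ---------------------------------------------------------------------------
# tree construction helpers
# ---------------------------------------------------------------------------

def make_tree(specs: list[dict]) -> AirwayTree:
    """Build a small tree from [{'parent': int|None, 'd': mm, 'l': mm}, ...].

    Generations are derived from the parent chain; each branch is laid out
    downward from its parent's distal point so lengths match endpoint
    distances exactly.
    """
    n = len(specs)
    parent = np.array(
        [-1 if s["parent"] is None else s["parent"] for s in specs], dtype=np.int64
    )
    generation = np.zeros(n, dtype=np.int64)
    proximal = np.zeros((n, 3))
    distal = np.zeros((n, 3))
    for i, s in enumerate(specs):
        p = parent[i]
        if p < 0:
            generation[i] = 1
            proximal[i] = (0.0, 0.0, 0.0)
        else:
            assert p < i, "parents must precede children"
            generation[i] = generation[p] + 1
            proximal[i] = distal[p]
        # spread siblings slightly in x so endpoints are distinct
        distal[i] = proximal[i] + (0.3 * i, -s["l"], 0.0)
    length = np.linalg.norm(distal - proximal, axis=1)
    # correct stated length: rescale the segment direction to the requested l
    for i, s in enumerate(specs):
        direction = (distal[i] - proximal[i]) / length[i]
        distal[i] = proximal[i] + direction * s["l"]
    # children must start at the corrected parent endpoints
    for i in range(n):
        if parent[i] >= 0:
            shift = distal[parent[i]] - proximal[i]
            proximal[i] += shift
            distal[i] += shift
    has_child = np.zeros(n, dtype=bool)
    has_child[parent[parent >= 0]] = True
    tree = AirwayTree(
        parent=parent,
        generation=generation,
        diameter_mm=np.array([s["d"] for s in specs], dtype=float),
        length_mm=np.linalg.norm(distal - proximal, axis=1),
        proximal_mm=proximal,
        distal_mm=distal,
        is_terminal=~has_child,
        metadata={},
    )
    tree.validate()
    return tree


def random_tree(rng: np.random.Generator, max_branches: int = 15) -> AirwayTree:
    """Random small tree: each branch attaches to a uniformly chosen parent."""
    n = int(rng.integers(1, max_branches + 1))
    specs = [{"parent": None, "d": float(rng.uniform(2, 12)), "l": float(rng.uniform(5, 80))}]
    for i in range(1, n):
        specs.append(
            {
                "parent": int(rng.integers(0, i)),
                "d": float(rng.uniform(0.5, 10)),
                "l": float(rng.uniform(2, 60)),
            }
        )
    return make_tree(specs)


# ---------------------------------------------------------------------------
# independent impedance oracle: full nodal analysis (linear solve)
# ---------------------------------------------------------------------------

def nodal_input_impedance(
    tree: AirwayTree,
    frequency_hz: float,
    gas: ls.GasProperties = ls.GasProperties(),
    elastance: ls.ElastanceModel = ls.ElastanceModel(),
) -> complex:
    """Input impedance by assembling and solving the full nodal system.

    Nodes: the tracheal inlet plus the distal junction of every branch; the
    alveolar/pleural reference is ground. Each branch contributes its Womersley
    impedance between its endpoints' nodes; each terminal branch's distal node
    connects to ground through the elastic element -j E_t / omega. Unit flow is
    injected at the inlet and the resulting inlet pressure is the impedance.
    This is an independent check of the series/parallel tree reduction.
    """
    omega = 2 * np.pi * frequency_hz
    e_t = elastance.terminal_elastance(tree.n_terminals)
    n = tree.n_branches
    # node 0 = inlet, node i+1 = distal end of branch i
    n_nodes = n + 1
    Y = np.zeros((n_nodes, n_nodes), dtype=complex)

    def stamp(a: int, b: int | None, z: complex) -> None:
        y = 1.0 / z
        Y[a, a] += y
        if b is not None:
            Y[b, b] += y
            Y[a, b] -= y
            Y[b, a] -= y

    for i in range(n):
        za = ls.branch_impedance(tree.branch(i), frequency_hz, gas)
        a = 0 if tree.parent[i] < 0 else int(tree.parent[i]) + 1
        stamp(a, i + 1, za)
        if tree.is_terminal[i]:
            stamp(i + 1, None, -1j * e_t / omega)  # element to ground
    rhs = np.zeros(n_nodes, dtype=complex)
    rhs[0] = 1.0  # unit oscillatory flow into the inlet
    pressures = np.linalg.solve(Y, rhs)
    return complex(pressures[0])


# ---------------------------------------------------------------------------
# independent Bessel-series oracle
# ---------------------------------------------------------------------------

def series_womersley_factor(alpha: float, n_terms: int = 60) -> complex:
    """[1 - 2 J1(z)/(z J0(z))]^-1 via the power series of J0 and J1."""
    z = alpha * np.exp(-0.25j * np.pi)
    half = z / 2.0
    j0 = 0j
    j1 = 0j
    term0 = 1.0 + 0j  # (z/2)^(2m) / (m!)^2 at m=0
    term1 = half  # (z/2)^(2m+1) / (m!(m+1)!) at m=0
    for m in range(n_terms):
        j0 += (-1) ** m * term0
        j1 += (-1) ** m * term1
        term0 = term0 * half * half / ((m + 1) ** 2)
        term1 = term1 * half * half / ((m + 1) * (m + 2))
    return 1.0 / (1.0 - 2.0 * j1 / (z * j0))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def structured_morphometry(n_generations: int = 8) -> MorphometryTable:
    """A small physiologically ordered table: doubling counts, shrinking calibres."""
    rows = []
    b = 1
    for g in range(1, n_generations + 1):
        d = 14.0 * 0.7 ** (g - 1)
        rows.append(
            {
                "generation": g,
                "branches": b,
                "terminal_branches": 0 if g < n_generations else b,
                "d_mean": d,
                "d_max": 1.2 * d,
                "d_min": 0.7 * d,
                "d_std": 0.1 * d,
            }
        )
        b *= 2
    return MorphometryTable(pd.DataFrame(rows, columns=list(COLUMNS)))


@pytest.fixture(scope="session")
def structured_tree() -> AirwayTree:
    """255-branch, 8-generation tree with airway-like calibre ordering."""
    return ls.generate_tree(structured_morphometry(), seed=4)


@pytest.fixture(scope="session")
def morph26() -> MorphometryTable:
    """The packaged 26-generation morphometry table."""
    return ls.default_morphometry()


@pytest.fixture(scope="session")
def fixture_tree(morph26) -> AirwayTree:
    """The full 64,893-branch tree generated from the packaged table."""
    return ls.generate_tree(morph26, seed=1)


@pytest.fixture(scope="session")
def frc_tree(fixture_tree) -> AirwayTree:
    """The fixture tree deflated to functional residual capacity (factor 0.8)."""
    return ls.scale_to_frc(fixture_tree, 0.8)


@pytest.fixture(scope="session")
def frc_engine(frc_tree) -> ls.ImpedanceEngine:
    """Shared cached-impedance engine for the study tree at FRC."""
    return ls.ImpedanceEngine(frc_tree)


@pytest.fixture()
def toy_table() -> MorphometryTable:
    """1/2/4 branches over three generations, all four leaves at generation 3."""
    return MorphometryTable(
        pd.DataFrame(
            {
                "generation": [1, 2, 3],
                "branches": [1, 2, 4],
                "terminal_branches": [0, 0, 4],
                "d_mean": [10.0, 6.0, 3.0],
                "d_max": [10.0, 8.0, 4.0],
                "d_min": [10.0, 4.0, 2.0],
                "d_std": [0.0, 1.0, 0.5],
            }
        )
    )


@pytest.fixture()
def seven_branch_tree() -> AirwayTree:
    """Asymmetric 7-branch toy tree used against the nodal oracle."""
    return make_tree(
        [
            {"parent": None, "d": 12.0, "l": 100.0},
            {"parent": 0, "d": 8.0, "l": 50.0},
            {"parent": 0, "d": 7.0, "l": 40.0},
            {"parent": 1, "d": 5.0, "l": 30.0},
            {"parent": 1, "d": 4.0, "l": 25.0},
            {"parent": 3, "d": 3.0, "l": 20.0},
            {"parent": 3, "d": 2.5, "l": 15.0},
        ]
    )
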