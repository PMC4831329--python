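"""Asymmetric airway-tree model: generation, scaling, narrowing, serialisation.

The tree is stored column-wise (one numpy array per attribute, one entry per
branch) because downstream impedance computations are vectorised over branches.
Branch ids are the array indices 0..n-1; the root (trachea, generation 1) has
parent id -1. A :class:`AirwayBranch` view object is available for single-branch
access.

The stochastic generator reproduces a morphometry table exactly in branch and
terminal counts per generation, draws diameters from a clipped normal per
generation, and embeds the tree in a lung bounding box by recursive halving of
space so that every subtree occupies a spatially compact region. Branch lengths
are the Euclidean distances between the embedded endpoints; the embedding is
deliberately schematic (no anatomical centerlines) because only spatial
coincidence with defect masks matters downstream.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InfeasibleTreeError, LookupIdError, ValidationError
from .morphometry import COLUMNS, MorphometryTable

#: default lung bounding box in mm, centred on the origin:
#: 300 (x, left-right) x 250 (y, in-plane) x 210 (z, 14 coronal slabs of 15 mm)
DEFAULT_LUNG_EXTENT = ((-150.0, 150.0), (-125.0, 125.0), (-105.0, 105.0))

_CSV_COLUMNS = [
    "id",
    "parent_id",
    "generation",
    "diameter_mm",
    "length_mm",
    "x0",
    "y0",
    "z0",
    "x1",
    "y1",
    "z1",
    "is_terminal",
]


@dataclass(frozen=True)
class AirwayBranch:
    """Single-branch view of an :class:`AirwayTree` (all geometry in mm)."""

    id: int
    generation: int
    diameter_mm: float
    length_mm: float
    parent_id: int | None
    proximal_mm: np.ndarray
    distal_mm: np.ndarray
    is_terminal: bool

    @property
    def radius_m(self) -> float:
        return self.diameter_mm / 2000.0

    @property
    def length_m(self) -> float:
        return self.length_mm / 1000.0


@dataclass
class AirwayTree:
    """Rooted branching network of airway segments (column-wise storage)."""

    parent: np.ndarray        # (n,) int64, -1 for the root
    generation: np.ndarray    # (n,) int64, root = 1
    diameter_mm: np.ndarray   # (n,) float64, > 0
    length_mm: np.ndarray     # (n,) float64, > 0
    proximal_mm: np.ndarray   # (n, 3) float64
    distal_mm: np.ndarray     # (n, 3) float64
    is_terminal: np.ndarray   # (n,) bool
    metadata: dict = field(default_factory=dict)

    # -- basic properties ----------------------------------------------------
    @property
    def n_branches(self) -> int:
        return int(self.parent.shape[0])

    @property
    def n_terminals(self) -> int:
        return int(self.is_terminal.sum())

    @property
    def root_id(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots.size}")
        return int(roots[0])

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_branches)

    @property
    def midpoints_mm(self) -> np.ndarray:
        return 0.5 * (self.proximal_mm + self.distal_mm)

    def branch(self, branch_id: int) -> AirwayBranch:
        i = int(branch_id)
        if not 0 <= i < self.n_branches:
            raise LookupIdError(f"branch id {branch_id} out of range")
        parent = int(self.parent[i])
        return AirwayBranch(
            id=i,
            generation=int(self.generation[i]),
            diameter_mm=float(self.diameter_mm[i]),
            length_mm=float(self.length_mm[i]),
            parent_id=None if parent < 0 else parent,
            proximal_mm=self.proximal_mm[i].copy(),
            distal_mm=self.distal_mm[i].copy(),
            is_terminal=bool(self.is_terminal[i]),
        )

    def children_lists(self) -> list[list[int]]:
        """Children ids per branch (index = branch id)."""
        kids: list[list[int]] = [[] for _ in range(self.n_branches)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[int(p)].append(i)
        return kids

    def descendants(self, branch_ids: Sequence[int]) -> np.ndarray:
        """Ids of all strict descendants of the given branches (stack-based)."""
        kids = self.children_lists()
        out: list[int] = []
        stack = [int(b) for b in branch_ids]
        seen = set(stack)
        while stack:
            b = stack.pop()
            for c in kids[b]:
                if c not in seen:
                    seen.add(c)
                    out.append(c)
                    stack.append(c)
        return np.array(sorted(out), dtype=np.int64)

    def total_volume_mm3(self) -> float:
        """Total airway lumen volume, sum of pi r^2 l over branches."""
        r = self.diameter_mm / 2.0
        return float(np.sum(np.pi * r * r * self.length_mm))

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        n = self.n_branches
        if n == 0:
            raise ValidationError("empty tree")
        root = self.root_id  # also checks uniqueness
        if self.generation[root] != 1:
            raise ValidationError("root must have generation 1")
        nonroot = np.flatnonzero(self.parent >= 0)
        if np.any(self.parent[nonroot] >= n):
            raise ValidationError("parent id out of range")
        if np.any(
            self.generation[nonroot] != self.generation[self.parent[nonroot]] + 1
        ):
            raise ValidationError("child generation must be parent generation + 1")
        if np.any(self.diameter_mm <= 0) or np.any(self.length_mm <= 0):
            raise ValidationError("diameters and lengths must be positive")
        dist = np.linalg.norm(self.distal_mm - self.proximal_mm, axis=1)
        if np.any(np.abs(dist - self.length_mm) > 1e-6):
            raise ValidationError("length must equal endpoint distance within 1e-6 mm")
        has_child = np.zeros(n, dtype=bool)
        has_child[self.parent[nonroot]] = True
        if np.any(self.is_terminal == has_child):
            raise ValidationError("is_terminal must hold exactly for leaves")
        # reachability from root (counts check suffices for a parent-array forest
        # with a single root and consistent generations)
        order = np.argsort(self.generation, kind="stable")
        reach = np.zeros(n, dtype=bool)
        reach[root] = True
        for i in order:
            p = self.parent[i]
            if p >= 0:
                if not reach[p]:
                    raise ValidationError("branch not reachable from root")
                reach[i] = True

    def copy(self) -> "AirwayTree":
        return AirwayTree(
            parent=self.parent.copy(),
            generation=self.generation.copy(),
            diameter_mm=self.diameter_mm.copy(),
            length_mm=self.length_mm.copy(),
            proximal_mm=self.proximal_mm.copy(),
            distal_mm=self.distal_mm.copy(),
            is_terminal=self.is_terminal.copy(),
            metadata=copy.deepcopy(self.metadata),
        )

    # -- serialisation -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "parent_id": self.parent,
                "generation": self.generation,
                "diameter_mm": self.diameter_mm,
                "length_mm": self.length_mm,
                "x0": self.proximal_mm[:, 0],
                "y0": self.proximal_mm[:, 1],
                "z0": self.proximal_mm[:, 2],
                "x1": self.distal_mm[:, 0],
                "y1": self.distal_mm[:, 1],
                "z1": self.distal_mm[:, 2],
                "is_terminal": self.is_terminal,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "AirwayTree":
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"tree table missing columns: {missing}")
        frame = frame.sort_values("id").reset_index(drop=True)
        if not np.array_equal(frame["id"].to_numpy(), np.arange(len(frame))):
            raise ValidationError("branch ids must be 0..n-1")
        parent = frame["parent_id"].fillna(-1).to_numpy(dtype=np.int64)
        tree = cls(
            parent=parent,
            generation=frame["generation"].to_numpy(dtype=np.int64),
            diameter_mm=frame["diameter_mm"].to_numpy(dtype=float),
            length_mm=frame["length_mm"].to_numpy(dtype=float),
            proximal_mm=frame[["x0", "y0", "z0"]].to_numpy(dtype=float),
            distal_mm=frame[["x1", "y1", "z1"]].to_numpy(dtype=float),
            is_terminal=frame["is_terminal"].to_numpy(dtype=bool),
            metadata=metadata or {},
        )
        tree.validate()
        return tree

    @classmethod
    def from_csv(cls, path: str | Path) -> "AirwayTree":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metadata": self.metadata,
            "branches": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "AirwayTree":
        payload = json.loads(Path(path).read_text())
        frame = pd.DataFrame(payload["branches"])
        return cls.from_frame(frame, metadata=payload.get("metadata", {}))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _check_feasibility(morph: MorphometryTable) -> None:
    b = morph.branch_counts
    t = morph.terminal_counts
    nonterm = b - t
    for g in range(len(b) - 1):
        lo, hi = nonterm[g], 2 * nonterm[g]
        if not lo <= b[g + 1] <= hi:
            raise InfeasibleTreeError(
                f"generation {g + 2} holds {b[g + 1]} branches but generation "
                f"{g + 1} has {nonterm[g]} non-terminal parents "
                f"(feasible range {lo}..{hi} under binary branching)"
            )
    if nonterm[-1] != 0:
        raise InfeasibleTreeError(
            "last generation must be entirely terminal (no deeper rows exist)"
        )


def generate_tree(
    morphometry: MorphometryTable,
    seed: int = 0,
    lung_extent: Sequence[Sequence[float]] = DEFAULT_LUNG_EXTENT,
) -> AirwayTree:
    """Generate a stochastic airway tree matching a morphometry table exactly.

    Branch and terminal counts per generation are reproduced exactly; which
    branches of a generation terminate is a seeded random choice. Diameters are
    drawn per generation from a normal(d_mean, d_std) clipped to [d_min, d_max]
    and recentred so clipping does not bias the generation mean.
    The tree is embedded in ``lung_extent`` by recursive halving: each branch
    owns an axis-aligned box, two-child branches split it along its longest
    axis, so every subtree occupies a contiguous spatial region. Lengths are
    endpoint distances of this embedding (the morphometry table carries no
    length data).

    Same (table, seed, extent) always produces a bit-identical tree.
    """
    _check_feasibility(morphometry)
    rng = np.random.default_rng(seed)
    lo = np.array([e[0] for e in lung_extent], dtype=float)
    hi = np.array([e[1] for e in lung_extent], dtype=float)
    if np.any(hi <= lo):
        raise DomainError("lung_extent must have positive extent on every axis")

    b_counts = morphometry.branch_counts
    t_counts = morphometry.terminal_counts
    n_gen = len(b_counts)

    # accumulators over all generations
    parents: list[np.ndarray] = []
    gens: list[np.ndarray] = []
    diams: list[np.ndarray] = []
    prox: list[np.ndarray] = []
    dist: list[np.ndarray] = []
    terms: list[np.ndarray] = []

    # root: trachea enters the box from the +y face, ends at the box centre
    centre = 0.5 * (lo + hi)
    root_prox = np.array([centre[0], hi[1], centre[2]])
    cur_lo = lo[None, :].copy()
    cur_hi = hi[None, :].copy()
    cur_distal = centre[None, :].copy()
    cur_prox = root_prox[None, :].copy()
    cur_parent = np.array([-1], dtype=np.int64)
    id_offset = 0

    for g in range(n_gen):
        n_g = b_counts[g]
        assert cur_parent.shape[0] == n_g
        # terminal assignment for this generation
        is_term = np.zeros(n_g, dtype=bool)
        if g == n_gen - 1:
            is_term[:] = True
        elif t_counts[g] > 0:
            term_idx = rng.permutation(n_g)[: t_counts[g]]
            is_term[term_idx] = True
        # diameters: clipped normal, recentred so clipping does not bias the
        # generation mean away from the table value
        row = morphometry.frame.iloc[g]
        d = rng.normal(row["d_mean"], row["d_std"], size=n_g)
        d = np.clip(d, row["d_min"], row["d_max"])
        for _ in range(3):
            d = np.clip(d + (row["d_mean"] - d.mean()), row["d_min"], row["d_max"])

        parents.append(cur_parent)
        gens.append(np.full(n_g, g + 1, dtype=np.int64))
        diams.append(d)
        prox.append(cur_prox)
        dist.append(cur_distal)
        terms.append(is_term)

        if g == n_gen - 1:
            break

        # build next generation
        par_idx = np.flatnonzero(~is_term)  # local indices of parents
        m = par_idx.size
        n_next = b_counts[g + 1]
        n_two = n_next - m  # parents receiving two children
        two_mask = np.zeros(m, dtype=bool)
        if n_two > 0:
            two_mask[rng.permutation(m)[:n_two]] = True

        p_lo = cur_lo[par_idx]
        p_hi = cur_hi[par_idx]
        p_distal = cur_distal[par_idx]
        axis = np.argmax(p_hi - p_lo, axis=1)
        mid = 0.5 * (p_lo + p_hi)

        child_lo_parts = []
        child_hi_parts = []
        child_parent_parts = []
        # single-child parents keep their whole region
        one = ~two_mask
        if one.any():
            child_lo_parts.append(p_lo[one])
            child_hi_parts.append(p_hi[one])
            child_parent_parts.append(par_idx[one])
        if two_mask.any():
            rows = np.flatnonzero(two_mask)
            ax = axis[rows]
            lo_a = p_lo[rows].copy()
            hi_a = p_hi[rows].copy()
            hi_a[np.arange(rows.size), ax] = mid[rows, ax]
            lo_b = p_lo[rows].copy()
            lo_b[np.arange(rows.size), ax] = mid[rows, ax]
            hi_b = p_hi[rows].copy()
            child_lo_parts.extend([lo_a, lo_b])
            child_hi_parts.extend([hi_a, hi_b])
            child_parent_parts.extend([par_idx[rows], par_idx[rows]])

        nxt_lo = np.concatenate(child_lo_parts, axis=0)
        nxt_hi = np.concatenate(child_hi_parts, axis=0)
        nxt_parent_local = np.concatenate(child_parent_parts, axis=0)
        nxt_distal = 0.5 * (nxt_lo + nxt_hi)
        nxt_prox = p_distal[np.searchsorted(par_idx, nxt_parent_local)]
        # map local parent indices to global ids
        nxt_parent = nxt_parent_local + id_offset

        id_offset += n_g
        cur_lo, cur_hi = nxt_lo, nxt_hi
        cur_distal, cur_prox = nxt_distal, nxt_prox
        cur_parent = nxt_parent.astype(np.int64)

    proximal = np.concatenate(prox, axis=0)
    distal = np.concatenate(dist, axis=0)
    tree = AirwayTree(
        parent=np.concatenate(parents),
        generation=np.concatenate(gens),
        diameter_mm=np.concatenate(diams),
        length_mm=np.linalg.norm(distal - proximal, axis=1),
        proximal_mm=proximal,
        distal_mm=distal,
        is_terminal=np.concatenate(terms),
        metadata={
            "provenance": "lungsim.generate_tree",
            "seed": int(seed),
            "lung_extent_mm": [list(map(float, e)) for e in lung_extent],
            "scaling": [],
            "narrowing": [],
        },
    )
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def scale_to_frc(tree: AirwayTree, linear_factor: float) -> AirwayTree:
    """Scale all diameters, lengths and coordinates by ``linear_factor``.

    Intended for deflating a tree built at total lung capacity to functional
    residual capacity; the standard choice 0.8 gives a lumen volume ratio of
    0.8^3 = 0.512. Coordinates are scaled about the root's proximal point.
    """
    if not 0 < linear_factor <= 1:
        raise DomainError("linear_factor must be in (0, 1]")
    out = tree.copy()
    anchor = out.proximal_mm[out.root_id].copy()
    out.diameter_mm *= linear_factor
    out.length_mm *= linear_factor
    out.proximal_mm = anchor + linear_factor * (out.proximal_mm - anchor)
    out.distal_mm = anchor + linear_factor * (out.distal_mm - anchor)
    out.metadata.setdefault("scaling", []).append(float(linear_factor))
    return out


def narrow_branches(
    tree: AirwayTree, branch_ids: Sequence[int], diameter_factor: float
) -> AirwayTree:
    """Multiply the diameters of the listed branches by ``diameter_factor``.

    A factor of 0.1 raises each narrowed branch's Poiseuille resistance by
    10^4; zero is rejected so no branch ever has zero diameter.
    """
    if not 0 < diameter_factor <= 1:
        raise DomainError("diameter_factor must be in (0, 1]")
    ids = np.asarray(list(branch_ids), dtype=np.int64)
    if ids.size and (ids.min() < 0 or ids.max() >= tree.n_branches):
        bad = ids[(ids < 0) | (ids >= tree.n_branches)]
        raise LookupIdError(f"unknown branch ids: {bad.tolist()}")
    out = tree.copy()
    out.diameter_mm[ids] *= diameter_factor
    out.metadata.setdefault("narrowing", []).append(
        {"n_branches": int(ids.size), "diameter_factor": float(diameter_factor)}
    )
    return out


def tree_summary(tree: AirwayTree) -> MorphometryTable:
    """Per-generation counts and diameter statistics computed from a tree.

    Round-trips with :func:`generate_tree`: counts match the source table
    exactly, diameter statistics match in distribution. d_std uses the
    population convention (ddof=0) so a single-branch generation reports 0.
    """
    gens = np.unique(tree.generation)
    rows = []
    for g in gens:
        sel = tree.generation == g
        d = tree.diameter_mm[sel]
        rows.append(
            {
                "generation": int(g),
                "branches": int(sel.sum()),
                "terminal_branches": int(tree.is_terminal[sel].sum()),
                "d_mean": float(d.mean()),
                "d_max": float(d.max()),
                "d_min": float(d.min()),
                "d_std": float(d.std(ddof=0)),
            }
        )
    return MorphometryTable(pd.DataFrame(rows, columns=list(COLUMNS)))
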