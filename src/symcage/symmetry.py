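"""Cubic rotation groups and symmetry expansion.

The three chiral cubic point groups — tetrahedral T (order 12), octahedral O
(order 24), and icosahedral I (order 60) — are constructed as explicit sets of
3x3 proper rotation matrices in a fixed canonical orientation:

* T and O: two-fold / four-fold axes along the coordinate axes.
* I: the "222" convention, with three mutually perpendicular two-fold axes
  along x, y, z; five-fold axes pass through icosahedron vertices at cyclic
  permutations of (0, +-1, +-phi), phi the golden ratio.

These orientations match common crystallographic and cryo-EM conventions, so
axis lists and dock identifiers are reproducible across runs and tools.

A one-component nanoparticle is built by placing a Cn-symmetric oligomer on a
group axis of matching order and applying one coset representative of the Cn
subgroup per building block: 60/3 = 20 trimers for icosahedra ("I3"),
24/4 = 6 tetramers for octahedra ("O4"), 12/2 = 6 dimers for tetrahedra
("T2").
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import Assembly, AssemblyChain, chain_id_for
from .errors import GroupAxisError, UnknownSymmetryError

#: golden ratio, fixes the icosahedral vertex coordinates
PHI = (1.0 + 5.0**0.5) / 2.0

#: numeric tolerance for group-theoretic identities (orthogonality, closure)
GROUP_TOL = 1e-9

#: numeric tolerance for coordinate identities after symmetry expansion (Angstrom)
COORD_TOL = 1e-6

GROUP_ORDERS = {"T": 12, "O": 24, "I": 60}


def rotation_matrix(direction, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about ``direction`` (right-handed)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * d).as_matrix()


@dataclass(frozen=True)
class RotationOp:
    """A proper rotation with its cyclic order (smallest k with R^k = I)."""

    matrix: np.ndarray
    order: int

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m @ m.T, np.eye(3), atol=GROUP_TOL):
            raise ValueError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(m) - 1.0) > 1e-9:
            raise ValueError("rotation matrix is not proper (det != +1)")

    @property
    def is_identity(self) -> bool:
        return self.order == 1


@dataclass(frozen=True)
class SymmetryAxis:
    """An (un)directed rotation axis of a point group.

    ``order`` is the maximal cyclic order realized about this direction in the
    parent group, so e.g. the coordinate axes of O are reported as four-fold,
    not two-fold. Axes are stored undirected (v ~ -v); the docking flip degree
    of freedom covers both orientations of a block on an axis.
    """

    direction: np.ndarray
    order: int
    directed: bool = False

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")


@dataclass(frozen=True)
class SymmetryGroup:
    symbol: str
    ops: tuple
    orientation_tag: str

    def __len__(self) -> int:
        return len(self.ops)

    @property
    def matrices(self) -> np.ndarray:
        return np.stack([op.matrix for op in self.ops])


@dataclass(frozen=True)
class Architecture:
    """Pairing of a point group with the cyclic order of its building block.

    The three one-component architectures place a Cn oligomer on a group axis
    of order n: T2 (six dimers, 12 chains), O4 (six tetramers, 24 chains),
    I3 (twenty trimers, 60 chains). ``clash_cutoff`` and ``contact_min``
    carry the architecture-specific dock filter defaults.
    """

    name: str
    group_symbol: str
    n: int
    n_building_blocks: int
    clash_cutoff: float
    contact_min: int

    def __post_init__(self):
        if self.n_building_blocks * self.n != GROUP_ORDERS[self.group_symbol]:
            raise ValueError("blocks x cyclic order must equal group order")

    @property
    def n_chains(self) -> int:
        return self.n_building_blocks * self.n


#: the three architectures with their published dock filter thresholds:
#: clashes are Ca pairs closer than 3 A (O4, I3) or 2.5 A (T2); at least 10
#: Ca contacts in 3-8 A are required for all architectures.
ARCHITECTURES = {
    "T2": Architecture("T2", "T", 2, 6, clash_cutoff=2.5, contact_min=10),
    "O4": Architecture("O4", "O", 4, 6, clash_cutoff=3.0, contact_min=10),
    "I3": Architecture("I3", "I", 3, 20, clash_cutoff=3.0, contact_min=10),
}


def get_architecture(name: str) -> Architecture:
    try:
        return ARCHITECTURES[name]
    except KeyError:
        raise UnknownSymmetryError(
            f"unknown architecture {name!r}; expected one of {sorted(ARCHITECTURES)}"
        ) from None


def _mat_key(m: np.ndarray, ndigits: int = 9) -> tuple:
    return tuple(np.round(m, ndigits).ravel() + 0.0)  # +0.0 folds -0.0 into 0.0


def _close_group(generators: list[np.ndarray]) -> list[np.ndarray]:
    """Close a generator set under matrix multiplication."""
    elements = {_mat_key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    while frontier:
        new = []
        for a in frontier:
            for g in generators:
                prod = g @ a
                key = _mat_key(prod)
                if key not in elements:
                    elements[key] = prod
                    new.append(prod)
        frontier = new
        if len(elements) > 60:
            raise RuntimeError("group closure exceeded order 60; bad generators")
    return list(elements.values())


def _element_order(m: np.ndarray, max_order: int = 60) -> int:
    p = np.eye(3)
    for k in range(1, max_order + 1):
        p = p @ m
        if np.allclose(p, np.eye(3), atol=GROUP_TOL * 10):
            return k
    raise RuntimeError("element order not found (matrix not of finite order)")


_GENERATORS = {
    "T": lambda: [rotation_matrix([0, 0, 1], 180.0), rotation_matrix([1, 1, 1], 120.0)],
    "O": lambda: [rotation_matrix([0, 0, 1], 90.0), rotation_matrix([1, 1, 1], 120.0)],
    "I": lambda: [
        rotation_matrix([0, 0, 1], 180.0),
        rotation_matrix([0, 1, PHI], 72.0),
        rotation_matrix([1, 1, 1], 120.0),
    ],
}

_ORIENTATION_TAGS = {
    "T": "2-folds along xyz",
    "O": "4-folds along xyz",
    "I": "I222 (2-folds along xyz, golden-ratio vertices)",
}


@functools.lru_cache(maxsize=None)
def point_group(symbol: str) -> SymmetryGroup:
    """Construct the cubic rotation group T, O, or I in canonical orientation.

    Element ordering is deterministic: identity first, then sorted by trace
    descending with a lexicographic matrix tie-break, so dock and chain
    identifiers derived from the op list are stable across runs.
    """
    if symbol not in _GENERATORS:
        raise UnknownSymmetryError(
            f"unknown point-group symbol {symbol!r}; expected 'T', 'O' or 'I'"
        )
    mats = _close_group(_GENERATORS[symbol]())
    if len(mats) != GROUP_ORDERS[symbol]:
        raise RuntimeError(
            f"group {symbol} closed to order {len(mats)}, expected {GROUP_ORDERS[symbol]}"
        )

    def sort_key(m):
        return (-round(np.trace(m), 9),) + _mat_key(m)

    identity = [m for m in mats if np.allclose(m, np.eye(3), atol=GROUP_TOL)]
    rest = sorted(
        (m for m in mats if not np.allclose(m, np.eye(3), atol=GROUP_TOL)),
        key=sort_key,
    )
    ops = tuple(RotationOp(m, _element_order(m)) for m in identity + rest)
    return SymmetryGroup(symbol=symbol, ops=ops, orientation_tag=_ORIENTATION_TAGS[symbol])


def _axis_of(matrix: np.ndarray) -> np.ndarray:
    """Unit rotation axis of a non-identity rotation, sign-canonicalized."""
    rv = Rotation.from_matrix(matrix).as_rotvec()
    d = rv / np.linalg.norm(rv)
    # undirected: first component of magnitude > 1e-8 made positive
    for c in d:
        if abs(c) > 1e-8:
            if c < 0:
                d = -d
            break
    return d


def _axis_groups(group: SymmetryGroup) -> dict:
    """Map undirected-axis key -> (direction, max cyclic order about it)."""
    axes: dict[tuple, list] = {}
    for op in group.ops:
        if op.is_identity:
            continue
        d = _axis_of(op.matrix)
        key = tuple(np.round(d, 5) + 0.0)
        if key in axes:
            axes[key][1] = max(axes[key][1], op.order)
        else:
            axes[key] = [d, op.order]
    return axes


def axes_of_order(group: SymmetryGroup, order: int) -> list[SymmetryAxis]:
    """Undirected symmetry axes whose maximal cyclic order equals ``order``.

    With maximal-order classification the census is the classical one:
    T = 3xC2 + 4xC3; O = 6xC2 + 4xC3 + 3xC4; I = 15xC2 + 10xC3 + 6xC5.
    Orders absent from the group yield an empty list.
    """
    if order not in (2, 3, 4, 5):
        raise ValueError(f"axis order must be in 2..5, got {order}")
    found = []
    for key in sorted(_axis_groups(group)):
        d, max_order = _axis_groups(group)[key]
        if max_order == order:
            found.append(SymmetryAxis(direction=d, order=order, directed=False))
    return found


def _cyclic_subgroup(group: SymmetryGroup, axis: SymmetryAxis, n: int) -> list[RotationOp]:
    """The Cn subgroup of rotations about ``axis`` (identity included)."""
    d = axis.direction
    sub = [
        op
        for op in group.ops
        if np.allclose(op.matrix @ d, d, atol=1e-8) and n % op.order == 0
    ]
    if len(sub) != n:
        raise GroupAxisError(
            f"group {group.symbol} has no C{n} subgroup about axis {np.round(d, 4)}"
        )
    return sub


def coset_representatives(
    group: SymmetryGroup, axis: SymmetryAxis, n: int
) -> list[RotationOp]:
    """One representative per left coset of the Cn subgroup about ``axis``.

    Applying the |group|/n representatives to a Cn-symmetric building block
    tiles the whole group without duplicating any chain: 20 for a trimer on
    an icosahedral 3-fold, 6 for a dimer on a tetrahedral 2-fold, 6 for a
    tetramer on an octahedral 4-fold. The identity is always the first
    representative (the reference block).
    """
    sub = _cyclic_subgroup(group, axis, n)
    reps: list[RotationOp] = []
    covered: set[tuple] = set()
    for op in group.ops:
        coset_key = min(_mat_key(op.matrix @ s.matrix, 8) for s in sub)
        if coset_key not in covered:
            covered.add(coset_key)
            reps.append(op)
    assert len(reps) == len(group) // n
    return reps


def expand_asu(
    block_chains: list[np.ndarray],
    group: SymmetryGroup,
    axis: SymmetryAxis,
    n: int,
    sequence: str = "",
    resids: np.ndarray | None = None,
    architecture: str | None = None,
    provenance="external",
) -> Assembly:
    """Expand one placed Cn building block into the full assembly.

    ``block_chains`` are the n chains (Ca coordinate arrays) of the block,
    already positioned on ``axis``. Chain 0 of block 0 is the input chain 0
    bitwise (the first coset representative is the identity). Provenance
    (block index per chain) is recorded for downstream clash/contact logic.
    """
    if len(block_chains) != n:
        raise GroupAxisError(
            f"building block has {len(block_chains)} chains; expected n={n}"
        )
    reps = coset_representatives(group, axis, n)
    chains = []
    idx = 0
    for block_index, rep in enumerate(reps):
        for local in block_chains:
            coords = local @ rep.matrix.T
            chains.append(
                AssemblyChain(
                    chain_id=chain_id_for(idx),
                    block_index=block_index,
                    coords=coords,
                    sequence=sequence,
                    resids=(
                        resids.copy()
                        if resids is not None
                        else np.arange(1, len(local) + 1)
                    ),
                )
            )
            idx += 1
    return Assembly(chains=chains, architecture=architecture, provenance=provenance)


def group_to_json(group: SymmetryGroup) -> str:
    """Serialize a group (matrices row-major, 17 significant digits)."""
    payload = {
        "symbol": group.symbol,
        "orientation_tag": group.orientation_tag,
        "ops": [
            {
                "order": op.order,
                "matrix": [float(f"{x:.17g}") for x in op.matrix.ravel()],
            }
            for op in group.ops
        ],
    }
    return json.dumps(payload, indent=1)


def axes_to_json(group: SymmetryGroup) -> str:
    payload = []
    for order in (2, 3, 4, 5):
        for ax in axes_of_order(group, order):
            payload.append(
                {
                    "order": order,
                    "direction": [float(f"{x:.17g}") for x in ax.direction],
                    "directed": ax.directed,
                }
            )
    return json.dumps(payload, indent=1)
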