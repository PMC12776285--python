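"""Cyclic oligomeric building blocks.

A building block is a Cn homo-oligomer: n identical chains related by
rotations of 360/n degrees about a common axis. Generative backbone design
produces such oligomers as the input to symmetric docking; here a synthetic
generator stands in for that step, producing idealized Cn oligomers of 150- or
200-residue protomers with *exact* internal cyclic symmetry, plus an optional
axis-centered C3 coiled-coil motif stub emulating an antigen anchor (the
C-terminal residues at the base of a trimeric coiled coil).

The module also detects the cyclic axis of an arbitrary oligomer, reduces it
to a canonical frame (axis on +z, centroid at origin, chain-0 azimuth zero)
so that the docking degrees of freedom are well-defined, and verifies motif
placement on the symmetry axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import AsymmetricBlockError, BuildingBlockError, MotifError

#: default Ca RMSD tolerance for accepting an oligomer as Cn-symmetric (Angstrom)
SYMMETRY_TOL = 0.5

#: the 20 canonical one-letter amino-acid codes
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# ideal alpha-helix Ca-trace parameters
_HELIX_RADIUS = 2.30  # A
_HELIX_RISE = 1.51  # A per residue
_HELIX_TWIST = 99.6  # degrees per residue

#: superhelical radius of an idealized trimeric coiled coil (A)
_COIL_RADIUS = 6.5


class MotifAnnotation(NamedTuple):
    """Inclusive 1-based residue span of a scaffolded motif, per chain."""

    start: int
    end: int
    expected_symmetry: int
    description: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class AxisFit(NamedTuple):
    """Result of cyclic-axis detection."""

    direction: np.ndarray  # unit vector
    angle_deg: float  # rotation angle of the fitted cyclic generator
    symmetry_rmsd: float  # Ca RMSD of the optimal cyclic superposition
    symmetric: bool  # symmetry_rmsd <= tolerance


@dataclass
class BuildingBlock:
    """A Cn oligomer: n equal chains of Ca coordinates plus one sequence.

    The homomer contract is enforced: all chains share length and sequence.
    ``axis`` (a unit direction; the axis line passes through the oligomer
    centroid) is present once detected or by construction. Residue numbering
    is 1-based and contiguous per chain.
    """

    chains: list[np.ndarray]
    sequence: str
    name: str = "bb"
    axis: np.ndarray | None = None
    motif: MotifAnnotation | None = None

    def __post_init__(self):
        if len(self.chains) < 2:
            raise BuildingBlockError("a building block needs at least 2 chains")
        self.chains = [np.asarray(c, dtype=float) for c in self.chains]
        lengths = [len(c) for c in self.chains]
        if len(set(lengths)) != 1:
            short = int(np.argmin(lengths))
            raise BuildingBlockError(
                f"homomer contract violated: chain {short} has {lengths[short]} "
                f"residues, others have {sorted(set(lengths))}"
            )
        if len(self.sequence) != lengths[0]:
            raise BuildingBlockError(
                f"sequence length {len(self.sequence)} != chain length {lengths[0]}"
            )
        if self.motif is not None and self.motif.end > lengths[0]:
            raise BuildingBlockError("motif span exceeds chain length")

    @property
    def n(self) -> int:
        """Cyclic order = number of chains."""
        return len(self.chains)

    @property
    def protomer_len(self) -> int:
        return len(self.chains[0])

    def centroid(self) -> np.ndarray:
        return np.concatenate(self.chains).mean(axis=0)

    def stacked(self) -> np.ndarray:
        return np.concatenate(self.chains, axis=0)

    def circumradius(self) -> float:
        """Largest Ca distance from the oligomer centroid (A)."""
        return float(np.linalg.norm(self.stacked() - self.centroid(), axis=1).max())

    def copy(self) -> "BuildingBlock":
        return BuildingBlock(
            chains=[c.copy() for c in self.chains],
            sequence=self.sequence,
            name=self.name,
            axis=None if self.axis is None else self.axis.copy(),
            motif=self.motif,
        )

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "BuildingBlock":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return BuildingBlock(
            chains=[c @ R.T + t for c in self.chains],
            sequence=self.sequence,
            name=self.name,
            axis=None if self.axis is None else R @ self.axis,
            motif=self.motif,
        )


# ---------------------------------------------------------------------------
# synthetic generator


def _helix_trace(n_res: int, phase_deg: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix Ca trace along +z, starting at z = 0."""
    i = np.arange(n_res)
    ang = np.deg2rad(phase_deg + _HELIX_TWIST * i)
    return np.column_stack(
        [_HELIX_RADIUS * np.cos(ang), _HELIX_RADIUS * np.sin(ang), _HELIX_RISE * i]
    )


def _hairpin_protomer(length: int, rng: np.random.Generator) -> np.ndarray:
    """Two antiparallel ideal helices joined by a short loop, axis along z.

    The hairpin is laid out radially (helix centers offset along x) so that
    protomers arranged about the z axis at moderate radius stay clash-free
    for all supported cyclic orders.
    """
    n_loop = 4
    n_up = (length - n_loop) // 2
    n_down = length - n_loop - n_up
    up = _helix_trace(n_up) + np.array([-5.0, 0.0, 0.0])
    down = _helix_trace(n_down)[::-1]  # antiparallel: runs back down in z
    down = down + np.array([5.0, 0.0, up[-1, 2] - down[0, 2]])
    # loop interpolates between helix ends, bulging +z
    t = np.linspace(0.0, 1.0, n_loop + 2)[1:-1, None]
    loop = up[-1] * (1 - t) + down[0] * t
    loop[:, 2] += 2.5 * np.sin(np.pi * t[:, 0])
    trace = np.vstack([up, loop, down])
    trace += rng.normal(scale=0.15, size=trace.shape)  # mild backbone texture
    return trace - trace.mean(axis=0)


def _zigzag_protomer(length: int, rng: np.random.Generator) -> np.ndarray:
    """Degenerate fast-test trace: a zigzag ladder rising along z."""
    i = np.arange(length)
    trace = np.column_stack(
        [1.0 * (-1.0) ** i, np.zeros(length), 1.9 * i]
    )
    trace += rng.normal(scale=0.05, size=trace.shape)
    return trace - trace.mean(axis=0)


_STYLES = {"helical_bundle": _hairpin_protomer, "zigzag": _zigzag_protomer}


def synth_cn(
    n: int,
    protomer_len: int,
    style: str = "helical_bundle",
    seed: int = 0,
    radius: float = 11.0,
    name: str | None = None,
) -> BuildingBlock:
    """Synthesize an idealized Cn oligomer with exact internal symmetry.

    One protomer is generated (deterministically for a fixed seed), placed
    with its centroid ``radius`` Angstrom from the z axis, and rotated into
    n copies, so the cyclic symmetry is exact by construction. The sequence
    is a seed-determined random draw from the 20-letter alphabet, shared by
    all chains (homomer).

    Parameters are validated: n in {2, 3, 4}, protomer_len in [30, 400].
    The generated chains are internally clash-free (min inter-chain Ca
    distance >= 3.5 A), which is asserted.
    """
    if n not in (2, 3, 4):
        raise BuildingBlockError(f"cyclic order n={n} out of supported range {{2,3,4}}")
    if not 30 <= protomer_len <= 400:
        raise BuildingBlockError(
            f"protomer_len={protomer_len} outside supported range [30, 400]"
        )
    if style not in _STYLES:
        raise BuildingBlockError(f"unknown style {style!r}; expected {sorted(_STYLES)}")
    rng = np.random.default_rng(seed)
    protomer = _STYLES[style](protomer_len, rng) + np.array([radius, 0.0, 0.0])
    chains = [
        protomer @ Rotation.from_euler("z", 360.0 * k / n, degrees=True).as_matrix().T
        for k in range(n)
    ]
    sequence = "".join(rng.choice(list(AA_ALPHABET), size=protomer_len))
    bb = BuildingBlock(
        chains=chains,
        sequence=sequence,
        name=name or f"synC{n}L{protomer_len}s{seed}",
        axis=np.array([0.0, 0.0, 1.0]),
    )
    min_sep = min(
        cdist(chains[0], chains[k]).min() for k in range(1, n)
    )
    if min_sep < 3.5:
        raise BuildingBlockError(
            f"generated chains clash (min inter-chain Ca distance {min_sep:.2f} A); "
            f"increase radius"
        )
    return bb


# ---------------------------------------------------------------------------
# axis detection and canonicalization


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation R, translation t with R @ P + t ~= Q; returns rmsd."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - cq, P - cp)
    R = rot.as_matrix()
    rmsd = rssd / np.sqrt(len(P))
    t = cq - R @ cp
    return R, t, float(rmsd)


def detect_cyclic_axis(bb: BuildingBlock, symmetry_tol: float = SYMMETRY_TOL) -> AxisFit:
    """Detect the cyclic symmetry axis of an oligomer.

    The cyclic generator is fitted as the single optimal rigid superposition
    mapping the chain concatenation (0, 1, ..., n-1) onto its cyclic shift
    (1, ..., n-1, 0); its rotation axis is the symmetry axis and its RMSD the
    reported symmetry deviation. Fitting all cyclic pair mappings jointly is
    better conditioned than averaging per-pair fits and is exact for a true
    Cn oligomer.

    The axis direction is oriented so that a positive (right-handed) rotation
    by ~360/n maps chain i onto chain i+1. The fit is flagged not-Cn-symmetric
    when the RMSD exceeds ``symmetry_tol``.
    """
    n = bb.n
    P = np.concatenate(bb.chains, axis=0)
    Q = np.concatenate(bb.chains[1:] + bb.chains[:1], axis=0)
    R, _, rmsd = _kabsch(P, Q)
    rv = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rv)))
    if angle < 1e-6:
        # degenerate (all chains coincident); report +z with infinite deviation
        return AxisFit(np.array([0.0, 0.0, 1.0]), 0.0, float("inf"), False)
    direction = rv / np.linalg.norm(rv)
    angle_ok = abs(angle - 360.0 / n) <= 15.0
    return AxisFit(direction, angle, rmsd, bool(rmsd <= symmetry_tol and angle_ok))


def _frame_to_z(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``direction`` to +z (minimal rotation)."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(d, z, atol=1e-12):
        return np.eye(3)
    if np.allclose(d, -z, atol=1e-12):
        return Rotation.from_euler("x", 180.0, degrees=True).as_matrix()
    axis = np.cross(d, z)
    axis /= np.linalg.norm(axis)
    ang = np.arccos(np.clip(d @ z, -1.0, 1.0))
    return Rotation.from_rotvec(ang * axis).as_matrix()


def _canonical_given_axis(bb: BuildingBlock, direction: np.ndarray) -> BuildingBlock:
    center = bb.centroid()
    A = _frame_to_z(direction)
    chains = [(c - center) @ A.T for c in bb.chains]
    # fix the in-plane orientation: chain-0 centroid azimuth = 0
    ref = chains[0].mean(axis=0)
    if np.hypot(ref[0], ref[1]) < 1e-6:
        ref = chains[0][0]  # chain centroid on the axis: fall back to residue 1
    az = np.arctan2(ref[1], ref[0])
    Rz = Rotation.from_euler("z", -az).as_matrix()
    chains = [c @ Rz.T for c in chains]
    return BuildingBlock(
        chains=chains,
        sequence=bb.sequence,
        name=bb.name,
        axis=np.array([0.0, 0.0, 1.0]),
        motif=bb.motif,
    )


def _is_canonical(bb: BuildingBlock, fit: AxisFit) -> bool:
    if abs(fit.direction[2] - 1.0) > 1e-9 or np.abs(fit.direction[:2]).max() > 1e-9:
        return False
    if np.abs(bb.centroid()).max() > 1e-9:
        return False
    ref = bb.chains[0].mean(axis=0)
    if np.hypot(ref[0], ref[1]) < 1e-6:
        ref = bb.chains[0][0]
    return bool(abs(np.arctan2(ref[1], ref[0])) <= 1e-9)


def canonicalize(bb: BuildingBlock, symmetry_tol: float = SYMMETRY_TOL) -> BuildingBlock:
    """Map a Cn oligomer to its canonical frame.

    Axis on +z, centroid at the origin, chain-0 centroid azimuth zero. The
    result is invariant under rigid pre-motion of the input and the map is
    idempotent (a block already in canonical position is returned bitwise
    unchanged). For dimers, whose axis direction is sign-ambiguous, both
    orientations are tried and the lexicographically smaller coordinate array
    (rounded to 1e-6 A) is kept, which keeps the choice rigid-motion
    invariant.
    """
    fit = detect_cyclic_axis(bb, symmetry_tol)
    if not fit.symmetric:
        raise AsymmetricBlockError(
            f"block {bb.name!r} is not C{bb.n}-symmetric "
            f"(symmetry RMSD {fit.symmetry_rmsd:.3f} A > tol {symmetry_tol} A)"
        )
    if _is_canonical(bb, fit):
        return bb.copy()
    cand = _canonical_given_axis(bb, fit.direction)
    if bb.n == 2:
        alt = _canonical_given_axis(bb, -fit.direction)
        ka = np.round(cand.stacked(), 6).tobytes()
        kb = np.round(alt.stacked(), 6).tobytes()
        if kb < ka:
            cand = alt
    return cand


# ---------------------------------------------------------------------------
# motif scaffolding


class MotifReport(NamedTuple):
    axis_offset: float  # distance from motif centroid to the block axis (A)
    symmetry_rmsd: float  # cyclic-superposition RMSD over motif residues (A)
    on_axis: bool


def attach_motif(
    bb: BuildingBlock,
    motif_len: int = 7,
    geometry: str = "c_terminal_coiled_coil",
    symmetry_tol: float = SYMMETRY_TOL,
) -> BuildingBlock:
    """Append an idealized axis-centered C3 coiled-coil stub to each chain.

    Emulates a trimeric-antigen anchor: the C-terminal residues at the base of
    a trimeric coiled coil, placed on the oligomer's three-fold axis. Each
    chain grows by ``motif_len`` residues forming one strand of an idealized
    three-helix coiled coil (superhelical radius 6.5 A) just beyond the
    block's top along its axis. Pre-existing residue coordinates are preserved
    bitwise. The motif sequence is a poly-alanine placeholder — motif residues
    are sequence-variable during design — and the recorded annotation excludes
    the span from alanine-run sequence filters.

    Only defined for C3 blocks (the geometry is a trimeric coiled coil).
    """
    if bb.n != 3:
        raise MotifError(f"coiled-coil motif geometry requires a C3 block, got C{bb.n}")
    if motif_len < 1:
        raise MotifError("motif_len must be >= 1")
    if geometry != "c_terminal_coiled_coil":
        raise MotifError(f"unknown motif geometry {geometry!r}")
    fit = detect_cyclic_axis(bb, symmetry_tol)
    if not fit.symmetric:
        raise AsymmetricBlockError(
            f"cannot place motif on asymmetric block (RMSD {fit.symmetry_rmsd:.3f} A)"
        )
    center = bb.centroid()
    A = _frame_to_z(fit.direction)  # block frame -> axis-aligned frame
    # top of the block along the axis, in the axis-aligned frame
    zmax = max(((c - center) @ A.T)[:, 2].max() for c in bb.chains)
    # stub strand for chain 0: short ideal helix at the coiled-coil radius,
    # azimuth taken from chain 0 so strands interleave with their chains
    ref = (bb.chains[0].mean(axis=0) - center) @ A.T
    az0 = np.arctan2(ref[1], ref[0]) if np.hypot(ref[0], ref[1]) > 1e-6 else 0.0
    strand = _helix_trace(motif_len)
    strand = strand - strand.mean(axis=0)
    base = np.array(
        [_COIL_RADIUS * np.cos(az0), _COIL_RADIUS * np.sin(az0), 0.0]
    )
    strand = strand + base + np.array([0.0, 0.0, zmax + 4.0 + _HELIX_RISE * motif_len / 2.0])
    new_chains = []
    for k in range(3):
        Rz = Rotation.from_euler("z", 120.0 * k, degrees=True).as_matrix()
        stub_frame = strand @ Rz.T
        stub = stub_frame @ A + center  # back to the original frame (A.T inverse)
        new_chains.append(np.vstack([bb.chains[k], stub]))
    span = MotifAnnotation(
        start=bb.protomer_len + 1,
        end=bb.protomer_len + motif_len,
        expected_symmetry=3,
        description="idealized C-terminal trimeric coiled-coil anchor stub",
    )
    return BuildingBlock(
        chains=new_chains,
        sequence=bb.sequence + "A" * motif_len,
        name=bb.name + "-motif",
        axis=None if bb.axis is None else bb.axis.copy(),
        motif=span,
    )


def check_motif_placement(
    bb: BuildingBlock,
    axis_tol: float = 1.0,
    symmetry_tol: float = SYMMETRY_TOL,
) -> MotifReport:
    """Verify that the annotated motif sits on the block's symmetry axis.

    ``axis_offset`` is the perpendicular distance from the motif Ca centroid
    to the block axis (the line through the block centroid along the detected
    axis direction). The motif's own cyclic symmetry is measured by the same
    joint superposition used for whole-block axis detection, restricted to
    motif residues. ``on_axis`` requires both the offset and the symmetry
    deviation to be within tolerance.
    """
    if bb.motif is None:
        raise MotifError(f"block {bb.name!r} carries no motif annotation")
    if bb.axis is not None:
        # trust the stored axis: re-detection on a motif-perturbed block
        # would partially absorb the very deviation being measured
        direction = bb.axis / np.linalg.norm(bb.axis)
    else:
        direction = detect_cyclic_axis(bb, symmetry_tol=np.inf).direction
    lo, hi = bb.motif.start - 1, bb.motif.end
    motif_chains = [c[lo:hi] for c in bb.chains]
    centroid = np.concatenate(motif_chains).mean(axis=0)
    rel = centroid - bb.centroid()
    offset = float(np.linalg.norm(rel - (rel @ direction) * direction))
    P = np.concatenate(motif_chains, axis=0)
    Q = np.concatenate(motif_chains[1:] + motif_chains[:1], axis=0)
    if len(motif_chains[0]) >= 3:
        _, _, motif_rmsd = _kabsch(P, Q)
    else:  # too few points for a meaningful fit; use the block generator
        gen = Rotation.from_rotvec(
            np.deg2rad(360.0 / bb.n) * direction
        ).as_matrix()
        moved = (P - bb.centroid()) @ gen.T + bb.centroid()
        motif_rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    on_axis = offset <= axis_tol and motif_rmsd <= symmetry_tol
    return MotifReport(axis_offset=offset, symmetry_rmsd=float(motif_rmsd), on_axis=bool(on_axis))


# ---------------------------------------------------------------------------
# file ingestion


def load_oligomer(path, model_index: int = 0, name: str | None = None) -> BuildingBlock:
    """Load a Cn oligomer from a PDB/mmCIF file (Ca atoms required).

    Chains are kept in file order; the homomer contract (>= 2 chains, equal
    lengths, identical sequences) is enforced at construction.
    """
    from . import structio

    chains = structio.read_structure(path, model_index=model_index)
    if len(chains) < 2:
        raise BuildingBlockError(
            f"{path}: an oligomer needs >= 2 chains, found {len(chains)}"
        )
    seqs = {c.sequence for c in chains}
    if len(seqs) > 1:
        raise BuildingBlockError(f"{path}: chains have differing sequences (homomer contract)")
    return BuildingBlock(
        chains=[c.coords for c in chains],
        sequence=chains[0].sequence,
        name=name or str(path),
    )
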