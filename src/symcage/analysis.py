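"""Symmetry-aware structure comparison and interface composition.

Comparing a designed nanoparticle with an experimental structure requires a
chain correspondence: the 12/24/60 chains of the two assemblies can be
relabeled by any symmetry operation without changing the structure. RMSDs are
therefore minimized over candidate correspondences found by *anchored
propagation*: superpose one model chain onto each reference chain in turn,
propagate the implied mapping to all chains by nearest-centroid assignment
(solved as a linear assignment problem), and keep the correspondence with the
lowest global Ca RMSD. For near-symmetric structures this recovers the exact
optimal permutation without searching all 60! relabelings.

Comparison is offered at the three levels used to judge design accuracy:

* ``full_assembly`` — all chains at once;
* ``interface_pair`` — the two building blocks sharing the highest-contact
  (two-fold) nanoparticle interface;
* ``building_block`` — a single oligomer.

Interface composition is characterized by the hydrophobic fraction of
interface residues, where a residue is at an interface when its Ca lies
within 8 A (the contact-band upper bound) of any Ca in a partner chain —
within the same building block for the oligomeric interface, across blocks
for the nanoparticle interface. The hydrophobic set defaults to
{A, V, L, I, M, F, W, C} and is always reported alongside the fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .assembly import Assembly, AssemblyChain
from .docking import contact_count, _cross_block_pairs
from .errors import AnalysisError

#: default apolar residue classification
HYDROPHOBIC_DEFAULT = frozenset("AVLIMFWC")

RMSD_LEVELS = ("full_assembly", "interface_pair", "building_block")


class ChainMap(NamedTuple):
    """Bijection model-chain index -> reference-chain index."""

    pairs: tuple  # ((model_idx, ref_idx), ...)
    n_residues: int  # mapped residues per chain after trimming


@dataclass(frozen=True)
class RMSDReport:
    level: str
    rmsd: float
    n_atoms: int
    chain_map: ChainMap


@dataclass(frozen=True)
class InterfaceReport:
    interface_class: str  # "oligomeric" | "nanoparticle"
    residues: frozenset  # of (chain_id, residue id)
    hydrophobic_fraction: float | None
    hydrophobic_set_used: frozenset


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray):
    """Least-squares optimal rigid superposition of two Ca coordinate lists.

    Returns ``(rmsd, rotation, translation)`` such that
    ``P @ rotation.T + translation`` optimally superposes P onto Q. The
    rotation is proper (no reflection). Requires equal lengths and at least
    3 points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise AnalysisError(f"coordinate shapes differ: {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise AnalysisError("superposition needs at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - cq, P - cp)
    R = rot.as_matrix()
    return float(rssd / np.sqrt(len(P))), R, cq - R @ cp


def _trim_chains(chains: list[AssemblyChain], length: int) -> list[np.ndarray]:
    # unresolved termini are trimmed from the C-terminal end
    return [c.coords[:length] for c in chains]


def _correspondence_rmsd(
    mcoords: list[np.ndarray], rcoords: list[np.ndarray]
) -> tuple[float, tuple]:
    """Min global RMSD over anchored-propagation chain correspondences."""
    n = len(rcoords)
    mcent = np.stack([c.mean(axis=0) for c in mcoords])
    rcent = np.stack([c.mean(axis=0) for c in rcoords])
    best = (np.inf, tuple((i, i) for i in range(n)))
    for anchor in range(n):
        _, R, t = kabsch_rmsd(mcoords[0], rcoords[anchor])
        moved = mcent @ R.T + t
        cost = np.linalg.norm(moved[:, None, :] - rcent[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        order = dict(zip(rows, cols))
        P = np.concatenate(mcoords)
        Q = np.concatenate([rcoords[order[i]] for i in range(n)])
        rmsd, _, _ = kabsch_rmsd(P, Q)
        if rmsd < best[0]:
            best = (rmsd, tuple((i, int(order[i])) for i in range(n)))
    return best


def _interface_pair_blocks(asm: Assembly) -> tuple[int, int]:
    """Reference block and its highest-contact neighbor."""
    pairs, dists, labels = _cross_block_pairs(asm, 8.0)
    ref = asm.block_indices()[0]
    if len(pairs) == 0:
        raise AnalysisError("assembly has no inter-block contacts within 8 A")
    b = labels[pairs]
    involves = (b[:, 0] == ref) | (b[:, 1] == ref)
    partners = np.where(b[:, 0] == ref, b[:, 1], b[:, 0])[involves]
    if len(partners) == 0:
        raise AnalysisError("reference block has no neighbors within 8 A")
    return ref, int(np.bincount(partners).argmax())


def symmetric_rmsd(model: Assembly, ref: Assembly, level: str = "full_assembly") -> RMSDReport:
    """Ca RMSD between two assemblies, minimized over chain correspondence.

    The two assemblies must share an architecture (same chain count and
    block structure); chains are compared by residue index after trimming
    both to the shorter common length. The reported value is symmetric in
    its arguments (the search is run in both directions and the minimum
    kept).
    """
    if level not in RMSD_LEVELS:
        raise AnalysisError(f"unknown RMSD level {level!r}; expected {RMSD_LEVELS}")
    if model.n_chains != ref.n_chains or model.n_blocks != ref.n_blocks:
        raise AnalysisError(
            f"architecture mismatch: {model.n_chains} chains/{model.n_blocks} blocks "
            f"vs {ref.n_chains}/{ref.n_blocks}"
        )
    length = min(model.chain_length, ref.chain_length)
    if length < 3:
        raise AnalysisError("chains too short to superpose")

    if level == "full_assembly":
        msel, rsel = model.chains, ref.chains
    elif level == "building_block":
        # the reference oligomer matching model block 0 is taken from the
        # full-assembly chain correspondence (choosing the best-RMSD block
        # among all reference blocks would bias the estimate low when every
        # block carries independent experimental error)
        full = symmetric_rmsd(model, ref, "full_assembly")
        mapping = dict(full.chain_map.pairs)
        msel = model.block(model.block_indices()[0])
        midx = {id(c): i for i, c in enumerate(model.chains)}
        rsel = [ref.chains[mapping[midx[id(c)]]] for c in msel]
    else:  # interface_pair
        mb = _interface_pair_blocks(model)
        rb = _interface_pair_blocks(ref)
        msel = model.block(mb[0]) + model.block(mb[1])
        rsel = ref.block(rb[0]) + ref.block(rb[1])

    mcoords = _trim_chains(msel, length)
    rcoords = _trim_chains(rsel, length)
    if len(mcoords) != len(rcoords):
        raise AnalysisError("unmappable chains: selections differ in chain count")
    best = _correspondence_rmsd(mcoords, rcoords)
    rev = _correspondence_rmsd(rcoords, mcoords)
    if rev[0] < best[0]:
        best = (rev[0], tuple((m, r) for r, m in rev[1]))

    rmsd, pairs = best
    if not np.isfinite(rmsd):
        raise AnalysisError("no admissible chain correspondence found")
    return RMSDReport(
        level=level,
        rmsd=float(rmsd),
        n_atoms=length * len(pairs),
        chain_map=ChainMap(pairs=pairs, n_residues=length),
    )


# ---------------------------------------------------------------------------
# interface composition


def interface_residues(asm: Assembly, interface_class: str, contact_hi: float = 8.0):
    """Residues whose Ca lies within ``contact_hi`` of a partner-class chain.

    ``oligomeric`` pairs chains within one building block (the interface
    fixed by backbone generation); ``nanoparticle`` pairs chains across
    building blocks (the designed assembly interface). Returns a set of
    (chain_id, residue id) pairs.
    """
    if interface_class not in ("oligomeric", "nanoparticle"):
        raise AnalysisError(f"unknown interface class {interface_class!r}")
    from scipy.spatial import cKDTree

    X = asm.stacked_coords()
    blocks = asm.atom_block_labels()
    chains = asm.atom_chain_labels()
    tree = cKDTree(X)
    pairs = tree.query_pairs(contact_hi, output_type="ndarray")
    residues: set = set()
    if len(pairs) == 0:
        return residues
    same_block = blocks[pairs[:, 0]] == blocks[pairs[:, 1]]
    diff_chain = chains[pairs[:, 0]] != chains[pairs[:, 1]]
    if interface_class == "oligomeric":
        keep = pairs[same_block & diff_chain]
    else:
        keep = pairs[~same_block]
    offsets = np.cumsum([0] + [len(c) for c in asm.chains])
    for atom in np.unique(keep.ravel()):
        ci = int(chains[atom])
        chain = asm.chains[ci]
        resid = int(chain.resids[atom - offsets[ci]])
        residues.add((chain.chain_id, resid))
    return residues


def hydrophobic_fraction(
    asm: Assembly,
    residues,
    hydrophobic_set=HYDROPHOBIC_DEFAULT,
) -> float | None:
    """Exact hydrophobic fraction of an interface residue set.

    Residues are resolved to one-letter codes through each chain's sequence.
    An empty set has no defined fraction and yields None (never 0).
    """
    if not residues:
        return None
    by_id = {c.chain_id: c for c in asm.chains}
    total = 0
    hydro = 0
    for chain_id, resid in residues:
        chain = by_id[chain_id]
        pos = np.flatnonzero(chain.resids == resid)
        if len(pos) != 1:
            raise AnalysisError(f"residue {resid} not resolvable on chain {chain_id}")
        letter = chain.sequence[int(pos[0])]
        total += 1
        hydro += letter in hydrophobic_set
    return hydro / total


def interface_report(
    asm: Assembly,
    interface_class: str,
    contact_hi: float = 8.0,
    hydrophobic_set=HYDROPHOBIC_DEFAULT,
) -> InterfaceReport:
    residues = interface_residues(asm, interface_class, contact_hi)
    return InterfaceReport(
        interface_class=interface_class,
        residues=frozenset(residues),
        hydrophobic_fraction=hydrophobic_fraction(asm, residues, hydrophobic_set),
        hydrophobic_set_used=frozenset(hydrophobic_set),
    )
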