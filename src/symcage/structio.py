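"""PDB/mmCIF structure I/O (gemmi-backed) and FASTA/JSON sidecar export.

mmCIF is the canonical output format (it carries arbitrarily many chains and
long chain IDs); legacy PDB is offered for assemblies of at most 62 chains,
using the single-character auth chain alphabet A-Z, a-z, 0-9 in provenance
order. Coordinates are Angstrom throughout; residues are numbered 1-based
and contiguous per chain. Round-trips preserve Ca coordinates to format
precision (1e-3 A for PDB).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .assembly import Assembly, AssemblyChain, CHAIN_ALPHABET
from .errors import StructureIOError

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass
class ChainModel:
    """One chain as read from a file: Ca trace plus sequence."""

    chain_id: str
    coords: np.ndarray
    sequence: str
    resids: np.ndarray


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def read_structure(path, model_index: int = 0) -> list[ChainModel]:
    """Read a PDB/mmCIF file into per-chain Ca models.

    Residues missing a Ca atom are rejected with their identities listed.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"{path}: cannot parse structure file: {exc}") from exc
    if len(st) == 0:
        raise StructureIOError(f"{path}: file contains no models")
    if model_index >= len(st):
        raise StructureIOError(
            f"{path}: model index {model_index} out of range (file has {len(st)})"
        )
    st.setup_entities()
    model = st[model_index]
    chains = []
    for chain in model:
        coords, seq, resids, missing = [], [], [], []
        for res in chain:
            if not gemmi.find_tabulated_residue(res.name) or not gemmi.find_tabulated_residue(res.name).is_amino_acid():
                continue
            ca = res.find_atom("CA", "\0")
            if ca is None:
                missing.append(f"{chain.name}/{res.name}{res.seqid.num}")
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            seq.append(_one_letter(res.name))
            resids.append(res.seqid.num)
        if missing:
            raise StructureIOError(
                f"{path}: residues missing Ca atoms: {', '.join(missing)}"
            )
        if coords:
            chains.append(
                ChainModel(
                    chain_id=chain.name,
                    coords=np.asarray(coords, dtype=float),
                    sequence="".join(seq),
                    resids=np.asarray(resids, dtype=int),
                )
            )
    if not chains:
        raise StructureIOError(f"{path}: no protein chains with Ca atoms found")
    return chains


def assembly_to_gemmi(asm: Assembly, name: str = "symcage") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for chain_rec in asm.chains:
        chain = gemmi.Chain(chain_rec.chain_id)
        for i, xyz in enumerate(chain_rec.coords):
            res = gemmi.Residue()
            letter = chain_rec.sequence[i] if i < len(chain_rec.sequence) else "G"
            res.name = _ONE_TO_THREE.get(letter, "GLY")
            res.seqid = gemmi.SeqId(int(chain_rec.resids[i]), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(asm: Assembly, path, fmt: str | None = None) -> None:
    """Write an assembly as mmCIF (canonical) or legacy PDB (<= 62 chains)."""
    path = str(path)
    if fmt is None:
        fmt = "pdb" if path.endswith(".pdb") else "mmcif"
    if fmt not in ("pdb", "mmcif"):
        raise StructureIOError(f"unknown structure format {fmt!r}")
    if fmt == "pdb" and asm.n_chains > len(CHAIN_ALPHABET):
        raise StructureIOError(
            f"legacy PDB supports at most {len(CHAIN_ALPHABET)} chains; "
            f"assembly has {asm.n_chains} (use mmCIF)"
        )
    st = assembly_to_gemmi(asm)
    if fmt == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


def read_assembly(path, model_index: int = 0, block_size: int | None = None) -> Assembly:
    """Read an assembly; chains grouped into building blocks of ``block_size``.

    With ``block_size`` None every chain is its own block (external structures
    carry no provenance).
    """
    chains = read_structure(path, model_index)
    if block_size is None:
        block_size = 1
    if len(chains) % block_size:
        raise StructureIOError(
            f"{path}: {len(chains)} chains not divisible into blocks of {block_size}"
        )
    recs = [
        AssemblyChain(
            chain_id=c.chain_id,
            block_index=i // block_size,
            coords=c.coords,
            sequence=c.sequence,
            resids=c.resids,
        )
        for i, c in enumerate(chains)
    ]
    return Assembly(chains=recs, architecture=None, provenance="external")


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def block_to_assembly(bb, architecture: str | None = None) -> Assembly:
    """View a lone building block as a single-block assembly (for writing)."""
    recs = [
        AssemblyChain(
            chain_id=CHAIN_ALPHABET[i],
            block_index=0,
            coords=c,
            sequence=bb.sequence,
        )
        for i, c in enumerate(bb.chains)
    ]
    return Assembly(chains=recs, architecture=architecture, provenance="external")
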