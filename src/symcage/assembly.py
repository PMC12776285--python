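"""Assembly container: the fully expanded nanoparticle.

An :class:`Assembly` holds all 12/24/60 chains of a one-component nanoparticle
with chain -> building-block provenance, which the docking filters need to
distinguish the designable inter-block interface from the fixed intra-oligomer
one.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

#: auth chain-ID alphabet for legacy PDB output: A..Z, a..z, 0..9 (62 symbols)
CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_for(index: int) -> str:
    """Chain identifier in provenance order; single characters up to 62 chains."""
    if index < len(CHAIN_ALPHABET):
        return CHAIN_ALPHABET[index]
    return f"C{index}"  # mmCIF-only territory


@dataclass
class AssemblyChain:
    chain_id: str
    block_index: int
    coords: np.ndarray  # (N, 3) Ca coordinates, Angstrom
    sequence: str = ""
    resids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("chain coordinates must be (N, 3)")
        if len(self.resids) == 0:
            self.resids = np.arange(1, len(self.coords) + 1)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class Assembly:
    chains: list[AssemblyChain]
    architecture: str | None = None
    provenance: object = "external"

    def __post_init__(self):
        lengths = {len(c) for c in self.chains}
        if len(lengths) > 1:
            raise ValueError(f"assembly chains have unequal lengths {sorted(lengths)}")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_blocks(self) -> int:
        return len({c.block_index for c in self.chains})

    @property
    def chain_length(self) -> int:
        return len(self.chains[0]) if self.chains else 0

    def stacked_coords(self) -> np.ndarray:
        """All Ca coordinates, chain-major, shape (n_chains * L, 3)."""
        return np.concatenate([c.coords for c in self.chains], axis=0)

    def atom_block_labels(self) -> np.ndarray:
        """Building-block index of every atom in ``stacked_coords`` order."""
        return np.concatenate(
            [np.full(len(c), c.block_index, dtype=int) for c in self.chains]
        )

    def atom_chain_labels(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(c), i, dtype=int) for i, c in enumerate(self.chains)]
        )

    def block(self, block_index: int) -> list[AssemblyChain]:
        """Chains of one building block, in provenance order."""
        found = [c for c in self.chains if c.block_index == block_index]
        if not found:
            raise KeyError(f"no building block with index {block_index}")
        return found

    def block_indices(self) -> list[int]:
        return sorted({c.block_index for c in self.chains})

    def centroid(self) -> np.ndarray:
        return self.stacked_coords().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Assembly":
        """Rigidly moved copy (provenance preserved)."""
        chains = [
            AssemblyChain(
                chain_id=c.chain_id,
                block_index=c.block_index,
                coords=c.coords @ np.asarray(rotation).T + np.asarray(translation),
                sequence=c.sequence,
                resids=c.resids.copy(),
            )
            for c in self.chains
        ]
        return Assembly(chains=chains, architecture=self.architecture, provenance=self.provenance)
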