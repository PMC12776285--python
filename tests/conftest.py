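"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

from symcage import canonicalize, get_architecture, synth_cn


def brute_force_cross_block_counts(asm, clash_cutoff, lo=3.0, hi=8.0):
    """O(N^2) enumeration of inter-building-block Ca pair counts.

    Returns (clash pairs strictly < clash_cutoff, contacts in [lo, hi]
    assembly-wide, contacts block0-to-best-neighbor). Independent of the
    tree-accelerated implementation.
    """
    X = asm.stacked_coords()
    labels = asm.atom_block_labels()
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(len(X), 1)
    d = D[iu]
    cross = labels[iu[0]] != labels[iu[1]]
    clash = int(((d < clash_cutoff) & cross).sum())
    band = (d >= lo) & (d <= hi) & cross
    total = int(band.sum())
    ref = asm.block_indices()[0]
    b0, b1 = labels[iu[0]][band], labels[iu[1]][band]
    involves = (b0 == ref) | (b1 == ref)
    partners = np.where(b0 == ref, b1, b0)[involves]
    best = int(np.bincount(partners).max()) if len(partners) else 0
    return clash, total, best


@pytest.fixture(scope="session")
def archs():
    return {name: get_architecture(name) for name in ("T2", "O4", "I3")}


@pytest.fixture(scope="session")
def small_blocks(archs):
    """Fast canonical zigzag fixtures, one per architecture."""
    return {
        name: canonicalize(synth_cn(arch.n, 40, style="zigzag", seed=11))
        for name, arch in archs.items()
    }


@pytest.fixture(scope="session")
def bundle_block():
    """A realistic-scale helical-bundle trimer (150-residue protomers)."""
    return canonicalize(synth_cn(3, 150, style="helical_bundle", seed=1))
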