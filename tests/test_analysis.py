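"""Kabsch superposition, symmetry-aware RMSD, interface composition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from symcage import (
    Assembly,
    AssemblyChain,
    HYDROPHOBIC_DEFAULT,
    hydrophobic_fraction,
    interface_report,
    interface_residues,
    kabsch_rmsd,
    place,
    symmetric_rmsd,
    synth_cn,
)
from symcage.analysis import _correspondence_rmsd
from symcage.errors import AnalysisError
from symcage.structio import block_to_assembly
from symcage.symmetry import point_group


def _rigid(seed):
    rng = np.random.default_rng(seed)
    return Rotation.random(random_state=rng).as_matrix(), rng.uniform(-30, 30, 3)


@pytest.fixture(scope="module")
def i3_assembly():
    from symcage import canonicalize, get_architecture

    bb = canonicalize(synth_cn(3, 60, style="zigzag", seed=2))
    arch = get_architecture("I3")
    return place(bb, arch, omega=60.0, r=62.0, flip=True)


def _noised(asm, sigma, seed=0):
    rng = np.random.default_rng(seed)
    return Assembly(
        chains=[
            AssemblyChain(
                c.chain_id,
                c.block_index,
                c.coords + rng.normal(scale=sigma, size=c.coords.shape),
                c.sequence,
                c.resids.copy(),
            )
            for c in asm.chains
        ],
        architecture=asm.architecture,
    )


class TestKabsch:
    def test_rigidly_moved_copy_gives_zero(self):
        P = np.random.default_rng(1).normal(size=(200, 3)) * 10
        R, t = _rigid(2)
        rmsd, _, _ = kabsch_rmsd(P, P @ R.T + t)
        assert rmsd < 1e-9

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(50, 3)) * 8
        Q = P + rng.normal(scale=1.0, size=P.shape)
        assert kabsch_rmsd(P, Q)[0] == pytest.approx(kabsch_rmsd(Q, P)[0], abs=1e-9)

    def test_gaussian_noise_closed_form(self):
        # iid per-coordinate noise sigma => rmsd ~ sigma * sqrt(3) at large N
        rng = np.random.default_rng(4)
        sigma = 0.7
        P = rng.normal(size=(600, 3)) * 15
        Q = P + rng.normal(scale=sigma, size=P.shape)
        rmsd, _, _ = kabsch_rmsd(P, Q)
        assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_transform_superposes(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(30, 3)) * 5
        R, t = _rigid(6)
        Q = P @ R.T + t
        rmsd, Rhat, that = kabsch_rmsd(P, Q)
        assert np.abs(P @ Rhat.T + that - Q).max() < 1e-8

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AnalysisError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(AnalysisError):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestSymmetricRMSD:
    @pytest.mark.parametrize("level", ["full_assembly", "interface_pair", "building_block"])
    def test_self_comparison_zero(self, i3_assembly, level):
        assert symmetric_rmsd(i3_assembly, i3_assembly, level).rmsd < 1e-9

    @pytest.mark.parametrize("level", ["full_assembly", "interface_pair", "building_block"])
    def test_rigidly_moved_copy_zero(self, i3_assembly, level):
        moved = i3_assembly.transformed(*_rigid(7))
        assert symmetric_rmsd(i3_assembly, moved, level).rmsd < 1e-6

    def test_symmetry_permuted_copy_zero(self, i3_assembly):
        # relabel chains by a group operation: geometry identical, labels not
        op = point_group("I").ops[13]
        permuted = i3_assembly.transformed(op.matrix, np.zeros(3))
        rep = symmetric_rmsd(i3_assembly, permuted, "full_assembly")
        assert rep.rmsd < 1e-6
        # the recovered correspondence is not the identity map
        assert rep.chain_map.pairs != tuple((i, i) for i in range(60))

    @pytest.mark.parametrize("level", ["full_assembly", "interface_pair", "building_block"])
    def test_noised_copy_sigma_sqrt3(self, i3_assembly, level):
        sigma = 1.0
        noised = _noised(i3_assembly, sigma, seed=8)
        rep = symmetric_rmsd(i3_assembly, noised, level)
        assert rep.n_atoms >= 600 or level != "full_assembly"
        assert rep.rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_symmetric_in_arguments(self, i3_assembly):
        noised = _noised(i3_assembly, 0.8, seed=9)
        a = symmetric_rmsd(i3_assembly, noised, "full_assembly").rmsd
        b = symmetric_rmsd(noised, i3_assembly, "full_assembly").rmsd
        assert a == pytest.approx(b, abs=1e-6)

    def test_minimizes_over_correspondences(self, i3_assembly):
        """Optimized RMSD <= RMSD under random fixed correspondences."""
        noised = _noised(i3_assembly, 1.0, seed=10)
        best = symmetric_rmsd(i3_assembly, noised, "full_assembly").rmsd
        rng = np.random.default_rng(11)
        mcoords = [c.coords for c in i3_assembly.chains]
        rcoords = [c.coords for c in noised.chains]
        for _ in range(10):
            perm = rng.permutation(len(rcoords))
            P = np.concatenate(mcoords)
            Q = np.concatenate([rcoords[j] for j in perm])
            fixed, _, _ = kabsch_rmsd(P, Q)
            assert best <= fixed + 1e-9

    def test_architecture_mismatch_rejected(self, i3_assembly):
        from symcage import canonicalize, get_architecture

        bb = canonicalize(synth_cn(2, 60, style="zigzag", seed=2))
        t2 = place(bb, get_architecture("T2"), omega=0.0, r=40.0)
        with pytest.raises(AnalysisError):
            symmetric_rmsd(i3_assembly, t2, "full_assembly")

    def test_terminal_trimming(self, i3_assembly):
        # reference missing 5 C-terminal residues per chain still comparable
        trimmed = Assembly(
            chains=[
                AssemblyChain(
                    c.chain_id, c.block_index, c.coords[:-5], c.sequence[:-5], c.resids[:-5]
                )
                for c in i3_assembly.chains
            ],
            architecture=i3_assembly.architecture,
        )
        rep = symmetric_rmsd(i3_assembly, trimmed, "full_assembly")
        assert rep.rmsd < 1e-9
        assert rep.chain_map.n_residues == i3_assembly.chain_length - 5


class TestInterfaces:
    def test_separated_blocks_empty_nanoparticle_interface(self):
        from symcage import canonicalize, get_architecture

        bb = canonicalize(synth_cn(3, 40, style="zigzag", seed=2))
        asm = place(bb, get_architecture("I3"), omega=0.0, r=500.0)
        assert interface_residues(asm, "nanoparticle") == set()
        assert interface_report(asm, "nanoparticle").hydrophobic_fraction is None

    def test_constructed_cross_block_interface_counts(self):
        # two parallel 10-residue strands 6 A apart in different blocks:
        # every residue of each chain is within 8 A of the partner
        a = np.column_stack([np.arange(10) * 3.8, np.zeros(10), np.zeros(10)])
        b = a + np.array([0.0, 6.0, 0.0])
        asm = Assembly(
            chains=[
                AssemblyChain("A", 0, a, "L" * 10),
                AssemblyChain("B", 1, b, "K" * 10),
            ]
        )
        res = interface_residues(asm, "nanoparticle")
        assert res == {("A", i) for i in range(1, 11)} | {("B", i) for i in range(1, 11)}
        assert hydrophobic_fraction(asm, res) == pytest.approx(0.5)

    def test_oligomeric_interface_symmetric_across_chains(self):
        bb = synth_cn(3, 150, seed=1)
        asm = block_to_assembly(bb)
        res = interface_residues(asm, "oligomeric")
        assert res
        by_chain = {}
        for cid, resid in res:
            by_chain.setdefault(cid, set()).add(resid)
        ids = list(by_chain.values())
        assert ids[0] == ids[1] == ids[2]

    def test_invariant_under_rigid_motion_and_relabeling(self, i3_assembly):
        res0 = interface_residues(i3_assembly, "nanoparticle")
        moved = i3_assembly.transformed(*_rigid(12))
        assert interface_residues(moved, "nanoparticle") == res0

    def test_hydrophobic_fraction_direct_count_oracle(self):
        rng = np.random.default_rng(13)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=30))
            coords = rng.normal(size=(30, 3)) * 20
            asm = Assembly(chains=[AssemblyChain("A", 0, coords, seq)])
            picked = {("A", int(i)) for i in rng.choice(30, size=12, replace=False) + 1}
            frac = hydrophobic_fraction(asm, picked)
            oracle = np.mean([seq[i - 1] in HYDROPHOBIC_DEFAULT for _, i in picked])
            assert frac == pytest.approx(oracle)

    def test_all_hydrophobic_interface(self):
        a = np.column_stack([np.arange(4) * 3.8, np.zeros(4), np.zeros(4)])
        asm = Assembly(
            chains=[
                AssemblyChain("A", 0, a, "LLLL"),
                AssemblyChain("B", 1, a + [0, 5, 0], "IIII"),
            ]
        )
        rep = interface_report(asm, "nanoparticle")
        assert rep.hydrophobic_fraction == 1.0
        assert rep.hydrophobic_set_used == HYDROPHOBIC_DEFAULT
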