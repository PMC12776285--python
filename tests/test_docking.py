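"""Docking grid, clash/contact filters, planted-truth recovery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from symcage import (
    BuildingBlock,
    FilterConfig,
    canonicalize,
    clash_count,
    contact_count,
    place,
    refine_r,
    scan_docks,
    synth_cn,
)
from symcage.docking import evaluate_pose
from symcage.errors import DockingError

from conftest import brute_force_cross_block_counts


@pytest.mark.parametrize(
    "arch_name,chains,blocks", [("T2", 12, 6), ("O4", 24, 6), ("I3", 60, 20)]
)
def test_place_expands_to_architecture(archs, small_blocks, arch_name, chains, blocks):
    asm = place(small_blocks[arch_name], archs[arch_name], omega=0.0, r=40.0)
    assert asm.n_chains == chains
    assert asm.n_blocks == blocks


def test_omega_fundamental_domain_periodicity(archs, small_blocks):
    bb, arch = small_blocks["I3"], archs["I3"]
    a0 = place(bb, arch, omega=17.0, r=35.0)
    a1 = place(bb, arch, omega=17.0 + 120.0, r=35.0)
    # identical point sets up to chain permutation: compare sorted coordinates
    s0 = np.sort(np.round(a0.stacked_coords(), 6), axis=0)
    s1 = np.sort(np.round(a1.stacked_coords(), 6), axis=0)
    assert np.abs(s0 - s1).max() < 1e-5


def test_separation_limit_no_contacts(archs, small_blocks):
    asm = place(small_blocks["I3"], archs["I3"], omega=0.0, r=1e4)
    assert contact_count(asm, scope="assembly_wide") == 0
    assert clash_count(asm, 3.0) == 0


def test_order_mismatch_rejected(archs, small_blocks):
    with pytest.raises(DockingError):
        place(small_blocks["T2"], archs["I3"], omega=0.0, r=30.0)


def test_overlapping_blocks_full_cross_pair_clash_count(archs):
    # degenerate fixture: two blocks fully overlapping at r=0 on a 2-fold
    # axis; every cross-block pair at distance 0 plus all close pairs
    bb = canonicalize(synth_cn(2, 40, style="zigzag", seed=3))
    arch = archs["T2"]
    asm = place(bb, arch, omega=0.0, r=0.0)
    oracle = brute_force_cross_block_counts(asm, arch.clash_cutoff)[0]
    assert clash_count(asm, arch.clash_cutoff) == oracle
    assert oracle > 0


@pytest.mark.parametrize("arch_name", ["T2", "O4", "I3"])
def test_counts_match_brute_force_oracle_on_random_poses(archs, small_blocks, arch_name):
    """Tree-accelerated counts equal O(N^2) enumeration on 50 random poses."""
    bb, arch = small_blocks[arch_name], archs[arch_name]
    rng = np.random.default_rng(17)
    rmax = 1.5 * bb.circumradius()
    for _ in range(50):
        omega = rng.uniform(0, 360.0 / arch.n)
        r = rng.uniform(0.3 * rmax, rmax)
        flip = bool(rng.integers(2))
        asm = place(bb, arch, omega, r, flip)
        clash_bf, total_bf, best_bf = brute_force_cross_block_counts(
            asm, arch.clash_cutoff
        )
        assert clash_count(asm, arch.clash_cutoff) == clash_bf
        assert contact_count(asm, scope="assembly_wide") == total_bf
        assert contact_count(asm, scope="best_neighbor") == best_bf


def test_scan_flags_consistent_with_recount(archs, small_blocks):
    bb, arch = small_blocks["I3"], archs["I3"]
    config = FilterConfig(omega_step=30.0, r_step=4.0)
    poses = scan_docks(bb, arch, config)
    resolved = config.resolved(bb, arch)
    for pose in poses[:40]:
        asm = place(bb, arch, pose.omega, pose.r, pose.flip)
        clashes = clash_count(asm, resolved.clash_cutoff)
        contacts = contact_count(asm, scope="best_neighbor")
        assert pose.clash_count == clashes
        assert pose.contact_count == contacts
        assert pose.passes_filters == (clashes == 0 and contacts >= resolved.contact_min)


def test_scan_ranking_deterministic(archs, small_blocks):
    bb, arch = small_blocks["T2"], archs["T2"]
    config = FilterConfig(omega_step=45.0, r_step=5.0)
    a = scan_docks(bb, arch, config)
    b = scan_docks(bb, arch, config)
    assert [(p.omega, p.r, p.flip) for p in a] == [(p.omega, p.r, p.flip) for p in b]
    scores = [p.surrogate_score for p in a]
    assert scores == sorted(scores, reverse=True)


def test_r_max_below_contact_range_all_fail(archs, small_blocks):
    bb, arch = small_blocks["I3"], archs["I3"]
    config = FilterConfig(omega_step=60.0, r_step=1.0, r_min=0.0, r_max=2.0)
    poses = scan_docks(bb, arch, config)
    assert not any(p.passes_filters for p in poses)


def test_planted_truth_recovered_within_one_grid_step(archs, small_blocks):
    """Coarse scan lands within one grid step of the fine-grid optimum."""
    bb, arch = small_blocks["I3"], archs["I3"]
    coarse = FilterConfig(omega_step=20.0, r_step=3.0)
    poses = scan_docks(bb, arch, coarse)
    top = poses[0]
    assert top.passes_filters
    # independent oracle: exhaustive fine 1-D scan over r at the top (omega,
    # flip), using brute-force counting
    resolved = coarse.resolved(bb, arch)
    best_r, best_score = None, -np.inf
    for r in np.arange(max(0.0, top.r - 4.0), top.r + 4.0 + 1e-9, 0.25):
        asm = place(bb, arch, top.omega, float(r), top.flip)
        clash_bf, _, best_bf = brute_force_cross_block_counts(asm, resolved.clash_cutoff)
        score = -np.inf if clash_bf else best_bf
        if score > best_score:
            best_r, best_score = float(r), score
    assert abs(top.r - best_r) <= coarse.r_step
    refined = refine_r(bb, arch, top, half_window=4.0, fine_step=0.25, config=coarse)
    assert abs(refined.r - best_r) <= 0.25
    assert refined.surrogate_score >= top.surrogate_score
    assert refined.surrogate_score == best_score


def test_refine_zero_window_returns_input(archs, small_blocks):
    bb, arch = small_blocks["O4"], archs["O4"]
    pose = scan_docks(bb, arch, FilterConfig(omega_step=45.0, r_step=5.0))[0]
    assert refine_r(bb, arch, pose, half_window=0.0) is pose


def test_omega_equivariance_under_block_prerotation(archs, small_blocks):
    """Pre-rotating the canonical block by delta shifts passing omega by -delta."""
    bb, arch = small_blocks["I3"], archs["I3"]
    delta = 14.0
    Rz = Rotation.from_euler("z", delta, degrees=True).as_matrix()
    rotated = BuildingBlock(
        chains=[c @ Rz.T for c in bb.chains], sequence=bb.sequence, name=bb.name
    )
    config = FilterConfig(omega_step=20.0, r_step=4.0).resolved(bb, arch)
    for omega in (0.0, 20.0, 60.0):
        for r in (20.0, 35.0):
            a = evaluate_pose(bb, arch, omega + delta, r, False, config)
            b = evaluate_pose(rotated, arch, omega, r, False, config)
            assert a.clash_count == b.clash_count
            assert a.contact_count == b.contact_count


def test_flip_symmetric_block_has_flip_symmetric_landscape(archs):
    """A block invariant under the flip rotation scores identically flipped."""
    # odd-length zigzag protomer with y=0 and z symmetric about 0 maps onto
    # itself (residue-reversed) under the 180-degree flip about x
    L = 41
    i = np.arange(L)
    protomer = np.column_stack([11.0 + (-1.0) ** i, np.zeros(L), 1.9 * (i - (L - 1) / 2)])
    Rz = Rotation.from_euler("z", 180.0, degrees=True).as_matrix()
    bb = BuildingBlock(
        chains=[protomer, protomer @ Rz.T], sequence="A" * L, name="flipsym"
    )
    arch = archs["T2"]
    config = FilterConfig(omega_step=30.0, r_step=4.0).resolved(bb, arch)
    for omega in (0.0, 30.0, 60.0):
        for r in (15.0, 25.0, 35.0):
            a = evaluate_pose(bb, arch, omega, r, False, config)
            b = evaluate_pose(bb, arch, omega, r, True, config)
            assert a.contact_count == b.contact_count
            assert a.clash_count == b.clash_count


@pytest.mark.parametrize("arch_name", ["T2", "O4", "I3"])
def test_helical_fixture_has_passing_docks(archs, arch_name):
    """Pipeline smoke: the bundle fixture docks successfully at some radius."""
    arch = archs[arch_name]
    found = False
    for radius in (11.0, 14.0):
        bb = canonicalize(synth_cn(arch.n, 60, style="helical_bundle", seed=1, radius=radius))
        poses = scan_docks(bb, arch, FilterConfig(omega_step=15.0, r_step=2.0))
        if any(p.passes_filters for p in poses):
            found = True
            break
    assert found
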