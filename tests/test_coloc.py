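"""First-shell selection and co-localization angles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sterolorder as so
from sterolorder import fold_theta90
from sterolorder.coloc import chain_geometry
from sterolorder.io import molecule_com


# ---------------------------------------------------------------------------
# independent oracle


def brute_force_theta90_counts(snapshots, species_map, sterol_species,
                               lipid_species, bin_width=5.0, cutoff=0.75):
    """Explicit-loop enumeration of the theta90 histogram."""
    n_bins = int(90 / bin_width)
    counts = np.zeros(n_bins, dtype=int)
    spec_s = species_map[sterol_species]
    spec_l = species_map[lipid_species]
    for snap in snapshots:
        lx, ly = snap.box[0], snap.box[1]
        for leaflet in snap.leaflets:
            sterols = [m for m in snap.molecules
                       if m.species == sterol_species and m.leaflet == leaflet]
            lipids = [m for m in snap.molecules
                      if m.species == lipid_species and m.leaflet == leaflet]
            for st_mol in sterols:
                ring_names = [n for n in spec_s.ring_atoms if n in st_mol.atoms]
                masses = [spec_s.atom_masses[n] for n in ring_names]
                anchor = sum(
                    m * st_mol.atoms[n] for m, n in zip(masses, ring_names)
                ) / sum(masses)
                for lm in lipids:
                    coms = []
                    for chain in (spec_l.sn1_chain_atoms, spec_l.sn2_chain_atoms):
                        ms = [spec_l.atom_masses[n] for n in chain]
                        coms.append(
                            sum(m * lm.atoms[n] for m, n in zip(ms, chain)) / sum(ms)
                        )
                    in_shell = False
                    for c in coms:
                        dx = c[0] - anchor[0]
                        dy = c[1] - anchor[1]
                        dx -= round(dx / lx) * lx
                        dy -= round(dy / ly) * ly
                        if math.hypot(dx, dy) <= cutoff:
                            in_shell = True
                    if not in_shell:
                        continue
                    vcx = coms[1][0] - coms[0][0]
                    vcy = coms[1][1] - coms[0][1]
                    mx = 0.5 * (coms[0][0] + coms[1][0]) - anchor[0]
                    my = 0.5 * (coms[0][1] + coms[1][1]) - anchor[1]
                    mx -= round(mx / lx) * lx
                    my -= round(my / ly) * ly
                    cosang = (vcx * mx + vcy * my) / (
                        math.hypot(vcx, vcy) * math.hypot(mx, my)
                    )
                    theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    t90 = 90.0 - abs(90.0 - theta)
                    counts[min(int(t90 // bin_width), n_bins - 1)] += 1
    return counts


# ---------------------------------------------------------------------------
# first-shell selection


def _place_lipid_at(snap, species_map, lipid, sterol, lateral_chain_com_distance):
    """Orient a lipid with its chain axis radial (sn-2 nearer) and put the
    sn-2 chain COM at the given lateral distance from the sterol ring COM."""
    spec_l = species_map[lipid.species]
    spec_s = species_map[sterol.species]
    anchor = molecule_com(sterol, spec_s, "ring")
    geom = chain_geometry(lipid, spec_l)
    axis = geom.sn2_com[:2] - geom.sn1_com[:2]
    ang = np.arctan2(axis[1], axis[0])
    rot = np.array([[np.cos(-ang), -np.sin(-ang)], [np.sin(-ang), np.cos(-ang)]])
    mid = geom.midpoint
    for n, p in lipid.atoms.items():
        lat = rot @ (p[:2] - mid[:2]) + mid[:2]
        lipid.atoms[n] = np.array([lat[0], lat[1], p[2]])
    geom = chain_geometry(lipid, spec_l)  # chain axis now along +x
    target = anchor + np.array([-lateral_chain_com_distance, 0.0, 0.0])
    shift = np.array([target[0] - geom.sn2_com[0], target[1] - geom.sn2_com[1], 0.0])
    lipid.atoms.update({n: p + shift for n, p in lipid.atoms.items()})


def test_first_shell_cutoff_boundary(species_map):
    """A chain COM at 0.70 nm admits the lipid; at 0.80 nm (the other chain
    even further) it is excluded."""
    params = so.GeneratorParams(mode="csr", n_sterols=1, n_lipids=1,
                                box=(20.0, 20.0, 6.0), n_frames=1, seed=8)
    snaps, _ = so.generate_leaflet(params)
    snap = snaps[0]
    sterol, lipid = snap.molecules
    _place_lipid_at(snap, species_map, lipid, sterol, 0.70)
    assert so.select_first_shell_lipids(snap, species_map, sterol.mol_id) == [lipid.mol_id]
    _place_lipid_at(snap, species_map, lipid, sterol, 0.80)
    assert so.select_first_shell_lipids(snap, species_map, sterol.mol_id) == []


def test_first_shell_dedup_and_empty(species_map):
    params = so.GeneratorParams(mode="csr", n_sterols=1, n_lipids=1,
                                box=(20.0, 20.0, 6.0), n_frames=1, seed=8)
    snaps, _ = so.generate_leaflet(params)
    snap = snaps[0]
    sterol, lipid = snap.molecules
    spec_s = species_map["CHOL"]
    anchor = molecule_com(sterol, spec_s, "ring")
    geom = chain_geometry(lipid, species_map["DSPC"])
    shift = anchor - geom.midpoint  # both chains at ~0.35 nm: inside twice
    shift[2] = 0.0
    lipid.atoms.update({n: p + shift for n, p in lipid.atoms.items()})
    ids = so.select_first_shell_lipids(snap, species_map, sterol.mol_id)
    assert ids == [lipid.mol_id]  # listed exactly once


# ---------------------------------------------------------------------------
# angles


def test_colocalization_angle_collinear_and_facing():
    geom = so.ChainGeometry(sn1_com=np.array([1.0, 0.0, 0.0]),
                            sn2_com=np.array([2.0, 0.0, 0.0]))
    assert so.colocalization_angle((0, 0, 0), geom) == pytest.approx(0.0, abs=1e-9)
    facing = so.ChainGeometry(sn1_com=np.array([1.0, 0.4, 0.0]),
                              sn2_com=np.array([1.0, -0.4, 0.0]))
    assert so.colocalization_angle((0, 0, 0), facing) == pytest.approx(90.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_chain_swap_maps_theta_to_supplement(seed):
    """Swapping sn-1/sn-2 labels maps theta -> 180 - theta (symmetry
    oracle), leaving theta90 invariant."""
    rng = np.random.default_rng(seed)
    sn1, sn2 = rng.normal(size=(2, 3))
    anchor = rng.normal(size=3)
    g1 = so.ChainGeometry(sn1_com=sn1, sn2_com=sn2)
    g2 = so.ChainGeometry(sn1_com=sn2, sn2_com=sn1)
    t1 = so.colocalization_angle(anchor, g1)
    t2 = so.colocalization_angle(anchor, g2)
    assert t1 + t2 == pytest.approx(180.0, abs=1e-9)
    assert fold_theta90(t1) == pytest.approx(fold_theta90(t2), abs=1e-9)


def test_degenerate_colocalization_rejected():
    geom = so.ChainGeometry(sn1_com=np.zeros(3), sn2_com=np.zeros(3))
    with pytest.raises(so.DegenerateGeometryError):
        so.colocalization_angle((1, 0, 0), geom)


@pytest.mark.parametrize("theta,expected", [(120.0, 60.0), (180.0, 0.0),
                                            (90.0, 90.0), (0.0, 0.0), (45.0, 45.0)])
def test_fold_theta90_values(theta, expected):
    assert fold_theta90(theta) == expected


@given(st.floats(min_value=0.0, max_value=180.0, allow_nan=False))
def test_fold_theta90_formula(theta):
    assert fold_theta90(theta) == 90.0 - abs(90.0 - theta)
    assert 0.0 <= fold_theta90(theta) <= 90.0


def test_fold_theta90_out_of_range():
    with pytest.raises(so.AnalysisError):
        fold_theta90(-1.0)
    with pytest.raises(so.AnalysisError):
        fold_theta90(181.0)


# ---------------------------------------------------------------------------
# distributions


def test_facing_generator_fills_top_bin(species_map):
    """Isolated sterols with 'facing' first-shell lipids put all probability
    mass in the theta90 = [85, 90] bin."""
    params = so.GeneratorParams(mode="triangular", neighbor_angles=(),
                                n_sterols=8, n_lipids=40, box=(24.0, 24.0, 6.0),
                                cluster_exclusion=4.0, lipid_rule="first_shell",
                                lipid_theta_rule=("fixed", 90.0),
                                n_frames=2, seed=44)
    snaps, _ = so.generate_leaflet(params)
    dist = so.theta90_distribution(snaps, species_map, "CHOL", "DSPC")
    assert dist.n_pairs > 0
    assert dist.frequencies[-1] == pytest.approx(1.0)


def test_theta90_histogram_matches_brute_force(mixed_fixture, species_map):
    snaps, _ = mixed_fixture
    dist = so.theta90_distribution(snaps, species_map, "CHOL", "DSPC")
    oracle = brute_force_theta90_counts(snaps, species_map, "CHOL", "DSPC")
    assert np.array_equal(dist.counts, oracle)
    assert dist.n_pairs == oracle.sum()
    assert dist.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


def test_sector_split_conserves_counts(mixed_fixture, species_map):
    snaps, _ = mixed_fixture
    total = so.theta90_distribution(snaps, species_map, "CHOL", "DSPC")
    sectors = so.theta90_distribution(snaps, species_map, "CHOL", "DSPC",
                                      sector_resolved=True)
    assert set(sectors) == set(so.SECTOR_NAMES)
    combined = sum(d.counts for d in sectors.values())
    assert np.array_equal(combined, total.counts)


def test_global_chain_relabeling_leaves_histogram(mixed_fixture, species_map):
    """Relabeling sn-1 <-> sn-2 on every lipid leaves the theta90 histogram
    exactly unchanged."""
    snaps, _ = mixed_fixture
    base = so.theta90_distribution(snaps, species_map, "CHOL", "DSPC")
    spec = species_map["DSPC"]
    swapped_spec = so.PhospholipidSpec(
        name="DSPC", sn1_chain_atoms=spec.sn2_chain_atoms,
        sn2_chain_atoms=spec.sn1_chain_atoms,
        headgroup_anchor=spec.headgroup_anchor, atom_masses=spec.atom_masses,
    )
    swapped_map = so.SpeciesMap({**species_map.species, "DSPC": swapped_spec})
    swapped = so.theta90_distribution(snaps, swapped_map, "CHOL", "DSPC")
    assert np.array_equal(base.counts, swapped.counts)


def test_empty_distribution_flagged(species_map):
    params = so.GeneratorParams(mode="csr", n_sterols=2, n_lipids=2,
                                box=(40.0, 40.0, 6.0), n_frames=1, seed=2)
    snaps, _ = so.generate_leaflet(params)
    # 4 molecules in 1600 nm^2: almost surely no first-shell pair
    dist = so.theta90_distribution(snaps, species_map, "CHOL", "DSPC")
    if dist.n_pairs == 0:
        assert dist.is_empty
        assert dist.frequencies.sum() == 0.0


def test_chain_separation_fixed_and_gaussian(species_map):
    """The rigid template fixes the chain separation at 0.70 nm: recovered
    with zero spread for first-shell lipids."""
    params = so.GeneratorParams(mode="hard_disk", n_sterols=6, n_lipids=30,
                                box=(12.0, 12.0, 6.0), lipid_rule="first_shell",
                                n_frames=2, seed=3)
    snaps, _ = so.generate_leaflet(params)
    mean, sd, n = so.chain_separation_summary(snaps, species_map, "DSPC",
                                              sterol_species="CHOL")
    assert n > 0
    assert mean == pytest.approx(0.70, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)
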