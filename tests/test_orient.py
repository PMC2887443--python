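"""Sterol pair relative-orientation distributions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sterolorder as so
from sterolorder import relative_orientation_angle
from sterolorder.orient import OrientationSpec

from conftest import embed_snapshots, rotate_snapshots


def brute_force_sector_counts(snapshots, species_map, species, *,
                              radial_range=(0.8, 1.1), bin_width=5.0):
    """Explicit-loop enumeration of the per-sector orientation histograms."""
    spec = species_map[species]
    n_bins = int(360 / bin_width)
    counts = {s: np.zeros(n_bins, dtype=int) for s in so.SECTOR_NAMES}
    for snap in snapshots:
        lx, ly = snap.box[0], snap.box[1]
        for leaflet in snap.leaflets:
            mols = [m for m in snap.molecules
                    if m.species == species and m.leaflet == leaflet]
            data = []
            for m in mols:
                names = [n for n in spec.ring_atoms if n in m.atoms]
                ms = [spec.atom_masses[n] for n in names]
                com = sum(w * m.atoms[n] for w, n in zip(ms, names)) / sum(ms)
                c13 = m.atoms["C13"]
                ex = m.atoms["C18"] - c13 if "C18" in m.atoms else None
                if ex is None:  # reconstructed methyl
                    ex = so.reconstruct_tetrahedral_substituent(
                        c13, m.atoms["C12"], m.atoms["C14"], m.atoms["C17"]
                    ) - c13
                ex = ex / np.linalg.norm(ex)
                v10 = m.atoms["C10"] - c13
                ez = v10 - (v10 @ ex) * ex
                ez /= np.linalg.norm(ez)
                ey = np.cross(ez, ex)
                c6, c11 = spec.orientation_atoms
                w = (m.atoms[c11] - m.atoms[c6])[:2]
                w /= math.hypot(*w)
                data.append((com, ex, ey, w))
            for i, (ci, exi, eyi, wi) in enumerate(data):
                for j, (cj, _, _, wj) in enumerate(data):
                    if i == j:
                        continue
                    d = cj - ci
                    d[0] -= round(d[0] / lx) * lx
                    d[1] -= round(d[1] / ly) * ly
                    x = d @ exi
                    y = d @ eyi
                    r = math.hypot(x, y)
                    if not (radial_range[0] <= r <= radial_range[1]):
                        continue
                    phi = math.degrees(math.atan2(y, x)) % 360.0
                    ang = math.degrees(
                        math.atan2(wi[0] * wj[1] - wi[1] * wj[0],
                                   wi[0] * wj[0] + wi[1] * wj[1])
                    ) % 360.0
                    counts[so.sector_of(phi)][min(int(ang // bin_width), n_bins - 1)] += 1
    return counts


# ---------------------------------------------------------------------------
# orientation vectors and relative angles


def test_c6c11_vector_projects_laterally(species_map):
    params = so.GeneratorParams(mode="csr", n_sterols=1, n_lipids=0,
                                box=(6.0, 6.0, 6.0), n_frames=1, seed=0)
    snaps, truth = so.generate_leaflet(params)
    mol = snaps[0].molecules[0]
    v = so.c6c11_lateral_vector(mol, species_map["CHOL"])
    assert np.hypot(*v) == pytest.approx(1.0)
    # the template's C6->C11 lateral direction is +y rotated by psi
    psi = truth.molecules[0].psi_deg
    expected = np.array([np.cos(np.radians(90 + psi)), np.sin(np.radians(90 + psi))])
    assert np.abs(v - expected).max() < 1e-9


def test_c6c11_degenerate_rejected(species_map):
    mol = so.Molecule(1, "CHOL", {"C6": np.zeros(3), "C11": np.array([0, 0, 0.4])})
    with pytest.raises(so.DegenerateGeometryError):
        so.c6c11_lateral_vector(mol, species_map["CHOL"])


def test_molecule_rotation_rotates_vector(species_map):
    params = so.GeneratorParams(mode="csr", n_sterols=1, n_lipids=0,
                                box=(6.0, 6.0, 6.0), n_frames=1, seed=1)
    snaps, _ = so.generate_leaflet(params)
    mol = snaps[0].molecules[0]
    v0 = so.c6c11_lateral_vector(mol, species_map["CHOL"])
    a = np.radians(30.0)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    rotated = so.Molecule(
        1, "CHOL",
        {n: np.array([*(rot @ p[:2]), p[2]]) for n, p in mol.atoms.items()},
    )
    v1 = so.c6c11_lateral_vector(rotated, species_map["CHOL"])
    assert np.abs(v1 - rot @ v0).max() < 1e-9


@pytest.mark.parametrize(
    "a,b,expected",
    [((1, 0), (1, 0), 0.0), ((1, 0), (-1, 0), 180.0), ((0, 1), (0, 1), 0.0)],
)
def test_relative_angle_trivia(a, b, expected):
    assert relative_orientation_angle(a, b) == pytest.approx(expected)


@given(st.floats(min_value=0.0, max_value=359.99), st.floats(min_value=0.01, max_value=359.99))
def test_relative_angle_antisymmetric(base, offset):
    a = (np.cos(np.radians(base)), np.sin(np.radians(base)))
    b = (np.cos(np.radians(base + offset)), np.sin(np.radians(base + offset)))
    ab = relative_orientation_angle(a, b)
    ba = relative_orientation_angle(b, a)
    assert ab == pytest.approx(offset % 360.0, abs=1e-6)
    assert (ab + ba) % 360.0 == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# sector-resolved distributions


def _single_bin_at(dist, angle_deg):
    """All counts concentrated at ``angle_deg``: only bins whose closed
    interval touches the angle are populated (a delta constructed exactly on
    a bin edge may split across the two adjacent bins by float rounding)."""
    touching = [
        k
        for k in range(len(dist.counts))
        if dist.edges[k] - 1e-6 <= angle_deg <= dist.edges[k + 1] + 1e-6
    ]
    mass = sum(int(dist.counts[k]) for k in touching)
    others = dist.counts.sum() - mass
    return mass == dist.n_pairs and others == 0


def test_fixed_offset_construction(species_map):
    """Neighbors placed only in NE with a 40-degree orientation offset: NE
    holds a single bin at 40 and the reverse pair members land in W at 320;
    every other sector is empty."""
    params = so.GeneratorParams(mode="triangular", neighbor_angles=(45.0,),
                                n_sterols=20, n_lipids=0, box=(24.0, 24.0, 6.0),
                                angular_jitter_deg=0.0, radial_jitter_nm=0.0,
                                orientation_rule=("fixed", 40.0),
                                n_frames=2, seed=10)
    snaps, _ = so.generate_leaflet(params)
    dists = so.sector_orientation_distributions(snaps, species_map, "CHOL")
    ne = dists["NE"]
    w = dists["W"]
    assert ne.n_pairs > 0 and w.n_pairs == ne.n_pairs
    assert _single_bin_at(ne, 40.0)
    assert _single_bin_at(w, 320.0)
    for s in set(so.SECTOR_NAMES) - {"NE", "W"}:
        assert dists[s].is_empty


def test_antialigned_pairs_are_mutual(species_map):
    """With the anti-aligned default every motif pair contributes twice to
    the same sector at a relative angle of 180 degrees."""
    params = so.GeneratorParams(mode="triangular", neighbor_angles=(45.0,),
                                n_sterols=16, n_lipids=0, box=(24.0, 24.0, 6.0),
                                angular_jitter_deg=0.0, radial_jitter_nm=0.0,
                                n_frames=1, seed=3)
    snaps, _ = so.generate_leaflet(params)
    dists = so.sector_orientation_distributions(snaps, species_map, "CHOL")
    ne = dists["NE"]
    assert ne.n_pairs == 16  # 8 unordered pairs, each counted twice
    assert _single_bin_at(ne, 180.0)
    assert sum(d.n_pairs for d in dists.values()) % 2 == 0


def test_sector_counts_match_brute_force(mixed_fixture, species_map):
    snaps, _ = mixed_fixture
    dists = so.sector_orientation_distributions(snaps, species_map, "CHOL")
    oracle = brute_force_sector_counts(snaps, species_map, "CHOL")
    for s in so.SECTOR_NAMES:
        assert np.array_equal(dists[s].counts, oracle[s]), s
    total = sum(d.n_pairs for d in dists.values())
    assert total % 2 == 0  # ordered-pair bookkeeping


def test_rigid_rotation_leaves_distributions(species_map):
    params = so.GeneratorParams(mode="triangular", n_sterols=12, n_lipids=0,
                                box=(8.0, 8.0, 6.0), n_frames=2, seed=6,
                                orientation_rule="uniform")
    snaps, _ = so.generate_leaflet(params)
    big = embed_snapshots(snaps, (32.0, 32.0, 6.0), (12.0, 12.0))
    rotated = rotate_snapshots(big, 141.7, (16.0, 16.0))
    d0 = so.sector_orientation_distributions(big, species_map, "CHOL")
    d1 = so.sector_orientation_distributions(rotated, species_map, "CHOL")
    for s in so.SECTOR_NAMES:
        assert np.array_equal(d0[s].counts, d1[s].counts)


def test_von_mises_circular_mean_recovery(species_map):
    """von Mises orientation offsets (mu = 120, kappa = 8) are recovered by
    the circular mean of the target-sector distribution within 2 degrees."""
    params = so.GeneratorParams(mode="triangular", neighbor_angles=(180.0,),
                                n_sterols=100, n_lipids=0, box=(38.0, 38.0, 6.0),
                                orientation_rule=("vonmises", 120.0, 8.0),
                                n_frames=50, seed=5)
    snaps, _ = so.generate_leaflet(params)
    dists = so.sector_orientation_distributions(snaps, species_map, "CHOL")
    w = dists["W"]
    assert w.n_pairs >= 2400
    assert abs(w.circular_mean_deg() - 120.0) < 2.0


def test_dchl_pairs_use_reconstructed_frame(species_map):
    """The flat sterol's orientation statistics work through the
    reconstructed methyl frame (linear motif, anti-aligned)."""
    params = so.GeneratorParams(mode="linear", sterol_species="DCHL",
                                n_sterols=12, n_lipids=0, box=(20.0, 20.0, 6.0),
                                angular_jitter_deg=0.0, radial_jitter_nm=0.0,
                                n_frames=1, seed=9)
    snaps, _ = so.generate_leaflet(params)
    dists = so.sector_orientation_distributions(snaps, species_map, "DCHL")
    populated = {s for s, d in dists.items() if not d.is_empty}
    assert populated == {"E", "W"}
    for s in populated:
        assert _single_bin_at(dists[s], 180.0)


def test_orientation_spec_validation():
    with pytest.raises(so.AnalysisError):
        OrientationSpec(radial_range=(1.1, 0.8))
    with pytest.raises(so.AnalysisError):
        OrientationSpec(bin_width=7.0)
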