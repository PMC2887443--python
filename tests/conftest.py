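import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sterolorder import GeneratorParams, generate_leaflet, load_species_map
from sterolorder.io import Molecule, Snapshot

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def species_map():
    return load_species_map()


@pytest.fixture(scope="session")
def mixed_fixture():
    """50-molecule mixed leaflet (15 CHOL + 35 DSPC), 3 frames: the shared
    brute-force comparison fixture."""
    params = GeneratorParams(
        mode="hard_disk",
        n_sterols=15,
        n_lipids=35,
        box=(9.0, 9.0, 6.0),
        hard_core_radius=0.6,
        lipid_rule="first_shell",
        lipid_theta_rule="uniform",
        n_frames=3,
        seed=123,
    )
    return generate_leaflet(params)


def rotate_snapshots(snapshots, angle_deg, center_xy):
    """Rigidly rotate every atom of every snapshot about the lab z-axis."""
    a = np.radians(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    center = np.asarray(center_xy, dtype=float)
    out = []
    for snap in snapshots:
        mols = []
        for m in snap.molecules:
            atoms = {}
            for n, p in m.atoms.items():
                lat = rot @ (p[:2] - center) + center
                atoms[n] = np.array([lat[0], lat[1], p[2]])
            mols.append(
                Molecule(
                    mol_id=m.mol_id,
                    species=m.species,
                    atoms=atoms,
                    leaflet=m.leaflet,
                    atom_order=m.atom_order,
                )
            )
        out.append(
            Snapshot(
                frame_index=snap.frame_index,
                time=snap.time,
                box=snap.box.copy(),
                molecules=mols,
            )
        )
    return out


def embed_snapshots(snapshots, big_box, offset_xy):
    """Translate all molecules into the middle of a larger box, so that no
    pair distance involves a periodic image (exact-equivariance fixtures)."""
    off = np.array([offset_xy[0], offset_xy[1], 0.0])
    out = []
    for snap in snapshots:
        mols = [
            Molecule(
                mol_id=m.mol_id,
                species=m.species,
                atoms={n: p + off for n, p in m.atoms.items()},
                leaflet=m.leaflet,
                atom_order=m.atom_order,
            )
            for m in snap.molecules
        ]
        out.append(
            Snapshot(
                frame_index=snap.frame_index,
                time=snap.time,
                box=np.array(big_box, dtype=float),
                molecules=mols,
            )
        )
    return out
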