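"""Per-sterol molecular reference frames and angular sectors.

The frame of a sterol is an orthonormal right-handed triad anchored at C13:
``e_x`` points along C13->C18 (the off-plane methyl, i.e. toward the rough
beta face), ``e_z`` is the component of C13->C10 orthogonal to ``e_x`` (up the
ring system), and ``e_y = e_z x e_x``.  The frame xy-plane is the projection
plane for all molecular-frame maps; y > 0 is the beta1 sub-face and y < 0 the
beta2 sub-face under this handedness convention (a mirror flag is provided
because the absolute chirality of the printed maps cannot be recovered from
the text alone).

In-plane angles phi are measured from +x, anticlockwise, in [0, 360).  The
eight angular sectors are, verbatim from the analysis they implement:
NE [22.5-67.5), N [67.5-122.5), NW [122.5-157.5), W [157.5-202.5),
SW [202.5-247.5), S [247.5-292.5), SE [292.5-337.5), E [337.5-22.5)
(E wraps through 0; note NW spans 35 degrees while the others span 45).
Sector intervals are half-open; an exact boundary value belongs to the
anticlockwise-later sector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .species import SterolSpec

__all__ = [
    "SterolFrame",
    "FrameCoords",
    "build_sterol_frame",
    "reconstruct_tetrahedral_substituent",
    "to_frame_coords",
    "sector_of",
    "sectors_of",
    "SECTOR_BOUNDS",
    "SECTOR_NAMES",
    "sterol_frame_for",
    "sterol_frame_atom",
    "frames_table",
]

_EPS = 1e-9

SECTOR_BOUNDS: dict[str, tuple[float, float]] = {
    "NE": (22.5, 67.5),
    "N": (67.5, 122.5),
    "NW": (122.5, 157.5),
    "W": (157.5, 202.5),
    "SW": (202.5, 247.5),
    "S": (247.5, 292.5),
    "SE": (292.5, 337.5),
    "E": (337.5, 22.5),  # wraps through 0
}
SECTOR_NAMES: tuple[str, ...] = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")

# sorted interior boundaries for vectorized lookup: angle in [22.5, 337.5)
# falls into one of the non-wrapping sectors, anything else is E.
_INNER_EDGES = np.array([22.5, 67.5, 122.5, 157.5, 202.5, 247.5, 292.5, 337.5])
_INNER_NAMES = np.array(["NE", "N", "NW", "W", "SW", "S", "SE"])


@dataclass(frozen=True)
class SterolFrame:
    """Orthonormal right-handed triad with origin at C13 (nm)."""

    origin: np.ndarray
    e_x: np.ndarray
    e_y: np.ndarray
    e_z: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are (e_x, e_y, e_z): lab -> frame coords."""
        return np.stack([self.e_x, self.e_y, self.e_z])


@dataclass(frozen=True)
class FrameCoords:
    """Coordinates of a point in a sterol frame."""

    x: float
    y: float
    z: float

    @property
    def r_xy(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def phi_deg(self) -> float:
        """In-plane angle, 0 along +x, anticlockwise, in [0, 360).

        The origin itself (r_xy == 0) is assigned phi = 0 by convention.
        """
        if self.r_xy == 0.0:
            return 0.0
        return float(np.degrees(np.arctan2(self.y, self.x)) % 360.0)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateGeometryError(f"{what}: zero-length vector")
    return v / n


def build_sterol_frame(c13, c18, c10, *, mirror: bool = False) -> SterolFrame:
    """Build the molecular frame from the C13, C18 and C10 positions.

    ``e_x = unit(c18 - c13)``; ``e_z`` is the unit component of ``c10 - c13``
    orthogonal to ``e_x`` (so the xz-plane contains C13->C10, with
    ``(c10 - c13) . e_z > 0``); ``e_y = e_z x e_x``.  ``mirror=True`` flips
    ``e_y`` (swapping the beta1/beta2 labelling; the triad is then
    left-handed, which is the point of the flag).

    Raises :class:`DegenerateGeometryError` for coincident or collinear input.
    """
    c13 = np.asarray(c13, dtype=float)
    c18 = np.asarray(c18, dtype=float)
    c10 = np.asarray(c10, dtype=float)
    e_x = _unit(c18 - c13, "C13->C18")
    v = c10 - c13
    rej = v - (v @ e_x) * e_x
    if np.linalg.norm(rej) < _EPS:
        raise DegenerateGeometryError(
            "C10 lies on the C13-C18 line; frame xz-plane is undefined"
        )
    e_z = rej / np.linalg.norm(rej)
    e_y = np.cross(e_z, e_x)
    if mirror:
        e_y = -e_y
    return SterolFrame(origin=c13, e_x=e_x, e_y=e_y, e_z=e_z)


def reconstruct_tetrahedral_substituent(center, neighbor1, neighbor2, neighbor3,
                                        bond_length: float = 0.153) -> np.ndarray:
    """Place a missing sp3 substituent opposite three known neighbors.

    Returns ``center + bond_length * unit(-sum_i unit(neighbor_i - center))``.
    Raises :class:`DegenerateGeometryError` when the unit bond vectors sum to
    (numerically) zero, e.g. for three coplanar neighbors at 120 degrees.
    """
    center = np.asarray(center, dtype=float)
    total = np.zeros(3)
    for i, nb in enumerate((neighbor1, neighbor2, neighbor3), start=1):
        total += _unit(np.asarray(nb, dtype=float) - center, f"neighbor {i}")
    norm = np.linalg.norm(total)
    if norm < 1e-8:
        raise DegenerateGeometryError(
            "tetrahedral reconstruction undefined: neighbor bond vectors sum to zero"
        )
    return center + bond_length * (-total / norm)


def to_frame_coords(frame: SterolFrame, point) -> FrameCoords:
    """Express a lab-frame point in the sterol frame."""
    d = np.asarray(point, dtype=float) - frame.origin
    return FrameCoords(x=float(d @ frame.e_x), y=float(d @ frame.e_y), z=float(d @ frame.e_z))


def sector_of(phi_deg: float) -> str:
    """Map an in-plane angle (degrees) to its sector label.

    Sectors are half-open ``[lo, hi)``; E wraps across 0.
    """
    phi = float(phi_deg) % 360.0
    if phi < 22.5 or phi >= 337.5:
        return "E"
    idx = int(np.searchsorted(_INNER_EDGES, phi, side="right")) - 1
    return str(_INNER_NAMES[idx])


def sectors_of(phi_deg: np.ndarray) -> np.ndarray:
    """Vectorized :func:`sector_of`."""
    phi = np.asarray(phi_deg, dtype=float) % 360.0
    out = np.empty(phi.shape, dtype="<U2")
    wrap = (phi < 22.5) | (phi >= 337.5)
    out[wrap] = "E"
    inner = ~wrap
    idx = np.searchsorted(_INNER_EDGES, phi[inner], side="right") - 1
    out[inner] = _INNER_NAMES[idx]
    return out


# ---------------------------------------------------------------------------
# species-aware helpers


def sterol_frame_atom(mol, spec: SterolSpec, name: str) -> np.ndarray:
    """Position of a (possibly reconstructed) sterol role atom, nm."""
    if name in mol.atoms:
        return mol.atoms[name]
    rule = spec.reconstructed_atoms.get(name)
    if rule is None:
        raise KeyError(f"molecule {mol.mol_id}: atom {name!r} absent and not reconstructable")
    return reconstruct_tetrahedral_substituent(
        mol.atoms[rule.center],
        *(mol.atoms[n] for n in rule.neighbors),
        bond_length=rule.bond_length,
    )


def sterol_frame_for(mol, spec: SterolSpec, *, mirror: bool = False) -> SterolFrame:
    """Build the molecular frame of one sterol molecule (reconstructing C18
    for species that lack it)."""
    c13_name, c18_name, c10_name = spec.frame_atoms
    return build_sterol_frame(
        sterol_frame_atom(mol, spec, c13_name),
        sterol_frame_atom(mol, spec, c18_name),
        sterol_frame_atom(mol, spec, c10_name),
        mirror=mirror,
    )


def frames_table(snapshot, species_map, *, mirror: bool = False):
    """Tabulate every sterol frame in a snapshot as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for mol in snapshot.molecules:
        spec = species_map[mol.species]
        if spec.role != "sterol":
            continue
        fr = sterol_frame_for(mol, spec, mirror=mirror)
        rows.append(
            {
                "mol_id": mol.mol_id,
                "species": mol.species,
                "leaflet": mol.leaflet,
                "origin_x": fr.origin[0],
                "origin_y": fr.origin[1],
                "origin_z": fr.origin[2],
                **{f"e_{ax}_{c}": float(getattr(fr, f"e_{ax}")[i])
                   for ax in "xyz" for i, c in enumerate("xyz")},
            }
        )
    return pd.DataFrame(rows)
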