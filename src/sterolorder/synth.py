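"""Synthetic single-leaflet (and mirrored-bilayer) configuration generator.

Molecules are rigid idealized templates placed upright (long axis along the
membrane normal, zero tilt) and rotated about the lab z-axis only, so that
the sterol molecular xy-plane coincides with the lab plane and placement
geometry directly predicts every downstream statistic.  Four lateral
ordering modes are provided:

``csr``
    complete spatial randomness: uniform positions, uniform orientations.
``hard_disk``
    dart throwing with a minimum center-center separation.
``triangular``
    each seed sterol receives up to three second-shell sterol neighbors at
    frame angles {180, 45, 315} (the alpha/beta1/beta2 sector centers of the
    three-fold cholesterol motif) at the set spacing, plus optional
    first-shell lipids at preferred angles.
``linear``
    neighbors at frame angles {0, 180}: the two-fold motif of a flat sterol.

Neighbor orientations default to anti-aligned (offset 180 degrees), which
makes each member of a motif pair see the other at the same frame angle;
fixed-offset, von Mises and uniform orientation rules are available.  A
:class:`GroundTruth` record stores every placement (position, orientation,
leaflet, pair angle/distance/orientation offset, lipid angle/radius/theta)
so recovery tests can check analysis output against it without touching
generator internals.

The template coordinates are constraint-driven idealizations, not a force
field: C13/C18/C10/C6/C11 satisfy the frame-construction invariants exactly,
the three ring neighbors of C13 are arranged so tetrahedral reconstruction
of the missing methyl in the flat sterol reproduces the true C18 direction
exactly, and each template is laterally centered on its ring centroid so
that frame origin, ring COM and whole-molecule COM agree to < 0.01 nm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, PackingError
from .io import LOWER, UPPER, Molecule, Snapshot, write_snapshots  # noqa: F401

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "MoleculeTruth",
    "PairTruth",
    "LipidTruth",
    "REFERENCE_COMPOSITIONS",
    "mole_fraction_to_counts",
    "sterol_template",
    "pc_template",
    "generate_leaflet",
    "write_snapshots",
]

# 128-PC reference compositions (sterol counts per mole fraction) used by the
# bilayer systems this generator emulates.
REFERENCE_COMPOSITIONS: dict[float, int] = {0.10: 14, 0.20: 32, 0.30: 56, 0.40: 86, 0.50: 122}

TRIANGULAR_ANGLES: tuple[float, ...] = (180.0, 45.0, 315.0)
LINEAR_ANGLES: tuple[float, ...] = (0.0, 180.0)


def mole_fraction_to_counts(n_lipids: int, sterol_fraction: float) -> int:
    """Number of sterols giving the requested sterol mole fraction.

    ``n = round(n_lipids * f / (1 - f))``; f = 1 is rejected.
    """
    f = float(sterol_fraction)
    if not (0.0 <= f < 1.0):
        raise ConfigurationError(f"sterol fraction must lie in [0, 1), got {f}")
    return int(round(n_lipids * f / (1.0 - f)))


# ---------------------------------------------------------------------------
# rigid templates (nm, molecule-internal coordinates)


def _raw_sterol_coords() -> dict[str, np.ndarray]:
    c13 = np.zeros(3)
    c12 = np.array([-0.070, 0.130, 0.030])
    c14 = np.array([-0.070, -0.130, 0.030])
    # C17 placed so the unit bond vectors from C13 to its three ring
    # neighbors sum to a pure -x vector: tetrahedral reconstruction of the
    # missing methyl then reproduces the C18 direction exactly.
    u12 = c12 / np.linalg.norm(c12)
    u14 = c14 / np.linalg.norm(c14)
    sz = u12[2] + u14[2]
    c17 = c13 + 0.155 * np.array([-np.sqrt(1.0 - sz * sz), 0.0, -sz])
    x0 = -0.002  # near-planar ring sheet, slightly on the alpha side
    coords = {
        "C13": c13,
        "C18": np.array([0.153, 0.0, 0.0]),
        "C10": np.array([0.0, 0.0, 0.5]),
        "C19": np.array([0.153, 0.0, 0.5]),
        "C12": c12,
        "C14": c14,
        "C17": c17,
        "C1": np.array([x0, 0.125, 0.56]),
        "C2": np.array([x0, 0.120, 0.69]),
        "C3": np.array([x0, 0.125, 0.76]),
        "C4": np.array([x0, -0.120, 0.69]),
        "C5": np.array([x0, -0.125, 0.56]),
        "C6": np.array([x0, -0.130, 0.42]),
        "C7": np.array([x0, -0.130, 0.28]),
        "C8": np.array([x0, -0.120, 0.17]),
        "C9": np.array([x0, 0.125, 0.38]),
        "C11": np.array([x0, 0.130, 0.28]),
        "C15": np.array([x0, -0.110, -0.14]),
        "C16": np.array([x0, 0.060, -0.27]),
        "O3": np.array([x0, 0.0, 0.90]),
    }
    return coords

_CHOL_RING = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9", "C10",
              "C11", "C12", "C13", "C14", "C17", "C18", "C19")
_DCHL_RING = _CHOL_RING[:-2]

STEROL_ATOM_ORDER = ("O3",) + tuple(f"C{i}" for i in range(1, 20))


def sterol_template(species: str = "CHOL") -> dict[str, np.ndarray]:
    """Rigid sterol template, laterally centered on its ring centroid."""
    coords = _raw_sterol_coords()
    if species == "CHOL":
        ring = _CHOL_RING
    elif species == "DCHL":
        ring = _DCHL_RING
        coords.pop("C18")
        coords.pop("C19")
    else:
        raise ConfigurationError(f"no sterol template for species {species!r}")
    centroid = np.mean([coords[n] for n in ring], axis=0)
    return {n: p - np.array([centroid[0], centroid[1], 0.0]) for n, p in coords.items()}


PC_CHAIN_X = 0.35  # nm lateral half-separation of the two chains
PC_CHAIN_RISE = 0.118  # nm z drop per united-atom carbon

PC_ATOM_ORDER = ("P",) + tuple(f"C{i}A" for i in range(1, 19)) + tuple(
    f"C{i}B" for i in range(1, 19)
)


def pc_template(species: str = "DSPC") -> dict[str, np.ndarray]:
    """Rigid PC template: headgroup anchor over two straight 18-carbon
    chains; chain COM lateral midpoint at the origin, sn-1 -> sn-2 along +x
    (chain-chain separation 0.70 nm)."""
    if species not in ("DSPC", "DOPC"):
        raise ConfigurationError(f"no phospholipid template for species {species!r}")
    coords = {"P": np.array([0.0, 0.0, 0.95])}
    for k in range(18):
        z = 0.50 - PC_CHAIN_RISE * k
        coords[f"C{k + 1}A"] = np.array([-PC_CHAIN_X, 0.0, z])
        coords[f"C{k + 1}B"] = np.array([PC_CHAIN_X, 0.0, z])
    return coords


def template_for(species: str) -> tuple[dict[str, np.ndarray], tuple[str, ...]]:
    if species in ("CHOL", "DCHL"):
        order = tuple(n for n in STEROL_ATOM_ORDER if species == "CHOL" or n not in ("C18", "C19"))
        return sterol_template(species), order
    return pc_template(species), PC_ATOM_ORDER


def _rot2(psi_deg: float) -> np.ndarray:
    a = np.radians(psi_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def place_molecule(template: dict[str, np.ndarray], order: Sequence[str],
                   xy: np.ndarray, z0: float, psi_deg: float, *,
                   mirror_z: bool = False) -> dict[str, np.ndarray]:
    """Rotate a template about the lab z-axis, optionally mirror it through
    the lab plane (lower leaflet), and translate to (xy, z0)."""
    rot = _rot2(psi_deg)
    out = {}
    for name in order:
        p = template[name]
        lat = rot @ p[:2] + xy
        z = z0 + (-p[2] if mirror_z else p[2])
        out[name] = np.array([lat[0], lat[1], z])
    return out


# ---------------------------------------------------------------------------
# parameters and ground truth


@dataclass(frozen=True)
class GeneratorParams:
    """Synthetic leaflet parameters.

    Defaults emulate a 128-PC leaflet with 32 sterols (20 mol%) in a box of
    lateral area 39.90 nm^2.  ``orientation_rule`` is ``"uniform"``,
    ``("fixed", offset_deg)`` or ``("vonmises", mu_deg, kappa)``; by default
    csr/hard_disk use uniform orientations and the motif modes use
    anti-aligned pairs (fixed offset 180).
    """

    n_lipids: int = 128
    n_sterols: int | None = 32
    sterol_fraction: float | None = None
    lipid_species: str = "DSPC"
    sterol_species: str = "CHOL"
    box: tuple[float, float, float] = (6.3166, 6.3166, 6.0)
    mode: str = "csr"  # csr | hard_disk | triangular | linear
    spacing: float = 1.0  # nm, motif neighbor distance
    hard_core_radius: float = 0.45  # nm, min center-center separation
    cluster_exclusion: float | None = None  # nm; default 3.3 * spacing
    neighbor_angles: tuple[float, ...] | None = None  # default by mode
    angular_jitter_deg: float = 5.0
    radial_jitter_nm: float = 0.02
    orientation_rule: object = None
    lipid_rule: str = "uniform"  # uniform | first_shell
    lipid_angles: tuple[float, ...] = (90.0, 162.0, 234.0, 306.0, 18.0)
    first_shell_radius: float = 0.55  # nm, chain midpoint distance
    lipid_theta_rule: object = ("fixed", 90.0)  # or "uniform"
    n_frames: int = 1
    seed: int = 0
    bilayer: bool = False
    leaflet_offset: float = 1.0  # nm, leaflet midplane from box center
    area_jitter_sd: float = 0.0  # nm^2 SD of per-frame lateral area
    max_attempts: int = 2000

    def __post_init__(self):
        if self.mode not in ("csr", "hard_disk", "triangular", "linear"):
            raise ConfigurationError(f"unknown ordering mode {self.mode!r}")
        if self.n_lipids < 0 or (self.n_sterols is not None and self.n_sterols < 0):
            raise ConfigurationError("molecule counts must be >= 0")
        if self.spacing <= 0:
            raise ConfigurationError("spacing must be > 0")
        if self.mode == "hard_disk" and self.hard_core_radius >= self.spacing:
            raise ConfigurationError("hard-core radius must be < spacing")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if not all(b > 0 for b in self.box):
            raise ConfigurationError("box lengths must be > 0")

    @property
    def resolved_n_sterols(self) -> int:
        if self.sterol_fraction is not None:
            return mole_fraction_to_counts(self.n_lipids, self.sterol_fraction)
        return int(self.n_sterols or 0)

    @property
    def resolved_neighbor_angles(self) -> tuple[float, ...]:
        if self.neighbor_angles is not None:
            return self.neighbor_angles
        return TRIANGULAR_ANGLES if self.mode == "triangular" else LINEAR_ANGLES

    @property
    def resolved_orientation_rule(self):
        if self.orientation_rule is not None:
            return self.orientation_rule
        if self.mode in ("triangular", "linear"):
            return ("fixed", 180.0)
        return "uniform"

    @property
    def resolved_cluster_exclusion(self) -> float:
        if self.cluster_exclusion is not None:
            return self.cluster_exclusion
        return 3.3 * self.spacing


@dataclass(frozen=True)
class MoleculeTruth:
    frame: int
    mol_id: int
    species: str
    leaflet: str
    x: float
    y: float
    psi_deg: float  # rotation about lab z applied to the template


@dataclass(frozen=True)
class PairTruth:
    frame: int
    central: int
    neighbor: int
    frame_angle_deg: float  # realized angle of the neighbor in the central frame
    distance_nm: float
    orientation_offset_deg: float  # psi_neighbor - psi_central, mod 360


@dataclass(frozen=True)
class LipidTruth:
    frame: int
    sterol: int
    lipid: int
    frame_angle_deg: float
    radius_nm: float
    theta_deg: float  # co-localization angle realized by construction


@dataclass
class GroundTruth:
    """Everything needed to predict the generator's statistics."""

    seed: int
    mode: str
    molecules: list[MoleculeTruth] = field(default_factory=list)
    sterol_pairs: list[PairTruth] = field(default_factory=list)
    lipid_placements: list[LipidTruth] = field(default_factory=list)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "mode": self.mode,
            "molecules": [dataclasses.asdict(m) for m in self.molecules],
            "sterol_pairs": [dataclasses.asdict(p) for p in self.sterol_pairs],
            "lipid_placements": [dataclasses.asdict(p) for p in self.lipid_placements],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            mode=payload["mode"],
            molecules=[MoleculeTruth(**m) for m in payload["molecules"]],
            sterol_pairs=[PairTruth(**p) for p in payload["sterol_pairs"]],
            lipid_placements=[LipidTruth(**p) for p in payload["lipid_placements"]],
        )

    def leaflet_of(self, frame: int, mol_id: int) -> str:
        for m in self.molecules:
            if m.frame == frame and m.mol_id == mol_id:
                return m.leaflet
        raise KeyError((frame, mol_id))


# ---------------------------------------------------------------------------
# placement


def _uniform_xy(rng, box2) -> np.ndarray:
    return rng.random(2) * box2


def _min_image_dist(a, b, box2) -> float:
    d = a - b
    d -= np.round(d / box2) * box2
    return float(np.hypot(d[0], d[1]))


def _throw_darts(rng, n, box2, min_sep, max_attempts, existing=None):
    placed = list(existing) if existing else []
    new = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            cand = _uniform_xy(rng, box2)
            if all(_min_image_dist(cand, p, box2) >= min_sep for p in placed):
                placed.append(cand)
                new.append(cand)
                break
        else:
            raise PackingError(
                f"dart throwing failed after {max_attempts} attempts "
                f"(placed {len(new)}/{n} at separation {min_sep} nm)",
                achieved=len(new),
            )
    return new


def _draw_orientation_offset(rng, rule) -> float:
    if rule == "uniform":
        return float(rng.random() * 360.0)
    kind = rule[0]
    if kind == "fixed":
        return float(rule[1])
    if kind == "vonmises":
        mu, kappa = float(rule[1]), float(rule[2])
        return float(np.degrees(rng.vonmises(np.radians(mu), kappa)) % 360.0)
    raise ConfigurationError(f"unknown orientation rule {rule!r}")


def _place_leaflet(rng, params: GeneratorParams, box2: np.ndarray, leaflet: str,
                   frame: int, first_id: int, truth: GroundTruth):
    """Place sterols and lipids of one leaflet; returns (sterol placements,
    lipid placements) as lists of (xy, psi)."""
    n_st = params.resolved_n_sterols
    n_lip = params.n_lipids
    mode = params.mode
    sterols: list[tuple[np.ndarray, float]] = []
    pair_records: list[tuple[int, int, float, float, float]] = []

    if mode == "csr":
        for _ in range(n_st):
            sterols.append((_uniform_xy(rng, box2), float(rng.random() * 360.0)))
    elif mode == "hard_disk":
        pts = _throw_darts(rng, n_st, box2, params.hard_core_radius, params.max_attempts)
        for p in pts:
            sterols.append((p, float(rng.random() * 360.0)))
    else:  # triangular | linear motifs
        angles = params.resolved_neighbor_angles
        cluster_size = 1 + len(angles)
        n_clusters = -(-n_st // cluster_size)  # ceil
        centers = _throw_darts(
            rng, n_clusters, box2, params.resolved_cluster_exclusion, params.max_attempts
        )
        rule = params.resolved_orientation_rule
        remaining = n_st
        for center in centers:
            if remaining <= 0:
                break
            psi_c = float(rng.random() * 360.0)
            central_idx = len(sterols)
            sterols.append((center % box2, psi_c))
            remaining -= 1
            for a in angles:
                if remaining <= 0:
                    break
                a_real = a + rng.normal(0.0, params.angular_jitter_deg)
                d_real = params.spacing + rng.normal(0.0, params.radial_jitter_nm)
                lab = np.radians(psi_c + a_real)
                xy = (center + d_real * np.array([np.cos(lab), np.sin(lab)])) % box2
                offset = _draw_orientation_offset(rng, rule)
                neighbor_idx = len(sterols)
                sterols.append((xy, (psi_c + offset) % 360.0))
                remaining -= 1
                pair_records.append(
                    (central_idx, neighbor_idx, float(a_real % 360.0), float(d_real),
                     float(offset % 360.0))
                )

    lipids: list[tuple[np.ndarray, float]] = []
    lipid_records: list[tuple[int, int, float, float, float]] = []
    if params.lipid_rule == "first_shell" and sterols:
        st_idx = 0
        ang_idx = 0
        while len(lipids) < n_lip and st_idx < len(sterols):
            xy_s, psi_s = sterols[st_idx]
            a = params.lipid_angles[ang_idx]
            a_real = a + rng.normal(0.0, params.angular_jitter_deg)
            r_real = params.first_shell_radius + rng.normal(0.0, params.radial_jitter_nm)
            gamma = psi_s + a_real  # lab angle of the midpoint from the sterol
            mid = (xy_s + r_real * np.array([np.cos(np.radians(gamma)),
                                             np.sin(np.radians(gamma))])) % box2
            if params.lipid_theta_rule == "uniform":
                theta = float(rng.random() * 180.0)
            else:
                theta = float(params.lipid_theta_rule[1])
            sign = 1.0 if rng.random() < 0.5 else -1.0
            psi_l = (gamma + sign * theta) % 360.0
            lipid_records.append(
                (st_idx, len(lipids), float(a_real % 360.0), float(r_real), theta)
            )
            lipids.append((mid, psi_l))
            ang_idx += 1
            if ang_idx >= len(params.lipid_angles):
                ang_idx = 0
                st_idx += 1
    while len(lipids) < n_lip:
        lipids.append((_uniform_xy(rng, box2), float(rng.random() * 360.0)))

    # ground-truth bookkeeping with global molecule ids
    sterol_ids = [first_id + i for i in range(len(sterols))]
    lipid_ids = [first_id + len(sterols) + i for i in range(len(lipids))]
    for (xy, psi), mid_ in zip(sterols, sterol_ids):
        truth.molecules.append(
            MoleculeTruth(frame, mid_, params.sterol_species, leaflet,
                          float(xy[0]), float(xy[1]), float(psi))
        )
    for (xy, psi), mid_ in zip(lipids, lipid_ids):
        truth.molecules.append(
            MoleculeTruth(frame, mid_, params.lipid_species, leaflet,
                          float(xy[0]), float(xy[1]), float(psi))
        )
    for c, nbh, a, d, off in pair_records:
        truth.sterol_pairs.append(
            PairTruth(frame, sterol_ids[c], sterol_ids[nbh], a, d, off)
        )
    for s, li, a, r, th in lipid_records:
        truth.lipid_placements.append(
            LipidTruth(frame, sterol_ids[s], lipid_ids[li], a, r, th)
        )
    return sterols, lipids


def generate_leaflet(params: GeneratorParams) -> tuple[list[Snapshot], GroundTruth]:
    """Generate snapshots with known lateral and orientational structure.

    Returns the snapshot sequence (leaflet labels pre-assigned from the
    construction) and the ground-truth record.  Identical parameters and
    seed reproduce the output bit-identically; frames are independent
    redraws from the same seeded stream.
    """
    rng = np.random.default_rng(params.seed)
    st_template, st_order = template_for(params.sterol_species)
    li_template, li_order = template_for(params.lipid_species)
    base_box = np.array(params.box, dtype=float)
    base_area = base_box[0] * base_box[1]
    truth = GroundTruth(seed=params.seed, mode=params.mode)
    snapshots: list[Snapshot] = []

    for frame in range(params.n_frames):
        if params.area_jitter_sd > 0:
            area = max(rng.normal(base_area, params.area_jitter_sd), 0.25 * base_area)
            scale = np.sqrt(area / base_area)
        else:
            scale = 1.0
        box = np.array([base_box[0] * scale, base_box[1] * scale, base_box[2]])
        box2 = box[:2]
        molecules: list[Molecule] = []

        leaflets = ((UPPER, False),) if not params.bilayer else ((UPPER, False), (LOWER, True))
        next_id = 1
        for leaflet, mirrored in leaflets:
            if params.bilayer:
                z0 = box[2] / 2.0 + (params.leaflet_offset if leaflet == UPPER
                                     else -params.leaflet_offset)
            else:
                z0 = box[2] / 2.0
            sterols, lipids = _place_leaflet(
                rng, params, box2, leaflet, frame, next_id, truth
            )
            for xy, psi in sterols:
                molecules.append(
                    Molecule(
                        mol_id=next_id,
                        species=params.sterol_species,
                        atoms=place_molecule(st_template, st_order, xy, z0, psi,
                                             mirror_z=mirrored),
                        leaflet=leaflet,
                        atom_order=st_order,
                    )
                )
                next_id += 1
            for xy, psi in lipids:
                molecules.append(
                    Molecule(
                        mol_id=next_id,
                        species=params.lipid_species,
                        atoms=place_molecule(li_template, li_order, xy, z0, psi,
                                             mirror_z=mirrored),
                        leaflet=leaflet,
                        atom_order=li_order,
                    )
                )
                next_id += 1
        snapshots.append(
            Snapshot(frame_index=frame, time=float(frame), box=box, molecules=molecules)
        )
    return snapshots, truth
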