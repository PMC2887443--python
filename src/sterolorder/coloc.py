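"""First-shell lipid selection and co-localization angle statistics.

A phospholipid belongs to a sterol's first coordination shell when the
center of mass of at least one of its acyl chains lies within 0.75 nm
(lateral, minimum image) of the sterol's center.  For each such
(sterol, lipid) pair the co-localization angle theta is the in-plane angle
between the chain-chain vector (sn-1 COM -> sn-2 COM) and the vector from
the sterol anchor to the chain midpoint.  Because the two chains are
treated as equivalent, theta is folded to theta90 = 90 - |90 - theta| in
[0, 90]: 0 means collinear (chains lined up with the sterol), 90 means
'facing' (both chains equidistant from the sterol).

The sterol-side anchor defaults to the ring center of mass; a whole-molecule
mode is provided since either convention is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError, DegenerateGeometryError
from .frames import sector_of, sterol_frame_for, SECTOR_NAMES
from .io import Snapshot, min_image_shift, molecule_com
from .species import SpeciesMap

__all__ = [
    "AngleDistribution",
    "ChainGeometry",
    "FIRST_SHELL_CUTOFF",
    "chain_geometry",
    "select_first_shell_lipids",
    "colocalization_angle",
    "fold_theta90",
    "theta90_distribution",
    "chain_separation_summary",
]

FIRST_SHELL_CUTOFF = 0.75  # nm


@dataclass(frozen=True)
class AngleDistribution:
    """Binned angular statistics over a fixed domain."""

    domain: str  # e.g. "theta90 [0, 90]" or "relative orientation [0, 360)"
    edges: np.ndarray  # degrees, uniform
    counts: np.ndarray  # raw pair counts (ints)
    n_pairs: int

    @property
    def frequencies(self) -> np.ndarray:
        """Normalized frequencies (sum to 1); zeros when empty."""
        if self.n_pairs == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.counts.sum()

    @property
    def is_empty(self) -> bool:
        return self.n_pairs == 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def circular_mean_deg(self) -> float:
        """Circular mean of the binned angles (bin centers, count-weighted)."""
        if self.n_pairs == 0:
            raise AnalysisError("circular mean of an empty distribution")
        ang = np.radians(self.centers)
        s = (self.counts * np.sin(ang)).sum()
        c = (self.counts * np.cos(ang)).sum()
        return float(np.degrees(np.arctan2(s, c)) % 360.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "angle_mid": self.centers,
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )


@dataclass(frozen=True)
class ChainGeometry:
    """Acyl-chain centers of mass of one phospholipid (nm, unwrapped)."""

    sn1_com: np.ndarray
    sn2_com: np.ndarray

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.sn1_com + self.sn2_com)

    @property
    def lateral_separation(self) -> float:
        d = self.sn2_com[:2] - self.sn1_com[:2]
        return float(np.hypot(d[0], d[1]))


def chain_geometry(mol, spec, *, mass_weighted: bool = True) -> ChainGeometry:
    return ChainGeometry(
        sn1_com=molecule_com(mol, spec, "sn1", mass_weighted=mass_weighted),
        sn2_com=molecule_com(mol, spec, "sn2", mass_weighted=mass_weighted),
    )


def _sterol_anchor(mol, spec, anchor: str) -> np.ndarray:
    if anchor == "ring":
        return molecule_com(mol, spec, "ring")
    if anchor == "molecule":
        return molecule_com(mol, spec, "whole")
    raise AnalysisError(f"unknown sterol anchor {anchor!r} (expected 'ring' or 'molecule')")


def select_first_shell_lipids(snapshot: Snapshot, species_map: SpeciesMap,
                              sterol_id: int, *, cutoff: float = FIRST_SHELL_CUTOFF,
                              lipid_species: str | None = None,
                              anchor: str = "ring") -> list[int]:
    """Ids of lipids with >= 1 chain COM within ``cutoff`` of the sterol
    (lateral minimum-image distance, same leaflet); each lipid listed once."""
    sterol = next((m for m in snapshot.molecules if m.mol_id == sterol_id), None)
    if sterol is None:
        raise AnalysisError(f"no molecule with id {sterol_id}")
    spec_s = species_map[sterol.species]
    if spec_s.role != "sterol":
        raise AnalysisError(f"molecule {sterol_id} ({sterol.species}) is not a sterol")
    center = _sterol_anchor(sterol, spec_s, anchor)
    box2 = snapshot.box[:2]
    out: list[int] = []
    for mol in snapshot.molecules:
        spec = species_map[mol.species]
        if spec.role != "phospholipid" or mol.leaflet != sterol.leaflet:
            continue
        if lipid_species is not None and mol.species != lipid_species:
            continue
        geom = chain_geometry(mol, spec)
        for com in (geom.sn1_com, geom.sn2_com):
            d = min_image_shift(com[:2] - center[:2], box2)
            if np.hypot(d[0], d[1]) <= cutoff:
                out.append(mol.mol_id)
                break
    return out


def colocalization_angle(sterol_anchor, geometry: ChainGeometry, *,
                         box=None, planar: bool = True) -> float:
    """Co-localization angle theta in [0, 180] degrees.

    theta is the angle between ``v_chains = sn2_com - sn1_com`` and
    ``v_ref = midpoint - sterol_anchor`` using their in-plane projections
    (set ``planar=False`` for the 3D angle).  Passing ``box`` applies the
    minimum image to ``v_ref``.
    """
    anchor = np.asarray(sterol_anchor, dtype=float)
    v_chains = geometry.sn2_com - geometry.sn1_com
    v_ref = geometry.midpoint - anchor
    if box is not None:
        v_ref = np.asarray(v_ref, dtype=float)
        v_ref[:2] = min_image_shift(v_ref[:2], np.asarray(box)[:2])
    if planar:
        v_chains = v_chains[:2]
        v_ref = v_ref[:2]
    nc = np.linalg.norm(v_chains)
    nr = np.linalg.norm(v_ref)
    if nc < 1e-12 or nr < 1e-12:
        raise DegenerateGeometryError(
            "co-localization angle undefined: zero-length projected vector"
        )
    cosang = np.clip((v_chains @ v_ref) / (nc * nr), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def fold_theta90(theta: float) -> float:
    """Fold theta in [0, 180] onto the chain-symmetric theta90 = 90 - |90 - theta|."""
    theta = float(theta)
    if not (0.0 <= theta <= 180.0):
        raise AnalysisError(f"theta must lie in [0, 180] degrees, got {theta}")
    return 90.0 - abs(90.0 - theta)


def theta90_distribution(snapshots: Sequence[Snapshot], species_map: SpeciesMap,
                         sterol_species: str, lipid_species: str, *,
                         bin_width: float = 5.0, cutoff: float = FIRST_SHELL_CUTOFF,
                         anchor: str = "ring", sector_resolved: bool = False,
                         planar: bool = True):
    """theta90 histogram over all (sterol, first-shell lipid) pairs.

    With ``sector_resolved=True`` a dict of per-sector distributions is
    returned, binned by the sector of the chain midpoint in the sterol's
    molecular frame (sector counts sum to the total).  A configuration with
    zero pairs yields an empty, flagged distribution.
    """
    n_bins = int(round(90.0 / bin_width))
    if abs(n_bins * bin_width - 90.0) > 1e-9:
        raise AnalysisError("bin width must evenly divide 90 degrees")
    edges = np.arange(n_bins + 1) * bin_width
    spec_s = species_map[sterol_species]
    spec_l = species_map[lipid_species]
    if spec_s.role != "sterol" or spec_l.role != "phospholipid":
        raise AnalysisError("theta90_distribution expects (sterol, phospholipid) species")

    keys = SECTOR_NAMES if sector_resolved else ("all",)
    counts = {k: np.zeros(n_bins, dtype=np.int64) for k in keys}

    for snap in snapshots:
        box2 = snap.box[:2]
        for leaflet in snap.leaflets:
            sterols = snap.by_species(sterol_species, leaflet)
            lipids = snap.by_species(lipid_species, leaflet)
            if not sterols or not lipids:
                continue
            geoms = {m.mol_id: chain_geometry(m, spec_l) for m in lipids}
            for st in sterols:
                center = _sterol_anchor(st, spec_s, anchor)
                frame = sterol_frame_for(st, spec_s) if sector_resolved else None
                for lm in lipids:
                    geom = geoms[lm.mol_id]
                    in_shell = False
                    for com in (geom.sn1_com, geom.sn2_com):
                        d = min_image_shift(com[:2] - center[:2], box2)
                        if np.hypot(d[0], d[1]) <= cutoff:
                            in_shell = True
                            break
                    if not in_shell:
                        continue
                    theta = colocalization_angle(center, geom, box=snap.box, planar=planar)
                    t90 = fold_theta90(theta)
                    b = min(int(t90 // bin_width), n_bins - 1)
                    if sector_resolved:
                        delta = geom.midpoint - frame.origin
                        delta = min_image_shift(delta, snap.box)
                        x = float(delta @ frame.e_x)
                        y = float(delta @ frame.e_y)
                        phi = float(np.degrees(np.arctan2(y, x)) % 360.0)
                        counts[sector_of(phi)][b] += 1
                    else:
                        counts["all"][b] += 1

    def _dist(c):
        return AngleDistribution(
            domain="theta90 [0, 90]",
            edges=edges,
            counts=c,
            n_pairs=int(c.sum()),
        )

    if sector_resolved:
        return {k: _dist(c) for k, c in counts.items()}
    return _dist(counts["all"])


def chain_separation_summary(snapshots: Sequence[Snapshot], species_map: SpeciesMap,
                             lipid_species: str, *,
                             sterol_species: str | None = None,
                             cutoff: float = FIRST_SHELL_CUTOFF,
                             anchor: str = "ring") -> tuple[float, float, int]:
    """Mean and SD (nm) of the lateral sn-1/sn-2 chain COM separation.

    With ``sterol_species`` given, only lipids in the first shell of a sterol
    are counted (each (sterol, lipid) pair contributes once, matching the
    pair-based angle statistics); otherwise all lipids contribute once per
    frame.  Returns ``(mean, sd, n)``.
    """
    spec_l = species_map[lipid_species]
    seps: list[float] = []
    for snap in snapshots:
        for leaflet in snap.leaflets:
            lipids = snap.by_species(lipid_species, leaflet)
            if sterol_species is None:
                seps.extend(chain_geometry(m, spec_l).lateral_separation for m in lipids)
                continue
            for st in snap.by_species(sterol_species, leaflet):
                ids = select_first_shell_lipids(
                    snap, species_map, st.mol_id,
                    cutoff=cutoff, lipid_species=lipid_species, anchor=anchor,
                )
                id_set = set(ids)
                seps.extend(
                    chain_geometry(m, spec_l).lateral_separation
                    for m in lipids
                    if m.mol_id in id_set
                )
    if not seps:
        return (float("nan"), float("nan"), 0)
    arr = np.array(seps)
    return (float(arr.mean()), float(arr.std()), len(arr))
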