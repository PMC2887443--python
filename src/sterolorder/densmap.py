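"""Two-dimensional density maps of neighbor atoms in the sterol frame.

For every reference sterol the minimum-image lab displacement of each
selected same-leaflet target atom is rotated into the sterol's molecular
frame and projected onto the frame xy-plane; bin counts are normalized to
total densities in atoms nm^-2 per reference per frame (so a spatially
random target field of density rho produces a map ~ rho everywhere).  No cut
is applied along the frame z-axis by default (full projection); an optional
``frame_z_range`` restricts it.

Peak extraction finds local maxima above a threshold (a multiplier of the
map mean) inside a radial band, greedily pruned by minimum separation
(highest first), and annotates each peak with its in-plane angle, radius and
angular sector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import AnalysisError
from .frames import sector_of, sterol_frame_for
from .io import Snapshot, min_image_shift, molecule_com
from .species import SpeciesMap

__all__ = [
    "DensityMap2D",
    "Peak",
    "PeakSet",
    "accumulate_density_map",
    "find_peaks",
]

TARGET_ROLES = ("ring", "chains", "terminal_methyls", "ring_com", "com")


@dataclass(frozen=True)
class DensityMap2D:
    """Square molecular-frame density grid.

    ``values[i, j]`` is the density (atoms nm^-2 per reference per frame) in
    the bin with frame-x in ``[x_edges[i], x_edges[i+1])`` and frame-y in
    ``[y_edges[j], y_edges[j+1])``.
    """

    values: np.ndarray
    extent: float  # nm; grid covers [-extent, extent] in x and y
    bin_size: float  # nm
    selection: str
    n_references: int  # total (reference, frame) units accumulated
    n_frames: int

    @property
    def edges(self) -> np.ndarray:
        n = self.values.shape[0]
        return -self.extent + np.arange(n + 1) * self.bin_size

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def bin_area(self) -> float:
        return self.bin_size**2

    def mean_in_window_count(self) -> float:
        """Mean number of selected atoms inside the window per reference per
        frame (the map integral)."""
        return float(self.values.sum() * self.bin_area)

    # -- export ------------------------------------------------------------

    def to_text(self, path) -> Path:
        """Plain-text matrix with a metadata header."""
        path = Path(path)
        header = (
            f"selection: {self.selection}\n"
            f"extent_nm: {self.extent}\n"
            f"bin_size_nm: {self.bin_size}\n"
            f"n_references: {self.n_references}\n"
            f"n_frames: {self.n_frames}\n"
            f"units: atoms nm^-2 per reference per frame; rows = frame x, cols = frame y"
        )
        np.savetxt(path, self.values, header=header)
        return path

    @classmethod
    def from_text(cls, path) -> "DensityMap2D":
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
        values = np.loadtxt(path)
        return cls(
            values=values,
            extent=float(meta["extent_nm"]),
            bin_size=float(meta["bin_size_nm"]),
            selection=meta.get("selection", ""),
            n_references=int(meta.get("n_references", 0)),
            n_frames=int(meta.get("n_frames", 0)),
        )

    def to_hdf5(self, path) -> Path:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("density", data=self.values)
            ds.attrs["extent_nm"] = self.extent
            ds.attrs["bin_size_nm"] = self.bin_size
            ds.attrs["selection"] = self.selection
            ds.attrs["n_references"] = self.n_references
            ds.attrs["n_frames"] = self.n_frames
        return path

    @classmethod
    def from_hdf5(cls, path) -> "DensityMap2D":
        import h5py

        with h5py.File(path, "r") as fh:
            ds = fh["density"]
            return cls(
                values=ds[()],
                extent=float(ds.attrs["extent_nm"]),
                bin_size=float(ds.attrs["bin_size_nm"]),
                selection=str(ds.attrs["selection"]),
                n_references=int(ds.attrs["n_references"]),
                n_frames=int(ds.attrs["n_frames"]),
            )

    def plot(self, ax=None, **imshow_kw):
        """Render the map with frame x horizontal and y vertical."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            self.values.T,
            origin="lower",
            extent=(-self.extent, self.extent, -self.extent, self.extent),
            **imshow_kw,
        )
        ax.set_xlabel("frame x (nm)")
        ax.set_ylabel("frame y (nm)")
        ax.set_title(self.selection)
        plt.colorbar(im, ax=ax, label=r"density (nm$^{-2}$)")
        return ax


@dataclass(frozen=True)
class Peak:
    phi_deg: float
    r_nm: float
    height: float  # atoms nm^-2
    sector: str
    x: float
    y: float


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]
    threshold: float  # absolute height threshold applied

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def _target_positions(mol, spec, role: str, atoms: Sequence[str] | None):
    if atoms is not None:
        return mol.positions(atoms)
    if role == "ring":
        names = [n for n in spec.ring_atoms if n in mol.atoms]
        return mol.positions(names)
    if role == "chains":
        return mol.positions([*spec.sn1_chain_atoms, *spec.sn2_chain_atoms])
    if role == "terminal_methyls":
        return mol.positions([spec.sn1_chain_atoms[-1], spec.sn2_chain_atoms[-1]])
    if role == "ring_com":
        return molecule_com(mol, spec, "ring")[None, :]
    if role == "com":
        return molecule_com(mol, spec, "whole")[None, :]
    raise AnalysisError(f"unknown target role {role!r} (expected one of {TARGET_ROLES})")


def accumulate_density_map(snapshots: Sequence[Snapshot], species_map: SpeciesMap,
                           reference_species: str, target_species: str,
                           target_role: str = "ring", *,
                           target_atoms: Sequence[str] | None = None,
                           extent: float = 2.5, bin_size: float = 0.05,
                           mirror: bool = False,
                           frame_z_range: tuple[float, float] | None = None
                           ) -> DensityMap2D:
    """Accumulate the frame-projected density of target atoms around every
    reference sterol.

    ``target_role`` selects the atoms: ``ring`` (ring-atom selection, the
    map of neighbouring sterol rings), ``chains`` (all united-atom acyl
    carbons of both chains), ``terminal_methyls``, ``ring_com`` / ``com``
    (one point per molecule), or pass explicit ``target_atoms``.  The
    reference's own atoms are excluded; only same-leaflet targets count.
    """
    if not snapshots:
        raise AnalysisError("accumulate_density_map needs at least one snapshot")
    ref_spec = species_map[reference_species]
    if ref_spec.role != "sterol":
        raise AnalysisError(f"reference species {reference_species!r} is not a sterol")
    tgt_spec = species_map[target_species]

    n = int(round(2 * extent / bin_size))
    if abs(n * bin_size - 2 * extent) > 1e-9:
        raise AnalysisError("extent must be an integer multiple of bin_size")
    edges = -extent + np.arange(n + 1) * bin_size

    half_min_box = min(float(min(s.box[0], s.box[1])) for s in snapshots) / 2.0
    if extent > half_min_box:
        warnings.warn(
            f"grid extent {extent} nm exceeds half the smallest lateral box "
            f"length ({half_min_box:.3f} nm); peripheral bins mix periodic images",
            stacklevel=2,
        )

    hist = np.zeros((n, n))
    n_ref_units = 0
    frames = set()
    for snap in snapshots:
        frames.add(snap.frame_index)
        box2 = snap.box[:2]
        for leaflet in snap.leaflets:
            refs = snap.by_species(reference_species, leaflet)
            targets = snap.by_species(target_species, leaflet)
            if not refs:
                continue
            pos_blocks = []
            owner_blocks = []
            for mol in targets:
                p = _target_positions(mol, tgt_spec, target_role, target_atoms)
                pos_blocks.append(p)
                owner_blocks.append(np.full(len(p), mol.mol_id))
            if pos_blocks:
                all_pos = np.concatenate(pos_blocks)
                owners = np.concatenate(owner_blocks)
            else:
                all_pos = np.zeros((0, 3))
                owners = np.zeros(0, dtype=int)
            for mol in refs:
                frame = sterol_frame_for(mol, ref_spec, mirror=mirror)
                n_ref_units += 1
                if not len(all_pos):
                    continue
                keep = owners != mol.mol_id
                delta = all_pos[keep] - frame.origin
                delta[:, :2] = min_image_shift(delta[:, :2], box2)
                fc = delta @ frame.rotation.T
                if frame_z_range is not None:
                    zlo, zhi = frame_z_range
                    fc = fc[(fc[:, 2] >= zlo) & (fc[:, 2] <= zhi)]
                h, _, _ = np.histogram2d(fc[:, 0], fc[:, 1], bins=(edges, edges))
                hist += h
    if n_ref_units == 0:
        raise AnalysisError(f"no {reference_species!r} references found")
    values = hist / (bin_size**2 * n_ref_units)
    label = f"{target_species}:{target_role if target_atoms is None else 'atoms'}" \
            f" around {reference_species}"
    return DensityMap2D(
        values=values,
        extent=extent,
        bin_size=bin_size,
        selection=label,
        n_references=n_ref_units,
        n_frames=len(frames),
    )


def find_peaks(density_map: DensityMap2D, *, threshold: float = 2.0,
               min_separation: float = 0.2,
               radial_band: tuple[float, float] | None = None) -> PeakSet:
    """Local maxima of a density map above ``threshold`` x the map mean.

    Maxima inside ``radial_band`` (nm, on the bin-center radius) are kept and
    greedily pruned: peaks closer than ``min_separation`` (nm, Euclidean) to
    an already-accepted higher peak are dropped.  The threshold multiplier is
    applied to the mean over the searched region (the radial band when one is
    given, the whole map otherwise).  An empty band yields an empty peak set.
    """
    values = density_map.values
    centers = density_map.centers
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    radius = np.hypot(cx, cy)

    local_max = values == ndimage.maximum_filter(values, size=3, mode="nearest")
    if radial_band is not None:
        lo, hi = radial_band
        band = (radius >= lo) & (radius <= hi)
        if not band.any():
            return PeakSet(peaks=(), threshold=float("inf"))
        abs_threshold = threshold * float(values[band].mean())
        mask = local_max & (values > abs_threshold) & band
    else:
        abs_threshold = threshold * float(values.mean())
        mask = local_max & (values > abs_threshold)

    idx = np.argwhere(mask)
    if not len(idx):
        return PeakSet(peaks=(), threshold=abs_threshold)
    heights = values[mask]
    order = np.argsort(heights)[::-1]
    accepted: list[Peak] = []
    accepted_xy: list[np.ndarray] = []
    for k in order:
        i, j = idx[k]
        xy = np.array([cx[i, j], cy[i, j]])
        if any(np.linalg.norm(xy - a) < min_separation for a in accepted_xy):
            continue
        phi = float(np.degrees(np.arctan2(xy[1], xy[0])) % 360.0)
        accepted.append(
            Peak(
                phi_deg=phi,
                r_nm=float(np.hypot(*xy)),
                height=float(values[i, j]),
                sector=sector_of(phi),
                x=float(xy[0]),
                y=float(xy[1]),
            )
        )
        accepted_xy.append(xy)
    return PeakSet(peaks=tuple(accepted), threshold=abs_threshold)
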