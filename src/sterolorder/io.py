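"""Coordinate snapshot I/O, leaflet assignment and centers of mass.

Snapshots are read from GRO or PDB files through MDAnalysis.  All coordinates
are stored in nm internally (PDB Angstrom converted on read).  Molecules are
grouped by residue id, matched to a species map by residue name, and made
whole across periodic boundaries on read by nearest-image chaining along the
file's atom order; every center of mass is computed on these unwrapped
coordinates.

Multi-frame input is either a list of files, a concatenated multi-frame GRO
file, or a multi-model PDB.  Binary trajectory formats (XTC/TRR/DCD) are out
of scope; an adapter only needs to yield one MDAnalysis Universe per frame
and feed it to :func:`snapshot_from_universe`.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError, ConfigurationError, FormatError
from .species import SpeciesMap

__all__ = [
    "Molecule",
    "Snapshot",
    "AreaSummary",
    "read_snapshots",
    "write_snapshots",
    "assign_leaflets",
    "center_of_mass",
    "mean_lateral_area",
    "molecule_com",
    "min_image_shift",
]

UPPER = "upper"
LOWER = "lower"
UNASSIGNED = "unassigned"


@dataclass
class Molecule:
    """One molecule: identity plus named-atom positions (nm, unwrapped)."""

    mol_id: int
    species: str
    atoms: dict[str, np.ndarray]
    leaflet: str = UNASSIGNED
    atom_order: tuple[str, ...] = ()

    def positions(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.atoms[n] for n in names])


@dataclass
class Snapshot:
    """One time frame of a (single- or double-leaflet) membrane patch."""

    frame_index: int
    time: float  # ps
    box: np.ndarray  # (3,) lateral Lx, Ly and normal Lz, nm
    molecules: list[Molecule] = field(default_factory=list)

    @property
    def lateral_area(self) -> float:
        return float(self.box[0] * self.box[1])

    def by_species(self, species: str, leaflet: str | None = None) -> list[Molecule]:
        return [
            m
            for m in self.molecules
            if m.species == species and (leaflet is None or m.leaflet == leaflet)
        ]

    @property
    def leaflets(self) -> tuple[str, ...]:
        return tuple(sorted({m.leaflet for m in self.molecules}))


@dataclass(frozen=True)
class AreaSummary:
    mean: float  # nm^2
    sd: float  # nm^2 (population SD over frames)
    n_frames: int


# ---------------------------------------------------------------------------
# periodic-box helpers


def min_image_shift(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement(s) ``delta``.

    Works on the trailing axis; only the first ``len(box)`` components are
    wrapped (pass ``box[:2]`` for lateral-only wrapping).
    """
    delta = np.array(delta, dtype=float)
    nb = len(box)
    delta[..., :nb] -= np.round(delta[..., :nb] / box[:nb]) * box[:nb]
    return delta


def _unwrap_molecule(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a molecule whole: chain each atom to the nearest image of its
    predecessor in file order."""
    out = positions.copy()
    for k in range(1, len(out)):
        step = min_image_shift(out[k] - out[k - 1], box)
        out[k] = out[k - 1] + step
    return out


# ---------------------------------------------------------------------------
# reading


def _universe_to_snapshot(u, species_map: SpeciesMap, frame_index: int,
                          time: float, box_nm: np.ndarray, *, source="") -> Snapshot:
    molecules: list[Molecule] = []
    for res in u.residues:
        resname = str(res.resname).strip()
        if resname not in species_map:
            raise ConfigurationError(
                f"{source}: residue {int(res.resid)} has species {resname!r} "
                f"not present in the species map"
            )
        spec = species_map[resname]
        names = [spec.atom_aliases.get(str(n).strip(), str(n).strip()) for n in res.atoms.names]
        pos = res.atoms.positions.astype(float) * 0.1  # Angstrom -> nm
        pos = _unwrap_molecule(pos, box_nm)
        atoms = {n: p for n, p in zip(names, pos)}
        if len(atoms) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise FormatError(
                f"molecule {int(res.resid)} ({resname}): duplicate atom names {sorted(dupes)}",
                path=source,
            )
        missing = [n for n in spec.required_atoms if n not in atoms]
        if missing:
            raise FormatError(
                f"molecule {int(res.resid)} ({resname}): missing role atoms {missing}",
                path=source,
            )
        if not np.all(np.isfinite(pos)):
            raise FormatError(
                f"molecule {int(res.resid)} ({resname}): non-finite coordinates",
                path=source,
            )
        molecules.append(
            Molecule(
                mol_id=int(res.resid),
                species=resname,
                atoms=atoms,
                atom_order=tuple(names),
            )
        )
    if not np.all(box_nm > 0):
        raise FormatError(f"non-positive box {box_nm}", path=source)
    return Snapshot(frame_index=frame_index, time=time, box=box_nm, molecules=molecules)


def _split_gro_frames(text: str, path, allow_partial: bool) -> list[str]:
    lines = text.splitlines()
    chunks: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        if i + 1 >= len(lines):
            if allow_partial:
                break
            raise FormatError("truncated frame: missing atom-count line", path=path, line=i + 2)
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(
                f"expected atom count, got {lines[i + 1]!r}", path=path, line=i + 2
            ) from None
        end = i + 2 + natoms + 1
        if end > len(lines):
            if allow_partial:
                break
            raise FormatError(
                f"truncated frame: expected {natoms} atom lines plus a box line",
                path=path,
                line=len(lines),
            )
        chunks.append("\n".join(lines[i:end]) + "\n")
        i = end
    if not chunks:
        raise FormatError("no frames found", path=path)
    return chunks


def _read_gro(path: Path, species_map: SpeciesMap, start_index: int,
              allow_partial: bool) -> list[Snapshot]:
    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    chunks = _split_gro_frames(path.read_text(), path, allow_partial)
    snapshots = []
    for k, chunk in enumerate(chunks):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(NamedStream(_stdio.StringIO(chunk), "frame.gro"))
        except (ValueError, OSError) as exc:
            raise FormatError(f"unparseable GRO frame {k}: {exc}", path=path) from exc
        if u.dimensions is None:
            raise FormatError(f"GRO frame {k} has no box line", path=path)
        box_nm = np.asarray(u.dimensions[:3], dtype=float) * 0.1
        snapshots.append(
            _universe_to_snapshot(
                u, species_map, start_index + k, float(start_index + k), box_nm,
                source=str(path),
            )
        )
    return snapshots


def _read_pdb(path: Path, species_map: SpeciesMap, start_index: int) -> list[Snapshot]:
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"unparseable PDB: {exc}", path=path) from exc

    # MDAnalysis does not propagate a single leading CRYST1 to every MODEL of
    # a multi-model PDB; fall back to reading the record directly.
    cryst_box = None
    for line in path.read_text().splitlines():
        if line.startswith("CRYST1"):
            cryst_box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            break
    snapshots = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, ts in enumerate(u.trajectory):
            dims = ts.dimensions
            if dims is not None:
                box = np.asarray(dims[:3], dtype=float)
            elif cryst_box is not None:
                box = cryst_box.copy()
            else:
                raise FormatError(f"PDB frame {k}: no CRYST1 box record", path=path)
            snapshots.append(
                _universe_to_snapshot(
                    u, species_map, start_index + k, float(start_index + k),
                    box * 0.1, source=str(path),
                )
            )
    return snapshots


def read_snapshots(paths, species_map: SpeciesMap, *, allow_partial: bool = False
                   ) -> list[Snapshot]:
    """Read one or more GRO/PDB files into a list of snapshots.

    ``allow_partial=True`` returns the complete frames of a file whose final
    frame is truncated instead of raising :class:`FormatError`.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    snapshots: list[Snapshot] = []
    for p in paths:
        path = Path(p)
        if not path.exists():
            raise FormatError("file not found", path=path)
        suffix = path.suffix.lower()
        if suffix == ".gro":
            snapshots.extend(_read_gro(path, species_map, len(snapshots), allow_partial))
        elif suffix in (".pdb", ".ent"):
            snapshots.extend(_read_pdb(path, species_map, len(snapshots)))
        else:
            raise FormatError(
                f"unsupported coordinate dialect {suffix!r} (expected .gro or .pdb)",
                path=path,
            )
    return snapshots


# ---------------------------------------------------------------------------
# writing


def _build_universe(snapshots: Sequence[Snapshot]):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    first = snapshots[0]
    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    atom_resindex: list[int] = []
    for ri, mol in enumerate(first.molecules):
        order = mol.atom_order or tuple(mol.atoms)
        for n in order:
            names.append(n)
            atom_resindex.append(ri)
        resids.append(mol.mol_id)
        resnames.append(mol.species)

    n_atoms = len(names)
    coords = np.empty((len(snapshots), n_atoms, 3))
    dims = np.empty((len(snapshots), 6))
    for fi, snap in enumerate(snapshots):
        if len(snap.molecules) != len(first.molecules):
            raise AnalysisError("all snapshots must share the same topology to be written")
        k = 0
        for mol in snap.molecules:
            order = mol.atom_order or tuple(mol.atoms)
            for n in order:
                coords[fi, k] = mol.atoms[n] * 10.0  # nm -> Angstrom
                k += 1
        dims[fi] = [*(snap.box * 10.0), 90.0, 90.0, 90.0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms,
            n_residues=len(resids),
            atom_resindex=np.array(atom_resindex),
            residue_segindex=np.zeros(len(resids), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resids", resids)
        u.add_TopologyAttr("resnames", resnames)
        u.load_new(coords, format=MemoryReader, dimensions=dims)
    return u


def write_snapshots(snapshots: Sequence[Snapshot], path, dialect: str = "gro"
                    ) -> list[Path]:
    """Write snapshots to coordinate files; returns the paths written.

    GRO output is one file per frame (``stem_0000.gro`` numbering when there
    is more than one frame); PDB output is a single multi-model file.  Both
    round-trip losslessly at format precision (0.001 nm for GRO, 0.0001 nm
    for PDB) through :func:`read_snapshots`.
    """
    import MDAnalysis as mda

    if not snapshots:
        raise AnalysisError("no snapshots to write")
    dialect = dialect.lower()
    if dialect not in ("gro", "pdb"):
        raise ConfigurationError(f"unsupported dialect {dialect!r} (expected 'gro' or 'pdb')")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    u = _build_universe(snapshots)
    written: list[Path] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if dialect == "gro":
            for fi, _ in enumerate(u.trajectory):
                fp = (
                    path
                    if len(snapshots) == 1
                    else path.with_name(f"{path.stem}_{fi:04d}{path.suffix or '.gro'}")
                )
                with mda.Writer(str(fp), u.atoms.n_atoms) as w:
                    w.write(u.atoms)
                written.append(fp)
        else:
            with mda.Writer(str(path), multiframe=True) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# leaflets, centers of mass, area


def assign_leaflets(snapshot: Snapshot, species_map: SpeciesMap) -> Snapshot:
    """Label each molecule upper/lower by the sign of (headgroup anchor z -
    mass-weighted z-centroid of all lipids).

    Assignment is per frame (no flip-flop tracking); a single-leaflet input
    yields one populated label.  Returns a new snapshot.
    """
    if not snapshot.molecules:
        raise AnalysisError("cannot assign leaflets in an empty snapshot")
    total_mass = 0.0
    weighted_z = 0.0
    for mol in snapshot.molecules:
        spec = species_map[mol.species]
        for name, pos in mol.atoms.items():
            m = float(spec.atom_masses.get(name, 0.0)) or 0.0
            total_mass += m
            weighted_z += m * pos[2]
    midplane = weighted_z / total_mass
    labelled = []
    for mol in snapshot.molecules:
        spec = species_map[mol.species]
        z = mol.atoms[spec.headgroup_anchor][2]
        labelled.append(replace(mol, leaflet=UPPER if z >= midplane else LOWER))
    return replace(snapshot, molecules=labelled)


def molecule_com(mol: Molecule, spec, subset: str = "whole", *,
                 mass_weighted: bool = True) -> np.ndarray:
    """Center of mass of a molecule or named subset ('whole', 'ring', 'sn1',
    'sn2'), on unwrapped coordinates."""
    if subset == "whole":
        names = list(mol.atoms)
    elif subset == "ring":
        names = list(spec.ring_atoms)
        names = [n for n in names if n in mol.atoms]  # Dchol: C18 virtual
    elif subset == "sn1":
        names = list(spec.sn1_chain_atoms)
    elif subset == "sn2":
        names = list(spec.sn2_chain_atoms)
    else:
        raise ValueError(f"unknown COM subset {subset!r}")
    if not names:
        raise AnalysisError(f"molecule {mol.mol_id}: empty atom subset {subset!r}")
    pos = mol.positions(names)
    if not mass_weighted:
        return pos.mean(axis=0)
    masses = np.array([float(spec.atom_masses[n]) for n in names])
    return (pos * masses[:, None]).sum(axis=0) / masses.sum()


def center_of_mass(snapshot: Snapshot, mol_id: int, species_map: SpeciesMap,
                   atom_subset: Iterable[str] | None = None, *,
                   mass_weighted: bool = True) -> np.ndarray:
    """Center of mass of one molecule (nm), mass-weighted by default.

    ``atom_subset`` restricts to the named atoms; it must be non-empty and
    all atoms must be present.
    """
    for mol in snapshot.molecules:
        if mol.mol_id == mol_id:
            break
    else:
        raise AnalysisError(f"no molecule with id {mol_id} in frame {snapshot.frame_index}")
    spec = species_map[mol.species]
    if atom_subset is None:
        return molecule_com(mol, spec, "whole", mass_weighted=mass_weighted)
    names = list(atom_subset)
    if not names:
        raise AnalysisError(f"molecule {mol_id}: empty atom subset")
    missing = [n for n in names if n not in mol.atoms]
    if missing:
        raise AnalysisError(f"molecule {mol_id}: atoms not present: {missing}")
    pos = mol.positions(names)
    if not mass_weighted:
        return pos.mean(axis=0)
    masses = np.array([float(spec.atom_masses[n]) for n in names])
    return (pos * masses[:, None]).sum(axis=0) / masses.sum()


def mean_lateral_area(snapshots: Sequence[Snapshot]) -> AreaSummary:
    """Mean and SD of the lateral box area Lx*Ly over frames (nm^2)."""
    if not snapshots:
        raise AnalysisError("mean_lateral_area needs at least one snapshot")
    areas = np.array([s.lateral_area for s in snapshots])
    return AreaSummary(mean=float(areas.mean()), sd=float(areas.std()), n_frames=len(areas))
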