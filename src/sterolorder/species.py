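"""Species maps: semantic atom roles per molecule type.

A species map names, for every molecule type in a membrane, the atoms that
carry analysis semantics: the three atoms defining a sterol's molecular frame
(C13, C18, C10), the C6/C11 orientation atoms, the ring-atom selection used as
density-map target, the two acyl chains of a phospholipid, the headgroup
anchor used for leaflet assignment, and per-atom united-atom masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

__all__ = [
    "ReconstructionRule",
    "SterolSpec",
    "PhospholipidSpec",
    "SpeciesMap",
    "load_species_map",
]

STEROL = "sterol"
PHOSPHOLIPID = "phospholipid"


@dataclass(frozen=True)
class ReconstructionRule:
    """Tetrahedral reconstruction of a missing substituent.

    The reconstructed atom sits at ``center + bond_length * u`` where ``u`` is
    the unit vector opposing the sum of the unit bond vectors to the three
    named neighbors (ideal sp3 geometry).
    """

    atom: str
    center: str
    neighbors: tuple[str, str, str]
    bond_length: float = 0.153  # nm, standard C-C


@dataclass(frozen=True)
class SterolSpec:
    name: str
    frame_atoms: tuple[str, str, str]  # (c13, c18, c10)
    orientation_atoms: tuple[str, str]  # (c6, c11)
    ring_atoms: tuple[str, ...]
    headgroup_anchor: str
    atom_masses: Mapping[str, float]
    reconstructed_atoms: Mapping[str, ReconstructionRule] = field(default_factory=dict)
    atom_aliases: Mapping[str, str] = field(default_factory=dict)

    role = STEROL

    @property
    def required_atoms(self) -> tuple[str, ...]:
        """Atoms that must be present in a coordinate file for this species."""
        needed: list[str] = list(self.ring_atoms)
        for name in (*self.frame_atoms, *self.orientation_atoms, self.headgroup_anchor):
            if name not in needed and name not in self.reconstructed_atoms:
                needed.append(name)
        # reconstruction inputs must themselves be present
        for rule in self.reconstructed_atoms.values():
            for name in (rule.center, *rule.neighbors):
                if name not in needed:
                    needed.append(name)
        return tuple(n for n in needed if n not in self.reconstructed_atoms)


@dataclass(frozen=True)
class PhospholipidSpec:
    name: str
    sn1_chain_atoms: tuple[str, ...]
    sn2_chain_atoms: tuple[str, ...]
    headgroup_anchor: str
    atom_masses: Mapping[str, float]
    atom_aliases: Mapping[str, str] = field(default_factory=dict)

    role = PHOSPHOLIPID

    @property
    def required_atoms(self) -> tuple[str, ...]:
        needed = list(self.sn1_chain_atoms)
        needed += [n for n in self.sn2_chain_atoms if n not in needed]
        if self.headgroup_anchor not in needed:
            needed.append(self.headgroup_anchor)
        return tuple(needed)


class SpeciesMap:
    """Validated collection of species specs, indexed by species name."""

    def __init__(self, species: Mapping[str, SterolSpec | PhospholipidSpec]):
        self._species = dict(species)

    def __getitem__(self, name: str) -> SterolSpec | PhospholipidSpec:
        try:
            return self._species[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown species {name!r}; species map defines "
                f"{sorted(self._species)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def __iter__(self):
        return iter(self._species)

    @property
    def species(self) -> dict[str, SterolSpec | PhospholipidSpec]:
        return dict(self._species)

    @property
    def sterols(self) -> tuple[str, ...]:
        return tuple(n for n, s in self._species.items() if s.role == STEROL)

    @property
    def phospholipids(self) -> tuple[str, ...]:
        return tuple(n for n, s in self._species.items() if s.role == PHOSPHOLIPID)


_STEROL_KEYS = {
    "role",
    "frame_atoms",
    "orientation_atoms",
    "ring_atoms",
    "reconstructed_atoms",
    "headgroup_anchor",
    "atom_masses",
    "atom_aliases",
}
_LIPID_KEYS = {
    "role",
    "sn1_chain_atoms",
    "sn2_chain_atoms",
    "headgroup_anchor",
    "atom_masses",
    "atom_aliases",
}


def _require(entry: dict, key: str, species: str):
    if key not in entry or entry[key] is None:
        raise ConfigurationError(f"species {species!r}: missing role entry {key!r}")
    return entry[key]


def _name_list(value, species: str, key: str) -> tuple[str, ...]:
    if not isinstance(value, (list, tuple)) or not all(isinstance(v, str) for v in value):
        raise ConfigurationError(f"species {species!r}: {key!r} must be a list of atom names")
    return tuple(v.strip() for v in value)


def _parse_sterol(name: str, entry: dict) -> SterolSpec:
    unknown = set(entry) - _STEROL_KEYS
    if unknown:
        raise ConfigurationError(f"species {name!r}: unknown keys {sorted(unknown)}")
    frame = _name_list(_require(entry, "frame_atoms", name), name, "frame_atoms")
    if len(frame) != 3:
        raise ConfigurationError(
            f"species {name!r}: frame_atoms must name exactly 3 atoms (C13, C18, C10)"
        )
    orient = _name_list(_require(entry, "orientation_atoms", name), name, "orientation_atoms")
    if len(orient) != 2:
        raise ConfigurationError(
            f"species {name!r}: orientation_atoms must name exactly 2 atoms (C6, C11)"
        )
    ring = _name_list(_require(entry, "ring_atoms", name), name, "ring_atoms")
    anchor = _require(entry, "headgroup_anchor", name)
    masses = dict(_require(entry, "atom_masses", name))

    recon: dict[str, ReconstructionRule] = {}
    for atom, rule in (entry.get("reconstructed_atoms") or {}).items():
        extra = set(rule) - {"center", "neighbors", "bond_length"}
        if extra:
            raise ConfigurationError(
                f"species {name!r}: reconstructed atom {atom!r} has unknown keys {sorted(extra)}"
            )
        neighbors = _name_list(rule["neighbors"], name, "neighbors")
        if len(neighbors) != 3:
            raise ConfigurationError(
                f"species {name!r}: reconstruction of {atom!r} needs 3 neighbors"
            )
        recon[atom] = ReconstructionRule(
            atom=atom,
            center=rule["center"],
            neighbors=neighbors,
            bond_length=float(rule.get("bond_length", 0.153)),
        )

    for role_key, atoms in (("frame_atoms", frame), ("orientation_atoms", orient)):
        for a in atoms:
            if a not in ring and a not in recon:
                raise ConfigurationError(
                    f"species {name!r}: {role_key} atom {a!r} is neither in "
                    f"ring_atoms nor a reconstructed atom"
                )
    spec = SterolSpec(
        name=name,
        frame_atoms=(frame[0], frame[1], frame[2]),
        orientation_atoms=(orient[0], orient[1]),
        ring_atoms=ring,
        headgroup_anchor=str(anchor).strip(),
        atom_masses=masses,
        reconstructed_atoms=recon,
        atom_aliases={str(k).strip(): str(v).strip() for k, v in (entry.get("atom_aliases") or {}).items()},
    )
    _check_masses(spec)
    return spec


def _parse_lipid(name: str, entry: dict) -> PhospholipidSpec:
    unknown = set(entry) - _LIPID_KEYS
    if unknown:
        raise ConfigurationError(f"species {name!r}: unknown keys {sorted(unknown)}")
    spec = PhospholipidSpec(
        name=name,
        sn1_chain_atoms=_name_list(_require(entry, "sn1_chain_atoms", name), name, "sn1_chain_atoms"),
        sn2_chain_atoms=_name_list(_require(entry, "sn2_chain_atoms", name), name, "sn2_chain_atoms"),
        headgroup_anchor=str(_require(entry, "headgroup_anchor", name)).strip(),
        atom_masses=dict(_require(entry, "atom_masses", name)),
        atom_aliases={str(k).strip(): str(v).strip() for k, v in (entry.get("atom_aliases") or {}).items()},
    )
    _check_masses(spec)
    return spec


def _check_masses(spec) -> None:
    for atom in spec.required_atoms:
        mass = spec.atom_masses.get(atom)
        if mass is None:
            raise ConfigurationError(
                f"species {spec.name!r}: atom_masses missing entry for {atom!r}"
            )
        if not mass > 0:
            raise ConfigurationError(
                f"species {spec.name!r}: mass of {atom!r} must be > 0, got {mass}"
            )


def load_species_map(config_path: str | Path | None = None) -> SpeciesMap:
    """Load and validate a species map.

    With ``config_path=None`` the bundled defaults (CHOL, DCHL, DSPC, DOPC)
    are loaded.  Unknown keys anywhere in the file are rejected; a sterol
    entry lacking one of its role lists raises :class:`ConfigurationError`
    naming the species and the role.
    """
    if config_path is None:
        text = resources.files("sterolorder").joinpath("data/species_default.yaml").read_text()
        source = "<bundled>"
    else:
        path = Path(config_path)
        if not path.exists():
            raise ConfigurationError(f"species map file not found: {path}")
        text = path.read_text()
        source = str(path)
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{source}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict) or "species" not in raw:
        raise ConfigurationError(f"{source}: species map must have a top-level 'species' mapping")
    unknown = set(raw) - {"species"}
    if unknown:
        raise ConfigurationError(f"{source}: unknown top-level keys {sorted(unknown)}")

    species: dict[str, SterolSpec | PhospholipidSpec] = {}
    for name, entry in raw["species"].items():
        if not isinstance(entry, dict):
            raise ConfigurationError(f"species {name!r}: entry must be a mapping")
        role = entry.get("role")
        if role == STEROL:
            species[name] = _parse_sterol(name, entry)
        elif role == PHOSPHOLIPID:
            species[name] = _parse_lipid(name, entry)
        else:
            raise ConfigurationError(
                f"species {name!r}: role must be {STEROL!r} or {PHOSPHOLIPID!r}, got {role!r}"
            )
    return SpeciesMap(species)
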